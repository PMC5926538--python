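"""Gene-level expression summaries: level bins, tau, PEM, HPA-style categories.

Transcript abundances (Kallisto-style TPM tables) are summed to gene level;
per-tissue means then feed the specificity statistics:

* ``tau`` = sum_i (1 - x_i / x_max) / (N - 1) over per-tissue means, 0 for a
  flat (housekeeping) profile and 1 for single-tissue expression;
* the mean TPM across all samples divided by the median across tissue means
  (median floored at 0.01 when zero);
* PEM(t) = log2(max(mean TPM in t, 1)) minus the gene's mean of those log
  values across tissues, which sums to zero by construction.

Expression level bins are half-open so the partition is total: average TPM
< 1 not detected, [1, 10) low, [10, 50) medium, >= 50 high.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

CATEGORIES = (
    "tissue_specific",
    "tissue_enriched",
    "tissue_enhanced",
    "group_enriched",
    "mixed",
    "expressed_in_all",
    "not_detected",
)

LEVEL_BINS = ("not_detected", "low", "medium", "high")

FOLD = 5.0
DETECTED_TPM = 1.0


@dataclass
class ExpressionMatrix:
    """Genes x samples TPM with sample metadata (tissue, replicate, group)."""

    tpm: pd.DataFrame  # index: gene_id, columns: sample
    metadata: pd.DataFrame  # columns: sample, tissue, replicate, group
    counts: Optional[pd.DataFrame] = None  # est_counts, same shape as tpm

    def __post_init__(self) -> None:
        meta_samples = list(self.metadata["sample"])
        if set(self.tpm.columns) != set(meta_samples):
            raise ValueError("metadata samples do not match matrix columns")
        self.tpm = self.tpm[meta_samples]
        if (self.tpm.values < 0).any():
            raise ValueError("negative TPM")

    def tissue_of(self) -> Mapping[str, str]:
        return dict(zip(self.metadata["sample"], self.metadata["tissue"]))

    def group_of_tissue(self) -> Mapping[str, str]:
        return dict(zip(self.metadata["tissue"], self.metadata["group"]))

    def tissue_means(self) -> pd.DataFrame:
        """Per-gene mean TPM per tissue (replicates collapsed)."""
        tissue = self.metadata.set_index("sample")["tissue"]
        return self.tpm.T.groupby(tissue).mean().T


def aggregate_to_genes(
    abundances: Mapping[str, pd.DataFrame],
    tx2gene: Mapping[str, str],
    metadata: pd.DataFrame,
) -> ExpressionMatrix:
    """Sum member-transcript TPM (and est_counts) per gene per sample."""
    tpm_cols = {}
    count_cols = {}
    for sample, table in abundances.items():
        unmapped = sorted(set(table["target_id"]) - set(tx2gene))
        if unmapped:
            raise ValueError(f"unmapped transcripts: {unmapped[:10]}")
        genes = table["target_id"].map(tx2gene)
        tpm_cols[sample] = table.groupby(genes)["tpm"].sum()
        count_cols[sample] = table.groupby(genes)["est_counts"].sum()
    tpm = pd.DataFrame(tpm_cols).fillna(0.0)
    counts = pd.DataFrame(count_cols).reindex(tpm.index).fillna(0.0)
    return ExpressionMatrix(tpm=tpm, metadata=metadata, counts=counts)


def compute_tau(tissue_means: Sequence[float]) -> float:
    """Specificity index over per-tissue means; NaN for an all-zero profile."""
    x = np.asarray(tissue_means, dtype=float)
    if x.size < 2:
        raise ValueError("tau needs >= 2 tissues")
    if (x < 0).any():
        raise ValueError("negative expression")
    xmax = x.max()
    if xmax == 0:
        return float("nan")
    return float(np.sum(1.0 - x / xmax) / (x.size - 1))


def compute_mean_median_ratio(
    sample_values: Sequence[float], tissue_means: Sequence[float]
) -> float:
    """Mean over samples / median over tissue means; zero median becomes 0.01."""
    mean = float(np.mean(sample_values))
    med = float(np.median(tissue_means))
    if med == 0.0:
        med = 0.01
    return mean / med


def compute_pem(tissue_means: Mapping[str, float]) -> Dict[str, float]:
    """Preferential expression measure per tissue; values sum to zero."""
    tissues = list(tissue_means)
    if len(tissues) < 2:
        raise ValueError("PEM needs >= 2 tissues")
    s = {t: np.log2(max(float(tissue_means[t]), 1.0)) for t in tissues}
    a = float(np.mean(list(s.values())))
    return {t: s[t] - a for t in tissues}


def level_bin(average_tpm: float) -> str:
    if average_tpm < 1.0:
        return "not_detected"
    if average_tpm < 10.0:
        return "low"
    if average_tpm < 50.0:
        return "medium"
    return "high"


def categorize(
    tissue_means: Mapping[str, float],
    groups: Mapping[str, str],
) -> str:
    """HPA-style expression category; evaluation order is fixed.

    not_detected -> tissue_specific -> tissue_enriched -> group_enriched ->
    tissue_enhanced -> expressed_in_all -> mixed. ``tissue_specific`` is the
    degenerate case of ``tissue_enriched`` where every other tissue is 0 TPM.
    ``group_enriched`` demands every in-group tissue at least five-fold above
    every out-group tissue, for one of the predefined tissue groups.
    """
    tissues = sorted(tissue_means)
    missing = [t for t in tissues if t not in groups]
    if missing:
        raise ValueError(f"tissues without group label: {missing}")
    x = {t: float(tissue_means[t]) for t in tissues}
    vals = np.array([x[t] for t in tissues])

    if (vals < DETECTED_TPM).all():
        return "not_detected"

    top = max(tissues, key=lambda t: (x[t], t))
    others = [x[t] for t in tissues if t != top]
    if x[top] > 0 and all(v == 0.0 for v in others):
        return "tissue_specific"
    if all(x[top] >= FOLD * v for v in others) and x[top] > 0:
        return "tissue_enriched"

    by_group: Dict[str, List[str]] = {}
    for t in tissues:
        by_group.setdefault(groups[t], []).append(t)
    for g in sorted(by_group):
        members = by_group[g]
        if len(members) < 2:
            continue
        out = [x[t] for t in tissues if t not in members]
        if not out:
            continue
        if all(x[t] > 0 and x[t] >= FOLD * v for t in members for v in out):
            return "group_enriched"

    detected = [v for v in vals if v >= DETECTED_TPM]
    if detected:
        mean_det = float(np.mean(detected))
        if any(v >= FOLD * mean_det for v in vals):
            return "tissue_enhanced"

    if (vals > 1.0).all():
        return "expressed_in_all"
    return "mixed"


def flag_reproducible(
    gene_id: str,
    matrix: ExpressionMatrix,
    mode: str = "count1_all_reps",
) -> bool:
    """Reproducible-detection flag.

    ``count1_all_reps``: est_counts >= 1 in every replicate of the tissue
    where the gene's mean TPM is highest (ties broken lexicographically).
    ``tpm_gt_0.01_all_individuals``: TPM > 0.01 in every replicate slot
    (replicates standing in for individuals).
    """
    if mode == "count1_all_reps":
        if matrix.counts is None:
            raise ValueError("est_counts required for count1_all_reps")
        tm = matrix.tissue_means().loc[gene_id]
        top = min([t for t in tm.index if tm[t] == tm.max()])
        samples = matrix.metadata.loc[
            matrix.metadata["tissue"] == top, "sample"
        ]
        return bool((matrix.counts.loc[gene_id, samples] >= 1.0).all())
    if mode == "tpm_gt_0.01_all_individuals":
        by_rep = matrix.tpm.loc[gene_id].groupby(
            matrix.metadata.set_index("sample")["replicate"]
        ).max()
        return bool((by_rep > 0.01).all())
    raise ValueError(f"unknown mode {mode!r}")


def summarize(
    matrix: ExpressionMatrix,
    reproducible_mode: str = "count1_all_reps",
) -> pd.DataFrame:
    """Per-gene summary table with all statistics and the category."""
    tm = matrix.tissue_means()
    groups = dict(matrix.group_of_tissue())
    rows = []
    for gene in tm.index:
        means = tm.loc[gene].to_dict()
        all_zero = all(v == 0 for v in means.values())
        pem = compute_pem(means)
        max_pem_tissue = max(pem, key=lambda t: (pem[t], t)) if pem else ""
        rows.append(
            dict(
                gene_id=gene,
                level_bin=level_bin(float(matrix.tpm.loc[gene].mean())),
                tau=float("nan") if all_zero else compute_tau(list(means.values())),
                mean_median_ratio=compute_mean_median_ratio(
                    matrix.tpm.loc[gene].values, list(means.values())
                ),
                max_pem_tissue=max_pem_tissue,
                max_pem=pem[max_pem_tissue],
                category=categorize(means, groups),
                reproducible=(
                    flag_reproducible(gene, matrix, reproducible_mode)
                    if matrix.counts is not None
                    else False
                ),
            )
        )
    return pd.DataFrame(rows)
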