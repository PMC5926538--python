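"""Randomisation tests for lncRNA proximity to co-expressed coding genes.

For each lncRNA, the distance to its nearest same-cluster protein-coding gene
is compared with the nearest-gene distance over s = 1000 random, equally
sized subsets of protein-coding genes from the same chromosome. Two p-values
are reported: ``p_literal`` = (s - q + 1)/(s + 1), with q the number of
subsets whose distance the observed value exceeds — exactly the literal counting
formula, which approaches 1 when the lncRNA is unusually close; and
``p_empirical`` = (#{subset distance <= observed} + 1)/(s + 1), the standard
one-sided add-one permutation p-value for "the observed distance is unusually
small", which is what significance calls should use. An analogous test
compares the |Pearson r| with the nearest coding gene against 1000 random
coding genes from the same chromosome.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .models import Annotation, GeneRecord

log = logging.getLogger(__name__)


@dataclass
class RandomizationResult:
    lnc_id: str
    observed: float
    s: int
    q: int
    p_literal: float
    p_empirical: float
    seed: int
    comparator_set_size: int


def genomic_distance(a: Tuple[str, int, int], b: Tuple[str, int, int]) -> int:
    """Gap in bp between two intervals; 0 when they overlap or abut."""
    chrom_a, s_a, e_a = a
    chrom_b, s_b, e_b = b
    if chrom_a != chrom_b:
        raise ValueError(f"intervals on different chromosomes: {chrom_a} vs {chrom_b}")
    if s_a <= e_b and s_b <= e_a:  # overlap
        return 0
    return max(0, max(s_a, s_b) - min(e_a, e_b) - 1)


def _lnc_rng(lnc_id: str, seed: int) -> np.random.Generator:
    """Per-lncRNA stream: reproducible regardless of processing order."""
    return np.random.default_rng((zlib.crc32(lnc_id.encode()) + seed) % (2**31))


def _nearest_distance(
    lnc: Tuple[str, int, int], genes: Sequence[GeneRecord]
) -> int:
    return min(genomic_distance(lnc, (g.chrom, g.start, g.end)) for g in genes)


def cluster_distance_test(
    lnc_id: str,
    lnc_interval: Tuple[str, int, int],
    cluster_genes: Sequence[GeneRecord],
    chromosome_pool: Sequence[GeneRecord],
    s: int = 1000,
    seed: int = 0,
) -> RandomizationResult:
    """Is the lncRNA closer to its co-expression cluster than chance expects?

    ``cluster_genes``: protein-coding members of the lncRNA's cluster;
    ``chromosome_pool``: all protein-coding genes on the lncRNA's chromosome.
    Random subsets have the size of the same-chromosome cluster membership
    and are drawn without replacement, independently across the s repeats.
    """
    chrom = lnc_interval[0]
    members = [g for g in cluster_genes if g.chrom == chrom]
    if not members:
        raise ValueError(f"{lnc_id}: no same-chromosome protein-coding cluster member")
    pool = sorted(
        (g for g in chromosome_pool if g.chrom == chrom), key=lambda g: g.gene_id
    )
    y = len(members)
    if len(pool) < y:
        raise ValueError(
            f"{lnc_id}: chromosome pool ({len(pool)}) smaller than subset size {y}"
        )
    observed = _nearest_distance(lnc_interval, members)
    rng = _lnc_rng(lnc_id, seed)
    q = 0
    n_le = 0
    for _rep in range(s):
        subset_idx = rng.choice(len(pool), size=y, replace=False)
        d = _nearest_distance(lnc_interval, [pool[i] for i in subset_idx])
        if observed > d:
            q += 1
        if d <= observed:
            n_le += 1
    return RandomizationResult(
        lnc_id=lnc_id,
        observed=float(observed),
        s=s,
        q=q,
        p_literal=(s - q + 1) / (s + 1),
        p_empirical=(n_le + 1) / (s + 1),
        seed=seed,
        comparator_set_size=y,
    )


def nearest_gene_correlation(
    lnc_id: str,
    lnc_interval: Tuple[str, int, int],
    annotation: Annotation,
    tpm: pd.DataFrame,
) -> Optional[pd.DataFrame]:
    """Nearest protein-coding gene on each side plus Pearson r with each.

    The 5' side is the lower-coordinate side; a gene overlapping the lncRNA
    is nearest on both sides at distance 0. Returns None (logged) when the
    chromosome carries no protein-coding gene with expression data.
    """
    chrom, s0, e0 = lnc_interval
    genes = [
        g
        for g in annotation.genes.values()
        if g.biotype == "protein_coding" and g.chrom == chrom and g.gene_id in tpm.index
    ]
    if not genes or lnc_id not in tpm.index:
        log.warning("%s: no protein-coding gene with expression on %s", lnc_id, chrom)
        return None
    overlapping = [g for g in genes if g.start <= e0 and s0 <= g.end]
    left = overlapping or [g for g in genes if g.end < s0]
    right = overlapping or [g for g in genes if g.start > e0]
    rows = []
    for side, cands in (("5prime", left), ("3prime", right)):
        if not cands:
            continue
        nearest = min(
            cands,
            key=lambda g: (genomic_distance(lnc_interval, (g.chrom, g.start, g.end)), g.gene_id),
        )
        r = float(
            np.corrcoef(
                tpm.loc[lnc_id].to_numpy(float), tpm.loc[nearest.gene_id].to_numpy(float)
            )[0, 1]
        )
        rows.append(
            dict(
                lnc_id=lnc_id,
                side=side,
                gene_id=nearest.gene_id,
                distance=genomic_distance(
                    lnc_interval, (nearest.chrom, nearest.start, nearest.end)
                ),
                pearson_r=r,
            )
        )
    return pd.DataFrame(rows) if rows else None


def correlation_randomization_test(
    lnc_id: str,
    observed_r: float,
    lnc_profile: Sequence[float],
    pool_profiles: pd.DataFrame,
    s: int = 1000,
    seed: int = 0,
) -> RandomizationResult:
    """Is |r| with the nearest gene larger than with random same-chromosome genes?

    ``pool_profiles``: genes x samples TPM for the chromosome's protein-coding
    genes. Sampling is without replacement when the pool allows, else with
    replacement (logged).
    """
    observed = abs(float(observed_r))
    pool = pool_profiles.sort_index()
    rng = _lnc_rng(lnc_id, seed)
    replace = len(pool) < s
    if replace:
        log.info("%s: pool %d < s=%d, sampling with replacement", lnc_id, len(pool), s)
    idx = rng.choice(len(pool), size=s, replace=replace)
    x = np.asarray(lnc_profile, dtype=float)
    xc = x - x.mean()
    xn = np.sqrt((xc**2).sum())
    n_ge = 0
    q = 0
    for i in idx:
        yv = pool.iloc[int(i)].to_numpy(float)
        yc = yv - yv.mean()
        denom = xn * np.sqrt((yc**2).sum())
        r = float(np.dot(xc, yc) / denom) if denom > 0 else 0.0
        if observed > abs(r):
            q += 1
        if abs(r) >= observed:
            n_ge += 1
    return RandomizationResult(
        lnc_id=lnc_id,
        observed=observed,
        s=s,
        q=q,
        p_literal=(s - q + 1) / (s + 1),
        p_empirical=(n_ge + 1) / (s + 1),
        seed=seed,
        comparator_set_size=len(pool),
    )


def spearman_distance_correlation(
    pairs: Sequence[Tuple[float, float]],
) -> Tuple[float, float]:
    """Spearman rho (average-rank ties) between distance and |r|; NaN if constant."""
    if len(pairs) < 3:
        raise ValueError("need >= 3 pairs")
    d = np.array([p[0] for p in pairs], dtype=float)
    r = np.array([p[1] for p in pairs], dtype=float)
    if np.all(d == d[0]) or np.all(r == r[0]):
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(d, r)
    return float(rho), float(p)


def benjamini_hochberg(pvals: Sequence[float]) -> List[float]:
    """BH-adjusted q-values, emitted as a convenience column only."""
    return list(stats.false_discovery_control(np.asarray(pvals), method="bh"))
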