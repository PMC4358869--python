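"""Linkage disequilibrium: signed r, decay with distance, and
between-breed persistence of LD phase.

Signed r is computed from phased haplotype frequencies,
``r = (p_AB - p_A p_B) / sqrt(p_A q_A p_B q_B)``, with a consistent
reference allele (allele 1) so that the sign is comparable across
populations.  Pairs are grouped by map distance into 1-cM bins; the
persistence of LD phase between two breeds is the Pearson correlation of
signed r across the pairs of a bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PairwiseLD",
    "pairwise_r",
    "adjacent_r2",
    "decay_curve",
    "phase_persistence",
    "phase_correlation",
]

CM_PER_MORGAN = 100.0


@dataclass
class PairwiseLD:
    """Signed r and map distance for every retained SNP pair.

    ``kept`` indexes the SNPs (columns of the input) that passed the MAF
    filter; ``r``/``distance_cm`` are condensed upper-triangle vectors
    over those SNPs.
    """

    kept: np.ndarray
    r: np.ndarray
    distance_cm: np.ndarray

    @property
    def r2(self) -> np.ndarray:
        return self.r * self.r


def _signed_r_matrix(gametes: np.ndarray) -> np.ndarray:
    """Correlation of allele indicators across gametes (signed r)."""
    h = gametes.astype(np.float64)
    p = h.mean(axis=0)
    c = h.T @ h / h.shape[0] - np.outer(p, p)
    denom = np.sqrt(p * (1.0 - p))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = c / np.outer(denom, denom)
    return r


def pairwise_r(gametes: np.ndarray, positions_cm: np.ndarray,
               maf_min: float = 0.0) -> PairwiseLD:
    """Signed r for all pairs of SNPs passing a strict MAF filter.

    Parameters
    ----------
    gametes
        Phased haplotypes, shape ``(2n, m)`` with 0/1 alleles.
    positions_cm
        SNP map positions in centimorgans.
    maf_min
        Pairs are formed only between SNPs with MAF strictly above this
        (monomorphic SNPs are always excluded).
    """
    pos = np.asarray(positions_cm, dtype=np.float64)
    if pos.size != gametes.shape[1]:
        raise ValueError("one position per SNP is required")
    p = gametes.mean(axis=0)
    maf = np.minimum(p, 1.0 - p)
    kept = np.flatnonzero(maf > maf_min)
    if kept.size < 2:
        return PairwiseLD(kept=kept, r=np.empty(0), distance_cm=np.empty(0))
    r = _signed_r_matrix(gametes[:, kept])
    iu = np.triu_indices(kept.size, k=1)
    dist = np.abs(pos[kept][iu[1]] - pos[kept][iu[0]])
    return PairwiseLD(kept=kept, r=r[iu], distance_cm=dist)


def adjacent_r2(gametes: np.ndarray, positions_cm: np.ndarray,
                maf_min: float = 0.1) -> float:
    """Mean r^2 between consecutive SNPs of the MAF-filtered panel."""
    p = gametes.mean(axis=0)
    maf = np.minimum(p, 1.0 - p)
    kept = np.flatnonzero(maf > maf_min)
    if kept.size < 2:
        return float("nan")
    order = np.argsort(np.asarray(positions_cm, dtype=np.float64)[kept])
    h = gametes[:, kept[order]].astype(np.float64)
    pk = h.mean(axis=0)
    left, right = h[:, :-1], h[:, 1:]
    cov = (left * right).mean(axis=0) - pk[:-1] * pk[1:]
    denom = np.sqrt(pk * (1.0 - pk))
    r = cov / (denom[:-1] * denom[1:])
    return float(np.mean(r * r))


def decay_curve(ld: PairwiseLD, max_cm: float = 100.0,
                bin_cm: float = 1.0) -> pd.Series:
    """Mean r^2 per half-open distance bin ``[k, k+bin)`` cM.

    Empty bins are NaN.  The index holds the left bin edges.
    """
    edges = np.arange(0.0, max_cm + bin_cm, bin_cm)
    idx = np.digitize(ld.distance_cm, edges) - 1
    means = np.full(edges.size - 1, np.nan)
    for b in range(edges.size - 1):
        sel = idx == b
        if np.any(sel):
            means[b] = np.mean(ld.r2[sel])
    return pd.Series(means, index=edges[:-1], name="mean_r2")


def _common_pairs(gametes_a: np.ndarray, gametes_b: np.ndarray,
                  positions_cm: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Signed r in each breed over the identical pair set of SNPs
    segregating (MAF > 0) in both breeds."""
    if gametes_a.shape[1] != gametes_b.shape[1]:
        raise ValueError("both breeds must be typed at the same SNPs")
    pa = gametes_a.mean(axis=0)
    pb = gametes_b.mean(axis=0)
    seg = np.flatnonzero((pa > 0) & (pa < 1) & (pb > 0) & (pb < 1))
    if seg.size < 2:
        return np.empty(0), np.empty(0), np.empty(0)
    ra = _signed_r_matrix(gametes_a[:, seg])
    rb = _signed_r_matrix(gametes_b[:, seg])
    iu = np.triu_indices(seg.size, k=1)
    pos = np.asarray(positions_cm, dtype=np.float64)[seg]
    dist = np.abs(pos[iu[1]] - pos[iu[0]])
    return ra[iu], rb[iu], dist


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 2 or np.std(x) == 0.0 or np.std(y) == 0.0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def phase_persistence(gametes_a: np.ndarray, gametes_b: np.ndarray,
                      positions_cm: np.ndarray, max_cm: float = 50.0,
                      bin_cm: float = 1.0) -> pd.Series:
    """Correlation of signed r between two breeds per 1-cM distance bin.

    Only SNPs segregating in both breeds enter; bins with fewer than two
    pairs are NaN.
    """
    ra, rb, dist = _common_pairs(gametes_a, gametes_b, positions_cm)
    edges = np.arange(0.0, max_cm + bin_cm, bin_cm)
    out = np.full(edges.size - 1, np.nan)
    if ra.size:
        idx = np.digitize(dist, edges) - 1
        for b in range(edges.size - 1):
            sel = idx == b
            if np.count_nonzero(sel) >= 2:
                out[b] = _pearson(ra[sel], rb[sel])
    return pd.Series(out, index=edges[:-1], name="phase_correlation")


def phase_correlation(gametes_a: np.ndarray, gametes_b: np.ndarray,
                      positions_cm: np.ndarray,
                      max_distance_cm: float) -> float:
    """Phase persistence over all pairs closer than ``max_distance_cm``.

    Under the 1 cM ~ 1 Mb convention, ``max_distance_cm=0.05`` is the
    "< 50 kb" statistic.
    """
    ra, rb, dist = _common_pairs(gametes_a, gametes_b, positions_cm)
    if ra.size == 0:
        return float("nan")
    sel = dist < max_distance_cm
    return _pearson(ra[sel], rb[sel])
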