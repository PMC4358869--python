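"""True and genomic breeding values for purebred and crossbred
performance, their additive/dominance partition, and accuracies.

A parent's breeding value for purebred performance (TBVP) is the expected
genotypic value of its offspring under random mating to its own line; for
crossbred performance (TBVC) the mate's gamete is drawn from the other
line, so the other line's allele frequencies enter the same formula.
Per locus, with p the frequency of allele 1 (q = 1 - p) in the mate line:

    genotype 11 (count 2):  p*a + q*d
    heterozygote (count 1): 0.5*(p - q)*a + 0.5*d
    genotype 00 (count 0): -q*a + p*d

Genomic estimates (GEBVP/GEBVC) apply the identical formula to the SNP
panel with estimated effects and candidate-derived SNP frequencies.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

__all__ = ["BreedingValues", "breeding_value", "accuracy"]


class BreedingValues(NamedTuple):
    """Total breeding values plus their additive and dominance parts."""

    total: np.ndarray
    additive: np.ndarray
    dominance: np.ndarray


def breeding_value(genotypes: np.ndarray, a: np.ndarray, d: np.ndarray,
                   freqs: np.ndarray) -> BreedingValues:
    """Breeding values per individual given mate-line allele frequencies.

    Parameters
    ----------
    genotypes
        Allele-1 counts, shape ``(n, m)`` with values in {0,1,2}.
    a, d
        Effects per locus (true QTL effects or posterior-mean SNP effects).
    freqs
        Frequency of allele 1 per locus in the line the parent is mated
        to: own line for purebred performance, other line for crossbred
        performance.
    """
    g = np.asarray(genotypes)
    p = np.asarray(freqs, dtype=np.float64)
    if p.shape != (g.shape[1],) or a.shape != p.shape or d.shape != p.shape:
        raise ValueError("effects and frequencies must have one entry per locus")
    q = 1.0 - p
    hom1 = (g == 2).astype(np.float64)
    het = (g == 1).astype(np.float64)
    hom0 = (g == 0).astype(np.float64)

    add = hom1 @ (p * a) + het @ (0.5 * (p - q) * a) + hom0 @ (-q * a)
    dom = hom1 @ (q * d) + het @ (0.5 * d) + hom0 @ (p * d)
    total = hom1 @ (p * a + q * d) \
        + het @ (0.5 * (p - q) * a + 0.5 * d) \
        + hom0 @ (-q * a + p * d)
    return BreedingValues(total=total, additive=add, dominance=dom)


def accuracy(true_values: np.ndarray, estimated_values: np.ndarray) -> float:
    """Pearson correlation between true and estimated values.

    Returns NaN when either vector is degenerate (fewer than 3 records or
    zero variance).
    """
    t = np.asarray(true_values, dtype=np.float64)
    e = np.asarray(estimated_values, dtype=np.float64)
    if t.shape != e.shape:
        raise ValueError("vectors must have equal length")
    if t.size < 3 or np.std(t) == 0.0 or np.std(e) == 0.0:
        return float("nan")
    return float(np.corrcoef(t, e)[0, 1])
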