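"""Trait architecture: QTL effects, variance scaling, genotypic values
and phenotypes.

The additive effect ``a`` of a QTL is half the difference between the
alternate homozygotes; the dominance effect ``d`` is the deviation of the
heterozygote from the homozygote midpoint.  Unsigned additive effects are
gamma-distributed, the sign is a fair coin, and dominance degrees
``h ~ N(0.5, 0.1)`` give ``d = h |a|`` — directional, mostly positive
dominance.  Effects are rescaled so that the additive and dominance
variances in a reference population (under HWE) hit their targets
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .config import TraitParams

__all__ = [
    "TraitArchitecture",
    "sample_effects",
    "scale_effects",
    "genotypic_value",
    "phenotype",
    "hwe_variances",
]


@dataclass
class TraitArchitecture:
    """Per-QTL effects plus the scaling record.

    ``a`` is signed; ``h`` is the dominance degree drawn at sampling time
    (so pre-scaling ``d == h * |a|`` exactly).  ``scale_a``/``scale_d``
    are the global multipliers applied by :func:`scale_effects` and
    ``reference_frequencies`` the allele frequencies they were computed
    at (``None`` before scaling).
    """

    a: np.ndarray
    d: np.ndarray
    h: np.ndarray
    scale_a: float = 1.0
    scale_d: float = 1.0
    reference_frequencies: np.ndarray | None = None

    @property
    def n_qtl(self) -> int:
        return self.a.size


def sample_effects(params: TraitParams, n_qtl: int,
                   rng: np.random.Generator) -> TraitArchitecture:
    """Draw an unscaled architecture: |a| ~ Gamma(shape, scale) with a
    random sign, h ~ N(h_mean, h_sd) independent of a, d = h |a|."""
    if n_qtl < 1:
        raise ValueError("n_qtl must be >= 1")
    mag = rng.gamma(params.gamma_shape, params.gamma_scale, size=n_qtl)
    sign = rng.choice([-1.0, 1.0], size=n_qtl)
    h = rng.normal(params.h_mean, params.h_sd, size=n_qtl)
    a = sign * mag
    return TraitArchitecture(a=a, d=h * mag, h=h)


def hwe_variances(a: np.ndarray, d: np.ndarray,
                  p: np.ndarray) -> tuple[float, float]:
    """Additive and dominance variances under HWE at frequencies ``p``.

    V_A = sum 2 p q alpha^2 with alpha = a + d (q - p);
    V_D = sum (2 p q d)^2.
    """
    q = 1.0 - p
    alpha = a + d * (q - p)
    v_a = float(np.sum(2.0 * p * q * alpha**2))
    v_d = float(np.sum((2.0 * p * q * d) ** 2))
    return v_a, v_d


def scale_effects(arch: TraitArchitecture, reference_frequencies: np.ndarray,
                  params: TraitParams) -> TraitArchitecture:
    """Rescale effects so the reference population's HWE variances equal
    the targets exactly.

    The dominance variance depends only on ``d``, so ``d`` is scaled
    first in closed form.  With ``d`` fixed, V_A is an exact quadratic in
    the additive scale factor, whose positive root is used.  Scaling is
    idempotent: the recorded factors are cumulative.
    """
    p = np.asarray(reference_frequencies, dtype=np.float64)
    if p.shape != arch.a.shape:
        raise ValueError("one reference frequency per QTL is required")
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("a QTL fixed in the reference population cannot "
                         "contribute variance; all frequencies must lie in (0,1)")
    q = 1.0 - p
    w = 2.0 * p * q

    v_d_unit = float(np.sum((w * arch.d) ** 2))
    if v_d_unit <= 0.0 and params.target_v_d > 0.0:
        raise ValueError("dominance effects are all zero; cannot scale V_D")
    s_d = np.sqrt(params.target_v_d / v_d_unit) if params.target_v_d > 0 else 0.0
    d_new = s_d * arch.d

    # V_A(s) = A s^2 + B s + C0 with alpha = s*a + d_new*(q-p)
    A = float(np.sum(w * arch.a**2))
    B = float(np.sum(w * 2.0 * arch.a * d_new * (q - p)))
    C0 = float(np.sum(w * (d_new * (q - p)) ** 2))
    C = C0 - params.target_v_a
    disc = B * B - 4.0 * A * C
    if disc < 0 or A <= 0:
        raise ValueError("cannot reach the target additive variance")
    s_a = (-B + np.sqrt(disc)) / (2.0 * A)
    return TraitArchitecture(
        a=s_a * arch.a,
        d=d_new,
        h=arch.h,
        scale_a=arch.scale_a * s_a,
        scale_d=arch.scale_d * s_d,
        reference_frequencies=p,
    )


def genotypic_value(genotypes_at_qtl: np.ndarray,
                    arch: TraitArchitecture) -> np.ndarray:
    """Total genotypic value per individual.

    Genotypes are allele-1 counts in {0,1,2}; per locus the three
    genotypes contribute -a, d and +a respectively.
    """
    g = np.asarray(genotypes_at_qtl)
    if np.any((g < 0) | (g > 2)):
        raise ValueError("genotype counts must be 0, 1 or 2")
    g = g.astype(np.float64)
    return (g - 1.0) @ arch.a + (g == 1.0) @ arch.d


def phenotype(genotypic_values: np.ndarray, params: TraitParams,
              rng: np.random.Generator) -> np.ndarray:
    """Add an independent normal residual with variance ``residual_variance``."""
    g = np.asarray(genotypic_values, dtype=np.float64)
    if params.residual_variance == 0.0:
        return g.copy()
    return g + rng.normal(0.0, np.sqrt(params.residual_variance), size=g.shape)
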