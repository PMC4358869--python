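"""Configuration objects for the simulation, trait and sampler.

Defaults reproduce the study conditions: a 1-Morgan genome with ~2500
candidate biallelic loci, 2000 historical generations (1000 at census size
2000, then a gradual decline to 100), breed formation from two disjoint
50-animal founder samples, an 8-generation expansion, and a unit-variance
trait with V_A = 0.3, V_D = 0.1 and V_E = 0.6.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

__all__ = [
    "SimConfig",
    "TraitParams",
    "LassoHyperparams",
    "MCMCConfig",
    "ScenarioConfig",
    "SCENARIOS",
    "smoke_sim_config",
]


@dataclass
class SimConfig:
    """Parameters of the neutral forward simulation (steps 1-3).

    The ``ld_regime`` switch controls how much linkage disequilibrium the
    common ancestral population carries into the breed split.  The low
    regime is the literal published schedule (decline from 2000 to 100).
    The high regime appends a deeper ancestral bottleneck (a drop to
    ``bottleneck_size`` for ``bottleneck_generations``, then a short
    recovery to 100 so the breeds can be founded) so that the correlation
    of LD phase between the two derived breeds in the first 1-cM bin
    reaches ~0.7 instead of ~0.2; see docs/methods.md for the calibration.
    """

    n_candidate_loci: int = 2500
    chromosome_length: float = 1.0  # Morgans

    phase1_generations: int = 1000
    phase1_size: int = 2000
    phase2_generations: int = 1000
    phase2_end_size: int = 100
    # optional ancestral bottleneck appended after the decline (high-LD
    # regime): the census drops to bottleneck_size for
    # bottleneck_generations and then returns to phase2_end_size for
    # recovery_generations before the breeds are founded
    bottleneck_size: int = 0
    bottleneck_generations: int = 0
    recovery_generations: int = 0

    breed_founder_males: int = 25
    breed_founder_females: int = 25
    breed_generations: int = 100
    breed_formation_dams: int = 50
    offspring_per_dam_bf: int = 5

    expansion_founder_males: int = 100
    expansion_founder_females: int = 100
    expansion_generations: int = 8
    offspring_per_dam_eg: int = 10

    mutation_rate: float = 2.5e-4  # per locus per transmitted gamete
    n_snp: int = 1000
    n_qtl: int = 100
    maf_threshold: float = 0.05

    ld_regime: Literal["low", "high"] = "low"

    def __post_init__(self) -> None:
        counts = (
            self.n_candidate_loci,
            self.phase1_generations,
            self.phase1_size,
            self.phase2_generations,
            self.phase2_end_size,
            self.breed_founder_males,
            self.breed_founder_females,
            self.breed_generations,
            self.offspring_per_dam_bf,
            self.expansion_founder_males,
            self.expansion_founder_females,
            self.expansion_generations,
            self.offspring_per_dam_eg,
            self.n_snp,
            self.n_qtl,
        )
        if any(c <= 0 for c in counts):
            raise ValueError("all population/genome counts must be positive")
        if not 0.0 < self.maf_threshold < 0.5:
            raise ValueError("maf_threshold must lie in (0, 0.5)")
        if not 0.0 <= self.mutation_rate < 1.0:
            raise ValueError("mutation_rate must lie in [0, 1)")
        if self.ld_regime not in ("low", "high"):
            raise ValueError(f"unknown ld_regime {self.ld_regime!r}")

    @classmethod
    def for_regime(cls, regime: Literal["low", "high"], **overrides) -> "SimConfig":
        """Published parameter set for one of the two LD-phase regimes."""
        if regime == "low":
            return cls(ld_regime="low", **overrides)
        # Calibrated for maximal between-breed correlation of LD phase:
        # the deep ancestral bottleneck roughly doubles it relative to
        # the low regime (~0.5 vs ~0.25 in the first 1-cM bin).  Deeper
        # or longer bottlenecks gain nothing: post-split drift and
        # recurrent mutation put a ceiling on phase persistence (see
        # docs/methods.md).  More candidate loci keep the MAF >= 0.05
        # panel feasible despite the diversity lost in the bottleneck.
        defaults = dict(bottleneck_size=16, bottleneck_generations=20,
                        recovery_generations=5, n_candidate_loci=5000)
        defaults.update(overrides)
        return cls(ld_regime="high", **defaults)

    def to_dict(self) -> dict:
        return asdict(self)


def smoke_sim_config(regime: Literal["low", "high"] = "low", **overrides) -> SimConfig:
    """A reduced profile for quick end-to-end runs (tests, examples).

    Keeps the shape of the study (two phases, breed split, expansion) at a
    fraction of the historical depth and census size.
    """
    defaults = dict(
        n_candidate_loci=600,
        n_snp=200,
        n_qtl=30,
        phase1_generations=100,
        phase1_size=200,
        phase2_generations=100,
        phase2_end_size=60,
        breed_founder_males=10,
        breed_founder_females=10,
        breed_formation_dams=12,
        breed_generations=20,
        expansion_generations=3,
        expansion_founder_males=20,
        expansion_founder_females=20,
        offspring_per_dam_eg=5,
        ld_regime=regime,
    )
    if regime == "high":
        defaults.update(bottleneck_size=20, bottleneck_generations=10,
                        recovery_generations=3, n_candidate_loci=1500)
    defaults.update(overrides)
    return SimConfig(**defaults)


@dataclass
class TraitParams:
    """Genetic architecture of the trait.

    ``|a| ~ Gamma(shape, scale)`` with a random sign, dominance degrees
    ``h ~ N(h_mean, h_sd)`` independent of ``a``, and ``d = h * |a|``.
    After variance scaling the trait has V_A = 0.3, V_D = 0.1 and a
    residual variance of 0.6, i.e. phenotypic variance 1, broad-sense
    heritability 0.4 and narrow-sense heritability 0.3.
    """

    gamma_shape: float = 0.4
    gamma_scale: float = 1.66
    h_mean: float = 0.5
    h_sd: float = 0.1
    target_v_a: float = 0.3
    target_v_d: float = 0.1
    residual_variance: float = 0.6

    @property
    def broad_h2(self) -> float:
        return self.target_v_a + self.target_v_d

    @property
    def narrow_h2(self) -> float:
        return self.target_v_a

    def __post_init__(self) -> None:
        if self.residual_variance < 0:
            raise ValueError("residual_variance must be >= 0")


@dataclass
class LassoHyperparams:
    """Priors of the dominance-model Bayesian LASSO.

    Residual variance: scaled inverse chi-square with ``df_e`` degrees of
    freedom and scale ``S_e`` (density proportional to
    ``(s2)**(-df/2-1) * exp(-df*S/(2*s2))``).  Dominance effects share a
    common variance with a scaled inverse chi-square prior (``df_d``,
    ``S_d``).  Additive effects have marker-specific variances
    ``sigma_e^2 * tau_j^2`` with ``tau_j^2`` exponential and the
    regularisation parameter ``lambda^2`` gamma-distributed.
    """

    df_e: float = 3.5
    S_e: float = 3.0
    df_d: float = 3.0
    S_d: float = 0.0005
    lambda2_shape: float = 0.52
    lambda2_rate: float = 1e-4

    def __post_init__(self) -> None:
        vals = (self.df_e, self.S_e, self.df_d, self.S_d,
                self.lambda2_shape, self.lambda2_rate)
        if any(v <= 0 for v in vals):
            raise ValueError("all hyperparameters must be positive")


@dataclass
class MCMCConfig:
    n_iter: int = 10_000
    burn_in: int = 1_500
    thinning: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iter")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")


#: Selection criterion per breed and reference-population structure for the
#: five study scenarios.  "P" = own-line performance (GEBVP), "C" =
#: crossbred performance (GEBVC).
SCENARIOS: dict[str, tuple[str, str, str]] = {
    "ref": ("P", "P", "separate"),
    "1": ("C", "P", "separate"),
    "2": ("C", "C", "separate"),
    "3": ("C", "P", "common"),
    "4": ("C", "C", "common"),
}


@dataclass
class ScenarioConfig:
    """One row of the scenario table plus breeding-program sizes."""

    name: str = "ref"
    criterion_A: Literal["P", "C"] = "P"
    criterion_B: Literal["P", "C"] = "P"
    training_mode: Literal["separate", "common"] = "separate"
    n_selected_males: int = 100
    n_selected_females: int = 200
    offspring_per_dam: int = 5
    n_generations: int = 5

    @classmethod
    def from_name(cls, name: str, **overrides) -> "ScenarioConfig":
        try:
            ca, cb, mode = SCENARIOS[str(name)]
        except KeyError:
            raise ValueError(
                f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}"
            ) from None
        return cls(name=str(name), criterion_A=ca, criterion_B=cb,
                   training_mode=mode, **overrides)
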