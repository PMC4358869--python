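"""Estimation of additive and dominance SNP effects with a Bayesian
LASSO Gibbs sampler.

The model is ``y_i = mu + sum_j X_ij a_j + sum_j Z_ij d_j + e_i`` where
``X`` is the allele-count coding (0/1/2) and ``Z`` the heterozygosity
indicator.  Additive effects carry marker-specific double-exponential
shrinkage (normal with variance ``sigma_e^2 tau_j^2``, exponential
``tau_j^2``, gamma-distributed ``lambda^2``); dominance effects share a
common normal variance with a scaled inverse chi-square prior.  Marker
effects are summarised as plain posterior means of the post-burn-in
draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import gibbs_lasso_kernel
from .config import LassoHyperparams, MCMCConfig
from .population import Population

__all__ = ["TrainingSet", "MarkerEstimates", "build_training_set", "fit"]


@dataclass
class TrainingSet:
    """Phenotypes plus additive (0/1/2) and dominance (0/1) codings."""

    y: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    ids: np.ndarray
    breed_of_origin: np.ndarray

    def __post_init__(self) -> None:
        n = self.y.shape[0]
        if self.X.shape[0] != n or self.Z.shape != self.X.shape:
            raise ValueError("phenotype/genotype dimensions are inconsistent")
        if len(self.ids) != n or len(self.breed_of_origin) != n:
            raise ValueError("ids/breed labels must match the phenotypes")
        if not (np.isfinite(self.y).all() and np.isfinite(self.X).all()):
            raise ValueError("training data contain non-finite values")
        if np.any(((self.X == 1) != (self.Z == 1))):
            raise ValueError("Z must indicate exactly the heterozygous entries of X")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def n_markers(self) -> int:
        return self.X.shape[1]


@dataclass
class MarkerEstimates:
    """Posterior-mean SNP effects plus sampler provenance."""

    a_hat: np.ndarray
    d_hat: np.ndarray
    mu_hat: float
    sigma_e2: float
    sigma_d2: float
    lambda2: float
    training_breeds: tuple[str, ...] = ()
    seed: int | None = None
    n_iter: int = 0
    burn_in: int = 0


def build_training_set(populations: list[Population],
                       phenotypes: list[np.ndarray],
                       snp_idx: np.ndarray,
                       mode: str = "separate"
                       ) -> dict[str, TrainingSet]:
    """Assemble training sets from phenotyped cohorts.

    ``separate`` returns one TrainingSet per breed; ``common``
    concatenates all cohorts into a single set keyed ``"common"`` (no
    breed term enters the model — the intercept absorbs the average).
    """
    if len(populations) != len(phenotypes):
        raise ValueError("one phenotype vector per population is required")
    parts = []
    for pop, y in zip(populations, phenotypes):
        y = np.asarray(y, dtype=np.float64)
        if y.shape[0] != pop.n:
            raise ValueError(
                f"breed {pop.breed}: {y.shape[0]} phenotypes for {pop.n} animals")
        X = pop.dosage(snp_idx).astype(np.float64)
        Z = (X == 1.0).astype(np.float64)
        parts.append(TrainingSet(
            y=y, X=X, Z=Z, ids=pop.ids.copy(),
            breed_of_origin=np.repeat(pop.breed, pop.n)))
    if mode == "separate":
        return {ts.breed_of_origin[0]: ts for ts in parts}
    if mode == "common":
        return {"common": TrainingSet(
            y=np.concatenate([t.y for t in parts]),
            X=np.vstack([t.X for t in parts]),
            Z=np.vstack([t.Z for t in parts]),
            ids=np.concatenate([t.ids for t in parts]),
            breed_of_origin=np.concatenate([t.breed_of_origin for t in parts]),
        )}
    raise ValueError(f"unknown training mode {mode!r}")


def fit(train: TrainingSet,
        hyper: LassoHyperparams | None = None,
        mcmc: MCMCConfig | None = None,
        _fixed_variances: tuple[float, float, float] | None = None
        ) -> MarkerEstimates:
    """Run the Gibbs sampler and return posterior-mean marker effects.

    ``_fixed_variances = (sigma_e2, sigma_d2, tau2)`` clamps all variance
    parameters, reducing the model to conjugate ridge regression; it
    exists so tests can compare the chain against the closed form.
    """
    hyper = hyper or LassoHyperparams()
    mcmc = mcmc or MCMCConfig()
    if train.n < 2:
        raise ValueError("at least two training records are required")

    Xt = np.ascontiguousarray(train.X.T)
    Zt = np.ascontiguousarray(train.Z.T)
    xtx = np.einsum("ji,ji->j", Xt, Xt)
    ztz = np.einsum("ji,ji->j", Zt, Zt)

    fix = _fixed_variances is not None
    se_f, sd_f, tau_f = _fixed_variances if fix else (1.0, 1.0, 1.0)
    a_hat, d_hat, mu_hat, se, sd, lam2 = gibbs_lasso_kernel(
        np.ascontiguousarray(train.y, dtype=np.float64), Xt, Zt, xtx, ztz,
        hyper.df_e, hyper.S_e, hyper.df_d, hyper.S_d,
        hyper.lambda2_shape, hyper.lambda2_rate,
        mcmc.n_iter, mcmc.burn_in, int(mcmc.seed) % 2**31,
        fix, se_f, sd_f, tau_f,
    )
    if not (np.isfinite(a_hat).all() and np.isfinite(d_hat).all()):
        raise FloatingPointError("sampler produced non-finite estimates")
    return MarkerEstimates(
        a_hat=a_hat, d_hat=d_hat, mu_hat=float(mu_hat),
        sigma_e2=float(se), sigma_d2=float(sd), lambda2=float(lam2),
        training_breeds=tuple(sorted(set(train.breed_of_origin.tolist()))),
        seed=int(mcmc.seed), n_iter=mcmc.n_iter, burn_in=mcmc.burn_in,
    )
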