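"""Orchestration of full replicates of the selection study.

One replicate = neutral simulation of the base populations (steps 1-3),
one trait architecture scaled at the last historical generation, one
round of marker-effect estimation per reference-population structure,
and the five selection scenarios run from a shared founding of the
selection lines.  All randomness flows from a master seed through named
`numpy.random.SeedSequence` substreams, so scenario contrasts are paired
within a replicate and reruns are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (MCMCConfig, LassoHyperparams, ScenarioConfig, SimConfig,
                     TraitParams, SCENARIOS)
from .genome import GeneticMap, simulate_base_populations
from .lasso import MarkerEstimates, build_training_set, fit
from .ld import adjacent_r2, decay_curve, pairwise_r, phase_correlation, \
    phase_persistence
from .population import Population
from .program import Cohort, found_base, run_scenario
from .trait import TraitArchitecture, genotypic_value, phenotype, \
    sample_effects, scale_effects

__all__ = [
    "ReplicateResult",
    "simulate_replicate_base",
    "ld_statistics",
    "run_replicate",
    "run_study",
    "aggregate",
]


@dataclass
class ReplicateBase:
    """Everything the scenarios of one replicate share."""

    config: SimConfig
    gmap: GeneticMap
    historical: Population
    train_a: Population
    train_b: Population
    arch: TraitArchitecture
    y_train_a: np.ndarray
    y_train_b: np.ndarray


@dataclass
class ReplicateResult:
    replicate: int
    summaries: pd.DataFrame
    r_tbvp_tbvc: dict[str, float]
    manifest: dict = field(default_factory=dict)
    base: "ReplicateBase | None" = None


def _int_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % 2**31)


def simulate_replicate_base(config: SimConfig,
                            params: TraitParams,
                            seed_seq: np.random.SeedSequence) -> ReplicateBase:
    """Steps 1-3 plus the trait architecture and training phenotypes."""
    ss_sim, ss_trait, ss_noise = seed_seq.spawn(3)
    rng = np.random.default_rng(ss_sim)
    hist, train_a, train_b, gmap = simulate_base_populations(config, rng)

    trng = np.random.default_rng(ss_trait)
    arch = sample_effects(params, config.n_qtl, trng)
    ref_freq = hist.allele_frequencies(gmap.qtl_idx)
    arch = scale_effects(arch, ref_freq, params)

    nrng = np.random.default_rng(ss_noise)
    y_a = phenotype(genotypic_value(train_a.dosage(gmap.qtl_idx), arch),
                    params, nrng)
    y_b = phenotype(genotypic_value(train_b.dosage(gmap.qtl_idx), arch),
                    params, nrng)
    return ReplicateBase(config=config, gmap=gmap, historical=hist,
                         train_a=train_a, train_b=train_b, arch=arch,
                         y_train_a=y_a, y_train_b=y_b)


def ld_statistics(base: ReplicateBase) -> dict[str, float]:
    """LD and phase-persistence summaries of the training populations.

    Binned quantities are labelled by their bin: ``r2_0to1cm`` is the
    mean r^2 of pairs 0-1 cM apart (the bin a printed "r^2 at 1 cM"
    refers to), ``r2_4to5cm`` the 4-5 cM bin, and so on.
    """
    pos_cm = base.gmap.snp_positions() * 100.0
    gam_a = base.train_a.gametes(base.gmap.snp_idx)
    gam_b = base.train_b.gametes(base.gmap.snp_idx)
    stats: dict[str, float] = {}
    for label, gam in (("A", gam_a), ("B", gam_b)):
        stats[f"adjacent_r2_{label}"] = adjacent_r2(gam, pos_cm, maf_min=0.1)
        decay = decay_curve(pairwise_r(gam, pos_cm, maf_min=0.1))
        stats[f"r2_0to1cm_{label}"] = float(decay.loc[0.0])
        stats[f"r2_4to5cm_{label}"] = float(decay.loc[4.0])
    persistence = phase_persistence(gam_a, gam_b, pos_cm)
    stats["phase_corr_0to1cm"] = float(persistence.loc[0.0])
    stats["phase_corr_50kb"] = phase_correlation(gam_a, gam_b, pos_cm,
                                                 max_distance_cm=0.05)
    return stats


def _fit_marker_effects(base: ReplicateBase, modes: set[str],
                        hyper: LassoHyperparams, mcmc_template: MCMCConfig,
                        seed_seq: np.random.SeedSequence
                        ) -> dict[str, MarkerEstimates]:
    """Fit the sampler once per needed training configuration."""
    seeds = {name: _int_seed(ss)
             for name, ss in zip(("A", "B", "common"), seed_seq.spawn(3))}
    pops = [base.train_a, base.train_b]
    phen = [base.y_train_a, base.y_train_b]
    fits: dict[str, MarkerEstimates] = {}
    if "separate" in modes:
        for label, ts in build_training_set(pops, phen, base.gmap.snp_idx,
                                            "separate").items():
            cfg = MCMCConfig(n_iter=mcmc_template.n_iter,
                             burn_in=mcmc_template.burn_in,
                             seed=seeds[label])
            fits[label] = fit(ts, hyper, cfg)
    if "common" in modes:
        (ts,) = build_training_set(pops, phen, base.gmap.snp_idx,
                                   "common").values()
        cfg = MCMCConfig(n_iter=mcmc_template.n_iter,
                         burn_in=mcmc_template.burn_in, seed=seeds["common"])
        fits["common"] = fit(ts, hyper, cfg)
    return fits


def run_replicate(replicate: int,
                  master_seed: int,
                  regime: str = "low",
                  scenarios: tuple[str, ...] = ("ref", "1", "2", "3", "4"),
                  config: SimConfig | None = None,
                  params: TraitParams | None = None,
                  hyper: LassoHyperparams | None = None,
                  mcmc: MCMCConfig | None = None,
                  n_generations: int = 5,
                  base: ReplicateBase | None = None,
                  keep_base: bool = False) -> ReplicateResult:
    """One full replicate: simulate, train, and run the scenarios.

    All scenarios share the simulated base populations, the trait
    architecture, the marker-effect estimates and the founded selection
    lines; only the selection criterion and reference structure differ.
    """
    params = params or TraitParams()
    hyper = hyper or LassoHyperparams()
    mcmc = mcmc or MCMCConfig()
    config = config or SimConfig.for_regime(regime)

    root = np.random.SeedSequence(entropy=master_seed,
                                  spawn_key=(replicate,))
    ss_base, ss_fit, ss_found, ss_scen = root.spawn(4)

    if base is None:
        base = simulate_replicate_base(config, params, ss_base)

    modes = {SCENARIOS[s][2] for s in scenarios}
    fits = _fit_marker_effects(base, modes, hyper, mcmc, ss_fit)

    # selected proportions are 20% of males and 40% of females; at full
    # scale this is the printed 100 sires / 200 dams out of 500 + 500
    sizing = dict(
        n_selected_males=max(1, round(0.2 * base.train_a.males().size)),
        n_selected_females=max(1, round(0.4 * base.train_a.females().size)),
    )
    base_rng = np.random.default_rng(ss_found)
    cand_a, cand_b = found_base(base.train_a, base.train_b, base.arch,
                                params, base.gmap, base_rng,
                                scenario_cfg=ScenarioConfig(**sizing))

    r_pc_vals = {"A": _rpc(cand_a, cand_b, base),
                 "B": _rpc(cand_b, cand_a, base)}
    r_pc_vals["pooled"] = float(np.mean([r_pc_vals["A"], r_pc_vals["B"]]))

    records = []
    scen_streams = ss_scen.spawn(len(scenarios))
    for name, ss in zip(scenarios, scen_streams):
        scen = ScenarioConfig.from_name(name, n_generations=n_generations,
                                        **sizing)
        est = _resolve_estimates(scen, fits)
        rng = np.random.default_rng(ss)
        for summary in run_scenario(scen, (cand_a, cand_b), base.arch,
                                    params, base.gmap, est, rng):
            records.append(summary.to_record())

    manifest = {
        "replicate": replicate,
        "master_seed": master_seed,
        "regime": config.ld_regime,
        "scenarios": list(scenarios),
        "sim_config": config.to_dict(),
        "mcmc": {"n_iter": mcmc.n_iter, "burn_in": mcmc.burn_in},
    }
    return ReplicateResult(replicate=replicate,
                           summaries=pd.DataFrame.from_records(records),
                           r_tbvp_tbvc=r_pc_vals,
                           manifest=manifest,
                           base=base if keep_base else None)


def _resolve_estimates(scen: ScenarioConfig,
                       fits: dict[str, MarkerEstimates]
                       ) -> dict[str, MarkerEstimates]:
    if scen.training_mode == "common":
        return {"A": fits["common"], "B": fits["common"]}
    return {"A": fits["A"], "B": fits["B"]}


def _rpc(cohort: Cohort, other: Cohort, base: ReplicateBase) -> float:
    """Purebred-crossbred genetic correlation among a line's candidates."""
    from .breeding_values import accuracy, breeding_value

    dos = cohort.pop.dosage(base.gmap.qtl_idx)
    own_freq = cohort.pop.allele_frequencies(base.gmap.qtl_idx)
    other_freq = other.pop.allele_frequencies(base.gmap.qtl_idx)
    tbvp = breeding_value(dos, base.arch.a, base.arch.d, own_freq)
    tbvc = breeding_value(dos, base.arch.a, base.arch.d, other_freq)
    return accuracy(tbvp.total, tbvc.total)


def run_study(n_replicates: int,
              master_seed: int,
              regime: str = "low",
              scenarios: tuple[str, ...] = ("ref", "1", "2", "3", "4"),
              **kwargs) -> tuple[pd.DataFrame, list[ReplicateResult]]:
    """Run ``n_replicates`` full replicates and aggregate the summaries.

    Returns the aggregated table (mean and standard error per scenario,
    generation and column) together with the per-replicate results.
    """
    results = [run_replicate(rep, master_seed, regime=regime,
                             scenarios=scenarios, **kwargs)
               for rep in range(n_replicates)]
    frames = []
    for res in results:
        df = res.summaries.copy()
        df["replicate"] = res.replicate
        frames.append(df)
    per_rep = pd.concat(frames, ignore_index=True)
    return aggregate(per_rep), results


def aggregate(per_replicate: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard error (SD / sqrt(n)) over replicates."""
    value_cols = [c for c in per_replicate.columns
                  if c not in ("scenario", "generation", "replicate")]
    grouped = per_replicate.groupby(["scenario", "generation"])[value_cols]
    mean = grouped.mean()
    n = grouped.count()
    se = grouped.std(ddof=1) / np.sqrt(n)
    out = pd.concat({"mean": mean, "se": se}, axis=1)
    return out.reset_index()
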