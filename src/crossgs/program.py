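"""The two-way crossbreeding program: founding of the selection lines,
five generations of truncation selection on genomic breeding values, and
production of terminal crossbreds.

Breed A is the sire line and breed B the dam line.  Every generation has
1000 candidates per breed (500 of each sex); the top 100 males and top
200 females by the scenario's criterion (GEBVP or GEBVC) are selected,
mated within breed (5 offspring per dam) to produce the replacements,
while the selected A males x selected B females produce 1000 terminal
crossbreds.  SNP effects are estimated once, before selection starts;
allele frequencies entering the breeding-value formula are recomputed
from the current candidates every generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .breeding_values import BreedingValues, accuracy, breeding_value
from .config import ScenarioConfig, TraitParams
from .genome import GeneticMap, _IdCounter, _draw_gametes, _litter_mating
from .lasso import MarkerEstimates
from .population import Population
from .trait import TraitArchitecture, genotypic_value, phenotype

__all__ = [
    "Cohort",
    "GenerationSummary",
    "found_base",
    "select_top",
    "heterosis",
    "run_scenario",
]


@dataclass
class Cohort:
    """A phenotyped cohort: population plus genotypic values and phenotypes."""

    pop: Population
    g: np.ndarray
    y: np.ndarray

    @property
    def n(self) -> int:
        return self.pop.n


def make_cohort(pop: Population, arch: TraitArchitecture,
                params: TraitParams, gmap: GeneticMap,
                rng: np.random.Generator) -> Cohort:
    g = genotypic_value(pop.dosage(gmap.qtl_idx), arch)
    return Cohort(pop=pop, g=g, y=phenotype(g, params, rng))


@dataclass
class GenerationSummary:
    """Per-generation report of one scenario run."""

    scenario: str
    generation: int
    mean_pheno_A: float
    mean_pheno_B: float
    breed_average: float
    crossbred_mean: float
    heterosis: float
    qtl_freq_divergence: float  # sum over QTL of (p_A - p_B)^2
    accuracies: dict = field(default_factory=dict)
    qtl_freq_A: np.ndarray | None = None
    qtl_freq_B: np.ndarray | None = None

    def to_record(self) -> dict:
        rec = {k: v for k, v in asdict(self).items()
               if k not in ("accuracies", "qtl_freq_A", "qtl_freq_B")}
        rec.update(self.accuracies)
        return rec


def heterosis(d: np.ndarray, p_a: np.ndarray, p_b: np.ndarray) -> float:
    """Expected heterosis under pure dominance: sum_l d_l (p_A,l - p_B,l)^2."""
    return float(np.sum(d * (p_a - p_b) ** 2))


def select_top(values: np.ndarray, pop: Population, n_males: int,
               n_females: int) -> tuple[np.ndarray, np.ndarray]:
    """Truncation selection within sex; ties broken by individual id."""
    if not np.all(np.isfinite(values)):
        raise ValueError("selection criterion contains non-finite values")
    out = []
    for sex_idx, quota in ((pop.males(), n_males), (pop.females(), n_females)):
        if sex_idx.size < quota:
            raise ValueError(
                f"only {sex_idx.size} candidates for a quota of {quota}")
        order = np.lexsort((pop.ids[sex_idx], -values[sex_idx]))
        out.append(sex_idx[order[:quota]])
    return out[0], out[1]


def found_base(train_a: Population, train_b: Population,
               arch: TraitArchitecture, params: TraitParams,
               gmap: GeneticMap, rng: np.random.Generator,
               scenario_cfg: ScenarioConfig | None = None,
               ids: _IdCounter | None = None) -> tuple[Cohort, Cohort]:
    """Found the selection lines: 100 sires and 200 dams sampled at
    random from each training population, mated randomly (5 offspring
    per dam) to give 1000 candidates per breed."""
    cfg = scenario_cfg or ScenarioConfig()
    if ids is None:
        ids = _IdCounter(int(max(train_a.ids.max(), train_b.ids.max())) + 1)
    out = []
    for pop, label in ((train_a, "A0"), (train_b, "B0")):
        males, females = pop.males(), pop.females()
        if males.size < cfg.n_selected_males or females.size < cfg.n_selected_females:
            raise ValueError("training population too small to found the base")
        sires = rng.choice(males, size=cfg.n_selected_males, replace=False)
        dams = rng.choice(females, size=cfg.n_selected_females, replace=False)
        nxt = _litter_mating(pop, sires, dams, cfg.offspring_per_dam, gmap,
                             0.0, rng, ids, pop.breed, label)
        out.append(make_cohort(nxt, arch, params, gmap, rng))
    return out[0], out[1]


def _crossbreed(pop_a: Population, sires: np.ndarray, pop_b: Population,
                dams: np.ndarray, litter: int, gmap: GeneticMap,
                rng: np.random.Generator, ids: _IdCounter,
                generation: str) -> Population:
    """Terminal cross: each selected B dam is mated to one selected A
    sire drawn uniformly with replacement."""
    sire_of_dam = sires[rng.integers(0, sires.size, size=dams.size)]
    sire_of = np.repeat(sire_of_dam, litter)
    dam_of = np.repeat(dams, litter)
    paternal = _draw_gametes(pop_a.haplotypes, sire_of, gmap, 0.0, rng)
    maternal = _draw_gametes(pop_b.haplotypes, dam_of, gmap, 0.0, rng)
    haps = np.stack([paternal, maternal], axis=1)
    n = haps.shape[0]
    sex = np.ones(n, dtype=np.uint8)
    sex[: n // 2] = 0
    rng.shuffle(sex)
    return Population(haplotypes=haps, sex=sex, ids=ids.take(n),
                      sire=pop_a.ids[sire_of], dam=pop_b.ids[dam_of],
                      breed="AB", generation=generation)


def _breeding_value_panel(cohort: Cohort, est: MarkerEstimates,
                          snp_idx: np.ndarray, freqs: np.ndarray
                          ) -> BreedingValues:
    return breeding_value(cohort.pop.dosage(snp_idx), est.a_hat, est.d_hat, freqs)


def run_scenario(scenario: ScenarioConfig, base: tuple[Cohort, Cohort],
                 arch: TraitArchitecture, params: TraitParams,
                 gmap: GeneticMap, estimates: dict[str, MarkerEstimates],
                 rng: np.random.Generator,
                 keep_frequencies: bool = False) -> list[GenerationSummary]:
    """Run one scenario for ``n_generations`` of selection.

    ``estimates`` maps breed label ("A"/"B") to the marker estimates that
    breed's GEBV are computed with (the same object for both breeds under
    a common reference population).  ``base`` is shared across scenarios
    of a replicate so that scenario contrasts are paired.
    """
    cand_a, cand_b = base
    ids = _IdCounter(int(max(cand_a.pop.ids.max(), cand_b.pop.ids.max())) + 1)
    summaries: list[GenerationSummary] = []

    for g in range(1, scenario.n_generations + 1):
        p_qtl = {"A": cand_a.pop.allele_frequencies(gmap.qtl_idx),
                 "B": cand_b.pop.allele_frequencies(gmap.qtl_idx)}
        p_snp = {"A": cand_a.pop.allele_frequencies(gmap.snp_idx),
                 "B": cand_b.pop.allele_frequencies(gmap.snp_idx)}

        acc: dict[str, float] = {}
        criterion: dict[str, np.ndarray] = {}
        for label, cohort, other in (("A", cand_a, "B"), ("B", cand_b, "A")):
            dos_qtl = cohort.pop.dosage(gmap.qtl_idx)
            tbvp = breeding_value(dos_qtl, arch.a, arch.d, p_qtl[label])
            tbvc = breeding_value(dos_qtl, arch.a, arch.d, p_qtl[other])
            est = estimates[label]
            gebvp = _breeding_value_panel(cohort, est, gmap.snp_idx, p_snp[label])
            gebvc = _breeding_value_panel(cohort, est, gmap.snp_idx, p_snp[other])
            for tag, tbv, gebv in (("P", tbvp, gebvp), ("C", tbvc, gebvc)):
                acc[f"acc_{tag}_{label}"] = accuracy(tbv.total, gebv.total)
                acc[f"acc_{tag}_add_{label}"] = accuracy(tbv.additive, gebv.additive)
                acc[f"acc_{tag}_dom_{label}"] = accuracy(tbv.dominance, gebv.dominance)
            acc[f"r_tbvp_tbvc_{label}"] = accuracy(tbvp.total, tbvc.total)
            crit = scenario.criterion_A if label == "A" else scenario.criterion_B
            criterion[label] = (gebvp if crit == "P" else gebvc).total
            acc[f"acc_criterion_{label}"] = acc[f"acc_{crit}_{label}"]

        sel_am, sel_af = select_top(criterion["A"], cand_a.pop,
                                    scenario.n_selected_males,
                                    scenario.n_selected_females)
        sel_bm, sel_bf = select_top(criterion["B"], cand_b.pop,
                                    scenario.n_selected_males,
                                    scenario.n_selected_females)

        cross_pop = _crossbreed(cand_a.pop, sel_am, cand_b.pop, sel_bf,
                                scenario.offspring_per_dam, gmap, rng, ids,
                                f"AB{g}")
        cross = make_cohort(cross_pop, arch, params, gmap, rng)

        summaries.append(GenerationSummary(
            scenario=scenario.name,
            generation=g,
            mean_pheno_A=float(cand_a.y.mean()),
            mean_pheno_B=float(cand_b.y.mean()),
            breed_average=float((cand_a.y.mean() + cand_b.y.mean()) / 2.0),
            crossbred_mean=float(cross.y.mean()),
            heterosis=heterosis(arch.d, p_qtl["A"], p_qtl["B"]),
            qtl_freq_divergence=float(np.sum((p_qtl["A"] - p_qtl["B"]) ** 2)),
            accuracies=acc,
            qtl_freq_A=p_qtl["A"] if keep_frequencies else None,
            qtl_freq_B=p_qtl["B"] if keep_frequencies else None,
        ))

        if g < scenario.n_generations:
            next_a = _litter_mating(cand_a.pop, sel_am, sel_af,
                                    scenario.offspring_per_dam, gmap, 0.0,
                                    rng, ids, "A", f"G{g + 1}")
            next_b = _litter_mating(cand_b.pop, sel_bm, sel_bf,
                                    scenario.offspring_per_dam, gmap, 0.0,
                                    rng, ids, "B", f"G{g + 1}")
            cand_a = make_cohort(next_a, arch, params, gmap, rng)
            cand_b = make_cohort(next_b, arch, params, gmap, rng)

    return summaries
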