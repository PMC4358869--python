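"""Forward-in-time neutral simulation: historical population, breed
formation and expansion.

The genome is a single chromosome of 1 Morgan carrying ~2500 candidate
biallelic loci at random positions.  Meiosis follows the Haldane model
(Poisson crossovers, uniform positions, no interference) and recurrent
mutation flips each transmitted allele with a fixed per-locus probability.
Only mutation and drift act during these steps; mating is by random union
of gametes with an equal sex ratio maintained in every generation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import make_gametes_kernel
from .config import SimConfig
from .population import Population

__all__ = [
    "GeneticMap",
    "random_map",
    "make_gamete",
    "simulate_historical",
    "split_and_diverge",
    "expand",
    "select_panels",
    "simulate_base_populations",
]


@dataclass
class GeneticMap:
    """Locus positions (Morgans) plus the SNP/QTL panel assignment.

    ``snp_idx`` and ``qtl_idx`` are disjoint index arrays into the
    candidate loci; they are ``None`` until :func:`select_panels` runs.
    """

    positions: np.ndarray
    snp_idx: np.ndarray | None = None
    qtl_idx: np.ndarray | None = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.float64)
        if pos.ndim != 1:
            raise ValueError("positions must be one-dimensional")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("positions must be strictly increasing")
        if pos.size and (pos[0] < 0 or pos[-1] > 1.0):
            raise ValueError("positions must lie in [0, 1] Morgans")
        self.positions = pos
        if self.snp_idx is not None and self.qtl_idx is not None:
            if np.intersect1d(self.snp_idx, self.qtl_idx).size:
                raise ValueError("SNP and QTL panels must be disjoint")

    @property
    def n_loci(self) -> int:
        return self.positions.size

    @property
    def length(self) -> float:
        return 1.0

    def snp_positions(self) -> np.ndarray:
        return self.positions[self.snp_idx]

    def qtl_positions(self) -> np.ndarray:
        return self.positions[self.qtl_idx]


def random_map(n_loci: int, rng: np.random.Generator) -> GeneticMap:
    """Candidate loci placed uniformly at random on the 1-Morgan chromosome."""
    pos = np.sort(rng.random(n_loci))
    # strictly increasing positions (ties have probability 0 but guard anyway)
    while np.any(np.diff(pos) <= 0):
        pos = np.sort(rng.random(n_loci))
    return GeneticMap(positions=pos)


def _draw_gametes(parent_haps: np.ndarray, parent_idx: np.ndarray,
                  gmap: GeneticMap, mutation_rate: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Vectorised meiosis for a batch of gametes."""
    G = parent_idx.size
    L = gmap.n_loci
    # crossovers fall on the whole 1-Morgan chromosome
    xo_counts = rng.poisson(1.0, size=G).astype(np.int64)
    total_xo = int(xo_counts.sum())
    xo_pos = rng.random(total_xo)
    xo_off = np.zeros(G, dtype=np.int64)
    np.cumsum(xo_counts[:-1], out=xo_off[1:])
    start_hap = rng.integers(0, 2, size=G).astype(np.int64)
    if mutation_rate > 0.0:
        mut_counts = rng.binomial(L, mutation_rate, size=G).astype(np.int64)
        total_mut = int(mut_counts.sum())
        mut_pos = rng.integers(0, L, size=total_mut).astype(np.int64)
    else:
        mut_counts = np.zeros(G, dtype=np.int64)
        mut_pos = np.zeros(0, dtype=np.int64)
    mut_off = np.zeros(G, dtype=np.int64)
    np.cumsum(mut_counts[:-1], out=mut_off[1:])
    out = np.empty((G, L), dtype=np.uint8)
    make_gametes_kernel(parent_haps, parent_idx.astype(np.int64), start_hap,
                        xo_counts, xo_pos, xo_off,
                        mut_counts, mut_pos, mut_off,
                        gmap.positions, out)
    return out


def make_gamete(parent_haplotypes: np.ndarray, gmap: GeneticMap,
                rng: np.random.Generator,
                mutation_rate: float = 0.0) -> np.ndarray:
    """One recombinant gamete from a single parent's pair of haplotypes."""
    if parent_haplotypes.shape != (2, gmap.n_loci):
        raise ValueError("parent must have exactly 2 haplotypes over all loci")
    haps = parent_haplotypes[np.newaxis].astype(np.uint8)
    return _draw_gametes(haps, np.zeros(1, dtype=np.int64), gmap,
                         mutation_rate, rng)[0]


def _balanced_sexes(n: int, rng: np.random.Generator) -> np.ndarray:
    """Sex vector with exactly floor(n/2) males, randomly placed."""
    sex = np.ones(n, dtype=np.uint8)
    sex[: n // 2] = 0
    rng.shuffle(sex)
    return sex


class _IdCounter:
    def __init__(self, start: int = 0) -> None:
        self.next = start

    def take(self, n: int) -> np.ndarray:
        ids = np.arange(self.next, self.next + n, dtype=np.int64)
        self.next += n
        return ids


def _offspring_generation(pop: Population, sire_of: np.ndarray,
                          dam_of: np.ndarray, gmap: GeneticMap,
                          mutation_rate: float, rng: np.random.Generator,
                          ids: _IdCounter, breed: str,
                          generation: str) -> Population:
    """Produce one offspring cohort given per-offspring parent indices."""
    n = sire_of.size
    paternal = _draw_gametes(pop.haplotypes, sire_of, gmap, mutation_rate, rng)
    maternal = _draw_gametes(pop.haplotypes, dam_of, gmap, mutation_rate, rng)
    haps = np.stack([paternal, maternal], axis=1)
    return Population(
        haplotypes=haps,
        sex=_balanced_sexes(n, rng),
        ids=ids.take(n),
        sire=pop.ids[sire_of],
        dam=pop.ids[dam_of],
        breed=breed,
        generation=generation,
    )


def _random_union(pop: Population, n_off: int, gmap: GeneticMap,
                  mutation_rate: float, rng: np.random.Generator,
                  ids: _IdCounter, breed: str, generation: str) -> Population:
    """Random union of gametes: each offspring draws a sire and a dam
    uniformly (with replacement) from the male and female pools."""
    males, females = pop.males(), pop.females()
    if males.size == 0 or females.size == 0:
        raise ValueError("population lost one sex entirely; cannot continue")
    sire_of = males[rng.integers(0, males.size, size=n_off)]
    dam_of = females[rng.integers(0, females.size, size=n_off)]
    return _offspring_generation(pop, sire_of, dam_of, gmap, mutation_rate,
                                 rng, ids, breed, generation)


def _litter_mating(pop: Population, sire_pool: np.ndarray,
                   dam_pool: np.ndarray, litter: int, gmap: GeneticMap,
                   mutation_rate: float, rng: np.random.Generator,
                   ids: _IdCounter, breed: str, generation: str) -> Population:
    """Each dam produces a fixed litter, sired by one sire drawn
    uniformly with replacement from the sire pool."""
    sire_of_dam = sire_pool[rng.integers(0, sire_pool.size, size=dam_pool.size)]
    dam_of = np.repeat(dam_pool, litter)
    sire_of = np.repeat(sire_of_dam, litter)
    return _offspring_generation(pop, sire_of, dam_of, gmap, mutation_rate,
                                 rng, ids, breed, generation)


def _phase2_schedule(config: SimConfig) -> np.ndarray:
    """Census sizes for the declining phase: linear from phase1_size to
    phase2_end_size, rounded to the nearest even integer, plus an
    optional bottleneck episode with a short recovery (high-LD regime)."""
    t = np.arange(1, config.phase2_generations + 1)
    sizes = config.phase1_size + (config.phase2_end_size - config.phase1_size) \
        * t / config.phase2_generations
    sizes = (2 * np.round(sizes / 2)).astype(np.int64)
    sizes = np.maximum(sizes, 2)
    if config.bottleneck_generations:
        bsize = max(2 * round(config.bottleneck_size / 2), 2)
        episode = np.full(config.bottleneck_generations, bsize, dtype=np.int64)
        recovery = np.full(config.recovery_generations,
                           max(2 * round(config.phase2_end_size / 2), 2),
                           dtype=np.int64)
        sizes = np.concatenate([sizes, episode, recovery])
    if np.any(sizes <= 0):
        raise ValueError("population size schedule reaches zero")
    return sizes


def simulate_historical(config: SimConfig, rng: np.random.Generator,
                        gmap: GeneticMap | None = None,
                        ids: _IdCounter | None = None) -> tuple[Population, GeneticMap]:
    """Steps of the historical population: constant size, then decline.

    Initial allele frequencies are sampled uniformly per locus and founder
    haplotypes are drawn from them independently.  Returns the final
    historical generation and the genetic map.
    """
    if gmap is None:
        gmap = random_map(config.n_candidate_loci, rng)
    if ids is None:
        ids = _IdCounter()
    L = gmap.n_loci
    n0 = config.phase1_size
    freqs = rng.random(L)
    haps = (rng.random((n0, 2, L)) < freqs).astype(np.uint8)
    minus1 = np.full(n0, -1, dtype=np.int64)
    pop = Population(haplotypes=haps, sex=_balanced_sexes(n0, rng),
                     ids=ids.take(n0), sire=minus1, dam=minus1,
                     breed="historical", generation="HG0")
    sizes = np.concatenate([
        np.full(config.phase1_generations, config.phase1_size, dtype=np.int64),
        _phase2_schedule(config),
    ])
    for g, size in enumerate(sizes, start=1):
        pop = _random_union(pop, int(size), gmap, config.mutation_rate, rng,
                            ids, "historical", f"HG{g}")
    return pop, gmap


def split_and_diverge(historical: Population, config: SimConfig,
                      rng: np.random.Generator, gmap: GeneticMap,
                      ids: _IdCounter | None = None
                      ) -> tuple[Population, Population]:
    """Found breeds A and B from the last historical generation and let
    them drift apart for ``breed_generations`` of random mating.

    The breeds start from two disjoint random samples (25 males + 25
    females each) of the 100 final historical animals.  Afterwards every
    generation 50 dams are sampled, each mated to a sire drawn from all
    males, and their litters (5 offspring per dam) keep the census at
    250.
    """
    nm, nf = config.breed_founder_males, config.breed_founder_females
    males, females = historical.males(), historical.females()
    if males.size < 2 * nm or females.size < 2 * nf:
        raise ValueError("historical population too small to found two breeds")
    if ids is None:
        ids = _IdCounter(int(historical.ids.max()) + 1)
    # Two disjoint random samples found the breeds; afterwards each
    # generation all males are eligible sires while the dam count is held
    # at config.breed_formation_dams so that the fixed litter size keeps
    # the census constant.
    perm_m = rng.permutation(males)
    perm_f = rng.permutation(females)
    breeds = []
    for k, b in enumerate("AB"):
        fm = perm_m[k * nm:(k + 1) * nm]
        ff = perm_f[k * nf:(k + 1) * nf]
        pop = historical.subset(np.concatenate([fm, ff]), generation="BF0")
        pop.breed = b
        for g in range(1, config.breed_generations + 1):
            pm, pf = pop.males(), pop.females()
            n_dams = min(config.breed_formation_dams, pf.size)
            dams = rng.choice(pf, size=n_dams, replace=False)
            pop = _litter_mating(pop, pm, dams, config.offspring_per_dam_bf,
                                 gmap, config.mutation_rate, rng, ids, b,
                                 f"BF{g}")
        breeds.append(pop)
    return breeds[0], breeds[1]


def expand(breed: Population, config: SimConfig, rng: np.random.Generator,
           gmap: GeneticMap, ids: _IdCounter | None = None) -> Population:
    """Expansion step: 100 sires and 100 dams per generation, 10 offspring
    per dam, for 8 generations.  The final generation (1000 animals) is
    the training population."""
    if breed.n < config.expansion_founder_males + config.expansion_founder_females:
        raise ValueError("breed too small for the expansion step")
    if ids is None:
        ids = _IdCounter(int(breed.ids.max()) + 1)
    pop = breed
    for g in range(1, config.expansion_generations + 1):
        pm, pf = pop.males(), pop.females()
        if pm.size < config.expansion_founder_males or \
                pf.size < config.expansion_founder_females:
            raise ValueError("not enough parental candidates during expansion")
        sires = rng.choice(pm, size=config.expansion_founder_males, replace=False)
        dams = rng.choice(pf, size=config.expansion_founder_females, replace=False)
        pop = _litter_mating(pop, sires, dams, config.offspring_per_dam_eg,
                             gmap, config.mutation_rate, rng, ids, pop.breed,
                             f"EG{g}")
    return pop


def select_panels(historical_final: Population, gmap: GeneticMap,
                  config: SimConfig, rng: np.random.Generator) -> GeneticMap:
    """Draw the 1000-SNP and 100-QTL panels from candidate loci with
    MAF >= threshold in the last historical generation."""
    freqs = historical_final.allele_frequencies()
    maf = np.minimum(freqs, 1.0 - freqs)
    qualifying = np.flatnonzero(maf >= config.maf_threshold)
    need = config.n_snp + config.n_qtl
    if qualifying.size < need:
        raise ValueError(
            f"only {qualifying.size} candidate loci have MAF >= "
            f"{config.maf_threshold} (need {need}); increase "
            "n_candidate_loci (the candidate locus multiplier)"
        )
    chosen = rng.choice(qualifying, size=need, replace=False)
    snp_idx = np.sort(chosen[: config.n_snp])
    qtl_idx = np.sort(chosen[config.n_snp:])
    return GeneticMap(positions=gmap.positions, snp_idx=snp_idx, qtl_idx=qtl_idx)


def simulate_base_populations(config: SimConfig, rng: np.random.Generator
                              ) -> tuple[Population, Population, Population, GeneticMap]:
    """Run steps 1-3 end to end.

    Returns ``(historical_final, training_A, training_B, map_with_panels)``
    where the training populations are generation 8 of the expansion.
    """
    ids = _IdCounter()
    hist, gmap = simulate_historical(config, rng, ids=ids)
    gmap = select_panels(hist, gmap, config, rng)
    breed_a, breed_b = split_and_diverge(hist, config, rng, gmap, ids=ids)
    train_a = expand(breed_a, config, rng, gmap, ids=ids)
    train_b = expand(breed_b, config, rng, gmap, ids=ids)
    return hist, train_a, train_b, gmap
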