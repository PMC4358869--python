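# crossgs

Genomic selection of purebred lines for **crossbred performance**, with
dominance, from purebred data only.

In pig and poultry production the commercial animal is a two-way cross,
but selection happens inside the purebred nucleus lines.  When dominance
drives heterosis, an animal's value as a parent of crossbreds differs
from its value as a parent of purebreds: the expected merit of its
offspring depends on the allele frequencies of the *mate* line.  With
additive and dominance SNP effects (â, d̂) estimated once from purebred
records, the breeding value of animal *i* for either goal is, per locus,

    AA : p â + q d̂
    Aa : ½(p − q) â + ½ d̂
    aa : −q â + p d̂

summed over loci, where *p* is the frequency of allele A in the line the
animal is mated to — its own line for **GEBVP** (purebred performance),
the other line for **GEBVC** (crossbred performance).  Under pure
dominance, crossbred merit decomposes as CP = BA + H with heterosis
H = Σ_l d_l (p_{A,l} − p_{B,l})².

`crossgs` implements the full simulation study around this idea:

- **`crossgs.genome`** — forward-in-time neutral simulation: 2000
  historical generations (census 2000 declining to 100), a split into
  two breeds that drift apart for 100 generations, an expansion step,
  and selection of 1000-SNP / 100-QTL panels at MAF ≥ 0.05.  Meiosis is
  Haldane (Poisson crossovers), with recurrent mutation at 2.5 × 10⁻⁴.
- **`crossgs.trait`** — QTL effects |a| ~ Gamma(0.4, 1.66) with random
  sign, dominance degrees h ~ N(0.5, 0.1), d = h|a|, rescaled exactly to
  V_A = 0.3 and V_D = 0.1 (phenotypic variance 1, h² = 0.3, H² = 0.4).
- **`crossgs.lasso`** — a Gibbs sampler for the dominance-model Bayesian
  LASSO y = μ + Xa + Zd + e (marker-specific shrinkage on a, common
  variance on d), numba-accelerated, 10 000 iterations by default.
- **`crossgs.breeding_values`** — TBVP/TBVC/GEBVP/GEBVC, their exact
  additive + dominance partition, and accuracies.
- **`crossgs.ld`** — signed r from phased haplotypes, distance-binned r²
  decay, and between-breed persistence of LD phase R_AB.
- **`crossgs.program` / `crossgs.study`** — the five selection scenarios
  (GEBVP vs GEBVC per breed × separate vs combined reference
  population), run for five generations with terminal crossbreds, under
  a low or a high LD-phase-correlation regime, with seeded replicate
  orchestration and aggregation.

## Worked example

`examples/run_selection_study.py` runs one reduced-profile replicate of
all five scenarios (three generations, short chains) and prints:

```
scenario  generation  breed_average  crossbred_mean  heterosis  acc_criterion_A  acc_criterion_B
     ref           1          0.772           1.314      0.576            0.764            0.683
     ref           2          0.979           1.599      0.540            0.662            0.679
     ref           3          1.193           1.804      0.541            0.441            0.617
       1           1          0.772           1.522      0.576            0.567            0.683
...
       2           3          1.246           2.063      0.479            0.531            0.434

r_pc among founding candidates: A 0.64, B 0.74
```

Reading it: `breed_average` is the mean phenotype of the purebred
candidates (the response to selection), `crossbred_mean` the mean
phenotype of the terminal A×B crossbreds, and `heterosis` the expected
Σ d (p_A − p_B)² at the current candidate frequencies — the crossbred
mean exceeds the breed average by roughly the heterosis plus the
selection differential carried by the selected parents.  Scenarios
selecting on GEBVC gain crossbred merit relative to the reference
scenario at some cost in purebred response, which is the study's
central trade-off; accuracies decline over generations because marker
effects are estimated only once.  (At this toy scale the numbers are
illustrative only.)  The other example scripts cover the simulator,
LD/phase-persistence analysis, the sampler, and breeding values, each
printing a few annotated numbers.

At full scale, one replicate of the published design is

```python
from crossgs import run_replicate
res = run_replicate(replicate=0, master_seed=1, regime="low")   # ~75 s
print(res.summaries)          # 5 scenarios x 5 generations
```

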