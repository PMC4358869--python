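"""One replicate of the five-scenario selection study (reduced profile).

Each scenario selects the top 100 males and 200 females per breed on
GEBVP or GEBVC (here scaled down), mates them within line, and crosses
the selected A males to the selected B females for terminal crossbreds.
Prints crossbred response, heterosis and selection accuracy per
generation; at full scale this is `run_replicate(rep, seed)` and
`run_study(n_replicates, seed)`.
"""

import pandas as pd

from crossgs import MCMCConfig, run_replicate, smoke_sim_config

res = run_replicate(0, master_seed=99, config=smoke_sim_config(),
                    mcmc=MCMCConfig(n_iter=800, burn_in=200),
                    n_generations=3)

df = res.summaries
pd.set_option("display.width", 120)
cols = ["scenario", "generation", "breed_average", "crossbred_mean",
        "heterosis", "acc_criterion_A", "acc_criterion_B"]
print(df[cols].round(3).to_string(index=False))
print()
print(f"r_pc among founding candidates: A {res.r_tbvp_tbvc['A']:.2f}, "
      f"B {res.r_tbvp_tbvc['B']:.2f}")
# breed_average tracks purebred response, crossbred_mean = breed average
# + heterosis + selection differential transmitted by the selected
# parents; scenarios selecting on GEBVC trade purebred response for
# heterosis
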