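"""Hill-number diversity partitioning of biofilm communities.

Filters a toy T-RFLP peak table to relative abundances, then partitions a
flume's community table (4 bedform microhabitats x 4 dates) into alpha,
beta and gamma components at Hill order q = 1 (exponential Shannon).
"""

import numpy as np

from flumeflux.diversity import (TrflpProfile, mean_pairwise_bc,
                                 partition_diversity, profile_to_abundances)
from flumeflux.synth import SynthConfig, gen_communities

# -- fingerprint to abundances: size window 30-900 bp, 2% height threshold
profile = TrflpProfile(fragment_sizes=[25, 120, 250, 480],
                       heights=[900.0, 500.0, 250.0, 4.0])
sizes, p = profile_to_abundances(profile)
print(f"retained fragments {sizes.astype(int).tolist()} bp "
      f"with abundances {np.round(p, 3)}")
print("(the 25 bp primer artifact and the 4-unit noise peak are gone)\n")

# -- partition one flume's communities
cfg = SynthConfig(seed=0)
for flume in (0, 5):
    table = gen_communities(cfg, flume)
    betas, bcs = [], []
    for _, day in table.data.groupby(level="date"):
        betas.append(partition_diversity(day.to_numpy(), q=1.0).beta)
        bcs.append(mean_pairwise_bc(day.to_numpy()))
    print(f"flume {flume}: beta (q=1) = {np.mean(betas):.3f} effective communities, "
          f"mean Bray-Curtis among microhabitats = {np.mean(bcs):.3f}")
print("\nbeta > 1 means the four microhabitats host distinguishable communities;")
print("the more heterogeneous flume shows the larger among-habitat turnover.")
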