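"""Windowed nucleotide diversity and the wild/farm ratio.

pi is the average pairwise difference per bp in 50 kb windows; the
ratio pi_wild / pi_farm rises above 1 where the farm line lost
diversity — at the sweep, and genome-wide from the founder bottleneck.
"""

import numpy as np

from sweepscan.dataio import PopulationPanel
from sweepscan.diversity import relative_diversity, windowed_pi
from sweepscan.simulate import SimulationConfig, simulate_two_pop

ds, truth = simulate_two_pop(
    SimulationConfig(seed=9001, genome=[("chr1", 1_500_000)],
                     sweep_loci=[("chr1", 725_000, 0.5)])
)
panel = PopulationPanel(
    populations={
        "wild": [s for s in ds.sample_ids if s.startswith("w")],
        "farm": [s for s in ds.sample_ids if s.startswith("f")],
    },
    reference="wild",
)
out = relative_diversity(windowed_pi(ds, panel), "wild", "farm")

print(out[["start", "end", "n_snps", "pi_wild", "pi_farm", "ratio"]].round(7).to_string(index=False))
sweep_bin = int(truth.sweep_loci["bin_start"].iloc[0])
row = out[out["start"] == sweep_bin].iloc[0]
print(f"\ngenome median ratio : {np.nanmedian(out['ratio']):.2f} (bottleneck-wide diversity loss)")
print(f"ratio at sweep bin  : {row['ratio']:.2f} (local loss from the selected haplotype)")
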