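"""Runs of homozygosity: F_ROH, length classes, and haplotype coalescence age.

F_ROH — the fraction of the autosomal genome in ROH of at least 100 kb —
estimates the inbreeding coefficient. Segment length dates the underlying
coalescence: the expected age of an ROH of length L Mb is g = 100/(2 r L)
generations at recombination rate r cM/Mb, so short segments reflect
historical inbreeding and long segments recent inbreeding.
"""

from pathlib import Path

from mutload import (
    SimulationConfig,
    coalescent_age,
    f_roh_table,
    load_roh,
    simulate_panel,
)

cfg = SimulationConfig(
    n_pops=6,
    n_ind_per_pop=6,
    chromosomes=[(f"LG{i}", 2_000_000) for i in range(1, 7)] + [("LG12", 1_000_000)],
    target_f_roh=[0.02, 0.1, 0.25, 0.4, 0.6, 0.8],
    seed=11,
)
sim = simulate_panel(cfg, Path("example_output/simulated"))

# round-trip through the BED reader, as one would with real caller output
roh = load_roh(sim.roh_bed_path, genome=sim.genome)
ft = f_roh_table(roh, sim.genome)
ft["population"] = [i.rsplit("_", 1)[0] for i in ft.index]
print("mean F_ROH by population and length class:")
print(ft.groupby("population").mean().round(3).to_string())

print("\nexpected coalescence age by segment length (r = 4.10 cM/Mb):")
for L in (0.1, 0.5, 1.0, 2.0, 5.0):
    print(f"  {L:4.1f} Mb -> {coalescent_age(L):6.1f} generations")
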