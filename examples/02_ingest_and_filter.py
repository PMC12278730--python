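"""Read a VCF, polarize alleles against the outgroup, and apply site filters.

Polarization re-expresses genotypes as derived-allele dosages: where the
outgroup is homozygous for the ALT allele, REF/ALT are swapped and dosages
flipped (d -> 2 - d); sites where the outgroup is heterozygous or missing
are dropped because the ancestral state is ambiguous. Filtering then masks
low-GQ genotypes and removes sites by depth, QUAL, missingness, annotation
warnings and the sex chromosome.
"""

from pathlib import Path

import pandas as pd

from mutload import FilterConfig, SimulationConfig, load_variants, simulate_panel

cfg = SimulationConfig(
    n_pops=6,
    n_ind_per_pop=6,
    chromosomes=[(f"LG{i}", 2_000_000) for i in range(1, 7)] + [("LG12", 1_000_000)],
    target_f_roh=[0.02, 0.1, 0.25, 0.4, 0.6, 0.8],
    seed=11,
)
sim = simulate_panel(cfg, Path("example_output/simulated"))

table, report = load_variants(
    sim.vcf_path, outgroup_id=cfg.outgroup_name, cfg=FilterConfig()
)

print("filter report (sites removed by each rule):")
print(report.to_string(index=False))
print(f"\nretained {table.n_sites} sites x {len(table.samples)} individuals")
print("effect classes among retained sites:")
print(pd.Series(table.effect).value_counts().to_string())
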