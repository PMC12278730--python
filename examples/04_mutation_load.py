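"""Mutation-load landscape: counts, ROH partitioning, and allele sharing.

Per individual and effect class we count derived alleles, homozygous and
heterozygous genotypes; homozygotes are then partitioned by whether they
fall inside ROH and by ROH length class, and normalized by the fraction of
the genome each partition covers. A normalized proportion above 1 means
deleterious homozygotes are enriched in that partition. The sharing
spectrum shows what fraction of a class's variants segregate in exactly k
populations — strongly deleterious variants tend to be private (k = 1).
"""

from pathlib import Path

from mutload import (
    EffectClass,
    SimulationConfig,
    count_load,
    enrichment_table,
    load_variants,
    partition_load,
    ratio_del_syn,
    sharing_spectrum,
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
table, _ = load_variants(sim.vcf_path, cfg.outgroup_name)

load = count_load(table)
print("mean load per individual, by class:")
print(load.groupby("class")[["n_alleles", "n_hom", "n_het"]].mean().round(1).to_string())

print("\nLoF/synonymous allele ratio, first 5 individuals:")
print(ratio_del_syn(load, EffectClass.LOF).head().round(4).to_string())

part = partition_load(table, sim.truth.roh, sim.genome)
enr = enrichment_table(part, sim.genome)
mis = enr[enr["class"] == "MISSENSE"]
print("\nmean missense homozygote enrichment by ROH partition:")
print(mis.groupby("partition")["enrichment"].mean().round(2).to_string())

spec = sharing_spectrum(table, sim.panel)
k1 = spec[spec["k"] == 1].set_index("class")["proportion"]
print("\nfraction of variants private to one population (k = 1):")
print(k1.round(3).to_string())
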