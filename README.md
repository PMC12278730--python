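# mutload

Mutation-load and purging analysis for panels of inbred and outbred
populations: runs of homozygosity (ROH), F_ROH, per-class derived-allele
load, the R_XY relative-load statistic with jackknife confidence intervals,
and phylogenetically corrected regressions — plus a deterministic synthetic
panel generator with known ground truth for validating every estimator.

## The science

Small, isolated populations accumulate deleterious mutations because
genetic drift overwhelms purifying selection; at the same time, inbreeding
exposes recessive deleterious alleles as homozygotes inside ROH, which can
*purge* the most harmful ones. Telling these forces apart requires careful
accounting:

- **F_ROH** (fraction of the autosome in ROH ≥ 100 kb) measures realized
  inbreeding; ROH length dates it, since an ROH of length L Mb coalesces
  ~`100/(2rL)` generations back (122 generations for 0.1 Mb, 6 for 2 Mb at
  r = 4.10 cM/Mb).
- **Load counts** per effect class (loss-of-function, missense, synonymous,
  intergenic) use derived alleles polarized against an outgroup genome,
  and partition homozygotes by ROH status: enrichment of deleterious
  homozygotes inside ROH is the signature of inbreeding exposing them.
- **R_XY** compares two populations' derived-allele burdens for a class,
  normalized by intergenic sites; R_XY < 1 means population X carries
  relatively fewer of the class's derived alleles than Y — more effective
  purifying selection or purging in X.
- **Phylogenetic GLS** regresses load on F_ROH across populations while
  accounting for their shared history via an identity-by-state
  neighbor-joining tree.

## Worked example

Simulate a 6-population panel (marine → increasingly inbred ponds), ingest
and polarize the VCF, and measure the load landscape. The scripts in
`examples/` run each step with commentary; condensed:

```python
from pathlib import Path
from mutload import (SimulationConfig, simulate_panel, load_variants,
                     f_roh_table, count_load, EffectClass, derived_freq, rxy)

cfg = SimulationConfig(
    n_pops=6, n_ind_per_pop=6,
    chromosomes=[(f"LG{i}", 2_000_000) for i in range(1, 7)] + [("LG12", 1_000_000)],
    target_f_roh=[0.02, 0.1, 0.25, 0.4, 0.6, 0.8], seed=11,
)
sim = simulate_panel(cfg, Path("example_output/simulated"))
table, report = load_variants(sim.vcf_path, cfg.outgroup_name)
print(f"retained {table.n_sites} sites x {len(table.samples)} individuals")

freqs = derived_freq(table, sim.panel)
for cls in (EffectClass.LOF, EffectClass.MISSENSE, EffectClass.SYNONYMOUS):
    r = rxy(freqs, "PON01", "MAR01", cls, seed=99)
    print(f"R_XY[{cls.value}] = {r.point:.3f} (95% CI {r.ci_low:.3f}..{r.ci_high:.3f})")
```

Output:

```
retained 12785 sites x 36 individuals
R_XY[LOF] = 0.781 (95% CI -0.130..1.692)
R_XY[MISSENSE] = 1.067 (95% CI 0.613..1.521)
R_XY[SYNONYMOUS] = 0.932 (95% CI 0.765..1.098)
```

Realized inbreeding recovered from the emitted truth BED matches the
configured targets, split by ROH length class:

```
            total  short  medium  long
LAK01        0.10  0.067   0.033   0.0
LAK02        0.25  0.151   0.099   0.0
LAK03        0.40  0.196   0.204   0.0
LAK04        0.60  0.261   0.339   0.0
MAR01        0.02  0.020   0.000   0.0
PON01        0.80  0.486   0.314   0.0
```

and the built-in patterns emerge: missense homozygotes are enriched inside
ROH (normalized proportion 2.00 in ROH vs 0.59 outside), LoF variants are
overwhelmingly private to single populations (93.8% at k = 1 vs 47.3% for
intergenic), and a phylogenetic GLS of population mean homozygote load on
F_ROH gives a strongly positive slope (3.33 ± 0.14 z-units per unit F_ROH,
p = 1.7e-05). See `examples/01_simulate_panel.py` through
`examples/06_phylo_regression.py` for the narrated versions.

## Layout

- `src/mutload/` — library: `core`, `simulate`, `ingest`, `roh`, `load`,
  `rxy`, `phylo`
- `examples/` — narrated scripts, one per capability
- `docs/methods.md` — methods note: models, conventions, design decisions,
  limitations
- `scripts/acceptance.py` — runnable acceptance report
- `tests/` — pytest suite
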