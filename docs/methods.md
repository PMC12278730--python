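# Methods

This note documents what each stage of `mutload` computes, the modelling
choices behind the synthetic data generator, and the numerical conventions,
so that results can be interpreted and reproduced without reading the code.

## Scope

`mutload` studies how inbreeding shapes the burden of deleterious variation
across populations that differ strongly in effective size — the situation of
a species fragmented into large outbred and small chronically inbred demes.
The package provides:

1. a synthetic genotype-panel generator with known ground truth,
2. VCF ingestion with ancestral-allele polarization and site filtering,
3. run-of-homozygosity (ROH) accounting and the F_ROH inbreeding estimate,
4. mutation-load counting, ROH partitioning and allele-sharing spectra,
5. the R_XY relative-load statistic with a chromosome-block jackknife,
6. phylogenetically corrected regression of load on inbreeding.

## Polarization

Derived alleles are defined against a single outgroup genome. For each
biallelic SNP:

- outgroup homozygous reference: the ALT allele is derived; dosages are kept;
- outgroup homozygous alternate: REF and ALT are swapped and each dosage `d`
  becomes `2 - d`;
- outgroup heterozygous or missing: the ancestral state is ambiguous and the
  site is dropped.

This makes "dosage" everywhere in the package mean *derived-allele dosage*.

## Effect classes

SnpEff-style `ANN` INFO strings are parsed from the first annotation entry.
Loss-of-function (LoF) is the union of `stop_gained`, `splice_donor_variant`,
`splice_acceptor_variant` and `start_lost`; `missense_variant`,
`synonymous_variant` and `intergenic_region` map to their own classes;
anything else is OTHER. Composite terms (`a&b`) match on any component.
Annotations carrying SnpEff warning flags are treated as unreliable and the
sites removed.

## Site and genotype filters

Genotypes with GQ below 20 are masked first; a site is then removed if any
of these independent rules fire: mean depth outside [8, 25]x, QUAL < 30,
more than 20% masked/missing genotypes, annotation warning, membership in a
supplied mask BED, or location on the sex chromosome (LG12 by default). The
filter report counts, per rule, how many sites that rule would remove; rules
are applied as a union so the report is order-independent.

## ROH and F_ROH

ROH are ingested from BED or `bcftools roh` RG lines (1-based inclusive,
converted to BED convention), dropped below 100 kb, and merged when
overlapping. F_ROH is ROH base pairs divided by the autosomal genome length.
Length classes partition segments exactly: SHORT (100 kb, 1 Mb), MEDIUM
[1 Mb, 2 Mb], LONG (2 Mb, ∞); placing the exact 1 Mb and 2 Mb boundaries in
MEDIUM is a convention chosen so the classes form a true partition. The
expected coalescence age of an ROH of length L Mb is `g = 100 / (2 r L)`
generations with r = 4.10 cM/Mb by default (so 0.1 Mb → ≈122 generations,
2 Mb → ≈6). The expected SNP support of a window is
`floor(window / spacing)`. A naive window-based ROH caller is included as
test plumbing only; it is not a genotype-likelihood HMM.

## Load accounting

Per individual and class we count derived alleles (`2·n_hom + n_het`),
homozygous and heterozygous sites, and callable sites; counts are NaN (not
zero) when nothing is callable. Homozygotes are partitioned into inside/
outside ROH and by ROH length class; the normalized proportion
`(n_hom_partition / n_hom_total) / f_partition` equals 1 when homozygotes
are spread uniformly, above 1 when they are enriched in the partition. It
is algebraically identical to the ratio of per-Mb densities. Undefined
cases (no homozygotes anywhere, zero-length partition) are NaN. The sharing
spectrum assigns each variant the number k of populations where its derived
allele segregates and reports, per class, the proportion of variants at
each k ≥ 1.

## R_XY

For populations X and Y and a variant category,
`L_{X not Y} = Σ f_X (1 - f_Y)` over the category's sites (and
symmetrically), each normalized by the same sum over an equal-size seeded
random subsample of intergenic sites; R_XY is the ratio of the normalized
one-sided loads. Sites with a missing frequency in either population are
excluded pairwise. R_XY < 1 indicates a relative deficit of the category's
derived alleles in X. Uncertainty comes from a delete-one-chromosome
jackknife: the four sums are accumulated per linkage group, each group is
left out in turn, pseudo-values `θ_j = nθ̂ - (n-1)θ̂_(-j)` give
`SE = sd(pseudo)/√n` and a normal-approximation CI `θ̂ ± 1.96·SE`. The
neutral reference is configurable (class, mask over genomic intervals,
number of subsample draws to average).

## Phylogenetic regression

Identity-by-state distance between two individuals is the mean of
`|d_i - d_j| / 2` over shared non-missing sites. A neighbor-joining tree is
built from the distance matrix and rooted on the outgroup branch; the root
bisects that branch so tip-to-tip path lengths are preserved, and negative
NJ branch lengths are clamped to zero with a warning. The phylogenetic
variance-covariance matrix takes `V[i, j]` as the root-to-MRCA shared
branch length, which is positive semidefinite for non-negative branch
lengths. The regression of a load metric on F_ROH is a closed-form
generalized least squares with that covariance (Cholesky whitening,
residual-variance scaling, two-sided t-test on the slope). This replaces a
Bayesian phylogenetic mixed model deliberately: for a single Gaussian
response with fixed V, GLS estimates the same fixed-effect slope
deterministically, which makes the result exactly reproducible and testable
against ordinary least squares in the V = I limit. The response is z-scored
by default so slopes are comparable across load metrics. For rank analyses
on very few populations an exact Spearman permutation test (3 ≤ n ≤ 8, no
ties) enumerates all n! rank permutations.

## Synthetic panel generator

The generator is the package's ground-truth instrument, not a population
genetics simulator. Default configuration: 17 populations (1 marine, 4
lake, 12 pond) of 12 individuals, 21 chromosomes of 5 Mb with LG12 as the
sex chromosome, per-population target F_ROH spanning ~0.015–0.91
geometrically (marine lowest, ponds highest), and one outgroup sample.

- **ROH placement.** Segments are drawn from a length mixture (50% 0.1–1 Mb,
  25% 1–2 Mb, 25% 2–5 Mb), placed without overlap into free gaps, trimmed
  or stretched so realized coverage matches the target within 2%; an
  unattainable target fails loudly naming the population.
- **Genotypes.** Each class's per-population derived-allele frequencies are
  Beta draws (LoF strongly skewed to 0, synonymous/intergenic milder), with
  a per-class probability that a variant also segregates in other
  populations (LoF mostly private). Outside ROH genotypes are
  Hardy–Weinberg `Binomial(2, f)` draws; inside ROH the two haplotypes are
  identical by descent, so the genotype is `2·Bernoulli(f)`. This is what
  makes homozygote enrichment in ROH a built-in truth.
- **Outgroup and noise.** The outgroup is homozygous ancestral except at
  configured rates of heterozygous (dropped by polarization) and
  homozygous-derived sites; for the latter the VCF REF is the derived
  allele, so the polarizer must swap them — the round trip is exact on
  noise-free data. Genotype errors, missingness, low-GQ and low-QUAL sites,
  depth outliers and annotation warnings are injected at configurable rates
  to give the filter stage material.
- **Determinism.** Identical config + seed produces byte-identical VCF/BED
  output. All randomness flows from one `numpy` generator.

What the generator does **not** model: linkage disequilibrium outside ROH,
realistic site-frequency spectra from demography, selection dynamics, gene
conversion, sequencing-error haplotype structure. Conclusions from the
synthetic panel are about the *estimators*, not about biology.

## Numerical conventions

- Missing genotype is -1 in all dosage matrices; frequencies and counts are
  missing-aware (denominators shrink, never silently zero).
- Undefined ratios are NaN, never 0.
- BED intervals are 0-based half-open; VCF positions 1-based.
- Seeds are explicit arguments everywhere randomness occurs; no global
  state.
- The acceptance script (`scripts/acceptance.py`) recomputes its reported
  quantities at runtime; nothing is hard-coded beyond the closed-form
  worked examples' inputs.

## Known limitations

- The jackknife CI is a normal approximation; with few linkage groups or
  few sites per group its coverage degrades (the acceptance suite checks
  coverage in an asymptotically reasonable regime: 21 blocks × 40 sites).
- The GLS assumes a Gaussian response and a known V up to scale; it does not
  propagate uncertainty in the tree.
- The naive ROH caller is for test fixtures; use a dedicated caller
  (e.g. `bcftools roh`) on real data and ingest its output.
- `spearman_exact` enumerates n! permutations and is limited to n ≤ 8.
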