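"""Synthetic multi-population genotype panels with known truth.

The generator emulates the statistical structure of a highly replicated
resequencing study of marine/lake/pond stickleback populations: per-effect
class derived-allele frequency spectra skewed by selection strength (LoF
rarest), a mix of private and shared variants, per-individual ROH coverage
spanning nearly the full [0, 1] range, a single diploid outgroup, and
genotype-level noise (errors, missingness, low GQ/QUAL, depth outliers) so
that the filtering stage has material to act on.

Within an ROH the two haplotypes are identical by descent, so the genotype
is twice a single Bernoulli(f) haplotype draw; outside ROH genotypes are
Hardy-Weinberg Binomial(2, f) draws, with f the population's derived-allele
frequency at the site. Selection is encoded implicitly through the per-class
Beta frequency parameters and sharing fractions, not via explicit s and h.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import MISSING, EffectClass, GenomeDef, PopulationPanel, VariantTable
from .roh import MIN_ROH_LEN, ROHSet

_BASES = np.array(["A", "C", "G", "T"])

_LOF_TERMS = ["stop_gained", "splice_donor_variant", "splice_acceptor_variant", "start_lost"]
_TERMS = {
    EffectClass.LOF.value: (_LOF_TERMS, "HIGH"),
    EffectClass.MISSENSE.value: (["missense_variant"], "MODERATE"),
    EffectClass.SYNONYMOUS.value: (["synonymous_variant"], "LOW"),
    EffectClass.INTERGENIC.value: (["intergenic_region"], "MODIFIER"),
    EffectClass.OTHER.value: (["downstream_gene_variant", "upstream_gene_variant"], "MODIFIER"),
}


class SimulationError(RuntimeError):
    """Raised when a configuration cannot be realized (e.g. unattainable F_ROH)."""


@dataclass
class SimulationConfig:
    """Parameters of a synthetic panel; identical config + seed => byte-identical output."""

    n_pops: int = 17
    n_ind_per_pop: int = 12
    #: (name, length bp); the sex chromosome is excluded from ROH placement
    #: and from the F_ROH denominator but still receives variant sites.
    chromosomes: list[tuple[str, int]] = field(
        default_factory=lambda: [(f"LG{i}", 5_000_000) for i in range(1, 22)]
    )
    sex_chromosome: str | None = "LG12"
    #: per-population genome fraction in ROH; default ramps over the
    #: observed study range 0.015-0.912.
    target_f_roh: list[float] = field(default_factory=list)
    #: (weight, min bp, max bp) per ROH length stratum.
    roh_length_mix: list[tuple[float, int, int]] = field(
        default_factory=lambda: [
            (0.50, 100_000, 1_000_000),
            (0.25, 1_000_000, 2_000_000),
            (0.25, 2_000_000, 5_000_000),
        ]
    )
    class_site_counts: dict[str, int] = field(
        default_factory=lambda: {
            "LOF": 400, "MISSENSE": 3000, "SYNONYMOUS": 3000,
            "INTERGENIC": 8000, "OTHER": 200,
        }
    )
    #: Beta(a, b) for population derived-allele frequencies; LoF most skewed
    #: toward 0 (strongest selection), synonymous tracking intergenic.
    class_freq_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "LOF": (0.2, 5.0), "MISSENSE": (0.35, 3.5),
            "SYNONYMOUS": (0.6, 2.0), "INTERGENIC": (0.6, 2.0),
            "OTHER": (0.6, 2.0),
        }
    )
    #: probability a variant segregates in more than one population.
    sharing_fraction: dict[str, float] = field(
        default_factory=lambda: {
            "LOF": 0.30, "MISSENSE": 0.40, "SYNONYMOUS": 0.70,
            "INTERGENIC": 0.75, "OTHER": 0.70,
        }
    )
    #: given sharing, each further population carries the variant with this probability.
    sharing_spread: float = 0.25
    outgroup_het_rate: float = 0.02
    outgroup_derived_rate: float = 0.05
    genotype_error_rate: float = 0.002
    missing_rate: float = 0.01
    low_gq_rate: float = 0.02
    low_qual_rate: float = 0.01
    depth_outlier_rate: float = 0.02
    ann_warning_rate: float = 0.01
    mean_depth: float = 15.0
    outgroup_name: str = "OUT"
    pop_names: list[str] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.target_f_roh:
            # geometric ramp over the study's observed F_ROH span
            self.target_f_roh = [
                float(x) for x in np.geomspace(0.015, 0.912, self.n_pops)
            ]
        if not self.pop_names:
            habs = self._habitats()
            counters: dict[str, int] = {}
            names = []
            for h in habs:
                counters[h] = counters.get(h, 0) + 1
                names.append(f"{h[:3].upper()}{counters[h]:02d}")
            self.pop_names = names
        self._validate()

    def _habitats(self) -> list[str]:
        """1 marine + up to 4 lake populations, the remainder ponds."""
        habs = []
        for i in range(self.n_pops):
            if i == 0:
                habs.append("marine")
            elif i <= min(4, self.n_pops - 1):
                habs.append("lake")
            else:
                habs.append("pond")
        return habs

    def _validate(self) -> None:
        if self.n_pops < 1 or self.n_ind_per_pop < 1:
            raise ValueError("need at least one population and one individual")
        if len(self.target_f_roh) != self.n_pops:
            raise ValueError("target_f_roh must have one entry per population")
        if len(self.pop_names) != self.n_pops:
            raise ValueError("pop_names must have one entry per population")
        rates = {
            "sharing_spread": self.sharing_spread,
            "outgroup_het_rate": self.outgroup_het_rate,
            "outgroup_derived_rate": self.outgroup_derived_rate,
            "genotype_error_rate": self.genotype_error_rate,
            "missing_rate": self.missing_rate,
            "low_gq_rate": self.low_gq_rate,
            "low_qual_rate": self.low_qual_rate,
            "depth_outlier_rate": self.depth_outlier_rate,
            "ann_warning_rate": self.ann_warning_rate,
            **{f"sharing_fraction[{k}]": v for k, v in self.sharing_fraction.items()},
            **{f"target_f_roh[{i}]": v for i, v in enumerate(self.target_f_roh)},
        }
        for name, v in rates.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if any(n < 0 for n in self.class_site_counts.values()):
            raise ValueError("site counts must be non-negative")
        if any(ln <= 0 for _, ln in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")
        if self.outgroup_het_rate + self.outgroup_derived_rate > 1.0:
            raise ValueError("outgroup het + derived rates exceed 1")
        w = sum(w for w, _, _ in self.roh_length_mix)
        if w <= 0 or any(lo <= 0 or hi < lo for _, lo, hi in self.roh_length_mix):
            raise ValueError("invalid roh_length_mix")

    @property
    def autosomes(self) -> GenomeDef:
        return GenomeDef(
            {n: ln for n, ln in self.chromosomes if n != self.sex_chromosome}
        )


@dataclass
class TruthRecord:
    """Ground truth emitted next to the synthetic VCF."""

    roh: ROHSet  # per-individual true ROH intervals
    site_class: np.ndarray  # per-site effect class (str), VCF site order
    chrom: np.ndarray
    pos: np.ndarray
    freqs: pd.DataFrame  # per-population true derived-allele frequencies
    dosage: np.ndarray  # error-free derived dosages, (n_sites, n_individuals)
    samples: list[str]

    def as_variant_table(self) -> VariantTable:
        """Error-free polarized table (bypasses VCF round trip) for testing."""
        n = len(self.pos)
        return VariantTable(
            chrom=self.chrom,
            pos=self.pos,
            ref=np.full(n, "A", dtype=object),
            alt=np.full(n, "T", dtype=object),
            effect=self.site_class,
            dosage=self.dosage,
            samples=list(self.samples),
        )


@dataclass
class SimulatedPanel:
    config: SimulationConfig
    truth: TruthRecord
    panel: PopulationPanel
    genome: GenomeDef
    vcf_path: Path
    roh_bed_path: Path
    panel_path: Path
    config_path: Path


def _place_roh(
    rng: np.random.Generator,
    genome: GenomeDef,
    target: float,
    mix: list[tuple[float, int, int]],
    label: str,
    min_seg: int = MIN_ROH_LEN,
    tol: float = 0.02,
) -> list[tuple[str, int, int]]:
    """Place non-overlapping segments until the covered fraction reaches target.

    Segments are drawn from the length mixture and dropped uniformly into
    free gaps (gap chosen with probability proportional to the number of
    valid offsets). The last segment is trimmed to hit the target exactly
    when the trim leaves it above the minimum length.
    """
    if target == 0.0:
        return []
    gaps: dict[str, list[tuple[int, int]]] = {n: [(0, L)] for n, L in genome.lengths.items()}
    G = genome.total
    target_bp = int(round(target * G))
    weights = np.array([w for w, _, _ in mix], dtype=float)
    weights /= weights.sum()
    segs: list[tuple[str, int, int]] = []
    covered = 0
    while covered < target_bp:
        if target_bp - covered < min_seg:
            # remainder below segment granularity: absorb it by stretching an
            # existing segment into an adjacent free gap where possible
            covered += _extend_segments(segs, gaps, target_bp - covered)
            break
        k = rng.choice(len(mix), p=weights)
        length = int(rng.integers(mix[k][1], mix[k][2] + 1))
        cand = [
            (chrom, gi, ge - gs)
            for chrom, glist in gaps.items()
            for gi, (gs, ge) in enumerate(glist)
            if ge - gs >= length
        ]
        if not cand:
            largest = max(
                (ge - gs for gl in gaps.values() for gs, ge in gl), default=0
            )
            if largest < min_seg:
                break  # genome saturated at this granularity
            length = int(rng.integers(min_seg, largest + 1))
            cand = [
                (chrom, gi, ge - gs)
                for chrom, glist in gaps.items()
                for gi, (gs, ge) in enumerate(glist)
                if ge - gs >= length
            ]
        if covered + length > target_bp and (length - (covered + length - target_bp)) >= min_seg:
            length -= covered + length - target_bp
        w = np.array([gl - length + 1 for _, _, gl in cand], dtype=float)
        chrom, gi, _ = cand[rng.choice(len(cand), p=w / w.sum())]
        gs, ge = gaps[chrom][gi]
        start = int(rng.integers(gs, ge - length + 1))
        end = start + length
        segs.append((chrom, start, end))
        new = []
        if start - gs > 0:
            new.append((gs, start))
        if ge - end > 0:
            new.append((end, ge))
        gaps[chrom][gi : gi + 1] = new
        covered += length
    realized = covered / G
    if abs(realized - target) > tol:
        raise SimulationError(
            f"target F_ROH {target:.3f} unattainable for {label}: "
            f"reached {realized:.3f} given chromosome lengths and segment mix"
        )
    return segs


def _extend_segments(
    segs: list[tuple[str, int, int]],
    gaps: dict[str, list[tuple[int, int]]],
    remainder: int,
) -> int:
    """Stretch placed segments into adjacent gaps to absorb ``remainder`` bp."""
    absorbed = 0
    for si in range(len(segs) - 1, -1, -1):
        if absorbed >= remainder:
            break
        chrom, start, end = segs[si]
        for gi, (gs, ge) in enumerate(gaps[chrom]):
            need = remainder - absorbed
            if gs == end:  # gap immediately after the segment
                take = min(need, ge - gs)
                segs[si] = (chrom, start, end + take)
                gaps[chrom][gi] = (gs + take, ge)
            elif ge == start:  # gap immediately before
                take = min(need, ge - gs)
                segs[si] = (chrom, start - take, end)
                gaps[chrom][gi] = (gs, ge - take)
            else:
                continue
            gaps[chrom] = [(a, b) for a, b in gaps[chrom] if b > a]
            absorbed += take
            break
    return absorbed


def _draw_sites(
    rng: np.random.Generator, cfg: SimulationConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique (chrom, pos, class) triples sorted in VCF order."""
    names = [n for n, _ in cfg.chromosomes]
    lens = np.array([ln for _, ln in cfg.chromosomes], dtype=float)
    p = lens / lens.sum()
    chroms, poss, classes = [], [], []
    taken: dict[str, set[int]] = {n: set() for n in names}
    for cls, count in cfg.class_site_counts.items():
        placed = 0
        while placed < count:
            ci = rng.choice(len(names), p=p)
            pos = int(rng.integers(1, int(lens[ci]) + 1))
            if pos in taken[names[ci]]:
                continue
            taken[names[ci]].add(pos)
            chroms.append(names[ci])
            poss.append(pos)
            classes.append(cls)
            placed += 1
    chrom_rank = {n: i for i, n in enumerate(names)}
    order = np.lexsort((np.array(poss), np.array([chrom_rank[c] for c in chroms])))
    return (
        np.array(chroms, dtype=object)[order],
        np.array(poss, dtype=np.int64)[order],
        np.array(classes, dtype=object)[order],
    )


def _draw_freqs(
    rng: np.random.Generator, cfg: SimulationConfig, classes: np.ndarray
) -> np.ndarray:
    """Per-site per-population true derived-allele frequencies."""
    n_sites = len(classes)
    F = np.zeros((n_sites, cfg.n_pops))
    for i, cls in enumerate(classes):
        a, b = cfg.class_freq_params[cls]
        primary = rng.integers(cfg.n_pops)
        carriers = {int(primary)}
        if cfg.n_pops > 1 and rng.random() < cfg.sharing_fraction[cls]:
            extra = [
                j for j in range(cfg.n_pops)
                if j != primary and rng.random() < cfg.sharing_spread
            ]
            if not extra:
                choices = [j for j in range(cfg.n_pops) if j != primary]
                extra = [int(rng.choice(choices))]
            carriers.update(extra)
        for j in carriers:
            F[i, j] = rng.beta(a, b)
    return F


def _ann_string(rng: np.random.Generator, cls: str, alt: str, warn: bool) -> str:
    terms, impact = _TERMS[cls]
    term = terms[int(rng.integers(len(terms)))]
    gene = f"GENE{int(rng.integers(1, 5000)):04d}"
    warning = "WARNING_TRANSCRIPT_INCOMPLETE" if warn else ""
    return f"{alt}|{term}|{impact}|{gene}|{gene}|transcript|TR1|protein_coding|1/1|c.1A>G||||||{warning}"


def simulate_panel(cfg: SimulationConfig, outdir: str | Path) -> SimulatedPanel:
    """Generate the panel and write VCF, truth ROH BED, panel TSV and config YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    genome = cfg.autosomes

    habitats = cfg._habitats()
    individuals = [
        f"{cfg.pop_names[p]}_{i:02d}"
        for p in range(cfg.n_pops)
        for i in range(cfg.n_ind_per_pop)
    ]
    pop_of = np.repeat(np.arange(cfg.n_pops), cfg.n_ind_per_pop)

    # N_e panel annotations: larger outbred populations have larger N_e;
    # ranks follow the (ascending) target F_ROH so inbreeding and N_e are
    # negatively associated, as in the study system.
    rank = np.argsort(np.argsort(cfg.target_f_roh))
    ne_hist = np.geomspace(20_000, 50, cfg.n_pops)[rank]
    ne_now = np.round(ne_hist * rng.uniform(0.3, 0.7, cfg.n_pops), 1)
    ne_hist = np.round(ne_hist, 1)

    # --- ROH truth ------------------------------------------------------
    roh_rows = []
    for idx, ind in enumerate(individuals):
        target = cfg.target_f_roh[pop_of[idx]]
        for chrom, s, e in _place_roh(
            rng, genome, target, cfg.roh_length_mix,
            label=f"{cfg.pop_names[pop_of[idx]]} ({ind})",
        ):
            roh_rows.append((ind, chrom, s, e))
    truth_roh = ROHSet(
        pd.DataFrame(roh_rows, columns=list(ROHSet.COLUMNS))
        if roh_rows
        else pd.DataFrame(columns=list(ROHSet.COLUMNS))
    )

    # --- sites, frequencies, genotypes ---------------------------------
    chrom, pos, classes = _draw_sites(rng, cfg)
    n_sites = len(pos)
    F = _draw_freqs(rng, cfg, classes)

    anc = _BASES[rng.integers(0, 4, n_sites)]
    der = np.array(
        [rng.choice([b for b in _BASES if b != a]) for a in anc], dtype=object
    )

    truth_dosage = np.zeros((n_sites, len(individuals)), dtype=np.int8)
    vcf_dosage = np.zeros((n_sites, len(individuals)), dtype=np.int8)
    pos0 = pos - 1
    for idx, ind in enumerate(individuals):
        f = F[:, pop_of[idx]]
        inroh = np.zeros(n_sites, dtype=bool)
        segs = truth_roh.for_individual(ind)
        for c, grp in segs.groupby("chrom", sort=False):
            cmask = chrom == c
            starts = np.sort(grp["start"].to_numpy())
            ends = grp.sort_values("start")["end"].to_numpy()
            gi = np.searchsorted(starts, pos0[cmask], side="right") - 1
            hit = gi >= 0
            hit[hit] = pos0[cmask][hit] < ends[gi[hit]]
            inroh[cmask] = hit
        g = np.where(
            inroh,
            2 * (rng.random(n_sites) < f).astype(np.int8),
            rng.binomial(2, f).astype(np.int8),
        ).astype(np.int8)
        truth_dosage[:, idx] = g
        gv = g.copy()
        err = rng.random(n_sites) < cfg.genotype_error_rate
        if err.any():
            flip_to = np.where(gv == 1, 2 * rng.integers(0, 2, n_sites), 1)
            gv[err] = flip_to[err].astype(np.int8)
        miss = rng.random(n_sites) < cfg.missing_rate
        gv[miss] = MISSING
        vcf_dosage[:, idx] = gv

    # --- outgroup and REF/ALT orientation -------------------------------
    u = rng.random(n_sites)
    og_het = u < cfg.outgroup_het_rate
    og_derived = (~og_het) & (u < cfg.outgroup_het_rate + cfg.outgroup_derived_rate)
    # At outgroup-homozygous-derived sites the reference genome carries the
    # derived allele: REF/ALT are flipped relative to ancestral/derived and
    # the polarization stage must swap them back.
    ref = np.where(og_derived, der, anc)
    alt = np.where(og_derived, anc, der)
    vcf_out = vcf_dosage.copy()
    flip = og_derived[:, None] & (vcf_out >= 0)
    vcf_out = np.where(flip, 2 - vcf_out, vcf_out).astype(np.int8)
    og_gt = np.where(og_het, "0/1", np.where(og_derived, "1/1", "0/0"))

    # --- site/genotype quality fields -----------------------------------
    qual = np.round(rng.uniform(100, 1000, n_sites), 1)
    lowq = rng.random(n_sites) < cfg.low_qual_rate
    qual[lowq] = np.round(rng.uniform(5, 29.9, lowq.sum()), 1)
    warn = rng.random(n_sites) < cfg.ann_warning_rate

    depth_mean = np.full(n_sites, cfg.mean_depth)
    outlier = rng.random(n_sites) < cfg.depth_outlier_rate
    high = rng.random(n_sites) < 0.5
    depth_mean[outlier & high] = cfg.mean_depth * 3.0
    depth_mean[outlier & ~high] = cfg.mean_depth * 0.25

    n_cols = len(individuals) + 1  # + outgroup
    gq = np.clip(rng.normal(70, 15, (n_sites, n_cols)).astype(int), 20, 99)
    low_gq = rng.random((n_sites, n_cols)) < cfg.low_gq_rate
    gq[low_gq] = rng.integers(2, 20, low_gq.sum())
    dp = rng.poisson(depth_mean[:, None], (n_sites, n_cols)).astype(int)

    anns = np.array(
        [_ann_string(rng, classes[i], str(alt[i]), bool(warn[i])) for i in range(n_sites)],
        dtype=object,
    )

    # --- write outputs ---------------------------------------------------
    vcf_path = outdir / "panel.vcf"
    _write_vcf(
        vcf_path, cfg, chrom, pos, ref, alt, qual, anns,
        vcf_out, og_gt, gq, dp, individuals,
    )
    roh_bed_path = outdir / "roh_truth.bed"
    truth_roh.to_bed(roh_bed_path)

    panel_df = pd.DataFrame(
        {
            "individual": individuals + [cfg.outgroup_name],
            "population": [cfg.pop_names[p] for p in pop_of] + [cfg.outgroup_name],
            "habitat": [habitats[p] for p in pop_of] + ["outgroup"],
            "ne_hist": [ne_hist[p] for p in pop_of] + [np.nan],
            "ne_now": [ne_now[p] for p in pop_of] + [np.nan],
        }
    )
    panel = PopulationPanel(panel_df)
    panel_path = outdir / "panel.tsv"
    panel.to_tsv(panel_path)

    config_path = outdir / "config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)

    freqs = pd.DataFrame(F, columns=cfg.pop_names)
    freqs.insert(0, "chrom", chrom)
    freqs.insert(1, "pos", pos)
    freqs.insert(2, "class", classes)
    freqs.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)

    truth = TruthRecord(
        roh=truth_roh,
        site_class=classes,
        chrom=chrom,
        pos=pos,
        freqs=freqs,
        dosage=truth_dosage,
        samples=individuals,
    )
    return SimulatedPanel(
        config=cfg,
        truth=truth,
        panel=panel,
        genome=genome,
        vcf_path=vcf_path,
        roh_bed_path=roh_bed_path,
        panel_path=panel_path,
        config_path=config_path,
    )


_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def _write_vcf(
    path: Path,
    cfg: SimulationConfig,
    chrom, pos, ref, alt, qual, anns, vcf_dosage, og_gt, gq, dp,
    individuals: list[str],
) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=mutload.simulate\n")
        for name, ln in cfg.chromosomes:
            fh.write(f"##contig=<ID={name},length={ln}>\n")
        fh.write(
            '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations: '
            "'Allele|Annotation|Impact|Gene_Name|Gene_ID|Feature_Type|Feature_ID|"
            "Transcript_BioType|Rank|HGVS.c|HGVS.p|cDNA|CDS|AA|Distance|"
            "Errors_Warnings'\">\n"
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        cols = individuals + [cfg.outgroup_name]
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(cols) + "\n"
        )
        n_ind = len(individuals)
        for i in range(len(pos)):
            fields = [
                str(chrom[i]), str(int(pos[i])), ".", str(ref[i]), str(alt[i]),
                f"{qual[i]:.1f}", "PASS", f"ANN={anns[i]}", "GT:GQ:DP",
            ]
            for j in range(n_ind):
                fields.append(
                    f"{_GT[int(vcf_dosage[i, j])]}:{gq[i, j]}:{dp[i, j]}"
                )
            fields.append(f"{og_gt[i]}:{gq[i, n_ind]}:{dp[i, n_ind]}")
            fh.write("\t".join(fields) + "\n")
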