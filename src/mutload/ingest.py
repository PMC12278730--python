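"""VCF ingestion: effect classification, outgroup polarization, site filters.

The pipeline is read -> polarize -> filter. Polarization re-orients each
biallelic SNP so that dosages count the derived allele, using a single
outgroup individual to determine the ancestral state: if the outgroup is
homozygous reference the reference allele is ancestral and nothing changes;
if it is homozygous alternate, REF/ALT labels are swapped and every dosage
d becomes 2 - d; heterozygous or missing outgroup genotypes leave the
ancestral state indeterminable and the site is dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import (
    LOF_TERMS,
    MISSING,
    EffectClass,
    VariantTable,
    merge_intervals,
    points_in_intervals,
)

logger = logging.getLogger(__name__)


def classify_effect(ann: str | None) -> EffectClass:
    """Map a SnpEff-style ANN entry to an effect class.

    Uses the first (most severe) effect term of the first annotation.
    Empty or unparseable ANN values fall back to OTHER.
    """
    if not ann:
        return EffectClass.OTHER
    first = ann.split(",")[0]
    parts = first.split("|")
    term = parts[1] if len(parts) > 1 else parts[0]
    # composite terms like "splice_donor_variant&intron_variant"
    for t in term.split("&"):
        if t in LOF_TERMS:
            return EffectClass.LOF
    lead = term.split("&")[0]
    if lead == "missense_variant":
        return EffectClass.MISSENSE
    if lead == "synonymous_variant":
        return EffectClass.SYNONYMOUS
    if lead == "intergenic_region":
        return EffectClass.INTERGENIC
    return EffectClass.OTHER


@dataclass
class FilterConfig:
    """Site and genotype quality thresholds.

    Defaults follow common resequencing practice for ~10-20x genomes:
    mean depth within [8, 25]x, genotype quality >= 20 (failing genotypes
    are masked, not the whole site), site QUAL >= 30, at most 20% missing
    genotypes after GQ masking, and exclusion of masked intervals and the
    sex chromosome.
    """

    depth_min: float = 8.0
    depth_max: float = 25.0
    gq_min: int = 20
    qual_min: float = 30.0
    max_missing: float = 0.20
    excluded_chroms: tuple[str, ...] = ("LG12",)

    def __post_init__(self) -> None:
        if self.depth_min >= self.depth_max:
            raise ValueError("depth_min must be below depth_max")
        if min(self.depth_min, self.gq_min, self.qual_min, self.max_missing) < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass
class VcfData:
    """Raw biallelic-SNP records straight from a VCF (dosages count ALT)."""

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    qual: np.ndarray
    effect: np.ndarray
    ann_warning: np.ndarray
    dosage: np.ndarray  # (n_sites, n_samples), ALT-allele dosage, MISSING for no-call
    gq: np.ndarray
    dp: np.ndarray
    samples: list[str]
    n_excluded_multiallelic: int = 0

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def subset(self, mask: np.ndarray) -> "VcfData":
        return VcfData(
            chrom=self.chrom[mask], pos=self.pos[mask], ref=self.ref[mask],
            alt=self.alt[mask], qual=self.qual[mask], effect=self.effect[mask],
            ann_warning=self.ann_warning[mask], dosage=self.dosage[mask],
            gq=self.gq[mask], dp=self.dp[mask], samples=list(self.samples),
            n_excluded_multiallelic=self.n_excluded_multiallelic,
        )


def read_vcf(path: str | Path) -> VcfData:
    """Read biallelic SNPs with GT/GQ/DP and ANN; skip multiallelic/symbolic sites."""
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    chroms, poss, refs, alts, quals, effects, warns = [], [], [], [], [], [], []
    dosages, gqs, dps = [], [], []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1 or v.ALT[0].startswith("<") or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_multi += 1
            continue
        ann = v.INFO.get("ANN")
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        quals.append(v.QUAL if v.QUAL is not None else np.nan)
        effects.append(classify_effect(ann).value)
        warns.append(bool(ann) and "WARNING" in ann)
        gt = v.gt_types.astype(np.int8)  # 0 homref, 1 het, 2 homalt, 3 unknown
        gt[gt == 3] = MISSING
        dosages.append(gt)
        g = v.format("GQ")
        d = v.format("DP")
        gqs.append(
            g[:, 0].astype(np.int32) if g is not None
            else np.full(len(samples), 99, dtype=np.int32)
        )
        dps.append(
            d[:, 0].astype(np.int32) if d is not None
            else np.full(len(samples), 0, dtype=np.int32)
        )
    if n_multi:
        logger.info("excluded %d multiallelic/symbolic/non-SNP sites", n_multi)
    n = len(poss)
    return VcfData(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        qual=np.array(quals, dtype=float),
        effect=np.array(effects, dtype=object),
        ann_warning=np.array(warns, dtype=bool),
        dosage=(
            np.vstack(dosages) if n else np.empty((0, len(samples)), dtype=np.int8)
        ),
        gq=np.vstack(gqs) if n else np.empty((0, len(samples)), dtype=np.int32),
        dp=np.vstack(dps) if n else np.empty((0, len(samples)), dtype=np.int32),
        samples=samples,
        n_excluded_multiallelic=n_multi,
    )


def polarize_sites(data: VcfData, outgroup_id: str) -> VcfData:
    """Re-orient dosages to count the derived allele; drop the outgroup column.

    Sites where the outgroup is heterozygous or missing are removed. Where
    the outgroup is homozygous ALT, REF/ALT labels are swapped and every
    dosage d becomes 2 - d (missing stays missing).
    """
    if outgroup_id not in data.samples:
        raise ValueError(f"outgroup {outgroup_id!r} not among VCF samples")
    oi = data.samples.index(outgroup_id)
    og = data.dosage[:, oi]
    keep = (og == 0) | (og == 2)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("dropped %d sites with heterozygous/missing outgroup", n_drop)
    sub = data.subset(keep)
    og = og[keep]
    swap = og == 2
    cols = [i for i in range(len(data.samples)) if i != oi]
    dosage = sub.dosage[:, cols].copy()
    valid = dosage >= 0
    dosage[swap[:, None] & valid] = 2 - dosage[swap[:, None] & valid]
    ref = sub.ref.copy()
    alt = sub.alt.copy()
    ref[swap], alt[swap] = sub.alt[swap], sub.ref[swap]
    return VcfData(
        chrom=sub.chrom, pos=sub.pos, ref=ref, alt=alt, qual=sub.qual,
        effect=sub.effect, ann_warning=sub.ann_warning, dosage=dosage,
        gq=sub.gq[:, cols], dp=sub.dp[:, cols],
        samples=[data.samples[i] for i in cols],
        n_excluded_multiallelic=sub.n_excluded_multiallelic,
    )


def read_mask_bed(path: str | Path) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Read a BED mask into per-chromosome merged interval arrays."""
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                if end <= start:
                    raise ValueError("end <= start")
            except (IndexError, ValueError) as exc:
                raise ValueError(f"malformed BED line {lineno} in {path}: {exc}") from exc
            per_chrom.setdefault(chrom, []).append((start, end))
    return {
        c: merge_intervals(
            np.array([s for s, _ in iv]), np.array([e for _, e in iv])
        )
        for c, iv in per_chrom.items()
    }


def filter_sites(
    data: VcfData,
    cfg: FilterConfig,
    masks: list[dict[str, tuple[np.ndarray, np.ndarray]]] | None = None,
) -> tuple[VariantTable, pd.DataFrame]:
    """Apply genotype GQ masking and then site-level filters.

    Genotypes with GQ below ``cfg.gq_min`` are set to missing first; sites
    are then removed when the mean per-sample depth falls outside
    [depth_min, depth_max], QUAL < qual_min, the post-masking missingness
    exceeds ``max_missing``, the position lies in a mask interval, the
    annotation carries a warning, or the chromosome is excluded. Returns
    the surviving polarized table and a per-rule removal tally (rules
    evaluated independently: a site may count against several rules).
    """
    dosage = data.dosage.copy()
    n_gq_masked = int(((data.gq < cfg.gq_min) & (dosage >= 0)).sum())
    dosage[data.gq < cfg.gq_min] = MISSING

    n_sites, n_samples = dosage.shape
    mean_dp = data.dp.mean(axis=1) if n_samples else np.zeros(n_sites)
    fail_depth = (mean_dp < cfg.depth_min) | (mean_dp > cfg.depth_max)
    fail_qual = ~(data.qual >= cfg.qual_min)  # NaN QUAL fails
    missing_frac = (dosage == MISSING).mean(axis=1)
    fail_missing = missing_frac > cfg.max_missing
    fail_warn = data.ann_warning.copy()
    fail_chrom = np.isin(data.chrom, list(cfg.excluded_chroms))
    fail_mask = np.zeros(n_sites, dtype=bool)
    for mask in masks or []:
        for chrom, (starts, ends) in mask.items():
            cmask = data.chrom == chrom
            fail_mask[cmask] |= points_in_intervals(
                data.pos[cmask] - 1, starts, ends
            )

    keep = ~(fail_depth | fail_qual | fail_missing | fail_warn | fail_chrom | fail_mask)
    report = pd.DataFrame(
        {
            "rule": [
                "multiallelic_or_non_snp", "genotypes_gq_masked", "depth", "qual",
                "missingness", "ann_warning", "excluded_chrom", "mask", "retained",
            ],
            "count": [
                data.n_excluded_multiallelic, n_gq_masked, int(fail_depth.sum()),
                int(fail_qual.sum()), int(fail_missing.sum()), int(fail_warn.sum()),
                int(fail_chrom.sum()), int(fail_mask.sum()), int(keep.sum()),
            ],
        }
    )
    table = VariantTable(
        chrom=data.chrom[keep], pos=data.pos[keep], ref=data.ref[keep],
        alt=data.alt[keep], effect=data.effect[keep], dosage=dosage[keep],
        samples=list(data.samples),
    )
    return table, report


def load_variants(
    vcf_path: str | Path,
    outgroup_id: str,
    cfg: FilterConfig | None = None,
    mask_beds: list[str | Path] | None = None,
) -> tuple[VariantTable, pd.DataFrame]:
    """Full ingest pipeline: read, polarize against the outgroup, filter."""
    cfg = cfg or FilterConfig()
    masks = [read_mask_bed(p) for p in (mask_beds or [])]
    data = read_vcf(vcf_path)
    data = polarize_sites(data, outgroup_id)
    return filter_sites(data, cfg, masks)
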