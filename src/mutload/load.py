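"""Mutation-load metrics: allele/homozygote/heterozygote counts per effect
class, their partition over the ROH landscape, deleterious/synonymous
ratios, and cross-population sharing spectra.

Counts are raw (not normalized by callable sites); a homozygote contributes
two alleles and a heterozygote one, so n_alleles = 2*n_hom + n_het holds
exactly for every individual and class.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core import (
    LOAD_CLASSES,
    EffectClass,
    GenomeDef,
    PopulationPanel,
    VariantTable,
)
from .roh import LengthClass, ROHSet

logger = logging.getLogger(__name__)

#: ROH partitions of the genome used for the homozygote landscape.
PARTITIONS = ("IN_ROH", "OUT_ROH", "SHORT", "MEDIUM", "LONG")


def count_load(
    table: VariantTable,
    classes: tuple[EffectClass, ...] = LOAD_CLASSES,
) -> pd.DataFrame:
    """Per-individual per-class allele, homozygote and heterozygote counts.

    Missing genotypes are skipped. Individuals with zero callable sites in
    a class get NaN counts (flagged, not silently zero).
    """
    rows = []
    for cls in classes:
        d = table.dosage[table.class_mask(cls)]
        callable_ = (d >= 0).sum(axis=0)
        n_hom = (d == 2).sum(axis=0).astype(float)
        n_het = (d == 1).sum(axis=0).astype(float)
        n_alleles = 2 * n_hom + n_het
        bad = callable_ == 0
        if bad.any():
            logger.warning(
                "%d individuals have zero callable %s sites", int(bad.sum()), cls.value
            )
            n_hom[bad] = n_het[bad] = n_alleles[bad] = np.nan
        for j, ind in enumerate(table.samples):
            rows.append(
                (ind, cls.value, n_alleles[j], n_hom[j], n_het[j], int(callable_[j]))
            )
    return pd.DataFrame(
        rows, columns=["individual", "class", "n_alleles", "n_hom", "n_het", "n_callable"]
    )


def population_load(load: pd.DataFrame, panel: PopulationPanel) -> pd.DataFrame:
    """Population summaries: mean of the individual counts."""
    df = load.merge(
        panel.table[["individual", "population"]], on="individual", how="left"
    )
    return (
        df.groupby(["population", "class"], sort=False)[["n_alleles", "n_hom", "n_het"]]
        .mean()
        .reset_index()
    )


def partition_load(
    table: VariantTable,
    rohset: ROHSet,
    genome: GenomeDef,
    classes: tuple[EffectClass, ...] = LOAD_CLASSES,
) -> pd.DataFrame:
    """Homozygote counts per individual/class within each ROH partition.

    Partitions: IN_ROH (all retained segments of any length), OUT_ROH, and
    the SHORT/MEDIUM/LONG length classes. Also reports the bp extent of
    each partition for the individual, for per-length normalization.
    n_hom(IN_ROH) + n_hom(OUT_ROH) equals the total homozygote count.
    """
    classed = rohset.with_length_class()
    rows = []
    pos0_all = table.pos - 1
    for ind in table.samples:
        j = table.sample_index(ind)
        segs = classed.loc[classed["individual"] == ind]
        roh_bp_total = int(segs["length"].sum())
        masks = {p: np.zeros(table.n_sites, dtype=bool) for p in PARTITIONS}
        for chrom, grp in segs.groupby("chrom", sort=False):
            cmask = table.chrom == chrom
            pos0 = pos0_all[cmask]
            order = np.argsort(grp["start"].to_numpy())
            starts = grp["start"].to_numpy()[order]
            ends = grp["end"].to_numpy()[order]
            lcs = grp["length_class"].to_numpy()[order]
            gi = np.searchsorted(starts, pos0, side="right") - 1
            hit = gi >= 0
            hit[hit] = pos0[hit] < ends[gi[hit]]
            masks["IN_ROH"][cmask] = hit
            for lc in LengthClass:
                sel = hit & np.isin(gi, np.flatnonzero(lcs == lc.value))
                masks[lc.value][cmask] = sel
        masks["OUT_ROH"] = ~masks["IN_ROH"]
        part_bp = {
            "IN_ROH": roh_bp_total,
            "OUT_ROH": genome.total - roh_bp_total,
            **{
                lc.value: int(segs.loc[segs["length_class"] == lc.value, "length"].sum())
                for lc in LengthClass
            },
        }
        for cls in classes:
            cmask = table.class_mask(cls)
            hom = table.dosage[:, j] == 2
            total = int((hom & cmask).sum())
            for p in PARTITIONS:
                rows.append(
                    (
                        ind, cls.value, p,
                        int((hom & cmask & masks[p]).sum()),
                        total, part_bp[p],
                    )
                )
    return pd.DataFrame(
        rows,
        columns=["individual", "class", "partition", "n_hom", "n_hom_total", "partition_bp"],
    )


def enrichment(n_hom_partition, n_hom_total, f_roh_partition):
    """Normalized proportion of homozygotes in an ROH partition.

    (n_hom in partition / n_hom total) / (partition genome fraction).
    Values above one indicate enrichment of homozygotes in the partition.
    Undefined (zero total homozygotes or zero partition fraction) -> NaN,
    never 0.
    """
    n_p = np.asarray(n_hom_partition, dtype=float)
    n_t = np.asarray(n_hom_total, dtype=float)
    f = np.asarray(f_roh_partition, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (n_p / n_t) / f
    out = np.where((n_t <= 0) | (f <= 0), np.nan, out)
    return out if out.ndim else float(out)


def per_length_load(n_hom, partition_bp):
    """Homozygotes per Mb of a genome partition; zero-length partition -> NaN."""
    n = np.asarray(n_hom, dtype=float)
    bp = np.asarray(partition_bp, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = n / (bp / 1e6)
    out = np.where(bp <= 0, np.nan, out)
    return out if out.ndim else float(out)


def enrichment_table(
    part: pd.DataFrame, genome: GenomeDef, panel: PopulationPanel | None = None
) -> pd.DataFrame:
    """Per-individual enrichment per class/partition; optional population means.

    The population value is the mean of individual enrichments (the pooled
    alternative is a deliberate non-default; compute it from the counts).
    """
    df = part.copy()
    df["f_partition"] = df["partition_bp"] / genome.total
    df["enrichment"] = enrichment(
        df["n_hom"].to_numpy(), df["n_hom_total"].to_numpy(), df["f_partition"].to_numpy()
    )
    if panel is not None:
        df = df.merge(
            panel.table[["individual", "population"]], on="individual", how="left"
        )
    return df


def ratio_del_syn(
    load: pd.DataFrame,
    del_class: EffectClass,
    zygosity: str = "alleles",
) -> pd.Series:
    """Per-individual deleterious/synonymous count ratio at matched zygosity.

    ``zygosity`` is one of 'alleles', 'hom', 'het'. A zero synonymous
    denominator yields NaN with a warning.
    """
    col = {"alleles": "n_alleles", "hom": "n_hom", "het": "n_het"}[zygosity]
    d = load.loc[load["class"] == del_class.value].set_index("individual")[col]
    s = load.loc[load["class"] == EffectClass.SYNONYMOUS.value].set_index("individual")[col]
    s = s.reindex(d.index)
    zero = s <= 0
    if zero.any():
        logger.warning(
            "%d individuals have zero synonymous %s count; ratio undefined",
            int(zero.sum()), zygosity,
        )
    out = d / s.where(~zero)
    out.name = f"{del_class.value.lower()}_syn_ratio_{zygosity}"
    return out


def ratio_del_syn_partition(
    part: pd.DataFrame, del_class: EffectClass, partition: str
) -> pd.Series:
    """Deleterious/synonymous homozygote ratio within an ROH partition."""
    sub = part.loc[part["partition"] == partition]
    d = sub.loc[sub["class"] == del_class.value].set_index("individual")["n_hom"]
    s = sub.loc[sub["class"] == EffectClass.SYNONYMOUS.value].set_index("individual")["n_hom"]
    s = s.reindex(d.index)
    out = d / s.where(s > 0)
    out.name = f"{del_class.value.lower()}_syn_hom_ratio_{partition.lower()}"
    return out


def sharing_spectrum(
    table: VariantTable,
    panel: PopulationPanel,
    classes: tuple[EffectClass, ...] = LOAD_CLASSES,
) -> pd.DataFrame:
    """Proportion of variants of each class present in exactly k populations.

    Presence means at least one derived allele among the population's
    genotyped individuals. Variants absent from every population are
    excluded, so each class's proportions sum to one over k = 1..n_pops.
    """
    pops = panel.populations
    if len(pops) < 2:
        raise ValueError("sharing spectrum needs at least two populations")
    presence = np.zeros((table.n_sites, len(pops)), dtype=bool)
    for p, pop in enumerate(pops):
        idx = [table.sample_index(i) for i in panel.members(pop) if i in table.samples]
        if idx:
            presence[:, p] = (table.dosage[:, idx] > 0).any(axis=1)
    k = presence.sum(axis=1)
    rows = []
    for cls in classes:
        kk = k[table.class_mask(cls)]
        kk = kk[kk > 0]
        n = len(kk)
        for j in range(1, len(pops) + 1):
            rows.append((cls.value, j, float((kk == j).sum() / n) if n else np.nan, n))
    return pd.DataFrame(rows, columns=["class", "k", "proportion", "n_variants"])
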