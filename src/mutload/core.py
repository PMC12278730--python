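"""Shared data containers for the mutation-load pipeline.

Coordinate conventions: VCF positions are 1-based inclusive; BED intervals
are 0-based half-open. Genotypes are stored as derived-allele dosage
(0, 1, 2) with -1 marking a missing call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1  # sentinel dosage for a missing genotype


class EffectClass(str, Enum):
    """Variant effect categories used for load accounting.

    LOF (stop gained, splice donor/acceptor, start lost) is the strongly
    deleterious class, MISSENSE the mildly deleterious class, SYNONYMOUS a
    slightly deleterious contrast, and INTERGENIC the neutral baseline.
    Everything else maps to OTHER and is excluded from load metrics.
    """

    LOF = "LOF"
    MISSENSE = "MISSENSE"
    SYNONYMOUS = "SYNONYMOUS"
    INTERGENIC = "INTERGENIC"
    OTHER = "OTHER"


#: SnpEff annotation terms counted as loss-of-function.
LOF_TERMS = frozenset(
    {"stop_gained", "splice_donor_variant", "splice_acceptor_variant", "start_lost"}
)

#: Classes that participate in load metrics (OTHER excluded).
LOAD_CLASSES = (
    EffectClass.LOF,
    EffectClass.MISSENSE,
    EffectClass.SYNONYMOUS,
    EffectClass.INTERGENIC,
)


@dataclass
class GenomeDef:
    """Autosome names and lengths; the F_ROH denominator.

    `lengths` maps chromosome name -> length in bp. Only autosomes belong
    here: sex chromosomes are excluded upstream.
    """

    lengths: dict[str, int]

    def __post_init__(self) -> None:
        if not self.lengths:
            raise ValueError("GenomeDef needs at least one chromosome")
        for name, ln in self.lengths.items():
            if ln <= 0:
                raise ValueError(f"chromosome {name} has non-positive length {ln}")

    @property
    def total(self) -> int:
        return int(sum(self.lengths.values()))

    @property
    def names(self) -> list[str]:
        return list(self.lengths)

    def __contains__(self, name: str) -> bool:
        return name in self.lengths


@dataclass
class PopulationPanel:
    """Individual -> population map with habitat and N_e annotations.

    The table has columns: individual, population, habitat, ne_hist, ne_now.
    The outgroup individual, if present, carries habitat == "outgroup" and is
    not a member of any study population.
    """

    table: pd.DataFrame

    REQUIRED = ("individual", "population", "habitat", "ne_hist", "ne_now")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"panel missing columns: {missing}")
        if self.table["individual"].duplicated().any():
            raise ValueError("panel maps an individual to more than one population")
        self.table = self.table.reset_index(drop=True)

    @property
    def individuals(self) -> list[str]:
        return self.table["individual"].tolist()

    @property
    def populations(self) -> list[str]:
        """Study population ids, in order of first appearance (outgroup excluded)."""
        mask = self.table["habitat"] != "outgroup"
        return list(dict.fromkeys(self.table.loc[mask, "population"]))

    @property
    def outgroup(self) -> str | None:
        rows = self.table.loc[self.table["habitat"] == "outgroup", "individual"]
        return None if rows.empty else rows.iloc[0]

    def population_of(self, individual: str) -> str:
        row = self.table.loc[self.table["individual"] == individual]
        if row.empty:
            raise KeyError(f"unknown individual {individual!r}")
        return row["population"].iloc[0]

    def members(self, population: str) -> list[str]:
        return self.table.loc[
            self.table["population"] == population, "individual"
        ].tolist()

    def population_info(self) -> pd.DataFrame:
        """One row per study population with habitat and N_e values."""
        mask = self.table["habitat"] != "outgroup"
        return (
            self.table.loc[mask]
            .groupby("population", sort=False)
            .agg(
                habitat=("habitat", "first"),
                ne_hist=("ne_hist", "first"),
                ne_now=("ne_now", "first"),
                n_individuals=("individual", "size"),
            )
            .reset_index()
        )

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PopulationPanel":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class VariantTable:
    """Polarized per-site records with per-individual derived-allele dosages.

    dosage has shape (n_sites, n_samples), dtype int8, with MISSING (-1)
    for uncalled genotypes. After polarization a dosage counts copies of the
    derived allele.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    effect: np.ndarray  # EffectClass values as str
    dosage: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        n = len(self.pos)
        if self.dosage.shape != (n, len(self.samples)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{n} sites x {len(self.samples)} samples"
            )

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, name: str) -> int:
        try:
            return self.samples.index(name)
        except ValueError:
            raise KeyError(f"sample {name!r} not in table") from None

    def class_mask(self, effect: EffectClass) -> np.ndarray:
        return self.effect == effect.value

    def subset_sites(self, mask: np.ndarray) -> "VariantTable":
        return VariantTable(
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            ref=self.ref[mask],
            alt=self.alt[mask],
            effect=self.effect[mask],
            dosage=self.dosage[mask],
            samples=list(self.samples),
        )

    def drop_samples(self, names: list[str]) -> "VariantTable":
        keep = [i for i, s in enumerate(self.samples) if s not in set(names)]
        return VariantTable(
            chrom=self.chrom,
            pos=self.pos,
            ref=self.ref,
            alt=self.alt,
            effect=self.effect,
            dosage=self.dosage[:, keep],
            samples=[self.samples[i] for i in keep],
        )

    def to_tsv(self, path: str | Path) -> None:
        """Write the polarized site table (chrom, pos, class, per-sample dosage)."""
        df = pd.DataFrame(
            {"chrom": self.chrom, "pos": self.pos, "ref": self.ref,
             "alt": self.alt, "class": self.effect}
        )
        for j, s in enumerate(self.samples):
            df[s] = self.dosage[:, j]
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "VariantTable":
        df = pd.read_csv(path, sep="\t")
        fixed = ["chrom", "pos", "ref", "alt", "class"]
        samples = [c for c in df.columns if c not in fixed]
        return cls(
            chrom=df["chrom"].to_numpy(dtype=object),
            pos=df["pos"].to_numpy(dtype=np.int64),
            ref=df["ref"].to_numpy(dtype=object),
            alt=df["alt"].to_numpy(dtype=object),
            effect=df["class"].to_numpy(dtype=object),
            dosage=df[samples].to_numpy(dtype=np.int8),
            samples=samples,
        )


def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge possibly overlapping half-open intervals; returns sorted, disjoint arrays."""
    if len(starts) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    order = np.argsort(starts, kind="stable")
    s, e = np.asarray(starts)[order], np.asarray(ends)[order]
    out_s, out_e = [int(s[0])], [int(e[0])]
    for i in range(1, len(s)):
        if s[i] <= out_e[-1]:
            out_e[-1] = max(out_e[-1], int(e[i]))
        else:
            out_s.append(int(s[i]))
            out_e.append(int(e[i]))
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


def points_in_intervals(
    pos0: np.ndarray, starts: np.ndarray, ends: np.ndarray
) -> np.ndarray:
    """Membership of 0-based positions in disjoint sorted half-open intervals."""
    if len(starts) == 0:
        return np.zeros(len(pos0), dtype=bool)
    idx = np.searchsorted(starts, pos0, side="right") - 1
    ok = idx >= 0
    out = np.zeros(len(pos0), dtype=bool)
    out[ok] = pos0[ok] < ends[idx[ok]]
    return out
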