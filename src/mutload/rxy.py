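"""The R_XY relative mutation-load statistic with chromosome-block jackknife.

For a focal population X and reference Y, the one-sided derived-allele load
is L_{X not Y} = sum_i f_i^X (1 - f_i^Y) over the category's sites, and
symmetrically L_{Y not X}. Each is normalized by the same sum taken over an
equal-size random subsample of neutral (intergenic) sites, and

    R_XY = [L_{X not Y} / L_{X not Y}^neu] / [L_{Y not X} / L_{Y not X}^neu].

R_XY < 1 indicates a deficiency of the category's derived alleles in X
relative to Y (purifying selection in X); > 1 an excess. Confidence
intervals come from a delete-one-chromosome jackknife, removing each
linkage group's category and neutral sites together.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import EffectClass, PopulationPanel, VariantTable

#: column names that are not population frequencies in a FrequencyTable
_META = ("chrom", "pos", "class")


def derived_freq(table: VariantTable, panel: PopulationPanel) -> pd.DataFrame:
    """Per-site per-population derived-allele frequency (missing-aware).

    f = sum(dosage) / (2 * genotyped individuals); NaN where a population
    has no genotyped individual at the site.
    """
    out = pd.DataFrame(
        {"chrom": table.chrom, "pos": table.pos, "class": table.effect}
    )
    for pop in panel.populations:
        idx = [table.sample_index(i) for i in panel.members(pop) if i in table.samples]
        if not idx:
            out[pop] = np.nan
            continue
        d = table.dosage[:, idx].astype(float)
        valid = d >= 0
        n = valid.sum(axis=1)
        s = np.where(valid, d, 0.0).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = s / (2.0 * n)
        out[pop] = np.where(n > 0, f, np.nan)
    return out


@dataclass
class RxyResult:
    """Point estimate, per-block jackknife quantities and 95% CI."""

    point: float
    blocks: list[str]
    loo: np.ndarray  # delete-one-block estimates, aligned with blocks
    pseudo_values: np.ndarray
    se: float
    ci_low: float
    ci_high: float
    n_class_sites: int
    n_neutral_sites: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.point <= self.ci_high):
            raise ValueError("CI does not contain the point estimate")


def _pair_sums(fx: np.ndarray, fy: np.ndarray) -> tuple[float, float]:
    """(sum fx(1-fy), sum fy(1-fx)) over sites."""
    return float(np.sum(fx * (1 - fy))), float(np.sum(fy * (1 - fx)))


def _estimator(terms: np.ndarray) -> float:
    """R_XY from the four aggregated sums [A, B, An, Bn]."""
    a, b, an, bn = terms
    names = ("L_XnotY", "L_YnotX", "L_XnotY_neutral", "L_YnotX_neutral")
    for val, name in zip(terms, names):
        if val <= 0:
            raise ValueError(f"degenerate R_XY term {name} = {val}")
    return (a / an) / (b / bn)


def jackknife_ci(
    block_terms: pd.DataFrame, estimator=_estimator, z: float = 1.96
) -> tuple[float, np.ndarray, np.ndarray, float, tuple[float, float]]:
    """Delete-one-block jackknife for an estimator of aggregated block sums.

    ``block_terms`` has one row per block (index = block name) and one
    column per term; the estimator consumes the column sums. Returns
    (point, leave-one-out estimates, pseudo-values, SE, CI) with
    pseudo-values theta_j = n*theta - (n-1)*theta_(-j) and
    CI = theta +/- z * sd(pseudo)/sqrt(n).
    """
    n = len(block_terms)
    if n < 2:
        raise ValueError("jackknife needs at least two blocks")
    totals = block_terms.to_numpy(dtype=float).sum(axis=0)
    point = estimator(totals)
    loo = np.empty(n)
    for j in range(n):
        left = totals - block_terms.iloc[j].to_numpy(dtype=float)
        try:
            loo[j] = estimator(left)
        except ValueError as exc:
            raise ValueError(
                f"block {block_terms.index[j]!r} holds all sites of a category: {exc}"
            ) from exc
    pseudo = n * point - (n - 1) * loo
    se = float(np.std(pseudo, ddof=1) / np.sqrt(n))
    ci = (point - z * se, point + z * se)
    return point, loo, pseudo, se, ci


def rxy(
    freqs: pd.DataFrame,
    x: str,
    y: str,
    class_: EffectClass,
    seed: int,
    neutral_class: EffectClass = EffectClass.INTERGENIC,
    neutral_mask: np.ndarray | None = None,
    n_subsamples: int = 1,
) -> RxyResult:
    """R_XY for a variant category with intergenic normalization and jackknife CI.

    The neutral subsample has exactly as many sites as the category (drawn
    without replacement, seeded); ``n_subsamples > 1`` averages the point
    estimate and block terms over repeated draws. Sites with a missing
    frequency in either population are excluded pairwise everywhere.
    ``neutral_mask`` optionally restricts the neutral pool (boolean over
    the rows of ``freqs``).
    """
    for pop in (x, y):
        if pop not in freqs.columns:
            raise KeyError(f"population {pop!r} not in frequency table")
    ok = freqs[x].notna() & freqs[y].notna()
    cls_rows = ok & (freqs["class"] == class_.value)
    neu_rows = ok & (freqs["class"] == neutral_class.value)
    if neutral_mask is not None:
        neu_rows &= neutral_mask
    n_class = int(cls_rows.sum())
    neu_idx = np.flatnonzero(neu_rows.to_numpy())
    if n_class == 0:
        raise ValueError(f"no usable {class_.value} sites for {x} vs {y}")
    if len(neu_idx) < n_class:
        raise ValueError(
            f"neutral pool ({len(neu_idx)}) smaller than category ({n_class})"
        )
    rng = np.random.default_rng(seed)
    chrom = freqs["chrom"].to_numpy()
    fx_all = freqs[x].to_numpy(dtype=float)
    fy_all = freqs[y].to_numpy(dtype=float)
    cls_idx = np.flatnonzero(cls_rows.to_numpy())
    blocks = list(pd.unique(chrom[np.concatenate([cls_idx, neu_idx])]))

    acc = np.zeros((len(blocks), 4))
    for _ in range(n_subsamples):
        sub = rng.choice(neu_idx, size=n_class, replace=False)
        for bi, blk in enumerate(blocks):
            ci = cls_idx[chrom[cls_idx] == blk]
            si = sub[chrom[sub] == blk]
            a, b = _pair_sums(fx_all[ci], fy_all[ci])
            an, bn = _pair_sums(fx_all[si], fy_all[si])
            acc[bi] += (a, b, an, bn)
    block_terms = pd.DataFrame(
        acc / n_subsamples, index=blocks, columns=["A", "B", "An", "Bn"]
    )
    point, loo, pseudo, se, ci = jackknife_ci(block_terms)
    return RxyResult(
        point=point, blocks=blocks, loo=loo, pseudo_values=pseudo, se=se,
        ci_low=ci[0], ci_high=ci[1],
        n_class_sites=n_class, n_neutral_sites=n_class,
    )


def rxy_table(
    freqs: pd.DataFrame,
    focal_pops: list[str],
    reference: str,
    classes: tuple[EffectClass, ...],
    seed: int,
    **kwargs,
) -> pd.DataFrame:
    """R_XY of each focal population vs the reference, per class (tidy TSV shape)."""
    rows = []
    for i, pop in enumerate(focal_pops):
        for j, cls in enumerate(classes):
            res = rxy(freqs, pop, reference, cls, seed=seed + 1000 * i + j, **kwargs)
            rows.append(
                (pop, cls.value, res.point, res.ci_low, res.ci_high,
                 res.se, res.n_class_sites)
            )
    return pd.DataFrame(
        rows,
        columns=["population", "class", "rxy", "ci_low", "ci_high", "se", "n_sites"],
    )


def interval_subset(
    chrom: np.ndarray,
    pos: np.ndarray,
    intervals: dict[str, tuple[np.ndarray, np.ndarray]],
) -> np.ndarray:
    """Boolean mask of sites (1-based pos) inside any half-open interval.

    Used e.g. to restrict R_XY to conserved single-copy gene intervals.
    """
    from .core import points_in_intervals

    out = np.zeros(len(pos), dtype=bool)
    for c, (starts, ends) in intervals.items():
        cmask = chrom == c
        if cmask.any():
            out[cmask] = points_in_intervals(pos[cmask] - 1, starts, ends)
    return out
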