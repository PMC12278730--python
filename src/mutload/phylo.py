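"""Phylogenetically corrected association of load metrics with inbreeding.

Pipeline: identity-by-state distances on one chromosome -> rooted
neighbor-joining tree (rooted on the outgroup branch) -> phylogenetic
variance-covariance matrix (shared root-to-MRCA branch length) ->
generalized least squares regression of a response on a predictor with that
covariance as the error structure. A closed-form GLS replaces Bayesian
mixed-model machinery: it estimates the same fixed-effect slope
deterministically. Also provides the exact small-n Spearman test.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Phylo
from Bio.Phylo.BaseTree import Tree
from Bio.Phylo.TreeConstruction import DistanceMatrix as _BioDM
from Bio.Phylo.TreeConstruction import DistanceTreeConstructor
from scipy import stats

from .core import PopulationPanel

logger = logging.getLogger(__name__)


def ibs_distance(dosage: np.ndarray, samples: list[str]) -> pd.DataFrame:
    """Pairwise identity-by-state distance over a dosage matrix.

    distance(i, j) = mean over shared non-missing sites of |d_i - d_j| / 2,
    so identical genotypes give 0 and opposite homozygotes give 1. A pair
    with no shared genotyped site is an error.
    """
    n = len(samples)
    if n < 2:
        raise ValueError("IBS distance needs at least two individuals")
    d = dosage.astype(float)
    d[dosage < 0] = np.nan
    out = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        diff = np.abs(d[:, i] - d[:, j])
        shared = ~np.isnan(diff)
        if not shared.any():
            raise ValueError(
                f"no shared genotyped sites between {samples[i]!r} and {samples[j]!r}"
            )
        out[i, j] = out[j, i] = float(diff[shared].mean() / 2.0)
    return pd.DataFrame(out, index=samples, columns=samples)


def nj_tree(dist: pd.DataFrame, outgroup: str) -> Tree:
    """Neighbor-joining tree rooted on the outgroup branch.

    Negative branch lengths produced by NJ are clamped to zero with a
    warning; the root is placed at the midpoint of the outgroup's branch.
    """
    arr = dist.to_numpy(dtype=float)
    if not np.allclose(arr, arr.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    if outgroup not in dist.index:
        raise KeyError(f"outgroup {outgroup!r} not in distance matrix")
    names = list(dist.index)
    lower = [[float(arr[i, j]) for j in range(i + 1)] for i in range(len(names))]
    tree = DistanceTreeConstructor().nj(_BioDM(names=names, matrix=lower))
    n_neg = 0
    for clade in tree.find_clades():
        if clade.branch_length is not None and clade.branch_length < 0:
            clade.branch_length = 0.0
            n_neg += 1
    if n_neg:
        logger.warning("clamped %d negative NJ branch lengths to zero", n_neg)
    og = next(tree.find_clades(name=outgroup))
    half = (og.branch_length or 0.0) / 2.0
    tree.root_with_outgroup({"name": outgroup}, outgroup_branch_length=half)
    # Biopython leaves the full pre-rooting outgroup branch on the ingroup
    # side; halve it so the root truly bisects the branch and tip-to-tip
    # path lengths are preserved.
    for clade in tree.root.clades:
        if not (clade.is_terminal() and clade.name == outgroup):
            clade.branch_length = half
    tree.rooted = True
    return tree


def tree_to_vcv(tree: Tree, taxa: list[str] | None = None) -> pd.DataFrame:
    """Phylogenetic variance-covariance matrix from a rooted tree.

    V[i, j] is the branch length shared from the root down to the MRCA of
    tips i and j; V[i, i] is the root-to-tip distance. The result is
    positive semidefinite by construction for non-negative branch lengths.
    """
    if not tree.rooted:
        raise ValueError("tree must be rooted to define shared root-to-MRCA depths")
    tips = [t.name for t in tree.get_terminals()]
    if taxa is None:
        taxa = tips
    missing = set(taxa) - set(tips)
    if missing:
        raise KeyError(f"taxa absent from tree: {sorted(missing)}")
    idx = {name: k for k, name in enumerate(taxa)}
    n = len(taxa)
    V = np.zeros((n, n))

    def walk(clade, depth):
        depth += clade.branch_length or 0.0
        below = [t.name for t in clade.get_terminals() if t.name in idx]
        ids = [idx[t] for t in below]
        for a in ids:
            for b in ids:
                V[a, b] = max(V[a, b], depth) if a != b else V[a, b]
        if clade.is_terminal() and clade.name in idx:
            V[idx[clade.name], idx[clade.name]] = depth
        for child in clade.clades:
            walk(child, depth)

    # root contributes no shared depth
    for child in tree.root.clades:
        walk(child, 0.0)
    # shared depth of a pair = depth of deepest clade containing both; the
    # max-accumulation above realizes exactly that.
    return pd.DataFrame(V, index=taxa, columns=taxa)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    p_value: float  # two-sided t-test on the slope
    df_resid: int
    response_mean: float
    response_sd: float
    standardized: bool


def phylo_gls(
    y: np.ndarray,
    x: np.ndarray,
    V: np.ndarray | pd.DataFrame,
    standardize: bool = True,
    jitter: float = 1e-10,
) -> RegressionResult:
    """GLS regression of y on x with phylogenetic error covariance V.

    beta = (X' V^-1 X)^-1 X' V^-1 y with an intercept; the residual
    variance scales V. With V = I this reduces to ordinary least squares.
    The response is z-scored by default so slopes are comparable across
    responses with different scales. Singular V gets a ridge jitter; V
    singular beyond that, or collinear predictors, raise.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    Vm = np.asarray(V, dtype=float)
    n = len(y)
    if Vm.shape != (n, n) or len(x) != n:
        raise ValueError("shape mismatch between y, x and V")
    mu, sd = float(np.mean(y)), float(np.std(y, ddof=1))
    if standardize:
        if sd == 0:
            raise ValueError("constant response cannot be standardized")
        y = (y - mu) / sd
    X = np.column_stack([np.ones(n), x])
    try:
        L = np.linalg.cholesky(Vm)
    except np.linalg.LinAlgError:
        try:
            L = np.linalg.cholesky(Vm + jitter * np.trace(Vm) / n * np.eye(n))
        except np.linalg.LinAlgError as exc:
            raise ValueError("V is singular beyond jitter tolerance") from exc
    Xw = np.linalg.solve(L, X)
    yw = np.linalg.solve(L, y)
    XtX = Xw.T @ Xw
    if np.linalg.cond(XtX) > 1e12:
        raise ValueError("predictor is collinear with the intercept (rank deficient)")
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    resid = yw - Xw @ beta
    df = n - 2
    if df <= 0:
        raise ValueError("not enough observations for a slope and intercept")
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov))
    t = beta[1] / se[1]
    p = 2.0 * stats.t.sf(abs(t), df)
    return RegressionResult(
        slope=float(beta[1]), intercept=float(beta[0]),
        slope_se=float(se[1]), intercept_se=float(se[0]),
        p_value=float(p), df_resid=df,
        response_mean=mu, response_sd=sd, standardized=standardize,
    )


def choose_representatives(panel: PopulationPanel, seed: int) -> dict[str, str]:
    """One randomly sampled individual per population (seeded, logged)."""
    rng = np.random.default_rng(seed)
    reps = {}
    for pop in panel.populations:
        members = panel.members(pop)
        reps[pop] = members[int(rng.integers(len(members)))]
    logger.info("population representatives: %s", reps)
    return reps


def population_vcv(
    V_ind: pd.DataFrame, panel: PopulationPanel, seed: int
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Restrict an individual-level VCV to one representative per population."""
    reps = choose_representatives(panel, seed)
    inds = list(reps.values())
    sub = V_ind.loc[inds, inds]
    sub.index = sub.columns = list(reps.keys())
    return sub, reps


def spearman_exact(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with exact one-sided (upper-tail) permutation p, small n.

    Valid for 3 <= n <= 8 with no ties; the p-value is the proportion of
    the n! rank permutations with rho at least the observed value. For
    perfectly concordant ranks at n = 5, p = 1/120; for rho = 0.9 at
    n = 5, p = 5/120 ~ 0.042.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y differ in length")
    if not 3 <= n <= 8:
        raise ValueError("exact test supported for 3 <= n <= 8")
    if len(np.unique(x)) < n or len(np.unique(y)) < n:
        raise ValueError("ties present: exact permutation null is invalid")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)

    def rho_of(r1, r2):
        d2 = float(np.sum((np.asarray(r1) - np.asarray(r2)) ** 2))
        return 1.0 - 6.0 * d2 / (n * (n * n - 1))

    rho = rho_of(rx, ry)
    count = sum(
        rho_of(rx, perm) >= rho - 1e-12
        for perm in itertools.permutations(ry)
    )
    from math import factorial

    return rho, count / factorial(n)


def write_newick(tree: Tree, path) -> None:
    Phylo.write(tree, str(path), "newick")
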