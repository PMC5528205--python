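"""Blomberg's K phylogenetic signal, per community, with permutation test.

K compares the observed ratio of tip variance (around the GLS ancestral
mean) to phylogenetically corrected variance against its expectation under
Brownian motion on the same tree:

    K = (MSE0 / MSE) / E_BM,   with
    a_hat = (1' C^-1 x) / (1' C^-1 1)
    MSE0  = (x - a_hat)'(x - a_hat) / (n - 1)
    MSE   = (x - a_hat)' C^-1 (x - a_hat) / (n - 1)
    E_BM  = [tr(C) - n / (1' C^-1 1)] / (n - 1)

where C is the phylogenetic covariance matrix.  K = 1 under Brownian motion
(exactly 1 on a star tree for any non-constant trait), K -> 0 when trait
values are random with respect to the tree, K > 1 when close relatives are
even more similar than Brownian motion predicts.

Significance uses the variance of phylogenetically independent contrasts
(PIC) as the test statistic: trait values are permuted across tips, and low
observed contrast variance relative to the permutations indicates signal.
Here the signal is assessed per community -- the pool tree pruned to each
plot's species -- so K can be regressed on environmental gradients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .community import CommunityTable, EnvTable, TraitTable
from .nulls import derive_rng
from .tree import PhyloTree, TreeError, prune_to_taxa


@dataclass
class SignalResult:
    plot: object
    trait: str
    k: float
    p: float
    n_tips: int
    degenerate: bool = False


def blomberg_k(tree: PhyloTree, x: pd.Series) -> float:
    """Blomberg's K of tip values ``x`` on ``tree`` (>= 3 tips)."""
    C, xv = _aligned_cov(tree, x)
    return _k_from_cov(C, xv)


def _aligned_cov(tree: PhyloTree, x: pd.Series):
    labels = tree.tip_labels
    if len(labels) < 3:
        raise TreeError("Blomberg's K needs at least 3 tips")
    missing = [l for l in labels if l not in x.index]
    if missing:
        raise ValueError("tips without trait value: " + ", ".join(missing))
    xv = x.loc[labels].to_numpy(dtype=float)
    if not np.isfinite(xv).all():
        raise ValueError("non-finite trait values")
    if np.ptp(xv) == 0:
        raise ValueError("constant trait: K undefined")
    C = tree.vcv_matrix().values
    return C, xv


def _k_from_cov(C: np.ndarray, x: np.ndarray) -> float:
    n = x.size
    one = np.ones(n)
    try:
        Cinv_one = np.linalg.solve(C, one)
        Cinv_x = np.linalg.solve(C, x)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular phylogenetic covariance matrix: {exc}") from exc
    denom = one @ Cinv_one
    a_hat = (one @ Cinv_x) / denom
    resid = x - a_hat
    mse0 = resid @ resid
    mse = resid @ np.linalg.solve(C, resid)
    if mse <= 0:
        raise ValueError("non-positive phylogenetic mean square; C not PD")
    e_bm = (np.trace(C) - n / denom) / (n - 1)
    return float((mse0 / mse) / e_bm)


# -- phylogenetically independent contrasts --------------------------------


def _resolved_copy(tree: PhyloTree) -> PhyloTree:
    """Bifurcating copy for PIC: polytomies resolved with zero-length branches,
    then zero lengths replaced by 1e-8 x tree depth (logged as a warning)."""
    out = tree.clone()
    dtree = out.dendropy_tree
    n_poly = sum(
        1 for nd in dtree.preorder_internal_node_iter() if len(nd.child_nodes()) > 2
    )
    if n_poly:
        dtree.resolve_polytomies(limit=2, update_bipartitions=False)
        warnings.warn(f"resolved {n_poly} polytomies with zero-length branches")
    depth = out.depth()
    eps = 1e-8 * (depth if depth > 0 else 1.0)
    for node in dtree.preorder_node_iter():
        if node.parent_node is not None and (node.edge.length or 0.0) == 0.0:
            node.edge.length = eps
    return out


def pic(tree: PhyloTree, x: pd.Series) -> np.ndarray:
    """Standardized independent contrasts (n - 1 values) by the pruning
    recursion.  The tree is resolved to bifurcating first if needed."""
    rtree = _resolved_copy(tree)
    labels = rtree.tip_labels
    missing = [l for l in labels if l not in x.index]
    if missing:
        raise ValueError("tips without trait value: " + ", ".join(missing))
    vals = {l: float(x.loc[l]) for l in labels}
    contrasts: List[float] = []

    def visit(node):
        if node.is_leaf():
            label = node.taxon.label if node.taxon else node.label
            return vals[label], float(node.edge.length or 0.0)
        kids = node.child_nodes()
        if len(kids) != 2:
            raise TreeError("internal node is not bifurcating after resolution")
        x1, v1 = visit(kids[0])
        x2, v2 = visit(kids[1])
        if v1 + v2 <= 0:
            raise TreeError("zero-length cherry: cannot standardize contrast")
        contrasts.append((x1 - x2) / np.sqrt(v1 + v2))
        xk = (x1 / v1 + x2 / v2) / (1.0 / v1 + 1.0 / v2)
        extra = v1 * v2 / (v1 + v2)
        bl = float(node.edge.length or 0.0)
        return xk, bl + extra

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * len(labels) + 1000))
    try:
        visit(rtree.dendropy_tree.seed_node)
    finally:
        sys.setrecursionlimit(old)
    return np.asarray(contrasts)


def _contrast_operator(tree: PhyloTree) -> tuple:
    """Linear map L with contrasts = L @ x (tip order as returned)."""
    rtree = _resolved_copy(tree)
    labels = rtree.tip_labels
    n = len(labels)
    L = np.empty((n - 1, n))
    basis = pd.DataFrame(np.eye(n), index=labels)
    for j in range(n):
        L[:, j] = pic(rtree, basis[j])
    return labels, L


def contrast_variance(contrasts: np.ndarray) -> float:
    """Mean squared standardized contrast (the permutation test statistic)."""
    contrasts = np.asarray(contrasts, dtype=float)
    return float(np.mean(contrasts**2))


def k_significance(
    tree: PhyloTree,
    x: pd.Series,
    n_perm: int = 999,
    seed: int = 0,
    plot: object = None,
    trait: str = "",
) -> SignalResult:
    """K plus a permutation p-value.

    Trait values are permuted across tips ``n_perm`` times; the statistic is
    the variance of standardized contrasts, and p is the fraction (with +1
    correction) of permutations with contrast variance <= observed -- lower
    contrast variance means stronger signal.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    k = blomberg_k(tree, x)
    labels, L = _contrast_operator(tree)
    xv = x.loc[labels].to_numpy(dtype=float)
    obs = contrast_variance(L @ xv)
    rng = derive_rng(seed, "ksig", plot, trait)
    n = xv.size
    perms = np.empty((n, n_perm))
    for i in range(n_perm):
        perms[:, i] = xv[rng.permutation(n)]
    stats_ = np.mean((L @ perms) ** 2, axis=0)
    p = (int(np.sum(stats_ <= obs)) + 1) / (n_perm + 1)
    return SignalResult(plot=plot, trait=trait, k=k, p=p, n_tips=n)


def community_signal_table(
    tree: PhyloTree,
    community: CommunityTable,
    traits: TraitTable,
    trait_names: Optional[Sequence[str]] = None,
    n_perm: int = 999,
    seed: int = 0,
    log10_traits: Sequence[str] = (),
) -> pd.DataFrame:
    """Blomberg's K of each trait in each community (pool tree pruned to the
    plot's species).  Plots with < 3 species yield degenerate-flagged rows."""
    names = list(trait_names or traits.traits)
    rows = []
    for plot in community.plots:
        species = community.species_in(plot)
        if len(species) < 3:
            for t in names:
                rows.append(
                    {"plot": plot, "trait": t, "n_tips": len(species),
                     "K": np.nan, "p": np.nan, "degenerate": True}
                )
            continue
        sub = prune_to_taxa(tree, species)
        for t in names:
            vals = traits.values_for(species, t)
            if t in log10_traits:
                vals = np.log10(vals)
            if np.ptp(vals.to_numpy(dtype=float)) == 0:
                rows.append(
                    {"plot": plot, "trait": t, "n_tips": len(species),
                     "K": np.nan, "p": np.nan, "degenerate": True}
                )
                continue
            res = k_significance(sub, vals, n_perm=n_perm, seed=seed,
                                 plot=plot, trait=t)
            rows.append(
                {"plot": plot, "trait": t, "n_tips": res.n_tips,
                 "K": res.k, "p": res.p, "degenerate": False}
            )
    return pd.DataFrame(rows)


def signal_along_gradient(
    results: pd.DataFrame,
    env: EnvTable,
    factor: str,
    trait: Optional[str] = None,
    alpha: float = 0.05,
) -> Dict:
    """Least-squares trend of per-community K along one environmental factor.

    Returns slope, intercept, R^2, the ANOVA (F-test) p, and the paper-style
    counts of plots with K > 1 and with significant permutation p.
    """
    df = results
    if trait is not None:
        df = df[df["trait"] == trait]
    df = df[~df["degenerate"].astype(bool)].dropna(subset=["K"])
    if len(df) < 3:
        raise ValueError("need at least 3 plots with defined K")
    xs = env.column(factor, df["plot"]).to_numpy(dtype=float)
    ys = df["K"].to_numpy(dtype=float)
    n_total = len(results[results["trait"] == trait]) if trait else len(results)
    if np.ptp(ys) == 0:
        slope, intercept, r2, p = 0.0, float(ys[0]), 0.0, 1.0
    else:
        res = stats.linregress(xs, ys)
        slope, intercept = float(res.slope), float(res.intercept)
        r2, p = float(res.rvalue**2), float(res.pvalue)
    return {
        "trait": trait,
        "factor": factor,
        "slope": slope,
        "intercept": intercept,
        "r2": r2,
        "p": p,
        "n_plots": int(len(df)),
        "n_plots_total": int(n_total),
        "n_k_gt_1": int((df["K"] > 1).sum()),
        "n_significant": int((df["p"] <= alpha).sum()),
    }
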