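"""Phylogenetic (MNTD/MPD -> NTI) and functional (SES-metric) dispersion.

MNTD is the mean, over the species of a sample, of the patristic distance to
the nearest co-occurring taxon; MPD averages over all unordered pairs.  NTI
is the negated standardized effect size of MNTD against a null in which
species identities are randomized across the regional pool: positive NTI
means phylogenetic clustering, negative means overdispersion.

Functional structure uses four dispersion metrics of a single trait within a
plot -- range, variance, mean pairwise distance (mpd_t), and mean
nearest-neighbour distance (mntd_t) -- optionally weighted by importance
values.  Weights belong to the plot's occupancy slots: the null shuffles
trait values over the pool while each slot keeps its weight, so observed and
null statistics sit on the same weighting footing.  The standardized effect
size (SES-metric) keeps the raw sign: positive = functional overdispersion,
negative = functional clustering.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .community import CommunityTable, TraitTable, importance_values
from .nulls import NullDistribution, SESResult, derive_rng, ses
from .tree import LabeledMatrix, PhyloTree

TRAIT_METRICS = ("range", "variance", "mpd_t", "mntd_t")


def _sample_matrix(sample: Sequence[str], d: LabeledMatrix) -> np.ndarray:
    idx = d.indices(sample)
    return d.values[np.ix_(idx, idx)]


def _mntd_from_matrix(sub: np.ndarray) -> float:
    sub = sub.copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def _mpd_from_matrix(sub: np.ndarray) -> float:
    n = sub.shape[0]
    iu = np.triu_indices(n, 1)
    return float(sub[iu].mean())


def mntd(sample: Iterable[str], d: LabeledMatrix) -> float:
    """Mean nearest taxon distance of a sample of >= 2 taxa."""
    sample = list(sample)
    if len(sample) < 2:
        raise ValueError("MNTD needs at least 2 taxa")
    return _mntd_from_matrix(_sample_matrix(sample, d))


def mpd(sample: Iterable[str], d: LabeledMatrix) -> float:
    """Mean pairwise patristic distance of a sample of >= 2 taxa."""
    sample = list(sample)
    if len(sample) < 2:
        raise ValueError("MPD needs at least 2 taxa")
    return _mpd_from_matrix(_sample_matrix(sample, d))


def _null_member_indices(
    n_pool: int, member_idx: np.ndarray, null_model: str, rng: np.random.Generator
) -> np.ndarray:
    if null_model == "shuffle":
        perm = rng.permutation(n_pool)
        return perm[member_idx]
    if null_model == "richness":
        return rng.choice(n_pool, size=member_idx.size, replace=False)
    raise ValueError(f"unknown null model {null_model!r}")


def nti(
    plot_species: Iterable[str],
    d: LabeledMatrix,
    n_iter: int = 999,
    seed: int = 0,
    plot: object = None,
    null_model: str = "shuffle",
    pool: Optional[Sequence[str]] = None,
) -> SESResult:
    """Nearest taxon index of one plot against a pool-level null.

    ``d`` is the pool patristic matrix (its labels are the default pool).
    NTI = -(MNTD_obs - mean MNTD_null) / sd MNTD_null.
    """
    species = list(plot_species)
    if len(species) < 2:
        raise ValueError("NTI needs at least 2 species")
    pool = list(pool) if pool is not None else list(d.labels)
    missing = [s for s in species if s not in d]
    if missing:
        raise ValueError("species absent from tree: " + ", ".join(missing))
    pool_idx = d.indices(pool)
    member_idx = d.indices(species)
    obs = _mntd_from_matrix(d.values[np.ix_(member_idx, member_idx)])
    # positions of the plot's members inside the pool ordering
    pos = {int(g): i for i, g in enumerate(pool_idx)}
    try:
        member_pos = np.array([pos[int(g)] for g in member_idx])
    except KeyError:
        raise ValueError("plot species not contained in the null pool")
    rng = derive_rng(seed, "nti", plot)
    reps = np.empty(n_iter)
    for i in range(n_iter):
        draw = pool_idx[_null_member_indices(len(pool), member_pos, null_model, rng)]
        reps[i] = _mntd_from_matrix(d.values[np.ix_(draw, draw)])
    nulls = NullDistribution(obs, reps, seed, null_model)
    return ses(obs, nulls, orientation="nti", plot=plot, statistic="NTI")


def trait_metric(
    values: Sequence[float],
    weights: Optional[Sequence[float]] = None,
    metric: str = "variance",
) -> float:
    """One trait-dispersion metric on >= 2 values.

    range     max - min (unweighted by definition)
    variance  sum w_i (x_i - xbar_w)^2 / sum w_i, xbar_w the weighted mean
    mpd_t     sum_{i<j} w_i w_j |x_i - x_j| / sum_{i<j} w_i w_j
    mntd_t    weighted mean of nearest-neighbour |x_i - x_j|
    Uniform weights reproduce the unweighted textbook value of each metric.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size < 2:
        raise ValueError("trait metric needs at least 2 values")
    if weights is None:
        w = np.ones_like(x)
    else:
        w = np.asarray(list(weights), dtype=float)
        if w.shape != x.shape:
            raise ValueError("weights length does not match values")
        if (w <= 0).any():
            raise ValueError("weights must be strictly positive")
    if metric == "range":
        return float(x.max() - x.min())
    if metric == "variance":
        xbar = float((w * x).sum() / w.sum())
        return float((w * (x - xbar) ** 2).sum() / w.sum())
    diff = np.abs(x[:, None] - x[None, :])
    if metric == "mpd_t":
        ww = np.outer(w, w)
        iu = np.triu_indices(x.size, 1)
        return float((ww[iu] * diff[iu]).sum() / ww[iu].sum())
    if metric == "mntd_t":
        np.fill_diagonal(diff, np.inf)
        nn = diff.min(axis=1)
        return float((w * nn).sum() / w.sum())
    raise ValueError(f"unknown metric {metric!r}; choose from {TRAIT_METRICS}")


def trait_ses(
    plot_species: Iterable[str],
    pool_values: pd.Series,
    weights: Optional[pd.Series] = None,
    metric: str = "variance",
    n_iter: int = 999,
    seed: int = 0,
    plot: object = None,
    null_model: str = "shuffle",
) -> SESResult:
    """SES of one trait-dispersion metric for one plot.

    ``pool_values`` maps every pool species to its trait value.  The null
    randomizes trait values over the pool; the plot's weights stay attached
    to its occupancy slots.
    """
    res = trait_ses_multi(
        plot_species, pool_values, weights, [metric], n_iter, seed, plot, null_model
    )
    return res[metric]


def trait_ses_multi(
    plot_species: Iterable[str],
    pool_values: pd.Series,
    weights: Optional[pd.Series],
    metrics: Sequence[str],
    n_iter: int = 999,
    seed: int = 0,
    plot: object = None,
    null_model: str = "shuffle",
) -> Dict[str, SESResult]:
    """Several metrics on one plot sharing the same null draws."""
    species = list(plot_species)
    if len(species) < 2:
        raise ValueError("trait SES needs at least 2 species")
    missing = [s for s in species if s not in pool_values.index]
    if missing:
        raise ValueError("species missing trait value: " + ", ".join(missing))
    if pool_values.isna().any():
        raise ValueError(
            "pool trait values contain NaN for "
            + ", ".join(map(str, pool_values.index[pool_values.isna()]))
        )
    for m in metrics:
        if m not in TRAIT_METRICS:
            raise ValueError(f"unknown metric {m!r}")
    pool_x = pool_values.to_numpy(dtype=float)
    pos = {s: i for i, s in enumerate(pool_values.index)}
    member_pos = np.array([pos[s] for s in species])
    if weights is not None:
        w = weights.loc[species].to_numpy(dtype=float)
    else:
        w = None
    obs = {m: trait_metric(pool_x[member_pos], w, m) for m in metrics}
    rng = derive_rng(seed, "trait_ses", plot, pool_values.name or "")
    reps = {m: np.empty(n_iter) for m in metrics}
    n_pool = pool_x.size
    for i in range(n_iter):
        draw = _null_member_indices(n_pool, member_pos, null_model, rng)
        xs = pool_x[draw]
        for m in metrics:
            reps[m][i] = trait_metric(xs, w, m)
    out = {}
    for m in metrics:
        nulls = NullDistribution(obs[m], reps[m], seed, null_model)
        out[m] = ses(obs[m], nulls, orientation="trait", plot=plot,
                     statistic=f"SES_{m}")
    return out


# -- table-level drivers ---------------------------------------------------


def nti_table(
    tree: PhyloTree,
    community: CommunityTable,
    n_iter: int = 999,
    seed: int = 0,
    null_model: str = "shuffle",
) -> pd.DataFrame:
    """Per-plot MNTD and NTI over all plots of a community table."""
    d = tree.patristic_matrix()
    tips = set(d.labels)
    orphans = sorted(set(community.all_species) - tips)
    if orphans:
        raise ValueError("community species absent from tree: " + ", ".join(orphans))
    rows = []
    for plot in community.plots:
        species = community.species_in(plot)
        if len(species) < 2:
            rows.append(
                {"plot": plot, "richness": len(species), "mntd_obs": np.nan,
                 "nti": np.nan, "nti_p": np.nan, "degenerate": True}
            )
            continue
        r = nti(species, d, n_iter=n_iter, seed=seed, plot=plot,
                null_model=null_model)
        rows.append(
            {"plot": plot, "richness": len(species), "mntd_obs": r.observed,
             "nti": r.ses, "nti_p": r.p, "degenerate": r.degenerate}
        )
    return pd.DataFrame(rows).set_index("plot")


def trait_ses_table(
    community: CommunityTable,
    traits: TraitTable,
    trait_names: Optional[Sequence[str]] = None,
    metrics: Sequence[str] = TRAIT_METRICS,
    weighted: bool = True,
    n_iter: int = 999,
    seed: int = 0,
    null_model: str = "shuffle",
    log10_traits: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-plot SES of each trait x metric combination.

    The pool for each trait is every species with a value in the trait table.
    ``log10_traits`` lists traits transformed to log10 before analysis
    (useful for strongly right-skewed traits such as LA, SM, H_max).
    """
    names = list(trait_names or traits.traits)
    rows = []
    for plot in community.plots:
        species = community.species_in(plot)
        iv = importance_values(community, plot) if weighted else None
        row = {"plot": plot, "richness": len(species)}
        for t in names:
            pool_values = traits.data[t].dropna()
            missing = [s for s in species if s not in pool_values.index]
            if missing:
                raise ValueError(
                    f"species missing trait {t!r}: " + ", ".join(missing)
                )
            if t in log10_traits:
                pool_values = np.log10(pool_values)
                pool_values.name = t
            if len(species) < 2:
                for m in metrics:
                    row[f"{t}:{m}:obs"] = np.nan
                    row[f"{t}:{m}:ses"] = np.nan
                    row[f"{t}:{m}:p"] = np.nan
                    row[f"{t}:{m}:degenerate"] = True
                continue
            res = trait_ses_multi(
                species, pool_values, iv, metrics, n_iter, seed, plot, null_model
            )
            for m in metrics:
                row[f"{t}:{m}:obs"] = res[m].observed
                row[f"{t}:{m}:ses"] = res[m].ses
                row[f"{t}:{m}:p"] = res[m].p
                row[f"{t}:{m}:degenerate"] = res[m].degenerate
        rows.append(row)
    return pd.DataFrame(rows).set_index("plot")
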