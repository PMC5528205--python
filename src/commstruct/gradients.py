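"""Environment-side statistics for gradient analyses.

Covers the abiotic workflow around the community statistics: soil water
content from fresh/dry masses, the pairwise Pearson correlation semimatrix of
environment factors, hierarchical variance partitioning (Chevan-Sutherland
all-subsets decomposition, as in R's ``hier.part``) of a per-plot response
(MNTD or a CWM) across environment factors, a PCA of standardized factors
yielding compound gradients, and simple OLS gradient regressions with an
optional quadratic term for U-shaped responses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .community import EnvTable


def soil_water_content(fresh: float, dry: float) -> float:
    """Gravimetric soil water content: (fresh - dry) / dry."""
    if dry <= 0:
        raise ValueError("dry mass must be positive")
    if fresh < dry:
        raise ValueError("fresh mass below dry mass")
    return (fresh - dry) / dry


def pearson_semimatrix(env: EnvTable, factors: Sequence[str]) -> pd.DataFrame:
    """Lower-triangle Pearson correlations (r, two-sided p) of factor pairs.

    A zero-variance factor is flagged: its pairs carry r = NaN rather than an
    exception, matching how a correlation table treats a constant column.
    """
    factors = list(factors)
    if len(env.plots) < 3:
        raise ValueError("need at least 3 plots for correlations")
    data = {f: env.column(f).to_numpy(dtype=float) for f in factors}
    rows = []
    for i in range(1, len(factors)):
        for j in range(i):
            f1, f2 = factors[i], factors[j]
            x, y = data[f1], data[f2]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                warnings.warn(f"zero-variance factor in pair ({f1}, {f2})")
                rows.append((f1, f2, np.nan, np.nan))
                continue
            r, p = stats.pearsonr(x, y)
            rows.append((f1, f2, float(r), float(p)))
    return pd.DataFrame(rows, columns=["factor1", "factor2", "r", "p"])


@dataclass
class PartitionResult:
    """Hierarchical variance partitioning of one response."""

    response: str
    predictors: List[str]
    independent: np.ndarray          # raw I per predictor
    joint: np.ndarray                # J = marginal R^2 - I
    independent_pct: np.ndarray      # I as % of sum(I)
    r2_full: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "independent": self.independent,
                "joint": self.joint,
                "independent_pct": self.independent_pct,
            },
            index=self.predictors,
        )


def _ols_r2(y: np.ndarray, X: Optional[np.ndarray]) -> float:
    n = y.size
    yc = y - y.mean()
    tss = float(yc @ yc)
    if tss == 0:
        return 0.0
    if X is None or X.shape[1] == 0:
        return 0.0
    A = np.column_stack([np.ones(n), X])
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1]:
        warnings.warn("rank-deficient design in a predictor subset; pseudo-inverse fit")
    resid = y - A @ coef
    return float(1.0 - (resid @ resid) / tss)


def hierarchical_partition(
    response: pd.Series,
    env: EnvTable,
    predictors: Sequence[str],
    name: str = "response",
) -> PartitionResult:
    """Chevan-Sutherland hierarchical partitioning with an OLS-R^2 goodness
    of fit.

    Fits all 2^k predictor subsets.  The independent contribution I_i of
    predictor i is the average, over hierarchy levels, of the mean R^2
    increase from adding i to subsets lacking it; the joint contribution is
    J_i = marginal R^2_i - I_i.  The I_i are a Shapley-value decomposition,
    so sum(I) equals the full-model R^2.  ``independent_pct`` reports each
    I_i as a percentage of sum(I).
    """
    predictors = list(predictors)
    k = len(predictors)
    if not 1 <= k <= 12:
        raise ValueError("1 to 12 predictors supported (2^k subset explosion)")
    plots = list(response.index)
    if len(plots) <= k + 1:
        raise ValueError("need more plots than predictors + 1")
    X = np.column_stack(
        [env.column(p, plots).to_numpy(dtype=float) for p in predictors]
    )
    _collinearity_check(X, predictors)
    y = response.to_numpy(dtype=float)

    r2: Dict[frozenset, float] = {frozenset(): 0.0}
    for size in range(1, k + 1):
        for subset in combinations(range(k), size):
            r2[frozenset(subset)] = _ols_r2(y, X[:, list(subset)])

    independent = np.zeros(k)
    for i in range(k):
        others = [j for j in range(k) if j != i]
        level_means = []
        for size in range(k):
            gains = [
                r2[frozenset(s) | {i}] - r2[frozenset(s)]
                for s in combinations(others, size)
            ]
            level_means.append(float(np.mean(gains)))
        independent[i] = float(np.mean(level_means))
    marginal = np.array([r2[frozenset({i})] for i in range(k)])
    joint = marginal - independent
    total_i = independent.sum()
    pct = 100.0 * independent / total_i if total_i > 0 else np.full(k, np.nan)
    return PartitionResult(
        response=name,
        predictors=predictors,
        independent=independent,
        joint=joint,
        independent_pct=pct,
        r2_full=r2[frozenset(range(k))],
    )


def _collinearity_check(X: np.ndarray, names: Sequence[str], limit: float = 0.999):
    """Refuse near-duplicate predictor pairs (|r| > limit), which make the
    partitioning meaningless (e.g. a factor that is a deterministic function
    of another, like MAT derived from elevation)."""
    k = X.shape[1]
    for i in range(k):
        for j in range(i + 1, k):
            if np.ptp(X[:, i]) == 0 or np.ptp(X[:, j]) == 0:
                bad = names[i] if np.ptp(X[:, i]) == 0 else names[j]
                raise ValueError(f"constant predictor {bad!r}")
            r = np.corrcoef(X[:, i], X[:, j])[0, 1]
            if abs(r) > limit:
                raise ValueError(
                    f"predictors {names[i]!r} and {names[j]!r} are collinear "
                    f"(|r| = {abs(r):.4f} > {limit}); drop one"
                )


def partition_table(
    responses: pd.DataFrame, env: EnvTable, predictors: Sequence[str]
) -> pd.DataFrame:
    """Predictor x response table of independent contributions in percent
    (each column sums to 100), one column per response."""
    cols = {}
    for name in responses.columns:
        res = hierarchical_partition(responses[name].dropna(), env, predictors, name)
        cols[name] = pd.Series(res.independent_pct, index=res.predictors)
    return pd.DataFrame(cols)


@dataclass
class PcaResult:
    factors: List[str]
    loadings: np.ndarray        # factors x axes, orthonormal columns
    scores: pd.DataFrame        # plots x axes
    pct_variance: np.ndarray    # per axis, non-increasing

    def loadings_frame(self) -> pd.DataFrame:
        axes = [f"PC{i+1}" for i in range(self.loadings.shape[1])]
        return pd.DataFrame(self.loadings, index=self.factors, columns=axes)


def pca_env(env: EnvTable, factors: Sequence[str], n_axes: int = 2) -> PcaResult:
    """PCA of the correlation matrix of standardized environment factors.

    Axis signs are fixed so the largest-|loading| factor of each axis loads
    positive.  Scores are the standardized data projected on the loadings.
    """
    factors = list(factors)
    if n_axes > len(factors):
        raise ValueError("n_axes exceeds number of factors")
    plots = env.plots
    if len(plots) < 3:
        raise ValueError("need at least 3 plots for PCA")
    X = np.column_stack([env.column(f).to_numpy(dtype=float) for f in factors])
    sds = X.std(axis=0, ddof=1)
    if (sds == 0).any():
        bad = [factors[i] for i in np.where(sds == 0)[0]]
        raise ValueError("constant factor(s): " + ", ".join(bad))
    Z = (X - X.mean(axis=0)) / sds
    corr = np.corrcoef(Z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0, None)
    load = eigvec[:, :n_axes]
    for a in range(n_axes):
        top = np.argmax(np.abs(load[:, a]))
        if load[top, a] < 0:
            load[:, a] = -load[:, a]
    scores = Z @ load
    pct = 100.0 * eigval[:n_axes] / eigval.sum()
    return PcaResult(
        factors=factors,
        loadings=load,
        scores=pd.DataFrame(
            scores, index=plots, columns=[f"PC{i+1}" for i in range(n_axes)]
        ),
        pct_variance=pct,
    )


def gradient_regression(
    y: pd.Series,
    env: EnvTable,
    factor: str,
    quadratic: bool = False,
) -> Dict:
    """OLS regression of a per-plot statistic on one environment factor.

    Returns slope, intercept, R^2 and the ANOVA (F-test) p.  With
    ``quadratic=True`` a squared term is added and its t-test p reported
    (``p_quadratic``), for U-shaped responses.  A constant response returns
    slope 0 with p = 1 by convention.
    """
    yv = y.dropna()
    if len(yv) < 3:
        raise ValueError("need at least 3 plots with defined response")
    x = env.column(factor, yv.index).to_numpy(dtype=float)
    yy = yv.to_numpy(dtype=float)
    out: Dict = {"factor": factor, "n": int(len(yv)), "quadratic": quadratic}
    if np.ptp(yy) == 0:
        out.update(slope=0.0, intercept=float(yy[0]), r2=0.0, p=1.0)
        if quadratic:
            out.update(coef_quadratic=0.0, p_quadratic=1.0)
        return out
    import statsmodels.api as sm

    cols = [x] + ([x**2] if quadratic else [])
    X = sm.add_constant(np.column_stack(cols))
    fit = sm.OLS(yy, X).fit()
    out.update(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r2=float(fit.rsquared),
        p=float(fit.f_pvalue),
    )
    if quadratic:
        out.update(
            coef_quadratic=float(fit.params[2]),
            p_quadratic=float(fit.pvalues[2]),
        )
    return out
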