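"""Randomization engines and standardized-effect-size (SES) machinery.

Community structure statistics (MNTD, trait dispersion) are interpreted
against a null distribution obtained by randomizing species identities over
the regional pool while holding each plot's richness (and, for weighted trait
metrics, its occupancy weights) fixed.  Two nulls are provided:

``shuffle``
    Draw a uniform permutation of the pool labels and push the community
    through it.  Membership structure is untouched; identities are relabelled.
``richness``
    Draw a uniform k-subset of the pool, k = plot richness.

For a single plot's presence-based statistic the two coincide in
distribution; both are kept because multi-plot co-occurrence structure (which
the shuffle preserves) can matter to downstream users.

SES = (observed - null mean) / null sd, with the sample (n-1) sd convention.
The nearest taxon index (NTI) negates this z-score so that positive values
mean phylogenetic clustering; trait SES keeps the raw sign so that positive
values mean functional overdispersion.  Rank p-values use the +1 correction
(the observation counts as one more replicate), so p is never 0.

Reproducibility: one root seed governs a run; each (plot, stage) gets its own
substream via a stable blake2b hash, so plot processing order never changes
any result.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np


def derive_rng(seed: int, *scope) -> np.random.Generator:
    """Deterministic substream for a named scope, independent of call order."""
    key = ":".join([str(int(seed))] + [str(s) for s in scope])
    digest = hashlib.blake2b(key.encode(), digest_size=8).digest()
    return np.random.default_rng(int.from_bytes(digest, "big") & 0x7FFFFFFFFFFFFFFF)


@dataclass
class NullDistribution:
    """Observed statistic plus its randomized replicates."""

    observed: float
    replicates: np.ndarray
    seed: Optional[int]
    null_model: str

    def __post_init__(self):
        self.replicates = np.asarray(self.replicates, dtype=float)
        if self.replicates.size < 1:
            raise ValueError("need at least one null replicate")

    @property
    def n_null(self) -> int:
        return int(self.replicates.size)

    @property
    def mean(self) -> float:
        return float(self.replicates.mean())

    @property
    def sd(self) -> float:
        if self.replicates.size < 2:
            return 0.0
        return float(self.replicates.std(ddof=1))


@dataclass
class SESResult:
    """Standardized effect size of one statistic in one plot."""

    plot: object
    statistic: str
    observed: float
    null_mean: float
    null_sd: float
    ses: float
    p: float
    degenerate: bool = False

    def as_dict(self) -> Dict:
        return {
            "plot": self.plot,
            "statistic": self.statistic,
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "ses": self.ses,
            "p": self.p,
            "degenerate": self.degenerate,
        }


def shuffle_labels(pool: Sequence[str], rng: np.random.Generator) -> Dict[str, str]:
    """Uniform random bijection pool -> pool (identity relabelling)."""
    pool = list(pool)
    if not pool:
        raise ValueError("empty pool")
    perm = rng.permutation(len(pool))
    return {pool[i]: pool[perm[i]] for i in range(len(pool))}


def draw_richness_null(
    pool: Sequence[str], k: int, rng: np.random.Generator
) -> List[str]:
    """Uniform k-subset of the pool, without replacement."""
    pool = list(pool)
    if not 1 <= k <= len(pool):
        raise ValueError(f"k={k} out of range 1..{len(pool)}")
    idx = rng.choice(len(pool), size=k, replace=False)
    return [pool[i] for i in idx]


def null_distribution(
    stat_fn: Callable,
    null_gen: Callable[[np.random.Generator], object],
    n_iter: int,
    seed: Optional[int] = None,
    observed: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
    null_model: str = "custom",
) -> NullDistribution:
    """Compute ``stat_fn`` on ``n_iter`` randomized samples from ``null_gen``.

    ``null_gen(rng)`` produces one randomized sample; ``stat_fn(sample)``
    evaluates the statistic on it.  A failure on replicate *i* is re-raised
    naming *i*.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    reps = np.empty(n_iter)
    for i in range(n_iter):
        sample = null_gen(rng)
        try:
            reps[i] = stat_fn(sample)
        except Exception as exc:
            raise RuntimeError(f"statistic failed on null replicate {i}: {exc}") from exc
    return NullDistribution(
        observed=np.nan if observed is None else float(observed),
        replicates=reps,
        seed=seed,
        null_model=null_model,
    )


def rank_p(observed: float, replicates: np.ndarray) -> float:
    """Two-tailed rank p with the +1 correction, capped at 1."""
    replicates = np.asarray(replicates, dtype=float)
    n = replicates.size
    r_low = int(np.sum(replicates <= observed)) + 1
    r_high = int(np.sum(replicates >= observed)) + 1
    return min(1.0, 2.0 * min(r_low, r_high) / (n + 1))


def ses(
    observed: float,
    nulls: NullDistribution,
    orientation: str = "trait",
    plot: object = None,
    statistic: str = "",
) -> SESResult:
    """Standardized effect size against a null distribution.

    ``orientation="trait"`` keeps the raw z (positive = overdispersion);
    ``orientation="nti"`` negates it (positive = phylogenetic clustering).
    A zero null sd yields a degenerate-flagged result, not an exception.
    """
    if orientation not in ("trait", "nti"):
        raise ValueError("orientation must be 'trait' or 'nti'")
    mu, sd = nulls.mean, nulls.sd
    if sd == 0 or not np.isfinite(sd):
        warnings.warn(
            f"degenerate null (sd=0) for statistic {statistic!r} in plot {plot!r}"
        )
        return SESResult(plot, statistic, observed, mu, sd, np.nan, np.nan, True)
    z = (observed - mu) / sd
    if orientation == "nti":
        z = -z
    return SESResult(
        plot, statistic, observed, mu, sd, z, rank_p(observed, nulls.replicates), False
    )
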