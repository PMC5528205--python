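"""Synthetic study generator: pool phylogeny, evolved traits, correlated
environmental gradient, and communities assembled under known regimes.

The generator emulates the design of an elevational woody-plant community
survey: 40 plots spanning 1,140-3,480 m, a regional pool of 389 species of
which ~148 are observed, soil factors correlated with elevation (soil water
content most strongly, r ~ 0.895), traits evolved on the pool phylogeny, and
per-plot communities assembled under one of three regimes:

``neutral``
    Uniform draws from the observed pool -- every species equally likely.
``filtering``
    Inclusion probability proportional to
    exp(-(trait - optimum(elevation))^2 / (2 tau^2)) with tau shrinking as
    the regime strength grows; selects trait-similar (and, for a conserved
    trait, phylogenetically close) species, producing clustering.
``limiting_similarity``
    Sequential draws rejecting candidates whose trait distance to any
    resident falls below a threshold that grows with strength; spreads trait
    values out, producing overdispersion.

Strength 0 reduces every regime to neutral.  Abundance, mean height, and
coverage are log-normal; they can optionally be coupled to the focal trait
so importance-value weighting is exercised against informative weights
(default coupling 0: ecological equivalence).  One seed reproduces a study
bit-identically.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, Mapping, Optional, Sequence, Tuple, Union

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .community import CommunityTable, EnvTable, TraitTable
from .nulls import derive_rng
from .tree import PhyloTree, parse_newick

#: Pearson correlation of each factor with elevation (survey defaults; the
#: soil factors track elevation, NN/slope do not).  WCD is computed from the
#: assembled communities, not generated.
DEFAULT_ENV_CORR: Dict[str, float] = {
    "SWC": 0.895,
    "TN": 0.470,
    "AN": 0.456,
    "NN": -0.005,
    "RAP": 0.492,
    "pH": 0.349,
    "slope": -0.131,
}

#: marginal (mean, sd) on each factor's natural scale
ENV_SCALES: Dict[str, Tuple[float, float]] = {
    "SWC": (0.45, 0.15),       # g/g
    "TN": (2.0, 0.6),          # g/kg
    "AN": (15.0, 4.0),         # mg/kg
    "NN": (5.0, 1.5),          # mg/kg
    "RAP": (10.0, 3.0),        # mg/kg
    "pH": (6.3, 0.7),
    "slope": (25.0, 8.0),      # degrees
}

# Pearson attenuation from passing one Gaussian of a correlated pair through
# the probit-to-uniform transform: corr(Phi(Z1), Z2) = rho * sqrt(12)/(2 sqrt(pi))
_UNIFORM_ATTENUATION = math.sqrt(12.0) / (2.0 * math.sqrt(math.pi))


@dataclass
class ScenarioConfig:
    """Full description of one synthetic study."""

    n_pool: int = 389
    n_observed: int = 148
    n_plots: int = 40
    elevation_range: Tuple[float, float] = (1140.0, 3480.0)
    env_corr: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ENV_CORR)
    )
    birth_rate: float = 1.0
    tree_depth: float = 1.0
    bm_sigma2: float = 1.0
    bm_root: float = 0.0
    regime: str = "neutral"
    strength: float = 0.0
    richness_range: Tuple[int, int] = (10, 25)
    abundance_lognormal: Tuple[float, float] = (1.0, 1.0)
    weight_trait_corr: float = 0.0
    focal_trait: str = "trait1"
    n_traits: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_pool < 2 or self.n_plots < 1 or self.n_observed < 2:
            raise ValueError("counts must be positive (pool/observed >= 2)")
        if self.n_observed > self.n_pool:
            raise ValueError("n_observed exceeds n_pool")
        lo, hi = self.elevation_range
        if not hi > lo:
            raise ValueError("elevation range must be increasing")
        if self.strength < 0:
            raise ValueError("regime strength must be >= 0")
        for f, r in self.env_corr.items():
            if not -1 < r < 1:
                raise ValueError(f"correlation target for {f} outside (-1, 1)")
        if self.regime not in ("neutral", "filtering", "limiting_similarity"):
            raise ValueError(f"unknown regime {self.regime!r}")


@dataclass
class SyntheticStudy:
    config: ScenarioConfig
    tree: PhyloTree
    traits: TraitTable
    env: EnvTable
    community: CommunityTable
    truth: pd.DataFrame  # per-plot regime label and strength

    def write(self, outdir) -> Dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "tree": outdir / "pool.nwk",
            "traits": outdir / "traits.tsv",
            "env": outdir / "env.tsv",
            "community": outdir / "community.tsv",
            "truth": outdir / "truth.tsv",
        }
        paths["tree"].write_text(self.tree.newick() + "\n")
        self.traits.to_tsv(paths["traits"])
        self.env.to_tsv(paths["env"])
        self.community.to_tsv(paths["community"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


# -- tree simulation -------------------------------------------------------


def simulate_yule(
    n_tips: int, seed: int = 0, birth_rate: float = 1.0, depth: Optional[float] = None
) -> PhyloTree:
    """Pure-birth (Yule) ultrametric tree with tips sp0001..spNNNN.

    Waiting time between successive birth events with m extant lineages is
    Exp(m * birth_rate); the lineage that splits is uniform.  All pendant
    branches are extended to the present, so the tree is ultrametric.  With
    ``depth`` given, total height is rescaled to it.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = derive_rng(seed, "yule", n_tips)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    t = 0.0
    # active: list of (node, birth_time)
    c1, c2 = dendropy.Node(), dendropy.Node()
    root.add_child(c1)
    root.add_child(c2)
    active = [(c1, 0.0), (c2, 0.0)]
    while len(active) < n_tips:
        m = len(active)
        t += rng.exponential(1.0 / (birth_rate * m))
        i = int(rng.integers(m))
        node, born = active.pop(i)
        node.edge.length = t - born
        a, b = dendropy.Node(), dendropy.Node()
        node.add_child(a)
        node.add_child(b)
        active.append((a, t))
        active.append((b, t))
    t += rng.exponential(1.0 / (birth_rate * n_tips))
    width = len(str(n_tips))
    for j, (node, born) in enumerate(active):
        node.edge.length = t - born
        node.taxon = taxa.new_taxon(label=f"sp{j + 1:0{width}d}")
    out = PhyloTree(tree)
    if depth is not None:
        scale = depth / out.depth()
        for node in out.dendropy_tree.preorder_node_iter():
            if node.parent_node is not None:
                node.edge.length *= scale
    return out


# -- trait evolution -------------------------------------------------------


def evolve_bm(
    tree: PhyloTree, sigma2: float, root: float = 0.0, seed: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> pd.Series:
    """Brownian-motion tip values: Gaussian increments of variance
    sigma2 * branch length down the tree."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    tree._require_lengths()
    if rng is None:
        rng = derive_rng(seed, "bm")
    values: Dict = {}
    out = {}
    for node in tree.dendropy_tree.preorder_node_iter():
        if node.parent_node is None:
            values[node] = float(root)
        else:
            bl = node.edge.length
            values[node] = values[node.parent_node] + rng.normal(
                0.0, math.sqrt(sigma2 * bl)
            )
        if node.is_leaf():
            out[node.taxon.label if node.taxon else node.label] = values[node]
    return pd.Series(out, name="trait")


def evolve_ou_gradient(
    tree: PhyloTree,
    strength: Union[float, Callable[[float], float]],
    sigma2: float,
    optimum_fn: Callable[[float], float],
    plot_elevations: Mapping[object, float],
    root: float = 0.0,
    seed: int = 0,
) -> Dict[object, pd.Series]:
    """Per-plot Ornstein-Uhlenbeck tip values with an elevation-linked optimum.

    For plot p at elevation e, trait values evolve on the tree under OU with
    optimum theta = optimum_fn(e) and pull alpha = strength (a scalar, or a
    callable of elevation).  alpha = 0 reduces exactly to Brownian motion;
    alpha -> infinity pins every tip to the optimum.  Each plot draws an
    independent realization from its own substream of ``seed``.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    tree._require_lengths()
    out = {}
    for plot, elev in plot_elevations.items():
        alpha = float(strength(elev)) if callable(strength) else float(strength)
        if alpha < 0:
            raise ValueError("OU strength must be >= 0")
        theta = float(optimum_fn(elev))
        rng = derive_rng(seed, "ou", plot)
        values: Dict = {}
        tips = {}
        for node in tree.dendropy_tree.preorder_node_iter():
            if node.parent_node is None:
                values[node] = float(root)
            else:
                t = node.edge.length
                x0 = values[node.parent_node]
                if alpha == 0:
                    mean, var = x0, sigma2 * t
                else:
                    decay = math.exp(-alpha * t)
                    mean = theta + (x0 - theta) * decay
                    var = sigma2 * (1.0 - decay**2) / (2.0 * alpha)
                values[node] = mean + rng.normal(0.0, math.sqrt(var)) if var > 0 else mean
            if node.is_leaf():
                tips[node.taxon.label if node.taxon else node.label] = values[node]
        out[plot] = pd.Series(tips, name=f"trait@{plot}")
    return out


# -- environment -----------------------------------------------------------


def generate_env(
    n_plots: int,
    elevation_range: Tuple[float, float] = (1140.0, 3480.0),
    corr_targets: Optional[Mapping[str, float]] = None,
    seed: int = 0,
    plot_ids: Optional[Sequence[str]] = None,
) -> EnvTable:
    """Plot x environment table with factors correlated to elevation.

    Elevation is uniform over its range (probit-transformed from the latent
    Gaussian); each factor f is Gaussian with latent correlation to elevation
    chosen so the *realized* Pearson correlation hits the target despite the
    uniform transform's attenuation.  The one-factor (single latent driver)
    structure keeps the implied correlation matrix positive definite for any
    feasible target set.
    """
    if corr_targets is None:
        corr_targets = dict(DEFAULT_ENV_CORR)
    lo, hi = elevation_range
    if not hi > lo:
        raise ValueError("elevation range must be increasing")
    rng = derive_rng(seed, "env")
    z_elev = rng.normal(size=n_plots)
    elev = lo + (hi - lo) * stats.norm.cdf(z_elev)
    data = {"elevation": elev}
    for factor, target in corr_targets.items():
        rho = target / _UNIFORM_ATTENUATION
        if abs(rho) >= 1:
            raise ValueError(
                f"correlation target {target} for {factor!r} infeasible with a "
                f"uniform elevation (max |r| = {_UNIFORM_ATTENUATION:.3f})"
            )
        z = rho * z_elev + math.sqrt(1.0 - rho**2) * rng.normal(size=n_plots)
        mean, sd = ENV_SCALES.get(factor, (0.0, 1.0))
        vals = mean + sd * z
        if factor in ("SWC", "TN", "AN", "NN", "RAP"):
            vals = np.clip(vals, 1e-3, None)  # physical non-negativity
        data[factor] = vals
    if plot_ids is None:
        plot_ids = [f"plot{i + 1:02d}" for i in range(n_plots)]
    return EnvTable(pd.DataFrame(data, index=list(plot_ids)))


# -- assembly --------------------------------------------------------------


def _gumbel_top_k(log_w: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k indices without replacement with probability proportional to exp(log_w)."""
    g = rng.gumbel(size=log_w.size)
    return np.argsort(-(log_w + g))[:k]


def assemble(
    pool_traits: pd.Series,
    env: EnvTable,
    regime: str = "neutral",
    strength: float = 0.0,
    richness_range: Tuple[int, int] = (10, 25),
    seed: int = 0,
    abundance_lognormal: Tuple[float, float] = (1.0, 1.0),
    weight_trait_corr: float = 0.0,
    available: Optional[Sequence[str]] = None,
    optimum_fn: Optional[Callable[[float], float]] = None,
    max_restarts: int = 200,
) -> CommunityTable:
    """Assemble one community per plot of ``env`` under a known regime.

    ``pool_traits`` maps every pool species to the focal trait value;
    ``available`` optionally restricts draws to the observed species pool.
    Abundance is log-normal (rounded up to >= 1 individual); mean height and
    coverage are log-normal, optionally rank-coupled to the focal trait with
    correlation ``weight_trait_corr`` so importance values carry signal.
    """
    if regime not in ("neutral", "filtering", "limiting_similarity"):
        raise ValueError(f"unknown regime {regime!r}")
    if strength < 0:
        raise ValueError("strength must be >= 0")
    species = list(available) if available is not None else list(pool_traits.index)
    x = pool_traits.loc[species].to_numpy(dtype=float)
    n_avail = len(species)
    lo_k, hi_k = richness_range
    if hi_k > n_avail:
        raise ValueError("richness range exceeds available pool size")
    mu_pool, sd_pool = float(np.mean(x)), float(np.std(x))
    rng_pool = pool_traits.to_numpy(dtype=float)
    elev = env.column("elevation")
    e_lo, e_hi = float(elev.min()), float(elev.max())
    if optimum_fn is None:
        span = e_hi - e_lo if e_hi > e_lo else 1.0

        def optimum_fn(e):  # linear sweep across the pool trait range
            u = (e - e_lo) / span
            return mu_pool + (2.0 * u - 1.0) * 1.5 * sd_pool

    records = []
    for plot in env.plots:
        rng = derive_rng(seed, "assemble", plot)
        k = int(rng.integers(lo_k, hi_k + 1))
        if regime == "neutral" or strength == 0.0:
            chosen = rng.choice(n_avail, size=k, replace=False)
        elif regime == "filtering":
            tau = sd_pool / strength
            opt = optimum_fn(float(elev.loc[plot]))
            log_w = -((x - opt) ** 2) / (2.0 * tau**2)
            chosen = _gumbel_top_k(log_w, k, rng)
        else:  # limiting_similarity
            delta = strength * sd_pool / k
            chosen = _limiting_similarity_draw(x, k, delta, rng, max_restarts)
        chosen = np.asarray(sorted(chosen))
        names = [species[i] for i in chosen]
        mu_a, sd_a = abundance_lognormal
        abund = np.ceil(rng.lognormal(mu_a, sd_a, size=k))
        if weight_trait_corr != 0.0:
            z_trait = stats.zscore(x[chosen]) if np.ptp(x[chosen]) > 0 else np.zeros(k)
            r = weight_trait_corr
            zh = r * z_trait + math.sqrt(1 - r**2) * rng.normal(size=k)
            zc = r * z_trait + math.sqrt(1 - r**2) * rng.normal(size=k)
        else:
            zh = rng.normal(size=k)
            zc = rng.normal(size=k)
        height = np.exp(1.5 + 0.5 * zh)          # ~ 4.5 m median
        coverage = np.exp(-2.5 + 0.8 * zc)       # fractional cover per species
        for s, a, h, c in zip(names, abund, height, coverage):
            records.append((plot, s, float(a), float(h), float(c)))
    return CommunityTable(
        pd.DataFrame(
            records, columns=["plot", "species", "abundance", "height", "coverage"]
        )
    )


def _limiting_similarity_draw(
    x: np.ndarray, k: int, delta: float, rng: np.random.Generator, max_restarts: int
) -> np.ndarray:
    for _ in range(max_restarts):
        order = rng.permutation(x.size)
        chosen: list = []
        for cand in order:
            if all(abs(x[cand] - x[r]) >= delta for r in chosen):
                chosen.append(int(cand))
                if len(chosen) == k:
                    return np.array(chosen)
    raise RuntimeError(
        f"could not seat {k} species with minimum trait gap {delta:.4g} after "
        f"{max_restarts} restarts; lower the regime strength or richness"
    )


# -- full scenario ---------------------------------------------------------


def scenario_suite(config: ScenarioConfig, outdir=None) -> SyntheticStudy:
    """End-to-end synthetic study from one config (bit-reproducible per seed).

    Traits trait1..traitN evolve independently under Brownian motion on the
    pool tree; trait1 is the focal (assembly-relevant) trait.  The observed
    community pool is a uniform ``n_observed``-subset of the regional pool.
    Environment factors follow the configured elevation correlations; WCD is
    computed from the assembled communities afterwards.
    """
    cfg = config
    tree = simulate_yule(cfg.n_pool, seed=cfg.seed, birth_rate=cfg.birth_rate,
                         depth=cfg.tree_depth)
    trait_names = [f"trait{i + 1}" for i in range(cfg.n_traits)]
    traits = pd.DataFrame(
        {
            name: evolve_bm(tree, cfg.bm_sigma2, cfg.bm_root,
                            rng=derive_rng(cfg.seed, "bm", name))
            for name in trait_names
        }
    )
    env = generate_env(
        cfg.n_plots, cfg.elevation_range, cfg.env_corr, seed=cfg.seed
    )
    rng = derive_rng(cfg.seed, "observed_pool")
    observed = sorted(
        rng.choice(tree.tip_labels, size=cfg.n_observed, replace=False)
    )
    community = assemble(
        traits[cfg.focal_trait],
        env,
        regime=cfg.regime,
        strength=cfg.strength,
        richness_range=cfg.richness_range,
        seed=cfg.seed,
        abundance_lognormal=cfg.abundance_lognormal,
        weight_trait_corr=cfg.weight_trait_corr,
        available=observed,
    )
    env_full = env.data.copy()
    env_full["WCD"] = community.wcd().reindex(env_full.index).fillna(0.0)
    truth = pd.DataFrame(
        {
            "plot": env.plots,
            "regime": cfg.regime,
            "strength": cfg.strength,
            "focal_trait": cfg.focal_trait,
        }
    )
    study = SyntheticStudy(
        config=cfg,
        tree=tree,
        traits=TraitTable(traits),
        env=EnvTable(env_full),
        community=community,
        truth=truth,
    )
    if outdir is not None:
        study.write(outdir)
    return study
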