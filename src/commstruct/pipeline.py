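"""End-to-end analysis pipeline and run manifest.

Reproduces the full gradient analysis sequence on one data bundle (tree +
community + traits + environment, real or synthetic): environment correlation
semimatrix, community-weighted means, hierarchical variance partitioning of
MNTD and each CWM across environment factors, PCA compound gradients,
per-plot NTI and trait SES, and per-community Blomberg's K with its trend
along gradients.  All outputs are TSV with a commented header carrying
units/metadata, plus a JSON manifest (input checksums, seed, version) that
suffices to reproduce the bundle bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .community import (
    CommunityTable,
    EnvTable,
    TraitTable,
    cwm_table,
    read_community_long,
    read_env,
    read_traits,
)
from .dispersion import TRAIT_METRICS, nti_table, trait_ses_table
from .gradients import partition_table, pca_env, pearson_semimatrix
from .signal import community_signal_table, signal_along_gradient
from .synthetic import ScenarioConfig, scenario_suite
from .tree import PhyloTree


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    tree_path: Optional[str] = None
    community_path: Optional[str] = None
    traits_path: Optional[str] = None
    env_path: Optional[str] = None
    scenario: Optional[ScenarioConfig] = None
    null_model: str = "shuffle"
    n_iter: int = 999
    n_perm: int = 999
    seed: int = 0
    metric: str = "variance"
    weighted: bool = True
    log10_traits: Sequence[str] = ()
    env_factors: Optional[Sequence[str]] = None
    outdir: str = "run"

    def __post_init__(self):
        real = all(
            p is not None
            for p in (self.tree_path, self.community_path, self.traits_path,
                      self.env_path)
        )
        if not real and self.scenario is None:
            raise ValueError("provide the four input paths or a scenario config")
        if self.n_iter < 1 or self.n_perm < 1:
            raise ValueError("n_iter and n_perm must be >= 1")


def _write_tsv(df: pd.DataFrame, path: Path, comment: str, index: bool = True):
    with open(path, "w") as fh:
        fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=index)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Dict[str, Path]:
    """Run the full analysis; returns the map of emitted files.

    Inputs are cross-validated first (community species must be tips of the
    tree and rows of the trait table); partial outputs are removed if any
    stage fails.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs: Dict[str, Path] = {}
    if config.scenario is not None:
        datadir = outdir / "data"
        study = scenario_suite(config.scenario)
        tree, community, traits, env = (
            study.tree, study.community, study.traits, study.env,
        )
        inputs = study.write(datadir)
    else:
        inputs = {
            "tree": Path(config.tree_path),
            "community": Path(config.community_path),
            "traits": Path(config.traits_path),
            "env": Path(config.env_path),
        }
        tree = PhyloTree.from_file(inputs["tree"])
        community = read_community_long(inputs["community"])
        traits = read_traits(inputs["traits"])
        env = read_env(inputs["env"])

    # cross-validation before any statistic runs
    tips = set(tree.tip_labels)
    orphans_tree = sorted(set(community.all_species) - tips)
    orphans_traits = sorted(set(community.all_species) - set(traits.species))
    orphans_env = sorted(set(community.plots) - set(env.plots))
    problems = []
    if orphans_tree:
        problems.append("species missing from tree: " + ", ".join(orphans_tree))
    if orphans_traits:
        problems.append("species missing from traits: " + ", ".join(orphans_traits))
    if orphans_env:
        problems.append("plots missing from env table: " + ", ".join(orphans_env))
    if problems:
        raise ValueError("; ".join(problems))

    factors = list(
        config.env_factors
        or [f for f in env.factors if f not in ("elevation",)]
    )
    outputs: Dict[str, Path] = {}
    try:
        semi = pearson_semimatrix(env, ["elevation"] + factors)
        outputs["semimatrix"] = outdir / "semimatrix.tsv"
        _write_tsv(semi, outputs["semimatrix"],
                   "pairwise Pearson correlations of environment factors",
                   index=False)

        cwms = cwm_table(community, traits)
        outputs["cwm"] = outdir / "cwm.tsv"
        _write_tsv(cwms, outputs["cwm"],
                   "community-weighted means (importance-value weights)")

        ntis = nti_table(tree, community, n_iter=config.n_iter,
                         seed=config.seed, null_model=config.null_model)
        outputs["nti"] = outdir / "nti.tsv"
        _write_tsv(ntis, outputs["nti"],
                   f"MNTD (time units) and NTI; null={config.null_model}, "
                   f"n_iter={config.n_iter}, seed={config.seed}")

        responses = cwms.copy()
        responses.insert(0, "MNTD", ntis["mntd_obs"])
        part = partition_table(responses, env, ["elevation"] + factors)
        outputs["varpart"] = outdir / "varpart.tsv"
        _write_tsv(part, outputs["varpart"],
                   "hierarchical partitioning: independent contributions, "
                   "% of their sum, per response column")

        pca = pca_env(env, factors, n_axes=2)
        outputs["pca_loadings"] = outdir / "pca_loadings.tsv"
        _write_tsv(pca.loadings_frame(), outputs["pca_loadings"],
                   "PCA loadings of standardized environment factors")
        outputs["pca_scores"] = outdir / "pca_scores.tsv"
        _write_tsv(pca.scores, outputs["pca_scores"],
                   "per-plot PCA scores; % variance: "
                   + ", ".join(f"{v:.2f}" for v in pca.pct_variance))

        ses = trait_ses_table(
            community, traits, metrics=TRAIT_METRICS,
            weighted=config.weighted, n_iter=config.n_iter, seed=config.seed,
            null_model=config.null_model, log10_traits=config.log10_traits,
        )
        outputs["trait_ses"] = outdir / "trait_ses.tsv"
        _write_tsv(ses, outputs["trait_ses"],
                   f"SES trait dispersion (positive = overdispersion); "
                   f"weighted={config.weighted}, n_iter={config.n_iter}")

        ksig = community_signal_table(
            tree, community, traits, n_perm=config.n_perm, seed=config.seed,
            log10_traits=config.log10_traits,
        )
        outputs["signal"] = outdir / "signal.tsv"
        _write_tsv(ksig, outputs["signal"],
                   "per-community Blomberg's K with permutation p", index=False)

        trends = []
        for t in traits.traits:
            sub = ksig[ksig["trait"] == t]
            if (~sub["degenerate"].astype(bool)).sum() >= 3:
                trends.append(signal_along_gradient(ksig, env, "elevation", t))
        outputs["signal_trends"] = outdir / "signal_trends.tsv"
        _write_tsv(pd.DataFrame(trends), outputs["signal_trends"],
                   "OLS trend of per-community K along elevation", index=False)

        manifest = {
            "version": __version__,
            "seed": config.seed,
            "n_iter": config.n_iter,
            "n_perm": config.n_perm,
            "null_model": config.null_model,
            "weighted": config.weighted,
            "log10_traits": list(config.log10_traits),
            "inputs": {k: {"path": str(v), "sha256": _sha256(v)}
                       for k, v in inputs.items()},
            "outputs": {k: str(v) for k, v in outputs.items()},
            "scenario": (dataclasses.asdict(config.scenario)
                         if config.scenario else None),
        }
        man_path = outdir / "manifest.json"
        man_path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
        outputs["manifest"] = man_path
    except Exception:
        for p in outputs.values():
            p.unlink(missing_ok=True)
        raise
    return outputs
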