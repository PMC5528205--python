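"""Community, trait, and environment tables; importance values; CWMs.

Field layout mirrors a plot-based vegetation survey: a long-format community
table of (plot, species, abundance, height, coverage) records, a species x
trait matrix for the eight woody-plant traits analysed here (LA, SLA, LDMC,
H_max, LNC, LCC, C:N, SM), and a plot x environment table (elevation, SWC,
soil nutrients, pH, slope, WCD).

The importance value (IV) of a species in a plot is the mean of its relative
abundance, relative height, and relative coverage; IVs within a plot sum to 1
and weight the community-weighted mean (CWM) of each trait.  Trees and shrubs
are mixed in these communities, so abundance alone would misstate ecological
importance -- hence the three-component IV rather than relative abundance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional

import numpy as np
import pandas as pd

#: canonical trait names (units: cm^2, cm^2/g, g/g, m, mg/g, mg/g, ratio, mg)
CANONICAL_TRAITS = ["LA", "SLA", "LDMC", "H_max", "LNC", "LCC", "C:N", "SM"]

COMMUNITY_COLUMNS = ["plot", "species", "abundance", "height", "coverage"]


class TableError(ValueError):
    """Invalid tabular input."""


@dataclass
class CommunityTable:
    """Long-format plot x species records."""

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        missing = [c for c in COMMUNITY_COLUMNS if c not in df.columns]
        if missing:
            raise TableError("community table missing column(s): " + ", ".join(missing))
        df = df.copy()
        for col, kind in [("abundance", float), ("height", float), ("coverage", float)]:
            try:
                df[col] = df[col].astype(float)
            except (TypeError, ValueError) as exc:
                raise TableError(f"non-numeric value in column {col!r}: {exc}") from exc
        dup = df.duplicated(subset=["plot", "species"])
        if dup.any():
            rows = (df.index[dup] + 0).tolist()
            raise TableError(f"duplicated (plot, species) record(s) at row(s) {rows}")
        bad = df.index[df["abundance"] < 0]
        if len(bad):
            raise TableError(f"negative abundance at row(s) {bad.tolist()}")
        bad = df.index[df["height"] <= 0]
        if len(bad):
            raise TableError(f"non-positive height at row(s) {bad.tolist()}")
        bad = df.index[df["coverage"] < 0]
        if len(bad):
            raise TableError(f"negative coverage at row(s) {bad.tolist()}")
        if df.empty:
            raise TableError("community table is empty")
        self.data = df

    @property
    def plots(self) -> List[str]:
        return list(dict.fromkeys(self.data["plot"]))

    def species_in(self, plot) -> List[str]:
        sub = self.data[self.data["plot"] == plot]
        if sub.empty:
            raise TableError(f"unknown plot {plot!r}")
        return list(sub["species"])

    @property
    def all_species(self) -> List[str]:
        return sorted(set(self.data["species"]))

    def plot_slice(self, plot) -> pd.DataFrame:
        sub = self.data[self.data["plot"] == plot]
        if sub.empty:
            raise TableError(f"unknown plot {plot!r}")
        return sub

    def wcd(self) -> pd.Series:
        """Woody species coverage degree: summed coverage per plot."""
        return self.data.groupby("plot", sort=False)["coverage"].sum()

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


def read_community_long(path) -> CommunityTable:
    """Read and validate a long-format community TSV (header required)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    missing = [c for c in COMMUNITY_COLUMNS if c not in df.columns]
    if missing:
        raise TableError("community table missing column(s): " + ", ".join(missing))
    for col in ("abundance", "height", "coverage"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise TableError(
                f"non-numeric {col!r} at data row(s) {[int(i) + 2 for i in bad]}"
            )
        if coerced.isna().any():
            raise TableError(
                f"missing {col!r} at data row(s) "
                f"{[int(i) + 2 for i in df.index[coerced.isna()]]}"
            )
        df[col] = coerced
    return CommunityTable(df)


@dataclass
class TraitTable:
    """Species x trait matrix; index = species labels, columns = trait names.

    Values for the eight canonical traits must be finite and strictly
    positive; if both LCC and LNC are present together with C:N, the ratio is
    checked for consistency (C:N = LCC/LNC) rather than trusted.
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data.copy()
        df.index = df.index.astype(str)
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].tolist()
            raise TableError(f"duplicate species in trait table: {dups}")
        for col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise")
        present = [t for t in CANONICAL_TRAITS if t in df.columns]
        for t in present:
            vals = df[t]
            if not np.isfinite(vals).all():
                raise TableError(f"non-finite value(s) in trait {t!r}")
            if (vals <= 0).any():
                sp = df.index[vals <= 0].tolist()
                raise TableError(f"non-positive {t!r} for species {sp}")
        if {"LCC", "LNC", "C:N"}.issubset(df.columns):
            expect = df["LCC"] / df["LNC"]
            if not np.allclose(df["C:N"], expect, rtol=0, atol=1e-9):
                bad = df.index[~np.isclose(df["C:N"], expect, rtol=0, atol=1e-9)]
                raise TableError(
                    f"C:N inconsistent with LCC/LNC for species {bad.tolist()}"
                )
        self.data = df

    @property
    def species(self) -> List[str]:
        return list(self.data.index)

    @property
    def traits(self) -> List[str]:
        return list(self.data.columns)

    def values_for(self, species: Iterable[str], trait: str) -> pd.Series:
        if trait not in self.data.columns:
            raise TableError(f"unknown trait {trait!r}")
        species = list(species)
        missing = [s for s in species if s not in self.data.index]
        if missing:
            raise TableError(
                f"species missing trait {trait!r}: " + ", ".join(missing)
            )
        vals = self.data.loc[species, trait]
        if vals.isna().any():
            missing = vals.index[vals.isna()].tolist()
            raise TableError(f"species missing trait {trait!r}: {missing}")
        return vals

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="species")


def read_traits(path) -> TraitTable:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return TraitTable(df)


def derive_cn_ratio(traits: TraitTable) -> TraitTable:
    """Add (or validate) the leaf C:N column as LCC/LNC."""
    df = traits.data.copy()
    if "LCC" not in df.columns or "LNC" not in df.columns:
        raise TableError("derive_cn_ratio requires both LCC and LNC")
    if (df["LNC"] <= 0).any():
        bad = df.index[df["LNC"] <= 0].tolist()
        raise TableError(f"non-positive LNC for species {bad}")
    ratio = df["LCC"] / df["LNC"]
    if "C:N" in df.columns:
        if not np.allclose(df["C:N"], ratio, rtol=0, atol=1e-9):
            bad = df.index[~np.isclose(df["C:N"], ratio, rtol=0, atol=1e-9)]
            raise TableError(f"existing C:N inconsistent for species {bad.tolist()}")
    df["C:N"] = ratio
    return TraitTable(df)


@dataclass
class EnvTable:
    """Plot x environment-factor table (one row per plot)."""

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data.copy()
        df.index = df.index.astype(str)
        if df.index.duplicated().any():
            raise TableError(
                f"duplicate plot(s) in environment table: "
                f"{df.index[df.index.duplicated()].tolist()}"
            )
        self.data = df

    @property
    def plots(self) -> List[str]:
        return list(self.data.index)

    @property
    def factors(self) -> List[str]:
        return list(self.data.columns)

    def column(self, factor: str, plots: Optional[Iterable[str]] = None) -> pd.Series:
        if factor not in self.data.columns:
            raise TableError(f"unknown environment factor {factor!r}")
        col = self.data[factor]
        if plots is not None:
            col = col.loc[list(plots)]
        if col.isna().any():
            raise TableError(
                f"missing {factor!r} for plot(s) {col.index[col.isna()].tolist()}"
            )
        return col

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="plot")


def read_env(path) -> EnvTable:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return EnvTable(df)


# -- importance values and community-weighted means ------------------------


def importance_values(table: CommunityTable, plot) -> pd.Series:
    """Per-species importance values in one plot.

    IV_i = (a_i/sum a + h_i/sum h + c_i/sum c) / 3; the plot's IVs sum to 1.
    """
    sub = table.plot_slice(plot)
    out = {}
    parts = []
    for col in ("abundance", "height", "coverage"):
        total = sub[col].sum()
        if total <= 0:
            raise TableError(f"plot {plot!r} has zero total {col}; IV undefined")
        parts.append(sub[col] / total)
    iv = (parts[0] + parts[1] + parts[2]) / 3.0
    return pd.Series(iv.values, index=list(sub["species"]), name="IV")


def importance_value_table(table: CommunityTable) -> pd.DataFrame:
    """Long-form IV table (plot, species, IV) over all plots."""
    rows = []
    for plot in table.plots:
        iv = importance_values(table, plot)
        for sp, v in iv.items():
            rows.append((plot, sp, v))
    return pd.DataFrame(rows, columns=["plot", "species", "IV"])


def cwm(trait_values: pd.Series, iv: pd.Series) -> float:
    """Community-weighted mean: sum over species of IV_i * trait_i.

    ``trait_values`` must cover every species carrying weight; a missing
    species is an error, never a silent drop.
    """
    missing = [s for s in iv.index if s not in trait_values.index]
    if missing:
        raise TableError("species missing trait value: " + ", ".join(missing))
    vals = trait_values.loc[iv.index]
    if vals.isna().any():
        missing = vals.index[vals.isna()].tolist()
        raise TableError("species missing trait value: " + ", ".join(missing))
    total = iv.sum()
    if not np.isclose(total, 1.0, atol=1e-9):
        raise TableError(f"importance values sum to {total}, expected 1")
    return float((vals * iv).sum())


def cwm_table(
    community: CommunityTable, traits: TraitTable, trait_names: Optional[list] = None
) -> pd.DataFrame:
    """Plot x trait matrix of community-weighted means."""
    names = trait_names or traits.traits
    rows = {}
    for plot in community.plots:
        iv = importance_values(community, plot)
        rows[plot] = {
            t: cwm(traits.values_for(iv.index, t), iv) for t in names
        }
    return pd.DataFrame.from_dict(rows, orient="index")[names]
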