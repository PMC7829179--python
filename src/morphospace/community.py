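"""Plot x species incidence data and elevational-interval pooling.

Plots carry an elevation and a transect label.  Analyses operate on
assemblages: plots pooled into 500-m elevational intervals whose
species list is the union of the member plots' presences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .traits import _sep_for

META_COLS = ("plot_id", "transect", "elevation_m")

_ROMAN = (
    (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"), (90, "XC"),
    (50, "L"), (40, "XL"), (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I"),
)


def roman(n: int) -> str:
    out = []
    for val, sym in _ROMAN:
        while n >= val:
            out.append(sym)
            n -= val
    return "".join(out)


@dataclass
class CommunityData:
    """Binary plot x species incidence with plot metadata.

    ``incidence`` is indexed by plot id; ``meta`` holds ``transect`` and
    ``elevation_m`` per plot.  Abundance inputs are binarized on
    construction — all analyses are presence/absence.
    """

    incidence: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.incidence.index.equals(self.meta.index):
            raise ValueError("incidence and meta must share the plot index")
        elev = self.meta["elevation_m"].astype(float)
        if not np.isfinite(elev).all():
            raise ValueError("non-finite plot elevations")
        if (elev < 0).any():
            bad = self.meta.index[elev < 0].tolist()
            raise ValueError(f"negative elevations for plots {bad}")
        inc = (self.incidence.astype(float) > 0).astype(np.int8)
        empty = inc.columns[inc.sum(axis=0) == 0].tolist()
        if empty:
            raise ValueError(f"species occur in no plot: {empty}")
        self.incidence = inc.rename_axis("plot_id")
        self.meta = self.meta.assign(elevation_m=elev).rename_axis("plot_id")

    @property
    def plot_ids(self) -> list[str]:
        return self.incidence.index.tolist()

    @property
    def species_ids(self) -> list[str]:
        return self.incidence.columns.tolist()

    @property
    def transects(self) -> list[str]:
        return sorted(self.meta["transect"].unique())


@dataclass
class IntervalAssemblage:
    """One elevational interval on one transect.

    ``species`` is the duplicate-free union of presences over the
    member plots; ``incidence`` is the member-plot x pooled-species
    submatrix (needed by the Chao estimator).
    """

    transect: str
    index: int  # 1-based, ordered by elevation
    lower: float
    upper: float  # half-open [lower, upper)
    plot_ids: list[str]
    species: list[str]
    incidence: pd.DataFrame

    def __post_init__(self) -> None:
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species in assemblage species list")

    @property
    def richness(self) -> int:
        return len(self.species)

    @property
    def label(self) -> str:
        return f"{self.transect}:{roman(self.index)}"

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lower + self.upper)


def interval_bounds(elevation: float, width: float = 500.0, first_bound: float = 400.0):
    """Map an elevation to its half-open interval ``[lower, upper)``.

    The first interval is ``[0, first_bound)``; subsequent intervals
    have the given width: [0, 400), [400, 900), [900, 1400), ...
    """
    if elevation < 0:
        raise ValueError(f"negative elevation {elevation}")
    if elevation < first_bound:
        return 0.0, first_bound
    k = int((elevation - first_bound) // width)
    return first_bound + k * width, first_bound + (k + 1) * width


def bin_plots_to_intervals(
    community: CommunityData, width: float = 500.0, first_bound: float = 400.0
) -> list[IntervalAssemblage]:
    """Pool plots into elevational intervals, per transect.

    Plots are assigned to half-open bins; each occupied interval pools
    the union of its member plots' species.  Intervals with no plots
    are omitted.  The returned list is ordered by transect then
    elevation, with 1-based interval indices counted from the lowest
    occupied interval of each transect.
    """
    out: list[IntervalAssemblage] = []
    for transect in community.transects:
        plots = community.meta.index[community.meta["transect"] == transect]
        lowers: dict[float, list[str]] = {}
        for pid in plots:
            lo, _ = interval_bounds(community.meta.at[pid, "elevation_m"], width, first_bound)
            lowers.setdefault(lo, []).append(pid)
        for i, lo in enumerate(sorted(lowers), start=1):
            member = lowers[lo]
            sub = community.incidence.loc[member]
            species = sub.columns[sub.sum(axis=0) > 0].tolist()
            up = first_bound if lo == 0.0 else lo + width
            out.append(
                IntervalAssemblage(
                    transect=transect, index=i, lower=lo, upper=up,
                    plot_ids=list(member), species=species,
                    incidence=sub[species].copy(),
                )
            )
    return out


def read_community(path: str) -> CommunityData:
    """Read a plot x species CSV/TSV with plot_id, transect, elevation_m columns."""
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = [c for c in META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"community table missing columns {missing}")
    df = df.set_index("plot_id")
    df.index = df.index.astype(str)
    meta = df[["transect", "elevation_m"]].copy()
    inc = df.drop(columns=["transect", "elevation_m"])
    return CommunityData(inc, meta)


def write_community(community: CommunityData, path: str) -> None:
    df = pd.concat([community.meta, community.incidence], axis=1)
    df.index.name = "plot_id"
    df.to_csv(path, sep=_sep_for(path), float_format="%.10g")
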