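"""Synthetic data with the statistical structure the analyses assume.

Generates (a) species trait tables over the five-trait fern schema,
(b) pure-birth phylogenies with Brownian traits for phylogenetic-signal
calibration, (c) multi-transect elevational communities with a
hump-shaped richness gradient and tunable trait–environment filtering,
and (d) per-interval climate covariates.

The filtering knob ``phi`` interpolates between uniform random assembly
(``phi = 0`` — the exact world the trait-shuffle null model assumes,
used for type-I calibration) and strict trait–elevation sorting
(``phi = 1`` — used for power experiments).  Each species' optimal
elevation is tied to a latent morphological axis (standardized laminar
texture + standardized log laminar length), so filtering leaves a
signature the morphospace indices can detect.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .community import CommunityData
from .traits import FERN_SCHEMA, TraitSchema, TraitTable

DEFAULT_MARGINALS = {
    "rhizome_type": {0: 0.05, 1: 0.50, 2: 0.40, 3: 0.05},
    "laminar_dissection": {0: 0.20, 1: 0.40, 2: 0.40},
    "laminar_texture": {1: 0.30, 2: 0.45, 3: 0.25},
    "hydathodes": {0: 0.70, 1: 0.30},
}


@dataclass
class SimConfig:
    """Study-design parameters for the generator.

    Defaults describe one tropical elevational transect: a pool of 100
    species, intervals of 500 m from 400 m up (first interval 0–400 m
    when the transect starts at sea level), four plots per interval,
    and a Gaussian richness hump rising from about 10 species at the
    extremes to 40 at mid-elevation.
    """

    n_species_pool: int = 100
    n_transects: int = 1
    elevation_min: float = 200.0
    elevation_max: float = 3700.0
    interval_width: float = 500.0
    first_bound: float = 400.0
    plots_per_interval: int = 4
    peak_elevation: float = 1900.0
    peak_richness: int = 40
    base_richness: int = 10
    hump_width: float = 1200.0  # sd of the Gaussian richness hump, m
    phi: float = 0.0  # filtering strength: 0 random assembly, 1 strict sorting
    filter_width: float = 250.0  # tau: sd of the trait-elevation match kernel, m
    plot_occupancy: float = 0.6  # per-plot occurrence probability within an interval
    marginals: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_MARGINALS.items()
    })
    length_log_mean: float = np.log(30.0)  # cm
    length_log_sd: float = 0.8
    length_bounds: tuple[float, float] = (1.0, 600.0)
    birth_rate: float = 1.0
    bm_rate: float = 1.0  # sigma^2 of Brownian trait evolution
    schema: TraitSchema = FERN_SCHEMA

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError("phi must be in [0, 1]")
        for name, probs in self.marginals.items():
            total = sum(probs.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"marginals for {name!r} sum to {total}, not 1")
        if self.peak_richness > self.n_species_pool:
            raise ValueError("peak richness exceeds the species pool")

    def interval_grid(self) -> list[tuple[float, float]]:
        """Half-open interval bounds covering the transect's elevation span."""
        bounds = []
        lo = 0.0
        up = self.first_bound
        while lo <= self.elevation_max:
            if up > self.elevation_min:
                bounds.append((lo, up))
            lo, up = up, up + self.interval_width
        return bounds

    def target_richness(self, midpoint: float) -> int:
        hump = np.exp(-((midpoint - self.peak_elevation) ** 2) / (2 * self.hump_width ** 2))
        s = self.base_richness + (self.peak_richness - self.base_richness) * hump
        return int(min(round(s), self.n_species_pool))


def gen_trait_table(
    cfg: SimConfig, rng: np.random.Generator | int | None = None, prefix: str = "sp"
) -> TraitTable:
    """Draw a species pool with independent trait marginals.

    Laminar length is log-normal truncated to the configured bounds (cm);
    coded traits follow the configured category probabilities.
    """
    rng = np.random.default_rng(rng)
    n = cfg.n_species_pool
    ids = [f"{prefix}{i + 1:04d}" for i in range(n)]
    cols = {}
    for name, probs in cfg.marginals.items():
        levels = np.array(sorted(probs))
        p = np.array([probs[l] for l in levels], dtype=float)
        cols[name] = rng.choice(levels, size=n, p=p / p.sum())
    lo, hi = cfg.length_bounds
    a = (np.log(lo) - cfg.length_log_mean) / cfg.length_log_sd
    b = (np.log(hi) - cfg.length_log_mean) / cfg.length_log_sd
    z = stats.truncnorm.rvs(a, b, size=n, random_state=rng)
    cols["laminar_length"] = np.exp(cfg.length_log_mean + cfg.length_log_sd * z)
    df = pd.DataFrame(cols, index=pd.Index(ids, name="species_id"))
    return TraitTable(df[cfg.schema.trait_names], cfg.schema)


def latent_axis(traits: TraitTable) -> np.ndarray:
    """Morphological latent axis driving trait–elevation sorting.

    The species scores on the first principal coordinate of the trait
    Gower matrix — the dominant axis of the morphospace itself, onto
    which laminar texture and length load heavily.  Filtering on this
    axis clusters co-occurring species in the same space the diversity
    indices measure, so sorting strength translates into index signal;
    a latent built from a trait pair leaves most morphospace axes
    unsorted and makes even strict filtering nearly undetectable.
    """
    from .ordination import gower_dissimilarity, pcoa

    d = gower_dissimilarity(traits)
    return pcoa(d, n_axes=1).coordinates.iloc[:, 0].to_numpy()


def optimal_elevations(traits: TraitTable, cfg: SimConfig) -> np.ndarray:
    """Map latent-axis ranks uniformly onto the transect's elevation span."""
    lat = latent_axis(traits)
    ranks = stats.rankdata(lat, method="ordinal") - 0.5
    frac = ranks / len(lat)
    return cfg.elevation_min + frac * (cfg.elevation_max - cfg.elevation_min)


def gen_transect(
    cfg: SimConfig,
    traits: TraitTable,
    rng: np.random.Generator | int | None = None,
    transect: str = "T1",
) -> CommunityData:
    """Simulate one transect's plot x species incidence matrix.

    Per interval the target richness is imposed from the hump curve and
    species are drawn without replacement with weight

        w_i = (1 - phi) + phi * exp(-(opt_i - midpoint)^2 / (2 tau^2)),

    then scattered over four plots (each member occurs in each plot
    with the configured occupancy, at least one plot per species).
    Plot elevations jitter uniformly within the interval.
    """
    rng = np.random.default_rng(rng)
    n = traits.n_species
    opt = optimal_elevations(traits, cfg)
    species = np.array(traits.species_ids, dtype=object)
    rows = []
    meta_rows = []
    plot_counter = 0
    for lo, up in cfg.interval_grid():
        mid = 0.5 * (lo + up)
        s_target = cfg.target_richness(mid)
        w = (1 - cfg.phi) + cfg.phi * np.exp(
            -((opt - mid) ** 2) / (2 * cfg.filter_width ** 2)
        )
        w = np.maximum(w, 1e-12)
        members = rng.choice(n, size=s_target, replace=False, p=w / w.sum())
        plot_elevs = np.sort(
            rng.uniform(max(lo, cfg.elevation_min), min(up, cfg.elevation_max),
                        cfg.plots_per_interval)
        )
        occ = rng.random((s_target, cfg.plots_per_interval)) < cfg.plot_occupancy
        none = ~occ.any(axis=1)
        occ[none, rng.integers(0, cfg.plots_per_interval, size=none.sum())] = True
        for j in range(cfg.plots_per_interval):
            plot_counter += 1
            row = np.zeros(n, dtype=np.int8)
            row[members[occ[:, j]]] = 1
            rows.append(row)
            meta_rows.append(
                {"plot_id": f"{transect}_p{plot_counter:03d}", "transect": transect,
                 "elevation_m": float(plot_elevs[j])}
            )
    inc = pd.DataFrame(np.array(rows), columns=species,
                       index=[m["plot_id"] for m in meta_rows])
    meta = pd.DataFrame(meta_rows).set_index("plot_id")
    present = inc.columns[inc.sum(axis=0) > 0]
    return CommunityData(inc[present], meta)


def gen_pure_birth_tree(
    n_tips: int, birth_rate: float = 1.0, rng: np.random.Generator | int | None = None
) -> dendropy.Tree:
    """Constant-rate pure-birth (Yule) tree with ``n_tips`` extant tips."""
    rng = np.random.default_rng(rng)
    seed = int(rng.integers(0, 2**31 - 1))
    tree = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=birth_rate, death_rate=0.0, num_extant_tips=n_tips,
        rng=random.Random(seed),
    )
    # the simulator stops exactly at the n-th birth, leaving a
    # zero-length cherry (singular covariance); run the clock on to the
    # next, unobserved event so all pendant edges are positive
    extra = rng.exponential(1.0 / (n_tips * birth_rate))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"t{i}"
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    return tree


def brownian_trait(
    tree: dendropy.Tree, rate: float = 1.0,
    rng: np.random.Generator | int | None = None, root_value: float = 0.0,
) -> pd.Series:
    """Evolve a continuous trait by Brownian motion along the tree."""
    rng = np.random.default_rng(rng)
    values: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[id(node)] = root_value
        else:
            bl = node.edge.length or 0.0
            values[id(node)] = values[id(node.parent_node)] + rng.normal(
                0.0, np.sqrt(rate * bl)
            )
    tips = {leaf.taxon.label: values[id(leaf)] for leaf in tree.leaf_node_iter()}
    return pd.Series(tips, name="trait")


def gen_phylo_bm(
    cfg: SimConfig, rng: np.random.Generator | int | None = None, n_tips: int | None = None
) -> tuple[dendropy.Tree, pd.Series]:
    """Pure-birth tree plus one Brownian trait per tip (root value 0)."""
    rng = np.random.default_rng(rng)
    n = cfg.n_species_pool if n_tips is None else n_tips
    tree = gen_pure_birth_tree(n, cfg.birth_rate, rng)
    return tree, brownian_trait(tree, cfg.bm_rate, rng)


def gen_climate(
    cfg: SimConfig, rng: np.random.Generator | int | None = None,
    mat_base: float = 26.0, lapse: float = 5.5, ap_peak: float = 3000.0,
    ap_peak_elevation: float = 1500.0, noise_sd: float = 0.02,
) -> pd.DataFrame:
    """Per-interval climate covariates (one row per interval).

    MAT falls linearly with elevation (lapse in degrees C per km from the
    sea-level base); AP is unimodal in elevation; TS and PS are
    constants plus noise; bryophyte cover rises and saturates with
    elevation (air-humidity proxy).
    """
    rng = np.random.default_rng(rng)
    rows = []
    for i, (lo, up) in enumerate(cfg.interval_grid(), start=1):
        mid = 0.5 * (lo + up)
        mat = mat_base - lapse * mid / 1000.0
        ap = ap_peak * np.exp(-((mid - ap_peak_elevation) ** 2) / (2 * 1500.0 ** 2))
        ts = 1.5 * (1 + noise_sd * rng.standard_normal())
        ps = 40.0 * (1 + noise_sd * rng.standard_normal())
        bc = 90.0 / (1 + np.exp(-(mid - 1200.0) / 500.0))
        bc *= 1 + noise_sd * rng.standard_normal()
        rows.append(
            {"interval": i, "lower_m": lo, "upper_m": up, "midpoint_m": mid,
             "MAT": mat, "AP": ap, "TS": ts, "PS": ps, "bryophyte_cover": bc}
        )
    return pd.DataFrame(rows)


def gen_four_transects(
    seed: int = 0, phi: float = 0.0, cfg: SimConfig | None = None
) -> tuple[TraitTable, CommunityData, dict[str, SimConfig]]:
    """Four-transect preset emulating contrasting regional richness.

    Transects differ in elevational span and peak richness (rich and
    poor regions); each transect draws its pool from a shared trait
    table so cross-transect analyses share one morphospace.
    """
    base = cfg or SimConfig()
    presets = {
        "ECU": dict(elevation_min=500, elevation_max=4050, peak_elevation=2100,
                    peak_richness=40, base_richness=12),
        "MX": dict(elevation_min=300, elevation_max=3000, peak_elevation=1600,
                   peak_richness=20, base_richness=8),
        "PNG": dict(elevation_min=200, elevation_max=3700, peak_elevation=1100,
                    peak_richness=30, base_richness=10),
        "UG": dict(elevation_min=700, elevation_max=3200, peak_elevation=1650,
                   peak_richness=18, base_richness=6),
    }
    rng = np.random.default_rng(seed)
    cfgs = {}
    traits = gen_trait_table(base, rng)
    parts_inc, parts_meta = [], []
    for name, kw in presets.items():
        tcfg = SimConfig(**{**base.__dict__, **kw, "phi": phi})
        cfgs[name] = tcfg
        com = gen_transect(tcfg, traits, rng, transect=name)
        parts_inc.append(com.incidence)
        parts_meta.append(com.meta)
    inc = pd.concat(parts_inc).fillna(0).astype(np.int8)
    meta = pd.concat(parts_meta)
    return traits, CommunityData(inc, meta), cfgs
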