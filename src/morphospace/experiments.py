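"""Calibration, power, and correctness experiments.

These procedures run the package's statistical machinery on synthetic
worlds whose generating process is known, and report the summary
numbers that validate it: type-I error and SES calibration of the null
model on random-assembly worlds, power under strict trait sorting,
Blomberg's K under Brownian motion, and the optimality gap of the
greedy packing decomposition against exhaustive search.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .community import bin_plots_to_intervals
from .indices import hull_volume
from .nullmodels import ses
from .ordination import gower_dissimilarity, pcoa
from .packing import decompose
from .phylosignal import blomberg_k, k_test
from .simulate import SimConfig, gen_phylo_bm, gen_pure_birth_tree, gen_trait_table, gen_transect


def ses_calibration(
    n_worlds: int = 200,
    n_reps: int = 999,
    phi: float = 0.0,
    filter_width: float = 250.0,
    index: str = "mNND",
    seed: int = 0,
    cfg: SimConfig | None = None,
) -> dict:
    """SES distribution of an index across simulated elevational worlds.

    Each world draws a fresh 100-species pool and one transect; with
    ``phi = 0`` assembly is uniform, exactly the null model's own
    assumption, so the SES should be centred at 0 with unit spread and
    a ~5% |SES| > 1.96 rejection rate.  With ``phi = 1`` and a narrow
    filter the SES should shift strongly negative (trait clustering).
    """
    base = cfg or SimConfig()
    values = []
    root = np.random.SeedSequence(seed)
    for child in root.spawn(n_worlds):
        rng = np.random.default_rng(child)
        wcfg = SimConfig(**{**base.__dict__, "phi": phi, "filter_width": filter_width})
        traits = gen_trait_table(wcfg, rng)
        ordination = pcoa(gower_dissimilarity(traits), n_axes=5)
        community = gen_transect(wcfg, traits, rng)
        assemblages = bin_plots_to_intervals(community)
        for r in ses(assemblages, traits, index, n_reps=n_reps, rng=rng,
                     ordination=ordination):
            if np.isfinite(r.ses):
                values.append(r.ses)
    v = np.asarray(values)
    return {
        "n_worlds": n_worlds,
        "n_assemblages": len(v),
        "mean_ses": float(v.mean()),
        "sd_ses": float(v.std(ddof=1)),
        "rejection_rate": float(np.mean(np.abs(v) > 1.96)),
        "negative_rejection_rate": float(np.mean(v < -1.96)),
    }


def blomberg_bm_calibration(
    n_sims: int = 500, n_tips: int = 64, seed: int = 0, bm_rate: float = 1.0
) -> dict:
    """Mean K over Brownian-motion traits on fresh pure-birth trees.

    K is constructed to equal 1 in expectation under Brownian
    evolution, so the mean should sit near 1.
    """
    ks = []
    cfg = SimConfig(bm_rate=bm_rate)
    for child in np.random.SeedSequence(seed).spawn(n_sims):
        rng = np.random.default_rng(child)
        tree, x = gen_phylo_bm(cfg, rng, n_tips=n_tips)
        ks.append(blomberg_k(tree, x))
    ks = np.asarray(ks)
    return {"n_sims": n_sims, "mean_k": float(ks.mean()), "sd_k": float(ks.std(ddof=1))}


def k_test_calibration(
    n_sims: int = 400,
    n_reps: int = 199,
    n_tips: int = 64,
    alpha: float = 0.05,
    seed: int = 0,
    trait: str = "noise",
) -> dict:
    """Rejection rate of the tip-shuffle signal test.

    ``trait="noise"`` draws white-noise tip values (type-I error: the
    rate should be ~alpha); ``trait="bm"`` draws Brownian traits
    (power: the rate should be high).
    """
    rejections = 0
    cfg = SimConfig()
    for child in np.random.SeedSequence(seed).spawn(n_sims):
        rng = np.random.default_rng(child)
        if trait == "bm":
            tree, x = gen_phylo_bm(cfg, rng, n_tips=n_tips)
        else:
            tree = gen_pure_birth_tree(n_tips, cfg.birth_rate, rng)
            x = pd.Series(rng.standard_normal(n_tips),
                          index=[l.taxon.label for l in tree.leaf_node_iter()])
        rejections += k_test(tree, x, n_reps=n_reps, rng=rng).p_signal <= alpha
    return {"n_sims": n_sims, "rejection_rate": rejections / n_sims}


def exhaustive_max_retained(points: np.ndarray, ceiling: float, k: int = 2) -> int:
    """Exact search for the largest subset whose hull volume fits the
    ceiling; exponential, for small instances only."""
    n = points.shape[0]
    for size in range(n, 0, -1):
        for combo in combinations(range(n), size):
            v, _ = hull_volume(points[list(combo)][:, :k])
            if v <= ceiling:
                return size
    return 0


def packing_greedy_vs_exhaustive(
    n_instances: int = 200, seed: int = 0, max_s1: int = 12, tol: float = 0.01
) -> dict:
    """Optimality gap of the greedy decomposition on random 2-D instances.

    Returns the worst and mean shortfall in retained species relative
    to the exhaustive optimum, and checks expansion + packing = ΔS on
    every instance.
    """
    gaps = []
    conserved = True
    root = np.random.SeedSequence(seed)
    done = 0
    child_iter = iter(root.spawn(4 * n_instances))
    while done < n_instances:
        rng = np.random.default_rng(next(child_iter))
        s1 = int(rng.integers(7, max_s1 + 1))
        s2 = int(rng.integers(4, min(s1, 7)))
        e1 = rng.normal(size=(s1, 2))
        e2 = rng.normal(size=(s2, 2)) * rng.uniform(0.4, 1.0)
        try:
            res = decompose(e1, e2, tol=tol, n_starts=20, rng=rng)
        except ValueError:
            continue  # degenerate E2 hull; redraw
        v2, _ = hull_volume(e2)
        opt = exhaustive_max_retained(e1, v2 * (1 + tol))
        gaps.append(opt - (s1 - res.expansion))
        conserved &= res.expansion + res.packing == s1 - s2
        done += 1
    gaps = np.asarray(gaps)
    return {
        "n_instances": n_instances,
        "max_gap": int(gaps.max()),
        "mean_gap": float(gaps.mean()),
        "conservation_holds": bool(conserved),
    }
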