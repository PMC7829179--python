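"""End-to-end analysis driver: simulate (or load) a multi-transect
dataset, build the morphospace, and write every stage's table to disk.

Outputs are plain CSV (plus one newick tree) with fixed float
formatting, so a rerun with the same seed is byte-identical — the
determinism contract the test suite asserts.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import indices as idx
from .community import bin_plots_to_intervals, write_community
from .nullmodels import ses, ses_table
from .ordination import gower_dissimilarity, pcoa, write_ordination
from .packing import decompose_transect
from .phylosignal import k_test_axes
from .richness import chao_table, obs_vs_est_r2
from .simulate import SimConfig, gen_climate, gen_four_transects, gen_phylo_bm
from .traits import write_trait_table

FLOAT_FMT = "%.10g"


def run_pipeline(
    seed: int,
    outdir: str | Path,
    phi: float = 0.0,
    n_reps: int = 99,
    n_reps_hyp: int = 19,
    n_axes: int = 5,
    k_reps: int = 199,
    packing_starts: int = 10,
) -> dict[str, pd.DataFrame]:
    """Run every stage on a seeded four-transect simulation.

    Writes traits, community, ordination, index, SES, Chao, packing,
    phylogenetic-signal, and climate tables under ``outdir`` and
    returns them keyed by stage name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    traits, community, cfgs = gen_four_transects(seed=seed, phi=phi)
    write_trait_table(traits, outdir / "traits.csv")
    write_community(community, outdir / "community.csv")

    d = gower_dissimilarity(traits)
    ordination = pcoa(d, n_axes=None)
    write_ordination(ordination, outdir / "ordination.csv", outdir / "eigenvalues.csv")

    assemblages = bin_plots_to_intervals(community)

    fd_rows = [
        idx.compute_indices(ordination.points(a.species), a.label, k=n_axes).__dict__
        for a in assemblages
    ]
    fd = pd.DataFrame(fd_rows)
    fd.to_csv(outdir / "indices.csv", index=False, float_format=FLOAT_FMT)

    ses_frames = []
    for name in ("FRic", "FEve", "mNND", "sdNND"):
        ses_frames.append(ses_table(ses(
            assemblages, traits, name, n_reps=n_reps, rng=rng,
            n_axes=n_axes, ordination=ordination,
        )))
    ses_frames.append(ses_table(ses(
        assemblages, traits, "Hyp", n_reps=n_reps_hyp, rng=rng,
        n_axes=n_axes, ordination=ordination,
    )))
    ses_df = pd.concat(ses_frames, ignore_index=True)
    ses_df.to_csv(outdir / "ses.csv", index=False, float_format=FLOAT_FMT)

    chao = chao_table(assemblages)
    chao["r2_overall"] = obs_vs_est_r2(chao[["s_obs", "s_chao"]].to_numpy())
    chao.to_csv(outdir / "chao.csv", index=False, float_format=FLOAT_FMT)

    pack_rows = []
    for transect in community.transects:
        members = [a for a in assemblages if a.transect == transect]
        for res in decompose_transect(
            members, ordination, k=n_axes, rng=rng, n_starts=packing_starts
        ):
            pack_rows.append(res.__dict__)
    packing = pd.DataFrame(pack_rows)
    packing.to_csv(outdir / "packing.csv", index=False, float_format=FLOAT_FMT)

    tree, _ = gen_phylo_bm(SimConfig(), rng, n_tips=traits.n_species)
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = traits.species_ids[i]
    tree.write(path=str(outdir / "tree.nwk"), schema="newick")
    ksig = k_test_axes(tree, ordination.coordinates, n_axes=2, n_reps=k_reps, rng=rng)
    kdf = pd.DataFrame([r.__dict__ for r in ksig])
    kdf.to_csv(outdir / "phylosignal.csv", index=False, float_format=FLOAT_FMT)

    climate = gen_climate(next(iter(cfgs.values())), rng)
    climate.to_csv(outdir / "climate.csv", index=False, float_format=FLOAT_FMT)

    return {
        "indices": fd, "ses": ses_df, "chao": chao,
        "packing": packing, "phylosignal": kdf, "climate": climate,
    }
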