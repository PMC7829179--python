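"""Morphospace construction: Gower dissimilarity and principal coordinates.

Gower's coefficient averages per-trait distances across mixed
measurement scales, giving pairwise dissimilarities in [0, 1]; classical
multidimensional scaling (PCoA) of that matrix yields the coordinate
system in which all diversity indices are computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .traits import TraitTable


@dataclass
class DissimilarityMatrix:
    """Square symmetric dissimilarity matrix with species ids."""

    values: np.ndarray
    species_ids: list[str]
    constant_traits: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        d = np.asarray(self.values, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] != len(self.species_ids):
            raise ValueError("dissimilarity matrix shape does not match species ids")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("dissimilarity matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("dissimilarity matrix has nonzero diagonal")
        if d.min() < -1e-12 or d.max() > 1 + 1e-12:
            raise ValueError("dissimilarities outside [0, 1]")
        self.values = np.clip(d, 0.0, 1.0)


@dataclass
class Ordination:
    """PCoA coordinates with eigenvalue bookkeeping.

    ``coordinates`` is species x axes (eigenvalues descending);
    ``cum_variance`` is cumulative variance explained relative to the
    sum of the retained positive eigenvalues; ``n_negative`` counts
    discarded negative eigenvalues.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    cum_variance: np.ndarray
    n_negative: int
    truncated: bool = False  # fewer axes available than requested

    @property
    def species_ids(self) -> list[str]:
        return self.coordinates.index.tolist()

    def points(self, species: list[str], k: int | None = None) -> np.ndarray:
        """Coordinate rows for an assemblage, optionally on the first k axes."""
        pts = self.coordinates.loc[species].to_numpy()
        return pts if k is None else pts[:, : min(k, pts.shape[1])]


def gower_dissimilarity(
    traits: TraitTable, log_continuous: bool = False, asymmetric_binary: bool = False
) -> DissimilarityMatrix:
    """Pairwise Gower dissimilarity over the mixed-scale trait table.

    Per-trait distances: categorical and binary -> 0/1 mismatch
    (binary symmetric by default: joint absence counts as similarity;
    set ``asymmetric_binary`` to drop 0/0 pairs from the average);
    ordinal -> absolute code difference over the declared code range;
    continuous -> absolute difference over the observed range
    (optionally after log transform).  The dissimilarity is the mean of
    per-trait distances with equal weights.

    Continuous traits with zero observed range contribute 0 and are
    flagged; a table where every trait is constant is an error.
    """
    if traits.n_species < 2:
        raise ValueError("Gower dissimilarity needs at least 2 species")
    n = traits.n_species
    schema = traits.schema
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    constant: list[str] = []
    for name in schema.trait_names:
        scale = schema.scales[name]
        x = traits.data[name].to_numpy(dtype=float)
        if scale == "continuous":
            if log_continuous:
                x = np.log(x)
            rng = x.max() - x.min()
            if rng == 0:
                constant.append(name)
                den += 1.0
                continue
            d = np.abs(x[:, None] - x[None, :]) / rng
            num += d
            den += 1.0
        elif scale == "ordinal":
            levels = schema.levels[name]
            rng = max(levels) - min(levels)
            if np.ptp(x) == 0:
                constant.append(name)
            d = np.abs(x[:, None] - x[None, :]) / rng
            num += d
            den += 1.0
        else:  # categorical or binary
            if np.ptp(x) == 0:
                constant.append(name)
            d = (x[:, None] != x[None, :]).astype(float)
            if scale == "binary" and asymmetric_binary:
                both_absent = (x[:, None] == 0) & (x[None, :] == 0)
                num += np.where(both_absent, 0.0, d)
                den += np.where(both_absent, 0.0, 1.0)
                continue
            num += d
            den += 1.0
    if len(constant) == len(schema.trait_names):
        raise ValueError("all traits are constant; dissimilarity undefined")
    if constant:
        warnings.warn(f"constant traits contribute zero distance: {constant}")
    with np.errstate(invalid="ignore"):
        d = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix((d + d.T) / 2.0, traits.species_ids, constant)


def pcoa(d: DissimilarityMatrix, n_axes: int | None = None) -> Ordination:
    """Classical scaling (principal coordinates analysis).

    Double-centers -D^2/2, eigendecomposes, and returns coordinates
    ``eigenvector * sqrt(eigenvalue)`` for the positive eigenvalues in
    descending order.  Negative eigenvalues (Gower matrices need not be
    Euclidean) are discarded and counted; no Cailliez/Lingoes
    correction is applied, and variance fractions are relative to the
    positive eigenvalues only.  If fewer positive axes exist than
    requested, the result is truncated and flagged rather than failing.
    """
    dm = d.values
    n = dm.shape[0]
    if n_axes is not None and n_axes > n - 1:
        raise ValueError(f"n_axes={n_axes} exceeds S-1={n - 1}")
    b = dm ** 2
    b = -0.5 * (b - b.mean(axis=0) - b.mean(axis=1)[:, None] + b.mean())
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(abs(eigval[0]), 1.0) * 1e-10
    pos = eigval > tol
    n_negative = int((eigval < -tol).sum())
    lam = eigval[pos]
    coords = eigvec[:, pos] * np.sqrt(lam)
    truncated = False
    if n_axes is not None:
        if n_axes > coords.shape[1]:
            warnings.warn(
                f"only {coords.shape[1]} positive axes available (requested {n_axes})"
            )
            truncated = True
        coords = coords[:, :n_axes]
    k = coords.shape[1]
    cum = np.cumsum(lam) / lam.sum()
    frame = pd.DataFrame(
        coords, index=pd.Index(d.species_ids, name="species_id"),
        columns=[f"axis_{i + 1}" for i in range(k)],
    )
    return Ordination(frame, lam[:k], cum[:k], n_negative, truncated)


def write_ordination(ord_: Ordination, path: str, eig_path: str | None = None) -> None:
    ord_.coordinates.to_csv(path, float_format="%.10g")
    if eig_path is not None:
        pd.DataFrame(
            {"eigenvalue": ord_.eigenvalues, "cum_variance": ord_.cum_variance},
            index=ord_.coordinates.columns,
        ).to_csv(eig_path, float_format="%.10g")


def write_dissimilarity(d: DissimilarityMatrix, path: str) -> None:
    pd.DataFrame(d.values, index=d.species_ids, columns=d.species_ids).to_csv(
        path, float_format="%.10g"
    )
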