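"""Decomposition of richness differences between adjacent assemblages
into morphoniche expansion and packing.

Given a richer assemblage E1 and a poorer adjacent assemblage E2, the
procedure removes species from E1 until its convex-hull volume shrinks
to (a vicinity of) E2's volume.  Species that had to be removed
represent richness gained through *expansion* of the occupied volume;
species retained beyond E2's richness represent richness accommodated
through *packing* inside an E2-sized volume.

The search for the maximum-cardinality subset of E1 under the volume
ceiling is a multi-start greedy peripheral removal: at each step one
hull vertex is deleted, preferring removals that immediately satisfy
the ceiling, otherwise those that most reduce volume, with randomized
tie-breaking across starts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .community import IntervalAssemblage
from .indices import hull_volume


@dataclass
class PackingResult:
    pair: str
    s1: int
    s2: int
    delta_s: int
    expansion: int
    packing: int
    expansion_pct: float
    packing_pct: float
    volume_ratio: float  # V(E1 reduced) / V(E2)
    k_used: int
    status: str = "ok"  # "ok", "none" (no richness change), "negative_packing"


@dataclass
class PairSpec:
    """An adjacent assemblage pair oriented richer (e1) -> poorer (e2)."""

    e1: IntervalAssemblage | None
    e2: IntervalAssemblage | None
    status: str  # "ok", "none", "inverted"
    label: str


def order_pairs(assemblages: list[IntervalAssemblage]) -> list[PairSpec]:
    """Orient adjacent interval pairs from the elevational extremes
    toward the richness peak.

    Walking from each extreme toward the peak interval, every adjacent
    pair whose richness increases in the walking direction yields a
    (richer E1, poorer E2) pair.  Pairs with no richness change are
    emitted with status ``"none"``; decreases against the walking
    direction are emitted with status ``"inverted"`` and not
    decomposable.
    """
    if len(assemblages) < 2:
        raise ValueError("need at least 2 assemblages to form pairs")
    a = sorted(assemblages, key=lambda x: x.lower)
    rich = [x.richness for x in a]
    peak = int(np.argmax(rich))
    pairs: list[PairSpec] = []

    def classify(i_far: int, i_near: int) -> PairSpec:
        far, near = a[i_far], a[i_near]
        label = f"{near.label}~{far.label}"
        if near.richness > far.richness:
            return PairSpec(near, far, "ok", label)
        if near.richness == far.richness:
            return PairSpec(None, None, "none", label)
        return PairSpec(None, None, "inverted", label)

    for i in range(peak):  # ascending side: walk upward toward the peak
        pairs.append(classify(i, i + 1))
    for i in range(peak, len(a) - 1):  # descending side: walk downward toward the peak
        pairs.append(classify(i + 1, i))
    return pairs


def _greedy_reduce(
    points: np.ndarray, ceiling: float, k: int, min_size: int,
    rng: np.random.Generator, slack: float = 0.25, explore: float = 0.15,
) -> list[int]:
    """One randomized greedy run; returns retained row indices.

    Removes one hull vertex at a time, preferring removals that most
    reduce volume; with probability ``explore`` an arbitrary hull
    vertex is removed instead, so repeated starts escape configurations
    where the optimum is a thin (near-degenerate) subset.  A final
    augmentation pass re-adds any removed species that still fits under
    the ceiling.
    """
    from scipy.spatial import ConvexHull, QhullError

    current = list(range(points.shape[0]))
    while True:
        pts = points[current][:, :k]
        vol, degen = hull_volume(pts)
        if vol <= ceiling or len(current) <= min_size:
            break
        try:
            vertices = ConvexHull(pts).vertices
        except QhullError:
            break
        cand_vols = np.empty(len(vertices))
        for j, vtx in enumerate(vertices):
            rest = np.delete(np.arange(len(current)), vtx)
            cand_vols[j], _ = hull_volume(pts[rest])
        feasible = np.flatnonzero(cand_vols <= ceiling)
        if len(feasible):
            pick = int(rng.choice(feasible))
        elif rng.random() < explore:
            pick = int(rng.integers(len(vertices)))
        else:
            vmin = cand_vols.min()
            near = np.flatnonzero(cand_vols <= vmin * (1 + slack) + 1e-300)
            pick = int(rng.choice(near))
        del current[int(vertices[pick])]
    # augmentation: greedily restore species that fit inside the ceiling
    removed = [i for i in range(points.shape[0]) if i not in set(current)]
    rng.shuffle(removed)
    for i in removed:
        trial = current + [i]
        vol, _ = hull_volume(points[trial][:, :k])
        if vol <= ceiling:
            current = trial
    return current


def decompose(
    points1: np.ndarray,
    points2: np.ndarray,
    tol: float = 0.01,
    n_starts: int = 20,
    rng: np.random.Generator | int | None = None,
    k: int | None = None,
    pair: str = "",
) -> PackingResult:
    """Expansion/packing decomposition of the richness surplus of E1 over E2.

    Searches for the maximum-cardinality subset of E1's points whose
    hull volume is at most ``V2 * (1 + tol)``.  ``expansion`` is the
    number of species removed, ``packing`` the retained count minus
    E2's richness; the two always sum to ``S1 - S2``.  Axes are shared:
    ``k = min(k_requested, S2 - 1)`` so both hulls are well defined.

    ``packing`` can be negative when E2's species are not nested in E1
    (the morphospace regions barely overlap); this is flagged rather
    than clamped.
    """
    rng = np.random.default_rng(rng)
    p1 = np.asarray(points1, dtype=float)
    p2 = np.asarray(points2, dtype=float)
    s1, s2 = p1.shape[0], p2.shape[0]
    if s1 <= s2:
        raise ValueError(f"E1 must be richer than E2 (S1={s1}, S2={s2})")
    k_max = min(p1.shape[1], p2.shape[1], s2 - 1)
    k_used = k_max if k is None else min(k, k_max)
    if k_used < 1:
        raise ValueError("E2 too small for any shared axis (S2 < 2)")
    v2, degen = hull_volume(p2[:, :k_used])
    if degen or v2 <= 0:
        raise ValueError(
            f"E2 hull degenerate on {k_used} axes (V2={v2}); reduce the axis count"
        )
    ceiling = v2 * (1 + tol)
    min_size = 1  # subsets smaller than k+1 have zero volume, hence feasible
    best: list[int] | None = None
    for _ in range(max(1, n_starts)):
        retained = _greedy_reduce(p1, ceiling, k_used, min_size, rng)
        if best is None or len(retained) > len(best):
            best = retained
    v_final, _ = hull_volume(p1[best][:, :k_used])
    expansion = s1 - len(best)
    packing = len(best) - s2
    delta = s1 - s2
    status = "negative_packing" if packing < 0 else "ok"
    return PackingResult(
        pair=pair, s1=s1, s2=s2, delta_s=delta,
        expansion=expansion, packing=packing,
        expansion_pct=100.0 * expansion / delta,
        packing_pct=100.0 * packing / delta,
        volume_ratio=v_final / v2, k_used=k_used, status=status,
    )


def decompose_transect(
    assemblages: list[IntervalAssemblage],
    ordination,
    k: int = 5,
    tol: float = 0.01,
    n_starts: int = 20,
    rng: np.random.Generator | int | None = None,
) -> list[PackingResult]:
    """Run the decomposition over every oriented adjacent pair of a transect."""
    rng = np.random.default_rng(rng)
    results = []
    for spec in order_pairs(assemblages):
        if spec.status != "ok":
            results.append(
                PackingResult(spec.label, 0, 0, 0, 0, 0, np.nan, np.nan,
                              np.nan, 0, status=spec.status)
            )
            continue
        p1 = ordination.points(spec.e1.species)
        p2 = ordination.points(spec.e2.species)
        results.append(decompose(p1, p2, tol, n_starts, rng, k=k, pair=spec.label))
    return results
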