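"""Phylogenetic signal of continuous traits: Blomberg's K and a
tip-shuffle randomization test on the variance of phylogenetically
independent contrasts (PICs).

K compares the observed ratio of trait variance to
phylogenetically-corrected variance against its expectation under
Brownian motion on the same tree: K ~ 1 under Brownian evolution,
K -> 0 under convergence (less signal than Brownian), K > 1 under
stronger-than-Brownian conservatism.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd


@dataclass
class KResult:
    axis: str
    k: float
    p_signal: float  # low observed PIC variance (phylogenetic signal)
    p_anti: float    # high observed PIC variance (overdispersion)
    pic_variance: float
    n_reps: int

    @property
    def p(self) -> float:
        return self.p_signal


def load_tree(path: str) -> dendropy.Tree:
    return dendropy.Tree.get(path=path, schema="newick")


def _tip_order(tree: dendropy.Tree) -> list[str]:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate tip labels in tree")
    return labels


def _trait_vector(trait, tips: list[str]) -> np.ndarray:
    if isinstance(trait, pd.Series):
        trait = trait.to_dict()
    missing = [t for t in tips if t not in trait]
    extra = [t for t in trait if t not in set(tips)]
    if missing or extra:
        raise ValueError(
            f"tip/trait mismatch: missing traits for {missing}, extra traits for {extra}"
        )
    return np.array([float(trait[t]) for t in tips])


def phylo_covariance(tree: dendropy.Tree) -> tuple[np.ndarray, list[str]]:
    """Brownian covariance matrix: V[i, j] = shared root-to-MRCA path length."""
    tips = _tip_order(tree)
    n = len(tips)
    pos = {t: i for i, t in enumerate(tips)}
    v = np.zeros((n, n))
    for node in tree.postorder_node_iter():
        node._ms_tips = (
            [pos[node.taxon.label]] if node.is_leaf()
            else [i for c in node.child_nodes() for i in c._ms_tips]
        )
        bl = node.edge.length or 0.0
        if node.parent_node is not None:
            idx = np.array(node._ms_tips)
            v[np.ix_(idx, idx)] += bl
    for node in tree.postorder_node_iter():
        del node._ms_tips
    return v, tips


def blomberg_k(tree: dendropy.Tree, trait) -> float:
    """Blomberg's K for one continuous trait.

    With phylogenetic covariance V and phylogenetic mean
    a = (1'V^-1 x)/(1'V^-1 1):

        K = [ (x-a)'(x-a) / (x-a)'V^-1(x-a) ]
            / [ (tr V - n/(1'V^-1 1)) / (n - 1) ]
    """
    v, tips = phylo_covariance(tree)
    x = _trait_vector(trait, tips)
    n = len(tips)
    if n < 4:
        raise ValueError("Blomberg's K needs at least 4 tips")
    try:
        vinv = np.linalg.inv(v)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular phylogenetic covariance matrix: {exc}") from exc
    one = np.ones(n)
    denom1 = one @ vinv @ one
    a = (one @ vinv @ x) / denom1
    resid = x - a
    mse0 = resid @ resid
    mse = resid @ vinv @ resid
    expected = (np.trace(v) - n / denom1) / (n - 1)
    return float((mse0 / mse) / expected)


def pic_coefficients(tree: dendropy.Tree) -> tuple[np.ndarray, list[str]]:
    """Linear map from tip values to standardized independent contrasts.

    Contrasts are linear in the tip values for a fixed topology and
    branch lengths, so the Felsenstein pruning recursion is run once on
    tip-indicator vectors, yielding an (n-1) x n coefficient matrix C
    with PIC = C @ x.  Polytomies are resolved arbitrarily with
    zero-length branches first.
    """
    tree = tree.clone(depth=1)
    tree.resolve_polytomies(update_bipartitions=False)
    tips = _tip_order(tree)
    n = len(tips)
    pos = {t: i for i, t in enumerate(tips)}
    rows: list[np.ndarray] = []
    # per node: (coefficient vector for the nodal value, adjusted branch length)
    state: dict[int, tuple[np.ndarray, float]] = {}
    for node in tree.postorder_node_iter():
        bl = node.edge.length or 0.0
        if node.is_leaf():
            w = np.zeros(n)
            w[pos[node.taxon.label]] = 1.0
            state[id(node)] = (w, bl)
            continue
        children = node.child_nodes()
        if len(children) != 2:
            raise ValueError("tree not bifurcating after polytomy resolution")
        (w1, v1), (w2, v2) = state.pop(id(children[0])), state.pop(id(children[1]))
        if v1 + v2 <= 0:
            # zero-length cherry (e.g. resolved polytomy of identical tips):
            # the contrast is degenerate; standardize by an infinitesimal
            # branch is undefined, so treat as zero contrast with tiny length
            v1 = v2 = 1e-12
        rows.append((w1 - w2) / np.sqrt(v1 + v2))
        w = (v2 * w1 + v1 * w2) / (v1 + v2)
        state[id(node)] = (w, bl + v1 * v2 / (v1 + v2))
    return np.array(rows), tips


def pic(tree: dendropy.Tree, trait) -> np.ndarray:
    """Standardized phylogenetically independent contrasts."""
    c, tips = pic_coefficients(tree)
    return c @ _trait_vector(trait, tips)


def k_test(
    tree: dendropy.Tree,
    trait,
    n_reps: int = 999,
    rng: np.random.Generator | int | None = None,
    axis: str = "trait",
) -> KResult:
    """Randomization test for phylogenetic signal.

    Tip labels are shuffled across the phylogeny ``n_reps`` times; the
    null distribution is the variance of PICs under shuffling.  Low
    observed PIC variance relative to the null indicates signal
    (``p_signal``); both tail probabilities are reported.
    """
    rng = np.random.default_rng(rng)
    c, tips = pic_coefficients(tree)
    x = _trait_vector(trait, tips)
    if np.ptp(x) == 0:
        # constant trait: every contrast is 0, observed and in every null
        return KResult(axis, np.nan, 1.0, 1.0, 0.0, n_reps)
    obs = float(np.var(c @ x, ddof=1))
    shuffled = np.empty((len(x), n_reps))
    for r in range(n_reps):
        shuffled[:, r] = x[rng.permutation(len(x))]
    null = np.var(c @ shuffled, axis=0, ddof=1)
    p_signal = float((1 + np.sum(null <= obs)) / (n_reps + 1))
    p_anti = float((1 + np.sum(null >= obs)) / (n_reps + 1))
    k = blomberg_k(tree, trait)
    return KResult(axis, k, p_signal, p_anti, obs, n_reps)


def k_test_axes(
    tree: dendropy.Tree,
    ordination_coords: pd.DataFrame,
    n_axes: int = 2,
    n_reps: int = 999,
    rng: np.random.Generator | int | None = None,
) -> list[KResult]:
    """K and its randomization test on the first ordination axes."""
    rng = np.random.default_rng(rng)
    return [
        k_test(tree, ordination_coords.iloc[:, i], n_reps, rng,
               axis=str(ordination_coords.columns[i]))
        for i in range(min(n_axes, ordination_coords.shape[1]))
    ]
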