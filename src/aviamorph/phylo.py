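"""Brownian-motion phylogenetic covariance, whitening, and simulation.

Under Brownian motion (BM), trait values at the tips of a rooted tree are
jointly Gaussian with among-taxon covariance ``C``: ``C[i, i]`` is the
root-to-tip path length of taxon i and ``C[i, j]`` the root-to-MRCA path
length shared by taxa i and j (all in the tree's time units). The
symmetric inverse square root ``P = C^{-1/2}`` whitens the tips: rows of
``U = P (Y - 1 a)``, with ``a`` the GLS root estimate, are exchangeable
and homoscedastic, which is what makes residual-permutation inference and
the multivariate rate statistic valid on phylogenetically correlated data.

``P`` is computed by symmetric eigendecomposition rather than Cholesky:
the symmetric square root is unique and easy to verify, and every
quadratic-form statistic downstream is invariant to the choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import dendropy
import numpy as np
from scipy import linalg

EIGEN_FLOOR = 1e-12


@dataclass(frozen=True)
class PhyloCovariance:
    """Among-taxon BM covariance ``C`` and its inverse square root ``P``."""

    taxa: tuple[str, ...]
    C: np.ndarray                            # (N, N), time units
    P: np.ndarray                            # (N, N), C^{-1/2}
    eigen_floor: float = EIGEN_FLOOR

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @classmethod
    def identity(cls, taxa: Sequence[str]) -> "PhyloCovariance":
        """The non-phylogenetic limit (star tree with unit branches)."""
        n = len(taxa)
        return cls(tuple(taxa), np.eye(n), np.eye(n))


def _root_distances(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    dist: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            dist[node] = 0.0
        else:
            length = node.edge.length
            if length is None:
                raise ValueError("tree has an edge without branch length")
            dist[node] = dist[node.parent_node] + float(length)
    return dist


def phylo_covariance(tree: dendropy.Tree, taxa: Sequence[str]) -> PhyloCovariance:
    """Build the BM covariance for ``taxa`` (rows/columns in that order).

    Raises if a requested taxon is not a tip of the tree, or if ``C`` is
    numerically singular (eigenvalues below the floor) — which cannot
    happen for a tree with positive terminal branches.
    """
    taxa = [str(t).strip() for t in taxa]
    depth = _root_distances(tree)
    leaf_by_label = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    missing = [t for t in taxa if t not in leaf_by_label]
    if missing:
        raise ValueError(f"taxa absent from tree: {missing}")
    index = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    C = np.zeros((n, n))
    for t in taxa:
        C[index[t], index[t]] = depth[leaf_by_label[t]]

    # postorder: tips below each child of a node meet at that node
    below: dict[dendropy.Node, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            below[node] = [index[label]] if label in index else []
            continue
        child_sets = [below[c] for c in node.child_nodes()]
        for a in range(len(child_sets)):
            for b in range(a + 1, len(child_sets)):
                if child_sets[a] and child_sets[b]:
                    C[np.ix_(child_sets[a], child_sets[b])] = depth[node]
                    C[np.ix_(child_sets[b], child_sets[a])] = depth[node]
        below[node] = [i for s in child_sets for i in s]

    w, V = np.linalg.eigh(C)
    if np.any(w < EIGEN_FLOOR):
        raise ValueError(
            f"phylogenetic covariance is singular (min eigenvalue {w.min():.3e}); "
            "check for zero-length terminal branches or duplicated tips"
        )
    P = (V * (1.0 / np.sqrt(w))) @ V.T
    return PhyloCovariance(tuple(taxa), C, P)


@dataclass(frozen=True)
class TransformedDataset:
    """GLS root estimate and phylogenetically whitened residuals."""

    a: np.ndarray                            # (t,) root state estimate
    U: np.ndarray                            # (N, t) whitened residuals P (Y - 1a)
    d: np.ndarray                            # (N,) row norms of U


def _as_matrix(Y: np.ndarray) -> np.ndarray:
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    return Y


def gls_root_estimate(Y: np.ndarray, cov: PhyloCovariance) -> np.ndarray:
    """Generalized least-squares grand mean a = (1' C^-1 1)^-1 1' C^-1 Y."""
    Y = _as_matrix(Y)
    if Y.shape[0] != cov.n_taxa:
        raise ValueError(f"Y has {Y.shape[0]} rows but covariance is for {cov.n_taxa} taxa")
    cho = linalg.cho_factor(cov.C)
    ones = np.ones(cov.n_taxa)
    Ci1 = linalg.cho_solve(cho, ones)
    return (Ci1 @ Y) / (ones @ Ci1)


def phylo_transform(Y: np.ndarray, cov: PhyloCovariance) -> TransformedDataset:
    """Whiten tip data: U = P (Y - 1a); d_i = Euclidean norm of row i of U."""
    Y = _as_matrix(Y)
    a = gls_root_estimate(Y, cov)
    U = cov.P @ (Y - a[None, :])
    d = np.sqrt((U ** 2).sum(axis=1))
    return TransformedDataset(a, U, d)


RateSpec = float | Mapping[dendropy.Node, float] | Callable[[dendropy.Node], float]


def _rate_for(rates: RateSpec, node: dendropy.Node) -> float:
    if callable(rates):
        r = float(rates(node))
    elif isinstance(rates, Mapping):
        r = float(rates[node])
    else:
        r = float(rates)
    if r < 0:
        raise ValueError(f"negative BM rate {r}")
    return r


def simulate_bm(
    tree: dendropy.Tree,
    rates: RateSpec,
    n_traits: int,
    seed: int | np.random.Generator,
    taxa: Sequence[str] | None = None,
    root_state: np.ndarray | None = None,
) -> tuple[list[str], np.ndarray]:
    """Simulate Brownian motion along the tree, branch by branch.

    ``rates`` is the per-trait variance accumulated per unit branch length;
    it may be a scalar, a mapping keyed by the branch's child node, or a
    callable of the child node (regime-dependent rates). The root state is
    0 unless given. Returns tip labels (in ``taxa`` order when provided,
    else leaf-iteration order) and the (N, n_traits) tip matrix;
    deterministic for a given seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    root = np.zeros(n_traits) if root_state is None else np.asarray(root_state, float)
    if root.shape != (n_traits,):
        raise ValueError(f"root_state must have shape ({n_traits},)")
    values: dict[dendropy.Node, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[node] = root
            continue
        length = float(node.edge.length or 0.0)
        rate = _rate_for(rates, node)
        step = 0.0
        if length > 0 and rate > 0:
            step = rng.normal(scale=np.sqrt(rate * length), size=n_traits)
        else:
            # consume no randomness on degenerate branches
            step = np.zeros(n_traits)
        values[node] = values[node.parent_node] + step
    leaves = {leaf.taxon.label: values[leaf] for leaf in tree.leaf_node_iter()}
    labels = [str(t).strip() for t in taxa] if taxa is not None else list(leaves)
    missing = [t for t in labels if t not in leaves]
    if missing:
        raise ValueError(f"taxa absent from tree: {missing}")
    return labels, np.stack([leaves[t] for t in labels])
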