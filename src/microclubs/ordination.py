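"""Phylogenetic beta diversity, principal coordinates, PERMANOVA, dispersion.

UniFrac distances come from scikit-bio.  PCoA uses Gower double-centering of
the squared distance matrix; axes with negative eigenvalues (the
non-Euclidean part of the distance) are retained as a separate imaginary
block so that group dispersions can be computed the way betadisper does:
squared distances to a group center are real-part minus imaginary-part,
floored at zero.  PERMANOVA is the distance-based pseudo-F with a seeded
label-permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio import TreeNode
from skbio.diversity import beta_diversity
from skbio.diversity.beta import unweighted_unifrac as _uw_unifrac
from skbio.diversity.beta import weighted_unifrac as _w_unifrac

from .io import OtuTable

__all__ = [
    "DistanceMatrix",
    "Ordination",
    "PermanovaResult",
    "unweighted_unifrac",
    "weighted_unifrac",
    "unifrac_matrix",
    "pcoa",
    "permanova",
    "dispersion",
]


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix must be square over sample_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(self.values)) > 1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.values < -1e-12):
            raise ValueError("distances must be non-negative")
        self.values = np.clip((self.values + self.values.T) / 2.0, 0.0, None)
        np.fill_diagonal(self.values, 0.0)


@dataclass
class Ordination:
    sample_ids: list[str]
    coordinates: np.ndarray          # samples x retained (positive) axes
    eigenvalues: np.ndarray          # all eigenvalues, non-increasing
    proportion_explained: np.ndarray  # per retained axis, over positive sum
    imaginary_coordinates: np.ndarray  # samples x negative axes, sqrt(-lambda) scale


@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    seed: int


def _leaf_names(tree: TreeNode) -> set[str]:
    return {t.name for t in tree.tips()}


def _prep_tree(tree: TreeNode) -> TreeNode:
    """Zero out missing branch lengths so skbio metrics accept the tree.

    skbio's validator also rejects trifurcating roots; such trees are accepted
    here as given (validation of taxon membership is done by the callers), so
    the skbio metrics are invoked with ``validate=False``.
    """
    for node in tree.traverse():
        if node.length is None:
            node.length = 0.0
    return tree


def unweighted_unifrac(a, b, tree: TreeNode) -> float:
    """Unique / total branch length of the two communities' subtrees."""
    a, b = set(a), set(b)
    if not a or not b:
        raise ValueError("both communities must be non-empty")
    tips = _leaf_names(tree)
    unknown = sorted((a | b) - tips)
    if unknown:
        raise ValueError(f"taxa absent from tree: {unknown[:5]}")
    taxa = sorted(a | b)
    u = np.array([1.0 if t in a else 0.0 for t in taxa])
    v = np.array([1.0 if t in b else 0.0 for t in taxa])
    return float(_uw_unifrac(u, v, taxa=taxa, tree=_prep_tree(tree), validate=False))


def weighted_unifrac(a: dict, b: dict, tree: TreeNode,
                     normalized: bool = True) -> float:
    """Abundance-weighted UniFrac between two taxon -> proportion maps."""
    for name, comm in (("a", a), ("b", b)):
        total = float(sum(comm.values()))
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"community {name} proportions sum to {total}, expected 1")
    tips = _leaf_names(tree)
    unknown = sorted((set(a) | set(b)) - tips)
    if unknown:
        raise ValueError(f"taxa absent from tree: {unknown[:5]}")
    taxa = sorted(set(a) | set(b))
    # skbio vectorizes counts as integers; proportions are scaled up so the
    # cast loses at most ~1e-9 relative mass
    scale = 10 ** 9
    u = np.rint([a.get(t, 0.0) * scale for t in taxa])
    v = np.rint([b.get(t, 0.0) * scale for t in taxa])
    return float(_w_unifrac(u, v, taxa=taxa, tree=_prep_tree(tree),
                            normalized=normalized, validate=False))


def unifrac_matrix(table: OtuTable, tree: TreeNode, weighted: bool = False,
                   normalized: bool = True) -> DistanceMatrix:
    """All-pairs UniFrac over the samples of a table (counts or relative)."""
    unknown = sorted(set(table.taxon_ids) - _leaf_names(tree))
    if unknown:
        raise ValueError(f"taxa absent from tree: {unknown[:5]}")
    if weighted:
        # scale to large integers: skbio casts counts to int64 internally
        rows = table.values / table.values.sum(axis=1, keepdims=True)
        data = np.rint(rows * 10 ** 9)
    else:
        data = (table.values > 0).astype(int)
    metric = "weighted_unifrac" if weighted else "unweighted_unifrac"
    kwargs = {"normalized": normalized} if weighted else {}
    dm = beta_diversity(metric, data, ids=table.sample_ids,
                        taxa=table.taxon_ids, tree=_prep_tree(tree),
                        validate=False, **kwargs)
    return DistanceMatrix(list(table.sample_ids), np.asarray(dm.data))


def pcoa(dm: DistanceMatrix, eig_tol: float = 1e-10) -> Ordination:
    """Classical multidimensional scaling of a distance matrix.

    Gower-center -1/2 J D^2 J, eigendecompose, scale eigenvectors by
    sqrt(lambda).  Axes with lambda < 0 get no (real) coordinates but are kept
    as an imaginary block scaled by sqrt(-lambda).
    """
    n = len(dm.sample_ids)
    if n < 3:
        raise ValueError("PCoA needs at least 3 samples")
    d2 = dm.values ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    scale = max(abs(eigvals[0]), 1.0)
    pos = eigvals > eig_tol * scale
    neg = eigvals < -eig_tol * scale
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    imag = eigvecs[:, neg] * np.sqrt(-eigvals[neg])
    pos_sum = eigvals[pos].sum()
    prop = eigvals[pos] / pos_sum if pos_sum > 0 else eigvals[pos]
    return Ordination(list(dm.sample_ids), coords, eigvals, prop, imag)


def _group_indices(sample_ids, labels) -> dict[str, np.ndarray]:
    if len(labels) != len(sample_ids):
        raise ValueError("one label per sample required")
    out: dict[str, list[int]] = {}
    for i, lab in enumerate(labels):
        out.setdefault(str(lab), []).append(i)
    return {g: np.array(idx) for g, idx in out.items()}


def _permanova_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    df_b, df_w = n_groups - 1, n - n_groups
    return (ss_between / df_b) / (ss_within / df_w)


def permanova(dm: DistanceMatrix, labels, n_permutations: int = 999,
              seed: int = 0) -> PermanovaResult:
    """Distance-based one-way PERMANOVA with a label-permutation p-value."""
    groups = _group_indices(dm.sample_ids, labels)
    if len(groups) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if any(len(idx) < 2 for idx in groups.values()):
        small = [g for g, idx in groups.items() if len(idx) < 2]
        raise ValueError(f"singleton groups not allowed: {small}")
    names = sorted(groups)
    codes = np.empty(len(dm.sample_ids), dtype=int)
    for g, name in enumerate(names):
        codes[groups[name]] = g
    d2 = dm.values ** 2
    f_obs = _permanova_f(d2, codes, len(names))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        if _permanova_f(d2, perm, len(names)) >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return PermanovaResult(float(f_obs), float(p), n_permutations, seed)


def _spatial_median(points: np.ndarray, tol: float = 1e-8,
                    max_iter: int = 1000) -> np.ndarray:
    """Geometric (L1-of-L2) median by Weiszfeld iterative reweighting."""
    if points.shape[1] == 0:
        return np.zeros(0)
    m = points.mean(axis=0)
    for _ in range(max_iter):
        dist = np.linalg.norm(points - m, axis=1)
        if np.any(dist < tol):  # median coincides with a data point
            return points[np.argmin(dist)].copy()
        w = 1.0 / dist
        new = (points * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(new - m) < tol:
            return new
        m = new
    return m


def dispersion(dm: DistanceMatrix, labels, center: str = "median") -> dict[str, float]:
    """Per-group mean distance to the group's spatial median (or centroid).

    Samples are embedded by PCoA keeping the negative-eigenvalue axes as an
    imaginary block; squared distance to the center is the real part minus
    the imaginary part, floored at zero.
    """
    if center not in ("median", "centroid"):
        raise ValueError(f"unknown center {center!r}")
    groups = _group_indices(dm.sample_ids, labels)
    small = [g for g, idx in groups.items() if len(idx) < 2]
    if small:
        raise ValueError(f"singleton groups not allowed: {small}")
    ord_ = pcoa(dm)
    real, imag = ord_.coordinates, ord_.imaginary_coordinates
    out: dict[str, float] = {}
    for g in sorted(groups):
        idx = groups[g]
        if center == "median":
            c_real = _spatial_median(real[idx])
            c_imag = _spatial_median(imag[idx])
        else:
            c_real = real[idx].mean(axis=0)
            c_imag = imag[idx].mean(axis=0)
        d2 = (np.sum((real[idx] - c_real) ** 2, axis=1)
              - np.sum((imag[idx] - c_imag) ** 2, axis=1))
        out[g] = float(np.sqrt(np.clip(d2, 0.0, None)).mean())
    return out
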