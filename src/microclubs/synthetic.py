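"""Synthetic compositional count data with planted community structure.

The generator is the stand-in for the study cohort: a logistic-normal →
multinomial model in which latent log-abundances carry block-correlated
"clubs", negative cross-block "rivalries" and group-specific log-fold shifts,
and sequencing draws a multinomial of a few thousand reads per sample.  A
random rooted binary phylogeny over the taxa supports the phylogenetic
diversity and UniFrac stages.

The default specification emulates a 55-subject, 3-group cohort (9/24/22
samples, read depths uniform in 2 500–4 100) with three planted clubs and one
planted rivalry; see :func:`default_spec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io import OtuTable

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "default_spec",
    "generate_dataset",
    "generate_tree",
    "planted_truth_summary",
]


@dataclass
class SyntheticSpec:
    """Parameters of the planted-structure generative model.

    ``blocks`` lists (taxon index set, intra-block correlation); every pair of
    taxa inside a block shares that latent correlation.  ``rival_pairs`` lists
    (block index a, block index b, cross correlation in (-1, 0)) imposing
    co-avoidance between two blocks.  ``group_logfold`` maps (group name,
    block index) to an additive shift of the latent log-mean of that block's
    taxa in that group.
    """

    groups: list[tuple[str, int]]
    n_taxa: int
    blocks: list[tuple[list[int], float]] = field(default_factory=list)
    rival_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    group_logfold: dict[tuple[str, int], float] = field(default_factory=dict)
    base_log_mean: np.ndarray | None = None
    base_log_sd: np.ndarray | None = None
    depth_range: tuple[int, int] = (2500, 4100)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 1:
            raise ValueError("n_taxa must be positive")
        if self.depth_range[0] < 100 or self.depth_range[1] < self.depth_range[0]:
            raise ValueError("depth_range min must be >= 100 and <= max")
        seen: set[int] = set()
        for members, rho in self.blocks:
            if not 0 < rho < 1:
                raise ValueError(f"intra-block correlation {rho} outside (0, 1)")
            overlap = seen.intersection(members)
            if overlap:
                raise ValueError(f"blocks overlap at taxa {sorted(overlap)}")
            seen.update(members)
            if max(members) >= self.n_taxa or min(members) < 0:
                raise ValueError("block taxon index out of range")
        for a, b, rho in self.rival_pairs:
            if not -1 < rho < 0:
                raise ValueError(f"rival correlation {rho} outside (-1, 0)")
            if a >= len(self.blocks) or b >= len(self.blocks) or a == b:
                raise ValueError(f"invalid rival block pair ({a}, {b})")
        if self.base_log_mean is None:
            self.base_log_mean = np.zeros(self.n_taxa)
        self.base_log_mean = np.asarray(self.base_log_mean, dtype=float)
        if self.base_log_sd is None:
            self.base_log_sd = np.ones(self.n_taxa)
        self.base_log_sd = np.asarray(self.base_log_sd, dtype=float)
        if self.base_log_mean.shape != (self.n_taxa,) or self.base_log_sd.shape != (self.n_taxa,):
            raise ValueError("base_log_mean / base_log_sd must have length n_taxa")
        if np.any(self.base_log_sd < 0):
            raise ValueError("base_log_sd must be non-negative")

    def latent_correlation(self) -> np.ndarray:
        """The planted taxon x taxon latent correlation matrix."""
        corr = np.eye(self.n_taxa)
        for members, rho in self.blocks:
            for i in members:
                for j in members:
                    if i != j:
                        corr[i, j] = rho
        for a, b, rho in self.rival_pairs:
            for i in self.blocks[a][0]:
                for j in self.blocks[b][0]:
                    corr[i, j] = corr[j, i] = rho
        return corr

    def latent_covariance(self) -> np.ndarray:
        sd = self.base_log_sd
        cov = self.latent_correlation() * np.outer(sd, sd)
        # guard against numerically singular diagonals (sd == 0 taxa)
        eigmin = np.linalg.eigvalsh(self.latent_correlation()).min()
        if eigmin <= 1e-10:
            involved = sorted({b for pair in self.rival_pairs for b in pair[:2]})
            raise ValueError(
                "planted correlations are not positive definite "
                f"(min eigenvalue {eigmin:.3g}); check blocks {involved or 'all'}"
            )
        return cov


@dataclass
class SyntheticDataset:
    """A generated cohort: counts table, phylogeny and the planted truth."""

    table: OtuTable
    tree: TreeNode
    truth_correlation: np.ndarray
    block_labels: dict[str, int]
    rival_pairs: list[tuple[int, int, float]]
    spec: SyntheticSpec


def default_spec(seed: int = 0) -> SyntheticSpec:
    """The default cohort: 3 groups (9/24/22), 60 taxa, 3 clubs, 1 rivalry.

    Blocks of 6/5/5 abundant taxa at intra-correlation 0.85 play the role of
    the social clubs; blocks 0 and 1 are rivals at -0.5.  The AS group gets a
    +1.5 log-fold shift on block 0, a dominance effect that concentrates reads
    and depresses observed richness, mimicking the smokers' Proteobacteria
    takeover.  Non-block taxa follow a 0 to -6 log-mean rank-abundance decay,
    so the tail is rare enough to fall under the prevalence filter.
    """
    n_taxa = 60
    blocks = [(list(range(0, 6)), 0.85),
              (list(range(6, 11)), 0.85),
              (list(range(11, 16)), 0.85)]
    base_mean = np.zeros(n_taxa)
    base_mean[16:] = np.linspace(0.0, -6.0, n_taxa - 16)
    return SyntheticSpec(
        groups=[("NS", 9), ("FS", 24), ("AS", 22)],
        n_taxa=n_taxa,
        blocks=blocks,
        rival_pairs=[(0, 1, -0.5)],
        group_logfold={("AS", 0): 1.5},
        base_log_mean=base_mean,
        base_log_sd=np.ones(n_taxa),
        depth_range=(2500, 4100),
        seed=seed,
    )


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw a cohort from the logistic-normal -> multinomial model.

    Per sample: latent log-abundances ~ MVN(base mean + group shift, block
    covariance); exponentiate and renormalize to proportions; draw counts
    multinomially at a uniform-random depth in ``depth_range``.  Deterministic
    for a fixed ``spec.seed``.
    """
    spec.latent_covariance()  # positive-definiteness check
    # factor = diag(sd) @ chol(corr) so taxa with sd = 0 are legal
    chol = spec.base_log_sd[:, None] * np.linalg.cholesky(spec.latent_correlation())
    rng = np.random.default_rng(spec.seed)
    taxon_ids = [f"Taxon.{j:03d}" for j in range(spec.n_taxa)]

    sample_ids: list[str] = []
    group_of: dict[str, str] = {}
    rows: list[np.ndarray] = []
    for gname, n in spec.groups:
        shift = np.zeros(spec.n_taxa)
        for (g, block_idx), delta in spec.group_logfold.items():
            if g == gname:
                shift[spec.blocks[block_idx][0]] += delta
        mean = spec.base_log_mean + shift
        for k in range(n):
            sid = f"{gname}{k + 1:02d}"
            sample_ids.append(sid)
            group_of[sid] = gname
            z = mean + chol @ rng.standard_normal(spec.n_taxa)
            x = np.exp(z)
            p = x / x.sum()
            depth = int(rng.integers(spec.depth_range[0], spec.depth_range[1] + 1))
            rows.append(rng.multinomial(depth, p).astype(float))

    table = OtuTable(sample_ids, taxon_ids, np.vstack(rows), kind="counts",
                     group_of=group_of)
    tree = generate_tree(taxon_ids, seed=spec.seed + 1)
    block_labels = {taxon_ids[i]: b
                    for b, (members, _) in enumerate(spec.blocks) for i in members}
    return SyntheticDataset(table, tree, spec.latent_correlation(), block_labels,
                            list(spec.rival_pairs), spec)


def generate_tree(taxon_ids, seed: int = 0) -> TreeNode:
    """Random rooted binary tree over the taxa by sequential random joins.

    Each of the 2n-2 branches gets an independent Exponential(1) length.
    """
    taxon_ids = list(taxon_ids)
    if len(taxon_ids) < 2:
        raise ValueError("need at least 2 taxa to build a tree")
    rng = np.random.default_rng(seed)
    lineages = [str(t) for t in taxon_ids]
    while len(lineages) > 1:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        right = lineages.pop(j)
        left = lineages.pop(i)
        la, lb = (float(x) for x in rng.exponential(1.0, size=2))
        lineages.append(f"({left}:{la!r},{right}:{lb!r})")
    tree = TreeNode.read([lineages[0] + ";"])
    tree.length = 0.0
    return tree


def planted_truth_summary(ds: SyntheticDataset) -> pd.DataFrame:
    """All within-block and cross-rival taxon pairs with their latent
    correlations, for parameter-recovery checks.

    Columns: taxon_a, taxon_b, relation ("club"/"rival"), block_a, block_b,
    true_correlation.
    """
    taxa = ds.table.taxon_ids
    records = []
    for b, (members, rho) in enumerate(ds.spec.blocks):
        for ii, i in enumerate(members):
            for j in members[ii + 1:]:
                records.append((taxa[i], taxa[j], "club", b, b, rho))
    for a, b, rho in ds.rival_pairs:
        for i in ds.spec.blocks[a][0]:
            for j in ds.spec.blocks[b][0]:
                records.append((taxa[i], taxa[j], "rival", a, b, rho))
    return pd.DataFrame(records, columns=["taxon_a", "taxon_b", "relation",
                                          "block_a", "block_b", "true_correlation"])
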