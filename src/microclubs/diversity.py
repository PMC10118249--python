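"""Alpha-diversity indices and their group-level comparisons.

Chao1 estimates true richness from the singleton/doubleton tail of the count
vector; the inverse Simpson index 1 / sum(p_i^2) is the effective number of
equally abundant taxa; Faith's PD is the branch length of the minimal subtree
spanning the root and the observed taxa.  Group contrasts use classical
one-way ANOVA and the richness-diversity relationship is summarized by a
Pearson correlation with its t-based two-sided p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import TreeNode
from skbio.diversity.alpha import faith_pd as _skbio_faith_pd

from .io import OtuTable

__all__ = [
    "DiversityRecord",
    "chao1",
    "inverse_simpson",
    "faith_pd",
    "richness_diversity_correlation",
    "one_way_anova",
    "alpha_diversity_table",
]


@dataclass
class DiversityRecord:
    sample_id: str
    s_obs: int
    f1: int
    f2: int
    chao1: float
    inv_simpson: float
    reads: float
    faith_pd: float | None = None


def chao1(counts, bias_corrected: str = "auto") -> float:
    """Chao1 richness from an integer count vector.

    ``auto`` uses the classic estimator S_obs + F1^2 / (2 F2) when doubletons
    exist and the bias-corrected form S_obs + F1 (F1 - 1) / (2 (F2 + 1)) when
    F2 = 0; ``always``/``never`` force one form.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0 or np.any(counts < 0):
        raise ValueError("chao1 requires a non-empty, non-negative count vector")
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("chao1 requires counts")
    counts = np.round(counts).astype(int)
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if bias_corrected not in ("auto", "always", "never"):
        raise ValueError(f"unknown bias_corrected mode {bias_corrected!r}")
    corrected = bias_corrected == "always" or (bias_corrected == "auto" and f2 == 0)
    if corrected:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f2 == 0:
        return float(s_obs)
    return s_obs + f1 * f1 / (2.0 * f2)


def inverse_simpson(proportions) -> float:
    """1 / sum(p_i^2) over the positive entries of a composition."""
    p = np.asarray(proportions, dtype=float)
    if p.size == 0 or np.all(p == 0):
        raise ValueError("inverse_simpson requires at least one positive entry")
    if np.any(p < 0):
        raise ValueError("proportions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions sum to {p.sum()!r}, expected 1")
    return 1.0 / float(np.square(p[p > 0]).sum())


def faith_pd(present_taxa, tree: TreeNode) -> float:
    """Total branch length of the minimal root-spanning subtree of the taxa."""
    present = sorted(set(present_taxa))
    if not present:
        raise ValueError("faith_pd requires at least one present taxon")
    tips = {t.name for t in tree.tips()}
    unknown = [t for t in present if t not in tips]
    if unknown:
        raise ValueError(f"taxa absent from tree: {unknown[:5]}")
    for node in tree.traverse():
        if node.length is None:
            node.length = 0.0
    # validate=False: membership is checked above, and trees with
    # trifurcating roots are accepted as given
    return float(_skbio_faith_pd(np.ones(len(present), dtype=int),
                                 taxa=present, tree=tree, validate=False))


def richness_diversity_correlation(richness, diversity):
    """Pearson r between paired richness and diversity vectors, with the
    two-sided p from the t transform on n - 2 df."""
    x = np.asarray(richness, dtype=float)
    y = np.asarray(diversity, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need paired vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def one_way_anova(groups):
    """Classical between/within F statistic over >= 2 groups of n >= 2."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs at least 2 observations")
    f, p = stats.f_oneway(*groups)
    if np.isnan(f):  # all groups identical constant -> no variance anywhere
        return 0.0, 1.0
    return float(f), float(p)


def alpha_diversity_table(counts: OtuTable, tree: TreeNode | None = None,
                          chao1_mode: str = "auto") -> pd.DataFrame:
    """Per-sample richness/diversity table from a counts OtuTable.

    Columns: reads, s_obs, f1, f2, chao1, inv_simpson and, when a tree is
    given, faith_pd.
    """
    if counts.kind != "counts":
        raise ValueError("alpha diversity is computed on the counts table")
    records = []
    for i, sid in enumerate(counts.sample_ids):
        row = counts.values[i]
        total = row.sum()
        if total <= 0:
            raise ValueError(f"sample {sid!r} has zero total count")
        props = row / total
        rec = {
            "sample": sid,
            "reads": float(total),
            "s_obs": int((row > 0).sum()),
            "f1": int((row == 1).sum()),
            "f2": int((row == 2).sum()),
            "chao1": chao1(row, bias_corrected=chao1_mode),
            "inv_simpson": inverse_simpson(props),
        }
        if tree is not None:
            present = [t for t, c in zip(counts.taxon_ids, row) if c > 0]
            rec["faith_pd"] = faith_pd(present, tree)
        records.append(rec)
    return pd.DataFrame(records).set_index("sample")
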