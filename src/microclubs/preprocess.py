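"""Contaminant removal, total-sum scaling and group-wise prevalence filtering.

The filters mirror a standard low-biomass 16S workflow: name-based removal of
a known reagent contaminant genus (Halomonas by default), normalization of
each sample's counts to proportions, and elimination of taxa that are
non-zero in less than half of a group's samples.  Prevalence boundaries are
read strictly: a taxon present in *exactly* the threshold fraction is
retained under the per-group rule, and must *exceed* the threshold in some
group to enter the uniform set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import OtuTable

__all__ = [
    "FilterConfig",
    "remove_contaminants",
    "total_sum_scale",
    "prevalent_taxa",
    "prevalence_filter",
]


@dataclass
class FilterConfig:
    contaminant_patterns: list[str] = field(default_factory=lambda: ["Halomonas"])
    min_prevalence: float = 0.5
    uniform_set: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.min_prevalence <= 1:
            raise ValueError("min_prevalence must be in (0, 1]")


def remove_contaminants(table: OtuTable, patterns=("Halomonas",)) -> OtuTable:
    """Drop every taxon whose label contains any pattern (case-insensitive)."""
    lowered = [p.lower() for p in patterns]
    keep = [t for t in table.taxon_ids
            if not any(p in t.lower() for p in lowered)]
    if not keep:
        raise ValueError("contaminant patterns removed every taxon")
    return table.select_taxa(keep)


def total_sum_scale(table: OtuTable) -> OtuTable:
    """Normalize counts to proportions by dividing each row by its total."""
    if table.kind != "counts":
        raise ValueError("total_sum_scale expects a counts table")
    totals = table.values.sum(axis=1)
    if np.any(totals <= 0):
        bad = table.sample_ids[int(np.argmax(totals <= 0))]
        raise ValueError(f"sample {bad!r} has zero total count")
    return OtuTable(list(table.sample_ids), list(table.taxon_ids),
                    table.values / totals[:, None], kind="relative",
                    group_of=dict(table.group_of))


def _group_samples(table: OtuTable) -> dict[str, list[str]]:
    missing = [s for s in table.sample_ids if s not in table.group_of]
    if missing:
        raise ValueError(f"samples without group labels: {missing[:5]}")
    out: dict[str, list[str]] = {}
    for s in table.sample_ids:
        out.setdefault(table.group_of[s], []).append(s)
    return out


def prevalent_taxa(table: OtuTable, min_prevalence: float = 0.5,
                   uniform_set: bool = False):
    """Taxon sets surviving the prevalence bar.

    Per-group rule (``uniform_set=False``): within each group a taxon is kept
    iff its non-zero fraction is >= ``min_prevalence`` ("less than" the bar is
    eliminated); returns a dict group -> taxon list.  Uniform-set rule: a
    taxon exceeding the bar (strictly) in at least one group is kept for all
    groups; returns a single taxon list.
    """
    groups = _group_samples(table)
    for g, samples in groups.items():
        if not samples:
            raise ValueError(f"group {g!r} has no samples")
    prevalence: dict[str, np.ndarray] = {}
    for g, samples in groups.items():
        idx = [table.sample_ids.index(s) for s in samples]
        prevalence[g] = (table.values[idx] > 0).mean(axis=0)
    if uniform_set:
        keep = np.zeros(table.n_taxa, dtype=bool)
        for prev in prevalence.values():
            keep |= prev > min_prevalence
        return [t for t, k in zip(table.taxon_ids, keep) if k]
    return {g: [t for t, p in zip(table.taxon_ids, prev) if p >= min_prevalence]
            for g, prev in prevalence.items()}


def prevalence_filter(table: OtuTable, min_prevalence: float = 0.5,
                      uniform_set: bool = False):
    """Apply the prevalence rule to a relative-abundance table.

    Returns one table per group (group -> OtuTable restricted to that group's
    samples and retained taxa) under the per-group rule, or a single table
    over all samples under the uniform-set rule.  Rows are *not* renormalized
    after taxon drops: proportions keep their original denominators.
    """
    if table.kind != "relative":
        raise ValueError("prevalence_filter expects a relative-abundance table")
    kept = prevalent_taxa(table, min_prevalence, uniform_set)
    if uniform_set:
        return _subset_no_renorm(table, table.sample_ids, kept)
    groups = _group_samples(table)
    return {g: _subset_no_renorm(table, groups[g], kept[g]) for g in groups}


def _subset_no_renorm(table: OtuTable, samples, taxa) -> OtuTable:
    sidx = [table.sample_ids.index(s) for s in samples]
    tidx = [table.taxon_ids.index(t) for t in taxa]
    return OtuTable(list(samples), list(taxa), table.values[np.ix_(sidx, tidx)],
                    kind="relative",
                    group_of={s: table.group_of[s] for s in samples if s in table.group_of})
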