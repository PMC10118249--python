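"""Reading and writing the tabular, tree and network formats of the pipeline.

The canonical table dialect is TSV with one header row and one label column;
comma-separated files are accepted by sniffing the header line.  Trees are
newick (parsed into :class:`skbio.TreeNode`); networks are exported as GraphML
or a plain ``taxonA<TAB>taxonB<TAB>correlation`` edge list, both loadable by
Cytoscape-class viewers.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "OtuTable",
    "FormatError",
    "read_counts_table",
    "write_table",
    "read_metadata",
    "write_metadata",
    "read_tree",
    "write_tree",
    "read_matrix",
    "write_matrix",
    "write_network",
    "genus_of",
]


class FormatError(ValueError):
    """Raised when an input file violates the expected layout."""


@dataclass
class OtuTable:
    """A samples x taxa abundance table with per-sample group labels.

    ``values[i, j]`` is the abundance of taxon ``taxon_ids[j]`` in sample
    ``sample_ids[i]`` — raw read counts when ``kind == "counts"`` or
    proportions summing to 1 per sample when ``kind == "relative"``.
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    values: np.ndarray
    kind: str = "counts"
    group_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise FormatError("duplicate taxon ids")
        if np.any(self.values < 0):
            raise FormatError("negative abundance entries")
        if self.kind not in ("counts", "relative"):
            raise ValueError(f"unknown table kind {self.kind!r}")
        if self.kind == "relative" and len(self.taxon_ids):
            # rows sum to 1 when freshly normalized; prevalence filtering drops
            # taxa without renormalizing, so sums may fall below 1 but never above
            sums = self.values.sum(axis=1)
            if np.any(sums > 1.0 + 1e-9):
                bad = self.sample_ids[int(np.argmax(sums))]
                raise ValueError(f"relative table row exceeds 1 (sample {bad!r})")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def groups(self) -> list[str]:
        """Distinct group labels in first-appearance order over samples."""
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            if s in self.group_of:
                seen.setdefault(self.group_of[s], None)
        return list(seen)

    def with_groups(self, group_of: dict[str, str]) -> "OtuTable":
        missing = [s for s in self.sample_ids if s not in group_of]
        if missing:
            raise FormatError(f"samples absent from metadata: {missing[:5]}")
        return OtuTable(self.sample_ids, self.taxon_ids, self.values.copy(),
                        self.kind, {s: group_of[s] for s in self.sample_ids})

    def select_samples(self, samples: list[str]) -> "OtuTable":
        idx = [self.sample_ids.index(s) for s in samples]
        return OtuTable(list(samples), list(self.taxon_ids), self.values[idx],
                        self.kind, {s: self.group_of[s] for s in samples if s in self.group_of})

    def select_taxa(self, taxa: list[str]) -> "OtuTable":
        idx = [self.taxon_ids.index(t) for t in taxa]
        return OtuTable(list(self.sample_ids), list(taxa), self.values[:, idx],
                        self.kind, dict(self.group_of))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.taxon_ids)


def _sniff_sep(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    return "\t"


def read_counts_table(path, orientation: str = "samples_in_rows") -> OtuTable:
    """Read a counts TSV into an :class:`OtuTable` (samples x taxa).

    ``orientation`` names what the file's *rows* are; the returned table is
    always samples x taxa, so reading a transposed file with the opposite
    flag yields an equal table.
    """
    if orientation not in ("samples_in_rows", "taxa_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = _sniff_sep(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if len(set(header)) != len(header):  # pandas would mangle these to A, A.1
        raise FormatError(f"{path}: duplicate column labels in header")
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.has_duplicates:
        raise FormatError(f"{path}: duplicate row labels")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            row = df.index[coerced.isna().to_numpy().argmax()]
            raise FormatError(f"{path}: non-numeric cell at row {row!r}, column {col!r}")
    values = df.to_numpy(dtype=float)
    if np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise FormatError(f"{path}: negative entry at row {df.index[i]!r}, column {df.columns[j]!r}")
    if orientation == "taxa_in_rows":
        df = df.T
    return OtuTable([str(s) for s in df.index], [str(t) for t in df.columns],
                    df.to_numpy(dtype=float), kind="counts")


def write_table(table: OtuTable, path) -> None:
    """Write samples-in-rows TSV; round-trips bit-identically through read."""
    table.to_dataframe().to_csv(path, sep="\t", index_label="sample")


def read_metadata(path) -> dict[str, str]:
    """Read a two-column (sample, group) TSV into a sample -> group map."""
    df = pd.read_csv(path, sep=_sniff_sep(path))
    cols = {c.lower(): c for c in df.columns}
    if "sample" not in cols or "group" not in cols:
        raise FormatError(f"{path}: metadata needs 'sample' and 'group' columns")
    if df.empty:
        raise FormatError(f"{path}: empty metadata file")
    samples = df[cols["sample"]].astype(str)
    if samples.duplicated().any():
        dup = samples[samples.duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicated sample id {dup!r}")
    return dict(zip(samples, df[cols["group"]].astype(str)))


def write_metadata(group_of: dict[str, str], path) -> None:
    pd.DataFrame({"sample": list(group_of), "group": list(group_of.values())}
                 ).to_csv(path, sep="\t", index=False)


def read_tree(path) -> TreeNode:
    """Parse a rooted newick tree; missing branch lengths are set to 0."""
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises several parser error types
        raise FormatError(f"{path}: unparseable newick ({exc})") from exc
    for node in tree.traverse():
        if node.length is None:
            node.length = 0.0
        elif node.length < 0:
            raise FormatError(f"{path}: negative branch length at {node.name!r}")
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_matrix(path) -> pd.DataFrame:
    """Read a labeled square matrix TSV (rho, p-values, distances)."""
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise FormatError(f"{path}: matrix row and column labels differ")
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="")


def write_network(network: nx.Graph, clustering, path, format: str = "graphml") -> None:
    """Export a co-occurrence network with node/edge annotations.

    GraphML carries node attributes ``relative_abundance`` and ``cluster_id``
    (when a clustering is given) and edge attributes ``correlation`` and
    ``sign``; the edge-list format is ``taxonA<TAB>taxonB<TAB>correlation``.
    """
    if format not in ("graphml", "edgelist"):
        raise ValueError(f"unknown network format {format!r}")
    g = network.copy()
    if clustering is not None:
        missing = [n for n in clustering.assignment if n not in g]
        if missing:
            raise ValueError(f"clustering covers nodes absent from network: {missing[:5]}")
        for node, cid in clustering.assignment.items():
            g.nodes[node]["cluster_id"] = int(cid)
    for u, v, data in g.edges(data=True):
        data["sign"] = "+" if data.get("correlation", 0.0) >= 0 else "-"
    if format == "graphml":
        nx.write_graphml(g, str(path))
    else:
        with open(path, "w") as fh:
            for u, v, data in sorted(g.edges(data=True)):
                fh.write(f"{u}\t{v}\t{data.get('correlation', float('nan'))!r}\n")


def genus_of(taxon_id: str) -> str:
    """Display genus for labels like ``Ralstonia.01`` (strip the .NN suffix)."""
    stem, _, suffix = taxon_id.rpartition(".")
    if stem and suffix.isdigit():
        return stem
    return taxon_id
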