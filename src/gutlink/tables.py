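"""Tabular data model and I/O shared by every pipeline stage.

The pipeline consumes a finished taxon-by-sample count table (e.g. a genus
or OTU table produced upstream by an amplicon workflow) together with a
sample-to-group metadata table and, optionally, per-sample behavioral
measurements.  All tables travel as TSV (tab-delimited, UTF-8, header row);
networks travel as GraphML, tab-separated edge lists or node-link JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "AbundanceTable",
    "PresenceMatrix",
    "SampleMetadata",
    "BehaviorTable",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "read_behavior_table",
    "write_behavior_table",
    "to_relative_abundance",
    "to_presence",
    "collapse_by_lineage_prefix",
    "write_network",
    "read_network",
]

BEHAVIOR_INDICES = ("SP", "IT", "OAT", "CT")


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


@dataclass
class CountTable:
    """Taxa x samples matrix of non-negative integer counts."""

    taxon_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    taxonomy: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.counts = np.asarray(self.counts)
        _check_unique(self.taxon_ids, "taxon")
        _check_unique(self.sample_ids, "sample")
        if self.counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if len(self.taxon_ids) < 2 or len(self.sample_ids) < 2:
            raise ValueError("a count table needs at least 2 taxa and 2 samples")
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            bad = np.argwhere(~np.isclose(self.counts, rounded, atol=1e-9))
            if bad.size:
                i, j = bad[0]
                raise ValueError(
                    f"non-integer count at taxon {self.taxon_ids[i]!r}, "
                    f"sample {self.sample_ids[j]!r}: {self.counts[i, j]}"
                )
            self.counts = rounded.astype(np.int64)
        bad = np.argwhere(self.counts < 0)
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"negative count at taxon {self.taxon_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}: {self.counts[i, j]}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)


@dataclass
class AbundanceTable:
    """Taxa x samples relative abundances; every sample column sums to 1."""

    taxon_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.taxon_ids, "taxon")
        _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match identifier lists")
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValueError("relative abundances must lie in [0, 1]")
        colsums = self.values.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            j = int(np.argmax(np.abs(colsums - 1.0)))
            raise ValueError(
                f"sample {self.sample_ids[j]!r} abundances sum to {colsums[j]}, not 1"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxon_ids, columns=self.sample_ids)


@dataclass
class PresenceMatrix:
    """Binary taxa x samples occupancy matrix.

    Rows are taxa; ``row_totals`` gives each taxon's occupancy R_i and
    ``shared_counts`` the pairwise co-occupancy matrix S_ij used by the
    checkerboard (C-score) statistics.
    """

    taxon_ids: list[str]
    sample_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("presence matrix entries must be 0 or 1")
        self.matrix = self.matrix.astype(np.int64)
        if self.matrix.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise ValueError("matrix shape does not match identifier lists")

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def row_totals(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    def shared_counts(self) -> np.ndarray:
        return self.matrix @ self.matrix.T


@dataclass
class SampleMetadata:
    """Mapping from sample id to group label drawn from a declared set."""

    groups: dict[str, str]
    group_order: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.group_order:
            seen: list[str] = []
            for g in self.groups.values():
                if g not in seen:
                    seen.append(g)
            self.group_order = tuple(seen)
        unknown = set(self.groups.values()) - set(self.group_order)
        if unknown:
            raise ValueError(f"group labels outside the declared set: {unknown}")
        counts = pd.Series(list(self.groups.values())).value_counts()
        small = [g for g in self.group_order if counts.get(g, 0) < 2]
        if small:
            raise ValueError(f"each group needs >= 2 samples; too small: {small}")

    def group_of(self, sample_id: str) -> str:
        return self.groups[sample_id]

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]

    def validate_samples(self, sample_ids) -> None:
        missing = [s for s in sample_ids if s not in self.groups]
        if missing:
            raise ValueError(f"samples without a group assignment: {missing}")


@dataclass
class BehaviorTable:
    """Per-sample behavioral indices.

    SP = sucrose preference (percent, 0-100), IT = immobility time (s),
    OAT = open-arm time (s), CT = center time (s).  Any subset of the four
    indices may be present; missing measurements are NaN.
    """

    data: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.data = pd.DataFrame(self.data, dtype=float)
        unknown = [c for c in self.data.columns if c not in BEHAVIOR_INDICES]
        if unknown:
            raise ValueError(f"unknown behavioral indices: {unknown}")
        if "SP" in self.data:
            sp = self.data["SP"].dropna()
            if ((sp < 0) | (sp > 100)).any():
                raise ValueError("SP must lie in [0, 100] percent")
        for col in ("IT", "OAT", "CT"):
            if col in self.data and (self.data[col].dropna() < 0).any():
                raise ValueError(f"{col} times must be >= 0")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index.astype(str))

    @property
    def indices(self) -> list[str]:
        return list(self.data.columns)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_count_table(path, orientation: str = "taxa_rows") -> CountTable:
    """Read a TSV count table; first column holds identifiers.

    ``orientation`` declares what the file's rows are; the returned table is
    always taxa x samples.
    """
    if orientation not in ("taxa_rows", "samples_rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    _check_unique(list(df.index), "row")
    _check_unique(list(df.columns), "column")
    mat = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            try:
                v = float(raw)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric count at row {df.index[i]!r}, column {col!r}: {raw!r}"
                ) from None
            if v < 0:
                raise ValueError(
                    f"negative count at row {df.index[i]!r}, column {col!r}: {raw}"
                )
            if v != int(v):
                raise ValueError(
                    f"non-integer count at row {df.index[i]!r}, column {col!r}: {raw}"
                )
            mat[i, j] = int(v)
    if orientation == "samples_rows":
        return CountTable(list(df.columns), list(df.index), mat.T)
    return CountTable(list(df.index), list(df.columns), mat)


def write_count_table(t: CountTable, path) -> None:
    t.to_frame().to_csv(path, sep="\t", index_label="taxon_id")


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    col = df.columns[0]
    return SampleMetadata({str(s): str(g) for s, g in df[col].items()})


def write_metadata(m: SampleMetadata, path) -> None:
    pd.Series(m.groups, name="group").rename_axis("sample_id").to_csv(path, sep="\t")


def read_behavior_table(path) -> BehaviorTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return BehaviorTable(df)


def write_behavior_table(b: BehaviorTable, path) -> None:
    b.data.rename_axis("sample_id").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Derived tables
# ---------------------------------------------------------------------------


def to_relative_abundance(t: CountTable) -> AbundanceTable:
    """Normalize each sample column to relative abundances summing to 1."""
    totals = t.counts.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"sample {t.sample_ids[zero[0]]!r} has zero total count")
    return AbundanceTable(list(t.taxon_ids), list(t.sample_ids), t.counts / totals)


def to_presence(t: CountTable | PresenceMatrix, min_count: int = 1) -> PresenceMatrix:
    """Binarize a count table: present iff count >= ``min_count``."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    mat = t.matrix if isinstance(t, PresenceMatrix) else t.counts
    return PresenceMatrix(
        list(t.taxon_ids), list(t.sample_ids), (mat >= min_count).astype(np.int64)
    )


def collapse_by_lineage_prefix(t: CountTable, depth: int, sep: str = ";") -> CountTable:
    """Sum counts of taxa sharing the first ``depth`` lineage fields.

    Requires ``t.taxonomy``.  This is intentionally a plain exact-prefix
    aggregation, not a taxonomy-aware reconciliation.
    """
    if not t.taxonomy:
        raise ValueError("count table has no taxonomy mapping")
    keys = [sep.join(t.taxonomy[tid].split(sep)[:depth]) for tid in t.taxon_ids]
    frame = t.to_frame().groupby(keys, sort=True).sum()
    return CountTable(
        list(frame.index),
        list(t.sample_ids),
        frame.to_numpy(),
        taxonomy={k: k for k in frame.index},
    )


# ---------------------------------------------------------------------------
# Network export / import
# ---------------------------------------------------------------------------

_NETWORK_FORMATS = ("graphml", "edge_tsv", "json")


def write_network(n: nx.Graph, path, format: str = "graphml") -> None:
    """Write a co-occurrence network.

    graphml and json preserve node attributes; edge_tsv is an edge list
    (source, target, weight, sign) for spreadsheet / Gephi import.
    """
    if format not in _NETWORK_FORMATS:
        raise ValueError(f"unknown network format: {format!r}")
    if format == "graphml":
        nx.write_graphml(n, path)
    elif format == "edge_tsv":
        rows = [
            {"source": u, "target": v, **d}
            for u, v, d in n.edges(data=True)
        ]
        cols = ["source", "target", "weight", "sign"]
        df = pd.DataFrame(rows)
        for c in cols:
            if c not in df.columns:
                df[c] = pd.Series(dtype=float)
        df[cols].to_csv(path, sep="\t", index=False)
    else:
        payload = nx.node_link_data(n, edges="links")
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def read_network(path, format: str = "graphml") -> nx.Graph:
    if format not in _NETWORK_FORMATS:
        raise ValueError(f"unknown network format: {format!r}")
    if format == "graphml":
        return nx.read_graphml(path)
    if format == "edge_tsv":
        df = pd.read_csv(path, sep="\t")
        g = nx.Graph()
        for _, row in df.iterrows():
            g.add_edge(
                str(row["source"]),
                str(row["target"]),
                weight=float(row["weight"]),
                sign=int(row["sign"]) if not pd.isna(row["sign"]) else 0,
            )
        return g
    with open(path) as fh:
        return nx.node_link_graph(json.load(fh), edges="links")
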