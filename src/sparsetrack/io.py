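"""Count-table and metadata I/O, and assembly of aligned source/sink problems.

File dialect
------------
Count tables are UTF-8 TSV. With ``orientation="taxa_rows"`` the first
column header is ``TaxonID`` and the remaining headers are sample ids;
with ``orientation="samples_rows"`` the table is transposed and the first
header is ``SampleID``. All cells must parse as nonnegative integers —
relative-abundance tables are rejected, because the downstream multinomial
model needs read counts.

Metadata is TSV with header ``SampleID<TAB>Env<TAB>SourceSink`` and an
optional ``id`` column grouping a sink with its designated candidate
sources. ``SourceSink`` is ``Source`` or ``Sink``, case-insensitive.

Orientation is never auto-detected: silent transposition is a classic
microbiome-tooling bug, so the caller must state it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "SampleMetadata",
    "SourceSinkProblem",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "build_problem",
    "write_results",
    "read_results",
]

_ROLES = {"source": "Source", "sink": "Sink"}


@dataclass
class CountTable:
    """Integer taxon-by-sample count matrix with identifiers.

    ``counts`` is taxa x samples, nonnegative integers. Identifiers must be
    unique and match the matrix dimensions.
    """

    taxa_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.floor(self.counts)):
                raise ValueError(
                    "counts must be integers; got fractional values "
                    "(relative abundances? rescale to read counts)"
                )
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if self.counts.shape != (len(self.taxa_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.taxa_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if len(set(self.taxa_ids)) != len(self.taxa_ids):
            raise ValueError("duplicate taxon identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_totals(self) -> np.ndarray:
        """Reads per sample (column sums)."""
        return self.counts.sum(axis=0)

    def column(self, sample_id: str) -> np.ndarray:
        return self.counts[:, self.sample_ids.index(sample_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.taxa_ids, columns=self.sample_ids
        )


@dataclass
class SampleMetadata:
    """One sample's role annotation: Source or Sink, with environment label."""

    sample_id: str
    env_label: str
    role: str
    pair_id: str | None = None

    def __post_init__(self) -> None:
        key = self.role.strip().lower()
        if key not in _ROLES:
            raise ValueError(
                f"sample {self.sample_id!r}: role must be Source or Sink, "
                f"got {self.role!r}"
            )
        self.role = _ROLES[key]


@dataclass
class SourceSinkProblem:
    """One sink count vector aligned with a candidate source count matrix.

    ``sink`` has length N; ``sources`` is M x N over the identical taxon
    axis. Totals are derived and must all be positive.
    """

    sink: np.ndarray
    sources: np.ndarray
    taxon_ids: list[str]
    source_ids: list[str]
    sink_id: str = "sink"
    source_totals: np.ndarray = field(init=False)
    sink_total: int = field(init=False)

    def __post_init__(self) -> None:
        self.sink = np.asarray(self.sink, dtype=np.int64)
        self.sources = np.atleast_2d(np.asarray(self.sources, dtype=np.int64))
        n = self.sink.shape[0]
        if self.sources.shape[1] != n or len(self.taxon_ids) != n:
            raise ValueError("sink, sources and taxon_ids disagree on N")
        if self.sources.shape[0] != len(self.source_ids):
            raise ValueError("sources and source_ids disagree on M")
        if n < 1 or self.sources.shape[0] < 1:
            raise ValueError("need at least one taxon and one source")
        self.source_totals = self.sources.sum(axis=1)
        self.sink_total = int(self.sink.sum())
        if self.sink_total <= 0:
            raise ValueError(f"sink {self.sink_id!r} has zero total count")
        for sid, tot in zip(self.source_ids, self.source_totals):
            if tot <= 0:
                raise ValueError(f"source {sid!r} has zero total count")

    @property
    def n_taxa(self) -> int:
        return self.sink.shape[0]

    @property
    def n_sources(self) -> int:
        return self.sources.shape[0]


def _parse_int_cells(df: pd.DataFrame, path: str | Path) -> np.ndarray:
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() | (numeric != numeric.round()) | (numeric < 0)
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: cell at row {df.index[r]!r}, column {df.columns[c]!r} "
            f"({df.iat[r, c]!r}) is not a nonnegative integer"
        )
    return numeric.to_numpy().astype(np.int64)


def read_count_table(
    path: str | Path, orientation: str = "taxa_rows"
) -> CountTable:
    """Read a TSV count table into canonical taxa x samples orientation.

    Parameters
    ----------
    path : file path
    orientation : {"taxa_rows", "samples_rows"}
        Whether file rows are taxa (columns are samples) or the transpose.
    """
    if orientation not in ("taxa_rows", "samples_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    counts = _parse_int_cells(df, path)
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    if orientation == "samples_rows":
        counts = counts.T
        row_ids, col_ids = col_ids, row_ids
    return CountTable(taxa_ids=row_ids, sample_ids=col_ids, counts=counts)


def write_count_table(
    table: CountTable, path: str | Path, orientation: str = "taxa_rows"
) -> None:
    """Write a count table as TSV in the requested orientation."""
    df = table.to_frame()
    if orientation == "taxa_rows":
        df.index.name = "TaxonID"
    elif orientation == "samples_rows":
        df = df.T
        df.index.name = "SampleID"
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    df.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read sample metadata TSV (SampleID, Env, SourceSink[, id])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("SampleID", "Env", "SourceSink"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    has_pair = "id" in df.columns
    records = []
    for _, row in df.iterrows():
        pair = None
        if has_pair and pd.notna(row["id"]):
            pair = str(row["id"])
        records.append(
            SampleMetadata(
                sample_id=str(row["SampleID"]),
                env_label=str(row["Env"]),
                role=str(row["SourceSink"]),
                pair_id=pair,
            )
        )
    return records


def write_metadata(records: Sequence[SampleMetadata], path: str | Path) -> None:
    has_pair = any(r.pair_id is not None for r in records)
    cols = {
        "SampleID": [r.sample_id for r in records],
        "Env": [r.env_label for r in records],
        "SourceSink": [r.role for r in records],
    }
    if has_pair:
        cols["id"] = [r.pair_id if r.pair_id is not None else "" for r in records]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def build_problem(
    table: CountTable,
    metadata: Sequence[SampleMetadata],
    sink_id: str,
) -> SourceSinkProblem:
    """Assemble an aligned SourceSinkProblem for one sink.

    The taxon axis is the union of taxa observed (count > 0) in the sink and
    the selected sources, zero-filled. Sink taxa absent from every source are
    retained so the unknown-source machinery can see them. Source order
    follows metadata order; when the sink carries a pair id, candidate
    sources are restricted to that group.
    """
    by_id = {r.sample_id: r for r in metadata}
    if sink_id not in by_id:
        raise ValueError(f"sink id {sink_id!r} not present in metadata")
    sink_meta = by_id[sink_id]
    if sink_meta.role != "Sink":
        raise ValueError(f"sample {sink_id!r} is labeled {sink_meta.role}, not Sink")
    sources = [r for r in metadata if r.role == "Source"]
    if sink_meta.pair_id is not None:
        sources = [r for r in sources if r.pair_id == sink_meta.pair_id]
    if not sources:
        raise ValueError(f"no candidate sources for sink {sink_id!r}")
    for r in sources + [sink_meta]:
        if r.sample_id not in table.sample_ids:
            raise ValueError(
                f"metadata sample {r.sample_id!r} absent from count table"
            )
    sink_col = table.column(sink_id)
    src_mat = np.stack([table.column(r.sample_id) for r in sources])
    observed = (sink_col > 0) | (src_mat > 0).any(axis=0)
    taxon_ids = [t for t, keep in zip(table.taxa_ids, observed) if keep]
    return SourceSinkProblem(
        sink=sink_col[observed],
        sources=src_mat[:, observed],
        taxon_ids=taxon_ids,
        source_ids=[r.sample_id for r in sources],
        sink_id=sink_id,
    )


def write_results(
    source_ids: Sequence[str],
    proportions: np.ndarray,
    path: str | Path,
    extra: dict | None = None,
) -> None:
    """Write mixing proportions as TSV: source rows plus an ``Unknown`` row.

    Proportions are printed to 6 decimals and adjusted on the largest entry
    so the printed column sums to exactly 1.000000.
    """
    proportions = np.asarray(proportions, dtype=float)
    if len(proportions) != len(source_ids) + 1:
        raise ValueError("expected len(source_ids)+1 proportions (with unknown)")
    rounded = np.round(proportions / proportions.sum(), 6)
    drift = round(1.0 - rounded.sum(), 6)
    rounded[int(np.argmax(rounded))] += drift
    lines = ["SampleID\tproportion"]
    for sid, p in zip(list(source_ids) + ["Unknown"], rounded):
        lines.append(f"{sid}\t{p:.6f}")
    if extra:
        for k, v in extra.items():
            lines.append(f"#{k}\t{v}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_results(path: str | Path) -> pd.Series:
    """Read a proportions TSV back into a Series indexed by source id."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return pd.Series(df["proportion"].to_numpy(), index=df["SampleID"].tolist())
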