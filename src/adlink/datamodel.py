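"""Shared data model and tabular IO.

Every pipeline stage exchanges plain tab-separated text: a genus-by-sample
feature table, a sample metadata table, a qPCR table and a per-reactor-pair
soluble-COD (sCOD) table.  Tables are held in memory as pandas objects
wrapped in light containers that enforce the invariants the downstream
statistics rely on (unique labels, nonnegative integer counts, one feed and
stage per reactor).
"""

from __future__ import annotations

import enum
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("adlink")


class Stage(str, enum.Enum):
    """Reactor stage: acidogenic (first) or methanogenic (second)."""

    first = "first"
    second = "second"


class Feed(str, enum.Enum):
    """The five high-strength wastewater feeds."""

    starch = "starch"
    protein = "protein"
    lipid = "lipid"
    brewery = "brewery"
    dairy = "dairy"


FEEDS: tuple[Feed, ...] = tuple(Feed)
STAGES: tuple[Stage, ...] = tuple(Stage)


class FormatError(ValueError):
    """Malformed input table (bad values, duplicated labels, wrong schema)."""


class ConsistencyError(ValueError):
    """Metadata violates a structural invariant (e.g. one reactor, two feeds)."""


class AlignmentError(ValueError):
    """Two tables that must share samples cannot be aligned."""


@dataclass(frozen=True)
class SampleRecord:
    """Per-sample metadata.

    ``v_s`` is the volume of reactor sample processed for DNA extraction
    (mL); ``v_t`` is the volume of eluted DNA template (µL).  Both enter the
    qPCR copy-number normalization.
    """

    sample_id: str
    reactor_id: str
    stage: Stage
    feed: Feed
    day: int
    v_s: float
    v_t: float

    def __post_init__(self) -> None:
        if self.day < 0:
            raise FormatError(f"sample {self.sample_id}: day must be >= 0")
        if self.v_s <= 0 or self.v_t <= 0:
            raise FormatError(f"sample {self.sample_id}: volumes must be positive")


class CountTable:
    """Genus-by-sample table of nonnegative integer sequence counts."""

    def __init__(self, data: pd.DataFrame):
        if data.index.duplicated().any():
            dups = sorted(set(data.index[data.index.duplicated()]))
            raise FormatError(f"duplicated taxon label(s): {dups}")
        if data.columns.duplicated().any():
            dups = sorted(set(data.columns[data.columns.duplicated()]))
            raise FormatError(f"duplicated sample label(s): {dups}")
        values = data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise FormatError("counts must be numeric")
        if values.size:
            if np.any(values < 0):
                raise FormatError("counts must be nonnegative")
            if not np.allclose(values, np.round(values)):
                raise FormatError("counts must be integers")
        self.data = data.astype(np.int64)

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def column(self, sample_id: str) -> np.ndarray:
        return self.data[sample_id].to_numpy()

    def depths(self) -> pd.Series:
        """Per-sample total counts (sequencing depth)."""
        return self.data.sum(axis=0)

    def select_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        return CountTable(self.data.loc[:, list(sample_ids)])

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CountTable) and self.data.equals(other.data)

    def __repr__(self) -> str:
        return f"CountTable({self.shape[0]} taxa x {self.shape[1]} samples)"


@dataclass
class PerformanceSeries:
    """Combined two-stage sCOD series for one reactor pair.

    ``records`` holds (day, influent sCOD mg/L, 2nd-stage effluent sCOD
    mg/L); ``smoothed`` holds (day, moving-average removal percent) once
    computed.
    """

    pair_id: str
    records: list[tuple[int, float, float]]
    smoothed: list[tuple[int, float]] | None = None

    def __post_init__(self) -> None:
        days = [r[0] for r in self.records]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise FormatError(f"pair {self.pair_id}: days must be strictly increasing")
        if any(r[1] < 0 or r[2] < 0 for r in self.records):
            raise FormatError(f"pair {self.pair_id}: sCOD concentrations must be >= 0")

    @property
    def days(self) -> list[int]:
        return [r[0] for r in self.records]


@dataclass
class ResultRecord:
    """Generic keyed output record carrying provenance."""

    kind: str
    stage: str
    feed: str
    payload: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {"kind": self.kind, "stage": self.stage, "feed": self.feed}
        row.update(self.payload)
        return row


# ---------------------------------------------------------------------------
# Readers / writers (tab-separated text is the canonical interchange format)
# ---------------------------------------------------------------------------

METADATA_COLUMNS = ("sample_id", "reactor_id", "stage", "feed", "day", "v_s", "v_t")


def read_count_table(path: str | Path) -> CountTable:
    """Read a TSV feature table: first column taxon labels, header sample ids."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dup = sorted({h for h in header if header.count(h) > 1})
    if dup:  # pandas would silently mangle duplicated sample columns
        raise FormatError(f"{path}: duplicated sample label(s): {dup}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    try:
        return CountTable(df)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_count_table(table: CountTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index_label="taxon")


def read_metadata(path: str | Path) -> list[SampleRecord]:
    """Read and validate the sample metadata TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "reactor_id": str})
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if df["sample_id"].duplicated().any():
        dups = sorted(set(df.loc[df["sample_id"].duplicated(), "sample_id"]))
        raise FormatError(f"{path}: duplicated sample_id(s): {dups}")
    records = []
    for _, row in df.iterrows():
        try:
            stage = Stage(row["stage"])
        except ValueError:
            raise FormatError(
                f"{path}: sample {row['sample_id']}: unknown stage {row['stage']!r}"
            ) from None
        try:
            feed = Feed(row["feed"])
        except ValueError:
            raise FormatError(
                f"{path}: sample {row['sample_id']}: unknown feed {row['feed']!r}"
            ) from None
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                reactor_id=str(row["reactor_id"]),
                stage=stage,
                feed=feed,
                day=int(row["day"]),
                v_s=float(row["v_s"]),
                v_t=float(row["v_t"]),
            )
        )
    validate_reactor_map(records)
    return records


def validate_reactor_map(records: Iterable[SampleRecord]) -> dict[str, tuple[Stage, Feed]]:
    """Each reactor maps to exactly one (stage, feed); raise otherwise."""
    mapping: dict[str, tuple[Stage, Feed]] = {}
    for rec in records:
        key = (rec.stage, rec.feed)
        if rec.reactor_id in mapping and mapping[rec.reactor_id] != key:
            raise ConsistencyError(
                f"reactor {rec.reactor_id} mapped to both "
                f"{mapping[rec.reactor_id]} and {key}"
            )
        mapping[rec.reactor_id] = key
    return mapping


def write_metadata(records: Sequence[SampleRecord], path: str | Path) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "reactor_id": r.reactor_id,
            "stage": r.stage.value,
            "feed": r.feed.value,
            "day": r.day,
            "v_s": r.v_s,
            "v_t": r.v_t,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(METADATA_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_qpcr(path: str | Path) -> pd.DataFrame:
    """Read the qPCR TSV.

    Must contain ``sample_id`` plus either ``copies_per_ul_template`` or
    replicate Cq columns (``cq_1``, ``cq_2``, ...) to be quantified against a
    standard curve.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: missing sample_id column")
    cq_cols = [c for c in df.columns if c.startswith("cq_")]
    if "copies_per_ul_template" not in df.columns and not cq_cols:
        raise FormatError(
            f"{path}: need copies_per_ul_template or cq_* replicate columns"
        )
    if df["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicated sample_id in qPCR table")
    return df


def read_scod(path: str | Path) -> list[PerformanceSeries]:
    """Read the sCOD TSV (pair_id, day, scod_in, scod_out2) into series."""
    df = pd.read_csv(path, sep="\t", dtype={"pair_id": str})
    required = {"pair_id", "day", "scod_in", "scod_out2"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    out = []
    for pair_id, grp in df.groupby("pair_id", sort=True):
        grp = grp.sort_values("day")
        records = [
            (int(d), float(i), float(o))
            for d, i, o in zip(grp["day"], grp["scod_in"], grp["scod_out2"])
        ]
        out.append(PerformanceSeries(pair_id=str(pair_id), records=records))
    return out


def write_scod(series: Sequence[PerformanceSeries], path: str | Path) -> None:
    rows = []
    for s in series:
        for day, cin, cout in s.records:
            rows.append(
                {"pair_id": s.pair_id, "day": day, "scod_in": cin, "scod_out2": cout}
            )
    pd.DataFrame(rows, columns=["pair_id", "day", "scod_in", "scod_out2"]).to_csv(
        path, sep="\t", index=False
    )


def align_tables(
    counts: CountTable, meta: Sequence[SampleRecord]
) -> tuple[CountTable, list[SampleRecord]]:
    """Restrict counts and metadata to their shared samples, in count order.

    Samples present on only one side are dropped with a logged warning; an
    empty intersection is fatal.
    """
    meta_ids = {r.sample_id for r in meta}
    shared = [s for s in counts.samples if s in meta_ids]
    if not shared:
        raise AlignmentError("no samples shared between count table and metadata")
    dropped_counts = [s for s in counts.samples if s not in meta_ids]
    dropped_meta = sorted(meta_ids - set(shared))
    if dropped_counts or dropped_meta:
        log.warning(
            "align_tables dropped %d count-only sample(s) %s and %d "
            "metadata-only sample(s) %s",
            len(dropped_counts), dropped_counts, len(dropped_meta), dropped_meta,
        )
    by_id = {r.sample_id: r for r in meta}
    return counts.select_samples(shared), [by_id[s] for s in shared]


def samples_by(
    meta: Sequence[SampleRecord],
    stage: Stage | None = None,
    feed: Feed | None = None,
    reactor_id: str | None = None,
) -> list[SampleRecord]:
    """Filter metadata records by stage / feed / reactor."""
    out = []
    for r in meta:
        if stage is not None and r.stage != stage:
            continue
        if feed is not None and r.feed != feed:
            continue
        if reactor_id is not None and r.reactor_id != reactor_id:
            continue
        out.append(r)
    return out


def file_digest(path: str | Path) -> str:
    """Short sha256 digest of a file, for run-report provenance."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]
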