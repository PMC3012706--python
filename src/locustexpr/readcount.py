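"""Cluster-aware read counting from alignment records.

Classical unique-read counting discards any read mapping to more than one
transcript.  In a de novo transcriptome, isoforms and near-identical
paralogs make such multireads common, so counting is done per *unit* — a
similarity cluster or a singleton transcript: a read whose hits all fall
inside one unit counts once for that unit; a read whose hits span two or
more units is discarded.  Per-library totals N count assigned reads only.

Alignments travel either as :class:`AlignmentRecord` objects or as a
pandas DataFrame with columns ``read_id, library, lane, hits`` (hits a
tuple of transcript ids); the DataFrame form is used for large inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .catalog import ClusterMap, ConsistencyError, TranscriptCatalog

ALN_COLUMNS = ["read_id", "library", "lane", "hits"]


@dataclass(frozen=True)
class AlignmentRecord:
    """All hits of one read: >=1 distinct transcript ids."""

    read_id: str
    library: str
    lane: str
    hits: tuple[str, ...]
    mismatches: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.hits) == 0:
            raise ValueError(f"read {self.read_id!r} has no hits")
        if len(set(self.hits)) != len(self.hits):
            raise ValueError(f"read {self.read_id!r} lists duplicate hits")


def as_frame(alignments) -> pd.DataFrame:
    """Normalize alignment input (records or DataFrame) to a DataFrame."""
    if isinstance(alignments, pd.DataFrame):
        missing = set(ALN_COLUMNS) - set(alignments.columns)
        if missing:
            raise ValueError(f"alignment table lacks columns {sorted(missing)}")
        return alignments
    rows = [(a.read_id, a.library, a.lane, tuple(a.hits)) for a in alignments]
    return pd.DataFrame(rows, columns=ALN_COLUMNS)


@dataclass
class CountTable:
    """Per-unit, per-library mapped-read counts with assigned totals N."""

    counts: pd.DataFrame
    totals: pd.Series
    discarded: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        self.counts.index = self.counts.index.rename("unit_id")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        self.totals = pd.Series(self.totals).reindex(self.counts.columns).astype(np.int64)
        if self.discarded is None:
            self.discarded = pd.Series(0, index=self.counts.columns, dtype=np.int64)
        else:
            self.discarded = (
                pd.Series(self.discarded).reindex(self.counts.columns).fillna(0).astype(np.int64)
            )

    @property
    def libraries(self) -> pd.Index:
        return self.counts.columns

    @property
    def units(self) -> pd.Index:
        return self.counts.index

    def column(self, library: str) -> pd.Series:
        return self.counts[library]

    def subset(self, libraries: Iterable[str]) -> "CountTable":
        libs = list(libraries)
        return CountTable(self.counts[libs], self.totals[libs], self.discarded[libs])

    # ---- I/O ---------------------------------------------------------

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for lib in self.counts.columns:
                fh.write(f"#total_mapped\t{lib}\t{self.totals[lib]}\n")
                fh.write(f"#discarded\t{lib}\t{self.discarded[lib]}\n")
            self.counts.rename_axis("unit_id").to_csv(fh, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CountTable":
        totals: dict[str, int] = {}
        discarded: dict[str, int] = {}
        with open(path) as fh:
            pos = fh.tell()
            for line in iter(fh.readline, ""):
                if not line.startswith("#"):
                    fh.seek(pos)
                    break
                parts = line.rstrip("\n").split("\t")
                if len(parts) == 3:
                    tag, lib, value = parts
                    if tag == "#total_mapped":
                        totals[lib] = int(value)
                    elif tag == "#discarded":
                        discarded[lib] = int(value)
                pos = fh.tell()
            counts = pd.read_csv(fh, sep="\t", index_col="unit_id")
        counts.index = counts.index.astype(str)
        return cls(counts, pd.Series(totals), pd.Series(discarded))


def _units_of_hits(df: pd.DataFrame, clusters: ClusterMap) -> pd.DataFrame:
    """Explode hits to one row per hit, with its counting unit attached."""
    n_hits = df["hits"].map(len).to_numpy()
    flat = pd.DataFrame(
        {
            "row": np.repeat(np.arange(len(df)), n_hits),
            "hit": np.concatenate([list(h) for h in df["hits"]]) if len(df) else [],
        }
    )
    unit_map = clusters._unit_of
    units = flat["hit"].map(unit_map)
    if units.isna().any():
        bad = flat.loc[units.isna(), "hit"].iloc[0]
        raise ConsistencyError(f"alignment hit on transcript {bad!r} absent from cluster map")
    flat["unit"] = units
    return flat


def assign_reads(alignments, clusters: ClusterMap) -> CountTable:
    """Count reads per unit: all-hits-in-one-unit reads count once; others
    are discarded.  Zero-count units are retained in the table."""
    df = as_frame(alignments)
    libraries = sorted(df["library"].unique())
    units = clusters.units.sort_values()
    if len(df) == 0:
        empty = pd.DataFrame(0, index=units, columns=libraries, dtype=np.int64)
        return CountTable(empty, pd.Series(0, index=libraries), pd.Series(0, index=libraries))

    flat = _units_of_hits(df, clusters)
    grouped = flat.groupby("row")["unit"]
    n_units_per_read = grouped.nunique()
    unit_per_read = grouped.first()
    assigned_mask = (n_units_per_read == 1).to_numpy()

    lib_per_read = df["library"].to_numpy()
    assigned = pd.DataFrame(
        {"unit": unit_per_read.to_numpy()[assigned_mask], "library": lib_per_read[assigned_mask]}
    )
    counts = (
        assigned.groupby(["unit", "library"], sort=True)
        .size()
        .unstack(fill_value=0)
        .reindex(index=units, columns=libraries, fill_value=0)
    )
    totals = pd.Series(assigned["library"].value_counts()).reindex(libraries).fillna(0)
    per_lib = pd.Series(lib_per_read).value_counts().reindex(libraries).fillna(0)
    discarded = per_lib - totals
    return CountTable(counts, totals, discarded)


def detection_by_lanes(alignments, clusters: ClusterMap) -> pd.DataFrame:
    """Per unit x library: number of lanes with >=1 assigned read."""
    df = as_frame(alignments)
    units = clusters.units.sort_values()
    if len(df) == 0:
        return pd.DataFrame(index=units, dtype=np.int64)
    flat = _units_of_hits(df, clusters)
    grouped = flat.groupby("row")["unit"]
    assigned_mask = (grouped.nunique() == 1).to_numpy()
    sub = pd.DataFrame(
        {
            "unit": grouped.first().to_numpy()[assigned_mask],
            "library": df["library"].to_numpy()[assigned_mask],
            "lane": df["lane"].to_numpy()[assigned_mask],
        }
    )
    det = (
        sub.drop_duplicates()
        .groupby(["unit", "library"])
        .size()
        .unstack(fill_value=0)
        .reindex(index=units, fill_value=0)
        .astype(np.int64)
    )
    return det


def detection_histogram(lane_counts: pd.Series) -> pd.Series:
    """Histogram of units over number of lanes detected (index = #lanes)."""
    return lane_counts.value_counts().sort_index()


def lane_detection_groups(lane_counts: pd.Series, n_lanes: int) -> pd.Series:
    """Summarize detection into all / some / one / none groups."""
    def label(k: int) -> str:
        if k == 0:
            return "none"
        if k == 1:
            return "one"
        if k == n_lanes:
            return "all"
        return "some"

    return lane_counts.map(label).value_counts().reindex(
        ["all", "some", "one", "none"], fill_value=0
    )


def downsample_to_lane(alignments, library: str, seed: int) -> pd.DataFrame:
    """Keep one randomly selected lane of ``library`` (other libraries kept).

    Emulates representing a deeply sequenced paired-end library by a single
    randomly chosen lane so it is comparable to one-lane libraries.
    """
    df = as_frame(alignments)
    lanes = sorted(df.loc[df["library"] == library, "lane"].unique())
    if not lanes:
        raise ValueError(f"no alignments for library {library!r}")
    rng = np.random.default_rng(seed)
    chosen = lanes[int(rng.integers(len(lanes)))]
    keep = (df["library"] != library) | (df["lane"] == chosen)
    return df[keep].reset_index(drop=True)


# ---- alignment I/O -------------------------------------------------------

def write_alignment_tsv(alignments, path: str | Path) -> None:
    """Tabular dialect: read_id, library, lane, comma-separated hits."""
    df = as_frame(alignments)
    out = df.copy()
    out["hits"] = out["hits"].map(",".join)
    out.to_csv(path, sep="\t", index=False)


def read_alignment_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"read_id": str, "library": str, "lane": str})
    df["hits"] = df["hits"].map(lambda s: tuple(s.split(",")))
    return df


def read_sam(path: str | Path, library: str, lane: str = "L1") -> pd.DataFrame:
    """Collect mapped records per read name from a SAM file (multi-hit
    reporting as secondary alignments)."""
    import pysam

    hits: dict[str, list[str]] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.reference_name is None:
                continue
            hits.setdefault(rec.query_name, [])
            if rec.reference_name not in hits[rec.query_name]:
                hits[rec.query_name].append(rec.reference_name)
    rows = [(rid, library, lane, tuple(h)) for rid, h in hits.items()]
    return pd.DataFrame(rows, columns=ALN_COLUMNS)


def write_sam(alignments, catalog: TranscriptCatalog, path: str | Path) -> None:
    """Write alignments as unsorted SAM; extra hits become secondary records.

    Positions are placeholders (the counting rule uses hit identity only).
    """
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": t, "LN": int(catalog.lengths[t])} for t in catalog.ids],
    }
    tid = {t: i for i, t in enumerate(catalog.ids)}
    df = as_frame(alignments)
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for row in df.itertuples(index=False):
            for i, hit in enumerate(row.hits):
                rec = pysam.AlignedSegment(out.header)
                rec.query_name = row.read_id
                rec.reference_id = tid[hit]
                rec.reference_start = 0
                rec.mapping_quality = 0
                rec.cigarstring = "35M"
                rec.flag = 0 if i == 0 else 256
                rec.set_tag("RG", f"{row.library}.{row.lane}")
                out.write(rec)
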