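"""Assembly quality metrics: length statistics, reference coverage,
chimera flagging.

Length statistics follow the usual assembly-report conventions: counts in
half-open bins [100, 500), [500, 1000), [1000, 2000), [2000, inf), and
N50 defined as the length of the sequence at which the descending
cumulative length first reaches half the total.

Coverage evaluation aligns reads (or transcript matches) onto trusted
reference sequences (e.g. Sanger ESTs) with 1-based inclusive intervals:
a reference qualifies when the fraction of its bases at depth >= d
exceeds a cutoff, and the mismatch rate is total mismatches over total
covered bases.  Chimera flagging marks assembled sequences hitting more
than one distinct protein, each hit passing identity, e-value and score
thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import ConsistencyError

LENGTH_BIN_EDGES = (100, 500, 1000, 2000)
LENGTH_BIN_LABELS = ("100-500", "500-1000", "1000-2000", ">=2000")


@dataclass
class AssemblyStats:
    n_sequences: int
    total_bp: int
    mean: float
    median: float
    min: int
    max: int
    n50: int
    bin_counts: dict[str, int]

    def to_series(self) -> pd.Series:
        out = {
            "n_sequences": self.n_sequences,
            "total_bp": self.total_bp,
            "mean": self.mean,
            "median": self.median,
            "min": self.min,
            "max": self.max,
            "n50": self.n50,
        }
        out.update({f"bin_{k}": v for k, v in self.bin_counts.items()})
        return pd.Series(out)


def length_stats(lengths) -> AssemblyStats:
    """Summary statistics and N50 of a sequence length set."""
    arr = np.asarray(list(lengths), dtype=np.int64)
    if arr.size == 0:
        raise ValueError("empty length set")
    if (arr < 1).any():
        raise ValueError("lengths must be >= 1")
    total = int(arr.sum())
    desc = np.sort(arr)[::-1]
    cum = np.cumsum(desc)
    n50 = int(desc[np.searchsorted(cum, total / 2.0)])
    edges = list(LENGTH_BIN_EDGES)
    bins = {
        LENGTH_BIN_LABELS[0]: int((arr < edges[1]).sum()),
        LENGTH_BIN_LABELS[1]: int(((arr >= edges[1]) & (arr < edges[2])).sum()),
        LENGTH_BIN_LABELS[2]: int(((arr >= edges[2]) & (arr < edges[3])).sum()),
        LENGTH_BIN_LABELS[3]: int((arr >= edges[3]).sum()),
    }
    return AssemblyStats(
        n_sequences=int(arr.size),
        total_bp=total,
        mean=float(arr.mean()),
        median=float(np.median(arr)),
        min=int(arr.min()),
        max=int(arr.max()),
        n50=n50,
        bin_counts=bins,
    )


@dataclass
class CoverageReport:
    per_reference: pd.DataFrame  # length, covered_bases, covered_fraction, qualifies, mismatches
    min_depth: int
    min_cov: float
    mismatch_rate: float         # total mismatches / total depth>=1 covered bases


def coverage_eval(
    intervals: pd.DataFrame,
    ref_lengths: pd.Series,
    min_depth: int = 2,
    min_cov: float = 0.9,
) -> CoverageReport:
    """Per-base coverage of references by alignment intervals.

    ``intervals`` columns: ref, start, end (1-based inclusive), mismatches.
    A reference qualifies when its fraction of bases at depth >=
    ``min_depth`` strictly exceeds ``min_cov``.  With ``min_depth=1`` the
    covered set equals the union of alignment spans, so both the
    read-depth and the span-based evaluation modes are available through
    this one parameter.
    """
    ref_lengths = pd.Series(ref_lengths)
    need = {"ref", "start", "end"}
    if not need <= set(intervals.columns):
        raise ValueError(f"interval table needs columns {sorted(need)}")
    mm_col = intervals["mismatches"] if "mismatches" in intervals.columns else 0

    depth = {r: np.zeros(int(n), dtype=np.int32) for r, n in ref_lengths.items()}
    mism = dict.fromkeys(ref_lengths.index, 0)
    for row, mm in zip(intervals.itertuples(index=False), np.broadcast_to(np.asarray(mm_col), (len(intervals),))):
        if row.ref not in depth:
            raise ConsistencyError(f"interval on unknown reference {row.ref!r}")
        start, end = int(row.start), int(row.end)
        if start < 1 or end > len(depth[row.ref]) or start > end:
            raise ConsistencyError(
                f"interval {start}-{end} out of bounds on {row.ref!r} "
                f"(length {len(depth[row.ref])})"
            )
        depth[row.ref][start - 1 : end] += 1
        mism[row.ref] += int(mm)

    rows = {}
    total_mm = 0
    total_cov1 = 0
    for ref, d in depth.items():
        covered = int((d >= min_depth).sum())
        cov1 = int((d >= 1).sum())
        frac = covered / len(d)
        rows[ref] = {
            "length": len(d),
            "covered_bases": covered,
            "covered_fraction": frac,
            "qualifies": frac > min_cov,
            "mismatches": mism[ref],
        }
        total_mm += mism[ref]
        total_cov1 += cov1
    per_ref = pd.DataFrame.from_dict(rows, orient="index")
    per_ref.index.name = "ref"
    rate = total_mm / total_cov1 if total_cov1 else 0.0
    return CoverageReport(per_ref, min_depth, min_cov, rate)


def depth_profile(intervals: pd.DataFrame, ref_length: int, ref: str) -> np.ndarray:
    """Per-base depth vector for one reference (inspection aid)."""
    d = np.zeros(ref_length, dtype=np.int32)
    for row in intervals[intervals["ref"] == ref].itertuples(index=False):
        d[int(row.start) - 1 : int(row.end)] += 1
    return d


def chimera_flags(
    hits: pd.DataFrame,
    min_identity: float = 0.3,
    max_evalue: float = 1e-10,
    min_score: float = 200,
) -> set[str]:
    """Flag sequences with >=2 distinct qualifying protein hits.

    ``hits`` columns: query, subject, identity (fraction), evalue, score.
    Thresholds are strict: identity > 0.3, e-value < 1e-10, score > 200.
    """
    if len(hits) == 0:
        return set()
    ok = hits[
        (hits["identity"] > min_identity)
        & (hits["evalue"] < max_evalue)
        & (hits["score"] > min_score)
    ]
    n_subjects = ok.groupby("query")["subject"].nunique()
    return set(n_subjects.index[n_subjects >= 2].astype(str))
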