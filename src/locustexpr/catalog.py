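"""Shared containers: transcript catalogs and similarity-cluster maps.

A :class:`TranscriptCatalog` holds the assembled transcript set (ids,
lengths in bp, optionally sequences).  A :class:`ClusterMap` is a partition
of the catalog into similarity clusters; each cluster is named after its
representative, the longest member.  Singleton transcripts form their own
cluster.  Cluster ids double as "counting units" downstream: reads are
counted per unit, and member transcripts inherit the unit's count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd


class ConsistencyError(ValueError):
    """Input records refer to entities absent from the catalog/cluster map."""


@dataclass
class TranscriptCatalog:
    """Transcript ids with lengths (bp) and optional sequences."""

    lengths: pd.Series
    sequences: dict[str, str] | None = None

    def __post_init__(self) -> None:
        s = pd.Series(self.lengths).astype(int)
        s.index = s.index.astype(str)
        if len(s) and (s <= 0).any():
            raise ValueError("transcript lengths must be positive")
        if not s.index.is_unique:
            raise ValueError("duplicate transcript ids in catalog")
        s.name = "length"
        self.lengths = s

    @property
    def ids(self) -> pd.Index:
        return self.lengths.index

    def __len__(self) -> int:
        return len(self.lengths)

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.lengths.index

    # ---- I/O ---------------------------------------------------------

    def write_lengths(self, path: str | Path) -> None:
        df = self.lengths.rename_axis("transcript_id").reset_index()
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_lengths(cls, path: str | Path) -> "TranscriptCatalog":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(lengths=pd.Series(df["length"].values, index=df["transcript_id"].astype(str)))

    def write_fasta(self, path: str | Path) -> None:
        if self.sequences is None:
            raise ValueError("catalog carries no sequences")
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        records = [SeqRecord(Seq(self.sequences[t]), id=t, description="") for t in self.ids]
        seqio_write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "TranscriptCatalog":
        from Bio import SeqIO

        seqs: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            seqs[rec.id] = str(rec.seq)
        lengths = pd.Series({k: len(v) for k, v in seqs.items()})
        return cls(lengths=lengths, sequences=seqs)


@dataclass
class ClusterMap:
    """Partition of transcripts into clusters named after their representative.

    ``assignments`` maps transcript id -> cluster id; ``representatives``
    maps cluster id -> representative transcript id (the longest member,
    ties broken by lexicographically smallest id).
    """

    assignments: pd.Series
    representatives: pd.Series

    def __post_init__(self) -> None:
        a = pd.Series(self.assignments).astype(str)
        a.index = a.index.astype(str)
        r = pd.Series(self.representatives).astype(str)
        r.index = r.index.astype(str)
        if not a.index.is_unique:
            raise ValueError("a transcript may belong to only one cluster")
        missing = set(a.unique()) - set(r.index)
        if missing:
            raise ValueError(f"clusters without representative: {sorted(missing)[:5]}")
        self.assignments = a
        self.representatives = r
        self._unit_of: dict[str, str] = a.to_dict()

    @classmethod
    def singletons(cls, transcript_ids) -> "ClusterMap":
        ids = pd.Index(transcript_ids).astype(str)
        same = pd.Series(ids, index=ids)
        return cls(assignments=same, representatives=same.copy())

    @property
    def units(self) -> pd.Index:
        return pd.Index(self.representatives.index)

    @property
    def n_units(self) -> int:
        return len(self.representatives)

    def unit_of(self, transcript_id: str) -> str:
        try:
            return self._unit_of[transcript_id]
        except KeyError:
            raise ConsistencyError(f"transcript {transcript_id!r} absent from cluster map")

    def members(self, cluster_id: str) -> list[str]:
        return sorted(self.assignments.index[self.assignments == cluster_id])

    def cluster_sizes(self) -> pd.Series:
        return self.assignments.value_counts().reindex(self.units, fill_value=0)

    def check_partition(self, catalog: TranscriptCatalog) -> None:
        """Raise unless this map is an exact partition of the catalog."""
        got = set(self.assignments.index)
        want = set(catalog.ids)
        if got != want:
            raise ConsistencyError(
                f"cluster map covers {len(got)} transcripts, catalog has {len(want)}"
            )

    # ---- I/O ---------------------------------------------------------

    def write_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "transcript_id": self.assignments.index,
                "cluster_id": self.assignments.values,
            }
        )
        rep_of = self.representatives.to_dict()
        df["is_representative"] = [
            int(rep_of[c] == t) for t, c in zip(df["transcript_id"], df["cluster_id"])
        ]
        df = df.sort_values(["cluster_id", "transcript_id"], kind="mergesort")
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ClusterMap":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        df["is_representative"] = df["is_representative"].astype(int)
        assignments = pd.Series(df["cluster_id"].values, index=df["transcript_id"].values)
        reps = df[df["is_representative"] == 1]
        representatives = pd.Series(reps["transcript_id"].values, index=reps["cluster_id"].values)
        return cls(assignments=assignments, representatives=representatives)
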