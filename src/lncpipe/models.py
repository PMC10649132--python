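"""Core in-memory containers shared by every pipeline stage.

Coordinates are 0-based half-open throughout the package; conversion to and
from the 1-based inclusive GTF convention happens only in :mod:`lncpipe.formats`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

VALID_ALPHABET = frozenset("ACGTN")
_SEQ_RE = re.compile(r"[^ACGTN]")


@dataclass(frozen=True)
class SequenceRecord:
    """A nucleotide sequence with a unique identifier.

    The sequence is canonical uppercase over {A, C, G, T, N}.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"sequence for {self.id!r} is empty")
        m = _SEQ_RE.search(self.sequence)
        if m:
            raise ValueError(
                f"sequence for {self.id!r} has invalid character "
                f"{m.group()!r} at position {m.start()}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TranscriptModel:
    """One spliced transcript: exon intervals on a chromosome strand.

    ``exons`` are 0-based half-open [start, end) intervals, sorted by start
    and pairwise non-overlapping.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    biotype: str = "other"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript has no exons")
        prev_end = -1
        for start, end in self.exons:
            if start < 0 or start >= end:
                raise ValueError(
                    f"{self.transcript_id}: invalid exon interval [{start}, {end})"
                )
            if start < prev_end:
                raise ValueError(
                    f"{self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = end
        if self.biotype not in ("protein_coding", "lncRNA", "other"):
            raise ValueError(f"{self.transcript_id}: unknown biotype {self.biotype!r}")

    @property
    def length(self) -> int:
        """Spliced (mature) transcript length in nt."""
        return sum(e - s for s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic span from first exon start to last exon end."""
        return self.exons[0][0], self.exons[-1][1]

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Intron intervals (0-based half-open) between consecutive exons."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )


@dataclass(frozen=True)
class HomologyHit:
    """One tabular homology-search hit against a classified subject."""

    query_id: str
    subject_id: str
    subject_class: str  # "coding_or_other" | "lncRNA"
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative E-value for {self.query_id}/{self.subject_id}")
        if self.subject_class not in ("coding_or_other", "lncRNA"):
            raise ValueError(f"unknown subject class {self.subject_class!r}")


class CountMatrix:
    """Features x samples raw count matrix with a two-group design.

    Wraps a pandas DataFrame of non-negative integers plus a sample -> group
    map with groups "control" and "treated".
    """

    def __init__(self, counts: pd.DataFrame, groups: Mapping[str, str]):
        if counts.index.has_duplicates:
            raise ValueError("duplicate feature ids in count matrix")
        if counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids in count matrix")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.equal(np.mod(values, 1), 0)):
                raise ValueError("count matrix contains non-integer values")
            counts = counts.astype(np.int64)
        if (counts.to_numpy() < 0).any():
            raise ValueError("count matrix contains negative values")
        missing = [s for s in counts.columns if s not in groups]
        if missing:
            raise ValueError(f"samples without group assignment: {missing}")
        bad = {s: g for s, g in groups.items()
               if s in counts.columns and g not in ("control", "treated")}
        if bad:
            raise ValueError(f"unknown group labels: {bad}")
        self.counts = counts
        self.groups = {s: groups[s] for s in counts.columns}

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.groups[s] == group]

    def drop_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        keep = [s for s in self.sample_ids if s not in set(sample_ids)]
        return CountMatrix(self.counts[keep], {s: self.groups[s] for s in keep})

    def require_two_per_group(self) -> None:
        for g in ("control", "treated"):
            n = len(self.samples_in_group(g))
            if n < 2:
                raise ValueError(f"group {g!r} has {n} samples; need >= 2")

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, CountMatrix)
            and self.counts.equals(other.counts)
            and self.groups == other.groups
        )

    def __repr__(self) -> str:
        return (f"CountMatrix({len(self.feature_ids)} features x "
                f"{len(self.sample_ids)} samples)")


@dataclass
class ClassCodeResult:
    """Structural relation of one assembled transcript to the reference."""

    transcript_id: str
    code: str  # one of = j o x i u
    matched_reference_id: str | None = None

    def __post_init__(self) -> None:
        if self.code not in "=joxiu" or len(self.code) != 1:
            raise ValueError(f"unknown class code {self.code!r}")
        if self.code in ("=", "j") and self.matched_reference_id is None:
            raise ValueError(f"code {self.code!r} requires a matched reference")
        if self.code == "u" and self.matched_reference_id is not None:
            raise ValueError("code 'u' cannot have a matched reference")


@dataclass
class CandidateSet:
    """Outcome of the lncRNA retention cascade.

    Every input transcript lands in exactly one of novel_candidates,
    annotated_lncRNAs or removal_log.
    """

    novel_candidates: list[str] = field(default_factory=list)
    annotated_lncRNAs: list[str] = field(default_factory=list)
    removal_log: dict[str, str] = field(default_factory=dict)

    def check_partition(self, all_ids: Sequence[str]) -> None:
        seen = set(self.novel_candidates) | set(self.annotated_lncRNAs) | set(self.removal_log)
        if set(self.novel_candidates) & set(self.annotated_lncRNAs):
            raise AssertionError("novel candidates and annotated lncRNAs overlap")
        if set(self.novel_candidates) & set(self.removal_log):
            raise AssertionError("novel candidates appear in removal log")
        if set(self.annotated_lncRNAs) & set(self.removal_log):
            raise AssertionError("annotated lncRNAs appear in removal log")
        if seen != set(all_ids):
            raise AssertionError("candidate set does not partition the input")


@dataclass(frozen=True)
class CorrelationEdge:
    """One DEL-DEG co-expression link."""

    del_id: str
    deg_id: str
    r: float
    p: float
    mode: str  # "cis" | "trans"
    sign: str  # "positive" | "negative"
    distance_bp: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("cis", "trans"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.sign != ("positive" if self.r > 0 else "negative"):
            raise ValueError("edge sign inconsistent with r")
        if self.mode == "cis" and self.distance_bp is None:
            raise ValueError("cis edge requires a distance")
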