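"""Readers and writers for the standard text formats the pipeline consumes.

FASTA (wrap 60), GTF2.2, TSV count tables and BLAST tabular (outfmt 6).
All writers emit UNIX newlines in UTF-8.  GTF coordinates are 1-based
inclusive on disk and converted to the package's 0-based half-open internal
form here and only here.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .models import CountMatrix, HomologyHit, SequenceRecord, TranscriptModel

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into validated :class:`SequenceRecord` objects.

    Order is preserved, wrapped sequences are concatenated, lowercase is
    uppercased.  Duplicate ids, empty sequences and non-{A,C,G,T,N}
    characters are hard errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                line_width: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``line_width``."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), line_width):
                fh.write(rec.sequence[i:i + line_width] + "\n")


def _parse_attributes(field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field))


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read transcript models from a GTF2.2 file.

    Only ``exon`` features are used.  Exons are grouped by transcript_id and
    sorted; the biotype comes from a ``gene_biotype`` or ``transcript_biotype``
    attribute and defaults to ``other``.  Transcripts whose exons disagree on
    chromosome or strand, 0-based-looking coordinates and start > end are
    hard errors.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str, str]] = {}  # tid -> (gene, chrom, strand, biotype)
    order: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 tab-separated columns")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            start, end = int(start_s), int(end_s)
            if start < 1:
                raise ValueError(f"{path}:{lineno}: GTF coordinates are 1-based; got start {start}")
            if start > end:
                raise ValueError(f"{path}:{lineno}: start {start} > end {end}")
            attr = _parse_attributes(attrs)
            tid = attr.get("transcript_id")
            if not tid:
                raise ValueError(f"{path}:{lineno}: exon without transcript_id")
            gene = attr.get("gene_id", tid)
            biotype = attr.get("gene_biotype") or attr.get("transcript_biotype") or "other"
            if biotype not in ("protein_coding", "lncRNA"):
                biotype = "other"
            if tid not in meta:
                meta[tid] = (gene, chrom, strand, biotype)
                order.append(tid)
            else:
                _, c0, s0, _ = meta[tid]
                if c0 != chrom:
                    raise ValueError(f"{path}:{lineno}: transcript {tid} spans multiple chromosomes")
                if s0 != strand:
                    raise ValueError(f"{path}:{lineno}: transcript {tid} mixes strands")
            # 1-based inclusive -> 0-based half-open
            exons.setdefault(tid, []).append((start - 1, end))
    out = []
    for tid in order:
        gene, chrom, strand, biotype = meta[tid]
        out.append(TranscriptModel(
            transcript_id=tid, gene_id=gene, chrom=chrom, strand=strand,
            exons=tuple(sorted(exons[tid])), biotype=biotype,
        ))
    return out


def write_gtf(transcripts: Iterable[TranscriptModel], path: str | Path,
              source: str = "lncpipe") -> None:
    """Write transcript models as GTF2.2 exon lines (1-based inclusive)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for t in transcripts:
            for start, end in t.exons:
                attrs = (f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                         f'gene_biotype "{t.biotype}";')
                fh.write("\t".join([
                    t.chrom, source, "exon", str(start + 1), str(end), ".",
                    t.strand, ".", attrs,
                ]) + "\n")


def read_count_table(path: str | Path, group_map: Mapping[str, str]) -> CountMatrix:
    """Read a TSV count table (first column feature id, header sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [s for s in df.columns if s not in group_map]
    if missing:
        raise ValueError(f"{path}: samples missing from group map: {missing}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValueError(f"{path}: non-numeric counts in sample {col!r}")
    return CountMatrix(df, group_map)


def write_count_table(matrix: CountMatrix, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        matrix.counts.rename_axis("feature_id").to_csv(fh, sep="\t")


_OUTFMT6_NCOL = 12


def read_hit_table(path: str | Path,
                   subject_class_map: Mapping[str, str]) -> list[HomologyHit]:
    """Read BLAST tabular (outfmt 6) homology hits.

    ``subject_class_map`` maps subject ids to {"coding_or_other", "lncRNA"};
    unknown subjects default to coding_or_other.
    """
    hits: list[HomologyHit] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != _OUTFMT6_NCOL:
                raise ValueError(
                    f"{path}:{lineno}: expected {_OUTFMT6_NCOL} columns, got {len(fields)}")
            qseqid, sseqid = fields[0], fields[1]
            try:
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable numeric field") from exc
            hits.append(HomologyHit(
                query_id=qseqid, subject_id=sseqid,
                subject_class=subject_class_map.get(sseqid, "coding_or_other"),
                evalue=evalue, bitscore=bitscore,
            ))
    return hits


def write_hit_table(hits: Iterable[HomologyHit], path: str | Path) -> None:
    """Write hits in outfmt-6 layout; alignment columns not tracked are 0."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for h in hits:
            fh.write("\t".join([
                h.query_id, h.subject_id, "0", "0", "0", "0", "0", "0", "0", "0",
                format(h.evalue, "g"), format(h.bitscore, "g"),
            ]) + "\n")


def write_removal_log(log: Mapping[str, tuple[str, str]] | Sequence[tuple[str, str, str]],
                      path: str | Path) -> None:
    """Write a removal log TSV with columns id, stage, reason."""
    if isinstance(log, Mapping):
        rows = [(tid, stage, reason) for tid, (stage, reason) in log.items()]
    else:
        rows = list(log)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("transcript_id\tstage\treason\n")
        for tid, stage, reason in sorted(rows):
            fh.write(f"{tid}\t{stage}\t{reason}\n")
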