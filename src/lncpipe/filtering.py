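"""Class-code assignment against a reference annotation and the lncRNA
retention cascade.

An assembled transcript is compared with every reference transcript on its
chromosome and receives one of six structural class codes, evaluated per
candidate reference and resolved by precedence ``=`` > ``j`` > ``o`` > ``x``
> ``i`` > ``u``:

``=``  identical ordered intron chain (mono-exonic transcripts: same-strand
       exonic overlap with both termini within 100 bp),
``j``  shares at least one exact intron (donor+acceptor) with a same-strand
       reference,
``o``  any other same-strand exonic base overlap,
``x``  exonic base overlap on the opposite strand,
``i``  entirely inside a single reference intron (any strand),
``u``  no base overlap with any reference exon or intron.

A query that touches a reference intron without exonic overlap but is not
fully contained in a single intron collapses to ``i`` (the nearest of the
implemented codes).

The retention cascade then keeps codes {x, o, i, u, j} as novel-lncRNA
candidates, routes ``=`` matches to annotated-lncRNA resolution by reference
biotype, removes candidates shorter than 200 nt (mature length) or with
fewer than 2 exons, and deduplicates byte-identical sequences.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping, Sequence

from .models import CandidateSet, ClassCodeResult, SequenceRecord, TranscriptModel

MONO_EXON_END_TOLERANCE = 100
CODE_PRECEDENCE = "=joxiu"

_RETAINED_CODES = frozenset("xoiuj")


def _intervals_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _exonic_overlap(query: TranscriptModel, ref: TranscriptModel) -> bool:
    # both exon lists are sorted; a merge scan is enough at these sizes
    for qe in query.exons:
        for re_ in ref.exons:
            if _intervals_overlap(qe, re_):
                return True
    return False


def _pair_code(query: TranscriptModel, ref: TranscriptModel) -> str | None:
    """Class code of query against one reference transcript, or None."""
    if query.chrom != ref.chrom:
        return None
    same_strand = query.strand == ref.strand
    q_introns, r_introns = query.introns, ref.introns

    if same_strand:
        if q_introns and r_introns and q_introns == r_introns:
            return "="
        if not q_introns and not r_introns and _exonic_overlap(query, ref):
            qs, qe = query.span
            rs, re_ = ref.span
            if (abs(qs - rs) <= MONO_EXON_END_TOLERANCE
                    and abs(qe - re_) <= MONO_EXON_END_TOLERANCE):
                return "="
        if q_introns and r_introns and set(q_introns) & set(r_introns):
            return "j"
    if _exonic_overlap(query, ref):
        return "o" if same_strand else "x"
    qs, qe = query.span
    for is_, ie in r_introns:
        if is_ <= qs and qe <= ie:
            return "i"
    return None


def _touches_any(query: TranscriptModel, ref: TranscriptModel) -> bool:
    """True if any query exon overlaps any reference exon or intron base."""
    if query.chrom != ref.chrom:
        return False
    blocks = list(ref.exons) + list(ref.introns)
    return any(_intervals_overlap(qe, b) for qe in query.exons for b in blocks)


def assign_class_code(query: TranscriptModel,
                      reference: Sequence[TranscriptModel]) -> ClassCodeResult:
    """Assign the best class code of ``query`` over all reference transcripts.

    Ties between references yielding the same code break to the
    lexicographically smallest reference transcript id.
    """
    best_code: str | None = None
    best_ref: str | None = None
    for ref in reference:
        code = _pair_code(query, ref)
        if code is None:
            continue
        if (best_code is None
                or CODE_PRECEDENCE.index(code) < CODE_PRECEDENCE.index(best_code)
                or (code == best_code and ref.transcript_id < best_ref)):
            best_code, best_ref = code, ref.transcript_id
    if best_code is not None:
        return ClassCodeResult(query.transcript_id, best_code, best_ref)
    if any(_touches_any(query, ref) for ref in reference):
        # partial intron overlap without exonic overlap: nearest code is "i"
        touched = min(r.transcript_id for r in reference if _touches_any(query, r))
        return ClassCodeResult(query.transcript_id, "i", touched)
    return ClassCodeResult(query.transcript_id, "u", None)


def filter_by_class(results: Iterable[ClassCodeResult],
                    retained: frozenset[str] = _RETAINED_CODES,
                    ) -> tuple[list[str], list[ClassCodeResult], dict[str, str]]:
    """Split class-code results into novel candidates vs '='-matches.

    Returns (candidate ids, '=' results routed to annotated resolution,
    removal_log for anything else).
    """
    candidates: list[str] = []
    equals: list[ClassCodeResult] = []
    removal: dict[str, str] = {}
    for res in results:
        if res.code in retained:
            candidates.append(res.transcript_id)
        elif res.code == "=":
            equals.append(res)
        else:  # pragma: no cover - only six codes exist
            removal[res.transcript_id] = f"class_code:{res.code}"
    return candidates, equals, removal


def split_annotated_lncRNAs(equal_results: Iterable[ClassCodeResult],
                            reference: Sequence[TranscriptModel],
                            ) -> tuple[list[str], dict[str, str]]:
    """Resolve '='-matches: lncRNA-biotype references are annotated lncRNAs,
    protein-coding matches are known mRNAs, anything else is dropped."""
    biotype = {t.transcript_id: t.biotype for t in reference}
    annotated: list[str] = []
    removal: dict[str, str] = {}
    for res in equal_results:
        ref_bt = biotype.get(res.matched_reference_id, "other")
        if ref_bt == "lncRNA":
            annotated.append(res.transcript_id)
        elif ref_bt == "protein_coding":
            removal[res.transcript_id] = "known_mRNA"
        else:
            removal[res.transcript_id] = "known_other_biotype"
    return annotated, removal


def structural_filter(candidates: Sequence[str],
                      transcripts: Mapping[str, TranscriptModel],
                      min_length: int = 200,
                      min_exons: int = 2) -> tuple[list[str], dict[str, str]]:
    """Keep candidates with mature length >= min_length and >= min_exons exons."""
    kept: list[str] = []
    removal: dict[str, str] = {}
    for tid in candidates:
        t = transcripts[tid]
        if t.length < min_length:
            removal[tid] = f"length<{min_length}"
        elif t.n_exons < min_exons:
            removal[tid] = f"exons<{min_exons}"
        else:
            kept.append(tid)
    return kept, removal


def deduplicate(records: Sequence[SequenceRecord],
                ) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Collapse byte-identical sequences, keeping the smallest id."""
    by_seq: dict[str, list[str]] = defaultdict(list)
    for rec in records:
        by_seq[rec.sequence].append(rec.id)
    removal: dict[str, str] = {}
    keep_ids: set[str] = set()
    for ids in by_seq.values():
        ids_sorted = sorted(ids)
        keep_ids.add(ids_sorted[0])
        for other in ids_sorted[1:]:
            removal[other] = f"duplicate_of:{ids_sorted[0]}"
    kept = [rec for rec in records if rec.id in keep_ids]
    return kept, removal


def run_cascade(queries: Sequence[TranscriptModel],
                sequences: Mapping[str, str],
                reference: Sequence[TranscriptModel],
                min_length: int = 200,
                min_exons: int = 2,
                ) -> tuple[CandidateSet, dict[str, ClassCodeResult]]:
    """Run the full retention cascade.

    Order: class filter -> annotated split -> structural filter -> dedup.
    Returns the resulting :class:`CandidateSet` (a partition of the input)
    and the per-transcript class codes.
    """
    by_id = {t.transcript_id: t for t in queries}
    codes = {t.transcript_id: assign_class_code(t, reference) for t in queries}

    candidates, equals, removal = filter_by_class(codes.values())
    annotated, rm_eq = split_annotated_lncRNAs(equals, reference)
    removal.update(rm_eq)

    candidates, rm_struct = structural_filter(candidates, by_id, min_length, min_exons)
    removal.update(rm_struct)

    records = [SequenceRecord(tid, sequences[tid]) for tid in candidates]
    kept, rm_dup = deduplicate(records)
    removal.update(rm_dup)

    result = CandidateSet(
        novel_candidates=[r.id for r in kept],
        annotated_lncRNAs=sorted(annotated),
        removal_log=removal,
    )
    result.check_partition([t.transcript_id for t in queries])
    return result, codes
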