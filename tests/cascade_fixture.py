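"""A 60-transcript retention-cascade fixture with hand-annotated outcomes.

Every query transcript is constructed to exercise one branch of the cascade
(class filter, annotated split, structural filter, dedup) or the downstream
ORF filter, including the documented boundary cases: mature length 199 vs
200 nt, 1 vs 2 exons, longest ORF 297 vs 300 nt.  Sequences are synthetic
and assigned independently of the genomic coordinates; dedup groups share a
byte-identical sequence on purpose.

``build_fixture()`` returns (queries, sequences, reference, expected) where
``expected`` maps every query id to its hand-written fate:
"novel", "annotated", or "removed:<reason prefix>".
"""

from __future__ import annotations

from lncpipe.models import TranscriptModel

# no-ATG filler: repeating CCTGA never contains ATG in any frame
_FILLER = "CCTGA"


def _pad(n: int, salt: int) -> str:
    """Unique ATG-free sequence of length n (salt encoded as C/G prefix)."""
    prefix = "".join("G" if (salt >> b) & 1 else "C" for b in range(8))
    body = (_FILLER * (n // 5 + 3))[: n - 8]
    return (prefix + body)[:n]


def _orf_seq(total: int, orf_nt: int, salt: int) -> str:
    """Length-``total`` sequence whose single longest ORF is ``orf_nt`` nt."""
    assert orf_nt % 3 == 0 and orf_nt >= 6
    orf = "ATG" + "GCT" * (orf_nt // 3 - 2) + "TAA"
    head = _pad(16, salt)
    tail_n = total - len(head) - len(orf)
    assert tail_n >= 0
    tail = (_FILLER * (tail_n // 5 + 2))[:tail_n]
    return head + orf + tail


def build_reference() -> list[TranscriptModel]:
    return [
        # coding gene with a large second intron (hosts the "i" cases)
        TranscriptModel("REF_MRNA1", "RG1", "chr1", "+",
                        ((1000, 1200), (1500, 1700), (3000, 3200)),
                        "protein_coding"),
        # two-exon annotated lncRNA (anchor for =, o, x cases)
        TranscriptModel("REF_LNC1", "RG2", "chr1", "+",
                        ((10000, 10400), (11000, 11400)), "lncRNA"),
        # three-exon lncRNA (anchor for j cases)
        TranscriptModel("REF_LNC2", "RG3", "chr1", "+",
                        ((20000, 20300), (21000, 21300), (22000, 22300)),
                        "lncRNA"),
    ]


def build_fixture():
    reference = build_reference()
    queries: list[TranscriptModel] = []
    seqs: dict[str, str] = {}
    expected: dict[str, str] = {}
    salt = 0

    def add(t: TranscriptModel, seq: str, fate: str) -> None:
        queries.append(t)
        seqs[t.transcript_id] = seq
        expected[t.transcript_id] = fate

    def nxt() -> int:
        nonlocal salt
        salt += 1
        return salt

    mrna = reference[0]
    lnc1 = reference[1]
    lnc2 = reference[2]

    # 5 exact copies of the coding reference -> removed as known mRNA
    for i in range(5):
        t = TranscriptModel(f"Q_EQM{i}", f"Q_EQM{i}", "chr1", "+",
                            mrna.exons, "other")
        add(t, _orf_seq(t.length, 300, nxt()), "removed:known_mRNA")

    # 5 exact copies of the annotated lncRNA -> annotated
    for i in range(5):
        t = TranscriptModel(f"Q_EQL{i}", f"Q_EQL{i}", "chr1", "+",
                            lnc1.exons, "other")
        add(t, _pad(t.length, nxt()), "annotated")

    # 5 intergenic two-exon transcripts at the exact 200 nt boundary -> novel
    for i in range(5):
        base = 50_000 + 2000 * i
        t = TranscriptModel(f"Q_U{i}", f"Q_U{i}", "chr1", "+",
                            ((base, base + 100), (base + 400, base + 500)),
                            "other")
        add(t, _pad(200, nxt()), "novel")

    # 5 intergenic transcripts one base short (199 nt) -> removed (length)
    for i in range(5):
        base = 70_000 + 2000 * i
        t = TranscriptModel(f"Q_SHORT{i}", f"Q_SHORT{i}", "chr1", "+",
                            ((base, base + 100), (base + 400, base + 499)),
                            "other")
        add(t, _pad(199, nxt()), "removed:length<200")

    # 5 long mono-exonic transcripts -> removed (exon count)
    for i in range(5):
        base = 90_000 + 7000 * i
        t = TranscriptModel(f"Q_MONO{i}", f"Q_MONO{i}", "chr1", "+",
                            ((base, base + 5000),), "other")
        add(t, _pad(5000, nxt()), "removed:exons<2")

    # 5 intergenic transcripts with a 300 nt ORF -> removed at the ORF filter
    for i in range(5):
        base = 130_000 + 2000 * i
        t = TranscriptModel(f"Q_ORF300_{i}", f"Q_ORF300_{i}", "chr1", "+",
                            ((base, base + 200), (base + 500, base + 700)),
                            "other")
        add(t, _orf_seq(400, 300, nxt()), "removed:orf>=300")

    # 5 intergenic transcripts with a 297 nt ORF -> novel (below threshold)
    for i in range(5):
        base = 150_000 + 2000 * i
        t = TranscriptModel(f"Q_ORF297_{i}", f"Q_ORF297_{i}", "chr1", "+",
                            ((base, base + 200), (base + 500, base + 700)),
                            "other")
        add(t, _orf_seq(400, 297, nxt()), "novel")

    # 5 junction-sharing variants of the 3-exon lncRNA -> novel (code j)
    for i in range(5):
        t = TranscriptModel(f"Q_J{i}", f"Q_J{i}", "chr1", "+",
                            lnc2.exons[:2], "other")
        add(t, _pad(t.length, nxt()), "novel")

    # 5 same-strand overlaps with shifted splice sites -> novel (code o)
    for i in range(5):
        t = TranscriptModel(f"Q_O{i}", f"Q_O{i}", "chr1", "+",
                            ((10100 + i, 10350), (10600, 10800)), "other")
        add(t, _pad(t.length, nxt()), "novel")

    # 5 antisense overlaps of the annotated lncRNA -> novel (code x)
    for i in range(5):
        t = TranscriptModel(f"Q_X{i}", f"Q_X{i}", "chr1", "-",
                            ((10150 + i, 10350), (10550, 10750)), "other")
        add(t, _pad(t.length, nxt()), "novel")

    # 5 transcripts inside the coding gene's large intron -> novel (code i)
    for i in range(5):
        base = 1750 + 10 * i
        t = TranscriptModel(f"Q_I{i}", f"Q_I{i}", "chr1", "+",
                            ((base, base + 150), (base + 500, base + 650)),
                            "other")
        add(t, _pad(300, nxt()), "novel")

    # duplicate groups: a pair and a triple of byte-identical sequences
    dup_pair_seq = _pad(260, nxt())
    dup_triple_seq = _pad(280, nxt())
    for i, (seq, fate) in enumerate([
            (dup_pair_seq, "novel"), (dup_pair_seq, "removed:duplicate_of"),
            (dup_triple_seq, "novel"), (dup_triple_seq, "removed:duplicate_of"),
            (dup_triple_seq, "removed:duplicate_of")]):
        base = 170_000 + 2000 * i
        t = TranscriptModel(f"Q_DUP{i}", f"Q_DUP{i}", "chr1", "+",
                            ((base, base + 130), (base + 400, base + 400 + len(seq) - 130)),
                            "other")
        add(t, seq, fate)

    assert len(queries) == 60
    return queries, seqs, reference, expected
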