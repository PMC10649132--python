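"""Synthetic inputs with the statistical structure the pipeline assumes.

The generator emulates the study design end to end: a small multi-chromosome
genome with non-overlapping coding and lncRNA gene loci; coding transcripts
carrying a long (>= 300 nt) codon-biased ORF and noncoding transcripts
rejection-sampled to stay below it; assembled transcripts engineered to
receive each structural class code (=, j, o, x, i, u); and a negative-
binomial count matrix for an unbalanced two-group design (default 4 control
vs 3 treated) with planted log2 fold changes, correlated cis lncRNA/target
pairs within 20 kb, and an optional outlier sample.

Every output is byte-reproducible from (config, seed): one SeedSequence is
spawned into independent per-stage streams.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .formats import write_count_table, write_fasta, write_gtf
from .models import CountMatrix, SequenceRecord, TranscriptModel

import itertools
import pandas as pd

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# background nucleotide model (slightly AT-rich, as in real intergenic DNA)
BACKGROUND_PROBS = {"A": 0.3, "C": 0.2, "G": 0.2, "T": 0.3}

STOPS = ("TAA", "TAG", "TGA")
SENSE_CODONS = tuple(
    "".join(c) for c in itertools.product("ACGT", repeat=3)
    if "".join(c) not in STOPS
)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; defaults mirror the emulated design."""

    seed: int = 0
    n_chromosomes: int = 4
    chrom_length_bp: int = 2_500_000
    n_coding_genes: int = 300
    n_lnc_genes: int = 120
    n_control: int = 4
    n_treated: int = 3
    frac_de: float = 0.1
    planted_lfc: float = 2.0
    cis_planted_lfc: float = 4.0
    nb_dispersion: float = 0.1
    mean_count_log_range: tuple[float, float] = (math.log(20), math.log(2000))
    n_cis_pairs: int = 10
    cis_max_distance_bp: int = 20_000
    cis_latent_sdlog: float = 0.7
    outlier_sample: bool = False
    coding_bias_strength: float = 0.75
    # assembled-transcript plan
    n_equal_to_coding: int = 10
    n_equal_to_lnc: int = 10
    n_per_code: int = 10          # each of j, o, x, i, u anchored on noncoding loci
    n_j_coding: int = 10          # junction-sharing extensions of coding loci
    n_duplicate_pairs: int = 3
    min_orf_nt: int = 300
    max_rejection_attempts: int = 500

    def __post_init__(self) -> None:
        if not (0.0 <= self.frac_de <= 1.0):
            raise ValueError("frac_de must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if not (0.0 <= self.coding_bias_strength <= 1.0):
            raise ValueError("coding_bias_strength must be in [0, 1]")
        for name in ("n_chromosomes", "chrom_length_bp", "n_coding_genes",
                     "n_lnc_genes", "n_control", "n_treated"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class GroundTruth:
    """Planted labels for every synthetic object."""

    coding_label: dict[str, str] = field(default_factory=dict)       # ref tid -> coding|noncoding
    assembled_label: dict[str, str] = field(default_factory=dict)    # asm tid -> coding|noncoding
    planted_class_code: dict[str, str] = field(default_factory=dict)  # asm tid -> code
    planted_equal_ref: dict[str, str] = field(default_factory=dict)   # asm tid -> ref tid
    planted_duplicates: dict[str, str] = field(default_factory=dict)  # dup tid -> original tid
    de_features: dict[str, float] = field(default_factory=dict)       # gene -> true log2FC
    cis_pairs: list[tuple[str, str, int]] = field(default_factory=list)
    outlier_sample: str | None = None

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
        # asdict keeps tuples as lists in JSON; from_json restores them

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        raw["cis_pairs"] = [tuple(p) for p in raw["cis_pairs"]]
        return cls(**raw)


# ---------------------------------------------------------------------------
# Reference simulation

def _draw_exons(rng: np.random.Generator, start: int, n_exons: int,
                exon_range: tuple[int, int],
                intron_range: tuple[int, int]) -> tuple[tuple[int, int], ...]:
    exons = []
    pos = start
    for i in range(n_exons):
        length = int(rng.integers(exon_range[0], exon_range[1] + 1))
        exons.append((pos, pos + length))
        pos += length
        if i < n_exons - 1:
            pos += int(rng.integers(intron_range[0], intron_range[1] + 1))
    return tuple(exons)


def simulate_reference(config: SimulationConfig,
                       rng: np.random.Generator | None = None,
                       ) -> tuple[list[TranscriptModel], GroundTruth]:
    """Place non-overlapping gene loci and record the ground-truth seed block.

    The first ``n_cis_pairs`` lncRNA genes are placed directly downstream of
    a coding partner at a gene-body gap drawn uniformly from
    [0, cis_max_distance_bp).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    truth = GroundTruth()

    coding_ids = [f"CG{i:04d}" for i in range(config.n_coding_genes)]
    lnc_ids = [f"LG{i:04d}" for i in range(config.n_lnc_genes)]
    if config.n_cis_pairs > min(config.n_coding_genes, config.n_lnc_genes):
        raise ValueError("n_cis_pairs exceeds available genes")

    # placement plan: cis pairs first (adjacent), then everything else shuffled
    plan: list[tuple[str, ...]] = []
    for i in range(config.n_cis_pairs):
        plan.append(("cis_pair", coding_ids[i], lnc_ids[i]))
    rest = ([("coding", g) for g in coding_ids[config.n_cis_pairs:]]
            + [("lnc", g) for g in lnc_ids[config.n_cis_pairs:]])
    order = rng.permutation(len(rest))
    plan.extend(rest[i] for i in order)

    transcripts: list[TranscriptModel] = []
    chrom_idx, cursor = 0, 10_000
    margin = 60_000

    def place_gene(gene_id: str, biotype: str, start: int) -> TranscriptModel:
        if biotype == "protein_coding":
            n_exons = int(rng.integers(3, 13))
            exons = _draw_exons(rng, start, n_exons, (150, 400), (200, 1500))
        else:
            n_exons = int(rng.integers(2, 5))
            exons = _draw_exons(rng, start, n_exons, (150, 400), (200, 1500))
        strand = "+" if rng.random() < 0.5 else "-"
        return TranscriptModel(
            transcript_id=gene_id + ".t1", gene_id=gene_id,
            chrom=f"chr{chrom_idx + 1}", strand=strand,
            exons=exons, biotype=biotype)

    for item in plan:
        if chrom_idx >= config.n_chromosomes:
            raise RuntimeError("chromosomes too short to place requested genes")
        if item[0] == "cis_pair":
            _, cg, lg = item
            t_c = place_gene(cg, "protein_coding", cursor)
            gap = int(rng.integers(0, config.cis_max_distance_bp))
            t_l = place_gene(lg, "lncRNA", t_c.span[1] + gap)
            transcripts.extend([t_c, t_l])
            truth.cis_pairs.append((lg, cg, gap))
            truth.coding_label[t_c.transcript_id] = "coding"
            truth.coding_label[t_l.transcript_id] = "noncoding"
            cursor = t_l.span[1] + int(rng.integers(5000, 12_000))
        else:
            kind, g = item
            biotype = "protein_coding" if kind == "coding" else "lncRNA"
            t = place_gene(g, biotype, cursor)
            transcripts.append(t)
            truth.coding_label[t.transcript_id] = (
                "coding" if kind == "coding" else "noncoding")
            cursor = t.span[1] + int(rng.integers(5000, 12_000))
        if cursor > config.chrom_length_bp - margin:
            chrom_idx += 1
            cursor = 10_000
    return transcripts, truth


# ---------------------------------------------------------------------------
# Sequence simulation

def _random_background(rng: np.random.Generator, length: int) -> str:
    probs = [BACKGROUND_PROBS[b] for b in "ACGT"]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=probs)])


def _codon_probs(bias_strength: float) -> np.ndarray:
    # preference grows with codon GC content: a simple, strong usage bias
    weights = np.array([2.0 ** sum(c in "GC" for c in codon)
                        for codon in SENSE_CODONS])
    biased = weights / weights.sum()
    uniform = np.full(len(SENSE_CODONS), 1.0 / len(SENSE_CODONS))
    return (1 - bias_strength) * uniform + bias_strength * biased


def _coding_sequence(rng: np.random.Generator, length: int,
                     codon_p: np.ndarray, min_orf: int) -> str:
    """UTR5 + ATG + biased codons + stop + UTR3, total ``length`` nt."""
    if length < min_orf + 40:
        raise ValueError(f"coding transcript of {length} nt cannot hold a "
                         f"{min_orf} nt ORF")
    utr5 = int(rng.integers(20, min(100, length - min_orf - 6) + 1))
    orf_len = 3 * ((length - utr5 - 20) // 3)
    orf_len = max(orf_len, min_orf)
    n_codons = orf_len // 3 - 2  # minus ATG and stop
    codons = rng.choice(len(SENSE_CODONS), size=n_codons, p=codon_p)
    orf = "ATG" + "".join(SENSE_CODONS[i] for i in codons) + \
        STOPS[int(rng.integers(0, 3))]
    utr3 = length - utr5 - len(orf)
    return (_random_background(rng, utr5) + orf + _random_background(rng, utr3))


def _noncoding_sequence(rng: np.random.Generator, length: int,
                        max_orf_exclusive: int, max_attempts: int) -> str:
    from .coding import find_longest_orf
    for _ in range(max_attempts):
        seq = _random_background(rng, length)
        orf = find_longest_orf(seq)
        if orf is None or orf.length < max_orf_exclusive:
            return seq
    raise RuntimeError(
        f"could not sample a {length} nt sequence with longest ORF < "
        f"{max_orf_exclusive} nt in {max_attempts} attempts")


def simulate_sequences(reference: list[TranscriptModel], config: SimulationConfig,
                       rng: np.random.Generator | None = None,
                       ) -> dict[str, SequenceRecord]:
    """Per-transcript sequences: codon-biased ORFs for coding, ORF-poor
    background for noncoding; lengths follow the reference exon structure."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    codon_p = _codon_probs(config.coding_bias_strength)
    out: dict[str, SequenceRecord] = {}
    for t in reference:
        if t.biotype == "protein_coding":
            seq = _coding_sequence(rng, t.length, codon_p, config.min_orf_nt + 6)
        else:
            seq = _noncoding_sequence(rng, t.length, config.min_orf_nt,
                                      config.max_rejection_attempts)
        out[t.transcript_id] = SequenceRecord(t.transcript_id, seq)
    return out


# ---------------------------------------------------------------------------
# Genome assembly from transcript sequences

def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class Genome:
    """Mutable per-chromosome sequence store."""

    def __init__(self, config: SimulationConfig, rng: np.random.Generator):
        probs = [BACKGROUND_PROBS[b] for b in "ACGT"]
        self.chroms: dict[str, np.ndarray] = {}
        for i in range(config.n_chromosomes):
            draws = rng.choice(4, size=config.chrom_length_bp, p=probs)
            self.chroms[f"chr{i + 1}"] = _BASES[draws].copy()

    def write_transcript(self, t: TranscriptModel, seq: str) -> None:
        if len(seq) != t.length:
            raise ValueError(f"{t.transcript_id}: sequence/model length mismatch")
        genomic = revcomp(seq) if t.strand == "-" else seq
        arr = self.chroms[t.chrom]
        offset = 0
        for s, e in t.exons:
            arr[s:e] = np.frombuffer(genomic[offset:offset + e - s].encode(), dtype="S1")
            offset += e - s

    def spliced_sequence(self, t: TranscriptModel) -> str:
        arr = self.chroms[t.chrom]
        parts = [arr[s:e].tobytes().decode() for s, e in t.exons]
        seq = "".join(parts)
        return revcomp(seq) if t.strand == "-" else seq

    def records(self) -> list[SequenceRecord]:
        return [SequenceRecord(name, arr.tobytes().decode())
                for name, arr in self.chroms.items()]


# ---------------------------------------------------------------------------
# Assembled-transcript simulation

def _shift_splice(t: TranscriptModel, tid: str, rng: np.random.Generator,
                  strand: str | None = None) -> TranscriptModel:
    """Two-exon variant of ``t`` overlapping its exons with different introns."""
    e1, e2 = t.exons[0], t.exons[1]
    d1 = int(rng.integers(11, 41))
    d2 = int(rng.integers(11, 41))
    exons = ((e1[0] + 7, e1[1] - d1), (e2[0] + d2, e2[1] - 5))
    return TranscriptModel(tid, tid, t.chrom, strand or t.strand, exons, "other")


def simulate_assembly(reference: list[TranscriptModel], config: SimulationConfig,
                      truth: GroundTruth,
                      rng: np.random.Generator | None = None,
                      ) -> list[TranscriptModel]:
    """Emit assembled transcripts engineered to receive each class code.

    Novel (j, o, x, i, u) transcripts anchor on noncoding loci or neutral
    background so their planted coding label is noncoding; the j_coding set
    extends coding loci with an extra upstream exon and stays coding.
    Duplicate pairs re-emit an existing novel transcript under a new id.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    coding_refs = [t for t in reference if t.biotype == "protein_coding"]
    lnc_refs = [t for t in reference if t.biotype == "lncRNA"]
    cis_genes = {g for pair in truth.cis_pairs for g in pair[:2]}
    # keep planted cases on well-separated loci
    free_coding = [t for t in coding_refs if t.gene_id not in cis_genes]
    free_lnc = [t for t in lnc_refs if t.gene_id not in cis_genes]

    def take(pool: list[TranscriptModel], n: int, pred=None) -> list[TranscriptModel]:
        ok = [t for t in pool if pred is None or pred(t)]
        if len(ok) < n:
            raise RuntimeError(f"not enough reference loci to plant {n} cases")
        idx = rng.choice(len(ok), size=n, replace=False)
        chosen = [ok[int(i)] for i in sorted(idx)]
        for t in chosen:
            pool.remove(t)
        return chosen

    out: list[TranscriptModel] = []

    def emit(t: TranscriptModel, code: str, label: str,
             ref: TranscriptModel | None) -> None:
        out.append(t)
        truth.planted_class_code[t.transcript_id] = code
        truth.assembled_label[t.transcript_id] = label
        if ref is not None:
            truth.planted_equal_ref[t.transcript_id] = ref.transcript_id

    # "=": exact copies of reference transcripts
    for i, ref in enumerate(take(free_coding, config.n_equal_to_coding)):
        t = TranscriptModel(f"ASM_EQC{i:03d}", f"ASM_EQC{i:03d}", ref.chrom,
                            ref.strand, ref.exons, "other")
        emit(t, "=", "coding", ref)
    for i, ref in enumerate(take(free_lnc, config.n_equal_to_lnc)):
        t = TranscriptModel(f"ASM_EQL{i:03d}", f"ASM_EQL{i:03d}", ref.chrom,
                            ref.strand, ref.exons, "other")
        emit(t, "=", "noncoding", ref)

    # "j": first two exons of a multi-intron noncoding locus (subset chain)
    for i, ref in enumerate(take(free_lnc, config.n_per_code,
                                 pred=lambda t: t.n_exons >= 3)):
        t = TranscriptModel(f"ASM_J{i:03d}", f"ASM_J{i:03d}", ref.chrom,
                            ref.strand, ref.exons[:2], "other")
        emit(t, "j", "noncoding", ref)

    # "o": same-strand exonic overlap with shifted splice sites
    for i, ref in enumerate(take(free_lnc, config.n_per_code)):
        t = _shift_splice(ref, f"ASM_O{i:03d}", rng)
        emit(t, "o", "noncoding", ref)

    # "x": antisense two-exon transcript over a noncoding locus
    for i, ref in enumerate(take(free_lnc, config.n_per_code)):
        anti = "-" if ref.strand == "+" else "+"
        e1 = ref.exons[0]
        exons = ((e1[0] - 300, e1[0] + 100), (e1[1] - 80, e1[1] + 150))
        if exons[0][1] >= exons[1][0]:  # short first exon: fall back inside span
            exons = ((e1[0] - 300, e1[0] + 60), (e1[0] + 90, e1[0] + 240))
        t = TranscriptModel(f"ASM_X{i:03d}", f"ASM_X{i:03d}", ref.chrom,
                            anti, exons, "other")
        emit(t, "x", "noncoding", ref)

    # "i": fully inside a large intron of a coding locus
    def has_big_intron(t: TranscriptModel) -> bool:
        return any(e - s >= 700 for s, e in t.introns)

    for i, ref in enumerate(take(free_coding, config.n_per_code, has_big_intron)):
        intron = next((s, e) for s, e in ref.introns if e - s >= 700)
        start = intron[0] + 60
        exons = ((start, start + 140), (start + 280, start + 440))
        strand = "+" if rng.random() < 0.5 else "-"
        t = TranscriptModel(f"ASM_I{i:03d}", f"ASM_I{i:03d}", ref.chrom,
                            strand, exons, "other")
        emit(t, "i", "noncoding", ref)

    # "u": intergenic transcripts in large gaps
    spans: dict[str, list[tuple[int, int]]] = {}
    for t in reference:
        spans.setdefault(t.chrom, []).append(t.span)
    gaps: list[tuple[str, int, int]] = []
    for chrom, ivals in spans.items():
        ivals.sort()
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            if s2 - e1 >= 4000:
                gaps.append((chrom, e1 + 1200, s2 - 1200))
    if len(gaps) < config.n_per_code:
        raise RuntimeError("not enough intergenic gaps to plant 'u' transcripts")
    gap_idx = rng.choice(len(gaps), size=config.n_per_code, replace=False)
    for i, gi in enumerate(sorted(int(g) for g in gap_idx)):
        chrom, lo, hi = gaps[gi]
        start = lo + int(rng.integers(0, max(1, hi - lo - 800)))
        exons = ((start, start + 180), (start + 420, start + 620))
        strand = "+" if rng.random() < 0.5 else "-"
        t = TranscriptModel(f"ASM_U{i:03d}", f"ASM_U{i:03d}", chrom, strand,
                            exons, "other")
        emit(t, "u", "noncoding", None)

    # "j" over coding loci: extra upstream exon, full ORF retained
    for i, ref in enumerate(take(free_coding, config.n_j_coding)):
        first = ref.exons[0]
        exons = ((first[0] - 420, first[0] - 220),) + ref.exons
        t = TranscriptModel(f"ASM_JC{i:03d}", f"ASM_JC{i:03d}", ref.chrom,
                            ref.strand, exons, "other")
        emit(t, "j", "coding", ref)

    # duplicates: re-emit an existing novel transcript under a new id
    novel = [t for t in out if truth.planted_class_code[t.transcript_id]
             in ("j", "o", "x", "i", "u")
             and truth.assembled_label[t.transcript_id] == "noncoding"]
    dup_idx = rng.choice(len(novel), size=config.n_duplicate_pairs, replace=False)
    for i, di in enumerate(sorted(int(d) for d in dup_idx)):
        orig = novel[di]
        t = TranscriptModel(f"ASM_DUP{i:03d}", f"ASM_DUP{i:03d}", orig.chrom,
                            orig.strand, orig.exons, "other")
        out.append(t)
        truth.planted_class_code[t.transcript_id] = \
            truth.planted_class_code[orig.transcript_id]
        truth.assembled_label[t.transcript_id] = "noncoding"
        truth.planted_duplicates[t.transcript_id] = orig.transcript_id
    return out


# ---------------------------------------------------------------------------
# Count simulation

def simulate_counts(features: list[str], config: SimulationConfig,
                    cis_pairs: list[tuple[str, str, int]] | None = None,
                    rng: np.random.Generator | None = None,
                    ) -> tuple[CountMatrix, GroundTruth]:
    """NB counts for the two-group design with planted effects.

    Cis pairs get a strong same-sign planted fold change plus a shared
    per-sample lognormal latent factor, so their expression is correlated
    across samples well beyond unrelated features.  With
    ``config.outlier_sample`` the last treated sample is drawn from an
    unrelated baseline.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    cis_pairs = cis_pairs or []
    truth = GroundTruth(cis_pairs=list(cis_pairs))
    n_f = len(features)
    if n_f == 0:
        raise ValueError("feature list is empty")
    feat_idx = {f: i for i, f in enumerate(features)}

    samples = ([f"control_{i+1}" for i in range(config.n_control)]
               + [f"treated_{i+1}" for i in range(config.n_treated)])
    groups = {s: ("control" if s.startswith("control") else "treated")
              for s in samples}
    n_s = len(samples)
    treated_mask = np.array([groups[s] == "treated" for s in samples])

    lo, hi = config.mean_count_log_range
    base = np.exp(rng.uniform(lo, hi, size=n_f))

    # planted effects: cis-pair members first (same sign, strong), then a
    # random fill of unrelated features up to frac_de of all features
    lfc = np.zeros(n_f)
    cis_members: set[int] = set()
    for lnc_g, cod_g, _dist in cis_pairs:
        sign = 1.0 if rng.random() < 0.5 else -1.0
        for g in (lnc_g, cod_g):
            if g not in feat_idx:
                raise ValueError(f"cis pair feature {g!r} not in feature list")
            i = feat_idx[g]
            lfc[i] = sign * config.cis_planted_lfc
            cis_members.add(i)
            # boost baseline so NB noise does not mask the correlation
            base[i] = max(base[i], float(np.exp(hi) / 4.0))
    n_de = int(round(config.frac_de * n_f))
    pool = np.array([i for i in range(n_f) if i not in cis_members])
    n_extra = max(0, n_de - len(cis_members))
    if n_extra > len(pool):
        n_extra = len(pool)
    extra = rng.choice(pool, size=n_extra, replace=False) if n_extra else []
    for i in extra:
        lfc[int(i)] = config.planted_lfc * (1.0 if rng.random() < 0.5 else -1.0)

    mean = np.tile(base[:, None], (1, n_s))
    mean[:, treated_mask] = mean[:, treated_mask] * (2.0 ** lfc)[:, None]

    # shared lognormal latent factor per cis pair
    for lnc_g, cod_g, _dist in cis_pairs:
        latent = np.exp(rng.normal(0.0, config.cis_latent_sdlog, size=n_s))
        for g in (lnc_g, cod_g):
            mean[feat_idx[g]] *= latent

    outlier_id = None
    if config.outlier_sample:
        outlier_id = samples[-1]
        alt_base = np.exp(rng.uniform(lo, hi, size=n_f))
        mean[:, n_s - 1] = alt_base
        truth.outlier_sample = outlier_id

    alpha = config.nb_dispersion
    r = 1.0 / alpha
    p = r / (r + mean)
    counts = rng.negative_binomial(r, p)

    for i in range(n_f):
        if lfc[i] != 0.0:
            truth.de_features[features[i]] = float(lfc[i])

    df = pd.DataFrame(counts, index=features, columns=samples)
    return CountMatrix(df, groups), truth


# ---------------------------------------------------------------------------
# Full-study driver

@dataclass
class SyntheticStudy:
    config: SimulationConfig
    reference: list[TranscriptModel]
    ref_sequences: dict[str, SequenceRecord]
    genome: Genome
    assembled: list[TranscriptModel]
    asm_sequences: dict[str, SequenceRecord]
    counts: CountMatrix
    truth: GroundTruth


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate reference, sequences, genome, assembly and counts in one call."""
    ss = np.random.SeedSequence(config.seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(5)]
    reference, truth = simulate_reference(config, rngs[0])
    ref_seqs = simulate_sequences(reference, config, rngs[1])
    genome = Genome(config, rngs[2])
    for t in reference:
        genome.write_transcript(t, ref_seqs[t.transcript_id].sequence)
    assembled = simulate_assembly(reference, config, truth, rngs[3])
    asm_seqs = {t.transcript_id:
                SequenceRecord(t.transcript_id, genome.spliced_sequence(t))
                for t in assembled}
    gene_ids = sorted({t.gene_id for t in reference})
    counts, count_truth = simulate_counts(gene_ids, config, truth.cis_pairs,
                                          rngs[4])
    truth.de_features = count_truth.de_features
    truth.outlier_sample = count_truth.outlier_sample
    return SyntheticStudy(config, reference, ref_seqs, genome, assembled,
                          asm_seqs, counts, truth)


def write_study(study: SyntheticStudy, outdir: str | Path) -> dict[str, Path]:
    """Write all study inputs as plain-text files; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "reference_gtf": outdir / "reference.gtf",
        "reference_fa": outdir / "reference_transcripts.fa",
        "assembled_gtf": outdir / "assembled.gtf",
        "assembled_fa": outdir / "assembled_transcripts.fa",
        "counts": outdir / "counts.tsv",
        "groups": outdir / "groups.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_fasta(study.genome.records(), paths["genome"])
    write_gtf(study.reference, paths["reference_gtf"])
    write_fasta([study.ref_sequences[t.transcript_id] for t in study.reference],
                paths["reference_fa"])
    write_gtf(study.assembled, paths["assembled_gtf"])
    write_fasta([study.asm_sequences[t.transcript_id] for t in study.assembled],
                paths["assembled_fa"])
    write_count_table(study.counts, paths["counts"])
    with open(paths["groups"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample_id\tgroup\n")
        for s in study.counts.sample_ids:
            fh.write(f"{s}\t{study.counts.groups[s]}\n")
    study.truth.to_json(paths["ground_truth"])
    return paths
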