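"""Coding-potential assessment of lncRNA candidates.

Sequence features (longest ORF, Fickett TESTCODE, hexamer usage log-ratio,
GC, length), a cross-validated random-forest coding/noncoding classifier,
the long-ORF exclusion, and homology triage of the survivors into the three
groups (coding match / lncRNA match / no match).

A small self-contained seed-and-extend nucleotide aligner is included so
tests can exercise the homology triage without an external search tool; real
analyses should supply a BLASTn tabular hit table instead.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score, precision_score, recall_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from .models import HomologyHit, SequenceRecord

STOP_CODONS = ("TAA", "TAG", "TGA")
START_CODON = "ATG"

FEATURE_NAMES = ("orf_length", "orf_coverage", "fickett", "hexamer", "gc", "log_length")

_HEXAMERS = ["".join(p) for p in itertools.product("ACGT", repeat=6)]
_HEXAMER_INDEX = {h: i for i, h in enumerate(_HEXAMERS)}


# ---------------------------------------------------------------------------
# ORF scanning

@dataclass(frozen=True)
class OrfResult:
    """Longest sense-strand open reading frame of a transcript."""

    start: int          # 0-based offset of the ATG
    length: int         # nt, multiple of 3, includes the stop codon if present
    frame: int          # start % 3
    has_stop: bool


def find_longest_orf(seq: str) -> OrfResult | None:
    """Longest ATG-initiated ORF over the three sense-strand frames.

    An ORF runs from an ATG to the first in-frame stop (TAA/TAG/TGA),
    stop included, or to the last complete in-frame codon when no stop
    follows.  Ties break to the smallest start.  Codons containing N never
    match ATG or a stop.
    """
    best: OrfResult | None = None
    n = len(seq)
    for frame in range(3):
        orf_start: int | None = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos:pos + 3]
            if orf_start is None:
                if codon == START_CODON:
                    orf_start = pos
            elif codon in STOP_CODONS:
                cand = OrfResult(orf_start, pos + 3 - orf_start, frame, True)
                if best is None or cand.length > best.length or (
                        cand.length == best.length and cand.start < best.start):
                    best = cand
                orf_start = None
        if orf_start is not None:
            last_codon_end = orf_start + 3 * ((n - orf_start) // 3)
            cand = OrfResult(orf_start, last_codon_end - orf_start, frame, False)
            if best is None or cand.length > best.length or (
                    cand.length == best.length and cand.start < best.start):
                best = cand
    return best


def orf_filter(candidates: Sequence[str], sequences: Mapping[str, str],
               threshold: int = 300) -> tuple[list[str], dict[str, str]]:
    """Remove candidates whose longest ORF is >= ``threshold`` nt.

    Transcripts with a long ORF are putatively protein-coding; ORF-free
    transcripts are retained.
    """
    kept: list[str] = []
    removal: dict[str, str] = {}
    for tid in candidates:
        orf = find_longest_orf(sequences[tid])
        if orf is not None and orf.length >= threshold:
            removal[tid] = f"orf>={threshold}"
        else:
            kept.append(tid)
    return kept, removal


# ---------------------------------------------------------------------------
# Fickett TESTCODE

def _load_fickett_tables() -> dict:
    with resources.files("lncpipe.data").joinpath("fickett_tables.json").open() as fh:
        return json.load(fh)


_FICKETT = _load_fickett_tables()


def _lookup(value: float, thresholds: Sequence[float], probs: Sequence[float]) -> float:
    for t, p in zip(thresholds, probs):
        if value >= t:
            return p
    return probs[-1]


def fickett_score(seq: str) -> float:
    """Fickett TESTCODE statistic from the published lookup tables.

    Combines, for each base, its 3-periodic positional asymmetry
    max(c1,c2,c3)/(min(c1,c2,c3)+1) and its overall content fraction, each
    mapped to a coding probability and weighted.  N bases are ignored.
    """
    if not seq:
        raise ValueError("empty sequence")
    counts = {b: [0, 0, 0] for b in "ACGT"}
    total = 0
    for i, ch in enumerate(seq):
        if ch in counts:
            counts[ch][i % 3] += 1
            total += 1
    if total == 0:
        raise ValueError("sequence contains no A/C/G/T bases")
    score = 0.0
    for base in "ACGT":
        c = counts[base]
        position_value = max(c) / (min(c) + 1)
        content_value = sum(c) / total
        score += _FICKETT["position_weight"][base] * _lookup(
            position_value, _FICKETT["position_thresholds"],
            _FICKETT["position_prob"][base])
        score += _FICKETT["content_weight"][base] * _lookup(
            content_value, _FICKETT["content_thresholds"],
            _FICKETT["content_prob"][base])
    return score


# ---------------------------------------------------------------------------
# Hexamer usage bias

@dataclass
class HexamerTable:
    """Per-hexamer log-likelihood ratio of coding vs noncoding usage."""

    log_ratio: np.ndarray  # 4096 entries, order = lexicographic over ACGT
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        self.log_ratio = np.asarray(self.log_ratio, dtype=float)
        if self.log_ratio.shape != (4096,):
            raise ValueError("hexamer table must have 4096 entries")
        if not np.all(np.isfinite(self.log_ratio)):
            raise ValueError("hexamer table has non-finite entries")

    def __getitem__(self, hexamer: str) -> float:
        return float(self.log_ratio[_HEXAMER_INDEX[hexamer]])


def _hexamer_counts(seqs: Iterable[str]) -> np.ndarray:
    counts = np.zeros(4096, dtype=float)
    for seq in seqs:
        for i in range(len(seq) - 5):
            idx = _HEXAMER_INDEX.get(seq[i:i + 6])
            if idx is not None:  # windows containing N are skipped
                counts[idx] += 1
    return counts


def build_hexamer_table(coding_seqs: Sequence[str], noncoding_seqs: Sequence[str],
                        pseudocount: float = 1.0) -> HexamerTable:
    """Build the coding-vs-noncoding hexamer log-ratio table.

    Sliding (step-1, frame-agnostic) hexamer counts from each set, with a
    pseudocount, give per-hexamer log((c_cod+a)/sum) - log((c_non+a)/sum).
    """
    c_cod = _hexamer_counts(coding_seqs)
    c_non = _hexamer_counts(noncoding_seqs)
    if c_cod.sum() == 0:
        raise ValueError("coding set has no countable hexamers")
    if c_non.sum() == 0:
        raise ValueError("noncoding set has no countable hexamers")
    p_cod = (c_cod + pseudocount) / (c_cod + pseudocount).sum()
    p_non = (c_non + pseudocount) / (c_non + pseudocount).sum()
    return HexamerTable(np.log(p_cod) - np.log(p_non), pseudocount)


def hexamer_score(seq: str, table: HexamerTable) -> float:
    """Mean table entry over all sliding hexamers of ``seq`` (N-windows skipped)."""
    if len(seq) < 6:
        warnings.warn("sequence shorter than 6 nt; hexamer score set to 0")
        return 0.0
    total, n = 0.0, 0
    for i in range(len(seq) - 5):
        idx = _HEXAMER_INDEX.get(seq[i:i + 6])
        if idx is not None:
            total += table.log_ratio[idx]
            n += 1
    return total / n if n else 0.0


# ---------------------------------------------------------------------------
# Feature assembly

def extract_features(seq: str, table: HexamerTable) -> np.ndarray:
    """Six-feature coding-potential vector in FEATURE_NAMES order."""
    orf = find_longest_orf(seq)
    orf_length = orf.length if orf else 0
    acgt = sum(seq.count(b) for b in "ACGT")
    gc = (seq.count("G") + seq.count("C")) / acgt if acgt else 0.0
    return np.array([
        orf_length,
        orf_length / len(seq),
        fickett_score(seq),
        hexamer_score(seq, table),
        gc,
        math.log(len(seq)),
    ])


def feature_matrix(records: Sequence[SequenceRecord], table: HexamerTable) -> np.ndarray:
    return np.vstack([extract_features(r.sequence, table) for r in records])


# ---------------------------------------------------------------------------
# Random-forest classifier

DEFAULT_GRID = (
    {"n_estimators": 100, "max_depth": None},
    {"n_estimators": 100, "max_depth": 10},
    {"n_estimators": 300, "max_depth": None},
    {"n_estimators": 300, "max_depth": 10},
)


@dataclass
class ClassifierModel:
    forest: RandomForestClassifier
    feature_names: tuple[str, ...]
    metadata: dict = field(default_factory=dict)


def train_classifier(features: np.ndarray, labels: Sequence[str],
                     n_folds: int = 10, seed: int = 0,
                     grid: Sequence[dict] = DEFAULT_GRID,
                     test_fraction: float = 0.2) -> ClassifierModel:
    """Train the coding/noncoding random forest with stratified CV.

    A held-out test fraction is reserved before cross-validation;
    hyperparameters are chosen from ``grid`` by mean CV F1 (coding as the
    positive class); the winner is refit on the full training portion.
    Metadata records per-fold precision/recall and held-out performance.
    """
    labels = np.asarray(labels)
    classes = set(labels)
    if classes != {"coding", "noncoding"}:
        raise ValueError(f"labels must be coding/noncoding, got {sorted(classes)}")
    y = (labels == "coding").astype(int)
    counts = np.bincount(y)
    if counts.min() < n_folds:
        raise ValueError(f"n_folds={n_folds} exceeds smallest class size {counts.min()}")

    X_tr, X_te, y_tr, y_te = train_test_split(
        features, y, test_size=test_fraction, stratify=y, random_state=seed)

    best_params, best_f1, best_folds = None, -1.0, None
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for params in grid:
        fold_stats = []
        for train_idx, val_idx in skf.split(X_tr, y_tr):
            rf = RandomForestClassifier(
                random_state=seed, class_weight="balanced", **params)
            rf.fit(X_tr[train_idx], y_tr[train_idx])
            pred = rf.predict(X_tr[val_idx])
            fold_stats.append({
                "precision": precision_score(y_tr[val_idx], pred, zero_division=0),
                "recall": recall_score(y_tr[val_idx], pred, zero_division=0),
                "f1": f1_score(y_tr[val_idx], pred, zero_division=0),
            })
        mean_f1 = float(np.mean([f["f1"] for f in fold_stats]))
        if mean_f1 > best_f1:
            best_params, best_f1, best_folds = params, mean_f1, fold_stats

    forest = RandomForestClassifier(
        random_state=seed, class_weight="balanced", **best_params)
    forest.fit(X_tr, y_tr)
    pred_te = forest.predict(X_te)
    metadata = {
        "seed": seed,
        "hyperparameters": dict(best_params),
        "cv_mean_f1": best_f1,
        "cv_folds": best_folds,
        "heldout_precision": float(precision_score(y_te, pred_te, zero_division=0)),
        "heldout_recall": float(recall_score(y_te, pred_te, zero_division=0)),
        "heldout_f1": float(f1_score(y_te, pred_te, zero_division=0)),
        "n_train": int(len(y_tr)),
        "n_test": int(len(y_te)),
    }
    return ClassifierModel(forest, FEATURE_NAMES, metadata)


def predict_noncoding(model: ClassifierModel, features: np.ndarray,
                      ids: Sequence[str], threshold: float = 0.5,
                      feature_names: Sequence[str] = FEATURE_NAMES,
                      ) -> tuple[list[str], dict[str, str], dict[str, float]]:
    """Classify candidates; predicted-mRNA (P(coding) >= threshold) removed.

    Returns (retained ids, removal_log, P(coding) per id).
    """
    if tuple(feature_names) != tuple(model.feature_names):
        raise ValueError("feature order at prediction differs from training")
    if len(ids) == 0:
        return [], {}, {}
    p_coding = model.forest.predict_proba(np.asarray(features))[:, 1]
    retained: list[str] = []
    removal: dict[str, str] = {}
    probs: dict[str, float] = {}
    for tid, p in zip(ids, p_coding):
        probs[tid] = float(p)
        if p >= threshold:
            removal[tid] = "predicted_mRNA"
        else:
            retained.append(tid)
    return retained, removal, probs


# ---------------------------------------------------------------------------
# Homology triage

def triage_by_homology(candidates: Sequence[str], hits: Iterable[HomologyHit],
                       evalue_threshold: float = 1e-5) -> dict[str, int]:
    """Assign each candidate to one of three homology groups.

    1: significant hit to a coding/other subject (to be removed);
    2: significant hit to a lncRNA subject (retained);
    3: no significant hit (retained).  Groups 2 and 3 are the novel lncRNAs.
    """
    candidate_set = set(candidates)
    sig: dict[str, set[str]] = {}
    for hit in hits:
        if hit.query_id not in candidate_set:
            warnings.warn(f"hit for unknown candidate {hit.query_id!r} ignored")
            continue
        if hit.evalue <= evalue_threshold:
            sig.setdefault(hit.query_id, set()).add(hit.subject_class)
    groups: dict[str, int] = {}
    for tid in candidates:
        classes = sig.get(tid, set())
        if "coding_or_other" in classes:
            groups[tid] = 1
        elif "lncRNA" in classes:
            groups[tid] = 2
        else:
            groups[tid] = 3
    return groups


# ---------------------------------------------------------------------------
# Naive self-contained nucleotide aligner (tests only; real runs use BLASTn)

_KA_LAMBDA = 1.33
_KA_K = 0.621


def naive_search(queries: Sequence[SequenceRecord],
                 subjects: Sequence[SequenceRecord],
                 subject_classes: Mapping[str, str],
                 word_size: int = 11, xdrop: int = 10,
                 ) -> list[HomologyHit]:
    """Exact-word seed + ungapped extension search (match +1 / mismatch -2).

    E-values use the Karlin-Altschul formula E = m*n*2^(-bitscore) with the
    ungapped +1/-2 constants.  Intended only for self-contained tests; not a
    BLASTn replacement.
    """
    index: dict[str, list[tuple[int, int]]] = {}
    for si, subj in enumerate(subjects):
        s = subj.sequence
        for i in range(len(s) - word_size + 1):
            word = s[i:i + word_size]
            if "N" not in word:
                index.setdefault(word, []).append((si, i))
    db_len = sum(len(s.sequence) for s in subjects)
    hits: list[HomologyHit] = []
    for query in queries:
        q = query.sequence
        best: dict[int, float] = {}  # subject index -> best raw score
        for qi in range(len(q) - word_size + 1):
            word = q[qi:qi + word_size]
            for si, sj in index.get(word, ()):  # seed hit
                s = subjects[si].sequence
                score = word_size
                # extend right
                run, i, j = score, qi + word_size, sj + word_size
                while i < len(q) and j < len(s):
                    run += 1 if q[i] == s[j] else -2
                    if run > score:
                        score = run
                    if score - run > xdrop:
                        break
                    i += 1
                    j += 1
                # extend left
                run2, i, j = 0, qi - 1, sj - 1
                best_left = 0
                while i >= 0 and j >= 0:
                    run2 += 1 if q[i] == s[j] else -2
                    if run2 > best_left:
                        best_left = run2
                    if best_left - run2 > xdrop:
                        break
                    i -= 1
                    j -= 1
                total = score + best_left
                if total > best.get(si, -1):
                    best[si] = total
        for si, raw in best.items():
            bitscore = (_KA_LAMBDA * raw - math.log(_KA_K)) / math.log(2)
            evalue = len(q) * db_len * 2.0 ** (-bitscore)
            sid = subjects[si].id
            hits.append(HomologyHit(
                query_id=query.id, subject_id=sid,
                subject_class=subject_classes.get(sid, "coding_or_other"),
                evalue=evalue, bitscore=bitscore))
    return hits
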