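"""Cis/trans target inference for differentially expressed lncRNAs, plus the
structural and over-representation summaries.

Every DEL x DEG pair is tested by Pearson correlation of log2(normalized
count + 1) expression across samples; pairs passing |r| >= 0.90 and
p <= 0.05 become edges.  A pair is *cis* when the two gene bodies lie within
20 kb on the same chromosome (gap between spans; overlap counts as 0),
otherwise *trans*; cis status only annotates the edge, the thresholds are
shared.  No multiple-testing correction is applied across the correlation
family (raw p threshold), recorded as a caveat in output metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import CorrelationEdge, TranscriptModel

DEFAULT_R_MIN = 0.90
DEFAULT_ALPHA = 0.05
DEFAULT_CIS_WINDOW = 20_000

EDGE_METADATA = {
    "expression_scale": "log2(normalized+1)",
    "multiple_testing": "none (raw p threshold across the DEL x DEG family)",
}


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with the two-sided t-test p-value (n-2 df).

    Constant vectors are undefined: the caller should skip the pair.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def gene_spans(annotation: Sequence[TranscriptModel]) -> dict[str, tuple[str, int, int]]:
    """Per-gene (chrom, start, end) as the union of its transcript spans."""
    spans: dict[str, tuple[str, int, int]] = {}
    for t in annotation:
        s, e = t.span
        if t.gene_id in spans:
            chrom, s0, e0 = spans[t.gene_id]
            if chrom != t.chrom:
                raise ValueError(f"gene {t.gene_id} spans multiple chromosomes")
            spans[t.gene_id] = (chrom, min(s0, s), max(e0, e))
        else:
            spans[t.gene_id] = (t.chrom, s, e)
    return spans


def gene_body_distance(a: tuple[str, int, int], b: tuple[str, int, int]) -> int | None:
    """Gap in bp between two gene bodies; 0 on overlap; None across chromosomes."""
    if a[0] != b[0]:
        return None
    gap = max(a[1], b[1]) - min(a[2], b[2])
    return max(gap, 0)


def cis_candidates(dels: Sequence[str], degs: Sequence[str],
                   annotation: Sequence[TranscriptModel],
                   window: int = DEFAULT_CIS_WINDOW) -> dict[tuple[str, str], int]:
    """DEL-DEG pairs whose gene bodies are closer than ``window`` bp.

    The boundary is strict: a gap of exactly ``window`` is not cis.
    Features missing from the annotation are skipped with a warning.
    """
    spans = gene_spans(annotation)
    pairs: dict[tuple[str, str], int] = {}
    for d in dels:
        if d not in spans:
            warnings.warn(f"DEL {d!r} missing from annotation; skipped")
            continue
        for g in degs:
            if g not in spans:
                warnings.warn(f"DEG {g!r} missing from annotation; skipped")
                continue
            dist = gene_body_distance(spans[d], spans[g])
            if dist is not None and dist < window:
                pairs[(d, g)] = dist
    return pairs


def build_target_network(del_expr: pd.DataFrame, deg_expr: pd.DataFrame,
                         cis_pairs: Mapping[tuple[str, str], int],
                         r_min: float = DEFAULT_R_MIN,
                         alpha: float = DEFAULT_ALPHA) -> list[CorrelationEdge]:
    """Correlate every DEL against every DEG and emit thresholded edges.

    Both expression matrices must share the same sample columns in the same
    order (normalized, log-scale expression over the samples used for DE).
    """
    if list(del_expr.columns) != list(deg_expr.columns):
        raise ValueError("DEL and DEG expression matrices have different samples")
    edges: list[CorrelationEdge] = []
    for d in del_expr.index:
        x = del_expr.loc[d].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            warnings.warn(f"constant expression for {d!r}; skipped")
            continue
        for g in deg_expr.index:
            if d == g:
                continue
            y = deg_expr.loc[g].to_numpy(dtype=float)
            if np.ptp(y) == 0:
                warnings.warn(f"constant expression for {g!r}; skipped")
                continue
            r, p = pearson_with_p(x, y)
            if abs(r) >= r_min and p <= alpha:
                is_cis = (d, g) in cis_pairs
                edges.append(CorrelationEdge(
                    del_id=d, deg_id=g, r=r, p=p,
                    mode="cis" if is_cis else "trans",
                    sign="positive" if r > 0 else "negative",
                    distance_bp=cis_pairs.get((d, g)),
                ))
    return edges


def edges_to_frame(edges: Sequence[CorrelationEdge]) -> pd.DataFrame:
    return pd.DataFrame([{
        "del_id": e.del_id, "deg_id": e.deg_id, "r": e.r, "p": e.p,
        "mode": e.mode, "sign": e.sign,
        "distance_bp": e.distance_bp if e.distance_bp is not None else "",
    } for e in edges], columns=["del_id", "deg_id", "r", "p", "mode", "sign",
                               "distance_bp"])


# ---------------------------------------------------------------------------
# Over-representation analysis

def ora_enrichment(hits: set[str], universe: set[str],
                   term_sets: Mapping[str, set[str]]) -> pd.DataFrame:
    """Hypergeometric over-representation of ``hits`` in each term's gene set.

    p = P(X >= k) with X ~ Hypergeometric(N=|universe|, K=|term|, n=|hits|),
    BH-adjusted across terms.  Term sets are intersected with the universe.
    """
    if not hits or not universe:
        raise ValueError("hit set and universe must be non-empty")
    if not hits <= universe:
        raise ValueError(f"hits outside universe: {sorted(hits - universe)[:5]}")
    from .de import bh_adjust

    N, n = len(universe), len(hits)
    rows = []
    for term in sorted(term_sets):
        members = term_sets[term] & universe
        K = len(members)
        k = len(hits & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        expected = n * K / N if N else 0.0
        rows.append({
            "term": term, "K": K, "k": k, "p": p,
            "enrichment_ratio": (k / expected) if expected > 0 else np.nan,
        })
    df = pd.DataFrame(rows)
    df["padj"] = bh_adjust(df["p"].to_numpy()) if len(df) else []
    return df


# ---------------------------------------------------------------------------
# Structural comparison of lncRNAs vs mRNAs

LENGTH_BIN_EDGES = list(range(0, 10_001, 500)) + [np.inf]
EXON_LENGTH_BIN_EDGES = [0, 50, 100, 200, 500, 1000, 2000, np.inf]


@dataclass
class StructureSummary:
    """Per-class transcript length / exon length / exon count statistics."""

    stats: pd.DataFrame       # index (class, metric) -> mean, sd, n
    pvalues: dict[str, float]  # metric -> two-sided Mann-Whitney U p
    histograms: dict[str, pd.DataFrame]


def _metrics(models: Sequence[TranscriptModel]) -> dict[str, np.ndarray]:
    return {
        "transcript_length": np.array([t.length for t in models], dtype=float),
        "exon_length": np.array([e - s for t in models for s, e in t.exons],
                                dtype=float),
        "exon_count": np.array([t.n_exons for t in models], dtype=float),
    }


def structure_summary(lnc_models: Sequence[TranscriptModel],
                      mrna_models: Sequence[TranscriptModel]) -> StructureSummary:
    """Compare lncRNA vs mRNA structure (Mann-Whitney U, two-sided)."""
    if not lnc_models or not mrna_models:
        raise ValueError("both classes must be non-empty")
    data = {"lncRNA": _metrics(lnc_models), "mRNA": _metrics(mrna_models)}
    rows, pvalues, histograms = [], {}, {}
    for metric in ("transcript_length", "exon_length", "exon_count"):
        a, b = data["lncRNA"][metric], data["mRNA"][metric]
        if np.ptp(np.concatenate([a, b])) == 0:
            pvalues[metric] = 1.0
        else:
            pvalues[metric] = float(stats.mannwhitneyu(
                a, b, alternative="two-sided").pvalue)
        for cls in ("lncRNA", "mRNA"):
            v = data[cls][metric]
            rows.append({"class": cls, "metric": metric,
                         "mean": float(v.mean()), "sd": float(v.std(ddof=1)),
                         "n": int(v.size)})
        if metric == "exon_count":
            edges = np.arange(0.5, max(a.max(), b.max()) + 1.5)
        elif metric == "exon_length":
            edges = np.array(EXON_LENGTH_BIN_EDGES, dtype=float)
        else:
            edges = np.array(LENGTH_BIN_EDGES, dtype=float)
        hist = {}
        for cls in ("lncRNA", "mRNA"):
            hist[cls], _ = np.histogram(data[cls][metric], bins=edges)
        histograms[metric] = pd.DataFrame(
            hist, index=[f"[{edges[i]:g},{edges[i+1]:g})"
                         for i in range(len(edges) - 1)])
    return StructureSummary(
        stats=pd.DataFrame(rows).set_index(["class", "metric"]),
        pvalues=pvalues,
        histograms=histograms,
    )
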