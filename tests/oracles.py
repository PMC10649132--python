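"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity along a different route from the library
implementation it checks: per-base occupancy sets instead of interval
arithmetic for class codes, position-list enumeration for ORFs, the literal
step-up definition for BH, closed forms for Pearson, exhaustive subset
enumeration for the hypergeometric tail, and pairwise comparison counting
for Mann-Whitney U.
"""

from __future__ import annotations

import itertools
import math
from bisect import bisect_left

import numpy as np


# ---------------------------------------------------------------------------
# Class codes via per-base occupancy sets

def classcode_oracle(query, reference) -> tuple[str, str | None]:
    """Best class code by explicit set logic over genomic base positions."""
    def exon_bases(t):
        return set(itertools.chain.from_iterable(range(s, e) for s, e in t.exons))

    def intron_bases(t):
        out = set()
        for s, e in t.introns:
            out.update(range(s, e))
        return out

    q_ex = exon_bases(query)
    qs, qe = query.span
    per_ref: list[tuple[str, str]] = []
    for ref in reference:
        if ref.chrom != query.chrom:
            continue
        r_ex = exon_bases(ref)
        same = ref.strand == query.strand
        code = None
        if same and query.introns and ref.introns and \
                list(query.introns) == list(ref.introns):
            code = "="
        elif same and not query.introns and not ref.introns and (q_ex & r_ex):
            rs, re_ = ref.span
            if abs(qs - rs) <= 100 and abs(qe - re_) <= 100:
                code = "="
        if code is None and same and set(query.introns) & set(ref.introns):
            code = "j"
        if code is None and (q_ex & r_ex):
            code = "o" if same else "x"
        if code is None:
            for is_, ie in ref.introns:
                if is_ <= qs and qe <= ie:
                    code = "i"
                    break
        if code is not None:
            per_ref.append((code, ref.transcript_id))
    if per_ref:
        prec = {c: i for i, c in enumerate("=joxiu")}
        per_ref.sort(key=lambda cr: (prec[cr[0]], cr[1]))
        return per_ref[0]
    # no pair code: u unless the query touches exon or intron bases
    touched = []
    for ref in reference:
        if ref.chrom != query.chrom:
            continue
        blocks = exon_bases(ref) | intron_bases(ref)
        if q_ex & blocks:
            touched.append(ref.transcript_id)
    if touched:
        return "i", min(touched)
    return "u", None


# ---------------------------------------------------------------------------
# Longest ORF via stop-position lists

def orf_oracle(seq: str) -> tuple[int, int] | None:
    """(start, length) of the longest ORF by enumerating ATG/stop positions."""
    n = len(seq)
    best = None  # (length, start)
    for frame in range(3):
        positions = list(range(frame, n - 2, 3))
        stops = [p for p in positions if seq[p:p + 3] in ("TAA", "TAG", "TGA")]
        atgs = [p for p in positions if seq[p:p + 3] == "ATG"]
        frame_end = frame + 3 * ((n - frame) // 3)
        used_stop: set[int] = set()
        for a in atgs:
            i = bisect_left(stops, a + 3)
            if i < len(stops):
                stop = stops[i]
                if stop in used_stop:
                    continue  # an earlier ATG already claims this stop (longer ORF)
                used_stop.add(stop)
                length = stop + 3 - a
            else:
                length = frame_end - a
            if length >= 3 and (best is None or length > best[0]
                                or (length == best[0] and a < best[1])):
                best = (length, a)
    if best is None:
        return None
    return best[1], best[0]


# ---------------------------------------------------------------------------
# Benjamini-Hochberg by the literal step-up definition

def bh_oracle(pvals) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    for rank_pos in range(m):
        i = order[rank_pos]
        k = rank_pos + 1
        # adjusted p = min over j >= k of m*p_(j)/j, capped at 1
        candidates = [m * p[order[j]] / (j + 1) for j in range(rank_pos, m)]
        adj[i] = min(1.0, min(candidates))
    return adj


# ---------------------------------------------------------------------------
# Pearson r and p by closed forms

def pearson_oracle(x, y) -> tuple[float, float]:
    from scipy.stats import t as tdist
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxy = (x * y).sum()
    sxx, syy = (x * x).sum(), (y * y).sum()
    r = (n * sxy - sx * sy) / math.sqrt((n * sxx - sx ** 2) * (n * syy - sy ** 2))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1 - r * r))
    return r, 2.0 * float(tdist.sf(abs(t), n - 2))


# ---------------------------------------------------------------------------
# Hypergeometric upper tail by exhaustive enumeration (small N)

def hypergeom_tail_oracle(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by enumerating all C(N, n) draws."""
    universe = list(range(N))
    hits = set(range(K))
    total = 0
    ge = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if len(hits.intersection(draw)) >= k:
            ge += 1
    return ge / total


# ---------------------------------------------------------------------------
# Mann-Whitney U by pairwise comparison

def mannwhitney_u_oracle(a, b) -> float:
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


# ---------------------------------------------------------------------------
# Fickett TESTCODE re-derived independently from the packaged tables

def fickett_oracle(seq: str) -> float:
    """Second implementation: dict-driven loops over explicit codon columns."""
    import json
    from importlib import resources
    with resources.files("lncpipe.data").joinpath("fickett_tables.json").open() as fh:
        tab = json.load(fh)
    cols = {0: {}, 1: {}, 2: {}}
    for base in "ACGT":
        for c in cols.values():
            c[base] = 0
    for i, ch in enumerate(seq):
        if ch in "ACGT":
            cols[i % 3][ch] += 1
    total = sum(sum(c.values()) for c in cols.values())
    score = 0.0
    for base in "ACGT":
        triple = [cols[0][base], cols[1][base], cols[2][base]]
        pos_val = max(triple) / (min(triple) + 1)
        cont_val = sum(triple) / total
        pos_prob = None
        for thr, pr in zip(tab["position_thresholds"], tab["position_prob"][base]):
            if pos_val >= thr:
                pos_prob = pr
                break
        if pos_prob is None:
            pos_prob = tab["position_prob"][base][-1]
        cont_prob = None
        for thr, pr in zip(tab["content_thresholds"], tab["content_prob"][base]):
            if cont_val >= thr:
                cont_prob = pr
                break
        if cont_prob is None:
            cont_prob = tab["content_prob"][base][-1]
        score += pos_prob * tab["position_weight"][base]
        score += cont_prob * tab["content_weight"][base]
    return score
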