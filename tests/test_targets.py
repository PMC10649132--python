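"""Pearson edges, cis windows, ORA and the structure summary."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lncpipe import targets
from lncpipe.models import TranscriptModel

from oracles import hypergeom_tail_oracle, mannwhitney_u_oracle, pearson_oracle


def _t(tid, gene, chrom, exons, strand="+", biotype="other"):
    return TranscriptModel(tid, gene, chrom, strand, tuple(exons), biotype)


class TestPearson:
    def test_perfect_correlation(self):
        r, p = targets.pearson_with_p(np.array([1, 2, 3]), np.array([2, 4, 6]))
        assert r == pytest.approx(1.0)

    def test_r090_at_n7_passes_alpha(self):
        """At the study's sample size (n=7), r=0.90 has p ~ 0.00562 < 0.05."""
        r = 0.90
        t = r * math.sqrt((7 - 2) / (1 - r * r))
        p = 2 * stats.t.sf(t, 5)
        assert p == pytest.approx(0.00562, abs=2e-4)
        assert p <= 0.05

    def test_matches_closed_form_oracle(self, rng):
        for _ in range(1000):
            n = int(rng.integers(3, 30))
            x, y = rng.normal(size=n), rng.normal(size=n)
            r, p = targets.pearson_with_p(x, y)
            ro, po = pearson_oracle(x, y)
            assert r == pytest.approx(ro, abs=1e-10)
            assert p == pytest.approx(po, abs=1e-10)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            targets.pearson_with_p(np.ones(5), np.arange(5.0))


class TestCisCandidates:
    REF = [
        _t("L1.t", "L1", "chr1", [(100_000, 101_000)], biotype="lncRNA"),
        _t("G1.t", "G1", "chr1", [(121_999 - 1_000, 121_999)]),  # gap computed below
        _t("G2.t", "G2", "chr2", [(100_000, 101_000)]),
    ]

    def _ref_with_gap(self, gap):
        return [
            _t("L1.t", "L1", "chr1", [(100_000, 101_000)], biotype="lncRNA"),
            _t("G1.t", "G1", "chr1", [(101_000 + gap, 102_000 + gap)]),
        ]

    @pytest.mark.parametrize("gap,is_cis", [(19_999, True), (20_000, False)])
    def test_window_boundary_is_strict(self, gap, is_cis):
        pairs = targets.cis_candidates(["L1"], ["G1"], self._ref_with_gap(gap))
        assert (("L1", "G1") in pairs) is is_cis
        if is_cis:
            assert pairs[("L1", "G1")] == gap

    def test_overlap_distance_zero(self):
        ref = [_t("L1.t", "L1", "chr1", [(100, 500)], biotype="lncRNA"),
               _t("G1.t", "G1", "chr1", [(400, 900)])]
        assert targets.cis_candidates(["L1"], ["G1"], ref) == {("L1", "G1"): 0}

    def test_different_chromosomes_never_cis(self):
        ref = [_t("L1.t", "L1", "chr1", [(100, 500)], biotype="lncRNA"),
               _t("G1.t", "G1", "chr2", [(100, 500)])]
        assert targets.cis_candidates(["L1"], ["G1"], ref) == {}

    def test_missing_feature_warns_and_skips(self):
        ref = self._ref_with_gap(10)
        with pytest.warns(UserWarning, match="missing"):
            pairs = targets.cis_candidates(["L1", "GHOST"], ["G1"], ref)
        assert pairs == {("L1", "G1"): 10}


class TestTargetNetwork:
    def _expr(self, rows, samples=7, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(rng.normal(size=(len(rows), samples)), index=rows,
                            columns=[f"s{i}" for i in range(samples)])

    def test_identical_profile_gives_positive_edge(self):
        deg = self._expr(["g1", "g2"])
        del_ = pd.DataFrame([deg.loc["g1"]], index=["l1"])
        edges = targets.build_target_network(del_, deg, {})
        assert any(e.deg_id == "g1" and e.r == pytest.approx(1.0)
                   and e.sign == "positive" for e in edges)

    def test_sample_mismatch_rejected(self):
        a = self._expr(["l1"])
        b = self._expr(["g1"]).rename(columns={"s0": "zz"})
        with pytest.raises(ValueError, match="samples"):
            targets.build_target_network(a, b, {})

    def test_equals_brute_force_threshold_filter(self, rng):
        dels = self._expr([f"l{i}" for i in range(8)], seed=1)
        degs = self._expr([f"g{i}" for i in range(15)], seed=2)
        cis = {("l0", "g0"): 500}
        edges = targets.build_target_network(dels, degs, cis)
        got = {(e.del_id, e.deg_id): (e.r, e.mode) for e in edges}
        want = {}
        for d in dels.index:
            for g in degs.index:
                r, p = pearson_oracle(dels.loc[d], degs.loc[g])
                if abs(r) >= 0.90 and p <= 0.05:
                    want[(d, g)] = (r, "cis" if (d, g) in cis else "trans")
        assert set(got) == set(want)
        for k in got:
            assert got[k][0] == pytest.approx(want[k][0], abs=1e-10)
            assert got[k][1] == want[k][1]

    def test_threshold_monotonicity(self, rng):
        dels = self._expr([f"l{i}" for i in range(6)], seed=3)
        degs = self._expr([f"g{i}" for i in range(12)], seed=4)
        loose = targets.build_target_network(dels, degs, {}, r_min=0.6, alpha=0.2)
        tight = targets.build_target_network(dels, degs, {}, r_min=0.8, alpha=0.05)
        loose_keys = {(e.del_id, e.deg_id) for e in loose}
        tight_keys = {(e.del_id, e.deg_id) for e in tight}
        assert tight_keys <= loose_keys

    def test_planted_cis_pairs_recovered(self, default_study):
        from lncpipe.pipeline import (PipelineConfig, normalized_log_expression,
                                      run_de_split)
        st = default_study
        lnc_genes = {t.gene_id for t in st.reference if t.biotype == "lncRNA"}
        de_g, de_l = run_de_split(st.counts, lnc_genes, PipelineConfig(seed=7))
        degs = list(de_g.index[de_g["call"] != "ns"])
        dels = list(de_l.index[de_l["call"] != "ns"])
        expr = normalized_log_expression(st.counts)
        cis = targets.cis_candidates(dels, degs, st.reference)
        edges = targets.build_target_network(expr.loc[dels], expr.loc[degs], cis)
        cis_edges = {(e.del_id, e.deg_id) for e in edges if e.mode == "cis"}
        planted = [(l, g) for l, g, _ in st.truth.cis_pairs]
        recovered = sum(1 for p in planted if p in cis_edges)
        # planted pairs must be recovered far above the background rate
        assert recovered >= 0.6 * len(planted)
        for e in edges:
            if e.mode == "cis":
                assert e.distance_bp is not None and e.distance_bp < 20_000


class TestOra:
    def test_term_equals_universe(self):
        universe = {f"g{i}" for i in range(20)}
        hits = {f"g{i}" for i in range(5)}
        df = targets.ora_enrichment(hits, universe, {"all": set(universe)})
        assert df["p"].iloc[0] == pytest.approx(1.0)

    def test_fully_enriched_term_closed_form(self):
        universe = {f"g{i}" for i in range(20)}
        hits = {f"g{i}" for i in range(5)}
        df = targets.ora_enrichment(hits, universe, {"t": set(hits)})
        assert df["p"].iloc[0] == pytest.approx(1 / math.comb(20, 5), rel=1e-9)

    def test_matches_enumeration_for_small_universes(self, rng):
        for _ in range(25):
            N = int(rng.integers(5, 13))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            universe = {f"g{i}" for i in range(N)}
            term = {f"g{i}" for i in range(K)}
            hits = set(rng.choice(sorted(universe), size=n, replace=False))
            df = targets.ora_enrichment(hits, universe, {"t": term})
            k = len(hits & term)
            assert df["p"].iloc[0] == pytest.approx(
                hypergeom_tail_oracle(N, K, n, k), abs=1e-12)

    def test_hit_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            targets.ora_enrichment({"x"}, {"a", "b"}, {"t": {"a"}})


class TestStructureSummary:
    def _models(self, n, n_exons, exon_len, prefix):
        out = []
        for i in range(n):
            exons, pos = [], 1000
            for _ in range(n_exons):
                exons.append((pos, pos + exon_len))
                pos += exon_len + 500
            out.append(_t(f"{prefix}{i}.t", f"{prefix}{i}", "chr1", exons))
        return out

    def test_identical_classes_p_near_one(self):
        a = self._models(30, 3, 200, "a")
        b = self._models(30, 3, 200, "b")
        s = targets.structure_summary(a, b)
        for metric, p in s.pvalues.items():
            assert p == pytest.approx(1.0)
        assert s.stats.loc[("lncRNA", "transcript_length"), "mean"] == \
            s.stats.loc[("mRNA", "transcript_length"), "mean"]

    def test_planted_ordering_recovered(self, small_study):
        lnc = [t for t in small_study.reference if t.biotype == "lncRNA"]
        mrna = [t for t in small_study.reference if t.biotype == "protein_coding"]
        s = targets.structure_summary(lnc, mrna)
        assert s.stats.loc[("lncRNA", "transcript_length"), "mean"] < \
            s.stats.loc[("mRNA", "transcript_length"), "mean"]
        assert s.stats.loc[("lncRNA", "exon_count"), "mean"] < \
            s.stats.loc[("mRNA", "exon_count"), "mean"]
        assert s.pvalues["transcript_length"] < 0.05
        assert s.pvalues["exon_count"] < 0.05

    def test_u_statistic_matches_pairwise_count(self, rng):
        a = rng.normal(size=40)
        b = rng.normal(loc=0.5, size=35)
        u = stats.mannwhitneyu(a, b, alternative="two-sided").statistic
        assert u == pytest.approx(mannwhitney_u_oracle(a, b))

    def test_histogram_counts_sum_to_class_sizes(self, small_study):
        lnc = [t for t in small_study.reference if t.biotype == "lncRNA"]
        mrna = [t for t in small_study.reference if t.biotype == "protein_coding"]
        s = targets.structure_summary(lnc, mrna)
        h = s.histograms["transcript_length"]
        assert h["lncRNA"].sum() == len(lnc)
        assert h["mRNA"].sum() == len(mrna)
        hc = s.histograms["exon_count"]
        assert hc["lncRNA"].sum() == len(lnc)
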