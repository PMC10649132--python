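"""ORF scanning, Fickett/hexamer features, classifier and homology triage."""

import math

import numpy as np
import pytest

from lncpipe import coding
from lncpipe.models import HomologyHit, SequenceRecord

from oracles import fickett_oracle, orf_oracle


def _random_seq(rng, n, probs=(0.25, 0.25, 0.25, 0.25)):
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=list(probs))])


class TestFindLongestOrf:
    def test_simple_orf(self):
        orf = coding.find_longest_orf("ATGAAATAG")
        assert (orf.start, orf.length, orf.frame, orf.has_stop) == (0, 9, 0, True)

    def test_no_orf(self):
        assert coding.find_longest_orf("CCCCCC") is None

    def test_open_ended_orf(self):
        orf = coding.find_longest_orf("CCATGAAAAAA")
        assert orf.start == 2 and orf.has_stop is False
        assert orf.length == 9  # ATG AAA AAA; trailing A is a partial codon

    def test_n_codons_never_match(self):
        assert coding.find_longest_orf("ATNAAATAG") is None

    def test_tie_breaks_to_smallest_start(self):
        # two 9-nt ORFs in different frames
        seq = "ATGAAATAGG" + "ATGCCCTAA"
        orf = coding.find_longest_orf(seq)
        assert orf.start == 0

    def test_matches_enumeration_oracle_on_random_sequences(self, rng):
        for _ in range(300):
            seq = _random_seq(rng, int(rng.integers(10, 500)))
            got = coding.find_longest_orf(seq)
            want = orf_oracle(seq)
            if want is None:
                assert got is None
            else:
                assert (got.start, got.length) == want


class TestOrfFilter:
    @pytest.mark.parametrize("orf_nt,kept", [(297, True), (300, False)])
    def test_boundary(self, orf_nt, kept):
        seq = "CC" + "ATG" + "GCT" * (orf_nt // 3 - 2) + "TAA" + "CC"
        ids, removed = coding.orf_filter(["t"], {"t": seq})
        assert (ids == ["t"]) is kept

    def test_orf_free_transcripts_retained(self):
        ids, removed = coding.orf_filter(["t"], {"t": "CCTGA" * 100})
        assert ids == ["t"] and removed == {}


class TestFickett:
    def test_period3_repeat_invariance(self):
        assert coding.fickett_score("ACG" * 20) == \
            pytest.approx(coding.fickett_score("ACG" * 40))

    def test_matches_independent_reimplementation(self, rng):
        fixed = "ATGGCGGCTAAACCCGGGTTTACGTACGTACGATCGATCGATCGGCATGCATGCATGCAT"
        assert len(fixed) == 60
        assert coding.fickett_score(fixed) == pytest.approx(fickett_oracle(fixed))
        for _ in range(50):
            seq = _random_seq(rng, int(rng.integers(30, 400)))
            assert coding.fickett_score(seq) == pytest.approx(fickett_oracle(seq))

    def test_scores_within_table_extrema(self, rng):
        lo = sum(min(p) * w for p, w in [
            (coding._FICKETT["position_prob"][b], coding._FICKETT["position_weight"][b])
            for b in "ACGT"]) + sum(min(p) * w for p, w in [
            (coding._FICKETT["content_prob"][b], coding._FICKETT["content_weight"][b])
            for b in "ACGT"])
        hi = sum(max(p) * w for p, w in [
            (coding._FICKETT["position_prob"][b], coding._FICKETT["position_weight"][b])
            for b in "ACGT"]) + sum(max(p) * w for p, w in [
            (coding._FICKETT["content_prob"][b], coding._FICKETT["content_weight"][b])
            for b in "ACGT"])
        for _ in range(200):
            s = coding.fickett_score(_random_seq(rng, 120))
            assert lo <= s <= hi

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            coding.fickett_score("")


class TestHexamer:
    def test_identical_sets_give_zero_table(self):
        t = coding.build_hexamer_table(["ACGTACGTAC"], ["ACGTACGTAC"])
        assert np.allclose(t.log_ratio, 0.0)

    def test_monotone_for_enriched_hexamer(self):
        t = coding.build_hexamer_table(["AAAAAA"], ["CCCCCC"])
        assert t["AAAAAA"] > 0

    def test_toy_table_equals_hand_computation(self):
        # coding: AAAAAAA -> AAAAAA twice; noncoding: CCCCCC -> CCCCCC once
        t = coding.build_hexamer_table(["AAAAAAA"], ["CCCCCC"], pseudocount=1)
        n_hex = 4096
        p_cod = (2 + 1) / (2 + n_hex)
        p_non = (0 + 1) / (1 + n_hex)
        assert t["AAAAAA"] == pytest.approx(math.log(p_cod) - math.log(p_non))

    def test_single_hexamer_score_is_table_entry(self):
        t = coding.build_hexamer_table(["AAAAAA"], ["CCCCCC"])
        assert coding.hexamer_score("AAAAAA", t) == pytest.approx(t["AAAAAA"])

    def test_short_sequence_scores_zero_with_warning(self):
        t = coding.build_hexamer_table(["AAAAAA"], ["CCCCCC"])
        with pytest.warns(UserWarning):
            assert coding.hexamer_score("ACG", t) == 0.0

    def test_n_windows_skipped(self):
        t = coding.build_hexamer_table(["AAAAAA"], ["CCCCCC"])
        assert coding.hexamer_score("AAAAAANAAAAAA", t) == \
            pytest.approx(t["AAAAAA"])

    def test_simulated_coding_scores_higher(self, small_study):
        truth = small_study.truth.coding_label
        seqs = small_study.ref_sequences
        cod = [seqs[t].sequence for t, l in truth.items() if l == "coding"]
        non = [seqs[t].sequence for t, l in truth.items() if l == "noncoding"]
        table = coding.build_hexamer_table(cod, non)
        mean_c = np.mean([coding.hexamer_score(s, table) for s in cod])
        mean_n = np.mean([coding.hexamer_score(s, table) for s in non])
        assert mean_c > mean_n


class TestFeatures:
    def test_no_orf_gives_zero_orf_features(self):
        t = coding.build_hexamer_table(["AAAAAA"], ["CCCCCC"])
        v = coding.extract_features("CCTGA" * 50, t)
        assert v[0] == 0 and v[1] == 0

    def test_coverage_in_unit_interval_and_deterministic(self, rng):
        t = coding.build_hexamer_table(["AAAAAA"], ["CCCCCC"])
        for _ in range(200):
            seq = _random_seq(rng, int(rng.integers(50, 500)))
            v1 = coding.extract_features(seq, t)
            v2 = coding.extract_features(seq, t)
            assert 0.0 <= v1[1] <= 1.0
            assert np.array_equal(v1, v2)


class TestClassifier:
    def _separable(self, rng, n=120):
        X0 = rng.normal(0, 1, size=(n, 6))
        X1 = rng.normal(8, 1, size=(n, 6))
        X = np.vstack([X0, X1])
        y = ["noncoding"] * n + ["coding"] * n
        return X, y

    def test_separable_data_perfect_heldout(self, rng):
        X, y = self._separable(rng)
        model = coding.train_classifier(X, y, seed=0)
        assert model.metadata["heldout_f1"] == 1.0
        assert len(model.metadata["cv_folds"]) == 10

    def test_permuted_labels_near_chance(self, rng):
        X, _ = self._separable(rng, n=150)
        y = list(rng.permutation(["coding", "noncoding"] * 150))
        model = coding.train_classifier(X, y, seed=1)
        acc = model.metadata["heldout_f1"]
        assert 0.2 <= acc <= 0.75  # chance-level with MC noise

    def test_same_seed_reproducible(self, rng):
        X, y = self._separable(rng)
        m1 = coding.train_classifier(X, y, seed=3)
        m2 = coding.train_classifier(X, y, seed=3)
        assert m1.metadata == m2.metadata

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(30, 6))
        with pytest.raises(ValueError):
            coding.train_classifier(X, ["coding"] * 30)

    def test_prediction_boundary_and_feature_order_check(self, rng):
        X, y = self._separable(rng)
        model = coding.train_classifier(X, y, seed=0)
        kept, removed, probs = coding.predict_noncoding(
            model, X[:5], [f"t{i}" for i in range(5)])
        assert set(kept) | set(removed) == {f"t{i}" for i in range(5)}
        with pytest.raises(ValueError, match="feature order"):
            coding.predict_noncoding(model, X[:2], ["a", "b"],
                                     feature_names=("x",) * 6)

    def test_empty_candidate_set(self, rng):
        X, y = self._separable(rng)
        model = coding.train_classifier(X, y, seed=0)
        assert coding.predict_noncoding(model, np.empty((0, 6)), []) == ([], {}, {})


class TestHomologyTriage:
    def _hit(self, q, cls, ev):
        return HomologyHit(q, "s", cls, ev, 50.0)

    def test_three_groups(self):
        hits = [self._hit("a", "coding_or_other", 1e-20),
                self._hit("b", "lncRNA", 1e-20)]
        groups = coding.triage_by_homology(["a", "b", "c"], hits)
        assert groups == {"a": 1, "b": 2, "c": 3}

    def test_weak_hit_is_no_match(self):
        groups = coding.triage_by_homology(
            ["a"], [self._hit("a", "coding_or_other", 1e-3)])
        assert groups == {"a": 3}

    def test_coding_match_dominates(self):
        hits = [self._hit("a", "lncRNA", 1e-30),
                self._hit("a", "coding_or_other", 1e-10)]
        assert coding.triage_by_homology(["a"], hits) == {"a": 1}

    def test_unknown_candidate_warns_and_ignored(self):
        with pytest.warns(UserWarning):
            groups = coding.triage_by_homology(
                ["a"], [self._hit("zzz", "lncRNA", 1e-20)])
        assert groups == {"a": 3}

    def test_naive_search_finds_planted_homolog(self):
        rng = np.random.default_rng(5)
        core = _random_seq(rng, 200)
        query = SequenceRecord("q", _random_seq(rng, 50) + core + _random_seq(rng, 50))
        subject = SequenceRecord("s", core)
        decoy = SequenceRecord("d", _random_seq(rng, 300))
        hits = coding.naive_search([query], [subject, decoy], {"s": "lncRNA"})
        best = min(hits, key=lambda h: h.evalue)
        assert best.subject_id == "s"
        assert best.evalue < 1e-5
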