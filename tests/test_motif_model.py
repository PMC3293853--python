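"""Unit and property tests for the information-theory site models."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from argbox import (SiteSet, build_site_matrix, make_tandem,
                    per_position_information, reverse_complement, rsequence,
                    scan, score_site)
from argbox.model import SCORE_FLOOR, InformationModel, small_sample_correction

from conftest import brute_force_scan, random_dna

dna = st.text(alphabet="ACGT", min_size=1, max_size=12)
site_sets = st.integers(2, 8).flatmap(
    lambda w: st.lists(st.text(alphabet="ACGT", min_size=w, max_size=w),
                       min_size=1, max_size=10))


class TestBuild:
    def test_perfectly_conserved_columns_score_two_bits(self):
        m = build_site_matrix(SiteSet(["AAAA", "AAAA"]), symmetrize=False,
                              pseudocount=0)
        assert np.allclose(m.riw[:, 0], 2.0)
        assert score_site(m, "AAAA") == pytest.approx(8.0)

    def test_uniform_columns_carry_no_information(self):
        m = build_site_matrix(SiteSet(["ACGT", "CGTA", "GTAC", "TACG"]),
                              symmetrize=False, pseudocount=0)
        assert np.allclose(m.riw, 0.0)
        assert score_site(m, "GGGG") == pytest.approx(0.0)

    def test_symmetrization_appends_complements(self):
        # {"AA"} + complements -> {"AA","TT"}: f(A)=f(T)=1/2 per column
        m = build_site_matrix(SiteSet(["AA"]), symmetrize=True, pseudocount=0)
        assert m.n_sites == 2
        assert m.riw[0, 0] == pytest.approx(1.0)   # A
        assert m.riw[0, 3] == pytest.approx(1.0)   # T
        assert score_site(m, "AA") == pytest.approx(2.0)

    def test_two_position_hand_example(self):
        # f(A,1)=1, f(C,2)=1/2 -> R_i("AC") = 2 + 1 = 3 bits
        m = build_site_matrix(SiteSet(["AC", "AG"]), symmetrize=False,
                              pseudocount=0)
        assert score_site(m, "AC") == pytest.approx(3.0)
        assert list(per_position_information(m)) == pytest.approx([2.0, 1.0])

    def test_zero_count_with_zero_pseudocount_hits_documented_floor(self):
        m = build_site_matrix(SiteSet(["AA"]), symmetrize=False, pseudocount=0)
        assert m.riw[0, 1] == SCORE_FLOOR
        assert math.isfinite(score_site(m, "CC"))

    def test_pseudocount_keeps_all_scores_finite_and_below_ceiling(self):
        m = build_site_matrix(SiteSet(["AAAA"] * 5), symmetrize=False,
                              pseudocount=0.5)
        assert np.all(np.isfinite(m.riw))
        assert np.all(m.riw < 2.0)

    def test_correction_subtracts_e_n_everywhere(self):
        s = SiteSet(["ACGT", "ACGT"])
        m0 = build_site_matrix(s, symmetrize=False, pseudocount=0)
        m1 = build_site_matrix(s, symmetrize=False, pseudocount=0,
                               correction=True)
        e = small_sample_correction(2)
        keep = m0.riw > SCORE_FLOOR
        assert np.allclose(m1.riw[keep], m0.riw[keep] - e)

    def test_genome_background_changes_scale(self):
        gc = 0.72
        bg = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
        m = build_site_matrix(SiteSet(["AAAA"] * 4), symmetrize=False,
                              pseudocount=0, background=bg)
        # a conserved AT base is worth more than 2 bits against a GC-rich bg
        assert m.riw[0, 0] == pytest.approx(-math.log2((1 - gc) / 2))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            SiteSet([])
        with pytest.raises(ValueError):
            SiteSet(["AC", "A"])
        with pytest.raises(ValueError):
            SiteSet(["AN"])
        with pytest.raises(ValueError):
            build_site_matrix(SiteSet(["AC"]), pseudocount=-1)
        m = build_site_matrix(SiteSet(["ACGT"]))
        with pytest.raises(ValueError):
            score_site(m, "ACG")
        with pytest.raises(ValueError):
            score_site(m, "ACGN")

    def test_ambiguity_neutral_policy_scores_zero_bits(self):
        m = build_site_matrix(SiteSet(["AAAA", "AAAA"]), symmetrize=False,
                              pseudocount=0)
        assert score_site(m, "AANA", ambiguity="neutral") == pytest.approx(6.0)

    @given(site_sets)
    def test_reverse_complement_symmetry_is_exact(self, sites):
        m = build_site_matrix(SiteSet(sites), symmetrize=True, pseudocount=0.5)
        # riw(b, l) == riw(comp(b), L+1-l): flip both axes
        assert np.array_equal(m.riw, m.riw[::-1, ::-1])

    @given(site_sets)
    def test_rsequence_equals_total_information_of_alignment(self, sites):
        ss = SiteSet(sites)
        m = build_site_matrix(ss, symmetrize=False, pseudocount=0)
        f = ss.counts() / len(ss)
        with np.errstate(divide="ignore", invalid="ignore"):
            h = -np.where(f > 0, f * np.log2(np.where(f > 0, f, 1)), 0).sum(1)
        assert rsequence(m, ss) == pytest.approx((2.0 - h).sum(), abs=1e-9)
        assert per_position_information(m).sum() == pytest.approx(
            (2.0 - h).sum(), abs=1e-9)


class TestTandem:
    def test_geometry_and_additivity(self):
        m = build_site_matrix(SiteSet(["A" * 18] * 2), symmetrize=False,
                              pseudocount=0)
        t = make_tandem(m, 2)
        assert t.width == 38
        window = "A" * 18 + "GC" + "A" * 18
        assert t.score(window) == pytest.approx(72.0)  # 36 + 0 + 36

    def test_zero_spacer_abuts_boxes(self):
        m = build_site_matrix(SiteSet(["ACG", "ACG"]), symmetrize=False,
                              pseudocount=0)
        t = make_tandem(m, 0)
        assert t.width == 6
        assert t.score("ACGACG") == pytest.approx(2 * score_site(m, "ACG"))

    def test_negative_spacer_rejected(self):
        m = build_site_matrix(SiteSet(["AC"]))
        with pytest.raises(ValueError):
            make_tandem(m, -1)

    def test_tandem_score_decomposes_on_random_sequences(self, rng):
        sites = SiteSet([random_dna(rng, 6) for _ in range(8)])
        m = build_site_matrix(sites, pseudocount=0.5)
        t = make_tandem(m, 3)
        seq = random_dna(rng, 300)
        for hit in scan(t, seq, -1e9, strands="+"):
            w = hit.window_seq
            expected = score_site(m, w[:6]) + score_site(m, w[-6:])
            assert hit.ri == pytest.approx(expected, abs=1e-9)


class TestScan:
    def _model(self, rng, width=8, n=10):
        return build_site_matrix(
            SiteSet([random_dna(rng, width) for _ in range(n)]),
            pseudocount=0.5)

    def test_sequence_shorter_than_model_yields_empty(self, rng):
        m = self._model(rng)
        assert scan(m, "ACGT", 0.0) == []

    def test_every_window_reported_at_minus_infinity_threshold(self, rng):
        m = self._model(rng)
        seq = random_dna(rng, 1000)
        hits = scan(m, seq, -1e9, strands="+")
        assert len(hits) == 1000 - m.width + 1

    @pytest.mark.parametrize("gc", [0.5, 0.72])
    @pytest.mark.parametrize("spacer", [None, 2])
    def test_scan_matches_brute_force_oracle(self, rng, gc, spacer):
        sites = SiteSet([random_dna(rng, 7) for _ in range(12)])
        m = build_site_matrix(sites, pseudocount=0.5)
        model = make_tandem(m, spacer) if spacer is not None else m
        for _ in range(10):
            seq = random_dna(rng, int(rng.integers(200, 2000)), gc)
            for threshold in (-5.0, 0.0, 3.0):
                got = [(h.offset, h.strand, h.ri)
                       for h in scan(model, seq, threshold)]
                want = brute_force_scan(m.riw, spacer, seq, threshold)
                assert [(o, s) for o, s, _ in got] == [(o, s)
                                                       for o, s, _ in want]
                for (_, _, a), (_, _, b) in zip(got, want):
                    assert a == pytest.approx(b, abs=1e-9)

    def test_hit_scores_equal_window_seq_rescoring(self, rng):
        m = self._model(rng)
        seq = random_dna(rng, 500)
        for h in scan(m, seq, -1e9):
            assert h.ri == pytest.approx(score_site(m, h.window_seq), abs=1e-9)

    def test_threshold_monotonicity(self, rng):
        m = self._model(rng)
        seq = random_dna(rng, 1500)
        keys = lambda hits: {(h.offset, h.strand) for h in hits}
        prev = keys(scan(m, seq, -10.0))
        for theta in (-5.0, 0.0, 2.0, 5.0):
            cur = keys(scan(m, seq, theta))
            assert cur <= prev
            prev = cur

    def test_symmetric_model_mirrors_hits_across_strands(self, rng):
        sites = SiteSet([random_dna(rng, 6) for _ in range(6)])
        m = build_site_matrix(sites, symmetrize=True, pseudocount=0.5)
        seq = random_dna(rng, 400)
        hits = scan(m, seq, -1e9)
        by_strand = {"+": {}, "-": {}}
        for h in hits:
            by_strand[h.strand][h.offset] = h.ri
        assert by_strand["+"].keys() == by_strand["-"].keys()
        for o in by_strand["+"]:
            assert by_strand["+"][o] == pytest.approx(by_strand["-"][o],
                                                      abs=1e-9)

    def test_dedupe_collapses_mirrored_hits_keeping_plus(self, rng):
        sites = SiteSet([random_dna(rng, 6) for _ in range(6)])
        m = build_site_matrix(sites, symmetrize=True, pseudocount=0.5)
        seq = random_dna(rng, 400)
        deduped = scan(m, seq, -1e9, dedupe=True)
        assert all(h.strand == "+" for h in deduped)
        assert len(deduped) == len(seq) - m.width + 1

    def test_windows_with_ambiguous_bases_are_skipped(self, rng):
        m = self._model(rng, width=4)
        seq = "ACGT" + "N" + "ACGT"
        offsets = {h.offset for h in scan(m, seq, -1e9)}
        assert offsets == {0, 5}

    def test_invalid_strand_selector(self, rng):
        m = self._model(rng)
        with pytest.raises(ValueError):
            scan(m, "ACGTACGTACGT", 0.0, strands="x")

    def test_no_window_reported_twice_per_strand(self, rng):
        m = self._model(rng)
        seq = random_dna(rng, 800)
        hits = scan(m, seq, -1e9)
        keys = [(h.offset, h.strand) for h in hits]
        assert len(keys) == len(set(keys))
        assert keys == sorted(keys)


class TestSerialization:
    def test_model_tsv_round_trip(self, tmp_path, rng):
        sites = SiteSet([random_dna(rng, 9) for _ in range(7)])
        m = build_site_matrix(sites, symmetrize=True, pseudocount=0.5,
                              correction=True, name="demo")
        path = tmp_path / "model.tsv"
        m.to_tsv(path)
        back = InformationModel.from_tsv(path)
        assert back.width == m.width
        assert back.n_sites == m.n_sites
        assert back.symmetrized and back.correction_enabled
        assert np.allclose(back.riw, m.riw, atol=1e-9)
        assert np.allclose(back.freqs, m.freqs, atol=1e-9)
        w = random_dna(rng, 9)
        assert back.score(w) == pytest.approx(m.score(w), abs=1e-8)

    @given(dna)
    def test_reverse_complement_involution(self, s):
        assert reverse_complement(reverse_complement(s)) == s
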