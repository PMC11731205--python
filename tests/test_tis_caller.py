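"""Candidate scanning, NB background fitting, tail test, BH control."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from tissense.io import TranscriptRecord
from tissense.psite import PSiteTrack
from tissense.tis_caller import (
    ATG_ONLY,
    NEAR_COGNATE_START_CODONS,
    BackgroundError,
    NBBackground,
    benjamini_hochberg,
    call_tis,
    find_candidates,
    fit_background,
)

from _oracles import nb_tail_by_summation


def _lnc(seq: str) -> TranscriptRecord:
    return TranscriptRecord("T", "G", "lncRNA", seq)


def _track(counts) -> PSiteTrack:
    return PSiteTrack("T", np.asarray(counts, dtype=np.int64))


class TestCandidates:
    def test_near_cognate_set_is_atg_plus_single_substitutions(self):
        assert "ATG" in NEAR_COGNATE_START_CODONS
        assert len(NEAR_COGNATE_START_CODONS) == 10
        for codon in NEAR_COGNATE_START_CODONS:
            assert sum(a != b for a, b in zip(codon, "ATG")) <= 1

    def test_all_zero_track_yields_no_candidates(self):
        rec = _lnc("ATGATGATGATG")
        assert find_candidates(_track([0] * 12), rec) == []

    def test_transcript_without_atg_yields_no_candidates(self):
        rec = _lnc("CCCCCCCCCCCC")
        assert find_candidates(_track([9] * 12), rec, codon_set=ATG_ONLY) == []

    def test_candidates_match_exhaustive_three_frame_scan(self, small_world, rng):
        tset, _ = small_world
        rec = next(iter(tset.values()))
        counts = rng.poisson(2.0, rec.length)
        track = PSiteTrack(rec.transcript_id, counts)
        found = find_candidates(track, rec, NEAR_COGNATE_START_CODONS, min_count=5)
        expected = []
        for i in range(rec.length - 2):
            if rec.sequence[i : i + 3] in NEAR_COGNATE_START_CODONS:
                s = int(counts[i] + counts[i + 1] + counts[i + 2])
                if s >= 5:
                    expected.append((i, s))
        assert [(c.position, c.psite_count) for c in found] == expected
        assert all(c.codon == rec.sequence[c.position : c.position + 3] for c in found)


class TestBackground:
    def test_constant_count_per_codon_gives_poisson_limit(self):
        rec_len = 120
        track = _track([0, 0, 4] * (rec_len // 3))  # 4 per codon, zero variance
        bg = fit_background(track, [], min_codons=10)
        assert bg.mu == 4.0 and bg.size is None  # Poisson limit

    def test_moment_estimates_match_direct_recomputation(self, rng):
        counts = rng.negative_binomial(2.0, 2.0 / 7.0, size=300)
        track = _track(counts)
        candidates = [10, 100, 200]
        bg = fit_background(track, candidates, exclusion_radius=1, min_codons=10)
        bins = counts[: 3 * (len(counts) // 3)].reshape(-1, 3).sum(axis=1)
        keep = np.ones(len(bins), dtype=bool)
        for pos in candidates:
            keep[max(0, pos // 3 - 1) : (pos + 2) // 3 + 2] = False
        mu, var = bins[keep].mean(), bins[keep].var(ddof=1)
        assert bg.mu == pytest.approx(mu)
        assert bg.size == pytest.approx(mu * mu / (var - mu))
        assert bg.n_codons == int(keep.sum())

    def test_background_unchanged_by_empty_candidate_list(self, rng):
        track = _track(rng.poisson(3.0, 150))
        assert fit_background(track, [], min_codons=10) == fit_background(
            track, np.array([], dtype=int), min_codons=10
        )

    def test_too_few_background_codons_raises(self):
        track = _track([1] * 30)
        with pytest.raises(BackgroundError, match="background codons"):
            fit_background(track, [15], min_codons=20)


class TestTailTest:
    def test_zero_count_has_pvalue_one(self):
        bg = NBBackground(mu=2.0, size=1.5, n_codons=50)
        assert float(bg.sf([0])[0]) == 1.0

    @pytest.mark.parametrize("mu", [0.2, 1.0, 5.0, 20.0])
    @pytest.mark.parametrize("size", [0.1, 1.0, 10.0])
    def test_tail_matches_brute_force_summation(self, mu, size):
        bg = NBBackground(mu=mu, size=size, n_codons=100)
        for x in (0, 1, 3, 10, 50):
            assert float(bg.sf([x])[0]) == pytest.approx(
                nb_tail_by_summation(x, mu, size), abs=1e-9
            )

    def test_pvalues_monotone_nonincreasing_in_count(self):
        bg = NBBackground(mu=3.0, size=2.0, n_codons=100)
        p = bg.sf(np.arange(0, 60))
        assert np.all(np.diff(p) <= 0)


class TestMultipleTesting:
    def test_single_pvalue_passes_through(self):
        assert benjamini_hochberg([0.03])[0] == pytest.approx(0.03)

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60)
    )
    def test_qvalues_match_reference_bh(self, pvals):
        ours = benjamini_hochberg(pvals)
        ref = multipletests(pvals, method="fdr_bh")[1]
        assert np.allclose(ours, ref)

    def test_wider_test_family_scales_qvalues(self):
        p = [0.001, 0.01]
        q = benjamini_hochberg(p, n_tests=100)
        # rank-1: 0.001*100/1 = 0.1; rank-2: 0.01*100/2 = 0.5
        assert q == pytest.approx([0.1, 0.5])
        with pytest.raises(ValueError):
            benjamini_hochberg(p, n_tests=1)

    def test_call_tis_flags_exactly_q_below_alpha(self):
        from tissense.tis_caller import TISCandidate

        cands = [
            TISCandidate("T", i, "ATG", 10, p_value=p)
            for i, p in enumerate([1e-6, 0.02, 0.2, 0.9])
        ]
        sig = call_tis(cands, alpha=0.05)
        assert [c.position for c in sig] == [0, 1]
        assert all((c.q_value < 0.05) == c.significant for c in cands)
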