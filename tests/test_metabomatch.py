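"""Tests of pseudo-spectrum construction and χ² peak-set compound matching."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nmrgwas.metabomatch import (
    MatchResult,
    PseudoSpectrum,
    ReferenceSpectrum,
    map_peaks,
    prune_correlated,
    pseudo_spectrum,
    rank_library,
    rank_pairs,
    score_metabolite,
    score_pair,
)


def make_ps(labels, z):
    z = np.asarray(z, dtype=float)
    p = 2 * stats.norm.sf(np.abs(z))
    tab = pd.DataFrame(
        {"feature_ppm": np.asarray(labels, float), "z": z,
         "minus_log10_p": -np.log10(np.clip(p, 1e-320, 1))}
    )
    return PseudoSpectrum(snp_id="rs1", table=tab)


def identity_r2(labels):
    labels = np.asarray(labels, float)
    return pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)


class TestPseudoSpectrum:
    def test_flat_when_all_p_one(self):
        rec = pd.DataFrame(
            {"snp_id": "rs1", "feature_label": [1.0, 2.0], "z": [0.0, 0.0], "p": [1.0, 1.0]}
        )
        ps = pseudo_spectrum(rec)
        assert np.allclose(ps.table["minus_log10_p"], 0.0)

    def test_minus_log10_transform(self):
        rec = pd.DataFrame(
            {"snp_id": "rs1", "feature_label": [1.0], "z": [2.58], "p": [0.01]}
        )
        assert pseudo_spectrum(rec).table["minus_log10_p"].iloc[0] == pytest.approx(2.0)

    def test_duplicate_feature_labels_error(self):
        rec = pd.DataFrame(
            {"snp_id": "rs1", "feature_label": [1.0, 1.0], "z": [1, 2], "p": [0.5, 0.5]}
        )
        with pytest.raises(ValueError, match="duplicate"):
            pseudo_spectrum(rec)

    def test_tsv_round_trip_lossless(self, tmp_path):
        ps = make_ps([1.0, 1.5, 2.0], [0.3, -2.2, 4.1])
        path = tmp_path / "ps.tsv"
        ps.to_tsv(path)
        back = PseudoSpectrum.from_tsv(path, snp_id="rs1")
        pd.testing.assert_frame_equal(ps.table, back.table, rtol=1e-9)

    def test_gap_flagging(self):
        rec = pd.DataFrame(
            {"snp_id": "rs1", "feature_label": [1.0], "z": [1.0], "p": [0.3]}
        )
        ps = pseudo_spectrum(rec, all_features=[1.0, 2.0])
        assert ps.gaps == [2.0]


class TestMapPeaks:
    def test_peak_at_bin_center(self):
        ref = ReferenceSpectrum("m", "m", peaks=((1.2025, 1.0),))
        idx, un = map_peaks(ref, [1.1975, 1.2025, 1.2075])
        assert list(idx) == [1] and un == 0

    def test_midpoint_resolves_to_lower_ppm(self):
        ref = ReferenceSpectrum("m", "m", peaks=((1.5, 1.0),))
        idx, _ = map_peaks(ref, [1.49, 1.51])
        assert list(idx) == [0]

    def test_fucose_peaks_map_to_their_bins(self):
        # four anomeric/methyl fucose resonances on a 0.005-ppm grid
        labels = np.round(np.arange(0.5, 9.5, 0.005) + 0.0025, 4)
        ref = ReferenceSpectrum(
            "fucose", "fucose",
            peaks=((1.2575, 1.0), (5.2125, 0.4), (5.2275, 0.4), (5.2825, 0.3)),
        )
        idx, un = map_peaks(ref, labels)
        assert un == 0
        assert [labels[i] for i in idx] == [1.2575, 5.2125, 5.2275, 5.2825]

    def test_peaks_sharing_a_bin_collapse(self):
        ref = ReferenceSpectrum("m", "m", peaks=((1.2024, 1.0), (1.2026, 0.5)))
        idx, _ = map_peaks(ref, [1.2025])
        assert list(idx) == [0]

    def test_out_of_tolerance_peaks_dropped(self):
        ref = ReferenceSpectrum("m", "m", peaks=((3.0, 1.0), (1.2, 0.5)))
        idx, un = map_peaks(ref, [1.2025], tolerance=0.02)
        assert list(idx) == [0] and un == 1


class TestPruneCorrelated:
    def test_uncorrelated_features_all_kept(self):
        labels = [1.0, 2.0, 3.0]
        kept = prune_correlated(
            np.array([0, 1, 2]), np.array([1.0, 2.0, 3.0]), identity_r2(labels), labels
        )
        assert list(kept) == [0, 1, 2]

    def test_perfectly_correlated_pair_keeps_larger_z(self):
        labels = [1.0, 2.0]
        r2 = pd.DataFrame([[1.0, 1.0], [1.0, 1.0]], index=labels, columns=labels)
        kept = prune_correlated(np.array([0, 1]), np.array([1.0, -3.0]), r2, labels)
        assert list(kept) == [1]

    def test_matches_brute_force_greedy_oracle(self):
        rng = np.random.default_rng(3)
        labels = [1.0, 2.0, 3.0, 4.0, 5.0]
        for _ in range(30):
            z = rng.normal(size=5)
            M = rng.random((5, 5))
            r2 = (M + M.T) / 2
            np.fill_diagonal(r2, 1.0)
            r2df = pd.DataFrame(r2, index=labels, columns=labels)

            # oracle: explicit greedy max-|z| independent set
            remaining = list(range(5))
            kept = []
            while remaining:
                best = max(remaining, key=lambda i: (abs(z[i]), -labels[i]))
                kept.append(best)
                remaining = [
                    i for i in remaining if i != best and not (r2[best, i] > 0.4)
                ]
            got = prune_correlated(np.arange(5), z, r2df, labels)
            assert sorted(kept) == list(got)


class TestScoring:
    def test_single_zero_statistic(self):
        ps = make_ps([1.0], [0.0])
        ref = ReferenceSpectrum("m", "m", peaks=((1.0, 1.0),))
        res = score_metabolite(ps, ref, identity_r2([1.0]))
        assert res.k == 1 and res.score == 0.0 and res.p == 1.0

    def test_chi2_2_closed_form(self):
        # k=2 with z=(2,2): score 8, χ²₂ survival = exp(-4)
        ps = make_ps([1.0, 2.0], [2.0, 2.0])
        ref = ReferenceSpectrum("m", "m", peaks=((1.0, 1.0), (2.0, 0.5)))
        res = score_metabolite(ps, ref, identity_r2([1.0, 2.0]))
        assert res.k == 2 and res.score == pytest.approx(8.0)
        assert res.p == pytest.approx(np.exp(-4.0), rel=1e-12)

    def test_chi2_3_against_monte_carlo_oracle(self):
        ps = make_ps([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        ref = ReferenceSpectrum("m", "m", peaks=((1.0, 1.0), (2.0, 1.0), (3.0, 1.0)))
        res = score_metabolite(ps, ref, identity_r2([1.0, 2.0, 3.0]))
        assert res.k == 3 and res.score == pytest.approx(14.0)
        # frozen from a 1e6-draw simulation of sum of 3 squared normals:
        # mean(draws >= 14) = 0.00284 (SE 5.3e-5); chi2.sf(14,3) = 0.002905
        assert res.p == pytest.approx(0.00284, abs=3 * 5.3e-5)
        rng = np.random.default_rng(12345)
        draws = rng.normal(size=(10**6, 3))
        mc = (np.sum(draws**2, axis=1) >= 14.0).mean()
        assert res.p == pytest.approx(mc, abs=3 * 5.3e-5)

    def test_unmatched_metabolite_is_unscorable(self):
        ps = make_ps([1.0], [2.0])
        ref = ReferenceSpectrum("m", "m", peaks=((8.0, 1.0),))
        res = score_metabolite(ps, ref, identity_r2([1.0]))
        assert not res.scorable

    def test_score_invariant_to_peak_order(self):
        labels = [1.0, 2.0, 3.0]
        ps = make_ps(labels, [1.0, -2.0, 0.5])
        peaks = [(1.0, 1.0), (2.0, 0.5), (3.0, 0.2)]
        r2 = identity_r2(labels)
        scores = set()
        import itertools

        for perm in itertools.permutations(peaks):
            ref = ReferenceSpectrum("m", "m", peaks=tuple(perm))
            scores.add(round(score_metabolite(ps, ref, r2).score, 12))
        assert len(scores) == 1

    def test_extra_zero_peak_increases_p(self):
        # adding a peak matching a z=0 feature keeps the score but adds a
        # degree of freedom, so the match becomes less significant
        labels = [1.0, 2.0]
        ps = make_ps(labels, [3.0, 0.0])
        r2 = identity_r2(labels)
        r1 = score_metabolite(ps, ReferenceSpectrum("m", "m", peaks=((1.0, 1.0),)), r2)
        r2_ = score_metabolite(
            ps, ReferenceSpectrum("m", "m", peaks=((1.0, 1.0), (2.0, 1.0))), r2
        )
        assert r2_.score == pytest.approx(r1.score)
        assert r2_.p > r1.p


class TestRanking:
    def test_tie_rule_on_flat_pseudospectrum(self):
        labels = [1.0, 2.0]
        ps = make_ps(labels, [1.0, 1.0])
        lib = [
            ReferenceSpectrum("b", "b", peaks=((2.0, 1.0),)),
            ReferenceSpectrum("a", "a", peaks=((1.0, 1.0),)),
        ]
        out = rank_library(ps, lib, identity_r2(labels))
        # identical p and score: tie broken by metabolite id
        assert list(out["metabolite_id"]) == ["a", "b"]
        assert list(out["rank"]) == [1, 2]

    def test_empty_library_errors(self):
        with pytest.raises(ValueError):
            rank_library(make_ps([1.0], [1.0]), [], identity_r2([1.0]))

    def test_percentile_ranks(self):
        labels = [1.0, 2.0, 3.0, 4.0]
        ps = make_ps(labels, [5.0, 1.0, 0.5, 0.1])
        lib = [
            ReferenceSpectrum(f"m{i}", f"m{i}", peaks=((labels[i], 1.0),))
            for i in range(4)
        ]
        out = rank_library(ps, lib, identity_r2(labels))
        assert out["percentile"].iloc[0] == pytest.approx(25.0)
        assert out["metabolite_id"].iloc[0] == "m0"


class TestScorePair:
    def test_self_pair_equals_single(self):
        labels = [1.0, 2.0]
        ps = make_ps(labels, [2.0, 1.0])
        ref = ReferenceSpectrum("m", "m", peaks=((1.0, 1.0), (2.0, 0.5)))
        r2 = identity_r2(labels)
        single = score_metabolite(ps, ref, r2)
        pair = score_pair(ps, ref, ref, r2)
        assert pair.k == single.k and pair.score == pytest.approx(single.score)

    def test_disjoint_single_peak_compounds_add(self):
        labels = [1.0, 2.0]
        ps = make_ps(labels, [2.0, 2.0])
        a = ReferenceSpectrum("a", "a", peaks=((1.0, 1.0),))
        b = ReferenceSpectrum("b", "b", peaks=((2.0, 1.0),))
        res = score_pair(ps, a, b, identity_r2(labels))
        assert res.k == 2 and res.score == pytest.approx(8.0)

    def test_anchor_mode_ranks_true_pair_first(self):
        # a SNP driving two single-peak compounds: the true partner should
        # rank first among anchor pairs
        rng = np.random.default_rng(5)
        labels = np.round(np.linspace(1.0, 5.0, 40), 4)
        z = rng.normal(0, 1, size=40)
        z[3] = 6.0   # anchor compound peak
        z[20] = 5.5  # true partner peak
        ps = make_ps(labels, z)
        lib = [
            ReferenceSpectrum(f"m{i:02d}", f"m{i:02d}", peaks=((float(labels[i]), 1.0),))
            for i in range(40)
        ]
        out = rank_pairs(ps, lib, identity_r2(labels), anchor_id="m03")
        assert out["metabolite_id"].iloc[0] == "m03+m20"
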