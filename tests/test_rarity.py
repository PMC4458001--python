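import numpy as np
import pandas as pd
import pytest

import heritagescan as hs

from conftest import make_panel


class TestMarkerScores:
    @pytest.mark.parametrize(
        "x,p,expected",
        [(2, 0.1, 1.8 / np.sqrt(0.18)), (1, 0.5, 0.0), (0, 0.5, -np.sqrt(2))],
    )
    def test_individual_score_hand_values(self, x, p, expected):
        assert hs.individual_marker_score(x, p) == pytest.approx(expected, abs=1e-4)

    def test_individual_score_undefined_outside_open_interval(self):
        assert np.isnan(hs.individual_marker_score(1, 0.0))
        assert np.isnan(hs.individual_marker_score(1, 1.0))

    def test_pair_score_hand_values(self):
        assert hs.pair_marker_score(2, 2, 0.1) == pytest.approx(18.0)
        assert hs.pair_marker_score(1, 2, 0.5) == pytest.approx(0.0)

    def test_pair_equals_product_of_individual_scores(self):
        doses = [0.0, 1.0, 2.0]
        ps = np.linspace(0.01, 0.99, 25)
        for xj in doses:
            for xk in doses:
                lhs = hs.pair_marker_score(xj, xk, ps)
                rhs = hs.individual_marker_score(xj, ps) * hs.individual_marker_score(xk, ps)
                np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_mean_pair_score_equals_grm_offdiagonal(self, rng):
        doses = rng.integers(0, 3, size=(10, 400)).astype(float)
        panel = make_panel(doses)
        freqs = hs.compute_freqs(panel)
        grm = hs.compute_grm(panel, maf_window=None)
        ok = (freqs.freq > 0) & (freqs.freq < 1)
        for j, k in [(0, 1), (2, 7), (4, 9)]:
            scores = hs.pair_marker_score(doses[j, ok], doses[k, ok], freqs.freq[ok])
            assert scores.mean() == pytest.approx(grm.matrix[j, k], abs=1e-10)


class TestRarityScore:
    def test_hand_example(self):
        total, terms = hs.rarity_score([1, 2, 0], [0.01, 0.05, 0.001])
        np.testing.assert_allclose(terms, [100.0, 10.0, 0.0])
        assert total == pytest.approx(110.0)

    def test_all_zero_doses_score_zero(self):
        total, terms = hs.rarity_score([0, 0, 0], [0.1, 0.2, 0.3])
        assert total == 0.0

    def test_selection_boundary_frequency(self):
        # a single-copy allele reaches the selection cutoff of 2,500 exactly
        # at p = 0.0004
        _, terms = hs.rarity_score([1], [0.0004])
        assert terms[0] == pytest.approx(2500.0)
        _, above = hs.rarity_score([1], [0.00041])
        assert above[0] < 2500.0

    def test_external_zero_frequency_with_carried_allele_raises(self):
        with pytest.raises(ValueError):
            hs.rarity_terms([1, 0], [0.0, 0.5], external_freqs=True)

    def test_monotone_in_frequency_and_dose(self):
        ps = np.linspace(0.001, 0.5, 50)
        for x in (1.0, 2.0):
            t = hs.rarity_terms(np.full(50, x), ps)
            assert (np.diff(t) < 0).all()
        for p in (0.01, 0.1):
            t1 = hs.rarity_terms([1.0], [p])[0]
            t2 = hs.rarity_terms([2.0], [p])[0]
            assert t2 < t1


class TestWindowRarity:
    def test_single_spike_window_mean(self):
        terms = np.zeros(50)
        terms[13] = 5_000.0
        win = hs.window_rarity(terms, np.ones(50), np.arange(1, 51))
        assert len(win) == 1
        assert win.loc[0, "mean_score"] == pytest.approx(100.0)

    def test_boundary_term_is_not_a_peak(self):
        # one term of exactly 2,500 gives a window mean of exactly 50,
        # which does not exceed the strict threshold
        terms = np.zeros(50)
        terms[0] = 2_500.0
        win = hs.window_rarity(terms, np.ones(50), np.arange(1, 51))
        assert win.loc[0, "mean_score"] == pytest.approx(50.0)
        assert hs.call_rare_peaks(win, threshold=50.0) == []

    def test_matches_brute_force_slicing(self, rng):
        terms = rng.exponential(5.0, size=487)
        chroms = np.repeat([1, 2, 3], [200, 150, 137])
        pos = np.concatenate([np.arange(1, 201), np.arange(1, 151), np.arange(1, 138)])
        win = hs.window_rarity(terms, chroms, pos, window=50)
        i = 0
        for c, size in [(1, 200), (2, 150), (3, 137)]:
            block = terms[np.flatnonzero(chroms == c)]
            for s in range(0, size, 50):
                sl = block[s : s + 50]
                assert win.loc[i, "mean_score"] == pytest.approx(sl.sum() / sl.size)
                assert bool(win.loc[i, "partial"]) == (sl.size < 50)
                i += 1

    def test_chromosome_smaller_than_window_is_single_partial(self):
        win = hs.window_rarity(np.ones(7), np.ones(7), np.arange(1, 8))
        assert len(win) == 1 and bool(win.loc[0, "partial"])


def _window_frame(means, chrom=1, window0=0):
    n = len(means)
    return pd.DataFrame(
        {
            "window": np.arange(window0, window0 + n),
            "chrom": chrom,
            "start_bp": np.arange(n) * 1000 + 1,
            "end_bp": np.arange(n) * 1000 + 900,
            "n_markers": 50,
            "mean_score": means,
            "partial": False,
        }
    )


def peak_oracle(flags, max_gap):
    """Independent interval-merging oracle over hot-window flags."""
    hot = [i for i, f in enumerate(flags) if f]
    if not hot:
        return []
    merged = [[hot[0], hot[0]]]
    for i in hot[1:]:
        if i - merged[-1][1] - 1 < max_gap:
            merged[-1][1] = i
        else:
            merged.append([i, i])
    return [tuple(m) for m in merged]


class TestPeakCalling:
    def test_nine_intervening_windows_merge(self):
        means = [60.0] + [1.0] * 9 + [60.0]
        peaks = hs.call_rare_peaks(_window_frame(means), threshold=50)
        assert len(peaks) == 1
        assert peaks[0].n_windows == 11

    def test_ten_intervening_windows_split(self):
        means = [60.0] + [1.0] * 10 + [60.0]
        peaks = hs.call_rare_peaks(_window_frame(means), threshold=50)
        assert len(peaks) == 2
        assert all(p.n_windows == 1 for p in peaks)

    def test_no_window_above_threshold(self):
        assert hs.call_rare_peaks(_window_frame([10.0] * 30), threshold=50) == []

    def test_peaks_never_span_chromosomes(self):
        w1 = _window_frame([60.0, 60.0], chrom=1, window0=0)
        w2 = _window_frame([60.0], chrom=2, window0=2)
        peaks = hs.call_rare_peaks(pd.concat([w1, w2], ignore_index=True), threshold=50)
        assert [p.chrom for p in peaks] == [1, 2]

    def test_coordinates_span_member_windows(self):
        means = [60.0, 1.0, 60.0]
        peaks = hs.call_rare_peaks(_window_frame(means), threshold=50)
        assert peaks[0].start_bp == 1
        assert peaks[0].end_bp == 2 * 1000 + 900

    def test_short_partial_window_cannot_seed(self):
        frame = _window_frame([60.0])
        frame.loc[0, ["partial", "n_markers"]] = [True, 5]
        assert hs.call_rare_peaks(frame, threshold=50) == []

    def test_partial_window_seeds_on_mass_not_mean(self):
        # 25-marker trailing window: mean 60 but mass 1500 (< 50 * 50)
        frame = _window_frame([60.0])
        frame.loc[0, ["partial", "n_markers"]] = [True, 25]
        assert hs.call_rare_peaks(frame, threshold=50, window=50) == []
        frame.loc[0, "mean_score"] = 120.0  # mass 3000 > 2500
        assert len(hs.call_rare_peaks(frame, threshold=50, window=50)) == 1

    def test_equals_interval_merging_oracle_on_random_tracks(self, rng):
        for _ in range(1_000):
            n = int(rng.integers(1, 60))
            means = np.where(rng.random(n) < 0.25, 60.0, 1.0)
            peaks = hs.call_rare_peaks(_window_frame(list(means)), threshold=50)
            expected = peak_oracle(means > 50, max_gap=10)
            assert [(p.first_window, p.last_window) for p in peaks] == expected


class TestOutlierClassification:
    def _profiles(self, coverages):
        out = []
        for i, cov in enumerate(coverages):
            peaks = []
            if cov:
                peaks = [hs.RarePeak(f"s{i}", 1, 1, int(cov), 0, 0, 1, 99.0)]
            out.append(hs.RarityProfile(sample=f"s{i}", total_score=0.0, peaks=peaks))
        return out

    def test_direct_arithmetic_on_coverage_vector(self):
        cov = [0, 0, 0, 0, 100_000_000]
        profiles, _ = hs.classify_rarity_outliers(self._profiles(cov))
        c = np.array([0, 0, 0, 0, 1e8])
        expected = 1e8 > c.mean() + 3 * c.std()
        assert profiles[-1].outlier == expected

    def test_equal_coverages_flag_nobody(self):
        profiles, summary = hs.classify_rarity_outliers(self._profiles([5_000] * 6))
        assert not any(p.outlier for p in profiles)
        assert summary[summary["group"] == "outliers"]["n_peaks"].isna().all()

    def test_summary_layout(self):
        profiles, summary = hs.classify_rarity_outliers(
            self._profiles([0] * 11 + [1_000_000, 200_000_000])
        )
        assert set(summary["group"]) == {"non-outliers", "outliers"}
        assert set(summary["statistic"]) == {"mean", "max", "min"}
        mean_out = summary.query("group == 'outliers' and statistic == 'mean'").iloc[0]
        assert mean_out["coverage_mb"] == pytest.approx(200.0)

    def test_fewer_than_two_samples_raises(self):
        with pytest.raises(ValueError):
            hs.classify_rarity_outliers(self._profiles([0]))


class TestOriginAssignment:
    def test_argmax_and_unknown(self, rng):
        doses = np.zeros((4, 3))
        doses[0, :] = 1.0  # sample 0 carries the rare allele at all markers
        panel = make_panel(doses)
        ref = pd.DataFrame(
            {"A": [0.15, 0.001], "B": [0.001, 0.2], "C": [0.0005, 0.01]},
            index=["m0", "m1"],
        )
        out = hs.assign_allele_origin(panel, ref, score_cutoff=2.0)
        out = out.set_index("marker")
        assert out.loc["m0", "origin"] == "A"
        assert out.loc["m1", "origin"] == "B"
        assert out.loc["m2", "origin"] == "unknown"

    def test_no_marker_above_cutoff_empty(self, rng):
        panel = make_panel(rng.binomial(2, 0.5, size=(20, 5)).astype(float))
        ref = pd.DataFrame({"A": np.full(5, 0.5)}, index=[f"m{i}" for i in range(5)])
        out = hs.assign_allele_origin(panel, ref, score_cutoff=2_500.0)
        assert out.empty


class TestCopyNumberCutoffs:
    def test_reference_cohort_scale_reproduces_published_cutoff(self):
        # at the 9,889-sample scale the 8-copy marker cutoff is ~2,500,
        # equivalently p <= 0.0004
        cutoff, _ = hs.copy_number_cutoffs(9_889)
        assert cutoff == pytest.approx(2_500, rel=0.02)
        assert 1.0 / cutoff == pytest.approx(0.0004, rel=0.02)
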