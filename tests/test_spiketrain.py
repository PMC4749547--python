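"""Interspike-interval statistics, group summaries, and comparisons."""

from __future__ import annotations

import numpy as np
import pytest

from dystmap.spiketrain import (
    REFERENCE_FIRING_TABLE,
    SpikeTrain,
    average_firing_rate,
    compare_groups,
    compute_isi_stats,
    cv_isi,
    fold_ratios,
    mode_isi,
    predominant_firing_rate,
    reference_summary_frame,
    summarize_groups,
)
from dystmap.simulate.spikes import simulate_cohort

from .oracles import ks_permutation_p, mw_permutation_p


def _train(times, duration, **kw):
    base = dict(cell_id="c", cell_class="DCN", genotype="WT",
                posture_state="none")
    base.update(kw)
    return SpikeTrain(times=np.asarray(times, float), duration=duration, **base)


class TestAverageRate:
    def test_count_over_time(self):
        assert average_firing_rate(_train(np.linspace(0.1, 1.9, 10), 2.0)) == 5.0

    def test_empty_train_is_zero(self):
        assert average_firing_rate(_train([], 2.0)) == 0.0

    def test_poisson_rate_recovered(self):
        rng = np.random.default_rng(0)
        times = np.cumsum(rng.exponential(1 / 50.0, size=40_000))
        times = times[times < 600.0]
        est = average_firing_rate(_train(times, 600.0))
        assert abs(est - 50.0) < 3 * np.sqrt(50.0 / 600.0)


class TestPredominantRate:
    def test_periodic_train_within_one_bin(self):
        times = np.arange(1, 101) * 0.1
        pf = predominant_firing_rate(_train(times, 11.0))
        assert abs(1 / pf - 0.1) <= 0.001  # one bin of quantization

    def test_burst_dominated_mode_is_the_intra_burst_bin(self):
        """Mode known by construction: intra-burst ISIs in the 5-6 ms bin
        dominate sparse long ISIs."""
        t, times = 0.0, []
        for _ in range(50):
            for k in range(8):
                times.append(t)
                t += 0.0052
            t += 0.35
        pf = predominant_firing_rate(_train(np.array(times), t + 1))
        assert mode_isi(_train(np.array(times), t + 1)) == pytest.approx(0.0055)
        assert pf == pytest.approx(1 / 0.0055)
        assert abs(1 / pf - 0.0052) <= 0.001

    def test_tie_broken_toward_shortest_isi(self):
        # equal counts in the 5-6 ms and 100-101 ms bins
        isis = [0.0055] * 5 + [0.1005] * 5
        times = np.concatenate([[0.0], np.cumsum(isis)])
        assert mode_isi(_train(times, 1.0)) == pytest.approx(0.0055)

    def test_requires_two_spikes(self):
        with pytest.raises(ValueError):
            predominant_firing_rate(_train([0.5], 1.0))


class TestCvIsi:
    def test_periodic_is_zero(self):
        assert cv_isi(_train(np.arange(1, 50) * 0.02, 1.0)) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_hand_computed_example(self):
        # ISIs 100, 100, 200 ms: sample SD 57.735 / mean 133.333 = 0.433
        times = np.array([0.0, 0.1, 0.2, 0.4])
        assert cv_isi(_train(times, 0.5)) == pytest.approx(0.433, abs=5e-4)

    def test_long_poisson_train_near_one(self):
        rng = np.random.default_rng(1)
        times = np.cumsum(rng.exponential(0.02, size=30_000))
        times = times[times < 500]
        assert abs(cv_isi(_train(times, 500.0)) - 1.0) < 0.05

    def test_requires_three_spikes(self):
        with pytest.raises(ValueError):
            cv_isi(_train([0.1, 0.2], 1.0))


def test_time_rescaling_invariance():
    """Scaling times, duration, and bin width by c scales rates by 1/c and
    leaves CV ISI unchanged."""
    rng = np.random.default_rng(5)
    times = np.sort(rng.uniform(0, 60, size=800))
    times = times[np.concatenate([[True], np.diff(times) > 1e-5])]
    a = _train(times, 60.0)
    c = 3.7
    b = _train(times * c, 60.0 * c)
    assert average_firing_rate(b) == pytest.approx(average_firing_rate(a) / c)
    pf_a = predominant_firing_rate(a, bin_width=0.001, max_isi=1.0)
    pf_b = predominant_firing_rate(b, bin_width=0.001 * c, max_isi=1.0 * c)
    assert pf_b == pytest.approx(pf_a / c)
    assert cv_isi(b) == pytest.approx(cv_isi(a))


class TestSummaries:
    def test_reference_fixture_reemitted_identically(self):
        frame = reference_summary_frame()
        for (cc, grp), d in REFERENCE_FIRING_TABLE.items():
            row = frame[(frame.cell_class == cc) & (frame.group == grp)].iloc[0]
            assert row["n_cells"] == d["n"]
            for col in ("average_fr", "predominant_fr", "cv_isi"):
                assert row[f"{col}_mean"] == d[col][0]
                assert row[f"{col}_sem"] == d[col][1]

    def test_sem_equals_sd_over_sqrt_n_by_brute_force(self):
        trains = simulate_cohort("DCN", "WT", n_cells=12, seed=8)
        summary = summarize_groups(trains)
        row = summary[(summary.cell_class == "DCN")
                      & (summary.group == "WT")].iloc[0]
        vals = np.array([
            compute_isi_stats(t).predominant_fr for t in trains
        ])
        assert row["predominant_fr_mean"] == pytest.approx(vals.mean())
        assert row["predominant_fr_sem"] == pytest.approx(
            np.std(vals, ddof=1) / np.sqrt(len(vals))
        )

    def test_low_spike_cells_flagged_and_excluded(self):
        good = simulate_cohort("DCN", "WT", n_cells=3, seed=2)
        sparse = _train([0.1, 0.5, 0.9], 60.0, cell_id="sparse",
                        genotype="WT", posture_state="none")
        summary = summarize_groups(good + [sparse])
        row = summary[(summary.cell_class == "DCN")
                      & (summary.group == "WT")].iloc[0]
        assert row["n_cells"] == 3

    def test_empty_cohort_is_an_error(self):
        with pytest.raises(ValueError):
            summarize_groups([])


class TestCompareGroups:
    def test_identical_samples(self):
        d, p = compare_groups([1, 2, 3], [1, 2, 3], method="ks")
        assert d == 0.0 and p == 1.0

    def test_fully_separated_samples_have_d_one(self):
        d, _ = compare_groups([1, 2, 3], [4, 5, 6], method="ks")
        assert d == 1.0

    @pytest.mark.parametrize("method,oracle", [
        ("ks", ks_permutation_p), ("mw", mw_permutation_p),
    ])
    def test_small_sample_p_matches_permutation_enumeration(self, method, oracle):
        rng = np.random.default_rng(4)
        for _ in range(6):
            na, nb = rng.integers(3, 9, size=2)
            a = np.round(rng.normal(0, 1, size=na), 3)
            b = np.round(rng.normal(0.8, 1, size=nb), 3)
            if np.unique(np.concatenate([a, b])).size < na + nb:
                continue
            _, p = compare_groups(a, b, method=method)
            assert p == pytest.approx(oracle(a, b), abs=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([], [1.0], method="ks")


class TestFoldRatios:
    def test_published_means_exceed_stated_folds(self):
        folds = fold_ratios(reference_summary_frame())
        dcn = folds[(folds.cell_class == "DCN")
                    & (folds.statistic_name == "predominant_fr")]
        ratios = {r.comparison: r.ratio for r in dcn.itertuples()}
        assert ratios["vs_WT"] == pytest.approx(221.9 / 61.0)
        assert ratios["vs_WT"] >= 3.0
        assert ratios["vs_no_posture"] == pytest.approx(221.9 / 110.1)
        assert ratios["vs_no_posture"] >= 2.0

    def test_identical_group_means_give_unit_ratios(self):
        frame = reference_summary_frame()
        for col in ("average_fr_mean", "predominant_fr_mean", "cv_isi_mean"):
            frame[col] = 7.0
        folds = fold_ratios(frame)
        assert np.allclose(folds["ratio"], 1.0)

    def test_missing_group_is_an_error(self):
        frame = reference_summary_frame()
        frame = frame[frame.group != "WT"]
        with pytest.raises(ValueError):
            fold_ratios(frame)


def test_across_seed_stability_of_group_means():
    """Across-seed spread of cohort means is comparable to the published
    SEMs at the recorded group sizes."""
    means = []
    for seed in range(5):
        trains = simulate_cohort("DCN", "mutant_abnormal", seed=seed)
        summary = summarize_groups(trains)
        row = summary[(summary.cell_class == "DCN")
                      & (summary.group == "mutant_abnormal")].iloc[0]
        means.append(row["predominant_fr_mean"])
    sem_published = REFERENCE_FIRING_TABLE[("DCN", "mutant_abnormal")][
        "predominant_fr"][1]
    assert np.std(means, ddof=1) < 3 * sem_published
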