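"""Cross-validation planning, condition counts, spectra and statistics."""

import numpy as np
import pandas as pd
import pytest

from conftest import balanced_windowset, make_windowset
from eegaug.containers import EEGError
from eegaug.crossval import (
    AugmentationCondition,
    build_training_set,
    make_fold_plan,
)
from eegaug.spectral import (
    band_power,
    band_power_table,
    match_synthetic_units,
    periodogram,
    subject_mean_spectrum,
)
from eegaug.stats import anova_two_way, one_sided_ttest, summarize


def _subjects(n_per_group):
    out = {}
    for g, n in (("HC", n_per_group), ("MDD", n_per_group)):
        for i in range(n):
            out[f"{g.lower()}{i:03d}"] = g
    return out


class TestFoldPlan:
    def test_24_plus_24_subjects_gives_24_folds_of_46_train(self):
        plan = make_fold_plan(_subjects(24))
        assert len(plan.folds) == 24
        for fold in plan.folds:
            assert len(fold.train) == 46
            assert len(set(fold.test) & set(fold.train)) == 0
        # every subject tests exactly once
        tested = [s for f in plan.folds for s in f.test]
        assert len(tested) == len(set(tested)) == 48

    def test_smallest_valid_case(self):
        plan = make_fold_plan(_subjects(2))
        assert len(plan.folds) == 2
        assert all(len(f.train) == 2 for f in plan.folds)

    def test_unbalanced_groups_rejected(self):
        subs = _subjects(3)
        subs["mdd999"] = "MDD"
        with pytest.raises(EEGError):
            make_fold_plan(subs)


class TestConditionCounts:
    """Frame-count accounting of the five augmentation-ratio conditions
    on the printed full-scale design: 24+24 subjects, 18 windows each."""

    @pytest.fixture
    def design(self):
        rng = np.random.default_rng(0)
        real = balanced_windowset(rng, 24, 18, channels=4, samples=32)
        aug = balanced_windowset(rng, 24, 40, channels=4, samples=32)
        aug.data_types = np.array(["noise"] * aug.n_frames, dtype=object)
        aug.subject_ids = np.array(
            [f"aug-{s}" for s in aug.subject_ids], dtype=object
        )
        plan = make_fold_plan(
            {s: str(real.groups[real.subject_ids == s][0])
             for s in real.subjects()}
        )
        return real, aug, plan.folds[0]

    @pytest.mark.parametrize(
        "condition,n_real,n_aug",
        [
            ("REAL_100", 46 * 18, 0),
            ("AUG_100_ONLY", 0, 46 * 18),
            ("REAL_50_AUG_50", 23 * 18, 23 * 18),
            ("REAL_100_AUG_100", 46 * 18, 46 * 18),
            ("REAL_100_AUG_200", 46 * 18, 2 * 46 * 18),
        ],
    )
    def test_counts_match_design_table(self, design, condition, n_real, n_aug):
        real, aug, fold = design
        ts = build_training_set(
            fold, AugmentationCondition(condition, "noise"), real, aug, seed=0
        )
        got_real = int(np.sum(ts.data_types == "real"))
        got_aug = int(np.sum(ts.data_types == "noise"))
        assert (got_real, got_aug) == (n_real, n_aug)
        # balanced across diagnoses
        assert int(np.sum(ts.groups == "HC")) == ts.n_frames // 2

    def test_no_test_subject_frame_in_any_condition(self, design):
        real, aug, fold = design
        for cond in ("REAL_100", "AUG_100_ONLY", "REAL_50_AUG_50",
                     "REAL_100_AUG_100", "REAL_100_AUG_200"):
            ts = build_training_set(
                fold, AugmentationCondition(cond, "noise"), real, aug, seed=1
            )
            assert not set(map(str, ts.subject_ids)) & set(fold.test)

    def test_insufficient_augmented_frames_rejected(self, design):
        real, _, fold = design
        rng = np.random.default_rng(3)
        small_aug = balanced_windowset(rng, 2, 3, channels=4, samples=32)
        small_aug.subject_ids = np.array(
            [f"aug-{s}" for s in small_aug.subject_ids], dtype=object
        )
        with pytest.raises(EEGError):
            build_training_set(
                fold, AugmentationCondition("REAL_100_AUG_200", "noise"),
                real, small_aug, seed=0,
            )


class TestPeriodogram:
    def test_tone_localized_at_10_hz(self):
        t = np.arange(2000) / 250.0
        freqs, p = periodogram(np.sin(2 * np.pi * 10 * t), 250.0)
        assert freqs[np.argmax(p)] == pytest.approx(10.0)

    def test_zero_series_gives_zero_power(self):
        _, p = periodogram(np.zeros(256), 64.0)
        assert np.allclose(p, 0.0)

    def test_parseval_total_power_within_1_percent(self, rng):
        x = rng.standard_normal(1024)
        freqs, p = periodogram(x, 64.0)
        total = p.sum() * (freqs[1] - freqs[0])
        assert total == pytest.approx(np.mean(x**2), rel=0.01)

    def test_empty_series_rejected(self):
        with pytest.raises(EEGError):
            periodogram(np.zeros(1), 64.0)


class TestSubjectMeanSpectrum:
    def _tone_frame(self, f0, rate=64.0, n=512):
        t = np.arange(n) / rate
        return np.tile(np.sin(2 * np.pi * f0 * t), (2, 1))

    def test_single_frame_equals_frame_periodogram(self):
        fr = self._tone_frame(10.0)[None]
        ws = make_windowset(fr, ["s"], ["HC"], window_seconds=8.0)
        freqs, spec = subject_mean_spectrum(ws, "s")
        _, expected = periodogram(fr[0], 64.0)
        assert np.allclose(spec, expected)

    def test_two_identical_frames_same_spectrum(self):
        fr = np.repeat(self._tone_frame(6.0)[None], 2, axis=0)
        ws = make_windowset(fr, ["s", "s"], ["HC", "HC"], window_seconds=8.0)
        _, spec = subject_mean_spectrum(ws, "s")
        _, single = periodogram(fr[0], 64.0)
        assert np.allclose(spec, single)

    def test_mixed_tones_average_to_half_height_peaks(self):
        fr = np.stack([self._tone_frame(6.0), self._tone_frame(10.0)])
        ws = make_windowset(fr, ["s", "s"], ["HC", "HC"], window_seconds=8.0)
        freqs, spec = subject_mean_spectrum(ws, "s")
        _, p6 = periodogram(fr[0], 64.0)
        i6 = np.argmin(np.abs(freqs - 6.0))
        i10 = np.argmin(np.abs(freqs - 10.0))
        assert spec[i6] == pytest.approx(p6[i6] / 2, rel=1e-6)
        assert spec[i10] == pytest.approx(p6[i6] / 2, rel=1e-6)

    def test_unknown_subject_rejected(self, rng):
        ws = make_windowset(rng.standard_normal((1, 2, 64)), ["s"], ["HC"])
        with pytest.raises(EEGError):
            subject_mean_spectrum(ws, "nobody")


class TestBandPower:
    def test_pure_tone_dominates_its_band_100x(self):
        t = np.arange(512) / 64.0
        freqs, p = periodogram(np.sin(2 * np.pi * 10 * t), 64.0)
        alpha = band_power(freqs, p, "alpha")
        for other in ("delta", "theta", "beta"):
            assert alpha > 100 * band_power(freqs, p, other)

    def test_white_noise_mean_band_power_flat_within_20_percent(self):
        rng = np.random.default_rng(0)
        acc = {b: 0.0 for b in ("delta", "theta", "alpha", "beta")}
        for _ in range(50):
            freqs, p = periodogram(rng.standard_normal(2048), 64.0)
            for b in acc:
                acc[b] += band_power(freqs, p, b)
        vals = np.array(list(acc.values())) / 50.0
        assert vals.max() / vals.min() < 1.2

    def test_zero_spectrum_zero_band_power(self):
        freqs, p = periodogram(np.zeros(256), 64.0)
        assert all(
            band_power(freqs, p, b) == 0.0
            for b in ("delta", "theta", "alpha", "beta")
        )

    def test_band_outside_spectrum_rejected(self):
        freqs, p = periodogram(np.zeros(256), 4.0)
        with pytest.raises(EEGError):
            band_power(freqs, p, (30.0, 40.0))


class TestMatchSyntheticUnits:
    def _synthetic(self, rng, n=30):
        ws = make_windowset(
            rng.standard_normal((2 * n, 2, 32)),
            [f"synthetic-{i}" for i in range(2 * n)],
            ["HC"] * n + ["MDD"] * n,
            data_types=["synthetic"] * (2 * n),
        )
        return ws

    def test_exact_units_per_group(self, rng):
        out = match_synthetic_units(self._synthetic(rng), 24, seed=0)
        assert out.n_frames == 48
        assert int(np.sum(out.groups == "HC")) == 24

    def test_deterministic_under_seed(self, rng):
        ws = self._synthetic(rng)
        a = match_synthetic_units(ws, 10, seed=3)
        b = match_synthetic_units(ws, 10, seed=3)
        assert np.array_equal(a.frames, b.frames)

    def test_insufficient_frames_rejected(self, rng):
        with pytest.raises(EEGError):
            match_synthetic_units(self._synthetic(rng, n=5), 24, seed=0)


def _brute_force_anova(y, a, b):
    """Balanced two-way fixed-effects decomposition, from first principles."""
    y, a, b = np.asarray(y, float), np.asarray(a), np.asarray(b)
    grand = y.mean()
    n = len(y)
    ss_a = sum(
        (y[a == lv].mean() - grand) ** 2 * (a == lv).sum() for lv in np.unique(a)
    )
    ss_b = sum(
        (y[b == lv].mean() - grand) ** 2 * (b == lv).sum() for lv in np.unique(b)
    )
    ss_cells = 0.0
    ss_err = 0.0
    for la in np.unique(a):
        for lb in np.unique(b):
            cell = y[(a == la) & (b == lb)]
            ss_cells += len(cell) * (cell.mean() - grand) ** 2
            ss_err += ((cell - cell.mean()) ** 2).sum()
    ss_ab = ss_cells - ss_a - ss_b
    df_err = n - 4
    return (
        ss_a / (ss_err / df_err),
        ss_b / (ss_err / df_err),
        ss_ab / (ss_err / df_err),
    )


def _table_from_powers(powers, data_types, diagnoses, band="delta"):
    rows = [
        {"unit_id": f"u{i}", "unit_kind": "subject", "diagnosis": d,
         "data_type": t, "band": band, "power": p}
        for i, (p, t, d) in enumerate(zip(powers, data_types, diagnoses))
    ]
    return pd.DataFrame(rows)


class TestAnova:
    def test_matches_brute_force_on_random_balanced_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(3, 12))
            types = np.repeat(["real", "synthetic"], 2 * n)
            diag = np.tile(np.repeat(["HC", "MDD"], n), 2)
            y = np.exp(rng.standard_normal(4 * n))
            table = _table_from_powers(y, types, diag)
            res = anova_two_way(table, "delta")
            f_a, f_b, f_ab = _brute_force_anova(y, types, diag)
            assert res["data_type"].statistic == pytest.approx(f_a, abs=1e-8)
            assert res["diagnosis"].statistic == pytest.approx(f_b, abs=1e-8)
            assert res["interaction"].statistic == pytest.approx(f_ab, abs=1e-8)
            assert res["data_type"].df == (1, 4 * n - 4)

    def test_degenerate_equal_observations_rejected(self):
        table = _table_from_powers(
            np.ones(8), np.repeat(["real", "synthetic"], 4),
            np.tile(np.repeat(["HC", "MDD"], 2), 2),
        )
        with pytest.raises(EEGError):
            anova_two_way(table, "delta")

    def test_empty_cell_rejected(self):
        table = _table_from_powers(
            np.arange(6.0), ["real"] * 4 + ["synthetic"] * 2,
            ["HC", "MDD"] * 3,
        )
        with pytest.raises(EEGError):
            anova_two_way(table, "delta")

    def test_pure_diagnosis_shift_detected_with_power(self):
        """Simulated log-normal powers with a diagnosis shift only: the
        diagnosis effect fires in >= 80% of replicates, the data-type
        effect near the nominal 5% rate."""
        rng = np.random.default_rng(7)
        n = 10
        diag_hits = dtype_hits = 0
        reps = 20
        for _ in range(reps):
            types = np.repeat(["real", "synthetic"], 2 * n)
            diag = np.tile(np.repeat(["HC", "MDD"], n), 2)
            shift = np.where(diag == "MDD", np.log(2.0), 0.0)
            y = np.exp(0.4 * rng.standard_normal(4 * n) + shift)
            res = anova_two_way(_table_from_powers(y, types, diag), "delta")
            diag_hits += res["diagnosis"].significant
            dtype_hits += res["data_type"].significant
        assert diag_hits >= 0.8 * reps
        assert dtype_hits <= 4

    def test_label_permutation_keeps_nominal_rate(self):
        rng = np.random.default_rng(11)
        n = 10
        hits = {"data_type": 0, "diagnosis": 0, "interaction": 0}
        reps = 40
        for _ in range(reps):
            types = np.repeat(["real", "synthetic"], 2 * n)
            diag = np.tile(np.repeat(["HC", "MDD"], n), 2)
            y = np.exp(0.4 * rng.standard_normal(4 * n))
            res = anova_two_way(_table_from_powers(y, types, diag), "delta")
            for k in hits:
                hits[k] += res[k].significant
        for k, v in hits.items():
            assert v / reps <= 0.15, k


class TestTTest:
    def test_identical_samples_give_t0_p_half(self):
        res = one_sided_ttest(np.full(10, 0.7), np.full(10, 0.7))
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(0.5)

    def test_degrees_of_freedom_pattern(self, rng):
        a = 0.6 + 0.05 * rng.standard_normal(24)
        b = 0.5 + 0.05 * rng.standard_normal(24)
        assert one_sided_ttest(a, b).df == (46,)
        c = 0.6 + 0.05 * rng.standard_normal(28)
        assert one_sided_ttest(c).df == (27,)

    def test_closed_form_one_sample_evaluation(self):
        acc = np.array([0.60, 0.601, 0.599, 0.6005, 0.5995] * 10)
        res = one_sided_ttest(acc, chance=0.5)
        t_manual = (acc.mean() - 0.5) / (acc.std(ddof=1) / np.sqrt(acc.size))
        assert res.statistic == pytest.approx(t_manual)
        assert res.p_value < 0.001

    def test_insufficient_observations_rejected(self):
        with pytest.raises(EEGError):
            one_sided_ttest(np.array([0.5]))


class TestSummarize:
    def test_constant_values_zero_width(self):
        mean, (lo, hi) = summarize(np.full(5, 0.8))
        assert mean == lo == hi == pytest.approx(0.8)

    def test_two_point_closed_form(self):
        from scipy import stats as st

        mean, (lo, hi) = summarize(np.array([0.0, 1.0]))
        half = st.t.ppf(0.975, 1) * 0.5
        assert mean == pytest.approx(0.5)
        assert hi - mean == pytest.approx(half)

    def test_interval_contains_mean(self, rng):
        mean, (lo, hi) = summarize(rng.standard_normal(10))
        assert lo <= mean <= hi

    def test_single_value_rejected(self):
        with pytest.raises(EEGError):
            summarize(np.array([1.0]))


def test_band_power_table_structure(rng):
    ws = balanced_windowset(rng, 3, 4, channels=2, samples=64)
    table = band_power_table(ws)
    assert set(table["band"]) == {"delta", "theta", "alpha", "beta"}
    assert len(table) == 6 * 4  # subjects x bands
    assert (table["power"] >= 0).all()
    assert set(table["unit_kind"]) == {"subject"}
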