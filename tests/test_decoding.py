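import numpy as np
import pytest

from critsort.decoding import (
    DecodingResult,
    TimepointClassifier,
    auc_score,
    balance_trials,
    criterion_contrast,
    find_peaks,
    forward_transform,
    loso_cv,
    posthoc_cells,
    train_timepoint_classifiers,
)

from conftest import make_toy_dataset


class TestTrainClassifiers:
    def test_separated_clouds_training_auc_one(self):
        rng = np.random.default_rng(0)
        n = 40
        x0 = rng.normal(-5, 0.5, (n, 2, 1))
        x1 = rng.normal(5, 0.5, (n, 2, 1))
        ds = make_toy_dataset(
            np.concatenate([x0, x1]), np.r_[np.zeros(n), np.ones(n)].astype(bool)
        )
        clf = train_timepoint_classifiers(ds, shrinkage=None, zscore=False)
        dv = clf.decision_values(ds.epochs)[:, 0]
        assert auc_score(dv, ds.is_target) == 1.0

    def test_equal_means_heldout_chance(self):
        rng = np.random.default_rng(1)
        train = make_toy_dataset(
            rng.normal(size=(200, 3, 1)), rng.random(200) < 0.5
        )
        test = make_toy_dataset(
            rng.normal(size=(200, 3, 1)), rng.random(200) < 0.5
        )
        clf = train_timepoint_classifiers(train)
        dv = clf.decision_values(test.epochs)[:, 0]
        assert abs(auc_score(dv, test.is_target) - 0.5) < 0.12

    def test_weights_match_closed_form_lda(self):
        # 3-channel toy; weights must solve pooled_cov @ w = mu1 - mu0
        rng = np.random.default_rng(2)
        n = 60
        scale = np.array([1.0, 2.0, 0.5])[None, :, None]
        x0 = rng.normal(0, 1, (n, 3, 2)) * scale
        x1 = rng.normal(1.0, 1.0, (n // 2, 3, 2)) * scale
        epochs = np.concatenate([x0, x1])
        y = np.r_[np.zeros(n), np.ones(n // 2)].astype(bool)
        ds = make_toy_dataset(epochs, y)
        clf = train_timepoint_classifiers(ds, shrinkage=None, zscore=False)
        for t in range(2):
            xt = epochs[:, :, t]
            mu0, mu1 = xt[~y].mean(0), xt[y].mean(0)
            z = xt - np.where(y, 1, 0)[:, None] * mu1 - np.where(y, 0, 1)[:, None] * mu0
            cov = z.T @ z / (len(y) - 2)
            expect = np.linalg.solve(cov, mu1 - mu0)
            np.testing.assert_allclose(clf.weights[:, t], expect, rtol=1e-10)

    def test_singular_covariance_advises_shrinkage(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(30, 1, 1))
        epochs = np.concatenate([base, base], axis=1)  # duplicated channel
        ds = make_toy_dataset(epochs, rng.random(30) < 0.5)
        with pytest.raises(np.linalg.LinAlgError, match="shrinkage"):
            train_timepoint_classifiers(ds, shrinkage=None, zscore=False)

    def test_needs_two_trials_per_class(self):
        ds = make_toy_dataset(np.zeros((3, 2, 1)), [True, True, True])
        with pytest.raises(ValueError, match="trials per class"):
            train_timepoint_classifiers(ds)


class TestAucScore:
    def test_pair_counting_example(self):
        # 3 of 4 cross-class pairs correctly ordered
        assert auc_score([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_perfect_ordering(self):
        assert auc_score([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0

    def test_all_ties(self):
        assert auc_score([1.0, 1.0, 1.0, 1.0], [0, 1, 0, 1]) == 0.5

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            auc_score([1.0, 2.0], [1, 1])

    def test_matches_pair_count_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            v = rng.integers(0, 6, 30).astype(float)  # many ties
            y = rng.random(30) < 0.4
            if y.all() or not y.any():
                continue
            pos, neg = v[y], v[~y]
            wins = (pos[:, None] > neg[None, :]).sum()
            ties = (pos[:, None] == neg[None, :]).sum()
            oracle = (wins + 0.5 * ties) / (pos.size * neg.size)
            assert auc_score(v, y) == pytest.approx(oracle)


class TestPosthocCells:
    def test_pas_collapsing(self, pas_cohort):
        _, cohort = pas_cohort
        cells = posthoc_cells(cohort[0])
        resp = cohort[0].response
        expect = np.where(resp > 0, "seen", "unseen")
        np.testing.assert_array_equal(cells["visibility"].to_numpy(), expect)
        assert len(cells) == cohort[0].n_trials

    def test_yes_no_mapping(self, strong_cohort):
        _, cohort = strong_cohort
        cells = posthoc_cells(cohort[0])
        assert set(cells["visibility"]) <= {"seen", "unseen"}
        counts = cells.groupby(["condition", "visibility"]).size().sum()
        assert counts == cohort[0].n_trials

    def test_bad_responses(self):
        ds = make_toy_dataset(np.zeros((4, 2, 2)), [0, 1, 0, 1], response=[0, 3, 0, 1])
        with pytest.raises(ValueError, match="yes_no"):
            posthoc_cells(ds, "yes_no")


class TestBalanceTrials:
    def _dataset(self, spec):
        """spec: list of (stimulus, response, condition, count)."""
        stim, resp, cond = [], [], []
        for s, r, c, k in spec:
            stim += [s] * k
            resp += [r] * k
            cond += [c] * k
        n = len(stim)
        ds = make_toy_dataset(
            np.zeros((n, 2, 2)),
            np.array(stim) == "target",
            condition=np.array(cond),
            response=np.array(resp),
        )
        return ds

    def test_overrepresented_cell_trimmed(self):
        ds = self._dataset(
            [("target", 1, "liberal", 30), ("target", 1, "conservative", 20)]
        )
        idx = balance_trials(ds, seed=0)
        cond = ds.condition[idx]
        assert (cond == "liberal").sum() == 20
        assert (cond == "conservative").sum() == 20

    def test_equal_counts_identity(self):
        ds = self._dataset(
            [("target", 1, "liberal", 15), ("target", 1, "conservative", 15),
             ("no_target", 0, "liberal", 5), ("no_target", 0, "conservative", 5)]
        )
        idx = balance_trials(ds, seed=1)
        np.testing.assert_array_equal(idx, np.arange(ds.n_trials))

    def test_multi_cell_minima_by_recount(self):
        ds = self._dataset(
            [("target", 1, "liberal", 40), ("target", 1, "conservative", 25),
             ("target", 0, "liberal", 10), ("target", 0, "conservative", 30)]
        )
        idx = balance_trials(ds, seed=2)
        tgt_seen = (ds.response[idx] == 1)
        tgt_unseen = (ds.response[idx] == 0)
        for cond in ("liberal", "conservative"):
            c = ds.condition[idx] == cond
            assert (c & tgt_seen).sum() == 25
            assert (c & tgt_unseen).sum() == 10

    def test_counts_identical_membership_varies(self, strong_cohort):
        _, cohort = strong_cohort
        ds = cohort[0]
        a = balance_trials(ds, seed=0)
        b = balance_trials(ds, seed=99)
        assert a.size == b.size
        assert not np.array_equal(a, b)
        for idx in (a, b):
            for stim in ("target", "no_target"):
                for r in (0, 1):
                    cell = (ds.stimulus[idx] == stim) & (ds.response[idx] == r)
                    nlib = (ds.condition[idx][cell] == "liberal").sum()
                    ncons = (ds.condition[idx][cell] == "conservative").sum()
                    assert nlib == ncons


class TestLosoCv:
    def test_needs_three_subjects(self, strong_cohort):
        _, cohort = strong_cohort
        with pytest.raises(ValueError, match="at least 3"):
            loso_cv(cohort[:2])

    def test_channel_mismatch_errors(self, strong_cohort):
        import dataclasses

        _, cohort = strong_cohort
        bad = dataclasses.replace(
            cohort[1], channel_names=tuple(reversed(cohort[1].channel_names))
        )
        with pytest.raises(ValueError, match="montage mismatch"):
            loso_cv([cohort[0], bad, cohort[2]])

    def test_pair_bookkeeping(self, strong_cohort):
        _, cohort = strong_cohort
        res = loso_cv(cohort[:3], time_indices=[30])
        assert res.provenance["n_classifier_test_pairs"] == 6

    def test_null_cohort_stays_at_chance(self, null_cohort):
        _, cohort = null_cohort
        res = loso_cv(cohort)
        gm = res.grand_mean("all")
        assert gm.min() > 0.45 and gm.max() < 0.55

    def test_prestim_carries_no_information(self, strong_cohort):
        _, cohort = strong_cohort
        res = loso_cv(cohort)
        gm = res.grand_mean("all")
        pre = gm[res.times < 0]
        assert pre.min() > 0.45 and pre.max() < 0.55

    def test_peaks_at_configured_latencies(self, strong_cohort):
        cfg, cohort = strong_cohort
        res = loso_cv(cohort)
        peaks = find_peaks(res.times, res.grand_mean("all"), 3)
        step = 1000.0 / cfg.sample_rate
        assert peaks.size == 3
        # widest kernel (45 ms) is flat over ~2 samples at its top
        for found, want in zip(peaks, cfg.component_latencies):
            nearest = res.times[np.argmin(np.abs(res.times - want))]
            assert abs(found - nearest) <= 2 * step + 1e-9

    def test_determinism(self, strong_cohort):
        _, cohort = strong_cohort
        a = loso_cv(cohort, cell_scheme="condition_visibility", balance_seed=5,
                    time_indices=[60, 90])
        b = loso_cv(cohort, cell_scheme="condition_visibility", balance_seed=5,
                    time_indices=[60, 90])
        np.testing.assert_array_equal(a.auc, b.auc)

    def test_matches_bruteforce_pair(self, strong_cohort):
        # per-test-subject AUC is the mean over training classifiers of
        # auc_score applied to that classifier's decision values
        _, cohort = strong_cohort
        sub = cohort[:3]
        ti = [80]
        res = loso_cv(sub, time_indices=ti)
        clfs = [train_timepoint_classifiers(ds, time_indices=ti) for ds in sub]
        ds0 = sub[0]
        aucs = []
        for j in (1, 2):
            dv = clfs[j].decision_values(ds0.epochs[:, :, ti])[:, 0]
            aucs.append(auc_score(dv, ds0.is_target))
        assert res.auc[0, 0, 0] == pytest.approx(np.mean(aucs), abs=1e-12)

    def test_missing_cell_flagged_nan(self):
        rng = np.random.default_rng(0)
        cohort = []
        for sid in range(3):
            n = 40
            ds = make_toy_dataset(
                rng.normal(size=(n, 2, 3)),
                np.r_[np.zeros(n // 2), np.ones(n // 2)].astype(bool),
                # nobody ever says "seen" in the liberal condition
                response=np.zeros(n, dtype=int),
                subject_id=sid,
            )
            cohort.append(ds)
        with pytest.warns(UserWarning, match="missing class"):
            res = loso_cv(cohort, cell_scheme="condition_visibility")
        i = res.cell_index("liberal:seen")
        assert np.isnan(res.auc[:, i, :]).all()
        flagged = res.n_trials[res.n_trials["cell"] == "liberal:seen"]
        assert (flagged["n_target"] == 0).all()


class TestFindPeaks:
    def _trace(self, latencies, times):
        series = np.full(times.size, 0.5)
        for amp, lat, wid in zip((0.2, 0.15, 0.1), latencies, (20, 30, 40)):
            series = series + amp * np.exp(-0.5 * ((times - lat) / wid) ** 2)
        return series

    def test_three_bump_fixture(self):
        times = (np.arange(219) - 26) * 1000.0 / 256.0
        series = self._trace((137, 266, 430), times)
        peaks = find_peaks(times, series, 3)
        for found, want in zip(peaks, (137, 266, 430)):
            nearest = times[np.argmin(np.abs(times - want))]
            assert found == nearest

    def test_monotone_trace_warns_empty(self):
        times = np.linspace(-100, 750, 200)
        with pytest.warns(UserWarning, match="no post-stimulus"):
            peaks = find_peaks(times, np.linspace(0, 1, 200), 3)
        assert peaks.size == 0

    def test_single_bump(self):
        times = np.linspace(-100, 750, 218)
        series = np.exp(-0.5 * ((times - 300) / 40) ** 2)
        with pytest.warns(UserWarning, match="local maxima"):
            peaks = find_peaks(times, series, 3)
        assert peaks.size == 1
        assert abs(peaks[0] - 300) <= np.diff(times)[0]

    def test_prestim_peaks_excluded(self):
        times = np.linspace(-100, 750, 218)
        series = np.exp(-0.5 * ((times + 50) / 10) ** 2) + 0.5 * np.exp(
            -0.5 * ((times - 400) / 30) ** 2
        )
        peaks = find_peaks(times, series, 1)
        assert peaks.size == 1 and peaks[0] > 0


class TestForwardTransform:
    def _classifier(self, weights):
        w = np.asarray(weights, dtype=float)[:, None]
        return TimepointClassifier(
            weights=w,
            intercept=np.zeros(1),
            training_subject=0,
            channel_names=tuple(f"ch{i}" for i in range(w.shape[0])),
        )

    def test_identity_covariance_pattern_proportional_to_weights(self):
        rng = np.random.default_rng(5)
        epochs = rng.standard_normal((20_000, 2, 1))
        clf = self._classifier([3.0, -1.0])
        pat = forward_transform(clf, epochs).pattern[:, 0]
        expect = np.array([3.0, -1.0]) / np.linalg.norm([3.0, -1.0])
        np.testing.assert_allclose(pat, expect, atol=0.03)

    def test_diagonal_covariance_hand_example(self):
        # exact sample covariance diag(4, 1) with w = [1, 1] -> pattern
        # proportional to [4, 1]
        a, b = np.sqrt(1.5), np.sqrt(0.375)
        epochs = np.array(
            [[[2 * a], [0.0]], [[-2 * a], [0.0]], [[0.0], [2 * b]], [[0.0], [-2 * b]]]
        )
        xc = epochs[:, :, 0]
        cov = xc.T @ xc / 3
        np.testing.assert_allclose(cov, np.diag([4.0, 1.0]), atol=1e-12)
        clf = self._classifier([1.0, 1.0])
        pat = forward_transform(clf, epochs).pattern[:, 0]
        np.testing.assert_allclose(
            pat, np.array([4.0, 1.0]) / np.linalg.norm([4.0, 1.0]), atol=1e-12
        )

    def test_invariant_to_balanced_duplication(self):
        rng = np.random.default_rng(6)
        epochs = rng.standard_normal((50, 3, 2))
        clf = TimepointClassifier(
            weights=rng.standard_normal((3, 2)),
            intercept=np.zeros(2),
            training_subject=0,
            channel_names=("a", "b", "c"),
        )
        p1 = forward_transform(clf, epochs).pattern
        p2 = forward_transform(clf, np.concatenate([epochs, epochs])).pattern
        np.testing.assert_allclose(p1, p2, atol=1e-12)


class TestCriterionContrast:
    def _result(self, deltas):
        """Two cells (lib/cons x seen) with given per-subject differences."""
        n = len(deltas)
        auc = np.zeros((n, 4, 1))
        cells = ("liberal:seen", "liberal:unseen", "conservative:seen",
                 "conservative:unseen")
        auc[:, 0, 0] = 0.6
        auc[:, 1, 0] = 0.6
        auc[:, 2, 0] = 0.6 + np.asarray(deltas)
        auc[:, 3, 0] = 0.6 + np.asarray(deltas)
        import pandas as pd

        return DecodingResult(
            auc=auc,
            cells=cells,
            times=np.array([266.0]),
            subjects=tuple(range(n)),
            n_trials=pd.DataFrame(),
            provenance={},
        )

    def test_zero_delta(self):
        res = criterion_contrast(self._result([0.0] * 6), [266])
        row = res.table[res.table["cell"] == "seen"].iloc[0]
        assert row["t"] == 0.0
        assert row["p_one_sided"] == 0.5

    def test_constant_positive_delta(self):
        res = criterion_contrast(self._result([0.05] * 6), [266])
        row = res.table[res.table["cell"] == "seen"].iloc[0]
        assert np.isinf(row["t"]) and row["t"] > 0
        assert row["p_one_sided"] == 0.0

    def test_collapsed_row_present(self):
        res = criterion_contrast(self._result([0.01, 0.02, -0.01, 0.03]), [266])
        assert "collapsed" in set(res.table["cell"])

    def test_requires_condition_cells(self, strong_cohort):
        _, cohort = strong_cohort
        res = loso_cv(cohort[:3], time_indices=[50])
        with pytest.raises(ValueError, match="cells to contrast"):
            criterion_contrast(res, [137])
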