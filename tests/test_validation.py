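"""Splitting, AUC, thresholds, confusion metrics, CV and the anomaly test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenoclim import (
    CVConfig,
    confusion_metrics,
    derive_thresholds,
    lpt_threshold,
    max_kappa_threshold,
    roc_auc,
    run_repeated_cv,
    split_data,
)
from phenoclim.validation import _cohen_kappa, fit_on_training


def brute_force_auc(scores, labels):
    s = np.asarray(scores, float)
    y = np.asarray(labels)
    pos, neg = s[y == 1], s[y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestSplit:
    def test_75_25_disjoint_exhaustive(self):
        ids = np.arange(100)
        reps = split_data(ids, 0.75, 10, seed=3)
        for r in reps:
            assert len(r.train_ids) == 75 and len(r.test_ids) == 25
            assert set(r.train_ids).isdisjoint(r.test_ids)
            assert set(r.train_ids) | set(r.test_ids) == set(ids)

    def test_seeding_contract(self):
        a = split_data(np.arange(40), seed=7)
        b = split_data(np.arange(40), seed=7)
        c = split_data(np.arange(40), seed=8)
        assert all(np.array_equal(x.train_ids, y.train_ids) for x, y in zip(a, b))
        assert any(not np.array_equal(x.train_ids, y.train_ids) for x, y in zip(a, c))

    def test_each_row_tested_about_a_quarter_of_reps(self):
        ids = np.arange(200)
        reps = split_data(ids, 0.75, 10, seed=1)
        counts = np.zeros(200)
        for r in reps:
            counts[r.test_ids] += 1
        assert counts.mean() == pytest.approx(2.5, abs=1e-12)  # exact: 25% per rep
        # binomial(10, .25) spread
        assert counts.std() < 3 * np.sqrt(10 * 0.25 * 0.75)

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            split_data(np.arange(1), 0.75, 2, seed=0)


class TestAUC:
    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0.5] * 10, [0, 1] * 5) == 0.5

    def test_four_sample_hand_count(self):
        assert roc_auc([0.2, 0.6, 0.4, 0.8], [0, 1, 1, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        n=st.integers(4, 60),
        seed=st.integers(0, 10_000),
        ties=st.booleans(),
    )
    def test_matches_exhaustive_pair_counting(self, n, seed, ties):
        rng = np.random.default_rng(seed)
        s = rng.integers(0, 5, n) / 4.0 if ties else rng.random(n)
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        assert roc_auc(s, y) == pytest.approx(brute_force_auc(s, y), abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        s = rng.random(500)
        y = (rng.random(500) < s).astype(int)
        assert roc_auc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)


class TestMaxKappa:
    def test_perfect_separation_smallest_candidate_in_gap(self):
        s = np.array([0.1, 0.2, 0.7, 0.9])
        y = np.array([0, 0, 1, 1])
        t, kappa = max_kappa_threshold(s, y)
        assert kappa == 1.0
        assert t == pytest.approx(0.45)  # midpoint 0.2/0.7 is the smallest maximiser

    def test_null_data_kappa_near_zero(self, rng):
        s = rng.random(2000)
        y = rng.integers(0, 2, 2000)
        _, kappa = max_kappa_threshold(s, y)
        assert kappa < 0.1

    def test_grid_scan_oracle(self, rng):
        for _ in range(5):
            s = rng.random(300)
            y = (rng.random(300) < np.clip(s + rng.normal(0, 0.3, 300), 0, 1)).astype(int)
            if y.min() == y.max():
                continue
            t, kappa = max_kappa_threshold(s, y)
            grid = np.linspace(0, 1, 1001)
            kappas = []
            for g in grid:
                pred = (s >= g).astype(int)
                m = confusion_metrics(pred, y)
                kappas.append(_cohen_kappa(m.tp, m.fp, m.tn, m.fn))
            assert kappa >= max(kappas) - 1e-12

    def test_kappa_at_max_dominates_lpt_thresholds(self, rng):
        s = rng.random(400)
        y = (rng.random(400) < s).astype(int)
        th = derive_thresholds(s, y)
        for t in (th.lpt, th.lpt5):
            m = confusion_metrics((s >= t).astype(int), y)
            assert th.kappa_at_max >= _cohen_kappa(m.tp, m.fp, m.tn, m.fn) - 1e-12


class TestLPT:
    def test_minimum_presence_score(self):
        s = np.array([0.3, 0.5, 0.7, 0.2, 0.1])
        y = np.array([1, 1, 1, 0, 0])
        assert lpt_threshold(s, y, 0.0) == 0.3

    def test_five_percent_rule_counts(self):
        s = 0.01 * np.arange(1, 101)
        y = np.ones(100, dtype=int)
        t = lpt_threshold(s, y, 0.05)
        assert t == pytest.approx(0.06)
        assert (s >= t).sum() == 95

    def test_single_presence_degenerate(self):
        s = np.array([0.42, 0.1])
        y = np.array([1, 0])
        assert lpt_threshold(s, y, 0.0) == 0.42
        assert lpt_threshold(s, y, 0.05) == 0.42

    def test_no_presences_rejected(self):
        with pytest.raises(ValueError):
            lpt_threshold([0.1], [0], 0.0)

    def test_lpt_never_exceeds_lpt5(self, rng):
        s = rng.random(200)
        y = (rng.random(200) < 0.3).astype(int)
        th = derive_thresholds(s, y)
        assert th.lpt <= th.lpt5
        # by construction the LPT classifies every calibration presence as presence
        m = confusion_metrics((s >= th.lpt).astype(int), y)
        assert m.omission_rate == 0.0


class TestConfusion:
    def test_hand_arithmetic(self):
        pred = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        obs = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        m = confusion_metrics(pred, obs)
        assert (m.tp, m.fp, m.tn, m.fn) == (3, 2, 5, 0)
        assert m.overall_accuracy == pytest.approx(80.0)
        assert m.commission_rate == pytest.approx(100 * 2 / 7)
        assert m.omission_rate == 0.0

    def test_identity_and_inversion(self):
        y = np.array([0, 1, 1, 0, 1])
        assert confusion_metrics(y, y).overall_accuracy == 100.0
        m = confusion_metrics(1 - y, y)
        assert m.overall_accuracy == 0.0
        assert m.commission_rate == 100.0
        assert m.omission_rate == 100.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics([], [])

    def test_threshold_sweep_monotonicity(self, rng):
        s = rng.random(300)
        y = (rng.random(300) < s).astype(int)
        prev_comm, prev_omit = -1.0, 101.0
        for t in np.linspace(1.0, 0.0, 41):  # lowering the threshold
            m = confusion_metrics((s >= t).astype(int), y)
            comm, omit = m.commission_rate, m.omission_rate
            assert comm >= prev_comm - 1e-9  # commission never decreases
            assert omit <= prev_omit + 1e-9  # omission never increases
            prev_comm, prev_omit = comm, omit


class TestCV:
    def test_null_labels_auc_near_half(self, rng):
        n = 600
        df = pd.DataFrame(
            {
                "record_id": [f"r{i}" for i in range(n)],
                "gdd": rng.uniform(0, 400, n),
                "avg_precip": rng.uniform(0, 4, n),
                "daylength": rng.uniform(9, 15, n),
                "y": rng.integers(0, 2, n),
                "period": "normal",
            }
        )
        _, summary = run_repeated_cv(df, config=CVConfig(n_reps=5, seed=2))
        assert summary["mean_auc_test"] == pytest.approx(0.5, abs=0.05)

    def test_anomaly_rows_refused_in_calibration(self, rng):
        n = 80
        df = pd.DataFrame(
            {
                "record_id": [f"r{i}" for i in range(n)],
                "gdd": rng.uniform(0, 400, n),
                "avg_precip": rng.uniform(0, 4, n),
                "daylength": rng.uniform(9, 15, n),
                "y": rng.integers(0, 2, n),
                "period": ["normal"] * 70 + ["anomalous"] * 10,
            }
        )
        with pytest.raises(ValueError, match="anomalous"):
            fit_on_training(df)
        with pytest.raises(ValueError, match="anomalous"):
            run_repeated_cv(df, config=CVConfig(n_reps=2, seed=0))
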