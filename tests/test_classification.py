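import numpy as np
import pandas as pd
import pytest

from fpbarcodes.classify import (
    SplitPlan,
    ThresholdSet,
    apply_intensity_cutoff,
    choose_threshold,
    classify_table,
    classify_top_k,
    roc_curve,
    score,
    score_table,
    signal_to_noise,
    split_indices,
    split_train_test,
    train_thresholds,
)
from fpbarcodes.io import EventTable
from fpbarcodes.synthetic import CellSimConfig, simulate_panel
from fpbarcodes.unmix import unmix_table


class TestSplitting:
    def test_seventy_thirty_arithmetic(self):
        (tr, te), *_ = split_indices(10, SplitPlan(n_repeats=1, seed=0))
        assert (len(tr), len(te)) == (7, 3)
        assert set(tr) | set(te) == set(range(10))
        assert not set(tr) & set(te)

    def test_same_seed_same_partitions(self):
        a = split_indices(100, SplitPlan(seed=5))
        b = split_indices(100, SplitPlan(seed=5))
        for (tr1, te1), (tr2, te2) in zip(a, b):
            np.testing.assert_array_equal(tr1, tr2)
            np.testing.assert_array_equal(te1, te2)

    def test_three_repeats_are_distinct(self):
        parts = split_indices(50, SplitPlan(n_repeats=3, seed=1))
        trains = [tuple(tr) for tr, _ in parts]
        assert len(set(trains)) == 3

    def test_event_table_lifting(self):
        t = EventTable(
            channel_names=["A"],
            intensities=np.arange(10, dtype=float)[:, None],
            truth_labels=[str(i) for i in range(10)],
        )
        (train, test), *_ = split_train_test(t, SplitPlan(n_repeats=1, seed=2))
        assert train.n_cells == 7 and test.n_cells == 3
        assert set(train.truth_labels) | set(test.truth_labels) == set(t.truth_labels)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            split_indices(1, SplitPlan())


class TestROC:
    abund = np.array([5, 6, 7, 1, 2, 8], dtype=float)
    is_pos = np.array([True, True, True, False, False, False])

    def test_exhaustive_counts(self):
        roc = roc_curve(self.abund, self.is_pos)
        at5 = roc[roc["threshold"] == 5].iloc[0]
        assert at5["tpr"] == 1.0
        assert at5["fpr"] == pytest.approx(1 / 3)

    def test_endpoints(self):
        roc = roc_curve(self.abund, self.is_pos)
        assert (roc.iloc[0][["fpr", "tpr"]] == 0).all()  # +inf sentinel
        assert (roc.iloc[-1][["fpr", "tpr"]] == 1).all()  # min value

    def test_perfectly_separated_reaches_corner(self):
        roc = roc_curve(np.array([1.0, 2, 10, 11]), np.array([0, 0, 1, 1], bool))
        assert ((roc["fpr"] == 0) & (roc["tpr"] == 1)).any()

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        a = rng.random(200)
        y = rng.random(200) < 0.4
        roc = roc_curve(a, y)  # ordered by descending threshold
        assert (np.diff(roc["tpr"]) >= 0).all()
        assert (np.diff(roc["fpr"]) >= 0).all()

    def test_monotone_and_anchored_for_arbitrary_scores(self):
        from hypothesis import assume, given, settings
        from hypothesis import strategies as st

        @settings(max_examples=40, deadline=None, derandomize=True)
        @given(
            vals=st.lists(st.floats(0, 1e6), min_size=2, max_size=40),
            labels=st.lists(st.booleans(), min_size=2, max_size=40),
        )
        def check(vals, labels):
            n = min(len(vals), len(labels))
            a, y = np.asarray(vals[:n]), np.asarray(labels[:n])
            assume(y.any() and (~y).any())
            roc = roc_curve(a, y)
            assert (np.diff(roc["tpr"]) >= 0).all()
            assert (np.diff(roc["fpr"]) >= 0).all()
            assert (roc.iloc[0][["fpr", "tpr"]] == 0).all()
            assert (roc.iloc[-1][["fpr", "tpr"]] == 1).all()

        check()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_curve(np.array([1.0, 2.0]), np.array([True, True]))

    def test_matches_sklearn(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(3)
        a = np.round(rng.random(300), 3)
        y = rng.random(300) < 0.5
        ours = roc_curve(a, y)
        fpr, tpr, thr = sklearn_metrics.roc_curve(y, a, drop_intermediate=False)
        np.testing.assert_allclose(ours["fpr"], fpr)
        np.testing.assert_allclose(ours["tpr"], tpr)


class TestThresholdChoice:
    def test_corner_distance_enumeration(self):
        roc = roc_curve(TestROC.abund, TestROC.is_pos)
        assert choose_threshold(roc) == 5.0

    def test_perfect_separation_zero_distance(self):
        roc = roc_curve(np.array([1.0, 2, 10, 11]), np.array([0, 0, 1, 1], bool))
        t = choose_threshold(roc)
        assert 2 < t <= 10

    def test_degenerate_curve_returns_sentinel_with_warning(self):
        roc = roc_curve(np.array([3.0, 3.0]), np.array([True, False]))
        with pytest.warns(UserWarning, match="degenerate"):
            assert np.isinf(choose_threshold(roc))

    def test_tie_break_prefers_largest(self):
        roc = pd.DataFrame(
            {"fpr": [0.1, 0.1], "tpr": [0.9, 0.9], "threshold": [2.0, 4.0]}
        )
        assert choose_threshold(roc) == 4.0


class TestTraining:
    def _toy_pool(self):
        abund = pd.DataFrame(
            {
                "A": [10.0, 12, 11, 0.1, 0.2, 0.3],
                "B": [0.2, 0.1, 0.4, 9.0, 8.0, 10.0],
                "autofluorescence": [1.0] * 6,
            }
        )
        labels = ["A", "A", "A", "B", "B", "B"]
        return abund, labels

    def test_thresholds_inside_separating_gaps(self):
        abund, labels = self._toy_pool()
        ts = train_thresholds(abund, labels)
        assert 0.3 < ts.thresholds["A"] <= 10
        assert 0.4 < ts.thresholds["B"] <= 8
        assert "autofluorescence" not in ts.thresholds

    def test_missing_class_named_in_error(self):
        abund, labels = self._toy_pool()
        with pytest.raises(ValueError, match="'C'"):
            train_thresholds(abund, labels, fp_labels=["A", "B", "C"])

    def test_training_is_deterministic(self):
        abund, labels = self._toy_pool()
        a = train_thresholds(abund, labels)
        b = train_thresholds(abund, labels)
        assert a.thresholds == b.thresholds


class TestScoring:
    ts = ThresholdSet({"A": 2.0, "B": 4.0})

    def test_ratio_definition(self):
        s = score({"A": 4.0, "B": 0.0, "autofluorescence": 99.0}, self.ts)
        assert s == {"A": 2.0, "B": 0.0}

    def test_nineteen_to_eighteen(self):
        fps = [f"F{i}" for i in range(18)]
        ts = ThresholdSet({f: 1.0 for f in fps})
        abund = {f: 1.0 for f in fps} | {"autofluorescence": 5.0}
        assert len(score(abund, ts)) == 18

    def test_autofluorescence_threshold_rejected(self):
        with pytest.raises(ValueError):
            ThresholdSet({"autofluorescence": 1.0})

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            ThresholdSet({"A": 0.0})


class TestTopK:
    def test_top1(self):
        call = classify_top_k({"A": 3.0, "B": 1.0, "C": 0.2}, k=1)
        assert call.members == {"A"}

    def test_top2(self):
        call = classify_top_k({"A": 3.0, "B": 2.5, "C": 0.2}, k=2)
        assert call.members == {"A", "B"}

    def test_tie_break_by_catalog_order(self):
        # exhaustive check over all permutations of a tied pair
        for cat in (["A", "B", "C"], ["B", "A", "C"]):
            call = classify_top_k({"A": 2.0, "B": 2.0, "C": 1.0}, k=1, catalog=cat)
            assert call.members == {cat[0]}

    def test_optional_unclassified_mode(self):
        call = classify_top_k({"A": 0.4, "B": 0.2}, k=1, min_score=1.0)
        assert call.members == frozenset()
        call = classify_top_k({"A": 1.4, "B": 0.2}, k=1, min_score=1.0)
        assert call.members == {"A"}

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_top_k({"A": 1.0}, k=2)

    def test_table_form_agrees_with_scalar_form(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.random((20, 5)), columns=list("ABCDE"))
        calls = classify_table(df, k=2)
        for i, row in df.iterrows():
            assert calls[i].members == classify_top_k(row, k=2).members


class TestIntensityCutoff:
    def test_counting(self):
        t = EventTable(
            channel_names=["A", "B"],
            intensities=np.array([[5e3, 100.0], [2e4, 50.0]]),
        )
        assert apply_intensity_cutoff(t, 1e4).n_cells == 1

    def test_zero_cutoff_identity(self):
        t = EventTable(channel_names=["A"], intensities=np.ones((4, 1)))
        assert apply_intensity_cutoff(t, 0).n_cells == 4

    def test_infinite_cutoff_empties(self):
        t = EventTable(channel_names=["A"], intensities=np.ones((4, 1)))
        assert apply_intensity_cutoff(t, np.inf).n_cells == 0

    def test_snr_arithmetic(self):
        assert signal_to_noise() == 10.0
        assert signal_to_noise(2e4, 1e3) == 20.0


class TestScaleInvariance:
    def test_calls_unchanged_under_rescaling(self, small_refs, small_basis):
        cfg = CellSimConfig(n_cells=40, seed=8)
        panel = simulate_panel(
            small_refs, [r.fp_id for r in small_refs[:3]], cfg
        )
        ts = ThresholdSet({r.fp_id: 100.0 for r in small_refs})
        fps = [r.fp_id for r in small_refs]
        base_calls = None
        for alpha in (0.1, 1.0, 10.0):
            scaled = EventTable(
                channel_names=panel.channel_names,
                intensities=panel.intensities * alpha,
            )
            abund = unmix_table(small_basis, scaled)
            calls = classify_table(score_table(abund, ts), k=1, catalog=fps)
            members = [c.members for c in calls]
            if base_calls is None:
                base_calls = members
            else:
                assert members == base_calls
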