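"""Stratified compound-level resampling, ROC/AUC and the single-marker baseline."""

import numpy as np
import pandas as pd
import pytest

from sensisig.dataio import (
    CLASS_CONTROL,
    CLASS_NONSENSITIZER,
    CLASS_SENSITIZER,
    Dataset,
)
from sensisig.simulate import SynthConfig, generate_dataset
from sensisig.validation import (
    confusion_metrics,
    permute_compound_labels,
    roc_auc,
    run_validation,
    single_marker_screen,
    stratified_split,
)

from conftest import STRONG_EFFECTS, toy_dataset

S, N = CLASS_SENSITIZER, CLASS_NONSENSITIZER


def mannwhitney_auc(scores, labels):
    """Brute-force pair counting with half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = sum(
        1.0 if p > q else (0.5 if p == q else 0.0) for p in pos for q in neg
    )
    return wins / (len(pos) * len(neg))


class TestStratifiedSplit:
    @staticmethod
    def _panel(n_sens, n_nonsens, replicates=3, n_genes=4, seed=0):
        cfg = SynthConfig(
            n_genes=n_genes, n_informative=2, n_sens_compounds=n_sens,
            n_nonsens_compounds=n_nonsens, replicates=replicates,
            n_controls_per_vehicle=2, seed=seed,
        )
        return generate_dataset(cfg)[0]

    def test_rounding_rule_18_plus_20(self):
        """round(0.7*18)=13 and round(0.7*20)=14 train compounds."""
        ds = self._panel(18, 20)
        plan = stratified_split(ds, 0.7, seed=1)
        by_class = {S: [], N: []}
        for c in plan.train_compounds:
            by_class[S if c.startswith("sens") else N].append(c)
        assert len(by_class[S]) == 13
        assert len(by_class[N]) == 14
        assert len(plan.test_compounds) == 5 + 6

    def test_partition_is_exact(self):
        ds = self._panel(6, 6)
        plan = stratified_split(ds, 0.7, seed=3)
        assert set(plan.train_compounds) & set(plan.test_compounds) == set()
        assert set(plan.train_compounds) | set(plan.test_compounds) == set(
            ds.compounds()
        )

    def test_extreme_fraction_keeps_one_test_compound(self):
        ds = self._panel(4, 4)
        plan = stratified_split(ds, 0.99, seed=0)
        sens_test = [c for c in plan.test_compounds if c.startswith("sens")]
        nons_test = [c for c in plan.test_compounds if c.startswith("nonsens")]
        assert len(sens_test) == 1 and len(nons_test) == 1

    def test_seed_determinism(self):
        ds = self._panel(8, 8)
        a = stratified_split(ds, 0.7, seed=17)
        b = stratified_split(ds, 0.7, seed=17)
        assert a.train_compounds == b.train_compounds
        assert a.test_compounds == b.test_compounds

    def test_invalid_fraction_rejected(self):
        ds = self._panel(4, 4)
        with pytest.raises(ValueError):
            stratified_split(ds, 1.5, seed=0)

    def test_replicates_never_split(self):
        ds = self._panel(8, 8)
        for seed in range(10):
            plan = stratified_split(ds, 0.7, seed=seed)
            train = set(plan.train_compounds)
            test = set(plan.test_compounds)
            for comp in ds.compounds():
                sids = ds.annot.index[ds.annot["compound_id"] == comp]
                sides = {("train" if comp in train else "test") for _ in sids}
                assert len(sides) == 1


class TestRocAuc:
    def test_worked_example(self):
        roc = roc_auc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0])
        assert roc.auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        roc = roc_auc([5, 6, 1, 2], [1, 1, 0, 0])
        assert roc.auc == 1.0

    def test_all_ties_is_half(self):
        roc = roc_auc([3, 3, 3, 3], [1, 0, 1, 0])
        assert roc.auc == 0.5

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(0)
        roc = roc_auc(rng.normal(size=30), rng.integers(0, 2, size=30) | (np.arange(30) < 2))
        assert roc.fpr[0] == 0 and roc.tpr[0] == 0
        assert roc.fpr[-1] == 1 and roc.tpr[-1] == 1
        assert np.all(np.diff(roc.fpr) >= 0)
        assert np.all(np.diff(roc.tpr) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(500):
            n = rng.integers(4, 25)
            labels = np.zeros(n, int)
            labels[: rng.integers(1, n - 1)] = 1
            rng.shuffle(labels)
            scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
            assert roc_auc(scores, labels).auc == pytest.approx(
                mannwhitney_auc(scores, labels), abs=1e-12
            )


class TestConfusionMetrics:
    def test_half_sensitive_fully_specific(self):
        """10 of 20 positives called, 0 of 20 negatives called."""
        truth = [1] * 20 + [0] * 20
        calls = [1] * 10 + [0] * 10 + [0] * 20
        m = confusion_metrics(calls, truth)
        assert m.sensitivity == pytest.approx(0.50)
        assert m.specificity == pytest.approx(1.00)
        assert m.accuracy == pytest.approx(0.75)

    def test_all_correct(self):
        m = confusion_metrics([1, 0, 1], [1, 0, 1])
        assert m == (1.0, 1.0, 1.0)

    def test_all_inverted(self):
        m = confusion_metrics([0, 1, 0, 1], [1, 0, 1, 0])
        assert m == (0.0, 0.0, 0.0)

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics([1, 0], [1, 1])


class TestSingleMarkerScreen:
    @staticmethod
    def _marker_dataset(marker_shift_for, shift=5.0, noise=0.1, seed=0):
        """4 sens + 4 nonsens compounds in triplicate + 3 controls per vehicle;
        the marker gene is shifted only for compounds in ``marker_shift_for``."""
        rng = np.random.default_rng(seed)
        comps = [(f"sens_{i}", S) for i in range(1, 5)] + [
            (f"nonsens_{i}", N) for i in range(1, 5)
        ]
        values, classes, compounds = [], [], []
        for cid, label in comps:
            for _ in range(3):
                base = rng.normal(0.0, noise)
                values.append(base + (shift if cid in marker_shift_for else 0.0))
                classes.append(label)
                compounds.append(cid)
        for _ in range(3):
            values.append(rng.normal(0.0, noise))
            classes.append(CLASS_CONTROL)
            compounds.append("VEHICLE_DMSO")
        return toy_dataset(
            np.array(values)[None, :], classes, gene_ids=["CD86like"],
            compounds=compounds,
        )

    def test_unshifted_compound_not_called(self):
        ds = self._marker_dataset(set())
        calls, metrics = single_marker_screen(ds, "CD86like")
        assert not calls["positive"].any()
        assert metrics.sensitivity == 0.0 and metrics.specificity == 1.0

    def test_shifted_compound_called(self):
        ds = self._marker_dataset({"sens_1"})
        calls, _ = single_marker_screen(ds, "CD86like")
        assert calls.loc["sens_1", "positive"]

    def test_half_marker_gives_sensitivity_half_specificity_one(self):
        ds = self._marker_dataset({"sens_1", "sens_2"})
        _, metrics = single_marker_screen(ds, "CD86like")
        assert metrics.sensitivity == pytest.approx(0.5)
        assert metrics.specificity == pytest.approx(1.0)

    def test_missing_controls_error(self):
        ds = self._marker_dataset({"sens_1"})
        no_ctrl = ds.subset_compounds(ds.compounds())
        with pytest.raises(ValueError):
            single_marker_screen(no_ctrl, "CD86like")


class TestRunValidation:
    @pytest.fixture(scope="class")
    @staticmethod
    def panel():
        cfg = SynthConfig(
            n_genes=60, n_informative=8, n_sens_compounds=6, n_nonsens_compounds=6,
            n_controls_per_vehicle=2, potency_effects=dict(STRONG_EFFECTS), seed=21,
        )
        return generate_dataset(cfg)[0]

    def test_single_iteration_frequencies_binary(self, panel):
        res = run_validation(panel, n_iter=1, top_k=10, seed=2)
        assert set(res.call_frequency.unique()) <= {0.0, 100.0}
        assert len(res.iterations) == 1

    def test_call_frequency_bounds_and_union(self, panel):
        res = run_validation(panel, n_iter=3, top_k=10, seed=2)
        assert ((res.call_frequency >= 0) & (res.call_frequency <= 100)).all()
        union = set().union(*(it.signature for it in res.iterations))
        assert set(res.call_frequency.index) == union
        always = [g for g in union
                  if all(g in it.signature for it in res.iterations)]
        assert all(res.call_frequency[g] == 100.0 for g in always)

    def test_mean_auc_is_mean(self, panel):
        res = run_validation(panel, n_iter=3, top_k=10, seed=2)
        assert res.mean_auc == pytest.approx(float(np.mean(res.aucs)))

    def test_youden_point_metrics_reported(self, panel):
        res = run_validation(panel, n_iter=2, top_k=10, seed=2)
        for it in res.iterations:
            assert it.metrics is not None
            for v in it.metrics:
                assert 0.0 <= v <= 1.0

    def test_youden_threshold_separates_perfectly_separable(self):
        from sensisig.validation import youden_threshold

        scores = np.array([-2.0, -1.0, 1.0, 2.0])
        labels = np.array([0, 0, 1, 1])
        thr = youden_threshold(scores, labels)
        assert (scores >= thr).astype(int).tolist() == labels.tolist()

    def test_fixed_signature_mode_size(self, panel):
        res = run_validation(panel, n_iter=1, top_k=10,
                             signature_mode="fixed", signature_size=4, seed=2)
        assert len(res.iterations[0].signature) == 4

    def test_no_test_set_leakage(self, panel):
        """Perturbing held-out expression never changes the derived signature."""
        res1 = run_validation(panel, n_iter=1, top_k=10, seed=5)
        plan = res1.iterations[0].plan
        perturbed = panel.expr.copy()
        test_samples = panel.annot.index[
            panel.annot["compound_id"].isin(plan.test_compounds)
        ]
        rng = np.random.default_rng(0)
        perturbed[test_samples] += rng.normal(0, 10, size=(panel.n_genes, len(test_samples)))
        ds2 = Dataset(perturbed, panel.annot)
        res2 = run_validation(ds2, n_iter=1, top_k=10, seed=5)
        assert res2.iterations[0].plan.test_compounds == plan.test_compounds
        assert res2.iterations[0].signature == res1.iterations[0].signature

    def test_permuted_labels_have_permuted_annotation_only(self, panel):
        null = permute_compound_labels(panel, seed=3)
        assert null.expr.equals(panel.expr)
        assert sorted(null.annot["class_label"]) == sorted(panel.annot["class_label"])
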