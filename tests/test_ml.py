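"""mRMR, SMOTE, MC folds, ensemble training and scoring."""

import numpy as np
import pandas as pd
import pytest

from fibroscar.ml import (
    BinaryMetrics,
    ScarClassifier,
    ScarClassifierResults,
    _quantile_discretize,
    balance_with_smote,
    build_mc_folds,
    mrmr_rank,
    score,
    smote_oversample,
)

import _oracles as O


def _toy_table(rng, n=60, n_noise=6):
    y = rng.integers(0, 2, n)
    data = {"label_copy": y.astype(float) + rng.normal(0, 0.01, n)}
    for k in range(n_noise):
        data[f"noise{k}"] = rng.normal(0, 1, n)
    return pd.DataFrame(data), y


class TestMRMR:
    def test_label_copy_ranked_first(self, rng):
        X, y = _toy_table(rng)
        assert mrmr_rank(X, y)[0] == "label_copy"

    def test_redundancy_penalty_on_duplicate_label_copy(self, rng):
        """With two exact label copies and a weak feature, the second-pick
        scores match a brute-force mRMR scorer, and the duplicate's score
        collapses from full relevance to ~0 under the redundancy penalty."""
        n = 80
        y = rng.integers(0, 2, n)
        weak = y + rng.normal(0, 1.2, n)
        X = pd.DataFrame({"copy_a": y.astype(float), "copy_b": y.astype(float),
                          "weak": weak})
        ranked = mrmr_rank(X, y, n_select=2)
        assert ranked[0] in ("copy_a", "copy_b")
        disc = {c: _quantile_discretize(X[c].to_numpy()) for c in X}
        rel_copy = O.oracle_mrmr_scores(disc, y, [], "copy_b")
        score_copy = O.oracle_mrmr_scores(disc, y, [ranked[0]], "copy_b")
        score_weak = O.oracle_mrmr_scores(disc, y, [ranked[0]], "weak")
        assert rel_copy > 0.5          # duplicate carries full relevance...
        assert abs(score_copy) < 1e-9  # ...which redundancy cancels entirely
        # implementation's second pick is the oracle argmax (ties -> column order)
        candidates = [c for c in X.columns if c != ranked[0]]
        scores = [O.oracle_mrmr_scores(disc, y, [ranked[0]], c)
                  for c in candidates]
        assert ranked[1] == candidates[int(np.argmax(scores))]
        assert score_weak == pytest.approx(scores[candidates.index("weak")])

    def test_column_permutation_invariance(self, rng):
        X, y = _toy_table(rng)
        shuffled = X[list(reversed(X.columns))]
        assert set(mrmr_rank(X, y, 3)) == set(mrmr_rank(shuffled, y, 3))
        assert mrmr_rank(X, y, 1) == mrmr_rank(shuffled, y, 1)

    def test_single_class_rejected(self, rng):
        X, _ = _toy_table(rng)
        with pytest.raises(ValueError):
            mrmr_rank(X, np.zeros(len(X), dtype=int))


class TestSMOTE:
    def test_two_point_segment_convexity(self, rng):
        minority = np.array([[0.0, 0.0], [2.0, 2.0]])
        synth = smote_oversample(minority, 1, 50, rng)
        assert synth.shape == (50, 2)
        # every point on the segment y = x, within the box
        np.testing.assert_allclose(synth[:, 0], synth[:, 1], atol=1e-12)
        assert np.all(synth >= 0.0) and np.all(synth <= 2.0)

    def test_interpolation_formula_midpoint(self):
        x = np.array([0.0, 0.0])
        x_nn = np.array([2.0, 2.0])
        t = 0.5
        np.testing.assert_array_equal(x + t * (x_nn - x), [1.0, 1.0])

    def test_convex_combination_of_real_rows(self, rng):
        minority = rng.normal(0, 1, (10, 4))
        synth = smote_oversample(minority, 3, 30, rng)
        lo = minority.min(axis=0) - 1e-12
        hi = minority.max(axis=0) + 1e-12
        assert np.all(synth >= lo) and np.all(synth <= hi)

    def test_balancing_arithmetic_45_vs_117(self, rng):
        X = rng.normal(0, 1, (162, 5))
        y = np.array([0] * 45 + [1] * 117)
        Xb, yb = balance_with_smote(X, y, 5, rng)
        assert (yb == 0).sum() == (yb == 1).sum() == 117
        assert len(Xb) == 234

    def test_minority_too_small_rejected(self, rng):
        with pytest.raises(ValueError):
            smote_oversample(np.zeros((1, 2)), 1, 5, rng)


def _feature_table(rng, n_healthy, n_path, n_features=12, separation=4.0):
    rows = []
    for i in range(n_healthy + n_path):
        path = i >= n_healthy
        mu = separation if path else 0.0
        feats = rng.normal(mu, 1.0, n_features)
        rows.append({
            "plane_id": f"p{i:03d}", "roi_id": f"roi{i % 3}",
            "tissue_class": "fibrotic" if path else "healthy",
            "binary_label": "pathologic" if path else "healthy",
            **{f"f{k}": feats[k] for k in range(n_features)},
        })
    return pd.DataFrame(rows)


class TestMCFolds:
    def test_printed_cohort_arithmetic(self, rng):
        table = _feature_table(rng, 56, 128)
        folds = build_mc_folds(table, n_folds=5, seed=0)
        for f in folds:
            assert len(f.validation_ids) == 22
            assert len(f.training_ids) == 162
            val_labels = table.set_index("plane_id").loc[
                list(f.validation_ids), "binary_label"]
            assert (val_labels == "healthy").sum() == 11
            assert (val_labels == "pathologic").sum() == 11
            assert not set(f.validation_ids) & set(f.training_ids)

    def test_folds_pairwise_distinct(self, rng):
        table = _feature_table(rng, 20, 40)
        folds = build_mc_folds(table, n_folds=10, seed=1)
        vals = [frozenset(f.validation_ids) for f in folds]
        assert len(set(vals)) == len(vals)

    def test_minority_five_gives_one_per_class(self, rng):
        table = _feature_table(rng, 5, 30)
        folds = build_mc_folds(table, n_folds=2, seed=2)
        assert all(len(f.validation_ids) == 2 for f in folds)

    def test_seeded_determinism(self, rng):
        table = _feature_table(rng, 20, 40)
        f1 = build_mc_folds(table, 4, seed=3)
        f2 = build_mc_folds(table, 4, seed=3)
        assert [f.validation_ids for f in f1] == [f.validation_ids for f in f2]

    def test_capacity_exhaustion(self, rng):
        table = _feature_table(rng, 5, 6)
        with pytest.raises(ValueError):
            build_mc_folds(table, n_folds=500, seed=0)


class TestScore:
    @pytest.mark.parametrize("tp,fn,tn,fp,acc,sens,spec", [
        (9, 1, 9, 1, 0.9, 0.9, 0.9),
        (10, 0, 10, 0, 1.0, 1.0, 1.0),
        (11, 0, 0, 11, 0.5, 1.0, 0.0),
    ])
    def test_confusion_arithmetic(self, tp, fn, tn, fp, acc, sens, spec):
        y_true = np.array([1] * (tp + fn) + [0] * (tn + fp))
        y_pred = np.array([1] * tp + [0] * fn + [0] * tn + [1] * fp)
        m = score(y_pred, y_true)
        assert (m.accuracy, m.sensitivity, m.specificity) == \
            pytest.approx((acc, sens, spec))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            score(np.array([1]), np.array([1, 0]))


class TestEnsemble:
    def test_separated_cohort_high_validation_accuracy(self, rng):
        table = _feature_table(rng, 20, 40, separation=5.0)
        model = ScarClassifier(table, d=4, n_folds=3, smote_k=3)
        res = model.fit(seed=0)
        for _, row in res.validation_metrics_frame().iterrows():
            assert row["accuracy"] >= 0.9

    def test_d_equals_total_features_is_reordering(self, rng):
        table = _feature_table(rng, 10, 14, n_features=5)
        model = ScarClassifier(table, d=5, n_folds=2, smote_k=2)
        res = model.fit(seed=0)
        for ff in res.fold_fits:
            assert sorted(ff.selected_features) == [f"f{k}" for k in range(5)]

    def test_same_fold_seed_identical_selection(self, rng):
        table = _feature_table(rng, 12, 20)
        model = ScarClassifier(table, d=3, n_folds=2, smote_k=3)
        r1 = model.fit(seed=5)
        r2 = model.fit(seed=5)
        assert [f.selected_features for f in r1.fold_fits] == \
            [f.selected_features for f in r2.fold_fits]

    def test_no_validation_leakage(self, rng):
        """Corrupting validation-row features does not change the fitted
        selection or the validation-row-independent training pipeline."""
        table = _feature_table(rng, 12, 20)
        model = ScarClassifier(table, d=3, n_folds=1, smote_k=3)
        res = model.fit(seed=7)
        fold = res.fold_fits[0].fold
        corrupted = table.copy()
        val_rows = corrupted["plane_id"].isin(fold.validation_ids)
        feat_cols = [c for c in corrupted.columns if c.startswith("f")]
        corrupted.loc[val_rows, feat_cols] = 1e6
        model2 = ScarClassifier(corrupted, d=3, n_folds=1, smote_k=3)
        res2 = model2.fit(seed=7)
        assert res2.fold_fits[0].selected_features == \
            res.fold_fits[0].selected_features

    def test_scrambled_labels_near_chance(self, rng):
        table = _feature_table(rng, 30, 50, separation=5.0)
        scrambled = table.copy()
        perm = rng.permutation(len(table))
        scrambled["binary_label"] = table["binary_label"].to_numpy()[perm]
        scrambled["tissue_class"] = table["tissue_class"].to_numpy()[perm]
        res = ScarClassifier(scrambled, d=4, n_folds=5, smote_k=3).fit(seed=0)
        acc = res.pooled_validation_metrics().accuracy
        assert 0.3 <= acc <= 0.7

    def test_summary_contains_key_sections(self, rng):
        table = _feature_table(rng, 10, 14)
        res = ScarClassifier(table, d=3, n_folds=2, smote_k=3).fit(seed=0)
        text = res.summary()
        assert "Pooled validation metrics" in text
        assert "accuracy" in text


class _StubClassifier:
    """Fixed-probability classifier for vote/tie-rule unit tests."""

    classes_ = [0, 1]

    def __init__(self, p):
        self.p = p

    def predict_proba(self, X):
        return np.column_stack([np.full(len(X), 1 - self.p),
                                np.full(len(X), self.p)])


def _stub_results(probs, feature_names=("f0",)):
    from fibroscar.ml import FoldFit, MCFold

    model = ScarClassifier.__new__(ScarClassifier)
    model.feature_names = list(feature_names)
    fold = MCFold(fold_id=0, validation_ids=(), training_ids=(), seed=0)
    ff = FoldFit(fold=fold, selected_features=list(feature_names),
                 classifiers={f"c{i}": _StubClassifier(p)
                              for i, p in enumerate(probs)},
                 validation_metrics={})
    return ScarClassifierResults(model=model, fold_fits=[ff], seed=0)


class TestVoteAggregation:
    def _table(self):
        return pd.DataFrame({"plane_id": ["a"], "f0": [0.0]})

    def test_majority_vote(self):
        res = _stub_results([0.9, 0.8, 0.2])
        out = res.predict(self._table())
        assert out.loc[0, "vote"] == "pathologic"

    def test_rho_is_arithmetic_mean(self):
        res = _stub_results([0.9, 0.8, 1.0])
        assert res.predict(self._table()).loc[0, "rho"] == pytest.approx(0.9)

    def test_even_split_tie_resolved_by_rho(self):
        res = _stub_results([0.5, 0.5])
        out = res.predict(self._table())
        assert out.loc[0, "vote"] == "pathologic"
        res_low = _stub_results([0.1, 0.51])
        assert res_low.predict(self._table()).loc[0, "vote"] == "healthy"

    def test_feature_mismatch_rejected(self):
        res = _stub_results([0.5], feature_names=("missing_feature",))
        with pytest.raises(ValueError):
            res.predict(pd.DataFrame({"plane_id": ["a"], "f0": [1.0]}))
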