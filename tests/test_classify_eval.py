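import math
import random

import numpy as np
import pytest

from pressc.classify_eval import (
    NEGATIVE_LABEL,
    POSITIVE_LABEL,
    PRESETS,
    ConfusionCounts,
    EvaluationError,
    SvmConfig,
    _roc_and_auc,
    cross_validate,
    default_param_grid,
    default_svm_grid,
    grid_search,
    load_model,
    metrics_from_counts,
    predict,
    save_model,
    train,
)
from pressc.features import FeatureVector, PsesscParams


def textbook_mcc(n_pos, n_neg, fn, fp):
    """Independent oracle: (TP*TN - FP*FN) / sqrt(prod of marginals)."""
    tp, tn = n_pos - fn, n_neg - fp
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return None
    return (tp * tn - fp * fn) / math.sqrt(denom)


class TestMetrics:
    def test_perfect_prediction(self):
        m = metrics_from_counts(ConfusionCounts(100, 100, 0, 0))
        assert (m.sn, m.sp, m.acc, m.mcc) == (1.0, 1.0, 1.0, 1.0)

    def test_random_prediction(self):
        m = metrics_from_counts(ConfusionCounts(200, 200, 100, 100))
        assert m.mcc == 0.0

    def test_total_disagreement(self):
        m = metrics_from_counts(ConfusionCounts(100, 100, 100, 100))
        assert m.mcc == -1.0
        assert m.acc == 0.0

    def test_invalid_counts(self):
        with pytest.raises(EvaluationError):
            ConfusionCounts(0, 10, 0, 0)
        with pytest.raises(EvaluationError):
            ConfusionCounts(10, 10, 11, 0)

    def test_mcc_equals_textbook_brute_force(self):
        # Every confusion table with N+, N- <= 20.
        for n_pos in range(1, 21):
            for n_neg in range(1, 21):
                for fn in range(n_pos + 1):
                    for fp in range(n_neg + 1):
                        got = metrics_from_counts(
                            ConfusionCounts(n_pos, n_neg, fn, fp)
                        ).mcc
                        want = textbook_mcc(n_pos, n_neg, fn, fp)
                        if want is None:
                            assert got is None
                        else:
                            assert got == pytest.approx(want, abs=1e-12)

    def test_acc_identity(self):
        rng = random.Random(5)
        for _ in range(200):
            n_pos, n_neg = rng.randrange(1, 50), rng.randrange(1, 50)
            c = ConfusionCounts(n_pos, n_neg, rng.randrange(n_pos + 1), rng.randrange(n_neg + 1))
            m = metrics_from_counts(c)
            assert m.acc == pytest.approx((m.sn * n_pos + m.sp * n_neg) / (n_pos + n_neg))

    def test_undefined_when_all_predicted_one_class(self):
        # fn = n_pos, fp = 0: everything predicted negative.
        m = metrics_from_counts(ConfusionCounts(5, 5, 5, 0))
        assert m.mcc is None


_PARAMS = PsesscParams(n=1, lam=1, w=0.5)  # dimension 11


def _vectors(centers_labels, per_class=10, seed=0, spread=0.05):
    rng = np.random.default_rng(seed)
    out = []
    for ci, (center, label) in enumerate(centers_labels):
        for k in range(per_class):
            values = center + rng.normal(0, spread, size=11)
            out.append(FeatureVector(
                record_id=f"c{ci}_{k}", kind="PseSSC", params=_PARAMS,
                values=values, label=label))
    return out


def _separable(per_class=10, seed=0):
    return _vectors(
        [(np.zeros(11), "negative"), (np.ones(11), "positive")],
        per_class=per_class, seed=seed)


class TestTrainPredict:
    def test_separable_training_accuracy(self):
        vecs = _separable()
        model = train(vecs, SvmConfig(C=8.0, gamma=0.5))
        labels, _ = predict(model, vecs)
        want = [POSITIVE_LABEL if v.label == "positive" else NEGATIVE_LABEL for v in vecs]
        assert labels == want

    def test_conflicting_duplicates_tolerated(self):
        base = np.full(11, 0.5)
        vecs = [
            FeatureVector(record_id=f"r{i}", kind="PseSSC", params=_PARAMS,
                          values=base, label="positive" if i % 2 else "negative")
            for i in range(8)
        ]
        model = train(vecs, SvmConfig())
        labels, _ = predict(model, vecs)
        want = [POSITIVE_LABEL if v.label == "positive" else NEGATIVE_LABEL for v in vecs]
        assert labels != want  # cannot be perfect on contradictions

    def test_single_class_error(self):
        vecs = _vectors([(np.zeros(11), "negative")])
        with pytest.raises(EvaluationError, match="both classes"):
            train(vecs, SvmConfig())

    def test_dimension_mismatch_error(self):
        model = train(_separable(), SvmConfig())
        other = FeatureVector(record_id="o", kind="PseSSC",
                              params=PsesscParams(n=1, lam=3, w=0.5),
                              values=np.zeros(13), label=None)
        with pytest.raises(EvaluationError, match="11"):
            predict(model, [other])

    def test_empty_predict(self):
        model = train(_separable(), SvmConfig())
        labels, scores = predict(model, [])
        assert labels == [] and len(scores) == 0

    def test_persisted_bundle_identical_predictions(self, tmp_path):
        vecs = _separable(seed=3)
        model = train(vecs, SvmConfig())
        path = str(tmp_path / "model.joblib")
        save_model(model, path)
        reloaded = load_model(path)
        l1, s1 = predict(model, vecs)
        l2, s2 = predict(reloaded, vecs)
        assert l1 == l2
        assert np.array_equal(s1, s2)


class TestRocAuc:
    def test_tie_only_scores_give_half(self):
        y = np.array([1, 1, 0, 0])
        _, auc = _roc_and_auc(y, np.zeros(4))
        assert auc == 0.5

    def test_perfect_ranking(self):
        y = np.array([1, 1, 0, 0])
        points, auc = _roc_and_auc(y, np.array([2.0, 1.5, -1.0, -2.0]))
        assert auc == 1.0
        assert points[0] == (0.0, 0.0) and points[-1] == (1.0, 1.0)

    def test_rank_auc_equals_trapezoid_on_random_scores(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(4, 30))
            y = np.zeros(n, dtype=int)
            y[: max(1, n // 3)] = 1
            rng.shuffle(y)
            scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
            points, auc = _roc_and_auc(y, scores)
            xs, ys = zip(*points)
            assert auc == pytest.approx(np.trapezoid(ys, xs), abs=1e-12)


class TestCrossValidate:
    def test_separable_jackknife_perfect(self):
        vecs = _separable(per_class=8)
        result = cross_validate(vecs, SvmConfig(C=8.0, gamma=0.5), scheme="jackknife")
        assert result.metrics.acc == 1.0
        assert result.auc == 1.0

    def test_k_equals_n_matches_jackknife(self):
        vecs = _separable(per_class=6, seed=2)
        jk = cross_validate(vecs, SvmConfig(), scheme="jackknife")
        kf = cross_validate(vecs, SvmConfig(), scheme="kfold", k=len(vecs))
        assert jk.counts == kf.counts

    def test_invalid_k(self):
        vecs = _separable(per_class=4)
        with pytest.raises(EvaluationError):
            cross_validate(vecs, SvmConfig(), scheme="kfold", k=1)
        with pytest.raises(EvaluationError):
            cross_validate(vecs, SvmConfig(), scheme="kfold", k=100)

    def test_jackknife_order_invariance(self):
        vecs = _separable(per_class=6, seed=4)
        shuffled = list(vecs)
        random.Random(0).shuffle(shuffled)
        a = cross_validate(vecs, SvmConfig(), scheme="jackknife")
        b = cross_validate(shuffled, SvmConfig(), scheme="jackknife")
        assert a.counts == b.counts
        # libsvm's optimizer is order-sensitive at ~1e-5; scores must agree
        # to well within that, per record.
        for rid, val in a.decision_values.items():
            assert b.decision_values[rid] == pytest.approx(val, abs=1e-3)


class TestGridSearch:
    def test_paper_grid_has_800_cells(self):
        assert len(default_param_grid()) == 800

    def test_default_svm_grid_shape(self):
        grid = default_svm_grid()
        assert len(grid) == 11 * 10
        assert min(c.C for c in grid) == 2.0 ** -5
        assert max(c.C for c in grid) == 2.0 ** 15

    def test_single_cell_returned(self):
        vecs = _separable(per_class=10)
        params = PsesscParams(n=1, lam=1, w=0.5)
        best_p, best_c, cells = grid_search(
            lambda p: vecs, [params], [SvmConfig(C=2.0, gamma=0.25)], folds=3)
        assert best_p == params
        assert best_c == SvmConfig(C=2.0, gamma=0.25)
        assert len(cells) == 1

    def test_tie_breaks_on_smaller_lam(self):
        vecs = _separable(per_class=10)

        def featurize(params):
            # Same 11-dim values regardless of params: all cells tie.
            return [FeatureVector(record_id=v.record_id, kind="PseSSC",
                                  params=params,
                                  values=np.resize(v.values, params.pse_dim),
                                  label=v.label)
                    for v in vecs]

        p_big = PsesscParams(n=1, lam=5, w=0.5)
        p_small = PsesscParams(n=1, lam=1, w=0.5)
        best_p, _, _ = grid_search(featurize, [p_big, p_small],
                                   [SvmConfig(C=8.0, gamma=0.5)], folds=3)
        assert best_p == p_small

    def test_infeasible_cell_skipped_with_warning(self, caplog):
        vecs = _separable(per_class=6)

        def featurize(params):
            if params.lam > 1:
                raise ValueError("lam too large for these sequences")
            return vecs

        with caplog.at_level("WARNING"):
            best_p, _, cells = grid_search(
                featurize,
                [PsesscParams(n=1, lam=1, w=0.5), PsesscParams(n=1, lam=9, w=0.5)],
                [SvmConfig()], folds=3)
        assert best_p.lam == 1
        assert "skipping" in caplog.text


def test_presets_match_published_optima():
    params, cfg = PRESETS["pressc"]
    assert (params.n, params.lam, params.w) == (2, 13, 0.5)
    assert (cfg.C, cfg.gamma) == (8.0, 2.0 ** -5)
    params, cfg = PRESETS["expressc"]
    assert (params.n, params.lam, params.w) == (1, 17, 0.2)
    assert (cfg.C, cfg.gamma) == (128.0, 2.0 ** -7)
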