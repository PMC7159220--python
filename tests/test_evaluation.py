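"""Confusion metrics, box statistics, and cross-validation orchestration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grimace.classifier import Prediction, TrainConfig, build_own_cnn
from grimace.evaluation import (
    BoxStats,
    ConfusionCounts,
    MetricResult,
    box_stats,
    confidence_over_time,
    confusion,
    cross_validate,
    metrics,
)
from grimace.labeling import subject_kfold


class TestConfusion:
    def test_all_correct(self):
        c = confusion(["effect", "no_effect"], ["effect", "no_effect"])
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 1, 0, 0)

    def test_enumerated_four_cases(self):
        c = confusion(["effect", "effect", "no_effect", "no_effect"],
                      ["effect", "no_effect", "effect", "no_effect"])
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 1)

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(0)
        labs = np.array(["effect", "no_effect"])
        p = labs[rng.integers(0, 2, 1000)]
        t = labs[rng.integers(0, 2, 1000)]
        c = confusion(p, t)
        assert c.tp == sum(1 for a, b in zip(p, t) if a == b == "effect")
        assert c.tn == sum(1 for a, b in zip(p, t) if a == b == "no_effect")
        assert c.fp == sum(1 for a, b in zip(p, t) if a == "effect" != b)
        assert c.fn == sum(1 for a, b in zip(p, t) if a == "no_effect" != b)
        assert c.total == 1000

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion(["effect"], ["effect", "no_effect"])

    def test_unknown_label_errors(self):
        with pytest.raises(ValueError, match="unknown"):
            confusion(["maybe"], ["effect"])


class TestMetrics:
    def test_arithmetic(self):
        m = metrics(ConfusionCounts(tp=9, tn=8, fp=1, fn=2))
        assert m.accuracy == pytest.approx(0.85)
        assert m.tpr == pytest.approx(9 / 11)
        assert m.tnr == pytest.approx(8 / 9)

    def test_tpr_three_quarters(self):
        m = metrics(ConfusionCounts(tp=3, tn=0, fp=1, fn=1))
        assert m.tpr == pytest.approx(0.75)

    def test_undefined_ratio_flagged_not_raised(self):
        m = metrics(ConfusionCounts(tp=0, tn=5, fp=2, fn=0))
        assert np.isnan(m.tpr)
        assert m.undefined == {"tpr"}
        assert not np.isnan(m.tnr)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            metrics(ConfusionCounts(0, 0, 0, 0))

    def test_pair_permutation_invariance(self):
        rng = np.random.default_rng(1)
        labs = np.array(["effect", "no_effect"])
        p = labs[rng.integers(0, 2, 60)]
        t = labs[rng.integers(0, 2, 60)]
        m1 = metrics(confusion(p, t))
        perm = rng.permutation(60)
        m2 = metrics(confusion(p[perm], t[perm]))
        assert m1 == m2

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(tp=st.integers(0, 50), tn=st.integers(0, 50),
           fp=st.integers(0, 50), fn=st.integers(0, 50))
    def test_accuracy_is_prevalence_weighted_tpr_tnr(self, tp, tn, fp, fn):
        if tp + tn + fp + fn == 0:
            return
        m = metrics(ConfusionCounts(tp, tn, fp, fn))
        pos, neg = tp + fn, tn + fp
        if pos and neg:
            expected = (m.tpr * pos + m.tnr * neg) / (pos + neg)
            assert m.accuracy == pytest.approx(expected)
            assert min(m.tpr, m.tnr) - 1e-12 <= m.accuracy <= max(m.tpr, m.tnr) + 1e-12


class TestBoxStats:
    def test_odd_length_median(self):
        bs = box_stats([0, 0, 0.2, 0.4, 0.6])
        assert bs.median == pytest.approx(0.2)

    def test_constant_values(self):
        bs = box_stats([0.7] * 8)
        assert bs.q25 == bs.q75 == bs.median == pytest.approx(0.7)
        assert bs.whisker_low == bs.whisker_high == pytest.approx(0.7)
        assert bs.outliers == ()

    def test_against_independent_quantiles(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(0, 1, 200)
        bs = box_stats(vals)
        # independent implementation: pandas quantiles + manual whiskers
        s = pd.Series(vals)
        q25, med, q75 = s.quantile([0.25, 0.5, 0.75])
        assert bs.q25 == pytest.approx(q25)
        assert bs.median == pytest.approx(med)
        assert bs.q75 == pytest.approx(q75)
        iqr = q75 - q25
        inside = s[(s >= q25 - 1.5 * iqr) & (s <= q75 + 1.5 * iqr)]
        assert bs.whisker_low == pytest.approx(inside.min())
        assert bs.whisker_high == pytest.approx(inside.max())
        assert len(bs.outliers) == int((~s.isin(inside)).sum())

    def test_whiskers_are_data_values(self):
        vals = [0.0, 1.0, 1.1, 1.2, 1.3, 9.0]
        bs = box_stats(vals)
        assert bs.whisker_high in vals
        assert bs.whisker_low in vals
        assert 9.0 in bs.outliers

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            box_stats([])


class TestConfidenceOverTime:
    def _setup(self):
        rng = np.random.default_rng(3)
        rows, preds = [], []
        for t in ("baseline", "30min"):
            for i in range(6):
                rows.append({"animal_id": f"a{i % 2}", "treatment": "KXN",
                             "time_label": t, "binary_label": "no_effect",
                             "mean_latent_score": rng.uniform(0, 2)})
                preds.append(Prediction.from_confidence(
                    [rng.uniform(0.01, 0.99), 0.5][0:1] + [0.0]))
        # renormalize fake confidences properly
        preds = [Prediction.from_confidence([p.confidence[0], 1 - p.confidence[0]])
                 for p in preds]
        return preds, pd.DataFrame(rows)

    def test_group_medians_match_brute_force(self):
        preds, records = self._setup()
        out = confidence_over_time(preds, records)
        df = records.copy()
        df["conf"] = [p.confidence[0] for p in preds]
        for _, row in out.iterrows():
            grp = df[(df["treatment"] == row["treatment"])
                     & (df["time_label"] == row["time_label"])]
            assert row["confidence"].median == pytest.approx(grp["conf"].median())

    def test_rows_follow_canonical_grid_order(self):
        preds, records = self._setup()
        out = confidence_over_time(preds, records)
        assert list(out["time_label"]) == ["baseline", "30min"]

    def test_mgs_panel_optional(self):
        preds, records = self._setup()
        with_mgs = confidence_over_time(preds, records)
        assert "mgs" in with_mgs.columns
        without = confidence_over_time(
            preds, records.drop(columns=["mean_latent_score"]))
        assert "mgs" not in without.columns

    def test_constant_confidence_group(self):
        records = pd.DataFrame([
            {"animal_id": "a", "treatment": "IN", "time_label": "30min",
             "binary_label": "effect"}] * 4)
        preds = [Prediction.from_confidence([1.0, 0.0])] * 4
        out = confidence_over_time(preds, records)
        bs = out.loc[0, "confidence"]
        assert bs.median == 1.0
        assert bs.q75 - bs.q25 == 0.0


class TestFigures:
    def test_confidence_plot_smoke(self, tmp_path):
        from grimace.evaluation import plot_confidence_over_time

        rng = np.random.default_rng(7)
        records = pd.DataFrame([
            {"animal_id": f"a{i % 3}", "treatment": "KXN", "time_label": t,
             "binary_label": "no_effect", "mean_latent_score": rng.uniform(0, 2)}
            for t in ("baseline", "30min") for i in range(6)])
        preds = [Prediction.from_confidence([c, 1 - c])
                 for c in rng.uniform(0.05, 0.95, len(records))]
        summary = confidence_over_time(preds, records)
        fig = plot_confidence_over_time(summary, tmp_path / "conf.png")
        assert (tmp_path / "conf.png").exists()
        assert fig.axes

    def test_matrix_plot_smoke(self, tmp_path):
        from grimace.evaluation import plot_cross_treatment_matrix

        rows = [{"train_treatment": a, "test_treatment": b,
                 "accuracy_mean": 0.5 + 0.3 * (a == b),
                 "accuracy_sd": 0.05, "subject_overlap": a != b and a == "C",
                 "diagonal": a == b}
                for a in ("IN", "KXN", "C") for b in ("IN", "KXN", "C")]
        fig = plot_cross_treatment_matrix(pd.DataFrame(rows),
                                          tmp_path / "matrix.svg")
        assert (tmp_path / "matrix.svg").exists()
        assert fig.axes


class TestCrossValidate:
    def test_matches_manual_fold_replay(self):
        """Orchestrated per-fold metrics equal running one fold by hand."""
        from grimace.classifier import predict as predict_images
        from grimace.classifier import train as train_model
        from grimace.evaluation import confusion as conf
        from grimace.labeling import balance_by_subsampling
        from grimace.synth import DatasetConfig, generate_dataset

        ds = generate_dataset(DatasetConfig(
            animals={"KXN": 6}, images_per_time=2,
            time_labels={"KXN": ("baseline", "30min")}), 31)
        cfg = TrainConfig(input_size=(16, 16), epochs=2, batch_size=20, seed=0)
        from grimace.classifier import preprocess_batch

        x = preprocess_batch(ds.images, cfg)
        folds = subject_kfold(ds.frame, 3, rng_seed=5)

        def builder(s):
            return build_own_cnn((16, 16), seed=s)

        res = cross_validate(ds.frame, x, folds, builder, cfg, seed=3)
        assert len(res.per_fold) == 3
        assert len(res.loss_traces[0]) == cfg.epochs

        # replay fold 0 manually with the same seeds
        fold = folds[0]
        rec = ds.frame
        tr = rec[rec["animal_id"].isin(fold.train_animals)]
        tr = balance_by_subsampling(tr, rng_seed=3 * 1009 + 0)
        model = builder(3 * 10007 + 0)
        train_model(model, x[[rec.index.get_loc(i) for i in tr.index]],
                    tr["binary_label"].to_numpy(), cfg)
        te_mask = rec["animal_id"].isin(fold.test_animals).to_numpy()
        preds = predict_images(model, x[te_mask])
        manual = metrics(conf([p.hard_label for p in preds],
                              rec[te_mask]["binary_label"]))
        assert res.per_fold[0] == manual

    def test_identical_fold_metrics_give_zero_sd(self):
        from grimace.evaluation import _summarize

        m = MetricResult(accuracy=0.8, tpr=0.8, tnr=0.8)
        summary = _summarize([m, m, m])
        assert summary["accuracy"] == (pytest.approx(0.8), pytest.approx(0.0))

    def test_mean_of_two_folds(self):
        from grimace.evaluation import _summarize

        summary = _summarize([
            MetricResult(accuracy=0.8, tpr=0.8, tnr=0.8),
            MetricResult(accuracy=1.0, tpr=1.0, tnr=1.0)])
        assert summary["accuracy"][0] == pytest.approx(0.9)
        assert summary["accuracy"][1] == pytest.approx(np.std([0.8, 1.0], ddof=1))

    def test_unknown_animal_in_fold_errors(self):
        from grimace.labeling import FoldSpec
        from grimace.synth import DatasetConfig, generate_dataset
        from grimace.classifier import preprocess_batch

        ds = generate_dataset(DatasetConfig(
            animals={"KXN": 2}, images_per_time=1,
            time_labels={"KXN": ("baseline", "30min")}), 1)
        cfg = TrainConfig(input_size=(16, 16), epochs=1)
        x = preprocess_batch(ds.images, cfg)
        bad = FoldSpec(0, frozenset({"ghost"}),
                       frozenset(ds.frame["animal_id"].unique()))
        with pytest.raises(ValueError, match="ghost"):
            cross_validate(ds.frame, x, [bad],
                           lambda s: build_own_cnn((16, 16), seed=s), cfg)
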