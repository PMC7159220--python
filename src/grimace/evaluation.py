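"""Confusion metrics, cross-validation orchestration and summaries.

"effect" is the positive class throughout: TPR (sensitivity) is
tp/(tp+fn), TNR (specificity) tn/(tn+fp), accuracy (tp+tn)/total.
Cross-validated results are summarised as mean +/- sample standard
deviation (ddof=1) over folds.  Undefined ratios (e.g. a single-animal
test fold containing only one class) are flagged and excluded from fold
means with a warning, never silently zeroed.

Box statistics follow the 1.5 x IQR whisker convention: the box spans
the 25th-75th percentile (linear interpolation between order
statistics), whiskers reach the most extreme data values within
1.5 x IQR of the quartiles, and points beyond are outliers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from .classifier import (
    CLASSES,
    TrainConfig,
    average_group_confidence,
    predict,
    train,
)
from .labeling import (
    CrossTreatmentSpec,
    FoldSpec,
    balance_by_subsampling,
    cross_treatment_design,
    subject_kfold,
)
from .utils import stable_seed

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "MetricResult",
    "BoxStats",
    "confusion",
    "metrics",
    "box_stats",
    "cross_validate",
    "CrossValResult",
    "cross_treatment_matrix",
    "confidence_over_time",
    "plot_confidence_over_time",
    "plot_cross_treatment_matrix",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricResult:
    """Accuracy/TPR/TNR; undefined ratios are NaN and listed in ``undefined``."""

    accuracy: float
    tpr: float
    tnr: float
    undefined: frozenset[str] = field(default_factory=frozenset)

    def as_dict(self) -> dict[str, float]:
        return {"accuracy": self.accuracy, "tpr": self.tpr, "tnr": self.tnr}


def confusion(pred_labels, true_labels) -> ConfusionCounts:
    """Cross-tabulate hard predictions against labels ("effect" positive)."""
    pred_labels = list(pred_labels)
    true_labels = list(true_labels)
    if len(pred_labels) != len(true_labels):
        raise ValueError(
            f"length mismatch: {len(pred_labels)} predictions vs "
            f"{len(true_labels)} labels")
    for lab in (*pred_labels, *true_labels):
        if lab not in CLASSES:
            raise ValueError(f"unknown label {lab!r}")
    pos = CLASSES[0]
    tp = sum(p == pos and t == pos for p, t in zip(pred_labels, true_labels))
    tn = sum(p != pos and t != pos for p, t in zip(pred_labels, true_labels))
    fp = sum(p == pos and t != pos for p, t in zip(pred_labels, true_labels))
    fn = sum(p != pos and t == pos for p, t in zip(pred_labels, true_labels))
    return ConfusionCounts(tp, tn, fp, fn)


def metrics(counts: ConfusionCounts) -> MetricResult:
    if counts.total == 0:
        raise ValueError("no evaluated units")
    undefined = set()

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.add(name)
            return float("nan")
        return num / den

    return MetricResult(
        accuracy=(counts.tp + counts.tn) / counts.total,
        tpr=ratio(counts.tp, counts.tp + counts.fn, "tpr"),
        tnr=ratio(counts.tn, counts.tn + counts.fp, "tnr"),
        undefined=frozenset(undefined),
    )


@dataclass(frozen=True)
class BoxStats:
    median: float
    q25: float
    q75: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]


def box_stats(values) -> BoxStats:
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("box_stats needs at least one value")
    q25, med, q75 = np.percentile(values, [25, 50, 75])  # linear interpolation
    iqr = q75 - q25
    lo_lim, hi_lim = q25 - 1.5 * iqr, q75 + 1.5 * iqr
    inside = values[(values >= lo_lim) & (values <= hi_lim)]
    outliers = values[(values < lo_lim) | (values > hi_lim)]
    return BoxStats(
        median=float(med), q25=float(q25), q75=float(q75),
        whisker_low=float(inside.min()), whisker_high=float(inside.max()),
        outliers=tuple(float(v) for v in np.sort(outliers)),
    )


# ---------------------------------------------------------------------------
# cross-validation


def _summarize(fold_results: list[MetricResult]) -> dict[str, tuple[float, float]]:
    out = {}
    for name in ("accuracy", "tpr", "tnr"):
        vals = np.array([getattr(r, name) for r in fold_results], dtype=float)
        defined = vals[~np.isnan(vals)]
        if len(defined) < len(vals):
            logger.warning(
                "%s undefined in %d of %d folds; excluded from the mean",
                name, len(vals) - len(defined), len(vals))
        mean = float(defined.mean()) if len(defined) else float("nan")
        sd = float(defined.std(ddof=1)) if len(defined) > 1 else float("nan")
        out[name] = (mean, sd)
    return out


@dataclass
class CrossValResult:
    per_fold: list[MetricResult]
    summary: dict[str, tuple[float, float]]
    per_fold_grouped: list[MetricResult] | None = None
    summary_grouped: dict[str, tuple[float, float]] | None = None
    loss_traces: list[list[float]] = field(default_factory=list)


def _fold_indices(records: pd.DataFrame, fold: FoldSpec) -> tuple[np.ndarray, np.ndarray]:
    known = set(records["animal_id"])
    unknown = (fold.train_animals | fold.test_animals) - known
    if unknown:
        raise ValueError(f"fold references unknown animal(s): {sorted(unknown)}")
    pos = {idx: i for i, idx in enumerate(records.index)}
    tr = records.index[records["animal_id"].isin(fold.train_animals)]
    te = records.index[records["animal_id"].isin(fold.test_animals)]
    return (np.array([pos[i] for i in tr]), np.array([pos[i] for i in te]))


def cross_validate(
    records: pd.DataFrame,
    x: np.ndarray,
    folds: list[FoldSpec],
    model_builder,
    config: TrainConfig | None = None,
    *,
    average: bool = False,
    balance: bool = True,
    seed: int = 0,
) -> CrossValResult:
    """Train and evaluate one model per fold.

    ``x`` is the preprocessed input tensor aligned row-for-row with
    ``records``.  The training portion of each fold is balanced by
    sub-sampling (the test portion is left as-is; TPR/TNR absorb test
    imbalance).  With ``average=True``, additionally evaluates per
    (animal, time) groups classified by mean confidence.
    """
    config = config or TrainConfig()
    per_fold, grouped, traces = [], [], []
    for fold in folds:
        tr_idx, te_idx = _fold_indices(records, fold)
        train_rec = records.iloc[tr_idx]
        if balance:
            train_rec = balance_by_subsampling(
                train_rec, rng_seed=seed * 1009 + fold.fold_index)
            tr_pos = {idx: p for idx, p in zip(records.index, range(len(records)))}
            tr_idx = np.array([tr_pos[i] for i in train_rec.index])
        model = model_builder(seed * 10007 + fold.fold_index)
        traces.append(train(model, x[tr_idx], train_rec["binary_label"].to_numpy(),
                            config))
        preds = predict(model, x[te_idx])
        test_rec = records.iloc[te_idx]
        per_fold.append(metrics(confusion(
            [p.hard_label for p in preds], test_rec["binary_label"])))
        if average:
            g = average_group_confidence(preds, test_rec)
            grouped.append(metrics(confusion(g["hard_label"], g["binary_label"])))
    return CrossValResult(
        per_fold=per_fold,
        summary=_summarize(per_fold),
        per_fold_grouped=grouped or None,
        summary_grouped=_summarize(grouped) if grouped else None,
        loss_traces=traces,
    )


# ---------------------------------------------------------------------------
# cross-treatment matrix


def cross_treatment_matrix(
    records: pd.DataFrame,
    x: np.ndarray,
    model_builder,
    config: TrainConfig | None = None,
    *,
    seed: int = 0,
    k_diagonal: int = 2,
    specs: list[CrossTreatmentSpec] | None = None,
) -> pd.DataFrame:
    """Accuracy for every train-treatment x test-treatment combination.

    Diagonal cells are evaluated subject-disjointly (``k_diagonal``-fold
    animal-level cross-validation inside the treatment); off-diagonal
    cells train one model on the full (size-matched) training subset and
    test on the other treatment, with the subject-overlap flag carried
    through.  Returns a long-format frame with one row per cell.
    """
    config = config or TrainConfig()
    if specs is None:
        specs = cross_treatment_design(records, rng_seed=seed)
    pos = {idx: i for i, idx in enumerate(records.index)}

    row_models: dict[str, object] = {}

    def fit_on(index_tuple, fit_seed: int):
        sub = records.loc[list(index_tuple)]
        sub = balance_by_subsampling(sub, rng_seed=fit_seed)
        idx = np.array([pos[i] for i in sub.index])
        model = model_builder(fit_seed)
        train(model, x[idx], sub["binary_label"].to_numpy(), config)
        return model

    rows = []
    for spec in specs:
        if spec.diagonal:
            sub = records.loc[list(spec.train_index)]
            folds = subject_kfold(
                sub, k_diagonal,
                rng_seed=stable_seed(seed, "diag", spec.train_treatment))
            res = cross_validate(sub, x[[pos[i] for i in sub.index]], folds,
                                 model_builder, config, seed=seed)
            acc_mean, acc_sd = res.summary["accuracy"]
        else:
            if spec.train_treatment not in row_models:
                row_models[spec.train_treatment] = fit_on(
                    spec.train_index, seed * 97 + len(row_models))
            model = row_models[spec.train_treatment]
            te = np.array([pos[i] for i in spec.test_index])
            preds = predict(model, x[te])
            m = metrics(confusion([p.hard_label for p in preds],
                                  records.iloc[te]["binary_label"]))
            acc_mean, acc_sd = m.accuracy, float("nan")
        rows.append({
            "train_treatment": spec.train_treatment,
            "test_treatment": spec.test_treatment,
            "accuracy_mean": acc_mean,
            "accuracy_sd": acc_sd,
            "subject_overlap": spec.subject_overlap,
            "diagonal": spec.diagonal,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# confidence over time


def confidence_over_time(
    predictions,
    records: pd.DataFrame,
    mgs_column: str | None = None,
) -> pd.DataFrame:
    """Per (treatment, time point) box statistics of effect confidence.

    When a grimace-score column is present (``mean_mgs``, or the
    generator's ``mean_latent_score``), its box statistics are reported
    alongside; otherwise that panel is omitted.  Rows follow each
    treatment's canonical acquisition grid.
    """
    from .labeling import TIME_GRID

    if len(predictions) != len(records):
        raise ValueError("predictions and records must align")
    df = records.reset_index(drop=True).copy()
    df["conf_effect"] = [p.confidence[0] for p in predictions]
    if mgs_column is None:
        for cand in ("mean_mgs", "mean_latent_score"):
            if cand in df.columns:
                mgs_column = cand
                break
    rows = []
    for treatment, grp in df.groupby("treatment", sort=True):
        grid = TIME_GRID.get(treatment, tuple(sorted(grp["time_label"].unique())))
        for t in grid:
            sub = grp[grp["time_label"] == t]
            if sub.empty:
                continue
            bs = box_stats(sub["conf_effect"])
            row = {"treatment": treatment, "time_label": t, "n": len(sub),
                   "confidence": bs}
            if mgs_column is not None:
                row["mgs"] = box_stats(sub[mgs_column])
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# detection-rate arithmetic (exact rationals, formatted late)


def rates_from_counts(accepted: int, total: int) -> Fraction:
    if total <= 0:
        raise ValueError("total must be positive")
    return Fraction(accepted, total)


# ---------------------------------------------------------------------------
# figures


def plot_confidence_over_time(summary: pd.DataFrame, path=None):
    """Box plots of effect-class confidence per time point, one panel per
    treatment (grimace-score boxes alongside when present).  ``summary``
    is the output of :func:`confidence_over_time`."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    def bxp_dict(bs: BoxStats, label):
        return {"med": bs.median, "q1": bs.q25, "q3": bs.q75,
                "whislo": bs.whisker_low, "whishi": bs.whisker_high,
                "fliers": [], "label": str(label)}

    treatments = list(summary["treatment"].unique())
    fig, axes = plt.subplots(1, len(treatments), squeeze=False,
                             figsize=(4 * len(treatments), 3.2))
    for ax, tr in zip(axes[0], treatments):
        sub = summary[summary["treatment"] == tr]
        stats_conf = [bxp_dict(r["confidence"], r["time_label"])
                      for _, r in sub.iterrows()]
        pos = np.arange(len(stats_conf)) * (2.5 if "mgs" in sub.columns else 1.0)
        ax.bxp(stats_conf, positions=pos, widths=0.8,
               boxprops={"color": "tab:blue"}, medianprops={"color": "tab:blue"})
        if "mgs" in sub.columns:
            stats_mgs = [bxp_dict(r["mgs"], "") for _, r in sub.iterrows()]
            ax.bxp(stats_mgs, positions=pos + 1.0, widths=0.8,
                   boxprops={"color": "grey"}, medianprops={"color": "grey"})
            ax.set_xticks(pos + 0.5)
            ax.set_xticklabels(sub["time_label"])
        ax.set_title(tr)
        ax.set_ylabel("effect confidence / grimace score")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
    return fig


def plot_cross_treatment_matrix(matrix: pd.DataFrame, path=None):
    """Heatmap of the train-treatment x test-treatment accuracy matrix;
    subject-overlap cells are marked SO."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    piv = matrix.pivot(index="train_treatment", columns="test_treatment",
                       values="accuracy_mean")
    flags = matrix.pivot(index="train_treatment", columns="test_treatment",
                         values="subject_overlap")
    fig, ax = plt.subplots(figsize=(4, 3.5))
    im = ax.imshow(piv.to_numpy(), vmin=0.0, vmax=1.0, cmap="viridis")
    ax.set_xticks(range(len(piv.columns)), piv.columns)
    ax.set_yticks(range(len(piv.index)), piv.index)
    ax.set_xlabel("test treatment")
    ax.set_ylabel("train treatment")
    for i, tr in enumerate(piv.index):
        for j, te in enumerate(piv.columns):
            label = f"{100 * piv.loc[tr, te]:.1f}"
            if flags.loc[tr, te]:
                label += "\nSO"
            ax.text(j, i, label, ha="center", va="center", color="white",
                    fontsize=8)
    fig.colorbar(im, ax=ax, label="accuracy")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
    return fig
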