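"""Binary labels, class balancing, and subject-disjoint split construction.

The label rule maps treatment x acquisition time to one of two states,
"effect" (post-anesthetic/surgical effect visible in the face) or
"no_effect".  Effect time points per procedure:

* isoflurane anesthesia (IN): 30 min post-procedure;
* ketamine/xylazine anesthesia (KXN): 30 min and 150 min;
* castration (C): 30 min, 150 min and 300 min.

Baseline images, later time points, and untreated animals are all
"no_effect".  Unknown treatment/time pairs are a hard error, never a
silent "no_effect".

Splits are built at the animal level ("subject" = mouse): an animal's
images never appear on both sides of a fold, which prevents identity
leakage and near-duplicate train/test images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ACTION_UNITS",
    "TIME_GRID",
    "EFFECT_TIMES",
    "LABELS",
    "FoldSpec",
    "CrossTreatmentSpec",
    "assign_binary_label",
    "balance_by_subsampling",
    "subject_kfold",
    "leave_one_animal_out",
    "cross_treatment_design",
    "folds_to_frame",
    "folds_from_frame",
]

ACTION_UNITS = (
    "orbital_tightening",
    "nose_bulge",
    "cheek_bulge",
    "ear_position",
    "whisker_change",
)

#: acquisition time grid per treatment; untreated animals were imaged on
#: the same grids as their matched treated groups, so they get the union
TIME_GRID: dict[str, tuple[str, ...]] = {
    "IN": ("baseline", "30min", "150min"),
    "KXN": ("baseline", "30min", "150min", "day2", "day9"),
    "C": ("baseline", "30min", "150min", "300min", "day2", "day3", "day7"),
}
TIME_GRID["untreated"] = tuple(dict.fromkeys(
    t for grid in (TIME_GRID["IN"], TIME_GRID["KXN"], TIME_GRID["C"]) for t in grid))

#: time points carrying the "effect" label, per treatment
EFFECT_TIMES: dict[str, frozenset[str]] = {
    "IN": frozenset({"30min"}),
    "KXN": frozenset({"30min", "150min"}),
    "C": frozenset({"30min", "150min", "300min"}),
    "untreated": frozenset(),
}

LABELS = ("effect", "no_effect")


def assign_binary_label(treatment: str, time_label: str) -> str:
    """Label one (treatment, time point) cell; errors on unknown pairs."""
    if treatment not in TIME_GRID:
        raise ValueError(f"unknown treatment {treatment!r}")
    if time_label not in TIME_GRID[treatment]:
        raise ValueError(
            f"unknown (treatment, time) pair ({treatment!r}, {time_label!r})")
    return "effect" if time_label in EFFECT_TIMES[treatment] else "no_effect"


def balance_by_subsampling(
    records: pd.DataFrame,
    rng_seed: int,
    label_col: str = "binary_label",
) -> pd.DataFrame:
    """Equalize class counts by uniform sub-sampling of the majority class.

    Returns a subset of ``records`` (original rows, original order) in
    which both classes have exactly min(class counts) rows.  Never
    fabricates records.  Raises if a class is absent.
    """
    counts = records[label_col].value_counts()
    missing = [lab for lab in LABELS if lab not in counts.index]
    if missing:
        raise ValueError(f"cannot balance: class(es) absent: {missing}")
    n_min = int(counts.min())
    rng = np.random.default_rng(rng_seed)
    keep = []
    for lab in LABELS:
        idx = records.index[records[label_col] == lab].to_numpy()
        if len(idx) > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        keep.append(idx)
    keep_set = set(np.concatenate(keep).tolist())
    return records.loc[[i for i in records.index if i in keep_set]]


@dataclass(frozen=True)
class FoldSpec:
    """Train/test assignment of animal ids for one cross-validation fold."""

    fold_index: int
    train_animals: frozenset[str]
    test_animals: frozenset[str]

    def __post_init__(self) -> None:
        if self.train_animals & self.test_animals:
            raise ValueError("train and test animal sets overlap")


def subject_kfold(records: pd.DataFrame, k: int, rng_seed: int) -> list[FoldSpec]:
    """Partition animals (not images) into k near-equal test groups.

    Group sizes differ by at most one; fold i tests group i and trains
    on all other animals.  All images of an animal follow its
    assignment.
    """
    animals = np.array(sorted(records["animal_id"].unique()))
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(animals):
        raise ValueError(f"k={k} exceeds number of animals ({len(animals)})")
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(len(animals))
    groups = np.array_split(animals[perm], k)
    all_animals = frozenset(animals)
    return [
        FoldSpec(i, all_animals - frozenset(g), frozenset(g))
        for i, g in enumerate(groups)
    ]


def leave_one_animal_out(records: pd.DataFrame) -> list[FoldSpec]:
    """One fold per animal; fold i tests exactly animal i."""
    animals = sorted(records["animal_id"].unique())
    if len(animals) < 2:
        raise ValueError("leave-one-animal-out needs at least 2 animals")
    all_animals = frozenset(animals)
    return [
        FoldSpec(i, all_animals - {a}, frozenset({a}))
        for i, a in enumerate(animals)
    ]


def folds_to_frame(folds: list[FoldSpec]) -> pd.DataFrame:
    """Serialize folds as long-format rows (fold_index, animal_id, role)."""
    return pd.DataFrame([
        {"fold_index": f.fold_index, "animal_id": a, "role": role}
        for f in folds
        for role, animals in (("train", f.train_animals),
                              ("test", f.test_animals))
        for a in sorted(animals)])


def folds_from_frame(df: pd.DataFrame) -> list[FoldSpec]:
    """Inverse of :func:`folds_to_frame`."""
    required = {"fold_index", "animal_id", "role"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"fold table is missing column(s): {sorted(missing)}")
    folds = []
    for fi, grp in df.groupby("fold_index", sort=True):
        folds.append(FoldSpec(
            int(fi),
            frozenset(grp.loc[grp["role"] == "train", "animal_id"]),
            frozenset(grp.loc[grp["role"] == "test", "animal_id"])))
    return folds


@dataclass(frozen=True)
class CrossTreatmentSpec:
    """One cell of the cross-treatment train/test matrix."""

    train_treatment: str
    test_treatment: str
    train_index: tuple
    test_index: tuple
    subject_overlap: bool
    diagonal: bool = field(default=False)


def cross_treatment_design(
    records: pd.DataFrame,
    rng_seed: int = 0,
    treatments: tuple[str, ...] = ("IN", "KXN", "C"),
) -> list[CrossTreatmentSpec]:
    """Full train-treatment x test-treatment experiment matrix.

    The KXN subset (typically much larger) is first sub-sampled at the
    animal level so its image count does not exceed the smaller subsets,
    making the comparison fair.  Diagonal cells are marked for
    subject-disjoint splitting downstream; off-diagonal cells carry a
    subject-overlap flag whenever the same animal contributed images to
    both treatments.
    """
    missing = [t for t in treatments if t not in set(records["treatment"])]
    if missing:
        raise ValueError(f"treatment(s) absent from records: {missing}")
    subsets: dict[str, pd.DataFrame] = {
        t: records[records["treatment"] == t] for t in treatments}

    sizes = {t: len(df) for t, df in subsets.items()}
    target = min(sizes[t] for t in treatments if t != "KXN") if "KXN" in treatments else None
    if target is not None and sizes["KXN"] > target:
        rng = np.random.default_rng(rng_seed)
        kxn = subsets["KXN"]
        animals = rng.permutation(sorted(kxn["animal_id"].unique()))
        kept: list[str] = []
        total = 0
        for a in animals:
            n = int((kxn["animal_id"] == a).sum())
            if total + n <= target:
                kept.append(a)
                total += n
        if not kept:  # every single animal exceeds the target: keep one anyway? no -
            raise ValueError("cannot match KXN size: single animal exceeds target")
        subsets["KXN"] = kxn[kxn["animal_id"].isin(kept)]

    specs = []
    for tr in treatments:
        for te in treatments:
            train_df, test_df = subsets[tr], subsets[te]
            overlap = bool(
                set(train_df["animal_id"]) & set(test_df["animal_id"])) and tr != te
            specs.append(CrossTreatmentSpec(
                train_treatment=tr,
                test_treatment=te,
                train_index=tuple(train_df.index),
                test_index=tuple(test_df.index),
                subject_overlap=overlap,
                diagonal=tr == te,
            ))
    return specs
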