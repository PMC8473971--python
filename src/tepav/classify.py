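"""Coverage-stratified random-forest genotyping of TE presence/absence.

Two random forests are trained on identically structured inputs at two
sequencing depths (a 15x and a 30x model); at inference the model is
selected by each sample's realized coverage with a 25x switch point. The
probability of presence is thresholded into present (>= 0.7), absent
(<= 0.3) or ambiguous, and two post-classification filters remove TEs
that cannot be genotyped from short reads (not called present even in
their cognate sample) or that are ambiguous in more than 25% of samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.compose import ColumnTransformer
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import RepeatedStratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import OneHotEncoder

from .annotations import ABSENT, AMBIGUOUS, MISSING, PRESENT, CallMatrix
from .coverage import SampleCoverage

FEATURE_COLUMNS = ["start_cov", "end_cov", "order"]

#: Probability-of-presence thresholds: <= ABSENT_MAX -> absent,
#: >= PRESENT_MIN -> present, strictly between -> ambiguous.
ABSENT_MAX = 0.3
PRESENT_MIN = 0.7

#: Realized-coverage switch point between the 15x and the 30x model.
SWITCH_DEPTH = 25.0


@dataclass
class TrainingReport:
    cv_accuracy_mean: float
    cv_accuracy_se: float
    fold_scores: list[float]
    importances: dict[str, float]
    n_train: int

    def to_dict(self) -> dict:
        return {
            "cv_accuracy_mean": self.cv_accuracy_mean,
            "cv_accuracy_se": self.cv_accuracy_se,
            "fold_scores": list(self.fold_scores),
            "importances": dict(self.importances),
            "n_train": self.n_train,
        }


@dataclass
class ModelBundle:
    """The deployable pair of depth-stratified models plus thresholds."""

    model_15x: Pipeline
    model_30x: Pipeline
    switch_depth: float = SWITCH_DEPTH
    absent_max: float = ABSENT_MAX
    present_min: float = PRESENT_MIN
    training_report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.absent_max < self.present_min <= 1.0:
            raise ValueError(
                f"thresholds must satisfy 0 <= absent_max < present_min <= 1, "
                f"got ({self.absent_max}, {self.present_min})"
            )

    def model_for(self, coverage: SampleCoverage | float) -> Pipeline:
        return (
            self.model_30x
            if select_model(self, coverage) == "30x"
            else self.model_15x
        )

    def save(self, path: str | Path) -> None:
        joblib.dump(
            {"format": "tepav-model-bundle", "version": 1, "bundle": self}, path
        )

    @classmethod
    def load(cls, path: str | Path) -> "ModelBundle":
        payload = joblib.load(path)
        if payload.get("format") != "tepav-model-bundle":
            raise ValueError(f"{path}: not a tepav model bundle")
        return payload["bundle"]


def select_model(bundle: ModelBundle, coverage: SampleCoverage | float) -> str:
    """``"30x"`` if realized depth >= switch (default 25x), else ``"15x"``."""
    depth = coverage.realized_depth if isinstance(coverage, SampleCoverage) else float(coverage)
    if depth <= 0:
        raise ValueError(f"realized depth must be positive, got {depth}")
    return "30x" if depth >= bundle.switch_depth else "15x"


# ---------------------------------------------------------------------------
# Training


def assemble_training_set(
    truth: CallMatrix,
    features: pd.DataFrame,
    n_max: int = 500_000,
    balance: float = 0.5,
    groups: Mapping[str, str] | None = None,
    holdout: str | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Balanced training sample plus held-out test records.

    ``truth`` gives the binary present/absent label per (TE, sample);
    records whose truth is ambiguous or missing are dropped. ``groups``
    maps sample -> genome group and ``holdout`` names the group whose
    records form the test set (the leave-one-genome-out scheme); with no
    holdout the test frame is empty. The training sample is drawn without
    replacement at ~``balance`` present fraction, capped by availability
    (with a warning) when one class is scarce.
    """
    rng = np.random.default_rng(seed)
    truth_long = (
        truth.labels.stack().rename("label").rename_axis(["te_id", "sample_id"]).reset_index()
    )
    truth_long = truth_long[truth_long["label"].isin([PRESENT, ABSENT])]
    labeled = features.merge(truth_long, on=["te_id", "sample_id"], how="inner")
    labeled = labeled.dropna(subset=["start_cov", "end_cov"])

    if holdout is not None:
        if groups is None:
            raise ValueError("holdout requires a sample->group mapping")
        sample_group = labeled["sample_id"].map(groups)
        test = labeled[sample_group == holdout]
        pool = labeled[sample_group != holdout]
    else:
        test = labeled.iloc[0:0]
        pool = labeled

    pos = pool[pool["label"] == PRESENT]
    neg = pool[pool["label"] == ABSENT]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError(
            f"cannot balance training set: {len(pos)} present / {len(neg)} absent"
        )
    n_pos_target = int(round(n_max * balance))
    n_neg_target = n_max - n_pos_target
    n_each = min(n_pos_target, n_neg_target, len(pos), len(neg))
    if n_each < min(n_pos_target, n_neg_target):
        warnings.warn(
            f"training classes capped at availability: {n_each} per class "
            f"(requested {n_pos_target}/{n_neg_target}, available "
            f"{len(pos)}/{len(neg)})"
        )
    pos_idx = rng.choice(len(pos), size=n_each, replace=False)
    neg_idx = rng.choice(len(neg), size=n_each, replace=False)
    train = pd.concat([pos.iloc[np.sort(pos_idx)], neg.iloc[np.sort(neg_idx)]])
    train = train.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(
        drop=True
    )
    return train, test.reset_index(drop=True)


def _make_pipeline(seed: int, n_estimators: int) -> Pipeline:
    # With only 3 predictors every split considers all features; depth is
    # left unlimited.
    pre = ColumnTransformer(
        [("order", OneHotEncoder(handle_unknown="error"), ["order"])],
        remainder="passthrough",
    )
    rf = RandomForestClassifier(
        n_estimators=n_estimators,
        max_features=None,
        random_state=seed,
        n_jobs=1,
    )
    return Pipeline([("pre", pre), ("rf", rf)])


def train(
    train_set: pd.DataFrame,
    folds: int = 10,
    repeats: int = 3,
    seed: int = 0,
    n_estimators: int = 500,
    cv: bool = True,
) -> tuple[Pipeline, TrainingReport]:
    """Fit the presence/absence forest with repeated stratified k-fold CV.

    The report's accuracy is the mean over all fold evaluations; its SE is
    the standard error across the per-repeat means. Feature importances
    for the one-hot order levels are summed back into a single "order"
    importance.
    """
    X = train_set[FEATURE_COLUMNS]
    y = train_set["label"].to_numpy()
    bad = ~np.isfinite(X[["start_cov", "end_cov"]].to_numpy()).all(axis=1)
    if bad.any():
        raise ValueError(
            f"non-finite features in training rows {np.flatnonzero(bad)[:10].tolist()}"
        )
    if min((y == PRESENT).sum(), (y == ABSENT).sum()) < folds:
        raise ValueError(f"need >= {folds} examples per class for {folds}-fold CV")

    pipe = _make_pipeline(seed, n_estimators)
    fold_scores: list[float] = []
    cv_mean = cv_se = float("nan")
    if cv:
        splitter = RepeatedStratifiedKFold(
            n_splits=folds, n_repeats=repeats, random_state=seed
        )
        scores = cross_val_score(pipe, X, y, cv=splitter, scoring="accuracy", n_jobs=1)
        fold_scores = scores.tolist()
        cv_mean = float(scores.mean())
        repeat_means = scores.reshape(repeats, folds).mean(axis=1)
        cv_se = (
            float(repeat_means.std(ddof=1) / np.sqrt(repeats)) if repeats > 1 else 0.0
        )

    pipe.fit(X, y)
    names = pipe.named_steps["pre"].get_feature_names_out()
    raw = pipe.named_steps["rf"].feature_importances_
    importances = {"start_cov": 0.0, "end_cov": 0.0, "order": 0.0}
    for name, imp in zip(names, raw):
        if name.startswith("order__"):
            importances["order"] += float(imp)
        elif name.endswith("start_cov"):
            importances["start_cov"] = float(imp)
        elif name.endswith("end_cov"):
            importances["end_cov"] = float(imp)
    report = TrainingReport(
        cv_accuracy_mean=cv_mean,
        cv_accuracy_se=cv_se,
        fold_scores=fold_scores,
        importances=importances,
        n_train=len(train_set),
    )
    return pipe, report


# ---------------------------------------------------------------------------
# Classification


@dataclass(frozen=True)
class PresenceCall:
    te_id: str
    sample_id: str
    probability: float
    label: str


def label_from_probability(
    p: float, absent_max: float = ABSENT_MAX, present_min: float = PRESENT_MIN
) -> str:
    """Threshold rule with inclusive boundaries: p >= present_min is
    present, p <= absent_max is absent, everything between is ambiguous."""
    if p >= present_min:
        return PRESENT
    if p <= absent_max:
        return ABSENT
    return AMBIGUOUS


def classify_table(
    model: Pipeline,
    features: pd.DataFrame,
    absent_max: float = ABSENT_MAX,
    present_min: float = PRESENT_MIN,
) -> pd.DataFrame:
    """Classify many (TE, sample) feature rows at once.

    Returns the feature frame plus ``probability`` (of presence) and
    ``label`` columns. Rows with missing coverage get a missing label.
    """
    out = features.copy()
    valid = np.isfinite(out[["start_cov", "end_cov"]].to_numpy()).all(axis=1)
    prob = np.full(len(out), np.nan)
    if valid.any():
        proba = model.predict_proba(out.loc[valid, FEATURE_COLUMNS])
        present_col = list(model.named_steps["rf"].classes_).index(PRESENT)
        prob[valid] = proba[:, present_col]
    out["probability"] = prob
    labels = np.where(
        ~valid,
        MISSING,
        np.where(
            prob >= present_min, PRESENT, np.where(prob <= absent_max, ABSENT, AMBIGUOUS)
        ),
    )
    out["label"] = labels
    return out


def classify(
    model: Pipeline,
    fv: pd.Series | Mapping,
    absent_max: float = ABSENT_MAX,
    present_min: float = PRESENT_MIN,
) -> PresenceCall:
    """Classify a single feature vector."""
    row = pd.DataFrame([dict(fv)])
    res = classify_table(model, row, absent_max, present_min).iloc[0]
    return PresenceCall(
        te_id=str(res.get("te_id", "")),
        sample_id=str(res.get("sample_id", "")),
        probability=float(res["probability"]),
        label=str(res["label"]),
    )


def calls_to_matrix(calls: pd.DataFrame) -> CallMatrix:
    """Pivot long-form classified rows into a :class:`CallMatrix`."""
    labels = calls.pivot(index="te_id", columns="sample_id", values="label").fillna(
        MISSING
    )
    probs = calls.pivot(index="te_id", columns="sample_id", values="probability")
    return CallMatrix(labels, probs)


def classify_panel(
    bundle: ModelBundle,
    features: pd.DataFrame,
    coverages: Mapping[str, float],
) -> CallMatrix:
    """Classify a whole panel, selecting the depth model per sample."""
    parts = []
    for sample_id, sub in features.groupby("sample_id", sort=False):
        model = bundle.model_for(coverages[str(sample_id)])
        parts.append(
            classify_table(model, sub, bundle.absent_max, bundle.present_min)
        )
    return calls_to_matrix(pd.concat(parts, ignore_index=True))


# ---------------------------------------------------------------------------
# Post-classification filters


def filter_recalcitrant(
    calls: CallMatrix, cognate_sample: str
) -> tuple[list[str], pd.DataFrame]:
    """Keep only TEs called present in the assembly's own resequenced sample.

    A TE not scored present when the assembly's own reads are mapped back
    to it cannot be genotyped from short reads at all and is removed.
    Returns (retained te_ids, report of removed ids with their cognate
    label).
    """
    if cognate_sample not in calls.sample_ids:
        raise ValueError(f"cognate sample {cognate_sample!r} not in call matrix")
    col = calls.labels[cognate_sample]
    retained = col.index[col == PRESENT].tolist()
    removed = col[col != PRESENT]
    report = pd.DataFrame(
        {"te_id": removed.index, "cognate_label": removed.values}
    )
    return retained, report


def filter_high_ambiguity(
    calls: CallMatrix, max_frac: float = 0.25
) -> list[str]:
    """Keep TEs whose ambiguous fraction (of non-missing calls) is <= max_frac.

    Removal is strict: exactly 25% ambiguous is retained.
    """
    frac = calls.ambiguous_fraction()
    return frac.index[(frac <= max_frac) | frac.isna()].tolist()


def confusion_rates(calls: CallMatrix, truth: CallMatrix) -> dict[str, float]:
    """Present/absent confusion rates against a truth matrix.

    Ambiguous and missing calls are excluded from all denominators.
    Rates are conditional on the truth class: ``true_present_rate`` is
    P(called present | truly present), ``false_absent_rate`` its
    complement, and symmetrically for absent.
    """
    tes = calls.te_ids.intersection(truth.te_ids)
    samples = calls.sample_ids.intersection(truth.sample_ids)
    if len(tes) == 0 or len(samples) == 0:
        raise ValueError("no shared (TE, sample) keys between calls and truth")
    c = calls.labels.loc[tes, samples].to_numpy()
    t = truth.labels.loc[tes, samples].to_numpy()
    usable = np.isin(c, [PRESENT, ABSENT]) & np.isin(t, [PRESENT, ABSENT])
    c, t = c[usable], t[usable]
    if c.size == 0:
        raise ValueError("no non-ambiguous overlapping calls to compare")
    tp = int(((c == PRESENT) & (t == PRESENT)).sum())
    ta = int(((c == ABSENT) & (t == ABSENT)).sum())
    fp = int(((c == PRESENT) & (t == ABSENT)).sum())
    fa = int(((c == ABSENT) & (t == PRESENT)).sum())
    n_pres, n_abs = tp + fa, ta + fp
    return {
        "n": int(c.size),
        "true_present_rate": tp / n_pres if n_pres else float("nan"),
        "false_absent_rate": fa / n_pres if n_pres else float("nan"),
        "true_absent_rate": ta / n_abs if n_abs else float("nan"),
        "false_present_rate": fp / n_abs if n_abs else float("nan"),
        "accuracy": (tp + ta) / c.size,
    }
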