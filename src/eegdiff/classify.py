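"""Repeated stratified five-fold CV with three tree ensembles.

Models: Random Forest (bagging), LightGBM and XGBoost (boosting), each
with library-default hyperparameters pinned to single-thread execution
and a per-repeat random state, so a full grid is reproducible from one
seed.

The CV split unit is selectable. ``split_unit='epoch'`` assigns epoch
rows to folds directly, which mirrors segment-level protocols but leaks
within-subject information (epochs of one subject appear on both sides
of a split) and inflates accuracy. ``split_unit='subject'`` keeps every
subject's epochs in a single fold and is the leakage-free option. Both
are first-class; every report records which was used.

Metrics (accuracy, precision, recall, F1) are computed from confusion
counts pooled over the 5 test folds of each repeat, then averaged with
s.d. over repeats. The positive class is the second group label
(the DD-equivalent), by convention.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .core import BAND_NAMES
from .features import FEATURE_FAMILIES, split_feature_id

MODEL_NAMES = ("RF", "LightGBM", "XGBoost")
DEFAULT_FOLDS = 5
DEFAULT_REPEATS = 10


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, precision, recall, F1 from confusion counts (fractions).

    A metric whose denominator is zero is reported as nan, never as a
    silent 0.
    """
    def ratio(num, den):
        return num / den if den else float("nan")

    return {
        "accuracy": ratio(c.tp + c.tn, c.total),
        "precision": ratio(c.tp, c.tp + c.fp),
        "recall": ratio(c.tp, c.tp + c.fn),
        "f1": ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
    }


@dataclass(frozen=True)
class FeatureScope:
    """Selects feature columns by family and/or band; None = all."""

    families: tuple[str, ...] | None = None
    bands: tuple[str, ...] | None = None

    def select(self, columns) -> list[str]:
        out = []
        for col in columns:
            try:
                fam, band, _ = split_feature_id(col)
            except ValueError:
                continue
            if fam not in FEATURE_FAMILIES:
                continue
            if self.families is not None and fam not in self.families:
                continue
            if self.bands is not None and band not in self.bands:
                continue
            out.append(col)
        return out

    def label(self) -> str:
        fam = "+".join(self.families) if self.families else "all-features"
        band = "+".join(self.bands) if self.bands else "all-rhythms"
        return f"{fam}/{band}"


@dataclass
class ClassificationReport:
    """Mean +- s.d. (percent) of the four metrics over CV repeats."""

    model: str
    scope: str
    metrics_mean: dict[str, float]
    metrics_sd: dict[str, float]
    n_folds: int
    n_repeats: int
    split_unit: str
    seed: int
    positive_class: str
    per_repeat: pd.DataFrame = field(repr=False, default=None)

    def summary_row(self) -> dict:
        row = {"model": self.model, "scope": self.scope,
               "split_unit": self.split_unit}
        for k in ("accuracy", "precision", "recall", "f1"):
            row[k] = self.metrics_mean[k]
            row[k + "_sd"] = self.metrics_sd[k]
        return row


def _make_model(name: str, random_state: int):
    if name == "RF":
        return RandomForestClassifier(random_state=random_state, n_jobs=1)
    if name == "LightGBM":
        from lightgbm import LGBMClassifier
        return LGBMClassifier(random_state=random_state, n_jobs=1,
                              deterministic=True, verbose=-1)
    if name == "XGBoost":
        from xgboost import XGBClassifier
        return XGBClassifier(random_state=random_state, n_jobs=1,
                             verbosity=0)
    raise ValueError(f"unknown model {name!r}; expected one of {MODEL_NAMES}")


def crossval_evaluate(table: pd.DataFrame, scope: FeatureScope, model: str,
                      k: int = DEFAULT_FOLDS, repeats: int = DEFAULT_REPEATS,
                      seed: int = 0, split_unit: str = "epoch",
                      ) -> ClassificationReport:
    """Repeated stratified k-fold CV of one model on one feature scope."""
    cols = scope.select(table.columns)
    if not cols:
        raise ValueError(f"scope {scope.label()} selects no feature columns")
    groups_present = list(pd.unique(table["group"]))
    if len(groups_present) != 2:
        raise ValueError("both classes must be present")
    # positive class = second group label in first-seen order
    positive = groups_present[1]
    X = table[cols].to_numpy(float)
    y = (table["group"] == positive).to_numpy(int)
    subj = table["subject_id"].to_numpy()

    rng = np.random.default_rng(seed)
    repeat_seeds = rng.integers(0, 2**31 - 1, size=repeats)

    rows = []
    for rep, rep_seed in enumerate(repeat_seeds):
        if split_unit == "epoch":
            cv = StratifiedKFold(n_splits=k, shuffle=True,
                                 random_state=int(rep_seed))
            splits = cv.split(X, y)
        elif split_unit == "subject":
            cv = StratifiedGroupKFold(n_splits=k, shuffle=True,
                                      random_state=int(rep_seed))
            splits = cv.split(X, y, groups=subj)
        else:
            raise ValueError("split_unit must be 'epoch' or 'subject'")
        tp = fp = fn = tn = 0
        for train, test in splits:
            if len(np.unique(y[train])) < 2:
                raise ValueError("a class is absent from a training fold")
            if split_unit == "subject":
                assert not set(subj[train]) & set(subj[test])
            clf = _make_model(model, random_state=int(rep_seed))
            with warnings.catch_warnings():
                # lightgbm's sklearn wrapper warns about feature names even
                # when fit and predict both receive plain arrays
                warnings.filterwarnings(
                    "ignore", message=".*does not have valid feature names.*")
                clf.fit(X[train], y[train])
                pred = np.asarray(clf.predict(X[test]), dtype=int)
            truth = y[test]
            tp += int(((pred == 1) & (truth == 1)).sum())
            fp += int(((pred == 1) & (truth == 0)).sum())
            fn += int(((pred == 0) & (truth == 1)).sum())
            tn += int(((pred == 0) & (truth == 0)).sum())
        m = confusion_metrics(ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn))
        rows.append({"repeat": rep, **{k_: v * 100 for k_, v in m.items()}})

    per_repeat = pd.DataFrame(rows)
    keys = ("accuracy", "precision", "recall", "f1")
    mean = {k_: float(per_repeat[k_].mean()) for k_ in keys}
    sd = {k_: float(per_repeat[k_].std(ddof=1)) if repeats > 1 else 0.0
          for k_ in keys}
    return ClassificationReport(model=model, scope=scope.label(),
                                metrics_mean=mean, metrics_sd=sd, n_folds=k,
                                n_repeats=repeats, split_unit=split_unit,
                                seed=seed, positive_class=positive,
                                per_repeat=per_repeat)


def feature_family_comparison(table: pd.DataFrame,
                              models=MODEL_NAMES, **kw
                              ) -> list[ClassificationReport]:
    """One report per (feature family, model): PSD-only, FE-only, PLI-only."""
    reports = []
    for family in FEATURE_FAMILIES:
        for model in models:
            reports.append(crossval_evaluate(
                table, FeatureScope(families=(family,)), model, **kw))
    return reports


def rhythm_comparison(table: pd.DataFrame, models=MODEL_NAMES, **kw
                      ) -> list[ClassificationReport]:
    """One report per (rhythm scope, model): each band alone + all bands."""
    scopes = [FeatureScope(bands=(b,)) for b in BAND_NAMES]
    scopes.append(FeatureScope(bands=None))
    reports = []
    for scope in scopes:
        for model in models:
            reports.append(crossval_evaluate(table, scope, model, **kw))
    return reports


def reports_frame(reports: list[ClassificationReport]) -> pd.DataFrame:
    """Grid of reports as a table (mean and s.d. per metric, percent)."""
    return pd.DataFrame([r.summary_row() for r in reports])
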