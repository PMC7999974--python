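"""Gaussian-kernel SVM sleep staging with band-fusion strategies.

Three ways of combining per-band PLV feature tables are implemented, with
the field's usual shorthand:

* ``C``  — feature-level fusion: concatenate the band feature blocks
  (6 bands × 66 pairs → 396 columns) and train one SVM;
* ``E``  — decision-level fusion (stacking): one base SVM per band, a
  meta classifier trained on their out-of-fold decision scores;
* ``E(C)`` — hybrid: feature-level fusion within fixed band pairs, then
  stacking over the pair classifiers.

The classifier is a radial-basis-function SVM (one-against-one
multiclass, as implemented by libsvm inside scikit-learn) on
train-standardized features, evaluated on a stratified 75/25 split.
Reports carry overall accuracy, per-class true-positive rates and the
confusion matrix, all in percent/counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.ensemble import StackingClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .bands import BAND_ORDER, BAND_RANK, STAGE_ORDER
from .connectivity import feature_columns

DEFAULT_TRAIN_FRACTION = 0.75

#: band pairs used for hybrid fusion: a strong discriminator paired with
#: a complementary weaker band in each group
DEFAULT_HYBRID_PAIRS: tuple[tuple[str, str], ...] = (
    ("delta", "beta1"), ("theta", "gamma"), ("alpha", "beta2"),
)

#: band subsets mirroring the fusion experiment layout: the three pairs,
#: the best three bands, those plus gamma, and all six
DEFAULT_BAND_SUBSETS: tuple[tuple[str, ...], ...] = (
    ("delta", "beta1"), ("theta", "gamma"), ("alpha", "beta2"),
    ("alpha", "beta1", "delta"),
    ("alpha", "beta1", "delta", "gamma"),
    tuple(BAND_ORDER),
)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """samples × features matrix with per-column (band, pair) provenance."""

    matrix: np.ndarray
    column_provenance: tuple[tuple[str, str], ...]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be samples × features")
        if len(self.column_provenance) != self.matrix.shape[1]:
            raise ValueError("provenance must cover every column")
        if len(self.labels) != self.matrix.shape[0]:
            raise ValueError("one label per sample required")
        if np.isnan(self.matrix).any():
            raise ValueError("feature matrix contains missing values")

    @property
    def bands(self) -> tuple[str, ...]:
        seen: list[str] = []
        for band, _ in self.column_provenance:
            if band not in seen:
                seen.append(band)
        return tuple(seen)


@dataclass(frozen=True)
class SplitSpec:
    """A stratified train/test partition of sample indices."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    train_fraction: float
    seed: int

    def __post_init__(self) -> None:
        train = set(self.train_indices.tolist())
        test = set(self.test_indices.tolist())
        if train & test:
            raise ValueError("train and test indices overlap")


@dataclass
class ClassificationReport:
    """Accuracy (%), per-class TPR (%) and the confusion-count matrix."""

    accuracy: float
    per_class_tpr: dict[str, float]
    confusion: np.ndarray
    classes: tuple[str, ...]
    strategy: str = "single"
    bands: tuple[str, ...] = ()

    def as_row(self) -> dict:
        row = {
            "strategy": self.strategy,
            "bands": "+".join(self.bands),
            "accuracy": self.accuracy,
        }
        row.update({f"tpr_{c}": self.per_class_tpr[c] for c in self.classes})
        return row


# ---------------------------------------------------------------------------
# feature tables from the long-format PLV frame
# ---------------------------------------------------------------------------

def band_feature_tables(features: pd.DataFrame) -> dict[str, FeatureTable]:
    """Split the long PLV feature frame into per-band sample × 66 tables.

    Sample order is aligned across bands by epoch index, so tables can be
    concatenated column-wise.
    """
    cols = feature_columns(features)
    out: dict[str, FeatureTable] = {}
    for band, sub in features.groupby("band", sort=False):
        sub = sub.sort_values("epoch", kind="mergesort")
        out[band] = FeatureTable(
            matrix=sub[cols].to_numpy(),
            column_provenance=tuple((band, c) for c in cols),
            labels=sub["stage"].to_numpy(),
        )
    ref = next(iter(out.values())).labels
    for band, table in out.items():
        if not np.array_equal(table.labels, ref):
            raise ValueError(f"band {band} has a different sample ordering")
    return out


def feature_level_fusion(band_tables: Mapping[str, FeatureTable] | Sequence[FeatureTable],
                         bands: Sequence[str] | None = None) -> FeatureTable:
    """Column-wise concatenation of band tables in canonical band order."""
    if isinstance(band_tables, Mapping):
        if bands is None:
            bands = sorted(band_tables, key=lambda b: BAND_RANK.get(b, 99))
        tables = [band_tables[b] for b in bands]
    else:
        tables = list(band_tables)
    if not tables:
        raise ValueError("no band tables given")
    ref = tables[0].labels
    for t in tables[1:]:
        if not np.array_equal(t.labels, ref):
            raise ValueError("sample ordering differs between band tables")
    return FeatureTable(
        matrix=np.concatenate([t.matrix for t in tables], axis=1),
        column_provenance=tuple(p for t in tables for p in t.column_provenance),
        labels=ref.copy(),
    )


# ---------------------------------------------------------------------------
# split / train / evaluate
# ---------------------------------------------------------------------------

def split_train_test(labels: Sequence[str],
                     train_fraction: float = DEFAULT_TRAIN_FRACTION,
                     seed: int = 0) -> SplitSpec:
    """Seeded stratified split; deterministic given the seed."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if (counts < 4).any():
        raise ValueError("every class needs at least 4 samples to split 75/25")
    idx = np.arange(len(labels))
    train, test = train_test_split(
        idx, train_size=train_fraction, random_state=seed, stratify=labels,
    )
    return SplitSpec(np.sort(train), np.sort(test), train_fraction, seed)


class ColumnSelector(BaseEstimator, TransformerMixin):
    """Select a fixed set of columns (used to route bands to base classifiers)."""

    def __init__(self, columns: Sequence[int] = ()):  # noqa: D107
        self.columns = columns

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return np.asarray(X)[:, list(self.columns)]


def make_svm(C: float = 1.0, gamma: str | float = "scale") -> Pipeline:
    """Standardize-then-RBF-SVM pipeline (libsvm one-against-one multiclass)."""
    return Pipeline([
        ("scale", StandardScaler()),
        ("svc", SVC(kernel="rbf", C=C, gamma=gamma,
                    decision_function_shape="ovr")),
    ])


def train_classifier(train_matrix: np.ndarray, train_labels: Sequence[str],
                     C: float = 1.0, gamma: str | float = "scale") -> Pipeline:
    """Fit the Gaussian-kernel SVM; exposes ``predict`` and ``decision_function``."""
    train_labels = np.asarray(train_labels)
    if len(np.unique(train_labels)) < 2:
        raise ValueError("training data must contain at least two classes")
    model = make_svm(C=C, gamma=gamma)
    model.fit(np.asarray(train_matrix, dtype=float), train_labels)
    return model


def evaluate(predictions: Sequence[str], test_labels: Sequence[str],
             strategy: str = "single", bands: Sequence[str] = ()) -> ClassificationReport:
    """Accuracy, per-class true-positive rates and confusion matrix (percent)."""
    predictions = np.asarray(predictions)
    test_labels = np.asarray(test_labels)
    if predictions.shape != test_labels.shape:
        raise ValueError("predictions and labels must have equal length")
    if predictions.size == 0:
        raise ValueError("empty test set")
    present = set(test_labels) | set(predictions)
    classes = tuple([s for s in STAGE_ORDER if s in present]
                    + sorted(present - set(STAGE_ORDER)))
    k = len(classes)
    pos = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((k, k), dtype=int)
    for truth, pred in zip(test_labels, predictions):
        confusion[pos[truth], pos[pred]] += 1
    accuracy = 100.0 * np.trace(confusion) / confusion.sum()
    tpr = {}
    for c in classes:
        row = confusion[pos[c]]
        tpr[c] = 100.0 * row[pos[c]] / row.sum() if row.sum() else float("nan")
    return ClassificationReport(
        accuracy=float(accuracy), per_class_tpr=tpr, confusion=confusion,
        classes=classes, strategy=strategy, bands=tuple(bands),
    )


def classify(table: FeatureTable, split: SplitSpec, strategy: str = "single",
             C: float = 1.0, gamma: str | float = "scale") -> ClassificationReport:
    """Train on the split's train part, evaluate on its test part."""
    model = train_classifier(table.matrix[split.train_indices],
                             table.labels[split.train_indices], C=C, gamma=gamma)
    preds = model.predict(table.matrix[split.test_indices])
    return evaluate(preds, table.labels[split.test_indices],
                    strategy=strategy, bands=table.bands)


# ---------------------------------------------------------------------------
# fusion strategies
# ---------------------------------------------------------------------------

def _column_groups(fused: FeatureTable,
                   groups: Sequence[Sequence[str]]) -> list[tuple[str, list[int]]]:
    out = []
    for group in groups:
        cols = [i for i, (band, _) in enumerate(fused.column_provenance)
                if band in group]
        if not cols:
            raise ValueError(f"no columns found for band group {group}")
        out.append(("+".join(group), cols))
    return out


def _stacked_report(fused: FeatureTable, groups: Sequence[Sequence[str]],
                    split: SplitSpec, strategy: str, C: float, gamma,
                    meta_C: float, cv_folds: int) -> ClassificationReport:
    """Stacking over group classifiers with out-of-fold meta-features."""
    estimators = [
        (name, Pipeline([
            ("select", ColumnSelector(cols)),
            ("scale", StandardScaler()),
            ("svc", SVC(kernel="rbf", C=C, gamma=gamma,
                        decision_function_shape="ovr")),
        ]))
        for name, cols in _column_groups(fused, groups)
    ]
    stack = StackingClassifier(
        estimators=estimators,
        final_estimator=Pipeline([
            ("scale", StandardScaler()),
            ("svc", SVC(kernel="rbf", C=meta_C, gamma="scale",
                        decision_function_shape="ovr")),
        ]),
        stack_method="decision_function",
        cv=StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=split.seed),
    )
    stack.fit(fused.matrix[split.train_indices], fused.labels[split.train_indices])
    preds = stack.predict(fused.matrix[split.test_indices])
    return evaluate(preds, fused.labels[split.test_indices],
                    strategy=strategy, bands=fused.bands)


def decision_level_stacking(band_tables: Mapping[str, FeatureTable],
                            split: SplitSpec, bands: Sequence[str] | None = None,
                            C: float = 1.0, gamma: str | float = "scale",
                            meta_C: float = 1.0, cv_folds: int = 5
                            ) -> ClassificationReport:
    """Strategy ``E``: one base SVM per band, meta SVM on their class scores.

    The meta classifier is trained on out-of-fold base predictions over
    the training split only; the test split stays untouched until final
    evaluation.
    """
    if bands is None:
        bands = sorted(band_tables, key=lambda b: BAND_RANK.get(b, 99))
    if len(bands) < 2:
        raise ValueError("stacking needs at least two bands")
    fused = feature_level_fusion(band_tables, bands)
    return _stacked_report(fused, [[b] for b in bands], split, "E",
                           C, gamma, meta_C, cv_folds)


def hybrid_fusion(band_tables: Mapping[str, FeatureTable],
                  split: SplitSpec,
                  band_pairs: Sequence[Sequence[str]] = DEFAULT_HYBRID_PAIRS,
                  C: float = 1.0, gamma: str | float = "scale",
                  meta_C: float = 1.0, cv_folds: int = 5) -> ClassificationReport:
    """Strategy ``E(C)``: feature fusion within each band pair, stacking across pairs."""
    if len(band_pairs) < 2:
        raise ValueError("hybrid fusion needs at least two band groups")
    bands = [b for pair in band_pairs for b in pair]
    if len(set(bands)) != len(bands):
        raise ValueError("band groups must be disjoint")
    fused = feature_level_fusion(band_tables, bands)
    return _stacked_report(fused, band_pairs, split, "E(C)",
                           C, gamma, meta_C, cv_folds)


def run_experiment_grid(band_tables: Mapping[str, FeatureTable],
                        strategies: Sequence[str] = ("C", "E", "E(C)"),
                        band_subsets: Sequence[Sequence[str]] = DEFAULT_BAND_SUBSETS,
                        seed: int = 0,
                        hybrid_pairs: Sequence[Sequence[str]] = DEFAULT_HYBRID_PAIRS,
                        train_fraction: float = DEFAULT_TRAIN_FRACTION,
                        C: float = 1.0, gamma: str | float = "scale",
                        include_single_bands: bool = True) -> pd.DataFrame:
    """Accuracy / per-class TPR table over band subsets × fusion strategies.

    ``E(C)`` rows are produced only for subsets decomposable into the
    given hybrid pairs (pairs fully inside the subset, covering it).
    """
    known = {"single", "C", "E", "E(C)"}
    unknown = set(strategies) - known
    if unknown:
        raise ValueError(f"unknown strategies {sorted(unknown)}; choose from {sorted(known)}")
    any_table = next(iter(band_tables.values()))
    split = split_train_test(any_table.labels, train_fraction, seed)
    rows = []
    if include_single_bands or "single" in strategies:
        for band in sorted(band_tables, key=lambda b: BAND_RANK.get(b, 99)):
            rows.append(classify(band_tables[band], split, "single").as_row())
    for subset in band_subsets:
        subset = tuple(subset)
        if "C" in strategies:
            fused = feature_level_fusion(band_tables, subset)
            rows.append(classify(fused, split, "C", C=C, gamma=gamma).as_row())
        if "E" in strategies and len(subset) >= 2:
            rows.append(decision_level_stacking(
                band_tables, split, subset, C=C, gamma=gamma).as_row())
        if "E(C)" in strategies:
            pairs = [p for p in hybrid_pairs if set(p) <= set(subset)]
            covered = set(b for p in pairs for b in p)
            if len(pairs) >= 2 and covered == set(subset):
                rows.append(hybrid_fusion(
                    band_tables, split, pairs, C=C, gamma=gamma).as_row())
    return pd.DataFrame(rows)
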