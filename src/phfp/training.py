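"""Per-assay classifier training: nested CV, MCC scoring, model retention.

Each assay dataset (actives + 4:1 decoys) trains its own random-forest
activity classifier. Performance is estimated by ten-fold *nested*
cross-validation: the data is split 90:10 ten times; within each 90%
training portion an inner 5-fold grid search picks the tree count from
{20, 60, 100, 140, 180} (max_features = all features), and the winning
configuration is refit on the full 90% and scored on the held-out 10%.
The held-out data therefore never influences hyperparameter choice, and
the reported performance is the mean of the ten outer-fold Matthews
correlation coefficients.

Only assays whose mean MCC reaches the retention threshold (0.90 by
default) enter the model registry; the registry's canonical sorted-key
order defines the bit order of every Ph-fp built from it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import KFold

from .chem import BitVector, DescriptorVector, Molecule, encode
from .curation import AssayDataset, AssayKey

__all__ = [
    "ConfusionCounts",
    "CVResult",
    "RegistryEntry",
    "ModelRegistry",
    "TREE_GRID",
    "mcc",
    "feature_matrix",
    "random_forest_factory",
    "nested_cv",
    "select_models",
]

#: Tree-count hyperparameter grid searched in the inner CV loop.
TREE_GRID: tuple[int, ...] = (20, 60, 100, 140, 180)


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


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient.

    MCC = (tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)),
    defined as 0 whenever any factor of the denominator vanishes.
    Ranges over [-1, +1]: +1 for perfect classification, -1 for complete
    misclassification, 0 for a chance-level classifier.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def _mcc_from_labels(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return mcc(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))


def feature_matrix(molecules: Sequence[Molecule], encoding: str) -> np.ndarray:
    """Stack per-molecule encodings into an (n, p) float matrix."""
    rows = []
    for mol in molecules:
        enc = encode(mol, encoding)
        rows.append(enc.bits if isinstance(enc, BitVector) else enc.values)
    return np.stack(rows).astype(float)


def random_forest_factory(n_trees: int, seed: int):
    """Default learner: bagged decision-tree ensemble, all features per split."""
    return RandomForestClassifier(
        n_estimators=n_trees,
        max_features=None,
        random_state=seed,
        n_jobs=1,
    )


@dataclass(frozen=True)
class CVResult:
    assay: AssayKey
    fold_mccs: tuple[float, ...]
    chosen_trees: int

    def __post_init__(self) -> None:
        if not self.fold_mccs:
            raise ValueError("no folds")

    @property
    def mean_mcc(self) -> float:
        return float(np.mean(self.fold_mccs))

    @property
    def sd_mcc(self) -> float:
        return float(np.std(self.fold_mccs, ddof=1)) if len(self.fold_mccs) > 1 else 0.0


def _inner_grid_search(
    X: np.ndarray,
    y: np.ndarray,
    grid: Sequence[int],
    inner_folds: int,
    seed: int,
    model_factory: Callable,
) -> int:
    """Mean inner-CV MCC per tree count; ties broken toward fewer trees."""
    inner = KFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    best_trees, best_score = None, -np.inf
    for n_trees in grid:
        scores = []
        for tr, va in inner.split(X):
            if len(np.unique(y[tr])) < 2:
                raise ValueError("inner training fold contains a single class")
            clf = model_factory(n_trees, seed)
            clf.fit(X[tr], y[tr])
            scores.append(_mcc_from_labels(y[va], clf.predict(X[va])))
        score = float(np.mean(scores))
        if score > best_score:  # strict: first (smallest) grid value wins ties
            best_trees, best_score = n_trees, score
    return int(best_trees)


def nested_cv(
    dataset: AssayDataset,
    encoding: str,
    grid: Sequence[int] = TREE_GRID,
    outer_folds: int = 10,
    inner_folds: int = 5,
    seed: int = 0,
    model_factory: Callable = random_forest_factory,
) -> CVResult:
    """Ten-fold nested cross-validation of one assay classifier.

    Fold assignment is a seeded shuffled K-fold without stratification.
    ``chosen_trees`` reports the modal inner-loop winner across outer folds
    (smallest on ties) — the configuration the replicate predictors reuse.
    """
    X = feature_matrix(dataset.molecules, encoding)
    y = dataset.labels
    outer = KFold(n_splits=outer_folds, shuffle=True, random_state=seed)
    fold_mccs: list[float] = []
    winners: list[int] = []
    for k, (tr, te) in enumerate(outer.split(X)):
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            raise ValueError(
                f"assay {dataset.key.slug()}: outer fold {k} has a single class"
            )
        n_trees = _inner_grid_search(
            X[tr], y[tr], grid, inner_folds, seed + k + 1, model_factory
        )
        winners.append(n_trees)
        clf = model_factory(n_trees, seed + k + 1)
        clf.fit(X[tr], y[tr])
        fold_mccs.append(_mcc_from_labels(y[te], clf.predict(X[te])))
    counts = {t: winners.count(t) for t in sorted(set(winners))}
    chosen = max(counts, key=lambda t: (counts[t], -t))
    return CVResult(
        assay=dataset.key, fold_mccs=tuple(fold_mccs), chosen_trees=int(chosen)
    )


@dataclass(frozen=True)
class RegistryEntry:
    """One retained assay: its data, winning hyperparameters and CV score."""

    key: AssayKey
    dataset: AssayDataset
    n_trees: int
    mean_mcc: float


@dataclass(frozen=True)
class ModelRegistry:
    """Ordered list of retained assays; order defines Ph-fp bit order."""

    entries: tuple[RegistryEntry, ...]
    encoding: str
    cutoff: int
    threshold: float = 0.90
    model_factory: Callable = field(default=random_forest_factory, compare=False)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def assay_slugs(self) -> tuple[str, ...]:
        return tuple(e.key.slug() for e in self.entries)


def select_models(
    cv_results: Sequence[CVResult],
    datasets: Sequence[AssayDataset],
    encoding: str,
    cutoff: int,
    threshold: float = 0.90,
    model_factory: Callable = random_forest_factory,
) -> ModelRegistry:
    """Retain assays with mean MCC >= threshold, in sorted assay-key order."""
    by_key = {d.key: d for d in datasets}
    retained = [r for r in cv_results if r.mean_mcc >= threshold]
    retained.sort(key=lambda r: r.assay.as_tuple())
    entries = tuple(
        RegistryEntry(
            key=r.assay,
            dataset=by_key[r.assay],
            n_trees=r.chosen_trees,
            mean_mcc=r.mean_mcc,
        )
        for r in retained
    )
    return ModelRegistry(
        entries=entries,
        encoding=encoding,
        cutoff=cutoff,
        threshold=threshold,
        model_factory=model_factory,
    )
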