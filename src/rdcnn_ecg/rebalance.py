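"""Class-imbalance handling and data partitioning.

Arrhythmia corpora are heavily skewed towards normal beats, so a
classifier can minimize its loss by ignoring the minority classes.  This
module provides the two plain-resampling remedies used by the pipeline —
uniform majority subsampling and per-class resampling to a common target
count (without replacement when shrinking, with replacement when growing)
— plus the stratified 80:20 train/test split and k-fold indexing used for
evaluation.  Every stochastic operation takes an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class MissingClassError(ValueError):
    """Raised when a required class has no rows to resample from."""


class InsufficientSamplesError(ValueError):
    """Raised when a subsample request exceeds the available rows."""


class SplitConfigError(ValueError):
    """Raised for invalid split/fold settings."""


class EmptyDatasetError(ValueError):
    """Raised when a split is requested on an empty dataset."""


@dataclass(frozen=True)
class SplitSpec:
    """Train/test and cross-validation settings."""

    train_fraction: float = 0.8
    stratified: bool = True
    k_folds: int = 5
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise SplitConfigError(
                f"train_fraction must be in (0, 1), got {self.train_fraction}"
            )
        if self.k_folds < 2:
            raise SplitConfigError(f"k_folds must be >= 2, got {self.k_folds}")


def resample_to_balance(
    beats: np.ndarray,
    labels: np.ndarray,
    target_per_class: int,
    seed: int = 0,
    classes=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Resample every class to exactly ``target_per_class`` rows.

    Classes above the target are drawn without replacement; classes below
    it are drawn with replacement.  ``classes`` optionally fixes the class
    set that must be present (defaults to the classes observed in
    ``labels``).  The result is shuffled deterministically by the seed.
    """
    beats = np.asarray(beats)
    labels = np.asarray(labels)
    if target_per_class < 1:
        raise ValueError(f"target_per_class must be >= 1, got {target_per_class}")
    if classes is None:
        classes = np.unique(labels)
    rng = np.random.default_rng(seed)
    chosen = []
    for c in classes:
        idx = np.nonzero(labels == c)[0]
        if idx.size == 0:
            raise MissingClassError(f"class {c} has no rows to resample from")
        if idx.size >= target_per_class:
            pick = rng.choice(idx, size=target_per_class, replace=False)
        else:
            pick = rng.choice(idx, size=target_per_class, replace=True)
        chosen.append(pick)
    all_idx = np.concatenate(chosen)
    all_idx = all_idx[rng.permutation(all_idx.size)]
    return beats[all_idx], labels[all_idx]


def subsample_majority(
    beats: np.ndarray,
    labels: np.ndarray,
    majority_class: int,
    n_keep: int,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniformly subsample the majority class to ``n_keep`` rows.

    Rows of other classes are untouched and the original row order is
    preserved (majority rows not drawn are dropped).
    """
    beats = np.asarray(beats)
    labels = np.asarray(labels)
    maj_idx = np.nonzero(labels == majority_class)[0]
    if maj_idx.size < n_keep:
        raise InsufficientSamplesError(
            f"class {majority_class} has {maj_idx.size} rows, cannot keep {n_keep}"
        )
    rng = np.random.default_rng(seed)
    keep_maj = rng.choice(maj_idx, size=n_keep, replace=False)
    keep = np.zeros(labels.size, dtype=bool)
    keep[labels != majority_class] = True
    keep[keep_maj] = True
    return beats[keep], labels[keep]


def split_train_test(
    beats: np.ndarray,
    labels: np.ndarray,
    spec: SplitSpec | None = None,
) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Disjoint, exhaustive train/test split.

    Train size is ``floor(train_fraction * n)``; under stratification the
    floor rule applies per class with remainders going to the test side.
    """
    beats = np.asarray(beats)
    labels = np.asarray(labels)
    if spec is None:
        spec = SplitSpec()
    spec.validate()
    n = labels.size
    if n == 0:
        raise EmptyDatasetError("cannot split an empty dataset")
    if n < 2:
        raise SplitConfigError("need at least 2 rows to split")
    rng = np.random.default_rng(spec.seed)
    if spec.stratified:
        train_idx, test_idx = [], []
        for c in np.unique(labels):
            idx = np.nonzero(labels == c)[0]
            if idx.size < 2:
                raise SplitConfigError(
                    f"stratified split needs >= 2 rows per class; class {c} "
                    f"has {idx.size}"
                )
            idx = rng.permutation(idx)
            n_train = int(np.floor(spec.train_fraction * idx.size))
            train_idx.append(idx[:n_train])
            test_idx.append(idx[n_train:])
        train_idx = np.concatenate(train_idx)
        test_idx = np.concatenate(test_idx)
        train_idx = train_idx[rng.permutation(train_idx.size)]
        test_idx = test_idx[rng.permutation(test_idx.size)]
    else:
        perm = rng.permutation(n)
        n_train = int(np.floor(spec.train_fraction * n))
        train_idx, test_idx = perm[:n_train], perm[n_train:]
    return (
        (beats[train_idx], labels[train_idx]),
        (beats[test_idx], labels[test_idx]),
    )


def kfold_indices(n: int, spec: SplitSpec | None = None) -> list[np.ndarray]:
    """Split ``0..n-1`` into ``k_folds`` disjoint folds of near-equal size.

    Fold sizes differ by at most one, with the larger folds first; the
    assignment is a seeded permutation.
    """
    if spec is None:
        spec = SplitSpec()
    spec.validate()
    if n < spec.k_folds:
        raise SplitConfigError(
            f"cannot make {spec.k_folds} folds from {n} rows"
        )
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    return list(np.array_split(perm, spec.k_folds))
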