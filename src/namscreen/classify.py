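"""Supervised chemical-class prediction with repeated 5-fold cross-validation.

A random-forest classifier (bagged, feature-subsampled decision trees) is
evaluated with stratified-as-possible k-fold cross-validation repeated over
many random splits.  Outputs are the summed confusion matrix across repeats,
overall accuracy, a label-permutation null for the accuracy, and permutation
feature importance measured on held-out folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

log = logging.getLogger(__name__)


class ClassSizeError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    n_estimators: int = 500
    max_features: str | float = "sqrt"
    max_depth: int | None = None


@dataclass(frozen=True)
class CVScheme:
    folds: int = 5
    repeats: int = 50
    seed: int = 0

    def fold_assignments(self, labels: pd.Series) -> list[np.ndarray]:
        """Per-repeat fold ids (0..folds-1) for every item.

        Each class's members are shuffled and dealt round-robin into folds
        from a random offset: classes with >= ``folds`` members are spread
        evenly (stratified), and any class with >= 2 members is guaranteed a
        training instance whenever one member is held out.
        """
        y = np.asarray(labels)
        n = y.size
        counts = pd.Series(y).value_counts()
        small = counts[counts < 2]
        if not small.empty:
            raise ClassSizeError(
                f"classes with a single member cannot be cross-validated; "
                f"merge or drop: {list(small.index)}"
            )
        root = np.random.SeedSequence(self.seed)
        assignments = []
        for rep_seq in root.spawn(self.repeats):
            rng = np.random.default_rng(rep_seq)
            folds = np.empty(n, dtype=int)
            for cls in counts.index:
                idx = np.flatnonzero(y == cls)
                rng.shuffle(idx)
                offset = rng.integers(self.folds)
                folds[idx] = (offset + np.arange(idx.size)) % self.folds
            assignments.append(folds)
        return assignments


@dataclass
class ConfusionSummary:
    matrix: pd.DataFrame  # true (rows) x predicted (cols), summed over repeats
    accuracy: float  # % correct over all repeats
    per_repeat_accuracy: list[float]
    classes: tuple[str, ...]


def _validate_features(features: pd.DataFrame) -> np.ndarray:
    x = features.to_numpy()
    if not np.issubdtype(x.dtype, np.number):
        raise ValueError("feature matrix must be numeric")
    if not np.all(np.isfinite(x)):
        raise ValueError("feature matrix contains non-finite values")
    return x.astype(float)


def _forest(config: ModelConfig, seed) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=config.n_estimators,
        max_features=config.max_features,
        max_depth=config.max_depth,
        random_state=int(seed),
        n_jobs=1,
    )


def repeated_cv_classify(
    features: pd.DataFrame,
    labels: pd.Series,
    scheme: CVScheme = CVScheme(),
    config: ModelConfig = ModelConfig(),
) -> ConfusionSummary:
    """Cross-validated class prediction, aggregated over random splits.

    Every chemical is predicted exactly once per repeat, always from a model
    that never saw it; confusion counts are summed over repeats so the matrix
    total equals n_chemicals x repeats.
    """
    x = _validate_features(features)
    y = np.asarray(labels.reindex(features.index))
    classes = tuple(sorted(pd.unique(y)))
    class_to_i = {c: i for i, c in enumerate(classes)}
    conf = np.zeros((len(classes), len(classes)), dtype=int)
    per_repeat = []
    fit_seeds = np.random.SeedSequence(scheme.seed ^ 0x5EED).generate_state(
        scheme.repeats * scheme.folds
    ) % (2**31)
    for rep, folds in enumerate(scheme.fold_assignments(labels.reindex(features.index))):
        correct = 0
        for fold in range(scheme.folds):
            test = folds == fold
            if not test.any():
                continue
            model = _forest(config, fit_seeds[rep * scheme.folds + fold])
            model.fit(x[~test], y[~test])
            pred = model.predict(x[test])
            for t, p in zip(y[test], pred):
                conf[class_to_i[t], class_to_i[p]] += 1
            correct += int((pred == y[test]).sum())
        per_repeat.append(100.0 * correct / y.size)
    matrix = pd.DataFrame(conf, index=list(classes), columns=list(classes))
    matrix.index.name = "true"
    matrix.columns.name = "predicted"
    accuracy = 100.0 * np.trace(conf) / conf.sum()
    return ConfusionSummary(matrix, float(accuracy), per_repeat, classes)


def permutation_baseline(
    features: pd.DataFrame,
    labels: pd.Series,
    scheme: CVScheme = CVScheme(),
    config: ModelConfig = ModelConfig(),
    n_label_perms: int = 99,
    seed: int = 0,
) -> dict:
    """Label-permutation null for the cross-validated accuracy.

    Labels are permuted uniformly, the full repeated-CV procedure is re-run
    per permutation, and p = (1 + #{null >= observed}) / (n_label_perms + 1).
    """
    if n_label_perms < 99:
        raise ValueError("need >= 99 label permutations")
    observed = repeated_cv_classify(features, labels, scheme, config).accuracy
    rng = np.random.default_rng(seed)
    y = labels.reindex(features.index)
    null = np.empty(n_label_perms)
    for i in range(n_label_perms):
        permuted = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
        null[i] = repeated_cv_classify(features, permuted, scheme, config).accuracy
    p = (1.0 + float((null >= observed).sum())) / (n_label_perms + 1.0)
    return {"observed_accuracy": observed, "null_accuracies": null, "p": p}


def feature_importance(
    features: pd.DataFrame,
    labels: pd.Series,
    scheme: CVScheme = CVScheme(),
    config: ModelConfig = ModelConfig(),
    k: int = 10,
) -> pd.DataFrame:
    """Top-k permutation feature importance on held-out folds.

    Importance of a feature = mean decrease in held-out accuracy when its
    values are shuffled within the test fold, averaged over folds x repeats.
    Model-agnostic and out-of-sample; a constant or irrelevant feature scores
    ~0.  Ties in the ranking break by feature name.
    """
    x = _validate_features(features)
    y = np.asarray(labels.reindex(features.index))
    n_feat = x.shape[1]
    if k > n_feat:
        log.warning("k=%d exceeds feature count %d; clipping", k, n_feat)
        k = n_feat
    drops = np.zeros(n_feat)
    n_eval = 0
    root = np.random.SeedSequence(scheme.seed ^ 0xF00D)
    fit_seeds = root.generate_state(scheme.repeats * scheme.folds) % (2**31)
    shuffle_rng = np.random.default_rng(root.spawn(1)[0])
    for rep, folds in enumerate(scheme.fold_assignments(labels.reindex(features.index))):
        for fold in range(scheme.folds):
            test = folds == fold
            if not test.any():
                continue
            model = _forest(config, fit_seeds[rep * scheme.folds + fold])
            model.fit(x[~test], y[~test])
            x_test, y_test = x[test], y[test]
            base = (model.predict(x_test) == y_test).mean()
            for j in range(n_feat):
                shuffled = x_test.copy()
                shuffled[:, j] = shuffle_rng.permutation(shuffled[:, j])
                drops[j] += base - (model.predict(shuffled) == y_test).mean()
            n_eval += 1
    table = pd.DataFrame(
        {"feature": list(features.columns), "importance": drops / n_eval}
    ).sort_values(by=["importance", "feature"], ascending=[False, True], kind="mergesort")
    table["rank"] = np.arange(1, n_feat + 1)
    return table.head(k).reset_index(drop=True)
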