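"""Undersampling random-forest ensemble for imbalanced ECM classification.

With roughly 11 negatives (non-ECM) per positive (ECM), a single
classifier trained on the raw data buys accuracy by sacrificing minority
recall.  The ensemble instead partitions the negatives into
K = round(|neg| / |pos|) groups, pairs each group with *all* positives to
form K near-balanced training subsets, trains one random forest per
subset, and predicts by majority vote.  Every negative is used exactly
once, so no information is discarded as it would be by plain
undersampling.

Also here: the evaluation metrics (sensitivity, specificity, accuracy,
balanced accuracy), seeded stratified 10-fold cross-validation with pooled
confusion counts, and the imbalance-ratio sweep experiment that documents
the pathology the ensemble corrects.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .io_formats import FeatureMatrix


@dataclasses.dataclass(frozen=True)
class RFParams:
    """Random-forest settings, mirroring classic WEKA-era defaults.

    ``n_trees=10``, unlimited depth, and floor(log2 d) + 1 candidate
    features per split.  ``max_features=None`` means that log2 rule;
    an int fixes the count explicitly.
    """

    n_trees: int = 10
    max_depth: int | None = None
    max_features: int | None = None

    def resolve_max_features(self, n_features: int) -> int:
        if self.max_features is not None:
            return min(self.max_features, n_features)
        return min(int(math.log2(n_features)) + 1 if n_features > 1 else 1, n_features)


@dataclasses.dataclass(frozen=True)
class EnsembleModel:
    """K trained forests sharing one feature list and a vote rule."""

    members: tuple
    feature_names: tuple
    seed: int
    rf_params: RFParams = RFParams()
    tie_rule: str = "positive"
    vocabulary: tuple | None = None

    def __post_init__(self) -> None:
        if len(self.members) < 1:
            raise ValueError("ensemble needs at least one member")

    @property
    def n_members(self) -> int:
        return len(self.members)


@dataclasses.dataclass(frozen=True)
class MetricsReport:
    """Confusion counts and the four derived rates.

    When the truth contains no positives (or no negatives) the
    corresponding rate is NaN — an explicit undefined marker, never a
    silent zero.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    sn: float
    sp: float
    acc: float
    bacc: float


@dataclasses.dataclass(frozen=True)
class RatioSweepResult:
    """Averaged metrics per positive:negative training ratio."""

    ratios: tuple
    mean_sn: tuple
    mean_sp: tuple
    mean_acc: tuple
    mean_bacc: tuple
    repeats: int
    seed: int


# ---------------------------------------------------------------------------
# subset construction and training
# ---------------------------------------------------------------------------


def make_undersampled_subsets(
    pos_ids: Sequence[str], neg_ids: Sequence[str], seed: int
) -> list:
    """Partition negatives into K groups and pair each with all positives.

    K = round(|neg| / |pos|), at least 1 (half-way cases round up).
    Negatives are shuffled by the seed and split into near-equal groups
    whose sizes differ by at most one; every negative lands in exactly one
    subset.  Each returned subset is a list: group-k negatives followed by
    all positives.
    """
    if not pos_ids or not neg_ids:
        raise ValueError("both id lists must be non-empty")
    k = max(1, int(math.floor(len(neg_ids) / len(pos_ids) + 0.5)))
    rng = np.random.default_rng(seed)
    shuffled = list(neg_ids)
    rng.shuffle(shuffled)
    groups = np.array_split(np.array(shuffled, dtype=object), k)
    return [list(group) + list(pos_ids) for group in groups]


def _fit_forest(X: np.ndarray, y: np.ndarray, params: RFParams, seed: int):
    if np.unique(y).size < 2:
        raise ValueError("training subset contains a single class")
    forest = RandomForestClassifier(
        n_estimators=params.n_trees,
        max_depth=params.max_depth,
        max_features=params.resolve_max_features(X.shape[1]),
        random_state=seed,
    )
    forest.fit(X, y)
    return forest


def train_ensemble(
    matrix: FeatureMatrix,
    feature_subset: Sequence[str] | None = None,
    seed: int = 0,
    rf_params: RFParams = RFParams(),
) -> EnsembleModel:
    """Train the K-member undersampling ensemble on a labeled matrix."""
    if matrix.labels is None:
        raise ValueError("feature matrix must carry labels")
    names = list(feature_subset) if feature_subset is not None else matrix.feature_names
    sub = matrix.subset_features(names)
    row_of = {sample_id: i for i, sample_id in enumerate(sub.ids)}
    pos_ids = [sid for sid, lab in zip(sub.ids, sub.labels) if lab == 1]
    neg_ids = [sid for sid, lab in zip(sub.ids, sub.labels) if lab == 0]
    subsets = make_undersampled_subsets(pos_ids, neg_ids, seed)
    members = []
    for k, subset_ids in enumerate(subsets):
        # rows in matrix order so K=1 reduces exactly to the single-forest fit
        rows = sorted(row_of[sid] for sid in subset_ids)
        X = sub.values[rows]
        y = sub.labels[rows]
        members.append(_fit_forest(X, y, rf_params, seed + 1000 * k))
    return EnsembleModel(tuple(members), tuple(names), seed, rf_params)


def predict_vote(model: EnsembleModel, matrix: FeatureMatrix) -> tuple:
    """Majority-vote prediction.

    Returns ``(labels, positive_votes)``.  Each member casts a hard vote;
    with an even member count, exact ties go to the positive class — a
    documented rule favouring minority recall (the reference configuration
    K = 11 cannot tie).
    """
    sub = matrix.subset_features(list(model.feature_names))
    votes = np.zeros(sub.n_samples, dtype=int)
    for member in model.members:
        votes += member.predict(sub.values).astype(int)
    k = model.n_members
    labels = (2 * votes >= k).astype(int)  # ties (2v == k) -> positive
    return labels, votes


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def metrics_from_counts(tp: int, tn: int, fp: int, fn: int) -> MetricsReport:
    """Build the report from confusion counts; undefined rates are NaN."""
    pos = tp + fn
    neg = tn + fp
    sn = tp / pos if pos else float("nan")
    sp = tn / neg if neg else float("nan")
    total = pos + neg
    acc = (tp + tn) / total if total else float("nan")
    bacc = (sn + sp) / 2
    return MetricsReport(tp, tn, fp, fn, sn, sp, acc, bacc)


def compute_metrics(
    true_labels: Sequence[int], predicted_labels: Sequence[int]
) -> MetricsReport:
    """Sensitivity, specificity, accuracy and balanced accuracy.

    Sn = TP/(TP+FN), Sp = TN/(TN+FP), Acc = (TP+TN)/n,
    BAcc = (Sn+Sp)/2.  Labels are 1 = positive, 0 = negative.
    """
    y = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if y.shape != p.shape:
        raise ValueError("label vectors must have the same length")
    tp = int(np.sum((y == 1) & (p == 1)))
    tn = int(np.sum((y == 0) & (p == 0)))
    fp = int(np.sum((y == 0) & (p == 1)))
    fn = int(np.sum((y == 1) & (p == 0)))
    return metrics_from_counts(tp, tn, fp, fn)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def _stratified_folds(labels: np.ndarray, folds: int, rng) -> list:
    """Index sets of the fold test sets: class-wise shuffled near-equal splits."""
    test_sets = [[] for _ in range(folds)]
    for cls in (1, 0):
        idx = np.flatnonzero(labels == cls)
        if idx.size < folds:
            raise ValueError(
                f"class {cls} has {idx.size} samples, fewer than {folds} folds"
            )
        rng.shuffle(idx)
        for f, part in enumerate(np.array_split(idx, folds)):
            test_sets[f].extend(part.tolist())
    return [sorted(s) for s in test_sets]


def stratified_cv(
    matrix: FeatureMatrix,
    folds: int = 10,
    seed: int = 0,
    feature_subset: Sequence[str] | None = None,
    rf_params: RFParams = RFParams(),
    use_ensemble: bool = True,
) -> MetricsReport:
    """Stratified k-fold cross-validation with pooled confusion counts.

    Positives and negatives are independently split into ``folds``
    near-equal parts; fold f tests on part f of each class and trains on
    the rest.  With ``use_ensemble=False`` a single forest is trained on
    the full (possibly imbalanced) training rows instead of the
    undersampling ensemble.  Predictions from all folds are pooled into
    one confusion matrix, so every sample is tested exactly once.
    """
    if matrix.labels is None:
        raise ValueError("feature matrix must carry labels")
    names = list(feature_subset) if feature_subset is not None else matrix.feature_names
    sub = matrix.subset_features(names)
    rng = np.random.default_rng(seed)
    test_sets = _stratified_folds(sub.labels, folds, rng)

    y_true_all, y_pred_all = [], []
    for f, test_idx in enumerate(test_sets):
        test_mask = np.zeros(sub.n_samples, dtype=bool)
        test_mask[test_idx] = True
        train = sub.take_rows(np.flatnonzero(~test_mask))
        test = sub.take_rows(test_idx)
        fold_seed = seed + 7919 * (f + 1)
        if use_ensemble:
            model = train_ensemble(train, seed=fold_seed, rf_params=rf_params)
            pred, _ = predict_vote(model, test)
        else:
            forest = _fit_forest(train.values, train.labels, rf_params, fold_seed)
            pred = forest.predict(test.values).astype(int)
        y_true_all.append(test.labels)
        y_pred_all.append(pred)
    return compute_metrics(np.concatenate(y_true_all), np.concatenate(y_pred_all))


def cv_evaluator(
    matrix: FeatureMatrix,
    folds: int = 10,
    seed: int = 0,
    rf_params: RFParams = RFParams(),
    use_ensemble: bool = True,
):
    """Bind a matrix and settings into the evaluator signature IFS expects."""

    def evaluate(feature_names):
        return stratified_cv(
            matrix,
            folds=folds,
            seed=seed,
            feature_subset=feature_names,
            rf_params=rf_params,
            use_ensemble=use_ensemble,
        )

    return evaluate


# ---------------------------------------------------------------------------
# imbalance-ratio sweep
# ---------------------------------------------------------------------------


def ratio_sweep(
    matrix: FeatureMatrix,
    ratios: Sequence[int] = tuple(range(1, 11)),
    repeats: int = 10,
    seed: int = 0,
    folds: int = 10,
    rf_params: RFParams = RFParams(),
) -> RatioSweepResult:
    """Measure how the positive:negative training ratio skews performance.

    For each ratio r, ``repeats`` datasets are built from all positives
    plus r * |pos| randomly drawn negatives, each evaluated by stratified
    cross-validation with a *single* forest (no undersampling ensemble —
    the experiment isolates the imbalance effect the ensemble later
    corrects), and the four rates are averaged over repeats.
    """
    if matrix.labels is None:
        raise ValueError("feature matrix must carry labels")
    pos_idx = np.flatnonzero(matrix.labels == 1)
    neg_idx = np.flatnonzero(matrix.labels == 0)
    n_pos = pos_idx.size
    max_ratio = max(ratios)
    if neg_idx.size < max_ratio * n_pos:
        raise ValueError(
            f"need at least {max_ratio * n_pos} negatives for ratio 1:{max_ratio}, "
            f"have {neg_idx.size}"
        )
    rng = np.random.default_rng(seed)
    mean_sn, mean_sp, mean_acc, mean_bacc = [], [], [], []
    for r in ratios:
        reports = []
        for rep in range(repeats):
            chosen = rng.choice(neg_idx, size=r * n_pos, replace=False)
            rows = np.concatenate([pos_idx, chosen])
            subset = matrix.take_rows(rows)
            reports.append(
                stratified_cv(
                    subset,
                    folds=folds,
                    seed=seed + 104729 * (rep + 1) + r,
                    rf_params=rf_params,
                    use_ensemble=False,
                )
            )
        mean_sn.append(float(np.mean([m.sn for m in reports])))
        mean_sp.append(float(np.mean([m.sp for m in reports])))
        mean_acc.append(float(np.mean([m.acc for m in reports])))
        mean_bacc.append(float(np.mean([m.bacc for m in reports])))
    return RatioSweepResult(
        tuple(ratios),
        tuple(mean_sn),
        tuple(mean_sp),
        tuple(mean_acc),
        tuple(mean_bacc),
        repeats,
        seed,
    )
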