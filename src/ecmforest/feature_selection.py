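"""Information-gain-ratio ranking and incremental feature selection.

The gain ratio of a (discretized) feature F for the binary class C is

    IGR(F) = (H(C) - H(C | F)) / H(F),        entropies in bits,

taken as 0 when H(F) = 0 (a constant feature carries no information and
would otherwise divide by zero).  Features are ranked by descending IGR,
ties broken by canonical column order, and incremental feature selection
evaluates growing rank-ordered prefixes with a cross-validated classifier,
choosing the smallest prefix whose balanced accuracy is within a tolerance
of the best seen.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np

from .io_formats import FeatureMatrix


@dataclasses.dataclass
class DiscretizationRule:
    """Binning of continuous features for the entropy computations.

    Strategies: ``quantile`` (equal-frequency, robust to skew; the default)
    or ``width`` (equal-width).  Edges are the interior cut points; values
    are assigned by right-open binning.  A constant feature yields no edges
    and collapses to a single bin.
    """

    bins: int = 10
    strategy: str = "quantile"

    def __post_init__(self) -> None:
        if self.bins < 2:
            raise ValueError("bins must be >= 2")
        if self.strategy not in ("quantile", "width"):
            raise ValueError(f"unknown strategy {self.strategy!r}")

    def edges(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.strategy == "quantile":
            qs = np.linspace(0, 1, self.bins + 1)[1:-1]
            cuts = np.quantile(values, qs)
        else:
            lo, hi = values.min(), values.max()
            cuts = np.linspace(lo, hi, self.bins + 1)[1:-1]
        return np.unique(cuts)  # strictly increasing; empty for constants

    def discretize(self, values: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.edges(values), np.asarray(values, dtype=float), side="left")


@dataclasses.dataclass(frozen=True)
class RankedFeatureList:
    """Feature names with gain-ratio scores, descending."""

    names: tuple
    scores: tuple

    def __post_init__(self) -> None:
        if len(self.names) != len(self.scores):
            raise ValueError("names and scores must align")

    def __len__(self) -> int:
        return len(self.names)

    def top(self, k: int) -> list:
        return list(self.names[:k])


@dataclasses.dataclass(frozen=True)
class IFSTrace:
    """Per-prefix cross-validated metrics and the selected prefix size."""

    sizes: tuple
    sn: tuple
    sp: tuple
    acc: tuple
    bacc: tuple
    delta: float
    selected_k: int

    @property
    def selected_bacc(self) -> float:
        return self.bacc[self.sizes.index(self.selected_k)]


def _entropy_from_counts(counts: np.ndarray) -> float:
    counts = counts[counts > 0]
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def igr_score(
    values: Sequence[float],
    labels: Sequence[int],
    rule: DiscretizationRule | None = DiscretizationRule(),
) -> float:
    """Gain ratio of one feature for binary labels, in [0, 1].

    With ``rule`` given, values are discretized first; with ``rule=None``
    the distinct values themselves are the discrete categories (the score
    is invariant under any renaming of those categories).
    """
    values = np.asarray(values)
    labels = np.asarray(labels, dtype=int)
    if values.shape != labels.shape:
        raise ValueError("values and labels must have the same length")
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("labels contain a single class; gain ratio is undefined")

    if rule is not None:
        codes = rule.discretize(values.astype(float))
    else:
        _, codes = np.unique(values, return_inverse=True)

    n = labels.size
    n_codes = int(codes.max()) + 1
    joint = np.zeros((n_codes, 2))
    np.add.at(joint, (codes, (labels == classes.max()).astype(int)), 1)

    h_class = _entropy_from_counts(joint.sum(axis=0))
    h_feature = _entropy_from_counts(joint.sum(axis=1))
    if h_feature == 0:
        return 0.0
    h_cond = 0.0
    for row in joint:
        total = row.sum()
        if total:
            h_cond += (total / n) * _entropy_from_counts(row)
    igr = (h_class - h_cond) / h_feature
    # clamp tiny negative round-off
    return float(min(max(igr, 0.0), 1.0))


def rank_features(
    matrix: FeatureMatrix, rule: DiscretizationRule = DiscretizationRule()
) -> RankedFeatureList:
    """Score every column and sort descending, ties in canonical order."""
    if matrix.labels is None:
        raise ValueError("feature matrix must carry labels")
    scores = [
        igr_score(matrix.values[:, j], matrix.labels, rule)
        for j in range(matrix.n_features)
    ]
    order = sorted(range(matrix.n_features), key=lambda j: (-scores[j], j))
    return RankedFeatureList(
        tuple(matrix.feature_names[j] for j in order),
        tuple(scores[j] for j in order),
    )


def ifs_select(
    matrix: FeatureMatrix,
    ranking: RankedFeatureList,
    evaluator: Callable,
    delta: float = 0.001,
    step: int = 1,
) -> IFSTrace:
    """Incremental feature selection over rank-ordered prefixes.

    ``evaluator(feature_names)`` must return a metrics report with
    ``sn``/``sp``/``acc``/``bacc`` attributes (typically a seeded
    cross-validated ensemble run).  Prefixes of sizes step, 2*step, ...
    (always including the full set) are evaluated; the selected size is
    the smallest whose balanced accuracy is within ``delta`` of the
    maximum, trading a negligible accuracy loss for a lower dimension.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    if step < 1:
        raise ValueError("step must be >= 1")
    d = len(ranking)
    if d == 0:
        raise ValueError("empty ranking")
    sizes = list(range(step, d + 1, step))
    if sizes[-1] != d:
        sizes.append(d)

    sn, sp, acc, bacc = [], [], [], []
    for k in sizes:
        try:
            report = evaluator(ranking.top(k))
        except Exception as exc:
            raise RuntimeError(f"evaluator failed at prefix size {k}: {exc}") from exc
        sn.append(report.sn)
        sp.append(report.sp)
        acc.append(report.acc)
        bacc.append(report.bacc)

    best = max(bacc)
    selected = next(k for k, b in zip(sizes, bacc) if b >= best - delta)
    return IFSTrace(
        tuple(sizes), tuple(sn), tuple(sp), tuple(acc), tuple(bacc), delta, selected
    )
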