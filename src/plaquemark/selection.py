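"""Pixel-feature selection strategies and classifier adapters.

Four selectors are provided:

* ``caga_filter_select`` — CAGA search driven by the class-separability
  distance criterion (filter mode, computed on train + validation data);
* ``caga_wrapper_select`` — CAGA search driven by the validation accuracy
  of a classifier trained on the training set (wrapper mode, SVM or RF);
* ``pca_select`` — a PCA comparator that ranks original pixels by
  variance-weighted absolute loadings of the components retained at 95 %
  cumulative variance;
* plus ``classify_test`` for final testing of a selected mask.

The separability distance criterion is the ratio of inter-class to
prior-weighted intra-class variance over the selected values,

    lambda = S_b / S_w,
    S_b = (c1 - c2)^2,
    S_w = (P1/N1) * sum_ik (c_1ik - c1)^2 + (P2/N2) * sum_jk (c_2jk - c2)^2,

where c1, c2 are the scalar class centers over all selected values of a
class and P = N / (N1 + N2) are the class priors.  Larger lambda means the
selected gray values separate the classes better.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from .caga import CAGAConfig, run_caga
from .features import FeatureMatrix
from .phantom import LABEL_AD

__all__ = [
    "ClassifierConfig",
    "SelectionResult",
    "ConfusionCounts",
    "separability_fitness",
    "make_separability_objective",
    "wrapper_fitness",
    "caga_filter_select",
    "caga_wrapper_select",
    "pca_select",
    "classify_test",
]

_EPS = 1e-12  # guards zero within-class variance


@dataclass(frozen=True)
class ClassifierConfig:
    """Classifier adapter settings.

    ``rf_repeats`` is the number of independently built forests whose
    accuracies are averaged in the RF wrapper fitness (reduces the variance
    that forest randomness injects into the search signal).
    """

    kind: str = "svm"  # "svm" (linear kernel) or "rf"
    svm_c: float = 1.0
    rf_trees: int = 500
    rf_repeats: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("svm", "rf"):
            raise ValueError("classifier kind must be 'svm' or 'rf'")
        if self.rf_trees < 1 or self.rf_repeats < 1:
            raise ValueError("tree and repeat counts must be >= 1")

    def build(self, seed: int | None = None):
        if self.kind == "svm":
            return SVC(kernel="linear", C=self.svm_c)
        return RandomForestClassifier(
            n_estimators=self.rf_trees, random_state=seed
        )


@dataclass
class SelectionResult:
    """A selected binary feature mask with its provenance."""

    mask: np.ndarray
    fitness: float
    algorithm: str
    seed: int | None = None
    repeat_index: int | None = None

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())

    def to_dict(self) -> dict:
        # run-length encoded mask keeps serialized results compact
        mask = np.asarray(self.mask, dtype=np.uint8)
        edges = np.flatnonzero(np.diff(mask)) + 1
        runs = np.diff(np.concatenate([[0], edges, [len(mask)]]))
        return {
            "first_value": int(mask[0]) if len(mask) else 0,
            "run_lengths": runs.astype(int).tolist(),
            "length": int(len(mask)),
            "fitness": float(self.fitness),
            "algorithm": self.algorithm,
            "seed": self.seed,
            "repeat_index": self.repeat_index,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SelectionResult":
        mask = np.zeros(d["length"], dtype=bool)
        value, pos = bool(d["first_value"]), 0
        for run in d["run_lengths"]:
            mask[pos : pos + run] = value
            value, pos = not value, pos + run
        return cls(
            mask=mask,
            fitness=d["fitness"],
            algorithm=d["algorithm"],
            seed=d.get("seed"),
            repeat_index=d.get("repeat_index"),
        )


@dataclass
class ConfusionCounts:
    """TP/TN/FP/FN tallies with AD as the positive class."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @classmethod
    def from_labels(
        cls, true: Sequence[str], predicted: Sequence[str], positive: str = LABEL_AD
    ) -> "ConfusionCounts":
        true = np.asarray(true)
        predicted = np.asarray(predicted)
        if true.shape != predicted.shape:
            raise ValueError("label lists differ in length")
        t_pos, p_pos = true == positive, predicted == positive
        return cls(
            tp=int(np.sum(t_pos & p_pos)),
            tn=int(np.sum(~t_pos & ~p_pos)),
            fp=int(np.sum(~t_pos & p_pos)),
            fn=int(np.sum(t_pos & ~p_pos)),
        )

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def separability_fitness(
    class1: np.ndarray, class2: np.ndarray, eps: float = _EPS
) -> float:
    """Separability distance criterion over two classes of selected values.

    ``class1`` and ``class2`` are (n_samples, n_selected_features) arrays of
    gray values.  Returns S_b / S_w; when the within-class variance S_w
    falls below ``eps`` the ratio is reported against ``eps`` instead.
    """
    class1 = np.atleast_2d(np.asarray(class1, dtype=np.float64))
    class2 = np.atleast_2d(np.asarray(class2, dtype=np.float64))
    if class1.size == 0 or class2.size == 0:
        raise ValueError("both classes need at least one selected value")
    n1, n2 = class1.shape[0], class2.shape[0]
    p1 = n1 / (n1 + n2)
    p2 = n2 / (n1 + n2)
    c1 = class1.mean()
    c2 = class2.mean()
    s_b = (c1 - c2) ** 2
    s_w = (p1 / n1) * float(((class1 - c1) ** 2).sum()) + (p2 / n2) * float(
        ((class2 - c2) ** 2).sum()
    )
    return float(s_b / max(s_w, eps))


def make_separability_objective(
    matrix: FeatureMatrix, sample_idx: np.ndarray
):
    """Build a fast mask -> lambda objective over train+validation samples.

    Uses per-feature sums of values and squared values per class, so one
    evaluation costs O(selected features) instead of O(features x samples).
    Algebraically identical to :func:`separability_fitness` on the selected
    submatrix.
    """
    labels = matrix.labels[sample_idx]
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need two classes for the separability criterion")
    sub = matrix.matrix[:, sample_idx]
    a = sub[:, labels == classes[0]]
    b = sub[:, labels == classes[1]]
    n1, n2 = a.shape[1], b.shape[1]
    p1, p2 = n1 / (n1 + n2), n2 / (n1 + n2)
    s1, q1 = a.sum(axis=1), (a**2).sum(axis=1)
    s2, q2 = b.sum(axis=1), (b**2).sum(axis=1)

    def objective(mask: np.ndarray) -> float:
        sel = mask.astype(bool)
        m = int(sel.sum())
        if m == 0:
            raise ValueError("empty feature selection")
        t1, t2 = s1[sel].sum(), s2[sel].sum()
        c1, c2 = t1 / (m * n1), t2 / (m * n2)
        ss1 = q1[sel].sum() - 2 * c1 * t1 + m * n1 * c1**2
        ss2 = q2[sel].sum() - 2 * c2 * t2 + m * n2 * c2**2
        s_b = (c1 - c2) ** 2
        s_w = (p1 / n1) * ss1 + (p2 / n2) * ss2
        return float(s_b / max(s_w, _EPS))

    return objective


def wrapper_fitness(
    mask: np.ndarray,
    matrix: FeatureMatrix,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    clf: ClassifierConfig,
    rng: np.random.Generator | None = None,
) -> float:
    """Validation accuracy of a classifier trained under the mask.

    Trains on the training columns restricted to the selected features and
    scores on the validation columns.  For random forests the value is the
    mean accuracy over ``clf.rf_repeats`` independently seeded forests.
    """
    sel = np.asarray(mask, dtype=bool)
    if not sel.any():
        raise ValueError("empty feature selection")
    if np.intersect1d(train_idx, val_idx).size:
        raise ValueError("train and validation sets overlap")
    x_train = matrix.matrix[sel][:, train_idx].T
    x_val = matrix.matrix[sel][:, val_idx].T
    y_train = matrix.labels[train_idx]
    y_val = matrix.labels[val_idx]
    if clf.kind == "svm":
        model = clf.build()
        model.fit(x_train, y_train)
        return float(np.mean(model.predict(x_val) == y_val))
    rng = rng or np.random.default_rng(0)
    accs = []
    for _ in range(clf.rf_repeats):
        model = clf.build(seed=int(rng.integers(2**31 - 1)))
        model.fit(x_train, y_train)
        accs.append(float(np.mean(model.predict(x_val) == y_val)))
    return float(np.mean(accs))


def caga_filter_select(
    matrix: FeatureMatrix,
    trainval_idx: np.ndarray,
    config: CAGAConfig | None = None,
    rng: np.random.Generator | None = None,
    repeat_index: int | None = None,
) -> SelectionResult:
    """CAGA search with the separability criterion over train+validation."""
    config = config or CAGAConfig()
    objective = make_separability_objective(matrix, trainval_idx)
    best, _ = run_caga(objective, matrix.template_length, config, rng=rng)
    return SelectionResult(
        mask=best.genes.astype(bool),
        fitness=float(best.energy),
        algorithm="caga_filter",
        seed=config.seed,
        repeat_index=repeat_index,
    )


def caga_wrapper_select(
    matrix: FeatureMatrix,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    clf: ClassifierConfig,
    config: CAGAConfig | None = None,
    rng: np.random.Generator | None = None,
    repeat_index: int | None = None,
) -> SelectionResult:
    """CAGA search with classifier validation accuracy as fitness."""
    config = config or CAGAConfig()
    fitness_rng = np.random.default_rng(config.seed + 1) if rng is None else rng

    def objective(mask: np.ndarray) -> float:
        return wrapper_fitness(mask, matrix, train_idx, val_idx, clf, rng=fitness_rng)

    best, _ = run_caga(objective, matrix.template_length, config, rng=rng)
    return SelectionResult(
        mask=best.genes.astype(bool),
        fitness=float(best.energy),
        algorithm=f"caga_{clf.kind}_wrapper",
        seed=config.seed,
        repeat_index=repeat_index,
    )


def pca_select(
    matrix: FeatureMatrix,
    trainval_idx: np.ndarray,
    n_features: int = 125,
    variance_retained: float = 0.95,
) -> SelectionResult:
    """Rank original pixels by PCA loadings and keep the top ``n_features``.

    Components are fitted on the train+validation columns; those reaching
    ``variance_retained`` cumulative explained variance are kept, and each
    original feature is scored by the explained-variance-weighted sum of
    its absolute loadings over those components.
    """
    if n_features > matrix.template_length:
        raise ValueError("n_features exceeds the template length")
    x = matrix.matrix[:, trainval_idx].T  # samples x features
    if np.allclose(x.var(axis=0), 0.0):
        raise ValueError("degenerate (constant) feature matrix")
    pca = PCA(svd_solver="full")
    pca.fit(x)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_keep = int(np.searchsorted(cum, variance_retained) + 1)
    n_keep = min(n_keep, len(pca.explained_variance_))
    weights = pca.explained_variance_[:n_keep]
    loadings = np.abs(pca.components_[:n_keep])
    scores = (weights[:, None] * loadings).sum(axis=0)
    top = np.argsort(scores, kind="stable")[::-1][:n_features]
    mask = np.zeros(matrix.template_length, dtype=bool)
    mask[top] = True
    objective = make_separability_objective(matrix, trainval_idx)
    return SelectionResult(
        mask=mask, fitness=objective(mask), algorithm="pca"
    )


def classify_test(
    mask: np.ndarray,
    matrix: FeatureMatrix,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    clf: ClassifierConfig,
    seed: int | None = None,
) -> tuple[np.ndarray, ConfusionCounts]:
    """Train on the masked training columns and classify the test columns."""
    sel = np.asarray(mask, dtype=bool)
    if not sel.any():
        raise ValueError("empty feature selection")
    if np.intersect1d(train_idx, test_idx).size:
        raise ValueError("test set overlaps the training set")
    model = clf.build(seed=seed)
    model.fit(matrix.matrix[sel][:, train_idx].T, matrix.labels[train_idx])
    predicted = model.predict(matrix.matrix[sel][:, test_idx].T)
    counts = ConfusionCounts.from_labels(matrix.labels[test_idx], predicted)
    return predicted, counts
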