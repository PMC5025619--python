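"""Quantitative evaluation: confusion metrics, plaque match rate,
significance against random selection, and intensity contrast.

Match/miss rate scores the marked pixels against plaque ground truth: a
plaque is matched when some marked coordinate on its slice lies within a
given Euclidean radius of its center.  The mean-total-intensity (MTI)
contrast checks the hypointensity mechanism directly: summed over the
finally selected pixels, AD test slices should be darker than controls.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .phantom import LABEL_AD, LABEL_CTL, PlaqueMap
from .selection import ConfusionCounts
from .voting import MarkedImage

__all__ = [
    "MatchReport",
    "IntensityReport",
    "confusion_metrics",
    "match_rate",
    "significance_vs_random",
    "selection_correlation",
    "intensity_contrast",
    "mapped_pixel_significance",
    "intensity_significance",
]


@dataclass
class MatchReport:
    total: int
    matched: int
    radius: float

    @property
    def unmatched(self) -> int:
        return self.total - self.matched

    @property
    def match_rate(self) -> float:
        return self.matched / self.total if self.total else math.nan

    @property
    def miss_rate(self) -> float:
        return self.unmatched / self.total if self.total else math.nan


@dataclass
class IntensityReport:
    """Total and mean selected-pixel intensities per class for one split."""

    ti_ad: float
    ti_ctl: float
    n_ad: int
    n_ctl: int

    @property
    def mti_ad(self) -> float:
        return self.ti_ad / self.n_ad

    @property
    def mti_ctl(self) -> float:
        return self.ti_ctl / self.n_ctl


def confusion_metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity); NaN flags an undefined ratio."""

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else math.nan

    accuracy = ratio(c.tp + c.tn, c.total)
    sensitivity = ratio(c.tp, c.tp + c.fn)
    specificity = ratio(c.tn, c.tn + c.fp)
    return accuracy, sensitivity, specificity


def match_rate(
    marked: Sequence[MarkedImage],
    truth: PlaqueMap,
    radius: float,
    slice_keys: Sequence[tuple[str, int]] | None = None,
) -> MatchReport:
    """Score marked pixels against plaque ground truth.

    ``slice_keys`` names the AD slices under evaluation (default: every
    slice appearing in ``truth``); slices without marks contribute misses,
    so an AD slice misclassified as control counts against the rate.
    """
    if radius < 0:
        raise ValueError("match radius must be nonnegative")
    marks_by_slice: dict[tuple[str, int], np.ndarray] = {
        m.image.key: np.asarray(m.coords, dtype=float) for m in marked
    }
    if slice_keys is None:
        slice_keys = truth.keys()
    total = matched = 0
    for key in slice_keys:
        records = truth.for_slice(key)
        total += len(records)
        coords = marks_by_slice.get(key)
        if coords is None or len(coords) == 0:
            continue
        for rec in records:
            d = np.hypot(coords[:, 0] - rec.row, coords[:, 1] - rec.col)
            if (d <= radius).any():
                matched += 1
    if total == 0:
        raise ValueError("ground truth holds no plaques for the given slices")
    return MatchReport(total=total, matched=matched, radius=radius)


def significance_vs_random(
    proposed: Sequence[float],
    random_baseline: Sequence[float],
    alpha: float = 0.05,
    equal_var: bool = False,
) -> tuple[float, int]:
    """Two-sample t-test of proposed vs random-selection accuracies.

    Welch's variant by default.  Returns (p, H) with H = 1 iff p < alpha.
    Degenerate zero-variance groups: identical means give p = 1 (H = 0);
    different means with zero spread give p = 0.
    """
    a = np.asarray(proposed, dtype=float)
    b = np.asarray(random_baseline, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two values per group")
    if a.std() == 0.0 and b.std() == 0.0:
        p = 1.0 if a.mean() == b.mean() else 0.0
    else:
        with warnings.catch_warnings():
            # near-identical groups trigger a precision warning on the way
            # to the p ~ 1 we want anyway
            warnings.simplefilter("ignore", RuntimeWarning)
            p = float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)
        if math.isnan(p):
            p = 1.0
    return p, int(p < alpha)


def selection_correlation(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Pearson correlation of two binary masks; 0 when either is constant."""
    a = np.asarray(mask_a, dtype=float)
    b = np.asarray(mask_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("mask length mismatch")
    if a.std() == 0.0 or b.std() == 0.0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def intensity_contrast(
    final_mask: np.ndarray,
    matrix_columns: np.ndarray,
    labels: Sequence[str],
) -> IntensityReport:
    """Sum selected-pixel intensities per test sample and aggregate by class.

    ``matrix_columns`` is the template x n_test submatrix of the feature
    matrix; ``labels`` are the true class labels of those columns.
    """
    sel = np.asarray(final_mask, dtype=bool)
    if not sel.any():
        raise ValueError("empty feature selection")
    labels = np.asarray(labels)
    per_sample = matrix_columns[sel].sum(axis=0)
    ad = labels == LABEL_AD
    ctl = labels == LABEL_CTL
    if not ad.any() or not ctl.any():
        raise ValueError("both classes must appear in the test set")
    return IntensityReport(
        ti_ad=float(per_sample[ad].sum()),
        ti_ctl=float(per_sample[ctl].sum()),
        n_ad=int(ad.sum()),
        n_ctl=int(ctl.sum()),
    )


def mapped_pixel_significance(
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    matrix_columns: np.ndarray,
    alpha: float = 0.05,
) -> tuple[float, int]:
    """Are the pixels selected by one mask distinguishable from another's?

    Compares the per-pixel mean gray values (over the given sample columns,
    typically the AD test samples) of the two selections with a Welch
    t-test.  A selector that targets hypointense plaque pixels yields far
    darker values than a uniformly random selection, so this is the
    per-split check that a selection differs from chance.
    """
    a = matrix_columns[np.asarray(mask_a, dtype=bool)].mean(axis=1)
    b = matrix_columns[np.asarray(mask_b, dtype=bool)].mean(axis=1)
    return significance_vs_random(a, b, alpha=alpha)


def intensity_significance(
    mti_ad: Sequence[float], mti_ctl: Sequence[float], equal_var: bool = False
) -> float:
    """p-value of the MTI_AD vs MTI_CTL comparison across splits."""
    return float(
        stats.ttest_ind(
            np.asarray(mti_ad, float), np.asarray(mti_ctl, float), equal_var=equal_var
        ).pvalue
    )
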