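"""End-to-end experiment orchestration.

One experiment = generate (or load) data -> extract pixel vectors -> build
the template-aligned feature matrix -> for each of ``n_split_repeats``
random train/validation/test partitions: run the chosen selector k times,
vote the masks into a final mask, classify the test slices with it, mark
the AD-predicted slices, and score classification, plaque matching and
intensity contrast.  A matched-cardinality random-selection baseline and
per-split significance tests complete the analysis.

Stage seeds are derived from the master seed with
``numpy.random.SeedSequence([master_seed, repeat, stage, run])`` so every
repeat and selection run is independent yet exactly reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .caga import CAGAConfig
from .evaluate import (
    confusion_metrics,
    intensity_contrast,
    intensity_significance,
    mapped_pixel_significance,
    match_rate,
    selection_correlation,
    significance_vs_random,
)
from .features import FeatureMatrix, build_feature_matrix, extract_pixel_vector
from .phantom import (
    LABEL_AD,
    BrainImage,
    PhantomConfig,
    PlaqueMap,
    generate_dataset,
    split_dataset,
)
from .selection import (
    ClassifierConfig,
    SelectionResult,
    caga_filter_select,
    caga_wrapper_select,
    classify_test,
    pca_select,
)
from .voting import VotingConfig, mark_ad_images, vote

__all__ = [
    "VALID_PAIRINGS",
    "ExperimentConfig",
    "ExperimentContext",
    "run_experiment",
    "run_random_baseline",
    "attach_significance",
    "run_full_study",
    "report_table",
]

# the six studied selector/classifier pairings
VALID_PAIRINGS = {
    ("caga_filter", "svm"),
    ("caga_filter", "rf"),
    ("pca", "svm"),
    ("pca", "rf"),
    ("caga_svm_wrapper", "svm"),
    ("caga_rf_wrapper", "rf"),
}

_STAGE_SPLIT = 1
_STAGE_SELECT = 2
_STAGE_TEST = 3
_STAGE_BASELINE = 4


def _mean(xs: Sequence[float]) -> float | None:
    return float(np.mean(xs)) if len(xs) else None


def _median(xs: Sequence[float]) -> float | None:
    return float(np.median(xs)) if len(xs) else None


def _stage_rng(master_seed: int, repeat: int, stage: int, run: int = 0):
    return np.random.default_rng(
        np.random.SeedSequence([master_seed, repeat, stage, run])
    )


def _stage_seed(master_seed: int, repeat: int, stage: int, run: int = 0) -> int:
    return int(_stage_rng(master_seed, repeat, stage, run).integers(2**31 - 1))


@dataclass(frozen=True)
class ExperimentConfig:
    """Full experiment settings; defaults reproduce the reference protocol
    (CAGA filter selection, linear-SVM testing, 8 split repeats, 10 voted
    selection runs per split with threshold 8)."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    algorithm: str = "caga_filter"
    test_classifier: str = "svm"
    caga: CAGAConfig = field(default_factory=CAGAConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    voting: VotingConfig = field(default_factory=VotingConfig)
    n_split_repeats: int = 8
    test_composition: tuple[int, int] = (32, 20)
    pca_n_features: int = 125
    match_radius: float | None = None  # default: plaque radius + 1
    master_seed: int = 0

    def __post_init__(self) -> None:
        if (self.algorithm, self.test_classifier) not in VALID_PAIRINGS:
            raise ValueError(
                f"({self.algorithm}, {self.test_classifier}) is not one of the "
                f"six studied pairings: {sorted(VALID_PAIRINGS)}"
            )

    @property
    def effective_match_radius(self) -> float:
        if self.match_radius is not None:
            return self.match_radius
        return self.phantom.plaque_radius + 1.0


@dataclass
class ExperimentContext:
    """Artifacts shared by the experiment and its random baseline."""

    config: ExperimentConfig
    images: list[BrainImage]
    plaques: PlaqueMap
    vectors: list
    matrix: FeatureMatrix
    splits: list[tuple[np.ndarray, np.ndarray, np.ndarray]]


def _select_once(
    cfg: ExperimentConfig,
    matrix: FeatureMatrix,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    repeat: int,
    run: int,
) -> SelectionResult:
    seed = _stage_seed(cfg.master_seed, repeat, _STAGE_SELECT, run)
    rng = np.random.default_rng(seed)
    trainval = np.concatenate([train_idx, val_idx])
    if cfg.algorithm == "caga_filter":
        return caga_filter_select(matrix, trainval, cfg.caga, rng=rng, repeat_index=run)
    if cfg.algorithm in ("caga_svm_wrapper", "caga_rf_wrapper"):
        kind = "svm" if cfg.algorithm == "caga_svm_wrapper" else "rf"
        clf = ClassifierConfig(
            kind=kind,
            svm_c=cfg.classifier.svm_c,
            rf_trees=cfg.classifier.rf_trees,
            rf_repeats=cfg.classifier.rf_repeats,
        )
        return caga_wrapper_select(
            matrix, train_idx, val_idx, clf, cfg.caga, rng=rng, repeat_index=run
        )
    if cfg.algorithm == "pca":
        return pca_select(matrix, trainval, n_features=cfg.pca_n_features)
    raise ValueError(f"unknown algorithm {cfg.algorithm!r}")


def build_context(cfg: ExperimentConfig) -> ExperimentContext:
    """Generate the phantom data and the shared feature-space artifacts."""
    images, plaques = generate_dataset(cfg.phantom)
    vectors = [extract_pixel_vector(im) for im in images]
    matrix = build_feature_matrix(vectors, [im.label for im in images])
    splits = split_dataset(
        images,
        n_repeats=cfg.n_split_repeats,
        test_composition=cfg.test_composition,
        seed=_stage_seed(cfg.master_seed, 0, _STAGE_SPLIT),
    )
    return ExperimentContext(
        config=cfg,
        images=images,
        plaques=plaques,
        vectors=vectors,
        matrix=matrix,
        splits=splits,
    )


def run_experiment(
    cfg: ExperimentConfig, context: ExperimentContext | None = None
) -> tuple[dict, ExperimentContext]:
    """Execute all split repeats and return (report, context).

    The report is a plain JSON-serializable dict; per-split entries carry
    classification metrics, the voted mask size, match/miss rate against
    the plaque ground truth, intensity totals, and the test accuracies of
    the k individual selection runs (used by the significance analysis).
    A failed repeat (e.g. an empty voted mask) is recorded with an ``error``
    field and the remaining repeats continue.
    """
    ctx = context or build_context(cfg)
    matrix = ctx.matrix
    test_clf = ClassifierConfig(
        kind=cfg.test_classifier,
        svm_c=cfg.classifier.svm_c,
        rf_trees=cfg.classifier.rf_trees,
    )
    radius = cfg.effective_match_radius
    splits_out: list[dict] = []
    mti_ad_list, mti_ctl_list = [], []

    for repeat, (train_idx, val_idx, test_idx) in enumerate(ctx.splits):
        try:
            splits_out.append(
                _run_one_split(
                    cfg, ctx, test_clf, radius, repeat, train_idx, val_idx, test_idx
                )
            )
            if splits_out[-1].get("mti_ad") is not None:
                mti_ad_list.append(splits_out[-1]["mti_ad"])
                mti_ctl_list.append(splits_out[-1]["mti_ctl"])
        except Exception as exc:  # noqa: BLE001 - keep remaining repeats alive
            splits_out.append({"repeat": repeat, "error": f"{type(exc).__name__}: {exc}"})

    ok = [s for s in splits_out if "error" not in s]
    accs = [s["accuracy"] for s in ok]
    report = {
        "algorithm": cfg.algorithm,
        "test_classifier": cfg.test_classifier,
        "master_seed": cfg.master_seed,
        "n_samples": len(ctx.images),
        "template_length": matrix.template_length,
        "match_radius": radius,
        "splits": splits_out,
        "summary": {
            "n_splits_completed": len(ok),
            "accuracy_mean": _mean([s["accuracy"] for s in ok]),
            "accuracy_best": max(accs) if accs else None,
            "sensitivity_mean": _mean([s["sensitivity"] for s in ok]),
            "specificity_mean": _mean([s["specificity"] for s in ok]),
            "match_rate_mean": _mean([s["match_rate"] for s in ok]),
            "match_rate_median": _median([s["match_rate"] for s in ok]),
            "accuracy_median": _median(accs),
            "miss_rate_mean": _mean([s["miss_rate"] for s in ok]),
            "voted_pixels_mean": _mean([s["n_voted_pixels"] for s in ok]),
            "mti_ad_mean": _mean(mti_ad_list),
            "mti_ctl_mean": _mean(mti_ctl_list),
            "mti_p_value": (
                intensity_significance(mti_ad_list, mti_ctl_list)
                if len(mti_ad_list) >= 2
                else None
            ),
        },
    }
    return report, ctx


def _run_one_split(
    cfg: ExperimentConfig,
    ctx: ExperimentContext,
    test_clf: ClassifierConfig,
    radius: float,
    repeat: int,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    test_idx: np.ndarray,
) -> dict:
    matrix = ctx.matrix
    trainval = np.concatenate([train_idx, val_idx])
    selections = [
        _select_once(cfg, matrix, train_idx, val_idx, repeat, run)
        for run in range(cfg.voting.k)
    ]
    masks = [s.mask for s in selections]
    run_accuracies = []
    for run, sel in enumerate(selections):
        _, counts = classify_test(
            sel.mask, matrix, trainval, test_idx, test_clf,
            seed=_stage_seed(cfg.master_seed, repeat, _STAGE_TEST, run + 1),
        )
        run_accuracies.append(confusion_metrics(counts)[0])

    final_mask = vote(masks, cfg.voting)
    if not final_mask.any():
        raise ValueError("voting produced an empty final mask")

    predicted, counts = classify_test(
        final_mask, matrix, trainval, test_idx, test_clf,
        seed=_stage_seed(cfg.master_seed, repeat, _STAGE_TEST, 0),
    )
    accuracy, sensitivity, specificity = confusion_metrics(counts)

    test_images = [ctx.images[i] for i in test_idx]
    marked = mark_ad_images(
        final_mask,
        test_images,
        [ctx.vectors[i] for i in test_idx],
        [matrix.index_maps[i] for i in test_idx],
        predicted,
    )
    ad_keys = [im.key for im in test_images if im.label == LABEL_AD]
    match = match_rate(marked, ctx.plaques, radius, slice_keys=ad_keys)
    intensity = intensity_contrast(
        final_mask, matrix.matrix[:, test_idx], matrix.labels[test_idx]
    )
    return {
        "repeat": repeat,
        "n_train": len(train_idx),
        "n_validation": len(val_idx),
        "n_test": len(test_idx),
        "n_voted_pixels": int(final_mask.sum()),
        "run_mask_sizes": [int(m.sum()) for m in masks],
        "run_fitness": [float(s.fitness) for s in selections],
        "run_test_accuracies": run_accuracies,
        "accuracy": accuracy,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "confusion": {"tp": counts.tp, "tn": counts.tn, "fp": counts.fp, "fn": counts.fn},
        "n_plaques": match.total,
        "n_matched": match.matched,
        "match_rate": match.match_rate,
        "miss_rate": match.miss_rate,
        "ti_ad": intensity.ti_ad,
        "ti_ctl": intensity.ti_ctl,
        "mti_ad": intensity.mti_ad,
        "mti_ctl": intensity.mti_ctl,
        "final_mask_indices": np.flatnonzero(final_mask).astype(int).tolist(),
    }


def run_random_baseline(
    ctx: ExperimentContext,
    cardinalities_per_split: Sequence[Sequence[int]],
    seed_offset: int = 0,
) -> list[list[float]]:
    """Test accuracies of uniformly random masks of matched cardinality.

    For each split repeat, draws one random mask per requested cardinality
    (matching the per-run masks of the real experiment) and repeats only
    the classify/evaluate stages.  Returns per-split accuracy lists.
    """
    cfg = ctx.config
    test_clf = ClassifierConfig(
        kind=cfg.test_classifier,
        svm_c=cfg.classifier.svm_c,
        rf_trees=cfg.classifier.rf_trees,
    )
    out: list[list[float]] = []
    for repeat, (train_idx, val_idx, test_idx) in enumerate(ctx.splits):
        trainval = np.concatenate([train_idx, val_idx])
        accs = []
        for run, cardinality in enumerate(cardinalities_per_split[repeat]):
            if not 0 < cardinality <= ctx.matrix.template_length:
                raise ValueError(f"invalid baseline cardinality {cardinality}")
            rng = _stage_rng(
                cfg.master_seed, repeat, _STAGE_BASELINE, run + seed_offset
            )
            mask = np.zeros(ctx.matrix.template_length, dtype=bool)
            mask[rng.choice(ctx.matrix.template_length, cardinality, replace=False)] = True
            _, counts = classify_test(
                mask, ctx.matrix, trainval, test_idx, test_clf,
                seed=_stage_seed(cfg.master_seed, repeat, _STAGE_BASELINE, 1000 + run),
            )
            accs.append(confusion_metrics(counts)[0])
        out.append(accs)
    return out


def attach_significance(
    report: dict, ctx: ExperimentContext, alpha: float = 0.05
) -> dict:
    """Significance of the selection against uniformly random selection.

    Per split this adds two comparisons: (a) a t-test of the per-pixel mean
    gray values (over the AD test samples) of the voted mask against a
    random mask of the same cardinality — the check that the *selected
    pixels* differ from chance; and (b) a t-test of the k selection-run
    test accuracies against matched-cardinality random-mask accuracies.
    The correlation between the voted mask and the random mask is reported
    alongside.  When per-pixel class contrast is strong, (b) saturates
    (both groups classify perfectly) while (a) remains discriminating.
    """
    cardinalities = [
        s.get("run_mask_sizes", []) for s in report["splits"] if "error" not in s
    ]
    ok_splits = [s for s in report["splits"] if "error" not in s]
    baseline = run_random_baseline(ctx, cardinalities)
    for s, accs in zip(ok_splits, baseline):
        p, h = significance_vs_random(s["run_test_accuracies"], accs, alpha=alpha)
        s["baseline_accuracies"] = accs
        s["p_accuracy_vs_random"] = p
        s["h_accuracy_vs_random"] = h

        rng = _stage_rng(ctx.config.master_seed, s["repeat"], _STAGE_BASELINE, 999)
        rand_mask = np.zeros(ctx.matrix.template_length, dtype=bool)
        rand_mask[
            rng.choice(
                ctx.matrix.template_length, s["n_voted_pixels"], replace=False
            )
        ] = True
        final = np.zeros(ctx.matrix.template_length, dtype=bool)
        final[s["final_mask_indices"]] = True
        s["corr_vs_random"] = selection_correlation(final, rand_mask)

        _, _, test_idx = ctx.splits[s["repeat"]]
        ad_cols = ctx.matrix.matrix[:, test_idx][
            :, ctx.matrix.labels[test_idx] == LABEL_AD
        ]
        p_px, h_px = mapped_pixel_significance(final, rand_mask, ad_cols, alpha=alpha)
        s["p_pixels_vs_random"] = p_px
        s["h_pixels_vs_random"] = h_px
    report["summary"]["n_significant_splits_pixels"] = int(
        sum(s.get("h_pixels_vs_random", 0) for s in ok_splits)
    )
    report["summary"]["n_significant_splits_accuracy"] = int(
        sum(s.get("h_accuracy_vs_random", 0) for s in ok_splits)
    )
    return report


def run_full_study(cfg: ExperimentConfig) -> tuple[dict, ExperimentContext]:
    """Experiment plus baseline significance, as one reproducible call."""
    report, ctx = run_experiment(cfg)
    report = attach_significance(report, ctx)
    return report, ctx


def report_table(report: dict) -> pd.DataFrame:
    """Human-readable per-split table mirroring the evaluation layout."""
    rows = []
    for s in report["splits"]:
        if "error" in s:
            rows.append({"repeat": s["repeat"], "error": s["error"]})
            continue
        rows.append(
            {
                "repeat": s["repeat"],
                "voted_pixels": s["n_voted_pixels"],
                "accuracy": round(s["accuracy"], 4),
                "sensitivity": round(s["sensitivity"], 4),
                "specificity": round(s["specificity"], 4),
                "match_rate": round(s["match_rate"], 4),
                "miss_rate": round(s["miss_rate"], 4),
                "mti_ad": round(s["mti_ad"], 1),
                "mti_ctl": round(s["mti_ctl"], 1),
                "p_pixels_vs_random": s.get("p_pixels_vs_random"),
            }
        )
    return pd.DataFrame(rows)


def save_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True))
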