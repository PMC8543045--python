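"""Per-class and macro F1 metrics, and the three robustness experiment
variations.

Per class c: precision = M[c,c] / column-sum(c), recall = M[c,c] /
row-sum(c), F1 = 2 * precision * recall / (precision + recall); any zero
denominator yields 0 by convention.  The macro F1 is the arithmetic mean of
the three class F1s.  The experiment variations:

* ``same``        — train and test within each image dataset;
* ``clean_train`` — train on the clean dataset, test on every variant;
* ``noisy_train`` — train on the all-noise dataset, test on every variant.

Every cell is the mean +/- sd over the five predefined folds, with test
records always drawn from the fold's own test partition (fold-matched,
leakage-safe).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classify import FoldAssignment, TrainConfig, train
from .cohort import CLASSES

VARIATIONS = ("same", "clean_train", "noisy_train")


def confusion(true, pred, classes=CLASSES) -> np.ndarray:
    """3x3 confusion matrix; entry (i, j) counts true class i predicted as j."""
    true = list(true)
    pred = list(pred)
    if len(true) != len(pred):
        raise ValueError("true and pred must have equal length")
    index = {c: i for i, c in enumerate(classes)}
    m = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(true, pred):
        if t not in index or p not in index:
            raise ValueError(f"unknown label in ({t!r}, {p!r})")
        m[index[t], index[p]] += 1
    return m


def class_f1(m: np.ndarray, label: str, classes=CLASSES) -> float:
    """F1 of one class from the confusion matrix (0 on zero denominators)."""
    c = list(classes).index(label)
    col = m[:, c].sum()
    row = m[c, :].sum()
    precision = m[c, c] / col if col > 0 else 0.0
    recall = m[c, c] / row if row > 0 else 0.0
    if precision + recall == 0:
        return 0.0
    return float(2.0 * precision * recall / (precision + recall))


def macro_f1(m: np.ndarray, classes=CLASSES) -> float:
    """Arithmetic mean of the per-class F1 scores."""
    return float(np.mean([class_f1(m, c, classes) for c in classes]))


def metrics_row(true, pred, classes=CLASSES) -> dict:
    m = confusion(true, pred, classes)
    out = {"macro_f1": macro_f1(m, classes)}
    for c in classes:
        col, row = m[:, list(classes).index(c)].sum(), m[list(classes).index(c), :].sum()
        cc = m[list(classes).index(c), list(classes).index(c)]
        out[f"precision_{c}"] = cc / col if col > 0 else 0.0
        out[f"recall_{c}"] = cc / row if row > 0 else 0.0
        out[f"f1_{c}"] = class_f1(m, c, classes)
    return out


def _check_no_leakage(split: dict) -> None:
    tr = set(split["train"]) | set(split["val"])
    te = set(split["test"])
    if tr & te:
        raise AssertionError("train/validation and test partitions overlap")


def run_variation(
    variation: str,
    image_datasets: dict,
    labels: np.ndarray,
    folds: FoldAssignment,
    cfg: TrainConfig,
    keep_predictions: bool = False,
):
    """Run one experiment variation over the 12 image datasets.

    ``image_datasets`` maps (variant, kind) -> list of images ordered
    consistently with ``labels`` and the fold index arrays.  Returns a
    long-format DataFrame with one row per (kind, train variant, test
    variant, fold), plus the per-fold prediction store when requested.
    """
    if variation not in VARIATIONS:
        raise ValueError(f"unknown variation {variation!r}")
    variants = sorted({v for v, _ in image_datasets})
    kinds = sorted({k for _, k in image_datasets})
    labels = np.asarray(labels)

    if variation == "same":
        pairs = [(v, v) for v in variants]
    elif variation == "clean_train":
        if "clean" not in variants:
            raise ValueError("clean dataset variant missing")
        pairs = [("clean", v) for v in variants]
    else:
        if "all" not in variants:
            raise ValueError("all-noise dataset variant missing")
        pairs = [("all", v) for v in variants]

    rows, predictions = [], {}
    for kind in kinds:
        models = {}  # (train_variant, fold) -> fitted classifier, shared across test sets
        for train_variant, test_variant in pairs:
            if (train_variant, kind) not in image_datasets:
                raise ValueError(f"missing image dataset ({train_variant}, {kind})")
            if (test_variant, kind) not in image_datasets:
                raise ValueError(f"missing image dataset ({test_variant}, {kind})")
            for f in range(folds.n_folds):
                split = folds.splits[f]
                _check_no_leakage(split)
                key = (train_variant, f)
                if key not in models:
                    models[key] = train(image_datasets[(train_variant, kind)], labels, split, cfg)
                te = split["test"]
                pred = models[key].predict([image_datasets[(test_variant, kind)][i] for i in te])
                row = {
                    "variation": variation,
                    "kind": kind,
                    "train_dataset": train_variant,
                    "test_dataset": test_variant,
                    "fold": f,
                    "n_test": len(te),
                    **metrics_row(labels[te], pred),
                }
                rows.append(row)
                if keep_predictions:
                    predictions[(kind, train_variant, test_variant, f)] = (
                        np.asarray(te), np.asarray(pred)
                    )
    table = pd.DataFrame(rows)
    return (table, predictions) if keep_predictions else table


def aggregate(table: pd.DataFrame) -> pd.DataFrame:
    """Fold-aggregated table: mean and sd over folds for every metric cell."""
    keys = ["variation", "kind", "train_dataset", "test_dataset"]
    metric_cols = [c for c in table.columns if c.startswith(("macro_f1", "f1_", "precision_", "recall_"))]
    agg = table.groupby(keys)[metric_cols].agg(["mean", "std"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    return agg.reset_index()


def render_report(agg: pd.DataFrame) -> str:
    """Markdown summary shaped like the study's result tables."""
    lines = ["# Robustness results", ""]
    for variation, sub in agg.groupby("variation"):
        lines.append(f"## Variation: {variation}")
        lines.append("")
        lines.append("| transform | train | test | macro F1 (mean ± sd) |")
        lines.append("|---|---|---|---|")
        for _, r in sub.iterrows():
            sd = r["macro_f1_std"]
            sd_txt = "n/a" if pd.isna(sd) else f"{sd:.3f}"
            lines.append(
                f"| {r['kind']} | {r['train_dataset']} | {r['test_dataset']} "
                f"| {r['macro_f1_mean']:.3f} ± {sd_txt} |"
            )
        lines.append("")
    return "\n".join(lines)
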