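"""Experiment orchestration: ecotype/variety classification and castrate
one-vs-rest detection over element x variable-subset cells.

Each cell runs the same machinery: complete-case matrix -> Mosimann
size/shape features -> stratified 80/20 train/test split -> tenfold
cross-validated (lambda, gamma) tuning on the training data -> final fit ->
train and test metrics.  All randomness flows from one top-level seed via
named substreams, so a fixed configuration reproduces its report exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .filters import SUBSET_IDS, select_matrix
from .io import SpecimenRecord
from .mosimann import size_shape_features
from .rda import DEFAULT_GRID, fit_rda, predict_rda, stratified_split, tune_rda
from .registry import LONG_BONES, Element, Registry, default_registry

__all__ = [
    "confusion_matrix",
    "classification_metrics",
    "ExperimentConfig",
    "EvalReport",
    "run_ecotype_experiment",
    "run_castrate_detection",
]

logger = logging.getLogger(__name__)


def confusion_matrix(y_true: Sequence, y_pred: Sequence, labels: Sequence) -> np.ndarray:
    """K x K count matrix; rows = true class, columns = predicted class."""
    index = {c: i for i, c in enumerate(labels)}
    cm = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[index[t], index[p]] += 1
    return cm


def classification_metrics(cm: np.ndarray) -> tuple[float, float, float]:
    """(accuracy, balanced accuracy, macro F1), all in percent.

    Balanced accuracy averages per-class recall over classes with nonzero
    support.  Macro F1 is the unweighted mean of per-class F1, taking a
    class's F1 as 0 when its precision + recall is 0; classes with zero
    support and zero predictions are excluded from the mean.
    """
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1] or cm.sum() < 1:
        raise ValueError("confusion matrix must be square with >= 1 observation")
    if (cm < 0).any():
        raise ValueError("confusion matrix must be nonnegative")
    total = cm.sum()
    accuracy = np.trace(cm) / total

    support = cm.sum(axis=1)
    predicted = cm.sum(axis=0)
    recalls = [cm[k, k] / support[k] for k in range(len(cm)) if support[k] > 0]
    balanced = float(np.mean(recalls))

    f1s = []
    for k in range(len(cm)):
        if support[k] == 0 and predicted[k] == 0:
            continue
        prec = cm[k, k] / predicted[k] if predicted[k] > 0 else 0.0
        rec = cm[k, k] / support[k] if support[k] > 0 else 0.0
        f1s.append(0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec))
    macro_f1 = float(np.mean(f1s))
    return 100.0 * accuracy, 100.0 * balanced, 100.0 * macro_f1


@dataclass
class ExperimentConfig:
    """Classifier and protocol configuration shared by both experiments."""

    test_fraction: float = 0.2
    cv_folds: int = 10
    grid: tuple[tuple[float, float], ...] = DEFAULT_GRID
    priors: str = "empirical"
    seed: int = 0
    target: str = "ecovar3"  # "ecovar3" | "ecotype2" (tarandus vs fennicus)
    exclude_group_keys: tuple[str, ...] = ("wild_male",)
    exclude_elements: tuple[Element, ...] = (Element.PELVIS,)
    drop_policy: str = "last"
    min_class_n: int = 5
    subset_overrides: dict | None = None


@dataclass
class EvalReport:
    """Per element x subset x partition classification metrics."""

    frame: pd.DataFrame
    confusions: dict[tuple[str, str, str], np.ndarray]
    classes: dict[tuple[str, str], list]
    f1_averaging: str = "macro"
    skipped: list[tuple[str, str, str]] = field(default_factory=list)

    def row(self, element: str, subset: str, partition: str) -> pd.Series:
        m = self.frame
        sel = m[(m.element == element) & (m.subset_id == subset) & (m.partition == partition)]
        return sel.iloc[0]


_REPORT_COLUMNS = [
    "element", "subset_id", "partition", "accuracy", "balanced_accuracy",
    "macro_f1", "f1_positive", "n", "lambda", "gamma", "seed",
]


def _substream(seed: int, *indices: int) -> int:
    ss = np.random.SeedSequence([int(seed)] + [int(i) for i in indices])
    return int(ss.generate_state(1)[0] % (2**31))


def _target_labels(groups, target: str) -> np.ndarray:
    if target == "ecovar3":
        return np.array([g.ecovar for g in groups])
    if target == "ecotype2":
        return np.array([g.ecotype for g in groups])
    if target == "castrate_vs_rest":
        return np.array(["castrate" if g.castrated else "rest" for g in groups])
    raise ValueError(f"unknown target {target!r}")


def _run_cells(
    records: Sequence[SpecimenRecord],
    elements: Sequence[Element],
    subsets: Sequence[str],
    config: ExperimentConfig,
    registry: Registry,
    target: str,
    positive_class: str | None = None,
) -> EvalReport:
    rows: list[dict] = []
    confusions: dict[tuple[str, str, str], np.ndarray] = {}
    classes_by_cell: dict[tuple[str, str], list] = {}
    skipped: list[tuple[str, str, str]] = []

    usable = [
        r
        for r in records
        if r.group.key not in config.exclude_group_keys
        and r.element not in config.exclude_elements
    ]
    for ei, element in enumerate(elements):
        if element in config.exclude_elements:
            continue
        for si, subset in enumerate(subsets):
            cell = (element.value, subset)
            try:
                matrix, _ = select_matrix(
                    usable, element, subset, registry, config.subset_overrides
                )
            except ValueError as exc:
                skipped.append((*cell, f"matrix: {exc}"))
                logger.warning("skipping %s/%s: %s", element.value, subset, exc)
                continue
            _, feats = size_shape_features(matrix, drop_policy=config.drop_policy)
            y = _target_labels(feats.groups, target)
            labels, counts = np.unique(y, return_counts=True)
            if len(labels) < 2 or counts.min() < config.min_class_n:
                skipped.append((*cell, f"class support too small: {dict(zip(labels, counts))}"))
                logger.warning("skipping %s/%s: class support %s", *cell, counts)
                continue
            strata = [f"{g.ecovar}|{g.sex}" for g in feats.groups]
            split_seed = _substream(config.seed, ei, si, 0)
            tune_seed = _substream(config.seed, ei, si, 1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                plan = stratified_split(
                    strata, test_fraction=config.test_fraction, seed=split_seed
                )
                tr, te = plan.train_ids, plan.test_ids
                y_tr, y_te = y[tr], y[te]
                if len(np.unique(y_tr)) < 2 or len(np.unique(y_te)) < 1 or len(te) == 0:
                    skipped.append((*cell, "degenerate split"))
                    continue
                (lam, gam), _cv = tune_rda(
                    feats.X[tr], y_tr, grid=config.grid, k=config.cv_folds,
                    seed=tune_seed, priors=config.priors,
                )
                model = fit_rda(
                    feats.X[tr], y_tr, lam, gam, priors=config.priors,
                    feature_names=feats.feature_names,
                )
            cell_classes = list(model.classes)
            classes_by_cell[cell] = cell_classes
            for partition, idx, y_part in (("train", tr, y_tr), ("test", te, y_te)):
                pred, _, _ = predict_rda(model, feats.X[idx])
                cm = confusion_matrix(y_part, pred, labels=cell_classes)
                acc, ba, f1 = classification_metrics(cm)
                f1_pos = np.nan
                if positive_class is not None and positive_class in cell_classes:
                    k = cell_classes.index(positive_class)
                    prec = cm[k, k] / cm[:, k].sum() if cm[:, k].sum() > 0 else 0.0
                    rec = cm[k, k] / cm[k, :].sum() if cm[k, :].sum() > 0 else 0.0
                    f1_pos = 0.0 if prec + rec == 0 else 100.0 * 2 * prec * rec / (prec + rec)
                confusions[(*cell, partition)] = cm
                rows.append(
                    {
                        "element": element.value,
                        "subset_id": subset,
                        "partition": partition,
                        "accuracy": acc,
                        "balanced_accuracy": ba,
                        "macro_f1": f1,
                        "f1_positive": f1_pos,
                        "n": len(idx),
                        "lambda": lam,
                        "gamma": gam,
                        "seed": config.seed,
                    }
                )
    frame = pd.DataFrame(rows, columns=_REPORT_COLUMNS)
    return EvalReport(frame=frame, confusions=confusions, classes=classes_by_cell, skipped=skipped)


def run_ecotype_experiment(
    records: Sequence[SpecimenRecord],
    elements: Sequence[Element] = LONG_BONES,
    subsets: Sequence[str] = ("all",),
    config: ExperimentConfig | None = None,
    registry: Registry | None = None,
) -> EvalReport:
    """Classify ecotype/variety (domestic / wild tarandus / fennicus).

    By default the pelvis and the tiny wild-male group are excluded; with
    ``config.target = "ecotype2"`` the task collapses to tarandus vs
    fennicus.
    """
    config = config or ExperimentConfig()
    registry = registry or default_registry()
    for s in subsets:
        if s not in SUBSET_IDS:
            raise ValueError(f"unknown subset {s!r}")
    target = "ecovar3" if config.target == "ecovar3" else "ecotype2"
    return _run_cells(records, elements, subsets, config, registry, target)


def run_castrate_detection(
    records: Sequence[SpecimenRecord],
    elements: Sequence[Element] = LONG_BONES,
    subsets: Sequence[str] = ("all",),
    config: ExperimentConfig | None = None,
    registry: Registry | None = None,
) -> EvalReport:
    """One-vs-rest detection of castrates against all other groups.

    All non-castrate groups map to "rest"; the same split/tune/fit/evaluate
    machinery applies, and the report carries the F1 of the castrate class
    in ``f1_positive``.
    """
    config = config or ExperimentConfig()
    registry = registry or default_registry()
    n_castrate = len(
        {
            r.individual_id
            for r in records
            if r.group.castrated
            and r.group.key not in config.exclude_group_keys
            and r.element not in config.exclude_elements
        }
    )
    if n_castrate < 5:
        raise ValueError(
            f"castrate detection requires >= 5 castrated individuals, found {n_castrate}"
        )
    return _run_cells(
        records, elements, subsets, config, registry,
        target="castrate_vs_rest", positive_class="castrate",
    )
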