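"""Cross-validated evaluation of the full selection pipeline.

Stratified k-fold (default fivefold) cross-validation; within each fold
the entire pipeline — normalization, Fisher filtering of the genotype
block, joint multi-task selection, and a linear SVM — is fitted on the
training split only and then frozen before touching the test split.
Reported metrics are accuracy, sensitivity and specificity in percent;
for binary tasks the positive class is the *later* disease stage (the
last entry of the dataset's class order).  The report also counts, per
feature, in how many folds it was selected — the "most selected"
biomarker analysis.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import fisher as fisher_mod
from . import preprocess, selector
from .data import MultiModalDataset
from .errors import ConfigurationError
from .selector import SelectorConfig


@dataclass
class EvalConfig:
    """Knobs of the per-fold pipeline around the selector itself."""

    schemes: dict[str, str] = field(default_factory=lambda: dict(preprocess.DEFAULT_SCHEMES))
    norm_eps: float = preprocess.DEFAULT_EPS
    fisher_blocks: tuple[str, ...] = ("snp",)
    top_m: int | None = None          # None -> width of the imaging block
    fisher_eps: float = preprocess.DEFAULT_EPS
    # sum-to-one weights shrink the k selected columns by ~1/k, so a fixed
    # C=1 margin penalty would over-regularize; 10 sits on the plateau that
    # restores unit-scale behaviour for k ~ 5.
    selector: SelectorConfig = field(default_factory=SelectorConfig)
    svm_C: float = 10.0


@dataclass
class FoldResult:
    accuracy: float
    sensitivity: float
    specificity: float
    selected_features: list[str]
    fitted_state: dict = field(default_factory=dict)   # frozen training-side artifacts


@dataclass
class CVReport:
    folds: list[FoldResult]
    mean_accuracy: float
    mean_sensitivity: float
    mean_specificity: float
    selection_frequency: dict[str, int]
    n_folds: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "n_folds": self.n_folds,
            "seed": self.seed,
            "folds": [
                {
                    "accuracy": f.accuracy,
                    "sensitivity": f.sensitivity,
                    "specificity": f.specificity,
                    "selected_features": f.selected_features,
                }
                for f in self.folds
            ],
            "mean": {
                "accuracy": self.mean_accuracy,
                "sensitivity": self.mean_sensitivity,
                "specificity": self.mean_specificity,
            },
            "selection_frequency": self.selection_frequency,
        }


def make_folds(y: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Stratified fold assignment (array of fold index per sample).

    Per-class counts across folds differ by at most one; ``n_folds`` equal
    to the sample count yields the leave-one-out partition.
    """
    y = np.asarray(y, dtype=str)
    if n_folds < 2:
        raise ConfigurationError("need at least 2 folds")
    if n_folds == len(y):
        return np.arange(len(y))
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        raise ConfigurationError(
            f"smallest class has {counts.min()} samples, fewer than {n_folds} folds; "
            "reduce the fold count"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros((len(y), 1)), y)):
        assignment[test_idx] = fold
    return assignment


def _binary_metrics(y_true: np.ndarray, y_pred: np.ndarray, positive: str) -> tuple[float, float, float]:
    tp = int(np.sum((y_true == positive) & (y_pred == positive)))
    tn = int(np.sum((y_true != positive) & (y_pred != positive)))
    fp = int(np.sum((y_true != positive) & (y_pred == positive)))
    fn = int(np.sum((y_true == positive) & (y_pred != positive)))
    acc = 100.0 * (tp + tn) / max(tp + tn + fp + fn, 1)
    sens = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    spec = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    return acc, sens, spec


def train_eval_fold(
    ds: MultiModalDataset,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    config: EvalConfig,
) -> FoldResult:
    """Fit the whole pipeline on the training split, evaluate on the test split."""
    train = ds.subset_samples(train_idx)
    test = ds.subset_samples(test_idx)
    missing = set(np.unique(test.y)) - set(np.unique(train.y))
    if missing:
        raise ConfigurationError(f"test classes {missing} absent from training split")

    # 1. normalization: fit on train only
    norm_params = preprocess.fit_normalization(train, config.schemes, config.norm_eps)
    train_n = preprocess.apply_normalization(train, norm_params)
    test_n = preprocess.apply_normalization(test, norm_params)

    # 2. Fisher filter on flagged blocks (train labels only)
    top_m = config.top_m
    if top_m is None:
        widths = {n: stop - start for n, (start, stop) in ds.modality_blocks}
        top_m = widths.get("imaging", min(widths.values()))
    keep_global: list[int] = []
    fisher_reports = {}
    for name, (start, stop) in ds.modality_blocks:
        if name in config.fisher_blocks:
            rep = fisher_mod.fisher_scores(train_n.block(name), train_n.y, config.fisher_eps)
            retained, _ = fisher_mod.select_top_m(rep, min(top_m, stop - start))
            fisher_reports[name] = rep
            keep_global.extend((retained + start).tolist())
        else:
            keep_global.extend(range(start, stop))
    keep_global = sorted(keep_global)
    train_f = train_n.subset_features(keep_global)
    test_f = test_n.subset_features(keep_global)

    # 3. joint multi-task selection on the training split
    Y = selector.one_hot(train_f.y, train_f.class_order)
    weights, trace, converged = selector.fit(
        train_f.X.T, Y, train_f.modality_blocks, config.selector
    )
    sel, train_feats = selector.select_and_weight(
        weights, train_f.X, config.selector.k_per_modality, config.selector.weight_norm
    )
    sel.converged = converged
    sel.objective_trace = trace
    all_idx = np.concatenate([sel.selected[n] for n in train_f.block_names])
    all_w = np.concatenate([sel.normalized_weights[n] for n in train_f.block_names])
    test_feats = test_f.X[:, all_idx] * all_w
    selected_names = [train_f.feature_names[i] for i in all_idx]

    # 4. linear max-margin classifier
    clf = SVC(kernel="linear", C=config.svm_C)
    clf.fit(train_feats, train_f.y)
    y_pred = clf.predict(test_feats)

    positive = ds.class_order[-1]
    if ds.c == 2:
        acc, sens, spec = _binary_metrics(test_f.y, y_pred, positive)
    else:
        acc = 100.0 * float(np.mean(y_pred == test_f.y))
        sens = spec = float("nan")
    return FoldResult(
        accuracy=acc, sensitivity=sens, specificity=spec,
        selected_features=selected_names,
        fitted_state={
            "norm_params": norm_params,
            "fisher_retained": {n: r.retained for n, r in fisher_reports.items()},
            "W": weights.W,
            "svm_coef": clf.coef_.copy(),
        },
    )


def cross_validate(
    ds: MultiModalDataset, config: EvalConfig, n_folds: int = 5, seed: int = 0
) -> CVReport:
    """Run the pipeline over stratified folds and aggregate."""
    assignment = make_folds(ds.y, n_folds, seed)
    folds: list[FoldResult] = []
    freq: Counter[str] = Counter()
    for fold in range(n_folds):
        test_idx = np.where(assignment == fold)[0]
        train_idx = np.where(assignment != fold)[0]
        try:
            result = train_eval_fold(ds, train_idx, test_idx, config)
        except Exception as exc:
            raise type(exc)(f"fold {fold}: {exc}") from exc
        folds.append(result)
        freq.update(set(result.selected_features))
    return CVReport(
        folds=folds,
        mean_accuracy=float(np.mean([f.accuracy for f in folds])),
        mean_sensitivity=float(np.mean([f.sensitivity for f in folds])),
        mean_specificity=float(np.mean([f.specificity for f in folds])),
        selection_frequency=dict(freq),
        n_folds=n_folds,
        seed=seed,
    )
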