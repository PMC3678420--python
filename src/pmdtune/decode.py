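"""Multiclass SVM decoding of action labels from binned firing rates.

Feature vectors are the flattened (neuron-major) firing rates of a
neuron subset over a configurable slice of 100-ms bins; the default
slice keeps the last ``n_bins - 4`` bins, which reproduces the feature
dimensionality used throughout the analysis (18 bins for a 2.2-s
window, 14 for a 1.8-s window) while the exact epoch remains a
documented configuration point.

The classifier is a one-vs-one RBF-kernel SVM.  (C, gamma) are chosen
by stratified 2-fold cross-validated accuracy over a log2 grid; the
reported accuracy is, by default, the same 2-fold CV accuracy at the
best grid point ("cv" scheme).  A "holdout" scheme (grid search on one
half, score on the other) is also provided.  Features are standardized
per dimension with statistics fit on the training fold only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .infotheory import MIProfile
from .preprocess import BinnedRates
from .simulate import Category

__all__ = [
    "DEFAULT_C_GRID",
    "DEFAULT_GAMMA_GRID",
    "DecodingResult",
    "default_feature_bins",
    "build_features",
    "fit_and_score",
    "experiment_ensembles",
    "experiment_addition",
]

# log2 C in {-5..15 step 2}, log2 gamma in {-15..3 step 2}
DEFAULT_C_GRID: np.ndarray = 2.0 ** np.arange(-5, 16, 2)
DEFAULT_GAMMA_GRID: np.ndarray = 2.0 ** np.arange(-15, 4, 2)

N_ACTIONS = 4


@dataclass
class DecodingResult:
    subset_name: str
    neuron_ids: list[str]
    accuracy: float
    C: float
    gamma: float
    confusion: np.ndarray  # (4, 4), rows = true class
    fold_assignments: np.ndarray  # (trials,), fold index per trial
    seed: int
    eval_scheme: str = "cv"

    @property
    def n_neurons(self) -> int:
        return len(self.neuron_ids)


def default_feature_bins(n_bins: int) -> slice:
    """Default decoding feature slice: the last ``n_bins - 4`` bins
    (minimum 1)."""
    m = max(n_bins - 4, 1)
    return slice(n_bins - m, n_bins)


def build_features(
    binned: BinnedRates,
    subset: Optional[Sequence[str]] = None,
    feature_bins: Optional[slice] = None,
) -> np.ndarray:
    """Per-trial feature matrix: subset neurons' rates over the feature
    bins, flattened neuron-major.  Shape (trials, len(subset) * m)."""
    if subset is None:
        subset = binned.neuron_ids
    if len(subset) == 0:
        raise ValueError("neuron subset must be nonempty")
    unknown = [nid for nid in subset if nid not in binned.neuron_ids]
    if unknown:
        raise ValueError(f"unknown neuron ids: {unknown}")
    if feature_bins is None:
        feature_bins = default_feature_bins(binned.n_bins)
    cols = [binned.neuron_ids.index(nid) for nid in subset]
    block = binned.values[:, cols, feature_bins]  # (trials, subset, m)
    return block.reshape(block.shape[0], -1)


def _cv_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    C: float,
    gamma: float,
    folds: list[tuple[np.ndarray, np.ndarray]],
) -> tuple[float, np.ndarray]:
    """Mean out-of-fold accuracy and pooled out-of-fold predictions."""
    predictions = np.empty_like(y)
    accs = []
    for train, test in folds:
        model = make_pipeline(
            StandardScaler(),
            SVC(kernel="rbf", C=C, gamma=gamma, decision_function_shape="ovo"),
        )
        model.fit(X[train], y[train])
        pred = model.predict(X[test])
        predictions[test] = pred
        accs.append(float(np.mean(pred == y[test])))
    return float(np.mean(accs)), predictions


def fit_and_score(
    X: np.ndarray,
    y: np.ndarray,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    cv_folds: int = 2,
    seed: int = 0,
    eval_scheme: str = "cv",
    subset_name: str = "subset",
    neuron_ids: Optional[Sequence[str]] = None,
) -> DecodingResult:
    """Grid-search (C, gamma) by stratified k-fold CV accuracy.

    ``eval_scheme="cv"`` reports the best grid point's CV accuracy and an
    out-of-fold confusion matrix.  ``"holdout"`` performs the grid search
    (with its own internal CV) on the first half and reports accuracy on
    the held-out second half.  Ties in the grid resolve to the first
    point in (C, gamma) iteration order.  Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(C_grid) == 0 or len(gamma_grid) == 0:
        raise ValueError("hyperparameter grid must be nonempty")
    classes, class_counts = np.unique(y, return_counts=True)
    if (class_counts < cv_folds).any():
        raise ValueError("every class needs at least cv_folds trials")

    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = [(tr.copy(), te.copy()) for tr, te in skf.split(X, y)]
    fold_assignments = np.empty(len(y), dtype=int)
    for f, (_, test) in enumerate(folds):
        fold_assignments[test] = f

    def grid_search(
        Xs: np.ndarray, ys: np.ndarray, inner_folds
    ) -> tuple[float, float, float, np.ndarray]:
        best = None
        for C in C_grid:
            for gamma in gamma_grid:
                acc, preds = _cv_accuracy(Xs, ys, C, gamma, inner_folds)
                if best is None or acc > best[0]:
                    best = (acc, float(C), float(gamma), preds)
        return best

    if eval_scheme == "cv":
        acc, C, gamma, preds = grid_search(X, y, folds)
        conf = confusion_matrix(y, preds, labels=classes)
    elif eval_scheme == "holdout":
        fit_idx, test_idx = folds[0]
        inner = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed + 1)
        inner_folds = [
            (fit_idx[tr], fit_idx[te]) for tr, te in inner.split(X[fit_idx], y[fit_idx])
        ]
        _, C, gamma, _ = grid_search(X, y, inner_folds)
        model = make_pipeline(
            StandardScaler(),
            SVC(kernel="rbf", C=C, gamma=gamma, decision_function_shape="ovo"),
        )
        model.fit(X[fit_idx], y[fit_idx])
        pred = model.predict(X[test_idx])
        acc = float(np.mean(pred == y[test_idx]))
        conf = confusion_matrix(y[test_idx], pred, labels=classes)
    else:
        raise ValueError(f"unknown eval scheme {eval_scheme!r}")

    return DecodingResult(
        subset_name=subset_name,
        neuron_ids=list(neuron_ids) if neuron_ids is not None else [],
        accuracy=acc,
        C=C,
        gamma=gamma,
        confusion=conf,
        fold_assignments=fold_assignments,
        seed=seed,
        eval_scheme=eval_scheme,
    )


def _decode_subset(
    binned: BinnedRates,
    subset: Sequence[str],
    name: str,
    seed: int,
    feature_bins: Optional[slice] = None,
    **kwargs,
) -> DecodingResult:
    X = build_features(binned, subset, feature_bins=feature_bins)
    return fit_and_score(
        X, binned.labels, seed=seed, subset_name=name, neuron_ids=subset, **kwargs
    )


def experiment_ensembles(
    binned: BinnedRates,
    profile: MIProfile,
    seed: int = 0,
    top_k: int = 10,
    feature_bins: Optional[slice] = None,
    **kwargs,
) -> dict[str, Optional[DecodingResult]]:
    """Decode with (i) the full ensemble, (ii) the tuned subset for the
    block's task, and (iii) the top-k neurons by that task's MI (all
    neurons when the ensemble is smaller than k)."""
    task = binned.task.value
    full = list(binned.neuron_ids)
    tuned = profile.tuned_subset(task)
    top = profile.top_by_mi(task, min(top_k, len(full)))

    results: dict[str, Optional[DecodingResult]] = {
        "full_ensemble": _decode_subset(
            binned, full, "full_ensemble", seed, feature_bins, **kwargs
        ),
        "top_k": _decode_subset(binned, top, f"top_{top_k}", seed, feature_bins, **kwargs),
    }
    if tuned:
        results["tuned_subset"] = _decode_subset(
            binned, tuned, "tuned_subset", seed, feature_bins, **kwargs
        )
    else:
        results["tuned_subset"] = None  # empty tuned subset: decoding skipped
    return results


def experiment_addition(
    binned_reach: BinnedRates,
    binned_grasp: BinnedRates,
    profile: MIProfile,
    seed: int = 0,
    feature_bins: Optional[slice] = None,
    **kwargs,
) -> dict[str, dict]:
    """Compare single-property subsets with and without the BOTH neurons.

    Reach block: subset a (reach-only) vs a + c (reach-only plus BOTH);
    grasp block: subset b (grasp-only) vs b + c.  Reports the relative
    accuracy improvement (acc2 - acc1) / acc1 * 100 for each task; a task
    whose single-property subset is empty is reported as skipped.
    """
    subset_a = profile.neurons_in(Category.REACH_ONLY)
    subset_b = profile.neurons_in(Category.GRASP_ONLY)
    subset_c = profile.neurons_in(Category.BOTH)

    out: dict[str, dict] = {}
    for task, binned, single, name in (
        ("reach", binned_reach, subset_a, "a"),
        ("grasp", binned_grasp, subset_b, "b"),
    ):
        if not single:
            out[task] = {"skipped": True, "reason": f"subset {name} empty"}
            continue
        combined = single + [nid for nid in subset_c if nid not in single]
        res_single = _decode_subset(
            binned, single, f"subset_{name}", seed, feature_bins, **kwargs
        )
        res_combined = _decode_subset(
            binned, combined, f"subset_{name}+c", seed, feature_bins, **kwargs
        )
        improvement = (
            (res_combined.accuracy - res_single.accuracy) / res_single.accuracy * 100.0
            if res_single.accuracy > 0
            else np.nan
        )
        out[task] = {
            "skipped": False,
            "single": res_single,
            "combined": res_combined,
            "improvement_pct": improvement,
        }
    return out
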