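"""ANOVA-based task-relatedness and tuning tests.

Two screens per neuron, both one-way ANOVAs at alpha = 0.05 and neither
corrected for multiple comparisons:

* task-related: per-trial mean firing rate in the rest bins vs in the
  movement bins (two groups);
* tuned: for each movement bin, firing rate across the four actions; a
  neuron is tuned when at least ``min_bins`` (default 2) movement bins
  reject.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .preprocess import BinnedRates

__all__ = ["task_related_test", "tuning_test", "anova_report"]

N_ACTIONS = 4


def _safe_anova(*groups: np.ndarray) -> float:
    """One-way ANOVA p-value; degenerate inputs (zero variance
    everywhere) yield p = 1 rather than an error."""
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = sps.f_oneway(*groups)
    return 1.0 if np.isnan(p) else float(p)


def task_related_test(
    binned: BinnedRates,
    alpha: float = 0.05,
    observations: str = "trial_mean",
) -> pd.DataFrame:
    """Test each neuron for movement-state vs rest-state rate changes.

    With ``observations="trial_mean"`` (default) each trial contributes
    one observation per state, its mean rate over the state's bins; with
    ``"per_bin"`` every (trial, bin) rate is an observation.

    Returns a frame indexed like ``binned.neuron_ids`` with columns
    ``p_task_related`` and ``is_task_related``.
    """
    rest, move = binned.rest_bins, binned.move_bins
    if rest.size == 0 or move.size == 0:
        raise ValueError("need at least one REST and one MOVE bin")
    if binned.values.shape[0] < 2:
        raise ValueError("need at least 2 trials")
    if observations not in ("trial_mean", "per_bin"):
        raise ValueError(f"unknown observations mode {observations!r}")

    rows = []
    for j, nid in enumerate(binned.neuron_ids):
        if observations == "trial_mean":
            g_rest = binned.values[:, j, rest].mean(axis=1)
            g_move = binned.values[:, j, move].mean(axis=1)
        else:
            g_rest = binned.values[:, j, rest].ravel()
            g_move = binned.values[:, j, move].ravel()
        p = _safe_anova(g_rest, g_move)
        rows.append({"neuron_id": nid, "p_task_related": p, "is_task_related": p < alpha})
    return pd.DataFrame(rows).set_index("neuron_id")


def tuning_test(
    binned: BinnedRates,
    alpha: float = 0.05,
    min_bins: int = 2,
) -> pd.DataFrame:
    """Count movement bins whose across-action ANOVA rejects.

    Returns a frame with columns ``tuned_bins`` (number of movement bins
    with p < alpha across the 4 action groups) and ``is_tuned_anova``
    (tuned_bins >= min_bins).
    """
    labels = binned.labels
    groups_idx = [np.flatnonzero(labels == a) for a in range(1, N_ACTIONS + 1)]
    sizes = {len(g) for g in groups_idx}
    if 0 in sizes:
        raise ValueError("every action must appear in the trial labels")
    if len(sizes) != 1:
        raise ValueError("action groups must be balanced")
    if min(sizes) < 2:
        raise ValueError("need at least 2 trials per action")

    move = binned.move_bins
    rows = []
    for j, nid in enumerate(binned.neuron_ids):
        tuned_bins = 0
        for b in move:
            p = _safe_anova(*(binned.values[g, j, b] for g in groups_idx))
            if p < alpha:
                tuned_bins += 1
        rows.append(
            {"neuron_id": nid, "tuned_bins": tuned_bins, "is_tuned_anova": tuned_bins >= min_bins}
        )
    return pd.DataFrame(rows).set_index("neuron_id")


def anova_report(binned: BinnedRates, alpha: float = 0.05, min_bins: int = 2) -> pd.DataFrame:
    """Combined per-neuron report of both ANOVA screens."""
    report = task_related_test(binned, alpha=alpha).join(
        tuning_test(binned, alpha=alpha, min_bins=min_bins)
    )
    report["alpha"] = alpha
    return report
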