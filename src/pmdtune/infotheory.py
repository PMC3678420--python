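"""Plug-in mutual information between spike indicators and action labels,
cumulative-MI thresholding, neuron categorization, and information
contribution shares.

The estimator is the raw plug-in: empirical frequencies are substituted
into I(spk; y) = sum_y p(y) sum_spk p(spk|y) log2(p(spk|y) / p(spk)),
with 0 * log 0 := 0 and no small-sample bias correction.  Under the
balanced trial design p(y) is fixed at 1/4; an empirical override is
available for unbalanced data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .preprocess import IndicatorSamples
from .simulate import Category

__all__ = [
    "mi_from_counts",
    "spike_action_mi",
    "mi_threshold",
    "categorize_neurons",
    "MIProfile",
    "mi_profile",
    "contribution_table",
    "average_contributions",
]

N_ACTIONS = 4


def mi_from_counts(
    spike_counts: Sequence[int],
    sample_counts: Sequence[int],
    p_y: Optional[Sequence[float]] = None,
) -> float:
    """Plug-in MI (bits) from a 2 x 4 contingency table in count form.

    ``spike_counts[a]`` is the number of indicator-1 samples and
    ``sample_counts[a]`` the total samples for action ``a``.  ``p_y``
    defaults to the uniform 1/4 prior; pass the empirical marginal for
    unbalanced designs.
    """
    k = np.asarray(spike_counts, dtype=float)
    n = np.asarray(sample_counts, dtype=float)
    if k.shape != (N_ACTIONS,) or n.shape != (N_ACTIONS,):
        raise ValueError(f"expected {N_ACTIONS} actions, got shapes {k.shape}, {n.shape}")
    if (n <= 0).any():
        raise ValueError("every action needs at least one sample")
    if (k < 0).any() or (k > n).any():
        raise ValueError("spike counts must lie in [0, sample count]")

    py = np.full(N_ACTIONS, 1 / N_ACTIONS) if p_y is None else np.asarray(p_y, dtype=float)
    # conditional P(spk | y), rows = spk in {0, 1}
    p_spk_y = np.vstack([1 - k / n, k / n])
    p_spk = p_spk_y @ py

    with np.errstate(divide="ignore", invalid="ignore"):
        log_ratio = np.log2(p_spk_y / p_spk[:, None])
        terms = np.where(p_spk_y == 0, 0.0, py[None, :] * p_spk_y * log_ratio)
    return max(float(np.nansum(terms)), 0.0)


def spike_action_mi(
    samples: IndicatorSamples,
    neuron: int | str,
    p_y: Literal["uniform", "empirical"] = "uniform",
) -> float:
    """MI (bits) between one neuron's pooled spike indicators and the
    action label.

    All 10-ms steps of all trials in the samples' scope are pooled into
    one (spk, y) sample set.  With ``p_y="uniform"`` (the balanced
    design) unequal per-action sample counts raise; ``"empirical"``
    estimates p(y) from the label counts instead.
    """
    spk, y = samples.pooled(neuron)
    if spk.size == 0:
        raise ValueError("empty sample set")
    sample_counts = np.array([(y == a).sum() for a in range(1, N_ACTIONS + 1)])
    if (sample_counts == 0).any():
        missing = [a for a, c in enumerate(sample_counts, start=1) if c == 0]
        raise ValueError(f"labels missing from samples: {missing}")
    spike_counts = np.array([spk[y == a].sum() for a in range(1, N_ACTIONS + 1)])
    if p_y == "uniform":
        if len(set(sample_counts.tolist())) != 1:
            raise ValueError(
                "unbalanced labels under the uniform p(y) assumption; "
                "use p_y='empirical' for unbalanced data"
            )
        prior = None
    elif p_y == "empirical":
        prior = sample_counts / sample_counts.sum()
    else:
        raise ValueError(f"unknown p_y mode {p_y!r}")
    return mi_from_counts(spike_counts, sample_counts, p_y=prior)


def mi_threshold(mi_values: Iterable[float], fraction: float = 0.9) -> float:
    """Cumulative-sum threshold on a list of MI values.

    Sort descending, accumulate until the running sum reaches
    ``fraction`` of the total, and return the last value added.  An
    all-zero list yields threshold 0 (degenerate but defined).
    """
    values = np.asarray(list(mi_values), dtype=float)
    if values.size == 0:
        raise ValueError("empty MI list")
    if (values < 0).any():
        raise ValueError("MI values must be nonnegative")
    total = values.sum()
    if total == 0:
        return 0.0
    # stable sort keeps input order among ties
    order = np.argsort(-values, kind="stable")
    sorted_vals = values[order]
    cumulative = np.cumsum(sorted_vals)
    stop = int(np.searchsorted(cumulative, fraction * total - 1e-12))
    return float(sorted_vals[min(stop, values.size - 1)])


def categorize_neurons(
    mi_reach: Sequence[float],
    mi_grasp: Sequence[float],
    thr_reach: float,
    thr_grasp: float,
) -> list[Category]:
    """Categorize neurons by comparing each task's MI to its threshold.

    The comparison is inclusive: the neuron whose MI equals the threshold
    was the last one added to the cumulative sum and counts as tuned.
    """
    mi_reach = np.asarray(mi_reach, dtype=float)
    mi_grasp = np.asarray(mi_grasp, dtype=float)
    if mi_reach.shape != mi_grasp.shape:
        raise ValueError("mi_reach and mi_grasp must have equal length")
    categories = []
    for r, g in zip(mi_reach, mi_grasp):
        reach_tuned = r >= thr_reach
        grasp_tuned = g >= thr_grasp
        if reach_tuned and grasp_tuned:
            categories.append(Category.BOTH)
        elif reach_tuned:
            categories.append(Category.REACH_ONLY)
        elif grasp_tuned:
            categories.append(Category.GRASP_ONLY)
        else:
            categories.append(Category.UNTUNED)
    return categories


@dataclass
class MIProfile:
    """Per-neuron MI for both tasks, the task thresholds, and the
    resulting category assignment."""

    table: pd.DataFrame  # index neuron_id; mi_reach, mi_grasp, category
    thr_reach: float
    thr_grasp: float

    @property
    def neuron_ids(self) -> list[str]:
        return list(self.table.index)

    def neurons_in(self, *categories: Category) -> list[str]:
        wanted = {c.value for c in categories}
        return list(self.table.index[self.table["category"].isin(wanted)])

    def top_by_mi(self, task: str, k: int) -> list[str]:
        col = "mi_reach" if task in ("reach", "mi_reach") else "mi_grasp"
        order = self.table[col].sort_values(ascending=False, kind="stable")
        return list(order.index[:k])

    def tuned_subset(self, task: str) -> list[str]:
        """Neurons at/above the task's threshold (one-task-only + BOTH)."""
        if task in ("reach", "mi_reach"):
            only = Category.REACH_ONLY
        else:
            only = Category.GRASP_ONLY
        return self.neurons_in(only, Category.BOTH)


def mi_profile(
    samples_reach: IndicatorSamples,
    samples_grasp: IndicatorSamples,
    fraction: float = 0.9,
    p_y: Literal["uniform", "empirical"] = "uniform",
) -> MIProfile:
    """Full MI analysis of one session pair (reach block + grasp block).

    Requires both blocks to share the neuron roster.  Thresholds are
    computed per task from that session's MI values.
    """
    if samples_reach.neuron_ids != samples_grasp.neuron_ids:
        raise ValueError("reach and grasp blocks must share the neuron roster")
    ids = samples_reach.neuron_ids
    mi_reach = [spike_action_mi(samples_reach, nid, p_y=p_y) for nid in ids]
    mi_grasp = [spike_action_mi(samples_grasp, nid, p_y=p_y) for nid in ids]
    thr_reach = mi_threshold(mi_reach, fraction)
    thr_grasp = mi_threshold(mi_grasp, fraction)
    categories = categorize_neurons(mi_reach, mi_grasp, thr_reach, thr_grasp)
    table = pd.DataFrame(
        {
            "mi_reach": mi_reach,
            "mi_grasp": mi_grasp,
            "category": [c.value for c in categories],
        },
        index=pd.Index(ids, name="neuron_id"),
    )
    return MIProfile(table=table, thr_reach=thr_reach, thr_grasp=thr_grasp)


def contribution_table(profile: MIProfile) -> pd.DataFrame:
    """Share of each task's total MI carried by each category, in percent.

    Rows: task in {reach, grasp}; columns: one share and one neuron count
    per category.  Shares sum to 100% per task; when a task's total MI is
    zero its shares are NaN.
    """
    rows = []
    for task, col in (("reach", "mi_reach"), ("grasp", "mi_grasp")):
        mi = profile.table[col]
        total = mi.sum()
        row: dict[str, float] = {"task": task, "total_mi_bits": total}
        for cat in Category:
            mask = profile.table["category"] == cat.value
            row[f"share_{cat.value}"] = (
                float(mi[mask].sum() / total * 100.0) if total > 0 else np.nan
            )
            row[f"n_{cat.value}"] = int(mask.sum())
        rows.append(row)
    return pd.DataFrame(rows).set_index("task")


def average_contributions(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Arithmetic mean of per-session contribution tables (shares and
    counts averaged element-wise)."""
    if not tables:
        raise ValueError("no contribution tables to average")
    return sum(tables[1:], tables[0].copy()) / len(tables)
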