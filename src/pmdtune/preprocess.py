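"""Trial alignment, rate binning and binary spike indicators.

Spikes are aligned to cue onset (t = 0), cut to a half-open analysis
window [-pre_s, +post_s), binned into 100-ms firing rates, and reduced
to binary spike indicators at a 10-ms step.  All intervals are
half-open [start, end): a spike exactly at cue onset belongs to the
first post-cue bin, and no spike is ever counted in two bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .simulate import SessionData, Task

__all__ = [
    "AlignedTrials",
    "BinnedRates",
    "IndicatorSamples",
    "WindowError",
    "align_and_window",
    "bin_rates",
    "indicator_samples",
]

REST, MOVE = "REST", "MOVE"


class WindowError(ValueError):
    """Analysis window cannot be cut from the session."""


@dataclass
class AlignedTrials:
    """Per-trial spike times relative to cue onset.

    ``spikes[i][j]`` holds the aligned spike times of neuron ``j`` (in
    ``neuron_ids`` order) on trial ``i``, restricted to [-pre_s, post_s).
    """

    task: Task
    neuron_ids: list[str]
    spikes: list[list[np.ndarray]]
    labels: np.ndarray
    pre_s: float
    post_s: float

    @property
    def n_trials(self) -> int:
        return len(self.spikes)


@dataclass
class BinnedRates:
    """Trials x neurons x bins array of firing rates (Hz).

    Bins are tagged ``REST`` when they end at or before cue onset and
    ``MOVE`` otherwise.
    """

    task: Task
    neuron_ids: list[str]
    values: np.ndarray  # (trials, neurons, bins), Hz
    labels: np.ndarray  # (trials,), action 1..4
    bin_width_s: float
    pre_s: float
    post_s: float
    bin_epochs: np.ndarray  # (bins,), REST/MOVE strings

    @property
    def n_bins(self) -> int:
        return self.values.shape[2]

    @property
    def move_bins(self) -> np.ndarray:
        return np.flatnonzero(self.bin_epochs == MOVE)

    @property
    def rest_bins(self) -> np.ndarray:
        return np.flatnonzero(self.bin_epochs == REST)


@dataclass
class IndicatorSamples:
    """Binary spike indicators at a fixed step, one per step per trial.

    ``values[i, j, k]`` is 1 iff neuron ``j`` fired at least one spike in
    step ``k`` of trial ``i``.  ``pooled(j)`` flattens trials x steps
    into one sample vector paired with repeated trial labels, which is
    the sample set the mutual-information estimator consumes.
    """

    task: Task
    neuron_ids: list[str]
    values: np.ndarray  # (trials, neurons, steps), uint8
    labels: np.ndarray  # (trials,)
    step_s: float
    scope: str

    @property
    def n_steps(self) -> int:
        return self.values.shape[2]

    def pooled(self, neuron: int | str) -> tuple[np.ndarray, np.ndarray]:
        """Return (spk, y) sample vectors for one neuron, pooled over
        trials and steps."""
        j = self.neuron_ids.index(neuron) if isinstance(neuron, str) else neuron
        spk = self.values[:, j, :].ravel()
        y = np.repeat(self.labels, self.n_steps)
        return spk, y


def _index_in_window(times: np.ndarray, pre_s: float, width: float, n: int) -> np.ndarray:
    """Map aligned spike times to half-open interval indices; -1 outside.

    Scaled positions are rounded at 1 ns before flooring so that spikes
    lying exactly on an interval boundary (up to float noise) land in the
    interval that starts there.
    """
    idx = np.floor(np.round((times + pre_s) / width, 9)).astype(int)
    idx[(idx < 0) | (idx >= n)] = -1
    return idx


def align_and_window(session: SessionData, pre_s: float = 0.5, post_s: float = 1.7) -> AlignedTrials:
    """Re-express spike times relative to each trial's cue onset and keep
    those inside [-pre_s, post_s)."""
    if pre_s <= 0 or post_s <= 0:
        raise WindowError("pre_s and post_s must be positive")
    light_on = session.events["light_on_s"].to_numpy()
    bad = np.flatnonzero(light_on - pre_s < 0)
    if bad.size:
        raise WindowError(f"analysis window precedes session start for trials {bad.tolist()}")

    labels = session.events["action"].to_numpy().astype(int)
    per_trial: list[list[np.ndarray]] = []
    for on in light_on:
        row = []
        for nid in session.neuron_ids:
            times = session.spikes[nid]
            lo = np.searchsorted(times, on - pre_s, side="left")
            hi = np.searchsorted(times, on + post_s, side="left")
            row.append(times[lo:hi] - on)
        per_trial.append(row)
    return AlignedTrials(
        task=session.task,
        neuron_ids=list(session.neuron_ids),
        spikes=per_trial,
        labels=labels,
        pre_s=pre_s,
        post_s=post_s,
    )


def bin_rates(aligned: AlignedTrials, bin_width_s: float = 0.1) -> BinnedRates:
    """Bin aligned spikes into firing rates: rate = count / bin width.

    The number of bins is floor(window / width); spikes past the last
    full bin (only possible when the window is not an exact multiple of
    the width) are dropped.
    """
    if bin_width_s <= 0:
        raise WindowError("bin width must be positive")
    if aligned.n_trials == 0:
        raise WindowError("no trials to bin")
    window = aligned.pre_s + aligned.post_s
    n_bins = int(np.floor(np.round(window / bin_width_s, 9)))
    if n_bins < 1:
        raise WindowError("window shorter than one bin")

    n_neurons = len(aligned.neuron_ids)
    counts = np.zeros((aligned.n_trials, n_neurons, n_bins), dtype=np.int64)
    for i, row in enumerate(aligned.spikes):
        for j, times in enumerate(row):
            idx = _index_in_window(times, aligned.pre_s, bin_width_s, n_bins)
            idx = idx[idx >= 0]
            if idx.size:
                np.add.at(counts[i, j], idx, 1)

    bin_ends = -aligned.pre_s + (np.arange(n_bins) + 1) * bin_width_s
    epochs = np.where(bin_ends <= 1e-9, REST, MOVE)
    return BinnedRates(
        task=aligned.task,
        neuron_ids=list(aligned.neuron_ids),
        values=counts / bin_width_s,
        labels=aligned.labels.copy(),
        bin_width_s=bin_width_s,
        pre_s=aligned.pre_s,
        post_s=aligned.post_s,
        bin_epochs=epochs,
    )


def indicator_samples(
    aligned: AlignedTrials,
    step_s: float = 0.01,
    scope: Literal["full_window", "movement_only"] = "full_window",
) -> IndicatorSamples:
    """Binary spike indicator per step: 1 iff >= 1 spike in the step.

    ``scope="movement_only"`` restricts the steps to those starting at or
    after cue onset; the default pools the full analysis window.
    """
    if step_s <= 0:
        raise WindowError("step must be positive")
    if scope not in ("full_window", "movement_only"):
        raise WindowError(f"unknown scope {scope!r}")
    window = aligned.pre_s + aligned.post_s
    n_steps = int(np.floor(np.round(window / step_s, 9)))

    n_neurons = len(aligned.neuron_ids)
    values = np.zeros((aligned.n_trials, n_neurons, n_steps), dtype=np.uint8)
    for i, row in enumerate(aligned.spikes):
        for j, times in enumerate(row):
            idx = _index_in_window(times, aligned.pre_s, step_s, n_steps)
            idx = idx[idx >= 0]
            if idx.size:
                values[i, j, idx] = 1

    if scope == "movement_only":
        step_starts = -aligned.pre_s + np.arange(n_steps) * step_s
        keep = step_starts >= -1e-9
        values = values[:, :, keep]

    return IndicatorSamples(
        task=aligned.task,
        neuron_ids=list(aligned.neuron_ids),
        values=values,
        labels=aligned.labels.copy(),
        step_s=step_s,
        scope=scope,
    )
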