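"""Synthetic reach/grasp session generator.

Emulates the behavioural paradigm used throughout the package: two task
blocks (a four-direction reaching block and a four-object grasping block),
a trial clock of dark intertrial -> cue light on -> movement/hold -> cue
light off, and an ensemble of neurons whose firing is inhomogeneous
Poisson with a piecewise-constant rate profile (baseline at rest, a
gain-modulated and optionally action-tuned rate while the cue is lit).

Every neuron carries a ground-truth category (reach-tuned only,
grasp-tuned only, tuned to both, or untuned) so downstream tuning
classification can be validated by parameter recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Category",
    "Task",
    "NeuronSpec",
    "TrialClock",
    "SessionConfig",
    "SessionData",
    "ConfigurationError",
    "SessionParseError",
    "simulate_session",
    "default_ensemble",
    "write_session",
    "read_session",
]

N_ACTIONS = 4
#: spike times serialized at 1 microsecond resolution
TIME_DECIMALS = 6


class Category(str, Enum):
    """Ground-truth / inferred tuning category of a neuron."""

    REACH_ONLY = "REACH_ONLY"
    GRASP_ONLY = "GRASP_ONLY"
    BOTH = "BOTH"
    UNTUNED = "UNTUNED"


class Task(str, Enum):
    REACH = "reach"
    GRASP = "grasp"


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


class SessionParseError(ValueError):
    """Malformed on-disk session file."""


@dataclass(frozen=True)
class NeuronSpec:
    """Ground-truth description of one simulated neuron.

    Parameters
    ----------
    neuron_id
        Label used consistently across both task blocks of a session.
    category
        Planted tuning category.
    baseline_rate
        Resting firing rate in spikes/s; must be >= 0.
    movement_gain
        Multiplier (>= 1) applied to the baseline rate while the cue is
        lit, for every task the neuron is task-related to (i.e. any
        non-UNTUNED neuron).
    preferred_action_reach, preferred_action_grasp
        Preferred action index in 1..4, or ``None`` when the neuron
        carries no preference in that task.
    tuning_depth
        Rate contrast in [0, 1] between preferred and non-preferred
        actions: the movement rate is ``baseline*gain*(1 +/- depth)``.
    """

    neuron_id: str
    category: Category
    baseline_rate: float
    movement_gain: float = 1.0
    preferred_action_reach: Optional[int] = None
    preferred_action_grasp: Optional[int] = None
    tuning_depth: float = 0.0

    def __post_init__(self) -> None:
        if self.baseline_rate < 0:
            raise ConfigurationError(
                f"{self.neuron_id}: baseline_rate must be >= 0, got {self.baseline_rate}"
            )
        if self.movement_gain < 1:
            raise ConfigurationError(
                f"{self.neuron_id}: movement_gain must be >= 1, got {self.movement_gain}"
            )
        if not 0 <= self.tuning_depth <= 1:
            raise ConfigurationError(
                f"{self.neuron_id}: tuning_depth must lie in [0, 1], got {self.tuning_depth}"
            )
        for attr in ("preferred_action_reach", "preferred_action_grasp"):
            value = getattr(self, attr)
            if value is not None and value not in range(1, N_ACTIONS + 1):
                raise ConfigurationError(
                    f"{self.neuron_id}: {attr} must be 1..{N_ACTIONS} or None, got {value}"
                )
        cat = self.category
        if cat is Category.REACH_ONLY and self.preferred_action_grasp is not None:
            raise ConfigurationError(f"{self.neuron_id}: REACH_ONLY forbids a grasp preference")
        if cat is Category.GRASP_ONLY and self.preferred_action_reach is not None:
            raise ConfigurationError(f"{self.neuron_id}: GRASP_ONLY forbids a reach preference")
        if cat is Category.UNTUNED and (
            self.preferred_action_reach is not None or self.preferred_action_grasp is not None
        ):
            raise ConfigurationError(f"{self.neuron_id}: UNTUNED forbids any preference")
        if cat is Category.REACH_ONLY and self.preferred_action_reach is None:
            raise ConfigurationError(f"{self.neuron_id}: REACH_ONLY requires a reach preference")
        if cat is Category.GRASP_ONLY and self.preferred_action_grasp is None:
            raise ConfigurationError(f"{self.neuron_id}: GRASP_ONLY requires a grasp preference")
        if cat is Category.BOTH and (
            self.preferred_action_reach is None or self.preferred_action_grasp is None
        ):
            raise ConfigurationError(f"{self.neuron_id}: BOTH requires both preferences")

    def preferred_action(self, task: Task) -> Optional[int]:
        return self.preferred_action_reach if task is Task.REACH else self.preferred_action_grasp

    def movement_rate(self, task: Task, action: int) -> float:
        """Firing rate (Hz) from cue onset to cue offset for a given action."""
        if self.category is Category.UNTUNED:
            return self.baseline_rate
        preferred = self.preferred_action(task)
        rate = self.baseline_rate * self.movement_gain
        if preferred is None:
            return rate
        contrast = 1 + self.tuning_depth if action == preferred else 1 - self.tuning_depth
        return rate * contrast

    def to_dict(self) -> dict:
        return {
            "neuron_id": self.neuron_id,
            "category": self.category.value,
            "baseline_rate": self.baseline_rate,
            "movement_gain": self.movement_gain,
            "preferred_action_reach": self.preferred_action_reach,
            "preferred_action_grasp": self.preferred_action_grasp,
            "tuning_depth": self.tuning_depth,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NeuronSpec":
        return cls(
            neuron_id=d["neuron_id"],
            category=Category(d["category"]),
            baseline_rate=float(d["baseline_rate"]),
            movement_gain=float(d.get("movement_gain", 1.0)),
            preferred_action_reach=d.get("preferred_action_reach"),
            preferred_action_grasp=d.get("preferred_action_grasp"),
            tuning_depth=float(d.get("tuning_depth", 0.0)),
        )


@dataclass(frozen=True)
class TrialClock:
    """Timing parameters of one trial: dark intertrial interval drawn
    uniformly, a fixed movement deadline after cue onset, then a uniform
    hold that ends when the cue goes off."""

    intertrial_range_s: tuple[float, float] = (1.0, 2.5)
    reach_deadline_s: float = 0.6
    hold_range_s: tuple[float, float] = (1.0, 2.0)

    def __post_init__(self) -> None:
        lo, hi = self.intertrial_range_s
        hlo, hhi = self.hold_range_s
        if not (0 < lo <= hi and 0 < hlo <= hhi and self.reach_deadline_s > 0):
            raise ConfigurationError("trial clock durations must be positive and ordered")


DEFAULT_TRIALS_PER_ACTION = {Task.REACH: 25, Task.GRASP: 50}


@dataclass(frozen=True)
class SessionConfig:
    """Configuration for one simulated task block."""

    task: Task
    neurons: tuple[NeuronSpec, ...]
    rng_seed: int
    trials_per_action: Optional[int] = None
    pre_s: float = 0.5
    post_s: float = 1.7
    clock: TrialClock = field(default_factory=TrialClock)

    def __post_init__(self) -> None:
        if not isinstance(self.task, Task):
            object.__setattr__(self, "task", Task(self.task))
        object.__setattr__(self, "neurons", tuple(self.neurons))
        if not self.neurons:
            raise ConfigurationError("neuron list must be nonempty")
        ids = [n.neuron_id for n in self.neurons]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate neuron ids in ensemble")
        if self.trials_per_action is None:
            object.__setattr__(
                self, "trials_per_action", DEFAULT_TRIALS_PER_ACTION[self.task]
            )
        if self.trials_per_action <= 0:
            raise ConfigurationError(
                f"trials_per_action must be positive, got {self.trials_per_action}"
            )
        if self.pre_s <= 0 or self.post_s <= 0:
            raise ConfigurationError("analysis window extents must be positive")

    @property
    def n_trials(self) -> int:
        return self.trials_per_action * N_ACTIONS


@dataclass
class SessionData:
    """Spike timestamps and trial events for one task block.

    ``spikes`` maps neuron id to a strictly increasing array of spike
    times on the session clock (seconds).  ``events`` has one row per
    trial with columns ``trial``, ``light_on_s``, ``light_off_s`` and
    ``action`` in trial order.  ``ground_truth`` is present only for
    synthetic sessions.
    """

    task: Task
    neuron_ids: list[str]
    spikes: dict[str, np.ndarray]
    events: pd.DataFrame
    ground_truth: Optional[tuple[NeuronSpec, ...]] = None
    pre_s: float = 0.5
    post_s: float = 1.7

    def validate(self) -> None:
        for nid in self.neuron_ids:
            times = self.spikes[nid]
            if times.size and not np.all(np.diff(times) > 0):
                raise SessionParseError(f"spike times not strictly increasing for {nid}")
        ev = self.events
        if not (ev["light_on_s"] < ev["light_off_s"]).all():
            raise SessionParseError("light_on must precede light_off in every trial")
        if not ev["action"].isin(range(1, N_ACTIONS + 1)).all():
            raise SessionParseError("action labels must be in 1..4")
        if not ev["light_on_s"].is_monotonic_increasing:
            raise SessionParseError("trials must be time-ordered")
        if (ev["light_on_s"].to_numpy()[1:] < ev["light_off_s"].to_numpy()[:-1]).any():
            raise SessionParseError("trials overlap")

    def equals(self, other: "SessionData", atol: float = 10 ** -TIME_DECIMALS) -> bool:
        if self.task is not other.task or self.neuron_ids != other.neuron_ids:
            return False
        for nid in self.neuron_ids:
            a, b = self.spikes[nid], other.spikes[nid]
            if a.shape != b.shape or not np.allclose(a, b, atol=atol, rtol=0):
                return False
        ea, eb = self.events, other.events
        if len(ea) != len(eb) or not (ea["action"].to_numpy() == eb["action"].to_numpy()).all():
            return False
        for col in ("light_on_s", "light_off_s"):
            if not np.allclose(ea[col].to_numpy(), eb[col].to_numpy(), atol=atol, rtol=0):
                return False
        return True


def _balanced_labels(trials_per_action: int, rng: np.random.Generator) -> np.ndarray:
    labels = np.repeat(np.arange(1, N_ACTIONS + 1), trials_per_action)
    return rng.permutation(labels)


def _piecewise_poisson(
    segments: Sequence[tuple[float, float, float]], rng: np.random.Generator
) -> np.ndarray:
    """Sample a Poisson process with piecewise-constant rate.

    ``segments`` is a sequence of (start, end, rate) with start < end.
    Within each segment the count is Poisson(rate * duration) and the
    times are i.i.d. uniform, which is the standard conditional-uniform
    construction of a homogeneous Poisson process.
    """
    parts = []
    for start, end, rate in segments:
        if rate <= 0:
            continue
        count = rng.poisson(rate * (end - start))
        if count:
            parts.append(rng.uniform(start, end, size=count))
    if not parts:
        return np.empty(0, dtype=float)
    times = np.sort(np.concatenate(parts))
    # strict monotonicity at the stored resolution: perturb exact duplicates
    dup = np.flatnonzero(np.diff(times) <= 0)
    while dup.size:
        times[dup + 1] = np.nextafter(times[dup], np.inf)
        times = np.sort(times)
        dup = np.flatnonzero(np.diff(times) <= 0)
    return times


def simulate_session(config: SessionConfig) -> SessionData:
    """Simulate one task block.

    Per-neuron spike trains are inhomogeneous Poisson: baseline rate
    during the dark intertrial periods, and from cue onset to cue offset
    the neuron's :meth:`NeuronSpec.movement_rate` for the trial's action.
    The trial order is a seeded uniform permutation of the balanced
    action multiset.  Deterministic given ``config.rng_seed``.
    """
    master = np.random.SeedSequence(config.rng_seed)
    streams = master.spawn(len(config.neurons) + 1)
    clock_rng = np.random.default_rng(streams[0])

    labels = _balanced_labels(config.trials_per_action, clock_rng)
    n_trials = labels.size
    lo, hi = config.clock.intertrial_range_s
    hlo, hhi = config.clock.hold_range_s
    intertrials = clock_rng.uniform(lo, hi, size=n_trials)
    holds = clock_rng.uniform(hlo, hhi, size=n_trials)

    light_on = np.empty(n_trials)
    light_off = np.empty(n_trials)
    t = config.pre_s  # leading pad so the first analysis window fits
    for i in range(n_trials):
        t += intertrials[i]
        light_on[i] = t
        t += config.clock.reach_deadline_s + holds[i]
        light_off[i] = t
    session_end = t + max(config.post_s, 1.0)

    events = pd.DataFrame(
        {
            "trial": np.arange(n_trials),
            "light_on_s": light_on,
            "light_off_s": light_off,
            "action": labels.astype(int),
        }
    )

    spikes: dict[str, np.ndarray] = {}
    for spec, stream in zip(config.neurons, streams[1:]):
        rng = np.random.default_rng(stream)
        segments: list[tuple[float, float, float]] = []
        prev_end = 0.0
        for on, off, action in zip(light_on, light_off, labels):
            segments.append((prev_end, on, spec.baseline_rate))
            segments.append((on, off, spec.movement_rate(config.task, int(action))))
            prev_end = off
        segments.append((prev_end, session_end, spec.baseline_rate))
        spikes[spec.neuron_id] = _piecewise_poisson(segments, rng)

    session = SessionData(
        task=config.task,
        neuron_ids=[n.neuron_id for n in config.neurons],
        spikes=spikes,
        events=events,
        ground_truth=config.neurons,
        pre_s=config.pre_s,
        post_s=config.post_s,
    )
    session.validate()
    return session


# documented parameter ranges for the two ensemble presets; the source
# study reports no baseline rates or modulation depths, so these are a
# package choice (strong = comfortably recoverable, weak = marginal)
ENSEMBLE_PRESETS = {
    # narrow parameter spreads keep the per-neuron MI values comparable, so
    # the cumulative-90% threshold excludes at most ~1 tuned neuron per task;
    # moderate gains/depths keep single-subset decoding below ceiling
    "strong": {"baseline": (5.0, 7.0), "gain": (1.6, 1.9), "depth": (0.28, 0.38)},
    "weak": {"baseline": (2.0, 8.0), "gain": (1.3, 1.8), "depth": (0.1, 0.3)},
}


def default_ensemble(
    n_reach_only: int,
    n_grasp_only: int,
    n_both: int,
    n_untuned: int,
    effect: str = "strong",
    seed: int = 0,
) -> list[NeuronSpec]:
    """Build an ensemble with the requested category counts.

    Preferred actions are drawn uniformly; baseline rates, gains and
    tuning depths are drawn from the ``effect`` preset's documented
    ranges.  Deterministic given ``seed``.
    """
    counts = (n_reach_only, n_grasp_only, n_both, n_untuned)
    if any(c < 0 for c in counts):
        raise ConfigurationError(f"category counts must be >= 0, got {counts}")
    if sum(counts) == 0:
        raise ConfigurationError("ensemble must contain at least one neuron")
    if effect not in ENSEMBLE_PRESETS:
        raise ConfigurationError(f"unknown effect preset {effect!r}")
    preset = ENSEMBLE_PRESETS[effect]
    rng = np.random.default_rng(seed)

    specs: list[NeuronSpec] = []
    plan = (
        [Category.REACH_ONLY] * n_reach_only
        + [Category.GRASP_ONLY] * n_grasp_only
        + [Category.BOTH] * n_both
        + [Category.UNTUNED] * n_untuned
    )
    for i, category in enumerate(plan):
        baseline = rng.uniform(*preset["baseline"])
        gain = rng.uniform(*preset["gain"])
        depth = rng.uniform(*preset["depth"])
        pref_reach = int(rng.integers(1, N_ACTIONS + 1))
        pref_grasp = int(rng.integers(1, N_ACTIONS + 1))
        spec = NeuronSpec(
            neuron_id=f"n{i:03d}",
            category=category,
            baseline_rate=baseline,
            movement_gain=1.0 if category is Category.UNTUNED else gain,
            preferred_action_reach=(
                pref_reach if category in (Category.REACH_ONLY, Category.BOTH) else None
            ),
            preferred_action_grasp=(
                pref_grasp if category in (Category.GRASP_ONLY, Category.BOTH) else None
            ),
            tuning_depth=0.0 if category is Category.UNTUNED else depth,
        )
        specs.append(spec)
    return specs


def write_session(session: SessionData, path: str | Path) -> None:
    """Serialize a session to ``spikes.tsv``, ``events.tsv`` and
    ``session.json`` inside directory ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "spikes.tsv", "w") as fh:
        fh.write("neuron_id\tspike_time_s\n")
        for nid in session.neuron_ids:
            for t in session.spikes[nid]:
                fh.write(f"{nid}\t{t:.{TIME_DECIMALS}f}\n")
    with open(path / "events.tsv", "w") as fh:
        fh.write("trial\tlight_on_s\tlight_off_s\taction\n")
        for row in session.events.itertuples(index=False):
            fh.write(
                f"{row.trial}\t{row.light_on_s:.{TIME_DECIMALS}f}\t"
                f"{row.light_off_s:.{TIME_DECIMALS}f}\t{row.action}\n"
            )
    sidecar = {
        "task": session.task.value,
        "neuron_ids": session.neuron_ids,
        "pre_s": session.pre_s,
        "post_s": session.post_s,
        "ground_truth": (
            [spec.to_dict() for spec in session.ground_truth]
            if session.ground_truth is not None
            else None
        ),
    }
    with open(path / "session.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_session(path: str | Path) -> SessionData:
    """Read a session written by :func:`write_session`.

    Raises :class:`SessionParseError` naming the offending file and line
    for malformed rows, unsorted spike times or missing columns.
    """
    path = Path(path)
    try:
        with open(path / "session.json") as fh:
            sidecar = json.load(fh)
    except FileNotFoundError as exc:
        raise SessionParseError(f"missing session.json in {path}") from exc

    neuron_ids = list(sidecar["neuron_ids"])
    spikes: dict[str, list[float]] = {nid: [] for nid in neuron_ids}
    spikes_path = path / "spikes.tsv"
    with open(spikes_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["neuron_id", "spike_time_s"]:
            raise SessionParseError(f"{spikes_path}:1: expected columns neuron_id, spike_time_s")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise SessionParseError(f"{spikes_path}:{lineno}: expected 2 columns")
            nid, t = parts
            if nid not in spikes:
                raise SessionParseError(f"{spikes_path}:{lineno}: unknown neuron id {nid!r}")
            try:
                spikes[nid].append(float(t))
            except ValueError as exc:
                raise SessionParseError(
                    f"{spikes_path}:{lineno}: bad spike time {t!r}"
                ) from exc

    spike_arrays: dict[str, np.ndarray] = {}
    for nid, times in spikes.items():
        arr = np.asarray(times, dtype=float)
        if arr.size and not np.all(np.diff(arr) > 0):
            raise SessionParseError(f"{spikes_path}: spike times unsorted for neuron {nid}")
        spike_arrays[nid] = arr

    events_path = path / "events.tsv"
    try:
        events = pd.read_csv(events_path, sep="\t")
    except Exception as exc:
        raise SessionParseError(f"{events_path}: unreadable ({exc})") from exc
    required = ["trial", "light_on_s", "light_off_s", "action"]
    missing = [c for c in required if c not in events.columns]
    if missing:
        raise SessionParseError(f"{events_path}: missing columns {missing}")
    events = events[required]

    ground_truth = None
    if sidecar.get("ground_truth"):
        ground_truth = tuple(NeuronSpec.from_dict(d) for d in sidecar["ground_truth"])

    session = SessionData(
        task=Task(sidecar["task"]),
        neuron_ids=neuron_ids,
        spikes=spike_arrays,
        events=events,
        ground_truth=ground_truth,
        pre_s=float(sidecar.get("pre_s", 0.5)),
        post_s=float(sidecar.get("post_s", 1.7)),
    )
    session.validate()
    return session
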