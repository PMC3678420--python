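"""End-to-end orchestration: simulate (or load) a reach/grasp session
pair, preprocess, run the ANOVA screens, the MI categorization, and the
decoding experiments; write plain-text reports, figures and a
machine-readable summary sufficient for exact re-runs."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import decode, infotheory, preprocess, stats
from .simulate import (
    Category,
    ConfigurationError,
    SessionConfig,
    SessionData,
    Task,
    default_ensemble,
    read_session,
    simulate_session,
    write_session,
)

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("pmdtune")


@dataclass
class RunConfig:
    """Configuration of one full pipeline run.

    Either both ``reach_dir``/``grasp_dir`` point at serialized sessions
    (which must share the neuron roster), or the ensemble preset fields
    are used to simulate a session pair.
    """

    out_dir: str = "pmdtune-out"
    seed: int = 0
    # simulation preset (used when session dirs are not given)
    n_reach_only: int = 7
    n_grasp_only: int = 5
    n_both: int = 9
    n_untuned: int = 10
    effect: str = "strong"
    trials_per_action_reach: int = 25
    trials_per_action_grasp: int = 50
    # loading pre-existing sessions
    reach_dir: Optional[str] = None
    grasp_dir: Optional[str] = None
    # analysis options
    pre_s: float = 0.5
    post_s: float = 1.7
    scope: str = "full_window"
    alpha: float = 0.05
    min_tuned_bins: int = 2
    mi_fraction: float = 0.9
    top_k: int = 10
    eval_scheme: str = "cv"
    reduced_grid: bool = False
    make_plots: bool = True
    write_sessions: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _load_or_simulate(config: RunConfig) -> tuple[SessionData, SessionData]:
    if (config.reach_dir is None) != (config.grasp_dir is None):
        missing = "grasp_dir" if config.grasp_dir is None else "reach_dir"
        raise ConfigurationError(f"session pair incomplete: {missing} not given")
    if config.reach_dir is not None:
        reach = read_session(config.reach_dir)
        grasp = read_session(config.grasp_dir)
    else:
        ensemble = default_ensemble(
            config.n_reach_only,
            config.n_grasp_only,
            config.n_both,
            config.n_untuned,
            effect=config.effect,
            seed=config.seed,
        )
        reach = simulate_session(
            SessionConfig(
                task=Task.REACH,
                neurons=ensemble,
                rng_seed=config.seed + 1,
                trials_per_action=config.trials_per_action_reach,
                pre_s=config.pre_s,
                post_s=config.post_s,
            )
        )
        grasp = simulate_session(
            SessionConfig(
                task=Task.GRASP,
                neurons=ensemble,
                rng_seed=config.seed + 2,
                trials_per_action=config.trials_per_action_grasp,
                pre_s=config.pre_s,
                post_s=config.post_s,
            )
        )
    if reach.neuron_ids != grasp.neuron_ids:
        raise ConfigurationError(
            "reach and grasp sessions must share the neuron roster"
        )
    return reach, grasp


def _result_record(res: Optional[decode.DecodingResult]) -> Optional[dict]:
    if res is None:
        return None
    return {
        "subset": res.subset_name,
        "n_neurons": res.n_neurons,
        "accuracy": res.accuracy,
        "C": res.C,
        "gamma": res.gamma,
        "seed": res.seed,
        "eval_scheme": res.eval_scheme,
    }


def _plot_reports(out: Path, binned_reach, binned_grasp, profile, decoding_rows) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig_dir = out / "figures"
    fig_dir.mkdir(exist_ok=True)

    # PSTH panels for up to 4 neurons, one column per task
    n_show = min(4, len(binned_reach.neuron_ids))
    fig, axes = plt.subplots(n_show, 2, figsize=(9, 2.2 * n_show), squeeze=False)
    for row, nid in enumerate(binned_reach.neuron_ids[:n_show]):
        for col, binned in enumerate((binned_reach, binned_grasp)):
            ax = axes[row][col]
            j = binned.neuron_ids.index(nid)
            centers = -binned.pre_s + (np.arange(binned.n_bins) + 0.5) * binned.bin_width_s
            for action in range(1, 5):
                mask = binned.labels == action
                ax.plot(centers, binned.values[mask, j, :].mean(axis=0), label=f"A{action}")
            ax.axvline(0.0, color="k", lw=0.8)
            ax.set_title(f"{nid} ({binned.task.value})", fontsize=8)
    axes[0][0].legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(fig_dir / "psth.png", dpi=110)
    plt.close(fig)

    # per-neuron MI bars, both tasks
    fig, ax = plt.subplots(figsize=(10, 3))
    x = np.arange(len(profile.neuron_ids))
    ax.bar(x - 0.2, profile.table["mi_reach"], width=0.4, label="reach")
    ax.bar(x + 0.2, profile.table["mi_grasp"], width=0.4, label="grasp")
    ax.axhline(profile.thr_reach, color="C0", ls="--", lw=0.8)
    ax.axhline(profile.thr_grasp, color="C1", ls="--", lw=0.8)
    ax.set_xticks(x, profile.neuron_ids, rotation=90, fontsize=5)
    ax.set_ylabel("MI (bits)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(fig_dir / "mi.png", dpi=110)
    plt.close(fig)

    # decoding accuracy bars
    rows = [r for r in decoding_rows if r["accuracy"] is not None]
    if rows:
        fig, ax = plt.subplots(figsize=(8, 3))
        names = [f"{r['task']}:{r['subset']}" for r in rows]
        ax.bar(names, [r["accuracy"] for r in rows])
        ax.axhline(0.25, color="k", ls=":", lw=0.8)
        ax.set_ylabel("accuracy")
        ax.set_ylim(0, 1)
        plt.setp(ax.get_xticklabels(), rotation=45, ha="right", fontsize=7)
        fig.tight_layout()
        fig.savefig(fig_dir / "decoding.png", dpi=110)
        plt.close(fig)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write reports under ``config.out_dir``.

    Returns the machine-readable summary dict (also written as
    ``summary.json``).  Deterministic given the config, including seeds;
    no timestamps enter any output.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    reach, grasp = _load_or_simulate(config)
    log.info("sessions ready: %d neurons, %d reach trials, %d grasp trials",
             len(reach.neuron_ids), len(reach.events), len(grasp.events))
    if config.write_sessions:
        write_session(reach, out / "reach-session")
        write_session(grasp, out / "grasp-session")

    aligned_reach = preprocess.align_and_window(reach, config.pre_s, config.post_s)
    aligned_grasp = preprocess.align_and_window(grasp, config.pre_s, config.post_s)
    binned_reach = preprocess.bin_rates(aligned_reach)
    binned_grasp = preprocess.bin_rates(aligned_grasp)
    ind_reach = preprocess.indicator_samples(aligned_reach, scope=config.scope)
    ind_grasp = preprocess.indicator_samples(aligned_grasp, scope=config.scope)

    report_reach = stats.anova_report(binned_reach, config.alpha, config.min_tuned_bins)
    report_grasp = stats.anova_report(binned_grasp, config.alpha, config.min_tuned_bins)
    stats_table = report_reach.join(report_grasp, lsuffix="_reach", rsuffix="_grasp")
    stats_table.to_csv(out / "stats-report.tsv", sep="\t")

    profile = infotheory.mi_profile(ind_reach, ind_grasp, fraction=config.mi_fraction)
    profile.table.to_csv(out / "mi-profile.tsv", sep="\t")
    contributions = infotheory.contribution_table(profile)
    contributions.to_csv(out / "contributions.tsv", sep="\t")
    log.info("MI thresholds: reach %.4g bits, grasp %.4g bits",
             profile.thr_reach, profile.thr_grasp)

    svm_kwargs: dict = {"eval_scheme": config.eval_scheme}
    if config.reduced_grid:
        svm_kwargs["C_grid"] = 2.0 ** np.arange(-1, 12, 4)
        svm_kwargs["gamma_grid"] = 2.0 ** np.arange(-13, 0, 4)

    decoding_rows: list[dict] = []
    ensembles: dict[str, dict] = {}
    for task, binned in (("reach", binned_reach), ("grasp", binned_grasp)):
        res = decode.experiment_ensembles(
            binned, profile, seed=config.seed + 10, top_k=config.top_k, **svm_kwargs
        )
        ensembles[task] = {k: _result_record(v) for k, v in res.items()}
        for key, r in res.items():
            rec = _result_record(r) or {"subset": key, "accuracy": None, "n_neurons": 0}
            rec["task"] = task
            rec["experiment"] = "ensembles"
            decoding_rows.append(rec)

    addition_raw = decode.experiment_addition(
        binned_reach, binned_grasp, profile, seed=config.seed + 20, **svm_kwargs
    )
    addition: dict[str, dict] = {}
    for task, entry in addition_raw.items():
        if entry["skipped"]:
            addition[task] = {"skipped": True, "reason": entry["reason"]}
            continue
        addition[task] = {
            "skipped": False,
            "single": _result_record(entry["single"]),
            "combined": _result_record(entry["combined"]),
            "improvement_pct": entry["improvement_pct"],
        }
        for r in (entry["single"], entry["combined"]):
            rec = _result_record(r)
            rec["task"] = task
            rec["experiment"] = "addition"
            decoding_rows.append(rec)

    import pandas as pd

    pd.DataFrame(decoding_rows).to_csv(out / "decoding-results.tsv", sep="\t", index=False)

    summary = {
        "config": asdict(config),
        "n_neurons": len(reach.neuron_ids),
        "n_trials": {"reach": int(len(reach.events)), "grasp": int(len(grasp.events))},
        "thresholds_bits": {"reach": profile.thr_reach, "grasp": profile.thr_grasp},
        "category_counts": {
            c.value: int((profile.table["category"] == c.value).sum()) for c in Category
        },
        "contributions": json.loads(contributions.to_json(orient="index")),
        "decoding": {"ensembles": ensembles, "addition": addition},
    }
    if reach.ground_truth is not None:
        truth = [spec.category.value for spec in reach.ground_truth]
        predicted = list(profile.table["category"])
        summary["category_recovery_accuracy"] = float(
            np.mean([t == p for t, p in zip(truth, predicted)])
        )
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    if config.make_plots:
        _plot_reports(out, binned_reach, binned_grasp, profile, decoding_rows)
    return summary
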