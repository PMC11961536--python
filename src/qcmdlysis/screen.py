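"""End-to-end phage screening runs: simulate/load → δD → classify → report.

A :class:`ScreenConfig` declares the panel design (arms and replicate
counts), simulator overrides, analysis parameters and the master seed; a
:func:`run_screen` call turns it into a :class:`ScreenReport` holding one
row per experiment, the −phage vs +phage group comparison of the
fixed-timepoint readouts, and (optionally) a normalized-δD overlay plot
and a readout bar plot.  Reports are fully reproducible from
``(config, master_seed)``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .lysis import (
    DEFAULT_SMOOTHING_HALFWIDTH,
    GroupComparison,
    analyze_experiment,
    delta_d_spread,
    group_compare,
    normalize_spread,
)
from .simulate import (
    DEFAULT_TITERS,
    NON_INFECTIOUS_TITER,
    SimParams,
    simulate_panel,
)
from .traces import QcmdExperiment

__all__ = [
    "ArmDesign",
    "ScreenConfig",
    "ScreenReport",
    "run_screen",
    "analyze_panel",
    "earliest_separation_time",
]

log = logging.getLogger("qcmdlysis.screen")


@dataclass(frozen=True)
class ArmDesign:
    """One experimental arm of the panel."""

    scenario: str
    replicates: int = 1
    titer: Optional[float] = None  # PFU/mL; defaults depend on scenario

    def __post_init__(self) -> None:
        # YAML 1.1 reads bare scientific notation like 2.0e6 as a string;
        # coerce numeric fields so config files stay forgiving.
        object.__setattr__(self, "replicates", int(self.replicates))
        if self.titer is not None:
            object.__setattr__(self, "titer", float(self.titer))
        if self.replicates < 1:
            raise ValueError("replicate count must be >= 1")


@dataclass
class ScreenConfig:
    """Declarative description of a screening run."""

    panel: Sequence[ArmDesign] = field(
        default_factory=lambda: (
            ArmDesign("control", 2),
            *(ArmDesign("infectious", 1, t) for t in DEFAULT_TITERS),
            ArmDesign("non_infectious", 1),
        )
    )
    sim_overrides: dict = field(default_factory=dict)
    rule: str = "mean_sign"
    smoothing_halfwidth: int = DEFAULT_SMOOTHING_HALFWIDTH
    readout_time: float = 240.0
    settling_buffer: float = 10.0
    master_seed: int = 0
    outdir: Optional[Path] = None

    def __post_init__(self) -> None:
        self.panel = tuple(
            a if isinstance(a, ArmDesign) else ArmDesign(**a) for a in self.panel
        )
        if not self.panel:
            raise ValueError("panel must contain at least one arm")
        if self.outdir is not None:
            self.outdir = Path(self.outdir)

    @classmethod
    def from_yaml(cls, path) -> "ScreenConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**doc)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["panel"] = [dataclasses.asdict(a) for a in self.panel]
        d["outdir"] = str(self.outdir) if self.outdir else None
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def build_design(self) -> list[SimParams]:
        design = []
        for arm in self.panel:
            for _ in range(arm.replicates):
                kw = dict(self.sim_overrides)
                if arm.scenario == "control":
                    design.append(SimParams.control(**kw))
                elif arm.scenario == "infectious":
                    titer = arm.titer if arm.titer is not None else DEFAULT_TITERS[0]
                    design.append(SimParams.infectious(titer=titer, **kw))
                elif arm.scenario == "non_infectious":
                    titer = arm.titer if arm.titer is not None else NON_INFECTIOUS_TITER
                    design.append(SimParams.non_infectious(titer=titer, **kw))
                else:
                    raise ValueError(f"unknown scenario {arm.scenario!r}")
        return design


@dataclass
class ScreenReport:
    """Tabular outcome of a screening run."""

    table: pd.DataFrame  # one row per experiment
    comparison: Optional[GroupComparison]  # −phage vs +phage readouts
    metadata: dict

    def accuracy(self) -> float:
        """Fraction of experiments whose call matches the ground truth."""
        truth_lytic = self.table["truth"] == "infectious"
        called_lytic = self.table["call"] == "lytic"
        return float((truth_lytic == called_lytic).mean())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def analyze_panel(
    panel: Sequence[tuple[QcmdExperiment, Optional[str]]],
    config: ScreenConfig,
) -> ScreenReport:
    """Classify every experiment of a panel and compare the arms.

    ``panel`` holds ``(experiment, ground_truth)`` pairs; ground truth may
    be ``None`` for real (unlabelled) data, in which case accuracy is not
    defined but calls and readouts still are.
    """
    rows = []
    for exp, truth in panel:
        log.info("analyzing experiment %s (truth=%s)", exp.sensor_id, truth)
        call = analyze_experiment(
            exp,
            rule=config.rule,
            smoothing_halfwidth=config.smoothing_halfwidth,
            readout_time=config.readout_time,
            settling_buffer=config.settling_buffer,
        )
        rows.append(
            {
                "sensor_id": exp.sensor_id,
                "truth": truth,
                "titer": exp.metadata.get("titer", np.nan),
                "call": call.label,
                "drop_fraction": call.drop_fraction,
                "readout": call.readout_240,
                "derivative_mean": call.derivative_mean,
                "derivative_sum": call.derivative_sum,
            }
        )
    table = pd.DataFrame(rows)
    comparison = None
    if table["truth"].notna().any():
        minus = table.loc[table["truth"] != "infectious", "readout"]
        plus = table.loc[table["truth"] == "infectious", "readout"]
        if len(minus) >= 2 and len(plus) >= 2:
            comparison = group_compare(minus, plus)
            log.info(
                "-phage vs +phage readout: t=%.3f, p=%.2e (%s)",
                comparison.t_statistic,
                comparison.p_value,
                comparison.stars,
            )
    metadata = {
        "n_experiments": len(rows),
        "master_seed": config.master_seed,
        "config_hash": config.config_hash(),
        "version": __version__,
    }
    return ScreenReport(table=table, comparison=comparison, metadata=metadata)


def run_screen(config: ScreenConfig) -> ScreenReport:
    """Simulate the configured panel, analyze it, and (optionally) write
    the report table, comparison JSON and the two standard plots."""
    design = config.build_design()
    log.info("simulating panel of %d experiments (seed %d)", len(design), config.master_seed)
    panel = simulate_panel(design, config.master_seed)
    report = analyze_panel(panel, config)
    if config.outdir is not None:
        outdir = config.outdir
        outdir.mkdir(parents=True, exist_ok=True)
        report.to_csv(outdir / "screen_report.csv")
        payload = dict(report.metadata)
        if report.comparison is not None:
            payload["comparison"] = dataclasses.asdict(report.comparison)
        (outdir / "screen_summary.json").write_text(json.dumps(payload, indent=2))
        _plot_overlay(panel, config, outdir / "normalized_delta_d.png")
        _plot_readouts(report, outdir / "readout_240.png")
        log.info("wrote report to %s", outdir)
    return report


def earliest_separation_time(
    panel: Sequence[tuple[QcmdExperiment, str]],
    step: float = 10.0,
) -> Optional[float]:
    """Earliest time (min) at which the normalized-δD readout separates arms.

    Walks the schedule-aligned readout marks (every ``step`` minutes after
    the final flush) and returns the first at which every infectious
    replicate reads below every control/non-infectious replicate, i.e. the
    time by which a screening decision with no arm overlap is available.
    ``None`` if no mark separates the arms.
    """
    norms = []
    for exp, truth in panel:
        t_ref = exp.schedule.phase("second_injection").start
        norms.append((normalize_spread(delta_d_spread(exp), t_ref), truth))
    sched = panel[0][0].schedule
    flush_end = (
        sched.phase("flush_2").end
        if sched.has_phase("flush_2")
        else sched.phase("second_injection").end
    )
    t_max = min(float(n.time[-1]) for n, _ in norms)
    marks = np.arange(flush_end + step, t_max + 1e-9, step)
    for mark in marks:
        infectious, others = [], []
        for norm, truth in norms:
            value = float(np.interp(mark, norm.time, norm.value))
            (infectious if truth == "infectious" else others).append(value)
        if infectious and others and max(infectious) < min(others):
            return float(mark)
    return None


_ARM_COLORS = {"control": "k", "non_infectious": "tab:purple", "infectious": "tab:red"}


def _plot_overlay(panel, config: ScreenConfig, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    seen = set()
    for exp, truth in panel:
        t_ref = exp.schedule.phase("second_injection").start
        norm = normalize_spread(delta_d_spread(exp), t_ref)
        color = _ARM_COLORS.get(truth, "gray")
        label = truth if truth not in seen else None
        seen.add(truth)
        ax.plot(norm.time, norm.value, color=color, lw=1, alpha=0.8, label=label)
    ax.axvline(config.readout_time, ls="--", color="gray", lw=0.8)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("normalized $\\delta D$")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _plot_readouts(report: ScreenReport, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    tbl = report.table
    minus = tbl.loc[tbl["truth"] != "infectious", "readout"]
    plus = tbl.loc[tbl["truth"] == "infectious", "readout"]
    fig, ax = plt.subplots(figsize=(3.2, 4))
    means = [minus.mean(), plus.mean()]
    sds = [minus.std(ddof=1) if len(minus) > 1 else 0.0,
           plus.std(ddof=1) if len(plus) > 1 else 0.0]
    ax.bar([0, 1], means, yerr=sds, color=["0.6", "tab:red"], capsize=4)
    ax.set_xticks([0, 1], ["−phage", "+phage"])
    ax.set_ylabel("normalized $\\delta D$ at readout")
    if report.comparison is not None:
        ax.set_title(f"{report.comparison.stars} (p={report.comparison.p_value:.1e})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
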