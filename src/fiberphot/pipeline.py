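"""End-to-end orchestration: simulate → preprocess → align → stats.

``run_pipeline`` ties the stages together for a simulated cohort and
writes every intermediate product (traces, ΔF/F0, z-matrices, bin
tables, statistics) plus a run report with checksums.  The helper
functions are the same ones the command line and the acceptance
checks use, so a scripted analysis and a CLI run produce identical
numbers.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from fiberphot import io as fio
from fiberphot.alignment import (
    EventSeries,
    RandomSamplingSpec,
    bin_epoch_means,
    extract_epochs,
    per_animal_average,
    random_timestamps,
    zscore_epochs,
)
from fiberphot.preprocess import PhotometryTrace, ProcessedTrace, preprocess_session
from fiberphot.stats import (
    dunnett_vs_control,
    rm_anova_oneway,
    rm_anova_twoway_interaction,
)
from fiberphot.synthetic import BehaviorSpec, SimParams, simulate_cohort

__all__ = [
    "PipelineConfig",
    "RunReport",
    "session_bin_table",
    "cohort_bin_design",
    "cohort_event_vs_random",
    "analyze_oneway",
    "run_pipeline",
]

log = logging.getLogger("fiberphot")

BIN_EDGES = (-1.0, 0.0, 1.0, 2.0, 3.0)
BASELINE_BIN = "[-1,0)"


@dataclass
class PipelineConfig:
    """Everything a full run needs, in one validated bundle."""

    filter_cutoff_hz: float = 3.0
    epoch_window: tuple = (-1.0, 3.0)
    baseline_window: tuple = (-1.0, 0.0)
    bin_edges: tuple = BIN_EDGES
    alpha: float = 0.05
    seed: int = 0
    n_animals: int = 10
    n_per_window: int = 10
    out_dir: str = "fiberphot_out"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        pre, post = self.epoch_window
        blo, bhi = self.baseline_window
        if not (pre <= blo < bhi <= post):
            raise ValueError("baseline window must nest inside the epoch window")
        edges = np.asarray(self.bin_edges)
        if np.any(np.diff(edges) <= 0) or edges[0] < pre or edges[-1] > post:
            raise ValueError("bin edges must be increasing and inside the epoch window")
        if self.filter_cutoff_hz <= 0:
            raise ValueError("filter cutoff must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("epoch_window", "baseline_window", "bin_edges"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class RunReport:
    """Provenance for one pipeline run: config, seed, outputs, hashes."""

    config: dict
    seed: int
    outputs: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)

    def add(self, name: str, path: Path) -> None:
        self.outputs[name] = {"path": str(path), "sha256": fio.file_sha256(path)}


def session_bin_table(
    proc: ProcessedTrace,
    events: EventSeries,
    config: PipelineConfig = PipelineConfig(),
) -> pd.DataFrame:
    """Per-event per-second bin means of baseline z-scores for one session."""
    epochs = extract_epochs(proc, events, window=config.epoch_window)
    z = zscore_epochs(epochs, baseline=config.baseline_window,
                      session_dff=proc.dff)
    return bin_epoch_means(z, edges=config.bin_edges)


def cohort_bin_design(
    sessions: list,
    config: PipelineConfig = PipelineConfig(),
    label: str | None = None,
) -> pd.DataFrame:
    """Per-animal summary (one row per animal, one column per bin).

    ``sessions`` is a list of (trace, events, truth) triples or
    (trace, events) pairs; ``label`` restricts to one event type.
    """
    tables = []
    for sess in sessions:
        trace, events = sess[0], sess[1]
        if label is not None:
            events = events.select(label)
            if len(events) == 0:
                log.warning("animal %s has no %r events, excluded",
                            trace.animal_id, label)
                continue
        proc = preprocess_session(trace, cutoff_hz=config.filter_cutoff_hz)
        tables.append(session_bin_table(proc, events, config))
    return per_animal_average(tables)


def _design_matrix(summary: pd.DataFrame) -> tuple[np.ndarray, list]:
    bin_cols = [c for c in summary.columns if c.startswith("[")]
    return summary[bin_cols].to_numpy(dtype=float), bin_cols


def analyze_oneway(
    summary: pd.DataFrame,
    alpha: float = 0.05,
    seed: int = 12345,
) -> dict:
    """One-way RM ANOVA over bins plus Dunnett contrasts vs baseline."""
    X, bins = _design_matrix(summary)
    anova = rm_anova_oneway(X)
    contrasts = dunnett_vs_control(
        X, control=bins.index(BASELINE_BIN), level_labels=bins,
        alpha=alpha, seed=seed,
    )
    return {"anova": anova, "contrasts": contrasts, "bins": bins, "design": X}


def cohort_event_vs_random(
    sessions: list,
    config: PipelineConfig = PipelineConfig(),
    label: str | None = None,
    seed: int = 0,
) -> dict:
    """Time × (signal vs random) two-way RM design and interaction test.

    Factor A (time): baseline bin mean vs event-window (0 to +3 s) mean.
    Factor B (condition): behavior-locked epochs vs random timestamps.
    Returns the subjects × 2 × 2 array, the interaction ANOVA, and the
    per-animal random-stamp event-window means (the null calibration
    quantity).
    """
    rows = []
    for i, sess in enumerate(sessions):
        trace, events = sess[0], sess[1]
        if label is not None:
            events = events.select(label)
            if len(events) == 0:
                continue
        proc = preprocess_session(trace, cutoff_hz=config.filter_cutoff_hz)
        stamps = random_timestamps(
            trace.duration_s,
            RandomSamplingSpec(n_per_window=config.n_per_window),
            seed=seed + i,
            animal_id=trace.animal_id,
        )
        cells = []
        for ev in (events, stamps):
            tab = session_bin_table(proc, ev, config)
            bins = [c for c in tab.columns if c.startswith("[")]
            base = tab[BASELINE_BIN].mean()
            post = tab[[b for b in bins if b != BASELINE_BIN]].mean(axis=1).mean()
            cells.append((base, post))
        rows.append([[cells[0][0], cells[0][1]], [cells[1][0], cells[1][1]]])
    Y = np.asarray(rows)  # subjects × condition × time
    Y = np.transpose(Y, (0, 2, 1))  # subjects × time × condition
    anova = rm_anova_twoway_interaction(Y)
    return {
        "design": Y,
        "anova": anova,
        "random_event_mean_z": Y[:, 1, 1],
    }


def _contrast_frame(result: dict) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "level": c.level, "estimate": c.estimate, "t": c.t,
            "p_adjusted": c.p_adjusted, "ci_low": c.ci_low,
            "ci_high": c.ci_high, "adjust": c.adjust,
        }
        for c in result["contrasts"]
    ])


def run_pipeline(
    config: PipelineConfig,
    params: SimParams | None = None,
    behavior: BehaviorSpec | None = None,
) -> RunReport:
    """Simulate a novel/familiar social cohort and analyze it end to end.

    Writes, under ``config.out_dir``: raw trace and event CSVs, ΔF/F0
    CSVs with fit reports, z-matrices, per-animal bin tables, and a
    statistics JSON (one-way RM ANOVA + Dunnett per day, plus the
    two-way signal-vs-random interaction on the novel day).
    Deterministic given config and seed.
    """
    t_start = time.perf_counter()
    params = params or SimParams()
    behavior = behavior or BehaviorSpec(paradigm="social_novel")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=asdict(config), seed=config.seed)

    stats_payload: dict = {}
    for day in ("novel", "familiar"):
        t0 = time.perf_counter()
        sessions = simulate_cohort(
            config.n_animals, params, behavior, day=day, seed=config.seed)
        day_dir = out / day
        day_dir.mkdir(exist_ok=True)
        label = "social_novel" if day == "novel" else "social_familiar"
        for trace, events, truth in sessions:
            stem = day_dir / trace.animal_id
            report.add(f"{day}/{trace.animal_id}/trace",
                       fio.write_photometry_csv(trace, f"{stem}_trace.csv"))
            report.add(f"{day}/{trace.animal_id}/events",
                       fio.write_events_csv(events, f"{stem}_events.csv"))
            proc = preprocess_session(trace, cutoff_hz=config.filter_cutoff_hz)
            report.add(f"{day}/{trace.animal_id}/dff",
                       fio.write_processed(proc, f"{stem}_dff.csv",
                                           f"{stem}_fit.json"))
            epochs = extract_epochs(proc, events, window=config.epoch_window)
            z = zscore_epochs(epochs, baseline=config.baseline_window,
                              session_dff=proc.dff)
            report.add(f"{day}/{trace.animal_id}/zmatrix",
                       fio.write_zscore_matrix(z, f"{stem}_zmatrix.csv"))

        summary = cohort_bin_design(sessions, config, label=label)
        p = day_dir / "per_animal_bins.csv"
        summary.to_csv(p, index=False, float_format="%.12g")
        report.add(f"{day}/per_animal_bins", p)

        oneway = analyze_oneway(summary, alpha=config.alpha, seed=config.seed)
        contr = _contrast_frame(oneway)
        p = day_dir / "dunnett_contrasts.csv"
        contr.to_csv(p, index=False, float_format="%.12g")
        report.add(f"{day}/dunnett_contrasts", p)

        twoway = cohort_event_vs_random(sessions, config, label=label,
                                        seed=config.seed + 1000)
        stats_payload[day] = {
            "oneway": {
                "F": oneway["anova"].F, "df1": oneway["anova"].df1,
                "df2": oneway["anova"].df2, "p": oneway["anova"].p,
            },
            "interaction_vs_random": {
                "F": twoway["anova"].F, "df1": twoway["anova"].df1,
                "df2": twoway["anova"].df2, "p": twoway["anova"].p,
            },
            "random_event_mean_z": float(np.mean(twoway["random_event_mean_z"])),
        }
        report.timings_s[day] = round(time.perf_counter() - t0, 3)

    p = out / "stats_report.json"
    fio.write_json(stats_payload, p)
    report.add("stats_report", p)
    report.timings_s["total"] = round(time.perf_counter() - t_start, 3)
    fio.write_json(
        {"config": report.config, "seed": report.seed,
         "outputs": report.outputs, "timings_s": report.timings_s},
        out / "run_report.json",
    )
    return report
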