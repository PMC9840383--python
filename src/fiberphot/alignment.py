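"""Peri-event alignment, baseline z-scoring and the random-sampling null.

Behavioral events define t = 0 for each epoch.  ΔF/F0 is extracted over
a window around each onset (default −1 to +3 s), z-scored against the
mean and SD of the 1 s pre-onset baseline, summarized per second, and
averaged per animal — the per-animal bin means are the unit of the
downstream repeated-measures statistics.

The random-sampling null mirrors the event analysis on timestamps drawn
uniformly from two halves of the recording (10 + 10 by default), giving
a control distribution that is not time-locked to behavior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fiberphot.preprocess import ProcessedTrace

__all__ = [
    "EventSeries",
    "EpochMatrix",
    "ZScoreMatrix",
    "RandomSamplingSpec",
    "extract_epochs",
    "zscore_epochs",
    "bin_epoch_means",
    "per_animal_average",
    "random_timestamps",
    "heatmap_matrix",
]

KNOWN_LABELS = {
    "social_novel",
    "social_familiar",
    "open_arm_entry",
    "closed_arm_entry",
    "random",
}


@dataclass(frozen=True)
class EventSeries:
    """Labeled behavioral onsets (seconds) for one session."""

    onsets: np.ndarray
    labels: np.ndarray
    session_id: str = ""
    animal_id: str = ""

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=float)
        labels = np.asarray(self.labels, dtype=object)
        if onsets.ndim != 1 or labels.shape != onsets.shape:
            raise ValueError("onsets and labels must be 1-D and equal length")
        if len(onsets) and np.any(np.diff(onsets) < 0):
            raise ValueError("onsets must be sorted ascending")
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.onsets)

    def select(self, label: str) -> "EventSeries":
        keep = self.labels == label
        return EventSeries(self.onsets[keep], self.labels[keep],
                           self.session_id, self.animal_id)


@dataclass(frozen=True)
class EpochMatrix:
    """Events × samples matrix of peri-event ΔF/F0 values.

    ``time_rel_s`` is the shared relative-time axis (t = 0 at onset);
    ``dropped`` records (onset, reason) for events excluded because
    their window exceeded the recording.
    """

    values: np.ndarray
    time_rel_s: np.ndarray
    onsets: np.ndarray
    labels: np.ndarray
    animal_id: str = ""
    session_id: str = ""
    dropped: tuple = ()

    @property
    def n_events(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class ZScoreMatrix:
    """Peri-event epochs standardized against their pre-onset baseline.

    Each row i satisfies z = (dff − μ_i)/σ_i with μ_i, σ_i taken from
    that event's baseline window.  Rows whose baseline SD was
    degenerate fall back to the session-wide ΔF/F0 SD and are flagged
    in ``fallback_rows``.
    """

    values: np.ndarray
    time_rel_s: np.ndarray
    onsets: np.ndarray
    labels: np.ndarray
    baseline_mean: np.ndarray
    baseline_sd: np.ndarray
    baseline_window: tuple
    fallback_rows: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    animal_id: str = ""
    session_id: str = ""

    @property
    def n_events(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class RandomSamplingSpec:
    """Two uniform windows for null timestamps (10 + 10 by default)."""

    n_per_window: int = 10
    window1: tuple = (5.0, 149.99)
    window2: tuple = (150.0, 294.99)

    def __post_init__(self) -> None:
        if self.n_per_window < 1:
            raise ValueError("n_per_window must be >= 1")
        for lo, hi in (self.window1, self.window2):
            if not lo < hi:
                raise ValueError(f"degenerate window [{lo}, {hi}]")


def extract_epochs(
    proc: ProcessedTrace,
    events: EventSeries,
    window: tuple = (-1.0, 3.0),
) -> EpochMatrix:
    """Cut peri-event ΔF/F0 epochs around each onset.

    Onsets are snapped to the nearest sample.  Events whose window
    would run past either end of the recording are dropped and logged
    in ``EpochMatrix.dropped`` rather than padded.

    Raises
    ------
    ValueError
        If no event survives the boundary rule.
    """
    pre, post = window
    if not pre < post:
        raise ValueError(f"invalid window {window}")
    fs = proc.rate_hz
    n_pre = int(round(-pre * fs))
    n_post = int(round(post * fs))
    n_samp = n_pre + n_post
    t0 = proc.time_s[0]
    n_total = len(proc.dff)

    rows, kept_onsets, kept_labels, dropped = [], [], [], []
    for onset, label in zip(events.onsets, events.labels):
        i_on = int(round((onset - t0) * fs))
        lo, hi = i_on - n_pre, i_on + n_post
        if lo < 0 or hi > n_total:
            dropped.append((float(onset), "window exceeds recording"))
            continue
        rows.append(proc.dff[lo:hi])
        kept_onsets.append(onset)
        kept_labels.append(label)
    if not rows:
        raise ValueError("no events retained: all windows exceed the recording")
    time_rel = (np.arange(n_samp) - n_pre) / fs
    return EpochMatrix(
        values=np.asarray(rows),
        time_rel_s=time_rel,
        onsets=np.asarray(kept_onsets, dtype=float),
        labels=np.asarray(kept_labels, dtype=object),
        animal_id=proc.animal_id or events.animal_id,
        session_id=proc.session_id or events.session_id,
        dropped=tuple(dropped),
    )


def zscore_epochs(
    epochs: EpochMatrix,
    baseline: tuple = (-1.0, 0.0),
    session_dff: np.ndarray | None = None,
    eps: float = 1e-10,
) -> ZScoreMatrix:
    """Standardize each epoch against its own pre-onset baseline.

    z = (ΔF/F0 − μ_baseline) / σ_baseline per event, with the sample SD
    (n−1 denominator) of the same baseline segment.  A degenerate
    baseline SD (< ``eps``) falls back to the SD of ``session_dff``
    (the whole-session ΔF/F0 trace) and flags the row; if that too is
    degenerate, an error is raised.
    """
    lo, hi = baseline
    mask = (epochs.time_rel_s >= lo) & (epochs.time_rel_s < hi)
    if mask.sum() < 3:
        raise ValueError("baseline window must contain at least 3 samples")
    base = epochs.values[:, mask]
    mu = base.mean(axis=1)
    sd = base.std(axis=1, ddof=1)

    fallback = np.flatnonzero(sd < eps)
    if fallback.size:
        if session_dff is None:
            raise ValueError(
                f"{fallback.size} event(s) with degenerate baseline SD and no "
                "session_dff provided for fallback"
            )
        sd_sess = float(np.std(np.asarray(session_dff, dtype=float), ddof=1))
        if sd_sess < eps:
            raise ValueError("session-wide ΔF/F0 SD is also degenerate")
        sd = sd.copy()
        sd[fallback] = sd_sess
    z = (epochs.values - mu[:, None]) / sd[:, None]
    return ZScoreMatrix(
        values=z,
        time_rel_s=epochs.time_rel_s,
        onsets=epochs.onsets,
        labels=epochs.labels,
        baseline_mean=mu,
        baseline_sd=sd,
        baseline_window=(lo, hi),
        fallback_rows=fallback,
        animal_id=epochs.animal_id,
        session_id=epochs.session_id,
    )


def bin_epoch_means(
    z: ZScoreMatrix,
    edges: tuple = (-1.0, 0.0, 1.0, 2.0, 3.0),
) -> pd.DataFrame:
    """Mean z per half-open time bin [e_i, e_{i+1}) per event.

    Returns a tidy DataFrame with one row per event and one column per
    bin, labeled ``"[a,b)"``; event metadata in index columns.
    """
    edges = np.asarray(edges, dtype=float)
    if edges[0] < z.time_rel_s[0] - 1e-9 or edges[-1] > z.time_rel_s[-1] + 1.0:
        raise ValueError("bin edges must lie within the epoch window")
    cols = {}
    for a, b in zip(edges[:-1], edges[1:]):
        mask = (z.time_rel_s >= a) & (z.time_rel_s < b)
        if not mask.any():
            raise ValueError(f"empty bin [{a}, {b})")
        cols[f"[{a:g},{b:g})"] = z.values[:, mask].mean(axis=1)
    df = pd.DataFrame(cols)
    df.insert(0, "animal_id", z.animal_id)
    df.insert(1, "onset_s", z.onsets)
    df.insert(2, "label", z.labels)
    return df


def per_animal_average(bin_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Average per-event bin means into one row per animal.

    Each animal contributes the unweighted mean over all of its events
    (pooled across sessions); ``n_events`` records how many went in.
    Statistical comparisons downstream use these per-animal averages as
    the repeated-measures unit.
    """
    pooled = pd.concat(bin_tables, ignore_index=True)
    if pooled.empty:
        raise ValueError("no events to average")
    bin_cols = [c for c in pooled.columns if c.startswith("[")]
    grouped = pooled.groupby("animal_id", sort=True)
    out = grouped[bin_cols].mean()
    out["n_events"] = grouped.size()
    return out.reset_index()


def random_timestamps(
    duration_s: float,
    spec: RandomSamplingSpec = RandomSamplingSpec(),
    seed: int = 0,
    session_id: str = "",
    animal_id: str = "",
) -> EventSeries:
    """Draw null timestamps: n per window, uniform and independent.

    With the default spec this yields 10 stamps within [5, 149.99] s
    and 10 within [150, 294.99] s of a 5 min recording.  Stamps may
    fall arbitrarily close together (no collision checking).

    Raises
    ------
    ValueError
        If the recording is shorter than the second window's upper
        bound (default: duration < 295 s).
    """
    needed = max(spec.window1[1], spec.window2[1])
    if duration_s < needed:
        raise ValueError(
            f"duration {duration_s} s too short for sampling windows "
            f"(need >= {needed} s)"
        )
    rng = np.random.default_rng(seed)
    stamps = np.concatenate([
        rng.uniform(*spec.window1, size=spec.n_per_window),
        rng.uniform(*spec.window2, size=spec.n_per_window),
    ])
    stamps.sort()
    labels = np.full(stamps.shape, "random", dtype=object)
    return EventSeries(stamps, labels, session_id=session_id, animal_id=animal_id)


def heatmap_matrix(z: ZScoreMatrix, order: str = "event_order"):
    """Row-ordered copy of a z-score matrix for heatmap display.

    ``order="event_order"`` keeps rows as-is; ``order="peak"`` sorts by
    ascending peak time (argmax of each row).  Values are never
    modified.  Returns ``(matrix, time_rel_s, row_order)``.
    """
    if z.n_events < 1:
        raise ValueError("empty z-score matrix")
    if order == "event_order":
        idx = np.arange(z.n_events)
    elif order == "peak":
        idx = np.argsort(z.values.argmax(axis=1), kind="stable")
    else:
        raise ValueError(f"unknown order {order!r}")
    return z.values[idx].copy(), z.time_rel_s.copy(), idx
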