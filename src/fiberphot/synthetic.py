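"""Ground-truth simulators for photometry sessions, events and images.

The session generator emulates the statistical structure of a 5 min
two-channel recording of a dopamine sensor through an implanted fiber:

- a 465 nm signal channel carrying baseline fluorescence, slow
  double-exponential photobleaching, a shared motion artifact,
  measurement noise, and dopamine transients (event-locked and
  spontaneous);
- a 405 nm isosbestic control channel carrying the same bleaching and
  motion nuisances but, by construction, **no** transient component.

Channel model (volts)::

    f465(t) = baseline_465 · bleach_465(t) · (1 + ΔF/F_true(t))
              + motion_gain_465 · motion(t) + noise
    f405(t) = baseline_405 · bleach_405(t)
              + motion_gain_405 · motion(t) + noise

Every generator is a pure function of its parameters and an integer
seed; ground truth (transient times/amplitudes, motion and bleach
traces) is returned alongside the data so recovery can be tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from fiberphot.alignment import EventSeries
from fiberphot.preprocess import PhotometryTrace

__all__ = [
    "SimParams",
    "BehaviorSpec",
    "SimGroundTruth",
    "transient_kernel",
    "simulate_session",
    "simulate_cohort",
    "simulate_epm_events",
    "simulate_coloc_images",
    "simulate_fiber_image",
]

# events must leave room for the peri-event window at both ends
EVENT_MARGIN_PRE = 5.0   # s from recording start
EVENT_MARGIN_POST = 3.0  # s from recording end


@dataclass(frozen=True)
class SimParams:
    """Session generator parameters (defaults = reference conditions).

    Amplitude units are volts for channel-level quantities and ΔF/F0
    units for transient amplitudes.  The default transient amplitude
    (0.006 ΔF/F0) is calibrated so that, under the default noise and
    spontaneous-activity levels, the peri-event z-score peaks near 2 —
    a clear but realistic single-event response.
    """

    duration_s: float = 300.0
    rate_hz: float = 240.0
    baseline_465: float = 1.0
    baseline_405: float = 0.8
    bleach_amp_465: float = 0.10
    bleach_amp_405: float = 0.10
    bleach_tau_fast: float = 30.0
    bleach_tau_slow: float = 600.0
    motion_sd: float = 0.05
    motion_gain_465: float = 1.0
    motion_gain_405: float = 1.0
    transient_amp: float = 0.006
    habituated_amp: float = 0.0
    tau_rise: float = 0.15
    tau_decay: float = 1.0
    latency_jitter_sd: float = 0.2
    spont_rate: float = 0.05
    spont_amp: float = 0.006
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.rate_hz <= 6.0:
            raise ValueError("rate_hz must exceed 6 Hz (twice the 3 Hz filter)")
        for name in ("bleach_tau_fast", "bleach_tau_slow", "motion_sd",
                     "latency_jitter_sd", "spont_rate", "noise_sd",
                     "tau_rise", "tau_decay"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.tau_decay <= self.tau_rise:
            raise ValueError("tau_decay must exceed tau_rise")
        if self.baseline_465 <= 0 or self.baseline_405 <= 0:
            raise ValueError("channel baselines must be positive")


@dataclass(frozen=True)
class BehaviorSpec:
    """What behavioral events to generate for a session.

    ``paradigm`` is one of ``social_novel``, ``social_familiar`` or
    ``epm``.  Social paradigms place ``n_events`` sniffing-bout onsets;
    the EPM places alternating open/closed arm entries.  All onsets fall
    within [5 s, duration − 3 s] with gaps of at least ``min_gap_s``.
    """

    paradigm: str = "social_novel"
    n_events: int = 10
    n_open_entries: int = 5
    n_closed_entries: int = 5
    min_gap_s: float = 5.0

    def __post_init__(self) -> None:
        if self.paradigm not in ("social_novel", "social_familiar", "epm"):
            raise ValueError(f"unknown paradigm {self.paradigm!r}")
        if self.min_gap_s < 0:
            raise ValueError("min_gap_s must be >= 0")

    @property
    def total_events(self) -> int:
        if self.paradigm == "epm":
            return self.n_open_entries + self.n_closed_entries
        return self.n_events


@dataclass(frozen=True)
class SimGroundTruth:
    """Everything injected into a simulated session."""

    event_onsets: np.ndarray
    true_transient_times: np.ndarray
    true_amplitudes: np.ndarray
    dff_true: np.ndarray
    motion_trace: np.ndarray
    bleach_465: np.ndarray
    bleach_405: np.ndarray
    seed: int


def transient_kernel(t: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Difference-of-exponentials transient, normalized to unit peak.

    k(t) = (1 − e^(−t/τ_rise)) · e^(−t/τ_decay) for t ≥ 0, scaled so
    max k = 1; the peak sits at t* = τ_rise · ln(1 + τ_decay/τ_rise).
    With τ_rise = 0 the kernel degenerates to a pure decay.
    """
    t = np.asarray(t, dtype=float)
    k = np.where(t >= 0, np.exp(-np.maximum(t, 0) / tau_decay), 0.0)
    if tau_rise > 0:
        k = k * np.where(t >= 0, 1.0 - np.exp(-np.maximum(t, 0) / tau_rise), 0.0)
        t_peak = tau_rise * math.log1p(tau_decay / tau_rise)
        peak = (1.0 - math.exp(-t_peak / tau_rise)) * math.exp(-t_peak / tau_decay)
        k = k / peak
    return k


def _draw_onsets(rng, n: int, lo: float, hi: float, min_gap: float) -> np.ndarray:
    """n sorted onsets in [lo, hi] with consecutive gaps >= min_gap."""
    span = hi - lo
    slack = span - (n - 1) * min_gap
    if n < 1 or slack < 0:
        raise ValueError(
            f"cannot place {n} events with min gap {min_gap} s in "
            f"[{lo:g}, {hi:g}] s"
        )
    u = np.sort(rng.uniform(0.0, slack, size=n))
    return lo + u + min_gap * np.arange(n)


def _social_events(rng, params: SimParams, behavior: BehaviorSpec) -> EventSeries:
    lo = EVENT_MARGIN_PRE
    hi = params.duration_s - EVENT_MARGIN_POST
    onsets = _draw_onsets(rng, behavior.n_events, lo, hi, behavior.min_gap_s)
    labels = np.full(onsets.shape, behavior.paradigm, dtype=object)
    return EventSeries(onsets, labels)


def simulate_epm_events(
    duration_s: float,
    n_open_entries: int,
    n_closed_entries: int,
    seed: int,
    min_gap_s: float = 5.0,
) -> EventSeries:
    """Alternating open/closed arm-entry onsets for one EPM session.

    Entries interleave (a mouse cannot enter the same arm type twice
    without leaving it), starting with whichever type has more entries
    (open first on ties).

    Raises
    ------
    ValueError
        If the requested entries do not fit into the valid window with
        the minimum gap, or the counts cannot alternate.
    """
    if n_open_entries < 0 or n_closed_entries < 0:
        raise ValueError("entry counts must be >= 0")
    n = n_open_entries + n_closed_entries
    if abs(n_open_entries - n_closed_entries) > 1:
        raise ValueError(
            "open/closed entry counts must alternate (differ by at most 1)"
        )
    rng = np.random.default_rng(seed)
    onsets = _draw_onsets(
        rng, n, EVENT_MARGIN_PRE, duration_s - EVENT_MARGIN_POST, min_gap_s
    )
    first = "open_arm_entry" if n_open_entries >= n_closed_entries else "closed_arm_entry"
    second = "closed_arm_entry" if first == "open_arm_entry" else "open_arm_entry"
    labels = np.array([first if i % 2 == 0 else second for i in range(n)], dtype=object)
    return EventSeries(onsets, labels)


def _label_amplitude(label: str, amp: float) -> float:
    """Signed transient amplitude per event type.

    Open-arm entries and social sniffing drive positive dopamine
    transients; closed-arm entries drive deflections of equal magnitude
    and opposite sign.
    """
    return -amp if label == "closed_arm_entry" else amp


def _motion(rng, n: int, rate_hz: float, sd: float) -> np.ndarray:
    """Shared sub-1 Hz motion artifact, normalized to the requested SD."""
    if sd == 0:
        return np.zeros(n)
    raw = rng.standard_normal(n)
    b, a = signal.butter(2, 1.0 / (rate_hz / 2.0), btype="low")
    m = signal.filtfilt(b, a, raw)
    s = m.std()
    return m * (sd / s) if s > 0 else m


def simulate_session(
    params: SimParams,
    behavior: BehaviorSpec,
    seed: int,
    animal_id: str = "",
    session_id: str = "",
) -> tuple[PhotometryTrace, EventSeries, SimGroundTruth]:
    """Generate one two-channel session with known ground truth.

    Event-locked transients enter only the 465 nm channel (the
    isosbestic contract); motion and bleaching enter both.  Identical
    ``(params, behavior, seed)`` yield bit-identical output.
    """
    rng = np.random.default_rng(seed)
    n = int(round(params.duration_s * params.rate_hz))
    t = np.arange(n) / params.rate_hz

    # behavioral events
    if behavior.paradigm == "epm":
        sub_seed = int(rng.integers(0, 2**31 - 1))
        events = simulate_epm_events(
            params.duration_s, behavior.n_open_entries,
            behavior.n_closed_entries, seed=sub_seed,
            min_gap_s=behavior.min_gap_s,
        )
    else:
        events = _social_events(rng, params, behavior)
    events = EventSeries(events.onsets, events.labels,
                         session_id=session_id, animal_id=animal_id)

    # event-locked transients with latency jitter (never before onset)
    trans_times, trans_amps = [], []
    for onset, label in zip(events.onsets, events.labels):
        jitter = max(0.0, rng.normal(0.0, params.latency_jitter_sd))
        trans_times.append(onset + jitter)
        trans_amps.append(_label_amplitude(label, params.transient_amp))

    # spontaneous transients: homogeneous Poisson, positive amplitudes
    n_spont = rng.poisson(params.spont_rate * params.duration_s)
    spont_times = np.sort(rng.uniform(0.0, params.duration_s, size=n_spont))
    spont_amps = rng.uniform(0.5, 1.0, size=n_spont) * params.spont_amp
    trans_times.extend(spont_times.tolist())
    trans_amps.extend(spont_amps.tolist())
    trans_times = np.asarray(trans_times)
    trans_amps = np.asarray(trans_amps)

    dff_true = np.zeros(n)
    kern_support = int(round((params.tau_rise + 8 * params.tau_decay) * params.rate_hz))
    t_kern = np.arange(kern_support) / params.rate_hz
    for tt, aa in zip(trans_times, trans_amps):
        if aa == 0:
            continue
        i0 = int(round(tt * params.rate_hz))
        if i0 >= n:
            continue
        frac = tt - i0 / params.rate_hz
        seg = transient_kernel(t_kern - frac, params.tau_rise, params.tau_decay)
        stop = min(n, i0 + kern_support)
        dff_true[i0:stop] += aa * seg[: stop - i0]

    # multiplicative double-exponential bleach, per channel (volts)
    def bleach(baseline: float, amp: float) -> np.ndarray:
        droop = 0.5 * (1 - np.exp(-t / params.bleach_tau_fast)) \
            + 0.5 * (1 - np.exp(-t / params.bleach_tau_slow))
        return baseline - amp * droop

    bleach465 = bleach(params.baseline_465, params.bleach_amp_465)
    bleach405 = bleach(params.baseline_405, params.bleach_amp_405)

    motion = _motion(rng, n, params.rate_hz, params.motion_sd)
    noise465 = rng.normal(0.0, params.noise_sd, n) if params.noise_sd else np.zeros(n)
    noise405 = rng.normal(0.0, params.noise_sd, n) if params.noise_sd else np.zeros(n)

    f465 = bleach465 * (1.0 + dff_true) + params.motion_gain_465 * motion + noise465
    f405 = bleach405 + params.motion_gain_405 * motion + noise405

    trace = PhotometryTrace(
        time_s=t, f465=f465, f405=f405, rate_hz=params.rate_hz,
        animal_id=animal_id, session_id=session_id,
    )
    truth = SimGroundTruth(
        event_onsets=events.onsets.copy(),
        true_transient_times=trans_times,
        true_amplitudes=trans_amps,
        dff_true=dff_true,
        motion_trace=motion,
        bleach_465=bleach465,
        bleach_405=bleach405,
        seed=seed,
    )
    return trace, events, truth


def simulate_cohort(
    n_animals: int,
    params: SimParams,
    behavior: BehaviorSpec,
    day: str = "novel",
    seed: int = 0,
) -> list[tuple[PhotometryTrace, EventSeries, SimGroundTruth]]:
    """Simulate one session per animal for a novel or familiar day.

    On the familiar day the event-locked transient amplitude habituates
    to ``params.habituated_amp`` (default 0: no response to the
    now-familiar stimulus); spontaneous activity is unchanged.
    Per-animal seeds are ``seed + animal_index``, so a cohort is fully
    reproducible and each animal differs.
    """
    if n_animals < 2:
        raise ValueError("need at least 2 animals (group statistics undefined)")
    if day not in ("novel", "familiar"):
        raise ValueError(f"day must be 'novel' or 'familiar', got {day!r}")
    p = params
    b = behavior
    if day == "familiar":
        p = replace(params, transient_amp=params.habituated_amp)
        if behavior.paradigm == "social_novel":
            b = replace(behavior, paradigm="social_familiar")
    sessions = []
    for i in range(n_animals):
        aid = f"animal{i:02d}"
        sessions.append(
            simulate_session(p, b, seed=seed + i, animal_id=aid,
                             session_id=f"{aid}_{day}")
        )
    return sessions


# --------------------------------------------------------------------------
# imaging fixtures


def _place_centers(rng, n: int, size: int, margin: int, min_sep: float,
                   max_tries: int = 20000) -> np.ndarray:
    """Rejection-sample n centers with pairwise separation >= min_sep."""
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < n:
        if tries >= max_tries:
            raise ValueError(
                f"could not place {n} puncta in a {size}x{size} image "
                f"(min separation {min_sep:g} px): capacity exceeded"
            )
        tries += 1
        c = rng.uniform(margin, size - margin, size=2)
        if all((c[0] - a) ** 2 + (c[1] - b) ** 2 >= min_sep**2 for a, b in centers):
            centers.append((float(c[0]), float(c[1])))
    return np.asarray(centers)


def _disk_mask(size: int, centers: np.ndarray, radius: float) -> np.ndarray:
    mask = np.zeros((size, size), dtype=bool)
    yy, xx = np.mgrid[0:size, 0:size]
    for cy, cx in centers:
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    return mask


def simulate_coloc_images(
    size_px: int = 256,
    n_puncta: int = 60,
    overlap_fraction: float = 0.5,
    seed: int = 0,
    radius_green: float = 3.0,
    radius_red: float = 5.0,
    intensity: float = 200.0,
    background: float = 10.0,
    noise_sd: float = 3.0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Green/red punctum image pair with a known overlap fraction.

    ``round(overlap_fraction * n_puncta)`` green puncta are placed
    concentrically inside (larger) red puncta; the remaining green and
    red puncta are kept disjoint from everything else.  Truth masks and
    centers are returned for recovery tests.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must lie in [0, 1]")
    if n_puncta < 1:
        raise ValueError("n_puncta must be >= 1")
    rng = np.random.default_rng(seed)
    n_ov = int(round(overlap_fraction * n_puncta))
    margin = int(math.ceil(radius_red)) + 2
    min_sep = 2 * (radius_red + radius_green)
    # green centers plus standalone red centers, all mutually separated
    all_centers = _place_centers(rng, 2 * n_puncta - n_ov, size_px, margin, min_sep)
    green_centers = all_centers[:n_puncta]
    red_centers = np.vstack([green_centers[:n_ov], all_centers[n_puncta:]])

    green_mask = _disk_mask(size_px, green_centers, radius_green)
    red_mask = _disk_mask(size_px, red_centers, radius_red)

    def render(mask):
        img = np.full((size_px, size_px), background)
        img[mask] = intensity
        img += rng.normal(0.0, noise_sd, img.shape)
        return np.clip(img, 0.0, None)

    green = render(green_mask)
    red = render(red_mask)
    truth = {
        "green_mask": green_mask,
        "red_mask": red_mask,
        "green_centers": green_centers,
        "red_centers": red_centers,
        "n_overlapping": n_ov,
        "overlap_fraction": n_ov / n_puncta,
    }
    return green, red, truth


def simulate_fiber_image(
    shape: tuple = (200, 400),
    anterior_density: float = 0.02,
    posterior_factor: float = 3.0,
    seed: int = 0,
    intensity: float = 180.0,
    background: float = 20.0,
    noise_sd: float = 5.0,
) -> tuple[np.ndarray, dict]:
    """Single-channel axon-fiber image with a density gradient.

    The left half stands in for the anterior region, the right half for
    the posterior; posterior fiber-pixel density is
    ``posterior_factor`` times the anterior density.  Fibers are short
    bright strokes on a dim background.  Returns the image and a truth
    dict with region masks and true per-region fiber-pixel counts.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    half = w // 2
    fiber = np.zeros(shape, dtype=bool)

    def sprinkle(x0, x1, density):
        area = h * (x1 - x0)
        n_strokes = rng.poisson(density * area / 8.0)  # ~8 px per stroke
        for _ in range(n_strokes):
            y = rng.integers(2, h - 2)
            x = rng.integers(x0 + 2, x1 - 2)
            dy, dx = rng.choice([-1, 0, 1]), rng.choice([-1, 0, 1])
            for k in range(8):
                yy = int(np.clip(y + k * dy * 0.5, 0, h - 1))
                xx = int(np.clip(x + k * dx * 0.5, x0, x1 - 1))
                fiber[yy, xx] = True

    sprinkle(0, half, anterior_density)
    sprinkle(half, w, anterior_density * posterior_factor)

    img = np.full(shape, background)
    img[fiber] = intensity
    img += rng.normal(0.0, noise_sd, shape)
    img = np.clip(img, 0.0, None)
    anterior_mask = np.zeros(shape, dtype=bool)
    anterior_mask[:, :half] = True
    truth = {
        "fiber_mask": fiber,
        "anterior_mask": anterior_mask,
        "posterior_mask": ~anterior_mask,
        "anterior_count": int(fiber[:, :half].sum()),
        "posterior_count": int(fiber[:, half:].sum()),
    }
    return img, truth
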