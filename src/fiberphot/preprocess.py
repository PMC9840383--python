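"""Raw two-channel trace → motion-corrected ΔF/F0.

The correction exploits the isosbestic property of the 405 nm excitation
wavelength: the control channel carries motion artifacts, photobleaching
and other ligand-independent fluctuations, but no sensor signal.  The
processing chain is

1. zero-phase low-pass filter (default 3 Hz) on both channels,
2. ordinary least-squares scaling of the 405 nm channel onto the 465 nm
   channel (fitted405 = slope·f405 + intercept),
3. ΔF/F0 = (f465 − fitted405) / fitted405.

Whatever the shared artifact does to both channels is absorbed by the
fitted control and divides out of the fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

__all__ = [
    "PhotometryTrace",
    "IsosbesticFit",
    "ProcessedTrace",
    "lowpass_filter",
    "fit_isosbestic",
    "compute_dff",
    "preprocess_session",
]

#: relative tolerance on the median sampling interval (fraction of 1/rate)
_DT_RTOL = 0.01


@dataclass(frozen=True)
class PhotometryTrace:
    """A uniformly sampled two-channel photometry recording.

    Attributes
    ----------
    time_s : np.ndarray
        Sample times in seconds, strictly increasing, uniform.
    f465 : np.ndarray
        Signal channel (465 nm excitation) in volts.
    f405 : np.ndarray
        Isosbestic control channel (405 nm excitation) in volts.
    rate_hz : float
        Nominal sampling rate in samples/s.
    animal_id, session_id : str
        Free-form identifiers carried through the pipeline.
    """

    time_s: np.ndarray
    f465: np.ndarray
    f405: np.ndarray
    rate_hz: float
    animal_id: str = ""
    session_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        a = np.asarray(self.f465, dtype=float)
        b = np.asarray(self.f405, dtype=float)
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "f465", a)
        object.__setattr__(self, "f405", b)
        if not (len(t) == len(a) == len(b)):
            raise ValueError(
                f"channel length mismatch: time={len(t)}, f465={len(a)}, f405={len(b)}"
            )
        if len(t) < 2:
            raise ValueError("trace must contain at least 2 samples")
        if np.any(~np.isfinite(t)) or np.any(~np.isfinite(a)) or np.any(~np.isfinite(b)):
            raise ValueError("trace contains non-finite samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("time_s must be strictly increasing")
        expected = 1.0 / self.rate_hz
        if abs(np.median(dt) - expected) > _DT_RTOL * expected:
            raise ValueError(
                f"median sampling interval {np.median(dt):.6g} s deviates from "
                f"1/rate_hz = {expected:.6g} s by more than {_DT_RTOL:.0%}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.time_s)

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0]) + 1.0 / self.rate_hz

    def is_uniform(self, rtol: float = _DT_RTOL) -> bool:
        dt = np.diff(self.time_s)
        expected = 1.0 / self.rate_hz
        return bool(np.all(np.abs(dt - expected) <= rtol * expected))


@dataclass(frozen=True)
class IsosbesticFit:
    """OLS scaling of the control channel onto the signal channel."""

    slope: float
    intercept: float
    fitted405: np.ndarray
    sse: float


@dataclass(frozen=True)
class ProcessedTrace:
    """Motion-corrected ΔF/F0 series with the fit that produced it."""

    time_s: np.ndarray
    dff: np.ndarray
    fit: IsosbesticFit
    filter_cutoff_hz: float
    rate_hz: float
    animal_id: str = ""
    session_id: str = ""


def lowpass_filter(trace: PhotometryTrace, cutoff_hz: float = 3.0) -> PhotometryTrace:
    """Zero-phase low-pass filter both channels of a trace.

    A 2nd-order Butterworth filter is applied forward and backward
    (``scipy.signal.filtfilt``), giving unit DC gain and zero phase
    delay so event-onset latencies are preserved.

    Raises
    ------
    ValueError
        If the cutoff is at or above Nyquist, not positive, or the
        sampling is not uniform.
    """
    nyquist = trace.rate_hz / 2.0
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyquist:g}) Hz"
        )
    if not trace.is_uniform():
        raise ValueError("lowpass_filter requires uniform sampling")
    b, a = signal.butter(2, cutoff_hz / nyquist, btype="low")
    return replace(
        trace,
        f465=signal.filtfilt(b, a, trace.f465),
        f405=signal.filtfilt(b, a, trace.f405),
    )


def fit_isosbestic(f405: np.ndarray, f465: np.ndarray) -> IsosbesticFit:
    """Least-squares scale of the 405 nm channel to the 465 nm channel.

    Solves ``argmin_(slope, intercept) Σ (f465 − slope·f405 − intercept)²``
    by the normal equations.

    Raises
    ------
    ValueError
        On length mismatch, fewer than 3 samples, or a flat control
        channel (degenerate design).
    """
    x = np.asarray(f405, dtype=float)
    y = np.asarray(f465, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: f405 has {x.size}, f465 has {y.size}")
    if x.size < 2:
        raise ValueError("need at least 2 samples to fit")
    if np.ptp(x) == 0:
        raise ValueError("flat control channel: f405 is constant, scaling undefined")
    design = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = slope * x + intercept
    sse = float(np.sum((y - fitted) ** 2))
    return IsosbesticFit(float(slope), float(intercept), fitted, sse)


def compute_dff(
    f465: np.ndarray,
    fitted405: np.ndarray,
    eps_rel: float = 1e-6,
) -> np.ndarray:
    """ΔF/F0 = (f465 − fitted405) / fitted405, elementwise.

    The denominator must stay bounded away from zero: every sample of
    ``|fitted405|`` must exceed ``eps_rel`` times the median of
    ``|fitted405|``.
    """
    y = np.asarray(f465, dtype=float)
    f0 = np.asarray(fitted405, dtype=float)
    if y.shape != f0.shape:
        raise ValueError("f465 and fitted405 must have equal length")
    eps = eps_rel * np.median(np.abs(f0))
    bad = np.abs(f0) <= eps
    if np.any(bad):
        i = int(np.argmax(bad))
        raise ValueError(
            f"fitted405 too close to zero at sample {i} "
            f"(|{f0[i]:.3g}| <= eps={eps:.3g}); ΔF/F0 undefined"
        )
    return (y - f0) / f0


def preprocess_session(
    trace: PhotometryTrace,
    cutoff_hz: float = 3.0,
    eps_rel: float = 1e-6,
) -> ProcessedTrace:
    """Full preprocessing: filter → isosbestic fit → ΔF/F0.

    The regression is computed once over the entire recording (a single
    scaling of the whole session, not per-epoch).
    """
    filtered = lowpass_filter(trace, cutoff_hz)
    fit = fit_isosbestic(filtered.f405, filtered.f465)
    dff = compute_dff(filtered.f465, fit.fitted405, eps_rel=eps_rel)
    return ProcessedTrace(
        time_s=trace.time_s,
        dff=dff,
        fit=fit,
        filter_cutoff_hz=cutoff_hz,
        rate_hz=trace.rate_hz,
        animal_id=trace.animal_id,
        session_id=trace.session_id,
    )
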