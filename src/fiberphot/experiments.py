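"""Replicate simulation batteries under the reference conditions.

Each function here runs one of the package's headline validation
experiments end to end — simulate, preprocess, align, test — and
returns summary numbers.  They are used both by the test suite and by
``scripts/acceptance.py``, so the quantities reported anywhere are
always recomputed from scratch by the same code path.

Problem sizes follow the reference recording conditions (5 min
sessions at 240 Hz, 10-animal cohorts); replicate counts are chosen so
each battery completes in minutes on one core.
"""

from __future__ import annotations

import numpy as np

from fiberphot.pipeline import (
    BASELINE_BIN,
    PipelineConfig,
    analyze_oneway,
    cohort_bin_design,
    cohort_event_vs_random,
    session_bin_table,
)
from fiberphot.preprocess import lowpass_filter, preprocess_session
from fiberphot.stats import rm_anova_oneway
from fiberphot.synthetic import (
    BehaviorSpec,
    SimParams,
    simulate_coloc_images,
    simulate_fiber_image,
    simulate_session,
)
from fiberphot.imaging import (
    auto_threshold,
    manders_coefficients,
    place_random_rois,
    roi_fiber_pixel_count,
)

__all__ = [
    "isosbestic_correction_ratio",
    "novel_day_battery",
    "null_rejection_rate",
    "signal_vs_random_battery",
    "familiar_random_null_battery",
    "epm_sign_battery",
    "manders_recovery",
    "fiber_region_battery",
]

#: cohort seeds are spaced so per-animal seeds (seed + index) never overlap
COHORT_SEED_STRIDE = 1000


def isosbestic_correction_ratio(seed: int = 0) -> float:
    """RMS(ΔF/F0) / RMS(mean-normalized 465) on a motion-only session.

    The session carries a shared motion artifact with SD five times the
    default transient amplitude (in volts) and no transients at all, so
    everything left in ΔF/F0 after the isosbestic correction is
    uncorrected nuisance.  Small is good.
    """
    defaults = SimParams()
    params = SimParams(
        transient_amp=0.0, spont_amp=0.0,
        motion_sd=5.0 * defaults.transient_amp * defaults.baseline_465,
    )
    trace, _, _ = simulate_session(params, BehaviorSpec(), seed=seed)
    proc = preprocess_session(trace)
    raw465 = lowpass_filter(trace, proc.filter_cutoff_hz).f465
    raw = (raw465 - raw465.mean()) / raw465.mean()
    rms = lambda v: float(np.sqrt(np.mean(np.square(v))))
    return rms(proc.dff) / rms(raw)


def novel_day_battery(
    n_cohorts: int = 20,
    n_animals: int = 10,
    seed: int = 0,
) -> dict:
    """Novel-day recovery: omnibus + Dunnett detection over cohorts.

    Each cohort gets event-locked transients at the default amplitude
    (peri-event z ≈ 2).  Returns the fraction of cohorts where the
    one-way RM ANOVA rejects at α=0.05 AND at least one post-onset bin
    is Dunnett-significant, plus the grand-mean peak z.
    """
    from fiberphot.synthetic import simulate_cohort

    config = PipelineConfig()
    detected = 0
    peaks = []
    for c in range(n_cohorts):
        sessions = simulate_cohort(
            n_animals, SimParams(), BehaviorSpec(), day="novel",
            seed=seed + c * COHORT_SEED_STRIDE)
        summary = cohort_bin_design(sessions, config, label="social_novel")
        res = analyze_oneway(summary, alpha=config.alpha, seed=seed + c)
        omnibus = res["anova"].p < config.alpha
        dunnett = any(k.p_adjusted < config.alpha for k in res["contrasts"])
        detected += omnibus and dunnett
        X, bins = res["design"], res["bins"]
        peaks.append(X[:, [b != BASELINE_BIN for b in bins]].mean(axis=0).max())
    return {
        "detection_rate": detected / n_cohorts,
        "mean_peak_bin_z": float(np.mean(peaks)),
        "n_cohorts": n_cohorts,
    }


def null_rejection_rate(
    n_cohorts: int = 500,
    n_animals: int = 10,
    seed: int = 0,
) -> dict:
    """Familiar-day type-I error of the omnibus RM ANOVA.

    Cohorts with habituated (zero) event-locked amplitude but intact
    spontaneous transients; the rejection rate at α=0.05 should sit
    near the nominal level.
    """
    from fiberphot.synthetic import simulate_cohort

    config = PipelineConfig()
    rejections = 0
    for c in range(n_cohorts):
        sessions = simulate_cohort(
            n_animals, SimParams(), BehaviorSpec(), day="familiar",
            seed=seed + c * COHORT_SEED_STRIDE)
        summary = cohort_bin_design(sessions, config, label="social_familiar")
        X = summary[[b for b in summary.columns if b.startswith("[")]].to_numpy()
        rejections += rm_anova_oneway(X).p < config.alpha
    return {"rejection_rate": rejections / n_cohorts, "n_cohorts": n_cohorts}


def signal_vs_random_battery(
    n_cohorts: int = 20,
    n_animals: int = 10,
    seed: int = 0,
) -> dict:
    """Novel-day time × (signal vs random) interaction detection."""
    from fiberphot.synthetic import simulate_cohort

    config = PipelineConfig()
    detected = 0
    for c in range(n_cohorts):
        base = seed + c * COHORT_SEED_STRIDE
        sessions = simulate_cohort(
            n_animals, SimParams(), BehaviorSpec(), day="novel", seed=base)
        res = cohort_event_vs_random(sessions, config, label="social_novel",
                                     seed=base + 500)
        detected += res["anova"].p < config.alpha
    return {"detection_rate": detected / n_cohorts, "n_cohorts": n_cohorts}


def familiar_random_null_battery(
    n_cohorts: int = 20,
    n_animals: int = 10,
    seed: int = 0,
) -> dict:
    """Random-timestamp calibration on habituated (null) cohorts.

    Returns the grand mean z of the random-stamp event window per
    cohort; these should hover near zero.
    """
    from fiberphot.synthetic import simulate_cohort

    config = PipelineConfig()
    means = []
    for c in range(n_cohorts):
        base = seed + c * COHORT_SEED_STRIDE
        sessions = simulate_cohort(
            n_animals, SimParams(), BehaviorSpec(), day="familiar", seed=base)
        res = cohort_event_vs_random(sessions, config,
                                     label="social_familiar", seed=base + 500)
        means.append(float(np.mean(res["random_event_mean_z"])))
    return {
        "random_event_mean_z": means,
        "max_abs_mean_z": float(np.max(np.abs(means))),
        "n_cohorts": n_cohorts,
    }


def epm_sign_battery(
    n_seeds: int = 20,
    n_animals: int = 10,
    seed: int = 0,
) -> dict:
    """Bidirectional EPM responses: sign recovery per replicate cohort.

    Open-arm entries inject positive transients, closed-arm entries
    negative ones.  For each replicate the cohort-mean z of the [0,1)
    and [1,2) s bins must be positive for open entries and negative for
    closed entries.
    """
    config = PipelineConfig()
    behavior = BehaviorSpec(paradigm="epm", n_open_entries=5,
                            n_closed_entries=5)
    from fiberphot.synthetic import simulate_cohort

    correct = 0
    for c in range(n_seeds):
        sessions = simulate_cohort(
            n_animals, SimParams(), behavior, day="novel",
            seed=seed + c * COHORT_SEED_STRIDE)
        ok = True
        for label, sign in (("open_arm_entry", 1.0), ("closed_arm_entry", -1.0)):
            summary = cohort_bin_design(sessions, config, label=label)
            for b in ("[0,1)", "[1,2)"):
                ok &= sign * summary[b].mean() > 0
        correct += ok
    return {"sign_recovery_rate": correct / n_seeds, "n_seeds": n_seeds}


def manders_recovery(
    fractions: tuple = (0.0, 0.25, 0.5, 0.75, 1.0),
    seed: int = 0,
) -> dict:
    """M1 vs the constructed overlap fraction on punctum image pairs."""
    errors = {}
    for f in fractions:
        green, red, truth = simulate_coloc_images(
            256, 60, overlap_fraction=f, seed=seed)
        res = manders_coefficients(green, red)
        errors[f] = abs(res.m1 - truth["overlap_fraction"])
    return {
        "abs_error_by_fraction": errors,
        "max_abs_error": max(errors.values()),
    }


def fiber_region_battery(n_seeds: int = 5, seed: int = 0) -> dict:
    """Posterior-vs-anterior ordering on density-graded fiber images."""
    px = 0.001
    recovered = 0
    for s in range(n_seeds):
        img, truth = simulate_fiber_image(seed=seed + s, posterior_factor=3.0)
        thr = auto_threshold(img)
        kw = dict(extent_mm=(0.03, 0.04), pixel_size_mm=px)
        ant = place_random_rois(img.shape, truth["anterior_mask"], 6,
                                seed=seed + s, label="ant", **kw)
        post = place_random_rois(img.shape, truth["posterior_mask"], 6,
                                 seed=seed + s + 100, label="post", **kw)
        ca = roi_fiber_pixel_count(img, thr, ant, pixel_size_mm=px)
        cp = roi_fiber_pixel_count(img, thr, post, pixel_size_mm=px)
        recovered += sum(cp) > sum(ca)
    return {"ordering_recovery_rate": recovered / n_seeds, "n_seeds": n_seeds}
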