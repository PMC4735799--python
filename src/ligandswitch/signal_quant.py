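"""Quantification of phospho-signal time courses from densitometry.

Blot intensities are relative, so every analysis starts by normalizing to a
declared reference band (e.g. pERK in EGF-cultured cells at 10 min).  The
summary statistic is the integrated signal strength: the trapezoidal area
under the normalized curve over a stated window (0-60 min for the immediate
response, 0-310 min when delayed re-activation matters), computed per
replicate and summarized as mean +/- SD.  ERK re-activation onset is detected
as the first sustained rise after the post-peak trough.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "Replicate",
    "TimeCourseData",
    "SignalSummary",
    "OnsetResult",
    "InvalidReferenceError",
    "InsufficientCoverageError",
    "UndefinedRatioError",
    "WindowMismatchError",
    "normalize_timecourse",
    "integrated_signal",
    "fold_change",
    "reactivation_onset",
]


class InvalidReferenceError(ValueError):
    """Reference band missing from the dataset or has zero intensity."""


class InsufficientCoverageError(ValueError):
    """Sampling does not cover the requested integration window."""


class UndefinedRatioError(ZeroDivisionError):
    """Fold change against a zero-area denominator."""


class WindowMismatchError(ValueError):
    """Fold change between summaries computed over different windows."""


@dataclass(frozen=True)
class Replicate:
    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(
            self, "intensities", np.asarray(self.intensities, dtype=float)
        )
        if self.times.shape != self.intensities.shape or self.times.ndim != 1:
            raise ValueError("times and intensities must be matching 1-D arrays")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be >= 0")


@dataclass(frozen=True)
class TimeCourseData:
    """Replicated densitometry of one (condition, target), e.g. A-cell pERK."""

    condition: str
    target: str
    replicates: tuple[Replicate, ...]
    normalized: bool = False
    reference: tuple[str, str, float] | None = None  # (condition, target, time)

    def __post_init__(self):
        object.__setattr__(self, "replicates", tuple(self.replicates))
        if not self.replicates:
            raise ValueError("at least one replicate required")

    def mean_curve(self) -> tuple[np.ndarray, np.ndarray]:
        """Replicate-mean signal; replicates must share one time grid."""
        t0 = self.replicates[0].times
        for r in self.replicates[1:]:
            if r.times.shape != t0.shape or not np.allclose(r.times, t0):
                raise ValueError("replicates are on different time grids")
        y = np.mean([r.intensities for r in self.replicates], axis=0)
        return t0, y


@dataclass(frozen=True)
class SignalSummary:
    """Integrated signal strength over a window, mean +/- SD of replicates."""

    auc: float  # replicate mean, normalized-intensity * minutes
    auc_sd: float
    window: tuple[float, float]
    n_replicates: int
    per_replicate: tuple[float, ...] = ()

    def __post_init__(self):
        if not self.window[0] < self.window[1]:
            raise ValueError("window start must precede end")


@dataclass(frozen=True)
class OnsetResult:
    """Re-activation onset time, or None with a reason code."""

    onset_min: float | None
    reason: str | None = None


def _reference_value(tc: TimeCourseData, time: float, rep_index: int) -> float:
    """Replicate-matched reference intensity, falling back to replicate mean."""
    if rep_index < len(tc.replicates):
        r = tc.replicates[rep_index]
        idx = np.where(np.isclose(r.times, time))[0]
        if idx.size:
            return float(r.intensities[idx[0]])
    vals = []
    for r in tc.replicates:
        idx = np.where(np.isclose(r.times, time))[0]
        if idx.size:
            vals.append(float(r.intensities[idx[0]]))
    if not vals:
        raise InvalidReferenceError(
            f"time {time} not sampled in reference ({tc.condition}, {tc.target})"
        )
    return float(np.mean(vals))


def normalize_timecourse(
    tc: TimeCourseData,
    reference: tuple[str, str, float],
    reference_data: TimeCourseData | None = None,
) -> TimeCourseData:
    """Divide every intensity by the reference band.

    ``reference`` is (condition, target, time); the band is looked up in
    ``reference_data`` (default: ``tc`` itself), replicate-matched when the
    replicate structure lines up, otherwise by replicate mean.  Already
    normalized data pass through unchanged (idempotence).
    """
    if tc.normalized:
        return tc
    cond, target, time = reference
    ref_tc = reference_data if reference_data is not None else tc
    if ref_tc.condition != cond or ref_tc.target != target:
        raise InvalidReferenceError(
            f"reference ({cond}, {target}) not found; got "
            f"({ref_tc.condition}, {ref_tc.target})"
        )
    matched = len(ref_tc.replicates) == len(tc.replicates)
    new_reps = []
    for i, r in enumerate(tc.replicates):
        ref = _reference_value(ref_tc, time, i if matched else len(ref_tc.replicates))
        if ref <= 0:
            raise InvalidReferenceError("reference intensity must be > 0")
        new_reps.append(Replicate(r.times, r.intensities / ref))
    return replace(
        tc, replicates=tuple(new_reps), normalized=True, reference=reference
    )


def _trapz_window(times: np.ndarray, y: np.ndarray,
                  window: tuple[float, float]) -> float:
    start, end = window
    if times[0] > start or times[-1] < end:
        raise InsufficientCoverageError(
            f"sampling [{times[0]}, {times[-1]}] does not cover [{start}, {end}]"
        )
    grid = np.unique(np.concatenate([[start, end], times]))
    grid = grid[(grid >= start) & (grid <= end)]
    vals = np.interp(grid, times, y)
    return float(np.trapezoid(vals, grid))


def integrated_signal(tc: TimeCourseData,
                      window: tuple[float, float]) -> SignalSummary:
    """Per-replicate trapezoidal AUC over ``window``, then mean/SD.

    Sampling beyond the window edges is linearly interpolated to the edges;
    integrating per replicate before averaging preserves replicate variance.
    """
    if not tc.normalized:
        raise ValueError("normalize the time course before integrating")
    start, end = float(window[0]), float(window[1])
    if not start < end:
        raise ValueError("window start must precede end")
    aucs = []
    for r in tc.replicates:
        if r.times.size < 2:
            raise InsufficientCoverageError("replicate has fewer than 2 points")
        aucs.append(_trapz_window(r.times, r.intensities, (start, end)))
    aucs = np.array(aucs)
    sd = float(np.std(aucs, ddof=1)) if aucs.size > 1 else 0.0
    return SignalSummary(
        auc=float(np.mean(aucs)),
        auc_sd=sd,
        window=(start, end),
        n_replicates=aucs.size,
        per_replicate=tuple(float(a) for a in aucs),
    )


def fold_change(a: SignalSummary, b: SignalSummary) -> float:
    """Ratio of integrated signal strengths a/b over matching windows."""
    if a.window != b.window:
        raise WindowMismatchError(f"windows differ: {a.window} vs {b.window}")
    if b.auc == 0:
        raise UndefinedRatioError("denominator integrated signal is zero")
    return a.auc / b.auc


def reactivation_onset(
    tc: TimeCourseData, rise_fraction: float = 0.2
) -> OnsetResult:
    """Detect delayed re-activation after the initial transient.

    On the replicate-mean curve: locate the global peak, then the subsequent
    trough (minimum after the peak).  Onset is the earliest post-trough time
    at which the signal strictly exceeds trough + rise_fraction*(peak -
    trough) and does not fall back below that level at the next sample.
    Returns None (with a reason code) for monotone or non-re-activating
    signals.
    """
    if not tc.normalized:
        raise ValueError("normalize the time course before onset detection")
    times, y = tc.mean_curve()
    if times.size < 5:
        raise ValueError("need >= 5 time points spanning an initial peak")
    peak = int(np.argmax(y))
    if peak == times.size - 1:
        return OnsetResult(None, reason="no-peak")
    trough = peak + int(np.argmin(y[peak:]))
    if trough == times.size - 1:
        return OnsetResult(None, reason="no-post-trough-samples")
    thresh = y[trough] + rise_fraction * (y[peak] - y[trough])
    for i in range(trough + 1, times.size):
        if y[i] > thresh and (i == times.size - 1 or y[i + 1] > thresh):
            return OnsetResult(float(times[i]))
    return OnsetResult(None, reason="no-sustained-rise")
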