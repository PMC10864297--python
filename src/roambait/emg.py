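"""Facial-EMG trial preprocessing: raw trace -> per-trial percent change.

The chain mirrors a standard psychophysiology pipeline for zygomaticus
(smiling) and corrugator (frowning) recordings sampled at 1000 S/s:

1. condition: 20 Hz high-pass, 50 Hz and 100 Hz notch (all 4th order,
   zero-phase), full-wave rectification, exponential smoothing with a
   25 ms time constant (a digital contour follower);
2. bin: mean amplitude per 1000 ms segment, over a 4 s pre-cue baseline
   window and the event window (60 s silent recall, or movie duration);
3. reject artifacts: within participant x muscle x session x condition
   (baselines: across conditions), any segment >= 3 sample SDs from the
   group mean becomes missing — a single pass with statistics computed
   once on the original bins;
4. exclude trials with more than 50% of event or baseline segments
   missing; and
5. standardize: percent change of each event segment from the baseline
   mean, averaged over the retained segments.

Windows are half-open ``[start, end)`` in whole seconds relative to cue
onset at t = 0; the baseline is ``[-4, 0)``.  The unstandardized event and
baseline bin means are kept alongside the percent change because the
manipulation checks run on the raw amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "RawTrace",
    "SegmentSeries",
    "TrialResponse",
    "condition_signal",
    "bin_segments",
    "reject_artifacts",
    "exclude_trial",
    "percent_change_response",
    "preprocess_trials",
]

RATE = 1000  # samples per second
SMOOTH_TAU_S = 0.025
Z_CUTOFF = 3.0
MISSING_FRACTION = 0.5  # "more than 50%" exclusion rule


@dataclass
class RawTrace:
    """One trial's raw EMG trace, aligned so cue onset is at t = 0.

    ``samples`` covers ``[-baseline_s, event_s)`` contiguously at ``rate``
    samples per second (so ``len(samples) == (baseline_s + event_s) * rate``).
    """

    samples: np.ndarray
    participant: str
    muscle: str  # zygomaticus | corrugator
    condition: str  # positive | negative | neutral
    trial_index: int
    session: int = 2
    baseline_s: int = 4
    event_s: int = 60
    rate: int = RATE

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        expected = (self.baseline_s + self.event_s) * self.rate
        if self.samples.size != expected:
            raise ValueError(
                f"trace has {self.samples.size} samples, expected {expected} "
                f"for {self.baseline_s}+{self.event_s} s at {self.rate} S/s"
            )


@dataclass
class SegmentSeries:
    """Per-second mean amplitudes with a missing mask."""

    bins: np.ndarray
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=float)
        if self.missing is None:
            self.missing = ~np.isfinite(self.bins)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.missing.shape != self.bins.shape:
            raise ValueError("missing mask must align with bins")

    @property
    def n_missing(self) -> int:
        return int(self.missing.sum())

    def values(self) -> np.ndarray:
        return self.bins[~self.missing]


@dataclass
class TrialResponse:
    """Standardized outcome of one trial (or the reason it was excluded)."""

    pct_change: float | None
    excluded: bool = False
    reason: str = ""


def _sos_chain(rate: int = RATE) -> np.ndarray:
    hp = signal.butter(4, 20.0, btype="highpass", fs=rate, output="sos")
    n50 = signal.butter(2, [48.0, 52.0], btype="bandstop", fs=rate, output="sos")
    n100 = signal.butter(2, [98.0, 102.0], btype="bandstop", fs=rate, output="sos")
    return np.vstack([hp, n50, n100])


def condition_signal(samples: np.ndarray, rate: int = RATE) -> np.ndarray:
    """Filter, rectify and smooth one raw trace.

    20 Hz high-pass plus 50/100 Hz notches (4th order, zero-phase), then
    full-wave rectification and a first-order exponential smoother with a
    25 ms time constant.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < rate:
        raise ValueError("need at least 1 s of samples for filter warm-up")
    filtered = signal.sosfiltfilt(_sos_chain(rate), x)
    rectified = np.abs(filtered)
    # RC smoother: y[k] = a*x[k] + (1-a)*y[k-1], a = 1 - exp(-dt/tau)
    alpha = 1.0 - np.exp(-1.0 / (rate * SMOOTH_TAU_S))
    smoothed = signal.lfilter([alpha], [1.0, -(1.0 - alpha)], rectified,
                              zi=[(1.0 - alpha) * rectified[0]])[0]
    return smoothed


def bin_segments(
    conditioned: np.ndarray,
    start_s: int,
    end_s: int,
    baseline_s: int = 4,
    rate: int = RATE,
) -> SegmentSeries:
    """Mean amplitude per 1000 ms segment over the window ``[start_s, end_s)``.

    The window is given in whole seconds relative to cue onset; the trace
    is assumed to start at ``-baseline_s``.  Segments containing any
    non-finite sample are marked missing.
    """
    if start_s != int(start_s) or end_s != int(end_s) or end_s <= start_s:
        raise ValueError("window boundaries must be whole seconds with end > start")
    x = np.asarray(conditioned, dtype=float)
    i0 = (int(start_s) + baseline_s) * rate
    i1 = (int(end_s) + baseline_s) * rate
    if i0 < 0 or i1 > x.size:
        raise ValueError("window lies outside the trace")
    seg = x[i0:i1].reshape(-1, rate)
    with np.errstate(invalid="ignore"):
        bins = seg.mean(axis=1)
    missing = ~np.isfinite(seg).all(axis=1)
    bins = np.where(missing, np.nan, bins)
    return SegmentSeries(bins=bins, missing=missing)


def reject_artifacts(series_group: list[SegmentSeries]) -> list[SegmentSeries]:
    """3-SD artifact rejection across a group of segment series.

    The group is all segments sharing participant x muscle x session x
    condition (event segments) or participant x muscle x session across
    conditions (baselines).  The mean and sample SD (ddof=1) are computed
    once on the original non-missing bins; bins with ``|z| >= 3`` become
    missing.  A single pass — statistics are never recomputed after
    removal.  If the group SD is 0 (all bins equal) nothing is rejected.
    """
    pooled = np.concatenate([s.values() for s in series_group]) if series_group else np.array([])
    if pooled.size < 2:
        return [SegmentSeries(s.bins.copy(), s.missing.copy()) for s in series_group]
    mean = pooled.mean()
    sd = pooled.std(ddof=1)
    out = []
    for s in series_group:
        missing = s.missing.copy()
        if sd > 0:
            with np.errstate(invalid="ignore"):
                z = np.abs(s.bins - mean) / sd
            missing |= np.nan_to_num(z, nan=0.0) >= Z_CUTOFF
        bins = np.where(missing, np.nan, s.bins)
        out.append(SegmentSeries(bins=bins, missing=missing))
    return out


def exclude_trial(event: SegmentSeries, baseline: SegmentSeries) -> tuple[bool, str]:
    """Strict more-than-50% missing rule, event and baseline independently."""
    if event.n_missing > MISSING_FRACTION * event.bins.size:
        return True, f"event: {event.n_missing}/{event.bins.size} segments missing"
    if baseline.n_missing > MISSING_FRACTION * baseline.bins.size:
        return True, f"baseline: {baseline.n_missing}/{baseline.bins.size} segments missing"
    return False, ""


def percent_change_response(event: SegmentSeries, baseline: SegmentSeries) -> TrialResponse:
    """Mean percent change of event segments from the baseline mean.

    Applies the trial-exclusion rule first; a zero baseline mean is a
    degenerate trial and is excluded rather than divided by.
    """
    excluded, reason = exclude_trial(event, baseline)
    if excluded:
        return TrialResponse(pct_change=None, excluded=True, reason=reason)
    base = baseline.values().mean()
    if np.isclose(base, 0.0):
        return TrialResponse(pct_change=None, excluded=True, reason="degenerate baseline")
    pct = 100.0 * (event.values() - base) / base
    return TrialResponse(pct_change=float(pct.mean()), excluded=False)


def preprocess_trials(traces: list[RawTrace]) -> pd.DataFrame:
    """Run the full chain over a set of trials and tabulate responses.

    Returns one row per trial with the standardized percent change, the
    unstandardized event/baseline bin means (the manipulation checks run on
    those), and the exclusion flag with its reason.
    """
    rows = []
    binned = []
    for t in traces:
        conditioned = condition_signal(t.samples, t.rate)
        event = bin_segments(conditioned, 0, t.event_s, t.baseline_s, t.rate)
        base = bin_segments(conditioned, -t.baseline_s, 0, t.baseline_s, t.rate)
        binned.append({"trace": t, "event": event, "baseline": base})

    frame = pd.DataFrame(
        {
            "participant": [b["trace"].participant for b in binned],
            "muscle": [b["trace"].muscle for b in binned],
            "session": [b["trace"].session for b in binned],
            "condition": [b["trace"].condition for b in binned],
        }
    )
    # event segments: grouped within condition; baselines: across conditions
    for _, idx in frame.groupby(["participant", "muscle", "session", "condition"]).groups.items():
        cleaned = reject_artifacts([binned[i]["event"] for i in idx])
        for i, s in zip(idx, cleaned):
            binned[i]["event"] = s
    for _, idx in frame.groupby(["participant", "muscle", "session"]).groups.items():
        cleaned = reject_artifacts([binned[i]["baseline"] for i in idx])
        for i, s in zip(idx, cleaned):
            binned[i]["baseline"] = s

    for b in binned:
        t, event, base = b["trace"], b["event"], b["baseline"]
        resp = percent_change_response(event, base)
        rows.append(
            {
                "participant": t.participant,
                "muscle": t.muscle,
                "session": t.session,
                "condition": t.condition,
                "trial_index": t.trial_index,
                "pct_change": resp.pct_change,
                "recall_mean": float(np.nanmean(event.bins)) if event.n_missing < event.bins.size else np.nan,
                "baseline_mean": float(np.nanmean(base.bins)) if base.n_missing < base.bins.size else np.nan,
                "n_event_missing": event.n_missing,
                "n_baseline_missing": base.n_missing,
                "excluded": resp.excluded,
                "exclusion_reason": resp.reason,
            }
        )
    return pd.DataFrame(rows)
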