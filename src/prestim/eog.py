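"""Saccade-onset detection from EOG and trial exclusion rules.

Traces are smoothed with a Savitzky-Golay filter (order 3, 31 samples) and
the saccade onset on each trial is taken as the time of the maximal absolute
first difference of the horizontal EOG after target onset.  Trials are then
excluded when the baseline contains a blink/fixation violation, the saccade
amplitude falls short of half the stimulus eccentricity, the saccade goes
away from a single target, the latency falls outside 75-500 ms, or no onset
could be determined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .synthetic import EOGTraces

__all__ = [
    "SaccadeEvent",
    "smooth_eog",
    "detect_saccade_onset",
    "detect_all_saccades",
    "apply_exclusions",
]

#: accepted saccade latency range, ms after target onset
LATENCY_RANGE = (75.0, 500.0)
#: onset search window, ms (detection is wider than the validity range so
#: late saccades are detected and then rejected on latency grounds)
SEARCH_WINDOW = (75.0, 700.0)
#: minimal saccade amplitude, as a fraction of stimulus eccentricity
MIN_AMPLITUDE = 0.5

EXCLUSION_REASONS = (
    "blink/fixation",
    "amplitude",
    "direction-error",
    "latency-range",
    "undetermined",
)


@dataclass
class SaccadeEvent:
    trial_id: int
    onset_ms: float  # nan when undetermined
    direction: str  # 'left' / 'right' / 'none'
    amplitude: float  # fraction of stimulus eccentricity
    undetermined: bool = False


def smooth_eog(trace: np.ndarray, order: int = 3, window: int = 31) -> np.ndarray:
    """Savitzky-Golay smoothing (local least-squares polynomial fit).

    Mirror padding preserves length and introduces no phase shift; a cubic
    signal passes through unchanged (away from the padded edges).
    """
    trace = np.asarray(trace, float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= order:
        raise ValueError("window must exceed the polynomial order")
    if trace.shape[-1] <= window:
        raise ValueError("trace shorter than the smoothing window")
    return savgol_filter(trace, window, order, axis=-1, mode="mirror")


def detect_saccade_onset(
    h_eog: np.ndarray,
    v_eog: np.ndarray,
    sfreq: float,
    t0: float,
    trial_id: int = 0,
    eccentricity: float = 1.0,
    noise_floor: float | None = None,
) -> SaccadeEvent:
    """Locate the saccade on one (already smoothed) trial.

    Onset = time of the maximal |first difference| of the horizontal EOG
    within the post-target search window; direction = sign of that
    difference; amplitude = |post-saccade plateau - pre-saccade plateau|
    relative to ``eccentricity``.  If the peak difference does not exceed
    ``noise_floor`` (default: 6x the robust SD of the baseline differential)
    the trial is flagged undetermined.  Ties go to the earliest sample.
    """
    h_eog = np.asarray(h_eog, float)
    times = t0 + np.arange(h_eog.size) / sfreq
    # the search window is clipped to the epoch, but the epoch must at least
    # cover the latency validity range
    if times[-1] < LATENCY_RANGE[1] / 1000.0 - 1.0 / sfreq:
        raise ValueError("signal must cover the post-target latency range")
    d = np.diff(h_eog)
    dt_times = times[:-1]

    if noise_floor is None:
        base = d[dt_times < 0]
        mad = np.median(np.abs(base - np.median(base))) if base.size else 0.0
        noise_floor = 6.0 * 1.4826 * mad

    in_win = (dt_times >= SEARCH_WINDOW[0] / 1000.0) & (
        dt_times <= SEARCH_WINDOW[1] / 1000.0
    )
    idx_win = np.flatnonzero(in_win)
    absd = np.abs(d[idx_win])
    i = idx_win[int(np.argmax(absd))]  # argmax returns the first (earliest) max
    if np.abs(d[i]) <= noise_floor:
        return SaccadeEvent(trial_id, np.nan, "none", 0.0, undetermined=True)

    onset_ms = dt_times[i] * 1000.0
    direction = "right" if d[i] > 0 else "left"

    def _plateau(lo_ms, hi_ms):
        sel = (times >= (onset_ms + lo_ms) / 1000.0) & (
            times <= (onset_ms + hi_ms) / 1000.0
        )
        return float(np.mean(h_eog[sel])) if sel.any() else float(h_eog[i])

    pre = _plateau(-150.0, -50.0)
    post = _plateau(50.0, 150.0)
    amplitude = abs(post - pre) / eccentricity
    return SaccadeEvent(trial_id, onset_ms, direction, amplitude)


def detect_all_saccades(
    eog: EOGTraces, table: pd.DataFrame, eccentricity: float = 1.0
) -> pd.DataFrame:
    """Smooth both EOG channels and detect one saccade event per trial."""
    h = smooth_eog(eog.h)
    v = smooth_eog(eog.v)
    events = []
    for row, trial_id in enumerate(table["trial_id"].to_numpy()):
        ev = detect_saccade_onset(
            h[row], v[row], eog.sfreq, eog.t0, trial_id=trial_id,
            eccentricity=eccentricity,
        )
        events.append(ev.__dict__)
    return pd.DataFrame(events)


def _blink_flags(eog: EOGTraces, baseline=(-1.0, 0.0), threshold_sd: float = 5.0):
    """Baseline blink/fixation violations on the vertical channel.

    A trial is flagged when its smoothed vertical EOG departs from the
    session median by more than ``threshold_sd`` robust (MAD-based) SDs of
    the pooled baseline.
    """
    v = smooth_eog(eog.v)
    times = eog.times()
    sel = (times >= baseline[0]) & (times <= baseline[1])
    base = v[:, sel]
    med = np.median(base)
    sd = 1.4826 * np.median(np.abs(base - med))
    if sd == 0:
        return np.zeros(v.shape[0], bool)
    return np.max(np.abs(base - med), axis=1) > threshold_sd * sd


def apply_exclusions(
    events: pd.DataFrame,
    table: pd.DataFrame,
    eog: EOGTraces | None = None,
    baseline_window=(-1.0, 0.0),
    blink_threshold_sd: float = 5.0,
):
    """Apply the trial-exclusion rules; returns (filtered table, report).

    The filtered table keeps only surviving trials (with the measured saccade
    latency in ``rt_measured``); the report is a DataFrame of per-trial
    reason codes plus per-reason counts and the overall excluded fraction in
    ``report.attrs``.  Applying the rules again to an already filtered table
    removes nothing (idempotence).
    """
    events = events.set_index("trial_id").loc[table["trial_id"].to_numpy()]
    n = len(table)
    reasons = [[] for _ in range(n)]

    if eog is not None:
        blink = _blink_flags(eog, baseline_window, blink_threshold_sd)
        # eog rows align with the *original* trial order
        row_of = {tid: i for i, tid in enumerate(range(eog.h.shape[0]))}
        for i, tid in enumerate(table["trial_id"].to_numpy()):
            if tid in row_of and blink[row_of[tid]]:
                reasons[i].append("blink/fixation")

    onset = events["onset_ms"].to_numpy()
    amp = events["amplitude"].to_numpy()
    direction = events["direction"].to_numpy()
    undet = events["undetermined"].to_numpy()
    cond = table["condition"].to_numpy()

    for i in range(n):
        if undet[i]:
            reasons[i].append("undetermined")
            continue
        if amp[i] < MIN_AMPLITUDE:
            reasons[i].append("amplitude")
        if cond[i] in ("left", "right") and direction[i] != cond[i]:
            reasons[i].append("direction-error")
        if not (LATENCY_RANGE[0] <= onset[i] <= LATENCY_RANGE[1]):
            reasons[i].append("latency-range")

    excluded = np.array([len(r) > 0 for r in reasons])
    report = pd.DataFrame(
        {
            "trial_id": table["trial_id"].to_numpy(),
            "excluded": excluded,
            "reasons": [";".join(r) for r in reasons],
        }
    )
    counts = {
        reason: int(sum(reason in r for r in reasons)) for reason in EXCLUSION_REASONS
    }
    report.attrs["reason_counts"] = counts
    report.attrs["fraction_excluded"] = float(excluded.mean())

    filtered = table.loc[~excluded].copy()
    filtered["rt_measured"] = onset[~excluded]
    return filtered, report
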