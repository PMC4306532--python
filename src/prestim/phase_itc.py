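"""Quintile-sorted inter-trial coherence (ITC) analysis of phase-RT coupling.

If the phase of ongoing oscillations influences upcoming reaction time,
trials with similar RTs should have more similar phases than randomly
grouped trials.  Trials are sorted by RT and split into quintiles; the mean
within-quintile ITC (modulus of the mean unit phasor) is compared against a
null distribution obtained by shuffling trials into quintiles (100 shuffles
by default), yielding a z-like t-value and a one-sided normal-tail p per
(frequency, time) cell.  ITC is amplitude blind: only the phase tensor
enters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "ITCResult",
    "split_quintiles",
    "compute_itc",
    "quintile_itc_test",
    "label_itc_contrast",
    "itc_clusters",
]

#: frequency range used for the phase analysis (Hz)
PHASE_FREQ_RANGE = (5.0, 35.0)


@dataclass
class ITCResult:
    observed: np.ndarray  # mean ITC per (freq, time)
    null_mean: np.ndarray
    null_sd: np.ndarray
    t: np.ndarray  # (observed - null mean) / null SD
    p: np.ndarray  # one-sided (greater coherence) normal-tail p
    n_shuffles: int
    seed: int | None = None
    freqs: np.ndarray | None = None
    times: np.ndarray | None = None


def split_quintiles(rt: np.ndarray) -> np.ndarray:
    """Quintile labels 1..5 by RT (stable sort; remainder goes to the first
    quintiles, one extra trial each)."""
    rt = np.asarray(rt, float)
    n = rt.size
    if n < 5:
        raise ValueError("need at least 5 trials to form quintiles")
    order = np.argsort(rt, kind="stable")
    base, extra = divmod(n, 5)
    sizes = base + (np.arange(5) < extra)
    labels = np.empty(n, int)
    start = 0
    for q, size in enumerate(sizes, start=1):
        labels[order[start : start + size]] = q
        start += size
    return labels


def compute_itc(phases: np.ndarray, group: np.ndarray | None = None) -> np.ndarray:
    """ITC (modulus of the mean unit phasor) over the group's trial axis.

    ``phases`` is (trials, ...); the result drops the trial axis and lies in
    [0, 1] (1 = identical phases, 0 = perfectly balanced phases).
    """
    phases = np.asarray(phases, float)
    if group is not None:
        phases = phases[group]
    if phases.shape[0] < 1:
        raise ValueError("empty trial group")
    return np.abs(np.exp(1j * phases).mean(axis=0))


def _group_mean_itc(phasors: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Mean over groups of within-group ITC; phasors is (trials, ...)."""
    out = None
    groups = np.unique(labels)
    for g in groups:
        itc = np.abs(phasors[labels == g].mean(axis=0))
        out = itc if out is None else out + itc
    return out / len(groups)


def _shuffle_null(phasors, labels, n_shuffles, rng):
    null = np.empty((n_shuffles,) + phasors.shape[1:])
    perm_labels = labels.copy()
    for s in range(n_shuffles):
        rng.shuffle(perm_labels)
        null[s] = _group_mean_itc(phasors, perm_labels)
    return null


def _itc_test(phases, labels, n_shuffles, seed, freqs=None, times=None) -> ITCResult:
    if n_shuffles < 2:
        raise ValueError("need at least 2 shuffles to estimate the null")
    phases = np.asarray(phases, float)
    phasors = np.exp(1j * phases)
    observed = _group_mean_itc(phasors, labels)
    rng = np.random.default_rng(seed)
    null = _shuffle_null(phasors, labels, n_shuffles, rng)
    mu = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (observed - mu) / sd
    t = np.where(sd > 0, t, 0.0)
    p = stats.norm.sf(t)  # one-sided: greater-than-chance coherence
    return ITCResult(
        observed=observed, null_mean=mu, null_sd=sd, t=t, p=p,
        n_shuffles=n_shuffles, seed=seed, freqs=freqs, times=times,
    )


def quintile_itc_test(
    phases: np.ndarray,
    rt: np.ndarray,
    n_shuffles: int = 100,
    seed: int | None = None,
    freqs=None,
    times=None,
) -> ITCResult:
    """Quintile ITC bootstrap: observed statistic = mean over RT quintiles of
    within-quintile ITC; null = the same with trials shuffled into quintiles.

    The t value standardizes the quintile-mean ITC by the shuffle null's mean
    and SD; p comes from the upper normal tail (the alternative is *greater*
    phase similarity within quintiles).
    """
    labels = split_quintiles(rt)
    return _itc_test(phases, labels, n_shuffles, seed, freqs, times)


def label_itc_contrast(
    phases: np.ndarray,
    labels: np.ndarray,
    n_shuffles: int = 100,
    seed: int | None = None,
    freqs=None,
    times=None,
) -> ITCResult:
    """Same machinery with arbitrary label groups (e.g. left/right choice)."""
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least two label groups")
    if counts.min() < 2:
        raise ValueError("need at least 2 trials per label group")
    return _itc_test(phases, labels, n_shuffles, seed, freqs, times)


def itc_clusters(
    result: ITCResult,
    alpha: float = 0.05,
    min_freqs: int = 2,
    min_times: int = 2,
) -> pd.DataFrame:
    """Supra-threshold (freq, time) clusters of the ITC map.

    A cluster is a connected component of cells with p < alpha spanning at
    least ``min_freqs`` adjacent frequencies and ``min_times`` adjacent time
    bins.  Returns one row per cluster with its extent and minimal p.
    """
    mask = result.p < alpha
    labelled, n = ndimage.label(mask)
    rows = []
    for k in range(1, n + 1):
        fidx, tidx = np.nonzero(labelled == k)
        if np.ptp(fidx) + 1 < min_freqs or np.ptp(tidx) + 1 < min_times:
            continue
        rows.append(
            {
                "cluster": k,
                "n_cells": fidx.size,
                "freq_lo": result.freqs[fidx.min()] if result.freqs is not None else fidx.min(),
                "freq_hi": result.freqs[fidx.max()] if result.freqs is not None else fidx.max(),
                "time_lo": result.times[tidx.min()] if result.times is not None else tidx.min(),
                "time_hi": result.times[tidx.max()] if result.times is not None else tidx.max(),
                "min_p": float(result.p[fidx, tidx].min()),
                "max_t": float(result.t[fidx, tidx].max()),
            }
        )
    return pd.DataFrame(rows)
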