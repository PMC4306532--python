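"""Virtual-electrode time-frequency analysis.

A virtual electrode is a beamformer projection at a fixed anatomical
coordinate: its weights are built from a broadband (0-100 Hz) global
covariance, and the raw sensor signal is projected through them to a single
source time course per trial.  A Hilbert filter bank (Butterworth order 4,
centre +- 4 Hz, zero phase; analytic amplitude and phase; post-decimation by
2) yields per-trial time-frequency tensors, which are correlated trial-wise
with behavioural regressors in 50 ms bins, split into fast/slow RT halves,
or summarized as r-value time courses.

The default electrode set mirrors the visuo-oculomotor network: 20 sites
tiling left and right V1 plus SEF, left/right FEF and left/right IPS at
canonical MNI coordinates, mapped onto the spherical head model by a single
documented scale factor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from . import forward
from ._filters import bandpass
from .source_recon import BandWindow, pearson_columns, sam_weights, global_covariance
from .synthetic import SensorEpochs

__all__ = [
    "VirtualElectrode",
    "default_electrodes",
    "electrodes_to_json",
    "electrodes_from_json",
    "build_electrode_weights",
    "project_virtual_electrode",
    "TFTensor",
    "hilbert_tf",
    "TFMap",
    "tf_correlation",
    "fast_slow_spectrum",
    "r_timecourse_trend",
    "v1_amplitude_regressor",
]

#: broadband covariance band for electrode weights (Hz)
BROADBAND = (None, 100.0)

#: canonical MNI coordinates (mm) of the frontal/parietal electrodes
MNI_ELECTRODES = {
    "SEF": (0.0, -9.0, 70.5),
    "FEF-L": (-40.0, 0.0, 44.0),
    "FEF-R": (28.0, -6.0, 50.0),
    "IPS-L": (-30.0, -54.0, 52.0),
    "IPS-R": (36.0, -58.0, 58.0),
}


@dataclass
class VirtualElectrode:
    name: str
    position: np.ndarray  # head-frame mm

    def __post_init__(self):
        self.position = np.asarray(self.position, float).reshape(3)


def _v1_sites(side: str):
    """10 sites tiling V1 from central to peripheral representation.

    The calcarine strip is approximated as an arc running from the occipital
    pole anteriorly along the medial surface (MNI-like coordinates).
    """
    sign = -1.0 if side == "L" else 1.0
    frac = np.linspace(0.0, 1.0, 10)
    x = sign * (6.0 + 4.0 * frac)
    y = -95.0 + 25.0 * frac
    z = -2.0 + 12.0 * frac
    return [
        VirtualElectrode(f"V1-{side}-{i + 1:02d}", (x[i], y[i], z[i]))
        for i in range(10)
    ]


def default_electrodes(model: forward.SphereHeadModel, fill: float = 0.85):
    """20 V1 + SEF + FEF/IPS (left, right) electrodes inside the sphere.

    MNI-like coordinates are mapped into the spherical head model by one
    isotropic scale factor chosen so the outermost electrode sits at
    ``fill`` of the sphere radius.
    """
    elecs = _v1_sites("L") + _v1_sites("R")
    elecs += [VirtualElectrode(k, v) for k, v in MNI_ELECTRODES.items()]
    rmax = max(np.linalg.norm(e.position) for e in elecs)
    scale = fill * model.radius / rmax
    for e in elecs:
        e.position = model.center + scale * e.position
    return elecs


def electrodes_to_json(electrodes) -> str:
    return json.dumps(
        [{"name": e.name, "position": e.position.tolist()} for e in electrodes],
        indent=1,
    )


def electrodes_from_json(text: str):
    return [VirtualElectrode(**d) for d in json.loads(text)]


def build_electrode_weights(
    epochs: SensorEpochs,
    electrodes,
    model: forward.SphereHeadModel,
    window=None,
    regularization: float = 0.05,
):
    """Broadband (0-100 Hz) unit-gain weights at each electrode position."""
    window = window or (epochs.t0, epochs.t0 + epochs.data.shape[2] / epochs.sfreq)
    bw = BandWindow(band=(0.0, BROADBAND[1]), window=window)
    # BandWindow requires low < high; encode the low-pass as (0, 100)
    cov, _ = global_covariance(epochs, BandWindow(band=(1e-3, BROADBAND[1]), window=window))
    positions = np.array([e.position for e in electrodes])
    for e in electrodes:
        if not model.contains(e.position):
            raise forward.GeometryError(f"electrode {e.name} lies outside the head")
    return sam_weights(
        cov,
        model,
        positions,
        epochs.channel_positions,
        epochs.channel_orientations,
        bw=bw,
        regularization=regularization,
    )


def project_virtual_electrode(epochs: SensorEpochs, weights, index: int = 0):
    """(trials, T) source time course of one electrode (unfiltered signal)."""
    w = weights.weights[index]
    return np.einsum("c,tcs->ts", w, epochs.data)


@dataclass
class TFTensor:
    """Trials x freqs x time analytic amplitude and phase."""

    amplitude: np.ndarray
    phase: np.ndarray  # radians in (-pi, pi]
    freqs: np.ndarray  # Hz
    times: np.ndarray  # s relative to target onset
    sfreq: float  # effective (decimated) sampling rate


def hilbert_tf(
    signal: np.ndarray,
    sfreq: float,
    t0: float,
    freqs=None,
    half_bandwidth: float = 4.0,
    decimate: int = 2,
    pad: float = 1.0,
) -> TFTensor:
    """Hilbert filter-bank time-frequency decomposition of (trials, T) data.

    For each centre frequency the signal is zero-phase band-passed to
    ``f +- half_bandwidth`` (Butterworth order 4, mirror padding of ``pad``
    seconds), the analytic signal is computed, and amplitude/phase are
    subsampled by ``decimate`` (the narrow bands make further anti-aliasing
    unnecessary).
    """
    signal = np.atleast_2d(np.asarray(signal, float))
    if freqs is None:
        freqs = np.arange(5.0, 101.0)
    freqs = np.asarray(freqs, float)
    bad = freqs[sfreq < 2 * (freqs + half_bandwidth)]
    if bad.size:
        raise ValueError(
            f"sampling rate {sfreq} Hz too low for centre frequencies {bad}"
        )
    n_pad = int(round(pad * sfreq))
    n_pad = min(n_pad, signal.shape[1] - 1)
    padded = np.pad(signal, [(0, 0), (n_pad, n_pad)], mode="reflect")
    n_tr, n_samp = signal.shape
    keep = slice(n_pad, n_pad + n_samp)
    out_idx = np.arange(0, n_samp, decimate)
    amp = np.empty((n_tr, freqs.size, out_idx.size))
    ph = np.empty_like(amp)
    for k, f in enumerate(freqs):
        band = (max(f - half_bandwidth, 0.1), f + half_bandwidth)
        x = bandpass(padded, band, sfreq)
        analytic = hilbert(x, axis=-1)[:, keep][:, out_idx]
        amp[:, k] = np.abs(analytic)
        ph[:, k] = np.angle(analytic)
    times = t0 + out_idx / sfreq
    return TFTensor(
        amplitude=amp, phase=ph, freqs=freqs, times=times, sfreq=sfreq / decimate
    )


@dataclass
class TFMap:
    """Freqs x time-bin map of a statistic (r, t or p)."""

    values: np.ndarray  # (F, B)
    freqs: np.ndarray
    bin_centers: np.ndarray
    stat: str = "r"
    tag: str = ""


def bin_amplitude(tf: TFTensor, bin_width: float = 0.05, window=None):
    """Average the amplitude tensor into contiguous time bins.

    Returns ``(binned (trials, F, B), bin_centers)``.
    """
    t = tf.times
    lo = window[0] if window else t[0]
    hi = window[1] if window else t[-1]
    edges = np.arange(lo, hi + 1e-9, bin_width)
    if edges.size < 2:
        raise ValueError("window shorter than one bin")
    centers = edges[:-1] + bin_width / 2
    binned = np.empty(tf.amplitude.shape[:2] + (centers.size,))
    for b in range(centers.size):
        sel = (t >= edges[b]) & (t < edges[b + 1])
        binned[..., b] = tf.amplitude[..., sel].mean(-1)
    return binned, centers


def tf_correlation(
    tf: TFTensor,
    regressor: np.ndarray,
    bin_width: float = 0.05,
    window=None,
    tag: str = "",
) -> TFMap:
    """Trial-wise Pearson r between binned power and a regressor, per
    (frequency, 50 ms bin)."""
    binned, centers = bin_amplitude(tf, bin_width, window)
    n_tr, F, B = binned.shape
    r = pearson_columns(binned.reshape(n_tr, F * B), regressor).reshape(F, B)
    return TFMap(values=r, freqs=tf.freqs, bin_centers=centers, stat="r", tag=tag)


def average_tf_maps(maps) -> TFMap:
    """Electrode-averaged map: r-values (not amplitudes) are averaged."""
    vals = np.mean([m.values for m in maps], axis=0)
    m0 = maps[0]
    return TFMap(
        values=vals, freqs=m0.freqs, bin_centers=m0.bin_centers,
        stat=m0.stat, tag=f"mean({len(maps)})",
    )


def fast_slow_spectrum(
    tf: TFTensor,
    rt: np.ndarray,
    baseline=(-1.0, 0.0),
    norm_band=(5.0, 70.0),
    tc_norm_window=(-2.0, -1.0),
    bands=((5, 15), (15, 25), (25, 35)),
):
    """Fast/slow median-split power spectra and band time courses.

    Trials are split at the median RT (the median trial joins the fast half
    on odd counts).  Baseline power spectra per half are normalized by
    subtracting the all-trial mean power over ``norm_band``; band time
    courses are normalized to zero all-trial mean over ``tc_norm_window``.
    """
    rt = np.asarray(rt, float)
    order = np.argsort(rt, kind="stable")
    n = len(rt)
    n_fast = (n + 1) // 2
    fast = order[:n_fast]
    slow = order[n_fast:]
    if len(slow) < 2 or len(fast) < 2:
        raise ValueError("need at least 2 trials per half")
    power = tf.amplitude**2
    sel_t = (tf.times >= baseline[0]) & (tf.times <= baseline[1])
    spec_all = power[:, :, sel_t].mean((0, 2))
    in_band = (tf.freqs >= norm_band[0]) & (tf.freqs <= norm_band[1])
    offset = spec_all[in_band].mean()
    spectra = {
        "fast": power[fast][:, :, sel_t].mean((0, 2)) - offset,
        "slow": power[slow][:, :, sel_t].mean((0, 2)) - offset,
        "all": spec_all - offset,
    }
    sel_norm = (tf.times >= tc_norm_window[0]) & (tf.times <= tc_norm_window[1])
    timecourses = {}
    for lo, hi in bands:
        fsel = (tf.freqs >= lo) & (tf.freqs <= hi)
        tc_all = power[:, fsel].mean(1)
        base = tc_all[:, sel_norm].mean() if sel_norm.any() else tc_all.mean()
        timecourses[(lo, hi)] = {
            "fast": tc_all[fast].mean(0) - base,
            "slow": tc_all[slow].mean(0) - base,
        }
    return {
        "freqs": tf.freqs,
        "times": tf.times,
        "spectra": spectra,
        "timecourses": timecourses,
        "split": (fast, slow),
    }


def r_timecourse_trend(r_series: np.ndarray, times: np.ndarray, window=(-2.0, 0.0)):
    """Per-subject OLS slope of r over time, plus a group test against zero.

    ``r_series`` is (subjects, time points).  Returns ``(slopes, t, p)``.
    """
    from .group_stats import one_sample_group_test

    r_series = np.atleast_2d(np.asarray(r_series, float))
    times = np.asarray(times, float)
    sel = (times >= window[0]) & (times <= window[1])
    if sel.sum() < 3:
        raise ValueError("need at least 3 time points in the window")
    x = times[sel]
    slopes = np.polyfit(x, r_series[:, sel].T, 1)[0]
    t, p, _ = one_sample_group_test(slopes[:, None])
    return slopes, float(t[0]), float(p[0])


def v1_amplitude_regressor(
    tf_by_electrode: dict,
    band=(5.0, 15.0),
    window=(-1.0, 0.0),
    expected: int = 20,
) -> np.ndarray:
    """Per-trial mean V1 band amplitude across all 20 V1 electrodes.

    ``tf_by_electrode`` maps electrode name -> TFTensor; all names starting
    with ``V1-`` are used and all ``expected`` must be present.
    """
    names = sorted(k for k in tf_by_electrode if k.startswith("V1-"))
    if len(names) != expected:
        missing = expected - len(names)
        raise ValueError(
            f"expected {expected} V1 electrodes, got {len(names)} "
            f"({missing} missing); present: {names}"
        )
    per_elec = []
    for name in names:
        tf = tf_by_electrode[name]
        fsel = (tf.freqs >= band[0]) & (tf.freqs <= band[1])
        tsel = (tf.times >= window[0]) & (tf.times <= window[1])
        per_elec.append(tf.amplitude[:, fsel][:, :, tsel].mean((1, 2)))
    return np.mean(per_elec, axis=0)
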