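"""Synthetic MEG/behaviour generator with injected ground truth.

Emulates the structure of a saccadic reaction-time MEG experiment: a trial
schedule with a non-aging 3-4 s foreperiod and randomly interleaved
left/right/choice targets, reaction times composed of controlled
deterministic effects (inter-trial interval, condition history, blockwise
trends, a choice penalty) plus a spontaneous component coupled to the
baseline amplitude of band-limited dipole sources, multichannel sensor
epochs through the spherical forward model, and EOG traces containing the
scheduled saccades.  Every random quantity is driven by a single seed so a
configuration reproduces byte-identical data.

The generator exists so that each downstream analysis stage can be validated
against known injected parameters (coupling r, variance shares, saccade
latencies, artifact labels) rather than against unavailable recordings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import h5py
import numpy as np
import pandas as pd

from . import forward
from ._filters import bandpass, crop_window

__all__ = [
    "CONDITIONS",
    "SESSION_START",
    "ConfigurationError",
    "GroundTruthSource",
    "SimConfig",
    "SensorEpochs",
    "EOGTraces",
    "generate_trial_schedule",
    "generate_rt",
    "simulate_sensor_epochs",
    "simulate_eog",
    "inject_artifacts",
    "simulate_dataset",
    "save_meg_h5",
    "load_meg_h5",
]

CONDITIONS = ("left", "right", "choice")
#: previous-condition level for the first trial of each block/session
SESSION_START = "start"


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class GroundTruthSource:
    """A band-limited dipole source whose baseline amplitude may drive RT.

    Parameters
    ----------
    position : (3,) mm head frame; must lie inside the head sphere.
    orientation : (3,); only the tangential component radiates and is used.
    center_freq, bandwidth : Hz
        The source emits band-limited noise in ``center_freq +- bandwidth/2``.
    base_amplitude : source units (arbitrary, sets sensor-level SNR).
    rt_coupling_r : target Pearson correlation between the per-trial baseline
        band amplitude of this source and RT (amplitude coupling only; phase
        carries no RT information, so phase analyses see a true null).
    coupling_window : s relative to target onset over which the per-trial
        amplitude modulation is applied (and measured).
    amplitude_sigma : SD of the per-trial log-normal amplitude modulation.
    """

    position: tuple = (0.0, -60.0, 20.0)
    orientation: tuple = (1.0, 0.0, 0.0)
    center_freq: float = 10.0
    bandwidth: float = 4.0
    base_amplitude: float = 1.0
    rt_coupling_r: float = 0.0
    coupling_window: tuple = (-1.0, 0.0)
    amplitude_sigma: float = 0.5

    def __post_init__(self):
        if abs(self.rt_coupling_r) > 1:
            raise ConfigurationError("|rt_coupling_r| must be <= 1")
        if self.bandwidth <= 0:
            raise ConfigurationError("bandwidth must be positive")


@dataclass
class SimConfig:
    """Full description of one synthetic subject/session.

    Defaults mirror the emulated experiment: 800 trials in 4 blocks, equal
    thirds of left/right/choice targets, a non-aging foreperiod in [3, 4] s,
    grand-mean RT 262 ms with 48 ms spontaneous SD, 600 Hz sampling and a
    [-2.7, +0.7] s epoch.  ``n_channels`` defaults to a 30-sensor cap for
    desk-scale work; 272 reproduces a full whole-head array.
    """

    n_trials: int = 800
    n_blocks: int = 4
    condition_probs: tuple = (1 / 3, 1 / 3, 1 / 3)
    foreperiod_range: tuple = (3.0, 4.0)
    foreperiod_tau: float = 0.35  # hazard rate 1/tau of the truncated exponential
    rt_mean: float = 262.0
    rt_sd_spontaneous: float = 48.0
    iti_slope: float = 0.0  # ms per second of ITI
    condition_offsets: np.ndarray | None = None  # (3, 3) ms, current x previous
    block_trend_slopes: tuple | None = None  # ms per trial, one per block
    choice_penalty: float = 18.0  # ms added to choice trials
    choice_bias: float = 0.0  # added to P(left) = 0.5 on choice trials
    sfreq: float = 600.0
    epoch_window: tuple = (-2.7, 0.7)
    n_channels: int = 30
    head_radius: float = 90.0
    sensor_radius: float = 110.0
    source_specs: list = field(default_factory=list)
    sensor_noise_sd: float = 2e-4
    eog_noise_sd: float = 0.02
    eog_step_width: float = 0.008  # s, rise time constant of the saccade step
    seed: int = 0

    def __post_init__(self):
        probs = np.asarray(self.condition_probs, float)
        if probs.shape != (3,) or np.any(probs < 0) or abs(probs.sum() - 1) > 1e-9:
            raise ConfigurationError(
                "condition_probs must be 3 non-negative values summing to 1"
            )
        if self.n_trials % self.n_blocks:
            raise ConfigurationError("n_trials must divide into equal blocks")
        lo, hi = self.foreperiod_range
        if not (0 < lo < hi):
            raise ConfigurationError("foreperiod_range must satisfy 0 < lo < hi")
        if self.condition_offsets is not None:
            self.condition_offsets = np.asarray(self.condition_offsets, float)
            if self.condition_offsets.shape != (3, 3):
                raise ConfigurationError("condition_offsets must be 3x3 (current x previous)")
        if self.block_trend_slopes is not None and len(self.block_trend_slopes) != self.n_blocks:
            raise ConfigurationError("need one block trend slope per block")
        model = self.head_model()
        for src in self.source_specs:
            if not model.contains(src.position):
                raise forward.GeometryError(
                    f"source at {src.position} lies outside the head sphere"
                )

    def head_model(self) -> forward.SphereHeadModel:
        return forward.SphereHeadModel(radius=self.head_radius)

    def sensors(self):
        return forward.spherical_cap_sensors(self.n_channels, self.sensor_radius)

    def times(self) -> np.ndarray:
        n = int(round((self.epoch_window[1] - self.epoch_window[0]) * self.sfreq))
        return self.epoch_window[0] + np.arange(n) / self.sfreq

    def to_json(self) -> str:
        d = asdict(self)
        d["source_specs"] = [asdict(s) for s in self.source_specs]
        if isinstance(d.get("condition_offsets"), np.ndarray):
            d["condition_offsets"] = d["condition_offsets"].tolist()
        return json.dumps(d, indent=1, default=lambda o: np.asarray(o).tolist())

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        d = json.loads(text)
        d["source_specs"] = [GroundTruthSource(**s) for s in d.get("source_specs", [])]
        for key in ("condition_probs", "foreperiod_range", "epoch_window"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if d.get("block_trend_slopes") is not None:
            d["block_trend_slopes"] = tuple(d["block_trend_slopes"])
        return cls(**d)


@dataclass
class SensorEpochs:
    """Trials x channels x samples sensor data with epoch geometry."""

    data: np.ndarray
    sfreq: float
    t0: float
    channel_positions: np.ndarray
    channel_orientations: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.data.shape[2]) / self.sfreq


@dataclass
class EOGTraces:
    """Per-trial horizontal/vertical EOG, same clock as the MEG epochs."""

    h: np.ndarray  # trials x samples
    v: np.ndarray
    sfreq: float
    t0: float

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.h.shape[1]) / self.sfreq


# ---------------------------------------------------------------------------
# trial schedule and reaction times
# ---------------------------------------------------------------------------

def _truncated_exponential(rng, n, lo, hi, tau):
    """Non-aging (constant-hazard) foreperiod: exponential truncated to [lo, hi]."""
    u = rng.random(n)
    cmax = 1.0 - np.exp(-(hi - lo) / tau)
    return lo - tau * np.log1p(-u * cmax)


def generate_trial_schedule(config: SimConfig, rng=None) -> pd.DataFrame:
    """Draw the trial table (no RT yet).

    Conditions are i.i.d. from ``condition_probs``; the foreperiod/ITI has
    constant hazard on ``foreperiod_range``; blocks are contiguous and equal
    sized; the first trial of each block has ``prev_condition = 'start'``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_trials
    per_block = n // config.n_blocks
    cond_idx = rng.choice(3, size=n, p=np.asarray(config.condition_probs, float))
    condition = np.array(CONDITIONS, object)[cond_idx]
    block = np.repeat(np.arange(config.n_blocks), per_block)
    time_in_block = np.tile(np.arange(per_block), config.n_blocks)
    prev = np.empty(n, object)
    prev[1:] = condition[:-1]
    prev[time_in_block == 0] = SESSION_START
    iti = _truncated_exponential(
        rng, n, *config.foreperiod_range, config.foreperiod_tau
    )
    choice_made = np.full(n, "none", object)
    is_choice = condition == "choice"
    p_left = min(max(0.5 + config.choice_bias, 0.0), 1.0)
    choice_made[is_choice] = np.where(
        rng.random(is_choice.sum()) < p_left, "left", "right"
    )
    return pd.DataFrame(
        {
            "trial_id": np.arange(n),
            "block": block,
            "time_in_block": time_in_block,
            "condition": condition,
            "prev_condition": prev,
            "iti": iti,
            "choice_made": choice_made,
            "excluded": False,
            "reason": "",
        }
    )


def deterministic_rt_component(table: pd.DataFrame, config: SimConfig) -> np.ndarray:
    """Design-linked RT structure (ms, zero mean apart from the choice penalty)."""
    d = np.zeros(len(table))
    d += config.iti_slope * (table["iti"].to_numpy() - table["iti"].mean())
    if config.condition_offsets is not None:
        cur = pd.Categorical(table["condition"], categories=CONDITIONS).codes
        prev = pd.Categorical(table["prev_condition"], categories=CONDITIONS).codes
        valid = prev >= 0  # session-start rows take no history offset
        d[valid] += config.condition_offsets[cur[valid], prev[valid]]
    if config.block_trend_slopes is not None:
        tib = table["time_in_block"].to_numpy(float)
        tib = tib - tib.mean()
        slopes = np.asarray(config.block_trend_slopes, float)
        d += slopes[table["block"].to_numpy()] * tib
    d += config.choice_penalty * (table["condition"] == "choice").to_numpy(float)
    return d


def generate_rt(
    table: pd.DataFrame,
    config: SimConfig,
    latent_amplitude: np.ndarray | None = None,
    rng=None,
) -> pd.DataFrame:
    """Add an ``rt`` column: deterministic effects + amplitude coupling + noise.

    ``latent_amplitude`` holds one column per source (the per-trial baseline
    amplitudes returned by :func:`simulate_sensor_epochs`); each column is
    standardized and enters RT with a coefficient chosen so that the
    population correlation with RT equals that source's ``rt_coupling_r``.
    Trials drawing a non-positive RT are redrawn.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    table = table.copy()
    n = len(table)
    d = deterministic_rt_component(table, config)
    sigma = config.rt_sd_spontaneous
    var_other = np.var(d) + sigma**2

    coupling = np.zeros(n)
    if latent_amplitude is not None and len(config.source_specs):
        z = np.atleast_2d(np.asarray(latent_amplitude, float).T).T
        if z.shape != (n, len(config.source_specs)):
            raise ConfigurationError("latent_amplitude must be n_trials x n_sources")
        rs = np.array([s.rt_coupling_r for s in config.source_specs])
        r2 = float(np.sum(rs**2))
        if r2 >= 1:
            raise ConfigurationError(
                "requested coupling variance shares exceed total RT variance"
            )
        z = (z - z.mean(0)) / np.where(z.std(0) > 0, z.std(0), 1.0)
        coefs = rs * np.sqrt(var_other / (1.0 - r2))
        coupling = z @ coefs

    base = config.rt_mean + d + coupling
    rt = base + rng.normal(0.0, sigma, n)
    for _ in range(100):
        bad = rt <= 0
        if not bad.any():
            break
        rt[bad] = base[bad] + rng.normal(0.0, sigma, bad.sum())
    table["rt"] = rt
    return table


# ---------------------------------------------------------------------------
# sensor epochs
# ---------------------------------------------------------------------------

def _coupling_gate(times, window, ramp=0.1):
    """Smooth 0->1->0 gate over ``window`` with raised-cosine ramps."""
    lo, hi = window
    g = np.zeros_like(times)
    inside = (times >= lo) & (times <= hi)
    g[inside] = 1.0
    rise = (times > lo - ramp) & (times < lo)
    g[rise] = 0.5 * (1 + np.cos(np.pi * (times[rise] - lo) / ramp))
    fall = (times > hi) & (times < hi + ramp)
    g[fall] = 0.5 * (1 + np.cos(np.pi * (times[fall] - hi) / ramp))
    return g


def simulate_sensor_epochs(table: pd.DataFrame, config: SimConfig, rng=None):
    """Simulate sensor epochs; returns ``(SensorEpochs, true_amplitudes)``.

    Each ground-truth source emits independent band-limited noise per trial
    (unit RMS, scaled by ``base_amplitude``); within its coupling window the
    waveform is additionally scaled by a per-trial log-normal factor.  Fields
    reach the sensors through the spherical-conductor lead field and i.i.d.
    Gaussian sensor noise is added.  ``true_amplitudes`` (n_trials x
    n_sources) holds the realized RMS of each source over its coupling
    window — the ground truth that downstream amplitude estimates are
    compared against.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    n = len(table)
    times = config.times()
    n_samp = times.size
    sens_pos, sens_ori = config.sensors()
    model = config.head_model()

    data = np.zeros((n, config.n_channels, n_samp))
    true_amp = np.zeros((n, max(len(config.source_specs), 1)))

    for k, src in enumerate(config.source_specs):
        band = (
            max(src.center_freq - src.bandwidth / 2.0, 0.5),
            src.center_freq + src.bandwidth / 2.0,
        )
        wave = bandpass(rng.standard_normal((n, n_samp)), band, config.sfreq)
        wave /= np.sqrt(np.mean(wave**2, axis=1, keepdims=True))
        wave *= src.base_amplitude
        gate = _coupling_gate(times, src.coupling_window)
        gain = rng.lognormal(mean=0.0, sigma=src.amplitude_sigma, size=n)
        gain /= gain.mean()
        wave = wave * (1.0 + (gain[:, None] - 1.0) * gate[None, :])
        sl = crop_window(n_samp, config.epoch_window[0], config.sfreq, src.coupling_window)
        true_amp[:, k] = np.sqrt(np.mean(wave[:, sl] ** 2, axis=1))
        ori = forward.tangentialize(model, src.position, src.orientation)
        lf = forward.leadfield(model, src.position, ori, sens_pos, sens_ori)
        data += wave[:, None, :] * lf[None, :, None]

    if config.sensor_noise_sd > 0:
        data += rng.normal(0.0, config.sensor_noise_sd, data.shape)

    epochs = SensorEpochs(
        data=data,
        sfreq=config.sfreq,
        t0=config.epoch_window[0],
        channel_positions=sens_pos,
        channel_orientations=sens_ori,
    )
    if not config.source_specs:
        true_amp = np.zeros((n, 0))
    return epochs, true_amp


# ---------------------------------------------------------------------------
# EOG
# ---------------------------------------------------------------------------

def _saccade_direction(table: pd.DataFrame) -> np.ndarray:
    """-1 for leftward, +1 for rightward saccades (choice trials follow choice)."""
    cond = table["condition"].to_numpy()
    choice = table["choice_made"].to_numpy()
    target = np.where(cond == "choice", choice, cond)
    return np.where(target == "left", -1.0, 1.0)


def simulate_eog(table: pd.DataFrame, config: SimConfig, rng=None) -> EOGTraces:
    """Horizontal/vertical EOG traces with a sigmoidal saccade step at t = RT.

    The horizontal channel steps from 0 to +-1 (full stimulus eccentricity)
    with a logistic profile whose maximal slope falls exactly at target onset
    plus the trial's RT; the vertical channel is noise unless artifacts are
    injected later.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    times = config.times()
    n = len(table)
    rt_s = table["rt"].to_numpy() / 1000.0
    direction = _saccade_direction(table)
    arg = (times[None, :] - rt_s[:, None]) / config.eog_step_width
    h = direction[:, None] / (1.0 + np.exp(-np.clip(arg, -60, 60)))
    h += rng.normal(0.0, config.eog_noise_sd, h.shape)
    v = rng.normal(0.0, config.eog_noise_sd, h.shape)
    return EOGTraces(h=h, v=v, sfreq=config.sfreq, t0=config.epoch_window[0])


VIOLATION_KINDS = ("blink", "amplitude", "direction", "latency")


def inject_artifacts(
    table: pd.DataFrame,
    eog: EOGTraces,
    fraction: float,
    config: SimConfig,
    rng=None,
    kinds=VIOLATION_KINDS,
):
    """Corrupt a known fraction of trials so exclusion rules can be validated.

    Modifies ``eog`` in place and returns a copy of ``table`` with a
    ``violation`` column naming the injected defect ('' where clean):

    * ``blink``: large vertical excursion during the 1 s baseline;
    * ``amplitude``: saccade step shrunk below half the eccentricity;
    * ``direction``: horizontal step sign flipped on single-target trials;
    * ``latency``: step moved outside the valid 75-500 ms latency range.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 4)
    table = table.copy()
    table["violation"] = ""
    n = len(table)
    n_bad = int(round(fraction * n))
    bad = rng.choice(n, size=n_bad, replace=False)
    times = eog.times()
    direction = _saccade_direction(table)
    width = config.eog_step_width
    for i in bad:
        kind = kinds[int(rng.integers(len(kinds)))]
        if kind == "direction" and table.loc[i, "condition"] == "choice":
            kind = "blink"  # direction errors are only defined for single targets
        if kind == "blink":
            t_bl = rng.uniform(-0.9, -0.2)
            eog.v[i] += 8.0 * np.exp(-((times - t_bl) ** 2) / (2 * 0.04**2))
        elif kind == "amplitude":
            rt_s = table.loc[i, "rt"] / 1000.0
            step = 1.0 / (1.0 + np.exp(-np.clip((times - rt_s) / width, -60, 60)))
            eog.h[i] -= direction[i] * 0.7 * step  # leaves a 0.3-eccentricity saccade
        elif kind == "direction":
            rt_s = table.loc[i, "rt"] / 1000.0
            step = 1.0 / (1.0 + np.exp(-np.clip((times - rt_s) / width, -60, 60)))
            eog.h[i] -= direction[i] * 2.0 * step  # flip the saccade's sign
        elif kind == "latency":
            new_rt = 0.040 if rng.random() < 0.5 else 0.600
            rt_s = table.loc[i, "rt"] / 1000.0
            old = direction[i] / (1.0 + np.exp(-np.clip((times - rt_s) / width, -60, 60)))
            new = direction[i] / (1.0 + np.exp(-np.clip((times - new_rt) / width, -60, 60)))
            eog.h[i] += new - old
        table.loc[i, "violation"] = kind
    return table


def config_with_variance_shares(
    share_iti: float,
    share_condition: float,
    share_blocks: float,
    base: SimConfig | None = None,
    **kwargs,
) -> SimConfig:
    """Configure effect sizes so each deterministic factor contributes a
    prescribed fraction of the *total* population RT variance.

    The three components (ITI slope, 3x3 condition-history offsets, blockwise
    linear trends) are mutually orthogonal in the population, so with
    residual SD ``rt_sd_spontaneous`` the total variance is
    ``sigma^2 / (1 - sum(shares))`` and each effect size follows in closed
    form (truncated-exponential ITI variance from scipy, uniform trial-index
    variance for the trends).  The choice penalty is set to zero so the
    condition share is carried entirely by the offsets matrix.
    """
    from scipy import stats

    if base is None:
        base = SimConfig(**kwargs)
    total_share = share_iti + share_condition + share_blocks
    if not 0 <= total_share < 1:
        raise ConfigurationError("variance shares must sum to less than 1")
    sigma = base.rt_sd_spontaneous
    v_total = sigma**2 / (1.0 - total_share)

    lo, hi = base.foreperiod_range
    b = (hi - lo) / base.foreperiod_tau
    var_iti = stats.truncexpon.var(b, loc=lo, scale=base.foreperiod_tau)
    iti_slope = np.sqrt(share_iti * v_total / var_iti)

    # fixed 3x3 pattern, centred/scaled to unit variance under the cell probs
    pattern = np.array([[0.0, 1.0, -1.0], [1.0, -1.0, 0.0], [-1.0, 0.0, 1.0]])
    probs = np.asarray(base.condition_probs, float)
    w = np.outer(probs, probs)
    pattern = pattern - np.sum(w * pattern)
    pattern /= np.sqrt(np.sum(w * pattern**2))
    offsets = pattern * np.sqrt(share_condition * v_total)

    m = base.n_trials // base.n_blocks
    var_tib = (m**2 - 1) / 12.0
    s_block = np.sqrt(share_blocks * v_total / var_tib)
    signs = np.resize([1.0, -1.0], base.n_blocks)
    slopes = tuple(s_block * signs)

    cfg_dict = asdict(base)
    cfg_dict.update(
        iti_slope=float(iti_slope),
        condition_offsets=offsets,
        block_trend_slopes=slopes,
        choice_penalty=0.0,
    )
    cfg_dict["source_specs"] = list(base.source_specs)
    return SimConfig(**cfg_dict)


# ---------------------------------------------------------------------------
# one-call dataset + IO
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimConfig, artifact_fraction: float = 0.0):
    """Full single-subject dataset: (table, epochs, eog, true_amplitudes).

    Runs schedule -> sensor epochs (yielding the latent amplitudes) -> RT
    coupling -> EOG, optionally injecting labelled artifact trials.
    """
    rng = np.random.default_rng(config.seed)
    table = generate_trial_schedule(config, rng)
    epochs, amp = simulate_sensor_epochs(table, config, rng)
    table = generate_rt(table, config, amp if amp.size else None, rng)
    eog = simulate_eog(table, config, rng)
    if artifact_fraction > 0:
        table = inject_artifacts(table, eog, artifact_fraction, config, rng)
    return table, epochs, eog, amp


def save_meg_h5(path, epochs: SensorEpochs, eog: EOGTraces | None = None):
    with h5py.File(path, "w") as f:
        # track_times=False keeps files byte-identical across reruns
        f.create_dataset("epochs", data=epochs.data, track_times=False)
        f.create_dataset(
            "channel_positions", data=epochs.channel_positions, track_times=False
        )
        f.create_dataset(
            "channel_orientations", data=epochs.channel_orientations, track_times=False
        )
        f.attrs["sfreq"] = epochs.sfreq
        f.attrs["t0"] = epochs.t0
        if eog is not None:
            f.create_dataset("eog_h", data=eog.h, track_times=False)
            f.create_dataset("eog_v", data=eog.v, track_times=False)


def load_meg_h5(path):
    with h5py.File(path, "r") as f:
        epochs = SensorEpochs(
            data=f["epochs"][()],
            sfreq=float(f.attrs["sfreq"]),
            t0=float(f.attrs["t0"]),
            channel_positions=f["channel_positions"][()],
            channel_orientations=f["channel_orientations"][()],
        )
        eog = None
        if "eog_h" in f:
            eog = EOGTraces(
                h=f["eog_h"][()], v=f["eog_v"][()],
                sfreq=epochs.sfreq, t0=epochs.t0,
            )
    return epochs, eog
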