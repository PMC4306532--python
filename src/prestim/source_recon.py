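"""Scalar (SAM-style) beamforming and correlational source imaging.

One global band-limited sensor covariance is computed per frequency band and
baseline window, pooling all trials; a unit-gain spatial filter is derived
for every voxel of a regular source grid, with the scalar source orientation
chosen in the tangential plane by the standard generalized eigenproblem
(maximizing the unit-noise-gain output power, Sekihara's pseudo-Z).  The
per-trial RMS source amplitude in the window is then correlated across
trials with a behavioural regressor to form volumetric r images, or
contrasted between leftward and rightward choices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from . import forward
from ._filters import bandpass, crop_window
from .synthetic import SensorEpochs

__all__ = [
    "BandWindow",
    "SourceGrid",
    "WeightSet",
    "StatVolume",
    "global_covariance",
    "sam_weights",
    "trial_band_amplitude",
    "correlational_sam",
    "choice_contrast",
]

#: analysis frequency bands (Hz)
DEFAULT_BANDS = ((5, 15), (15, 25), (25, 35), (35, 70), (70, 100))
#: baseline windows (s relative to target onset)
DEFAULT_WINDOWS = ((-1.0, 0.0), (-0.2, 0.0))


@dataclass(frozen=True)
class BandWindow:
    """A frequency band (Hz) paired with a baseline window (s)."""

    band: tuple = (5.0, 15.0)
    window: tuple = (-1.0, 0.0)

    def __post_init__(self):
        if not self.band[0] < self.band[1]:
            raise ValueError("band must satisfy low < high")
        if not self.window[0] < self.window[1]:
            raise ValueError("window must satisfy start < stop")

    def tag(self) -> str:
        return (
            f"{self.band[0]:g}-{self.band[1]:g}Hz_"
            f"{self.window[0]:g}to{self.window[1]:g}s"
        )


@dataclass
class SourceGrid:
    """Regular voxel grid inside the head sphere, with optional ROI labels."""

    positions: np.ndarray  # (V, 3) mm
    spacing: float
    labels: dict = field(default_factory=dict)  # name -> boolean mask (V,)

    @classmethod
    def build(
        cls,
        model: forward.SphereHeadModel,
        spacing: float = 8.0,
        margin: float = 12.0,
    ) -> "SourceGrid":
        """Cubic lattice clipped to a sphere ``margin`` mm inside the scalp.

        Lattice nodes sit on integer multiples of ``spacing`` relative to the
        sphere centre, so voxel coordinates are stable across grid sizes.
        """
        rmax = model.radius - margin
        kmax = int(np.floor(rmax / spacing))
        ax = spacing * np.arange(-kmax, kmax + 1)
        xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
        pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
        rad = np.linalg.norm(pts, axis=1)
        # exclude the sphere centre: sources there are magnetically silent
        pts = pts[(rad < rmax) & (rad > spacing / 2)] + model.center
        return cls(positions=pts, spacing=spacing)

    def __len__(self):
        return len(self.positions)

    def nearest_voxel(self, position) -> int:
        d = np.linalg.norm(self.positions - np.asarray(position, float), axis=1)
        return int(np.argmin(d))

    def add_default_rois(self, model: forward.SphereHeadModel):
        """Six geometric ROIs (occipital/parietal/frontal x left/right).

        Stand-ins for the Brodmann 17/18, 7 and 6 regions: posterior-inferior,
        posterior-superior and anterior-superior sectors of the source sphere,
        split by hemisphere.
        """
        p = self.positions - model.center
        x, y, z = p.T
        occ = (y < -0.3 * model.radius) & (z < 0.45 * model.radius)
        par = (y < -0.1 * model.radius) & (z >= 0.45 * model.radius)
        fro = (y > 0.1 * model.radius) & (z > 0.2 * model.radius)
        for name, mask in (("occipital", occ), ("parietal", par), ("frontal", fro)):
            self.labels[f"{name}-L"] = mask & (x < 0)
            self.labels[f"{name}-R"] = mask & (x >= 0)
        return self


@dataclass
class WeightSet:
    """Per-voxel unit-gain spatial filters for one band/window covariance."""

    weights: np.ndarray  # (V, n_channels)
    orientations: np.ndarray  # (V, 3) chosen scalar source orientation
    positions: np.ndarray  # (V, 3)
    bw: BandWindow
    regularization: float

    def project(self, data: np.ndarray) -> np.ndarray:
        """(trials, channels, T) -> (trials, V, T) source time courses."""
        return np.einsum("vc,tcs->tvs", self.weights, data)


class RankWarning(UserWarning):
    pass


def global_covariance(epochs: SensorEpochs, bw: BandWindow):
    """Band-limited channel covariance pooled over all trials in the window.

    Each trial is zero-phase band-pass filtered, cropped to the baseline
    window, and all samples are pooled.  Returns ``(cov, n_samples_pooled)``.
    """
    filt = bandpass(epochs.data, bw.band, epochs.sfreq)
    sl = crop_window(epochs.data.shape[2], epochs.t0, epochs.sfreq, bw.window)
    x = filt[:, :, sl]
    n_ch = x.shape[1]
    pooled = np.moveaxis(x, 1, 2).reshape(-1, n_ch)
    n = pooled.shape[0]
    if n < n_ch + 1:
        import warnings

        warnings.warn(
            "fewer pooled samples than channels; covariance is rank deficient "
            "and diagonal loading is mandatory",
            RankWarning,
        )
    pooled = pooled - pooled.mean(0)
    return pooled.T @ pooled / max(n - 1, 1), n


def sam_weights(
    cov: np.ndarray,
    model: forward.SphereHeadModel,
    positions: np.ndarray,
    sensor_positions: np.ndarray,
    sensor_orientations: np.ndarray,
    bw: BandWindow | None = None,
    regularization: float = 0.05,
) -> WeightSet:
    """Unit-gain scalar beamformer weights for each source position.

    The covariance is diagonally loaded by ``regularization`` times its mean
    eigenvalue; for every position the scalar orientation maximizing the
    unit-noise-gain output power is the leading generalized eigenvector of
    (L'C^-1 L, L'C^-2 L) over the tangential plane, and the weight vector is
    ``C^-1 l / (l' C^-1 l)`` which satisfies ``w' l = 1`` exactly.
    """
    cov = np.asarray(cov, float)
    n_ch = cov.shape[0]
    loaded = cov + regularization * (np.trace(cov) / n_ch) * np.eye(n_ch)
    cinv = linalg.inv(loaded)
    cinv2 = cinv @ cinv
    positions = np.atleast_2d(np.asarray(positions, float))
    W = np.empty((len(positions), n_ch))
    oris = np.empty((len(positions), 3))
    for v, pos in enumerate(positions):
        L = forward.leadfield_tangential(
            model, pos, sensor_positions, sensor_orientations
        )
        A = L.T @ cinv @ L
        B = L.T @ cinv2 @ L
        vals, vecs = linalg.eigh(A, B)
        u = vecs[:, -1]
        u /= np.linalg.norm(u)
        l = L @ u
        cl = cinv @ l
        W[v] = cl / (l @ cl)
        basis = forward.tangential_basis(model, pos)
        oris[v] = u @ basis
    return WeightSet(
        weights=W,
        orientations=oris,
        positions=positions,
        bw=bw if bw is not None else BandWindow(),
        regularization=regularization,
    )


def trial_band_amplitude(
    weights: WeightSet,
    epochs: SensorEpochs,
    bw: BandWindow | None = None,
    prefiltered: np.ndarray | None = None,
    chunk: int = 64,
) -> np.ndarray:
    """Per-trial RMS source amplitude in the band/window, per voxel.

    Returns (n_trials, V).  ``prefiltered`` lets callers reuse band-passed
    epochs (e.g. those from the covariance step).
    """
    bw = bw or weights.bw
    if prefiltered is None:
        prefiltered = bandpass(epochs.data, bw.band, epochs.sfreq)
    sl = crop_window(epochs.data.shape[2], epochs.t0, epochs.sfreq, bw.window)
    x = prefiltered[:, :, sl]  # (trials, ch, T)
    n_tr, _, T = x.shape
    V = weights.weights.shape[0]
    amp = np.empty((n_tr, V))
    flat = np.moveaxis(x, 1, 2).reshape(n_tr * T, -1)  # (trials*T, ch)
    for lo in range(0, V, chunk):
        w = weights.weights[lo : lo + chunk]  # (v, ch)
        proj = flat @ w.T  # (trials*T, v)
        amp[:, lo : lo + chunk] = np.sqrt(
            np.mean(proj.reshape(n_tr, T, -1) ** 2, axis=1)
        )
    return amp


@dataclass
class StatVolume:
    """Voxelwise statistic map with band/window and regressor metadata."""

    values: np.ndarray  # (V,) primary statistic (r, t or mean difference)
    grid: SourceGrid
    bw: BandWindow
    stat: str = "r"
    regressor: str = "raw"
    extra: dict = field(default_factory=dict)

    def peak(self, roi: str | None = None):
        """(voxel index, value) of the maximal |statistic| (within an ROI)."""
        vals = self.values.copy()
        if roi is not None:
            mask = self.grid.labels[roi]
            vals = np.where(mask, vals, np.nan)
        idx = int(np.nanargmax(np.abs(vals)))
        return idx, float(self.values[idx])

    def to_nifti(self):
        """Dense NIfTI-1 image of the (sparse spherical) voxel values."""
        import nibabel as nib

        pos = self.grid.positions
        sp = self.grid.spacing
        origin = pos.min(0)
        ijk = np.round((pos - origin) / sp).astype(int)
        shape = ijk.max(0) + 1
        vol = np.full(shape, np.nan, dtype=np.float32)
        vol[tuple(ijk.T)] = self.values
        affine = np.diag([sp, sp, sp, 1.0])
        affine[:3, 3] = origin
        return nib.Nifti1Image(vol, affine)


def pearson_columns(amp: np.ndarray, regressor: np.ndarray) -> np.ndarray:
    """Pearson r of each column of ``amp`` against ``regressor``.

    Columns with zero variance yield NaN; a constant regressor is an error.
    """
    amp = np.asarray(amp, float)
    reg = np.asarray(regressor, float)
    if amp.shape[0] != reg.shape[0]:
        raise ValueError("amplitude and regressor trial counts differ")
    if amp.shape[0] < 3:
        raise ValueError("need at least 3 trials")
    zr = reg - reg.mean()
    sr = np.sqrt(zr @ zr)
    if sr == 0:
        raise ValueError("regressor is constant")
    a = amp - amp.mean(0)
    sa = np.sqrt(np.sum(a**2, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a.T @ zr) / (sa * sr)
    r[sa == 0] = np.nan
    return r


def correlational_sam(
    amp: np.ndarray,
    regressor: np.ndarray,
    grid: SourceGrid,
    bw: BandWindow,
    regressor_name: str = "raw",
) -> StatVolume:
    """Volumetric image of the trial-wise Pearson r between per-voxel source
    amplitude and a behavioural regressor."""
    r = pearson_columns(amp, regressor)
    return StatVolume(values=r, grid=grid, bw=bw, stat="r", regressor=regressor_name)


def choice_contrast(
    amp: np.ndarray, labels: np.ndarray, grid: SourceGrid, bw: BandWindow
) -> StatVolume:
    """Left-vs-right choice contrast per voxel (two-sample t, mean diff)."""
    labels = np.asarray(labels)
    left = amp[labels == "left"]
    right = amp[labels == "right"]
    if len(left) < 2 or len(right) < 2:
        raise ValueError("need at least 2 trials per choice label")
    t, p = stats.ttest_ind(left, right, axis=0)
    diff = left.mean(0) - right.mean(0)
    return StatVolume(
        values=np.asarray(t, float),
        grid=grid,
        bw=bw,
        stat="t",
        regressor="choice",
        extra={"mean_diff": diff, "p": np.asarray(p, float)},
    )
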