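"""Beamformer tests: covariance oracles, unit gain, source reconstruction
fidelity, correlational volumes and the choice contrast."""

import numpy as np
import pytest
from scipy import signal, stats

from prestim import forward, source_recon as sr, synthetic as syn

from conftest import SOURCE_POS


def _white_noise_epochs(n_trials=40, n_ch=8, n_samp=900, sigma=1.0, seed=0):
    rng = np.random.default_rng(seed)
    pos, ori = forward.spherical_cap_sensors(n_ch, 110.0)
    return syn.SensorEpochs(
        data=rng.normal(0, sigma, (n_trials, n_ch, n_samp)),
        sfreq=600.0,
        t0=-1.2,
        channel_positions=pos,
        channel_orientations=ori,
    )


def test_covariance_white_noise_spectral_flatness():
    """White-noise covariance ~= sigma^2 * (band fraction) * I, where the
    band fraction is the integral of |H|^4 of the zero-phase filter."""
    sigma = 2.0
    epochs = _white_noise_epochs(n_trials=200, sigma=sigma)
    bw = sr.BandWindow((5, 15), (-1.0, 0.0))
    cov, n = sr.global_covariance(epochs, bw)
    sos = signal.butter(4, [5, 15], btype="bandpass", fs=600.0, output="sos")
    w, h = signal.sosfreqz(sos, worN=8192, fs=600.0)
    band_fraction = np.trapezoid(np.abs(h) ** 4, w) / 300.0
    expected = sigma**2 * band_fraction
    diag = np.diag(cov)
    assert np.allclose(diag, expected, rtol=0.10)
    off = cov[~np.eye(cov.shape[0], dtype=bool)]
    assert np.max(np.abs(off)) < 0.05 * expected * 5


def test_covariance_deterministic():
    epochs = _white_noise_epochs()
    bw = sr.BandWindow((5, 15), (-1.0, 0.0))
    c1, _ = sr.global_covariance(epochs, bw)
    c2, _ = sr.global_covariance(epochs, bw)
    np.testing.assert_array_equal(c1, c2)
    np.testing.assert_allclose(c1, c1.T, atol=1e-15)
    assert np.all(np.linalg.eigvalsh(c1) > -1e-12)


def test_covariance_rank_one_for_single_source():
    cfg = syn.SimConfig(
        n_trials=20, n_blocks=1, n_channels=12, epoch_window=(-1.2, 0.2),
        sensor_noise_sd=0.0, seed=1,
        source_specs=[syn.GroundTruthSource(position=SOURCE_POS)],
    )
    table = syn.generate_trial_schedule(cfg)
    epochs, _ = syn.simulate_sensor_epochs(table, cfg)
    cov, _ = sr.global_covariance(epochs, sr.BandWindow((5, 15), (-1.0, 0.0)))
    ev = np.linalg.eigvalsh(cov)
    assert ev[-2] < 1e-8 * ev[-1]


def test_rank_warning_for_short_data():
    epochs = _white_noise_epochs(n_trials=1, n_ch=30, n_samp=900)
    with pytest.warns(sr.RankWarning):
        sr.global_covariance(epochs, sr.BandWindow((5, 15), (-1.19, -1.15)))


def test_unit_gain_constraint(coupled_dataset):
    """w' l = 1 exactly at every voxel, along the chosen orientation."""
    epochs = coupled_dataset["epochs"]
    cfg = coupled_dataset["config"]
    model = cfg.head_model()
    grid = sr.SourceGrid.build(model, spacing=30.0)
    bw = sr.BandWindow((5, 15), (-1.0, 0.0))
    cov, _ = sr.global_covariance(epochs, bw)
    ws = sr.sam_weights(
        cov, model, grid.positions,
        epochs.channel_positions, epochs.channel_orientations, bw,
    )
    for v in range(len(grid)):
        lf = forward.leadfield(
            model, grid.positions[v], ws.orientations[v],
            epochs.channel_positions, epochs.channel_orientations,
        )
        assert ws.weights[v] @ lf == pytest.approx(1.0, abs=1e-9)


def test_noiseless_reconstruction_correlation():
    """Unit-gain filter at the true voxel recovers the source time course."""
    cfg = syn.SimConfig(
        n_trials=30, n_blocks=1, n_channels=30, epoch_window=(-1.2, 0.2),
        sensor_noise_sd=0.0, seed=2,
        source_specs=[syn.GroundTruthSource(position=SOURCE_POS)],
    )
    table = syn.generate_trial_schedule(cfg)
    epochs, true_amp = syn.simulate_sensor_epochs(table, cfg)
    model = cfg.head_model()
    bw = sr.BandWindow((5, 15), (-1.0, 0.0))
    cov, _ = sr.global_covariance(epochs, bw)
    ws = sr.sam_weights(
        cov, model, np.array([SOURCE_POS]),
        epochs.channel_positions, epochs.channel_orientations, bw,
    )
    amp = sr.trial_band_amplitude(ws, epochs, bw)
    r = np.corrcoef(amp[:, 0], true_amp[:, 0])[0, 1]
    assert r > 0.999


def test_two_source_suppression():
    """The filter at source 1 suppresses source 2 by > 20 dB."""
    pos2 = (0.0, 45.0, 30.0)
    common = dict(
        n_trials=20, n_blocks=1, n_channels=30, epoch_window=(-1.2, 0.2), seed=3
    )
    cfg = syn.SimConfig(
        source_specs=[
            syn.GroundTruthSource(position=SOURCE_POS, center_freq=10.0),
            syn.GroundTruthSource(position=pos2, center_freq=11.0),
        ],
        **common,
    )
    table = syn.generate_trial_schedule(cfg)
    epochs, _ = syn.simulate_sensor_epochs(table, cfg)
    model = cfg.head_model()
    bw = sr.BandWindow((5, 15), (-1.0, 0.0))
    cov, _ = sr.global_covariance(epochs, bw)
    ws = sr.sam_weights(
        cov, model, np.array([SOURCE_POS]),
        epochs.channel_positions, epochs.channel_orientations, bw,
    )
    # project noiseless single-source datasets through the same filter
    powers = []
    for pos in (SOURCE_POS, pos2):
        cfg1 = syn.SimConfig(
            sensor_noise_sd=0.0,
            source_specs=[syn.GroundTruthSource(position=pos)],
            **common,
        )
        ep1, _ = syn.simulate_sensor_epochs(syn.generate_trial_schedule(cfg1), cfg1)
        proj = np.einsum("c,tcs->ts", ws.weights[0], ep1.data)
        powers.append(np.mean(proj**2))
    assert powers[0] / powers[1] > 100.0  # > 20 dB


def test_trial_amplitude_homogeneity_and_zero():
    epochs = _white_noise_epochs(n_trials=6)
    bw = sr.BandWindow((5, 15), (-1.0, 0.0))
    cov, _ = sr.global_covariance(epochs, bw)
    model = forward.SphereHeadModel()
    ws = sr.sam_weights(
        cov, model, np.array([SOURCE_POS]),
        epochs.channel_positions, epochs.channel_orientations, bw,
    )
    amp = sr.trial_band_amplitude(ws, epochs, bw)
    scaled = syn.SensorEpochs(
        data=-3.0 * epochs.data, sfreq=epochs.sfreq, t0=epochs.t0,
        channel_positions=epochs.channel_positions,
        channel_orientations=epochs.channel_orientations,
    )
    np.testing.assert_allclose(
        sr.trial_band_amplitude(ws, scaled, bw), 3.0 * amp, rtol=1e-10
    )
    zero = syn.SensorEpochs(
        data=np.zeros_like(epochs.data), sfreq=epochs.sfreq, t0=epochs.t0,
        channel_positions=epochs.channel_positions,
        channel_orientations=epochs.channel_orientations,
    )
    np.testing.assert_array_equal(sr.trial_band_amplitude(ws, zero, bw), 0.0)


def test_correlational_sam_exact_cases():
    grid = sr.SourceGrid(positions=np.zeros((3, 3)), spacing=8.0)
    bw = sr.BandWindow()
    amp = np.column_stack(
        [(1.0, 2.0, 3.0, 4.0, 5.0), (5.0, 1.0, 4.0, 2.0, 3.0), np.ones(5)]
    )
    vol = sr.correlational_sam(amp, np.array([210.0, 220, 230, 240, 250]), grid, bw)
    assert vol.values[0] == pytest.approx(1.0)
    assert np.isnan(vol.values[2])  # constant amplitude -> undefined r
    vol2 = sr.correlational_sam(amp, np.array([250.0, 240, 230, 220, 210]), grid, bw)
    assert vol2.values[0] == pytest.approx(-1.0)
    # regressor equals a voxel's own amplitude -> r = 1 there
    vol3 = sr.correlational_sam(amp, amp[:, 1], grid, bw)
    assert vol3.values[1] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        sr.correlational_sam(amp, np.ones(5), grid, bw)


def test_correlation_affine_invariance():
    rng = np.random.default_rng(4)
    amp = rng.lognormal(size=(60, 4))
    reg = rng.normal(262, 48, 60)
    grid = sr.SourceGrid(positions=np.zeros((4, 3)), spacing=8.0)
    bw = sr.BandWindow()
    base = sr.correlational_sam(amp, reg, grid, bw).values
    scaled = sr.correlational_sam(amp * [1, 10, 0.1, 3] + 5, 2 * reg - 100, grid, bw)
    np.testing.assert_allclose(scaled.values, base, atol=1e-12)


def test_choice_contrast_antisymmetry_and_null():
    rng = np.random.default_rng(5)
    amp = rng.normal(size=(200, 400))
    labels = np.array(["left"] * 100 + ["right"] * 100)
    grid = sr.SourceGrid(positions=np.zeros((400, 3)), spacing=8.0)
    bw = sr.BandWindow()
    vol = sr.choice_contrast(amp, labels, grid, bw)
    flipped = sr.choice_contrast(amp, np.where(labels == "left", "right", "left"),
                                 grid, bw)
    np.testing.assert_allclose(vol.values, -flipped.values, atol=1e-12)
    # identical distributions: ~5% of voxels beyond the t 0.025 quantile
    tcrit = stats.t.ppf(0.975, df=198)
    frac = np.mean(np.abs(vol.values) > tcrit)
    assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 400)
    with pytest.raises(ValueError):
        sr.choice_contrast(amp, np.array(["left"] * 200), grid, bw)


def test_choice_contrast_detects_injected_offset():
    """A 0.5 SD left/right offset at one voxel wins max |t| in nearly all
    replicates at n = 200 per label."""
    hits = 0
    for seed in range(8):
        rng = np.random.default_rng(100 + seed)
        amp = rng.normal(size=(400, 50))
        labels = np.array(["left"] * 200 + ["right"] * 200)
        amp[:200, 17] += 0.5
        grid = sr.SourceGrid(positions=np.zeros((50, 3)), spacing=8.0)
        vol = sr.choice_contrast(amp, labels, grid, sr.BandWindow())
        hits += int(np.argmax(np.abs(vol.values)) == 17)
    assert hits >= 7


def test_lateralization_null(coupled_dataset):
    """Direction-symmetric coupling: left-minus-right r maps hover around 0."""
    cfg = coupled_dataset["config"]
    table = coupled_dataset["table"]
    epochs = coupled_dataset["epochs"]
    model = cfg.head_model()
    grid = sr.SourceGrid.build(model, spacing=25.0)
    bw = sr.BandWindow((5, 15), (-1.0, 0.0))
    cov, _ = sr.global_covariance(epochs, bw)
    ws = sr.sam_weights(
        cov, model, grid.positions,
        epochs.channel_positions, epochs.channel_orientations, bw,
    )
    amp = sr.trial_band_amplitude(ws, epochs, bw)
    diffs = []
    for cond in ("left", "right"):
        sel = (table["condition"] == cond).to_numpy()
        diffs.append(sr.pearson_columns(amp[sel], table.loc[sel, "rt"].to_numpy()))
    diff = diffs[0] - diffs[1]
    n_per = min((table["condition"] == "left").sum(), (table["condition"] == "right").sum())
    se_diff = np.sqrt(2.0) / np.sqrt(n_per)
    assert abs(np.nanmean(diff)) < 3 * se_diff


def test_grid_and_rois():
    model = forward.SphereHeadModel()
    grid = sr.SourceGrid.build(model, spacing=15.0).add_default_rois(model)
    radii = np.linalg.norm(grid.positions - model.center, axis=1)
    assert radii.max() < model.radius - 12.0
    assert radii.min() > 0
    assert set(grid.labels) == {
        "occipital-L", "occipital-R", "parietal-L", "parietal-R",
        "frontal-L", "frontal-R",
    }
    assert all(mask.any() for mask in grid.labels.values())
    v = grid.nearest_voxel(SOURCE_POS)
    np.testing.assert_allclose(grid.positions[v], SOURCE_POS)
    assert grid.labels["occipital-L"][v] or grid.labels["occipital-R"][v]


def test_statvolume_nifti_roundtrip(tmp_path):
    model = forward.SphereHeadModel()
    grid = sr.SourceGrid.build(model, spacing=30.0)
    vals = np.arange(len(grid), dtype=float)
    vol = sr.StatVolume(values=vals, grid=grid, bw=sr.BandWindow())
    img = vol.to_nifti()
    data = np.asarray(img.dataobj)
    assert np.nansum(data) == pytest.approx(vals.sum())
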