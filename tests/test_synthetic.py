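"""Generator tests: schedule statistics, RT composition, injected coupling,
signal linearity and full determinism."""

import numpy as np
import pytest
from scipy import stats

from prestim import synthetic as syn
from prestim._filters import bandpass, crop_window

from conftest import SOURCE_POS


def test_degenerate_condition_probs():
    cfg = syn.SimConfig(n_trials=100, condition_probs=(1.0, 0.0, 0.0), seed=0)
    table = syn.generate_trial_schedule(cfg)
    assert (table["condition"] == "left").all()


def test_foreperiod_within_bounds():
    cfg = syn.SimConfig(n_trials=2000, seed=1)
    table = syn.generate_trial_schedule(cfg)
    assert table["iti"].between(3.0, 4.0).all()


def test_condition_frequencies_binomial():
    cfg = syn.SimConfig(n_trials=9000, n_blocks=4, seed=2)
    table = syn.generate_trial_schedule(cfg)
    se = np.sqrt((1 / 3) * (2 / 3) / 9000)
    for cond in syn.CONDITIONS:
        freq = (table["condition"] == cond).mean()
        assert abs(freq - 1 / 3) < 3 * se


def test_foreperiod_constant_hazard():
    """Chi-square goodness of fit of 1e5 foreperiod draws against the
    truncated-exponential (constant hazard) distribution, alpha = 0.01."""
    cfg = syn.SimConfig(n_trials=100_000, n_blocks=4, seed=3)
    iti = syn.generate_trial_schedule(cfg)["iti"].to_numpy()
    b = (4.0 - 3.0) / cfg.foreperiod_tau
    dist = stats.truncexpon(b, loc=3.0, scale=cfg.foreperiod_tau)
    edges = np.linspace(3.0, 4.0, 21)
    observed, _ = np.histogram(iti, edges)
    expected = np.diff(dist.cdf(edges)) * iti.size
    chi2 = ((observed - expected) ** 2 / expected).sum()
    p = stats.chi2.sf(chi2, df=len(observed) - 1)
    assert p > 0.01


def test_schedule_structure():
    cfg = syn.SimConfig(n_trials=80, n_blocks=4, seed=4)
    table = syn.generate_trial_schedule(cfg)
    assert (table.groupby("block").size() == 20).all()
    first = table[table["time_in_block"] == 0]
    assert (first["prev_condition"] == syn.SESSION_START).all()
    shifted = table["condition"].shift(1)
    rest = table["time_in_block"] > 0
    assert (table.loc[rest, "prev_condition"] == shifted[rest]).all()
    is_choice = table["condition"] == "choice"
    assert (table.loc[is_choice, "choice_made"].isin(["left", "right"])).all()
    assert (table.loc[~is_choice, "choice_made"] == "none").all()


def test_invalid_configs():
    with pytest.raises(syn.ConfigurationError):
        syn.SimConfig(condition_probs=(0.5, 0.5, 0.5))
    with pytest.raises(syn.ConfigurationError):
        syn.SimConfig(n_trials=100, n_blocks=3)
    with pytest.raises(Exception):
        syn.SimConfig(source_specs=[syn.GroundTruthSource(position=(0, 0, 200.0))])


def test_rt_null_moments():
    """With all effects off, RT is Gaussian around (rt_mean, rt_sd)."""
    n = 5000
    cfg = syn.SimConfig(n_trials=n, choice_penalty=0.0, seed=5)
    table = syn.generate_rt(syn.generate_trial_schedule(cfg), cfg)
    se_mean = cfg.rt_sd_spontaneous / np.sqrt(n)
    se_sd = cfg.rt_sd_spontaneous / np.sqrt(2 * n)
    assert abs(table["rt"].mean() - cfg.rt_mean) < 3 * se_mean
    assert abs(table["rt"].std() - cfg.rt_sd_spontaneous) < 3 * se_sd


def test_rt_iti_slope_recovery():
    n = 5000
    cfg = syn.SimConfig(n_trials=n, iti_slope=10.0, choice_penalty=0.0, seed=6)
    table = syn.generate_rt(syn.generate_trial_schedule(cfg), cfg)
    fit = stats.linregress(table["iti"], table["rt"])
    assert abs(fit.slope - 10.0) < 3 * fit.stderr


def test_rt_coupling_correlation():
    """Injected amplitude-RT coupling reproduces the target Pearson r."""
    n, r = 5000, 0.3
    cfg = syn.SimConfig(
        n_trials=n, choice_penalty=0.0, seed=7,
        source_specs=[syn.GroundTruthSource(position=SOURCE_POS, rt_coupling_r=r)],
    )
    # independent stream for the latent (generate_rt uses seed+1 internally)
    rng = np.random.default_rng(1234)
    latent = rng.lognormal(0, 0.5, (n, 1))
    table = syn.generate_rt(syn.generate_trial_schedule(cfg), cfg, latent)
    got = np.corrcoef(latent[:, 0], table["rt"])[0, 1]
    se = (1 - r**2) / np.sqrt(n)
    assert abs(got - r) < 3 * se


def test_rt_excessive_coupling_errors():
    cfg = syn.SimConfig(
        n_trials=40, seed=0,
        source_specs=[syn.GroundTruthSource(position=SOURCE_POS, rt_coupling_r=0.8),
                      syn.GroundTruthSource(position=(0, 40.0, 30.0), rt_coupling_r=0.7)],
    )
    latent = np.random.default_rng(0).normal(size=(40, 2))
    with pytest.raises(syn.ConfigurationError):
        syn.generate_rt(syn.generate_trial_schedule(cfg), cfg, latent)


def test_variance_share_bookkeeping():
    """ANOVA decomposition of a config built for prescribed variance shares.

    The realized shares of each deterministic component plus the residual
    must tile the total RT variance within sampling error.
    """
    shares = (0.05, 0.10, 0.08)
    cfg = syn.config_with_variance_shares(
        *shares, n_trials=20_000, n_blocks=4, seed=9
    )
    table = syn.generate_rt(syn.generate_trial_schedule(cfg), cfg)
    rt = table["rt"].to_numpy()
    d_iti = cfg.iti_slope * (table["iti"] - table["iti"].mean())
    cur = table["condition"].map({c: i for i, c in enumerate(syn.CONDITIONS)})
    prev = table["prev_condition"].map({c: i for i, c in enumerate(syn.CONDITIONS)})
    valid = prev.notna()
    d_cond = np.zeros(len(table))
    d_cond[valid] = cfg.condition_offsets[
        cur[valid].astype(int), prev[valid].astype(int)
    ]
    tib = table["time_in_block"] - table["time_in_block"].mean()
    d_block = np.asarray(cfg.block_trend_slopes)[table["block"]] * tib
    total = rt.var()
    realized = [np.var(d) / total for d in (d_iti, d_cond, d_block)]
    for got, want in zip(realized, shares):
        assert abs(got - want) < 0.01
    resid = rt - d_iti - d_cond - d_block
    assert abs(resid.var() / total - (1 - sum(shares))) < 0.02


def test_full_determinism(tiny_config):
    a = syn.simulate_dataset(tiny_config, artifact_fraction=0.1)
    b = syn.simulate_dataset(tiny_config, artifact_fraction=0.1)
    assert a[0].equals(b[0])
    np.testing.assert_array_equal(a[1].data, b[1].data)
    np.testing.assert_array_equal(a[2].h, b[2].h)
    np.testing.assert_array_equal(a[3], b[3])


def test_noiseless_epochs_are_rank_one_and_unit_gain_reconstructable():
    """Noiseless single-source data equal lead field (x) source time series."""
    from prestim import forward

    cfg = syn.SimConfig(
        n_trials=10, n_blocks=1, n_channels=12, epoch_window=(-1.2, 0.2),
        sensor_noise_sd=0.0, seed=10,
        source_specs=[syn.GroundTruthSource(position=SOURCE_POS)],
    )
    table = syn.generate_trial_schedule(cfg)
    epochs, amp = syn.simulate_sensor_epochs(table, cfg)
    X = epochs.data.transpose(1, 0, 2).reshape(cfg.n_channels, -1)
    s = np.linalg.svd(X, compute_uv=False)
    assert s[1] < 1e-10 * s[0]
    model = cfg.head_model()
    ori = forward.tangentialize(model, SOURCE_POS, (1, 0, 0))
    lf = forward.leadfield(
        model, SOURCE_POS, ori, epochs.channel_positions, epochs.channel_orientations
    )
    wave = (lf @ X) / (lf @ lf)  # least-squares source estimate
    np.testing.assert_allclose(np.outer(lf, wave), X, atol=1e-12 * np.abs(X).max())


def test_two_source_linearity():
    """Noiseless two-source data live in the span of the two lead fields."""
    cfg = syn.SimConfig(
        n_trials=8, n_blocks=1, n_channels=12, epoch_window=(-1.2, 0.2),
        sensor_noise_sd=0.0, seed=11,
        source_specs=[
            syn.GroundTruthSource(position=SOURCE_POS),
            syn.GroundTruthSource(position=(0.0, 45.0, 30.0), center_freq=20.0),
        ],
    )
    table = syn.generate_trial_schedule(cfg)
    epochs, _ = syn.simulate_sensor_epochs(table, cfg)
    X = epochs.data.transpose(1, 0, 2).reshape(cfg.n_channels, -1)
    s = np.linalg.svd(X, compute_uv=False)
    assert s[1] > 1e-6 * s[0]  # genuinely two components
    assert s[2] < 1e-10 * s[0]


def test_amplitude_doubling_quadruples_band_power():
    """Doubling source amplitude multiplies sensor band power by 4."""
    kw = dict(
        n_trials=30, n_blocks=1, n_channels=12, epoch_window=(-1.2, 0.2),
        sensor_noise_sd=0.0, seed=12,
    )
    powers = []
    for base in (1.0, 2.0):
        cfg = syn.SimConfig(
            source_specs=[
                syn.GroundTruthSource(
                    position=SOURCE_POS, base_amplitude=base, amplitude_sigma=0.0
                )
            ],
            **kw,
        )
        table = syn.generate_trial_schedule(cfg)
        epochs, _ = syn.simulate_sensor_epochs(table, cfg)
        filt = bandpass(epochs.data, (8, 12), cfg.sfreq)
        sl = crop_window(filt.shape[2], epochs.t0, cfg.sfreq, (-1.0, 0.0))
        ch = np.argmax(np.mean(filt[:, :, sl] ** 2, axis=(0, 2)))
        powers.append(np.mean(filt[:, ch, sl] ** 2))
    assert abs(powers[1] / powers[0] - 4.0) < 0.05


def test_eog_step_and_mirror_symmetry():
    cfg = syn.SimConfig(
        n_trials=4, n_blocks=1, n_channels=12, epoch_window=(-1.2, 0.7),
        eog_noise_sd=0.0, seed=13, condition_probs=(0.5, 0.5, 0.0),
    )
    table = syn.generate_trial_schedule(cfg)
    table["rt"] = 250.0
    eog = syn.simulate_eog(table, cfg)
    times = eog.times()
    for i in range(len(table)):
        peak = times[np.argmax(np.abs(np.diff(eog.h[i])))]
        assert abs(peak - 0.250) <= 1.5 / cfg.sfreq
    left = table.index[table["condition"] == "left"]
    right = table.index[table["condition"] == "right"]
    if len(left) and len(right):
        np.testing.assert_allclose(eog.h[left[0]], -eog.h[right[0]], atol=1e-12)


def test_artifact_injection_labels(tiny_config):
    table, epochs, eog, _ = syn.simulate_dataset(tiny_config, artifact_fraction=0.25)
    n_bad = (table["violation"] != "").sum()
    assert n_bad == round(0.25 * len(table))
    blink_rows = table.index[table["violation"] == "blink"]
    for i in blink_rows:
        assert np.abs(eog.v[i]).max() > 5.0


def test_h5_roundtrip(tmp_path, tiny_config):
    table, epochs, eog, _ = syn.simulate_dataset(tiny_config)
    path = tmp_path / "meg.h5"
    syn.save_meg_h5(path, epochs, eog)
    ep2, eog2 = syn.load_meg_h5(path)
    np.testing.assert_array_equal(ep2.data, epochs.data)
    np.testing.assert_array_equal(eog2.h, eog.h)
    assert ep2.sfreq == epochs.sfreq and ep2.t0 == epochs.t0


def test_config_json_roundtrip(coupled_config):
    text = coupled_config.to_json()
    cfg2 = syn.SimConfig.from_json(text)
    assert cfg2.n_trials == coupled_config.n_trials
    assert cfg2.source_specs[0].rt_coupling_r == 0.2
    assert tuple(cfg2.epoch_window) == tuple(coupled_config.epoch_window)
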