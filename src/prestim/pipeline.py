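"""End-to-end study orchestration.

Runs the full analysis over N synthetic subjects: simulate -> EOG
preprocessing/exclusions -> RT regressors -> beamformer + correlational SAM
volumes (bands x windows x regressor variants) -> virtual-electrode
time-frequency and V1-amplitude regressors -> quintile ITC -> group
statistics -> report.  Each stage is resumable, consumes the previous
stage's files, and is recorded (with checksums) in a JSON run manifest so a
study is reproducible from its master seed alone.

Per-subject seeds derive from the master seed through
``numpy.random.SeedSequence([master_seed, subject_index])``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import eog as eog_mod
from . import forward, group_stats, phase_itc, rt_model, spectral
from . import source_recon as sr
from . import synthetic as syn

__all__ = ["StudyConfig", "PipelineError", "run_study", "STAGES"]

STAGES = (
    "simulate",
    "preprocess",
    "regressors",
    "beamform",
    "tf",
    "itc",
    "group",
    "report",
)

ROI_GROUPS = {
    "V1": lambda name: name.startswith("V1-"),
    "IPS": lambda name: name.startswith("IPS-"),
    "FEF": lambda name: name.startswith("FEF-"),
    "SEF": lambda name: name == "SEF",
}


class PipelineError(RuntimeError):
    pass


@dataclass
class StudyConfig:
    """Study-level configuration (simulation + analysis parameters)."""

    n_subjects: int = 12
    master_seed: int = 0
    # --- simulation ---
    n_trials: int = 800
    n_blocks: int = 4
    n_channels: int = 30
    epoch_window: tuple = (-2.7, 0.7)
    rt_mean: float = 262.0
    rt_sd_spontaneous: float = 48.0
    variance_shares: tuple = (0.012, 0.079, 0.086)  # ITI, condition, block trends
    coupling_r: float = 0.2
    source_position: tuple = (0.0, -60.0, 20.0)
    source_freq: float = 10.0
    source_bandwidth: float = 8.0
    artifact_fraction: float = 0.12
    # --- analysis ---
    bands: tuple = sr.DEFAULT_BANDS
    windows: tuple = sr.DEFAULT_WINDOWS
    grid_spacing: float = 8.0
    regularization: float = 0.05
    tf_freq_range: tuple = (5.0, 40.0)
    tf_bin_width: float = 0.05
    tf_window: tuple = (-2.0, 0.0)
    itc_freq_range: tuple = phase_itc.PHASE_FREQ_RANGE
    itc_window: tuple = (-0.6, 0.0)
    itc_shuffles: int = 100
    fdr_q: float = 0.05

    def subject_seed(self, subject: int) -> int:
        ss = np.random.SeedSequence([self.master_seed, subject])
        return int(ss.generate_state(1)[0] % (2**31))

    def sim_config(self, subject: int) -> syn.SimConfig:
        src = syn.GroundTruthSource(
            position=tuple(self.source_position),
            center_freq=self.source_freq,
            bandwidth=self.source_bandwidth,
            rt_coupling_r=self.coupling_r,
        )
        base = syn.SimConfig(
            n_trials=self.n_trials,
            n_blocks=self.n_blocks,
            n_channels=self.n_channels,
            epoch_window=tuple(self.epoch_window),
            rt_mean=self.rt_mean,
            rt_sd_spontaneous=self.rt_sd_spontaneous,
            source_specs=[src],
            seed=self.subject_seed(subject),
        )
        return syn.config_with_variance_shares(*self.variance_shares, base=base)

    def head_model(self) -> forward.SphereHeadModel:
        return forward.SphereHeadModel()

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        return yaml.safe_dump(json.loads(json.dumps(d, default=list)))

    @classmethod
    def from_yaml(cls, text: str) -> "StudyConfig":
        d = yaml.safe_load(text) or {}
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - fields
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        for key, val in d.items():
            if isinstance(val, list):
                d[key] = tuple(tuple(v) if isinstance(v, list) else v for v in val)
        return cls(**d)


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class Manifest:
    def __init__(self, outdir: Path, config: StudyConfig):
        self.path = Path(outdir) / "manifest.json"
        if self.path.exists():
            self.data = json.loads(self.path.read_text())
        else:
            self.data = {
                "version": __version__,
                "config_hash": hashlib.sha256(
                    config.to_yaml().encode()
                ).hexdigest(),
                "master_seed": config.master_seed,
                "subject_seeds": [
                    config.subject_seed(s) for s in range(config.n_subjects)
                ],
                "stages": {},
            }

    def record(self, stage: str, files, seconds: float):
        self.data["stages"][stage] = {
            "files": [
                {"path": str(p), "sha256": _sha256(Path(p))} for p in sorted(map(str, files))
            ],
            "seconds": round(seconds, 3),
        }
        self.path.write_text(json.dumps(self.data, indent=1))

    def done(self, stage: str) -> bool:
        entry = self.data["stages"].get(stage)
        if not entry:
            return False
        return all(Path(f["path"]).exists() for f in entry["files"])

    def require(self, stage: str):
        if not self.done(stage):
            raise PipelineError(
                f"missing upstream artifact: stage '{stage}' has not been run"
            )


def _subdir(outdir, subject) -> Path:
    d = Path(outdir) / f"sub-{subject:02d}"
    d.mkdir(parents=True, exist_ok=True)
    return d


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: StudyConfig, outdir) -> list:
    files = []
    for s in range(cfg.n_subjects):
        sim = cfg.sim_config(s)
        table, epochs, eog, amp = syn.simulate_dataset(
            sim, artifact_fraction=cfg.artifact_fraction
        )
        d = _subdir(outdir, s)
        table.to_csv(d / "trials.csv", index=False)
        syn.save_meg_h5(d / "meg.h5", epochs, eog)
        np.savetxt(d / "true_amplitudes.csv", amp, delimiter=",")
        (d / "sim_config.json").write_text(sim.to_json())
        files += [d / "trials.csv", d / "meg.h5", d / "true_amplitudes.csv",
                  d / "sim_config.json"]
    return files


def stage_preprocess(cfg: StudyConfig, outdir) -> list:
    files = []
    for s in range(cfg.n_subjects):
        d = _subdir(outdir, s)
        table = pd.read_csv(d / "trials.csv")
        _, eog = syn.load_meg_h5(d / "meg.h5")
        events = eog_mod.detect_all_saccades(eog, table)
        clean, report = eog_mod.apply_exclusions(events, table, eog)
        events.to_csv(d / "saccades.csv", index=False)
        clean.to_csv(d / "trials_clean.csv", index=False)
        (d / "exclusions.json").write_text(
            json.dumps(
                {
                    "fraction_excluded": report.attrs["fraction_excluded"],
                    "reason_counts": report.attrs["reason_counts"],
                },
                indent=1,
            )
        )
        files += [d / "saccades.csv", d / "trials_clean.csv", d / "exclusions.json"]
    return files


def stage_regressors(cfg: StudyConfig, outdir) -> list:
    files = []
    for s in range(cfg.n_subjects):
        d = _subdir(outdir, s)
        clean = pd.read_csv(d / "trials_clean.csv")
        rt_col = "rt_measured" if "rt_measured" in clean else "rt"
        regs = rt_model.build_regressors(clean, rt_col=rt_col)
        out = pd.concat([clean.reset_index(drop=True), regs.to_frame().drop(columns=[])], axis=1)
        out.to_csv(d / "trials_reg.csv", index=False)
        (d / "ledger.json").write_text(json.dumps(regs.ledger.as_dict(), indent=1))
        files += [d / "trials_reg.csv", d / "ledger.json"]
    return files


REGRESSOR_COLUMNS = ("raw_rt", "rt_corrected", "rt_detrended")


def stage_beamform(cfg: StudyConfig, outdir) -> list:
    model = cfg.head_model()
    grid = sr.SourceGrid.build(model, spacing=cfg.grid_spacing).add_default_rois(model)
    outdir = Path(outdir)
    np.savez(
        outdir / "grid.npz",
        positions=grid.positions,
        spacing=grid.spacing,
        **{f"label_{k}": v for k, v in grid.labels.items()},
    )
    files = [outdir / "grid.npz"]
    for s in range(cfg.n_subjects):
        d = _subdir(outdir, s)
        epochs, _ = syn.load_meg_h5(d / "meg.h5")
        reg = pd.read_csv(d / "trials_reg.csv")
        single = reg[reg["condition"].isin(["left", "right"])]
        rows = single["trial_id"].to_numpy()
        choice = reg[reg["condition"] == "choice"]
        arrays = {}
        for band in cfg.bands:
            for window in cfg.windows:
                bw = sr.BandWindow(band=tuple(band), window=tuple(window))
                cov, _ = sr.global_covariance(epochs, bw)
                weights = sr.sam_weights(
                    cov, model, grid.positions,
                    epochs.channel_positions, epochs.channel_orientations,
                    bw=bw, regularization=cfg.regularization,
                )
                amp = sr.trial_band_amplitude(weights, epochs, bw)
                for col in REGRESSOR_COLUMNS:
                    vol = sr.correlational_sam(
                        amp[rows], single[col].to_numpy(), grid, bw, col
                    )
                    arrays[f"r__{bw.tag()}__{col}"] = vol.values
                if len(choice) >= 4 and choice["choice_made"].nunique() == 2:
                    cvol = sr.choice_contrast(
                        amp[choice["trial_id"].to_numpy()],
                        choice["choice_made"].to_numpy(),
                        grid, bw,
                    )
                    arrays[f"t__{bw.tag()}__choice"] = cvol.values
        np.savez(d / "sam_maps.npz", **arrays)
        files.append(d / "sam_maps.npz")
    return files


def stage_tf(cfg: StudyConfig, outdir) -> list:
    model = cfg.head_model()
    outdir = Path(outdir)
    freqs = np.arange(cfg.tf_freq_range[0], cfg.tf_freq_range[1] + 1.0)
    files = []
    for s in range(cfg.n_subjects):
        d = _subdir(outdir, s)
        epochs, _ = syn.load_meg_h5(d / "meg.h5")
        reg = pd.read_csv(d / "trials_reg.csv")
        single = reg[reg["condition"].isin(["left", "right"])]
        rows = single["trial_id"].to_numpy()
        electrodes = spectral.default_electrodes(model)
        weights = spectral.build_electrode_weights(
            epochs, electrodes, model, regularization=cfg.regularization
        )
        np.savez(
            d / "electrode_weights.npz",
            weights=weights.weights,
            positions=weights.positions,
            names=np.array([e.name for e in electrodes]),
        )
        files.append(d / "electrode_weights.npz")

        tf_by_elec = {}
        maps = {col: {} for col in ("raw_rt", "rt_detrended")}
        for i, e in enumerate(electrodes):
            proj = spectral.project_virtual_electrode(epochs, weights, i)[rows]
            tf = spectral.hilbert_tf(proj, epochs.sfreq, epochs.t0, freqs=freqs)
            tf_by_elec[e.name] = tf
            for col in maps:
                maps[col][e.name] = spectral.tf_correlation(
                    tf, single[col].to_numpy(),
                    bin_width=cfg.tf_bin_width, window=cfg.tf_window, tag=e.name,
                )

        # V1 amplitude regressor and V1-corrected RT
        v1_reg = spectral.v1_amplitude_regressor(tf_by_elec, band=cfg.bands[0])
        rt = single["raw_rt"].to_numpy()
        reg_full = pd.read_csv(d / "trials_reg.csv")
        reg_full.loc[reg_full["condition"].isin(["left", "right"]), "rt_v1corrected"] = (
            rt_model.correct_v1_power(rt, v1_reg)
        )
        reg_full.to_csv(d / "trials_reg.csv", index=False)

        # ROI-averaged r maps, fast/slow split, r time courses
        arrays = {}
        bin_centers = None
        for col, per_elec in maps.items():
            for roi, match in ROI_GROUPS.items():
                sel = [m for name, m in per_elec.items() if match(name)]
                avg = spectral.average_tf_maps(sel)
                arrays[f"tfr__{roi}__{col}"] = avg.values
                bin_centers = avg.bin_centers
        v1_tf_mean = spectral.TFTensor(
            amplitude=np.mean(
                [tf_by_elec[n].amplitude for n in tf_by_elec if n.startswith("V1-")],
                axis=0,
            ),
            phase=tf_by_elec["SEF"].phase,  # placeholder, unused below
            freqs=freqs,
            times=tf_by_elec["SEF"].times,
            sfreq=tf_by_elec["SEF"].sfreq,
        )
        fs = spectral.fast_slow_spectrum(
            v1_tf_mean, rt,
            tc_norm_window=(max(cfg.tf_window[0], epochs.t0 + 0.2), cfg.tf_window[0] + 1.0),
            bands=tuple(b for b in cfg.bands if b[1] <= freqs[-1]),
        )
        arrays["fastslow__freqs"] = fs["freqs"]
        arrays["fastslow__fast"] = fs["spectra"]["fast"]
        arrays["fastslow__slow"] = fs["spectra"]["slow"]
        arrays["tf__freqs"] = freqs
        arrays["tf__bins"] = bin_centers
        # r time course: mean r over the alpha band rows per time bin
        alpha_rows = (freqs >= cfg.bands[0][0]) & (freqs <= cfg.bands[0][1])
        for col in maps:
            for roi in ROI_GROUPS:
                arrays[f"rtc__{roi}__{col}"] = arrays[f"tfr__{roi}__{col}"][
                    alpha_rows
                ].mean(0)
        np.savez(d / "tf_maps.npz", **arrays)
        files.append(d / "tf_maps.npz")
        files.append(d / "trials_reg.csv")
    return files


def stage_itc(cfg: StudyConfig, outdir) -> list:
    model = cfg.head_model()
    outdir = Path(outdir)
    freqs = np.arange(cfg.itc_freq_range[0], cfg.itc_freq_range[1] + 1.0)
    files = []
    for s in range(cfg.n_subjects):
        d = _subdir(outdir, s)
        epochs, _ = syn.load_meg_h5(d / "meg.h5")
        reg = pd.read_csv(d / "trials_reg.csv")
        single = reg[reg["condition"].isin(["left", "right"])]
        rows = single["trial_id"].to_numpy()
        rt = single["raw_rt"].to_numpy()
        w = np.load(d / "electrode_weights.npz", allow_pickle=False)
        names = [str(n) for n in w["names"]]
        weights = sr.WeightSet(
            weights=w["weights"], orientations=np.zeros((len(names), 3)),
            positions=w["positions"], bw=sr.BandWindow(), regularization=cfg.regularization,
        )
        # coarse time sampling (~50 ms) is enough for the ITC maps
        decim = max(int(round(epochs.sfreq * 0.05)), 1)
        arrays = {"freqs": freqs}
        times = None
        for roi, match in ROI_GROUPS.items():
            t_maps = []
            for i, name in enumerate(names):
                if not match(name):
                    continue
                proj = spectral.project_virtual_electrode(epochs, weights, i)[rows]
                tf = spectral.hilbert_tf(
                    proj, epochs.sfreq, epochs.t0, freqs=freqs, decimate=decim
                )
                tsel = (tf.times >= cfg.itc_window[0]) & (tf.times <= cfg.itc_window[1])
                res = phase_itc.quintile_itc_test(
                    tf.phase[:, :, tsel], rt,
                    n_shuffles=cfg.itc_shuffles,
                    seed=cfg.subject_seed(s) + 7,
                    freqs=freqs, times=tf.times[tsel],
                )
                t_maps.append(res.t)
                times = tf.times[tsel]
            arrays[f"itc_t__{roi}"] = np.mean(t_maps, axis=0)
        arrays["times"] = times
        np.savez(d / "itc_maps.npz", **arrays)
        files.append(d / "itc_maps.npz")
    return files


def stage_group(cfg: StudyConfig, outdir) -> list:
    outdir = Path(outdir)
    g = np.load(outdir / "grid.npz")
    grid = sr.SourceGrid(positions=g["positions"], spacing=float(g["spacing"]))
    grid.labels = {
        k[len("label_"):]: g[k] for k in g.files if k.startswith("label_")
    }
    subject_sam = [
        np.load(_subdir(outdir, s) / "sam_maps.npz") for s in range(cfg.n_subjects)
    ]
    keys = [k for k in subject_sam[0].files if k.startswith("r__")]
    summary_rows = []
    group_maps = {}
    for key in keys:
        maps = np.stack([sub[key] for sub in subject_sam])
        maps = np.nan_to_num(maps, nan=0.0)
        res = group_stats.permutation_omnibus(maps, seed=cfg.master_seed)
        group_maps[f"group_mean__{key}"] = res.mean_map
        group_maps[f"group_p__{key}"] = res.p_corrected
        _, bwtag, regtag = key.split("__")
        for roi, mask in grid.labels.items():
            if not mask.any():
                continue
            mean_map = res.mean_map
            peak_lower = float(
                mean_map[mask][np.argmax(np.abs(mean_map[mask]))]
            )
            per_subj_peaks = [
                m[mask][np.argmax(np.abs(m[mask]))] for m in maps
            ]
            summary_rows.append(
                {
                    "band_window": bwtag,
                    "regressor": regtag,
                    "roi": roi,
                    "peak_r_lower": peak_lower,
                    "peak_r_upper": float(np.mean(per_subj_peaks)),
                    "min_p_omnibus": float(res.p_corrected[mask].min()),
                    "n_sig_voxels": int((res.p_corrected[mask] < 0.05).sum()),
                }
            )
    np.savez(outdir / "group_sam.npz", **group_maps)
    roi_summary = pd.DataFrame(summary_rows)
    roi_summary.to_csv(outdir / "group_roi_summary.csv", index=False)

    # TF maps: one-sample t across subjects per cell + FDR over the family
    subject_tf = [
        np.load(_subdir(outdir, s) / "tf_maps.npz") for s in range(cfg.n_subjects)
    ]
    tf_keys = [k for k in subject_tf[0].files if k.startswith("tfr__")]
    fam_p, fam_ctx, tf_group = [], [], {}
    freqs = subject_tf[0]["tf__freqs"]
    bins = subject_tf[0]["tf__bins"]
    for key in tf_keys:
        maps = np.stack([sub[key] for sub in subject_tf])
        t, p, _ = group_stats.one_sample_group_test(maps)
        tf_group[f"group_t__{key}"] = t
        tf_group[f"group_p__{key}"] = p
        _, roi, regtag = key.split("__")
        fi, bi = np.meshgrid(np.arange(len(freqs)), np.arange(len(bins)), indexing="ij")
        fam_p.append(p.ravel())
        fam_ctx.append(
            pd.DataFrame(
                {
                    "roi": roi,
                    "regressor": regtag,
                    "freq": freqs[fi.ravel()],
                    "time": bins[bi.ravel()],
                }
            )
        )
    fdr = group_stats.fdr_correct(
        np.concatenate(fam_p), q=cfg.fdr_q, context=pd.concat(fam_ctx, ignore_index=True)
    )
    fdr.context.to_csv(outdir / "group_tf_fdr.csv", index=False)
    np.savez(outdir / "group_tf.npz", freqs=freqs, bins=bins, **tf_group)

    # ITC: subject t maps against zero + FDR
    subject_itc = [
        np.load(_subdir(outdir, s) / "itc_maps.npz") for s in range(cfg.n_subjects)
    ]
    itc_group = {
        "freqs": subject_itc[0]["freqs"],
        "times": subject_itc[0]["times"],
    }
    itc_rows = []
    for roi in ROI_GROUPS:
        maps = np.stack([sub[f"itc_t__{roi}"] for sub in subject_itc])
        t, p, _ = group_stats.one_sample_group_test(maps)
        itc_group[f"group_t__{roi}"] = t
        itc_group[f"group_p__{roi}"] = p
        itc_rows.append(
            {"roi": roi, "min_p": float(p.min()), "n_sig_uncorrected": int((p < 0.05).sum())}
        )
    np.savez(outdir / "group_itc.npz", **itc_group)

    # r time-course trends
    rtc_rows = []
    for roi in ROI_GROUPS:
        for col in ("raw_rt", "rt_detrended"):
            series = np.stack([sub[f"rtc__{roi}__{col}"] for sub in subject_tf])
            slopes, t, p = spectral.r_timecourse_trend(
                series, bins, window=cfg.tf_window
            )
            rtc_rows.append(
                {"roi": roi, "regressor": col, "mean_slope": float(np.mean(slopes)),
                 "t": t, "p": p}
            )
    pd.DataFrame(rtc_rows).to_csv(outdir / "group_r_trends.csv", index=False)
    pd.DataFrame(itc_rows).to_csv(outdir / "group_itc_summary.csv", index=False)

    ledgers = [
        json.loads((_subdir(outdir, s) / "ledger.json").read_text())
        for s in range(cfg.n_subjects)
    ]
    group_summary = {
        "n_subjects": cfg.n_subjects,
        "mean_ledger": {
            k: float(np.mean([led[k] for led in ledgers])) for k in ledgers[0]
        },
        "n_group_significant_voxels": int(
            sum(
                (group_maps[k] < 0.05).sum()
                for k in group_maps
                if k.startswith("group_p__")
            )
        ),
    }
    (outdir / "group_summary.json").write_text(json.dumps(group_summary, indent=1))
    return [
        outdir / "group_sam.npz",
        outdir / "group_roi_summary.csv",
        outdir / "group_tf_fdr.csv",
        outdir / "group_tf.npz",
        outdir / "group_itc.npz",
        outdir / "group_itc_summary.csv",
        outdir / "group_r_trends.csv",
        outdir / "group_summary.json",
    ]


def stage_report(cfg: StudyConfig, outdir) -> list:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    files = []

    roi = pd.read_csv(outdir / "group_roi_summary.csv")
    fig, ax = plt.subplots(figsize=(9, 4))
    pivot = roi.pivot_table(
        index=["roi", "band_window"], columns="regressor", values="peak_r_lower"
    )
    pivot.plot.bar(ax=ax)
    ax.set_ylabel("peak r (group average)")
    ax.set_title("Peak power-RT correlation per ROI / band / regressor")
    fig.tight_layout()
    fig.savefig(outdir / "fig_roi_peaks.png", dpi=110)
    plt.close(fig)
    pivot.to_csv(outdir / "fig_roi_peaks.csv")
    files += [outdir / "fig_roi_peaks.png", outdir / "fig_roi_peaks.csv"]

    tf = np.load(outdir / "group_tf.npz")
    freqs, bins = tf["freqs"], tf["bins"]
    for roi_name in ROI_GROUPS:
        key = f"group_t__tfr__{roi_name}__raw_rt"
        if key not in tf:
            continue
        fig, ax = plt.subplots(figsize=(6, 4))
        im = ax.pcolormesh(bins, freqs, tf[key], shading="nearest", cmap="RdBu_r")
        fig.colorbar(im, ax=ax, label="group t of r(power, RT)")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("frequency (Hz)")
        ax.set_title(f"{roi_name}: power-RT correlation")
        fig.tight_layout()
        fig.savefig(outdir / f"fig_tf_{roi_name}.png", dpi=110)
        plt.close(fig)
        pd.DataFrame(tf[key], index=freqs, columns=np.round(bins, 3)).to_csv(
            outdir / f"fig_tf_{roi_name}.csv"
        )
        files += [outdir / f"fig_tf_{roi_name}.png", outdir / f"fig_tf_{roi_name}.csv"]

    sub0 = np.load(_subdir(outdir, 0) / "tf_maps.npz")
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(sub0["fastslow__freqs"], sub0["fastslow__fast"], "k", label="fast half")
    ax.plot(sub0["fastslow__freqs"], sub0["fastslow__slow"], "0.6", label="slow half")
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("normalized baseline power")
    ax.legend()
    ax.set_title("V1 baseline power, fast vs slow RT (subject 0)")
    fig.tight_layout()
    fig.savefig(outdir / "fig_fast_slow.png", dpi=110)
    plt.close(fig)
    pd.DataFrame(
        {
            "freq": sub0["fastslow__freqs"],
            "fast": sub0["fastslow__fast"],
            "slow": sub0["fastslow__slow"],
        }
    ).to_csv(outdir / "fig_fast_slow.csv", index=False)
    files += [outdir / "fig_fast_slow.png", outdir / "fig_fast_slow.csv"]

    itc = np.load(outdir / "group_itc.npz")
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.pcolormesh(
        itc["times"], itc["freqs"], itc["group_t__V1"], shading="nearest", cmap="RdBu_r"
    )
    fig.colorbar(im, ax=ax, label="group t of quintile-ITC t")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    ax.set_title("V1 phase-RT quintile ITC")
    fig.tight_layout()
    fig.savefig(outdir / "fig_itc_V1.png", dpi=110)
    plt.close(fig)
    files.append(outdir / "fig_itc_V1.png")

    summary = json.loads((outdir / "group_summary.json").read_text())
    trends = pd.read_csv(outdir / "group_r_trends.csv")
    report = {
        "group_summary": summary,
        "r_trends": trends.to_dict(orient="records"),
        "figures": [
            str(Path(f).relative_to(outdir)) for f in files if str(f).endswith(".png")
        ],
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=1))
    files.append(outdir / "report.json")
    return files


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "regressors": stage_regressors,
    "beamform": stage_beamform,
    "tf": stage_tf,
    "itc": stage_itc,
    "group": stage_group,
    "report": stage_report,
}

STAGE_DEPS = {
    "simulate": (),
    "preprocess": ("simulate",),
    "regressors": ("preprocess",),
    "beamform": ("regressors",),
    "tf": ("regressors",),
    "itc": ("tf",),
    "group": ("beamform", "tf", "itc"),
    "report": ("group",),
}


def run_stage(stage: str, cfg: StudyConfig, outdir, manifest: Manifest | None = None):
    """Run one named stage, enforcing its upstream dependencies."""
    if stage not in STAGE_FUNCS:
        raise PipelineError(f"unknown stage '{stage}'")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = manifest or Manifest(outdir, cfg)
    for dep in STAGE_DEPS[stage]:
        manifest.require(dep)
    t0 = time.perf_counter()
    files = STAGE_FUNCS[stage](cfg, outdir)
    manifest.record(stage, files, time.perf_counter() - t0)
    return manifest


def run_study(cfg: StudyConfig, outdir, force: bool = False) -> Manifest:
    """Execute all stages in order; completed stages are skipped unless
    ``force``.  Returns the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "study_config.yaml").write_text(cfg.to_yaml())
    manifest = Manifest(outdir, cfg)
    for stage in STAGES:
        if manifest.done(stage) and not force:
            continue
        run_stage(stage, cfg, outdir, manifest)
    return manifest
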