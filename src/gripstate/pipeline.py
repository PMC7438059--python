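"""End-to-end pipeline: simulate -> features -> events -> decode -> maps ->
latent dynamics -> NVA -> classify, with one JSON report.

Each stage draws its randomness from a seed derived deterministically from
the top-level seed, so the whole report is reproducible bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import behavior, classify, decoding, lfads, maps, nva
from .features import compute_band_features, build_lagged_design
from .simulate import SimulationConfig, simulate_session

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("gripstate")


@dataclass
class PipelineConfig:
    seed: int = 7
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    n_lags: int = 10
    decode_folds: int = 11
    map_folds: int = 10
    lfads_enabled: bool = True
    lfads_epochs: int = 200
    lfads_band: str = "high"
    lfads_factors: int | None = None
    nva_k: int = 3
    nva_smooth_bins: int = 5
    classify_method: str = "bagged_trees"
    classify_folds: int = 5
    n_shuffles: int = 0  # 0 disables the chance-level permutation stage
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        return cls(simulation=sim, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _stage(report, name):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, *exc):
            if exc[0] is not None:
                log.error("stage %s failed: %s", name, exc[1])
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc[1]}") from exc[1]
            dt = time.perf_counter() - self.t0
            report[name]["elapsed_s"] = round(dt, 3)
            log.info("stage %s: done in %.2fs", name, dt)

    report[name] = {}
    return _Timer()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on one synthetic session and return the JSON report."""
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(8)]
    report: dict = {"config": cfg.to_dict(), "seed": cfg.seed}

    with _stage(report, "simulate"):
        sim_cfg = cfg.simulation.replace(seed=seeds[0])
        session, true_trials, truth = simulate_session(sim_cfg)
        report["simulate"].update(
            n_trials=int(len(true_trials)),
            n_channels=int(session.signal.shape[0]),
            duration_s=round(session.duration_s, 3),
        )

    with _stage(report, "features"):
        feats = compute_band_features(session)
        design = build_lagged_design(feats, cfg.n_lags)
        report["features"].update(
            n_bins=int(feats.n_bins),
            n_features=int(feats.n_features),
            design_columns=int(design.values.shape[1]),
            step_s=feats.step_s,
        )

    with _stage(report, "events"):
        pc1 = behavior.kinematic_pc1(session.kinematics)
        trials = behavior.detect_onsets(
            pc1, session.force, session.cue_times_s, session.fs_hz
        )
        labels = behavior.label_modes(trials, feats.bin_times)
        report["events"].update(
            n_valid_trials=int(trials["valid"].sum()),
            n_labeled_bins=int(labels.labeled().sum()),
        )

    with _stage(report, "decode"):
        fs = session.fs_hz
        y_mov = decoding.sample_trace_at_bins(pc1, fs, design.bin_times)
        y_frc = decoding.sample_trace_at_bins(session.force, fs, design.bin_times)
        cv_mov = decoding.crossval_decode(design, y_mov, n_folds=cfg.decode_folds)
        cv_frc = decoding.crossval_decode(design, y_frc, n_folds=cfg.decode_folds)
        report["decode"].update(
            movement_fvaf_median=round(cv_mov.median, 4),
            movement_fvaf_iqr=round(cv_mov.iqr, 4),
            force_fvaf_median=round(cv_frc.median, 4),
            force_fvaf_iqr=round(cv_frc.iqr, 4),
            n_folds=cfg.decode_folds,
        )

    with _stage(report, "maps"):
        coords = session.channels[["x_mm", "y_mm"]].to_numpy(dtype=float)
        maps_mov = maps.single_electrode_maps(
            feats, y_mov, coords, "movement", n_folds=cfg.map_folds, n_lags=cfg.n_lags
        )
        maps_frc = maps.single_electrode_maps(
            feats, y_frc, coords, "force", n_folds=cfg.map_folds, n_lags=cfg.n_lags
        )
        comp = maps.compare_inter_intra(maps_mov, maps_frc)
        report["maps"].update(
            median_d_inter=round(comp.median_inter, 4),
            median_d_intra=round(comp.median_intra, 4),
            wilcoxon_p=float(comp.p_value),
            mean_peak_displacement_mm=round(float(comp.displacements_mm.mean()), 3),
            planted_shift_mm=cfg.simulation.planted_peak_shift_mm,
        )

    lat_traj = None
    with _stage(report, "lfads"):
        if cfg.lfads_enabled:
            windows = lfads.trial_feature_windows(feats, trials, band=cfg.lfads_band)
            model = lfads.fit_gaussian_lfads(
                windows,
                n_factors=cfg.lfads_factors,
                seed=seeds[5],
                epochs=cfg.lfads_epochs,
            )
            lat_traj = lfads.denoise(model, windows)
            flat_raw = windows.values.reshape(-1, windows.values.shape[-1])
            flat_den = lat_traj.mu.reshape(-1, lat_traj.mu.shape[-1])
            report["lfads"].update(
                band=cfg.lfads_band,
                n_factors=model.n_factors,
                final_elbo=round(float(model.elbo_history[-1]), 3),
                pcs90_raw=lfads.pcs_for_variance(flat_raw),
                pcs90_denoised=lfads.pcs_for_variance(flat_den),
            )
        else:
            report["lfads"].update(enabled=False)

    with _stage(report, "nva"):
        avg, _ = nva.trial_averaged_traces(feats, trials)
        bands = [b for _, b in feats.feature_index]
        clustering = nva.select_feature_clusters(avg, bands, k=cfg.nva_k, seed=seeds[6])
        res = nva.nva_time_course(
            feats, clustering, trials, smooth_bins=cfg.nva_smooth_bins
        )
        tests = nva.compare_modes_nva(res, trials)
        report["nva"].update(
            k=cfg.nva_k,
            selected_clusters={t: int(c) for t, c in clustering.selected.items()},
            kruskal_p={t: tests[t]["p"] for t in tests},
            mode_medians={t: tests[t]["medians"] for t in tests},
        )

    with _stage(report, "classify"):
        lab = labels.codes[cfg.n_lags - 1 :]
        tid = labels.trial_of_bin[cfg.n_lags - 1 :]
        keep = lab != behavior.UNLABELED
        X = design.values[keep]
        res_feat = classify.classify_modes(
            X, lab[keep], method=cfg.classify_method,
            n_folds=cfg.classify_folds, seed=seeds[7],
        )
        report["classify"].update(
            method=cfg.classify_method,
            accuracy_median=round(res_feat.median, 4),
            accuracy_iqr=round(res_feat.iqr, 4),
        )
        if lat_traj is not None:
            # classify from denoised features on the same peri-event bins
            win = lfads.trial_feature_windows(feats, trials, band=cfg.lfads_band)
            den = lat_traj.mu.reshape(-1, lat_traj.mu.shape[-1])
            win_modes = _window_mode_labels(win, trials, feats.step_s)
            keep_w = win_modes.ravel() != behavior.UNLABELED
            if len(np.unique(win_modes.ravel()[keep_w])) == 3:
                res_den = classify.classify_modes(
                    den[keep_w], win_modes.ravel()[keep_w],
                    method=cfg.classify_method, n_folds=cfg.classify_folds,
                    seed=seeds[7], input_kind="lfads_denoised",
                )
                cmpres = classify.compare_inputs(res_feat, res_den)
                report["classify"].update(
                    denoised_accuracy_median=round(res_den.median, 4),
                    feature_vs_denoised_p=cmpres["p"],
                )
        if cfg.n_shuffles:
            chance = classify.chance_level(
                X, lab[keep], n_shuffles=cfg.n_shuffles, seed=seeds[7],
                method=cfg.classify_method, n_folds=cfg.classify_folds,
                trial_ids=tid[keep],
            )
            report["classify"]["chance_mean"] = round(float(chance.mean()), 4)
            report["classify"]["chance_p975"] = round(
                float(np.percentile(chance, 97.5)), 4
            )

    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report


def _window_mode_labels(win, trials, step_s):
    """Mode code per (trial, peri-event bin) of a trial feature window."""
    modes = np.zeros((win.values.shape[0], win.values.shape[1]), dtype=np.int8)
    for i, ti in enumerate(win.trial_index):
        tr = trials.loc[ti]
        t_abs = tr["force_onset_s"] + win.rel_times
        modes[i][(t_abs >= tr["cue_time_s"]) & (t_abs < tr["movement_onset_s"])] = behavior.PREMOVEMENT
        modes[i][(t_abs >= tr["movement_onset_s"]) & (t_abs < tr["force_onset_s"])] = behavior.MOVEMENT
        modes[i][(t_abs >= tr["force_onset_s"]) & (t_abs < tr["force_onset_s"] + 0.5)] = behavior.FORCE
    return modes
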