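"""Staged pipeline: simulate -> filter -> fit -> states -> predict -> report.

Configuration is a YAML-loadable, schema-validated model (unknown keys
rejected).  Every stage writes its artifacts plus a ``manifest_<stage>.json``
recording the configuration hash, so reruns are reproducible and
incremental: each stage reads only the files earlier stages wrote into
the run directory.  All randomness is routed through seeds derived
deterministically from the single top-level seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator

from . import ensemble as ens
from . import macro, mappings, mvmodel, spectral, synth

__all__ = ["GeneratorConfig", "EstimatorConfig", "PipelineConfig",
           "load_config", "run_pipeline", "write_report", "STAGES"]

log = logging.getLogger("betaclc")

STAGES = ("simulate", "filter", "fit", "states", "predict", "report")
TASKS = ("BC", "MC")


class GeneratorConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    duration_s: float = 120.0
    n_trials: int = 60
    n_units: int = 6
    f0: float = 28.0
    psd_peak_level_db: float = -46.0
    hemi_kappa: float = 2.0
    kappa_intercept: float = 2.67
    kappa_slope_per_mm: float = -0.4435
    desync: bool = True


class EstimatorConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_bins: int = 25
    n_ab: int = 8
    n_pb: int = 16
    n_perm: int = 200
    subset_sizes: list[int] = [4, 16]
    n_predict_channels: int = 16


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    out_dir: str = "betaclc_run"
    stages: list[str] = list(STAGES)
    generator: GeneratorConfig = GeneratorConfig()
    estimator: EstimatorConfig = EstimatorConfig()

    @field_validator("stages")
    @classmethod
    def _known_stages(cls, v):
        for s in v:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}; expected one of {STAGES}")
        return v

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | None = None, **overrides) -> PipelineConfig:
    """Load a YAML config file; unknown keys raise a schema error."""
    data = {}
    if path is not None:
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update(overrides)
    return PipelineConfig(**data)


def _manifest(cfg: PipelineConfig, out: str, stage: str, files: list) -> None:
    with open(os.path.join(out, f"manifest_{stage}.json"), "w") as fh:
        json.dump({"stage": stage, "config_hash": cfg.config_hash(),
                   "files": sorted(files)}, fh, indent=1)


def _meso_path(out, task):
    return os.path.join(out, f"meso_{task}.h5")


def _save_meso(path, meso: synth.MesoLFP):
    import h5py
    with h5py.File(path, "w") as fh:
        for k in ("s_L", "s_R", "phase_diff", "gain"):
            fh.create_dataset(k, data=getattr(meso, k).astype(np.float32))
        fh.attrs["fs"] = meso.fs
        fh.attrs["f0"] = meso.f0


def _load_meso(path):
    import h5py
    with h5py.File(path, "r") as fh:
        return {k: fh[k][...].astype(float) for k in ("s_L", "s_R")} | {
            "fs": float(fh.attrs["fs"]), "f0": float(fh.attrs["f0"])}


def _analytic(meso, fs, f0):
    return spectral.normalize_amplitude(spectral.filter_signal(meso, f0, fs=fs))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: PipelineConfig, out: str) -> list:
    g = cfg.generator
    files = []
    units = synth.default_ensemble(g.n_units, seed=cfg.seed)
    gt_path = os.path.join(out, "ground_truth.json")
    synth.export_ground_truth(units, gt_path)
    files.append(gt_path)
    for ti, task in enumerate(TASKS):
        trials = synth.generate_trials(task, g.n_trials, seed=cfg.seed + 10 + ti)
        # keep the trial block inside the recording
        span = trials["t_reward_off"].max() / 1000.0
        if span > g.duration_s - 1.0:
            keep = trials["t_reward_off"] / 1000.0 <= g.duration_s - 1.0
            trials = trials[keep].reset_index(drop=True)
        synth.validate_trials(trials)
        meso = synth.generate_meso_lfp(
            trials, g.duration_s, psd_peak_freq=g.f0,
            psd_peak_level_db=g.psd_peak_level_db,
            desync=synth.DesyncProfile() if g.desync else None,
            hemi_kappa=g.hemi_kappa, seed=cfg.seed + 20 + ti,
        )
        arr = synth.generate_array_lfp(
            meso.s_L, seed=cfg.seed + 30 + ti,
            kappa_law=(g.kappa_intercept, g.kappa_slope_per_mm),
            v0=g.f0, fs=meso.fs,
        )
        sig_l = _analytic(meso.s_L, meso.fs, g.f0)
        sig_r = _analytic(meso.s_R, meso.fs, g.f0)
        phi = macro.phase_difference(sig_l, sig_r)
        trains = [
            synth.generate_spikes(u, task, sig_l, phi.phi, trials,
                                  seed=cfg.seed + 100 + 10 * ti + ui)
            for ui, u in enumerate(units)
        ]
        for tr in trains:
            tr.validate()
        tr_path = os.path.join(out, f"trials_{task}.csv")
        trials.to_csv(tr_path, index=False)
        sp_path = os.path.join(out, f"spikes_{task}.csv")
        synth.spikes_to_csv(trains, sp_path)
        ms_path = _meso_path(out, task)
        _save_meso(ms_path, meso)
        ar_path = os.path.join(out, f"array_{task}.h5")
        synth.save_lfp_h5(ar_path, arr)
        files += [tr_path, sp_path, ms_path, ar_path]
    return files


def _stage_filter(cfg: PipelineConfig, out: str) -> list:
    files = []
    for task in TASKS:
        m = _load_meso(_meso_path(out, task))
        trials = pd.read_csv(os.path.join(out, f"trials_{task}.csv"))
        sig = _analytic(m["s_L"], m["fs"], m["f0"])
        win = (-1000.0, 2000.0)
        t, trace = spectral.event_locked_average(
            sig.amplitude, trials["t_go"].to_numpy(), win, m["fs"])
        path = os.path.join(out, f"beta_amp_golocked_{task}.csv")
        pd.DataFrame({"t_ms": t, "amplitude": trace}).to_csv(path, index=False)
        files.append(path)
    return files


def _unit_series(cfg, out, task):
    m = _load_meso(_meso_path(out, task))
    sig_l = _analytic(m["s_L"], m["fs"], m["f0"])
    sig_r = _analytic(m["s_R"], m["fs"], m["f0"])
    phi = macro.phase_difference(sig_l, sig_r)
    trials = pd.read_csv(os.path.join(out, f"trials_{task}.csv"))
    trains = synth.spikes_from_csv(os.path.join(out, f"spikes_{task}.csv"),
                                   len(sig_l.z), m["fs"])
    return sig_l, phi, trials, trains, m["fs"]


def _stage_fit(cfg: PipelineConfig, out: str) -> list:
    e = cfg.estimator
    records = []
    for task in TASKS:
        sig, phi, trials, trains, fs = _unit_series(cfg, out, task)
        amp, ph, valid = sig.amplitude, sig.phase, sig.valid
        for ui, tr in enumerate(trains):
            rec = {"unit_id": tr.unit_id, "task": task}
            am = mappings.equal_count_binning(amp, tr, e.n_bins, fs, valid=valid,
                                              name="amplitude")
            s = mappings.fit_sigmoid(am)
            rec["sigmoid"] = dict(zip("p1 p2 p3 p4".split(), map(float, s.params)))
            rec["sigmoid"]["r2"] = s.r2
            pm = mappings.equal_count_binning(ph, tr, e.n_bins, fs, valid=valid,
                                              name="phase")
            c = mappings.fit_cosine(pm)
            rec["cosine"] = dict(zip("p1 p2 p3".split(), map(float, c.params)))
            rec["cosine"]["r2"] = c.r2
            dm = mappings.equal_count_binning(phi.phi, tr, e.n_bins, fs,
                                              valid=valid & phi.valid,
                                              name="phase_diff")
            try:
                v = mappings.fit_vonmises_rate(dm)
                rec["vonmises"] = dict(zip("p1 p2 p3 p4".split(), map(float, v.params)))
                rec["vonmises"]["r2"] = v.r2
            except mappings.FitError as exc:
                rec["vonmises"] = {"error": str(exc)}
            try:
                jb = mappings.joint_binning(amp, ph, tr, e.n_ab, e.n_pb, fs,
                                            valid=valid)
                b = mappings.fit_beta_rate(jb)
                rec["beta"] = {f"p{i+1}": float(p) for i, p in enumerate(b.p)}
                rec["beta"]["r2"] = b.r2
            except (ValueError, mappings.FitError) as exc:
                rec["beta"] = {"error": str(exc)}
            rec["perm_p_amp"] = mappings.permutation_test(
                amp, tr, e.n_bins, e.n_perm, seed=cfg.seed + 1000 + ui,
                fs=fs, valid=valid)
            halves = mappings.split_half_fits(amp, tr, trials,
                                              mappings.fit_sigmoid,
                                              e.n_bins, fs, valid=valid)
            rec["split_half"] = {
                k: dict(zip("p1 p2 p3 p4".split(), map(float, f.params)))
                for k, (_, f) in halves.items()
            }
            records.append(rec)
    path = os.path.join(out, "fits.json")
    with open(path, "w") as fh:
        json.dump({"config_hash": cfg.config_hash(), "fits": records}, fh, indent=1)
    return [path]


def _stage_states(cfg: PipelineConfig, out: str) -> list:
    with open(os.path.join(out, "fits.json")) as fh:
        fits = json.load(fh)["fits"]
    files = []
    for task in TASKS:
        recs = [r for r in fits if r["task"] == task]
        sigs = [mappings.SigmoidFit(**{k: r["sigmoid"][k]
                                       for k in ("p1", "p2", "p3", "p4")})
                for r in recs]
        seq = ens.rank_order_states(sigs, domain=(0.2, 2.5),
                                    unit_ids=[r["unit_id"] for r in recs])
        rows = [{"interval_lo": lo, "interval_hi": hi,
                 "permutation": "-".join(str(i) for i in perm)}
                for (lo, hi), perm in zip(seq.intervals, seq.permutations)]
        p = os.path.join(out, f"states_{task}.csv")
        pd.DataFrame(rows).to_csv(p, index=False)
        cos = {r["unit_id"]: mappings.CosineFit(
            r["cosine"]["p1"], r["cosine"]["p2"], r["cosine"]["p3"])
            for r in recs}
        tt = ens.timing_table(cos, cfg.generator.f0)
        p2 = os.path.join(out, f"timing_{task}.csv")
        tt.to_csv(p2, index=False)
        files += [p, p2]
    return files


def _stage_predict(cfg: PipelineConfig, out: str) -> list:
    g, e = cfg.generator, cfg.estimator
    data = {}
    for task in TASKS:
        arr = synth.load_lfp_h5(os.path.join(out, f"array_{task}.h5"))
        chans = mvmodel.nested_channel_subsets(
            arr.coords_mm, sizes=(e.n_predict_channels,))[e.n_predict_channels]
        z, valid = mvmodel.filter_channels(arr.data, g.f0, arr.fs)
        trials = pd.read_csv(os.path.join(out, f"trials_{task}.csv"))
        trains = synth.spikes_from_csv(os.path.join(out, f"spikes_{task}.csv"),
                                       z.shape[1], arr.fs)
        unit = max(trains, key=lambda t: t.n_spikes)
        n = z.shape[1]
        odd = mappings.trial_sample_mask(trials, n, arr.fs, "odd")
        even = mappings.trial_sample_mask(trials, n, arr.fs, "even")
        data[task] = {"z": z, "z_sub": z[chans], "valid": valid, "spikes": unit,
                      "train_mask": odd, "test_mask": even,
                      "coords": arr.coords_mm}
    transfer = mvmodel.cross_task_transfer(
        {t: {"z": d["z_sub"], "valid": d["valid"], "spikes": d["spikes"],
             "train_mask": d["train_mask"], "test_mask": d["test_mask"]}
         for t, d in data.items()})
    rows = [{"train_task": a, "test_task": b, **v}
            for (a, b), v in transfer.items()]
    d = data["BC"]
    subsets = mvmodel.channel_subset_analysis(
        d["z"], d["valid"], d["spikes"], d["spikes"],
        d["train_mask"], d["test_mask"], d["coords"],
        sizes=tuple(e.subset_sizes))
    sub_rows = [{"n_channels": s, "slope": v["slope"], "r2": v["r2"],
                 "measured_range": v["measured_range"]}
                for s, v in subsets.items()]
    p1 = os.path.join(out, "prediction_transfer.csv")
    pd.DataFrame(rows).to_csv(p1, index=False)
    p2 = os.path.join(out, "prediction_subsets.csv")
    pd.DataFrame(sub_rows).to_csv(p2, index=False)
    return [p1, p2]


def run_pipeline(cfg: PipelineConfig) -> str:
    """Execute the configured stages into the run directory; returns its path."""
    out = cfg.out_dir
    os.makedirs(out, exist_ok=True)
    runners = {
        "simulate": _stage_simulate,
        "filter": _stage_filter,
        "fit": _stage_fit,
        "states": _stage_states,
        "predict": _stage_predict,
        "report": lambda c, o: write_report(o),
    }
    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        t0 = time.perf_counter()
        log.info("stage %s: starting", stage)
        try:
            files = runners[stage](cfg, out)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        _manifest(cfg, out, stage, list(files))
        log.info("stage %s: done in %.1f s", stage, time.perf_counter() - t0)
    return out


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def write_report(run_dir: str) -> list:
    """Summary figures and tables from a completed (or partial) run.

    Missing inputs are listed; sections whose stage did not run are marked
    skipped in ``report/summary.json``.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rep = os.path.join(run_dir, "report")
    os.makedirs(rep, exist_ok=True)
    summary = {"sections": {}, "missing": []}
    files = []

    fits_path = os.path.join(run_dir, "fits.json")
    if os.path.exists(fits_path):
        with open(fits_path) as fh:
            fits = json.load(fh)["fits"]
        units = sorted({r["unit_id"] for r in fits})
        summary["units"] = units
        fig, ax = plt.subplots(figsize=(6, 4))
        a = np.linspace(0.2, 2.5, 200)
        for r in fits:
            s = r["sigmoid"]
            curve = s["p1"] + s["p2"] * np.tanh((a - s["p3"]) / (2 * s["p4"]))
            ax.plot(a, curve, color="red" if r["task"] == "BC" else "blue",
                    alpha=0.6)
        ax.set_xlabel("beta amplitude (mean = 1)")
        ax.set_ylabel("spike rate (spikes/s)")
        ax.set_title("amplitude-to-rate mappings (BC red, MC blue)")
        p = os.path.join(rep, "amplitude_to_rate.png")
        fig.savefig(p, dpi=100)
        plt.close(fig)
        files.append(p)

        # split-half parameter scatter
        fig, ax = plt.subplots(figsize=(4, 4))
        for r in fits:
            sh = r.get("split_half", {})
            if "odd" in sh and "even" in sh:
                ax.scatter(sh["odd"]["p2"], sh["even"]["p2"],
                           color="red" if r["task"] == "BC" else "blue")
        ax.set_xlabel("p2 (odd trials)")
        ax.set_ylabel("p2 (even trials)")
        ax.set_title("split-half stability of the sigmoid half-range")
        p = os.path.join(rep, "split_half_scatter.png")
        fig.savefig(p, dpi=100)
        plt.close(fig)
        files.append(p)
        summary["sections"]["fits"] = "ok"

        gt_path = os.path.join(run_dir, "ground_truth.json")
        if os.path.exists(gt_path):
            units_gt = synth.load_ground_truth(gt_path)
            rows = []
            for u in units_gt:
                for task, p_ in u.tasks.items():
                    rec = next((r for r in fits
                                if r["unit_id"] == u.unit_id and r["task"] == task),
                               None)
                    if rec is None:
                        continue
                    rows.append({
                        "unit_id": u.unit_id, "task": task,
                        "true_baseline": p_.r_baseline,
                        "fit_p1": rec["sigmoid"]["p1"],
                        "true_amp_p2": p_.amp_p2,
                        "fit_p2": rec["sigmoid"]["p2"],
                        "true_phase_pref": p_.phase_pref,
                        "fit_phase_pref": rec["cosine"]["p3"],
                    })
            p = os.path.join(rep, "recovered_vs_true.csv")
            pd.DataFrame(rows).to_csv(p, index=False)
            files.append(p)
            summary["sections"]["ground_truth"] = "ok"
        else:
            summary["missing"].append(gt_path)
    else:
        summary["missing"].append(fits_path)
        summary["sections"]["fits"] = "skipped"

    pred_path = os.path.join(run_dir, "prediction_transfer.csv")
    if os.path.exists(pred_path):
        df = pd.read_csv(pred_path)
        fig, ax = plt.subplots(figsize=(5, 4))
        labels = [f"{a}->{b}" for a, b in zip(df.train_task, df.test_task)]
        ax.bar(labels, df.r2)
        ax.set_ylabel("prediction r^2")
        ax.set_title("within- vs cross-task predictability")
        p = os.path.join(rep, "prediction_transfer.png")
        fig.savefig(p, dpi=100)
        plt.close(fig)
        files.append(p)
        summary["sections"]["prediction"] = "ok"
    else:
        summary["sections"]["prediction"] = "skipped"

    with open(os.path.join(rep, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1)
    files.append(os.path.join(rep, "summary.json"))
    return files
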