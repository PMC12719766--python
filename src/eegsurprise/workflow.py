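"""Configuration and orchestration binding the stages into reproducible runs.

Each stage reads its inputs from and writes its outputs to a run directory in
open formats (delimited text, JSON, HDF5 for epochs). A single top-level seed
fans out deterministically to all stage seeds, and the effective configuration
is echoed into ``provenance.json`` so a run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from eegsurprise import encoding, erp_peaks, rsa
from eegsurprise.eeg_preprocess import Epochs, PARIETO_OCCIPITAL_ROI
from eegsurprise.exceptions import EEGSurpriseError
from eegsurprise.feature_models import MODEL_ORDER, RDM
from eegsurprise.synthetic_data import GeneratorSpec, synth_cohort


@dataclasses.dataclass
class RunConfig:
    """Stage parameters with study-scale defaults and a reduced fast profile."""

    out_dir: str = "runs/demo"
    seed: int = 0
    fast_test: bool = False
    n_participants: int = 38
    n_blocks: int = 8
    n_channels: int = 64
    sfreq: float = 256.0
    epoch_window: tuple[float, float] = (-0.8, 1.0)
    n_perm: int = 100_000
    alpha_form: float = 0.05
    roi: tuple[str, ...] = PARIETO_OCCIPITAL_ROI
    onset_window: tuple[float, float] = (0.0, 0.2)

    def __post_init__(self) -> None:
        if self.fast_test:
            self.n_participants = min(self.n_participants, 8)
            self.n_blocks = min(self.n_blocks, 2)
            self.n_perm = min(self.n_perm, 1_000)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise EEGSurpriseError(f"unknown config keys: {sorted(unknown)}")
        for key in ("epoch_window", "roi", "onset_window"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def generator_spec(self) -> GeneratorSpec:
        return GeneratorSpec(
            n_participants=self.n_participants,
            n_blocks=self.n_blocks,
            n_channels=self.n_channels,
            sfreq=self.sfreq,
            epoch_window=self.epoch_window,
            seed=self.seed,
        )


def _out(cfg: RunConfig) -> Path:
    p = Path(cfg.out_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _log(stage: str, started: float, **counts) -> None:
    extra = ", ".join(f"{k}={v}" for k, v in counts.items())
    print(f"[eegsurprise] {stage}: {time.time() - started:.1f} s ({extra})")


def _epoch_path(out: Path, p: int) -> Path:
    return out / f"epochs_p{p:02d}.h5"


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise EEGSurpriseError(f"missing artifact {path}; run `{producer}` first")
    return path


def cmd_simulate(cfg: RunConfig) -> Path:
    """Generate the synthetic dataset (epochs, trials, feature RDMs) on disk."""
    t0 = time.time()
    out = _out(cfg)
    spec = cfg.generator_spec()
    _, rdms_all, trials_all, epochs = synth_cohort(spec, lazy=True)
    for p, rdms in enumerate(rdms_all):
        for m, r in rdms.items():
            r.to_csv(out / f"rdm_{m}_p{p:02d}.csv")
    n = 0
    for p, e in enumerate(epochs):
        e.save_h5(_epoch_path(out, p))
        n += e.n_trials
    all_trials = pd.concat(trials_all, ignore_index=True)
    all_trials.to_csv(out / "trials.csv", index=False)
    provenance = {"config": dataclasses.asdict(cfg), "stage_seeds": {"generator": cfg.seed}}
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, default=str))
    _log("simulate", t0, participants=spec.n_participants, trials=n)
    return out


def _load_rdms(cfg: RunConfig, out: Path) -> list[dict[str, RDM]]:
    return [
        {
            m: RDM.from_csv(_require(out / f"rdm_{m}_p{p:02d}.csv", "simulate"),
                            metric_tag=m)
            for m in MODEL_ORDER
        }
        for p in range(cfg.n_participants)
    ]


def _load_epochs(cfg: RunConfig, out: Path):
    for p in range(cfg.n_participants):
        yield Epochs.load_h5(_require(_epoch_path(out, p), "simulate"))


def cmd_rdm(cfg: RunConfig) -> Path:
    """Write the five model RDM files for the configured stimulus set."""
    t0 = time.time()
    out = _out(cfg)
    from eegsurprise.synthetic_data import build_model_rdms, synth_feature_bank

    stimuli = synth_feature_bank(seed=cfg.seed)
    for m, r in build_model_rdms(stimuli, seed=cfg.seed).items():
        r.to_csv(out / f"rdm_{m}.csv")
    _log("rdm", t0, models=len(MODEL_ORDER))
    return out


def _cluster_rows(results: dict[str, encoding.ClusterResult]) -> list[dict]:
    rows = []
    for m, res in results.items():
        if not res.clusters:
            rows.append({"model": m, "t_start_ms": None, "t_end_ms": None,
                         "sign": None, "mass": None, "p_cluster": None,
                         "t_extreme": None, "significant": False})
        for c in res.clusters:
            rows.append({
                "model": m,
                "t_start_ms": round(c.t_start * 1000.0, 1),
                "t_end_ms": round(c.t_end * 1000.0, 1),
                "sign": c.sign,
                "mass": c.mass,
                "p_cluster": c.p_cluster,
                "t_extreme": c.t_extreme,
                "significant": c.p_cluster < 0.05,
            })
    return rows


def cmd_encode(cfg: RunConfig) -> Path:
    """ERP scaling analysis: betas per participant/model plus cluster stats."""
    t0 = time.time()
    out = _out(cfg)
    rdms = _load_rdms(cfg, out)
    bt, results, prov = encoding.run_erp_scaling(
        _load_epochs(cfg, out), rdms, roi=cfg.roi, n_perm=cfg.n_perm,
        alpha_form=cfg.alpha_form, seed=cfg.seed,
    )
    np.save(out / "betas.npy", bt.betas)
    pd.DataFrame(
        bt.betas.mean(axis=0).T, index=pd.Index(bt.times, name="time_s"),
        columns=bt.model_names,
    ).to_csv(out / "betas_groupmean.csv")
    (out / "encode_clusters.json").write_text(
        json.dumps({"provenance": prov, "clusters": _cluster_rows(results)},
                   indent=2, default=str)
    )
    _log("encode", t0, participants=bt.betas.shape[0], models=len(bt.model_names))
    return out


def cmd_rsa(cfg: RunConfig) -> Path:
    """Time-resolved RSA with cluster inference and jackknife onset latencies."""
    t0 = time.time()
    out = _out(cfg)
    rdms = _load_rdms(cfg, out)
    tc = rsa.rsa_timecourse(_load_epochs(cfg, out), rdms, model_order=MODEL_ORDER)
    results = rsa.rsa_group_inference(tc, n_perm=cfg.n_perm,
                                      alpha_form=cfg.alpha_form, seed=cfg.seed)
    np.save(out / "rsa_tau.npy", tc.tau)
    pd.DataFrame(
        tc.tau.mean(axis=0).T, index=pd.Index(tc.times, name="time_s"),
        columns=tc.model_names,
    ).to_csv(out / "rsa_tau_groupmean.csv")
    onsets = {}
    for m in tc.model_names:
        try:
            est = rsa.jackknife_onset(tc.for_model(m), tc.times, window=cfg.onset_window)
            onsets[m] = {
                "group_mean_ms": est.group_mean_ms,
                "grand_average_onset_ms": est.grand_average_onset_ms,
                "onsets_ms": est.onsets_ms.tolist(),
            }
        except EEGSurpriseError as exc:
            onsets[m] = {"error": str(exc)}
    (out / "rsa_clusters.json").write_text(
        json.dumps({"clusters": _cluster_rows(results), "onsets": onsets},
                   indent=2, default=str)
    )
    _log("rsa", t0, models=len(tc.model_names))
    return out


def cmd_peaks(cfg: RunConfig) -> Path:
    """Individual ERP peak betas with FDR-corrected frequentist + Bayes stats."""
    t0 = time.time()
    out = _out(cfg)
    _require(out / "betas.npy", "encode")
    betas = np.load(out / "betas.npy")
    erps, times = [], None
    for e in _load_epochs(cfg, out):
        times = e.times
        from eegsurprise.eeg_preprocess import roi_average

        erps.append(roi_average(e, cfg.roi).mean(axis=0))
    peaks = erp_peaks.detect_peaks(np.stack(erps), times)
    table = erp_peaks.peak_beta_table(betas, times, peaks, MODEL_ORDER)
    rows = []
    for (comp, model), grp in table.groupby(["component", "model"], sort=False):
        res = erp_peaks.group_onesample(grp.sort_values("participant")["beta"].to_numpy())
        rows.append({"component": comp, "model": model, "mean_beta": res.estimate,
                     "t": res.t, "df": res.df, "p_raw": res.p_raw, "d_z": res.d_z,
                     "bf10": res.bf10})
    stat = pd.DataFrame(rows)
    stat["p_fdr"] = erp_peaks.fdr_bh(stat["p_raw"])  # ERPs × models family
    peaks.to_csv(out / "peaks.csv", index=False)
    stat.to_csv(out / "peak_stats.csv", index=False)
    _log("peaks", t0, tests=len(stat))
    return out


def cmd_report(cfg: RunConfig) -> dict:
    """Summarize a finished run: cluster tables, onsets, peak stats, behavior."""
    t0 = time.time()
    out = _out(cfg)
    report: dict = {}
    enc = out / "encode_clusters.json"
    if enc.exists():
        report["encoding_clusters"] = json.loads(enc.read_text())["clusters"]
    rsa_file = out / "rsa_clusters.json"
    if rsa_file.exists():
        report["rsa"] = json.loads(rsa_file.read_text())
    stats_file = out / "peak_stats.csv"
    if stats_file.exists():
        report["peak_stats"] = pd.read_csv(stats_file).to_dict(orient="records")
    trials_file = out / "trials.csv"
    if trials_file.exists():
        trials = pd.read_csv(trials_file)
        beh = erp_peaks.behavioral_summary(trials)
        report["behavior"] = {
            "conditions": beh["conditions"],
            "rt_ms_means": beh["rt_ms"]["means"].round(1).tolist(),
            "accuracy_means": (100 * beh["accuracy"]["means"]).round(1).tolist(),
            "rt_anova": dataclasses.asdict(beh["rt_ms"]["anova"]),
            "accuracy_anova": dataclasses.asdict(beh["accuracy"]["anova"]),
        }
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    _log("report", t0, sections=len(report))
    return report
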