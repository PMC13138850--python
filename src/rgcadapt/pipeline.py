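"""Pipeline orchestration: simulate -> fit -> adapt -> evaluate -> rf ->
spectra -> report, driven by one TOML config and a master seed.

Stages communicate only through documented files in the run directory
(HDF5 stimuli/responses, JSON parameters, CSV tables); a manifest records
the config hash, per-stage seeds and completion flags so interrupted runs
can resume.  All randomness flows from the master seed via named per-stage
child seeds, so a config + seed pair reproduces its outputs exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .evaluation import CellEvaluation, compare_id_ood, odd_even_reliability, held_out_correlation
from .experiments import ExperimentConfig
from .io import load_params, load_responses, load_stimulus, save_params, save_responses, save_stimulus
from .ln_models import build_spatiotemporal_rf, params_to_json
from .receptive_fields import (
    clip_small,
    fit_dog_posthoc,
    mean_receptive_field,
    posthoc_center_size,
    posthoc_surround_strength,
    rf_metrics_dog,
    smoothed_surround_amplitude,
    threshold_center_size,
)
from .spectral import (
    band_from_transfer,
    filtered_spectrum,
    make_simulated_filters,
    stimulus_power_spectrum,
    transfer_function,
    whitening_percent,
)
from .synthetic_data import (
    PopulationSpec,
    StimulusGeometry,
    default_population_spec,
    generate_natural_surrogate,
    generate_white_noise,
    make_ground_truth_population,
    simulate_rgc,
    stage_seed,
)
from .training import FitConfig, adapt_ood, compute_sta, default_lr, equalize_training_frames, fit_ln
from scipy import stats

__all__ = ["RunConfig", "run_all", "resume", "load_config", "STAGES"]

STAGES = ("simulate", "fit", "adapt", "evaluate", "rf", "spectra", "report")


@dataclass
class RunConfig:
    """Declarative description of one full synthetic analysis run.

    The named defaults carry the emulated study's constants: 85 Hz frames,
    15x15 crops, 30-frame filters, learning rates 0.009/0.005/0.001,
    early-stop/scheduler patiences 30/15, learning-rate floor 1e-7, +-6
    frame surround window, Kaiser beta 7, 20% threshold, smoothing sigma
    1.5 — see the module defaults they reference.
    """

    seed: int = 0
    geometry: StimulusGeometry = field(default_factory=StimulusGeometry)
    n_trials: int = 6
    train_seconds: float = 20.0
    test_seconds: float = 5.0
    contrast: float = 0.3
    jitter_sd: float = 1.0
    temporal_corr: float = 0.95
    wn_distribution: str = "binary"
    n_per_type: int = 10
    adapt_population: bool = True
    model_kinds: tuple[str, ...] = ("dog",)
    max_epochs: int = 500
    batch_bins: int = 256
    surround_window: int = 6
    spectra_crop: int = 64
    spectra_max_frames: int = 400
    alpha_level: float = 0.05

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["model_kinds"] = list(self.model_kinds)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def load_config(path: str | Path | None = None, seed: int | None = None) -> RunConfig:
    """Build a RunConfig from a TOML file (all keys optional), with an
    optional seed override."""
    data = {}
    if path is not None:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    geom = StimulusGeometry(**data.get("geometry", {}))
    top = {k: v for k, v in data.items() if k != "geometry"}
    if "model_kinds" in top:
        top["model_kinds"] = tuple(top["model_kinds"])
    cfg = RunConfig(geometry=geom, **top)
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=int(seed))
    return cfg


# ---------------------------------------------------------------------------
# manifest


def _manifest_path(out_dir: Path) -> Path:
    return Path(out_dir) / "run_manifest.json"


def _load_manifest(out_dir: Path) -> dict:
    return json.loads(_manifest_path(out_dir).read_text())


def _write_manifest(out_dir: Path, manifest: dict):
    tmp = _manifest_path(out_dir).with_suffix(".tmp")
    tmp.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    tmp.replace(_manifest_path(out_dir))


def _new_manifest(config: RunConfig) -> dict:
    return {
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "version": __version__,
        "stages": {s: False for s in STAGES},
        "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGES},
        "timestamps": {},
    }


# ---------------------------------------------------------------------------
# stages


def _population_spec(config: RunConfig) -> PopulationSpec:
    spec = default_population_spec(n_per_type=config.n_per_type)
    return dataclasses.replace(spec, contrast=config.contrast)


def stage_simulate(config: RunConfig, out: Path, seed: int):
    stim_wn = generate_white_noise(
        config.geometry,
        n_trials=config.n_trials,
        train_seconds=config.train_seconds,
        test_seconds=config.test_seconds,
        contrast=config.contrast,
        seed=stage_seed(seed, "wn"),
        distribution=config.wn_distribution,
    )
    stim_nm = generate_natural_surrogate(
        config.geometry,
        n_trials=config.n_trials,
        train_seconds=config.train_seconds,
        test_seconds=config.test_seconds,
        contrast=config.contrast,
        jitter_sd=config.jitter_sd,
        temporal_corr=config.temporal_corr,
        seed=stage_seed(seed, "nm"),
    )
    cells = make_ground_truth_population(
        _population_spec(config),
        adapt=config.adapt_population,
        seed=stage_seed(seed, "population"),
        geometry=config.geometry,
    )
    with h5py.File(out / "data.h5", "w") as h5:
        save_stimulus(h5, stim_wn, "stimulus_wn")
        save_stimulus(h5, stim_nm, "stimulus_nm")
        for label, stim in (("wn", stim_wn), ("nm", stim_nm)):
            responses = [
                simulate_rgc(c, stim, seed=stage_seed(seed, f"resp_{label}_{c.cell_id}"))
                for c in cells
            ]
            save_responses(h5, responses, f"responses_{label}")
    gt = {
        c.cell_id: {
            "cell_type": c.cell_type_label,
            "polarity": c.polarity,
            "params_wn": json.loads(params_to_json(c.params_wn)),
            "params_nm": json.loads(params_to_json(c.params_nm)),
        }
        for c in cells
    }
    (out / "ground_truth.json").write_text(json.dumps(gt, indent=1, sort_keys=True))


def _load_data(out: Path):
    with h5py.File(out / "data.h5", "r") as h5:
        stim_wn = load_stimulus(h5, "stimulus_wn")
        stim_nm = load_stimulus(h5, "stimulus_nm")
        resp_wn = {r.cell_id: r for r in load_responses(h5, "responses_wn")}
        resp_nm = {r.cell_id: r for r in load_responses(h5, "responses_nm")}
    stim_wn, stim_nm = equalize_training_frames(stim_wn, stim_nm)
    gt = json.loads((out / "ground_truth.json").read_text())
    return stim_wn, stim_nm, resp_wn, resp_nm, gt


def _fit_cfg(config: RunConfig, ensemble: str, adapt: bool, seed: int) -> FitConfig:
    return FitConfig(
        max_epochs=config.max_epochs,
        lr_init=default_lr(ensemble, adapt=adapt),
        batch_bins=config.batch_bins,
        seed=seed,
    )


def stage_fit(config: RunConfig, out: Path, seed: int):
    stim_wn, stim_nm, resp_wn, resp_nm, gt = _load_data(out)
    fit_dir = out / "fits"
    fit_dir.mkdir(exist_ok=True)
    anchors = {}
    for cell_id in sorted(gt):
        sta = compute_sta(stim_wn, resp_wn[cell_id])
        anchors[cell_id] = {
            "crop_center": list(sta.crop_center),
            "polarity": sta.polarity,
        }
        for kind in config.model_kinds:
            for label, stim, resp in (
                ("wn", stim_wn, resp_wn[cell_id]),
                ("nm", stim_nm, resp_nm[cell_id]),
            ):
                ens = stim.ensemble_label
                fit = fit_ln(
                    kind,
                    stim,
                    resp,
                    _fit_cfg(config, ens, False, stage_seed(seed, f"{cell_id}_{kind}_{label}")),
                    tuple(sta.crop_center),
                    sta.polarity,
                    sta=sta,
                )
                stem = f"{cell_id}_{kind}_{label}"
                save_params(fit_dir / f"{stem}.json", fit.params)
                fit.history.to_csv(fit_dir / f"{stem}_history.csv", index=False)
    (out / "anchors.json").write_text(json.dumps(anchors, indent=1, sort_keys=True))


def stage_adapt(config: RunConfig, out: Path, seed: int):
    stim_wn, stim_nm, resp_wn, resp_nm, gt = _load_data(out)
    anchors = json.loads((out / "anchors.json").read_text())
    fit_dir = out / "fits"
    ad_dir = out / "adapted"
    ad_dir.mkdir(exist_ok=True)
    from .training import FitResult

    for cell_id in sorted(gt):
        pol = anchors[cell_id]["polarity"]
        for kind in config.model_kinds:
            for src, dst, stim, resp in (
                ("wn", "nm", stim_nm, resp_nm[cell_id]),
                ("nm", "wn", stim_wn, resp_wn[cell_id]),
            ):
                params = load_params(fit_dir / f"{cell_id}_{kind}_{src}.json")
                fitted = FitResult(
                    params=params,
                    history=pd.DataFrame(),
                    best_epoch=0,
                    best_val_cc=float("nan"),
                    model_kind=kind,
                    polarity=pol,
                )
                ad = adapt_ood(
                    fitted,
                    stim,
                    resp,
                    _fit_cfg(
                        config,
                        stim.ensemble_label,
                        True,
                        stage_seed(seed, f"{cell_id}_{kind}_{src}_to_{dst}"),
                    ),
                )
                stem = f"{cell_id}_{kind}_{src}_to_{dst}"
                save_params(ad_dir / f"{stem}.json", ad.params)
                ad.history.to_csv(ad_dir / f"{stem}_history.csv", index=False)


def stage_evaluate(config: RunConfig, out: Path, seed: int):
    stim_wn, stim_nm, resp_wn, resp_nm, gt = _load_data(out)
    rows = []
    rel_rows = []
    for cell_id in sorted(gt):
        rel_rows.append(
            {
                "cell_id": cell_id,
                "cell_type": gt[cell_id]["cell_type"],
                "reliability_wn": odd_even_reliability(stim_wn, resp_wn[cell_id]),
                "reliability_nm": odd_even_reliability(stim_nm, resp_nm[cell_id]),
            }
        )
        for kind in config.model_kinds:
            for label, stim, resp, src in (
                ("wn", stim_wn, resp_wn[cell_id], "nm"),
                ("nm", stim_nm, resp_nm[cell_id], "wn"),
            ):
                p_id = load_params(out / "fits" / f"{cell_id}_{kind}_{label}.json")
                p_ood = load_params(out / "adapted" / f"{cell_id}_{kind}_{src}_to_{label}.json")
                rows.append(
                    {
                        "cell_id": cell_id,
                        "cell_type": gt[cell_id]["cell_type"],
                        "model_kind": kind,
                        "ensemble": stim.ensemble_label,
                        "cc_id": held_out_correlation(p_id, stim, resp),
                        "cc_ood": held_out_correlation(p_ood, stim, resp),
                    }
                )
    pd.DataFrame(rows).to_csv(out / "evaluation.csv", index=False)
    pd.DataFrame(rel_rows).to_csv(out / "reliability.csv", index=False)


def stage_rf(config: RunConfig, out: Path, seed: int):
    _, _, _, _, gt = _load_data(out)
    rows = []
    for cell_id in sorted(gt):
        for kind in config.model_kinds:
            for label in ("wn", "nm"):
                params = load_params(out / "fits" / f"{cell_id}_{kind}_{label}.json")
                pol = gt[cell_id]["polarity"]
                if kind == "dog":
                    m = rf_metrics_dog(
                        params, cell_id, window=config.surround_window
                    )
                    rows.append(
                        {
                            "cell_id": cell_id,
                            "cell_type": gt[cell_id]["cell_type"],
                            "model_kind": kind,
                            "ensemble": label,
                            "method": m.method,
                            "center_size_px2": m.center_size,
                            "surround_amplitude": clip_small(m.surround_amplitude),
                            "surround_frame": m.surround_frame,
                            "max_frame": m.max_frame,
                        }
                    )
                else:
                    spatial = params.spatial
                    fit = fit_dog_posthoc(spatial)
                    rows.append(
                        {
                            "cell_id": cell_id,
                            "cell_type": gt[cell_id]["cell_type"],
                            "model_kind": kind,
                            "ensemble": label,
                            "method": "posthoc_dog",
                            "center_size_px2": posthoc_center_size(fit),
                            "surround_amplitude": clip_small(posthoc_surround_strength(fit)),
                            "surround_frame": None,
                            "max_frame": None,
                        }
                    )
                    rows.append(
                        {
                            "cell_id": cell_id,
                            "cell_type": gt[cell_id]["cell_type"],
                            "model_kind": kind,
                            "ensemble": label,
                            "method": "threshold",
                            "center_size_px2": threshold_center_size(spatial, pol),
                            "surround_amplitude": clip_small(
                                smoothed_surround_amplitude(spatial, pol)
                            ),
                            "surround_frame": None,
                            "max_frame": None,
                        }
                    )
    pd.DataFrame(rows).to_csv(out / "rf_metrics.csv", index=False)


def stage_spectra(config: RunConfig, out: Path, seed: int):
    stim_wn, stim_nm, _, _, gt = _load_data(out)
    crop = min(
        config.spectra_crop, stim_wn.frames.shape[1], stim_wn.frames.shape[2]
    )
    spec_wn = stimulus_power_spectrum(stim_wn, crop, max_frames=config.spectra_max_frames)
    spec_nm = stimulus_power_spectrum(stim_nm, crop, max_frames=config.spectra_max_frames)
    pd.DataFrame(
        {
            "frequency": spec_wn.frequency,
            "power_wn": spec_wn.power,
            "power_nm": spec_nm.power,
        }
    ).to_csv(out / "stimulus_spectra.csv", index=False)

    # mean RFs per cell type from the DoG fits, post-hoc DoG fits to them,
    # simulated efficient-coding filters and whitening quantification
    mean_rfs = {}
    for ctype in sorted({v["cell_type"] for v in gt.values()}):
        ids = [cid for cid in sorted(gt) if gt[cid]["cell_type"] == ctype]
        rfs, pols, centers = [], [], []
        for cid in ids:
            params = load_params(out / "fits" / f"{cid}_dog_nm.json")
            rfs.append(build_spatiotemporal_rf(params))
            pols.append(gt[cid]["polarity"])
            centers.append(tuple(params.g1.mean))
        mean_rfs[ctype] = mean_receptive_field(
            rfs, pols, centers, window=config.surround_window
        )
    np.savez(out / "mean_rfs.npz", **mean_rfs)

    fits = {ctype: fit_dog_posthoc(img) for ctype, img in mean_rfs.items()}
    sizes = {ctype: posthoc_center_size(f) for ctype, f in fits.items()}
    small = fits[min(sizes, key=sizes.get)]
    large = fits[max(sizes, key=sizes.get)]
    unfiltered = spec_nm
    whitening = {}
    # band from the small-center transfer ("receptive-field-relevant" range)
    from .spectral import SimulatedFilter, _isotropic_center

    center_only = SimulatedFilter(kind="white_noise_like", center=_isotropic_center(small))
    band = band_from_transfer(transfer_function(center_only.render(), crop))
    sim = make_simulated_filters(small, large, unfiltered, band)
    for f in sim:
        filt = filtered_spectrum(
            stim_nm, f.render(), mode="tf_product", crop=crop,
            max_frames=config.spectra_max_frames,
        )
        whitening[f.kind] = whitening_percent(unfiltered, filt, band)
    (out / "whitening.json").write_text(
        json.dumps({"band": list(band), "whitening_percent": whitening}, indent=1, sort_keys=True)
    )


def stage_report(config: RunConfig, out: Path, seed: int):
    ev = pd.read_csv(out / "evaluation.csv")
    rf = pd.read_csv(out / "rf_metrics.csv")
    evals = [
        CellEvaluation(
            cell_id=r.cell_id,
            cell_type=r.cell_type,
            ensemble=r.ensemble,
            cc_id=r.cc_id,
            cc_ood=r.cc_ood,
        )
        for r in ev.itertuples()
    ]
    summary, tests = compare_id_ood(evals)
    summary.to_csv(out / "id_ood_summary.csv", index=False)

    rf_tests = {}
    for (ctype, method), grp in rf.groupby(["cell_type", "method"]):
        wide = grp.pivot_table(
            index="cell_id", columns="ensemble",
            values=["center_size_px2", "surround_amplitude"],
        )
        entry = {}
        for metric in ("center_size_px2", "surround_amplitude"):
            try:
                a = wide[(metric, "wn")].to_numpy()
                b = wide[(metric, "nm")].to_numpy()
            except KeyError:
                continue
            diffs = b - a
            if np.any(diffs != 0):
                p = float(stats.wilcoxon(diffs, alternative="two-sided").pvalue)
            else:
                p = 1.0
            entry[metric] = {
                "median_diff_nm_minus_wn": float(np.median(diffs)),
                "p_value": p,
                "significant": p < config.alpha_level,
                "n": int(len(diffs)),
            }
        rf_tests[f"{ctype}|{method}"] = entry

    report = {
        "id_ood_tests": {
            f"{k[0]}|{k[1]}": v for k, v in tests.items()
        },
        "rf_change_tests": rf_tests,
    }
    if (out / "whitening.json").exists():
        report["whitening"] = json.loads((out / "whitening.json").read_text())
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "fit": stage_fit,
    "adapt": stage_adapt,
    "evaluate": stage_evaluate,
    "rf": stage_rf,
    "spectra": stage_spectra,
    "report": stage_report,
}

#: key output(s) whose absence marks a stage as needing a re-run on resume
_STAGE_OUTPUTS = {
    "simulate": ("data.h5", "ground_truth.json"),
    "fit": ("anchors.json",),
    "adapt": ("adapted",),
    "evaluate": ("evaluation.csv", "reliability.csv"),
    "rf": ("rf_metrics.csv",),
    "spectra": ("whitening.json", "stimulus_spectra.csv"),
    "report": ("report.json", "id_ood_summary.csv"),
}


def _run_stages(config: RunConfig, out: Path, manifest: dict, only: str | None = None):
    out = Path(out)
    for stage in STAGES:
        if manifest["stages"].get(stage):
            continue
        if only is not None and stage != only:
            if not manifest["stages"].get(stage):
                # stages before `only` must already be complete
                raise RuntimeError(f"stage {stage!r} incomplete; cannot skip to {only!r}")
            continue
        _STAGE_FUNCS[stage](config, out, manifest["stage_seeds"][stage])
        manifest["stages"][stage] = True
        manifest["timestamps"][stage] = time.time()
        _write_manifest(out, manifest)
        if only is not None and stage == only:
            break
    return out


def run_all(config: RunConfig, out_dir: str | Path) -> Path:
    """Run the full analysis into ``out_dir``; deterministic given config+seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _new_manifest(config)
    _write_manifest(out, manifest)
    return _run_stages(config, out, manifest)


def resume(config: RunConfig, out_dir: str | Path) -> Path:
    """Continue an interrupted run; refuses on config-hash mismatch.

    A stage whose key outputs have gone missing is re-run even if the
    manifest flagged it complete.
    """
    out = Path(out_dir)
    manifest = _load_manifest(out)
    if manifest["config_hash"] != config.config_hash():
        raise RuntimeError("config hash mismatch; refusing to resume")
    for stage in STAGES:
        if manifest["stages"].get(stage) and not all(
            (out / p).exists() for p in _STAGE_OUTPUTS[stage]
        ):
            manifest["stages"][stage] = False
    return _run_stages(config, out, manifest)
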