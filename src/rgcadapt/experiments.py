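"""End-to-end synthetic experiments.

These functions compose the generator, fitter and metrics into the study's
headline analyses, run entirely on simulated LN-Poisson neurons:

* :func:`run_population_experiment` — per-cell ID/OOD model fitting with
  frozen-spatial adaptation, test-set correlations and receptive-field
  metrics;
* :func:`id_ood_summary` — the in-domain vs out-of-domain comparison and the
  paired Wilcoxon tests on receptive-field changes;
* :func:`null_calibration` — the adapt=false control: the same pipeline
  should find no significant center-size change;
* :func:`dog_recovery` — parameter recovery of a DoG LN cell from white
  noise.

Problem sizes default to desk scale (30x40 stimulus pixels, a few minutes
of stimulus) so a full experiment runs in minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .evaluation import held_out_correlation
from .ln_models import build_spatiotemporal_rf
from .receptive_fields import center_size_dog, rf_metrics_dog
from .synthetic_data import (
    GroundTruthCell,
    PopulationSpec,
    Stimulus,
    StimulusGeometry,
    default_population_spec,
    desk_geometry,
    generate_natural_surrogate,
    generate_white_noise,
    make_ground_truth_population,
    simulate_rgc,
    stage_seed,
)
from .training import (
    FitConfig,
    FitResult,
    adapt_ood,
    compute_sta,
    default_lr,
    equalize_training_frames,
    fit_ln,
)

__all__ = [
    "CellExperimentResult",
    "ExperimentConfig",
    "run_population_experiment",
    "id_ood_summary",
    "null_calibration",
    "dog_recovery",
    "true_center_size",
]


@dataclass
class ExperimentConfig:
    """Study conditions for a synthetic population experiment."""

    geometry: StimulusGeometry = field(default_factory=desk_geometry)
    n_trials: int = 6
    train_seconds: float = 20.0
    test_seconds: float = 5.0
    contrast: float = 0.3
    jitter_sd: float = 1.0
    temporal_corr: float = 0.95
    max_epochs: int = 500
    batch_bins: int = 256
    model_kind: str = "dog"
    surround_window: int = 6


@dataclass
class CellExperimentResult:
    """Fits, adaptation and metrics for one simulated cell."""

    cell_id: str
    cell_type: str
    polarity: str
    fit_wn: FitResult
    fit_nm: FitResult
    adapt_wn_to_nm: FitResult | None
    adapt_nm_to_wn: FitResult | None
    cc_id_wn: float
    cc_id_nm: float
    cc_ood_wn: float
    cc_ood_nm: float
    size_wn: float
    size_nm: float
    surround_wn: float
    surround_nm: float


def true_center_size(cell: GroundTruthCell, ensemble: str) -> float:
    return center_size_dog(cell.params_for(ensemble))


def _make_stimuli(cfg: ExperimentConfig, seed: int) -> tuple[Stimulus, Stimulus]:
    stim_wn = generate_white_noise(
        cfg.geometry,
        n_trials=cfg.n_trials,
        train_seconds=cfg.train_seconds,
        test_seconds=cfg.test_seconds,
        contrast=cfg.contrast,
        seed=stage_seed(seed, "white_noise"),
    )
    stim_nm = generate_natural_surrogate(
        cfg.geometry,
        n_trials=cfg.n_trials,
        train_seconds=cfg.train_seconds,
        test_seconds=cfg.test_seconds,
        contrast=cfg.contrast,
        jitter_sd=cfg.jitter_sd,
        temporal_corr=cfg.temporal_corr,
        seed=stage_seed(seed, "natural_surrogate"),
    )
    return equalize_training_frames(stim_wn, stim_nm)


def run_cell(
    cell: GroundTruthCell,
    stim_wn: Stimulus,
    stim_nm: Stimulus,
    cfg: ExperimentConfig,
    seed: int,
    directions: tuple[str, ...] = ("wn_to_nm",),
) -> CellExperimentResult:
    """Simulate one cell on both ensembles, fit ID models, adapt OOD models
    with frozen spatial filters, and quantify performance and RF metrics."""
    resp_wn = simulate_rgc(cell, stim_wn, seed=stage_seed(seed, f"resp_wn_{cell.cell_id}"))
    resp_nm = simulate_rgc(cell, stim_nm, seed=stage_seed(seed, f"resp_nm_{cell.cell_id}"))
    sta = compute_sta(stim_wn, resp_wn)
    crop_center, polarity = sta.crop_center, sta.polarity

    def mk_cfg(ensemble, adapt=False):
        return FitConfig(
            max_epochs=cfg.max_epochs,
            lr_init=default_lr(ensemble, adapt=adapt),
            batch_bins=cfg.batch_bins,
            seed=stage_seed(seed, f"fit_{cell.cell_id}_{ensemble}_{adapt}"),
        )

    fit_wn = fit_ln(
        cfg.model_kind, stim_wn, resp_wn, mk_cfg("white_noise"), crop_center, polarity, sta=sta
    )
    fit_nm = fit_ln(
        cfg.model_kind, stim_nm, resp_nm, mk_cfg("natural_surrogate"), crop_center, polarity, sta=sta
    )

    ad_wn_nm = ad_nm_wn = None
    cc_ood_nm = cc_ood_wn = float("nan")
    if "wn_to_nm" in directions:
        ad_wn_nm = adapt_ood(fit_wn, stim_nm, resp_nm, mk_cfg("natural_surrogate", adapt=True))
        cc_ood_nm = held_out_correlation(ad_wn_nm.params, stim_nm, resp_nm)
    if "nm_to_wn" in directions:
        ad_nm_wn = adapt_ood(fit_nm, stim_wn, resp_wn, mk_cfg("white_noise", adapt=True))
        cc_ood_wn = held_out_correlation(ad_nm_wn.params, stim_wn, resp_wn)

    m_wn = rf_metrics_dog(fit_wn.params, cell.cell_id, window=cfg.surround_window)
    m_nm = rf_metrics_dog(fit_nm.params, cell.cell_id, window=cfg.surround_window)
    return CellExperimentResult(
        cell_id=cell.cell_id,
        cell_type=cell.cell_type_label,
        polarity=polarity,
        fit_wn=fit_wn,
        fit_nm=fit_nm,
        adapt_wn_to_nm=ad_wn_nm,
        adapt_nm_to_wn=ad_nm_wn,
        cc_id_wn=held_out_correlation(fit_wn.params, stim_wn, resp_wn),
        cc_id_nm=held_out_correlation(fit_nm.params, stim_nm, resp_nm),
        cc_ood_wn=cc_ood_wn,
        cc_ood_nm=cc_ood_nm,
        size_wn=m_wn.center_size,
        size_nm=m_nm.center_size,
        surround_wn=m_wn.surround_amplitude,
        surround_nm=m_nm.surround_amplitude,
    )


def run_population_experiment(
    spec: PopulationSpec | None = None,
    adapt: bool = True,
    seed: int = 0,
    cfg: ExperimentConfig | None = None,
    directions: tuple[str, ...] = ("wn_to_nm",),
):
    """Full synthetic experiment: population, stimuli, per-cell fits/metrics.

    Returns ``(results, cells, stim_wn, stim_nm)``.
    """
    cfg = cfg or ExperimentConfig()
    spec = spec or default_population_spec()
    cells = make_ground_truth_population(
        spec, adapt=adapt, seed=stage_seed(seed, "population"), geometry=cfg.geometry
    )
    stim_wn, stim_nm = _make_stimuli(cfg, seed)
    results = [
        run_cell(cell, stim_wn, stim_nm, cfg, seed, directions) for cell in cells
    ]
    return results, cells, stim_wn, stim_nm


def id_ood_summary(results: list[CellExperimentResult]) -> dict:
    """Headline comparisons: fraction of cells with ID > OOD test correlation
    (naturalistic-domain evaluation) and paired Wilcoxon tests on the
    receptive-field changes between ensembles."""
    cc_id = np.array([r.cc_id_nm for r in results])
    cc_ood = np.array([r.cc_ood_nm for r in results])
    ok = np.isfinite(cc_id) & np.isfinite(cc_ood)
    frac = float(np.mean(cc_id[ok] > cc_ood[ok])) if ok.any() else float("nan")
    out = {
        "n_cells": len(results),
        "frac_id_better_nm": frac,
        "median_id_minus_ood_nm": float(np.median(cc_id[ok] - cc_ood[ok])) if ok.any() else float("nan"),
    }
    surround_diff = np.array([r.surround_nm - r.surround_wn for r in results])
    size_diff = np.array([r.size_nm - r.size_wn for r in results])
    for name, diffs in (("surround", surround_diff), ("size", size_diff)):
        if np.any(diffs != 0):
            res = stats.wilcoxon(diffs, alternative="two-sided")
            out[f"{name}_wilcoxon_p"] = float(res.pvalue)
        else:
            out[f"{name}_wilcoxon_p"] = 1.0
        out[f"{name}_median_diff"] = float(np.median(diffs))
    return out


def null_calibration(
    n_runs: int = 20,
    seed: int = 0,
    spec: PopulationSpec | None = None,
    cfg: ExperimentConfig | None = None,
    alpha: float = 0.05,
) -> dict:
    """adapt=false control: with identical generative filters in both
    ensembles the center-size Wilcoxon test should not reject.

    Returns the fraction of runs without a significant center-size
    difference, plus the per-run p-values.
    """
    cfg = cfg or ExperimentConfig(
        n_trials=4, train_seconds=10.0, test_seconds=3.0, max_epochs=150
    )
    spec = spec or default_population_spec(n_per_type=4)
    pvals = []
    for k in range(n_runs):
        results, *_ = run_population_experiment(
            spec, adapt=False, seed=stage_seed(seed, f"null_{k}"), cfg=cfg, directions=()
        )
        diffs = np.array([r.size_nm - r.size_wn for r in results])
        if np.any(diffs != 0):
            pvals.append(float(stats.wilcoxon(diffs, alternative="two-sided").pvalue))
        else:
            pvals.append(1.0)
    pvals = np.array(pvals)
    return {
        "n_runs": n_runs,
        "frac_nonsignificant": float(np.mean(pvals >= alpha)),
        "p_values": pvals.tolist(),
    }


def dog_recovery(
    n_seeds: int = 5,
    seed: int = 0,
    train_seconds: float = 55.0,
    n_trials: int = 6,
    cfg: ExperimentConfig | None = None,
) -> dict:
    """Parameter recovery of a DoG LN-Poisson cell from white noise.

    For each seed: one midget-like cell, >= 5 minutes of non-repeating white
    noise, a fresh DoG fit; reports the median error of the recovered center
    location (full-frame pixels) and center size (percent).
    """
    cfg = cfg or ExperimentConfig(n_trials=n_trials, train_seconds=train_seconds, test_seconds=3.0)
    loc_errors, size_errors = [], []
    for k in range(n_seeds):
        s = stage_seed(seed, f"recovery_{k}")
        cells = make_ground_truth_population(
            default_population_spec(n_per_type=1), adapt=False, seed=s, geometry=cfg.geometry
        )
        cell = cells[0]  # midget-like
        stim = generate_white_noise(
            cfg.geometry,
            n_trials=cfg.n_trials,
            train_seconds=cfg.train_seconds,
            test_seconds=cfg.test_seconds,
            contrast=cfg.contrast,
            seed=stage_seed(s, "wn"),
        )
        resp = simulate_rgc(cell, stim, seed=stage_seed(s, "resp"))
        sta = compute_sta(stim, resp)
        fit = fit_ln(
            "dog",
            stim,
            resp,
            FitConfig(
                max_epochs=cfg.max_epochs,
                lr_init=default_lr("white_noise"),
                batch_bins=cfg.batch_bins,
                seed=stage_seed(s, "fit"),
            ),
            sta.crop_center,
            sta.polarity,
            sta=sta,
        )
        half = 7  # crop-local coordinate of the crop-center pixel
        true_global = np.asarray(cell.params_wn.crop_center) + (
            cell.params_wn.g1.mean - half
        )
        fit_global = np.asarray(fit.params.crop_center) + (fit.params.g1.mean - half)
        loc_errors.append(float(np.linalg.norm(true_global - fit_global)))
        true_size = center_size_dog(cell.params_wn)
        size_errors.append(
            100.0 * abs(center_size_dog(fit.params) - true_size) / true_size
        )
    return {
        "n_seeds": n_seeds,
        "median_center_location_error_px": float(np.median(loc_errors)),
        "median_center_size_error_pct": float(np.median(size_errors)),
        "location_errors": loc_errors,
        "size_errors_pct": size_errors,
    }
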