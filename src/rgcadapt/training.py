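"""Model fitting: STA-based crop selection, data splitting, Adam optimization
with early stopping, and the frozen-spatial out-of-domain adaptation protocol.

The models are tiny (at most ~260 parameters), so gradients are computed
analytically in numpy: the chain rule runs through the Gaussian rendering
(mean, Cholesky-parameterized SPD covariance, softplus-positive amplitude
magnitudes with a fixed polarity sign), the unit-norm reparameterization of
the temporal filters (``t = v / ||v||``), the temporal convolution, the
softplus nonlinearity and the Poisson loss.  A standard Adam optimizer with
a reduce-on-plateau learning-rate schedule (driven by the validation
correlation) performs the updates.

Out-of-domain adaptation re-runs the same machinery with the spatial
parameters frozen: only the temporal filters and the nonlinearity are
updated, and the returned parameters carry the input's spatial values
through unchanged.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ln_models import (
    CROP_SIZE,
    N_LAGS,
    DoGLNParams,
    GaussianSpatialFilter,
    RankOneLNParams,
    SoftplusParams,
    TemporalFilter,
)
from .synthetic_data import SpikeResponse, Stimulus, Trial
from .evaluation import correlation

__all__ = [
    "STAResult",
    "FitConfig",
    "FitResult",
    "compute_sta",
    "split_train_val",
    "equalize_training_frames",
    "fit_ln",
    "adapt_ood",
    "default_lr",
]

_EPS = 1e-12


# ---------------------------------------------------------------------------
# spike-triggered averaging


@dataclass
class STAResult:
    """Spike-triggered average over a ``delta``-frame window.

    ``sta[i]`` is the average stimulus frame ``delta - 1 - i`` frames before
    the spike bin, i.e. chronological order: ``sta[-1]`` is the spike-bin
    frame itself.  ``crop_center`` is the pixel of largest temporal variance,
    clipped so a 15x15 crop fits; ``peak_pixel`` is the unclipped argmax.
    """

    sta: np.ndarray
    crop_center: tuple[int, int]
    peak_pixel: tuple[int, int]
    n_spikes: int

    @property
    def polarity(self) -> str:
        r, c = self.peak_pixel
        trace = self.sta[:, r, c]
        return "ON" if trace[np.argmax(np.abs(trace))] >= 0 else "OFF"


def _counts_by_frame(stimulus: Stimulus, response: SpikeResponse) -> np.ndarray:
    """Counts aligned to the global frame index."""
    out = np.zeros(stimulus.n_frames, dtype=np.int64)
    for tr, c in zip(stimulus.trials, response.counts):
        if len(c) != tr.n_frames:
            raise ValueError("per-trial count length must equal the trial frame count")
        out[tr.nonrep[0] : tr.rep[1]] = c
    return out


def compute_sta(stimulus: Stimulus, response: SpikeResponse, delta: int = N_LAGS) -> STAResult:
    """Spike-count-weighted average of the stimulus history preceding spikes.

    Spikes in the first ``delta - 1`` bins of each contiguous segment are
    skipped (incomplete history).  Raises if no usable spikes remain.
    """
    if delta < 1:
        raise ValueError("delta must be >= 1")
    counts = _counts_by_frame(stimulus, response)
    H, W = stimulus.frames.shape[1:]
    sta = np.zeros((delta, H, W))
    n_spikes = 0
    for _, seg in stimulus.segment_slices("both"):
        y = counts[seg][delta - 1 :].astype(float)
        if y.size == 0 or y.sum() == 0:
            continue
        frames = stimulus.frames[seg]
        L = y.size
        for tau in range(delta):
            sta[tau] += np.tensordot(y, frames[tau : tau + L], axes=(0, 0))
        n_spikes += int(y.sum())
    if n_spikes == 0:
        raise ValueError("no spikes with a complete stimulus history")
    sta /= n_spikes
    var = sta.var(axis=0)
    peak = np.unravel_index(int(np.argmax(var)), var.shape)  # first max: (row, col) lexicographic
    h = CROP_SIZE // 2
    crop_center = (
        int(np.clip(peak[0], h, H - CROP_SIZE + h)),
        int(np.clip(peak[1], h, W - CROP_SIZE + h)),
    )
    return STAResult(sta=sta, crop_center=crop_center, peak_pixel=(int(peak[0]), int(peak[1])), n_spikes=n_spikes)


# ---------------------------------------------------------------------------
# data splitting


def split_train_val(trials, fraction: float = 0.8, seed: int = 0):
    """Shuffled deterministic split of trials into train/validation sets.

    Only the non-repeating parts of the returned trials should be used for
    optimization; repeating segments are never part of either set.
    """
    items = list(trials)
    n = len(items)
    if n < 2:
        raise ValueError("need at least 2 trials to split")
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    n_train = round(fraction * n)
    if n_train == 0 or n_train == n:
        raise ValueError(f"fraction {fraction} leaves an empty split for {n} trials")
    order = np.random.default_rng(seed).permutation(n)
    train_idx = sorted(order[:n_train].tolist())
    val_idx = sorted(order[n_train:].tolist())
    return [items[i] for i in train_idx], [items[i] for i in val_idx]


def equalize_training_frames(stim_a: Stimulus, stim_b: Stimulus):
    """Trim the larger stimulus so both have the same non-repeating frame count.

    Whole trailing trials' non-repeating parts are removed first, then
    trailing frames of the last surviving non-repeating segment.  Repeating
    segments are never touched; the frame arrays themselves are left intact
    (trimmed frames are simply no longer referenced by any trial range).
    """
    na, nb = stim_a.nonrep_frame_count(), stim_b.nonrep_frame_count()
    if na == 0 or nb == 0:
        raise ValueError("both stimuli need at least one non-repeating frame")
    target = min(na, nb)

    def trim(stim: Stimulus, total: int) -> Stimulus:
        if total == target:
            return stim
        trials = list(stim.trials)
        # drop whole trailing non-repeating segments while possible
        i = len(trials) - 1
        while i >= 0:
            size = trials[i].nonrep[1] - trials[i].nonrep[0]
            if total - size >= target and size > 0:
                trials[i] = replace(trials[i], nonrep=(trials[i].nonrep[0], trials[i].nonrep[0]))
                total -= size
                i -= 1
            else:
                break
        # then trim trailing frames of the last non-empty segment
        if total > target:
            for j in range(len(trials) - 1, -1, -1):
                lo, hi = trials[j].nonrep
                if hi > lo:
                    trials[j] = replace(trials[j], nonrep=(lo, hi - (total - target)))
                    break
        return replace(stim, trials=trials)

    return trim(stim_a, na), trim(stim_b, nb)


# ---------------------------------------------------------------------------
# configuration / results


@dataclass
class FitConfig:
    """Optimization settings.

    Defaults mirror the emulated study: up to 500 epochs, early stopping
    after 30 epochs without validation-correlation improvement, Adam with a
    reduce-on-plateau schedule (patience 15, factor 0.1, floor 1e-7) and
    ensemble-specific initial learning rates (0.009 white noise, 0.005
    naturalistic movies, 0.001 for adaptation; see :func:`default_lr`).
    """

    max_epochs: int = 500
    early_stop_patience: int = 30
    lr_init: float = 0.009
    scheduler_patience: int = 15
    lr_min: float = 1e-7
    lr_decay: float = 0.1
    batch_bins: int = 256
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.lr_min <= self.lr_init):
            raise ValueError("require 0 < lr_min <= lr_init")
        if self.early_stop_patience < 1 or self.scheduler_patience < 1:
            raise ValueError("patience values must be >= 1")
        if not (0 < self.lr_decay < 1):
            raise ValueError("lr_decay must be in (0, 1)")


def default_lr(ensemble_label: str, adapt: bool = False) -> float:
    """Study-default initial learning rate per ensemble / adaptation."""
    if adapt:
        return 0.001
    return 0.009 if ensemble_label == "white_noise" else 0.005


@dataclass
class FitResult:
    """Fitted parameters plus the per-epoch training record."""

    params: DoGLNParams | RankOneLNParams
    history: pd.DataFrame
    best_epoch: int
    best_val_cc: float
    model_kind: str
    polarity: str
    adapted: bool = False


# ---------------------------------------------------------------------------
# raw parameterization helpers


def _sp(x):
    """softplus"""
    return np.logaddexp(0.0, x)


def _sig(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def _inv_sp(y):
    """inverse softplus, stable for large y"""
    y = np.asarray(y, dtype=float)
    out = np.where(y > 30, y, np.log(np.expm1(np.minimum(y, 30.0))))
    return out


def _sta_init_info(sta: "STAResult", crop_center, sign: float, win: int = 4):
    """STA-derived initialization hints: center spatial scale (a variance in
    pixels^2 from second moments around the smoothed STA peak) and the
    unit-norm temporal course at the peak pixel (lag order, 0 = most recent).

    The rank-two DoG decomposition has near-degenerate alternative optima
    (two similar-width Gaussians with distinct temporal filters), so the
    optimizer is seeded near the center+surround solution the STA exposes —
    the field's standard initialization for LN fits.
    """
    from scipy import ndimage

    h = CROP_SIZE // 2
    r, c = crop_center
    cube = sta.sta[:, r - h : r - h + CROP_SIZE, c - h : c - h + CROP_SIZE]
    k = np.unravel_index(int(np.argmax(np.abs(cube))), cube.shape)[0]
    img = ndimage.gaussian_filter(sign * cube[k], 0.8)
    pr, pc = np.unravel_index(int(np.argmax(img)), img.shape)
    rows, cols = np.mgrid[0:CROP_SIZE, 0:CROP_SIZE]
    mask = (np.abs(rows - pr) <= win) & (np.abs(cols - pc) <= win)
    w = np.where(mask, np.clip(img, 0, None), 0.0) ** 2
    total = w.sum()
    if total == 0:
        return None
    w /= total
    v = (w * ((rows - pr) ** 2 + (cols - pc) ** 2)).sum() / 2
    sigma2 = float(np.clip(v - 0.8**2 / 2, 0.5, 9.0))  # deconvolve the smoothing
    trace = cube[:, pr, pc][::-1].copy()
    nrm = np.linalg.norm(trace)
    temporal = sign * trace / nrm if nrm > 0 else None
    return sigma2, temporal


class _DogModel:
    """Raw-parameter machinery for the rank-two DoG LN model."""

    spatial_keys = ("mu", "l1", "l2", "a1", "a2")

    def __init__(self, sign: float, crop_center):
        self.sign = float(sign)
        self.crop_center = tuple(int(v) for v in crop_center)
        rows, cols = np.mgrid[0:CROP_SIZE, 0:CROP_SIZE]
        self.P = np.stack([rows.ravel(), cols.ravel()], axis=1).astype(float)

    def init_raw(self, rng: np.random.Generator, sta_info=None) -> dict:
        mid = (CROP_SIZE - 1) / 2.0
        v1 = rng.normal(0, 1, N_LAGS)
        v2 = rng.normal(0, 1, N_LAGS)
        sig_c = 1.0
        if sta_info is not None:
            sig_c = float(np.sqrt(sta_info[0]))
            if sta_info[1] is not None:
                v1 = sta_info[1].copy()
        return {
            "mu": np.array([mid, mid]),
            "l1": np.array([_inv_sp(sig_c), _inv_sp(sig_c), 0.0]),
            "l2": np.array([_inv_sp(2 * sig_c), _inv_sp(2 * sig_c), 0.0]),
            "a1": np.array([_inv_sp(0.5)]),
            "a2": np.array([_inv_sp(0.05)]),  # surrounds start weak
            "v1": v1 / np.linalg.norm(v1),
            "v2": v2 / np.linalg.norm(v2),
            "alpha": np.array([_inv_sp(1.0)]),
            "beta": np.array([0.0]),
        }

    def from_structured(self, params: DoGLNParams) -> dict:
        def chol_raw(cov):
            L = np.linalg.cholesky(cov)
            return np.array([_inv_sp(L[0, 0]), _inv_sp(L[1, 1]), L[1, 0]])

        return {
            "mu": params.g1.mean.copy(),
            "l1": chol_raw(params.g1.covariance),
            "l2": chol_raw(params.g2.covariance),
            "a1": np.array([_inv_sp(abs(params.g1.amplitude))]),
            "a2": np.array([_inv_sp(abs(params.g2.amplitude))]),
            "v1": params.t1.weights.copy(),
            "v2": params.t2.weights.copy(),
            "alpha": np.array([_inv_sp(params.nonlinearity.alpha)]),
            "beta": np.array([params.nonlinearity.beta]),
        }

    @staticmethod
    def _chol(l):
        return np.array([[_sp(l[0]), 0.0], [l[2], _sp(l[1])]])

    def _gauss(self, raw, which: str):
        """Rendered Gaussian component: (exp image, signed amplitude, inv cov, deltas)."""
        l = raw["l1" if which == "1" else "l2"]
        L = self._chol(l)
        cov = L @ L.T
        inv = np.linalg.inv(cov)
        d = self.P - raw["mu"][None, :]
        q = inv[0, 0] * d[:, 0] ** 2 + 2 * inv[0, 1] * d[:, 0] * d[:, 1] + inv[1, 1] * d[:, 1] ** 2
        e = np.exp(-0.5 * q)
        a = self.sign * float(_sp(raw["a" + which][0]))
        return e, a, inv, d, L

    def drive(self, raw, flat: np.ndarray) -> np.ndarray:
        e1, a1, *_ = self._gauss(raw, "1")
        e2, a2, *_ = self._gauss(raw, "2")
        t1 = raw["v1"] / np.linalg.norm(raw["v1"])
        t2 = raw["v2"] / np.linalg.norm(raw["v2"])
        u1 = flat @ (a1 * e1)
        u2 = flat @ (a2 * e2)
        return np.convolve(u1, t1, "valid") - np.convolve(u2, t2, "valid")

    def loss_and_grad(self, raw, flat: np.ndarray, r: np.ndarray):
        e1, a1, inv1, d1, L1 = self._gauss(raw, "1")
        e2, a2, inv2, d2, L2 = self._gauss(raw, "2")
        n1 = np.linalg.norm(raw["v1"])
        n2 = np.linalg.norm(raw["v2"])
        t1 = raw["v1"] / n1
        t2 = raw["v2"] / n2
        img1 = a1 * e1
        img2 = a2 * e2
        u1 = flat @ img1
        u2 = flat @ img2
        d = np.convolve(u1, t1, "valid") - np.convolve(u2, t2, "valid")
        alpha = float(_sp(raw["alpha"][0]))
        z = d + raw["beta"][0]
        sp0 = np.logaddexp(0.0, z)
        p = alpha * sp0
        loss = float(np.sum(p - r * np.log(p + _EPS)))

        gp = 1.0 - r / (p + _EPS)
        g_alpha = float(np.sum(gp * sp0)) * float(_sig(raw["alpha"][0]))
        gz = gp * alpha * _sig(z)
        g_beta = float(np.sum(gz))
        gd = gz
        gt1 = np.correlate(u1, gd, "valid")[::-1]
        gt2 = -np.correlate(u2, gd, "valid")[::-1]
        gu1 = np.convolve(gd, t1[::-1], "full")
        gu2 = -np.convolve(gd, t2[::-1], "full")
        gimg1 = flat.T @ gu1
        gimg2 = flat.T @ gu2

        grads = {"alpha": np.array([g_alpha]), "beta": np.array([g_beta])}
        gmu = np.zeros(2)
        for which, (e, a, inv, dd, L, gimg, akey, lkey) in {
            "1": (e1, a1, inv1, d1, L1, gimg1, "a1", "l1"),
            "2": (e2, a2, inv2, d2, L2, gimg2, "a2", "l2"),
        }.items():
            g_a_signed = float(gimg @ e)
            grads[akey] = np.array(
                [g_a_signed * self.sign * float(_sig(raw[akey][0]))]
            )
            w = (gimg * a) * e  # per-pixel gradient through the exponential
            gmu += inv @ (dd.T @ w)
            M = dd.T @ (dd * w[:, None])
            gC = 0.5 * inv @ M @ inv
            gL = 2.0 * gC @ L
            grads[lkey] = np.array(
                [
                    gL[0, 0] * float(_sig(raw[lkey][0])),
                    gL[1, 1] * float(_sig(raw[lkey][1])),
                    gL[1, 0],
                ]
            )
        grads["mu"] = gmu
        for vkey, t, n, gt in (("v1", t1, n1, gt1), ("v2", t2, n2, gt2)):
            grads[vkey] = (gt - (gt @ t) * t) / n
        return loss, grads

    def structured(self, raw, spatial_override: DoGLNParams | None = None) -> DoGLNParams:
        t1 = TemporalFilter(raw["v1"] / np.linalg.norm(raw["v1"]))
        t2 = TemporalFilter(raw["v2"] / np.linalg.norm(raw["v2"]))
        nl = SoftplusParams(alpha=float(_sp(raw["alpha"][0])), beta=float(raw["beta"][0]))
        if spatial_override is not None:
            g1 = copy.deepcopy(spatial_override.g1)
            g2 = copy.deepcopy(spatial_override.g2)
        else:
            L1 = self._chol(raw["l1"])
            L2 = self._chol(raw["l2"])
            mean = raw["mu"].copy()
            g1 = GaussianSpatialFilter(
                self.sign * float(_sp(raw["a1"][0])), mean, L1 @ L1.T
            )
            g2 = GaussianSpatialFilter(
                self.sign * float(_sp(raw["a2"][0])), mean, L2 @ L2.T
            )
        return DoGLNParams(
            g1=g1, g2=g2, t1=t1, t2=t2, nonlinearity=nl, crop_center=self.crop_center
        )


class _RankOneModel:
    """Raw-parameter machinery for the unconstrained rank-one LN model."""

    spatial_keys = ("w",)

    def __init__(self, sign: float, crop_center):
        self.sign = float(sign)
        self.crop_center = tuple(int(v) for v in crop_center)

    def init_raw(self, rng: np.random.Generator) -> dict:
        return {
            "w": rng.normal(0, 0.1, CROP_SIZE * CROP_SIZE),
            "v": rng.normal(0, 1, N_LAGS) / np.sqrt(N_LAGS),
            "alpha": np.array([_inv_sp(1.0)]),
            "beta": np.array([0.0]),
        }

    def from_structured(self, params: RankOneLNParams) -> dict:
        return {
            "w": params.spatial.ravel().copy(),
            "v": params.temporal.copy(),
            "alpha": np.array([_inv_sp(params.nonlinearity.alpha)]),
            "beta": np.array([params.nonlinearity.beta]),
        }

    def drive(self, raw, flat):
        return np.convolve(flat @ raw["w"], raw["v"], "valid")

    def loss_and_grad(self, raw, flat, r):
        u = flat @ raw["w"]
        d = np.convolve(u, raw["v"], "valid")
        alpha = float(_sp(raw["alpha"][0]))
        z = d + raw["beta"][0]
        sp0 = np.logaddexp(0.0, z)
        p = alpha * sp0
        loss = float(np.sum(p - r * np.log(p + _EPS)))
        gp = 1.0 - r / (p + _EPS)
        gz = gp * alpha * _sig(z)
        gd = gz
        grads = {
            "alpha": np.array([float(np.sum(gp * sp0)) * float(_sig(raw["alpha"][0]))]),
            "beta": np.array([float(np.sum(gz))]),
            "v": np.correlate(u, gd, "valid")[::-1],
            "w": flat.T @ np.convolve(gd, raw["v"][::-1], "full"),
        }
        return loss, grads

    def structured(self, raw, spatial_override: RankOneLNParams | None = None) -> RankOneLNParams:
        spatial = (
            spatial_override.spatial.copy()
            if spatial_override is not None
            else raw["w"].reshape(CROP_SIZE, CROP_SIZE).copy()
        )
        return RankOneLNParams(
            spatial=spatial,
            temporal=raw["v"].copy(),
            nonlinearity=SoftplusParams(
                alpha=float(_sp(raw["alpha"][0])), beta=float(raw["beta"][0])
            ),
            crop_center=self.crop_center,
        )


# ---------------------------------------------------------------------------
# the optimization loop


def _make_batches(stimulus: Stimulus, train_trials: list[int], batch_bins: int):
    """Contiguous valid-bin batches: (frame_lo, frame_hi) with the 30-frame
    history starting at frame_lo - N_LAGS + 1 inside the same segment."""
    batches = []
    for i, seg in stimulus.segment_slices("nonrep"):
        if i not in train_trials:
            continue
        first_valid = seg.start + N_LAGS - 1
        if first_valid >= seg.stop:
            continue  # segment shorter than the filter: no valid bins
        for lo in range(first_valid, seg.stop, batch_bins):
            batches.append((lo, min(lo + batch_bins, seg.stop)))
    return batches


def _val_arrays(stimulus, counts, val_trials):
    segs = []
    for i, seg in stimulus.segment_slices("nonrep"):
        if i in val_trials and seg.stop - seg.start >= N_LAGS:
            segs.append(seg)
    return segs


def _adam_step(raw, grads, state, lr, frozen, t, beta1=0.9, beta2=0.999, eps=1e-8):
    for key, g in grads.items():
        if key in frozen:
            continue
        m, v = state[key]
        m[:] = beta1 * m + (1 - beta1) * g
        v[:] = beta2 * v + (1 - beta2) * g * g
        mhat = m / (1 - beta1**t)
        vhat = v / (1 - beta2**t)
        raw[key] = raw[key] - lr * mhat / (np.sqrt(vhat) + eps)


def _run_fit(
    model,
    raw: dict,
    stimulus: Stimulus,
    response: SpikeResponse,
    cfg: FitConfig,
    frozen: tuple[str, ...] = (),
    spatial_override=None,
    model_kind: str = "dog",
    adapted: bool = False,
) -> FitResult:
    counts = _counts_by_frame(stimulus, response)
    cropped = stimulus.crop(model.crop_center)
    flat = cropped.reshape(cropped.shape[0], -1).astype(np.float64)

    train_trials, val_trials = split_train_val(
        range(len(stimulus.trials)), cfg.train_fraction, cfg.seed
    )
    batches = _make_batches(stimulus, train_trials, cfg.batch_bins)
    if not batches:
        raise ValueError("no valid training bins (segments shorter than the filter?)")
    val_segs = _val_arrays(stimulus, counts, val_trials)

    rng = np.random.default_rng(cfg.seed)
    state = {k: (np.zeros_like(v), np.zeros_like(v)) for k, v in raw.items()}
    lr = cfg.lr_init
    best_cc = -np.inf
    best_epoch = 0
    best_raw = {k: v.copy() for k, v in raw.items()}
    es_wait = 0
    sch_wait = 0
    step = 0
    hist = {"epoch": [], "train_loss": [], "val_cc": [], "lr": []}

    for epoch in range(cfg.max_epochs):
        total_loss = 0.0
        total_bins = 0
        for bi in rng.permutation(len(batches)):
            lo, hi = batches[bi]
            loss, grads = model.loss_and_grad(
                raw, flat[lo - N_LAGS + 1 : hi], counts[lo:hi].astype(float)
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, batch {bi} "
                    f"(lr={lr:g}); aborting fit"
                )
            step += 1
            _adam_step(raw, grads, state, lr, frozen, step)
            total_loss += loss
            total_bins += hi - lo

        preds, obs = [], []
        for seg in val_segs:
            drive = model.drive(raw, flat[seg])
            alpha = float(_sp(raw["alpha"][0]))
            preds.append(alpha * np.logaddexp(0.0, drive + raw["beta"][0]))
            obs.append(counts[seg][N_LAGS - 1 :].astype(float))
        if preds:
            val_cc = correlation(np.concatenate(preds), np.concatenate(obs))
        else:
            val_cc = float("nan")

        hist["epoch"].append(epoch)
        hist["train_loss"].append(total_loss / max(total_bins, 1))
        hist["val_cc"].append(val_cc)
        hist["lr"].append(lr)

        improved = np.isfinite(val_cc) and val_cc > best_cc
        if improved:
            best_cc = val_cc
            best_epoch = epoch
            best_raw = {k: v.copy() for k, v in raw.items()}
            es_wait = 0
            sch_wait = 0
        else:
            es_wait += 1
            sch_wait += 1
            if sch_wait >= cfg.scheduler_patience and lr > cfg.lr_min:
                lr = max(lr * cfg.lr_decay, cfg.lr_min)
                sch_wait = 0
            if es_wait >= cfg.early_stop_patience:
                break

    params = model.structured(best_raw, spatial_override=spatial_override)
    return FitResult(
        params=params,
        history=pd.DataFrame(hist),
        best_epoch=best_epoch,
        best_val_cc=float(best_cc) if np.isfinite(best_cc) else float("nan"),
        model_kind=model_kind,
        polarity="ON" if model.sign >= 0 else "OFF",
        adapted=adapted,
    )


def fit_ln(
    model_kind: str,
    stimulus: Stimulus,
    response: SpikeResponse,
    cfg: FitConfig,
    crop_center: tuple[int, int] | None = None,
    polarity: str | None = None,
    sta: STAResult | None = None,
) -> FitResult:
    """Fit a DoG (``"dog"``) or free-spatial (``"rank_one"``) LN model.

    If ``crop_center``/``polarity``/``sta`` are not given they are taken
    from the STA of this stimulus/response pair (for naturalistic fits,
    pass the white-noise STA to match the emulated protocol).  The DoG fit
    is seeded from STA-derived spatial-scale and temporal-course hints (see
    :func:`_sta_init_info`).
    """
    if sta is None and (crop_center is None or polarity is None):
        sta = compute_sta(stimulus, response)
    if crop_center is None:
        crop_center = sta.crop_center
    if polarity is None:
        polarity = sta.polarity
    sign = 1.0 if polarity == "ON" else -1.0
    if model_kind == "dog":
        model = _DogModel(sign, crop_center)
        sta_info = _sta_init_info(sta, crop_center, sign) if sta is not None else None
        raw = model.init_raw(np.random.default_rng(cfg.seed), sta_info=sta_info)
    elif model_kind == "rank_one":
        model = _RankOneModel(sign, crop_center)
        raw = model.init_raw(np.random.default_rng(cfg.seed))
    else:
        raise ValueError("model_kind must be 'dog' or 'rank_one'")
    return _run_fit(model, raw, stimulus, response, cfg, model_kind=model_kind)


def adapt_ood(
    fitted: FitResult,
    target_stimulus: Stimulus,
    target_response: SpikeResponse,
    cfg: FitConfig,
) -> FitResult:
    """Adapt a fitted model to another stimulus ensemble with frozen spatial
    filters.

    Only the temporal filters and the softplus parameters are updated; the
    returned parameters reuse the input's spatial values verbatim, so their
    serialization is byte-identical.
    """
    params = fitted.params
    sign = 1.0 if fitted.polarity == "ON" else -1.0
    if isinstance(params, DoGLNParams):
        model = _DogModel(sign, params.crop_center)
    else:
        model = _RankOneModel(sign, params.crop_center)
    raw = model.from_structured(params)
    return _run_fit(
        model,
        raw,
        target_stimulus,
        target_response,
        cfg,
        frozen=model.spatial_keys,
        spatial_override=params,
        model_kind=fitted.model_kind,
        adapted=True,
    )
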