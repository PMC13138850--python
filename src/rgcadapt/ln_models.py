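"""Linear–nonlinear encoding models of retinal ganglion cells.

Two model families are defined:

* a rank-two *difference-of-Gaussians* (DoG) LN model whose spatial filters
  are parametric 2-D Gaussians sharing a center location and amplitude sign,
  combined with two unit-norm temporal filters:
  ``R(x, y, t) = G1(x, y) T1(t) - G2(x, y) T2(t)``;
* an unconstrained *rank-one* LN model with a free 15x15 spatial filter and a
  free 30-tap temporal filter.

Both drive a two-parameter softplus nonlinearity ``f(x) = alpha *
log(1 + exp(x + beta))`` and are trained by minimizing a Poisson loss
(see :mod:`rgcadapt.training`).

Conventions (fixed across the package): coordinates are 0-based ``(row,
column)`` with pixel centers at integers; temporal index 0 is the most
recent frame, so the linear drive at bin ``t`` uses frames ``t-29 .. t``;
predictions are valid-mode only — the first ``n_lags - 1`` bins of every
contiguous stimulus segment carry no prediction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CROP_SIZE",
    "N_LAGS",
    "GaussianSpatialFilter",
    "TemporalFilter",
    "SoftplusParams",
    "DoGLNParams",
    "RankOneLNParams",
    "SpatiotemporalRF",
    "render_spatial",
    "build_spatiotemporal_rf",
    "predict_rate",
    "predict_drive",
    "softplus",
    "poisson_loss",
    "poisson_loss_grad",
    "params_to_json",
    "params_from_json",
]

#: side length of the spatial crop, in stimulus pixels
CROP_SIZE = 15
#: temporal filter length in frames (~350 ms at 85 Hz)
N_LAGS = 30


def _as_cov(cov) -> np.ndarray:
    """Validate a 2x2 symmetric positive-definite covariance matrix."""
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (2, 2):
        raise ValueError(f"covariance must be 2x2, got {cov.shape}")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals.min() <= 0:
        raise ValueError(f"covariance must be positive definite, eigenvalues {eigvals}")
    return cov


@dataclass
class GaussianSpatialFilter:
    """An amplitude-scaled 2-D Gaussian profile, ``A exp(-1/2 d' C^-1 d)``.

    ``mean`` is in crop-local pixel coordinates (row, column); ``covariance``
    is in pixels^2.  The profile is a scaled density *shape* (peak value =
    ``amplitude``), not normalized to unit volume.
    """

    amplitude: float
    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float).reshape(2)
        self.covariance = _as_cov(self.covariance)


@dataclass
class TemporalFilter:
    """A unit-norm temporal filter of :data:`N_LAGS` taps (index 0 = most recent)."""

    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float).reshape(-1)
        nrm = np.linalg.norm(self.weights)
        if nrm == 0:
            raise ValueError("temporal filter cannot be all-zero")
        if abs(nrm - 1.0) > 1e-6:
            raise ValueError(f"temporal filter must have unit norm, got {nrm}")


@dataclass
class SoftplusParams:
    """Output nonlinearity parameters: gain ``alpha`` (> 0) and input offset ``beta``."""

    alpha: float = 1.0
    beta: float = 0.0

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


@dataclass
class DoGLNParams:
    """State of the rank-two DoG LN model.

    Constraints: ``g1`` and ``g2`` share the center location (``g2.mean`` is
    kept equal to ``g1.mean``) and have the same amplitude sign.
    ``crop_center`` locates the 15x15 crop in full-frame stimulus-pixel
    coordinates (row, column of the crop's central pixel).
    """

    g1: GaussianSpatialFilter
    g2: GaussianSpatialFilter
    t1: TemporalFilter
    t2: TemporalFilter
    nonlinearity: SoftplusParams = field(default_factory=SoftplusParams)
    crop_center: tuple[int, int] = (0, 0)

    def __post_init__(self):
        if not np.allclose(self.g1.mean, self.g2.mean):
            raise ValueError("g1 and g2 must share the same center location")
        # shared storage: a single mean array backs both Gaussians
        self.g2.mean = self.g1.mean
        if self.g1.amplitude * self.g2.amplitude < 0:
            raise ValueError("g1 and g2 amplitudes must have the same sign")

    @property
    def polarity(self) -> str:
        return "ON" if self.g1.amplitude >= 0 else "OFF"


@dataclass
class RankOneLNParams:
    """State of the unconstrained rank-one LN model (``CROP_SIZE**2`` free
    spatial weights, free temporal taps)."""

    spatial: np.ndarray
    temporal: np.ndarray
    nonlinearity: SoftplusParams = field(default_factory=SoftplusParams)
    crop_center: tuple[int, int] = (0, 0)

    def __post_init__(self):
        self.spatial = np.asarray(self.spatial, dtype=float)
        if self.spatial.shape != (CROP_SIZE, CROP_SIZE):
            raise ValueError(f"spatial filter must be {CROP_SIZE}x{CROP_SIZE}")
        self.temporal = np.asarray(self.temporal, dtype=float).reshape(-1)

    @property
    def n_free_spatial(self) -> int:
        """Number of freely learned spatial weights (225 at the default crop)."""
        return self.spatial.size


@dataclass
class SpatiotemporalRF:
    """A full spatiotemporal receptive field, ``values[t, y, x]`` with t=0 the
    most recent frame."""

    values: np.ndarray
    time_axis: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("RF values must be a (time, y, x) array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("RF values must be finite")
        if self.time_axis is None:
            self.time_axis = np.arange(self.values.shape[0])


def render_spatial(g: GaussianSpatialFilter, grid_size: int = CROP_SIZE) -> np.ndarray:
    """Evaluate a Gaussian spatial filter on a ``grid_size`` square pixel grid.

    Pixel ``(i, j)`` takes the value
    ``amplitude * exp(-1/2 (p - mean)' cov^-1 (p - mean))`` with
    ``p = (i, j)``.
    """
    if grid_size < 1:
        raise ValueError("grid_size must be >= 1")
    cov = _as_cov(g.covariance)
    inv = np.linalg.inv(cov)
    rows, cols = np.mgrid[0:grid_size, 0:grid_size]
    d0 = rows - g.mean[0]
    d1 = cols - g.mean[1]
    quad = inv[0, 0] * d0 * d0 + 2 * inv[0, 1] * d0 * d1 + inv[1, 1] * d1 * d1
    return g.amplitude * np.exp(-0.5 * quad)


def build_spatiotemporal_rf(params) -> SpatiotemporalRF:
    """Construct ``R(x, y, t)`` from DoG or rank-one parameters.

    For the DoG model ``R[t] = G1 * T1[t] - G2 * T2[t]``; for the rank-one
    model ``R[t] = spatial * temporal[t]``.
    """
    if isinstance(params, DoGLNParams):
        img1 = render_spatial(params.g1)
        img2 = render_spatial(params.g2)
        values = (
            img1[None, :, :] * params.t1.weights[:, None, None]
            - img2[None, :, :] * params.t2.weights[:, None, None]
        )
    elif isinstance(params, RankOneLNParams):
        values = params.spatial[None, :, :] * params.temporal[:, None, None]
    else:
        raise TypeError(f"unsupported parameter type {type(params)!r}")
    return SpatiotemporalRF(values=values)


def softplus(x, nl: SoftplusParams):
    """``f(x) = alpha * log(1 + exp(x + beta))``, numerically stable."""
    return nl.alpha * np.logaddexp(0.0, np.asarray(x, dtype=float) + nl.beta)


def predict_drive(params, cropped_stimulus: np.ndarray, pad: bool = False) -> np.ndarray:
    """Pre-nonlinearity linear drive on a contiguous cropped segment.

    Parameters
    ----------
    cropped_stimulus
        Array of shape ``(n_frames, CROP_SIZE, CROP_SIZE)`` for one contiguous
        segment.
    pad
        If True, prepend ``N_LAGS - 1`` mean-gray (zero) frames so that every
        bin receives a drive value; otherwise valid mode (output length
        ``n_frames - N_LAGS + 1``).
    """
    stim = np.asarray(cropped_stimulus, dtype=float)
    if stim.ndim != 3 or stim.shape[1:] != (CROP_SIZE, CROP_SIZE):
        raise ValueError(f"cropped stimulus must be (T, {CROP_SIZE}, {CROP_SIZE})")
    if pad:
        stim = np.concatenate(
            [np.zeros((N_LAGS - 1,) + stim.shape[1:]), stim], axis=0
        )
    if stim.shape[0] < N_LAGS:
        raise ValueError(
            f"segment has {stim.shape[0]} frames; at least {N_LAGS} required"
        )
    flat = stim.reshape(stim.shape[0], -1)
    if isinstance(params, DoGLNParams):
        u1 = flat @ render_spatial(params.g1).ravel()
        u2 = flat @ render_spatial(params.g2).ravel()
        drive = np.convolve(u1, params.t1.weights, mode="valid") - np.convolve(
            u2, params.t2.weights, mode="valid"
        )
    elif isinstance(params, RankOneLNParams):
        u = flat @ params.spatial.ravel()
        drive = np.convolve(u, params.temporal, mode="valid")
    else:
        raise TypeError(f"unsupported parameter type {type(params)!r}")
    return drive


def predict_rate(params, cropped_stimulus: np.ndarray, pad: bool = False) -> np.ndarray:
    """Predicted rate trace: softplus of the linear drive.

    Valid-mode by default: the first ``N_LAGS - 1`` bins of the segment are
    excluded (no fabricated pre-stimulus history).
    """
    drive = predict_drive(params, cropped_stimulus, pad=pad)
    return softplus(drive, params.nonlinearity)


def poisson_loss(pred, obs, eps: float = 1e-12) -> float:
    """Poisson loss ``sum_i p_i - r_i log(p_i + eps)``.

    ``eps`` guards ``log(0)`` for bins the softplus drives to (numerical)
    zero.  Predictions must be nonnegative — softplus output cannot be
    negative, so a negative prediction indicates a caller bug.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("prediction and observation traces must have equal length")
    if np.any(pred < 0):
        raise ValueError("predictions must be nonnegative")
    return float(np.sum(pred - obs * np.log(pred + eps)))


def poisson_loss_grad(pred, obs, eps: float = 1e-12) -> np.ndarray:
    """Gradient of :func:`poisson_loss` with respect to each prediction."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    return 1.0 - obs / (pred + eps)


# ---------------------------------------------------------------------------
# serialization


def params_to_json(params) -> str:
    """Serialize model parameters to a canonical JSON string.

    The DoG mean is stored once (shared center).  Deterministic formatting so
    identical parameters serialize byte-identically.
    """
    if isinstance(params, DoGLNParams):
        obj = {
            "kind": "dog",
            "mean": params.g1.mean.tolist(),
            "g1_amplitude": params.g1.amplitude,
            "g1_covariance": params.g1.covariance.tolist(),
            "g2_amplitude": params.g2.amplitude,
            "g2_covariance": params.g2.covariance.tolist(),
            "t1": params.t1.weights.tolist(),
            "t2": params.t2.weights.tolist(),
            "alpha": params.nonlinearity.alpha,
            "beta": params.nonlinearity.beta,
            "crop_center": list(params.crop_center),
            "polarity": params.polarity,
        }
    elif isinstance(params, RankOneLNParams):
        obj = {
            "kind": "rank_one",
            "spatial": params.spatial.tolist(),
            "temporal": params.temporal.tolist(),
            "alpha": params.nonlinearity.alpha,
            "beta": params.nonlinearity.beta,
            "crop_center": list(params.crop_center),
        }
    else:
        raise TypeError(f"unsupported parameter type {type(params)!r}")
    return json.dumps(obj, sort_keys=True)


def spatial_params_to_json(params) -> str:
    """Serialize only the spatial part of the parameters (frozen-filter checks)."""
    if isinstance(params, DoGLNParams):
        obj = {
            "mean": params.g1.mean.tolist(),
            "g1_amplitude": params.g1.amplitude,
            "g1_covariance": params.g1.covariance.tolist(),
            "g2_amplitude": params.g2.amplitude,
            "g2_covariance": params.g2.covariance.tolist(),
        }
    elif isinstance(params, RankOneLNParams):
        obj = {"spatial": params.spatial.tolist()}
    else:
        raise TypeError(f"unsupported parameter type {type(params)!r}")
    return json.dumps(obj, sort_keys=True)


def params_from_json(text: str):
    """Inverse of :func:`params_to_json`."""
    obj = json.loads(text)
    nl = SoftplusParams(alpha=obj["alpha"], beta=obj["beta"])
    crop_center = tuple(obj["crop_center"])
    if obj["kind"] == "dog":
        mean = np.asarray(obj["mean"])
        return DoGLNParams(
            g1=GaussianSpatialFilter(obj["g1_amplitude"], mean, np.asarray(obj["g1_covariance"])),
            g2=GaussianSpatialFilter(obj["g2_amplitude"], mean, np.asarray(obj["g2_covariance"])),
            t1=TemporalFilter(np.asarray(obj["t1"])),
            t2=TemporalFilter(np.asarray(obj["t2"])),
            nonlinearity=nl,
            crop_center=crop_center,
        )
    if obj["kind"] == "rank_one":
        return RankOneLNParams(
            spatial=np.asarray(obj["spatial"]),
            temporal=np.asarray(obj["temporal"]),
            nonlinearity=nl,
            crop_center=crop_center,
        )
    raise ValueError(f"unknown parameter kind {obj['kind']!r}")
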