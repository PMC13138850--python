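"""Synthetic stimuli and ground-truth LN-Poisson neurons.

The generator reproduces the statistical structure the downstream analysis
assumes, so the full pipeline is testable without recordings:

* spatiotemporal white noise — spatially and temporally uncorrelated
  contrast values, constant on stimulus-pixel blocks, flat spatial power
  spectrum;
* a naturalistic-movie surrogate — frames windowed out of a latent image
  with a 1/f^2 spatial power spectrum, viewed along a random-walk gaze path
  (simulated fixational eye movements) with slowly refreshed content;
* LN-Poisson model neurons whose generative filters may differ between the
  two ensembles (center size, surround strength), mimicking stimulus-domain
  adaptation.

Stimuli follow the trial structure of the emulated experiment: each trial is
a stretch of non-repeating (training) frames followed by a repeating
(test) sequence that is identical across trials.  Frames are mean-zero
contrast values ("mean gray" = 0) stored at stimulus-pixel resolution;
``Stimulus.to_screen_resolution`` expands to screen pixels.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .ln_models import (
    CROP_SIZE,
    N_LAGS,
    DoGLNParams,
    GaussianSpatialFilter,
    SoftplusParams,
    TemporalFilter,
    predict_drive,
    softplus,
)

__all__ = [
    "StimulusGeometry",
    "Trial",
    "Stimulus",
    "SpikeResponse",
    "GroundTruthCell",
    "CellTypeSpec",
    "PopulationSpec",
    "generate_white_noise",
    "generate_natural_surrogate",
    "simulate_rgc",
    "make_ground_truth_population",
    "default_population_spec",
    "desk_geometry",
    "stage_seed",
]


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a deterministic per-stage child seed from a master seed.

    Stage names map to fixed offsets via CRC32, so stages are independent
    and reproducible.  Result is kept below 2**31.
    """
    return int((int(master_seed) * 0x9E3779B1 + zlib.crc32(stage.encode())) % (2**31 - 1))


@dataclass(frozen=True)
class StimulusGeometry:
    """Screen and stimulus-grid geometry.

    ``stim_pixel_factor`` is the number of screen pixels per stimulus pixel
    per axis (white-noise blocks); ``pixel_pitch`` is micrometres per screen
    pixel.  The emulated recording used a 600x800 screen, factor 4
    (150x200 stimulus pixels), 7.5 um pitch, 85 Hz refresh.
    """

    screen_height: int = 600
    screen_width: int = 800
    stim_pixel_factor: int = 4
    pixel_pitch: float = 7.5
    frame_rate: float = 85.0

    def __post_init__(self):
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        if self.stim_pixel_factor < 1:
            raise ValueError("stim_pixel_factor must be >= 1")
        if (
            self.screen_height % self.stim_pixel_factor
            or self.screen_width % self.stim_pixel_factor
        ):
            raise ValueError(
                "screen dimensions must be divisible by stim_pixel_factor"
            )

    @property
    def stim_height(self) -> int:
        return self.screen_height // self.stim_pixel_factor

    @property
    def stim_width(self) -> int:
        return self.screen_width // self.stim_pixel_factor

    @property
    def stim_pixel_pitch(self) -> float:
        """Micrometres per stimulus pixel."""
        return self.pixel_pitch * self.stim_pixel_factor


def desk_geometry() -> StimulusGeometry:
    """Small geometry used throughout the tests (30x40 stimulus pixels)."""
    return StimulusGeometry(screen_height=120, screen_width=160)


@dataclass(frozen=True)
class Trial:
    """Frame-index ranges of one trial: half-open (start, stop) pairs."""

    nonrep: tuple[int, int]
    rep: tuple[int, int]

    @property
    def n_frames(self) -> int:
        return (self.nonrep[1] - self.nonrep[0]) + (self.rep[1] - self.rep[0])


@dataclass
class Stimulus:
    """A movie with trial bookkeeping.

    ``frames`` is (n_frames, H, W), mean-zero contrast units, at stimulus-
    pixel resolution (``pixel_size`` screen pixels per stored pixel).
    """

    frames: np.ndarray
    geometry: StimulusGeometry
    trials: list[Trial]
    ensemble_label: str = "user"
    pixel_size: int = 1
    seed: int | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_frames, height, width)")
        self.validate_trials()

    def validate_trials(self):
        """Check trial ranges are disjoint, in-bounds and exhaustive."""
        n = self.frames.shape[0]
        covered = []
        for tr in self.trials:
            for start, stop in (tr.nonrep, tr.rep):
                if not (0 <= start <= stop <= n):
                    raise ValueError(f"trial range ({start}, {stop}) out of bounds")
                covered.append((start, stop))
        covered.sort()
        pos = 0
        for start, stop in covered:
            if start < pos:
                raise ValueError("trial ranges overlap")
            pos = stop

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def nonrep_frame_count(self) -> int:
        return sum(t.nonrep[1] - t.nonrep[0] for t in self.trials)

    def segment_slices(self, kind: str = "both") -> list[tuple[int, slice]]:
        """Contiguous segments as (trial_index, slice) pairs.

        ``kind`` selects ``"nonrep"``, ``"rep"`` or ``"both"`` segments; each
        is treated as an independent contiguous stretch for valid-mode
        prediction.
        """
        out = []
        for i, tr in enumerate(self.trials):
            if kind in ("nonrep", "both") and tr.nonrep[1] > tr.nonrep[0]:
                out.append((i, slice(*tr.nonrep)))
            if kind in ("rep", "both") and tr.rep[1] > tr.rep[0]:
                out.append((i, slice(*tr.rep)))
        return out

    def crop(self, center: tuple[int, int], size: int = CROP_SIZE) -> np.ndarray:
        """Crop ``size`` x ``size`` pixels around ``center`` (row, col)."""
        r, c = int(center[0]), int(center[1])
        h = size // 2
        T, H, W = self.frames.shape
        if not (h <= r <= H - size + h and h <= c <= W - size + h):
            raise ValueError(
                f"crop center {center} too close to the edge for a {size}x{size} crop"
            )
        return self.frames[:, r - h : r - h + size, c - h : c - h + size]

    def to_screen_resolution(self) -> "Stimulus":
        """Expand stored pixels to screen pixels (block replication)."""
        if self.pixel_size == 1:
            return self
        f = self.pixel_size
        frames = np.kron(self.frames, np.ones((1, f, f), dtype=np.float32))
        return replace(self, frames=frames, pixel_size=1)


@dataclass
class SpikeResponse:
    """Per-trial binned spike counts aligned to stimulus frames."""

    counts: list[np.ndarray]
    cell_id: str = "cell"

    def __post_init__(self):
        self.counts = [np.asarray(c, dtype=np.int64) for c in self.counts]
        for c in self.counts:
            if np.any(c < 0):
                raise ValueError("spike counts must be nonnegative")

    def total_spikes(self) -> int:
        return int(sum(c.sum() for c in self.counts))


@dataclass
class GroundTruthCell:
    """Generative parameters of one simulated neuron, per stimulus ensemble."""

    params_wn: DoGLNParams
    params_nm: DoGLNParams
    polarity: str
    cell_type_label: str = ""
    cell_id: str = "cell"

    def __post_init__(self):
        for p in (self.params_wn, self.params_nm):
            if p.polarity != self.polarity:
                raise ValueError(
                    "cell polarity inconsistent with center amplitude sign"
                )

    def params_for(self, ensemble_label: str) -> DoGLNParams:
        if ensemble_label == "white_noise":
            return self.params_wn
        if ensemble_label == "natural_surrogate":
            return self.params_nm
        raise ValueError(
            f"no ground-truth parameters for ensemble {ensemble_label!r}"
        )


# ---------------------------------------------------------------------------
# stimulus generators


def _trial_layout(n_trials: int, n_nr: int, n_rep: int) -> list[Trial]:
    trials = []
    pos = 0
    for _ in range(n_trials):
        trials.append(Trial(nonrep=(pos, pos + n_nr), rep=(pos + n_nr, pos + n_nr + n_rep)))
        pos += n_nr + n_rep
    return trials


def generate_white_noise(
    geometry: StimulusGeometry,
    n_trials: int = 6,
    train_seconds: float = 20.0,
    test_seconds: float = 5.0,
    contrast: float = 0.3,
    seed: int = 0,
    distribution: str = "binary",
) -> Stimulus:
    """Spatiotemporal white noise in trials of non-repeating + repeating frames.

    Each stimulus pixel is drawn independently per frame: ``+-contrast``
    (binary, the default) or ``N(0, contrast^2)`` (``distribution="gaussian"``).
    Frames are stored at stimulus-pixel resolution; expanded frames are
    constant on ``stim_pixel_factor`` square screen-pixel blocks.  The
    repeating sequence is drawn once and reused in every trial.
    """
    if contrast <= 0:
        raise ValueError("contrast must be positive")
    if distribution not in ("binary", "gaussian"):
        raise ValueError("distribution must be 'binary' or 'gaussian'")
    n_nr = round(train_seconds * geometry.frame_rate)
    n_rep = round(test_seconds * geometry.frame_rate)
    H, W = geometry.stim_height, geometry.stim_width
    rng = np.random.default_rng(seed)

    def draw(n):
        if distribution == "binary":
            return (rng.integers(0, 2, size=(n, H, W)) * 2 - 1).astype(np.float32) * contrast
        return rng.normal(0.0, contrast, size=(n, H, W)).astype(np.float32)

    rep_block = draw(n_rep)
    parts = []
    for _ in range(n_trials):
        parts.append(draw(n_nr))
        parts.append(rep_block)
    frames = np.concatenate(parts, axis=0) if parts else np.zeros((0, H, W), np.float32)
    return Stimulus(
        frames=frames,
        geometry=geometry,
        trials=_trial_layout(n_trials, n_nr, n_rep),
        ensemble_label="white_noise",
        pixel_size=geometry.stim_pixel_factor,
        seed=seed,
    )


def _pink_latent(rng: np.random.Generator, size: int, contrast: float) -> np.ndarray:
    """A periodic latent image with 1/f amplitude (1/f^2 power) spectrum."""
    fy = np.fft.fftfreq(size)[:, None]
    fx = np.fft.fftfreq(size)[None, :]
    f = np.hypot(fy, fx)
    amp = np.zeros_like(f)
    amp[f > 0] = 1.0 / f[f > 0]
    phases = rng.uniform(0, 2 * np.pi, size=(size, size))
    spec = amp * np.exp(1j * phases)
    img = np.fft.ifft2(spec).real
    sd = img.std()
    if sd > 0:
        img *= contrast / sd
    return img.astype(np.float32)


def generate_natural_surrogate(
    geometry: StimulusGeometry,
    n_trials: int = 6,
    train_seconds: float = 20.0,
    test_seconds: float = 5.0,
    contrast: float = 0.3,
    jitter_sd: float = 1.0,
    temporal_corr: float = 0.95,
    seed: int = 0,
) -> Stimulus:
    """Naturalistic-movie surrogate: a 1/f^2-spectrum latent image viewed
    through a jittering window.

    Successive frames are shifted views of a larger periodic latent image
    following a seeded random-walk gaze path (step SD ``jitter_sd`` stimulus
    pixels, positions rounded to integers), while the latent content is
    refreshed as an AR(1) mixture ``c * old + sqrt(1 - c^2) * fresh`` with
    ``c = temporal_corr`` — which preserves the 1/f^2 marginal spectrum.
    The repeating sequence (gaze path and content) is generated once and
    reused across trials.
    """
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    if not (0 <= temporal_corr <= 1):
        raise ValueError("temporal_corr must be in [0, 1]")
    n_nr = round(train_seconds * geometry.frame_rate)
    n_rep = round(test_seconds * geometry.frame_rate)
    H, W = geometry.stim_height, geometry.stim_width
    latent_size = int(2 ** np.ceil(np.log2(2 * max(H, W))))
    rng = np.random.default_rng(seed)

    def make_segment(rng_seg: np.random.Generator, n: int) -> np.ndarray:
        latent = _pink_latent(rng_seg, latent_size, contrast)
        pos = rng_seg.uniform(0, latent_size, size=2)
        frames = np.empty((n, H, W), dtype=np.float32)
        c = temporal_corr
        mix = np.sqrt(max(0.0, 1.0 - c * c))
        for t in range(n):
            if t > 0:
                if mix > 0:
                    latent = c * latent + mix * _pink_latent(rng_seg, latent_size, contrast)
                pos = pos + rng_seg.normal(0.0, jitter_sd, size=2)
            r0, c0 = int(round(pos[0])) % latent_size, int(round(pos[1])) % latent_size
            tile = np.roll(latent, (-r0, -c0), axis=(0, 1))
            frames[t] = tile[:H, :W]
        return frames

    rep_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
    rep_block = make_segment(rep_rng, n_rep)
    parts = []
    for _ in range(n_trials):
        nr_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        parts.append(make_segment(nr_rng, n_nr))
        parts.append(rep_block)
    frames = np.concatenate(parts, axis=0) if parts else np.zeros((0, H, W), np.float32)
    return Stimulus(
        frames=frames,
        geometry=geometry,
        trials=_trial_layout(n_trials, n_nr, n_rep),
        ensemble_label="natural_surrogate",
        pixel_size=geometry.stim_pixel_factor,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# LN-Poisson simulation


def ground_truth_rate(cell: GroundTruthCell, stimulus: Stimulus) -> list[np.ndarray]:
    """Per-trial firing-rate trace (Hz), one value per stimulus frame.

    The drive of the first ``N_LAGS - 1`` bins of each segment uses mean-gray
    (zero) padded history; those bins are excluded from fitting and
    evaluation, and padding keeps repeating-segment rates identical across
    trials.
    """
    params = cell.params_for(stimulus.ensemble_label)
    cropped = stimulus.crop(params.crop_center)
    rates = [np.empty(tr.n_frames) for tr in stimulus.trials]
    for i, tr in enumerate(stimulus.trials):
        offset = tr.nonrep[0]
        for start, stop in (tr.nonrep, tr.rep):
            if stop <= start:
                continue
            drive = predict_drive(params, cropped[start:stop], pad=True)
            rates[i][start - offset : stop - offset] = softplus(drive, params.nonlinearity)
    return rates


def simulate_rgc(cell: GroundTruthCell, stimulus: Stimulus, seed: int = 0) -> SpikeResponse:
    """Draw Poisson spike counts from the cell's LN rate on this stimulus.

    Counts are independent per bin with mean ``rate / frame_rate``; repeating
    segments receive independent noise in every trial.
    """
    rng = np.random.default_rng(seed)
    rates = ground_truth_rate(cell, stimulus)
    counts = [rng.poisson(r / stimulus.geometry.frame_rate) for r in rates]
    return SpikeResponse(counts=counts, cell_id=cell.cell_id)


# ---------------------------------------------------------------------------
# ground-truth populations


@dataclass(frozen=True)
class CellTypeSpec:
    """Parameter ranges for one simulated cell type.

    Surround weights are the surround/center *volume* ratio of the generative
    DoG (0 = no surround, 1 = fully balanced).  ``nm_center_scale`` scales
    the center covariance under the naturalistic ensemble (midget-like types
    enlarge; 1.0 = unchanged).
    """

    name: str
    n: int
    polarity: str = "OFF"
    center_sigma_range: tuple[float, float] = (1.3, 1.9)
    surround_scale: float = 2.0
    wn_surround_weight: float = 0.10
    nm_surround_weight: float = 0.55
    nm_center_scale: float = 1.0


@dataclass(frozen=True)
class PopulationSpec:
    """Per-type counts/ranges plus response-scale settings shared by all cells."""

    types: tuple[CellTypeSpec, ...]
    drive_sd: float = 1.5
    mean_rate_hz: float = 15.0
    beta: float = -0.2
    contrast: float = 0.3


def default_population_spec(n_per_type: int = 10) -> PopulationSpec:
    """Two qualitative cell classes: midget-like (center enlarges under
    naturalistic stimulation) and parasol-like (center unchanged); both gain
    a stronger surround."""
    return PopulationSpec(
        types=(
            CellTypeSpec(
                name="midget_like",
                n=n_per_type,
                polarity="OFF",
                center_sigma_range=(1.2, 1.8),
                nm_center_scale=1.5,
            ),
            CellTypeSpec(
                name="parasol_like",
                n=n_per_type,
                polarity="ON",
                center_sigma_range=(1.8, 2.6),
                nm_center_scale=1.0,
            ),
        )
    )


def _biphasic_temporal(rng: np.random.Generator, lag_peak: float, lag_trough: float) -> TemporalFilter:
    """A smooth biphasic impulse response, unit norm, index 0 = most recent."""
    t = np.arange(N_LAGS, dtype=float)
    w = np.exp(-0.5 * ((t - lag_peak) / 1.8) ** 2) - 0.55 * np.exp(
        -0.5 * ((t - lag_trough) / 3.2) ** 2
    )
    w += rng.normal(0, 0.01, N_LAGS)
    return TemporalFilter(w / np.linalg.norm(w))


def _make_dog_params(
    rng: np.random.Generator,
    sign: float,
    center_sigma: float,
    surround_scale: float,
    surround_weight: float,
    crop_center: tuple[int, int],
    drive_sd: float,
    mean_rate_hz: float,
    beta: float,
    contrast: float,
    t1: TemporalFilter,
    t2: TemporalFilter,
) -> DoGLNParams:
    mid = (CROP_SIZE - 1) / 2
    mean = np.array([mid, mid]) + rng.uniform(-0.5, 0.5, 2)
    ecc = rng.uniform(0.85, 1.18)
    cov_c = np.diag([center_sigma**2 * ecc, center_sigma**2 / ecc])
    cov_s = cov_c * surround_scale**2
    # surround volume = weight * center volume:  A_s * sqrt(det cov_s) = w * A_c * sqrt(det cov_c)
    a_c = 1.0
    a_s = surround_weight * np.sqrt(np.linalg.det(cov_c) / np.linalg.det(cov_s))
    g1 = GaussianSpatialFilter(sign * a_c, mean, cov_c)
    g2 = GaussianSpatialFilter(sign * a_s, mean.copy(), cov_s)
    params = DoGLNParams(
        g1=g1, g2=g2, t1=t1, t2=t2,
        nonlinearity=SoftplusParams(alpha=1.0, beta=beta),
        crop_center=crop_center,
    )
    # scale amplitudes so the white-noise drive SD hits drive_sd:
    # Var(drive) = contrast^2 * ||R||_F^2 for uncorrelated unit-variance-contrast pixels
    from .ln_models import build_spatiotemporal_rf

    rf_norm = np.linalg.norm(build_spatiotemporal_rf(params).values)
    scale = drive_sd / (contrast * rf_norm)
    params.g1.amplitude *= scale
    params.g2.amplitude *= scale
    # gain alpha sets the mean rate given a standard-normal-ish drive
    z = rng.normal(0, 1, 4096) * drive_sd + beta
    params.nonlinearity.alpha = mean_rate_hz / float(np.mean(np.logaddexp(0, z)))
    return params


def make_ground_truth_population(
    spec: PopulationSpec | None = None,
    adapt: bool = True,
    seed: int = 0,
    geometry: StimulusGeometry | None = None,
) -> list[GroundTruthCell]:
    """Simulated population whose naturalistic-ensemble filters differ from
    the white-noise ones when ``adapt`` is true.

    With ``adapt=True``, every cell's NM parameters have a stronger surround
    and (for types with ``nm_center_scale > 1``) a larger center than its WN
    parameters; with ``adapt=False`` the two parameter sets are identical.
    """
    spec = spec or default_population_spec()
    geometry = geometry or desk_geometry()
    rng = np.random.default_rng(seed)
    h = CROP_SIZE // 2
    H, W = geometry.stim_height, geometry.stim_width
    if H < CROP_SIZE or W < CROP_SIZE:
        raise ValueError("stimulus grid too small for the model crop")
    cells: list[GroundTruthCell] = []
    for ts in spec.types:
        for k in range(ts.n):
            sign = 1.0 if ts.polarity == "ON" else -1.0
            crop_center = (
                int(rng.integers(h, H - CROP_SIZE + h + 1)),
                int(rng.integers(h, W - CROP_SIZE + h + 1)),
            )
            sigma = rng.uniform(*ts.center_sigma_range)
            t1 = _biphasic_temporal(rng, lag_peak=4.0 + rng.uniform(-1, 1), lag_trough=11.0)
            t2 = _biphasic_temporal(rng, lag_peak=6.0 + rng.uniform(-1, 1), lag_trough=13.0)
            common = dict(
                sign=sign,
                surround_scale=ts.surround_scale,
                crop_center=crop_center,
                drive_sd=spec.drive_sd,
                mean_rate_hz=spec.mean_rate_hz,
                beta=spec.beta,
                contrast=spec.contrast,
                t1=t1,
                t2=t2,
            )
            params_wn = _make_dog_params(
                rng,
                center_sigma=sigma,
                surround_weight=ts.wn_surround_weight,
                **common,
            )
            if adapt:
                params_nm = _make_dog_params(
                    rng,
                    center_sigma=sigma * np.sqrt(ts.nm_center_scale),
                    surround_weight=ts.nm_surround_weight,
                    **common,
                )
                # keep the NM center location identical to the WN one
                params_nm.g1.mean[:] = params_wn.g1.mean
            else:
                from copy import deepcopy

                params_nm = deepcopy(params_wn)
            cells.append(
                GroundTruthCell(
                    params_wn=params_wn,
                    params_nm=params_nm,
                    polarity=ts.polarity,
                    cell_type_label=ts.name,
                    cell_id=f"{ts.name}_{k:02d}",
                )
            )
    return cells
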