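"""Radially averaged power spectra, filter transfer functions and the
efficient-coding whitening analysis.

Spectra are computed per frame with an orthonormal 2-D FFT on center-cropped
square frames and radially averaged into unit-width annuli (each frequency
sample assigned by rounded radial distance).  The zero-frequency (DC) bin
reflects mean luminance, not spatial structure, and is excluded from all
reported spectra; "the first data point" used for normalization is the
first non-DC annulus.  Per-annulus frequencies are the mean sample radius
(in cycles/image), which makes closed-form comparisons meaningful at the
annulus level.

Whitening is quantified in the log-power domain as the fractional reduction
of the distance between a (normalized) spectrum and the flat reference, at
the in-band frequency where the reduction is largest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .ln_models import GaussianSpatialFilter, render_spatial
from .synthetic_data import Stimulus

__all__ = [
    "RadialSpectrum",
    "SimulatedFilter",
    "stimulus_power_spectrum",
    "transfer_function",
    "filtered_spectrum",
    "whitening_percent",
    "band_from_transfer",
    "make_simulated_filters",
    "mean_power_2d",
    "radial_average",
]


@dataclass
class RadialSpectrum:
    """Radially averaged power (or magnitude) vs spatial frequency.

    ``frequency`` holds the mean sample radius of each unit-width annulus in
    cycles/image (strictly increasing, DC excluded); ``counts`` the number
    of 2-D frequency samples per annulus; ``n`` the FFT size the binning was
    built for.
    """

    frequency: np.ndarray
    power: np.ndarray
    counts: np.ndarray
    n: int
    normalized: bool = False

    def __post_init__(self):
        self.frequency = np.asarray(self.frequency, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(np.diff(self.frequency) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(~np.isfinite(self.power)) or np.any(self.power < 0):
            raise ValueError("power must be finite and nonnegative")

    def normalize(self) -> "RadialSpectrum":
        """Normalize to the first data point (first non-DC annulus)."""
        if self.normalized:
            return self
        if self.power[0] == 0:
            raise ValueError("cannot normalize: first data point is zero")
        return RadialSpectrum(
            frequency=self.frequency.copy(),
            power=self.power / self.power[0],
            counts=self.counts.copy(),
            n=self.n,
            normalized=True,
        )


@lru_cache(maxsize=8)
def _radial_bins(n: int):
    """Annulus assignment for an n x n FFT: flat bin index per sample, mean
    radius and sample count per bin (DC bin 0 included here)."""
    f = np.fft.fftfreq(n) * n
    r = np.hypot(f[:, None], f[None, :])
    bins = np.rint(r).astype(int).ravel()
    nbins = bins.max() + 1
    counts = np.bincount(bins, minlength=nbins)
    mean_r = np.bincount(bins, weights=r.ravel(), minlength=nbins) / counts
    return bins, mean_r, counts


def radial_average(power2d: np.ndarray, include_dc: bool = False) -> RadialSpectrum:
    """Radially average a 2-D (fftfreq-ordered) power array into unit annuli."""
    n = power2d.shape[0]
    if power2d.shape != (n, n):
        raise ValueError("power array must be square")
    bins, mean_r, counts = _radial_bins(n)
    power = np.bincount(bins, weights=power2d.ravel(), minlength=counts.size) / counts
    lo = 0 if include_dc else 1
    return RadialSpectrum(
        frequency=mean_r[lo:], power=power[lo:], counts=counts[lo:], n=n
    )


def _center_crop(frames: np.ndarray, crop: int) -> np.ndarray:
    T, H, W = frames.shape
    if crop > H or crop > W:
        raise ValueError(f"crop {crop} larger than frame {H}x{W}")
    r0 = (H - crop) // 2
    c0 = (W - crop) // 2
    return frames[:, r0 : r0 + crop, c0 : c0 + crop]


def mean_power_2d(frames: np.ndarray, crop: int, max_frames: int | None = None) -> np.ndarray:
    """Across-frame mean 2-D power spectrum of center-cropped frames
    (orthonormal FFT, so total power equals total mean-square value)."""
    frames = np.asarray(frames, dtype=float)
    cropped = _center_crop(frames, crop)
    if max_frames is not None and cropped.shape[0] > max_frames:
        idx = np.linspace(0, cropped.shape[0] - 1, max_frames).astype(int)
        cropped = cropped[idx]
    F = np.fft.fft2(cropped, axes=(1, 2), norm="ortho")
    return (F.real**2 + F.imag**2).mean(axis=0)


def stimulus_power_spectrum(
    stimulus: Stimulus | np.ndarray,
    crop: int,
    normalize: bool = True,
    max_frames: int | None = None,
) -> RadialSpectrum:
    """Radially averaged spatial power spectrum of the stimulus frames.

    Each frame is center-cropped to ``crop`` x ``crop``, FFT'd, squared and
    radially averaged; results are averaged across frames.  ``max_frames``
    subsamples frames evenly for speed.
    """
    frames = stimulus.frames if isinstance(stimulus, Stimulus) else np.asarray(stimulus)
    spec = radial_average(mean_power_2d(frames, crop, max_frames))
    return spec.normalize() if normalize else spec


def _pad_filter(spatial: np.ndarray, crop: int) -> np.ndarray:
    """Zero-pad a filter into the center of a crop x crop field."""
    h, w = spatial.shape
    if h > crop or w > crop:
        raise ValueError("filter must be smaller than the padded field")
    field = np.zeros((crop, crop))
    r0 = (crop - h) // 2
    c0 = (crop - w) // 2
    field[r0 : r0 + h, c0 : c0 + w] = spatial
    return field


def transfer_function(spatial: np.ndarray, crop: int) -> RadialSpectrum:
    """Radially averaged Fourier *magnitude* of a zero-padded spatial filter."""
    F = np.fft.fft2(_pad_filter(np.asarray(spatial, dtype=float), crop))
    return radial_average(np.abs(F))


def filtered_spectrum(
    stimulus: Stimulus | np.ndarray,
    spatial: np.ndarray,
    mode: str = "tf_product",
    crop: int = 64,
    normalize: bool = True,
    tf_power: bool = True,
    max_frames: int | None = None,
) -> RadialSpectrum:
    """Spatial power spectrum of the stimulus after filtering.

    ``mode="convolve"`` circularly convolves each cropped frame with the
    filter and measures the result's spectrum; ``mode="tf_product"``
    multiplies the per-frame power spectrum by the filter's squared transfer
    magnitude (``tf_power=False`` multiplies by the plain magnitude — the
    amplitude-domain variant).  With the squared magnitude the two modes are
    mathematically identical.
    """
    frames = stimulus.frames if isinstance(stimulus, Stimulus) else np.asarray(stimulus)
    Ffilt = np.fft.fft2(_pad_filter(np.asarray(spatial, dtype=float), crop))
    if mode == "convolve":
        cropped = _center_crop(np.asarray(frames, dtype=float), crop)
        if max_frames is not None and cropped.shape[0] > max_frames:
            idx = np.linspace(0, cropped.shape[0] - 1, max_frames).astype(int)
            cropped = cropped[idx]
        F = np.fft.fft2(cropped, axes=(1, 2), norm="ortho") * Ffilt[None]
        p2 = (F.real**2 + F.imag**2).mean(axis=0)
    elif mode == "tf_product":
        p2 = mean_power_2d(frames, crop, max_frames)
        mag2 = Ffilt.real**2 + Ffilt.imag**2
        p2 = p2 * (mag2 if tf_power else np.sqrt(mag2))
    else:
        raise ValueError("mode must be 'convolve' or 'tf_product'")
    spec = radial_average(p2)
    return spec.normalize() if normalize else spec


def _band_mask(freq: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    mask = (freq >= lo) & (freq <= hi)
    if not mask.any():
        raise ValueError(f"band {band} outside the frequency support")
    return mask


def whitening_percent(
    unfiltered: RadialSpectrum, filtered: RadialSpectrum, band: tuple[float, float]
) -> float:
    """Percent flattening of the spectrum achieved by a filter.

    With ``D(s, f) = |log10 s(f)|`` the log-domain distance of a normalized
    spectrum to the flat reference, finds the in-band frequency ``f*``
    maximizing ``D(unfiltered) - D(filtered)`` and returns
    ``100 * (D(unfiltered, f*) - D(filtered, f*)) / D(unfiltered, f*)``.
    100 = fully whitened in band, 0 = no effect, negative = steepened.
    """
    unf = unfiltered.normalize()
    fil = filtered.normalize()
    if unf.frequency.shape != fil.frequency.shape or not np.allclose(
        unf.frequency, fil.frequency
    ):
        raise ValueError("spectra must share the same radial binning")
    mask = _band_mask(unf.frequency, band)
    with np.errstate(divide="ignore"):
        d_u = np.abs(np.log10(unf.power[mask]))
        d_f = np.abs(np.log10(fil.power[mask]))
    idx = int(np.argmax(d_u - d_f))
    if d_u[idx] == 0:
        return float("nan")
    return float(100.0 * (d_u[idx] - d_f[idx]) / d_u[idx])


def band_from_transfer(tf: RadialSpectrum, cutoff: float = 0.1) -> tuple[float, float]:
    """Receptive-field-relevant band: from the 2nd radial bin up to where the
    transfer magnitude first falls below ``cutoff`` of its peak."""
    peak = tf.power.max()
    lo = tf.frequency[1] if tf.frequency.size > 1 else tf.frequency[0]
    below = np.nonzero(tf.power < cutoff * peak)[0]
    start = int(np.argmax(tf.power))
    below = below[below > start]
    hi = tf.frequency[below[0] - 1] if below.size else tf.frequency[-1]
    if hi <= lo:
        hi = tf.frequency[min(2, tf.frequency.size - 1)]
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# simulated efficient-coding filters


@dataclass
class SimulatedFilter:
    """A synthetic center(+surround) filter for the whitening analysis.

    ``center`` has unit amplitude and an isotropic covariance (equal
    diagonal from the largest diagonal entry of the source fit, zero
    off-diagonal); ``surround`` is the subtracted Gaussian, or None.
    """

    kind: str
    center: GaussianSpatialFilter
    surround: GaussianSpatialFilter | None = None

    def __post_init__(self):
        cov = self.center.covariance
        if cov[0, 0] != cov[1, 1] or cov[0, 1] != 0:
            raise ValueError("simulated filter center must be isotropic")
        if abs(self.center.amplitude) != 1.0:
            raise ValueError("simulated filter center amplitude must be 1")

    def render(self, grid_size: int | None = None) -> np.ndarray:
        if grid_size is None:
            sig = np.sqrt(
                (self.surround or self.center).covariance[0, 0]
            )
            grid_size = int(2 * np.ceil(4 * sig) + 1)
        mid = (grid_size - 1) / 2.0
        center = GaussianSpatialFilter(
            self.center.amplitude, np.array([mid, mid]), self.center.covariance
        )
        img = render_spatial(center, grid_size)
        if self.surround is not None:
            surround = GaussianSpatialFilter(
                self.surround.amplitude, np.array([mid, mid]), self.surround.covariance
            )
            img = img - render_spatial(surround, grid_size)
        return img


def _isotropic_center(fit) -> GaussianSpatialFilter:
    """Unit-amplitude isotropic Gaussian from a post-hoc DoG fit's center:
    all diagonal entries equal to the largest diagonal value."""
    s2 = float(np.max(np.diag(fit.cov_c)))
    return GaussianSpatialFilter(1.0, np.zeros(2), np.diag([s2, s2]))


def _flatness(center, surround, target: RadialSpectrum, band) -> float:
    filt = SimulatedFilter(kind="candidate", center=center, surround=surround)
    img = filt.render()
    if img.shape[0] >= target.n:
        return np.inf
    tf = transfer_function(img, target.n)
    p = target.normalize().power * tf.power**2
    if p[0] == 0:
        return np.inf
    p = p / p[0]
    mask = _band_mask(target.frequency, band)
    with np.errstate(divide="ignore"):
        return float(np.max(np.abs(np.log10(p[mask]))))


def make_simulated_filters(
    mean_rf_fit_small,
    mean_rf_fit_large,
    target_spectrum: RadialSpectrum,
    band: tuple[float, float],
    surround_amps: np.ndarray | None = None,
    surround_scales: np.ndarray | None = None,
) -> list[SimulatedFilter]:
    """Construct the four efficient-coding test filters.

    ``white_noise_like``: small center (from the midget-like mean-RF DoG
    fit), no surround.  ``low_pass``: large center (parasol-like fit), no
    surround.  For each, a ``*_with_surround`` variant subtracts a second
    isotropic Gaussian whose amplitude and width are chosen by grid search
    to maximize the in-band flatness (minimal max |log10 power|) of the
    target spectrum after filtering.
    """
    if not target_spectrum.normalized:
        target_spectrum = target_spectrum.normalize()
    if surround_amps is None:
        surround_amps = np.arange(0.05, 1.0001, 0.05)
    if surround_scales is None:
        surround_scales = np.arange(1.2, 4.0001, 0.2)
    out = []
    for kind, fit in (("white_noise_like", mean_rf_fit_small), ("low_pass", mean_rf_fit_large)):
        center = _isotropic_center(fit)
        out.append(SimulatedFilter(kind=kind, center=center))
        base = _flatness(center, None, target_spectrum, band)
        best = (base, None)
        s2 = center.covariance[0, 0]
        for scale in surround_scales:
            cov_s = np.diag([s2 * scale**2, s2 * scale**2])
            for amp in surround_amps:
                surround = GaussianSpatialFilter(float(amp), np.zeros(2), cov_s)
                score = _flatness(center, surround, target_spectrum, band)
                if score < best[0]:
                    best = (score, surround)
        if best[1] is None:
            warnings.warn(
                f"no surround improved in-band flatness for {kind}; "
                "returning the surroundless filter"
            )
            out.append(SimulatedFilter(kind=f"{kind}_with_surround", center=center))
        else:
            out.append(
                SimulatedFilter(kind=f"{kind}_with_surround", center=center, surround=best[1])
            )
    return out
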