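"""Continuous wavelet transform, wavelet squared coherence, and broadband
power-weighted TVFC graphs.

The state representation is a time-indexed sequence of symmetric
region x region *coherence distance* graphs: 1 minus the cross-power-weighted
mean of the smoothed wavelet squared coherence across retained scales.
Temporal and spectral edges of the time-frequency plane (where the wavelet
kernel overlaps the undefined signal boundary, and where the scale-smoothing
window is truncated) are trimmed before averaging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from . import defaults
from .synthetic import ParcelSeries, StudyConfig

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Filterbank:
    """Log-spaced Morlet filterbank.

    Center frequencies are geometrically spaced and include both endpoints;
    scales follow the Morlet approximate conversion s = omega0 / (2 pi f).
    """

    omega0: float
    scales: np.ndarray        # seconds, increasing
    center_freqs: np.ndarray  # Hz, decreasing with scale
    f_min: float
    f_max: float

    @property
    def n_scales(self) -> int:
        return self.scales.size


def build_filterbank(f_min: float = defaults.F_MIN,
                     f_max: float = defaults.F_MAX,
                     n_scales: int = defaults.N_SCALES,
                     omega0: float = defaults.OMEGA0,
                     tr: float | None = None) -> Filterbank:
    """Build the log-spaced filterbank between ``f_min`` and ``f_max`` Hz."""
    if n_scales < 2:
        raise ValueError("need at least 2 scales")
    if not 0 < f_min < f_max:
        raise ValueError("need 0 < f_min < f_max")
    if tr is not None:
        nyquist = 1.0 / (2.0 * tr)
        if f_max >= nyquist:
            raise ValueError(
                f"f_max={f_max} Hz is at/above Nyquist {nyquist:.4g} Hz for TR={tr} s"
            )
    if omega0 < 6.0:
        raise ValueError("omega0 must be >= 6 so the kernel's nonzero mean is negligible")
    freqs = np.geomspace(f_max, f_min, n_scales)  # decreasing, endpoint-inclusive
    scales = omega0 / (2.0 * np.pi * freqs)
    return Filterbank(omega0=omega0, scales=scales, center_freqs=freqs,
                      f_min=f_min, f_max=f_max)


@dataclass
class Spectrogram:
    """Complex CWT coefficients, regions x scales x time."""

    coeffs: np.ndarray
    filterbank: Filterbank
    tr: float

    @property
    def n_regions(self) -> int:
        return self.coeffs.shape[0]


def morlet_kernel(scale: float, dt: float, omega0: float) -> np.ndarray:
    """Complex Morlet sampled on +-4 scale support: plane wave times Gaussian."""
    n = int(np.ceil(4.0 * scale / dt))
    t = np.arange(-n, n + 1) * dt
    return np.exp(1j * omega0 * t / scale) * np.exp(-t * t / (2.0 * scale * scale))


def cwt(series: ParcelSeries, fb: Filterbank) -> Spectrogram:
    """Continuous wavelet transform of every region's signal.

    W[r, s, u] = sum_t f_r(t) s^{-1/2} psi*((t-u)/s) dt, computed as a linear
    convolution with zero padding (trimmed margins absorb the edge effects).
    """
    T = series.n_samples
    dt = series.tr
    support = 2 * int(np.ceil(4.0 * fb.scales.max() / dt)) + 1
    if T < support:
        raise ValueError(
            f"series of {T} samples is shorter than the largest wavelet support "
            f"({support} samples); complete kernel overlap is required"
        )
    coeffs = np.empty((series.n_regions, fb.n_scales, T), dtype=complex)
    sig = series.signal
    for k, s in enumerate(fb.scales):
        # psi(-t) = conj(psi(t)), so the correlation with psi* equals a
        # convolution with psi(t/s)
        kern = morlet_kernel(s, dt, fb.omega0) * (dt / np.sqrt(s))
        coeffs[:, k, :] = fftconvolve(sig, kern[None, :], mode="same", axes=-1)
    return Spectrogram(coeffs=coeffs, filterbank=fb, tr=dt)


def _gauss_kernel(sigma: float) -> np.ndarray:
    n = max(1, int(np.ceil(4.0 * sigma)))
    t = np.arange(-n, n + 1, dtype=float)
    k = np.exp(-t * t / (2.0 * sigma * sigma))
    return k / k.sum()


def _smooth_time(arr: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian smoothing along the last axis (complex-safe, zero-padded)."""
    kern = _gauss_kernel(sigma).reshape((1,) * (arr.ndim - 1) + (-1,))
    if np.iscomplexobj(arr):
        return (fftconvolve(arr.real, kern, mode="same", axes=-1)
                + 1j * fftconvolve(arr.imag, kern, mode="same", axes=-1))
    return fftconvolve(arr, kern, mode="same", axes=-1)


def _smooth_field(field: np.ndarray, scales: np.ndarray, dt: float,
                  time_sigma_factor: float = 1.0,
                  scale_boxcar: int = 3) -> np.ndarray:
    """<.> operator: per-scale Gaussian in time (sd = factor * s), then a
    boxcar across scales. ``field`` has shape (..., n_scales, n_time)."""
    out = np.empty_like(field)
    for k, s in enumerate(scales):
        sigma = max(time_sigma_factor * s / dt, 0.5)
        out[..., k, :] = _smooth_time(field[..., k, :], sigma)
    if scale_boxcar > 1:
        half = scale_boxcar // 2
        padded = np.concatenate(
            [out[..., :1, :]] * half + [out] + [out[..., -1:, :]] * half, axis=-2
        )
        windowed = np.empty_like(out)
        for k in range(field.shape[-2]):
            windowed[..., k, :] = padded[..., k:k + scale_boxcar, :].mean(axis=-2)
        out = windowed
    return out


def wavelet_coherence_pair(Wx: np.ndarray, Wy: np.ndarray, scales: np.ndarray,
                           dt: float, time_sigma_factor: float = 1.0,
                           scale_boxcar: int = 3,
                           return_weights: bool = False):
    """Smoothed wavelet squared coherence R^2 between two spectrogram slices.

    R^2_t(s) = |<s^-1 Wx Wy*>|^2 / (<s^-1 |Wx|^2> <s^-1 |Wy|^2>), the
    instantaneous multispectral analogue of a squared Pearson correlation,
    clipped to [0, 1].

    With ``return_weights`` also returns the smoothed cross-wavelet power
    |<s^-1 Wxy>| used as the broadband averaging weight.
    """
    if Wx.shape != Wy.shape:
        raise ValueError("spectrogram slices must share shape")
    inv_s = (1.0 / scales)[:, None]
    cross = _smooth_field(inv_s * (Wx * np.conj(Wy)), scales, dt,
                          time_sigma_factor, scale_boxcar)
    px = _smooth_field(inv_s * np.abs(Wx) ** 2, scales, dt,
                       time_sigma_factor, scale_boxcar)
    py = _smooth_field(inv_s * np.abs(Wy) ** 2, scales, dt,
                       time_sigma_factor, scale_boxcar)
    denom = px * py
    bad = denom <= 0
    if bad.any():
        logger.debug("zero-power denominator at %d cells; coherence set to 0",
                     int(bad.sum()))
    r2 = np.zeros_like(denom)
    np.divide(np.abs(cross) ** 2, denom, out=r2, where=~bad)
    over = np.clip(r2 - 1.0, 0.0, None).max() if r2.size else 0.0
    if over > 1e-6:
        raise FloatingPointError(
            f"coherence exceeded 1 by {over:.3g}; smoothing is inconsistent"
        )
    r2 = np.clip(r2, 0.0, 1.0)
    if return_weights:
        return r2, np.abs(cross)
    return r2


def power_weighted_tvfc(r2: np.ndarray, crosspower: np.ndarray) -> np.ndarray:
    """Broadband coherence per time point: cross-power-weighted mean of R^2.

    C_t = sum_s w_s(t) R^2_t(s) / sum_s w_s(t), with w the cross-wavelet
    power. Sum-normalising the weights keeps C_t in [0, 1]; time points with
    all-zero weights get C_t = 0.
    """
    if r2.shape != crosspower.shape:
        raise ValueError("R^2 and cross-power fields must share shape")
    wsum = crosspower.sum(axis=-2)
    num = (crosspower * r2).sum(axis=-2)
    out = np.zeros_like(wsum)
    zero = wsum <= 0
    if zero.any():
        logger.debug("all-zero weights at %d time points; coherence set to 0",
                     int(zero.sum()))
    np.divide(num, wsum, out=out, where=~zero)
    return np.clip(out, 0.0, 1.0)


@dataclass
class TVFCSeries:
    """Per-retained-time-point symmetric coherence-distance graphs in [0,1]."""

    graphs: np.ndarray              # (n_retained, R, R)
    retained_time_index: np.ndarray  # original sample indices
    retained_scales: np.ndarray      # Hz
    point_meta: pd.DataFrame         # volunteer, time_index, condition, performance
    region_labels: list[str] = field(default_factory=list)
    spectrogram: Spectrogram | None = None  # retained-scale CWT, for node vectors

    @property
    def n_points(self) -> int:
        return self.graphs.shape[0]

    @property
    def n_regions(self) -> int:
        return self.graphs.shape[1]


def compute_tvfc(series: ParcelSeries, fb: Filterbank,
                 trim_time: int = defaults.TRIM_TIME,
                 trim_scales: int = defaults.TRIM_SCALES,
                 time_sigma_factor: float = 1.0,
                 scale_boxcar: int = 3,
                 pair_chunk: int = 256,
                 keep_spectrogram: bool = True) -> TVFCSeries:
    """All-pairs broadband coherence-distance graphs with edge trimming.

    Drops ``trim_scales`` scales at each spectral edge and ``trim_time``
    samples at each temporal edge before the weighted broadband average.
    """
    T = series.n_samples
    n_keep_s = fb.n_scales - 2 * trim_scales
    if n_keep_s < 1:
        raise ValueError("trimming removes every scale")
    n_keep_t = T - 2 * trim_time
    if n_keep_t < 1:
        raise ValueError("trimming removes every time point")
    spec = cwt(series, fb)
    R = series.n_regions
    s_slice = slice(trim_scales, fb.n_scales - trim_scales)
    t_slice = slice(trim_time, T - trim_time)
    scales = fb.scales
    dt = series.tr

    # smoothed auto energy densities, once per region
    inv_s = (1.0 / scales)[None, :, None]
    auto = _smooth_field(inv_s * np.abs(spec.coeffs) ** 2, scales, dt,
                         time_sigma_factor, scale_boxcar)

    iu, ju = np.triu_indices(R, k=1)
    graphs = np.zeros((n_keep_t, R, R))
    for start in range(0, iu.size, pair_chunk):
        ii = iu[start:start + pair_chunk]
        jj = ju[start:start + pair_chunk]
        cross = _smooth_field(
            (1.0 / scales)[None, :, None] * spec.coeffs[ii] * np.conj(spec.coeffs[jj]),
            scales, dt, time_sigma_factor, scale_boxcar)
        denom = auto[ii] * auto[jj]
        r2 = np.zeros_like(denom)
        np.divide(np.abs(cross) ** 2, denom, out=r2, where=denom > 0)
        r2 = np.clip(r2, 0.0, 1.0)
        w = np.abs(cross)[:, s_slice, t_slice]
        c = power_weighted_tvfc(r2[:, s_slice, t_slice], w)  # (chunk, n_keep_t)
        d = 1.0 - c
        graphs[:, ii, jj] = d.T
        graphs[:, jj, ii] = d.T

    retained = np.arange(trim_time, T - trim_time)
    conds, perfs = [], []
    for u in retained:
        c, p = series.condition_at(int(u))
        conds.append(c)
        perfs.append(p)
    meta = pd.DataFrame({
        "volunteer": series.volunteer_id,
        "time_index": retained,
        "condition": conds,
        "performance": perfs,
    })
    kept_spec = None
    if keep_spectrogram:
        kept_spec = Spectrogram(coeffs=spec.coeffs[:, s_slice, t_slice],
                                filterbank=fb, tr=dt)
    return TVFCSeries(
        graphs=graphs,
        retained_time_index=retained,
        retained_scales=fb.center_freqs[s_slice].copy(),
        point_meta=meta,
        region_labels=list(series.region_labels),
        spectrogram=kept_spec,
    )


def coherence_significance_threshold(config: StudyConfig, fb: Filterbank,
                                     n_surrogates: int = 50,
                                     quantile: float = 0.05,
                                     n_samples: int | None = None,
                                     trim_time: int = defaults.TRIM_TIME,
                                     trim_scales: int = defaults.TRIM_SCALES,
                                     time_sigma_factor: float = 1.0,
                                     scale_boxcar: int = 3,
                                     seed: int | None = None) -> float:
    """Coherence-distance threshold calibrated on independent AR1 pairs.

    Generates pairs of independent AR1 series matched to the study's noise
    model, computes their broadband edge distances at retained times, and
    returns the lower ``quantile`` of that null distribution: distances below
    it are significantly coherent.
    """
    if n_surrogates < 50:
        raise ValueError("need at least 50 surrogate pairs for a stable quantile")
    if not 0.0 <= quantile <= 1.0:
        raise ValueError("quantile must lie in [0, 1]")
    rng_seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed), 17]))
    T = n_samples if n_samples is not None else config.n_samples()
    from .synthetic import _ar1_noise  # shared noise model

    dists = []
    for _ in range(n_surrogates):
        sig = _ar1_noise((2, T), config.ar1_phi, config.noise_sd, rng)
        series = ParcelSeries(
            volunteer_id="surrogate", signal=sig, tr=config.tr,
            region_labels=["A", "B"], events=[],
        )
        tv = compute_tvfc(series, fb, trim_time=trim_time,
                          trim_scales=trim_scales,
                          time_sigma_factor=time_sigma_factor,
                          scale_boxcar=scale_boxcar, keep_spectrogram=False)
        dists.append(tv.graphs[:, 0, 1])
    pooled = np.concatenate(dists)
    if pooled.std() < 1e-12:
        raise ValueError("degenerate surrogate distance distribution")
    return float(np.quantile(pooled, quantile))
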