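"""Synthetic block-design multi-volunteer study generator.

Emulates a continuous block-design scanning session: conditions
{rest, video, math, memory} presented in 3-minute blocks (each preceded by a
12-s instruction block, tasks presented twice), condition-specific
inter-regional coupling restricted to the low-frequency BOLD band,
volunteer-specific idiosyncratic mixing, block-wise percent-correct
performance that modulates coupling strength, and AR1 observation noise.

The generator exists so that every downstream stage — wavelet coherence,
the six metric spaces, embedding, and the permutation statistics — can be
exercised and calibrated without external scan data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import defaults


@dataclass(frozen=True)
class Block:
    """One stimulus presentation: an instruction segment then the block proper.

    ``performance`` is the block-wise fraction of correct responses (None for
    conditions without a response task, e.g. rest).
    """

    condition: str
    duration: float                  # seconds
    instruction_duration: float = defaults.INSTRUCTION_DURATION
    performance: float | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"block duration must be positive, got {self.duration}")
        if self.instruction_duration < 0:
            raise ValueError("instruction duration must be nonnegative")
        if self.performance is not None and not 0.0 <= self.performance <= 1.0:
            raise ValueError(f"performance must lie in [0, 1], got {self.performance}")


def default_block_layout() -> list[Block]:
    """Two presentations each of rest, video, math and memory.

    Performance values straddle 0.5 so that each task has one
    higher-performance and one lower-performance presentation.
    """
    # rest first and video last: cone-of-influence trimming then removes one
    # whole rest and one whole video presentation, leaving both math and both
    # memory presentations intact for condition balancing
    return [
        Block("rest", defaults.BLOCK_DURATION),
        Block("math", defaults.BLOCK_DURATION, performance=0.90),
        Block("memory", defaults.BLOCK_DURATION, performance=0.80),
        Block("video", defaults.BLOCK_DURATION, performance=0.85),
        Block("rest", defaults.BLOCK_DURATION),
        Block("math", defaults.BLOCK_DURATION, performance=0.55),
        Block("memory", defaults.BLOCK_DURATION, performance=0.60),
        Block("video", defaults.BLOCK_DURATION, performance=0.65),
    ]


@dataclass
class StudyConfig:
    """Parameters of one synthetic study.

    coupling_strength scales the shared band-limited community signal;
    idiosyncrasy_strength scales a per-volunteer random mixing perturbation;
    performance_effect multiplies coupling by ``1 + effect * (perf - 0.5)``.
    """

    n_volunteers: int = 6
    n_regions: int = 60
    tr: float = defaults.TR
    block_layout: list[Block] = field(default_factory=default_block_layout)
    band: tuple[float, float] = defaults.BAND
    coupling_strength: float = 3.0
    idiosyncrasy_strength: float = 0.5
    performance_effect: float = 1.0
    ar1_phi: float = 0.4
    noise_sd: float = 1.0
    n_communities: int = 4
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("StudyConfig requires an explicit seed")
        if self.n_regions < 4:
            raise ValueError("need at least 4 regions")
        if self.n_volunteers < 1:
            raise ValueError("need at least 1 volunteer")
        nyquist = 1.0 / (2.0 * self.tr)
        f_lo, f_hi = self.band
        if not (0 < f_lo < f_hi < nyquist):
            raise ValueError(
                f"band must satisfy 0 < f_lo < f_hi < Nyquist={nyquist:.4g} Hz"
            )
        if self.coupling_strength < 0 or self.idiosyncrasy_strength < 0:
            raise ValueError("strengths must be nonnegative")
        if not -1.0 < self.ar1_phi < 1.0:
            raise ValueError("ar1_phi must lie in (-1, 1)")
        if not self.block_layout:
            raise ValueError("block layout is empty")
        for b in self.block_layout:
            if round(b.duration / self.tr) < 1:
                raise ValueError(f"zero-duration block for condition {b.condition!r}")

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for b in self.block_layout:
            if b.condition not in seen:
                seen.append(b.condition)
        return seen

    def n_samples(self) -> int:
        n = 0
        for b in self.block_layout:
            n += round(b.instruction_duration / self.tr) + round(b.duration / self.tr)
        return n


@dataclass
class ParcelSeries:
    """One volunteer's parcellated signal: regions x time, with events."""

    volunteer_id: str
    signal: np.ndarray               # (n_regions, n_samples)
    tr: float
    region_labels: list[str]
    # (condition, onset_s, duration_s, performance-or-None)
    events: list[tuple[str, float, float, float | None]]

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D regions x time matrix")
        if len(self.region_labels) != self.signal.shape[0]:
            raise ValueError("region_labels length must match signal rows")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")
        scan_end = self.signal.shape[1] * self.tr
        for cond, onset, dur, _ in self.events:
            if onset < 0 or onset + dur > scan_end + 1e-9:
                raise ValueError(
                    f"event {cond!r} at {onset}s (+{dur}s) lies outside the scan"
                )

    @property
    def n_regions(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def condition_at(self, sample: int) -> tuple[str, float | None]:
        """Condition label and block performance at a sample index.

        Samples outside every event (should not occur with generated layouts)
        are labelled 'instruction'.
        """
        t = sample * self.tr
        for cond, onset, dur, perf in self.events:
            if onset - 1e-9 <= t < onset + dur - 1e-9:
                return cond, perf
        return "instruction", None


def _band_limited_noise(n: int, dt: float, band: tuple[float, float],
                        rng: np.random.Generator) -> np.ndarray:
    """Unit-variance random-phase noise with support restricted to `band`."""
    freqs = np.fft.rfftfreq(n, d=dt)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not mask.any():
        # block too short to resolve the band; fall back to the nearest bin
        mask = np.zeros_like(freqs, dtype=bool)
        mask[max(1, np.argmin(np.abs(freqs - np.mean(band))))] = True
    phases = rng.uniform(0.0, 2.0 * np.pi, size=mask.sum())
    spec = np.zeros(freqs.size, dtype=complex)
    spec[mask] = np.exp(1j * phases)
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    if sd < 1e-15:
        return np.zeros(n)
    return (x - x.mean()) / sd


def _ar1_noise(shape: tuple[int, ...], phi: float, sd: float,
               rng: np.random.Generator) -> np.ndarray:
    """Stationary AR1 noise with marginal standard deviation `sd`."""
    innov_sd = sd * np.sqrt(1.0 - phi * phi)
    eps = rng.normal(0.0, innov_sd, size=shape)
    out = np.empty(shape)
    out[..., 0] = rng.normal(0.0, sd, size=shape[:-1])
    for t in range(1, shape[-1]):
        out[..., t] = phi * out[..., t - 1] + eps[..., t]
    return out


def condition_partitions(config: StudyConfig) -> dict[str, np.ndarray]:
    """Fixed community partition per condition, derived from the study seed.

    Returns, per condition, an integer array of length n_regions giving each
    region's community id.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 11]))
    parts: dict[str, np.ndarray] = {}
    for cond in config.conditions:
        perm = rng.permutation(config.n_regions)
        comm = np.empty(config.n_regions, dtype=int)
        for c, chunk in enumerate(np.array_split(perm, config.n_communities)):
            comm[chunk] = c
        parts[cond] = comm
    return parts


def generate_study(config: StudyConfig) -> list[ParcelSeries]:
    """Generate the full multi-volunteer study. Deterministic given the seed."""
    root = np.random.SeedSequence([int(config.seed), 7])
    parts = condition_partitions(config)
    R = config.n_regions
    n_samples = config.n_samples()
    out: list[ParcelSeries] = []
    vol_seeds = root.spawn(config.n_volunteers)
    region_labels = [f"R{r:03d}" for r in range(R)]

    for v, vseed in enumerate(vol_seeds):
        rng = np.random.default_rng(vseed)
        mixing = np.eye(R) + (
            config.idiosyncrasy_strength * rng.normal(size=(R, R)) / np.sqrt(R)
        )
        coupled = np.zeros((R, n_samples))
        events: list[tuple[str, float, float, float | None]] = []
        cursor = 0
        for block in config.block_layout:
            n_instr = round(block.instruction_duration / config.tr)
            n_block = round(block.duration / config.tr)
            if n_instr:
                events.append(("instruction", cursor * config.tr,
                               n_instr * config.tr, None))
            cursor += n_instr  # instruction segment stays uncoupled
            perf = block.performance
            gain = config.coupling_strength * (
                1.0 + config.performance_effect * ((perf if perf is not None else 0.5) - 0.5)
            )
            gain = max(gain, 0.0)
            comm = parts[block.condition]
            latents = np.stack([
                _band_limited_noise(n_block, config.tr, config.band, rng)
                for _ in range(config.n_communities)
            ])
            coupled[:, cursor:cursor + n_block] = gain * latents[comm]
            events.append((block.condition, cursor * config.tr,
                           n_block * config.tr, perf))
            cursor += n_block
        noise = _ar1_noise((R, n_samples), config.ar1_phi, config.noise_sd, rng)
        signal = mixing @ coupled + noise
        out.append(ParcelSeries(
            volunteer_id=f"vol{v:02d}",
            signal=signal,
            tr=config.tr,
            region_labels=region_labels,
            events=events,
        ))
    return out


def fit_ar1(x: np.ndarray) -> tuple[float, float, float]:
    """Method-of-moments AR1 fit: (mean, phi_hat, marginal variance)."""
    x = np.asarray(x, dtype=float)
    mu = x.mean()
    xc = x - mu
    var = xc.var()
    if var < 1e-15:
        raise ValueError("constant signal has no AR1 representation")
    phi = float(np.dot(xc[:-1], xc[1:]) / np.dot(xc[:-1], xc[:-1]))
    phi = float(np.clip(phi, -0.999, 0.999))
    return float(mu), phi, float(var)


def ar1_surrogate(series: ParcelSeries, seed: int) -> ParcelSeries:
    """Independent AR1 realisation matched per region in mean, variance and
    lag-1 autocorrelation.

    Used to calibrate significance thresholds for wavelet coherence distance:
    the surrogate destroys all inter-regional coupling while preserving each
    region's autocorrelation structure at lag 1.
    """
    if series.n_samples < 3:
        raise ValueError("series too short for an AR1 fit (need >= 3 samples)")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 13]))
    out = np.empty_like(series.signal)
    for r in range(series.n_regions):
        x = series.signal[r]
        if x.std() < 1e-12:
            raise ValueError(
                f"region {series.region_labels[r]!r} is constant; cannot fit AR1"
            )
        mu, phi, var = fit_ar1(x)
        y = _ar1_noise((series.n_samples,), phi, np.sqrt(var), rng)
        # re-standardise the finite sample so mean/variance match exactly
        y = (y - y.mean()) / max(y.std(), 1e-15) * np.sqrt(var) + mu
        out[r] = y
    return ParcelSeries(
        volunteer_id=f"{series.volunteer_id}-ar1",
        signal=out,
        tr=series.tr,
        region_labels=list(series.region_labels),
        events=list(series.events),
    )
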