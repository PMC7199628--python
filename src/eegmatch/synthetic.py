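"""Seeded synthetic EEG generator with the spectral structure the
detector assumes.

Normal segments are a stationary superposition of the five classical EEG
rhythms — delta (0.5–4 Hz), theta (4–8 Hz), alpha (8–14 Hz), beta
(14–30 Hz) and gamma (30–70 Hz) — each realized as band-limited Gaussian
noise scaled to a configured RMS amplitude, plus broadband white noise.
Band-limited noise (rather than pure sinusoids) yields continuous spectra
spread over many frequency bins, which is what the distribution-based
similarity metrics operate on.

Abnormal segments model two disturbance mechanisms jointly: disordered
band amplitudes (each band's amplitude multiplied by an independent
uniform draw per segment) and a raised noise floor (white-noise sigma
multiplied by a factor >= 1).  Either mechanism can be switched off for
ablation by setting the jitter range to (1, 1) or the factor to 1.

Every segment draws from its own random stream keyed by
(seed, class, index), so a dataset is reproducible and individual
segments are stable when counts change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .signal_model import Dataset, EEGSegment

__all__ = ["BANDS", "GeneratorConfig", "generate_normal", "generate_abnormal",
           "generate_dataset"]

#: EEG rhythm band edges in Hz (gamma capped at the 70 Hz analysis limit)
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 14.0),
    "beta": (14.0, 30.0),
    "gamma": (30.0, 70.0),
}

# RMS amplitudes (microvolts) resembling alpha-dominant adult resting
# scalp EEG, embedded in a heavy broadband noise floor (the clinical
# recordings this emulates are highly noisy).
_DEFAULT_AMPS = {"delta": 10.0, "theta": 9.0, "alpha": 11.0,
                 "beta": 8.0, "gamma": 5.0}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic EEG generator.

    Attributes
    ----------
    fs : float
        Sampling rate in Hz (default 512).
    n_samples : int
        Samples per segment (default 10000, i.e. ~19.5 s at 512 Hz).
    band_amps : dict
        Per-band RMS amplitude in arbitrary microvolt-like units.
    noise_sigma : float
        Standard deviation of the additive white noise.
    anomaly_amp_jitter : (float, float)
        Range of the uniform multiplicative factor applied independently
        to each band amplitude of an abnormal segment.
    anomaly_noise_factor : float
        Multiplier (>= 1) on ``noise_sigma`` for abnormal segments.
    seed : int
        Base seed of the per-segment random streams.
    """

    fs: float = 512.0
    n_samples: int = 10000
    band_amps: dict = field(default_factory=lambda: dict(_DEFAULT_AMPS))
    noise_sigma: float = 15.0
    anomaly_amp_jitter: tuple[float, float] = (0.2, 2.5)
    anomaly_noise_factor: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.band_amps) - set(BANDS)
        if unknown:
            raise ValueError(f"unknown bands {sorted(unknown)}; valid: {sorted(BANDS)}")
        top = max(BANDS[b][1] for b in self.band_amps) if self.band_amps else 0.0
        if self.fs <= 2 * top:
            raise ValueError(
                f"fs={self.fs} Hz cannot represent the {top} Hz band edge "
                f"(need fs > {2 * top} Hz)"
            )
        if self.n_samples < 2:
            raise ValueError("n_samples must be at least 2")
        if any(a < 0 for a in self.band_amps.values()):
            raise ValueError("band amplitudes must be nonnegative")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        lo, hi = self.anomaly_amp_jitter
        if not 0 <= lo <= hi:
            raise ValueError("anomaly_amp_jitter must satisfy 0 <= lo <= hi")
        if self.anomaly_noise_factor < 1:
            raise ValueError("anomaly_noise_factor must be >= 1")

    def to_dict(self) -> dict:
        return {
            "fs": self.fs, "n_samples": self.n_samples,
            "band_amps": dict(self.band_amps), "noise_sigma": self.noise_sigma,
            "anomaly_amp_jitter": list(self.anomaly_amp_jitter),
            "anomaly_noise_factor": self.anomaly_noise_factor, "seed": self.seed,
        }


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                low: float, high: float) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to [low, high] Hz.

    The noise is synthesized with guard padding on both sides and the
    central ``n`` samples kept, so the recursive filter's start-up
    transient (seconds long for the 0.5 Hz delta edge) never reaches
    the returned segment.
    """
    pad = min(int(round(4.0 * fs / low)), 4096)
    white = rng.standard_normal(n + 2 * pad)
    sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    shaped = sps.sosfiltfilt(sos, white)[pad: pad + n]
    rms = float(np.sqrt(np.mean(shaped**2)))
    return shaped / rms if rms > 0 else shaped


def _synthesize(rng: np.random.Generator, cfg: GeneratorConfig,
                amps: dict[str, float], sigma: float) -> np.ndarray:
    x = np.zeros(cfg.n_samples)
    for band, amp in amps.items():
        if amp > 0:
            low, high = BANDS[band]
            x = x + amp * _band_noise(rng, cfg.n_samples, cfg.fs, low, high)
    if sigma > 0:
        x = x + sigma * rng.standard_normal(cfg.n_samples)
    return x


def _stream(cfg: GeneratorConfig, kind: int, index: int) -> np.random.Generator:
    # independent stream per (seed, class, segment index)
    return np.random.default_rng([cfg.seed, kind, index])


def generate_normal(cfg: GeneratorConfig, n: int,
                    start_index: int = 0) -> list[EEGSegment]:
    """Generate *n* normal segments (stable band amplitudes)."""
    if n < 1:
        raise ValueError("n must be at least 1")
    segments = []
    for k in range(start_index, start_index + n):
        rng = _stream(cfg, 0, k)
        samples = _synthesize(rng, cfg, cfg.band_amps, cfg.noise_sigma)
        segments.append(EEGSegment(id=f"normal-{k:04d}", samples=samples,
                                   fs=cfg.fs, label="normal"))
    return segments


def generate_abnormal(cfg: GeneratorConfig, n: int,
                      start_index: int = 0) -> list[EEGSegment]:
    """Generate *n* abnormal segments (disordered amplitudes, extra noise)."""
    if n < 1:
        raise ValueError("n must be at least 1")
    lo, hi = cfg.anomaly_amp_jitter
    segments = []
    for k in range(start_index, start_index + n):
        rng = _stream(cfg, 1, k)
        amps = {band: amp * rng.uniform(lo, hi)
                for band, amp in cfg.band_amps.items()}
        sigma = cfg.noise_sigma * cfg.anomaly_noise_factor
        samples = _synthesize(rng, cfg, amps, sigma)
        segments.append(EEGSegment(id=f"abnormal-{k:04d}", samples=samples,
                                   fs=cfg.fs, label="abnormal"))
    return segments


def generate_dataset(cfg: GeneratorConfig, n_templates: int = 30,
                     n_normal_test: int = 30,
                     n_abnormal_test: int = 30) -> Dataset:
    """Generate a full labeled study dataset.

    Produces ``n_templates + n_normal_test`` normal segments (the first
    ``n_templates`` are flagged template-eligible in the metadata) and
    ``n_abnormal_test`` abnormal segments; fully reproducible from the
    config seed.
    """
    if min(n_templates, n_normal_test, n_abnormal_test) < 1:
        raise ValueError("all segment counts must be at least 1")
    normals = generate_normal(cfg, n_templates + n_normal_test)
    abnormals = generate_abnormal(cfg, n_abnormal_test)
    metadata = {
        "generator": cfg.to_dict(),
        "template_ids": [s.id for s in normals[:n_templates]],
    }
    return Dataset([*normals, *abnormals], metadata=metadata)
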