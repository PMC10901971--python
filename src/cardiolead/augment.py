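"""Stochastic training-time transforms for ECG windows.

Four transforms: additive Gaussian noise (per-record standard deviation
drawn uniformly from [0.01, 0.1]), temporal stretch/compression by a
factor in [0.8, 1.2], amplitude scaling by a factor in [0.7, 1.3], and a
random temporal crop of W consecutive samples.  Only the crop applies at
evaluation time; its width equals the network's receptive field so the
cropped window is exactly the minimal valid input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import ModelSpec, receptive_field


def default_crop_width(spec: ModelSpec | None = None) -> int:
    """Crop width = receptive field of the network (344 for the default spec)."""
    return receptive_field(spec if spec is not None else ModelSpec())


@dataclass
class AugmentConfig:
    noise_sigma_range: tuple[float, float] = (0.01, 0.1)
    time_scale_range: tuple[float, float] = (0.8, 1.2)
    amplitude_range: tuple[float, float] = (0.7, 1.3)
    crop_width: int | None = None     # None -> network receptive field
    apply_noise: bool = True
    apply_time_scale: bool = True
    apply_amplitude: bool = True
    per_lead_sigma: bool = False      # one sigma per record by default

    def __post_init__(self) -> None:
        for rng_ in (self.noise_sigma_range, self.time_scale_range, self.amplitude_range):
            if rng_[0] > rng_[1]:
                raise ValueError(f"range {rng_} is not ordered")
        if self.crop_width is not None and self.crop_width < 1:
            raise ValueError("crop_width must be >= 1")

    def resolved_crop_width(self, spec: ModelSpec | None = None) -> int:
        return self.crop_width if self.crop_width is not None else default_crop_width(spec)

    @classmethod
    def evaluation(cls, crop_width: int | None = None) -> "AugmentConfig":
        """Evaluation mode: cropping only."""
        return cls(
            apply_noise=False,
            apply_time_scale=False,
            apply_amplitude=False,
            crop_width=crop_width,
        )


def add_gaussian_noise(
    signal: np.ndarray,
    rng: np.random.Generator,
    sigma_range: tuple[float, float] = (0.01, 0.1),
    per_lead: bool = False,
) -> np.ndarray:
    """Add zero-mean Gaussian noise; sigma ~ U[sigma_range] per record.

    With ``per_lead=True`` an independent sigma is drawn for every lead
    instead of one per record.
    """
    signal = np.asarray(signal, dtype=np.float64)
    if per_lead:
        sigma = rng.uniform(*sigma_range, size=(signal.shape[0], 1))
    else:
        sigma = rng.uniform(*sigma_range)
    return signal + rng.standard_normal(signal.shape) * sigma


def time_scale(signal: np.ndarray, factor: float) -> np.ndarray:
    """Stretch/compress all leads by one factor via linear interpolation.

    Output length is round(T * factor); endpoints map to endpoints, so
    affine signals stay affine and factor 1 is the exact identity.
    """
    if factor <= 0:
        raise ValueError("time-scale factor must be positive")
    signal = np.atleast_2d(np.asarray(signal, dtype=np.float64))
    t_in = signal.shape[1]
    t_out = int(round(t_in * factor))
    if t_out < 2 or t_in < 2:
        raise ValueError("signal too short to rescale")
    if t_out == t_in:
        return signal.copy()
    grid = np.linspace(0.0, t_in - 1.0, t_out)
    base = np.arange(t_in, dtype=np.float64)
    return np.stack([np.interp(grid, base, lead) for lead in signal])


def amplitude_scale(signal: np.ndarray, factor: float) -> np.ndarray:
    """Multiply every sample of every lead by one factor."""
    if factor <= 0:
        raise ValueError("amplitude factor must be positive")
    return np.asarray(signal, dtype=np.float64) * factor


def random_crop(
    signal: np.ndarray, width: int, rng: np.random.Generator
) -> np.ndarray:
    """Crop ``width`` consecutive samples, same window across leads."""
    signal = np.atleast_2d(np.asarray(signal))
    t = signal.shape[1]
    if t < width:
        raise ValueError(f"signal of length {t} shorter than crop width {width}")
    start = int(rng.integers(0, t - width + 1))
    return signal[:, start : start + width].copy()


def center_crop(signal: np.ndarray, width: int) -> np.ndarray:
    """Deterministic central window (evaluation-time alternative)."""
    signal = np.atleast_2d(np.asarray(signal))
    t = signal.shape[1]
    if t < width:
        raise ValueError(f"signal of length {t} shorter than crop width {width}")
    start = (t - width) // 2
    return signal[:, start : start + width].copy()


def augment_pipeline(
    signal: np.ndarray,
    config: AugmentConfig,
    rng: np.random.Generator,
    spec: ModelSpec | None = None,
) -> np.ndarray:
    """Apply the full transform chain to an (L, T) window.

    Training mode: noise -> time-scale -> amplitude -> random crop, with
    fresh draws from ``rng`` on every call.  Evaluation mode (all apply_*
    flags off): a seeded random crop only, no value changes.
    """
    out = np.atleast_2d(np.asarray(signal, dtype=np.float64))
    if config.apply_noise:
        out = add_gaussian_noise(
            out, rng, config.noise_sigma_range, per_lead=config.per_lead_sigma
        )
    if config.apply_time_scale:
        out = time_scale(out, float(rng.uniform(*config.time_scale_range)))
    if config.apply_amplitude:
        out = amplitude_scale(out, float(rng.uniform(*config.amplitude_range)))
    return random_crop(out, config.resolved_crop_width(spec), rng)
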