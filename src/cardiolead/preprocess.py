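"""Signal preprocessing: decimation, per-lead normalization, lead algebra.

Normalization follows the split-level convention: each of the 12 leads is
z-scored with the mean and standard deviation pooled over every sample of
the training split, so validation/test records are transformed with
training statistics only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import resample_poly

from .leads import LeadSetup, get_setup
from .ptbxl import ECGRecord

#: Guard against zero-variance leads in degenerate (e.g. constant) inputs.
STD_EPS = 1e-8


def downsample(signal: np.ndarray, fs_in: float, fs_out: float = 100.0) -> np.ndarray:
    """Anti-aliased decimation from ``fs_in`` to ``fs_out`` (integer ratio).

    A 10 s, 500 Hz record (12 x 5000) becomes 12 x 1000 at 100 Hz.
    Polyphase FIR filtering with edge padding by the signal mean, so DC
    (constant) signals pass through unchanged.
    """
    signal = np.asarray(signal, dtype=np.float64)
    ratio = fs_in / fs_out
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(f"fs_in/fs_out must be an integer, got {ratio}")
    q = int(round(ratio))
    if q == 1:
        return signal.copy()
    return resample_poly(signal, 1, q, axis=-1, padtype="mean")


@dataclass
class NormalizationStats:
    """Per-lead mean/std (mV) fitted on a training split."""

    mean: np.ndarray
    std: np.ndarray
    source: str = "train"

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.std = np.asarray(self.std, dtype=np.float64)
        if self.mean.shape != self.std.shape:
            raise ValueError("mean and std must have matching shapes")
        if np.any(self.std < 0):
            raise ValueError("standard deviations must be non-negative")


def fit_normalization(
    train_records: list[ECGRecord], source: str = "train"
) -> NormalizationStats:
    """Pool all samples of all training records, per lead."""
    if not train_records:
        raise ValueError("cannot fit normalization on an empty training split")
    pooled = np.concatenate([r.signal for r in train_records], axis=1)
    return NormalizationStats(
        mean=pooled.mean(axis=1), std=pooled.std(axis=1), source=source
    )


def normalize_signal(signal: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    denom = np.maximum(stats.std, STD_EPS)
    return (signal - stats.mean[:, None]) / denom[:, None]


def denormalize_signal(signal: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    denom = np.maximum(stats.std, STD_EPS)
    return signal * denom[:, None] + stats.mean[:, None]


def normalize(record: ECGRecord, stats: NormalizationStats) -> ECGRecord:
    """Return a copy of ``record`` with each lead z-scored by ``stats``."""
    return ECGRecord(
        record_id=record.record_id,
        signal=normalize_signal(record.signal, stats),
        fs=record.fs,
        labels=record.labels.copy(),
        fold=record.fold,
        lead_names=record.lead_names,
    )


def derive_dependent_leads(
    d1: np.ndarray, d2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Einthoven/Goldberger identities: (D3, aVR, aVL, aVF) from (D1, D2).

    D3 = D2 - D1;  aVR = -(D1 + D2)/2;  aVL = D1 - D2/2;  aVF = D2 - D1/2.
    """
    d1 = np.asarray(d1, dtype=np.float64)
    d2 = np.asarray(d2, dtype=np.float64)
    if d1.shape != d2.shape:
        raise ValueError("D1 and D2 must have the same length")
    d3 = d2 - d1
    avr = -(d1 + d2) / 2.0
    avl = d1 - d2 / 2.0
    avf = d2 - d1 / 2.0
    return d3, avr, avl, avf


def select_setup(record_or_signal, setup: str | LeadSetup) -> np.ndarray:
    """Extract the rows of a 12-lead array for a named lead setup.

    Accepts an :class:`ECGRecord` or a bare (12, T) array in canonical
    order; returns an (L, T) array with rows in setup order.  Time samples
    are never altered or reordered.
    """
    setup = get_setup(setup)
    signal = (
        record_or_signal.signal
        if isinstance(record_or_signal, ECGRecord)
        else np.asarray(record_or_signal)
    )
    if signal.ndim != 2 or signal.shape[0] != 12:
        raise ValueError("expected a (12, T) canonical-order signal array")
    return signal[list(setup.indices)]
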