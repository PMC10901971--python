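"""Minimal WFDB record I/O (header + format-16 signal files).

Supports the subset of the WFDB specification that PTB-XL uses: a
``.hea`` text header describing one multiplexed ``.dat`` file holding
16-bit two's-complement little-endian samples, interleaved across
signals, with per-signal gain (ADC units per mV) and baseline.

physical [mV] = (digital - baseline) / gain
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

_INT16_MIN, _INT16_MAX = -32768, 32767


@dataclass
class WFDBHeader:
    record_name: str
    n_signals: int
    fs: float
    n_samples: int
    dat_file: str
    fmt: int
    gains: np.ndarray        # ADC units per mV, per signal
    baselines: np.ndarray    # digital zero level, per signal
    signal_names: list[str]


def _parse_gain_field(field: str) -> tuple[float, int]:
    """Parse a WFDB gain spec like ``1000``, ``1000(0)`` or ``1000.0(0)/mV``."""
    m = re.match(r"^(-?[\d.]+)(?:\((-?\d+)\))?(?:/(\S+))?$", field)
    if m is None:
        raise ValueError(f"unparseable WFDB gain field: {field!r}")
    gain = float(m.group(1))
    baseline = int(m.group(2)) if m.group(2) is not None else 0
    return (gain if gain != 0 else 200.0), baseline


def read_header(hea_path: str | Path) -> WFDBHeader:
    hea_path = Path(hea_path)
    if not hea_path.exists():
        raise FileNotFoundError(f"WFDB header not found: {hea_path}")
    lines = [
        ln.strip()
        for ln in hea_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    rec_fields = lines[0].split()
    record_name = rec_fields[0].split("/")[0]
    n_signals = int(rec_fields[1])
    fs = float(rec_fields[2].split("/")[0]) if len(rec_fields) > 2 else 250.0
    n_samples = int(rec_fields[3]) if len(rec_fields) > 3 else 0

    dat_file = None
    fmt = None
    gains, baselines, names = [], [], []
    for i, ln in enumerate(lines[1 : 1 + n_signals]):
        f = ln.split()
        if dat_file is None:
            dat_file = f[0]
        elif f[0] != dat_file:
            raise NotImplementedError("multi-.dat WFDB records are not supported")
        this_fmt = int(f[1].split("x")[0].split(":")[0].split("+")[0])
        if fmt is None:
            fmt = this_fmt
        gain, baseline = _parse_gain_field(f[2]) if len(f) > 2 else (200.0, 0)
        gains.append(gain)
        baselines.append(baseline)
        names.append(f[8] if len(f) > 8 else f"sig{i}")
    if fmt != 16:
        raise NotImplementedError(f"only WFDB format 16 is supported, got {fmt}")
    return WFDBHeader(
        record_name=record_name,
        n_signals=n_signals,
        fs=fs,
        n_samples=n_samples,
        dat_file=dat_file,
        fmt=fmt,
        gains=np.asarray(gains, dtype=float),
        baselines=np.asarray(baselines, dtype=float),
        signal_names=names,
    )


def read_record(record_path: str | Path) -> tuple[np.ndarray, WFDBHeader]:
    """Read a WFDB record; return (signals, header).

    ``record_path`` is the path without extension.  Signals are returned
    as a (n_signals, n_samples) float array in millivolts.
    """
    record_path = Path(record_path)
    header = read_header(record_path.with_suffix(".hea"))
    dat_path = record_path.parent / header.dat_file
    if not dat_path.exists():
        raise FileNotFoundError(f"WFDB signal file not found: {dat_path}")
    raw = np.fromfile(dat_path, dtype="<i2")
    n = raw.size // header.n_signals
    if header.n_samples and n < header.n_samples:
        raise ValueError(
            f"truncated WFDB signal file {dat_path}: "
            f"expected {header.n_samples} frames, found {n}"
        )
    n = header.n_samples or n
    digital = raw[: n * header.n_signals].reshape(n, header.n_signals).T
    physical = (digital - header.baselines[:, None]) / header.gains[:, None]
    return physical.astype(np.float64), header


def write_record(
    record_path: str | Path,
    signal_mv: np.ndarray,
    fs: float,
    signal_names: list[str] | None = None,
    gain: float = 1000.0,
) -> None:
    """Write a (n_signals, n_samples) mV array as a format-16 WFDB record."""
    record_path = Path(record_path)
    signal_mv = np.asarray(signal_mv, dtype=float)
    if signal_mv.ndim != 2:
        raise ValueError("signal must be a 2-D (signals x samples) array")
    n_sig, n_samp = signal_mv.shape
    if signal_names is None:
        signal_names = [f"sig{i}" for i in range(n_sig)]
    digital = np.clip(np.rint(signal_mv * gain), _INT16_MIN, _INT16_MAX).astype("<i2")

    record_path.parent.mkdir(parents=True, exist_ok=True)
    dat_name = record_path.name + ".dat"
    digital.T.reshape(-1).tofile(record_path.with_suffix(".dat"))

    lines = [f"{record_path.name} {n_sig} {fs:g} {n_samp}"]
    for i in range(n_sig):
        first = int(digital[i, 0]) if n_samp else 0
        lines.append(
            f"{dat_name} 16 {gain:g}(0)/mV 16 0 {first} 0 0 {signal_names[i]}"
        )
    record_path.with_suffix(".hea").write_text("\n".join(lines) + "\n")
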