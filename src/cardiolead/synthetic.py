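"""Seeded synthetic 12-lead ECG generator (Gaussian-pulse dipole model).

Each record is built from a 3-D cardiac dipole trajectory: every beat is
a sum of Gaussian pulses (P, Q, R, S, T), each with an amplitude, a
width and a fixed 3-D direction, repeated periodically at the drawn
heart rate.  The 12 leads are dot products of the dipole with fixed lead
axes, so the Einthoven/Goldberger limb-lead identities hold exactly
before per-lead sensor noise is added.

Axes: x points leftward (the D1 direction), y inferior (aVF), z
anterior.  Pathology classes perturb beat parameters: conduction blocks
widen the QRS and rotate its axis, AV block lengthens PR, hypertrophy
scales the R amplitude, and infarction/ischemia classes add Q-wave and
T-wave deflections along the wall's axis.  Inferior-wall classes (IMI,
ISCI) deflect along y, which is orthogonal to the D1 axis — their
signature is invisible in D1 and strong in D2, which is what makes
single-lead versus two-lead ablations on synthetic data meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .leads import LEAD_NAMES
from .ptbxl import CLASS_NAMES, ECGRecord

# ---------------------------------------------------------------------------
# lead geometry
# ---------------------------------------------------------------------------


def _frontal(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    return np.array([math.cos(a), math.sin(a), 0.0])


def _horizontal(angle_deg: float) -> np.ndarray:
    """Precordial axis in the x-z (horizontal) plane; 0 deg = leftward."""
    a = math.radians(angle_deg)
    return np.array([math.cos(a), 0.0, math.sin(a)])


def _build_lead_axes() -> np.ndarray:
    d1 = _frontal(0.0)
    d2 = _frontal(60.0)
    axes = {
        "D1": d1,
        "D2": d2,
        # exact linear combinations => Einthoven/Goldberger identities
        "D3": d2 - d1,
        "aVR": -(d1 + d2) / 2.0,
        "aVL": d1 - d2 / 2.0,
        "aVF": d2 - d1 / 2.0,
        "V1": _horizontal(115.0),
        "V2": _horizontal(94.0),
        "V3": _horizontal(76.0),
        "V4": _horizontal(54.0),
        "V5": _horizontal(28.0),
        "V6": _horizontal(8.0),
    }
    return np.stack([axes[name] for name in LEAD_NAMES])


#: (12, 3) projection axes in canonical lead order.
LEAD_AXES: np.ndarray = _build_lead_axes()

_X = np.array([1.0, 0.0, 0.0])   # lateral (D1) axis
_Y = np.array([0.0, 1.0, 0.0])   # inferior axis
_Z = np.array([0.0, 0.0, 1.0])   # anterior axis


# ---------------------------------------------------------------------------
# beat model
# ---------------------------------------------------------------------------


@dataclass
class Wave:
    """One Gaussian pulse: amp * exp(-(t-c)^2 / 2 sd^2) along a 3-D direction."""

    amplitude: float          # mV along the direction
    sd: float                 # seconds
    offset: float             # seconds relative to the R peak
    direction: np.ndarray

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, dtype=np.float64)
        if self.sd <= 0:
            raise ValueError("wave width must be positive")


@dataclass
class BeatParams:
    """Morphology parameters of one beat; pathology modifiers act on these."""

    heart_rate: float = 70.0        # bpm
    pr_interval: float = 0.16       # seconds, P center to R peak
    qrs_duration: float = 0.09      # seconds
    r_amplitude: float = 1.2        # mV
    qrs_axis_deg: float = 50.0      # frontal-plane angle
    qrs_anterior: float = 0.35      # z component of the QRS direction
    t_amplitude: float = 0.35
    t_offset: float = 0.32          # seconds after the R peak
    p_amplitude: float = 0.12
    p_width: float = 0.025
    amplitude_gain: float = 1.0     # global gain (hypertrophy)
    extra_waves: list[Wave] = field(default_factory=list)

    def qrs_direction(self) -> np.ndarray:
        d = _frontal(self.qrs_axis_deg) + self.qrs_anterior * _Z
        return d / np.linalg.norm(d)

    def build_waves(self) -> list[Wave]:
        """Assemble the P-QRS-T pulse train for one beat."""
        if self.qrs_duration <= 0 or self.pr_interval <= 0:
            raise ValueError("durations must be positive")
        qrs_dir = self.qrs_direction()
        p_dir = _frontal(55.0) + 0.1 * _Z
        p_dir = p_dir / np.linalg.norm(p_dir)
        t_dir = _frontal(45.0) + 0.25 * _Z
        t_dir = t_dir / np.linalg.norm(t_dir)
        g = self.amplitude_gain
        waves = [
            Wave(g * self.p_amplitude, self.p_width, -self.pr_interval, p_dir),
            Wave(-g * 0.1, self.qrs_duration / 8, -0.35 * self.qrs_duration, qrs_dir),
            Wave(g * self.r_amplitude, self.qrs_duration / 6, 0.0, qrs_dir),
            Wave(-g * 0.25, self.qrs_duration / 8, 0.35 * self.qrs_duration, qrs_dir),
            Wave(g * self.t_amplitude, 0.06, self.t_offset, t_dir),
        ]
        waves.extend(self.extra_waves)
        p_off = -self.pr_interval
        if not (p_off < -0.35 * self.qrs_duration <= 0.0 < self.t_offset):
            raise ValueError("wave timings must be ordered P < QRS < T")
        return waves


# ---------------------------------------------------------------------------
# pathology morphologies
# ---------------------------------------------------------------------------
# Classes with a distinct, physiologically motivated signature: NORM, _AVB,
# CLBBB, CRBBB, IMI, AMI, LVH, LMI (plus ISCI/ISCA T-wave variants used by
# the lead-ablation tests).  The remaining classes alias to mild amplitude
# or interval perturbations — enough to exercise every pipeline branch.


def _mod_avb(p: BeatParams, rng) -> None:
    p.pr_interval = rng.uniform(0.24, 0.32)


def _mod_clbbb(p: BeatParams, rng) -> None:
    p.qrs_duration = rng.uniform(0.13, 0.16)
    p.qrs_axis_deg -= rng.uniform(50.0, 70.0)     # leftward rotation
    p.qrs_anterior = -0.2


def _mod_crbbb(p: BeatParams, rng) -> None:
    p.qrs_duration = rng.uniform(0.13, 0.16)
    p.qrs_axis_deg += rng.uniform(45.0, 65.0)     # rightward rotation
    p.qrs_anterior = 0.6


def _mod_imi(p: BeatParams, rng) -> None:
    # deep Q and inverted T along the inferior (+y) axis: silent in D1
    q = rng.uniform(0.5, 0.7)
    p.extra_waves.append(Wave(-q, p.qrs_duration / 8, -0.35 * p.qrs_duration, _Y))
    p.extra_waves.append(Wave(-rng.uniform(0.4, 0.6), 0.06, p.t_offset, _Y))


def _mod_ami(p: BeatParams, rng) -> None:
    # anterior R loss plus ST shift: dominant in V2-V4
    p.extra_waves.append(Wave(-rng.uniform(0.5, 0.7), p.qrs_duration / 6, 0.0, _Z))
    p.extra_waves.append(Wave(rng.uniform(0.15, 0.25), 0.05, 0.18, _Z))


def _mod_lvh(p: BeatParams, rng) -> None:
    p.amplitude_gain *= rng.uniform(1.5, 2.5)


def _mod_lmi(p: BeatParams, rng) -> None:
    # lateral-axis Q and T changes: visible in D1/V5/V6
    p.extra_waves.append(Wave(-rng.uniform(0.5, 0.7), p.qrs_duration / 8,
                              -0.35 * p.qrs_duration, _X))
    p.extra_waves.append(Wave(-rng.uniform(0.3, 0.5), 0.06, p.t_offset, _X))


def _mod_isci(p: BeatParams, rng) -> None:
    p.extra_waves.append(Wave(-rng.uniform(0.4, 0.6), 0.06, p.t_offset, _Y))


def _mod_isca(p: BeatParams, rng) -> None:
    p.extra_waves.append(Wave(-rng.uniform(0.4, 0.6), 0.06, p.t_offset, _Z))


def _mod_generic_st(p: BeatParams, rng) -> None:
    p.extra_waves.append(
        Wave(rng.uniform(-0.25, -0.1), 0.05, 0.18, p.qrs_direction())
    )


def _mod_t_flatten(p: BeatParams, rng) -> None:
    p.t_amplitude *= rng.uniform(0.2, 0.5)


def _mod_mild_widening(p: BeatParams, rng) -> None:
    p.qrs_duration = rng.uniform(0.10, 0.12)


def _mod_lafb(p: BeatParams, rng) -> None:
    p.qrs_axis_deg -= rng.uniform(70.0, 90.0)


def _mod_wpw(p: BeatParams, rng) -> None:
    p.pr_interval = rng.uniform(0.08, 0.11)
    p.qrs_duration = rng.uniform(0.11, 0.13)


def _mod_lae(p: BeatParams, rng) -> None:
    p.p_width *= rng.uniform(1.6, 2.0)
    p.p_amplitude *= rng.uniform(1.2, 1.5)


def _mod_rae(p: BeatParams, rng) -> None:
    amp = p.p_amplitude * rng.uniform(1.0, 1.5)
    p.extra_waves.append(Wave(amp, p.p_width, -p.pr_interval, _Y))


PATHOLOGY_MODIFIERS: dict[str, callable] = {
    "_AVB": _mod_avb,
    "CLBBB": _mod_clbbb,
    "CRBBB": _mod_crbbb,
    "IMI": _mod_imi,
    "AMI": _mod_ami,
    "LVH": _mod_lvh,
    "LMI": _mod_lmi,
    "ISCI": _mod_isci,
    "ISCA": _mod_isca,
    "ISC_": _mod_generic_st,
    "NST_": _mod_t_flatten,
    "STTC": _mod_generic_st,
    "ILBBB": _mod_mild_widening,
    "IRBBB": _mod_mild_widening,
    "IVCD": _mod_mild_widening,
    "LAFB/LPFB": _mod_lafb,
    "WPW": _mod_wpw,
    "LAO/LAE": _mod_lae,
    "RAO/RAE": _mod_rae,
}


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def default_class_priors() -> dict[str, float]:
    """Marginal class priors for generated datasets.

    NORM is mutually exclusive with the pathological classes (mirroring
    the conflicting-label exclusion rule); pathological priors cover the
    morphologically distinct classes.
    """
    return {
        "NORM": 0.40,
        "CLBBB": 0.10,
        "CRBBB": 0.08,
        "_AVB": 0.10,
        "IMI": 0.12,
        "AMI": 0.10,
        "LVH": 0.12,
        "LMI": 0.08,
    }


@dataclass
class SynthConfig:
    n_records: int = 100
    class_priors: dict[str, float] = field(default_factory=default_class_priors)
    hr_range: tuple[float, float] = (50.0, 90.0)
    noise_sd: float = 0.01          # per-lead sensor noise, mV
    seed: int = 0
    fs: float = 500.0
    duration: float = 10.0          # seconds

    def __post_init__(self) -> None:
        for cls, p in self.class_priors.items():
            if cls not in CLASS_NAMES:
                raise ValueError(f"unknown class in priors: {cls!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prior for {cls} outside [0, 1]")


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def dipole_trajectory(
    waves: list[Wave],
    heart_rate: float,
    t: np.ndarray,
    phase: float = 0.0,
) -> np.ndarray:
    """Sum the periodic Gaussian pulse train -> (3, len(t)) source series.

    ``phase`` shifts the first R peak (seconds).  Raises when the beat's
    wave support exceeds the beat interval (rate too high for the widths).
    """
    rr = 60.0 / heart_rate
    if waves:
        # wave centers of one beat must fit within one beat interval
        # (tails of adjacent beats may legitimately overlap)
        lo = min(w.offset for w in waves)
        hi = max(w.offset for w in waves)
        if hi - lo >= rr:
            raise ValueError(
                f"beat wave centers span {hi - lo:.3f}s but the beat interval "
                f"is only {rr:.3f}s (heart rate {heart_rate:g} bpm too high)"
            )
    source = np.zeros((3, t.size))
    if not waves:
        return source
    n_beats = int(np.ceil((t[-1] - t[0]) / rr)) + 2
    beat_times = phase + rr * np.arange(-1, n_beats)
    for w in waves:
        centers = beat_times + w.offset
        # (n_beats, T) Gaussian bumps summed over beats
        bumps = np.exp(-0.5 * ((t[None, :] - centers[:, None]) / w.sd) ** 2)
        scalar = w.amplitude * bumps.sum(axis=0)
        source += w.direction[:, None] * scalar[None, :]
    return source


def project_to_leads(source: np.ndarray, axes: np.ndarray = LEAD_AXES) -> np.ndarray:
    """Project the (3, T) dipole onto the lead axes -> (12, T) mV array."""
    source = np.asarray(source, dtype=np.float64)
    if source.ndim != 2 or source.shape[0] != 3:
        raise ValueError("source must be a (3, T) array")
    return axes @ source


def _draw_beat_params(labels: np.ndarray, config: SynthConfig,
                      rng: np.random.Generator) -> BeatParams:
    params = BeatParams(
        heart_rate=rng.uniform(*config.hr_range),
        pr_interval=rng.uniform(0.12, 0.20),
        qrs_duration=rng.uniform(0.08, 0.10),
        r_amplitude=rng.uniform(1.0, 1.4),
        qrs_axis_deg=rng.uniform(40.0, 60.0),
    )
    for idx in np.flatnonzero(labels):
        cls = CLASS_NAMES[idx]
        modifier = PATHOLOGY_MODIFIERS.get(cls)
        if modifier is not None:
            modifier(params, rng)
    return params


def synth_record(
    labels: np.ndarray,
    config: SynthConfig,
    rng: np.random.Generator,
    record_id: int = 1,
    noise_free: bool = False,
) -> tuple[ECGRecord, BeatParams]:
    """Generate one 12-lead record with the given binary label vector.

    Returns the record and the beat parameters it was built from (so
    tests can assert morphology by construction).  With
    ``noise_free=True`` the limb-lead identities hold to machine
    precision.
    """
    labels = np.asarray(labels, dtype=np.int8)
    if labels.shape != (len(CLASS_NAMES),):
        raise ValueError("labels must be a binary vector of length 20")
    norm_idx = CLASS_NAMES.index("NORM")
    if labels[norm_idx] and labels.sum() > 1:
        raise ValueError("NORM is mutually exclusive with pathological classes")
    if labels.sum() == 0:
        raise ValueError("a record must carry at least one class")

    # phase/fold are drawn before the class modifiers so that records
    # sharing a seed differ only by their pathology deltas
    u_phase = rng.random()
    fold = int(rng.integers(1, 11))
    params = _draw_beat_params(labels, config, rng)
    t = np.arange(int(round(config.duration * config.fs))) / config.fs
    phase = u_phase * 60.0 / params.heart_rate
    source = dipole_trajectory(params.build_waves(), params.heart_rate, t, phase)
    signal = project_to_leads(source)
    if not noise_free and config.noise_sd > 0:
        signal = signal + rng.normal(0.0, config.noise_sd, size=signal.shape)
    signal = np.clip(signal, -10.0, 10.0)

    record = ECGRecord(
        record_id=record_id,
        signal=signal,
        fs=config.fs,
        labels=labels,
        fold=fold,
    )
    return record, params


def _draw_labels(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    labels = np.zeros(len(CLASS_NAMES), dtype=np.int8)
    priors = config.class_priors
    p_norm = priors.get("NORM", 0.0)
    if p_norm > 0 and rng.random() < p_norm:
        labels[CLASS_NAMES.index("NORM")] = 1
        return labels
    patho = {c: p for c, p in priors.items() if c != "NORM" and p > 0}
    if not patho:
        labels[CLASS_NAMES.index("NORM")] = 1
        return labels
    denom = 1.0 - p_norm
    # redraw until at least one pathological class fires; NORM's marginal
    # frequency stays exactly at its prior
    while True:
        drew = False
        labels[:] = 0
        for cls, p in patho.items():
            if rng.random() < min(p / denom, 1.0):
                labels[CLASS_NAMES.index(cls)] = 1
                drew = True
        if drew:
            return labels


def generate_dataset(
    config: SynthConfig, noise_free: bool = False
) -> tuple[list[ECGRecord], pd.DataFrame]:
    """Generate ``n_records`` seeded records plus a PTB-XL-style manifest.

    The manifest mirrors ``ptbxl_database.csv`` (ecg_id, scp_codes with
    likelihood 100, strat_fold, filenames) so an exported dataset can be
    read back through the PTB-XL loader.
    """
    rng = np.random.default_rng(config.seed)
    records: list[ECGRecord] = []
    rows = []
    for i in range(config.n_records):
        rid = i + 1
        labels = _draw_labels(config, rng)
        record, _ = synth_record(labels, config, rng, record_id=rid,
                                 noise_free=noise_free)
        records.append(record)
        scp = {CLASS_NAMES[j]: 100.0 for j in np.flatnonzero(labels)}
        rows.append(
            {
                "ecg_id": rid,
                "scp_codes": str(scp),
                "strat_fold": record.fold,
                "filename_lr": f"records100/{rid:05d}_lr",
                "filename_hr": f"records500/{rid:05d}_hr",
            }
        )
    manifest = pd.DataFrame(
        rows, columns=["ecg_id", "scp_codes", "strat_fold",
                       "filename_lr", "filename_hr"]
    )
    return records, manifest


def export_wfdb_dataset(
    records: list[ECGRecord],
    manifest: pd.DataFrame,
    out_dir: str | Path,
) -> Path:
    """Write records + manifest in the PTB-XL directory layout.

    Produces ``ptbxl_database.csv``, an identity ``scp_statements.csv``
    and WFDB record pairs under ``records500/`` (and ``records100/``
    with decimated signals), so the PTB-XL reader round-trips.
    """
    from .preprocess import downsample
    from .wfdbio import write_record

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest.to_csv(out_dir / "ptbxl_database.csv", index=False)
    scp = pd.DataFrame(
        {
            "code": list(CLASS_NAMES),
            "diagnostic": 1,
            "diagnostic_class": "",
            "diagnostic_subclass": list(CLASS_NAMES),
        }
    ).set_index("code")
    scp.to_csv(out_dir / "scp_statements.csv")

    by_id = {r.record_id: r for r in records}
    for row in manifest.itertuples(index=False):
        rec = by_id[int(row.ecg_id)]
        write_record(
            out_dir / row.filename_hr, rec.signal, rec.fs, list(LEAD_NAMES)
        )
        low = downsample(rec.signal, rec.fs, 100.0)
        write_record(out_dir / row.filename_lr, low, 100.0, list(LEAD_NAMES))
    return out_dir
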