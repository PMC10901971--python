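"""PTB-XL dataset access: metadata, label aggregation, filters, splits.

PTB-XL annotates each 10 s, 12-lead ECG with SCP statement codes, each
carrying a likelihood in [0, 100].  Diagnostic statements aggregate into
20 diagnostic subclasses; a record's multi-label target marks every
subclass reached by a statement with positive likelihood.  Records are
excluded when they (i) carry NORM together with a pathological class,
(ii) end up with no diagnostic class at all, or (iii) carry a diagnostic
statement (within the 20 classes) whose likelihood is exactly 0.  The
recommended 10-fold split maps folds 1-8 to training, fold 9 to
validation and fold 10 to test.
"""

from __future__ import annotations

import ast
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .leads import LEAD_NAMES, canonical_lead
from .wfdbio import read_record

logger = logging.getLogger(__name__)

#: The 20 diagnostic subclasses, in report order.
CLASS_NAMES: tuple[str, ...] = (
    "NORM", "ISC_", "ISCA", "ISCI", "NST_", "STTC", "_AVB", "CLBBB",
    "CRBBB", "ILBBB", "IRBBB", "IVCD", "LAFB/LPFB", "WPW", "LAO/LAE",
    "LVH", "RAO/RAE", "AMI", "IMI", "LMI",
)
N_CLASSES = len(CLASS_NAMES)


@dataclass
class RawRecordMeta:
    """One row of ``ptbxl_database.csv``."""

    record_id: int
    scp_codes: dict[str, float]          # statement code -> likelihood in [0, 100]
    strat_fold: int
    signal_path_100: str
    signal_path_500: str

    def __post_init__(self) -> None:
        if not 1 <= self.strat_fold <= 10:
            raise ValueError(
                f"record {self.record_id}: strat_fold must be in 1..10, "
                f"got {self.strat_fold}"
            )


@dataclass
class LabelMap:
    """Mapping from raw SCP statement codes to the 20 diagnostic subclasses."""

    class_names: tuple[str, ...] = CLASS_NAMES
    code_to_class: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.class_names)) != len(self.class_names):
            raise ValueError("duplicate class names in LabelMap")
        bad = {c for c in self.code_to_class.values() if c not in self.class_names}
        if bad:
            raise ValueError(f"code_to_class targets outside the class list: {bad}")

    def class_index(self, class_name: str) -> int:
        return self.class_names.index(class_name)

    @classmethod
    def identity(cls) -> "LabelMap":
        """Each subclass code maps to itself (used for synthetic manifests)."""
        return cls(code_to_class={c: c for c in CLASS_NAMES})

    @classmethod
    def from_scp_statements(cls, path: str | Path) -> "LabelMap":
        """Build the map from ``scp_statements.csv``.

        Only diagnostic statements whose ``diagnostic_subclass`` is one of
        the 20 supported subclasses are mapped; everything else (rhythm and
        form statements, subclasses such as PMI/RVH/SEHYP) is left unmapped
        and therefore ignored during aggregation.
        """
        df = pd.read_csv(path, index_col=0)
        if "diagnostic_subclass" not in df.columns:
            raise ValueError(f"{path}: missing diagnostic_subclass column")
        mapping = {}
        for code, row in df.iterrows():
            sub = row["diagnostic_subclass"]
            if isinstance(sub, str) and sub in CLASS_NAMES:
                mapping[str(code)] = sub
        return cls(code_to_class=mapping)


@dataclass
class ECGRecord:
    """One subject recording with its multi-label diagnostic target."""

    record_id: int
    signal: np.ndarray                     # (12, T) in mV, canonical lead order
    fs: float
    labels: np.ndarray                     # binary vector, length 20
    fold: int
    lead_names: tuple[str, ...] = LEAD_NAMES

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.signal.ndim != 2 or self.signal.shape[0] != len(self.lead_names):
            raise ValueError(
                f"record {self.record_id}: signal must have one row per lead"
            )
        if self.labels.shape != (N_CLASSES,):
            raise ValueError(f"record {self.record_id}: labels must have length 20")


@dataclass
class FilterAudit:
    """How many records each exclusion rule removed."""

    n_conflicting: int = 0       # NORM together with a non-NORM class
    n_unlabeled: int = 0         # no diagnostic class at all
    n_zero_likelihood: int = 0   # a mapped statement with likelihood exactly 0

    @property
    def n_removed(self) -> int:
        return self.n_conflicting + self.n_unlabeled + self.n_zero_likelihood


@dataclass
class DatasetSplit:
    """Fold-based partition: folds 1-8 train, fold 9 validation, fold 10 test."""

    train: list
    validation: list
    test: list

    def __iter__(self):
        yield from (self.train, self.validation, self.test)


def _parse_scp_cell(cell, record_id) -> dict[str, float]:
    if isinstance(cell, dict):
        return {str(k): float(v) for k, v in cell.items()}
    try:
        parsed = ast.literal_eval(cell)
        return {str(k): float(v) for k, v in parsed.items()}
    except (ValueError, SyntaxError, AttributeError) as exc:
        raise ValueError(
            f"record {record_id}: malformed scp_codes cell {cell!r}"
        ) from exc


def load_metadata(dataset_root: str | Path) -> list[RawRecordMeta]:
    """Read ``ptbxl_database.csv`` under ``dataset_root``, order preserved."""
    csv_path = Path(dataset_root) / "ptbxl_database.csv"
    if not csv_path.exists():
        raise FileNotFoundError(f"metadata file not found: {csv_path}")
    df = pd.read_csv(csv_path)
    metas = []
    for row in df.itertuples(index=False):
        rid = int(row.ecg_id)
        metas.append(
            RawRecordMeta(
                record_id=rid,
                scp_codes=_parse_scp_cell(row.scp_codes, rid),
                strat_fold=int(row.strat_fold),
                signal_path_100=str(row.filename_lr),
                signal_path_500=str(row.filename_hr),
            )
        )
    return metas


def aggregate_labels(
    meta: RawRecordMeta, label_map: LabelMap
) -> tuple[np.ndarray, bool]:
    """Aggregate SCP statements into the 20-class binary target.

    Returns ``(labels, had_zero_likelihood)``.  A class is positive when
    some statement maps to it with likelihood > 0; the flag is raised when
    a statement mapping into the 20 classes carries likelihood exactly 0.
    Unmapped codes are ignored.
    """
    labels = np.zeros(len(label_map.class_names), dtype=np.int8)
    had_zero = False
    for code, likelihood in meta.scp_codes.items():
        target = label_map.code_to_class.get(code)
        if target is None:
            logger.debug("record %s: ignoring unmapped code %s", meta.record_id, code)
            continue
        if likelihood > 0:
            labels[label_map.class_index(target)] = 1
        else:
            had_zero = True
    return labels, had_zero


def filter_records(
    items: list[tuple],
    label_map: LabelMap | None = None,
) -> tuple[list[tuple], FilterAudit]:
    """Apply the three record-exclusion rules.

    ``items`` is a list of ``(meta, labels, had_zero_likelihood)`` triples
    as produced by :func:`aggregate_labels`.  Returns the surviving triples
    (order preserved) and a per-rule audit.  Rules are tested in order
    (conflicting, unlabeled, zero-likelihood); a record is charged to the
    first rule it violates so the audit counts sum to the number removed.
    """
    label_map = label_map or LabelMap.identity()
    norm_idx = label_map.class_index("NORM")
    survivors: list[tuple] = []
    audit = FilterAudit()
    for item in items:
        _, labels, had_zero = item
        labels = np.asarray(labels)
        if labels[norm_idx] and labels.sum() > 1:
            audit.n_conflicting += 1
        elif labels.sum() == 0:
            audit.n_unlabeled += 1
        elif had_zero:
            audit.n_zero_likelihood += 1
        else:
            survivors.append(item)
    return survivors, audit


def assign_splits(records: list) -> DatasetSplit:
    """Split by fold: 1-8 train, 9 validation, 10 test.

    Accepts any objects exposing ``fold`` or ``strat_fold`` (ECGRecord,
    RawRecordMeta) or ``(meta, ...)`` tuples.
    """

    def fold_of(obj) -> int:
        if isinstance(obj, tuple):
            obj = obj[0]
        fold = getattr(obj, "fold", None)
        if fold is None:
            fold = getattr(obj, "strat_fold", None)
        if fold is None:
            raise ValueError(f"object {obj!r} carries no fold attribute")
        return int(fold)

    split = DatasetSplit(train=[], validation=[], test=[])
    for rec in records:
        fold = fold_of(rec)
        if not 1 <= fold <= 10:
            raise ValueError(f"fold {fold} outside 1..10")
        if fold <= 8:
            split.train.append(rec)
        elif fold == 9:
            split.validation.append(rec)
        else:
            split.test.append(rec)
    return split


def read_signal(
    meta: RawRecordMeta, dataset_root: str | Path, fs_choice: int = 100
) -> np.ndarray:
    """Read one record's WFDB signals as a (12, T) mV array, canonical order.

    ``fs_choice`` selects the pre-decimated 100 Hz files or the original
    500 Hz files, matching the released PTB-XL layout.
    """
    if fs_choice not in (100, 500):
        raise ValueError("fs_choice must be 100 or 500")
    rel = meta.signal_path_100 if fs_choice == 100 else meta.signal_path_500
    record_path = Path(dataset_root) / rel
    signal, header = read_record(record_path)
    order = [canonical_lead(n) for n in header.signal_names]
    if sorted(order) != sorted(LEAD_NAMES):
        raise ValueError(f"{record_path}: does not contain the 12 standard leads")
    perm = [order.index(name) for name in LEAD_NAMES]
    return signal[perm]


def load_dataset(
    dataset_root: str | Path,
    fs: int = 100,
    label_map: LabelMap | None = None,
) -> tuple[list[ECGRecord], FilterAudit]:
    """Load, label, filter and materialize a PTB-XL-layout dataset."""
    dataset_root = Path(dataset_root)
    if label_map is None:
        scp_path = dataset_root / "scp_statements.csv"
        label_map = (
            LabelMap.from_scp_statements(scp_path)
            if scp_path.exists()
            else LabelMap.identity()
        )
    metas = load_metadata(dataset_root)
    items = []
    for meta in metas:
        labels, had_zero = aggregate_labels(meta, label_map)
        items.append((meta, labels, had_zero))
    survivors, audit = filter_records(items, label_map)
    records = [
        ECGRecord(
            record_id=meta.record_id,
            signal=read_signal(meta, dataset_root, fs_choice=fs),
            fs=fs,
            labels=labels,
            fold=meta.strat_fold,
        )
        for meta, labels, _ in survivors
    ]
    return records, audit
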