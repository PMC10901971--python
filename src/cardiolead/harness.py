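"""Multi-run, multi-setup experiment orchestration.

An :class:`ExperimentPlan` names the lead setups to compare (including
the augmentation-free 12-lead arm), the number of seeded runs per setup
and the data source; :func:`run_experiment` trains every arm, aggregates
per-run AUCs into reports with confidence intervals, and writes a
comparison table against the reference setup.  Every number in the
emitted tables is recomputable from the stored per-run score CSVs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .augment import AugmentConfig
from .evaluation import (
    ComparisonTable,
    EvalReport,
    build_comparison,
    evaluate_runs,
)
from .leads import LeadSetup, get_setup
from .model import ECGClassifier
from .ptbxl import CLASS_NAMES
from .synthetic import SynthConfig, generate_dataset
from .training import TrainConfig

logger = logging.getLogger(__name__)

#: All arms of the full comparison (Table-1 layout).
DEFAULT_ARMS: tuple[str, ...] = (
    "12lead", "8lead", "D1", "D1+D2", "D1+V1", "D1+V2", "D1+V3",
    "D1+V4", "D1+V5", "D1+V6", "12lead-no-augment",
)


def resolve_arm(name: str) -> tuple[LeadSetup, AugmentConfig]:
    """Map an arm name to (lead setup, augmentation config).

    The "-no-augment" suffix disables the stochastic transforms but keeps
    the temporal crop, which the architecture requires.
    """
    if name.endswith("-no-augment"):
        setup = get_setup(name[: -len("-no-augment")])
        aug = AugmentConfig(
            apply_noise=False, apply_time_scale=False, apply_amplitude=False
        )
    else:
        setup = get_setup(name)
        aug = AugmentConfig()
    return setup, aug


@dataclass
class ExperimentPlan:
    """A lead-ablation experiment: arms x runs over one data source."""

    arms: tuple[str, ...] = ("12lead", "D1", "D1+D2")
    n_runs: int = 3
    base_seed: int = 0
    epochs: int = 20
    batch_size: int = 32
    reference: str = "12lead"
    synth: SynthConfig | None = None      # used when data_dir is None
    data_dir: str | Path | None = None    # PTB-XL-layout directory
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if not self.arms:
            raise ValueError("the experiment needs at least one arm")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


def _load_records(plan: ExperimentPlan):
    if plan.data_dir is not None:
        from .ptbxl import load_dataset

        records, audit = load_dataset(plan.data_dir)
        logger.info(
            "loaded %d records (removed: %d conflicting, %d unlabeled, "
            "%d zero-likelihood)",
            len(records), audit.n_conflicting, audit.n_unlabeled,
            audit.n_zero_likelihood,
        )
        return records
    cfg = plan.synth or SynthConfig(n_records=300, seed=plan.base_seed)
    records, _ = generate_dataset(cfg)
    return records


def run_experiment(
    plan: ExperimentPlan, records=None
) -> tuple[dict[str, EvalReport], ComparisonTable | None]:
    """Execute the plan; returns (reports by arm, comparison vs reference).

    Run r of every arm uses seed ``base_seed + r`` so arms differ only in
    their input leads.  Failed runs are logged and excluded; an arm with
    zero successful runs aborts the experiment.
    """
    if records is None:
        records = _load_records(plan)
    out_dir = Path(plan.out_dir) if plan.out_dir else None

    reports: dict[str, EvalReport] = {}
    for arm in plan.arms:
        setup, aug = resolve_arm(arm)
        clf = ECGClassifier(
            records,
            setup=setup,
            augment_config=aug,
            train_config=TrainConfig(
                epochs=plan.epochs, batch_size=plan.batch_size
            ),
        )
        run_scores, labels = [], None
        for r in range(plan.n_runs):
            seed = plan.base_seed + r
            try:
                res = clf.fit(seed=seed)
            except RuntimeError as exc:
                logger.warning("arm %s run %d failed: %s", arm, r, exc)
                continue
            scores = np.asarray(res.test_scores, dtype=np.float64)
            run_scores.append(scores)
            labels = res.test_labels
            if out_dir is not None:
                arm_dir = out_dir / arm
                arm_dir.mkdir(parents=True, exist_ok=True)
                pd.DataFrame(scores, columns=list(CLASS_NAMES)).to_csv(
                    arm_dir / f"scores_run{seed}.csv", index=False
                )
        if not run_scores:
            raise RuntimeError(f"arm {arm!r}: no successful runs")
        report = evaluate_runs(run_scores, labels, setup_name=arm)
        reports[arm] = report
        if out_dir is not None:
            arm_dir = out_dir / arm
            pd.DataFrame(labels, columns=list(CLASS_NAMES)).to_csv(
                arm_dir / "labels.csv", index=False
            )
            report.to_frame().to_csv(arm_dir / "report.csv")

    comparison = None
    if plan.reference in reports:
        comparison = build_comparison(reports, reference=plan.reference)
        if out_dir is not None:
            comparison.to_frame().to_csv(out_dir / "comparison.csv")
    return reports, comparison


def evaluate_stored(arm_dir: str | Path) -> EvalReport:
    """Rebuild an arm's report from its stored per-run score CSVs.

    Reproduces the emitted ``report.csv`` bit-for-bit, making report
    directories self-describing.
    """
    arm_dir = Path(arm_dir)
    labels = pd.read_csv(arm_dir / "labels.csv").to_numpy()
    score_files = sorted(arm_dir.glob("scores_run*.csv"))
    if not score_files:
        raise FileNotFoundError(f"no stored score files under {arm_dir}")
    run_scores = [pd.read_csv(f).to_numpy() for f in score_files]
    return evaluate_runs(run_scores, labels, setup_name=arm_dir.name)


def rank_second_leads(reports: dict[str, EvalReport | float]) -> list[str]:
    """Order the D1+X arms by mean macro AUC, best first (ties by name)."""
    pairs = []
    for name, rep in reports.items():
        if not name.startswith("D1+"):
            continue
        value = rep.macro_mean if isinstance(rep, EvalReport) else float(rep)
        pairs.append((name, value))
    if len(pairs) < 1:
        raise ValueError("no two-lead (D1+X) reports to rank")
    pairs.sort(key=lambda p: (-p[1], p[0]))
    return [name for name, _ in pairs]
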