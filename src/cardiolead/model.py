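"""Model/Results facade over the network and training machinery.

``ECGClassifier`` is constructed from a dataset (ECG records or a
ready-made fold split) plus a lead setup, handles preprocessing
(training-set normalization), and its :meth:`fit` returns an
``ECGClassifierResults`` carrying the trained weights, the training
traces, test-set scores and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .augment import AugmentConfig
from .evaluation import EvalReport, evaluate_runs, macro_average, roc_auc
from .leads import LeadSetup, get_setup
from .network import ModelSpec, count_parameters, describe, receptive_field
from .preprocess import downsample, fit_normalization, normalize
from .ptbxl import DatasetSplit, ECGRecord, assign_splits
from .training import (
    RunResult,
    TrainConfig,
    evaluation_inputs,
    predict_from_weights,
    train,
)


class ECGClassifier:
    """Multi-label ECG abnormality classifier for a chosen lead setup.

    Parameters
    ----------
    data : list of ECGRecord or DatasetSplit
        The dataset.  A flat record list is split by fold (1-8 train,
        9 validation, 10 test).
    setup : str or LeadSetup
        Which leads feed the network ("12lead", "8lead", "D1",
        "D1+D2", ..., "D1+V6").
    spec, train_config, augment_config : optional
        Hyperparameter overrides; the defaults follow the reference
        protocol (200 epochs, batch 32, lr 1e-2 -> 1e-4, the four
        training-time transforms, crop width = receptive field).
    preprocess : bool
        Downsample to 100 Hz and z-score each lead with training-split
        statistics (on by default; pass False for pre-normalized data).
    """

    def __init__(
        self,
        data,
        setup: str | LeadSetup = "12lead",
        spec: ModelSpec | None = None,
        train_config: TrainConfig | None = None,
        augment_config: AugmentConfig | None = None,
        preprocess: bool = True,
    ) -> None:
        self.setup = get_setup(setup)
        self.spec = spec or ModelSpec(n_leads=self.setup.n_leads)
        if self.spec.n_leads != self.setup.n_leads:
            raise ValueError(
                f"spec expects {self.spec.n_leads} leads, setup "
                f"{self.setup.name!r} provides {self.setup.n_leads}"
            )
        self.train_config = train_config or TrainConfig()
        self.augment_config = augment_config or AugmentConfig()

        split = data if isinstance(data, DatasetSplit) else assign_splits(list(data))
        if preprocess:
            split = DatasetSplit(
                train=[self._to_100hz(r) for r in split.train],
                validation=[self._to_100hz(r) for r in split.validation],
                test=[self._to_100hz(r) for r in split.test],
            )
            self.norm_stats = fit_normalization(split.train)
            split = DatasetSplit(
                train=[normalize(r, self.norm_stats) for r in split.train],
                validation=[normalize(r, self.norm_stats) for r in split.validation],
                test=[normalize(r, self.norm_stats) for r in split.test],
            )
        else:
            self.norm_stats = None
        self.split = split

    @staticmethod
    def _to_100hz(record: ECGRecord) -> ECGRecord:
        if record.fs == 100:
            return record
        return ECGRecord(
            record_id=record.record_id,
            signal=downsample(record.signal, record.fs, 100.0),
            fs=100.0,
            labels=record.labels.copy(),
            fold=record.fold,
            lead_names=record.lead_names,
        )

    @classmethod
    def from_synthetic(cls, synth_config=None, **kwargs) -> "ECGClassifier":
        """Build the model on a freshly generated synthetic dataset."""
        from .synthetic import SynthConfig, generate_dataset

        records, _ = generate_dataset(synth_config or SynthConfig())
        return cls(records, **kwargs)

    @property
    def n_parameters(self) -> int:
        return count_parameters(self.spec)

    @property
    def receptive_field(self) -> int:
        return receptive_field(self.spec)

    def fit(self, seed: int | None = None, **config_overrides) -> "ECGClassifierResults":
        """Run one seeded training; returns the fitted results object."""
        cfg = self.train_config
        if seed is not None:
            cfg = replace(cfg, run_seed=int(seed))
        if config_overrides:
            cfg = replace(cfg, **config_overrides)
        run = train(
            self.split,
            self.setup,
            model_spec=self.spec,
            train_config=cfg,
            augment_config=self.augment_config,
        )
        return ECGClassifierResults(self, run)

    def fit_runs(self, n_runs: int | None = None, base_seed: int = 0,
                 **config_overrides) -> list["ECGClassifierResults"]:
        """Repeat :meth:`fit` with consecutive seeds (base, base+1, ...)."""
        n = n_runs if n_runs is not None else self.train_config.n_runs
        return [
            self.fit(seed=base_seed + i, **config_overrides) for i in range(n)
        ]


class ECGClassifierResults:
    """Results of one seeded training run."""

    def __init__(self, model: ECGClassifier, run: RunResult) -> None:
        self.model = model
        self.run = run
        self.weights = run.weights
        self.loss_trace = np.asarray(run.loss_trace)
        self.val_auc_trace = np.asarray(run.val_auc_trace)
        self.test_scores = run.test_scores
        self.test_labels = run.test_labels

    @property
    def final_loss(self) -> float:
        return float(self.loss_trace[-1])

    def predict(self, records: list[ECGRecord], crop_seed: int = 0) -> np.ndarray:
        """Score records (deterministic seeded crops) -> (N, 20) in (0, 1)."""
        x, _ = evaluation_inputs(
            records, self.model.setup, self.model.spec, seed=crop_seed
        )
        return predict_from_weights(self.model.spec, self.weights, x)

    def test_macro_auc(self) -> float:
        """Macro AUC (percent) on the held-out test fold."""
        if self.test_scores is None:
            raise ValueError("no test split was available at fit time")
        y, s = self.test_labels, self.test_scores
        per_class = [
            100.0 * roc_auc(y[:, c], s[:, c])
            if 0 < y[:, c].sum() < len(y)
            else np.nan
            for c in range(y.shape[1])
        ]
        return macro_average(per_class)

    def evaluate(self) -> EvalReport:
        """Single-run EvalReport on the test fold (zero-width intervals)."""
        if self.test_scores is None:
            raise ValueError("no test split was available at fit time")
        return evaluate_runs(
            [self.test_scores], self.test_labels, setup_name=self.run.setup_name
        )

    def summary(self) -> str:
        lines = [
            "ECG abnormality classifier — fit summary",
            "=" * 56,
            f"lead setup      : {self.run.setup_name} "
            f"(L={self.model.setup.n_leads})",
            f"epochs          : {len(self.loss_trace)}",
            f"run seed        : {self.run.seed}",
            f"final train loss: {self.final_loss:.4f}",
        ]
        if self.val_auc_trace.size:
            lines.append(f"final val AUC   : {self.val_auc_trace[-1]:.2f}%")
        if self.test_scores is not None:
            lines.append(f"test macro AUC  : {self.test_macro_auc():.2f}%")
        lines += ["", describe(self.model.spec)]
        return "\n".join(lines)
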