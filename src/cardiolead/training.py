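"""Training: multi-label loss, linear learning-rate decay, Adam, the loop.

The network is trained to minimize the sum over the 20 outputs of the
binary cross-entropies (mean over the batch), with Adam and a learning
rate decaying linearly from 1e-2 to 1e-4 over 200 epochs at batch size
32.  Every epoch each training record contributes one freshly augmented
crop; validation/test records contribute one deterministic seeded crop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .augment import AugmentConfig, augment_pipeline
from .leads import LeadSetup, get_setup
from .network import ModelSpec, Network, build_network, sigmoid
from .preprocess import select_setup
from .ptbxl import DatasetSplit, ECGRecord

logger = logging.getLogger(__name__)

_EPS = 1e-7


@dataclass
class TrainConfig:
    epochs: int = 200
    batch_size: int = 32
    lr_start: float = 1e-2
    lr_end: float = 1e-4
    run_seed: int = 0
    n_runs: int = 50            # the full-scale protocol; desk runs use fewer
    model_selection: str = "final"   # "final" | "best_val"

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not self.lr_start >= self.lr_end > 0:
            raise ValueError("need lr_start >= lr_end > 0")


@dataclass
class RunResult:
    """Outcome of one seeded training run."""

    weights: list[np.ndarray]
    loss_trace: list[float]                  # per-epoch mean training loss
    val_auc_trace: list[float]               # per-epoch validation macro AUC
    test_scores: np.ndarray | None           # (n_test, 20) in (0, 1)
    test_labels: np.ndarray | None
    spec: ModelSpec
    setup_name: str
    seed: int


def multilabel_loss(targets: np.ndarray, scores: np.ndarray) -> float:
    """Mean over the batch of the sum over 20 classes of the BCE.

    Scores outside (0, 1) are clamped at 1e-7 from the boundary.
    """
    targets = np.atleast_2d(np.asarray(targets, dtype=np.float64))
    scores = np.atleast_2d(np.asarray(scores, dtype=np.float64))
    if targets.shape != scores.shape:
        raise ValueError("targets and scores must have the same shape")
    if np.any(scores < 0) or np.any(scores > 1):
        logger.debug("clamping scores outside [0, 1] for the cross-entropy")
    # clamp each log argument separately so exact predictions contribute 0
    pos_term = targets * np.log(np.clip(scores, _EPS, 1.0))
    neg_term = (1 - targets) * np.log(np.clip(1.0 - scores, _EPS, 1.0))
    per_record = -(pos_term + neg_term).sum(axis=1)
    return float(per_record.mean())


def _loss_and_grad_from_logits(
    targets: np.ndarray, logits: np.ndarray
) -> tuple[float, np.ndarray]:
    """Numerically stable loss and d(loss)/d(logits) = (sigmoid(z) - y)/N."""
    p = sigmoid(logits)
    loss = multilabel_loss(targets, p)
    grad = ((p - targets) / targets.shape[0]).astype(logits.dtype)
    return loss, grad


def lr_schedule(epoch: int, config: TrainConfig) -> float:
    """Per-epoch linear decay hitting both endpoints exactly."""
    if not 0 <= epoch < config.epochs:
        raise ValueError(f"epoch {epoch} outside [0, {config.epochs})")
    if config.epochs == 1:
        return config.lr_start
    frac = epoch / (config.epochs - 1)
    return config.lr_start + (config.lr_end - config.lr_start) * frac


class Adam:
    """Adaptive-moment optimizer over a fixed list of parameter arrays."""

    def __init__(
        self,
        params: list[np.ndarray],
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, grads: list[np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def _record_input(
    record: ECGRecord,
    setup: LeadSetup,
    config: AugmentConfig,
    rng: np.random.Generator,
    spec: ModelSpec,
) -> np.ndarray:
    return augment_pipeline(select_setup(record, setup), config, rng, spec)


def evaluation_inputs(
    records: list[ECGRecord],
    setup: str | LeadSetup,
    spec: ModelSpec,
    seed: int = 0,
    augment_config: AugmentConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic seeded crops for a record list -> (X (N,L,W), y (N,20)).

    Each record's crop position is drawn from a generator keyed on
    (seed, record_id), so reports are reproducible record by record.
    """
    setup = get_setup(setup)
    cfg = augment_config or AugmentConfig.evaluation()
    xs, ys = [], []
    for rec in records:
        rng = np.random.default_rng([int(seed), int(rec.record_id)])
        xs.append(_record_input(rec, setup, cfg, rng, spec))
        ys.append(rec.labels)
    return np.stack(xs), np.stack(ys).astype(np.float64)


def predict(network: Network, inputs: np.ndarray, batch_size: int = 256) -> np.ndarray:
    """Score a batch of (N, L, W) inputs -> (N, 20) sigmoid scores."""
    inputs = np.asarray(inputs, dtype=np.float64)
    if inputs.ndim == 2:
        inputs = inputs[None]
    if inputs.shape[2] != network.spec.input_width:
        raise ValueError(
            f"input width {inputs.shape[2]} does not match the network crop "
            f"width {network.spec.input_width}"
        )
    out = [
        network.predict_proba(inputs[i : i + batch_size])
        for i in range(0, len(inputs), batch_size)
    ]
    return np.concatenate(out, axis=0)


def predict_from_weights(
    spec: ModelSpec, weights: list[np.ndarray], inputs: np.ndarray
) -> np.ndarray:
    net = build_network(spec, seed=0)
    net.set_weights(weights)
    return predict(net, inputs)


def train(
    split: DatasetSplit,
    setup: str | LeadSetup,
    model_spec: ModelSpec | None = None,
    train_config: TrainConfig | None = None,
    augment_config: AugmentConfig | None = None,
    compute_val_auc: bool = True,
) -> RunResult:
    """Run one seeded training and score the test split with final weights.

    The training records must already be preprocessed (downsampled and
    normalized); the crop width is taken from the model spec's input
    width, which must equal the network receptive field.
    """
    from .evaluation import macro_average, roc_auc   # local import, no cycle

    setup = get_setup(setup)
    cfg = train_config or TrainConfig()
    aug = augment_config or AugmentConfig()
    spec = model_spec or ModelSpec(n_leads=setup.n_leads)
    if spec.n_leads != setup.n_leads:
        raise ValueError(
            f"model spec expects {spec.n_leads} leads but setup "
            f"{setup.name!r} provides {setup.n_leads}"
        )
    if not split.train:
        raise ValueError("training split is empty")

    rng = np.random.default_rng(cfg.run_seed)
    net = build_network(spec, seed=int(rng.integers(2**31)))
    optimizer = Adam(net.parameters())

    val_x = val_y = None
    if compute_val_auc and split.validation:
        val_x, val_y = evaluation_inputs(
            split.validation, setup, spec, seed=cfg.run_seed
        )

    n_train = len(split.train)
    loss_trace: list[float] = []
    val_auc_trace: list[float] = []
    best_val, best_weights = -np.inf, None

    for epoch in range(cfg.epochs):
        lr = lr_schedule(epoch, cfg)
        order = rng.permutation(n_train)
        epoch_losses = []
        for start in range(0, n_train, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            batch_x = np.stack(
                [_record_input(split.train[i], setup, aug, rng, spec) for i in idx]
            )
            batch_y = np.stack([split.train[i].labels for i in idx]).astype(np.float64)
            logits = net.forward(batch_x, training=True)
            loss, grad = _loss_and_grad_from_logits(batch_y, logits)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, "
                    f"lr={lr:g} (seed {cfg.run_seed})"
                )
            net.backward(grad)
            optimizer.step(net.gradients(), lr)
            epoch_losses.append(loss)
        loss_trace.append(float(np.mean(epoch_losses)))

        if val_x is not None:
            scores = predict(net, val_x)
            per_class = [
                100.0 * roc_auc(val_y[:, c], scores[:, c])
                for c in range(val_y.shape[1])
                if 0 < val_y[:, c].sum() < len(val_y)
            ]
            auc = macro_average(per_class)   # percent scale
            val_auc_trace.append(auc)
            if auc > best_val:
                best_val, best_weights = auc, net.get_weights()

    if cfg.model_selection == "best_val" and best_weights is not None:
        net.set_weights(best_weights)

    test_scores = test_labels = None
    if split.test:
        test_x, test_labels = evaluation_inputs(
            split.test, setup, spec, seed=cfg.run_seed + 1
        )
        test_scores = predict(net, test_x)

    return RunResult(
        weights=net.get_weights(),
        loss_trace=loss_trace,
        val_auc_trace=val_auc_trace,
        test_scores=test_scores,
        test_labels=test_labels,
        spec=spec,
        setup_name=setup.name,
        seed=cfg.run_seed,
    )
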