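"""Pre-training and the six layer-freezing transfer strategies.

A network is first trained on the master instrument by minimising MSE.  It is
then adapted to a slave instrument under one of six strategies:

1. freeze everything — direct testing, zero update steps;
2. fine-tune every layer;
3. retrain only the first fully connected layer;
4. retrain only the second fully connected layer;
5. retrain both fully connected layers, convolutional groups frozen;
6. as 5, with balanced distribution adaptation added to the loss — each
   batch draws matched-size samples from both domains, aligning FC1 features
   (marginal term) and predictions (conditional term) via MMD.

Freezing is structural: the optimiser is built over the trainable parameter
subset only, so frozen groups are bit-identical before and after any number
of steps.  The learning rate follows a plateau schedule (halved when the
monitored loss has not improved for a fixed number of epochs).

Targets are standardised on the master training split inside ``pretrain``;
the scaler travels with the network and predictions are de-standardised.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .data import SpectraSet
from .losses import LossWeights, MMDConfig, cda_loss, mda_loss, mse_loss, total_loss
from .model import GROUPS, ModelConfig, NetworkHandle, build_model
from .nn import Adam, Tensor

__all__ = [
    "TransferPlan",
    "TrainSchedule",
    "TrainHistory",
    "make_plan",
    "pretrain",
    "fine_tune",
    "plateau_scheduler",
    "PlateauScheduler",
    "group_hashes",
]

_STRATEGY_FREEZE = {
    1: frozenset(GROUPS),
    2: frozenset(),
    3: frozenset({"stem", "blocks", "fc2"}),
    4: frozenset({"stem", "blocks", "fc1"}),
    5: frozenset({"stem", "blocks"}),
    6: frozenset({"stem", "blocks"}),
}


@dataclass
class TransferPlan:
    strategy: int
    freeze: frozenset
    use_bda: bool
    weights: LossWeights = field(default_factory=LossWeights)

    @property
    def trainable_groups(self) -> tuple[str, ...]:
        return tuple(g for g in GROUPS if g not in self.freeze)


@dataclass
class TrainSchedule:
    batch_size: int = 8
    epochs: int = 100
    lr: float = 1e-3
    plateau_patience: int = 30
    lr_factor: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if not 0 < self.lr_factor < 1:
            raise ValueError("lr_factor must be in (0, 1)")
        if self.plateau_patience < 1:
            raise ValueError("plateau_patience must be >= 1")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch_size >= 1")


@dataclass
class TrainHistory:
    loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.loss)


def make_plan(strategy: int, weights: LossWeights | None = None) -> TransferPlan:
    """Build the freeze map and BDA switch for a strategy id 1-6."""
    if strategy not in _STRATEGY_FREEZE:
        raise ValueError(f"strategy must be in 1..6, got {strategy}")
    return TransferPlan(
        strategy=strategy,
        freeze=_STRATEGY_FREEZE[strategy],
        use_bda=(strategy == 6),
        weights=weights or LossWeights(),
    )


class PlateauScheduler:
    """Stateful plateau learning-rate decay.

    The learning rate is multiplied by ``factor`` whenever the monitored loss
    has not strictly improved on the running best for ``patience`` consecutive
    epochs; the stall counter resets after each reduction.
    """

    def __init__(self, lr: float, patience: int, factor: float):
        self.lr = lr
        self.patience = patience
        self.factor = factor
        self.best = np.inf
        self.stall = 0

    def step(self, loss: float) -> float:
        if loss < self.best:
            self.best = loss
            self.stall = 0
        else:
            self.stall += 1
            if self.stall >= self.patience:
                self.lr *= self.factor
                self.stall = 0
        return self.lr


def plateau_scheduler(history, patience: int, factor: float, lr: float) -> float:
    """Functional form: new learning rate given a loss history.

    Reduces ``lr`` by ``factor`` iff the most recent ``patience`` epochs
    contain no strict improvement over the best loss seen before them.
    """
    if patience < 1:
        raise ValueError("patience must be >= 1")
    hist = list(history)
    if not hist:
        raise ValueError("loss history is empty")
    if len(hist) < patience:
        return lr
    prior = hist[:-patience]
    best_prior = min(prior) if prior else np.inf
    running = best_prior
    for v in hist[-patience:]:
        if v < running:
            return lr  # an improvement happened within the window
        running = min(running, v)
    return lr * factor


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    bs = min(batch_size, n)
    for start in range(0, n - bs + 1, bs):
        yield order[start : start + bs]


def _check_finite(loss: float, epoch: int, stage: str) -> None:
    if not np.isfinite(loss):
        raise FloatingPointError(
            f"{stage}: loss became non-finite at epoch {epoch}"
        )


def pretrain(
    config: ModelConfig,
    master_train: SpectraSet,
    schedule: TrainSchedule,
    target: str | int = 0,
) -> tuple[NetworkHandle, TrainHistory]:
    """Train a fresh network on the master instrument by MSE minimisation."""
    if master_train.n_samples < 1:
        raise ValueError("master training set is empty")
    net = build_model(config, seed=schedule.seed)
    y = master_train.target(target)
    net.y_mean = float(y.mean())
    net.y_sd = float(y.std()) or 1.0
    y_std = (y - net.y_mean) / net.y_sd
    # condition the inputs: centre on the mean master spectrum and rescale so
    # the informative inter-sample variation is O(1); the scaler travels with
    # the network and is applied inside every forward pass
    net.x_mean = master_train.X.mean(axis=0)
    net.x_scale = float((master_train.X - net.x_mean).std()) or 1.0
    history = _train_loop(
        net,
        plan=None,
        X=master_train.X,
        y=y_std,
        schedule=schedule,
        stage="pretrain",
    )
    return net, history


def fine_tune(
    net: NetworkHandle,
    plan: TransferPlan,
    slave_train: SpectraSet,
    master_train: SpectraSet | None = None,
    schedule: TrainSchedule | None = None,
    mmd_cfg: MMDConfig | None = None,
    target: str | int = 0,
) -> tuple[NetworkHandle, TrainHistory]:
    """Adapt a pre-trained network to a slave instrument under a plan.

    Returns an adapted copy; the input network is never mutated.  Strategy 1
    performs zero update steps.  When the plan uses distribution adaptation,
    ``master_train`` supplies the source-domain batches.
    """
    if plan.use_bda and master_train is None:
        raise ValueError("plan uses BDA but no master (source-domain) data was given")
    schedule = schedule or TrainSchedule()
    adapted = net.copy()
    history = TrainHistory()
    if plan.strategy == 1 or schedule.epochs == 0:
        return adapted, history
    y = slave_train.target(target)
    y_std = (y - adapted.y_mean) / adapted.y_sd
    history = _train_loop(
        adapted,
        plan=plan,
        X=slave_train.X,
        y=y_std,
        schedule=schedule,
        stage=f"transfer-{plan.strategy}",
        master_X=master_train.X if master_train is not None else None,
        mmd_cfg=mmd_cfg or MMDConfig(),
    )
    return adapted, history


def _train_loop(
    net: NetworkHandle,
    plan: TransferPlan | None,
    X: np.ndarray,
    y: np.ndarray,
    schedule: TrainSchedule,
    stage: str,
    master_X: np.ndarray | None = None,
    mmd_cfg: MMDConfig | None = None,
) -> TrainHistory:
    groups = plan.trainable_groups if plan is not None else GROUPS
    params = net.group_parameters(groups)
    # switch off the tape for frozen groups: backward then skips both their
    # weight gradients and any input gradients upstream of the first
    # trainable layer, which makes head-only fine-tuning much cheaper
    all_params = net.group_parameters(GROUPS)
    trainable_ids = {id(p) for p in params}
    for p in all_params:
        p.requires_grad = id(p) in trainable_ids
    dtype = np.dtype(net.config.dtype)
    X = np.ascontiguousarray(X, dtype=dtype)
    y = np.asarray(y, dtype=dtype)
    if master_X is not None:
        master_X = np.ascontiguousarray(master_X, dtype=dtype)
    opt = Adam(params, lr=schedule.lr)
    sched = PlateauScheduler(schedule.lr, schedule.plateau_patience, schedule.lr_factor)
    # independent streams: slave/task batches, source-domain batches; keeping
    # them separate makes the lambda1=0 trajectory identical to strategy 5
    rng_task = np.random.default_rng([schedule.seed, 2])
    rng_src = np.random.default_rng([schedule.seed, 3])
    use_bda = plan is not None and plan.use_bda and plan.weights.lambda1 > 0
    history = TrainHistory()
    try:
        for epoch in range(schedule.epochs):
            losses = []
            for idx in _batches(X.shape[0], schedule.batch_size, rng_task):
                opt.zero_grad()
                feats, preds = net.forward(X[idx], training=True)
                task = mse_loss(Tensor(y[idx]), preds)
                if use_bda:
                    bs = min(len(idx), master_X.shape[0])
                    src_idx = rng_src.choice(master_X.shape[0], size=bs, replace=False)
                    src_feats, src_preds = net.forward(master_X[src_idx], training=True)
                    mda = mda_loss(src_feats, feats, mmd_cfg)
                    cda = cda_loss(src_preds, preds, mmd_cfg)
                    loss = total_loss(task, mda, cda, plan.weights)
                else:
                    loss = task
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            epoch_loss = float(np.mean(losses))
            _check_finite(epoch_loss, epoch, stage)
            opt.lr = sched.step(epoch_loss)
            history.loss.append(epoch_loss)
            history.lr.append(opt.lr)
    finally:
        for p in all_params:
            p.requires_grad = True
    return history


def group_hashes(net: NetworkHandle) -> dict[str, str]:
    """SHA-256 digest of each parameter group's concatenated bytes."""
    out: dict[str, str] = {}
    for g in GROUPS:
        h = hashlib.sha256()
        for grp, _, p in net.named_group_parameters():
            if grp == g:
                h.update(np.ascontiguousarray(p.data).tobytes())
        out[g] = h.hexdigest()
    return out
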