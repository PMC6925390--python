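"""Train and evaluate the recurrent sleep-deprivation classifier.

The protocol mirrors the reference setup: a stratified 90/10 split into
train+validation and test, the 90 split again 90/10 into train and
validation (81/9/10 overall), dropout 0.5 on the dense head, and AUC as
the success metric (0.5 = chance on an imbalanced dataset).  AUC is the
Mann-Whitney rank statistic with midranks for ties.  The epoch with the
best validation AUC is kept.  ``repeated_evaluation`` reruns the whole
split/train/test cycle over several seeds and reports the per-seed AUCs
with their mean and sample SD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import train_test_split

from .features import FeatureTensor
from .gru import GRUClassifier

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """Classifier training configuration.

    ``dropout``, ``test_fraction`` and ``val_fraction_of_trainval``
    default to the reference protocol (0.5 and the 90/10 + 90/10 splits);
    the remaining knobs (hidden size, optimizer budget) are desk-scale
    defaults, all exposed here.
    """

    hidden_units: int = 64
    dropout: float = 0.5
    test_fraction: float = 0.10
    val_fraction_of_trainval: float = 0.10
    epochs: int = 20
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0
    normalize_aux: bool = True
    n_runs: int = 5

    def __post_init__(self) -> None:
        if not (0.0 < self.dropout < 1.0):
            raise ValueError("dropout must be in (0, 1)")
        if not (0.0 < self.test_fraction < 1.0):
            raise ValueError("test_fraction must be in (0, 1)")
        if not (0.0 < self.val_fraction_of_trainval < 1.0):
            raise ValueError("val_fraction_of_trainval must be in (0, 1)")


@dataclass
class EvalResult:
    """AUC of one test evaluation, plus per-seed aggregates when several
    seeded runs were performed."""

    auc: float
    n_test: int
    per_seed_aucs: list[float] = field(default_factory=list)
    mean_auc: float = float("nan")
    sd_auc: float = float("nan")


def mann_whitney_auc(y_true, scores) -> float:
    """ROC AUC by the rank statistic; ties get midranks.

    AUC = (R1 - n1(n1+1)/2) / (n1 n0) with R1 the positive-class rank sum.
    """
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=np.float64)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def split_dataset(
    tensor: FeatureTensor, config: TrainConfig
) -> tuple[FeatureTensor, FeatureTensor, FeatureTensor]:
    """Stratified, seeded 81/9/10 split into (train, val, test)."""
    y = tensor.labels
    for cls in (0, 1):
        if int((y == cls).sum()) < 10:
            raise ValueError(
                f"need at least 10 rows of class {cls}, got {int((y == cls).sum())}"
            )
    idx = np.arange(len(tensor))
    trainval_idx, test_idx = train_test_split(
        idx,
        test_size=config.test_fraction,
        stratify=y,
        random_state=config.seed % (2**32),
    )
    train_idx, val_idx = train_test_split(
        trainval_idx,
        test_size=config.val_fraction_of_trainval,
        stratify=y[trainval_idx],
        random_state=(config.seed + 1) % (2**32),
    )
    return tensor.subset(train_idx), tensor.subset(val_idx), tensor.subset(test_idx)


def train_model(
    train: FeatureTensor, val: FeatureTensor, config: TrainConfig
) -> GRUClassifier:
    """Fit the GRU by Adam on binary cross-entropy.

    Keeps the weights of the epoch with the best validation AUC; the
    training curve is attached as ``model.history`` (epoch, train loss,
    val AUC).  A non-finite loss raises, naming the epoch.
    """
    model = GRUClassifier(
        input_dim=train.values.shape[2],
        hidden_units=config.hidden_units,
        dropout=config.dropout,
        seed=config.seed,
        normalize_aux=config.normalize_aux,
    )
    rng = np.random.default_rng(config.seed + 10_000)
    n = len(train)
    best = (-np.inf, None, -1)
    history: list[tuple[int, float, float]] = []
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        losses = []
        for b in range(0, n, config.batch_size):
            sel = order[b : b + config.batch_size]
            loss, grads = model.loss_and_grads(
                train.values[sel], train.labels[sel], rng
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged (non-finite loss) at epoch {epoch}"
                )
            model.adam_step(grads, lr=config.learning_rate)
            losses.append(loss)
        val_auc = mann_whitney_auc(val.labels, model.predict_scores(val.values))
        history.append((epoch, float(np.mean(losses)), val_auc))
        logger.info(
            "epoch %d: train loss %.4f, val AUC %.4f", epoch, np.mean(losses), val_auc
        )
        if val_auc > best[0]:
            best = (val_auc, model.get_weights(), epoch)
    model.set_weights(best[1])
    model.history = history
    model.best_epoch = best[2]
    return model


def evaluate_auc(model: GRUClassifier, test: FeatureTensor) -> EvalResult:
    """Test-set AUC of a trained model (single run)."""
    scores = model.predict_scores(test.values)
    auc = mann_whitney_auc(test.labels, scores)
    return EvalResult(
        auc=auc, n_test=len(test), per_seed_aucs=[auc], mean_auc=auc, sd_auc=0.0
    )


def repeated_evaluation(
    tensor: FeatureTensor, config: TrainConfig, seeds: list[int]
) -> EvalResult:
    """Full split/train/evaluate per seed; mean and sample SD over seeds."""
    if len(seeds) < 2:
        raise ValueError("repeated evaluation needs at least 2 seeds")
    aucs: list[float] = []
    n_test = 0
    for s in seeds:
        cfg = replace(config, seed=s)
        train, val, test = split_dataset(tensor, cfg)
        model = train_model(train, val, cfg)
        res = evaluate_auc(model, test)
        aucs.append(res.auc)
        n_test = res.n_test
        logger.info("seed %d: test AUC %.4f", s, res.auc)
    return EvalResult(
        auc=float(np.mean(aucs)),
        n_test=n_test,
        per_seed_aucs=aucs,
        mean_auc=float(np.mean(aucs)),
        sd_auc=float(np.std(aucs, ddof=1)),
    )
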