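"""Collaborative training loop, checkpointing, prediction and evaluation.

Training minimises the weighted multi-task objective with Adam.  Batches
are disjoint block-diagonal graphs; per-batch losses are averaged with
batch-size weighting so that the reported epoch loss equals the loss of a
single pass over the whole dataset.  Model selection uses the validation
average precision of the localization task.  Every source of randomness
(parameter initialisation and data order) derives from the config seed, so
two runs with the same seed produce identical loss curves.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .config import ModelConfig
from .contact_graph import ResidueGraph
from .losses import LossBundle, bce_multilabel, total_loss
from .metrics import MetricReport, evaluate
from .model import MultiTaskModel, PredictionBundle
from .nn import Adam

log = logging.getLogger(__name__)

__all__ = ["GraphSample", "TrainResult", "compute_batch_loss", "train",
           "predict_dataset", "evaluate_predictions", "save_checkpoint",
           "load_checkpoint"]


@dataclass
class GraphSample:
    """A featurised protein graph paired with its task label vectors."""

    graph: ResidueGraph
    go_bp: np.ndarray
    go_cc: np.ndarray
    go_mf: np.ndarray
    sl: np.ndarray

    @property
    def protein_id(self) -> str:
        return self.graph.protein_id


@dataclass
class TrainResult:
    model: MultiTaskModel
    log: pd.DataFrame
    best_state: dict[str, np.ndarray]
    best_epoch: int
    best_valid_ap: float

    def loss_curve(self) -> np.ndarray:
        return self.log["train_total"].to_numpy()


def _labels(batch: list[GraphSample], task: str) -> np.ndarray:
    return np.stack([getattr(s, task) for s in batch]).astype(float)


def compute_batch_loss(model: MultiTaskModel, batch: list[GraphSample]) -> LossBundle:
    """Forward one batch and assemble the collaborative loss bundle."""
    out = model([s.graph for s in batch])
    alpha, beta, omega = model.config.effective_weights()
    return total_loss(
        bp_bce=bce_multilabel(out["bp"], _labels(batch, "go_bp")),
        cc_bce=bce_multilabel(out["cc"], _labels(batch, "go_cc")),
        mf_bce=bce_multilabel(out["mf"], _labels(batch, "go_mf")),
        bp_mse=out["bp_mse"], cc_mse=out["cc_mse"], mf_mse=out["mf_mse"],
        sl=bce_multilabel(out["sl"], _labels(batch, "sl")),
        alpha=alpha, beta=beta, omega=omega,
    )


def train(config: ModelConfig, train_set: list[GraphSample],
          valid_set: list[GraphSample] | None = None,
          epochs: int | None = None) -> TrainResult:
    """Train a fresh model; returns the model with its best-validation state
    also retained separately."""
    epochs = epochs or config.epochs
    model = MultiTaskModel(config)
    optim = Adam(model.parameters(), lr=config.learning_rate,
                 weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed + 1)

    rows = []
    best_state = model.state_dict()
    best_ap, best_epoch = -np.inf, 0
    for epoch in range(1, epochs + 1):
        model.train()
        order = rng.permutation(len(train_set))
        sums: dict[str, float] = {}
        n_seen = 0
        for start in range(0, len(order), config.batch_size):
            batch = [train_set[i] for i in order[start : start + config.batch_size]]
            model.zero_grad()
            bundle = compute_batch_loss(model, batch)
            if not np.isfinite(bundle.total.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch} on proteins "
                    f"{[s.protein_id for s in batch]}: {bundle.as_floats()}"
                )
            bundle.total.backward()
            optim.step()
            for key, val in bundle.as_floats().items():
                sums[key] = sums.get(key, 0.0) + val * len(batch)
            n_seen += len(batch)
        row = {"epoch": epoch}
        row.update({f"train_{k}": v / n_seen for k, v in sums.items()})

        if valid_set:
            report = _validation_report(model, valid_set)
            row["valid_sl_ap"] = report.ap
            row["valid_sl_auroc"] = report.auroc
            if report.ap > best_ap:
                best_ap, best_epoch = report.ap, epoch
                best_state = model.state_dict()
        else:
            best_epoch = epoch
            best_state = model.state_dict()
        rows.append(row)
        log.info("epoch %d: %s", epoch,
                 {k: round(v, 4) for k, v in row.items() if k != "epoch"})
    if not np.isfinite(best_ap):
        # validation AP was never defined (e.g. all-constant labels in a
        # tiny split): keep the final state rather than the initial one
        best_state, best_epoch = model.state_dict(), epochs
    return TrainResult(model=model, log=pd.DataFrame(rows),
                       best_state=best_state, best_epoch=best_epoch,
                       best_valid_ap=float(best_ap))


def _validation_report(model: MultiTaskModel, samples: list[GraphSample]) -> MetricReport:
    bundles = predict_dataset(model, samples, batch_size=model.config.batch_size)
    scores = np.stack([b.sl for b in bundles])
    labels = _labels(samples, "sl")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return evaluate(scores, labels)


def predict_dataset(model: MultiTaskModel, samples: list[GraphSample],
                    batch_size: int = 8) -> list[PredictionBundle]:
    bundles: list[PredictionBundle] = []
    for start in range(0, len(samples), batch_size):
        chunk = samples[start : start + batch_size]
        bundles.extend(model.predict([s.graph for s in chunk]))
    return bundles


def evaluate_predictions(bundles: list[PredictionBundle],
                         samples: list[GraphSample]) -> dict[str, MetricReport]:
    """Metric reports for each task over a prediction set."""
    reports = {}
    for task, attr in (("bp", "go_bp"), ("cc", "go_cc"), ("mf", "go_mf"),
                       ("sl", "sl")):
        scores = np.stack([getattr(b, task) for b in bundles])
        labels = _labels(samples, attr)
        reports[task] = evaluate(scores, labels)
    return reports


# -- checkpoints --------------------------------------------------------------

def save_checkpoint(model: MultiTaskModel, path) -> None:
    """Versioned container of all parameters + config (hash-checked)."""
    state = model.state_dict()
    np.savez(path, __version__=np.int64(1),
             __config__=np.array(json.dumps(model.config.to_dict())),
             **state)


def load_checkpoint(path, expected_config: ModelConfig | None = None) -> MultiTaskModel:
    with np.load(path, allow_pickle=False) as data:
        if int(data["__version__"]) != 1:
            raise ValueError(f"{path}: unsupported checkpoint version")
        config = ModelConfig.from_dict(json.loads(str(data["__config__"])))
        if expected_config is not None and expected_config.hash() != config.hash():
            raise ValueError(
                f"{path}: checkpoint config hash {config.hash()} does not match "
                f"expected {expected_config.hash()}"
            )
        model = MultiTaskModel(config)
        state = {k: data[k] for k in data.files
                 if k not in ("__version__", "__config__")}
        model.load_state_dict(state)
    model.eval()
    return model
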