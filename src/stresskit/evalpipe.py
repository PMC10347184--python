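"""Training and evaluation protocol: stratified 3-fold cross-validation,
Adam optimization, accuracy / macro precision-recall-F1, fold-averaged
confusion matrices, and breakdowns by signal combination, scenario and
puzzle difficulty.

Fold performance is, by default, the mean of every epoch's validation
metrics (``epoch_mean``), which is the protocol this pipeline reproduces;
``final_epoch`` mode is available as the conventional alternative.  Folds
are stratified at segment level, so segments of one participant can appear
in both training and validation folds of the same split; a grouped-by-
participant mode gives honest subject-level generalization estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import GroupKFold, StratifiedKFold

from . import models as models_mod
from . import nn
from .transforms import TransformSpec, make_pretext_batch

logger = logging.getLogger(__name__)

#: the seven signal combinations evaluated in the study
SIGNAL_COMBINATIONS = (
    ("ppg",),
    ("ecg",),
    ("eeg",),
    ("ppg", "ecg"),
    ("ppg", "eeg"),
    ("ecg", "eeg"),
    ("ppg", "ecg", "eeg"),
)


class EvalError(ValueError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol knobs.

    Defaults follow the study protocol: 3-fold stratified CV, Adam with
    learning rate 0.001, 300 epochs for classifier training and 150 for
    self-supervised pretraining.  ``epochs_main``/``epochs_pretrain`` are the
    knobs to lower for desk-scale runs.
    """

    k_folds: int = 3
    learning_rate: float = 0.001
    epochs_main: int = 300
    epochs_pretrain: int = 150
    batch_size: int = 64
    seed: int = 0
    fold_metric_mode: str = "epoch_mean"  # or "final_epoch"

    def validate(self) -> None:
        if self.k_folds < 2:
            raise EvalError("k_folds must be >= 2")
        if self.epochs_main < 1 or self.epochs_pretrain < 1:
            raise EvalError("epoch counts must be >= 1")
        if self.learning_rate <= 0:
            raise EvalError("learning_rate must be positive")
        if self.fold_metric_mode not in {"epoch_mean", "final_epoch"}:
            raise EvalError(f"unknown fold_metric_mode {self.fold_metric_mode!r}")


@dataclass
class FoldResult:
    """Per-epoch validation curves and the summarized fold metrics."""

    history: pd.DataFrame  # epoch, train_loss, val_accuracy, val_macro_f1
    fold_accuracy: float
    fold_f1: float
    confusion: np.ndarray  # final-epoch validation confusion matrix


@dataclass
class EvalReport:
    """Aggregated cross-validation result for one model x data combination."""

    model_name: str
    combination: tuple[str, ...]
    subset: str  # "all", "scenario:1", "difficulty:hard", ...
    fold_accuracies: list[float]
    fold_f1s: list[float]
    accuracy: float
    f1: float
    confusion: np.ndarray  # averaged over folds
    n_segments: int
    n_parameters: int
    class_counts: np.ndarray
    config: TrainConfig = field(repr=False, default=None)

    def row(self) -> dict:
        return {
            "model": self.model_name,
            "data": "+".join(m.upper() for m in self.combination),
            "subset": self.subset,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "n_segments": self.n_segments,
            "n_parameters": self.n_parameters,
        }


# ---------------------------------------------------------------------------
# metrics (hand-written per the protocol's equations; sklearn serves as an
# independent cross-check in the test suite only)


def confusion_matrix(true, pred, n_classes: int = 3) -> np.ndarray:
    true = np.asarray(true, dtype=np.int64)
    pred = np.asarray(pred, dtype=np.int64)
    if true.shape != pred.shape:
        raise EvalError("true and pred must have equal length")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (true, pred), 1)
    return cm


def accuracy(pred, true) -> float:
    """Fraction of exactly matching labels."""
    pred = np.asarray(pred)
    true = np.asarray(true)
    if pred.shape != true.shape:
        raise EvalError("pred and true must have equal length")
    if pred.size == 0:
        raise EvalError("empty label vectors")
    return float(np.mean(pred == true))


def precision_recall_f1(
    pred, true, n_classes: int = 3, averaging: str = "macro"
) -> tuple[float, float, float]:
    """One-vs-rest precision/recall/F1, macro-averaged.

    Per-class ratios with zero denominators (a class never predicted, or
    absent from the data) contribute 0, which is what makes a majority-class
    predictor's macro-F1 collapse under heavy imbalance.
    """
    if averaging != "macro":
        raise EvalError("only macro averaging is supported")
    pred = np.asarray(pred)
    true = np.asarray(true)
    if pred.size == 0:
        raise EvalError("empty label vectors")
    cm = confusion_matrix(true, pred, n_classes)
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    with np.errstate(divide="ignore", invalid="ignore"):
        prec = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        rec = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(prec + rec > 0, 2 * prec * rec / (prec + rec), 0.0)
    return float(prec.mean()), float(rec.mean()), float(f1.mean())


# ---------------------------------------------------------------------------
# fold construction


def stratified_folds(
    labels, k: int = 3, seed: int = 0, groups=None
) -> list[np.ndarray]:
    """k disjoint validation index sets preserving class proportions.

    Every fold contains all classes (each class must have at least k
    members).  With ``groups`` given, folds are built per group
    (participant) instead, trading exact stratification for subject-level
    separation.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    for cls, cnt in zip(classes, counts):
        if cnt < k:
            raise EvalError(
                f"class {cls} has only {cnt} member(s); needs >= {k} for {k}-fold CV"
            )
    if groups is not None:
        splitter = GroupKFold(n_splits=k)
        return [val for _, val in splitter.split(labels, labels, groups)]
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [val for _, val in splitter.split(np.zeros_like(labels), labels)]


# ---------------------------------------------------------------------------
# training


def predict(model: nn.Module, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
    """Class predictions (argmax of logits; ties break to the lowest index)."""
    model.eval()
    out = []
    for start in range(0, x.shape[0], batch_size):
        logits = model.forward(np.asarray(x[start : start + batch_size], dtype=np.float32))
        out.append(np.argmax(logits, axis=1))
    model.train()
    return np.concatenate(out)


def train_model(
    model: nn.Module,
    x: np.ndarray,
    y: np.ndarray,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    config: TrainConfig,
    n_classes: int = 3,
) -> FoldResult:
    """Cross-entropy training with Adam, recording per-epoch validation
    accuracy and macro-F1; the fold metric follows ``fold_metric_mode``."""
    config.validate()
    train_idx = np.asarray(train_idx)
    val_idx = np.asarray(val_idx)
    if np.intersect1d(train_idx, val_idx).size:
        raise EvalError("train and validation indices overlap")
    rng = np.random.default_rng(config.seed)
    optimizer = nn.Adam(model.parameters(), lr=config.learning_rate)
    rows = []
    confusion = None
    for epoch in range(config.epochs_main):
        model.train()
        order = rng.permutation(train_idx)
        losses = []
        for start in range(0, order.size, config.batch_size):
            batch_idx = order[start : start + config.batch_size]
            xb = np.asarray(x[batch_idx], dtype=np.float32)
            logits = model.forward(xb)
            loss, dlogits = nn.softmax_cross_entropy(logits, y[batch_idx])
            if not np.isfinite(loss):
                raise EvalError(
                    f"training diverged to non-finite loss at epoch {epoch}"
                )
            model.zero_grad()
            model.backward(dlogits)
            optimizer.step()
            losses.append(loss)
        val_pred = predict(model, x[val_idx], config.batch_size)
        val_acc = accuracy(val_pred, y[val_idx])
        _, _, val_f1 = precision_recall_f1(val_pred, y[val_idx], n_classes)
        confusion = confusion_matrix(y[val_idx], val_pred, n_classes)
        rows.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(losses)),
                "val_accuracy": val_acc,
                "val_macro_f1": val_f1,
            }
        )
    history = pd.DataFrame(rows)
    if config.fold_metric_mode == "epoch_mean":
        fold_acc = float(history["val_accuracy"].mean())
        fold_f1 = float(history["val_macro_f1"].mean())
    else:
        fold_acc = float(history["val_accuracy"].iloc[-1])
        fold_f1 = float(history["val_macro_f1"].iloc[-1])
    return FoldResult(history, fold_acc, fold_f1, confusion)


def _pretext_arrays(segments, spec, seed):
    batch = make_pretext_batch(segments, spec, seed)
    return batch.inputs, batch.pretext_labels


def pretrain_then_classify(
    model_spec: models_mod.ModelSpec,
    x: np.ndarray,
    y: np.ndarray,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    config: TrainConfig,
    transform_spec: TransformSpec = TransformSpec(),
    pretrain: bool = True,
) -> tuple[models_mod.SSCNNHead, dict]:
    """Two-stage self-supervised pipeline.

    Stage 1 trains the 6-way pretext head on transformed copies of the
    training segments for ``epochs_pretrain`` epochs; stage 2 trains the
    3-way classifier for ``epochs_main`` epochs, reusing the shared encoder
    by reference (full fine-tuning).  ``pretrain=False`` skips stage 1,
    giving the plain-CNN ablation baseline.
    """
    config.validate()
    encoder = models_mod.build_sscnn_encoder(model_spec)
    pretext_model, classifier = models_mod.build_sscnn_heads(encoder, model_spec)
    report: dict = {"pretrained": pretrain}
    if pretrain:
        px, py = _pretext_arrays(x[train_idx], transform_spec, config.seed)
        pvx, pvy = _pretext_arrays(x[val_idx], transform_spec, config.seed + 1)
        pre_cfg = replace(config, epochs_main=config.epochs_pretrain)
        pre_result = train_model(
            pretext_model,
            np.concatenate([px, pvx]),
            np.concatenate([py, pvy]),
            np.arange(px.shape[0]),
            px.shape[0] + np.arange(pvx.shape[0]),
            pre_cfg,
            n_classes=model_spec.pretext_classes,
        )
        report["pretext_history"] = pre_result.history
        report["pretext_accuracy"] = pre_result.fold_accuracy
        report["pretext_final_accuracy"] = float(
            pre_result.history["val_accuracy"].iloc[-1]
        )
    cls_result = train_model(classifier, x, y, train_idx, val_idx, config)
    report["classifier_history"] = cls_result.history
    report["fold_accuracy"] = cls_result.fold_accuracy
    report["fold_f1"] = cls_result.fold_f1
    report["confusion"] = cls_result.confusion
    return classifier, report


# ---------------------------------------------------------------------------
# suite evaluation


def _combination_channels(channel_map: list[str], combination) -> list[int]:
    from .preprocess import MODALITY_CHANNELS

    wanted = [name for mod in combination for name in MODALITY_CHANNELS[mod]]
    missing = [name for name in wanted if name not in channel_map]
    if missing:
        raise EvalError(f"channels {missing} not present in segment set")
    return [channel_map.index(name) for name in wanted]


def run_cv(
    model_spec: models_mod.ModelSpec,
    x: np.ndarray,
    y: np.ndarray,
    config: TrainConfig,
    subset: str = "all",
    combination: tuple[str, ...] = ("ecg",),
    groups=None,
) -> EvalReport:
    """Full k-fold CV of one model on one data matrix."""
    folds = stratified_folds(y, config.k_folds, config.seed, groups)
    all_idx = np.arange(y.size)
    fold_accs, fold_f1s, confusions = [], [], []
    n_params = 0
    for fold_no, val_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, val_idx)
        spec = replace(model_spec, seed=model_spec.seed + fold_no)
        if model_spec.model_name == "sscnn":
            _, rep = pretrain_then_classify(
                spec, x, y, train_idx, val_idx, config
            )
            fold_accs.append(rep["fold_accuracy"])
            fold_f1s.append(rep["fold_f1"])
            confusions.append(rep["confusion"])
            n_params = models_mod.build_model(spec).n_parameters()
        else:
            model = models_mod.build_model(spec)
            n_params = model.n_parameters()
            result = train_model(model, x, y, train_idx, val_idx, config)
            fold_accs.append(result.fold_accuracy)
            fold_f1s.append(result.fold_f1)
            confusions.append(result.confusion)
    return EvalReport(
        model_name=model_spec.model_name,
        combination=combination,
        subset=subset,
        fold_accuracies=fold_accs,
        fold_f1s=fold_f1s,
        accuracy=float(np.mean(fold_accs)),
        f1=float(np.mean(fold_f1s)),
        confusion=np.mean(confusions, axis=0),
        n_segments=int(y.size),
        n_parameters=n_params,
        class_counts=np.bincount(y, minlength=3),
        config=config,
    )


def evaluate_suite(
    segment_set,
    model_names=("stressnext", "lrcn", "sscnn"),
    combinations=SIGNAL_COMBINATIONS,
    config: TrainConfig = TrainConfig(),
    breakdowns: bool = True,
    model_overrides: dict | None = None,
) -> list[EvalReport]:
    """Model x signal-combination grid, plus scenario and difficulty subsets.

    Subset rows retrain on the subset (independent-experiment framing) rather
    than slicing the global model's predictions.
    """
    overrides = model_overrides or {}
    prov = segment_set.provenance
    reports = []
    subset_masks = [("all", np.ones(len(segment_set), dtype=bool))]
    if breakdowns:
        for scen in sorted(prov["scenario"].unique()):
            subset_masks.append(
                (f"scenario:{scen}", (prov["scenario"] == scen).to_numpy())
            )
        for diff in sorted(prov["difficulty"].unique()):
            subset_masks.append(
                (f"difficulty:{diff}", (prov["difficulty"] == diff).to_numpy())
            )
    for name in model_names:
        for combo in combinations:
            ch_idx = _combination_channels(segment_set.channel_map, combo)
            x = segment_set.segments[:, ch_idx, :]
            for subset, mask in subset_masks:
                spec = models_mod.ModelSpec(
                    model_name=name,
                    in_channels=len(ch_idx),
                    seed=config.seed,
                    **overrides.get(name, {}),
                )
                reports.append(
                    run_cv(
                        spec,
                        x[mask],
                        segment_set.labels[mask],
                        config,
                        subset=subset,
                        combination=combo,
                    )
                )
    return reports


def reports_table(reports: list[EvalReport]) -> pd.DataFrame:
    return pd.DataFrame([r.row() for r in reports])


# ---------------------------------------------------------------------------
# self-report analysis


def selfreport_summary(manifest: pd.DataFrame) -> pd.DataFrame:
    """Per-participant scenario-to-scenario stress-score change counts.

    For each ordered scenario pair and difficulty group, counts how many
    participants' self-report score increased, decreased or held.
    """
    pivot = manifest.pivot_table(
        index=["participant_id", "difficulty"],
        columns="scenario",
        values="score",
        aggfunc="first",
    )
    scenarios = sorted(c for c in pivot.columns)
    rows = []
    for i, a in enumerate(scenarios):
        for b in scenarios[i + 1 :]:
            delta = pivot[b] - pivot[a]
            frame = pd.DataFrame(
                {
                    "difficulty": pivot.index.get_level_values("difficulty"),
                    "delta": delta.to_numpy(),
                }
            )
            for diff_name, grp in [("all", frame)] + list(frame.groupby("difficulty")):
                rows.append(
                    {
                        "comparison": f"scenario{b}_vs_{a}",
                        "difficulty": diff_name,
                        "increase": int((grp["delta"] > 0).sum()),
                        "decrease": int((grp["delta"] < 0).sum()),
                        "hold": int((grp["delta"] == 0).sum()),
                    }
                )
    return pd.DataFrame(rows)
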