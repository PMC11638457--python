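"""ResNet-18 slice-stack classifier: fivefold cross-validated training with
probability averaging, and Grad-CAM activation maps.

Training follows the published recipe: Adam (lr 1e-3, weight decay 1e-5),
binary cross-entropy, batch size 32, dropout 0.3, reduce-on-plateau schedule
and early stopping driven by validation AUC, keeping the best-epoch weights.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize
from sklearn.model_selection import StratifiedKFold

from .errors import ConfigurationError, DegenerateInputError, DomainError
from .evalstats import mann_whitney_auc
from .nn import Adam, ResNet18, bce_with_logits, sigmoid
from .preprocess import AugmentConfig, SlicePack, augment

log = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "FoldResult",
    "CnnEnsemble",
    "ActivationMap",
    "build_model",
    "train_fold",
    "crossval_train",
    "predict_proba",
    "gradcam",
    "save_ensemble",
    "load_ensemble",
]

# channel layout is sequence-major, slice-minor, image-then-mask; recorded in
# saved model metadata
CHANNEL_LAYOUT = "seq-major,slice-minor,image-then-mask"


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-3
    weight_decay: float = 1e-5
    batch_size: int = 32
    dropout: float = 0.3
    max_epochs: int = 500
    early_stop_patience: int = 30
    lr_factor: float = 0.5
    lr_patience: int = 10
    min_lr: float = 1e-6
    folds: int = 5
    seed: int = 0
    image_size: int = 512
    sequences: tuple[str, ...] = ("T1pre", "T2")
    base_width: int = 64

    def __post_init__(self):
        if self.lr <= 0:
            raise ConfigurationError("lr must be > 0")
        if self.folds < 2:
            raise ConfigurationError("folds must be >= 2")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")

    @property
    def in_channels(self) -> int:
        return len(self.sequences) * 5 * 2


@dataclass
class FoldResult:
    fold_id: int
    state: dict[str, np.ndarray]
    best_val_auc: float
    epoch_of_best: int
    train_case_ids: list[str]
    val_case_ids: list[str]
    history: list[dict] = field(default_factory=list)

    def __post_init__(self):
        if set(self.train_case_ids) & set(self.val_case_ids):
            raise DomainError("train and validation case ids overlap")


@dataclass
class CnnEnsemble:
    folds: list[FoldResult]
    config: TrainConfig
    oof_probs: dict[str, float] = field(default_factory=dict)
    _models: list[ResNet18] | None = None

    @property
    def in_channels(self) -> int:
        return int(self.folds[0].state["conv1.weight"].shape[1])

    def models(self) -> list[ResNet18]:
        if self._models is None:
            ms = []
            for fr in self.folds:
                m = build_model(self.in_channels, self.config.dropout,
                                self.config.base_width)
                m.load_state_dict(fr.state)
                ms.append(m)
            self._models = ms
        return self._models


@dataclass
class ActivationMap:
    heat: np.ndarray  # (H, W), >= 0, max 1 unless all-zero
    target_class: str = "cirrhosis"


def build_model(in_channels: int, dropout: float = 0.3, base_width: int = 64,
                seed: int = 0) -> ResNet18:
    """ResNet-18 with the stem widened to ``in_channels`` and a single-logit
    sigmoid head."""
    if in_channels < 1:
        raise ConfigurationError("in_channels must be >= 1")
    return ResNet18(in_channels=in_channels, dropout=dropout,
                    base_width=base_width, seed=seed)


def _as_array(packs) -> np.ndarray:
    if isinstance(packs, np.ndarray):
        return packs.astype(np.float32)
    return np.stack([p.slices if isinstance(p, SlicePack) else p for p in packs]).astype(
        np.float32)


def _predict_model(model: ResNet18, x: np.ndarray, batch: int = 32) -> np.ndarray:
    out = []
    for i in range(0, x.shape[0], batch):
        out.append(sigmoid(model.logits(x[i : i + batch], train=False)).ravel())
    return np.concatenate(out)


def train_fold(train_cases, val_cases, config: TrainConfig,
               augment_cfg: AugmentConfig | None = None, fold_id: int = 0) -> FoldResult:
    """Train one fold.  ``*_cases`` are lists of (case_id, SlicePack-or-array,
    label).  Validation AUC drives the plateau schedule, early stopping and
    best-weight retention.
    """
    train_ids = [c[0] for c in train_cases]
    val_ids = [c[0] for c in val_cases]
    y_train = np.array([c[2] for c in train_cases], dtype=np.float32)
    y_val = np.array([c[2] for c in val_cases], dtype=int)
    if len(set(train_ids) & set(val_ids)):
        raise DomainError("train and validation case sets must be disjoint")
    for name, y in (("training", y_train), ("validation", y_val)):
        if len(np.unique(y)) < 2:
            raise DegenerateInputError(f"{name} fold contains a single class")
    x_train = _as_array([c[1] for c in train_cases])
    x_val = _as_array([c[1] for c in val_cases])
    packs_train = [c[1] for c in train_cases] if isinstance(train_cases[0][1], SlicePack) else None

    rng = np.random.default_rng([config.seed, fold_id])
    model = build_model(x_train.shape[1], config.dropout, config.base_width,
                        seed=int(rng.integers(2**31)))
    model.dropout_layer.rng = np.random.default_rng([config.seed, fold_id, 1])
    opt = Adam(model.parameters(), lr=config.lr, weight_decay=config.weight_decay)

    best_auc, best_epoch, best_state = -np.inf, -1, model.state_dict()
    since_improve = 0
    history = []
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(train_cases))
        losses = []
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            if packs_train is not None and augment_cfg is not None and augment_cfg.enabled:
                xb = np.stack([augment(packs_train[j], augment_cfg, rng).slices
                               for j in idx]).astype(np.float32)
            else:
                xb = x_train[idx]
            z = model.logits(xb, train=True)
            loss, dz = bce_with_logits(z, y_train[idx])
            opt.zero_grad()
            model.backward(dz)
            opt.step()
            losses.append(loss)
        val_probs = _predict_model(model, x_val, config.batch_size)
        val_auc = mann_whitney_auc(val_probs, y_val)
        history.append({"epoch": epoch, "loss": float(np.mean(losses)),
                        "val_auc": float(val_auc), "lr": opt.lr})
        if val_auc > best_auc + 1e-12:
            best_auc, best_epoch = val_auc, epoch
            best_state = model.state_dict()
            since_improve = 0
        else:
            since_improve += 1
            if since_improve % config.lr_patience == 0:
                opt.lr = max(config.min_lr, opt.lr * config.lr_factor)
            if since_improve >= config.early_stop_patience:
                log.info("fold %d: early stop at epoch %d (best %.3f @ %d)",
                         fold_id, epoch, best_auc, best_epoch)
                break
    return FoldResult(fold_id=fold_id, state=best_state, best_val_auc=float(best_auc),
                      epoch_of_best=best_epoch, train_case_ids=train_ids,
                      val_case_ids=val_ids, history=history)


def crossval_train(cohort, config: TrainConfig,
                   augment_cfg: AugmentConfig | None = None) -> CnnEnsemble:
    """Stratified fivefold cross-validation over ``cohort`` (list of
    (case_id, pack, label)); stores each case's out-of-fold probability."""
    labels = np.array([c[2] for c in cohort], dtype=int)
    if len(cohort) < config.folds:
        raise DegenerateInputError("fewer cases than folds")
    if len(np.unique(labels)) < 2:
        raise DegenerateInputError("cohort contains a single class")
    skf = StratifiedKFold(n_splits=config.folds, shuffle=True, random_state=config.seed)
    folds, oof = [], {}
    for fold_id, (tr, va) in enumerate(skf.split(np.zeros(len(cohort)), labels)):
        fr = train_fold([cohort[i] for i in tr], [cohort[i] for i in va], config,
                        augment_cfg=augment_cfg, fold_id=fold_id)
        x_val = _as_array([cohort[i][1] for i in va])
        model = build_model(x_val.shape[1], config.dropout, config.base_width)
        model.load_state_dict(fr.state)
        probs = _predict_model(model, x_val, config.batch_size)
        for i, p in zip(va, probs):
            oof[cohort[i][0]] = float(p)
        folds.append(fr)
    return CnnEnsemble(folds=folds, config=config, oof_probs=oof)


def predict_proba(ensemble: CnnEnsemble, pack: SlicePack | np.ndarray):
    """Arithmetic mean of the fold models' sigmoid outputs."""
    x = pack.slices if isinstance(pack, SlicePack) else np.asarray(pack, np.float32)
    single = x.ndim == 3
    if single:
        x = x[None]
    if x.shape[1] != ensemble.in_channels:
        raise DomainError(
            f"pack has {x.shape[1]} channels, model expects {ensemble.in_channels}"
        )
    probs = np.mean([_predict_model(m, x) for m in ensemble.models()], axis=0)
    return float(probs[0]) if single else probs


def gradcam(model: ResNet18, pack: SlicePack | np.ndarray, stage: int = 4) -> ActivationMap:
    """Grad-CAM for the cirrhosis logit at the final block of ``stage``:
    channel weights are spatially averaged gradients, the weighted feature
    sum is ReLU-ed and bilinearly upsampled to the input size."""
    x = pack.slices if isinstance(pack, SlicePack) else np.asarray(pack, np.float32)
    if x.ndim == 3:
        x = x[None]
    target = model.last_conv_block(stage)
    _, act = model.forward_with_capture(x.astype(np.float32), target, train=False)
    dact = model.backward_to(np.ones((x.shape[0], 1), dtype=np.float32), target)
    weights = dact.mean(axis=(2, 3))  # (N, C)
    cam = np.maximum((weights[:, :, None, None] * act).sum(axis=1), 0.0)[0]
    heat = _sk_resize(cam.astype(np.float64), x.shape[2:], order=1,
                      preserve_range=True, anti_aliasing=False)
    heat = np.maximum(heat, 0.0)
    if heat.max() <= 0:
        warnings.warn("Grad-CAM: zero gradient everywhere; returning all-zero map")
    else:
        heat = heat / heat.max()
    return ActivationMap(heat=heat.astype(np.float32))


# -------------------------------------------------------------- serialization


def save_ensemble(ensemble: CnnEnsemble, path) -> None:
    """Single-file NPZ archive with config, fold metadata and weights."""
    import dataclasses as dc
    import json

    arrays, meta = {}, {"config": dc.asdict(ensemble.config),
                        "channel_layout": CHANNEL_LAYOUT, "folds": []}
    meta["config"]["sequences"] = list(ensemble.config.sequences)
    for fr in ensemble.folds:
        meta["folds"].append({
            "fold_id": fr.fold_id, "best_val_auc": fr.best_val_auc,
            "epoch_of_best": fr.epoch_of_best, "train_case_ids": fr.train_case_ids,
            "val_case_ids": fr.val_case_ids, "history": fr.history,
        })
        for k, v in fr.state.items():
            arrays[f"fold{fr.fold_id}/{k}"] = v
    meta["oof_probs"] = ensemble.oof_probs
    np.savez_compressed(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_ensemble(path) -> CnnEnsemble:
    import json

    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        cfg_d = meta["config"]
        cfg_d["sequences"] = tuple(cfg_d["sequences"])
        config = TrainConfig(**{k: v for k, v in cfg_d.items()
                                if k in TrainConfig.__dataclass_fields__})
        folds = []
        for fm in meta["folds"]:
            prefix = f"fold{fm['fold_id']}/"
            state = {k[len(prefix):]: z[k] for k in z.files if k.startswith(prefix)}
            folds.append(FoldResult(fold_id=fm["fold_id"], state=state,
                                    best_val_auc=fm["best_val_auc"],
                                    epoch_of_best=fm["epoch_of_best"],
                                    train_case_ids=fm["train_case_ids"],
                                    val_case_ids=fm["val_case_ids"],
                                    history=fm["history"]))
    return CnnEnsemble(folds=folds, config=config, oof_probs=meta["oof_probs"])
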