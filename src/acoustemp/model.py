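"""Temperature regression on mel-spectrogram chunks.

Training follows recording-grouped fivefold cross-validation: all chunks
from one recording share a fold, so the held-out fold never contains audio
from a recording seen in training.  The optimiser is AdamW with a cosine
annealed learning rate (1e-3 -> 1e-4 over the epoch budget) and MSE loss.

Labels are standardised with train-fold statistics inside the loop and
predictions mapped back to degrees C; reported MSE values are always on
the Celsius scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import zoom as _ndzoom

from .augment import AugmentationSpec, augment as _augment
from .nn import AdamW, ResNetRegressor, build_resnet18, build_small_cnn, cosine_annealing_lr, mse_loss
from .segmentation import Chunk, mel_spectrogram

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "FoldSplit",
    "TrainResult",
    "make_folds",
    "build_model",
    "chunk_features",
    "train",
    "predict",
    "aggregate_recording",
]

RESNET_INPUT = 224


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 70
    batch_size: int = 32
    lr_init: float = 1e-3
    lr_final: float = 1e-4
    weight_decay: float = 1e-2
    arch: str = "resnet18"          # "resnet18" | "small"
    pretrained: bool = True
    augmentation: AugmentationSpec | None = field(default_factory=AugmentationSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr_final > self.lr_init:
            raise ValueError("lr_final must not exceed lr_init")
        if self.arch not in ("resnet18", "small"):
            raise ValueError(f"unknown arch {self.arch!r}")


@dataclass
class FoldSplit:
    """Grouped fold assignment: chunk -> fold, via the chunk's recording."""

    n_folds: int
    chunk_folds: np.ndarray              # fold index per chunk
    recording_fold: dict[str, int]       # recording_id -> fold index

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.chunk_folds == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.chunk_folds != fold)

    def fold_sizes(self) -> np.ndarray:
        return np.bincount(self.chunk_folds, minlength=self.n_folds)


def make_folds(
    recording_ids: Sequence[str], n_folds: int = 5, rng: np.random.Generator | None = None
) -> FoldSplit:
    """Assign recordings to folds, balancing chunk counts greedily.

    Recordings are shuffled, ordered by descending chunk count (stable), and
    each is placed in the currently smallest fold; deterministic given rng.
    """
    rng = rng or np.random.default_rng(0)
    rec_ids = np.asarray(recording_ids)
    unique, counts = np.unique(rec_ids, return_counts=True)
    if len(unique) < n_folds:
        raise ValueError(
            f"need at least {n_folds} distinct recordings, got {len(unique)}"
        )
    order = rng.permutation(len(unique))
    order = order[np.argsort(-counts[order], kind="stable")]
    totals = np.zeros(n_folds, dtype=int)
    rec_fold: dict[str, int] = {}
    for i in order:
        f = int(np.argmin(totals))
        rec_fold[str(unique[i])] = f
        totals[f] += counts[i]
    chunk_folds = np.array([rec_fold[str(r)] for r in rec_ids], dtype=int)
    return FoldSplit(n_folds=n_folds, chunk_folds=chunk_folds, recording_fold=rec_fold)


def build_model(
    pretrained: bool = True,
    arch: str = "resnet18",
    rng: np.random.Generator | None = None,
    input_shape: tuple[int, int, int] = (1, 256, 10),
) -> ResNetRegressor:
    """Construct the regressor; the head always has exactly one output.

    Pretrained backbone weights are not shipped; when ``pretrained`` is
    requested the model falls back to random initialisation and records the
    fact on ``model.pretrained_loaded`` and in the log.
    """
    if arch == "resnet18":
        model = build_resnet18(rng=rng)
    else:
        model = build_small_cnn(rng=rng, input_shape=input_shape)
    model.arch = arch
    model.input_shape = input_shape if arch == "small" else (3, RESNET_INPUT, RESNET_INPUT)
    if pretrained:
        logger.warning(
            "pretrained backbone weights unavailable; using random initialisation"
        )
    model.pretrained_loaded = False
    return model


def _resize_bilinear(img: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    h, w = img.shape
    return _ndzoom(img, (out_h / h, out_w / w), order=1, grid_mode=True, mode="nearest")


def chunk_features(
    chunks: Sequence[Chunk], arch: str, input_shape: tuple[int, int, int] = (1, 256, 10)
) -> np.ndarray:
    """Mel-spectrogram feature tensor (N, C, H, W), scaled from dB to [0, 1].

    For the 18-layer backbone the single mel channel is replicated to three
    channels and bilinearly resized to the network's native resolution.
    """
    feats = []
    for ch in chunks:
        m = mel_spectrogram(ch).values
        img = (m + 80.0) / 80.0
        if arch == "resnet18":
            img = _resize_bilinear(img, RESNET_INPUT, RESNET_INPUT)
            feats.append(np.repeat(img[None], 3, axis=0))
        else:
            feats.append(img[None])
    return np.stack(feats)


@dataclass
class TrainResult:
    models: list[ResNetRegressor]
    history: pd.DataFrame                 # fold, epoch, lr, train_mse, test_mse
    best_rmse_per_fold: list[float]       # min over epochs of held-out RMSE
    predictions: pd.DataFrame             # held-out predictions at each fold's best epoch

    @property
    def best_rmse(self) -> float:
        return float(min(self.best_rmse_per_fold))

    @property
    def mean_best_rmse(self) -> float:
        return float(np.mean(self.best_rmse_per_fold))

    @property
    def std_best_rmse(self) -> float:
        return float(np.std(self.best_rmse_per_fold, ddof=1)) if len(
            self.best_rmse_per_fold
        ) > 1 else 0.0


def _forward_batched(model: ResNetRegressor, x: np.ndarray, batch: int = 64) -> np.ndarray:
    out = []
    for i in range(0, len(x), batch):
        out.append(model(x[i : i + batch])[:, 0])
    return np.concatenate(out) if out else np.empty(0)


def train(
    chunks: Sequence[Chunk],
    split: FoldSplit,
    cfg: TrainConfig,
) -> TrainResult:
    """Cross-validated training; returns models, loss curves and held-out
    predictions taken at each fold's best epoch.

    Augmentation (when configured) is applied to training waveforms each
    epoch before feature extraction; held-out chunks are never augmented.
    """
    labels = np.array([c.label_degc for c in chunks], dtype=np.float64)
    rec_ids = np.array([c.recording_id for c in chunks])
    mel_frames = 1 + len(chunks[0].samples) // 512
    input_shape = (1, 256, mel_frames)

    hist_rows = []
    models: list[ResNetRegressor] = []
    best_rmses: list[float] = []
    pred_rows = []
    root_ss = np.random.SeedSequence(cfg.seed)
    fold_seeds = root_ss.spawn(split.n_folds)

    for fold in range(split.n_folds):
        rng = np.random.default_rng(fold_seeds[fold])
        tr_idx = split.train_indices(fold)
        te_idx = split.test_indices(fold)
        if tr_idx.size == 0:
            raise ValueError(f"fold {fold}: empty training set")
        # leak check: grouped folds must keep recordings disjoint
        assert not set(rec_ids[tr_idx]) & set(rec_ids[te_idx])

        mu = labels[tr_idx].mean()
        sd = labels[tr_idx].std()
        if sd < 1e-8:
            sd = 1.0
        model = build_model(
            pretrained=cfg.pretrained, arch=cfg.arch, rng=rng, input_shape=input_shape
        )
        model.label_mean, model.label_std = float(mu), float(sd)
        opt = AdamW(model.parameters(), lr=cfg.lr_init, weight_decay=cfg.weight_decay)

        x_test = chunk_features([chunks[i] for i in te_idx], cfg.arch, input_shape)
        y_test = labels[te_idx]
        x_train_clean = None
        if cfg.augmentation is None:
            x_train_clean = chunk_features([chunks[i] for i in tr_idx], cfg.arch, input_shape)

        best_rmse = np.inf
        best_preds = None
        for epoch in range(cfg.epochs):
            opt.lr = cosine_annealing_lr(epoch, cfg.epochs, cfg.lr_init, cfg.lr_final)
            if cfg.augmentation is not None:
                aug = [_augment(chunks[i], cfg.augmentation, rng) for i in tr_idx]
                x_train = chunk_features(aug, cfg.arch, input_shape)
            else:
                x_train = x_train_clean
            y_train = (labels[tr_idx] - mu) / sd

            model.train()
            order = rng.permutation(len(tr_idx))
            epoch_losses = []
            for i in range(0, len(order), cfg.batch_size):
                sel = order[i : i + cfg.batch_size]
                model.zero_grad()
                pred = model(x_train[sel])[:, 0]
                loss, dloss = mse_loss(pred, y_train[sel])
                model.backward(dloss[:, None])
                opt.step()
                epoch_losses.append(loss)
            train_mse = float(np.mean(epoch_losses)) * sd**2

            model.eval()
            preds = _forward_batched(model, x_test) * sd + mu
            test_mse = float(np.mean((preds - y_test) ** 2))
            hist_rows.append(
                {"fold": fold, "epoch": epoch, "lr": opt.lr,
                 "train_mse": train_mse, "test_mse": test_mse}
            )
            if np.sqrt(test_mse) < best_rmse:
                best_rmse = float(np.sqrt(test_mse))
                best_preds = preds.copy()

        models.append(model)
        best_rmses.append(best_rmse)
        for j, i_chunk in enumerate(te_idx):
            pred_rows.append(
                {"chunk_id": int(i_chunk), "recording_id": rec_ids[i_chunk],
                 "truth": labels[i_chunk], "prediction": best_preds[j], "fold": fold}
            )
        logger.info("fold %d: best held-out RMSE %.3f degC", fold, best_rmse)

    return TrainResult(
        models=models,
        history=pd.DataFrame(hist_rows),
        best_rmse_per_fold=best_rmses,
        predictions=pd.DataFrame(pred_rows),
    )


def save_model(model: ResNetRegressor, path) -> None:
    """Serialise parameters, running statistics and metadata to ``.npz``."""
    import json

    arrays = {}
    for i, p in enumerate(model.parameters()):
        arrays[f"param_{i}"] = p.value
    from .nn import BatchNorm2d

    bn_idx = 0
    for m in model.modules():
        if isinstance(m, BatchNorm2d):
            arrays[f"bn_{bn_idx}_mean"] = m.running_mean
            arrays[f"bn_{bn_idx}_var"] = m.running_var
            bn_idx += 1
    meta = {
        "arch": getattr(model, "arch", "small"),
        "input_shape": list(getattr(model, "input_shape", (1, 256, 10))),
        "label_mean": getattr(model, "label_mean", 0.0),
        "label_std": getattr(model, "label_std", 1.0),
        "pretrained_loaded": bool(getattr(model, "pretrained_loaded", False)),
    }
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_model(path) -> ResNetRegressor:
    """Rebuild a saved regressor from ``.npz``."""
    import json

    data = np.load(path)
    meta = json.loads(bytes(data["meta_json"]).decode())
    model = build_model(
        pretrained=False,
        arch=meta["arch"],
        input_shape=tuple(meta["input_shape"]),
    )
    for i, p in enumerate(model.parameters()):
        p.value[...] = data[f"param_{i}"]
    from .nn import BatchNorm2d

    bn_idx = 0
    for m in model.modules():
        if isinstance(m, BatchNorm2d):
            m.running_mean[...] = data[f"bn_{bn_idx}_mean"]
            m.running_var[...] = data[f"bn_{bn_idx}_var"]
            bn_idx += 1
    model.label_mean = meta["label_mean"]
    model.label_std = meta["label_std"]
    model.pretrained_loaded = meta["pretrained_loaded"]
    return model


def predict(model: ResNetRegressor, chunks: Sequence[Chunk]) -> np.ndarray:
    """Per-chunk temperature predictions in degrees C."""
    if not chunks:
        return np.empty(0)
    model.eval()
    x = chunk_features(chunks, model.arch, model.input_shape)
    mu = getattr(model, "label_mean", 0.0)
    sd = getattr(model, "label_std", 1.0)
    return _forward_batched(model, x) * sd + mu


def aggregate_recording(
    chunk_predictions: np.ndarray,
    center_times: np.ndarray,
    L1: float,
    L2: float,
) -> float | None:
    """Recording-level prediction: mean over forward-motion chunks.

    Chunks whose centre lies outside [L1, L2] (e.g. the initiation pulse)
    are excluded; with no qualifying chunks the prediction is undefined and
    ``None`` is returned.
    """
    t = np.asarray(center_times, dtype=np.float64)
    p = np.asarray(chunk_predictions, dtype=np.float64)
    mask = (t >= L1) & (t <= L2)
    if not np.any(mask):
        return None
    return float(np.mean(p[mask]))
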