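"""Dataset splitting, training, evaluation, and the full comparison experiment.

Training follows a fixed protocol: Adam (lr 0.001, beta1 0.9, beta2 0.9,
eps 1e-7) on the combined BCE+Dice loss, shuffled mini-batches, and
best-model selection by the highest validation Dice coefficient across
epochs.  Every stage is driven by seeds fanned out from one master seed,
so a whole experiment is reproducible end to end.

Splits use floor arithmetic — validation and test each get
floor(frac * n) samples and the remainder goes to training — which is
what turns 3818 samples under an 80:10:10 ratio into 3056/381/381.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .layers import Adam
from .network import NetworkConfig, SegmentationModel, build_model
from .objectives import (
    ConfusionCounts,
    binarize,
    combined_loss_grad,
    compute_metrics,
    metrics_from_counts,
    DEFAULT_THRESHOLD,
    DICE_SMOOTH,
)
from .phantom import PhantomConfig, PhantomSample, generate_dataset
from .preprocess import AugmentParams, ClaheParams, balance_classes, clahe_enhance, resize_normalize  # noqa: F401  (AugmentParams is part of the config surface)
from .stats_compare import compare_models

__all__ = [
    "SplitSpec",
    "TrainConfig",
    "TrainResult",
    "split_dataset",
    "train",
    "evaluate",
    "save_checkpoint",
    "load_checkpoint",
    "ExperimentConfig",
    "run_experiment",
]

HISTORY_FIELDS = (
    "accuracy",
    "loss",
    "dice_loss",
    "dice_coefficient",
    "sensitivity",
    "specificity",
    "f1",
    "precision",
)


@dataclass
class SplitSpec:
    train_frac: float = 0.8
    val_frac: float = 0.1
    test_frac: float = 0.1
    stratify_by_class: bool = True
    seed: int = 0

    def __post_init__(self):
        if abs(self.train_frac + self.val_frac + self.test_frac - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if min(self.train_frac, self.val_frac, self.test_frac) <= 0:
            raise ValueError("all split fractions must be positive")


def _split_indices(n: int, spec: SplitSpec, rng: np.random.Generator):
    n_val = int(np.floor(spec.val_frac * n))
    n_test = int(np.floor(spec.test_frac * n))
    perm = rng.permutation(n)
    return perm[:n_val], perm[n_val : n_val + n_test], perm[n_val + n_test :]


def split_dataset(manifest: pd.DataFrame, spec: SplitSpec):
    """Split a manifest into (train, val, test) frames by the configured ratio.

    Validation and test sizes are floor(frac*n); the remainder trains.  With
    stratification the floor rule applies within each class.
    """
    if len(manifest) == 0:
        raise ValueError("manifest is empty")
    if spec.stratify_by_class and "label" in manifest.columns:
        ss = np.random.SeedSequence(spec.seed)
        val_parts, test_parts, train_parts = [], [], []
        classes = sorted(manifest["label"].unique())
        for label, child in zip(classes, ss.spawn(len(classes))):
            sub = manifest.index[manifest["label"] == label].to_numpy()
            v, t, tr = _split_indices(len(sub), spec, np.random.default_rng(child))
            val_parts.append(sub[v])
            test_parts.append(sub[t])
            train_parts.append(sub[tr])
        val_idx = np.concatenate(val_parts)
        test_idx = np.concatenate(test_parts)
        train_idx = np.concatenate(train_parts)
    else:
        v, t, tr = _split_indices(len(manifest), spec, np.random.default_rng(spec.seed))
        idx = manifest.index.to_numpy()
        val_idx, test_idx, train_idx = idx[v], idx[t], idx[tr]
    parts = tuple(manifest.loc[i] for i in (train_idx, val_idx, test_idx))
    if any(len(p) == 0 for p in parts):
        raise ValueError(
            f"split of {len(manifest)} samples at "
            f"{self_ratio(spec)} leaves an empty subset"
        )
    return parts


def self_ratio(spec: SplitSpec) -> str:
    return f"{spec.train_frac:.0%}:{spec.val_frac:.0%}:{spec.test_frac:.0%}"


@dataclass
class TrainConfig:
    epochs: int = 300
    batch_size: int = 32
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.9
    epsilon: float = 1e-7
    shuffle: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


@dataclass
class TrainResult:
    history: pd.DataFrame
    best_epoch: int
    best_val_dice: float
    best_state: dict


def _epoch_metrics(counts, loss_sum, n_pix, inter, psum, gsum) -> dict:
    rec = metrics_from_counts(counts)
    d = rec.to_dict()
    d["loss"] = loss_sum / max(n_pix, 1)
    d["dice_loss"] = 1.0 - (2.0 * inter + DICE_SMOOTH) / (psum + gsum + DICE_SMOOTH)
    return d


def train(
    model: SegmentationModel,
    train_images: np.ndarray,
    train_masks: np.ndarray,
    val_images: np.ndarray,
    val_masks: np.ndarray,
    config: TrainConfig,
    threshold: float = DEFAULT_THRESHOLD,
) -> TrainResult:
    """Train with Adam on BCE+Dice; keep the weights of the best validation Dice.

    Images are (N, H, W) floats in [0,1]; masks are (N, H, W) in {0,1}.
    The per-epoch history records all eight tracked quantities on both the
    training batches and the validation set.
    """
    opt = Adam(
        model.parameters(),
        lr=config.learning_rate,
        beta1=config.beta1,
        beta2=config.beta2,
        eps=config.epsilon,
    )
    rng = np.random.default_rng(config.seed)
    model.reseed_dropout(int(rng.integers(2**31)))
    n = len(train_images)
    rows = []
    best = (-1.0, -1, None)  # (val dice, epoch, state)
    for epoch in range(config.epochs):
        model.train()
        order = rng.permutation(n) if config.shuffle else np.arange(n)
        counts = ConfusionCounts()
        loss_sum = 0.0
        n_pix = 0
        inter = psum = gsum = 0.0
        for start in range(0, n, config.batch_size):
            sel = order[start : start + config.batch_size]
            xb = train_images[sel][..., None].astype(np.float32)
            yb = train_masks[sel].astype(np.float32)
            out = model.forward(xb)
            prob = out.data[..., 0]
            loss, grad = combined_loss_grad(prob, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss ({loss}) at epoch {epoch}, batch {start // config.batch_size}"
                )
            opt.zero_grad()
            out.backward(grad[..., None])
            opt.step()
            pred = prob > threshold
            counts = counts + ConfusionCounts.from_masks(pred, yb)
            loss_sum += loss * prob.size
            n_pix += prob.size
            inter += float((prob * yb).sum())
            psum += float(prob.sum())
            gsum += float(yb.sum())
        train_rec = _epoch_metrics(counts, loss_sum, n_pix, inter, psum, gsum)

        val_prob = model.predict(val_images, batch_size=config.batch_size)
        val_rec = compute_metrics(val_prob, val_masks, threshold).to_dict()

        row = {"epoch": epoch}
        row.update({f"train_{k}": train_rec.get(k) for k in HISTORY_FIELDS})
        row.update({f"val_{k}": val_rec.get(k) for k in HISTORY_FIELDS})
        rows.append(row)

        val_dice = val_rec.get("dice_coefficient")
        val_dice = -0.5 if val_dice is None else val_dice
        if val_dice > best[0]:
            best = (val_dice, epoch, {k: v.copy() for k, v in model.state_arrays().items()})

    if best[2] is not None:
        model.load_state_arrays(best[2])
    return TrainResult(
        history=pd.DataFrame(rows),
        best_epoch=best[1],
        best_val_dice=best[0],
        best_state=best[2],
    )


def evaluate(
    model: SegmentationModel,
    images: np.ndarray,
    masks: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
):
    """Micro-averaged metrics over all pixels, per-image records, binarized masks."""
    prob = model.predict(images)
    overall = compute_metrics(prob, masks, threshold)
    preds = binarize(prob, threshold)
    per_image = pd.DataFrame(
        [
            {"index": i, **compute_metrics(prob[i], masks[i], threshold).to_dict()}
            for i in range(len(images))
        ]
    )
    return overall, per_image, preds


def save_checkpoint(model: SegmentationModel, path: str) -> None:
    """Model weights as npz plus a JSON sidecar with the config and seed."""
    np.savez(path, **model.state_arrays())
    sidecar = {"network": asdict(model.config), "seed": model.seed}
    with open(os.fspath(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_checkpoint(path: str) -> SegmentationModel:
    with open(os.fspath(path) + ".json") as fh:
        sidecar = json.load(fh)
    net = dict(sidecar["network"])
    net["input_size"] = tuple(net["input_size"])
    model = build_model(NetworkConfig(**net), seed=sidecar["seed"])
    with np.load(path if os.fspath(path).endswith(".npz") else os.fspath(path) + ".npz") as data:
        model.load_state_arrays({k: data[k] for k in data.files})
    return model


# ---------------------------------------------------------------------------
# end-to-end experiment


@dataclass
class ExperimentConfig:
    """One comparison study: generate phantoms, train each variant, compare."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    modes: tuple = ("plain", "watunet")
    threshold: float = DEFAULT_THRESHOLD
    apply_clahe: bool = True
    clahe: ClaheParams = field(default_factory=ClaheParams)
    augment: AugmentParams | None = None
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        if len(self.modes) < 2:
            raise ValueError("an experiment needs at least two model variants")


@dataclass
class ExperimentResult:
    metrics: pd.DataFrame  # one row per model variant, test-set micro metrics
    comparison: pd.DataFrame  # pairwise McNemar + BH table
    histories: dict
    predictions: dict
    splits: tuple
    failures: dict = field(default_factory=dict)  # mode -> exception, if any variant failed


def _fan_out(master_seed: int, n: int) -> list[int]:
    """Derive n independent 31-bit sub-seeds from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(c.generate_state(1)[0] & 0x7FFFFFFF) for c in ss.spawn(n)]


def _prepare(samples, indices, cfg: ExperimentConfig):
    images, masks = [], []
    for i in indices:
        s = samples[i]
        img = clahe_enhance(s.image, cfg.clahe) if cfg.apply_clahe else s.image
        im, mk = resize_normalize(img, s.mask, target=cfg.network.input_size)
        images.append(im)
        masks.append(mk)
    return np.stack(images), np.stack(masks)


def desk_scale_config(seed: int = 0, modes: tuple = ("plain", "watunet")) -> ExperimentConfig:
    """CPU-scale study preset: 200 phantoms at 64x64, narrow network, 15 epochs.

    Small enough to train in minutes on one core while preserving the full
    architecture (depth 4, all gate types); used by the test suite and the
    reproduction script.
    """
    return ExperimentConfig(
        phantom=PhantomConfig(n_samples=200, image_size=(64, 64)),
        train=TrainConfig(epochs=15, batch_size=8),
        network=NetworkConfig(depth=4, base_channels=8, input_size=(64, 64)),
        modes=modes,
        seed=seed,
    )


def run_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Generate data once, train every skip-mode variant on identical splits,
    evaluate on the shared test set, and run the pairwise comparison."""
    seeds = _fan_out(cfg.seed, 3 + len(cfg.modes))
    phantom_cfg = PhantomConfig(**{**asdict(cfg.phantom), "seed": seeds[0]})
    samples, manifest = generate_dataset(phantom_cfg)
    split_spec = SplitSpec(**{**asdict(cfg.split), "seed": seeds[1]})
    tr_df, va_df, te_df = split_dataset(manifest, split_spec)

    train_samples = [samples[i] for i in tr_df.index]
    if cfg.augment is not None:
        # per-class augmentation to the majority-class count (training split only)
        aug_rng = np.random.default_rng(seeds[2])
        target = int(tr_df["label"].value_counts().max())
        triples = balance_classes(train_samples, target, cfg.augment, aug_rng)
        train_samples = [PhantomSample(image=im, mask=mk, label=lb) for im, mk, lb in triples]

    def prep_list(sample_list):
        images, masks = [], []
        for s in sample_list:
            img = clahe_enhance(s.image, cfg.clahe) if cfg.apply_clahe else s.image
            im, mk = resize_normalize(img, s.mask, target=cfg.network.input_size)
            images.append(im)
            masks.append(mk)
        return np.stack(images), np.stack(masks)

    x_tr, y_tr = prep_list(train_samples)
    x_va, y_va = prep_list([samples[i] for i in va_df.index])
    x_te, y_te = prep_list([samples[i] for i in te_df.index])

    metrics_rows = []
    histories = {}
    predictions = {}
    failures = {}
    for mode, mode_seed in zip(cfg.modes, seeds[3:]):
        try:
            net_cfg = NetworkConfig(**{**asdict(cfg.network), "skip_mode": mode})
            model = build_model(net_cfg, seed=mode_seed)
            train_cfg = TrainConfig(**{**asdict(cfg.train), "seed": mode_seed})
            result = train(model, x_tr, y_tr, x_va, y_va, train_cfg, threshold=cfg.threshold)
            overall, _, preds = evaluate(model, x_te, y_te, threshold=cfg.threshold)
        except Exception as exc:  # isolate per-variant failures
            failures[mode] = exc
            continue
        histories[mode] = result.history
        predictions[mode] = preds
        metrics_rows.append(
            {
                "model": mode,
                "best_epoch": result.best_epoch,
                "best_val_dice": result.best_val_dice,
                **{k: v for k, v in overall.to_dict().items()},
            }
        )
    if failures and len(predictions) < 2:
        done = sorted(predictions)
        raise RuntimeError(
            f"experiment cannot proceed: completed variants {done}; "
            f"failures: " + "; ".join(f"{m}: {e}" for m, e in failures.items())
        )
    metrics = pd.DataFrame(metrics_rows)
    comparison = compare_models(predictions, y_te, alpha=0.05)

    if cfg.out_dir:
        os.makedirs(cfg.out_dir, exist_ok=True)
        metrics.to_csv(os.path.join(cfg.out_dir, "metrics.csv"), index=False)
        comparison.to_csv(os.path.join(cfg.out_dir, "comparison.csv"), index=False)
        for mode, hist in histories.items():
            hist.to_csv(os.path.join(cfg.out_dir, f"history_{mode}.csv"), index=False)
    return ExperimentResult(
        metrics=metrics,
        comparison=comparison,
        histories=histories,
        predictions=predictions,
        splits=(tr_df, va_df, te_df),
        failures=failures,
    )
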