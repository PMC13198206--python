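"""Training and evaluation engine: balanced batch assembly, the per-
iteration semi-supervised step, validation-driven early stopping, ablation
switches, and balanced-accuracy metrics."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import losses as L
from .augment import AugmentConfig, augment_channel, center_crop, jitter_rgb
from .nets import DualEncoder, save_checkpoint
from .nn import RMSProp, Tensor
from .stainsep import (ChannelPair, RGBTile, StainBasis, fit_slide_basis,
                       fixed_default_basis, separate_tile)
from .synthesis import DatasetManifest

__all__ = [
    "TrainConfig",
    "EvalReport",
    "balanced_batch",
    "make_views",
    "train_step",
    "fit",
    "evaluate",
    "predict_tiles",
    "fit_all_bases",
    "balanced_accuracy_from_confusion",
]

VIEW_MODES = ("HE", "RedGreen", "RedBlue", "GreenBlue")
_RGB_INDEX = {"Red": 0, "Green": 1, "Blue": 2}


@lru_cache(maxsize=1)
def _fixed_basis_cached():
    return fixed_default_basis()


@dataclass(frozen=True)
class TrainConfig:
    """Every training hyperparameter plus the ablation switches.

    Defaults reproduce the full-scale configuration (batch 64, 8 labeled
    per class over 4 classes, 1000 iterations/epoch, patience 100,
    RMSProp at 1e-4 with per-epoch decay).  Use :meth:`desk` for a
    CPU-scale profile.
    """

    batch_size: int = 64
    labeled_per_class: int = 8
    n_classes: int = 4
    iterations_per_epoch: int = 1000
    max_epochs: int = 10_000
    patience_epochs: int = 100
    learning_rate: float = 1e-4
    lr_decay: float = 0.97
    optimizer: str = "rmsprop"
    weights: L.LossWeights = field(default_factory=L.LossWeights)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    view_mode: str = "HE"
    use_mixup: bool = True
    use_contrastive: bool = True
    use_rgb_aug: bool = True
    use_adaptive_stains: bool = True
    use_projection_heads: bool = False
    contrastive_kind: str = "triplet"  # or "infonce"
    contrastive_reduction: str = "mean"
    # linear ramp-up of the unlabeled squared-loss weight over this many
    # epochs (standard MixMatch practice; 0 disables the ramp)
    lambda_u_rampup_epochs: float = 16.0
    encoder: str = "small"
    feature_dim: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.view_mode not in VIEW_MODES:
            raise ValueError(f"view_mode must be one of {VIEW_MODES}")
        if self.contrastive_kind not in ("triplet", "infonce"):
            raise ValueError("contrastive_kind must be triplet or infonce")
        if self.labeled_per_batch > self.batch_size:
            raise ValueError("labeled_per_batch exceeds batch_size")
        if self.patience_epochs < 1:
            raise ValueError("patience must be >= 1")

    @property
    def labeled_per_batch(self) -> int:
        return self.labeled_per_class * self.n_classes

    @classmethod
    def desk(cls, n_classes: int = 3, **overrides) -> "TrainConfig":
        """CPU desk-scale profile for the synthetic datasets."""
        defaults = dict(
            batch_size=24,
            labeled_per_class=4,
            n_classes=n_classes,
            iterations_per_epoch=50,
            max_epochs=10,
            patience_epochs=5,
            learning_rate=1e-3,
            weights=L.LossWeights(lambda_u=1.5, lambda_c=0.2, margin=4.0,
                                  temperature=0.5, beta_alpha=2.0, k_augment=2),
            augment=AugmentConfig(crop_size=32),
            feature_dim=32,
            lambda_u_rampup_epochs=5.0,
        )
        defaults.update(overrides)
        return cls(**defaults)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "weights" in raw and isinstance(raw["weights"], dict):
            raw["weights"] = L.LossWeights(**raw["weights"])
        if "augment" in raw and isinstance(raw["augment"], dict):
            aug = {
                k: tuple(v) if isinstance(v, list) else v
                for k, v in raw["augment"].items()
            }
            raw["augment"] = AugmentConfig(**aug)
        return cls(**raw)


@dataclass
class EvalReport:
    """Per-class metrics; balanced accuracy is the mean of per-class recalls."""

    class_names: list[str]
    confusion: np.ndarray  # rows = truth, cols = prediction
    recalls: dict[str, float]
    precisions: dict[str, float]
    fscores: dict[str, float]
    balanced_accuracy: float
    missing_classes: list[str] = field(default_factory=list)
    seed: int = 0
    config_hash: str = ""

    def to_dict(self) -> dict:
        return {
            "class_names": self.class_names,
            "confusion": self.confusion.tolist(),
            "recalls": self.recalls,
            "precisions": self.precisions,
            "fscores": self.fscores,
            "balanced_accuracy": self.balanced_accuracy,
            "missing_classes": self.missing_classes,
            "seed": self.seed,
            "config_hash": self.config_hash,
        }


def balanced_accuracy_from_confusion(confusion: np.ndarray
                                     ) -> tuple[float, np.ndarray]:
    """Mean per-class recall over classes present in the truth rows."""
    confusion = np.asarray(confusion, dtype=float)
    support = confusion.sum(axis=1)
    present = support > 0
    recalls = np.divide(np.diag(confusion), support,
                        out=np.full(len(confusion), np.nan), where=present)
    return float(np.nanmean(recalls[present])), recalls


# ---------------------------------------------------------------------------
# Batch assembly and views
# ---------------------------------------------------------------------------


def balanced_batch(labeled_by_class: Mapping[str, Sequence[int]],
                   unlabeled_pool: Sequence[int], config: TrainConfig,
                   rng: np.random.Generator
                   ) -> tuple[list[tuple[int, str]], list[int]]:
    """Draw a class-balanced batch: exactly ``labeled_per_class`` tiles per
    class (with replacement when a pool is small), remainder unlabeled."""
    labeled: list[tuple[int, str]] = []
    for cls in sorted(labeled_by_class):
        pool = list(labeled_by_class[cls])
        if not pool:
            raise ValueError(f"class {cls!r} has no labeled tiles")
        replace_draw = len(pool) < config.labeled_per_class
        picks = rng.choice(len(pool), size=config.labeled_per_class,
                           replace=replace_draw)
        labeled.extend((pool[int(i)], cls) for i in picks)
    n_unlabeled = config.batch_size - len(labeled)
    unlabeled: list[int] = []
    if n_unlabeled > 0 and len(unlabeled_pool) > 0:
        picks = rng.choice(len(unlabeled_pool), size=n_unlabeled,
                           replace=len(unlabeled_pool) < n_unlabeled)
        unlabeled = [unlabeled_pool[int(i)] for i in picks]
    return labeled, unlabeled


def make_views(tile: RGBTile, basis: StainBasis | None,
               config: TrainConfig) -> ChannelPair:
    """Produce the two input views: H/E separation (default) or a raw
    RGB channel pair (ablation)."""
    if config.view_mode == "HE":
        if config.use_adaptive_stains:
            if basis is None:
                raise ValueError("adaptive HE views require a slide basis")
            use_basis = basis
        else:
            use_basis = _fixed_basis_cached()
        return separate_tile(tile, use_basis)
    first, second = {
        "RedGreen": ("Red", "Green"),
        "RedBlue": ("Red", "Blue"),
        "GreenBlue": ("Green", "Blue"),
    }[config.view_mode]
    px = np.asarray(tile.pixels, dtype=float) / tile.background_intensity
    return ChannelPair(px[..., _RGB_INDEX[first]], px[..., _RGB_INDEX[second]],
                       basis_ref=tile.slide_id)


def _train_views(tile: RGBTile, basis: StainBasis | None, config: TrainConfig,
                 rng: np.random.Generator) -> ChannelPair:
    """Full stochastic pipeline: RGB jitter -> views -> independent H/E
    channel augmentation."""
    if config.use_rgb_aug:
        tile = jitter_rgb(tile, config.augment, rng)
    pair = make_views(tile, basis, config)
    h = augment_channel(pair.h_image, config.augment, rng)
    e = augment_channel(pair.e_image, config.augment, rng)
    return ChannelPair(h, e, pair.basis_ref)


def _eval_views(tile: RGBTile, basis: StainBasis | None,
                config: TrainConfig) -> ChannelPair:
    """Deterministic preprocessing: views + center crop, no jitter."""
    pair = make_views(tile, basis, config)
    size = config.augment.crop_size
    if size == 0:
        return pair
    return ChannelPair(center_crop(pair.h_image, size),
                       center_crop(pair.e_image, size), pair.basis_ref)


def _stack(pairs: Sequence[ChannelPair]) -> tuple[np.ndarray, np.ndarray]:
    h = np.stack([p.h_image for p in pairs])[:, None, :, :]
    e = np.stack([p.e_image for p in pairs])[:, None, :, :]
    return h, e


# ---------------------------------------------------------------------------
# Training step
# ---------------------------------------------------------------------------


def _pseudo_labels_batched(model, tiles_in, basis_for, config: TrainConfig,
                           rng: np.random.Generator
                           ) -> list[L.LabelDistribution]:
    """Pseudo-labels for a set of unlabeled tiles in one forward pass.

    Semantically identical to calling :func:`classm.losses.pseudo_label`
    per tile (K fresh full-pipeline augmentations each, average, sharpen),
    but all K * n views share one batched forward for speed.
    """
    if not tiles_in:
        return []
    w = config.weights
    pairs = []
    for tile in tiles_in:
        for _ in range(w.k_augment):
            pairs.append(_train_views(tile, basis_for(tile), config, rng))
    h, e = _stack(pairs)
    probs = model.forward(h, e).probs.data  # detached
    probs = probs.reshape(len(tiles_in), w.k_augment, -1).mean(axis=1)
    return [
        L.LabelDistribution(L.sharpen(p, w.temperature), "pseudo")
        for p in probs
    ]


def train_step(model: DualEncoder, optimizer: RMSProp,
               labeled: Sequence[tuple[RGBTile, int]],
               unlabeled: Sequence[RGBTile],
               bases: Mapping[str, StainBasis], config: TrainConfig,
               rng: np.random.Generator) -> dict[str, float]:
    """One optimization step of the semi-supervised objective.

    ``labeled`` holds (tile, class index) pairs; ``unlabeled`` raw tiles.
    Honors the ablation flags: without MixUp, unlabeled samples contribute
    only through the contrastive term; without the contrastive term and
    MixUp, the step reduces to plain supervised cross-entropy training.
    """
    w = config.weights
    n_classes = config.n_classes

    def basis_for(tile: RGBTile) -> StainBasis | None:
        return bases.get(tile.slide_id)

    lab_pairs = [_train_views(t, basis_for(t), config, rng) for t, _ in labeled]
    lab_labels = [L.LabelDistribution.one_hot(c, n_classes) for _, c in labeled]

    use_unlabeled = (config.use_mixup or config.use_contrastive) and unlabeled
    unl_tiles = list(unlabeled) if use_unlabeled else []
    unl_pairs = [_train_views(t, basis_for(t), config, rng) for t in unl_tiles]

    if config.use_mixup:
        unl_labels = _pseudo_labels_batched(model, unl_tiles, basis_for,
                                            config, rng)
        virt_l, virt_u = L.mixup_batch(
            list(zip(lab_pairs, lab_labels)),
            list(zip(unl_pairs, unl_labels)),
            w.beta_alpha, rng,
        )
        fwd_pairs = [ChannelPair(v.h_image, v.e_image) for v in virt_l + virt_u]
        labels_l = np.stack([v.label.probs for v in virt_l])
        labels_u = (np.stack([v.label.probs for v in virt_u])
                    if virt_u else None)
        n_l, n_u = len(virt_l), len(virt_u)
    else:  # CLASS variant: unlabeled enter only through the contrastive term
        fwd_pairs = lab_pairs + unl_pairs
        labels_l = np.stack([y.probs for y in lab_labels])
        labels_u = None
        n_l, n_u = len(lab_pairs), 0

    h, e = _stack(fwd_pairs)
    result = model.forward(h, e)
    pred_l = result.probs.take_rows(np.arange(n_l))
    pred_u = (result.probs.take_rows(np.arange(n_l, n_l + n_u))
              if n_u else None)

    contrastive = None
    contrastive_value = 0.0
    if config.use_contrastive and len(fwd_pairs) >= 2:
        f_h = result.z_h if result.z_h is not None else result.f_h
        f_e = result.z_e if result.z_e is not None else result.f_e
        if config.contrastive_kind == "triplet":
            partners = L.contrastive_negatives(len(fwd_pairs), rng)
            contrastive = L.triplet_contrastive(
                f_h, f_e, f_e.take_rows(partners), w.margin
            )
            contrastive_value = float(contrastive.data.mean())
        else:
            contrastive = L.infonce_contrastive(f_h, f_e, w.temperature)
            contrastive_value = float(contrastive.data)
            # already a scalar; reduction flags do not apply
    loss = L.total_loss(pred_l, labels_l, pred_u, labels_u, contrastive,
                        w, n_classes,
                        contrastive_reduction=config.contrastive_reduction)
    if not np.isfinite(loss.data):
        raise FloatingPointError(f"non-finite training loss: {loss.data}")

    optimizer.zero_grad()
    loss.backward()
    optimizer.step()

    ce_value = float(L.cross_entropy(Tensor(pred_l.data), labels_l).data)
    u_value = 0.0
    if pred_u is not None:
        u_value = float(
            (((pred_u.data - labels_u) ** 2).sum(axis=1) / n_classes).mean()
        )
    return {
        "total": float(loss.data),
        "cross_entropy": ce_value,
        "unlabeled": u_value,
        "contrastive": contrastive_value,
    }


# ---------------------------------------------------------------------------
# Fit / evaluate / predict
# ---------------------------------------------------------------------------


def _label_index(manifest: DatasetManifest) -> dict[str, int]:
    return {name: i for i, name in enumerate(manifest.class_names)}


def _probe_distances(model: DualEncoder, h: np.ndarray, e: np.ndarray
                     ) -> tuple[float, float]:
    """Mean positive-pair and negative-pair H/E feature distances on a
    frozen probe batch (negatives via a fixed cyclic shift)."""
    result = model.forward(h, e)
    f_h, f_e = result.f_h.data, result.f_e.data
    d_pos = np.linalg.norm(f_h - f_e, axis=1).mean()
    d_neg = np.linalg.norm(f_h - np.roll(f_e, 1, axis=0), axis=1).mean()
    return float(d_pos), float(d_neg)


def fit(model: DualEncoder, manifest: DatasetManifest, tiles,
        bases: Mapping[str, StainBasis], config: TrainConfig,
        out_dir=None, track_probe: bool = False):
    """Epoch loop with per-epoch balanced validation accuracy and early
    stopping; returns ``(best_state_arrays, log)`` and restores the best
    parameters into ``model``.

    ``tiles`` is any store with ``get(tile_path) -> RGBTile``.
    """
    rng = np.random.default_rng(config.seed)
    label_idx = _label_index(manifest)

    train_rows = manifest.rows("train_labeled")
    if train_rows.empty:
        raise ValueError("no labeled training tiles")
    val_rows = manifest.rows("val")
    if val_rows.empty:
        raise ValueError("no validation tiles")
    unl_rows = manifest.rows("train_unlabeled")

    labeled_by_class: dict[str, list[int]] = {
        cls: list(idx)
        for cls, idx in train_rows.groupby("label").groups.items()
    }
    if set(labeled_by_class) != set(manifest.class_names):
        missing = set(manifest.class_names) - set(labeled_by_class)
        raise ValueError(f"classes without labeled tiles: {sorted(missing)}")
    unlabeled_pool = list(range(len(unl_rows)))

    optimizer = RMSProp(model.parameters(), lr=config.learning_rate)

    probe_h = probe_e = None
    if track_probe:
        # fixed random class-mixed probe batch (val frame is class-blocked,
        # so taking the head would make every negative pair same-class)
        probe_rng = np.random.default_rng(config.seed + 991)
        n_probe = min(16, len(val_rows))
        probe_idx = probe_rng.choice(len(val_rows), size=n_probe,
                                     replace=False)
        probe_rows = val_rows.iloc[np.sort(probe_idx)]
        probe_pairs = [
            _eval_views(tiles.get(r.tile_path), bases.get(r.slide_id), config)
            for r in probe_rows.itertuples()
        ]
        probe_h, probe_e = _stack(probe_pairs)

    log: list[dict] = []
    best_acc = -np.inf
    best_state = model.state_arrays()
    best_epoch = -1
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    if track_probe:
        d_pos, d_neg = _probe_distances(model, probe_h, probe_e)
        log.append({"epoch": -1, "probe_pos_dist": d_pos,
                    "probe_neg_dist": d_neg, "seed": config.seed})

    for epoch in range(config.max_epochs):
        t0 = time.time()
        if config.lambda_u_rampup_epochs > 0:
            ramp = min(1.0, (epoch + 1) / config.lambda_u_rampup_epochs)
            epoch_config = dataclasses.replace(
                config,
                weights=dataclasses.replace(
                    config.weights,
                    lambda_u=config.weights.lambda_u * ramp,
                ),
            )
        else:
            epoch_config = config
        sums = {"total": 0.0, "cross_entropy": 0.0, "unlabeled": 0.0,
                "contrastive": 0.0}
        for _ in range(config.iterations_per_epoch):
            lab, unl = balanced_batch(labeled_by_class, unlabeled_pool,
                                      config, rng)
            labeled_batch = [
                (tiles.get(train_rows.loc[i, "tile_path"]),
                 label_idx[cls])
                for i, cls in lab
            ]
            unlabeled_batch = [
                tiles.get(unl_rows.loc[i, "tile_path"]) for i in unl
            ]
            step_losses = train_step(model, optimizer, labeled_batch,
                                     unlabeled_batch, bases, epoch_config,
                                     rng)
            for key in sums:
                sums[key] += step_losses[key]

        report = evaluate(model, val_rows, tiles, bases, manifest.class_names,
                          config)
        record = {
            "epoch": epoch,
            "lr": optimizer.lr,
            "balanced_accuracy": report.balanced_accuracy,
            "seed": config.seed,
            "wall_time": time.time() - t0,
        }
        record.update({
            f"loss_{k}": v / config.iterations_per_epoch for k, v in sums.items()
        })
        if track_probe:
            d_pos, d_neg = _probe_distances(model, probe_h, probe_e)
            record["probe_pos_dist"] = d_pos
            record["probe_neg_dist"] = d_neg
        log.append(record)

        if report.balanced_accuracy > best_acc:
            best_acc = report.balanced_accuracy
            best_state = model.state_arrays()
            best_epoch = epoch
        optimizer.lr *= config.lr_decay
        if epoch - best_epoch >= config.patience_epochs:
            break

    model.load_state_arrays(best_state)
    if out_path is not None:
        with open(out_path / "train_log.jsonl", "w") as fh:
            for record in log:
                fh.write(json.dumps(record) + "\n")
        save_checkpoint(model, out_path / "best", meta={
            "best_balanced_accuracy": best_acc,
            "best_epoch": best_epoch,
            "config_hash": config.config_hash(),
            "seed": config.seed,
        })
    return best_state, log


def evaluate(model: DualEncoder, rows: pd.DataFrame, tiles,
             bases: Mapping[str, StainBasis],
             class_names: Sequence[str], config: TrainConfig,
             chunk: int = 64) -> EvalReport:
    """Deterministic evaluation (center crop, no augmentation)."""
    label_idx = {name: i for i, name in enumerate(class_names)}
    n = len(class_names)
    confusion = np.zeros((n, n), dtype=int)
    pairs, truths = [], []
    for r in rows.itertuples():
        if r.label == "":
            raise ValueError("evaluate requires labeled rows")
        pairs.append(_eval_views(tiles.get(r.tile_path),
                                 bases.get(r.slide_id), config))
        truths.append(label_idx[r.label])
    for start in range(0, len(pairs), chunk):
        h, e = _stack(pairs[start : start + chunk])
        probs = model.forward(h, e).probs.data
        preds = probs.argmax(axis=1)
        for t, p in zip(truths[start : start + chunk], preds):
            confusion[t, p] += 1

    support = confusion.sum(axis=1)
    predicted = confusion.sum(axis=0)
    recalls, precisions, fscores = {}, {}, {}
    missing = []
    for i, name in enumerate(class_names):
        if support[i] == 0:
            missing.append(name)
            continue
        rec = confusion[i, i] / support[i]
        prec = confusion[i, i] / predicted[i] if predicted[i] else 0.0
        recalls[name] = float(rec)
        precisions[name] = float(prec)
        fscores[name] = float(2 * prec * rec / (prec + rec)
                              if prec + rec else 0.0)
    bal_acc = float(np.mean(list(recalls.values()))) if recalls else 0.0
    return EvalReport(
        class_names=list(class_names),
        confusion=confusion,
        recalls=recalls,
        precisions=precisions,
        fscores=fscores,
        balanced_accuracy=bal_acc,
        missing_classes=missing,
        seed=config.seed,
        config_hash=config.config_hash(),
    )


def predict_tiles(model: DualEncoder, rows: pd.DataFrame, tiles,
                  bases: Mapping[str, StainBasis],
                  class_names: Sequence[str], config: TrainConfig,
                  out_path=None, chunk: int = 64) -> pd.DataFrame:
    """Per-tile prediction table: path, slide, class probabilities, argmax."""
    missing_slides = sorted(
        {r.slide_id for r in rows.itertuples()
         if config.view_mode == "HE" and config.use_adaptive_stains
         and r.slide_id not in bases}
    )
    if missing_slides:
        raise ValueError(f"no stain basis for slides: {missing_slides}")
    records = []
    pairs = [
        _eval_views(tiles.get(r.tile_path), bases.get(r.slide_id), config)
        for r in rows.itertuples()
    ]
    for start in range(0, len(pairs), chunk):
        h, e = _stack(pairs[start : start + chunk])
        probs = model.forward(h, e).probs.data
        sub = rows.iloc[start : start + len(probs)]
        for r, p in zip(sub.itertuples(), probs):
            rec = {"tile_path": r.tile_path, "slide_id": r.slide_id}
            rec.update({f"p_{c}": float(v) for c, v in zip(class_names, p)})
            rec["prediction"] = class_names[int(np.argmax(p))]
            records.append(rec)
    frame = pd.DataFrame(records)
    if out_path is not None:
        frame.to_csv(out_path, index=False)
    return frame


def fit_all_bases(manifest: DatasetManifest, tiles,
                  outlier_fraction: float = 0.01, min_od_norm: float = 0.1,
                  min_pixels: int = 1000, max_pixels: int = 200_000,
                  percentile: float = 99.0, target: float = 0.5,
                  seed: int = 0) -> dict[str, StainBasis]:
    """Fit one calibrated stain basis per slide from all of its tiles.

    Stain fitting is unsupervised, so validation/test slides are fitted the
    same way; bases are computed once before training and never refitted.
    """
    bases: dict[str, StainBasis] = {}
    for slide_id, group in manifest.frame.groupby("slide_id"):
        slide_tiles = [tiles.get(p) for p in group["tile_path"]]
        bases[slide_id] = fit_slide_basis(
            slide_tiles, outlier_fraction=outlier_fraction,
            min_od_norm=min_od_norm, min_pixels=min_pixels,
            max_pixels=max_pixels, percentile=percentile, target=target,
            seed=seed, slide_id=slide_id,
        )
    return bases
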