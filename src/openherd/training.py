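"""Split protocols and end-to-end joint training of backbone + heads.

The open-set protocol partitions the herd's individuals into *known* (seen in
training) and *unknown* (test-time only) sets.  Training is strictly
closed-world: only known-individual images from the training day ever enter
a batch.  Evaluation then scores the trained model on held-out days that
contain both known and unknown individuals.

Two split generators are provided: random known/unknown partitions repeated
over trials (the standard multi-trial OSR protocol), and an "openness
ladder" that holds the unknown set fixed within a trial while shrinking the
known set, so that performance can be traced against problem openness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from openherd.backbone import FeatureExtractorSpec, build_extractor
from openherd.heads import AMSoftmaxHead, ReciprocalPointSet, LossBreakdown, combined_loss_grad
from openherd.synthetic import DatasetManifest, load_image

__all__ = ["SplitSpec", "TrainConfig", "AugmentConfig", "TrainedModel",
           "make_splits", "make_openness_ladder", "train", "load_model"]


@dataclass(frozen=True)
class SplitSpec:
    """One known/unknown partition of the herd for one trial."""

    trial_index: int
    known_ids: tuple[str, ...]
    unknown_ids: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        known, unknown = set(self.known_ids), set(self.unknown_ids)
        if known & unknown:
            raise ValueError("known_ids and unknown_ids must be disjoint")
        if not known or not unknown:
            raise ValueError("both known and unknown sets must be nonempty")


def make_splits(all_ids: list[str], n_known: int, n_trials: int, seed: int) -> list[SplitSpec]:
    """Random known/unknown partitions, one per trial; deterministic in ``seed``.

    Each split is exhaustive: every individual is either known or unknown.
    """
    all_ids = list(all_ids)
    if not 1 <= n_known < len(all_ids):
        raise ValueError(f"n_known must lie in [1, {len(all_ids) - 1}], got {n_known}")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    splits = []
    for t in range(n_trials):
        trial_seed = int(np.random.SeedSequence([int(seed), t]).generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(trial_seed)
        perm = list(rng.permutation(all_ids))
        splits.append(SplitSpec(
            trial_index=t,
            known_ids=tuple(sorted(perm[:n_known])),
            unknown_ids=tuple(sorted(perm[n_known:])),
            seed=trial_seed,
        ))
    return splits


def make_openness_ladder(all_ids: list[str], n_unknown_fixed: int,
                         known_counts: list[int], n_trials: int,
                         seed: int) -> list[SplitSpec]:
    """Splits for the openness sweep: fixed unknowns, shrinking knowns.

    For each trial, a fixed unknown set of ``n_unknown_fixed`` individuals is
    drawn; each rung of ``known_counts`` then takes the first ``c`` of the
    remaining (shuffled) individuals as knowns, so rungs within a trial are
    nested and share their unknown set exactly.  Returns one
    :class:`SplitSpec` per (trial, rung), trials outermost.
    """
    all_ids = list(all_ids)
    if not known_counts:
        raise ValueError("known_counts must be nonempty")
    if min(known_counts) < 1:
        raise ValueError("known counts must be >= 1")
    if n_unknown_fixed < 1 or n_unknown_fixed + max(known_counts) > len(all_ids):
        raise ValueError(
            f"infeasible ladder: {n_unknown_fixed} unknowns + up to {max(known_counts)} "
            f"knowns exceeds the {len(all_ids)} available individuals")
    splits = []
    for t in range(n_trials):
        trial_seed = int(np.random.SeedSequence([int(seed), t, 1]).generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(trial_seed)
        perm = list(rng.permutation(all_ids))
        unknown = tuple(sorted(perm[:n_unknown_fixed]))
        pool = perm[n_unknown_fixed:]
        for c in known_counts:
            splits.append(SplitSpec(
                trial_index=t,
                known_ids=tuple(sorted(pool[:c])),
                unknown_ids=unknown,
                seed=trial_seed,
            ))
    return splits


@dataclass(frozen=True)
class AugmentConfig:
    """Training-time nuisance augmentation (reduced set; see docs/methods.md).

    Each image independently receives a small rotation, a brightness factor,
    an optional random crop-and-resize, and pixel noise.  A ``randaugment``
    hook (any callable ``(image, rng) -> image``) can replace the built-ins.
    """

    rotation_deg: float = 15.0
    brightness: float = 0.3
    crop_frac: float = 0.2
    noise_sd: float = 0.05
    prob: float = 0.7


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of one training run.

    Defaults follow the method's protocol where it states them (batch size
    32, s=10, m=0.5, joint AM + AMC objective) scaled to desk size elsewhere
    (20 epochs, Adam at 1e-3 for the small from-scratch backbone).
    """

    epochs: int = 20
    batch_size: int = 32
    learning_rate: float = 1e-3
    points_lr: float = 0.05
    optimizer: str = "adam"
    s: float = 10.0
    m: float = 0.5
    lambda_amc: float = 0.1
    lambda_rp_ce: float = 1.0
    gamma: float = 0.03
    predict_from: str = "am_head"   # or "rp_distance"
    train_day: str = "day1"
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.learning_rate <= 0 or self.points_lr <= 0:
            raise ValueError("learning rates must be positive")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.predict_from not in ("am_head", "rp_distance"):
            raise ValueError(f"predict_from must be 'am_head' or 'rp_distance'")


class _Adam:
    """Adam with one learning rate per parameter tensor (the reciprocal
    points need a much larger step than the backbone to traverse feature
    space within a short schedule)."""

    def __init__(self, shapes: list[np.ndarray], lrs: list[float],
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.lrs, self.b1, self.b2, self.eps = list(lrs), beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in shapes]
        self.v = [np.zeros_like(p) for p in shapes]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lrs[i] * mhat / (np.sqrt(vhat) + self.eps)


class _SGD:
    def __init__(self, shapes: list[np.ndarray], lrs: list[float]) -> None:
        self.lrs = list(lrs)

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        for p, g, lr in zip(params, grads, self.lrs):
            p -= lr * g


@dataclass
class TrainedModel:
    """Serializable bundle: extractor + heads + label map + provenance."""

    spec: FeatureExtractorSpec
    extractor: object
    head: AMSoftmaxHead
    points: ReciprocalPointSet
    label_map: tuple[str, ...]          # index -> known individual id
    config: TrainConfig
    loss_log: pd.DataFrame = None

    def save(self, path: str | Path) -> None:
        """Write a ``.npz`` checkpoint plus a JSON sidecar of the metadata."""
        path = Path(path)
        arrays = {f"net.{k}": v for k, v in self.extractor.state_dict().items()}
        arrays["head.W"] = self.head.W
        arrays["points.P"] = self.points.P
        arrays["points.R"] = self.points.R
        np.savez(path, **arrays)
        meta = {
            "spec": asdict(self.spec),
            "label_map": list(self.label_map),
            "head": {"s": self.head.s, "m": self.head.m},
            "points": {"gamma": self.points.gamma},
            "config": _config_to_dict(self.config),
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
        if self.loss_log is not None:
            self.loss_log.to_csv(path.parent / "loss_log.csv", index=False)


def _config_to_dict(config: TrainConfig) -> dict:
    d = asdict(config)
    return d


def _config_from_dict(d: dict) -> TrainConfig:
    d = dict(d)
    d["augment"] = AugmentConfig(**d["augment"])
    return TrainConfig(**d)


def load_model(path: str | Path) -> TrainedModel:
    """Reload a checkpoint written by :meth:`TrainedModel.save`."""
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    spec_d = dict(meta["spec"])
    spec_d["channels"] = tuple(spec_d["channels"])
    spec = FeatureExtractorSpec(**spec_d)
    with np.load(path) as z:
        arrays = {k: z[k] for k in z.files}
    extractor = build_extractor(spec, seed=0)
    extractor.load_state_dict({k[4:]: v for k, v in arrays.items() if k.startswith("net.")})
    head = AMSoftmaxHead(W=arrays["head.W"], **meta["head"])
    points = ReciprocalPointSet(P=arrays["points.P"], R=arrays["points.R"],
                                gamma=meta["points"]["gamma"])
    return TrainedModel(
        spec=spec, extractor=extractor, head=head, points=points,
        label_map=tuple(meta["label_map"]), config=_config_from_dict(meta["config"]),
    )


def load_split_images(manifest: DatasetManifest, ids: tuple[str, ...] | list[str],
                      day: str | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Load all images of the given individuals (optionally one day) into
    memory.  Returns ``(images, labels)`` with string labels."""
    frame = manifest.frame
    mask = frame["individual_id"].isin(list(ids))
    if day is not None:
        mask &= frame["day"] == day
    rows = frame[mask]
    if rows.empty:
        raise ValueError(f"no manifest rows for ids={list(ids)!r} day={day!r}")
    images = np.stack([load_image(manifest.resolve(p)) for p in rows["image_path"]])
    return images, rows["individual_id"].to_numpy()


def _augment_batch(images: np.ndarray, cfg: AugmentConfig,
                   rng: np.random.Generator) -> np.ndarray:
    out = images.copy()
    for i in range(len(out)):
        if rng.random() < cfg.prob and cfg.rotation_deg > 0:
            ang = rng.uniform(-cfg.rotation_deg, cfg.rotation_deg)
            out[i] = ndimage.rotate(out[i], ang, reshape=False, order=1, mode="nearest")
        if cfg.brightness > 0:
            out[i] *= 1.0 + rng.uniform(-cfg.brightness, cfg.brightness)
        if cfg.crop_frac > 0 and rng.random() < cfg.prob:
            h = out[i].shape[0]
            c = int(h * cfg.crop_frac)
            if c > 0:
                r0, c0 = rng.integers(0, c + 1, 2)
                crop = out[i][r0:h - c + r0, c0:h - c + c0]
                out[i] = ndimage.zoom(crop, h / crop.shape[0], order=1)[:h, :h]
    if cfg.noise_sd > 0:
        out += rng.normal(0.0, cfg.noise_sd, out.shape)
    return np.clip(out, 0.0, 1.0)


def train(manifest: DatasetManifest, split: SplitSpec,
          backbone_spec: FeatureExtractorSpec | None = None,
          config: TrainConfig | None = None,
          randaugment=None) -> TrainedModel:
    """Jointly train backbone, AM-Softmax head and reciprocal points.

    Only images of ``split.known_ids`` from ``config.train_day`` are used
    (closed-world training).  Returns the trained model with a per-epoch
    loss log (``epoch, am_loss, amc_loss, total``).  Fully reproducible
    given ``config.seed``.
    """
    backbone_spec = backbone_spec or FeatureExtractorSpec()
    config = config or TrainConfig()

    missing = set(split.known_ids) - set(manifest.per_individual)
    if missing:
        raise ValueError(f"known ids absent from manifest: {sorted(missing)}")
    images, str_labels = load_split_images(manifest, split.known_ids, day=config.train_day)
    label_map = tuple(sorted(split.known_ids))
    to_index = {lab: i for i, lab in enumerate(label_map)}
    labels = np.array([to_index[lab] for lab in str_labels])

    seed = int(config.seed)
    extractor = build_extractor(backbone_spec, seed=seed)
    head = AMSoftmaxHead.init(backbone_spec.embed_dim, len(label_map),
                              s=config.s, m=config.m, seed=seed)
    points = ReciprocalPointSet.init(backbone_spec.embed_dim, len(label_map),
                                     gamma=config.gamma, seed=seed)

    net_params = extractor.parameters()
    param_refs = [layer.params[name] for _, layer, name in net_params]
    param_refs += [head.W, points.P, points.R]
    lrs = [config.learning_rate] * (len(net_params) + 1) + [config.points_lr] * 2
    opt_cls = _Adam if config.optimizer == "adam" else _SGD
    opt = opt_cls(param_refs, lrs)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7E]))
    n = len(images)
    log_rows = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        sums = np.zeros(3)
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = images[idx]
            if randaugment is not None:
                batch = np.stack([randaugment(im, rng) for im in batch])
            else:
                batch = _augment_batch(batch, config.augment, rng)
            feats = extractor.forward(batch, train=True)
            breakdown, dfeat = combined_loss_grad(feats, labels[idx], head, points,
                                                  config.lambda_amc, config.lambda_rp_ce)
            extractor.backward(dfeat)
            grads = [layer.grads[name] for _, layer, name in net_params]
            grads += [head.grads["W"], points.grads["P"], points.grads["R"]]
            opt.step(param_refs, grads)
            points.clamp()
            sums += (breakdown.am_loss, breakdown.amc_loss, breakdown.total)
            n_batches += 1
        log_rows.append((epoch, *(sums / n_batches)))

    loss_log = pd.DataFrame(log_rows, columns=["epoch", "am_loss", "amc_loss", "total"])
    return TrainedModel(spec=backbone_spec, extractor=extractor, head=head, points=points,
                        label_map=label_map, config=config, loss_log=loss_log)
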