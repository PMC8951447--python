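"""Dataset handling, augmentation, and end-to-end orchestration.

Augmentation follows the capture-style recipe: a random crop slightly
smaller than the frame (which enlarges the eye in relative terms), a
horizontal flip with probability 0.5 (left and right eyes augment each
other), and a resize to the network resolution.  The identical
geometric transform is applied to the image and both masks; images are
resampled bilinearly, masks with nearest-neighbor and re-binarized.

``run_experiment`` wires the whole loop together at a configurable
scale: sample masks, render a real-data proxy, train the adversarial
synthesizer, synthesize additional training data, train segmentors on
each training-set composition, and score them on a held-out rendered
test set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

from .evaluation import segmentation_report
from .gen_net import Pix2PixSynthesizer
from .mask_model import FRAME_HEIGHT, FRAME_WIDTH, ParameterRanges
from .renderer import RenderConfig, RenderedDataset, render_dataset
from .seg_net import IrisSegmenter

# -------------------------------------------------------------- augment

#: named crop presets for 640x480 frames, (height, width)
CROP_PRESETS = {
    "default": (456, 608),
    "alternate": (432, 576),
}


@dataclass(frozen=True)
class AugmentationConfig:
    """Crop / flip / resize recipe applied identically to image and masks."""

    flip_prob: float = 0.5
    crop_size: tuple[int, int] = CROP_PRESETS["default"]
    output_size: tuple[int, int] = (256, 256)

    def validate(self, source_shape: tuple[int, int]) -> None:
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ValueError("flip probability must be in [0, 1]")
        ch, cw = self.crop_size
        if ch > source_shape[0] or cw > source_shape[1]:
            raise ValueError("crop larger than source image")
        if ch < 1 or cw < 1:
            raise ValueError("crop must be positive")

    def scaled_to(self, shape: tuple[int, int]) -> "AugmentationConfig":
        """Rescale the crop window from the nominal frame to ``shape``."""
        h, w = shape
        ch = max(1, round(self.crop_size[0] * h / FRAME_HEIGHT))
        cw = max(1, round(self.crop_size[1] * w / FRAME_WIDTH))
        return replace(self, crop_size=(min(ch, h), min(cw, w)), output_size=shape)


@dataclass(frozen=True)
class AppliedTransform:
    """Log of one augmentation draw; re-applying it is bit-exact."""

    crop_y: int
    crop_x: int
    flipped: bool


def _resize_image(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    if img.shape == tuple(shape):
        return img.astype(np.float32)
    return _sk_resize(
        img.astype(np.float64), shape, order=1, preserve_range=True, anti_aliasing=False
    ).astype(np.float32)


def _resize_mask(mask: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    if mask.shape == tuple(shape):
        return mask.astype(np.uint8)
    out = _sk_resize(
        mask.astype(np.float32), shape, order=0, preserve_range=True, anti_aliasing=False
    )
    return (out > 0.5).astype(np.uint8)


def apply_transform(
    image: np.ndarray,
    masks: tuple[np.ndarray, ...],
    config: AugmentationConfig,
    transform: AppliedTransform,
) -> tuple[np.ndarray, tuple[np.ndarray, ...]]:
    """Deterministically apply a logged crop/flip/resize to an aligned pair."""
    config.validate(image.shape)
    ch, cw = config.crop_size
    y0, x0 = transform.crop_y, transform.crop_x
    img = image[y0 : y0 + ch, x0 : x0 + cw]
    ms = [m[y0 : y0 + ch, x0 : x0 + cw] for m in masks]
    if transform.flipped:
        img = img[:, ::-1]
        ms = [m[:, ::-1] for m in ms]
    img = _resize_image(img, config.output_size)
    ms = tuple(_resize_mask(m, config.output_size) for m in ms)
    return img, ms


def augment(
    image: np.ndarray,
    masks: tuple[np.ndarray, ...],
    config: AugmentationConfig | None = None,
    rng: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, tuple[np.ndarray, ...], AppliedTransform]:
    """One random crop + flip + resize, identical for image and masks.

    Returns the transformed pair and the :class:`AppliedTransform` that
    produced it (so the draw can be replayed exactly).
    """
    config = config if config is not None else AugmentationConfig()
    for m in masks:
        if m.shape != image.shape:
            raise ValueError("image and masks are not aligned")
    config.validate(image.shape)
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    ch, cw = config.crop_size
    y0 = int(rng.integers(0, image.shape[0] - ch + 1))
    x0 = int(rng.integers(0, image.shape[1] - cw + 1))
    flipped = bool(rng.random() < config.flip_prob)
    t = AppliedTransform(y0, x0, flipped)
    img, ms = apply_transform(image, masks, config, t)
    return img, ms, t


# ------------------------------------------------------------- manifests


@dataclass(frozen=True)
class SampleRecord:
    image_path: str
    iris_mask_path: str
    periocular_mask_path: str
    origin: str  # "real" | "generated"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.origin not in ("real", "generated"):
            raise ValueError("origin must be 'real' or 'generated'")


@dataclass
class DatasetManifest:
    records: list[SampleRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def origin_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.records:
            counts[r.origin] = counts.get(r.origin, 0) + 1
        return counts

    def to_csv(self, path) -> None:
        pd.DataFrame([r.__dict__ for r in self.records]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DatasetManifest":
        df = pd.read_csv(path)
        recs = []
        for _, row in df.iterrows():
            seed = None if pd.isna(row.get("seed")) else int(row["seed"])
            recs.append(
                SampleRecord(
                    row["image_path"], row["iris_mask_path"],
                    row["periocular_mask_path"], row["origin"], seed,
                )
            )
        return cls(recs)


def mix_datasets(
    real: DatasetManifest, generated: DatasetManifest, seed: int | None = 0
) -> DatasetManifest:
    """Concatenate real and generated manifests (origins preserved),
    with a seeded shuffle; raises on duplicate image paths."""
    records = list(real.records) + list(generated.records)
    paths = [r.image_path for r in records]
    if len(set(paths)) != len(paths):
        raise ValueError("path collision between manifests")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    return DatasetManifest([records[i] for i in order])


# ---------------------------------------------------------- orchestration


def labels_from_conditions(conditions: np.ndarray, n_classes: int = 2) -> np.ndarray:
    """Segmentation labels from condition stacks.

    Binary mode: class 1 = iris annulus, class 0 = everything else.
    3-class mode: 0 = background, 1 = periocular (outside the iris),
    2 = iris annulus.
    """
    iris = conditions[:, 0] > 0.5
    if n_classes == 2:
        return iris.astype(np.int64)
    if n_classes == 3:
        peri = conditions[:, 1] > 0.5
        return (peri & ~iris).astype(np.int64) + 2 * iris.astype(np.int64)
    raise ValueError("n_classes must be 2 or 3")


@dataclass(frozen=True)
class ExperimentConfig:
    """Full configuration of one end-to-end run.

    Defaults are the desk-scale study conditions: 64x64 working frames,
    200 real-proxy renders, 200 adversarial update pairs, 200
    synthesized images, and a 10-epoch segmentor — small enough to run
    on one CPU while exercising every stage of the pipeline.
    """

    shape: tuple[int, int] = (64, 64)
    n_real: int = 200
    n_generated: int = 200
    n_test: int = 64
    seed: int = 0
    ranges: ParameterRanges = field(default_factory=ParameterRanges)
    render: RenderConfig = field(default_factory=RenderConfig)
    # adversarial synthesis (desk-scale preset)
    gan_depth: int = 6
    gan_base_width: int = 24
    gan_batch_size: int = 16
    gan_iterations: int = 200
    gan_learning_rate: float = 2e-3
    gan_disc_lr_factor: float = 0.25
    gan_ema_decay: float = 0.97
    l1_weight: float = 100.0
    # segmentation (desk-scale preset)
    seg_depth: int = 6
    seg_base_width: int = 32
    seg_batch_size: int = 16
    seg_epochs: int = 10
    seg_learning_rate: float = 2e-3
    seg_dropout_layers: int = 0
    n_classes: int = 2


@dataclass
class ExperimentReport:
    """Output of one full run: the metric table plus all loss curves."""

    table: pd.DataFrame
    gan_history: pd.DataFrame
    seg_histories: dict[str, pd.DataFrame]
    config: ExperimentConfig

    def save(self, outdir) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(outdir / "metrics.csv", index=False)
        self.gan_history.to_csv(outdir / "gan_loss.csv", index=False)
        for name, hist in self.seg_histories.items():
            hist.to_csv(outdir / f"seg_loss_{name.replace('+', '_')}.csv", index=False)
        return outdir


def _train_and_score(
    images: np.ndarray,
    labels: np.ndarray,
    test: RenderedDataset,
    cfg: ExperimentConfig,
    seed: int,
) -> tuple[dict, pd.DataFrame]:
    seg = IrisSegmenter(
        n_classes=cfg.n_classes,
        depth=cfg.seg_depth,
        base_width=cfg.seg_base_width,
        learning_rate=cfg.seg_learning_rate,
        batch_size=cfg.seg_batch_size,
        epochs=cfg.seg_epochs,
        dropout_layers=cfg.seg_dropout_layers,
        random_state=seed,
    )
    seg.fit(images, labels)
    pred = seg.predict(test.images)
    truth = labels_from_conditions(test.conditions, cfg.n_classes)
    return segmentation_report(pred, truth, cfg.n_classes), seg.history_


def run_experiment(config: ExperimentConfig | None = None) -> ExperimentReport:
    """Execute the complete self-supervised loop at the configured scale.

    Stages: render a real-data proxy and a held-out test set; train the
    mask-to-image synthesizer on the proxy; synthesize additional
    mask-conditioned training data; train one segmentor per training-set
    composition ("real", "real+generated"); report PA / mPA / mIoU /
    FWIoU per row.  Fully deterministic for a fixed ``config.seed``.
    """
    cfg = config if config is not None else ExperimentConfig()
    root = np.random.SeedSequence(cfg.seed)
    s_train, s_test, s_gan, s_syn, s_seg = (
        int(c.generate_state(1)[0] % (2**31)) for c in root.spawn(5)
    )

    try:
        train = render_dataset(cfg.n_real, cfg.ranges, cfg.render, s_train, cfg.shape)
        test = render_dataset(cfg.n_test, cfg.ranges, cfg.render, s_test, cfg.shape)
    except Exception as exc:  # pragma: no cover - diagnostics path
        raise RuntimeError(f"[render] stage failed: {exc}") from exc

    try:
        synth = Pix2PixSynthesizer(
            depth=cfg.gan_depth,
            base_width=cfg.gan_base_width,
            disc_base_width=cfg.gan_base_width,
            learning_rate=cfg.gan_learning_rate,
            disc_lr_factor=cfg.gan_disc_lr_factor,
            ema_decay=cfg.gan_ema_decay,
            batch_size=cfg.gan_batch_size,
            l1_weight=cfg.l1_weight,
            iterations=cfg.gan_iterations,
            random_state=s_gan,
        )
        synth.fit(train.conditions, train.images)
        generated = synth.synthesize(cfg.n_generated, cfg.ranges, seed=s_syn)
    except RuntimeError:
        raise
    except Exception as exc:  # pragma: no cover - diagnostics path
        raise RuntimeError(f"[synthesis] stage failed: {exc}") from exc

    rows = []
    histories: dict[str, pd.DataFrame] = {}
    compositions = {
        "real": (train.images, labels_from_conditions(train.conditions, cfg.n_classes)),
        "real+generated": (
            np.concatenate([train.images, generated.images]),
            np.concatenate(
                [
                    labels_from_conditions(train.conditions, cfg.n_classes),
                    labels_from_conditions(generated.conditions, cfg.n_classes),
                ]
            ),
        ),
    }
    for name, (imgs, labels) in compositions.items():
        try:
            report, hist = _train_and_score(imgs, labels, test, cfg, s_seg)
        except Exception as exc:  # pragma: no cover - diagnostics path
            raise RuntimeError(f"[segmentation:{name}] stage failed: {exc}") from exc
        rows.append({"training_set": name, "n_train": len(imgs), **report})
        histories[name] = hist

    return ExperimentReport(pd.DataFrame(rows), synth.history_, histories, cfg)


def trend_experiment(
    base_config: ExperimentConfig | None = None, seeds: tuple[int, ...] = (0, 1, 2)
) -> pd.DataFrame:
    """Training-set-size trend over several seeds.

    Runs the full loop once per seed and tabulates the held-out metrics
    of the "real" and "real+generated" compositions side by side; the
    expectation mirrored here is that adding synthesized training data
    does not degrade segmentation quality.
    """
    base = base_config if base_config is not None else ExperimentConfig()
    rows = []
    for seed in seeds:
        report = run_experiment(replace(base, seed=seed))
        t = report.table.set_index("training_set")
        rows.append(
            {
                "seed": seed,
                "mIoU_real": t.loc["real", "mIoU"],
                "mIoU_mixed": t.loc["real+generated", "mIoU"],
                "PA_real": t.loc["real", "PA"],
                "PA_mixed": t.loc["real+generated", "PA"],
            }
        )
    return pd.DataFrame(rows)
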