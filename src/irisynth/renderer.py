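"""Procedural eye-image renderer.

Fabricates grayscale eye images directly from mask parameters so the
whole synthesis-and-segmentation pipeline can run end to end without
any external capture data.  The appearance model is deliberately
simple: a dark pupil disc, a textured iris annulus (radial striation
sinusoid plus seeded smoothed noise), a bright sclera inside the
eyelid-aperture ellipse, and a skin-toned background, with optional
additive sensor noise and an optional eyeglasses mode (specular glare
discs plus a frame arc).  It makes no attempt at photorealism — its job
is to provide images whose ground-truth masks are exact by
construction.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .mask_model import (
    FRAME_HEIGHT,
    FRAME_WIDTH,
    ConditionPair,
    MaskParameters,
    ParameterRanges,
    rasterize_iris_mask,
    rasterize_periocular_mask,
    sample_parameters,
    save_mask_png,
)


@dataclass(frozen=True)
class RenderConfig:
    """Appearance knobs of the toy renderer (all intensities in [0, 1])."""

    pupil_level: float = 0.05
    iris_level: float = 0.45
    sclera_level: float = 0.95
    skin_level: float = 0.75
    texture_amplitude: float = 0.12
    texture_frequency: float = 6.0
    noise_sd: float = 0.02
    glasses: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in ("pupil_level", "iris_level", "sclera_level", "skin_level"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.texture_amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitudes must be non-negative")

    def digest(self) -> str:
        payload = repr(sorted(asdict(self).items())).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def scale_ranges(
    ranges: ParameterRanges, shape: tuple[int, int]
) -> ParameterRanges:
    """Rescale frame-coordinate sampling ranges to a smaller working frame.

    Center coordinates scale per axis; radii (and the pupil jitter)
    scale by the smaller axis factor so circles stay circles.
    """
    h, w = shape
    sx, sy = w / FRAME_WIDTH, h / FRAME_HEIGHT
    s = min(sx, sy)
    return replace(
        ranges,
        pupil_r=(ranges.pupil_r[0] * s, ranges.pupil_r[1] * s),
        iris_r=(ranges.iris_r[0] * s, ranges.iris_r[1] * s),
        center_x=(ranges.center_x[0] * sx, ranges.center_x[1] * sx),
        center_y=(ranges.center_y[0] * sy, ranges.center_y[1] * sy),
        pupil_center_jitter=ranges.pupil_center_jitter * s,
    )


def render_eye(
    params: MaskParameters,
    config: RenderConfig | None = None,
    shape: tuple[int, int] = (FRAME_HEIGHT, FRAME_WIDTH),
) -> np.ndarray:
    """Render one grayscale eye image in [0, 1] at ``shape`` (H, W).

    Deterministic for fixed ``params`` and ``config`` (the config seed
    drives both the iris texture noise and the sensor noise).
    """
    config = config if config is not None else RenderConfig()
    config.validate()
    params.validate()
    rng = np.random.default_rng(config.seed)
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]

    peri = rasterize_periocular_mask(params, shape).astype(bool)
    annulus = rasterize_iris_mask(params, shape).astype(bool)
    r = np.hypot(xs - params.iris_x, ys - params.iris_y)
    pupil = (np.hypot(xs - params.pupil_x, ys - params.pupil_y) <= params.pupil_r) & (
        r <= params.iris_r
    )

    img = np.full(shape, config.skin_level, dtype=np.float64)
    img[peri] = config.sclera_level

    # iris striations: radial sinusoid plus smoothed seeded noise
    band = np.clip((r - params.pupil_r) / max(params.iris_r - params.pupil_r, 1e-6), 0, 1)
    striae = np.sin(2.0 * np.pi * config.texture_frequency * band)
    smooth = gaussian_filter(rng.standard_normal(shape), sigma=1.5)
    smax = np.abs(smooth).max()
    if smax > 0:
        smooth = smooth / smax
    texture = config.texture_amplitude * striae + 0.5 * config.texture_amplitude * smooth
    img[annulus] = config.iris_level + texture[annulus]
    img[pupil] = config.pupil_level

    if config.glasses:
        gx, gy, gr = params.iris_x, params.iris_y, params.iris_r
        glare1 = np.hypot(xs - (gx - 0.45 * gr), ys - (gy - 0.40 * gr)) <= 0.14 * gr
        glare2 = np.hypot(xs - (gx + 0.50 * gr), ys - (gy - 0.25 * gr)) <= 0.09 * gr
        img[glare1 | glare2] = 1.0
        ring = np.abs(np.hypot(xs - gx, ys - gy) - 2.2 * gr) <= 0.05 * gr
        img[ring] = 0.15

    if config.noise_sd > 0:
        img = img + rng.normal(0.0, config.noise_sd, size=shape)
    return np.clip(img, 0.0, 1.0).astype(np.float32)


@dataclass
class RenderedSample:
    image: np.ndarray
    condition: ConditionPair
    params: MaskParameters
    seed: int


@dataclass
class RenderedDataset:
    """n aligned (image, condition pair, parameters) triplets plus a manifest."""

    samples: list[RenderedSample]
    config: RenderConfig
    shape: tuple[int, int]

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def images(self) -> np.ndarray:
        return np.stack([s.image for s in self.samples])

    @property
    def conditions(self) -> np.ndarray:
        return np.stack([s.condition.stack() for s in self.samples])

    @property
    def iris_masks(self) -> np.ndarray:
        return np.stack([s.condition.iris_mask for s in self.samples])

    def manifest(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.samples):
            row = {"sample_id": i, "seed": s.seed, **s.params.to_row(),
                   "config_hash": self.config.digest()}
            rows.append(row)
        return pd.DataFrame(rows)

    def save(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for i, s in enumerate(self.samples):
            iio.imwrite(outdir / f"sample_{i:05d}_image.png",
                        np.round(s.image * 255).astype(np.uint8))
            save_mask_png(s.condition.iris_mask, outdir / f"sample_{i:05d}_iris.png")
            save_mask_png(s.condition.periocular_mask, outdir / f"sample_{i:05d}_periocular.png")
        self.manifest().to_csv(outdir / "manifest.csv", index=False)
        return outdir


def render_dataset(
    n: int,
    ranges: ParameterRanges | None = None,
    config: RenderConfig | None = None,
    seed: int | None = None,
    shape: tuple[int, int] = (FRAME_HEIGHT, FRAME_WIDTH),
    rescale_ranges: bool = True,
) -> RenderedDataset:
    """Sample n parameter sets and render image / mask-pair triplets.

    ``seed`` drives both parameter sampling and per-sample render seeds;
    with ``rescale_ranges`` the frame-coordinate sampling ranges are
    rescaled to ``shape`` so shapes keep their relative proportions at
    small working resolutions.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranges = ranges if ranges is not None else ParameterRanges()
    config = config if config is not None else RenderConfig()
    if rescale_ranges and tuple(shape) != (FRAME_HEIGHT, FRAME_WIDTH):
        ranges = scale_ranges(ranges, shape)
    root = np.random.SeedSequence(seed)
    samples = []
    for child in root.spawn(n):
        rng = np.random.default_rng(child)
        params = sample_parameters(ranges, rng)
        sample_seed = int(child.generate_state(1)[0] % (2**31))
        cfg = replace(config, seed=sample_seed)
        image = render_eye(params, cfg, shape)
        condition = ConditionPair(
            rasterize_iris_mask(params, shape), rasterize_periocular_mask(params, shape)
        )
        samples.append(RenderedSample(image, condition, params, sample_seed))
    return RenderedDataset(samples, config, tuple(shape))


def load_rendered_dataset(outdir: str | Path, config: RenderConfig | None = None) -> RenderedDataset:
    """Re-load a saved dataset from its manifest (masks from PNG, params from CSV)."""
    from .mask_model import load_mask_png

    outdir = Path(outdir)
    df = pd.read_csv(outdir / "manifest.csv")
    samples = []
    for _, row in df.iterrows():
        i = int(row["sample_id"])
        image = iio.imread(outdir / f"sample_{i:05d}_image.png").astype(np.float32) / 255.0
        cond = ConditionPair(
            load_mask_png(outdir / f"sample_{i:05d}_iris.png"),
            load_mask_png(outdir / f"sample_{i:05d}_periocular.png"),
        )
        samples.append(RenderedSample(image, cond, MaskParameters.from_row(row), int(row["seed"])))
    shape = samples[0].image.shape
    return RenderedDataset(samples, config if config is not None else RenderConfig(), shape)
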