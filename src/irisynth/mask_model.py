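"""Parametric iris / periocular mask family.

An eye configuration is described by 11 shape parameters: pupil circle
(center, radius), iris circle (center, radius), and an eyelid-aperture
ellipse whose center is displaced from the iris center by an offset
vector, whose semi-axes are ratios of the iris radius, and which may be
rotated.  The iris mask is the annulus between the pupil and limbic
(outer iris) boundaries; the periocular mask is the elliptical open-eye
region.

Coordinates are 0-based with ``x`` = column and ``y`` = row, origin at
the top-left of the frame; rotation angles are degrees counter-clockwise
from the +x axis.  A pixel belongs to a mask iff its center satisfies
the defining inequality (hard labels, no anti-aliasing).
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.transform import resize

#: frame size (width, height) of the nominal capture geometry
FRAME_WIDTH = 640
FRAME_HEIGHT = 480

#: canonical column names for parameter tables (CSV round trips)
PARAM_NAMES = {
    "pupil_x": "PupilX",
    "pupil_y": "PupilY",
    "pupil_r": "PupilR",
    "iris_x": "IrisX",
    "iris_y": "IrisY",
    "iris_r": "IrisR",
    "x_offset": "xOffset",
    "y_offset": "yOffset",
    "x_ratio": "xRatio",
    "y_ratio": "yRatio",
    "degree": "Degree",
}


@dataclass(frozen=True)
class MaskParameters:
    """The 11 shape parameters of one eye configuration."""

    pupil_x: float
    pupil_y: float
    pupil_r: float
    iris_x: float
    iris_y: float
    iris_r: float
    x_offset: float
    y_offset: float
    x_ratio: float
    y_ratio: float
    degree: float

    def validate(self) -> None:
        if self.pupil_r <= 0 or self.iris_r <= 0:
            raise ValueError("radii must be positive")
        if self.pupil_r >= self.iris_r:
            raise ValueError("pupil radius must be smaller than iris radius")
        if self.x_ratio <= 0 or self.y_ratio <= 0:
            raise ValueError("ellipse axis ratios must be positive")
        d = np.hypot(self.pupil_x - self.iris_x, self.pupil_y - self.iris_y)
        if d + self.pupil_r > self.iris_r + 1e-9:
            raise ValueError("pupil circle is not contained in the iris circle")

    @property
    def ellipse_center(self) -> tuple[float, float]:
        return (self.iris_x + self.x_offset, self.iris_y + self.y_offset)

    @property
    def semi_axes(self) -> tuple[float, float]:
        return (self.x_ratio * self.iris_r, self.y_ratio * self.iris_r)

    def to_row(self) -> dict[str, float]:
        return {PARAM_NAMES[f.name]: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_row(cls, row: dict[str, float]) -> "MaskParameters":
        inv = {v: k for k, v in PARAM_NAMES.items()}
        return cls(**{inv[k]: float(row[k]) for k in PARAM_NAMES.values()})


@dataclass(frozen=True)
class ParameterRanges:
    """Closed sampling intervals for the mask family.

    Offsets are not stored: their intervals depend on the sampled
    ``x_ratio``/``y_ratio``/``iris_r`` — the offset is drawn uniformly
    from ``[-ratio * iris_r / 2, +ratio * iris_r / 2]`` per axis, which
    keeps the eyelid aperture overlapping the iris.  Centers are drawn
    from a margin box inside the frame so shapes stay mostly in view.
    """

    pupil_r: tuple[float, float] = (20.0, 60.0)
    iris_r: tuple[float, float] = (70.0, 120.0)
    x_ratio: tuple[float, float] = (1.3, 2.5)
    y_ratio: tuple[float, float] = (0.4, 1.1)
    degree: tuple[float, float] = (-15.0, 15.0)
    center_x: tuple[float, float] = (0.2 * FRAME_WIDTH, 0.8 * FRAME_WIDTH)
    center_y: tuple[float, float] = (0.2 * FRAME_HEIGHT, 0.8 * FRAME_HEIGHT)
    #: std (pixels) of the isotropic pupil-center jitter around the iris center
    pupil_center_jitter: float = 3.0

    def validate(self) -> None:
        for name in ("pupil_r", "iris_r", "x_ratio", "y_ratio", "degree", "center_x", "center_y"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"range {name} has lower > upper")
        if self.x_ratio[0] <= 0 or self.y_ratio[0] <= 0:
            raise ValueError("axis-ratio ranges must be positive")
        if self.pupil_r[0] >= self.iris_r[1]:
            raise ValueError("ranges admit no valid configuration: min pupil_r >= max iris_r")
        if self.pupil_center_jitter < 0:
            raise ValueError("jitter must be non-negative")

    def offset_bounds(self, ratio: float, iris_r: float) -> tuple[float, float]:
        half = ratio * iris_r / 2.0
        return (-half, half)


@dataclass(frozen=True)
class ConditionPair:
    """Two aligned binary masks — the 2-channel conditioning input."""

    iris_mask: np.ndarray
    periocular_mask: np.ndarray

    def __post_init__(self) -> None:
        im, pm = self.iris_mask, self.periocular_mask
        if im.shape != pm.shape:
            raise ValueError("mask shapes differ")
        for m in (im, pm):
            if not np.isin(m, (0, 1)).all():
                raise ValueError("masks must be binary {0,1}")

    @property
    def resolution(self) -> tuple[int, int]:
        return self.iris_mask.shape

    def stack(self) -> np.ndarray:
        """(2, H, W) float32 array: channel 0 iris, channel 1 periocular."""
        return np.stack([self.iris_mask, self.periocular_mask]).astype(np.float32)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sample_parameters(
    ranges: ParameterRanges | None = None,
    seed: int | np.random.Generator | None = None,
    max_tries: int = 1000,
) -> MaskParameters:
    """Draw one parameter set; rejection-sample until the pupil circle is
    contained in the iris circle.  Deterministic for a fixed seed."""
    ranges = ranges if ranges is not None else ParameterRanges()
    ranges.validate()
    rng = _rng(seed)
    for _ in range(max_tries):
        iris_r = rng.uniform(*ranges.iris_r)
        pupil_r = rng.uniform(*ranges.pupil_r)
        iris_x = rng.uniform(*ranges.center_x)
        iris_y = rng.uniform(*ranges.center_y)
        jitter = ranges.pupil_center_jitter
        pupil_x = iris_x + rng.normal(0.0, jitter) if jitter > 0 else iris_x
        pupil_y = iris_y + rng.normal(0.0, jitter) if jitter > 0 else iris_y
        x_ratio = rng.uniform(*ranges.x_ratio)
        y_ratio = rng.uniform(*ranges.y_ratio)
        degree = rng.uniform(*ranges.degree)
        x_offset = rng.uniform(*ranges.offset_bounds(x_ratio, iris_r))
        y_offset = rng.uniform(*ranges.offset_bounds(y_ratio, iris_r))
        params = MaskParameters(
            pupil_x, pupil_y, pupil_r, iris_x, iris_y, iris_r,
            x_offset, y_offset, x_ratio, y_ratio, degree,
        )
        try:
            params.validate()
        except ValueError:
            continue
        return params
    raise ValueError(f"no valid configuration found in {max_tries} draws; check ranges")


def _grid(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    h, w = shape
    if h <= 0 or w <= 0:
        raise ValueError("resolution must be positive")
    ys, xs = np.mgrid[0:h, 0:w]
    return xs.astype(np.float64), ys.astype(np.float64)


def rasterize_iris_mask(
    params: MaskParameters, shape: tuple[int, int] = (FRAME_HEIGHT, FRAME_WIDTH)
) -> np.ndarray:
    """Annulus between the pupillary and limbic boundaries, as uint8 {0,1}.

    ``shape`` is numpy-style (height, width); shapes extending past the
    frame are clipped to it.
    """
    params.validate()
    xs, ys = _grid(shape)
    inside_iris = (xs - params.iris_x) ** 2 + (ys - params.iris_y) ** 2 <= params.iris_r**2
    inside_pupil = (xs - params.pupil_x) ** 2 + (ys - params.pupil_y) ** 2 <= params.pupil_r**2
    return (inside_iris & ~inside_pupil).astype(np.uint8)


def rasterize_periocular_mask(
    params: MaskParameters, shape: tuple[int, int] = (FRAME_HEIGHT, FRAME_WIDTH)
) -> np.ndarray:
    """Rotated eyelid-aperture ellipse, as uint8 {0,1}."""
    params.validate()
    xs, ys = _grid(shape)
    cx, cy = params.ellipse_center
    a, b = params.semi_axes
    theta = np.deg2rad(params.degree)
    dx, dy = xs - cx, ys - cy
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    return ((u / a) ** 2 + (v / b) ** 2 <= 1.0).astype(np.uint8)


def resize_mask(mask: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbor resize that keeps labels binary."""
    if mask.shape == tuple(shape):
        return mask
    out = resize(mask.astype(np.float32), shape, order=0, preserve_range=True, anti_aliasing=False)
    return (out > 0.5).astype(np.uint8)


def make_condition_pair(
    params: MaskParameters,
    resolution: tuple[int, int] = (256, 256),
    frame: tuple[int, int] = (FRAME_HEIGHT, FRAME_WIDTH),
    clip_iris_to_periocular: bool = False,
) -> ConditionPair:
    """Rasterize both masks in the native frame, then resize to the
    network resolution with nearest-neighbor interpolation (the same
    geometric normalization images undergo).

    With ``clip_iris_to_periocular`` the iris annulus is intersected
    with the eyelid aperture, modelling eyelid occlusion of the iris.
    """
    iris = rasterize_iris_mask(params, frame)
    peri = rasterize_periocular_mask(params, frame)
    if clip_iris_to_periocular:
        iris = iris & peri
    return ConditionPair(resize_mask(iris, resolution), resize_mask(peri, resolution))


def fit_parameter_statistics(annotated_params: list[MaskParameters]) -> pd.DataFrame:
    """Per-parameter mean / sd / min / max summary of an annotated set.

    Rows are the canonical parameter names; columns are ``average``,
    ``std`` (population), ``min``, ``max``.
    """
    if len(annotated_params) == 0:
        raise ValueError("need at least one parameter set")
    df = pd.DataFrame([p.to_row() for p in annotated_params])
    return pd.DataFrame(
        {
            "average": df.mean(),
            "std": df.std(ddof=0),
            "min": df.min(),
            "max": df.max(),
        }
    )


def save_parameters_csv(params: list[MaskParameters], path) -> None:
    pd.DataFrame([p.to_row() for p in params]).to_csv(path, index=False)


def load_parameters_csv(path) -> list[MaskParameters]:
    df = pd.read_csv(path)
    return [MaskParameters.from_row(row) for _, row in df.iterrows()]


def save_mask_png(mask: np.ndarray, path) -> None:
    iio.imwrite(path, (mask.astype(np.uint8) * 255))


def load_mask_png(path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return (arr > 127).astype(np.uint8)
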