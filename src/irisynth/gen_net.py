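"""Mask-conditioned adversarial image synthesis.

A U-Net generator maps a 2-channel condition (iris mask, periocular
mask) to a grayscale eye image; a 5-layer patch discriminator scores
(mask pair, image) triplets.  The training objective is the conditional
adversarial loss

    L_cGAN(G, D) = E[log D(x, y)] + E[log(1 - D(x, G(x)))]

combined with an L1 reconstruction term weighted by ``l1_weight``
(lambda = 100 by default):

    G* = arg min_G max_D  L_cGAN(G, D) + lambda * L_L1(G).

The L1 term is the per-pixel mean absolute deviation, which keeps the
lambda weighting independent of the working resolution.  The generator's
adversarial term is implemented in the non-saturating form by default
(maximize log D(x, G(x))), with the minimax form available as a switch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .mask_model import (
    ConditionPair,
    MaskParameters,
    ParameterRanges,
    rasterize_iris_mask,
    rasterize_periocular_mask,
    sample_parameters,
)
from .nn import Adam, PatchDiscriminator, UNet
from .renderer import scale_ranges

_LOG_EPS = 1e-7


@dataclass(frozen=True)
class GanTrainingConfig:
    """Optimization recipe for the adversarial pair.

    Defaults are the full-scale recipe (Adam, lr 1e-4, beta1 0.5,
    beta2 0.99, batch 64, lambda 100, Gaussian weight init).
    """

    learning_rate: float = 1e-4
    beta1: float = 0.5
    beta2: float = 0.99
    batch_size: int = 64
    l1_weight: float = 100.0
    epochs: int = 1
    iterations: int | None = None
    init_std: float = 0.02
    non_saturating: bool = True

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.l1_weight < 0:
            raise ValueError("l1_weight must be non-negative")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")


def _check_scores(scores: np.ndarray, name: str) -> np.ndarray:
    scores = np.asarray(scores, dtype=np.float64)
    if scores.size == 0:
        raise ValueError(f"{name} is empty")
    if (scores < 0).any() or (scores > 1).any():
        raise ValueError(f"{name} must lie in [0, 1]")
    return scores


def cgan_objective(real_scores: np.ndarray, fake_scores: np.ndarray) -> float:
    """mean log D(x,y) + mean log(1 - D(x,G(x))), logs clamped at 1e-7."""
    r = _check_scores(real_scores, "real_scores")
    f = _check_scores(fake_scores, "fake_scores")
    return float(
        np.mean(np.log(np.clip(r, _LOG_EPS, None)))
        + np.mean(np.log(np.clip(1.0 - f, _LOG_EPS, None)))
    )


def l1_term(real_image: np.ndarray, generated_image: np.ndarray) -> float:
    """Per-pixel mean absolute deviation between target and synthesis."""
    real_image = np.asarray(real_image)
    generated_image = np.asarray(generated_image)
    if real_image.shape != generated_image.shape:
        raise ValueError("image shapes differ")
    return float(np.mean(np.abs(real_image.astype(np.float64) - generated_image)))


def generator_adversarial_term(fake_scores: np.ndarray, non_saturating: bool = True) -> float:
    """The generator's adversarial loss contribution (to be minimized)."""
    f = _check_scores(fake_scores, "fake_scores")
    if non_saturating:
        return float(-np.mean(np.log(np.clip(f, _LOG_EPS, None))))
    return float(np.mean(np.log(np.clip(1.0 - f, _LOG_EPS, None))))


def combined_generator_loss(
    fake_scores: np.ndarray,
    real_image: np.ndarray,
    generated_image: np.ndarray,
    l1_weight: float = 100.0,
    non_saturating: bool = True,
) -> float:
    """Adversarial generator term + lambda * L1 reconstruction term."""
    if l1_weight < 0:
        raise ValueError("l1_weight must be non-negative")
    return generator_adversarial_term(fake_scores, non_saturating) + l1_weight * l1_term(
        real_image, generated_image
    )


def _as_conditions(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=np.float32)
    if X.ndim != 4 or X.shape[1] != 2:
        raise ValueError("conditions must be (n, 2, H, W)")
    return X

def _as_images(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=np.float32)
    if y.ndim == 3:
        y = y[:, None]
    if y.ndim != 4 or y.shape[1] != 1:
        raise ValueError("images must be (n, H, W) or (n, 1, H, W)")
    return y


@dataclass
class SynthesizedDataset:
    """Mask-conditioned synthetic images; the conditioning masks are the labels."""

    images: np.ndarray          # (n, H, W) float32 in (0, 1)
    conditions: np.ndarray      # (n, 2, H, W) float32 binary
    params: list[MaskParameters]

    def __len__(self) -> int:
        return len(self.params)

    @property
    def iris_masks(self) -> np.ndarray:
        return self.conditions[:, 0].astype(np.uint8)

    def save(self, outdir) -> None:
        """PNG images + mask pairs + a parameter manifest CSV."""
        from pathlib import Path

        import imageio.v3 as iio

        from .mask_model import save_mask_png

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rows = []
        for i in range(len(self)):
            iio.imwrite(
                outdir / f"sample_{i:05d}_image.png",
                np.round(self.images[i] * 255).astype(np.uint8),
            )
            save_mask_png(self.conditions[i, 0] > 0.5, outdir / f"sample_{i:05d}_iris.png")
            save_mask_png(
                self.conditions[i, 1] > 0.5, outdir / f"sample_{i:05d}_periocular.png"
            )
            rows.append({"sample_id": i, "seed": -1, **self.params[i].to_row()})
        import pandas as pd

        pd.DataFrame(rows).to_csv(outdir / "manifest.csv", index=False)


class Pix2PixSynthesizer(BaseEstimator):
    """Conditional adversarial mask-to-image synthesizer.

    Parameters
    ----------
    depth : int
        Stride-2 stages per U-Net half; input resolution must be
        divisible by ``2**depth`` (8 for the nominal 256x256 input).
    base_width, disc_base_width : int
        First-stage channel counts of generator and discriminator.
    learning_rate, beta1, beta2, batch_size, l1_weight, epochs,
    iterations, init_std, non_saturating
        See :class:`GanTrainingConfig`; ``iterations`` overrides
        ``epochs`` with an explicit update-pair count.
    dropout_layers : int
        Decoder stages with p=0.5 dropout (5 at full depth).
    disc_lr_factor : float
        Discriminator learning rate as a fraction of the generator's.
        1.0 trains both at the same rate; smaller values slow the
        critic, a useful stabilization for short desk-scale runs where
        the L1 term carries most of the signal.
    ema_decay : float
        Exponential-moving-average decay applied to the generator
        weights; synthesis uses the averaged weights, smoothing out
        late-iteration optimization noise. 0 disables averaging.
    random_state : int
        Seeds weight init, batch order and dropout.

    Attributes
    ----------
    generator_ : UNet
        Trained mask-to-image network.
    discriminator_ : PatchDiscriminator
        Trained patch critic.
    history_ : pandas.DataFrame
        Per-iteration ``d_loss``, ``cgan_objective``, ``g_adv``, ``g_l1``.
    input_shape_ : tuple
        (H, W) the model was trained at.
    """

    def __init__(
        self,
        depth: int = 8,
        base_width: int = 64,
        disc_base_width: int = 64,
        learning_rate: float = 1e-4,
        beta1: float = 0.5,
        beta2: float = 0.99,
        batch_size: int = 64,
        l1_weight: float = 100.0,
        epochs: int = 1,
        iterations: int | None = None,
        dropout_layers: int = 5,
        init_std: float = 0.02,
        non_saturating: bool = True,
        disc_lr_factor: float = 1.0,
        ema_decay: float = 0.0,
        random_state: int = 0,
    ) -> None:
        self.depth = depth
        self.base_width = base_width
        self.disc_base_width = disc_base_width
        self.learning_rate = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.batch_size = batch_size
        self.l1_weight = l1_weight
        self.epochs = epochs
        self.iterations = iterations
        self.dropout_layers = dropout_layers
        self.init_std = init_std
        self.non_saturating = non_saturating
        self.disc_lr_factor = disc_lr_factor
        self.ema_decay = ema_decay
        self.random_state = random_state

    # -- estimator API ---------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "Pix2PixSynthesizer":
        """Adversarial training on (condition, image) pairs.

        X : (n, 2, H, W) binary conditions; y : (n, H, W) images in [0, 1].
        """
        X = _as_conditions(X)
        y = _as_images(y)
        if len(X) == 0:
            raise ValueError("empty training set")
        if len(X) != len(y) or X.shape[2:] != y.shape[2:]:
            raise ValueError("conditions and images disagree in count or resolution")
        rng = np.random.default_rng(self.random_state)
        h, w = X.shape[2:]
        gen = UNet(2, 1, depth=self.depth, base_width=self.base_width,
                   dropout_layers=self.dropout_layers, final="sigmoid", rng=rng)
        disc = PatchDiscriminator(3, base_width=self.disc_base_width, rng=rng)
        n = len(X)
        bs = min(self.batch_size, n)
        n_iter = (
            self.iterations
            if self.iterations is not None
            else self.epochs * max(1, n // bs)
        )
        opt_g = Adam(gen.parameters(), self.learning_rate, (self.beta1, self.beta2))
        # optionally slow the critic relative to the generator; with the
        # strong L1 term a too-confident critic mainly injects noise
        opt_d = Adam(
            disc.parameters(),
            self.learning_rate * self.disc_lr_factor,
            (self.beta1, self.beta2),
        )
        if not 0.0 <= self.ema_decay < 1.0:
            raise ValueError("ema_decay must be in [0, 1)")
        ema = [p.data.copy() for p in gen.parameters()] if self.ema_decay > 0 else None
        records = []
        for _ in range(int(n_iter)):
            idx = rng.choice(n, size=bs, replace=False)
            cond, real = X[idx], y[idx]
            fake = gen.forward(cond)  # train mode: dropout active
            real_trip = np.concatenate([cond, real], axis=1)
            fake_trip = np.concatenate([cond, fake], axis=1)

            # --- discriminator step: minimize -(log D(real) + log(1 - D(fake)))
            disc.zero_grad()
            s_r = disc.forward(real_trip)
            m = s_r.size
            disc.backward(-1.0 / (np.clip(s_r, _LOG_EPS, None) * m))
            s_f = disc.forward(fake_trip)
            disc.backward(1.0 / (np.clip(1.0 - s_f, _LOG_EPS, None) * m))
            obj = cgan_objective(s_r, s_f)
            opt_d.step()

            # --- generator step against the updated discriminator
            disc.zero_grad()
            s_f2 = disc.forward(fake_trip)
            if self.non_saturating:
                g_score = -1.0 / (np.clip(s_f2, _LOG_EPS, None) * s_f2.size)
            else:
                g_score = 1.0 / (np.clip(1.0 - s_f2, _LOG_EPS, None) * s_f2.size)
            dtrip = disc.backward(g_score.astype(np.float32))
            adv_grad = dtrip[:, 2:3]
            l1 = l1_term(real, fake)
            l1_grad = np.sign(fake - real) / fake.size
            gen.zero_grad()
            gen.backward((adv_grad + self.l1_weight * l1_grad).astype(np.float32))
            opt_g.step()
            disc.zero_grad()
            if ema is not None:
                for avg, p in zip(ema, gen.parameters()):
                    avg *= self.ema_decay
                    avg += (1.0 - self.ema_decay) * p.data

            records.append(
                {
                    "d_loss": -obj,
                    "cgan_objective": obj,
                    "g_adv": generator_adversarial_term(s_f2, self.non_saturating),
                    "g_l1": l1,
                }
            )
        if ema is not None:
            for avg, p in zip(ema, gen.parameters()):
                p.data[...] = avg
        self.generator_ = gen
        self.discriminator_ = disc
        self.history_ = pd.DataFrame(records)
        self.input_shape_ = (h, w)
        gen.eval()
        disc.eval()
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Synthesize images for condition stacks X (n, 2, H, W)."""
        self._check_fitted()
        X = _as_conditions(X)
        out = []
        for start in range(0, len(X), 32):
            out.append(self.generator_.forward(X[start : start + 32])[:, 0])
        return np.concatenate(out, axis=0)

    def generate(self, condition: ConditionPair) -> np.ndarray:
        """Synthesize one image from a condition pair (eval mode, deterministic)."""
        return self.transform(condition.stack()[None])[0]

    def synthesize(
        self,
        n: int,
        ranges: ParameterRanges | None = None,
        seed: int | None = 0,
        rescale_ranges: bool = True,
    ) -> SynthesizedDataset:
        """Sample n mask pairs and synthesize their images.

        The conditioning masks are stored untouched alongside the
        images — they are the free segmentation labels.
        """
        self._check_fitted()
        ranges = ranges if ranges is not None else ParameterRanges()
        shape = self.input_shape_
        if rescale_ranges:
            ranges = scale_ranges(ranges, shape)
        root = np.random.SeedSequence(seed)
        params_list, conds = [], []
        for child in root.spawn(n):
            params = sample_parameters(ranges, np.random.default_rng(child))
            params_list.append(params)
            conds.append(
                np.stack(
                    [
                        rasterize_iris_mask(params, shape),
                        rasterize_periocular_mask(params, shape),
                    ]
                ).astype(np.float32)
            )
        conditions = np.stack(conds)
        images = self.transform(conditions)
        return SynthesizedDataset(images, conditions, params_list)

    def _check_fitted(self) -> None:
        if not hasattr(self, "generator_"):
            raise RuntimeError("synthesizer is not fitted")

    # -- persistence -----------------------------------------------------

    def save(self, path) -> None:
        """Checkpoint: constructor params, input shape, and all weights."""
        import json

        self._check_fitted()
        arrays = {f"g{i}": p.data for i, p in enumerate(self.generator_.parameters())}
        arrays |= {f"d{i}": p.data for i, p in enumerate(self.discriminator_.parameters())}
        meta = json.dumps({"params": self.get_params(), "input_shape": list(self.input_shape_)})
        np.savez(path, meta=np.array(meta), **arrays)

    @classmethod
    def load(cls, path) -> "Pix2PixSynthesizer":
        import json

        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            model = cls(**meta["params"])
            rng = np.random.default_rng(model.random_state)
            gen = UNet(2, 1, depth=model.depth, base_width=model.base_width,
                       dropout_layers=model.dropout_layers, final="sigmoid", rng=rng)
            disc = PatchDiscriminator(3, base_width=model.disc_base_width, rng=rng)
            for i, p in enumerate(gen.parameters()):
                p.data[...] = data[f"g{i}"]
            for i, p in enumerate(disc.parameters()):
                p.data[...] = data[f"d{i}"]
        gen.eval()
        disc.eval()
        model.generator_ = gen
        model.discriminator_ = disc
        model.input_shape_ = tuple(meta["input_shape"])
        model.history_ = pd.DataFrame()
        return model


# -- thin functional wrappers -------------------------------------------


def generator_forward(generator: UNet, condition: np.ndarray) -> np.ndarray:
    """Run a condition stack (2, H, W) or batch (n, 2, H, W) through a generator."""
    condition = np.asarray(condition, dtype=np.float32)
    single = condition.ndim == 3
    if single:
        condition = condition[None]
    out = generator.forward(condition)
    return out[0, 0] if single else out[:, 0]


def discriminator_forward(
    discriminator: PatchDiscriminator, condition: np.ndarray, image: np.ndarray
) -> np.ndarray:
    """Score a (condition, image) pair; returns the sigmoid patch map."""
    condition = np.asarray(condition, dtype=np.float32)
    image = np.asarray(image, dtype=np.float32)
    single = condition.ndim == 3
    if single:
        condition = condition[None]
    if image.ndim == 2:
        image = image[None]
    if image.ndim == 3:
        image = image[:, None]
    if condition.shape[0] != image.shape[0] or condition.shape[2:] != image.shape[2:]:
        raise ValueError("condition and image shapes disagree")
    out = discriminator.forward(np.concatenate([condition, image], axis=1))
    return out[0, 0] if single else out[:, 0]


def train_generation_model(
    conditions: np.ndarray,
    images: np.ndarray,
    config: GanTrainingConfig | None = None,
    depth: int = 8,
    base_width: int = 64,
    random_state: int = 0,
) -> Pix2PixSynthesizer:
    """Functional entry point over :class:`Pix2PixSynthesizer`."""
    config = config if config is not None else GanTrainingConfig()
    config.validate()
    model = Pix2PixSynthesizer(
        depth=depth,
        base_width=base_width,
        disc_base_width=base_width,
        learning_rate=config.learning_rate,
        beta1=config.beta1,
        beta2=config.beta2,
        batch_size=config.batch_size,
        l1_weight=config.l1_weight,
        epochs=config.epochs,
        iterations=config.iterations,
        init_std=config.init_std,
        non_saturating=config.non_saturating,
        random_state=random_state,
    )
    return model.fit(conditions, images)


def synthesize_dataset(
    generator: Pix2PixSynthesizer,
    n: int,
    ranges: ParameterRanges | None = None,
    seed: int | None = 0,
) -> SynthesizedDataset:
    return generator.synthesize(n, ranges=ranges, seed=seed)
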