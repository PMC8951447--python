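"""Shared fixtures.

The heavyweight end-to-end artifacts (the smoke pipeline run and the
multi-seed trend table) are session-scoped so the several tests that
inspect them pay for one run only.
"""

from __future__ import annotations

import numpy as np
import pytest

from irisynth.data_pipeline import (
    ExperimentConfig,
    labels_from_conditions,
    trend_experiment,
)
from irisynth.evaluation import segmentation_report
from irisynth.gen_net import Pix2PixSynthesizer
from irisynth.renderer import render_dataset
from irisynth.seg_net import IrisSegmenter

SMOKE_SEED = 7


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def tiny_render():
    """Small rendered set for unit-level training tests (32x32)."""
    return render_dataset(48, seed=11, shape=(32, 32))


@pytest.fixture(scope="session")
def smoke_run():
    """The full self-supervised loop at desk scale, from one seed.

    Renders 200 real-proxy pairs at 64x64, trains the adversarial
    synthesizer for 200 update pairs, synthesizes 200 mask-conditioned
    images, trains the segmentor for 10 epochs on them alone, and
    scores it on a held-out rendered test set.
    """
    ss = np.random.SeedSequence(SMOKE_SEED)
    s = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(5)]
    train = render_dataset(200, seed=s[0], shape=(64, 64))
    test = render_dataset(64, seed=s[1], shape=(64, 64))
    synth = Pix2PixSynthesizer(
        depth=6, base_width=24, disc_base_width=24,
        learning_rate=2e-3, disc_lr_factor=0.25, ema_decay=0.97,
        batch_size=16, iterations=200, random_state=s[2],
    )
    synth.fit(train.conditions, train.images)
    generated = synth.synthesize(200, seed=s[3])
    seg = IrisSegmenter(
        depth=6, base_width=32, dropout_layers=0,
        learning_rate=2e-3, batch_size=16, epochs=10, random_state=s[4],
    )
    seg.fit(generated.images, labels_from_conditions(generated.conditions))
    report = segmentation_report(
        seg.predict(test.images), labels_from_conditions(test.conditions), 2
    )
    return {
        "train": train,
        "test": test,
        "synthesizer": synth,
        "generated": generated,
        "segmenter": seg,
        "report": report,
        "l1_history": synth.history_["g_l1"].to_numpy(),
    }


@pytest.fixture(scope="session")
def trend_table():
    """Reduced-scale training-set-size trend over three seeds (32x32)."""
    cfg = ExperimentConfig(
        shape=(32, 32), n_real=96, n_generated=96, n_test=48,
        gan_depth=5, gan_iterations=120, seg_depth=5, seg_epochs=8,
    )
    return trend_experiment(cfg, seeds=(0, 1, 2))
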