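"""Shared fixtures: small synthetic stacks generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from bcdquant import preprocess, spatialstats, spotdetect, synthgen

SMALL_SHAPE = (16, 192, 320)  # (z, y, x) desk-scale stack for unit tests


@pytest.fixture(scope="session")
def blasto_model():
    return synthgen.blastoderm_model()


@pytest.fixture(scope="session")
def early_model():
    return synthgen.early_model()


@pytest.fixture(scope="session")
def small_blasto(blasto_model):
    """A small rendered blastoderm stack with truth, preprocessed table."""
    particles = synthgen.sample_particles(blasto_model, 250, seed=7, shape=SMALL_SHAPE)
    stack = synthgen.render_stack(particles, blasto_model, synthgen.RenderSpec(seed=7), shape=SMALL_SHAPE)
    pre = preprocess.preprocess(stack, n_patches=1500, seed=7)
    table = spotdetect.detect(pre)
    reg = spatialstats.AxisRegistration.for_synthetic(blasto_model, SMALL_SHAPE)
    return dict(particles=particles, stack=stack, pre=pre, table=table, registration=reg)


@pytest.fixture(scope="session")
def separated_spots(blasto_model):
    """Well-separated bright spots on a jittered grid (high-SNR regime)."""
    rng = np.random.default_rng(42)
    shape = (14, 160, 160)
    particles = []
    i = 0
    for y in range(14, 146, 8):
        for x in range(14, 146, 8):
            if len(particles) >= 500:
                break
            particles.append(
                synthgen.ParticleTruth(
                    id=i,
                    x_px=x + rng.uniform(-1, 1),
                    y_px=y + rng.uniform(-1, 1),
                    z_slice=rng.uniform(3, 10),
                    ap_fraction=min(x / 160.0, 1.0),
                    depth_frac=0.0,
                    n_mrna=int(rng.integers(2, 8)),
                    photon_amplitude=float(rng.uniform(3000, 9000)),
                )
            )
            i += 1
    spec = synthgen.RenderSpec(seed=3)
    stack = synthgen.render_stack(particles, blasto_model, spec, shape=shape)
    return particles, stack
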