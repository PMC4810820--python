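"""Shared fixtures: synthetic objects rendered once per session."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from stackhull import synthstack as ss
from stackhull.pipeline import process_object

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

S = ss.DEFAULT_SLICES
Z = ss.DEFAULT_Z_STEP_UM


def disc_mask(n, r, center=None):
    cy = cx = n / 2.0 if center is None else None
    if center is not None:
        cy, cx = center
    yy, xx = np.mgrid[0:n, 0:n]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


@pytest.fixture(scope="session")
def hemisphere_truth():
    """Noisy rendered hemisphere (r = 300 µm) plus its analytic truth."""
    r, n = 300.0, 680
    spec = ss.ShapeSpec("hemispheroid", a_um=r, b_um=r, relief_um=r,
                        center_um=(n / 2.0, n / 2.0))
    hf, gt = ss.make_heightfield(spec, (n, n), px_um=1.0)
    stack = ss.render_zstack(hf, ss.Optics(), seed=7)
    return hf, gt, stack


@pytest.fixture(scope="session")
def hemisphere_result(hemisphere_truth):
    """End-to-end pipeline output for the rendered hemisphere."""
    _hf, _gt, stack = hemisphere_truth
    return process_object(stack)


@pytest.fixture(scope="session")
def noise_free_hemisphere():
    """Small noise-free hemisphere stack for focus-recovery properties."""
    r, n = 150.0, 340
    spec = ss.ShapeSpec("hemispheroid", a_um=r, b_um=r, relief_um=r,
                        center_um=(n / 2.0, n / 2.0))
    hf, gt = ss.make_heightfield(spec, (n, n), px_um=1.0)
    stack = ss.render_zstack(hf, ss.Optics(noise_sd=0.0), seed=3)
    return hf, gt, stack
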