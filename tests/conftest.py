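import math

import numpy as np
import pytest

from shadowcyte.optics import (OpticsConfig, Scene, bead_phantom,
                               render_shadow_image)


@pytest.fixture(scope="session")
def cfg_small() -> OpticsConfig:
    """Compact sensor for single-pattern tests."""
    return OpticsConfig(sensor_shape=(192, 192))


@pytest.fixture(scope="session")
def cfg_default() -> OpticsConfig:
    return OpticsConfig()


@pytest.fixture(scope="session")
def bead_frame(cfg_small):
    """One centred 15 um bead: (image, truth)."""
    scene = Scene(phantoms=(bead_phantom((0.0, 0.0), 15.0),),
                  field_extent=cfg_small.field_extent)
    return render_shadow_image(scene, cfg_small, seed=4)


def match_detections(truth, rois, tol_px=3.0):
    """Greedy one-to-one matching; returns (n_matched, errors)."""
    used = set()
    errors = []
    n = 0
    for t in truth:
        best, best_d = None, math.inf
        for k, roi in enumerate(rois):
            if k in used:
                continue
            d = math.hypot(roi.center[0] - t["row"], roi.center[1] - t["col"])
            if d < best_d:
                best_d, best = d, k
        if best is not None and best_d <= tol_px:
            used.add(best)
            errors.append(best_d)
            n += 1
    return n, errors
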