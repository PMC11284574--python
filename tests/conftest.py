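import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import petalseg as ps

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


SMALL_SPEC = dict(image_shape=(160, 160), n_slices=3, n_petals=6,
                  spiral_pitch=9.0, petal_thickness_px=5.0,
                  inter_petal_gap_px=2.0, noise_sigma=3.0, rng_seed=1)

MINI_CONFIG = dict(crop_length=260, crop_width=24, angle_step_deg=2.0, seed=1)


@pytest.fixture(scope="session")
def small_spec() -> ps.PhantomSpec:
    return ps.PhantomSpec(**SMALL_SPEC)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    """A 6-petal, 3-slice phantom volume with its ground truth."""
    return ps.generate_volume(small_spec)


@pytest.fixture(scope="session")
def mini_config() -> ps.PipelineConfig:
    return ps.PipelineConfig(**MINI_CONFIG)


@pytest.fixture(scope="session")
def mini_closure(small_phantom, mini_config):
    """Full pipeline on the small phantom with the zero-noise oracle."""
    vol, gt = small_phantom
    res = ps.run_pipeline(vol, ps.OracleBackend(gt.masks), mini_config, gt=gt)
    return res, gt


def best_iou_per_gt(pred: np.ndarray, gt: np.ndarray) -> dict[int, float]:
    """For each GT label, the best IoU over predicted labels (any dimension)."""
    out = {}
    pred_ids = np.unique(pred)
    pred_ids = pred_ids[pred_ids > 0]
    for gid in np.unique(gt):
        if gid == 0:
            continue
        gm = gt == gid
        best = 0.0
        for pid in pred_ids:
            pm = pred == pid
            inter = np.logical_and(gm, pm).sum()
            if inter == 0:
                continue
            best = max(best, inter / np.logical_or(gm, pm).sum())
        out[int(gid)] = float(best)
    return out
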