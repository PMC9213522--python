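import numpy as np
import pytest

import orbitlakes as ol


@pytest.fixture(scope="session")
def bowl_truth():
    """Noise-free single-basin lake: 21x21 bowl, 24 months of seasonal levels."""
    bathy = ol.make_bathymetry("bowl", (21, 21), seed=1)
    levels = ol.simulate_levels(ol.LevelParams(mean=0.5, seasonal_amplitude=0.3,
                                               noise_sd=0.0), T=24, seed=1)
    return ol.render_truth(bathy, levels)


@pytest.fixture(scope="session")
def corrupted_bowl():
    """Default-condition corrupted bowl with its ground truth (seed 42)."""
    cfg = ol.SyntheticLakeConfig(seed=42)
    stack, truth = ol.generate(cfg)
    return stack, truth


@pytest.fixture()
def clean_stack(bowl_truth):
    """Ternary stack with zero noise and zero missingness."""
    return ol.corrupt(
        bowl_truth.true_stack,
        ol.NoiseParams(0.0, 0.0),
        ol.MissingParams(0.0, 0, 0.0, 0),
        seed=0,
    )


def correct_extracted_lake(stack, **orbit_kwargs):
    """Extraction + correction of the largest lake in a scene stack."""
    occ = ol.compute_occurrence(stack)
    records = ol.extract_lakes(occ)
    rec = max(records, key=lambda r: r.n_pixels)
    local, mask = ol.extract_lake_stack(stack, rec)
    cfg = ol.OrbitConfig(**orbit_kwargs) if orbit_kwargs else ol.OrbitConfig()
    corrected = ol.correct_stack(local, mask=mask, config=cfg)
    return rec, local, corrected


def crop_like(arr_2d_or_3d, rec, scene_shape, padding=2):
    """Crop a truth array to the padded bounding box used by extract_lake_stack."""
    r0, r1, c0, c1 = rec.bbox
    R, C = scene_shape
    r0, c0 = max(0, r0 - padding), max(0, c0 - padding)
    r1, c1 = min(R, r1 + padding), min(C, c1 + padding)
    return arr_2d_or_3d[..., r0:r1, c0:c1]
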