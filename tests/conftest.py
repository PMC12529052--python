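import numpy as np
import pytest

import stomagrid as sg


@pytest.fixture(scope="session")
def small_leaf():
    """A 2 x 2 mm uniform-density leaf with veins and border, plus truth."""
    spec = sg.SyntheticLeafSpec(
        width_mm=2.0, height_mm=2.0, base_density_mm2=70.0, tip_density_mm2=70.0, seed=7
    )
    img, truth = sg.generate_leaf_image(spec)
    return spec, img, truth


@pytest.fixture(scope="session")
def small_detection(small_leaf):
    """Full preprocess + exclusion mask + detection on the small leaf."""
    _, img, _ = small_leaf
    pre = sg.preprocess(img)
    mask = sg.exclusion_mask(pre)
    stomata = sg.detect_stomata(pre, mask=mask)
    return pre, mask, stomata


@pytest.fixture(scope="session")
def flat_leaf():
    """A 2 x 2 mm leaf with no veins and no border (mask-free geometry)."""
    spec = sg.SyntheticLeafSpec(
        width_mm=2.0,
        height_mm=2.0,
        base_density_mm2=60.0,
        tip_density_mm2=60.0,
        vein_count=0,
        border_um=0.0,
        seed=11,
    )
    img, truth = sg.generate_leaf_image(spec)
    return spec, img, truth


def truth_stoma_set(truth, img):
    """Build a StomaSet directly from ground-truth centroids (no detection)."""
    import pandas as pd

    df = pd.DataFrame(
        {
            "centroid_x_um": truth.records.centroid_x_um,
            "centroid_y_um": truth.records.centroid_y_um,
            "area_um2": truth.records.area_um2,
            "circularity": 0.75,
            "method": "truth",
        }
    )
    return sg.StomaSet(df, None, img.area_um2)
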