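import warnings

import numpy as np
import pandas as pd
import pytest

import leukopan as lp
from leukopan.render import RenderParams, render_field

warnings.filterwarnings("ignore", message="only .* donors")
warnings.filterwarnings("ignore", message="donor .*: only")


@pytest.fixture(scope="session")
def panel():
    # smaller spots so the reduced test rosters cover every spot's demand
    return lp.default_panel(spot_diameter_mm=0.8)


@pytest.fixture(scope="session")
def small_cohort_params():
    """Smaller rosters for speed; statistics unchanged."""
    return lp.CohortParams(n_cells=8000)


@pytest.fixture(scope="session")
def healthy_truth(small_cohort_params):
    return lp.build_healthy_profile(small_cohort_params, seed=11)


@pytest.fixture(scope="session")
def healthy_capture(healthy_truth, panel):
    return lp.simulate_capture(healthy_truth, panel, seed=12)


@pytest.fixture(scope="session")
def mixed_field():
    """A rendered field with all common morphotypes, plus its ground truth."""
    morphs = (
        ["small_lymphocyte"] * 180
        + ["large_lymphocyte"] * 20
        + ["granular_lymphocyte"] * 60
        + ["lobed_lymphocyte"] * 12
        + ["granular_lobed_lymphocyte"] * 8
        + ["monocyte"] * 40
    )
    roster = pd.DataFrame({"morphotype": morphs, "diameter_um": np.nan})
    return render_field(roster, 0.62, 0.62, RenderParams(pixel_scale_um=0.25), seed=5)


@pytest.fixture(scope="session")
def mixed_field_segmentation(mixed_field):
    from leukopan.segment import segment_cells

    return segment_cells(mixed_field)


@pytest.fixture(scope="session")
def mixed_field_cells(mixed_field_segmentation):
    from leukopan.morphometry import measure_all

    return measure_all(mixed_field_segmentation)
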