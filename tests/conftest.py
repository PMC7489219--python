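import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim_config():
    from neuroscreen.synthetic_data import SimulationConfig

    return SimulationConfig(seed=0)


@pytest.fixture(scope="session")
def rendered_field(sim_config):
    """One default-density field (200 live + 50 dead) with truth."""
    from neuroscreen.synthetic_data import render_well_image

    img, truth = render_well_image(200, 50, sim_config, seed=11)
    return img, truth


@pytest.fixture(scope="session")
def segmented_field(rendered_field):
    from neuroscreen import nuclei

    img, truth = rendered_field
    labels, records = nuclei.segment_nuclei(img)
    feats = nuclei.extract_features(labels, img)
    return img, truth, labels, feats


@pytest.fixture(scope="session")
def labeled_features(segmented_field):
    """Segmented features carrying matched ground-truth classes."""
    from neuroscreen import nuclei

    img, truth, labels, feats = segmented_field
    tru = np.array([[t.row, t.col] for t in truth])
    cls = np.array([t.cls for t in truth])
    m = nuclei.match_centroids(
        feats[["centroid_row", "centroid_col"]].to_numpy(), tru, max_dist=5.0
    )
    out = feats.iloc[[d for _, d, _ in m["pairs"]]].copy()
    out["cls"] = [cls[t] for t, _, _ in m["pairs"]]
    return out
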