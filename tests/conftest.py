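import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from barcheck import chartgen, pipeline

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noiseless_table():
    """Oracle-parsed feature table with exact features (no OCR noise).

    A high violation rate keeps every violation kind well represented at a
    small corpus size.
    """
    return pipeline.corpus_feature_table(400, violation_rate=0.25, seed=101)


@pytest.fixture(scope="session")
def rendered_corpus():
    """200 rendered charts of all kinds with ground truth, for the pixel
    pipeline (localization / roles / axes)."""
    rng = np.random.default_rng(2024)
    kinds = (
        ["none"] * 150
        + ["nonzero_baseline"] * 20
        + ["inconsistent_scale"] * 15
        + ["hidden_axis"] * 15
    )
    out = []
    for kind in kinds:
        spec = chartgen.sample_spec(rng, kind)
        img, gt = chartgen.generate_chart(spec)
        out.append((spec, img, gt))
    return out
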