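import pandas as pd
import pytest

from pcpattach.synthetic import ScenarioConfig, generate, preset_paper_like


@pytest.fixture(scope="session")
def tiny_bundle():
    """A small mixed scenario exercising every table and both provider kinds."""
    cfg = ScenarioConfig(
        n_patients=300,
        n_providers=12,
        walk_in_provider_fraction=0.25,
        seed=42,
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def midsize_run():
    """Preset scenario at n=2000 with attachment already run (shared, read-only)."""
    from pcpattach.attachment import run_attachment

    bundle = generate(preset_paper_like(n_patients=2000, seed=5))
    index_dates = bundle.survey_index_dates()
    results, flow = run_attachment(bundle.data(), index_dates)
    return bundle, index_dates, results, flow


def frames_equal(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    try:
        pd.testing.assert_frame_equal(a.reset_index(drop=True), b.reset_index(drop=True))
        return True
    except AssertionError:
        return False
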