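import numpy as np
import pytest

from profilemix import datagen


@pytest.fixture(scope="session")
def small_scenario():
    """A compact use-report scenario shared by exposure/spatial tests."""
    cfg = datagen.ScenarioConfig(n_subjects=24, seed=7)
    apps, res, preg, sections, outcome, truth = datagen.generate_use_report_scenario(cfg)
    return {
        "config": cfg,
        "applications": apps,
        "residences": res,
        "pregnancies": preg,
        "sections": sections,
        "outcome": outcome,
        "truth": truth,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
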