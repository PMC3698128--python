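import pytest

from mscea import MarkovCohortModel, default_parameters

ALL_STRATEGIES = (
    None,
    "avonex",
    "rebif",
    "betaferon",
    "cbp_im_1a",
    "cbp_sc_1a",
    "cbp_sc_1b",
)


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def cohort_results(params):
    """One cohort projection per strategy (symptom management keyed None)."""
    return {sid: MarkovCohortModel(params, sid).run() for sid in ALL_STRATEGIES}


@pytest.fixture()
def fresh_params(params):
    return params.copy()
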