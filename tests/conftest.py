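import pandas as pd
import pytest
from hypothesis import settings

import afscreen as af

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def men():
    return af.default_transitions("men")


@pytest.fixture(scope="session")
def women():
    return af.default_transitions("women")


@pytest.fixture(scope="session")
def qol():
    return af.default_qol()


@pytest.fixture(scope="session")
def calibrated(men, qol):
    """Model config with accrual/discount conventions fixed on the anchor cell."""
    return af.calibrate_conventions(men, qol)


@pytest.fixture(scope="session")
def tables(men, women):
    return {"men": men, "women": women}


@pytest.fixture(scope="session")
def study_fixture():
    return af.fixture_table4()


@pytest.fixture(scope="session")
def make_flat_table():
    """Factory for synthetic transition tables with flat probabilities.

    All three alive profiles share the given stroke/death probabilities in
    every pre-terminal band; the terminal band forces death as always.
    """

    def factory(sex="men", p_stroke=0.0, p_death=0.0, p_post_death=0.0, **kwargs):
        rows = {}
        for band in af.AGE_BANDS:
            if band == "100+":
                rows[band] = dict(
                    p_s0e1=0.0, p_s0e2=1.0, p_t1e1=0.0, p_t1e2=1.0,
                    p_t0e1=0.0, p_t0e2=1.0, p_e1e2=1.0,
                )
            else:
                rows[band] = dict(
                    p_s0e1=p_stroke, p_s0e2=p_death,
                    p_t1e1=p_stroke, p_t1e2=p_death,
                    p_t0e1=p_stroke, p_t0e2=p_death,
                    p_e1e2=p_post_death,
                )
        probs = pd.DataFrame(rows).T
        return af.TransitionTable(sex=sex, probs=probs, **kwargs)

    return factory


@pytest.fixture()
def toy_population():
    """Flat population: 500k per five-year band, both sexes."""
    rows = [
        {"sex": s, "age_band": b, "count": 500_000}
        for s in ("men", "women")
        for b in ("65-69", "70-74", "75-79", "80-84")
    ]
    return af.PopulationTable(pd.DataFrame(rows))
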