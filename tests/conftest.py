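import numpy as np
import pytest

from deathscreen.medusa import MedusaScreen, ScreenTimeline
from deathscreen.rates import RatePair
from deathscreen import simulate as dssim

# Wild-type study conditions: untreated cells double every ~33 h with a low
# basal death rate; the drug halves proliferation and raises death ten-fold.
UNTREATED = RatePair(g=0.03, d=0.001)
TREATED = RatePair(g=0.015, d=0.01)


@pytest.fixture(scope="session")
def timeline() -> ScreenTimeline:
    return ScreenTimeline(untreated_rates=UNTREATED, treated_rates=TREATED)


@pytest.fixture(scope="session")
def screen_library():
    return dssim.random_guide_library(seed=1)


@pytest.fixture(scope="session")
def screen_truth(screen_library, timeline):
    return dssim.make_screen_truth(screen_library, timeline, seed=1)


@pytest.fixture(scope="session")
def screen_counts(screen_truth, screen_library, timeline):
    return dssim.simulate_screen(screen_truth, screen_library, timeline, seed=1)


@pytest.fixture(scope="session")
def medusa_results(screen_counts, screen_library, timeline):
    return MedusaScreen(screen_counts, screen_library, timeline).fit(
        iterations=2000, seed=1
    )


@pytest.fixture(scope="session")
def small_library():
    """Four-guide toy library, one non-targeting."""
    import pandas as pd
    from deathscreen.io import GuideLibrary

    return GuideLibrary(pd.DataFrame({
        "guide_id": ["g1", "g2", "g3", "nt1"],
        "sequence": ["ACGTACGTACGTACGTACGT", "TTTTACGTACGTACGTACGT",
                     "CCCCACGTACGTACGTACGT", "GGGGACGTACGTACGTACGT"],
        "gene": ["GENEA", "GENEA", "GENEB", "NON_TARGETING"],
        "is_nontargeting": [False, False, False, True],
    }))
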