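import numpy as np
import pandas as pd
import pytest

import catchvuln as cv
from catchvuln.synthetic import PLAY_NAMES


def small_profiles(n=80, dispersion=1.0):
    """Six plays scaled down to n catchments each (targets unchanged)."""
    profiles = []
    for p in cv.default_profiles(dispersion=dispersion):
        profiles.append(cv.PlayProfile(p.play_name, n, p.variables))
    return profiles


@pytest.fixture(scope="session")
def catchment_table():
    """A six-play synthetic table, 80 catchments per play."""
    return cv.generate_table(small_profiles(), seed=7)


@pytest.fixture(scope="session")
def score_table(catchment_table):
    return cv.score_table(catchment_table)
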