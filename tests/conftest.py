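"""Shared session fixtures for the full treatment-scenario simulations.

The three scenario reports are expensive (Rayleigh fields plus multi-phase
bioheat runs); they are computed once per session and shared by the
acceptance tests.
"""

import pytest

from hifufusion import scenarios as sc


@pytest.fixture(scope="session")
def spherical_report():
    return sc.run_scenario(sc.ScenarioConfig("single-spherical"))


@pytest.fixture(scope="session")
def raster_report():
    return sc.run_scenario(sc.ScenarioConfig("raster-7x7"))


@pytest.fixture(scope="session")
def toroidal_report():
    return sc.run_scenario(sc.ScenarioConfig("single-toroidal"))
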