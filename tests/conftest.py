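"""Shared fixtures.

The heavy treatment scenarios (full-resolution bioheat + 72 h transport)
are computed once per session and shared by the unit, property and
acceptance layers; every run is deterministic, so sharing loses nothing.
"""

from __future__ import annotations

import numpy as np
import pytest

import thermolipo as tl
from thermolipo.params import apply_overrides

# coarse but still converged-enough settings for structural unit tests
COARSE = {
    "solver.n_injection": 15, "solver.n_tumor": 40, "solver.n_normal": 25,
    "solver.dt_transport": 36.0, "solver.dt_transport_mht": 7.2,
    "solver.checkpoint_interval": 1800.0,
}


@pytest.fixture(scope="session")
def default_config():
    return tl.load_scenario("")


@pytest.fixture(scope="session")
def grid(default_config):
    g = default_config.geometry
    return tl.build_grid(g.injection_radius, g.tumor_radius, g.outer_radius)


@pytest.fixture(scope="session")
def coarse_combo_config():
    return apply_overrides(tl.load_preset("combo_9h"), COARSE)


@pytest.fixture(scope="session")
def mht11_result():
    return tl.run_scenario(tl.load_preset("mht_11kAm"))


@pytest.fixture(scope="session")
def mht13_result():
    return tl.run_scenario(tl.load_preset("mht_13kAm"))


@pytest.fixture(scope="session")
def combo_result():
    return tl.run_scenario(tl.load_preset("combo_9h"))


@pytest.fixture(scope="session")
def pore100_result():
    return tl.run_scenario(tl.load_preset("combo_pore_100nm"))


@pytest.fixture(scope="session")
def delay_sweep_rows():
    base = tl.load_preset("combo_9h")
    hours = [0.0, 9.0, 16.0, 24.0, 48.0]
    return tl.run_sweep(base, "delay", [h * 3600.0 for h in hours])


@pytest.fixture(scope="session")
def dose_sweep_rows():
    base = tl.load_preset("combo_9h")
    return tl.run_sweep(base, "dose", [0.5, 1.0, 1.5])
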