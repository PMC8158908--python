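"""Shared fixtures: default study conditions are built once per session."""

from __future__ import annotations

import time

import numpy as np
import pytest

from hrasim.geometry import AnatomySpec, ImplantSpec, build_cup_mesh, build_femur_mesh
from hrasim.sweep import SweepConfig, SweepEngine, run_sweep


@pytest.fixture(scope="session")
def anatomy() -> AnatomySpec:
    return AnatomySpec()


@pytest.fixture(scope="session")
def implant() -> ImplantSpec:
    return ImplantSpec()


@pytest.fixture(scope="session")
def femur(anatomy, implant):
    """Default femur at 1 mm target edge length (the study resolution)."""
    return build_femur_mesh(anatomy, implant, resolution=1.0)


@pytest.fixture(scope="session")
def cup(implant):
    return build_cup_mesh(implant, resolution=1.0)


@pytest.fixture(scope="session")
def engine() -> SweepEngine:
    """Engine under the default study conditions (calibrated foundation)."""
    return SweepEngine(SweepConfig())


@pytest.fixture(scope="session")
def sweep_result(engine):
    """Full 60-configuration sweep plus its wall-clock time (seconds)."""
    t0 = time.perf_counter()
    table = run_sweep(engine=engine)
    elapsed = time.perf_counter() - t0
    return table, elapsed


@pytest.fixture(scope="session")
def sweep_table(sweep_result):
    return sweep_result[0]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20210527)
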