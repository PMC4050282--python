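"""Shared fixtures: simulations of the canonical protocols are expensive, so
they run once per session and are reused across analysis tests."""

from __future__ import annotations

import numpy as np
import pytest

from axinit.cable import (
    SolverConfig,
    StimulusProtocol,
    forced_spike_protocol,
    run,
)
from axinit.morphology import (
    CableModel,
    DensityProfile,
    GranuleCellParams,
    Section,
    build_granule_cell,
)
from axinit.channels import ChannelSpec

PULSE_TIMES = tuple(40.0 + 50.0 * k for k in range(5))


@pytest.fixture(scope="session")
def default_model() -> CableModel:
    return build_granule_cell()


@pytest.fixture(scope="session")
def step_trace(default_model):
    """Depolarization-driven spiking: 130 pA somatic step (Depo+Spikes)."""
    proto = StimulusProtocol(kind="current_step", amplitude=130.0, onset=20.0,
                             duration=260.0)
    return run(default_model, proto,
               SolverConfig(duration=300.0, record_currents=("ca",)))


@pytest.fixture(scope="session")
def spikes_only_trace(default_model):
    """Five forced spikes at 20 Hz from rest (no holding depolarization)."""
    proto = forced_spike_protocol(5, 20.0, hold_at_rest=True)
    return run(default_model, proto,
               SolverConfig(duration=320.0, record_currents=("ca",),
                            record_gates=("na_a.h", "na_a.s")))


@pytest.fixture(scope="session")
def depo_spikes_trace(default_model):
    """Five forced spikes at 20 Hz riding a subthreshold depolarization."""
    proto = forced_spike_protocol(5, 20.0, hold_at_rest=False)
    return run(default_model, proto,
               SolverConfig(duration=320.0, record_currents=("ca",),
                            record_gates=("na_a.h", "na_a.s")))


def make_passive_single_compartment(
    g_leak: float = 2.5e-5, e_leak: float = -80.0,
    length: float = 10.0, diameter: float = 10.0,
) -> CableModel:
    """One cylindrical compartment with a leak conductance only."""
    leak = ChannelSpec("leak", "leak", e_leak, gates=())
    return CableModel(
        sections=[Section("soma", None, length, diameter, 150.0, 1, "soma")],
        channels=[(leak, DensityProfile("leak", "uniform", baseline=g_leak))],
        resting_potential=e_leak,
        calibrate_rest=False,
    )


@pytest.fixture()
def passive_comp() -> CableModel:
    return make_passive_single_compartment()
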