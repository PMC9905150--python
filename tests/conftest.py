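"""Shared fixtures: one mid-sized simulated exposure reused across modules.

All fixtures are deterministic; the forward simulation and the inverse solve
are session-scoped because they are the expensive pieces.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import softgrid as sg


@pytest.fixture(scope="session")
def default_spec() -> sg.PhantomSpec:
    return sg.PhantomSpec()


@pytest.fixture(scope="session")
def default_phantom(default_spec) -> sg.DigitalPhantom:
    return sg.make_phantom(default_spec, seed=7)


@pytest.fixture(scope="session")
def acq() -> sg.AcquisitionConfig:
    return sg.AcquisitionConfig(seed=3)


@pytest.fixture(scope="session")
def default_sim(default_phantom, acq) -> sg.SimulatedRadiograph:
    return sg.simulate_raw(default_phantom, acq)


@pytest.fixture(scope="session")
def tube_sim() -> sg.SimulatedRadiograph:
    """A thicker phantom with the tube insert: mean SPR above 1."""
    spec = sg.PhantomSpec(body_thickness_cm=12.0, thorax_thickness_cm=24.0)
    phantom = sg.make_phantom(spec, seed=5)
    return sg.simulate_raw(phantom, sg.AcquisitionConfig(seed=5))


@pytest.fixture(scope="session")
def tube_estimate(tube_sim) -> sg.ScatterEstimate:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sg.estimate_scatter(tube_sim.raw)


def uniform_slab(t_tissue_cm: float, shape=(64, 64), pitch_mm=1.6) -> sg.DigitalPhantom:
    return sg.DigitalPhantom(
        np.full(shape, float(t_tissue_cm)),
        np.zeros(shape),
        pixel_pitch_mm=pitch_mm,
    )


@pytest.fixture(scope="session")
def null_scores():
    """Default study design, no arm effect, seed 0."""
    return sg.generate_scores(sg.StudyDesign(), sg.EffectModel(seed=0))
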