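"""Shared fixtures: small synthetic sessions with planted ground truth.

Heavier fixtures are session-scoped so the expensive design/Gram
construction happens once per test run.
"""

from __future__ import annotations

import numpy as np
import pytest

from catglm.design import default_regressor_sets
from catglm.glm import GlmEngine
from catglm.simulate import (AgentParams, PlantedKernels,
                             simulate_behavior_session, simulate_neural_session)
from catglm.spaces import build_category_space, reduce_to_category_stimuli

#: chronic-imaging style space: 6 orientations x 5 SFs, 23 deg boundary,
#: reduced to the 10 stimuli nearest the boundary
CHRONIC_SFS = [0.04, 0.06, 0.08, 0.12, 0.16]


@pytest.fixture(scope="session")
def full_grid_space():
    """7x7 touch-screen space with the 45 deg diagonal boundary."""
    return build_category_space(
        7, 15.0, [0.03, 0.035, 0.04, 0.05, 0.07, 0.09, 0.11], 45.0, 0.0, 1)


@pytest.fixture(scope="session")
def reduced_space():
    space = build_category_space(6, 18.0, CHRONIC_SFS, 23.0, 0.1, 1)
    return reduce_to_category_stimuli(space, 5)


@pytest.fixture(scope="session")
def agent():
    return AgentParams(planted_boundary_angle_deg=23.0, lapse_rate=0.1,
                       steepness=3.0, miss_probability=0.1)


@pytest.fixture(scope="session")
def trials(reduced_space, agent):
    return simulate_behavior_session(reduced_space, agent, 120, seed=11)


def kernel_bump(set_label, center_s=1.0, amplitude=3.0, width_s=0.75):
    offsets = {s.label: s.offsets for s in default_regressor_sets()}[set_label]
    return amplitude * np.exp(-0.5 * ((offsets - center_s) / width_s) ** 2)


@pytest.fixture(scope="session")
def planted_kernels():
    """Three planted archetypes: category-left, orientation, offset-only."""
    return PlantedKernels([
        {("offset", ""): np.array([0.2]),
         ("category", "left"): kernel_bump("category")},
        {("offset", ""): np.array([0.2]),
         ("orientation", "3"): kernel_bump("orientation", 0.8)},
        {("offset", ""): np.array([0.4])},
    ])


@pytest.fixture(scope="session")
def session(trials, planted_kernels):
    return simulate_neural_session(trials, planted_kernels, 15.0,
                                   noise_sd=0.4, trial_gain_cv=0.2, seed=12)


@pytest.fixture(scope="session")
def noiseless_session(trials, planted_kernels):
    return simulate_neural_session(trials, planted_kernels, 15.0,
                                   noise_sd=0.0, trial_gain_cv=0.0, seed=13)


@pytest.fixture(scope="session")
def engine(session):
    return GlmEngine(session)
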