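"""Shared fixtures: a reduced toy complex and its scattering target.

The reduced sizes (trimer 3 x 36 beads, monomer 16+36 beads) keep the
annealing-based tests tractable while preserving every geometric
property of the full-size generator defaults.
"""

import numpy as np
import pytest

from dutstl import modeling, saxs, synth
from dutstl.io import StructureModel


SMALL_SPEC = dict(trimer_chain_residues=36, monomer_n_domain=16,
                  monomer_c_domain=36, trimer_interface=(8, 13),
                  trimer_interface2=(22, 26), monomer_interface=(38, 50),
                  seed=1)


@pytest.fixture(scope="session")
def small_complex():
    """(truth ComplexModel, trimer, monomer) at reduced size."""
    spec = synth.ToyComplexSpec(**SMALL_SPEC)
    return synth.make_toy_complex(spec)


@pytest.fixture(scope="session")
def s_grid():
    return np.linspace(0.008, 0.30, 70)


@pytest.fixture(scope="session")
def target_33(small_complex, s_grid):
    """Noisy 3:3 scattering target (1% counting-like noise)."""
    truth, _, _ = small_complex
    return synth.simulate_saxs(truth, s_grid, noise=(0.01, 0.001), seed=5)


@pytest.fixture(scope="session")
def target_32(small_complex, s_grid):
    truth, _, _ = small_complex
    truth32 = StructureModel.concatenate([truth.core] + truth.copy_models()[:2])
    return synth.simulate_saxs(truth32, s_grid, noise=(0.01, 0.001), seed=6)


@pytest.fixture(scope="session")
def model32_structure(small_complex):
    truth, _, _ = small_complex
    return StructureModel.concatenate([truth.core] + truth.copy_models()[:2])


@pytest.fixture(scope="session")
def sa_schedule():
    """Annealing schedule used by the recovery tests: auto temperature,
    12000 cooling steps plus a 2000-step quench."""
    return modeling.SAScedule(t0=None, gamma=None, steps=12000,
                              quench_steps=2000)


@pytest.fixture(scope="session")
def sphere_curve():
    """Noise-free solid-sphere form factor, R = 30 A."""
    from dutstl.io import ScatteringCurve
    R = 30.0
    s = np.linspace(0.002, 0.5, 400)
    x = s * R
    intensity = (3.0 * (np.sin(x) - x * np.cos(x)) / x ** 3) ** 2
    return ScatteringCurve(s, intensity, 0.01 * intensity + 1e-8,
                           label="sphere-R30")
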