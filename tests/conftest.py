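"""Shared fixtures.

Heavy objects (assembled systems on benchmark meshes) are session-scoped
and built lazily so that cheap test selections do not pay for them.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest
import scipy.linalg

from symbem import HeadModel, make_icosphere
from symbem.assembly import (assemble_dipole_source_matrix,
                             assemble_head_matrix)
from symbem.mesh import DipoleSet
from symbem.operators import QuadratureConfig

warnings.filterwarnings("ignore", message="sphere series")

RADII = (0.088, 0.092, 0.100)
SIGMAS = (1.0, 1.0 / 80.0, 1.0)
DEPTHS = (0.50, 0.70, 0.85, 0.93, 0.97)
MOMENT = 1e-8


def benchmark_dipoles() -> DipoleSet:
    q = np.array([1.0, 0.0, 1.0]) / np.sqrt(2.0) * MOMENT
    pos = [[0.0, 0.0, d * RADII[0]] for d in DEPTHS]
    return DipoleSet(pos, [q] * len(DEPTHS))


@pytest.fixture(scope="session")
def quad():
    return QuadratureConfig()


@pytest.fixture(scope="session")
def sphere_l1():
    return make_icosphere(0.1, 1)


@pytest.fixture(scope="session")
def sphere_l2():
    return make_icosphere(0.1, 2)


@pytest.fixture(scope="session")
def three_layer_l1():
    return HeadModel(tuple(make_icosphere(r, 1) for r in RADII), SIGMAS)


@pytest.fixture(scope="session")
def three_layer_l2():
    return HeadModel(tuple(make_icosphere(r, 2) for r in RADII), SIGMAS)


class SolvedModel:
    """A head model with its assembled/factorized system and dipole RHS."""

    def __init__(self, model, quad, dipoles=None):
        self.model = model
        self.quad = quad
        self.head = assemble_head_matrix(model, quad, check=False)
        self.lu = scipy.linalg.lu_factor(self.head.matrix)
        self.dipoles = (dipoles.resolve(model)
                        if dipoles is not None else None)
        self.source = (assemble_dipole_source_matrix(model, self.dipoles,
                                                     quad)
                       if dipoles is not None else None)
        self._x = None

    @property
    def x(self):
        if self._x is None:
            self._x = scipy.linalg.lu_solve(self.lu, self.source.matrix)
        return self._x

    def solve(self, rhs):
        return scipy.linalg.lu_solve(self.lu, rhs)


@pytest.fixture(scope="session")
def solved_l2(three_layer_l2, quad):
    """3-layer level-2 benchmark system with the 5 z-axis dipoles."""
    return SolvedModel(three_layer_l2, quad, benchmark_dipoles())


@pytest.fixture(scope="session")
def solved_homogeneous_l3(quad):
    """Homogeneous 642-vertex sphere (radius 0.1, sigma 1) with two interior
    dipoles; shared by the EIT and internal-potential tests."""
    model = HeadModel((make_icosphere(0.1, 3),), (1.0,))
    dip = DipoleSet([[0.0, 0.0, 0.005], [0.0, 0.0, 0.05]],
                    [[MOMENT, 0.0, MOMENT]] * 2)
    return SolvedModel(model, QuadratureConfig(tol=1e-3), dip)
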