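"""Shared fixtures and independent numeric oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from fibrilkit import SyntheticFibrilParams, make_fibril


def svd_kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Independent closed-form minimum RMSD via a hand-written SVD Kabsch.

    Deliberately separate from the package's fitting code path: centers,
    builds the covariance, corrects the sign of the smallest singular value
    and evaluates the RMSD directly.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    h = ac.T @ bc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    r = vt.T @ corr @ u.T
    return float(np.sqrt(np.mean(np.sum((ac @ r.T - bc) ** 2, axis=1))))


def quaternion_search_rmsd(a: np.ndarray, b: np.ndarray, n_starts: int = 40,
                           seed: int = 0) -> float:
    """Brute-force minimum RMSD over proper rotations.

    Multistart local minimization over the rotation-vector parameterization,
    seeded from random unit quaternions. Slower but entirely independent of
    any closed-form superposition formula.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)

    def cost(rotvec):
        r = Rotation.from_rotvec(rotvec).as_matrix()
        return np.sqrt(np.mean(np.sum((ac @ r.T - bc) ** 2, axis=1)))

    rng = np.random.default_rng(seed)
    best = np.inf
    starts = Rotation.random(n_starts, random_state=rng).as_rotvec()
    for rv in starts:
        res = minimize(cost, rv, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
        best = min(best, res.fun)
    return float(best)


def random_rigid_transform(rng: np.random.Generator):
    """A random proper rotation + translation as a package RigidTransform."""
    from fibrilkit import RigidTransform

    r = Rotation.random(random_state=rng).as_matrix()
    t = rng.uniform(-20, 20, size=3)
    return RigidTransform(rotation=r, translation=t)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def protofilament_5():
    """Exact helical 5-chain protofilament (rise 4.47 A, twist 9 deg)."""
    return make_fibril(
        SyntheticFibrilParams(n_chains=5, rise=4.47, twist=9.0, seed=0)
    )


@pytest.fixture
def fibril_30():
    """Exact helical 30-chain fibril with amyloid-like defaults."""
    return make_fibril(SyntheticFibrilParams(n_chains=30, seed=0))
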