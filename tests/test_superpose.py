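"""Rigid fitting, RMSD, model matrices, centroid and best-of-set selection."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from fibrilkit import (
    RigidTransform,
    SyntheticFibrilParams,
    best_model_rmsd,
    centroid_model,
    kabsch_fit,
    make_fibril,
    model_rmsd_matrix,
    rmsd_after_fit,
)
from fibrilkit.structure import ModelValidationError
from fibrilkit.superpose import DegenerateGeometryError
from tests.conftest import (
    quaternion_search_rmsd,
    random_rigid_transform,
    svd_kabsch_rmsd,
)


def test_identity_fit():
    pts = np.random.default_rng(0).normal(size=(13, 3))
    t = kabsch_fit(pts, pts)
    assert np.allclose(t.rotation, np.eye(3), atol=1e-10)
    assert np.allclose(t.translation, 0, atol=1e-10)


def test_exact_rigid_motion_recovered():
    rng = np.random.default_rng(1)
    pts = rng.normal(size=(13, 3))
    rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
    moved = pts @ rot.T + np.array([1.0, 2.0, 3.0])
    t = kabsch_fit(moved, pts)
    assert rmsd_after_fit(moved, pts) < 1e-8
    assert np.allclose(t.apply(moved), pts, atol=1e-8)


def test_fit_matches_brute_force_oracles(rng):
    """Post-fit RMSD equals both an independent SVD Kabsch and a
    quaternion-multistart numeric minimization."""
    a = rng.normal(size=(13, 3)) * 4.0
    b = a + rng.normal(scale=0.1, size=a.shape)
    ours = rmsd_after_fit(a, b)
    assert ours == pytest.approx(svd_kabsch_rmsd(a, b), abs=1e-10)
    assert ours == pytest.approx(quaternion_search_rmsd(a, b), abs=1e-6)


def test_hand_chosen_point_sets_match_oracle():
    a = np.array([[0, 0, 0], [3.8, 0, 0], [3.8, 3.8, 0], [0, 3.8, 1.0]], float)
    b = np.array([[0.2, 0, 0], [4.0, 0.3, 0], [3.5, 3.8, 0.4], [0, 4.1, 0.8]], float)
    assert rmsd_after_fit(a, b) == pytest.approx(quaternion_search_rmsd(a, b), abs=1e-6)


def test_degenerate_inputs_rejected():
    line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
    with pytest.raises(DegenerateGeometryError):
        kabsch_fit(line, line)
    with pytest.raises(ValueError):
        kabsch_fit(np.zeros((2, 3)), np.zeros((2, 3)))


def test_no_reflection_even_for_near_planar_points(rng):
    """Mirror-image point sets must not be matched by an improper rotation."""
    pts = rng.normal(size=(10, 3))
    pts[:, 2] *= 1e-4  # nearly planar
    mirrored = pts.copy()
    mirrored[:, 2] *= -1
    t = kabsch_fit(mirrored, pts)
    assert np.linalg.det(t.rotation) == pytest.approx(1.0, abs=1e-8)


def test_rmsd_symmetry_and_rigid_invariance(rng):
    a = rng.normal(size=(13, 3)) * 3
    b = a + rng.normal(scale=0.5, size=a.shape)
    assert rmsd_after_fit(a, b) == pytest.approx(rmsd_after_fit(b, a), abs=1e-8)
    ta, tb = random_rigid_transform(rng), random_rigid_transform(rng)
    assert rmsd_after_fit(ta.apply(a), tb.apply(b)) == pytest.approx(
        rmsd_after_fit(a, b), abs=1e-8
    )


def test_transform_compose_and_inverse(rng):
    t1, t2 = random_rigid_transform(rng), random_rigid_transform(rng)
    pts = rng.normal(size=(7, 3))
    assert np.allclose(t1.compose(t2).apply(pts), t1.apply(t2.apply(pts)), atol=1e-10)
    assert np.allclose(t1.inverse().apply(t1.apply(pts)), pts, atol=1e-10)


def test_matrix_of_duplicates_is_zero(protofilament_5):
    m = model_rmsd_matrix([protofilament_5] * 3)
    assert np.allclose(m.values, 0)
    assert np.all(np.diag(m.values) == 0)


def test_matrix_isolates_perturbed_model(rng):
    base = make_fibril(SyntheticFibrilParams(n_chains=5, seed=0))
    models = [base.transformed(random_rigid_transform(rng)) for _ in range(7)]
    models.append(make_fibril(SyntheticFibrilParams(n_chains=5, noise_sigma=1.0, seed=5)))
    m = model_rmsd_matrix(models)
    assert np.allclose(m.values[:7, :7], 0, atol=1e-6)
    assert np.all(m.values[7, :7] > 0.5)


def test_matrix_small_for_similar_noisy_fibrils():
    """Independently perturbed copies of one fibril stay within ~2 A."""
    models = [
        make_fibril(SyntheticFibrilParams(n_chains=30, noise_sigma=0.5, seed=s))
        for s in range(4)
    ]
    m = model_rmsd_matrix(models)
    off = m.values[np.triu_indices(4, k=1)]
    assert np.all(off > 0)
    assert np.all(off < 2.0)


def test_centroid_single_and_midpoint():
    a = make_fibril(SyntheticFibrilParams(n_chains=3, seed=0))
    assert centroid_model([a])[0] == 0
    # three frames on a line in conformation space: A, midpoint, B
    b = make_fibril(SyntheticFibrilParams(n_chains=3, noise_sigma=1.0, seed=9))
    mid_coords = 0.5 * (a.ca_coords() + b.ca_coords())
    import copy

    mid = copy.deepcopy(a)
    k = 0
    for ch in mid.chains:
        ch.coords = mid_coords[k:k + ch.n_residues]
        k += ch.n_residues
    mid.backbones = None
    idx, _ = centroid_model([a, mid, b])
    assert idx == 1


def test_centroid_of_noisy_cloud_is_representative():
    """The centroid frame is at least as close to the template as the median."""
    template = make_fibril(SyntheticFibrilParams(n_chains=5, seed=0))
    frames = [
        make_fibril(SyntheticFibrilParams(n_chains=5, noise_sigma=0.4, seed=s))
        for s in range(1, 51)
    ]
    idx, cent = centroid_model(frames)
    ref = template.ca_coords()
    to_template = [rmsd_after_fit(f.ca_coords(), ref) for f in frames]
    assert to_template[idx] <= np.median(to_template)


def test_best_model_selection():
    ref = make_fibril(SyntheticFibrilParams(n_chains=5, seed=0))
    noisy = {
        s: make_fibril(SyntheticFibrilParams(n_chains=5, noise_sigma=s, seed=3))
        for s in (0.2, 1.0, 3.0)
    }
    candidates = [noisy[1.0], noisy[0.2], ref, noisy[3.0]]
    idx, val = best_model_rmsd(candidates, ref)
    assert (idx, val) == (2, pytest.approx(0.0, abs=1e-8))
    idx, _ = best_model_rmsd([noisy[1.0], noisy[0.2], noisy[3.0]], ref)
    assert idx == 1
    with pytest.raises(ModelValidationError):
        best_model_rmsd([], ref)


def test_best_model_handles_reversed_chain_order():
    """Chain labels carry no meaning: a reversed fibril matches itself."""
    ref = make_fibril(SyntheticFibrilParams(n_chains=5, seed=0))
    _, val = best_model_rmsd([ref.reversed_chains()], ref)
    assert val < 1e-6


def test_best_of_k_improves_with_more_candidates():
    """Prefix minima of the candidate RMSDs decrease as the pool grows."""
    ref = make_fibril(SyntheticFibrilParams(n_chains=5, seed=0))
    cands = [
        make_fibril(SyntheticFibrilParams(n_chains=5, noise_sigma=0.8, seed=s))
        for s in range(1, 41)
    ]
    bests = [best_model_rmsd(cands[:k], ref)[1] for k in (5, 10, 20, 40)]
    assert all(b2 <= b1 for b1, b2 in zip(bests, bests[1:]))
    assert bests[-1] < bests[0]
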