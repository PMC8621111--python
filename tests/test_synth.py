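"""Synthetic monomer/fibril generator and restraint-table generation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fibrilkit import (
    SyntheticFibrilParams,
    cabsdock_restraints,
    make_fibril,
    make_hairpin_monomer,
    measure_fibril,
    pca_rmsd,
    write_model,
    write_restraints,
)
from fibrilkit.synth import (
    _ANGLE_CA_C_O,
    _ANGLE_N_CA_C,
    _BOND_C_N,
    _BOND_C_O,
    _BOND_CA_C,
    _BOND_N_CA,
)


def bond_angle(a, b, c) -> float:
    u = a - b
    v = c - b
    cosang = float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def test_hairpin_arm_lengths():
    mono = make_hairpin_monomer(13, turn_at=(8, 9))
    # torsion assignment: 7 extended residues, 2 turn residues, 4 extended
    assert mono.n_residues == 13
    arm1 = mono.ca[:7]
    diffs = np.diff(arm1, axis=0)
    # the extended arm zig-zags at the residue level but runs straight:
    # every other CA-CA step is parallel
    cos = [
        float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))
        for a, b in zip(diffs[:-2], diffs[2:])
    ]
    assert min(cos) > 0.99


def test_hairpin_consecutive_ca_distances():
    mono = make_hairpin_monomer()
    d = np.linalg.norm(np.diff(mono.ca, axis=0), axis=1)
    assert np.all(d > 3.7) and np.all(d < 3.9)


def test_hairpin_backbone_geometry_matches_canonical_values():
    """Bond lengths and angles recomputed from coordinates agree with the
    canonical internal coordinates within 5%."""
    mono = make_hairpin_monomer()
    for i in range(mono.n_residues):
        assert np.linalg.norm(mono.ca[i] - mono.n[i]) == pytest.approx(
            _BOND_N_CA, rel=0.05)
        assert np.linalg.norm(mono.c[i] - mono.ca[i]) == pytest.approx(
            _BOND_CA_C, rel=0.05)
        assert np.linalg.norm(mono.o[i] - mono.c[i]) == pytest.approx(
            _BOND_C_O, rel=0.05)
        assert bond_angle(mono.n[i], mono.ca[i], mono.c[i]) == pytest.approx(
            _ANGLE_N_CA_C, rel=0.05)
        assert bond_angle(mono.ca[i], mono.c[i], mono.o[i]) == pytest.approx(
            _ANGLE_CA_C_O, rel=0.05)
        if i + 1 < mono.n_residues:
            assert np.linalg.norm(mono.n[i + 1] - mono.c[i]) == pytest.approx(
                _BOND_C_N, rel=0.05)


def test_hairpin_validation():
    with pytest.raises(ValueError):
        make_hairpin_monomer(4)
    with pytest.raises(ValueError):
        make_hairpin_monomer(13, turn_at=(1, 2))  # turn at the terminus
    with pytest.raises(ValueError):
        make_hairpin_monomer(13, turn_at=(8, 10))  # non-consecutive


def test_noiseless_fibril_is_exact():
    fib = make_fibril(SyntheticFibrilParams(n_chains=30, rise=4.625, twist=9.0))
    g = measure_fibril(fib, rise_convention="per-interface")
    assert g.length_d == pytest.approx(29 * 4.625, abs=1e-8)
    assert np.allclose(g.interface_angles, 9.0, atol=1e-8)
    assert g.rise_per_chain == pytest.approx(4.625, abs=1e-10)
    assert pca_rmsd(fib).pca_rmsd == pytest.approx(0.0, abs=1e-10)


def test_single_chain_fibril_refuses_geometry():
    from fibrilkit import fibril_axis
    from fibrilkit.structure import ModelValidationError

    single = make_fibril(SyntheticFibrilParams(n_chains=1))
    with pytest.raises(ModelValidationError):
        fibril_axis(single)


def test_fixed_seed_reproducible_to_the_byte(tmp_path):
    params = dict(n_chains=5, noise_sigma=0.3, seed=77)
    a = make_fibril(SyntheticFibrilParams(**params))
    b = make_fibril(SyntheticFibrilParams(**params))
    assert pca_rmsd(a).pca_rmsd > 0
    pa, pb = tmp_path / "a.pdb", tmp_path / "b.pdb"
    write_model(a, pa)
    write_model(b, pb)
    assert pa.read_bytes() == pb.read_bytes()
    c = make_fibril(SyntheticFibrilParams(n_chains=5, noise_sigma=0.3, seed=78))
    assert not np.allclose(a.ca_coords(), c.ca_coords())


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        SyntheticFibrilParams(n_chains=0)
    with pytest.raises(ValueError):
        SyntheticFibrilParams(rise=0.0)
    with pytest.raises(ValueError):
        SyntheticFibrilParams(noise_sigma=-0.1)


# ---------------------------------------------------------------------------
# restraint tables
# ---------------------------------------------------------------------------

def test_restraint_counts_for_docking_defaults():
    """13 residues x 5 chains -> 52 inter-chain rows; +5 with the disulfide."""
    table = cabsdock_restraints(13, 5, pair_distance=5.0, weight=1.0)
    assert len(table) == 52
    assert set(table["distance"]) == {5.0}
    assert set(table["weight"]) == {1.0}

    with_ss = cabsdock_restraints(13, 5, ssbond=(6, 11, 6.5))
    assert len(with_ss) == 57
    intra = with_ss[with_ss["chain_a"] == with_ss["chain_b"]]
    assert len(intra) == 5
    assert set(intra["distance"]) == {6.5}
    assert set(zip(intra["residue_a"], intra["residue_b"])) == {(6, 11)}


def test_minimal_restraint_table():
    assert len(cabsdock_restraints(1, 2)) == 1
    with pytest.raises(ValueError):
        cabsdock_restraints(0, 2)
    with pytest.raises(ValueError):
        cabsdock_restraints(13, 5, ssbond=(6, 14, 6.5))


@settings(deadline=None, max_examples=30, derandomize=True)
@given(n_res=st.integers(1, 40), n_chains=st.integers(2, 30),
       with_ss=st.booleans())
def test_restraint_count_formula_property(n_res, n_chains, with_ss):
    ssbond = (1, n_res, 6.5) if with_ss else None
    table = cabsdock_restraints(n_res, n_chains, ssbond=ssbond)
    expected = n_res * (n_chains - 1) + (n_chains if with_ss else 0)
    assert len(table) == expected
    inter = table[table["chain_a"] != table["chain_b"]]
    assert (inter["residue_a"] == inter["residue_b"]).all()


def test_restraint_file_round_trips(tmp_path):
    import pandas as pd

    table = cabsdock_restraints(13, 5, ssbond=(6, 11, 6.5))
    path = tmp_path / "restraints.tsv"
    write_restraints(table, path)
    again = pd.read_csv(path, sep="\t", comment="#")
    assert len(again) == len(table)
    assert list(again.columns) == list(table.columns)
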