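"""Synthetic helical fibrils with full backbones, and docking restraint tables.

The generator provides ground-truth structures for every other stage:

* an idealized 13-residue beta-hairpin monomer (two extended strands joined
  by a two-residue turn, emulating a U-turn peptide fold) built with
  canonical backbone internal coordinates;
* helical fibrils/protofilaments obtained by applying an exact screw
  motion (rise along and twist about the z axis) to copies of the monomer,
  optionally with isotropic Gaussian coordinate noise;
* plain-text distance-restraint tables of the kind used to steer
  coarse-grained docking of aggregating peptides toward in-register
  parallel packing.

The monomer template is oriented so its carbonyls point along the screw
axis; stacked copies therefore hydrogen-bond chain-to-chain in the
cross-beta fashion of real amyloid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .structure import (
    AssemblyModel,
    BackboneChain,
    CalphaChain,
    chain_id_for_index,
)
from .superpose import RigidTransform

__all__ = [
    "SyntheticFibrilParams",
    "ACC_SEQUENCE",
    "make_extended_strand",
    "make_hairpin_monomer",
    "make_fibril",
    "cabsdock_restraints",
    "write_restraints",
]

#: Insulin A-chain N-terminal fragment (13 residues, Cys7->Ala variant):
#: GIVEQCAASVCSL.
ACC_SEQUENCE = (
    "GLY ILE VAL GLU GLN CYS ALA ALA SER VAL CYS SER LEU".split()
)

# canonical backbone internal coordinates (Engh-Huber-style values)
_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231
_ANGLE_N_CA_C = 111.2
_ANGLE_CA_C_N = 116.2
_ANGLE_C_N_CA = 121.7
_ANGLE_CA_C_O = 120.8

#: torsions of the two turn residues (a type-I' beta-turn)
_TURN_TORSIONS = ((60.0, 30.0), (90.0, 0.0))


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension placement: atom d with |cd|, angle(b,c,d), torsion(a,b,c,d)."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(torsion),
            bond * math.sin(angle) * math.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_backbone(torsions: list[tuple[float, float]],
                    omega: float = 180.0) -> tuple[np.ndarray, ...]:
    """Backbone N/CA/C/O arrays from per-residue (phi, psi) torsions."""
    nres = len(torsions)
    n = np.zeros((nres, 3))
    ca = np.zeros((nres, 3))
    c = np.zeros((nres, 3))
    o = np.zeros((nres, 3))
    n[0] = (0.0, 0.0, 0.0)
    ca[0] = (_BOND_N_CA, 0.0, 0.0)
    ang = math.radians(_ANGLE_N_CA_C)
    c[0] = ca[0] + _BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    for i in range(nres):
        _, psi = torsions[i]
        o[i] = _place(n[i], ca[i], c[i], _BOND_C_O, _ANGLE_CA_C_O, psi - 180.0)
        if i + 1 < nres:
            phi_next = torsions[i + 1][0]
            n[i + 1] = _place(n[i], ca[i], c[i], _BOND_C_N, _ANGLE_CA_C_N, psi)
            ca[i + 1] = _place(ca[i], c[i], n[i + 1], _BOND_N_CA,
                               _ANGLE_C_N_CA, omega)
            c[i + 1] = _place(c[i], n[i + 1], ca[i + 1], _BOND_CA_C,
                              _ANGLE_N_CA_C, phi_next)
    return n, ca, c, o


def _residue_names(n_residues: int) -> list[str]:
    if n_residues == len(ACC_SEQUENCE):
        return list(ACC_SEQUENCE)
    return ["ALA"] * n_residues


def make_extended_strand(n_residues: int = 13) -> BackboneChain:
    """Fully extended single strand (phi = psi = 180 deg), canonically oriented.

    Centered on its CA centroid, strand direction along x, carbonyls along
    +/-z; stacking copies along z at ~4.7 A gives an ideal parallel
    in-register beta-sheet.
    """
    if n_residues < 2:
        raise ValueError("a strand needs at least 2 residues")
    n, ca, c, o = _build_backbone([(180.0, 180.0)] * n_residues)
    com = ca.mean(axis=0)
    u = ca[-1] - ca[0]
    u = u / np.linalg.norm(u)
    w = o[0] - c[0]
    w = w - (w @ u) * u
    w = w / np.linalg.norm(w)
    v = np.cross(w, u)
    q = np.column_stack([u, v, w])
    return BackboneChain(
        chain_id="A",
        residue_numbers=np.arange(1, n_residues + 1),
        residue_names=_residue_names(n_residues),
        n=(n - com) @ q,
        ca=(ca - com) @ q,
        c=(c - com) @ q,
        o=(o - com) @ q,
    )


def make_hairpin_monomer(n_residues: int = 13,
                         turn_at: tuple[int, int] = (8, 9)) -> BackboneChain:
    """Idealized beta-hairpin monomer with a two-residue U-turn.

    Residues before ``turn_at[0]`` and after ``turn_at[1]`` (1-based) form
    fully extended strands (phi = psi = 180 deg); the two turn residues use
    type-I' torsions. The chain is centered on its CA centroid and oriented
    with the first strand along x and its carbonyls along +/-z, so screw
    stacking along z reproduces cross-beta hydrogen bonding. Deterministic.
    """
    if n_residues < 5:
        raise ValueError("a hairpin needs at least 5 residues")
    t1, t2 = turn_at
    if t2 != t1 + 1:
        raise ValueError("turn_at must be two consecutive 1-based positions")
    if t1 < 2 or t2 > n_residues - 1:
        raise ValueError("the turn cannot sit at the chain termini")
    torsions = [(180.0, 180.0)] * n_residues
    torsions[t1 - 1] = _TURN_TORSIONS[0]
    torsions[t2 - 1] = _TURN_TORSIONS[1]
    n, ca, c, o = _build_backbone(torsions)

    # canonical orientation: strand-1 direction -> x, strand-1 carbonyls -> z
    com = ca.mean(axis=0)
    u = ca[t1 - 2] - ca[0]
    u = u / np.linalg.norm(u)
    w = o[0] - c[0]
    w = w - (w @ u) * u
    w = w / np.linalg.norm(w)
    v = np.cross(w, u)
    q = np.column_stack([u, v, w])  # maps u->x, v->y, w->z

    def reframe(arr):
        return (arr - com) @ q

    return BackboneChain(
        chain_id="A",
        residue_numbers=np.arange(1, n_residues + 1),
        residue_names=_residue_names(n_residues),
        n=reframe(n),
        ca=reframe(ca),
        c=reframe(c),
        o=reframe(o),
    )


@dataclass
class SyntheticFibrilParams:
    """Ground-truth parameters of a generated helical fibril.

    Defaults follow a 30-chain amyloid-like stack: inter-chain rise
    4.625 A (an end-to-end length of ~134 A over 30 chains) and a 9 degree
    per-chain twist. ``noise_sigma`` is the standard deviation of isotropic
    Gaussian noise added per atom after the screw motion.
    """

    n_chains: int = 30
    rise: float = 4.625  # Angstrom per chain
    twist: float = 9.0  # degrees per chain
    noise_sigma: float = 0.0  # Angstrom
    seed: int = 0
    n_residues: int = 13
    turn_at: tuple[int, int] = (8, 9)
    template: BackboneChain | None = None  # overrides the built-in hairpin

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.rise <= 0:
            raise ValueError("rise must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def _screw(t: int, rise: float, twist_deg: float) -> RigidTransform:
    ang = math.radians(twist_deg * t)
    rot = np.array(
        [
            [math.cos(ang), -math.sin(ang), 0.0],
            [math.sin(ang), math.cos(ang), 0.0],
            [0.0, 0.0, 1.0],
        ]
    )
    return RigidTransform(rotation=rot, translation=np.array([0.0, 0.0, rise * t]))


def make_fibril(params: SyntheticFibrilParams) -> AssemblyModel:
    """Helical stack of monomer copies, optionally with coordinate noise.

    Chain t (0-based) is the template rotated by t*twist about z and
    translated by t*rise along z; Gaussian noise of sd ``noise_sigma`` is
    then added independently per atom using ``seed``. Deterministic for a
    fixed seed.
    """
    template = params.template or make_hairpin_monomer(
        params.n_residues, params.turn_at
    )
    rng = np.random.default_rng(params.seed)
    chains: list[CalphaChain] = []
    backbones: list[BackboneChain] = []
    for t in range(params.n_chains):
        bb = template.transformed(_screw(t, params.rise, params.twist))
        bb.chain_id = chain_id_for_index(t)
        if params.noise_sigma > 0:
            for arr in (bb.n, bb.ca, bb.c, bb.o):
                arr += params.noise_sigma * rng.standard_normal(arr.shape)
        backbones.append(bb)
        chains.append(bb.to_calpha())
    label = (
        f"synthetic(n={params.n_chains},rise={params.rise},"
        f"twist={params.twist},sigma={params.noise_sigma},seed={params.seed})"
    )
    return AssemblyModel(chains=chains, backbones=backbones, label=label)


# ---------------------------------------------------------------------------
# Docking restraints
# ---------------------------------------------------------------------------

_RESTRAINT_COLUMNS = [
    "chain_a", "residue_a", "chain_b", "residue_b", "distance", "weight",
]


def cabsdock_restraints(n_residues: int, n_chains: int,
                        pair_distance: float = 5.0, weight: float = 1.0,
                        ssbond: tuple[int, int, float] | None = None,
                        ) -> pd.DataFrame:
    """Distance-restraint table steering parallel in-register aggregation.

    One side-chain--side-chain restraint is emitted for every residue j of
    every adjacent chain pair (chain i residue j -- chain i+1 residue j):
    n_residues * (n_chains - 1) rows. With ``ssbond=(a, b, d)`` one
    intra-chain CA-CA restraint per chain is appended (e.g. a Cys6-Cys11
    disulfide held at 6.5 A), adding n_chains rows.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    if n_chains < 2:
        raise ValueError("n_chains must be >= 2")
    rows = []
    for i in range(1, n_chains):
        a, b = chain_id_for_index(i - 1), chain_id_for_index(i)
        for j in range(1, n_residues + 1):
            rows.append((a, j, b, j, pair_distance, weight))
    if ssbond is not None:
        ra, rb, dist = ssbond
        if not (1 <= ra <= n_residues and 1 <= rb <= n_residues):
            raise ValueError(
                f"ssbond residues ({ra}, {rb}) out of range 1..{n_residues}"
            )
        for i in range(n_chains):
            cid = chain_id_for_index(i)
            rows.append((cid, ra, cid, rb, dist, weight))
    return pd.DataFrame(rows, columns=_RESTRAINT_COLUMNS)


def write_restraints(table: pd.DataFrame, path: str | Path) -> None:
    """Write a restraint table as commented, tab-separated plain text."""
    header = (
        "# distance restraints, one per row\n"
        "# inter-chain rows map to CABS-dock --sc-rest-add "
        "CHAIN_A:RES_A CHAIN_B:RES_B DISTANCE WEIGHT (side-chain pseudoatoms);\n"
        "# intra-chain rows are CA-CA disulfide restraints\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        table.to_csv(fh, sep="\t", index=False)
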