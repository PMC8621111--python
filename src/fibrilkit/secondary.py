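"""Backbone hydrogen-bond detection and beta-sheet content.

Follows the Kabsch-Sander scheme that underlies DSSP: amide hydrogens are
placed geometrically (inputs carry no hydrogens), each candidate
donor/acceptor pair is scored with the electrostatic four-distance energy

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)   [kcal/mol]

and a hydrogen bond is recorded when E < -0.5 kcal/mol. Beta-bridge
residues are then identified from the parallel / antiparallel H-bond
patterns, and the beta content of a model is reported both as a percentage
of all residues and as a residue count. In a cross-beta amyloid stack,
these bonds run between adjacent chains along the fibril axis.

Also provides the extinction-coefficient correction used to turn amide-I
band component intensities into secondary-structure fractions: component
intensities are divided by their relative molar extinction weights and
renormalized (a beta-sheet absorbs roughly twice as strongly as turns, so
its raw intensity fraction overestimates its abundance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .structure import AssemblyModel, BackboneChain, ModelValidationError

__all__ = [
    "HBondAssignment",
    "BandComponent",
    "HBOND_ENERGY_CUTOFF",
    "place_amide_hydrogens",
    "hbond_energy",
    "find_hbonds",
    "beta_fraction",
    "band_correction",
]

#: kcal/mol; a hydrogen bond is recorded when E < this value.
HBOND_ENERGY_CUTOFF = -0.5

#: Kabsch-Sander coupling constant: q1*q2 (0.084 e^2) times 332 (kcal*A/mol/e^2).
_KS_FACTOR = 0.084 * 332.0

#: Distances below this are clamped (overlapping-atom convention).
_MIN_DISTANCE = 0.1


@dataclass(frozen=True)
class HBondAssignment:
    """One backbone hydrogen bond: donor N-H ... O=C acceptor."""

    donor: tuple[int, int]  # (chain index, residue position), 0-based
    acceptor: tuple[int, int]
    energy: float  # kcal/mol


@dataclass(frozen=True)
class BandComponent:
    """One fitted amide-I component: intensity fraction + extinction weight."""

    label: str
    intensity: float  # fraction of total integral amide-I intensity, [0, 1]
    weight: float  # relative molar extinction coefficient, > 0


def place_amide_hydrogens(chain: BackboneChain) -> BackboneChain:
    """Return a copy of the chain with amide H positions filled in.

    Standard geometric placement: H lies 1.0 A from N along the direction
    of the preceding residue's O->C vector (i.e. anti to its carbonyl).
    The first residue and prolines carry no amide hydrogen (NaN rows).
    """
    nres = chain.n_residues
    h = np.full((nres, 3), np.nan)
    for i in range(1, nres):
        if chain.residue_names[i].upper() == "PRO":
            continue
        co = chain.c[i - 1] - chain.o[i - 1]
        norm = float(np.linalg.norm(co))
        if norm < 1e-9:
            raise ModelValidationError(
                f"chain {chain.chain_id}: degenerate C=O at residue "
                f"{chain.residue_numbers[i - 1]}"
            )
        h[i] = chain.n[i] + co / norm
    return replace(chain, h=h)


def hbond_energy(donor_n: np.ndarray, donor_h: np.ndarray,
                 acceptor_c: np.ndarray, acceptor_o: np.ndarray) -> float:
    """Kabsch-Sander electrostatic H-bond energy in kcal/mol.

    Inter-atom distances below 0.1 A are clamped to 0.1 A so overlapping
    atoms yield a large finite repulsive value instead of dividing by zero.
    """
    r_on = max(float(np.linalg.norm(acceptor_o - donor_n)), _MIN_DISTANCE)
    r_ch = max(float(np.linalg.norm(acceptor_c - donor_h)), _MIN_DISTANCE)
    r_oh = max(float(np.linalg.norm(acceptor_o - donor_h)), _MIN_DISTANCE)
    r_cn = max(float(np.linalg.norm(acceptor_c - donor_n)), _MIN_DISTANCE)
    return _KS_FACTOR * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def _backbones(model: AssemblyModel) -> list[BackboneChain]:
    if model.backbones is None:
        raise ModelValidationError(
            "backbone coordinates (N/CA/C/O) are required; a CA-only trace "
            "cannot be scored for hydrogen bonds"
        )
    return model.backbones


def find_hbonds(model: AssemblyModel,
                cutoff: float = HBOND_ENERGY_CUTOFF) -> list[HBondAssignment]:
    """All backbone H-bonds with E < cutoff.

    Self-bonds and bonds between sequence neighbors (|i - j| < 2 within a
    chain) are never recorded; they cannot form bridges.
    """
    chains = [place_amide_hydrogens(bb) for bb in _backbones(model)]
    bonds: list[HBondAssignment] = []
    for ci, donor_chain in enumerate(chains):
        for i in range(donor_chain.n_residues):
            h = donor_chain.h[i]
            if np.any(np.isnan(h)):
                continue
            n = donor_chain.n[i]
            for cj, acc_chain in enumerate(chains):
                for j in range(acc_chain.n_residues):
                    if ci == cj and abs(i - j) < 2:
                        continue
                    e = hbond_energy(n, h, acc_chain.c[j], acc_chain.o[j])
                    if e < cutoff:
                        bonds.append(
                            HBondAssignment(donor=(ci, i), acceptor=(cj, j),
                                            energy=e)
                        )
    return bonds


def _bridge_partners(hb: set, i: tuple[int, int], j: tuple[int, int]) -> bool:
    """True if residues i and j form a parallel or antiparallel beta bridge.

    ``hb`` contains (donor, acceptor) pairs. The patterns below use the
    original Kabsch-Sander convention Hbond(a, b) = "the C=O of residue a
    accepts the N-H of residue b"; with the opposite reading an ideal
    parallel sheet would show no bridges. Indices are (chain, position).
    """
    def bond(a, b):
        return (b, a) in hb

    def shift(r, k):
        return (r[0], r[1] + k)

    parallel = (bond(shift(i, -1), j) and bond(j, shift(i, 1))) or (
        bond(shift(j, -1), i) and bond(i, shift(j, 1))
    )
    antiparallel = (bond(i, j) and bond(j, i)) or (
        bond(shift(i, -1), shift(j, 1)) and bond(shift(j, -1), shift(i, 1))
    )
    return parallel or antiparallel


def beta_fraction(model: AssemblyModel, *, cutoff: float = HBOND_ENERGY_CUTOFF,
                  include_isolated_bridges: bool = True,
                  ) -> tuple[float, int]:
    """Percentage and count of residues in beta bridges/sheets.

    Residue pairs are assigned to bridges by the DSSP parallel and
    antiparallel patterns; within a chain, bridge partners must be at
    least 3 positions apart (adjacent residues cannot pair). With
    ``include_isolated_bridges=False``, bridges without a neighboring
    bridge (isolated B state rather than extended-strand E) are dropped.
    Returns (fraction in percent, residue count).
    """
    chains = _backbones(model)
    hb = {(b.donor, b.acceptor) for b in find_hbonds(model, cutoff)}
    nres = [c.n_residues for c in chains]
    total = sum(nres)

    residues = [(ci, i) for ci in range(len(chains)) for i in range(nres[ci])]
    bridges: set[tuple[tuple[int, int], tuple[int, int]]] = set()
    for a in range(len(residues)):
        for b in range(a + 1, len(residues)):
            i, j = residues[a], residues[b]
            if i[0] == j[0] and abs(i[1] - j[1]) < 3:
                continue
            if _bridge_partners(hb, i, j):
                bridges.add((i, j))

    if not include_isolated_bridges:
        def has_neighbor(pair):
            (ci, ri), (cj, rj) = pair
            for di in (-1, 1):
                for dj in (-1, 1):
                    cand = ((ci, ri + di), (cj, rj + dj))
                    if cand in bridges or (cand[1], cand[0]) in bridges:
                        return True
            return False

        bridges = {p for p in bridges if has_neighbor(p)}

    beta_residues = {r for pair in bridges for r in pair}
    count = len(beta_residues)
    return 100.0 * count / total, count


def band_correction(components: Sequence[BandComponent]) -> dict[str, float]:
    """Extinction-corrected secondary-structure fractions from band intensities.

    corrected_c = (I_c / w_c) / sum_k (I_k / w_k). Intensities must be
    fractions of the total amide-I integral (sum to 1); weights are the
    components' relative molar extinction coefficients.
    """
    if not components:
        raise ValueError("no band components given")
    for c in components:
        if not 0.0 <= c.intensity <= 1.0:
            raise ValueError(f"component {c.label!r}: intensity outside [0, 1]")
        if c.weight <= 0:
            raise ValueError(f"component {c.label!r}: extinction weight must be > 0")
    total_i = sum(c.intensity for c in components)
    if abs(total_i - 1.0) > 1e-6:
        raise ValueError(f"intensity fractions must sum to 1, got {total_i:.8f}")
    scaled = {c.label: c.intensity / c.weight for c in components}
    norm = sum(scaled.values())
    return {label: v / norm for label, v in scaled.items()}
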