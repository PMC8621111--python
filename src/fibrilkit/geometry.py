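"""Quantitative fibril characterization: axis, length, twist, rise, pitch.

The observables mirror how twisted amyloid fibrils are described
experimentally:

* **length d** — distance between the CA centers of mass of the first and
  last chain along the stack;
* **rotation angle (twist) alpha** — for every adjacent chain pair, the
  angle between a fixed intra-chain CA-CA segment (by default residues
  3 to 9, the extended strand region) projected onto the plane
  perpendicular to the fibril axis;
* **rise** — axial advance per chain;
* **helical pitch** — axial length of one full 360 degree turn,
  pitch = (360 / alpha) * rise, with 360/alpha the number of chains per
  turn.

The fibril axis is the first principal direction of the per-chain CA
centers of mass (one global axis per model), with its sign fixed so chain
order increases along it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .structure import AssemblyModel, ModelValidationError

__all__ = [
    "FibrilGeometry",
    "fibril_axis",
    "order_chains",
    "fibril_length",
    "interface_angles",
    "helical_pitch",
    "measure_fibril",
]


@dataclass
class FibrilGeometry:
    """Derived scalar description of one fibril model."""

    length_d: float  # Angstrom
    interface_angles: list[float]  # degrees, one per adjacent chain pair
    mean_twist: float  # degrees
    twist_sd: float  # degrees
    rise_per_chain: float  # Angstrom
    pitch: float  # Angstrom (inf for an untwisted stack)
    chains_per_turn: float  # dimensionless (inf for an untwisted stack)
    handedness: int  # +1 right-handed, -1 left-handed, 0 untwisted


def fibril_axis(model: AssemblyModel) -> tuple[np.ndarray, np.ndarray]:
    """Unit axis direction and anchor point (centroid of chain centers).

    The axis is the first principal component of the per-chain CA centers
    of mass, signed so that the chain order increases along it.
    """
    if model.n_chains < 2:
        raise ModelValidationError("fibril axis needs at least 2 chains")
    centers = model.chain_centers()
    anchor = centers.mean(axis=0)
    centered = centers - anchor
    if np.allclose(centered, 0, atol=1e-9):
        raise ModelValidationError("all chain centers coincide; axis undefined")
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    # orient along increasing chain index (covariance of index with projection)
    proj = centered @ axis
    idx = np.arange(len(proj)) - (len(proj) - 1) / 2
    if float(idx @ proj) < 0:
        axis = -axis
    return axis, anchor


def order_chains(model: AssemblyModel) -> AssemblyModel:
    """Sort chains by their CA-center projection onto the fibril axis."""
    axis, anchor = fibril_axis(model)
    proj = (model.chain_centers() - anchor) @ axis
    order = np.argsort(proj, kind="stable")
    return model.reordered(order.tolist())


def fibril_length(model: AssemblyModel, *, assume_ordered: bool = False) -> float:
    """Distance between the CA centers of mass of the first and last chain."""
    if model.n_chains < 2:
        raise ModelValidationError("fibril length needs at least 2 chains")
    if not assume_ordered:
        model = order_chains(model)
    centers = model.chain_centers()
    return float(np.linalg.norm(centers[-1] - centers[0]))


def _projected_segment(chain, residue_a: int, residue_b: int,
                       axis: np.ndarray) -> np.ndarray:
    seg = chain.coords[residue_b - 1] - chain.coords[residue_a - 1]
    perp = seg - (seg @ axis) * axis
    norm = float(np.linalg.norm(perp))
    if norm < 1e-6:
        raise ModelValidationError(
            f"chain {chain.chain_id}: the residue {residue_a}-{residue_b} "
            "segment is parallel to the fibril axis; its projection vanishes"
        )
    return perp / norm


def interface_angles(model: AssemblyModel, residue_a: int = 3,
                     residue_b: int = 9, *, signed: bool = False) -> list[float]:
    """Per-interface rotation angles between adjacent chains, in degrees.

    In each chain the CA(residue_a)->CA(residue_b) segment (1-based chain
    positions) is projected onto the plane perpendicular to the fibril
    axis; the angle between projections of adjacent chains is returned,
    unsigned in [0, 180] by default. With ``signed=True`` the sign encodes
    handedness: positive where the rotation from chain i to chain i+1 is
    right-handed about the axis.
    """
    if model.n_chains < 2:
        raise ModelValidationError("interface angles need at least 2 chains")
    n = model.n_residues
    if not (1 <= residue_a < residue_b <= n):
        raise ValueError(
            f"need 1 <= residue_a < residue_b <= {n}, got ({residue_a}, {residue_b})"
        )
    axis, _ = fibril_axis(model)
    ordered = order_chains(model)
    units = [
        _projected_segment(c, residue_a, residue_b, axis) for c in ordered.chains
    ]
    angles: list[float] = []
    for u, v in zip(units[:-1], units[1:]):
        cross = np.cross(u, v)
        # atan2 form: stable near 0 and 180 degrees
        ang = math.degrees(math.atan2(float(np.linalg.norm(cross)), float(u @ v)))
        if signed:
            ang = math.copysign(ang, float(cross @ axis)) if ang > 0 else 0.0
        angles.append(ang)
    return angles


def helical_pitch(length_d: float, n_chains: int, mean_twist: float,
                  *, rise_convention: str = "per-chain") -> tuple[float, float]:
    """Helical pitch and chains-per-turn from fibril length and mean twist.

    ``rise_convention`` selects how the per-chain rise is derived from the
    end-to-end length: ``"per-chain"`` (default) uses d / n_chains,
    ``"per-interface"`` uses d / (n_chains - 1). Returns (pitch in
    Angstrom, chains per turn); an untwisted stack (mean_twist == 0)
    yields (inf, inf) rather than raising.
    """
    if n_chains < 2:
        raise ValueError("n_chains must be >= 2")
    if mean_twist < 0:
        raise ValueError("mean_twist must be >= 0")
    if rise_convention == "per-chain":
        rise = length_d / n_chains
    elif rise_convention == "per-interface":
        rise = length_d / (n_chains - 1)
    else:
        raise ValueError(f"unknown rise convention {rise_convention!r}")
    if mean_twist == 0:
        return math.inf, math.inf
    chains_per_turn = 360.0 / mean_twist
    return chains_per_turn * rise, chains_per_turn


def measure_fibril(model: AssemblyModel, residue_a: int = 3, residue_b: int = 9,
                   *, rise_convention: str = "per-chain") -> FibrilGeometry:
    """Full geometric characterization of one fibril model."""
    ordered = order_chains(model)
    d = fibril_length(ordered, assume_ordered=True)
    signed = interface_angles(ordered, residue_a, residue_b, signed=True)
    unsigned = [abs(a) for a in signed]
    mean_twist = float(np.mean(unsigned))
    twist_sd = float(np.std(unsigned, ddof=1)) if len(unsigned) > 1 else 0.0
    pitch, cpt = helical_pitch(d, ordered.n_chains, mean_twist,
                               rise_convention=rise_convention)
    if rise_convention == "per-chain":
        rise = d / ordered.n_chains
    else:
        rise = d / (ordered.n_chains - 1)
    mean_signed = float(np.mean(signed))
    handedness = 0 if mean_twist == 0 else (1 if mean_signed > 0 else -1)
    return FibrilGeometry(
        length_d=d,
        interface_angles=unsigned,
        mean_twist=mean_twist,
        twist_sd=twist_sd,
        rise_per_chain=rise,
        pitch=pitch,
        chains_per_turn=cpt,
        handedness=handedness,
    )
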