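"""Domain types and PDB I/O for C-alpha-trace and backbone multi-chain models.

The central container is :class:`AssemblyModel`: an ordered stack of M
equal-length peptide chains representing a protofilament (small M, e.g. 5)
or a full fibril (e.g. 30 chains). Chains are stored as C-alpha traces
(:class:`CalphaChain`); when the input provides a full backbone, a parallel
list of :class:`BackboneChain` objects carries the N/CA/C/O coordinates
needed for hydrogen-bond analysis.

Coordinates are in Angstrom throughout.
"""

from __future__ import annotations

import math
import string
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.PDB import PDBParser

__all__ = [
    "CalphaChain",
    "BackboneChain",
    "AssemblyModel",
    "PDBFormatError",
    "ModelValidationError",
    "CHAIN_ID_ALPHABET",
    "chain_id_for_index",
    "read_model",
    "read_models",
    "write_model",
    "write_models",
    "average_conformers",
    "require_same_layout",
]

#: Single-character chain identifiers, in assignment order: A-Z, a-z, 0-9.
CHAIN_ID_ALPHABET = string.ascii_uppercase + string.ascii_lowercase + string.digits


class PDBFormatError(ValueError):
    """Raised when a PDB file cannot be interpreted as a chain stack."""


class ModelValidationError(ValueError):
    """Raised when chains violate the equal-layout invariants."""


def chain_id_for_index(i: int) -> str:
    """Chain ID for 0-based chain index ``i`` under the A-Z/a-z/0-9 policy."""
    if not 0 <= i < len(CHAIN_ID_ALPHABET):
        raise ModelValidationError(
            f"chain index {i} exceeds the {len(CHAIN_ID_ALPHABET)}-character "
            "PDB chain-ID alphabet; split the model across several files"
        )
    return CHAIN_ID_ALPHABET[i]


@dataclass
class CalphaChain:
    """Ordered C-alpha trace of one peptide monomer."""

    chain_id: str
    residue_numbers: np.ndarray  # (N,) int, strictly increasing
    residue_names: list[str]  # 3-letter codes
    coords: np.ndarray  # (N, 3) float, Angstrom

    def __post_init__(self) -> None:
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ModelValidationError("coords must be an (N, 3) array")
        n = len(self.coords)
        if n < 1:
            raise ModelValidationError("a chain needs at least one residue")
        if len(self.residue_numbers) != n or len(self.residue_names) != n:
            raise ModelValidationError("residue metadata length mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise ModelValidationError(f"chain {self.chain_id}: non-finite coordinates")
        if n > 1 and not np.all(np.diff(self.residue_numbers) > 0):
            raise ModelValidationError(
                f"chain {self.chain_id}: residue numbers must be strictly increasing"
            )

    @property
    def n_residues(self) -> int:
        return len(self.coords)

    def transformed(self, transform) -> "CalphaChain":
        return replace(self, coords=transform.apply(self.coords))

    def center_of_mass(self) -> np.ndarray:
        """Equal-weight CA centroid (trace models carry no masses)."""
        return self.coords.mean(axis=0)


@dataclass
class BackboneChain:
    """Per-residue N/CA/C/O backbone coordinates of one peptide monomer.

    The optional ``h`` array holds amide-hydrogen positions (NaN where no
    amide H exists: the N-terminal residue and prolines); it is filled by
    :func:`fibrilkit.secondary.place_amide_hydrogens`.
    """

    chain_id: str
    residue_numbers: np.ndarray
    residue_names: list[str]
    n: np.ndarray  # (N, 3)
    ca: np.ndarray
    c: np.ndarray
    o: np.ndarray
    h: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        nres = len(self.residue_numbers)
        for name in ("n", "ca", "c", "o"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != (nres, 3):
                raise ModelValidationError(
                    f"chain {self.chain_id}: backbone atom array {name!r} has shape "
                    f"{arr.shape}, expected ({nres}, 3)"
                )
            if not np.all(np.isfinite(arr)):
                raise ModelValidationError(
                    f"chain {self.chain_id}: non-finite {name.upper()} coordinates"
                )
        if self.h is not None:
            self.h = np.asarray(self.h, dtype=float)

    @property
    def n_residues(self) -> int:
        return len(self.residue_numbers)

    def validate_geometry(self) -> None:
        """Check bonded-atom distances are physically plausible (0.5-3 A)."""
        for label, a, b in (
            ("CA-N", self.ca, self.n),
            ("CA-C", self.ca, self.c),
            ("C-O", self.c, self.o),
        ):
            d = np.linalg.norm(a - b, axis=1)
            bad = np.where((d <= 0.5) | (d >= 3.0))[0]
            if bad.size:
                raise ModelValidationError(
                    f"chain {self.chain_id}: implausible {label} distance "
                    f"{d[bad[0]]:.2f} A at residue {self.residue_numbers[bad[0]]}"
                )

    def transformed(self, transform) -> "BackboneChain":
        return replace(
            self,
            n=transform.apply(self.n),
            ca=transform.apply(self.ca),
            c=transform.apply(self.c),
            o=transform.apply(self.o),
            h=None if self.h is None else transform.apply(self.h),
        )

    def to_calpha(self) -> CalphaChain:
        return CalphaChain(
            chain_id=self.chain_id,
            residue_numbers=self.residue_numbers.copy(),
            residue_names=list(self.residue_names),
            coords=self.ca.copy(),
        )


@dataclass
class AssemblyModel:
    """Ordered collection of M equal-length chains (protofilament or fibril)."""

    chains: list[CalphaChain]
    backbones: list[BackboneChain] | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if not self.chains:
            raise ModelValidationError("a model needs at least one chain")
        lengths = [c.n_residues for c in self.chains]
        if len(set(lengths)) != 1:
            raise ModelValidationError(
                f"all chains must have the same residue count, got {lengths}"
            )
        seqs = {tuple(c.residue_names) for c in self.chains}
        if len(seqs) != 1:
            raise ModelValidationError("all chains must share one sequence")
        if self.backbones is not None and len(self.backbones) != len(self.chains):
            raise ModelValidationError("backbone list does not match chain list")

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    @property
    def n_residues(self) -> int:
        return self.chains[0].n_residues

    @property
    def sequence(self) -> tuple[str, ...]:
        return tuple(self.chains[0].residue_names)

    def ca_coords(self) -> np.ndarray:
        """All CA coordinates, chains concatenated in order: (M*N, 3)."""
        return np.concatenate([c.coords for c in self.chains], axis=0)

    def chain_centers(self) -> np.ndarray:
        """Equal-weight CA center of mass of each chain: (M, 3)."""
        return np.stack([c.center_of_mass() for c in self.chains])

    def transformed(self, transform) -> "AssemblyModel":
        return AssemblyModel(
            chains=[c.transformed(transform) for c in self.chains],
            backbones=None
            if self.backbones is None
            else [b.transformed(transform) for b in self.backbones],
            label=self.label,
        )

    def reversed_chains(self) -> "AssemblyModel":
        return AssemblyModel(
            chains=list(reversed(self.chains)),
            backbones=None if self.backbones is None else list(reversed(self.backbones)),
            label=self.label,
        )

    def reordered(self, order: Sequence[int]) -> "AssemblyModel":
        return AssemblyModel(
            chains=[self.chains[i] for i in order],
            backbones=None
            if self.backbones is None
            else [self.backbones[i] for i in order],
            label=self.label,
        )


def require_same_layout(models: Iterable[AssemblyModel]) -> None:
    """Validate that all models share chain count, residue count and sequence."""
    models = list(models)
    ref = models[0]
    for k, m in enumerate(models[1:], start=1):
        if m.n_chains != ref.n_chains or m.n_residues != ref.n_residues:
            raise ModelValidationError(
                f"model {k} layout ({m.n_chains} chains x {m.n_residues} residues) "
                f"differs from model 0 ({ref.n_chains} x {ref.n_residues})"
            )
        if m.sequence != ref.sequence:
            raise ModelValidationError(f"model {k} sequence differs from model 0")


# ---------------------------------------------------------------------------
# PDB input
# ---------------------------------------------------------------------------

_BACKBONE_ATOMS = ("N", "CA", "C", "O")


def _chain_from_biopdb(bio_chain, calpha_only: bool):
    numbers: list[int] = []
    names: list[str] = []
    atoms: dict[str, list[np.ndarray]] = {a: [] for a in _BACKBONE_ATOMS}
    for residue in bio_chain:
        hetflag, resseq, icode = residue.id
        if hetflag.strip():
            continue  # skip waters / hetero groups
        if icode.strip():
            raise PDBFormatError(
                f"insertion code {icode!r} at residue {resseq} of chain "
                f"{bio_chain.id!r} is not supported; renumber the input"
            )
        if "CA" not in residue:
            raise PDBFormatError(
                f"missing CA atom at residue {residue.resname} {resseq} "
                f"of chain {bio_chain.id!r}"
            )
        numbers.append(resseq)
        names.append(residue.resname.strip())
        wanted = _BACKBONE_ATOMS if not calpha_only else ("CA",)
        for atom_name in wanted:
            if atom_name not in residue:
                raise PDBFormatError(
                    f"missing backbone atom {atom_name} at residue "
                    f"{residue.resname} {resseq} of chain {bio_chain.id!r} "
                    "(read with calpha_only=True for trace-only files)"
                )
            # Bio.PDB resolves altlocs to the highest-occupancy conformer.
            atoms[atom_name].append(np.asarray(residue[atom_name].coord, dtype=float))
    if not numbers:
        return None
    ca = CalphaChain(
        chain_id=str(bio_chain.id),
        residue_numbers=np.array(numbers),
        residue_names=names,
        coords=np.stack(atoms["CA"]),
    )
    if calpha_only:
        return ca, None
    bb = BackboneChain(
        chain_id=str(bio_chain.id),
        residue_numbers=np.array(numbers),
        residue_names=names,
        n=np.stack(atoms["N"]),
        ca=np.stack(atoms["CA"]),
        c=np.stack(atoms["C"]),
        o=np.stack(atoms["O"]),
    )
    return ca, bb


def read_models(path: str | Path, calpha_only: bool = True) -> list[AssemblyModel]:
    """Read a PDB file into one AssemblyModel per MODEL record.

    With ``calpha_only=False`` every residue must carry N, CA, C and O and
    the models are returned with backbone chains attached.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure = parser.get_structure(path.stem, str(path))
    except PDBFormatError:
        raise
    except Exception as exc:
        raise PDBFormatError(f"{path}: not parseable as PDB ({exc})") from exc
    models: list[AssemblyModel] = []
    for bio_model in structure:
        chains: list[CalphaChain] = []
        backbones: list[BackboneChain] = []
        for bio_chain in bio_model:
            parsed = _chain_from_biopdb(bio_chain, calpha_only)
            if parsed is None:
                continue
            ca, bb = parsed
            chains.append(ca)
            if bb is not None:
                backbones.append(bb)
        if not chains:
            continue
        models.append(
            AssemblyModel(
                chains=chains,
                backbones=backbones or None,
                label=f"{path.stem}:{bio_model.id}",
            )
        )
    if not models:
        raise PDBFormatError(f"{path}: no chains with CA atoms found")
    return models


def read_model(path: str | Path, calpha_only: bool = True):
    """Read a PDB file; returns one AssemblyModel, or a list for multi-MODEL files."""
    models = read_models(path, calpha_only=calpha_only)
    return models[0] if len(models) == 1 else models


# ---------------------------------------------------------------------------
# PDB output
# ---------------------------------------------------------------------------

def _format_atom(serial: int, name: str, resname: str, chain_id: str,
                 resseq: int, xyz: np.ndarray, element: str) -> str:
    # PDB v3 fixed columns; 1-2 letter atom names start in column 14
    padded = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:5d} {padded}{'':1s}{resname:>3s} {chain_id}{resseq:4d}"
        f"{'':1s}   {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


def _model_lines(model: AssemblyModel, serial_start: int = 1) -> tuple[list[str], int]:
    lines: list[str] = []
    serial = serial_start
    for ci in range(model.n_chains):
        cid = chain_id_for_index(ci)
        if model.backbones is not None:
            bb = model.backbones[ci]
            for ri in range(bb.n_residues):
                for atom_name, arr, elem in (
                    ("N", bb.n, "N"),
                    ("CA", bb.ca, "C"),
                    ("C", bb.c, "C"),
                    ("O", bb.o, "O"),
                ):
                    lines.append(
                        _format_atom(serial, atom_name, bb.residue_names[ri], cid,
                                     int(bb.residue_numbers[ri]), arr[ri], elem)
                    )
                    serial += 1
        else:
            ch = model.chains[ci]
            for ri in range(ch.n_residues):
                lines.append(
                    _format_atom(serial, "CA", ch.residue_names[ri], cid,
                                 int(ch.residue_numbers[ri]), ch.coords[ri], "C")
                )
                serial += 1
        lines.append(f"TER   {serial:5d}")
        serial += 1
    return lines, serial


def write_model(model: AssemblyModel, path: str | Path) -> None:
    """Write a model as standard PDB text (3-decimal coordinates).

    Chain IDs are reassigned by position: A-Z, then a-z, then 0-9.
    """
    lines, _ = _model_lines(model)
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_models(models: Sequence[AssemblyModel], path: str | Path) -> None:
    """Write an ensemble as a multi-MODEL PDB file."""
    lines: list[str] = []
    for k, model in enumerate(models, start=1):
        lines.append(f"MODEL     {k:4d}")
        body, _ = _model_lines(model)
        lines.extend(body)
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Ensemble averaging
# ---------------------------------------------------------------------------

def average_conformers(ensemble: Sequence[AssemblyModel]) -> AssemblyModel:
    """Per-atom mean structure after superposing every conformer onto the first.

    Each conformer is best-fit (all CA atoms) onto the first conformer's
    frame, then coordinates are averaged atomwise. Used to build a single
    reference structure from an NMR-style ensemble.
    """
    from .superpose import kabsch_fit  # local import: avoid a module cycle

    ensemble = list(ensemble)
    if not ensemble:
        raise ModelValidationError("empty ensemble")
    require_same_layout(ensemble)
    ref = ensemble[0]
    fitted = [ref]
    target = ref.ca_coords()
    for conf in ensemble[1:]:
        t = kabsch_fit(conf.ca_coords(), target)
        fitted.append(conf.transformed(t))

    mean_chains = []
    for ci in range(ref.n_chains):
        mean_coords = np.mean([m.chains[ci].coords for m in fitted], axis=0)
        mean_chains.append(replace(ref.chains[ci], coords=mean_coords))
    mean_backbones = None
    if all(m.backbones is not None for m in fitted):
        mean_backbones = []
        for ci in range(ref.n_chains):
            bbs = [m.backbones[ci] for m in fitted]
            mean_backbones.append(
                replace(
                    ref.backbones[ci],
                    n=np.mean([b.n for b in bbs], axis=0),
                    ca=np.mean([b.ca for b in bbs], axis=0),
                    c=np.mean([b.c for b in bbs], axis=0),
                    o=np.mean([b.o for b in bbs], axis=0),
                    h=None,
                )
            )
    return AssemblyModel(chains=mean_chains, backbones=mean_backbones,
                         label=f"mean({len(ensemble)})")
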