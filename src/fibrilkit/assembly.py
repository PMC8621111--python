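"""Fibril assembly by iterated overlap superposition of a protofilament.

A long fibril is grown from a single M-chain protofilament by exploiting
its internal screw symmetry: a fresh copy of the protofilament is fitted
with its first M-1 chains onto the last M-1 chains of the fixed one,
which advances the copy by exactly one chain along the fibril axis. The
resulting one-chain-step transform is composed iteration after iteration,
and the central chain of each (virtually) shifted copy is collected; n
iterations yield an n-chain fibril. For a rigid, identical building block,
computing the step transform once and composing it is mathematically
identical to re-fitting a copy at every iteration, and avoids accumulating
floating-point fit noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .structure import AssemblyModel, CalphaChain, BackboneChain, chain_id_for_index
from .superpose import RigidTransform, kabsch_fit

__all__ = ["AssemblyConfig", "overlap_transform", "build_fibril"]


@dataclass
class AssemblyConfig:
    """Parameters of the overlap-assembly procedure.

    ``iterations`` is the number of chains in the output fibril (default 30).
    ``overlap`` is the number of chains used in the fit (default M-1: for a
    5-chain protofilament, chains 1-4 of the copy onto chains 2-5 of the
    fixed model). ``central_index`` is the 1-based chain extracted from each
    shifted copy (default the middle chain, index 3 for M=5). Chain indices
    are 1-based throughout.
    """

    iterations: int = 30
    overlap: int | None = None
    central_index: int | None = None

    def resolve(self, n_chains: int) -> tuple[int, int, int]:
        """Validated (iterations, overlap, central_index) for an M-chain model."""
        overlap = self.overlap if self.overlap is not None else n_chains - 1
        central = (
            self.central_index
            if self.central_index is not None
            else math.ceil(n_chains / 2)
        )
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 1 <= overlap <= n_chains - 1:
            raise ValueError(
                f"overlap must be in [1, {n_chains - 1}] for {n_chains} chains, "
                f"got {overlap}"
            )
        if not 1 <= central <= n_chains:
            raise ValueError(
                f"central_index must be in [1, {n_chains}], got {central}"
            )
        return self.iterations, overlap, central


def overlap_transform(fixed: AssemblyModel,
                      config: AssemblyConfig | None = None) -> RigidTransform:
    """One-chain-step transform of the protofilament's screw symmetry.

    Fits the CA atoms of chains 1..overlap of a fresh copy jointly onto
    chains M-overlap+1..M of the fixed model; the fixed model's coordinates
    never move. For an exactly helical protofilament the result is the
    generating screw motion (rise along and twist about the fibril axis).
    """
    config = config or AssemblyConfig()
    m = fixed.n_chains
    _, overlap, _ = config.resolve(m)
    import numpy as np

    mobile_pts = np.concatenate([fixed.chains[i].coords for i in range(overlap)])
    target_pts = np.concatenate(
        [fixed.chains[i].coords for i in range(m - overlap, m)]
    )
    return kabsch_fit(mobile_pts, target_pts)


def build_fibril(protofilament: AssemblyModel,
                 config: AssemblyConfig | None = None) -> AssemblyModel:
    """Assemble an n-chain fibril from one protofilament.

    Iteration t (1-based) contributes the protofilament's central chain
    transformed by the (t-1)-fold composition of the overlap step; iteration
    1 contributes the untransformed central chain. Output chains are ordered
    by iteration and renamed per the chain-ID policy; residue numbering is
    inherited from the template chain.
    """
    config = config or AssemblyConfig()
    n_iter, _, central = config.resolve(protofilament.n_chains)
    step = overlap_transform(protofilament, config)

    template_ca = protofilament.chains[central - 1]
    template_bb = (
        protofilament.backbones[central - 1]
        if protofilament.backbones is not None
        else None
    )

    chains: list[CalphaChain] = []
    backbones: list[BackboneChain] | None = [] if template_bb is not None else None
    current = RigidTransform.identity()
    for t in range(n_iter):
        cid = chain_id_for_index(t)
        ca = template_ca.transformed(current)
        ca.chain_id = cid
        chains.append(ca)
        if backbones is not None:
            bb = template_bb.transformed(current)
            bb.chain_id = cid
            backbones.append(bb)
        current = step.compose(current)
    return AssemblyModel(
        chains=chains,
        backbones=backbones,
        label=f"fibril(n={n_iter})@{protofilament.label}",
    )
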