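"""Translational-symmetry scoring of protofilament models (pcaRMSD).

An amyloid protofilament is a stack of chemically identical chains related
by quasi-translational symmetry, so in a good model every chain should adopt
nearly the same conformation. The peptide-chain-average RMSD (pcaRMSD)
quantifies this: every unordered pair of chains is superposed (proper-
rotation Kabsch over the chain's CA atoms) and the resulting pairwise RMSDs
are averaged,

    pcaRMSD = 1/(M^2 - M) * sum_i sum_j RMSD_fit(chain_i, chain_j)

where the double sum runs over ordered pairs, the diagonal contributes
zero, and M is the chain count. Because pairwise RMSD is symmetric this
equals the plain mean over the M(M-1)/2 unordered pairs. Low pcaRMSD means
high translational symmetry; models are ranked ascending.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .structure import AssemblyModel, ModelValidationError
from .superpose import rmsd_after_fit

__all__ = ["ScoredModel", "pca_rmsd", "rank_models"]


@dataclass
class ScoredModel:
    """A model together with its pcaRMSD and the per-pair RMSD table."""

    model: AssemblyModel
    pca_rmsd: float  # Angstrom
    pair_rmsds: list[tuple[int, int, float]]  # (i, j, A), 1-based, i < j

    @property
    def n_chains(self) -> int:
        return self.model.n_chains

    @property
    def n_residues(self) -> int:
        return self.model.n_residues


def pca_rmsd(model: AssemblyModel) -> ScoredModel:
    """Score a model's translational symmetry.

    Raises for single-chain models: symmetry of one chain is undefined.
    """
    m = model.n_chains
    if m < 2:
        raise ModelValidationError("pcaRMSD needs at least 2 chains")
    pairs: list[tuple[int, int, float]] = []
    for i in range(m):
        for j in range(i + 1, m):
            val = rmsd_after_fit(model.chains[i].coords, model.chains[j].coords)
            pairs.append((i + 1, j + 1, val))
    score = float(np.mean([p[2] for p in pairs]))
    return ScoredModel(model=model, pca_rmsd=score, pair_rmsds=pairs)


def rank_models(models: Sequence[AssemblyModel], top_k: int) -> list[ScoredModel]:
    """Score all models and return the ``top_k`` most symmetric ones.

    Sorted ascending by pcaRMSD; ties keep input order (stable sort).
    """
    models = list(models)
    if not models:
        raise ModelValidationError("no models to rank")
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    scored = [pca_rmsd(m) for m in models]
    scored.sort(key=lambda s: s.pca_rmsd)
    return scored[:top_k]
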