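"""Structure refinement over the three SVD coordinates.

A Cα structure, written as the 3 × natoms matrix of its centered atom
coordinates, factorizes as ``M = U Σ Vᵀ = Σ_k α_k u_k v_kᵀ`` with exactly
three singular values.  Any structure sharing the rank-3 basis
``{u_k v_kᵀ}`` is a linear combination ``M_new = Σ_k β_k u_k v_kᵀ``, so the
structure has only three coordinates (β1, β2, β3) in this basis.  The
refinement searches a box around β = α with the swarm optimizer and keeps
the refined structure only if its energy is strictly lower than the
input's (accept-if-better).

Coordinates are centered before the SVD (the centroid is stored and
restored on reconstruction), which makes the basis translation-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lda import SearchSpace
from .structures import CaTrace
from .swarm import SwarmConfig, optimize

__all__ = ["SVDBasis", "RefineConfig", "RefineReport", "svd_basis", "reconstruct_svd", "refine"]


@dataclass
class SVDBasis:
    """Rank-3 factorization of a centered 3 x natoms coordinate matrix."""

    U: np.ndarray       # 3 x 3 orthogonal
    alphas: np.ndarray  # 3 singular values, descending, >= 0
    V: np.ndarray       # natoms x 3, orthonormal columns
    centroid: np.ndarray  # removed per-axis mean, restored on reconstruction


@dataclass
class RefineConfig:
    """β-box half-width (relative, default ±20% of α) and swarm settings."""

    delta: float = 0.2
    swarm: SwarmConfig = field(default_factory=SwarmConfig)

    def __post_init__(self) -> None:
        if not 0.0 < self.delta < 1.0:
            raise ValueError(f"delta must be in (0, 1), got {self.delta}")


@dataclass
class RefineReport:
    """Energies before/after refinement and the chosen β coordinates."""

    input_energy: float
    refined_energy: float
    betas: np.ndarray
    alphas: np.ndarray
    accepted: bool


def svd_basis(trace: CaTrace) -> SVDBasis:
    """Thin SVD of the centered 3 x natoms coordinate matrix.

    Singular values come out descending; each ``u_k`` is sign-fixed so its
    largest-magnitude entry is positive (``v_k`` flipped along with it).
    Planar or collinear structures simply carry zero singular values.
    """
    centroid = trace.coords.mean(axis=0)
    M = (trace.coords - centroid).T  # 3 x natoms
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    for k in range(3):
        idx = int(np.argmax(np.abs(U[:, k])))
        if U[idx, k] < 0:
            U[:, k] = -U[:, k]
            Vt[k, :] = -Vt[k, :]
    return SVDBasis(U=U, alphas=s, V=Vt.T, centroid=centroid)


def reconstruct_svd(basis: SVDBasis, betas, centroid: np.ndarray | None = None,
                    label: str = "") -> CaTrace:
    """Structure ``Σ_k β_k u_k v_kᵀ`` with the centroid restored."""
    betas = np.asarray(betas, dtype=float)
    if betas.shape != (3,) or not np.all(np.isfinite(betas)):
        raise ValueError("betas must be 3 finite reals")
    if centroid is None:
        centroid = basis.centroid
    M = basis.U @ np.diag(betas) @ basis.V.T  # 3 x natoms
    return CaTrace(M.T + centroid, label=label)


def refine(trace: CaTrace, energy, config: RefineConfig | None = None) -> tuple[CaTrace, RefineReport]:
    """Swarm-optimize the β coordinates inside ±delta·α; accept if better.

    The search box is ``[(1-delta)·α_k, (1+delta)·α_k]`` per coordinate.
    If no sampled β beats the input energy strictly, the input trace is
    returned unchanged (refinement never worsens a structure).
    """
    if config is None:
        config = RefineConfig()
    basis = svd_basis(trace)
    lo = (1.0 - config.delta) * basis.alphas
    hi = (1.0 + config.delta) * basis.alphas
    space = SearchSpace(lower=lo, upper=hi, margin=0.0)

    def objective(betas: np.ndarray) -> float:
        return float(energy(reconstruct_svd(basis, betas, label=trace.label)))

    result = optimize(objective, space, config.swarm)
    input_energy = float(energy(trace))

    if result.best_value < input_energy:
        refined = reconstruct_svd(basis, result.best_position, label=trace.label)
        report = RefineReport(
            input_energy=input_energy,
            refined_energy=float(result.best_value),
            betas=result.best_position.copy(),
            alphas=basis.alphas.copy(),
            accepted=True,
        )
        return refined, report

    report = RefineReport(
        input_energy=input_energy,
        refined_energy=input_energy,
        betas=basis.alphas.copy(),
        alphas=basis.alphas.copy(),
        accepted=False,
    )
    return trace, report
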