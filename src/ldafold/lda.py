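"""Regularized linear-discriminant model reduction of a template ensemble.

Given an ensemble of superposed, flattened templates, the pipeline

1. partitions the templates into ``k`` classes by 1-D k-means on their
   energies (at most 10 classes — with more classes the reduced space
   would exceed the ~10 dimensions that can still be sampled efficiently);
2. forms the between-class and within-class scatter matrices
   ``SB = Σ_k n_k (μ_k - μ)(μ_k - μ)ᵀ`` and
   ``SW = Σ_k Σ_{m_i ∈ C_k} (m_i - μ_k)(m_i - μ_k)ᵀ``;
3. shrinks each scatter matrix towards a scaled identity,
   ``S_reg = (1 - λ) S + λ s I`` with a data-driven intensity ``λ`` —
   necessary because the number of coordinates (3n) far exceeds the number
   of templates, which leaves ``SW`` singular;
4. extracts the top-``d`` discriminant directions from the generalized
   eigenproblem ``SB_reg w = λ SW_reg w``;
5. appends a high-frequency (HF) column — the residual of the lowest-energy
   template after projection onto the discriminant directions — so that the
   reduced space can reconstruct that template exactly;
6. derives a prismatic (axis-aligned box) search space from the min/max
   projections of the selected templates.

The resulting affine map ``a ↦ μ + V a`` with ``V`` orthonormal is the
low-dimensional space the swarm optimizer samples.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .structures import CaTrace, flatten, unflatten

__all__ = [
    "TemplateEnsemble",
    "ClassPartition",
    "ScatterPair",
    "ShrinkageResult",
    "ReducedBasis",
    "SearchSpace",
    "InsufficientTemplatesError",
    "ClassLimitError",
    "PartitionError",
    "RegularizationRequiredError",
    "kmeans_energy_partition",
    "compute_scatter",
    "shrink_scatter",
    "lda_basis",
    "append_hf_term",
    "project",
    "reconstruct",
    "search_bounds",
]

MAX_CLASSES = 10  # sampling efficiency bound on the reduced dimension
HF_DEGENERATE_TOL = 1e-10


class InsufficientTemplatesError(ValueError):
    """Fewer templates than classes requested."""


class ClassLimitError(ValueError):
    """More than 10 classes requested."""


class PartitionError(ValueError):
    """A class partition does not cover the ensemble or has empty classes."""


class RegularizationRequiredError(np.linalg.LinAlgError):
    """The within-class scatter matrix is singular; shrinkage is required."""


@dataclass
class TemplateEnsemble:
    """Flattened template matrix ``X`` (n rows = 3·residues, l columns = templates).

    Columns are expected to be superposed to a common reference before any
    scatter computation.
    """

    X: np.ndarray
    labels: list
    energies: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix (n x l)")
        n, l = self.X.shape
        if l < 2:
            raise ValueError(f"need at least 2 templates, got {l}")
        if n % 3 != 0 or n < 9:
            raise ValueError(f"row count must be 3·residue_count with ≥ 3 residues, got {n}")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("template matrix contains non-finite values")
        if len(self.labels) != l or self.energies.shape != (l,):
            raise ValueError("labels/energies length must match the number of templates")

    @classmethod
    def from_traces(cls, traces, energies) -> "TemplateEnsemble":
        X = np.column_stack([flatten(t) for t in traces])
        return cls(X=X, labels=[t.label for t in traces], energies=energies)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def l(self) -> int:
        return self.X.shape[1]

    @property
    def residue_count(self) -> int:
        return self.n // 3

    def column_trace(self, j: int) -> CaTrace:
        return unflatten(self.X[:, j], label=str(self.labels[j]))


@dataclass
class ClassPartition:
    """Assignment of each template to one of ``k`` energy classes."""

    k: int
    labels: np.ndarray
    class_sizes: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.class_sizes = np.asarray(self.class_sizes, dtype=int)
        if not 2 <= self.k <= MAX_CLASSES:
            raise ClassLimitError(f"class count must be in [2, {MAX_CLASSES}], got {self.k}")
        if self.class_sizes.shape != (self.k,) or np.any(self.class_sizes <= 0):
            raise PartitionError("every class must be non-empty")
        if self.class_sizes.sum() != self.labels.size:
            raise PartitionError("class sizes do not cover the ensemble")

    def members(self, cls: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cls)


@dataclass
class ScatterPair:
    """Between-class (SB) and within-class (SW) scatter with the class means."""

    SB: np.ndarray
    SW: np.ndarray
    mu: np.ndarray
    class_means: np.ndarray  # (n, k)


@dataclass
class ShrinkageResult:
    """A scatter matrix shrunk towards ``s·I``: ``S_reg = (1-λ) S + λ s I``."""

    S_reg: np.ndarray
    lambda_: float
    s: float


@dataclass
class ReducedBasis:
    """Affine reduced space ``a ↦ μ + V a`` with orthonormal columns ``V``.

    The first ``d`` columns span the discriminant directions; the last
    column is the HF (lowest-energy-template residual) term.  When the
    residual vanishes the HF column is a zero sentinel (``hf_degenerate``)
    and the effective dimension is ``d``.
    """

    mu: np.ndarray
    V: np.ndarray
    d: int
    column_norms: np.ndarray
    hf_degenerate: bool = False

    @property
    def n_columns(self) -> int:
        return self.V.shape[1]

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "mu": self.mu.tolist(),
            "V": self.V.tolist(),
            "d": self.d,
            "column_norms": self.column_norms.tolist(),
            "hf_degenerate": self.hf_degenerate,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "ReducedBasis":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            mu=np.array(payload["mu"]),
            V=np.array(payload["V"]),
            d=int(payload["d"]),
            column_norms=np.array(payload["column_norms"]),
            hf_degenerate=bool(payload["hf_degenerate"]),
        )


@dataclass
class SearchSpace:
    """Axis-aligned (prismatic) box of admissible reduced coordinates."""

    lower: np.ndarray
    upper: np.ndarray
    margin: float = 0.1

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if self.lower.shape != self.upper.shape:
            raise ValueError("lower/upper shape mismatch")
        if np.any(self.lower > self.upper):
            raise ValueError("lower bound exceeds upper bound")

    @property
    def dim(self) -> int:
        return self.lower.size

    def contains(self, x: np.ndarray, atol: float = 0.0) -> bool:
        return bool(np.all(x >= self.lower - atol) and np.all(x <= self.upper + atol))


def kmeans_energy_partition(energies, k: int, seed: int = 0) -> ClassPartition:
    """Partition templates into ``k`` classes by 1-D k-means on energy.

    In one dimension the k-means problem is solvable exactly: the optimal
    clusters are contiguous in sorted order, so the globally cost-minimal
    partition is found by dynamic programming over split points (no random
    restarts, no local optima).  Classes are labeled in increasing-centroid
    order; duplicate boundary values are split by stable sorted position.
    Deterministic; ``seed`` is accepted for interface stability but unused.

    Raises
    ------
    InsufficientTemplatesError
        Fewer templates than classes.
    ClassLimitError
        More than 10 classes requested.
    """
    energies = np.asarray(energies, dtype=float)
    l = energies.size
    if not 2 <= k <= MAX_CLASSES:
        raise ClassLimitError(f"class count must be in [2, {MAX_CLASSES}], got {k}")
    if l < k:
        raise InsufficientTemplatesError(f"{l} templates cannot fill {k} classes")

    order = np.argsort(energies, kind="stable")
    x = energies[order]
    pre = np.concatenate([[0.0], np.cumsum(x)])
    pre2 = np.concatenate([[0.0], np.cumsum(x**2)])

    def seg_cost(i: int, j: int) -> float:
        # within-cluster SSE of sorted points i..j-1
        s = pre[j] - pre[i]
        s2 = pre2[j] - pre2[i]
        m = j - i
        return s2 - s * s / m

    INF = np.inf
    D = np.full((k + 1, l + 1), INF)
    split = np.zeros((k + 1, l + 1), dtype=int)
    D[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, l + 1):
            best, best_i = INF, c - 1
            for i in range(c - 1, j):
                cand = D[c - 1, i] + seg_cost(i, j)
                if cand < best:  # first minimum wins -> deterministic
                    best, best_i = cand, i
            D[c, j] = best
            split[c, j] = best_i

    labels_sorted = np.empty(l, dtype=int)
    j = l
    for c in range(k, 0, -1):
        i = split[c, j]
        labels_sorted[i:j] = c - 1
        j = i
    labels = np.empty(l, dtype=int)
    labels[order] = labels_sorted

    sizes = np.bincount(labels, minlength=k)
    return ClassPartition(k=k, labels=labels, class_sizes=sizes)


def partition_cost(energies, labels) -> float:
    """Within-class sum of squared deviations of a 1-D partition."""
    energies = np.asarray(energies, dtype=float)
    labels = np.asarray(labels, dtype=int)
    cost = 0.0
    for c in np.unique(labels):
        members = energies[labels == c]
        cost += float(np.sum((members - members.mean()) ** 2))
    return cost


def compute_scatter(ensemble: TemplateEnsemble, partition: ClassPartition) -> ScatterPair:
    """Between-class and within-class scatter of the ensemble under a partition.

    ``SB = Σ_k n_k (μ_k - μ)(μ_k - μ)ᵀ``,
    ``SW = Σ_k Σ_{m_i ∈ C_k} (m_i - μ_k)(m_i - μ_k)ᵀ``,
    with μ_k the class means and μ the grand mean over all templates.
    """
    if partition.labels.size != ensemble.l:
        raise PartitionError(
            f"partition covers {partition.labels.size} templates, ensemble has {ensemble.l}"
        )
    X = ensemble.X
    mu = X.mean(axis=1)
    k = partition.k
    n = ensemble.n
    class_means = np.empty((n, k))
    SB = np.zeros((n, n))
    SW = np.zeros((n, n))
    for c in range(k):
        members = partition.members(c)
        if members.size == 0:
            raise PartitionError(f"class {c} is empty")
        Xc = X[:, members]
        mu_c = Xc.mean(axis=1)
        class_means[:, c] = mu_c
        diff = mu_c - mu
        SB += members.size * np.outer(diff, diff)
        centered = Xc - mu_c[:, None]
        SW += centered @ centered.T
    SB = 0.5 * (SB + SB.T)
    SW = 0.5 * (SW + SW.T)
    return ScatterPair(SB=SB, SW=SW, mu=mu, class_means=class_means)


def scatter_samples(ensemble: TemplateEnsemble, partition: ClassPartition) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample deviation rows whose cross-product sums rebuild SB and SW.

    Returns ``(B, W)``: ``B`` has one row ``sqrt(n_k) (μ_k - μ)`` per class
    (so ``Bᵀ B = SB``) and ``W`` one row ``m_i - μ_k`` per template
    (so ``Wᵀ W = SW``).  These rows feed the shrinkage-intensity estimate.
    """
    X = ensemble.X
    mu = X.mean(axis=1)
    b_rows = []
    w_rows = []
    for c in range(partition.k):
        members = partition.members(c)
        Xc = X[:, members]
        mu_c = Xc.mean(axis=1)
        b_rows.append(np.sqrt(members.size) * (mu_c - mu))
        w_rows.append((Xc - mu_c[:, None]).T)
    return np.vstack(b_rows), np.vstack(w_rows)


def shrink_scatter(S: np.ndarray, centered_samples: np.ndarray) -> ShrinkageResult:
    """Shrink a scatter matrix towards a scaled identity, ``(1-λ) S + λ s I``.

    ``s`` is the mean diagonal, ``trace(S)/p``.  The intensity

    ``λ = 2 Σ_{i>j} var(S_ij) / (2 Σ_{i>j} S_ij² + Σ_i (S_ii - 1)²)``

    uses, as ``var(S_ij)``, the maximum-likelihood (divide-by-N) empirical
    variance of the per-sample cross-products ``N·x_ki·x_kj`` whose mean is
    ``S_ij``; the result is clamped to [0, 1], and a zero denominator is
    defined as λ = 0.

    Parameters
    ----------
    S : (p, p) symmetric matrix
        The scatter matrix, equal to ``centered_samples.T @ centered_samples``.
    centered_samples : (N, p) matrix
        The per-sample deviation rows used to build ``S``.
    """
    S = np.asarray(S, dtype=float)
    Y = np.asarray(centered_samples, dtype=float)
    p = S.shape[0]
    if S.shape != (p, p):
        raise ValueError("S must be square")
    if Y.ndim != 2 or Y.shape[1] != p:
        raise ValueError("centered_samples must be (N, p)")
    N = Y.shape[0]
    s = float(np.trace(S)) / p

    # var of the scaled cross-products w_kij = N * y_ki * y_kj (mean = S_ij):
    # (1/N) Σ_k w² - w̄² = N * Σ_k (y_ki y_kj)² - S_ij²
    Q = (Y**2).T @ (Y**2)  # Q_ij = Σ_k y_ki² y_kj²
    var = N * Q - S**2

    iu = np.triu_indices(p, k=1)
    numerator = 2.0 * float(np.sum(var[iu]))
    denominator = 2.0 * float(np.sum(S[iu] ** 2)) + float(np.sum((np.diag(S) - 1.0) ** 2))
    if denominator == 0.0:
        lam = 0.0
    else:
        lam = min(max(numerator / denominator, 0.0), 1.0)

    S_reg = (1.0 - lam) * S + lam * s * np.eye(p)
    return ShrinkageResult(S_reg=0.5 * (S_reg + S_reg.T), lambda_=lam, s=s)


def lda_basis(SB_reg: ShrinkageResult | np.ndarray, SW_reg: ShrinkageResult | np.ndarray,
              d: int) -> np.ndarray:
    """Top-``d`` discriminant directions of ``SW⁻¹ SB``.

    Solved as the symmetric generalized eigenproblem ``SB w = λ SW w``
    (Cholesky whitening inside LAPACK) rather than forming the inverse.
    Columns are unit-normalized, ordered by descending eigenvalue, and
    sign-fixed so the largest-magnitude entry of each column is positive.
    """
    SB = SB_reg.S_reg if isinstance(SB_reg, ShrinkageResult) else np.asarray(SB_reg, float)
    SW = SW_reg.S_reg if isinstance(SW_reg, ShrinkageResult) else np.asarray(SW_reg, float)
    n = SB.shape[0]
    if not 1 <= d <= n:
        raise ValueError(f"d must be in [1, {n}], got {d}")
    try:
        np.linalg.cholesky(SW)
    except np.linalg.LinAlgError as exc:
        raise RegularizationRequiredError(
            "within-class scatter is singular; apply shrinkage before the eigensolve"
        ) from exc
    eigvals, eigvecs = scipy.linalg.eigh(SB, SW)
    order = np.argsort(eigvals)[::-1][:d]
    V = eigvecs[:, order]
    V = V / np.linalg.norm(V, axis=0, keepdims=True)
    for j in range(V.shape[1]):
        idx = int(np.argmax(np.abs(V[:, j])))
        if V[idx, j] < 0:
            V[:, j] = -V[:, j]
    return V


def append_hf_term(Vd: np.ndarray, mu: np.ndarray, m_best: np.ndarray) -> ReducedBasis:
    """Complete the discriminant basis with the high-frequency (HF) residual.

    The HF column is the residual of the lowest-energy template after its
    least-squares projection onto the discriminant directions,
    ``v_{d+1} = m_best - (μ + V_d a)``.  It guarantees that the reduced
    space can reconstruct ``m_best`` exactly — without it the best template
    is generally unreachable from the discriminant span.  All ``d+1``
    columns are then orthonormalized (QR, span and order preserved); the
    pre-orthonormalization column scales are recorded in ``column_norms``.

    If ``m_best`` already lies in the affine span (residual below 1e-10 of
    the deviation norm), the HF column is a zero sentinel and the basis has
    effective dimension ``d``.
    """
    Vd = np.asarray(Vd, dtype=float)
    mu = np.asarray(mu, dtype=float)
    m_best = np.asarray(m_best, dtype=float)
    n, d = Vd.shape
    deviation = m_best - mu
    a, *_ = np.linalg.lstsq(Vd, deviation, rcond=None)
    residual = deviation - Vd @ a
    res_norm = float(np.linalg.norm(residual))
    scale = max(1.0, float(np.linalg.norm(deviation)))

    raw_norms = np.append(np.linalg.norm(Vd, axis=0), res_norm)

    if res_norm < HF_DEGENERATE_TOL * scale:
        Q, R = np.linalg.qr(Vd)
        signs = np.sign(np.diag(R))
        signs[signs == 0] = 1.0
        Q = Q * signs
        V = np.column_stack([Q, np.zeros(n)])
        return ReducedBasis(mu=mu, V=V, d=d, column_norms=raw_norms, hf_degenerate=True)

    M = np.column_stack([Vd, residual])
    Q, R = np.linalg.qr(M)
    signs = np.sign(np.diag(R))
    signs[signs == 0] = 1.0
    Q = Q * signs
    return ReducedBasis(mu=mu, V=Q, d=d, column_norms=raw_norms, hf_degenerate=False)


def project(basis: ReducedBasis, m: np.ndarray) -> np.ndarray:
    """Reduced coordinates ``a = Vᵀ (m - μ)`` (least-squares, V orthonormal)."""
    return basis.V.T @ (np.asarray(m, dtype=float) - basis.mu)


def reconstruct(basis: ReducedBasis, a: np.ndarray) -> np.ndarray:
    """Structure vector ``m̂ = μ + V a`` for reduced coordinates ``a``."""
    a = np.asarray(a, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("reduced coordinates must be finite")
    return basis.mu + basis.V @ a


def search_bounds(basis: ReducedBasis, ensemble: TemplateEnsemble,
                  margin: float = 0.1) -> SearchSpace:
    """Prismatic admissible region from the template projections.

    Per coordinate, the min/max projection over all templates, expanded by
    ``margin``·range on each side.  Zero-range coordinates are expanded to
    ``center ± margin·max(1, |center|)`` so the box never degenerates.
    """
    if ensemble.l < 2:
        raise ValueError("need at least 2 templates to derive bounds")
    if margin < 0:
        raise ValueError("margin must be non-negative")
    A = basis.V.T @ (ensemble.X - basis.mu[:, None])  # (d+1, l)
    lo = A.min(axis=1)
    hi = A.max(axis=1)
    rng = hi - lo
    center = 0.5 * (lo + hi)
    pad = np.where(rng > 0, margin * rng, margin * np.maximum(1.0, np.abs(center)))
    return SearchSpace(lower=lo - pad, upper=hi + pad, margin=margin)
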