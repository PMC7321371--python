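"""Independent brute-force oracles used only by the test suite.

Each oracle takes a deliberately different computational route from the
implementation it checks: rotation search instead of the Kabsch closed
form, an interval dynamic program instead of the production partitioner,
and naive double loops instead of vectorized shrinkage sums.
"""

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def quaternion_grid_rmsd(mobile: np.ndarray, reference: np.ndarray,
                         n_grid: int = 3000, seed: int = 0) -> float:
    """Minimum RMSD over proper rotations via random-rotation grid + polish.

    Centers both point sets, scores ``n_grid`` uniformly random rotations
    (unit quaternions), then polishes the best one with a local rotation-
    vector optimization.  Independent of the Kabsch closed form.
    """
    a = mobile - mobile.mean(axis=0)
    b = reference - reference.mean(axis=0)
    n = a.shape[0]

    def score_matrix(R: np.ndarray) -> float:
        return float(np.sqrt(np.mean(np.sum((a @ R.T - b) ** 2, axis=1))))

    rng = np.random.default_rng(seed)
    quats = rng.normal(size=(n_grid, 4))
    quats /= np.linalg.norm(quats, axis=1, keepdims=True)
    best_val, best_quat = np.inf, None
    for q in quats:
        val = score_matrix(Rotation.from_quat(q).as_matrix())
        if val < best_val:
            best_val, best_quat = val, q

    def objective(rotvec: np.ndarray) -> float:
        return score_matrix(Rotation.from_rotvec(rotvec).as_matrix())

    x0 = Rotation.from_quat(best_quat).as_rotvec()
    res = minimize(objective, x0, method="Nelder-Mead",
                   options={"xatol": 1e-13, "fatol": 1e-15, "maxiter": 20000})
    return min(best_val, float(res.fun))


def dp_kmeans_1d_cost(values, k: int) -> float:
    """Globally optimal 1-D k-means cost by interval dynamic programming.

    Enumerates the last-cluster start point over sorted values; uses direct
    (non-prefix-sum) interval costs, so the arithmetic path differs from
    the production partitioner.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size

    def interval_cost(i: int, j: int) -> float:  # inclusive
        seg = x[i : j + 1]
        return float(np.sum((seg - seg.mean()) ** 2))

    memo = {}

    def best(c: int, j: int) -> float:  # optimal cost of x[0..j] with c clusters
        if (c, j) in memo:
            return memo[(c, j)]
        if c == 1:
            result = interval_cost(0, j)
        else:
            result = min(best(c - 1, i - 1) + interval_cost(i, j) for i in range(c - 1, j + 1))
        memo[(c, j)] = result
        return result

    return best(k, n - 1)


def naive_shrinkage(S: np.ndarray, centered_samples: np.ndarray):
    """Double-loop shrinkage intensity and target scale (λ, s).

    Same estimator definition as the implementation — the per-sample
    cross-products ``N·x_ki·x_kj`` with ML (divide-by-N) variance — but
    summed with explicit Python loops.
    """
    S = np.asarray(S, float)
    Y = np.asarray(centered_samples, float)
    N, p = Y.shape

    s = sum(S[i, i] for i in range(p)) / p

    numerator = 0.0
    denominator = 0.0
    for i in range(1, p):
        for j in range(i):
            w = np.array([N * Y[k, i] * Y[k, j] for k in range(N)])
            numerator += 2.0 * float(np.mean((w - w.mean()) ** 2))
            denominator += 2.0 * S[i, j] ** 2
    for i in range(p):
        denominator += (S[i, i] - 1.0) ** 2

    lam = 0.0 if denominator == 0 else min(max(numerator / denominator, 0.0), 1.0)
    return lam, s
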