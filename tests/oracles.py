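"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorized implementations: pair
counting is a literal triple loop over voxels, features are literal double
loops over the matrix, and the regression oracle solves the normal
equations directly.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as sps


def brute_force_pair_counts(levels: np.ndarray, Ng: int,
                            offset: tuple[int, int, int]) -> np.ndarray:
    """Symmetric integer co-occurrence counts by exhaustive enumeration."""
    nx, ny, nz = levels.shape
    dx, dy, dz = offset
    counts = np.zeros((Ng, Ng), dtype=np.int64)
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                a = levels[x, y, z]
                if a < 1:
                    continue
                X, Y, Z = x + dx, y + dy, z + dz
                if not (0 <= X < nx and 0 <= Y < ny and 0 <= Z < nz):
                    continue
                b = levels[X, Y, Z]
                if b < 1:
                    continue
                counts[a - 1, b - 1] += 1
                counts[b - 1, a - 1] += 1
    return counts


def brute_force_features(p: np.ndarray, log_base: float = 2.0) -> dict[str, float]:
    """All eight second-order features by naive double-loop summation."""
    Ng = p.shape[0]
    energy = entropy = contrast = homogeneity = dissimilarity = 0.0
    sum_average = 0.0
    mu_x = 0.0
    for i in range(Ng):
        for j in range(Ng):
            pij = p[i, j]
            li, lj = i + 1, j + 1
            energy += pij * pij
            if pij > 0:
                entropy -= pij * math.log(pij, log_base)
            contrast += (li - lj) ** 2 * pij
            homogeneity += pij / (1 + abs(li - lj))
            dissimilarity += abs(li - lj) * pij
            sum_average += (li + lj) * pij
            mu_x += li * pij
    var_x = 0.0
    for i in range(Ng):
        for j in range(Ng):
            var_x += (i + 1 - mu_x) ** 2 * p[i, j]
    corr = float("nan")
    if var_x > 0:
        num = 0.0
        for i in range(Ng):
            for j in range(Ng):
                num += (i + 1 - mu_x) * (j + 1 - mu_x) * p[i, j]
        corr = num / var_x
    return {
        "energy": energy,
        "entropy": entropy,
        "contrast": contrast,
        "homogeneity": homogeneity,
        "correlation": corr,
        "variance": var_x,
        "sum_average": sum_average,
        "dissimilarity": dissimilarity,
    }


def normal_equations_ols(X: np.ndarray, y: np.ndarray) -> dict:
    """OLS via the normal equations: coefficients, SEs, t/p, R2, R2_adj.

    ``X`` must already contain the intercept column.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, k = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    df = n - k
    sigma2 = rss / df
    se = np.sqrt(np.diag(xtx_inv) * sigma2)
    t = beta / se
    p = 2 * sps.t.sf(np.abs(t), df)
    r2 = 1 - rss / tss
    n_pred = k - 1
    r2_adj = 1 - (1 - r2) * (n - 1) / (n - n_pred - 1)
    return {
        "beta": beta,
        "se": se,
        "t": t,
        "p": p,
        "r2": r2,
        "r2_adj": r2_adj,
        "df": df,
    }


def rotations24(a: np.ndarray):
    """The 24 proper axis-aligned rotations of a 3D array."""
    orientations = [
        a,
        np.rot90(a, 1, (0, 2)),
        np.rot90(a, 2, (0, 2)),
        np.rot90(a, 3, (0, 2)),
        np.rot90(a, 1, (1, 2)),
        np.rot90(a, 3, (1, 2)),
    ]
    for b in orientations:
        for k in range(4):
            yield np.rot90(b, k, (0, 1))
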