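"""Independent oracles used by the test suite.

These deliberately avoid the package's solver path: the design-tensor
oracle is a literal triple loop, the lambda=0 oracle alternates *exact*
non-negative least squares block solves (scipy.optimize.nnls) from many
random starts, and the 1-D oracle is a brute-force grid minimizer.
"""

import numpy as np
from scipy.optimize import nnls


def brute_force_design(Phi, G):
    """Z[j,k,i,t] = sum_d Phi[d,k] * G[j,d,i,t] by explicit loops."""
    J, D, I, T = G.shape
    K = Phi.shape[1]
    Z = np.zeros((J, K, I, T))
    for j in range(J):
        for k in range(K):
            for i in range(I):
                for t in range(T):
                    acc = 0.0
                    for d in range(D):
                        acc += Phi[d, k] * G[j, d, i, t]
                    Z[j, k, i, t] = acc
    return Z


def rss_uv(y, obs, u, v, Z):
    yhat = np.einsum("ji,jk,jkit->it", u, v, Z)
    r = (y - yhat)[obs]
    return float(r @ r)


def nnls_oracle(y, obs, Z, mask, n_starts=25, seed=0, max_iter=2000, tol=1e-13):
    """Best objective of the lambda=0 constrained problem via alternating
    exact NNLS block solves from random starts.

    u-block: for each region i, a J-variable NNLS over that region's
    observed years.  v-block: a (J*K)-variable NNLS over all observed
    cells.  Each block solve is a true bound-constrained QP handled by
    scipy's NNLS solver.
    """
    J, K, I, T = Z.shape
    rng = np.random.default_rng(seed)
    best = np.inf
    for _ in range(n_starts):
        u = rng.uniform(0, 2, size=(J, I))
        u[mask] = 0.0
        v = rng.uniform(0, 2, size=(J, K))
        prev = np.inf
        for _ in range(max_iter):
            # u-block: per-region NNLS
            for i in range(I):
                o = obs[i]
                if not o.any():
                    u[:, i] = 0.0
                    continue
                A = np.stack(
                    [np.einsum("k,kt->t", v[j], Z[j, :, i, :][:, o]) for j in range(J)],
                    axis=1,
                )
                free = [j for j in range(J) if not mask[j, i]]
                if free:
                    sol, _ = nnls(A[:, free], y[i, o])
                    u[:, i] = 0.0
                    u[free, i] = sol
                else:
                    u[:, i] = 0.0
            # v-block: joint NNLS over observed cells
            Acols = []
            for j in range(J):
                for k in range(K):
                    Acols.append((u[j][:, None] * Z[j, k])[obs])
            A = np.stack(Acols, axis=1)
            sol, _ = nnls(A, y[obs])
            v = sol.reshape(J, K)
            cur = rss_uv(y, obs, u, v, Z)
            if prev - cur < tol * max(1.0, abs(prev)):
                break
            prev = cur
        best = min(best, rss_uv(y, obs, u, v, Z))
    return best


def grid_min_1d(a, b, pen, x_max, n=200001):
    """Brute-force minimizer of a*x^2 - 2*b*x + pen*x over x in [0, x_max]."""
    x = np.linspace(0.0, x_max, n)
    q = a * x**2 - 2 * b * x + pen * x
    return x[np.argmin(q)]


def random_tiny_instance(rng):
    """Random small, well-posed instance for oracle comparison."""
    J = rng.integers(1, 3)
    I = rng.integers(2, 4)
    D = rng.integers(2, 5)
    K = rng.integers(1, min(3, D + 1))
    T = rng.integers(3, 7)
    G = rng.uniform(0, 0.3, size=(J, D, I, T))
    G /= np.maximum(G.sum(axis=2, keepdims=True), 1.0)  # enforce region-sum <= 1
    u_true = rng.uniform(0.5, 2.0, size=(J, I))
    v_true = rng.uniform(0.5, 2.0, size=(J, K))
    return J, I, D, K, T, G, u_true, v_true
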