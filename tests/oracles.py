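"""Independent reference solvers used only to check the ADMM implementation.

These deliberately share no code path with the package solver:

* ``smoothed_objective_solve`` — L-BFGS on an epsilon-smoothed copy of the
  penalized objective with a continuation schedule; for the small instances
  used in tests it localizes the optimum well below the comparison
  tolerances.
* ``lasso_oracle`` — scikit-learn's coordinate-descent Lasso with the
  penalty rescaled to match ``||y - Xb||^2 + lam1 ||b||_1``.
* ``prox_scalar_oracle`` — grid + analytic minimizer of the scalar prox
  problem ``w|a| + (rho/2)(a - z)^2``.
"""

import numpy as np
from scipy.optimize import minimize


def full_objective(beta, X_list, y, weights, D):
    p = X_list[0].shape[1]
    m = len(X_list)
    betas = [beta[k * p:(k + 1) * p] for k in range(m)]
    resid = y - sum(X @ b for X, b in zip(X_list, betas))
    val = resid @ resid
    for b in betas:
        val += weights.lambda1 * np.abs(b).sum() + weights.lambda2 * np.abs(D @ b).sum()
    val += weights.lambda3 * np.linalg.norm(np.stack(betas), axis=0).sum()
    return float(val)


def _smoothed(beta, X, y, lam1, lam2, lam3, D, m, p, eps):
    resid = y - X @ beta
    val = resid @ resid
    grad = -2.0 * (X.T @ resid)

    h = np.sqrt(beta**2 + eps**2)
    val += lam1 * h.sum()
    grad += lam1 * beta / h

    Db = D @ beta
    hD = np.sqrt(Db**2 + eps**2)
    val += lam2 * hD.sum()
    grad += lam2 * (D.T @ (Db / hD))

    B = beta.reshape(m, p)
    g = np.sqrt((B**2).sum(axis=0) + eps**2)
    val += lam3 * g.sum()
    grad += lam3 * (B / g[None, :]).reshape(-1)
    return val, grad


def smoothed_objective_solve(X_list, y, weights, D, beta0=None):
    """Minimize the penalized objective via smoothing + continuation.

    ``D`` is the single-modality gradient operator (applied per block);
    returns (beta, unsmoothed objective value).
    """
    import scipy.sparse as sp

    m = len(X_list)
    p = X_list[0].shape[1]
    X = np.hstack(X_list)
    Dblock = sp.block_diag([D] * m).tocsr()
    beta = np.zeros(m * p) if beta0 is None else beta0.copy()
    for eps in (1e-2, 1e-4, 1e-6, 1e-8):
        res = minimize(
            _smoothed,
            beta,
            args=(X, y, weights.lambda1, weights.lambda2, weights.lambda3,
                  Dblock, m, p, eps),
            jac=True,
            method="L-BFGS-B",
            options=dict(maxiter=20000, ftol=1e-16, gtol=1e-12),
        )
        beta = res.x
    obj = full_objective(beta, X_list, y, weights, D)
    return beta, obj


def lasso_oracle(X, y, lam1):
    """Coordinate-descent minimizer of ||y - Xb||^2 + lam1 ||b||_1."""
    from sklearn.linear_model import Lasso

    n = X.shape[0]
    model = Lasso(alpha=lam1 / (2.0 * n), fit_intercept=False, tol=1e-12,
                  max_iter=200000)
    model.fit(X, y)
    return model.coef_


def prox_scalar_oracle(z, w, rho):
    """Minimize w|a| + (rho/2)(a - z)^2 over a (analytic + grid check)."""
    analytic = np.sign(z) * max(abs(z) - w / rho, 0.0)
    grid = np.linspace(z - 2 * abs(z) - 1, z + 2 * abs(z) + 1, 40001)
    vals = w * np.abs(grid) + 0.5 * rho * (grid - z) ** 2
    best = grid[np.argmin(vals)]
    assert abs(best - analytic) < 1e-3  # internal consistency of the oracle
    return analytic
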