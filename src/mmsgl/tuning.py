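"""Hyperparameter reparameterization, information criteria, and grid search.

The three penalty weights are tuned through the reparameterization

    (lambda1, lambda2, lambda3) = lambda * (r12*(1-r3), (1-r12)*(1-r3), r3)

so that ``lambda`` sets the overall penalty mass (lambda1+lambda2+lambda3 =
lambda exactly) and the ratios split it between lasso, TV, and group terms.
Model selection uses the BIC computed on the full training set,

    BIC = n * log(RSS / n) + log(n) * df,

with ``df`` the number of nonzero coefficients; the GIC variant replaces
``log(n)`` with ``log(log(n)) * log(n_features)``.

Default grids: lambda log-uniform on [e^-9, e^0] (10 points), r12 in
{0.1, ..., 0.9}, with the model restrictions r3 = 0 for IS and JS (the JS
objective has no group term, so r3 > 0 points are redundant) and
(r12, r3) = (0.05, 0.6) for SGL.  A smaller lambda cap (e.g. e^-1, used for
real neuroimaging masks) can replace the upper endpoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import models
from .admm import PenaltyWeights, SolverSettings
from .models import MultimodalDesign

__all__ = ["TuningGrid", "reparameterize", "bic", "default_grid", "grid_search"]

NEG_INF = float("-inf")


def reparameterize(lam: float, r12: float, r3: float) -> PenaltyWeights:
    """Map ``(lambda, r12, r3)`` to ``(lambda1, lambda2, lambda3)``."""
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    if not 0.0 <= r12 <= 1.0:
        raise ValueError("r12 must lie in [0, 1]")
    if not 0.0 <= r3 < 1.0:
        raise ValueError("r3 must lie in [0, 1)")
    return PenaltyWeights(
        lambda1=lam * r12 * (1.0 - r3),
        lambda2=lam * (1.0 - r12) * (1.0 - r3),
        lambda3=lam * r3,
    )


@dataclass
class TuningGrid:
    """Grid of ``(lambda, r12, r3)`` values to search per model."""

    lambda_values: np.ndarray
    r12_values: np.ndarray
    r3_values: np.ndarray

    def __post_init__(self):
        self.lambda_values = np.sort(np.asarray(self.lambda_values, dtype=float))
        self.r12_values = np.asarray(self.r12_values, dtype=float)
        self.r3_values = np.asarray(self.r3_values, dtype=float)
        if min(self.lambda_values.size, self.r12_values.size, self.r3_values.size) == 0:
            raise ValueError("grids must be nonempty")
        if self.lambda_values.min() < 0:
            raise ValueError("lambda values must be nonnegative")

    @property
    def n_points(self) -> int:
        return self.lambda_values.size * self.r12_values.size * self.r3_values.size


def default_grid(
    model_kind: str,
    n_lambda: int = 10,
    lambda_max: float = 1.0,
    lambda_min: float = np.exp(-9.0),
) -> TuningGrid:
    """Per-model default grid with the standard restrictions applied."""
    lam = np.exp(np.linspace(np.log(lambda_min), np.log(lambda_max), n_lambda))
    r12_full = np.round(np.arange(0.1, 0.95, 0.1), 10)
    kind = model_kind.lower()
    if kind == "sgl":
        return TuningGrid(lam, np.array([0.05]), np.array([0.6]))
    if kind in ("js", "is"):
        return TuningGrid(lam, r12_full, np.array([0.0]))
    raise ValueError(f"unknown model kind {model_kind!r}")


def _df(fit) -> int:
    return int(fit.full_support.size)


def _criterion_value(rss, n, df, n_features, criterion, sigma2):
    if rss <= 0.0 and criterion in ("bic", "gic"):
        warnings.warn("zero RSS (interpolating fit); criterion set to -inf", RuntimeWarning)
        return NEG_INF
    if criterion == "bic":
        return float(n * np.log(rss / n) + np.log(n) * df)
    if criterion == "gic":
        return float(n * np.log(rss / n) + np.log(np.log(n)) * np.log(n_features) * df)
    if criterion == "bic_fixed":
        # Gaussian BIC with known noise variance: -2 loglik = RSS / sigma^2.
        # Unlike the profiled form, this stays informative when df >> n.
        if sigma2 is None or sigma2 <= 0:
            raise ValueError("criterion 'bic_fixed' needs a positive sigma2")
        return float(rss / sigma2 + np.log(n) * df)
    raise ValueError(f"unknown criterion {criterion!r}")


def bic(fit, design: MultimodalDesign, criterion: str = "bic", sigma2: float | None = None) -> float:
    """Information criterion of a fit on its training design.

    ``criterion='bic'`` is the profiled-variance form
    ``n log(RSS/n) + log(n) df``; ``'gic'`` swaps the ``log(n)`` factor for
    ``log(log n) log(p_total)``; ``'bic_fixed'`` is the known-variance form
    ``RSS/sigma2 + log(n) df`` (use when the noise variance is part of the
    study design, e.g. in simulations).  ``df`` is the nonzero count.
    """
    yhat = models.predict(fit, design)
    rss = float(np.sum((design.y - yhat) ** 2))
    return _criterion_value(
        rss, design.n, _df(fit), design.n_modalities * design.p, criterion, sigma2
    )


def _scale(w: PenaltyWeights, s: float) -> PenaltyWeights:
    return PenaltyWeights(s * w.lambda1, s * w.lambda2, s * w.lambda3)


def _search_joint(model_kind, design, grid, settings, criterion, penalty_scale, sigma2):
    """Warm-started search for the JS/SGL models (single shared fit)."""
    fit_fn = models.fit_sgl if model_kind == "sgl" else models.fit_js
    rows, fits = [], []
    for r12 in grid.r12_values:
        for r3 in grid.r3_values:
            state = None
            for lam in grid.lambda_values[::-1]:  # largest to smallest
                weights = _scale(reparameterize(lam, r12, r3), penalty_scale)
                fit = fit_fn(design, weights, settings, init=state)
                state = fit.state
                score = bic(fit, design, criterion, sigma2)
                rows.append(
                    dict(
                        model=model_kind, lam=lam, r12=r12, r3=r3, score=score,
                        df=_df(fit), converged=fit.converged, n_iter=fit.n_iter,
                    )
                )
                fits.append(fit)
    table = pd.DataFrame(rows)
    if not table.converged.any():
        raise RuntimeError(
            "no grid point converged; diagnostics:\n" + table.to_string(index=False)
        )
    best = _select(table)
    return fits[best], table


def _select(table: pd.DataFrame) -> int:
    """Argmin of the criterion; exact ties broken toward larger lambda."""
    order = np.lexsort((-table.lam.to_numpy(), table.score.to_numpy()))
    return int(order[0])


def _search_independent(design, grid, settings, criterion, penalty_scale, sigma2):
    """Per-modality searches for the IS model."""
    tables, best_fits = [], []
    for k in range(design.n_modalities):
        sub = models.standardize([design.X_list[k]], design.y, space=design.space)
        sub.y_sd = design.y_sd
        # reuse expensive caches: the sub-design shares geometry with the parent
        sub._cache[("bundle", 1)] = design.bundle(n_modalities=1)
        sub._cache[("xnorm", None)] = design.x_norm_sq(k)
        rows, fits = [], []
        for r12 in grid.r12_values:
            state = None
            for lam in grid.lambda_values[::-1]:
                weights = _scale(reparameterize(lam, r12, 0.0), penalty_scale)
                fit = models.fit_sgl(sub, weights, settings, init=state)
                state = fit.state
                score = bic(fit, sub, criterion, sigma2)
                rows.append(
                    dict(
                        model="is", modality=k, lam=lam, r12=r12, r3=0.0,
                        score=score, df=_df(fit), converged=fit.converged,
                        n_iter=fit.n_iter,
                    )
                )
                fits.append(fit)
        table = pd.DataFrame(rows)
        if not table.converged.any():
            raise RuntimeError(
                f"no grid point converged for modality {k}; diagnostics:\n"
                + table.to_string(index=False)
            )
        tables.append(table)
        best_fits.append(fits[_select(table)])
    return models.ISFit(fits=best_fits), pd.concat(tables, ignore_index=True)


def grid_search(
    model_kind: str,
    design: MultimodalDesign,
    grid: TuningGrid | None = None,
    settings: SolverSettings | None = None,
    criterion: str = "bic",
    penalty_scale: float = 1.0,
    sigma2: float | None = None,
):
    """Fit every grid point (warm-started along lambda) and select by BIC.

    Returns ``(best_fit, score_table)`` where the table holds one row per
    fitted grid point.  IS runs an independent search per modality and
    returns an :class:`~mmsgl.models.ISFit`.  ``penalty_scale`` multiplies
    the penalty weights at fit time (the score table keeps the nominal
    grid values); with ``penalty_scale=n`` and an SD-scaled response the
    objective is the mean-squared-error form of the problem, under which the
    default lambda range spans "select everything" to "select nothing".
    """
    kind = model_kind.lower()
    if grid is None:
        grid = default_grid(kind)
    if kind in ("sgl", "js"):
        return _search_joint(kind, design, grid, settings, criterion, penalty_scale, sigma2)
    if kind == "is":
        return _search_independent(design, grid, settings, criterion, penalty_scale, sigma2)
    raise ValueError(f"unknown model kind {model_kind!r}")
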