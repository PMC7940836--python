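"""Estimators over a shared standardized multimodal design.

Three models are exposed, all built on the same ADMM solver:

* ``fit_is`` — *independent sparse*: one lasso+TV fit per modality;
  predictions are unweighted averages across the per-modality models.
* ``fit_js`` — *joint sparse*: both modalities in one regression with lasso
  and TV penalties (the sparse-group weight is zero).
* ``fit_sgl`` — the *sparse group lasso* estimator: lasso + TV + a voxel-wise
  Euclidean group penalty coupling the modalities, encouraging (without
  forcing) overlap of the per-modality supports.

Design matrices are columnwise standardized (sample SD, ddof=1) before
fitting; test data is standardized with the stored training parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import admm
from .admm import FitResult, PenaltyWeights, SolverSettings
from .operators import VoxelSpace, build_operator_bundle

__all__ = [
    "MultimodalDesign",
    "ISFit",
    "standardize",
    "fit_sgl",
    "fit_js",
    "fit_is",
    "predict",
    "coefficients_raw",
]


@dataclass
class MultimodalDesign:
    """Standardized design matrices plus the parameters to reuse on new data.

    ``X_list`` holds one ``(n, p)`` columnwise-standardized matrix per
    modality; zero-variance columns are recorded in ``dropped`` and their
    standardized values set to zero (their coefficients stay at zero under
    any nonzero penalty).
    """

    X_list: list
    y: np.ndarray
    col_means: list
    col_sds: list
    dropped: list
    y_mean: float
    y_sd: float = 1.0
    space: VoxelSpace | None = None
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def y_fit(self) -> np.ndarray:
        """Response on the scale the solver sees (SD-scaled if requested)."""
        return self.y / self.y_sd

    @property
    def n(self) -> int:
        return self.X_list[0].shape[0]

    @property
    def p(self) -> int:
        return self.X_list[0].shape[1]

    @property
    def n_modalities(self) -> int:
        return len(self.X_list)

    def _default_space(self) -> VoxelSpace:
        if self.space is not None:
            return self.space
        from .operators import build_voxel_space

        # degenerate 1D lattice: no spatial structure beyond a chain
        space = build_voxel_space((self.p, 1, 1), np.ones((self.p, 1, 1), bool))
        return space

    def bundle(self, n_modalities: int | None = None):
        m = n_modalities or self.n_modalities
        key = ("bundle", m)
        if key not in self._cache:
            self._cache[key] = build_operator_bundle(self._default_space(), m)
        return self._cache[key]

    def x_norm_sq(self, modality: int | None = None) -> float:
        """Cached largest eigenvalue of X^T X (full design or one modality)."""
        key = ("xnorm", modality)
        if key not in self._cache:
            X = (
                np.hstack(self.X_list)
                if modality is None
                else np.asarray(self.X_list[modality])
            )
            self._cache[key] = admm.design_norm_sq(X)
        return self._cache[key]


def _standardize_matrix(X, means=None, sds=None):
    X = np.asarray(X, dtype=float)
    if means is None:
        means = X.mean(axis=0)
        sds = X.std(axis=0, ddof=1)
    dropped = np.flatnonzero(sds <= 1e-12)
    safe = np.where(sds <= 1e-12, 1.0, sds)
    Xs = (X - means) / safe
    if dropped.size:
        Xs[:, dropped] = 0.0
    return Xs, means, sds, dropped


def standardize(
    raw_X_list, y, space: VoxelSpace | None = None, scale_y: bool = False
) -> MultimodalDesign:
    """Columnwise standardize each modality and wrap into a design.

    Uses the sample-SD convention (ddof=1), constant across train/test.
    Already-standardized input passes through unchanged (idempotent).
    Constant columns are flagged in ``design.dropped`` and zeroed out.
    With ``scale_y=True`` the solver fits the SD-scaled response (penalty
    weights then act relative to a unit-variance response); predictions are
    always returned on the raw ``y`` scale.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    Xs_list, means, sds, dropped = [], [], [], []
    p0 = None
    for X in raw_X_list:
        X = np.asarray(X, dtype=float)
        if X.shape[0] != y.size:
            raise ValueError("all modalities must share n with y")
        if p0 is None:
            p0 = X.shape[1]
        elif X.shape[1] != p0:
            raise ValueError("all modalities must share the voxel count p")
        Xs, mu, sd, drop = _standardize_matrix(X)
        Xs_list.append(Xs)
        means.append(mu)
        sds.append(sd)
        dropped.append(drop)
    if space is not None and space.p != p0:
        raise ValueError(f"voxel space has p={space.p} but design has p={p0}")
    y_sd = float(np.std(y, ddof=1)) if scale_y else 1.0
    if y_sd <= 0:
        raise ValueError("response has zero variance; cannot scale y")
    return MultimodalDesign(
        X_list=Xs_list,
        y=y,
        col_means=means,
        col_sds=sds,
        dropped=dropped,
        y_mean=float(y.mean()),
        y_sd=y_sd,
        space=space,
    )


def fit_sgl(
    design: MultimodalDesign,
    weights: PenaltyWeights,
    settings: SolverSettings | None = None,
    init=None,
) -> FitResult:
    """Fit the sparse-group-lasso estimator (all three penalties)."""
    return admm.solve(
        design.X_list,
        design.y_fit,
        design.bundle(),
        weights,
        settings,
        init=init,
        X_norm_sq=design.x_norm_sq(),
    )


def fit_js(
    design: MultimodalDesign,
    weights: PenaltyWeights,
    settings: SolverSettings | None = None,
    init=None,
) -> FitResult:
    """Fit the joint sparse model: identical to SGL with lambda3 = 0."""
    w = PenaltyWeights(weights.lambda1, weights.lambda2, 0.0)
    return fit_sgl(design, w, settings, init=init)


@dataclass
class ISFit:
    """Pair of independent single-modality fits with an averaged prediction."""

    fits: list

    @property
    def n_modalities(self) -> int:
        return len(self.fits)

    @property
    def intercept(self) -> float:
        return self.fits[0].intercept

    def support(self, modality: int) -> np.ndarray:
        return self.fits[modality].support(0)

    @property
    def support1(self) -> np.ndarray:
        return self.support(0)

    @property
    def support2(self) -> np.ndarray:
        return self.support(1)

    @property
    def joint_support(self) -> np.ndarray:
        s = self.support(0)
        for k in range(1, self.n_modalities):
            s = np.intersect1d(s, self.support(k), assume_unique=True)
        return s

    @property
    def full_support(self) -> np.ndarray:
        p = self.fits[0].betas[0].size
        return np.concatenate([self.support(k) + k * p for k in range(self.n_modalities)])

    @property
    def betas(self) -> list:
        return [f.betas[0] for f in self.fits]

    @property
    def converged(self) -> bool:
        return all(f.converged for f in self.fits)


def fit_is(
    design: MultimodalDesign,
    weights: PenaltyWeights,
    settings: SolverSettings | None = None,
    inits=None,
) -> ISFit:
    """Fit one lasso+TV model per modality (the group weight is ignored)."""
    w = PenaltyWeights(weights.lambda1, weights.lambda2, 0.0)
    bundle1 = design.bundle(n_modalities=1)
    fits = []
    for k in range(design.n_modalities):
        init = inits[k] if inits is not None else None
        fits.append(
            admm.solve(
                [design.X_list[k]],
                design.y_fit,
                bundle1,
                w,
                settings,
                init=init,
                X_norm_sq=design.x_norm_sq(k),
            )
        )
    return ISFit(fits=fits)


def _standardize_new(design: MultimodalDesign, raw_X_list):
    out = []
    for k, X in enumerate(raw_X_list):
        Xs, *_ = _standardize_matrix(X, design.col_means[k], design.col_sds[k])
        drop = design.dropped[k]
        if drop.size:
            Xs[:, drop] = 0.0
        out.append(Xs)
    return out


def predict(fit, design: MultimodalDesign, raw_X_list=None) -> np.ndarray:
    """Predict the response for new (raw-scale) data.

    With ``raw_X_list=None`` the training design is used (fitted values).
    JS/SGL: ``yhat = ybar + sum_k X_k beta_k``.  IS: unweighted average of
    the per-modality predictions, i.e. ``ybar + mean_k(X_k beta_k)``.
    """
    if raw_X_list is None:
        Xs_list = design.X_list
    else:
        if len(raw_X_list) != design.n_modalities:
            raise ValueError("need one matrix per modality")
        for X in raw_X_list:
            if np.asarray(X).shape[1] != design.p:
                raise ValueError("new data has a different voxel count than training")
        Xs_list = _standardize_new(design, raw_X_list)
    if isinstance(fit, ISFit):
        preds = [
            f.intercept + Xs @ f.betas[0] for f, Xs in zip(fit.fits, Xs_list)
        ]
        return design.y_sd * np.mean(preds, axis=0)
    contrib = sum(Xs @ b for Xs, b in zip(Xs_list, fit.betas))
    return design.y_sd * (fit.intercept + contrib)


def coefficients_raw(fit, design: MultimodalDesign):
    """Back-transform coefficients to the raw (unstandardized) data scale.

    Returns ``(betas_raw, intercept_raw)`` such that
    ``intercept_raw + sum_k X_raw_k @ beta_raw_k`` reproduces the
    standardized-scale predictions exactly.
    """
    betas = fit.betas
    betas_raw, shift = [], 0.0
    for k, b in enumerate(betas):
        sd = np.where(design.col_sds[k] <= 1e-12, 1.0, design.col_sds[k])
        br = design.y_sd * b / sd
        if isinstance(fit, ISFit):
            br = br / fit.n_modalities  # averaging weight folded in
        betas_raw.append(br)
        shift += design.col_means[k] @ br
    intercept = fit.intercept if not isinstance(fit, ISFit) else fit.fits[0].intercept
    return betas_raw, float(design.y_sd * intercept - shift)
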