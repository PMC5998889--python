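"""Regulation-intensity estimation by leave-one-out parent regression.

The segmentation stage consumes an intensity matrix M whose sign encodes,
per regulated gene and time point, whether the gene's expression is explained
by its upstream regulators there.  This module provides a reference
leave-one-out estimator of M; externally computed matrices (e.g. from the
tacs R package) can equally be loaded with :func:`regushift.io.read_intensity`
and fed to the search unchanged.

For gene g with parent set P(g) and time point j, the estimator fits a
linear model of g's expression on its parents using every time point except
j, predicts the held-out value y^_j, and forms a standardized leave-one-out
residual

    rho_j^2 = (y_j - y^_j)^2 * (1 / s_r^2 + 1 / s_j^2),

where s_r is a robust scale of the gene's leave-one-out residuals and s_j
is the standard deviation of the j-th fit's fitted values (the scale of the
signal the parents actually explain).  The intensity is

    M_gj = lambda - min(rho_j^2, rho_cap)     (lambda = 2 by default).

Three features make this usable for transition analysis:

* The fit is robust (least-trimmed-squares style concentration steps over
  the ordinary least-squares core, run from several value-sorted starting
  subsets, keeping the solution with the best noise-to-signal ratio and
  re-fitting on its inliers).  Regulation that is active in only part of
  the time course is the very phenomenon being studied, so the fit must
  lock onto the locally consistent parent-child relation instead of
  averaging the active and inactive regimes into a meaningless global
  slope.
* The residual scale s_r is taken from the cleanest 40% of the gene's own
  leave-one-out residuals (with the Gaussian consistency factor), so points
  that follow the locked-on regime score rho^2 ~ 1 regardless of how badly
  the other regime misfits; dividing also by the explained-signal scale s_j
  means a point only scores positive when the parent model explains real
  signal.  A perfectly explained point gives M = lambda; under active
  regulation with signal well above noise, E[rho^2] ~ 1 so
  M ~ lambda - 1 > 0; a child decoupled from its parents leaves the fit
  with (near) zero explained signal, rho^2 blows up, and M goes strongly
  negative.
* rho^2 is capped (rho_cap = 9, a 3-sigma discrepancy) so no single time
  point can dominate a period sum or, downstream, justify a break on its
  own.

rho is invariant to affine rescaling of the child, and the estimator uses
no temporal ordering anywhere, so permuting time points permutes M's
columns identically.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .model import (
    ExpressionProfile,
    IntensityMatrix,
    RegulatoryNetwork,
    ValidationError,
)

__all__ = ["IntensityConfig", "ParentFit", "fit_parent_model", "loo_intensity"]

logger = logging.getLogger(__name__)

# fraction of leave-one-out residuals assumed to come from the locked-on
# regime when estimating the per-gene residual scale
_CLEAN_FRACTION = 0.4


@dataclass(frozen=True)
class IntensityConfig:
    """Parameters of the leave-one-out intensity estimator.

    lambda_offset
        Value of M at a perfectly explained point (> 0).  The default 2.0
        calibrates against the unit-mean chi-square of a standardized
        residual: well-explained points score about +1, outliers negative.
    sigma_floor
        Lower bound on the residual and signal scales (> 0), guarding exact
        fits and degenerate designs.
    robust
        Fit by trimmed least squares (default) so that a regulation active
        in only part of the time course is still scored against its own
        regime; set False for a plain pooled OLS fit.
    rho_cap
        Upper bound on the squared standardized residual (default 9, a
        3-sigma discrepancy), bounding the influence of any single time
        point on period sums.
    """

    lambda_offset: float = 2.0
    sigma_floor: float = 1e-8
    robust: bool = True
    rho_cap: float = 9.0

    def __post_init__(self) -> None:
        if not self.lambda_offset > 0:
            raise ValidationError("lambda_offset must be > 0")
        if not self.sigma_floor > 0:
            raise ValidationError("sigma_floor must be > 0")
        if not self.rho_cap > 0:
            raise ValidationError("rho_cap must be > 0")


@dataclass
class ParentFit:
    """OLS fit of a child gene on its parents (intercept included)."""

    intercept: float
    slopes: np.ndarray
    residual_scale: float
    signal_scale: float
    degenerate: bool

    @property
    def coef(self) -> np.ndarray:
        """Coefficients with the intercept first."""
        return np.concatenate([[self.intercept], self.slopes])

    def predict(self, parent_values) -> np.ndarray:
        X = np.atleast_2d(np.asarray(parent_values, dtype=float))
        return self.intercept + X @ self.slopes


def fit_parent_model(child_values, parent_values, sigma_floor: float = 1e-8) -> ParentFit:
    """Least-squares fit of a child's expression on its parents' expression.

    ``parent_values`` is (n points) x (p parents); at least p + 2 points are
    required.  The residual scale is ``sqrt(RSS / (n - rank - 1))`` floored
    at ``sigma_floor``.  Rank-deficient designs (e.g. a constant parent) are
    solved by pseudo-inverse on the centered design — which leaves the
    dependent directions at zero slope, so the intercept is the child mean —
    and flagged degenerate.
    """
    y = np.asarray(child_values, dtype=float).ravel()
    X = np.asarray(parent_values, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if y.size != n:
        raise ValidationError(f"child has {y.size} points but parents have {n}")
    if n < p + 2:
        raise ValidationError(
            f"need at least {p + 2} points to fit {p} parent(s), got {n}"
        )
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    if p == 1:  # closed form; this is the hot path of the LOO sweep
        sxx = float(Xc[:, 0] @ Xc[:, 0])
        if sxx > 0:
            slopes = np.array([float(Xc[:, 0] @ (y - y_mean)) / sxx])
            rank = 1
        else:
            slopes = np.zeros(1)
            rank = 0
    else:
        slopes, _, rank, _ = np.linalg.lstsq(Xc, y - y_mean, rcond=None)
    intercept = y_mean - float(x_mean @ slopes)
    fitted = intercept + X @ slopes
    rss = float(((y - fitted) ** 2).sum())
    dof = max(n - rank - 1, 1)
    residual_scale = max(np.sqrt(rss / dof), sigma_floor)
    signal_scale = max(float(fitted.std()), sigma_floor)
    return ParentFit(
        intercept=intercept,
        slopes=slopes,
        residual_scale=residual_scale,
        signal_scale=signal_scale,
        degenerate=rank < p,
    )


def _trim_correction(q: float) -> float:
    """Variance of the best q-fraction of Gaussian residuals relative to 1.

    Keeping the h = q*n observations with the smallest residuals deflates
    the residual variance by E[Z^2 | |Z| < a]/1 with a = Phi^-1((1+q)/2);
    the trimmed scale is divided by the square root of this factor.
    """
    a = float(norm.ppf((1.0 + q) / 2.0))
    return max((q - 2.0 * a * float(norm.pdf(a))) / q, 1e-3)


def _csteps(
    y: np.ndarray, X: np.ndarray, start: np.ndarray, h: int, sigma_floor: float
) -> ParentFit:
    """Concentration steps: refit on the h points with the smallest residuals
    until the subset stabilizes; returns the converged fit."""
    idx = list(start)
    fit = fit_parent_model(y[idx], X[idx, :], sigma_floor=sigma_floor)
    subset: tuple[int, ...] | None = None
    for _ in range(20):
        resid = np.abs(y - fit.predict(X))
        new = tuple(np.sort(np.argsort(resid, kind="stable")[:h]))
        if new == subset:
            break
        subset = new
        idx = list(new)
        fit = fit_parent_model(y[idx], X[idx, :], sigma_floor=sigma_floor)
    return fit


def _trimmed_fit(y: np.ndarray, X: np.ndarray, sigma_floor: float) -> ParentFit:
    """Least-trimmed-squares style fit with a final reweighting step.

    C-steps are run from several starting subsets and the converged solution
    with the best noise-to-signal ratio (trimmed residual scale over
    explained-signal scale) is kept — selecting the regime the parents
    explain best rather than the flattest stretch of data.  Starts are
    blocks of points sorted by the child's and each parent's expression
    values, never by time or by random draw, so the estimator stays
    deterministic and equivariant under permutation of time points.  The
    trimmed scale (Gaussian consistency corrected) then defines inliers
    (|residual| <= 2.5 sigma) and the returned fit is the plain OLS fit on
    the inliers, which coincides with the full OLS fit when the data are
    homogeneous.
    """
    n, p = X.shape
    h = max(p + 2, n // 2 + 1)
    if h >= n:
        return fit_parent_model(y, X, sigma_floor=sigma_floor)
    starts: list[np.ndarray] = [np.arange(n)]
    mid = (n - h) // 2
    for col in (y, *X.T):
        order = np.argsort(col, kind="stable")
        starts.extend((order[:h], order[-h:], order[mid : mid + h]))
    fit = min(
        (_csteps(y, X, s, h, sigma_floor) for s in starts),
        key=lambda f: f.residual_scale / f.signal_scale,
    )
    scale = max(fit.residual_scale / math.sqrt(_trim_correction(h / n)), sigma_floor)
    resid = np.abs(y - fit.predict(X))
    inliers = np.flatnonzero(resid <= 2.5 * scale)
    if inliers.size >= p + 2:
        fit = fit_parent_model(y[inliers], X[inliers, :], sigma_floor=sigma_floor)
    fitted_all = fit.predict(X)
    return ParentFit(
        intercept=fit.intercept,
        slopes=fit.slopes,
        residual_scale=max(fit.residual_scale, sigma_floor),
        signal_scale=max(float(fitted_all.std()), sigma_floor),
        degenerate=fit.degenerate,
    )


def loo_intensity(
    profile: ExpressionProfile,
    network: RegulatoryNetwork,
    config: IntensityConfig | None = None,
) -> IntensityMatrix:
    """Leave-one-out intensity matrix for every regulated gene in the network.

    Rows exist only for genes with at least one parent (other than
    themselves); every regulated gene and all its parents must be present in
    the profile, and |T| must be at least the largest parent count plus 3 so
    each leave-one-out fit retains two residual degrees of freedom.
    """
    config = config or IntensityConfig()
    regulated = [g for g in profile.gene_ids if network.parents(g)]
    missing = [g for g in network.regulated_genes if g not in profile.gene_ids]
    if missing:
        raise ValidationError(
            f"regulated gene(s) missing from profile: {missing}"
        )
    if not regulated:
        raise ValidationError("network has no regulated gene present in profile")
    max_parents = max(len(network.parents(g)) for g in regulated)
    if profile.n_times < max_parents + 3:
        raise ValidationError(
            f"need |T| >= {max_parents + 3} time points for {max_parents} "
            f"parent(s), got {profile.n_times}"
        )
    gene_index = {g: i for i, g in enumerate(profile.gene_ids)}
    n_times = profile.n_times
    M = np.empty((len(regulated), n_times))
    lam = config.lambda_offset
    # scale of the cleanest 40% of |residuals|, Gaussian-consistent
    z_clean = float(norm.ppf(0.5 + _CLEAN_FRACTION / 2.0))
    for gi, g in enumerate(regulated):
        parents = network.parents(g)
        absent = [p for p in parents if p not in gene_index]
        if absent:
            raise ValidationError(
                f"parent(s) of {g!r} missing from profile: {absent}"
            )
        y = profile.values[gene_index[g]]
        X = profile.values[[gene_index[p] for p in parents]].T  # T x p
        resid = np.empty(n_times)
        signal = np.empty(n_times)
        degenerate = False
        for j in range(n_times):
            keep = np.arange(n_times) != j
            if config.robust:
                fit = _trimmed_fit(y[keep], X[keep], sigma_floor=config.sigma_floor)
            else:
                fit = fit_parent_model(
                    y[keep], X[keep], sigma_floor=config.sigma_floor
                )
            degenerate |= fit.degenerate
            resid[j] = y[j] - fit.predict(X[j])[0]
            signal[j] = fit.signal_scale
        s_r = max(
            float(np.quantile(np.abs(resid), _CLEAN_FRACTION)) / z_clean,
            config.sigma_floor,
        )
        rho2 = resid * resid * (1.0 / s_r**2 + 1.0 / signal**2)
        M[gi] = lam - np.minimum(rho2, config.rho_cap)
        if degenerate:
            logger.warning(
                "degenerate parent design for gene %r (collinear or constant "
                "parents); intensities computed via pseudo-inverse", g
            )
    return IntensityMatrix(regulated, profile.time_points, M)
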