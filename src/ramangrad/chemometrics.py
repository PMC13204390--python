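"""Multivariate analysis of spectral matrices: PCA, ASCA, PLS, calibration.

* :func:`pca` — truncated SVD of the column-centered matrix, with a fixed
  sign convention (largest-magnitude element of each loading positive) so
  score trajectories are reproducible across runs.
* :func:`asca` — ANOVA-simultaneous component analysis: the matrix is split
  into a grand mean, one effect matrix per design factor (each sample's row
  is its factor-level mean deviation from the grand mean), and a residual;
  PCA is then applied to each effect matrix without further centering.
* :func:`pls_fit` / :func:`pls_predict` — single-response NIPALS partial
  least squares, used both for the pH calibration model and (with +/-1 coded
  responses) for zone projections.
* :func:`linear_calibration` — ordinary least squares of band intensity on
  concentration with R².
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PCAResult",
    "ASCAResult",
    "PLSModel",
    "CalibrationFit",
    "pca",
    "asca",
    "pls_fit",
    "pls_predict",
    "select_n_lv_loo",
    "linear_calibration",
]


@dataclass
class PCAResult:
    scores: np.ndarray                  # (n, k)
    loadings: np.ndarray                # (k, c), rows orthonormal
    explained_variance_ratio: np.ndarray
    column_means: np.ndarray


@dataclass
class ASCAResult:
    grand_mean: np.ndarray
    effect_matrices: Dict[str, np.ndarray]
    residual: np.ndarray
    factor_pca: Dict[str, PCAResult]
    factor_ss: Dict[str, float]         # sum of squares per factor effect
    residual_ss: float = 0.0


@dataclass
class PLSModel:
    n_lv: int
    x_weights: np.ndarray               # (n_lv, c)
    x_loadings: np.ndarray              # (n_lv, c)
    y_loadings: np.ndarray              # (n_lv,)
    x_scores: np.ndarray                # (n, n_lv)
    regression_coefficients: np.ndarray # (c,)
    x_mean: np.ndarray
    y_mean: float


@dataclass
class CalibrationFit:
    slope: float
    intercept: float
    r_squared: float
    n_points: int


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def _fix_signs(loadings: np.ndarray, scores: np.ndarray) -> None:
    for j in range(loadings.shape[0]):
        i = int(np.argmax(np.abs(loadings[j])))
        if loadings[j, i] < 0:
            loadings[j] *= -1.0
            scores[:, j] *= -1.0


def pca(X: np.ndarray, k: int, center: bool = True) -> PCAResult:
    """Principal component analysis by truncated SVD.

    ``center=False`` is used for ASCA effect matrices, which are already
    centered by construction on balanced designs.
    """
    X = np.asarray(X, dtype=float)
    n, c = X.shape
    if n < 2:
        raise ValueError("need at least 2 spectra")
    if k > min(n - 1, c) or k < 1:
        raise ValueError(f"k must lie in [1, min(n-1, n_channels)] = [1, {min(n - 1, c)}]")
    mu = X.mean(axis=0) if center else np.zeros(c)
    Xc = X - mu
    total = float(np.sum(Xc * Xc))
    if total <= 1e-300:
        raise ValueError("matrix has zero variance; no components to extract")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :k] * s[:k]
    loadings = Vt[:k].copy()
    _fix_signs(loadings, scores)
    evr = (s[:k] ** 2) / np.sum(s**2)
    return PCAResult(scores=scores, loadings=loadings,
                     explained_variance_ratio=evr, column_means=mu)


# ---------------------------------------------------------------------------
# ASCA
# ---------------------------------------------------------------------------


def asca(
    X: np.ndarray,
    factors: Dict[str, Sequence],
    n_components: int | None = None,
    include_interaction: bool = False,
) -> ASCAResult:
    """Partition a designed spectral matrix into per-factor effects + residual.

    ``factors`` maps factor name (e.g. "day", "zone") to a per-spectrum label
    sequence. Effects of a factor are the level-mean deviations from the
    grand mean, broadcast back onto the sample rows; on balanced designs each
    effect matrix has zero column means and the decomposition

        X = grand_mean + sum(effects) [+ interaction] + residual

    is exact by construction. The optional two-factor interaction effect is
    the cell-mean deviation from the additive model.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not factors:
        raise ValueError("need at least one factor")
    labels = {}
    for name, lab in factors.items():
        lab = np.asarray(lab)
        if lab.shape[0] != n:
            raise ValueError(f"factor {name!r} must label every spectrum")
        if np.unique(lab).size < 2:
            raise ValueError(f"factor {name!r} has fewer than 2 levels")
        labels[name] = lab

    grand = X.mean(axis=0)
    Xc = X - grand
    effects: Dict[str, np.ndarray] = {}
    for name, lab in labels.items():
        E = np.zeros_like(Xc)
        for lev in np.unique(lab):
            m = lab == lev
            E[m] = Xc[m].mean(axis=0)
        effects[name] = E

    if include_interaction:
        if len(labels) != 2:
            raise ValueError("interaction term requires exactly two factors")
        (na, la), (nb, lb) = labels.items()
        E = np.zeros_like(Xc)
        for leva in np.unique(la):
            for levb in np.unique(lb):
                m = (la == leva) & (lb == levb)
                if m.any():
                    E[m] = Xc[m].mean(axis=0)
        effects[f"{na}x{nb}"] = E - effects[na] - effects[nb]

    residual = Xc - sum(effects.values())
    factor_pca = {}
    factor_ss = {}
    for name, E in effects.items():
        factor_ss[name] = float(np.sum(E * E))
        k = n_components
        if k is None:
            n_levels = np.unique(labels[name]).size if name in labels else 2
            k = max(1, min(n_levels - 1, E.shape[1], E.shape[0] - 1))
        try:
            factor_pca[name] = pca(E, k, center=False)
        except ValueError:
            factor_pca[name] = None  # zero effect: nothing to decompose
    return ASCAResult(
        grand_mean=grand,
        effect_matrices=effects,
        residual=residual,
        factor_pca=factor_pca,
        factor_ss=factor_ss,
        residual_ss=float(np.sum(residual * residual)),
    )


# ---------------------------------------------------------------------------
# PLS (NIPALS, single response)
# ---------------------------------------------------------------------------


def pls_fit(X: np.ndarray, y: np.ndarray, n_lv: int) -> PLSModel:
    """NIPALS partial least squares with one response variable.

    Per component: weight w = X'y / ||X'y||, score t = X w, x-loading
    p = X't / t't, y-loading q = y't / t't, then deflate X and y. Regression
    coefficients are W (P'W)^-1 q on centered data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, c = X.shape
    if y.size != n:
        raise ValueError("y must have one value per spectrum")
    if not np.all(np.isfinite(y)):
        raise ValueError("y must be finite")
    if np.ptp(y) == 0:
        raise ValueError("y has zero variance")
    if n_lv < 1 or n_lv > min(n - 1, c):
        raise ValueError(f"n_lv must lie in [1, min(n-1, n_channels)] = [1, {min(n - 1, c)}]")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    E = X - x_mean
    f = y - y_mean
    W = np.zeros((n_lv, c))
    P = np.zeros((n_lv, c))
    q = np.zeros(n_lv)
    T = np.zeros((n, n_lv))
    for a in range(n_lv):
        w = E.T @ f
        nw = np.linalg.norm(w)
        if nw <= 1e-300:
            # residual response orthogonal to X: truncate
            W, P, q, T = W[:a], P[:a], q[:a], T[:, :a]
            n_lv = a
            break
        w /= nw
        t = E @ w
        tt = float(t @ t)
        p = E.T @ t / tt
        qa = float(f @ t / tt)
        E = E - np.outer(t, p)
        f = f - qa * t
        W[a], P[a], q[a], T[:, a] = w, p, qa, t
    if n_lv == 0:
        raise ValueError("no predictive structure: X'y vanishes")
    coef = W.T @ np.linalg.solve(P @ W.T, q)
    return PLSModel(n_lv=n_lv, x_weights=W, x_loadings=P, y_loadings=q,
                    x_scores=T, regression_coefficients=coef,
                    x_mean=x_mean, y_mean=y_mean)


def pls_predict(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Predict the response: (X - x_mean) b + y_mean."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != model.x_mean.size:
        raise ValueError("channel count does not match the model")
    return (X_new - model.x_mean) @ model.regression_coefficients + model.y_mean


def pls_scores(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Project spectra onto the model's latent variables."""
    X_new = np.asarray(X_new, dtype=float)
    R = model.x_weights.T @ np.linalg.inv(model.x_loadings @ model.x_weights.T)
    return (X_new - model.x_mean) @ R


def select_n_lv_loo(X: np.ndarray, y: np.ndarray, max_lv: int = 5) -> int:
    """Latent-variable count minimizing leave-one-out RMSE (capped at ``max_lv``)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    upper = min(max_lv, n - 2, X.shape[1])
    if upper < 1:
        raise ValueError("too few samples for cross-validation")
    press = np.zeros(upper)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        for lv in range(1, upper + 1):
            m = pls_fit(X[mask], y[mask], min(lv, np.sum(mask) - 1))
            press[lv - 1] += float((pls_predict(m, X[i])[0] - y[i]) ** 2)
    return int(np.argmin(press)) + 1


# ---------------------------------------------------------------------------
# Univariate calibration
# ---------------------------------------------------------------------------


def linear_calibration(conc: np.ndarray, intensity: np.ndarray) -> CalibrationFit:
    """Ordinary least squares of intensity on concentration, with R²."""
    conc = np.asarray(conc, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if conc.size != intensity.size:
        raise ValueError("conc and intensity must be the same length")
    if conc.size < 3:
        raise ValueError("need at least 3 calibration points")
    if np.ptp(conc) == 0:
        raise ValueError("concentrations must not all be equal")
    fit = stats.linregress(conc, intensity)
    ss_tot = float(np.sum((intensity - intensity.mean()) ** 2))
    if ss_tot == 0:
        r2 = 1.0  # perfectly flat response reproduced exactly by the fit
    else:
        resid = intensity - (fit.slope * conc + fit.intercept)
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return CalibrationFit(slope=float(fit.slope), intercept=float(fit.intercept),
                          r_squared=r2, n_points=int(conc.size))
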