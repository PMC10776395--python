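"""Penalized cubic regression spline smoothing for relocalization residuals.

Models the UPR membrane proportion as a smooth function of the control
membrane proportion. The smooth is a cubic B-spline basis with knots at
predictor quantiles, a second-order difference penalty plus a small identity
("shrinkage") term that also penalizes the penalty null space, and the
smoothing parameter chosen by generalized cross-validation. The residual from
the smooth measures UPR-resistant membrane retention: transcripts sitting
above the trend kept more membrane association than the global response
predicts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.interpolate import BSpline

SHRINKAGE = 1e-3  # identity share added to the difference penalty


def _bspline_design(x: np.ndarray, knots: np.ndarray, degree: int = 3
                    ) -> np.ndarray:
    n_basis = knots.size - degree - 1
    return BSpline.design_matrix(x, knots, degree, extrapolate=True) \
        .toarray()[:, :n_basis]


def _knots(x: np.ndarray, n_basis: int, degree: int = 3) -> np.ndarray:
    interior = np.quantile(x, np.linspace(0, 1, n_basis - degree + 1)[1:-1])
    lo, hi = x.min(), x.max()
    pad = 1e-8 * max(hi - lo, 1.0)
    return np.concatenate([
        np.repeat(lo - pad, degree + 1), interior, np.repeat(hi + pad,
                                                             degree + 1)
    ])


def _penalty(n_basis: int) -> np.ndarray:
    D = np.diff(np.eye(n_basis), n=2, axis=0)
    S = D.T @ D
    return S + SHRINKAGE * np.trace(S) / n_basis * np.eye(n_basis)


@dataclass
class GamFit:
    """A fitted penalized-spline smooth of y on x."""

    x: np.ndarray
    y: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    edf: float
    lam: float
    coefficients: np.ndarray
    knots: np.ndarray
    gcv: float

    def predict(self, x_new: np.ndarray) -> np.ndarray:
        B = _bspline_design(np.asarray(x_new, dtype=float), self.knots)
        return B @ self.coefficients


def _solve(B: np.ndarray, y: np.ndarray, P: np.ndarray
           ) -> tuple[np.ndarray, np.ndarray, float]:
    """Penalized LS: coefficients, fitted values and effective dof."""
    BtB = B.T @ B
    A = BtB + P
    coef = np.linalg.solve(A, B.T @ y)
    fitted = B @ coef
    edf = float(np.trace(np.linalg.solve(A, BtB)))
    return coef, fitted, edf


def fit_membrane_gam(
    control: np.ndarray,
    upr: np.ndarray,
    n_basis: int = 12,
    lambda_grid: np.ndarray | None = None,
) -> GamFit:
    """Smooth of the UPR membrane proportion on the control proportion.

    GCV(lambda) = n * RSS / (n - edf)^2 over a log-spaced grid selects the
    smoothing parameter. Residuals (observed - fitted) are the UPR-resistance
    measure.
    """
    x = np.asarray(control, dtype=float)
    y = np.asarray(upr, dtype=float)
    if x.size != y.size:
        raise ValueError("control and UPR vectors differ in length")
    if x.size < 10:
        raise ValueError("need at least 10 paired observations")
    knots = _knots(x, n_basis)
    B = _bspline_design(x, knots)
    S = _penalty(n_basis)
    grid = (np.geomspace(1e-4, 1e6, 41) if lambda_grid is None
            else np.asarray(lambda_grid, dtype=float))
    n = x.size
    best = None
    for lam in grid:
        coef, fitted, edf = _solve(B, y, lam * S)
        rss = float(np.sum((y - fitted) ** 2))
        gcv = n * rss / (n - edf) ** 2
        if best is None or gcv < best[0]:
            best = (gcv, lam, coef, fitted, edf)
    gcv, lam, coef, fitted, edf = best
    return GamFit(x=x, y=y, fitted=fitted, residuals=y - fitted, edf=edf,
                  lam=float(lam), coefficients=coef, knots=knots,
                  gcv=float(gcv))


def compare_gam_stratification(
    base_fit: GamFit, group_indicator: np.ndarray
) -> dict:
    """F-type nested comparison: smooth vs smooth + group offset.

    Refits the smooth (at the base fit's smoothing parameter) with an
    unpenalized group-indicator column added, and compares residual sums of
    squares with an approximate F test on the effective degrees of freedom.
    """
    z = np.asarray(group_indicator, dtype=float)
    if z.size != base_fit.x.size:
        raise ValueError("indicator length does not match the fit")
    if np.unique(z).size < 2:
        raise ValueError("group indicator is constant")
    B = _bspline_design(base_fit.x, base_fit.knots)
    S = _penalty(B.shape[1])
    P0 = base_fit.lam * S
    n = base_fit.x.size
    y = base_fit.y

    _, fitted0, edf0 = _solve(B, y, P0)
    rss0 = float(np.sum((y - fitted0) ** 2))

    B1 = np.column_stack([B, z])
    P1 = np.zeros((B1.shape[1], B1.shape[1]))
    P1[:-1, :-1] = P0
    _, fitted1, edf1 = _solve(B1, y, P1)
    rss1 = float(np.sum((y - fitted1) ** 2))

    df_num = max(edf1 - edf0, 1e-8)
    df_den = n - edf1
    f_stat = max(rss0 - rss1, 0.0) / df_num / (rss1 / df_den)
    p_value = float(stats.f.sf(f_stat, df_num, df_den))
    return {
        "f_statistic": float(f_stat),
        "p_value": p_value,
        "df_num": float(df_num),
        "df_den": float(df_den),
        "edf_base": float(edf0),
        "edf_augmented": float(edf1),
        "group_effect": None,
    }
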