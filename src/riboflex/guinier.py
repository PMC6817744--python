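"""Guinier analysis of small-angle scattering curves.

At low angle, ln I(q) ~ ln I(0) - Rg^2 q^2 / 3, valid for q*Rg below about
1.3.  The fit is a weighted linear regression of ln I on q^2 over a window
chosen iteratively: fit, compute Rg from the slope, keep only points with
q*Rg < limit, refit, until the window stabilizes.  Weights are
1/sigma(lnI)^2 with sigma(lnI) = sigma_I/I; without provided errors the
regression is unweighted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["ScatteringCurve", "GuinierResult", "GuinierError", "guinier_fit"]

QRG_LIMIT = 1.3
MIN_POINTS = 5
MAX_ITER = 20


class GuinierError(ValueError):
    """No usable Guinier region (non-decaying data or window too small)."""


@dataclass
class ScatteringCurve:
    """(q, I, sigma_I) triples; q in 1/Angstrom, strictly increasing."""

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if np.any(self.q <= 0):
            raise ValueError("q must be positive")

    @classmethod
    def from_dat(cls, path) -> "ScatteringCurve":
        """Read a 3-column whitespace-delimited (q, I, sigma) file."""
        arr = np.loadtxt(path, comments="#")
        if arr.ndim != 2 or arr.shape[1] < 2:
            raise ValueError(f"{path}: expected >= 2 whitespace-delimited columns")
        sigma = arr[:, 2] if arr.shape[1] >= 3 else None
        return cls(arr[:, 0], arr[:, 1], sigma)


@dataclass
class GuinierResult:
    Rg: float            # Angstrom
    sigma_Rg: float
    I0: float
    sigma_I0: float
    window: tuple[float, float]   # (q_min, q_max) of retained points
    n_points: int
    qRg_max: float
    n_iter: int


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted straight-line fit; returns (slope, intercept, cov 2x2)."""
    A = np.column_stack([x, np.ones_like(x)]) * np.sqrt(w)[:, None]
    b = y * np.sqrt(w)
    coef, *_ = np.linalg.lstsq(A, b, rcond=None)
    cov = np.linalg.inv(A.T @ A)
    return coef[0], coef[1], cov


def guinier_fit(curve: ScatteringCurve, qrg_limit: float = QRG_LIMIT) -> GuinierResult:
    """Iterative-window Guinier fit returning Rg, I(0) and their errors.

    Starts from the lowest min(15, n/3) points, then repeatedly refits over
    all points with q*Rg < ``qrg_limit`` until the window repeats.  Raises
    :class:`GuinierError` for non-decaying data or a window below 5 points.
    """
    mask_pos = curve.I > 0
    q = curve.q[mask_pos]
    I = curve.I[mask_pos]
    n = len(q)
    if n < MIN_POINTS:
        raise GuinierError("insufficient data: fewer than 5 positive-intensity points")
    y = np.log(I)
    x = q * q
    if curve.sigma is not None and np.all(curve.sigma[mask_pos] > 0):
        w_all = (I / curve.sigma[mask_pos]) ** 2  # 1/sigma(lnI)^2
    else:
        w_all = np.ones(n)

    idx = np.arange(min(max(MIN_POINTS, min(15, n // 3)), n))
    prev: set[int] | None = None
    n_iter = 0
    for n_iter in range(1, MAX_ITER + 1):
        slope, intercept, cov = _wls(x[idx], y[idx], w_all[idx])
        if slope >= 0:
            raise GuinierError("no Guinier region: intensity does not decay with q")
        rg = math.sqrt(-3.0 * slope)
        new_idx = np.flatnonzero(q * rg < qrg_limit)
        if len(new_idx) < MIN_POINTS:
            raise GuinierError("Guinier window shrank below 5 points")
        if prev is not None and set(new_idx) == set(idx):
            break
        prev, idx = set(idx), new_idx

    slope, intercept, cov = _wls(x[idx], y[idx], w_all[idx])
    rg = math.sqrt(-3.0 * slope)
    # scale covariance by reduced chi2 when weights are relative/unweighted
    resid = y[idx] - (slope * x[idx] + intercept)
    dof = max(len(idx) - 2, 1)
    s2 = float(np.sum(w_all[idx] * resid**2) / dof)
    cov = cov * s2
    sigma_slope = math.sqrt(cov[0, 0])
    sigma_rg = 3.0 * sigma_slope / (2.0 * rg)
    i0 = math.exp(intercept)
    sigma_i0 = i0 * math.sqrt(cov[1, 1])
    return GuinierResult(
        Rg=rg,
        sigma_Rg=sigma_rg,
        I0=i0,
        sigma_I0=sigma_i0,
        window=(float(q[idx[0]]), float(q[idx[-1]])),
        n_points=len(idx),
        qRg_max=float(q[idx[-1]] * rg),
        n_iter=n_iter,
    )
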