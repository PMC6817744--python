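"""Spin-relaxation analysis: R1/R1rho exponential fits, R2 via the tilt
angle, heteronuclear NOE, and R2/R1 & R2*R1 summaries with outlier exclusion.

Rates come from fitting peak heights I(t) = A*exp(-R*t) by nonlinear least
squares; rate uncertainties come from seeded Monte-Carlo resampling with the
point noise estimated from replicate-delay pairs.  R2 is obtained from the
rotating-frame rate with the tilt-angle relation

    R2 = R1rho*(1 + tan^2(theta)) - R1*tan^2(theta),   tan(theta) = dnu/nu1,

which reduces to R2 = R1rho on resonance (dnu = 0), the regime in which the
spin-lock data are recorded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .tablesio import IntensitySeries

__all__ = [
    "MonoExpFit",
    "NoePair",
    "RelaxationRates",
    "RatioSummary",
    "estimate_noise_sd",
    "fit_monoexponential",
    "r2_from_r1rho",
    "het_noe",
    "ratio_summary",
]

DEFAULT_SPINLOCK_HZ = 1500.0  # 1.5 kHz spin-lock field
DEFAULT_SATURATION_S = 3.0    # proton saturation time for the NOE experiment


@dataclass
class MonoExpFit:
    rate: float            # s^-1
    amplitude: float
    sigma_rate: float      # s^-1, Monte-Carlo SD
    noise_sd: float        # intensity units used for resampling
    converged: bool = True
    flags: list[str] = field(default_factory=list)


@dataclass
class NoePair:
    residue_id: int
    I_sat: float
    sigma_sat: float
    I_unsat: float
    sigma_unsat: float
    saturation_time: float = DEFAULT_SATURATION_S


@dataclass
class RelaxationRates:
    residue_id: int
    R1: float = np.nan
    sigma_R1: float = 0.0
    R1rho: float = np.nan
    sigma_R1rho: float = 0.0
    R2: float = np.nan
    sigma_R2: float = 0.0
    NOE: float = np.nan
    sigma_NOE: float = 0.0
    offset_hz: float = 0.0
    spinlock_hz: float = DEFAULT_SPINLOCK_HZ
    tilt_theta: float = 0.0


@dataclass
class RatioSummary:
    """Mean +/- SD of R2/R1 and R2*R1 after k-SD outlier exclusion."""

    ratios: dict[int, tuple[float, float]]       # residue -> (R2/R1, sigma)
    products: dict[int, tuple[float, float]]     # residue -> (R2*R1, sigma)
    ratio_mean: float
    ratio_sd: float
    product_mean: float
    product_sd: float
    excluded_ratio: list[int]
    excluded_product: list[int]
    exclusion_k: float


def estimate_noise_sd(series_list: list[IntensitySeries]) -> float | None:
    """Pooled intensity noise from replicate pairs as RMS of |dI|/sqrt(2).

    Returns ``None`` when no replicate pairs exist; callers then fall back
    to the residual RMS of the fit.
    """
    sds = []
    for s in series_list:
        for _, a, b in s.replicate_pairs():
            sds.append(abs(a - b) / math.sqrt(2.0))
    if not sds:
        return None
    return float(np.sqrt(np.mean(np.square(sds))))


def _fit_once(t: np.ndarray, y: np.ndarray, r0: float) -> tuple[float, float, float]:
    """Best (rate, amplitude, ssr) from one start; rate constrained >= 0."""

    def resid(p):
        return p[0] * np.exp(-p[1] * t) - y

    a0 = max(abs(y).max(), 1e-12)
    sol = least_squares(
        resid, x0=[a0, max(r0, 1e-9)], bounds=([-np.inf, 0.0], [np.inf, np.inf])
    )
    return float(sol.x[1]), float(sol.x[0]), float(2.0 * sol.cost)


def _initial_rate(t: np.ndarray, y: np.ndarray) -> float:
    """Two-point log estimate between the first and last positive points."""
    pos = y > 0
    if pos.sum() >= 2:
        i, j = np.flatnonzero(pos)[[0, -1]]
        if t[j] > t[i] and y[j] < y[i]:
            return math.log(y[i] / y[j]) / (t[j] - t[i])
    return 1.0


def _fit_multistart(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    r0 = _initial_rate(t, y)
    best = None
    for start in (r0, 0.5 * r0, 2.0 * r0):
        cand = _fit_once(t, y, start)
        if best is None or cand[2] < best[2]:
            best = cand
    return best


def fit_monoexponential(
    series: IntensitySeries,
    mc_iters: int = 500,
    seed: int | None = None,
    noise_sd: float | None = None,
) -> MonoExpFit:
    """Fit I(t) = A*exp(-R*t) by nonlinear least squares.

    ``noise_sd`` (intensity units) drives the Monte-Carlo rate uncertainty;
    when omitted it is estimated from the series' own replicate pairs, with
    the fit's residual RMS as fallback.
    """
    t = series.x
    y = series.intensities
    if len(np.unique(t)) < 4:
        raise ValueError("need at least 4 distinct delays to fit a decay")
    if np.allclose(y, 0.0):
        raise ValueError("intensities are all zero")

    flags: list[str] = []
    rate, amp, ssr = _fit_multistart(t, y)

    if noise_sd is None:
        noise_sd = estimate_noise_sd([series])
    if noise_sd is None:
        dof = max(len(y) - 2, 1)
        noise_sd = float(np.sqrt(ssr / dof))
        flags.append("noise_from_residuals")

    sigma_rate = 0.0
    if mc_iters > 0 and noise_sd > 0:
        rng = np.random.default_rng(seed)
        rates = np.empty(mc_iters)
        for i in range(mc_iters):
            y_mc = amp * np.exp(-rate * t) + rng.normal(0.0, noise_sd, size=len(t))
            rates[i] = _fit_once(t, y_mc, max(rate, 1e-3))[0]
        sigma_rate = float(np.std(rates))

    return MonoExpFit(rate, amp, sigma_rate, float(noise_sd), True, flags)


def r2_from_r1rho(
    R1rho: float,
    R1: float,
    offset_hz: float = 0.0,
    spinlock_hz: float = DEFAULT_SPINLOCK_HZ,
    sigma_R1rho: float = 0.0,
    sigma_R1: float = 0.0,
) -> tuple[float, float, float]:
    """Tilt-angle correction of the rotating-frame rate: returns (R2, theta, sigma_R2).

    With t = tan(theta) = offset/spin-lock, R2 = R1rho*(1+t^2) - R1*t^2;
    uncertainties are propagated linearly.  On resonance R2 equals R1rho.
    """
    if spinlock_hz <= 0:
        raise ValueError("spin-lock strength must be positive")
    t = offset_hz / spinlock_hz
    t2 = t * t
    R2 = R1rho * (1.0 + t2) - R1 * t2
    sigma = math.hypot((1.0 + t2) * sigma_R1rho, t2 * sigma_R1)
    return R2, math.atan(t), sigma


def het_noe(pair: NoePair) -> tuple[float, float, list[str]]:
    """NOE = I_sat/I_unsat with relative-error propagation.

    sigma/NOE = sqrt((sigma_sat/I_sat)^2 + (sigma_unsat/I_unsat)^2); when
    I_sat = 0 the relative form is singular and an absolute fallback
    sigma = sigma_sat/|I_unsat| is used and flagged.
    """
    if pair.I_unsat == 0:
        raise ValueError("unsaturated intensity must be nonzero")
    noe = pair.I_sat / pair.I_unsat
    flags: list[str] = []
    if pair.I_sat == 0:
        sigma = abs(pair.sigma_sat / pair.I_unsat)
        if pair.sigma_sat > 0:
            flags.append("absolute_error_fallback")
    else:
        sigma = abs(noe) * math.hypot(
            pair.sigma_sat / pair.I_sat, pair.sigma_unsat / pair.I_unsat
        )
    return noe, sigma, flags


def _exclude(values: np.ndarray, k: float) -> np.ndarray:
    """Single-pass k-SD exclusion mask (True = retained); population SD."""
    mean = values.mean()
    sd = values.std()  # ddof=0: matches the documented worked example
    if not math.isfinite(k) or sd == 0.0:
        return np.ones(len(values), dtype=bool)
    return np.abs(values - mean) <= k * sd


def ratio_summary(rates: list[RelaxationRates], k: float = 1.5) -> RatioSummary:
    """Per-residue R2/R1 and R2*R1 with single-pass k-SD outlier exclusion.

    The mean and SD are first computed over all residues; residues deviating
    by more than ``k`` SD are dropped and the mean +/- SD of the retained set
    is reported.  The exclusion is applied independently to the ratio and
    the product.
    """
    usable = [r for r in rates if np.isfinite(r.R1) and np.isfinite(r.R2) and r.R1 != 0]
    if len(usable) < 3:
        raise ValueError("need >= 3 residues with defined R1 and R2")

    res_ids = np.array([r.residue_id for r in usable])
    ratios = np.array([r.R2 / r.R1 for r in usable])
    prods = np.array([r.R2 * r.R1 for r in usable])
    sig_ratio = np.array(
        [
            abs(r.R2 / r.R1) * math.hypot(r.sigma_R2 / r.R2 if r.R2 else 0.0,
                                          r.sigma_R1 / r.R1)
            for r in usable
        ]
    )
    sig_prod = np.array(
        [
            abs(r.R2 * r.R1) * math.hypot(r.sigma_R2 / r.R2 if r.R2 else 0.0,
                                          r.sigma_R1 / r.R1)
            for r in usable
        ]
    )

    keep_r = _exclude(ratios, k)
    keep_p = _exclude(prods, k)
    if not keep_r.any() or not keep_p.any():
        raise ValueError("outlier exclusion removed every residue")

    return RatioSummary(
        ratios={int(i): (float(v), float(s)) for i, v, s in zip(res_ids, ratios, sig_ratio)},
        products={int(i): (float(v), float(s)) for i, v, s in zip(res_ids, prods, sig_prod)},
        ratio_mean=float(ratios[keep_r].mean()),
        ratio_sd=float(ratios[keep_r].std()),
        product_mean=float(prods[keep_p].mean()),
        product_sd=float(prods[keep_p].std()),
        excluded_ratio=[int(i) for i in res_ids[~keep_r]],
        excluded_product=[int(i) for i in res_ids[~keep_p]],
        exclusion_k=k,
    )
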