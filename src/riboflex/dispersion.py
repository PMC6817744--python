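"""CPMG relaxation dispersion: R2eff extraction and two-site exchange fitting.

Effective transverse rates come from constant-time CPMG peak heights,

    R2eff = (-1/T) * ln(I_nu / I0),        sigma = dI / (T * I_nu),

with dI the intensity difference of the repeated experiment (the acquisition
design duplicates nu_cpmg = 640 Hz).  Dispersion profiles are fit to the
fast-exchange two-site model

    R2(1/tau_cp) = R2_0 + Rex * [1 - 2*tanh(kex*tau_cp/2) / (kex*tau_cp)],

with Rex = pa*pb*dw^2/kex.  pa, pb and dw enter only through this product,
so only the composite Rex (equivalently Phi = Rex*kex) is reported.

The model's abscissa is the pulsing rate 1/tau_cp; by default the listed
nu_cpmg values are read as exactly that rate (tau_cp = 1/nu_cpmg,
``tau_convention="reciprocal"``).  The also-common convention in which
nu_cpmg counts full echo cycles (tau_cp = 1/(2*nu_cpmg),
``tau_convention="half"``) is selectable everywhere; it rescales fitted
kex by a factor of two and is otherwise equivalent.

Fitting scopes:

* ``individual`` — one residue, its own kex;
* ``segmental``  — residues of one secondary-structure element share kex;
* ``global``     — all members share kex.

In all scopes kex is shared across members and spectrometer fields, R2_0 is
free per (residue, field, constant-time block), and each residue has one
exchange amplitude referenced to the lowest field, scaled by the squared
field ratio at other fields (dw in rad/s is proportional to B0, and Rex is
quadratic in dw).  For fixed kex the model is linear in every remaining
parameter, so the fit profiles kex by exact weighted linear solves and
minimizes chi^2(kex) in one dimension — equivalent to the full joint
weighted least squares, but fast and immune to poor starting values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .tablesio import IntensitySeries

__all__ = [
    "DispersionPoint",
    "DispersionProfile",
    "ExchangeFit",
    "r2eff_from_intensity",
    "r2eff_error",
    "dispersion_model",
    "build_profiles",
    "fit_dispersion",
]

#: default constant transverse relaxation times (s) keyed by nu_cpmg (Hz);
#: the low-frequency points 66.67/133.33 Hz use the longer 60 ms block
DEFAULT_T_RELAX = 0.050
LONG_T_RELAX = 0.060
REPLICATE_NU_HZ = 640.0

KEX_STARTS = (50.0, 200.0, 800.0, 3200.0)  # s^-1, multi-start grid
_KEX_LO, _KEX_HI = 1.0, 1.0e5              # search bounds, s^-1
SIGMA_FLOOR_FRAC = 0.02                    # floor = 2% of median sigma

#: tau_cp (s) per unit nu_cpmg (Hz): "reciprocal" reads nu_cpmg as the
#: pulsing rate 1/tau_cp; "half" counts full echo cycles, tau_cp = 1/(2*nu)
TAU_CONVENTIONS = {"reciprocal": 1.0, "half": 0.5}
DEFAULT_TAU_CONVENTION = "reciprocal"


def _tau_cp(nu_cpmg, tau_convention: str):
    try:
        factor = TAU_CONVENTIONS[tau_convention]
    except KeyError:
        raise ValueError(
            f"unknown tau convention {tau_convention!r}; "
            f"choose from {sorted(TAU_CONVENTIONS)}"
        ) from None
    return factor / np.asarray(nu_cpmg, dtype=float)


@dataclass(frozen=True)
class DispersionPoint:
    nu_cpmg: float  # Hz
    R2eff: float    # s^-1
    sigma: float    # s^-1


@dataclass
class DispersionProfile:
    """R2eff(nu_cpmg) for one residue at one field and constant time."""

    residue_id: int
    field_mhz: float
    T_relax: float
    points: list[DispersionPoint] = field(default_factory=list)
    I0: float = np.nan
    flags: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.points = sorted(self.points, key=lambda p: p.nu_cpmg)

    @property
    def nu(self) -> np.ndarray:
        return np.array([p.nu_cpmg for p in self.points])

    @property
    def r2eff(self) -> np.ndarray:
        return np.array([p.R2eff for p in self.points])

    @property
    def sigma(self) -> np.ndarray:
        return np.array([p.sigma for p in self.points])


@dataclass
class ExchangeFit:
    scope: str                       # individual | segmental | global
    members: list[int]
    kex: float                       # s^-1, shared
    sigma_kex: float
    kex_ci95: tuple[float, float]
    r2_0: dict[tuple[int, float], float]               # (res, field) -> s^-1
    sigma_r2_0: dict[tuple[int, float], float]
    rex: dict[tuple[int, float], float]                # (res, field) -> s^-1
    sigma_rex: dict[tuple[int, float], float]
    chi2: float
    dof: int
    flags: dict[int, list[str]] = field(default_factory=dict)

    @property
    def phi(self) -> dict[tuple[int, float], float]:
        """Composite pa*pb*dw^2 = Rex*kex per (residue, field), s^-2."""
        return {k: v * self.kex for k, v in self.rex.items()}


def r2eff_from_intensity(I: float, I0: float, T_relax: float) -> float:
    """R2eff = (-1/T) ln(I/I0) from constant-time peak heights."""
    if I <= 0 or I0 <= 0 or T_relax <= 0:
        raise ValueError("intensities and constant time must be positive")
    return -math.log(I / I0) / T_relax


def r2eff_error(delta_I: float, I: float, T_relax: float) -> float:
    """sigma = dI/(T*I), dI being the replicate intensity difference."""
    if I <= 0 or T_relax <= 0:
        raise ValueError("intensity and constant time must be positive")
    return abs(delta_I) / (T_relax * I)


def dispersion_model(
    nu_cpmg,
    R2_0: float,
    Rex: float,
    kex: float,
    tau_convention: str = DEFAULT_TAU_CONVENTION,
):
    """Two-site fast-exchange dispersion R2(nu_cpmg); vectorized in nu."""
    x = kex * _tau_cp(nu_cpmg, tau_convention)
    bracket = 1.0 - 2.0 * np.tanh(0.5 * x) / x
    out = R2_0 + Rex * bracket
    return float(out) if np.isscalar(nu_cpmg) else out


def _dispersion_shape(
    nu: np.ndarray, kex: float, tau_convention: str = DEFAULT_TAU_CONVENTION
) -> np.ndarray:
    """The bracket factor g(nu; kex) in [0, 1], multiplying Rex."""
    x = kex * _tau_cp(nu, tau_convention)
    return 1.0 - 2.0 * np.tanh(0.5 * x) / x


def build_profiles(
    series_list: list[IntensitySeries],
    T_for_nu=None,
    replicate_nu: float = REPLICATE_NU_HZ,
) -> list[DispersionProfile]:
    """Convert CPMG intensity series into dispersion profiles.

    nu = 0 rows are the reference spectra (averaged into I0) and are never
    fitted.  Non-positive intensities are dropped with a flag.  Point errors
    use the replicate difference at ``replicate_nu``; residues lacking a
    replicate get the pooled dI of the others, flagged.  A floor of 2% of
    the median sigma prevents infinite weights.  ``T_for_nu`` maps a nu
    value to its constant time (default: 60 ms for the 66.67/133.33 Hz
    block, 50 ms otherwise).
    """
    if T_for_nu is None:
        def T_for_nu(nu):
            return LONG_T_RELAX if nu < 140.0 and abs(nu - 80.0) > 1.0 else DEFAULT_T_RELAX

    # pooled replicate differences for residues without their own replicate
    deltas = {}
    for s in series_list:
        if s.kind != "cpmg":
            raise ValueError(f"series for residue {s.residue_id} is not a CPMG series")
        for nu0, a, b in s.replicate_pairs():
            if abs(nu0 - replicate_nu) < 1e-6:
                deltas[(s.residue_id, s.field_mhz)] = abs(a - b)
    pooled = float(np.mean(list(deltas.values()))) if deltas else None

    profiles: dict[tuple[int, float, float], DispersionProfile] = {}
    for s in series_list:
        nu_arr, I_arr = s.x, s.intensities
        ref = I_arr[nu_arr == 0]
        if len(ref) == 0:
            raise ValueError(
                f"residue {s.residue_id} @ {s.field_mhz} MHz: no nu=0 reference point"
            )
        I0 = float(ref.mean())
        dI = deltas.get((s.residue_id, s.field_mhz))
        flags = []
        if dI is None:
            dI = pooled
            if dI is not None:
                flags.append("pooled_replicate_error")
        for nu0, I in zip(nu_arr, I_arr):
            if nu0 == 0:
                continue
            key = (s.residue_id, s.field_mhz, float(T_for_nu(nu0)))
            prof = profiles.setdefault(
                key,
                DispersionProfile(s.residue_id, s.field_mhz, key[2], [], I0, list(flags)),
            )
            if I <= 0:
                prof.flags.append(f"dropped_nonpositive_intensity_nu{nu0:g}")
                continue
            r2 = r2eff_from_intensity(I, I0, key[2])
            sig = r2eff_error(dI, I, key[2]) if dI is not None else 0.0
            prof.points.append(DispersionPoint(float(nu0), r2, sig))

    out = []
    for prof in profiles.values():
        prof.points = sorted(prof.points, key=lambda p: p.nu_cpmg)
        out.append(prof)
    _apply_sigma_floor(out)
    return out


def _apply_sigma_floor(profiles: list[DispersionProfile]) -> None:
    sigmas = np.concatenate([p.sigma for p in profiles]) if profiles else np.array([])
    if len(sigmas) == 0:
        return
    floor = SIGMA_FLOOR_FRAC * float(np.median(sigmas))
    if floor <= 0:
        positive = sigmas[sigmas > 0]
        floor = SIGMA_FLOOR_FRAC * float(np.median(positive)) if len(positive) else 1e-6
    for p in profiles:
        p.points = [
            DispersionPoint(pt.nu_cpmg, pt.R2eff, max(pt.sigma, floor))
            for pt in p.points
        ]


class _JointProblem:
    """Pre-assembled arrays for the shared-kex variable-projection fit."""

    def __init__(
        self,
        profiles: list[DispersionProfile],
        tau_convention: str = DEFAULT_TAU_CONVENTION,
    ):
        if not profiles:
            raise ValueError("no profiles to fit")
        self.tau_convention = tau_convention
        self.residues = sorted({p.residue_id for p in profiles})
        self.ref_field = min(p.field_mhz for p in profiles)
        self.by_residue: dict[int, list[DispersionProfile]] = {}
        for p in profiles:
            if len(p.points) == 0:
                continue
            self.by_residue.setdefault(p.residue_id, []).append(p)
        self.n_points = sum(len(p.points) for p in profiles)
        n_baselines = len({(p.residue_id, p.field_mhz) for p in profiles})
        # parameters: kex + one R2_0 per (residue, field) + one Rex_ref per residue
        self.n_params = 1 + n_baselines + len(self.by_residue)
        self.dof = self.n_points - self.n_params

    def solve_linear(self, kex: float):
        """Exact weighted linear solve at fixed kex.

        Returns (chi2, {(res, field): R2_0}, {residue: Rex_ref}); Rex is
        clamped at zero (no negative exchange amplitude), with the R2_0
        baselines re-solved.  R2_0 is shared across constant-time blocks
        of the same (residue, field): the block length does not change the
        intrinsic transverse rate.
        """
        chi2 = 0.0
        r2_0: dict[tuple[int, float], float] = {}
        rex_ref: dict[int, float] = {}
        for res, profs in self.by_residue.items():
            fields = sorted({p.field_mhz for p in profs})
            col = {f: j for j, f in enumerate(fields)}
            y, w, cols = [], [], []
            for p in profs:
                g = (
                    _dispersion_shape(p.nu, kex, self.tau_convention)
                    * (p.field_mhz / self.ref_field) ** 2
                )
                for i in range(len(p.points)):
                    row = np.zeros(len(fields) + 1)
                    row[col[p.field_mhz]] = 1.0
                    row[-1] = g[i]
                    cols.append(row)
                    y.append(p.points[i].R2eff)
                    w.append(1.0 / p.points[i].sigma)
            A = np.array(cols) * np.array(w)[:, None]
            b = np.array(y) * np.array(w)
            sol, *_ = np.linalg.lstsq(A, b, rcond=None)
            if sol[-1] < 0.0:  # clamp Rex >= 0, re-solve intercepts only
                sol = np.append(np.linalg.lstsq(A[:, :-1], b, rcond=None)[0], 0.0)
            resid = A @ sol - b
            chi2 += float(resid @ resid)
            for f, j in col.items():
                r2_0[(res, f)] = float(sol[j])
            rex_ref[res] = float(sol[-1])
        return chi2, r2_0, rex_ref

    def chi2(self, kex: float) -> float:
        return self.solve_linear(kex)[0]


def _minimize_kex(problem: _JointProblem, starts=KEX_STARTS, n_grid: int = 121) -> float:
    """1-D profile-chi2 minimization over kex (log grid + bounded refinement)."""
    grid = np.geomspace(_KEX_LO, _KEX_HI, n_grid)
    chi = np.array([problem.chi2(k) for k in grid])
    candidates = {float(grid[int(np.argmin(chi))])}
    candidates.update(starts)
    best_k, best_c = None, np.inf
    for k0 in candidates:
        lo = max(_KEX_LO, k0 / 4.0)
        hi = min(_KEX_HI, k0 * 4.0)
        res = minimize_scalar(problem.chi2, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-3})
        if res.fun < best_c:
            best_k, best_c = float(res.x), float(res.fun)
    return best_k


def fit_dispersion(
    profiles: list[DispersionProfile],
    scope: str = "individual",
    members: set[int] | None = None,
    mc_iters: int = 200,
    seed: int | None = None,
    tau_convention: str = DEFAULT_TAU_CONVENTION,
) -> ExchangeFit:
    """Weighted shared-kex fit of dispersion profiles at the given scope.

    ``members`` restricts the fit to a residue subset (a segment, or one
    residue for ``individual``).  Weights are 1/sigma^2.  Parameter
    uncertainties and the 95% kex interval come from ``mc_iters`` seeded
    Monte-Carlo synthetic datasets (best-fit curve + Gaussian noise at the
    point sigmas).  A residue whose exchange amplitude is indistinguishable
    from zero (chi2 improvement over Rex=0 below 2) is flagged
    ``no_detectable_exchange``.
    """
    if scope not in {"individual", "segmental", "global"}:
        raise ValueError(f"unknown fit scope {scope!r}")
    if members is not None:
        profiles = [p for p in profiles if p.residue_id in members]
    if scope == "individual" and len({p.residue_id for p in profiles}) > 1:
        raise ValueError("individual scope requires exactly one residue")
    for p in profiles:
        if any(pt.nu_cpmg <= 0 for pt in p.points):
            raise ValueError("fitted points must have nu_cpmg > 0")

    problem = _JointProblem(profiles, tau_convention)
    kex = _minimize_kex(problem)
    chi2, r2_0, rex_ref = problem.solve_linear(kex)

    fields = sorted({p.field_mhz for p in profiles})
    scale = {f: (f / problem.ref_field) ** 2 for f in fields}
    rex = {
        (res, f): rex_ref[res] * scale[f]
        for res in problem.by_residue
        for f in fields
        if any(p.field_mhz == f for p in problem.by_residue[res])
    }

    # flat-profile detection: chi2 with this residue's Rex forced to zero
    flags: dict[int, list[str]] = {res: [] for res in problem.by_residue}

    rng = np.random.default_rng(seed)
    sigma_kex, ci = 0.0, (kex, kex)
    sig_r20 = {k: 0.0 for k in r2_0}
    sig_rex = {k: 0.0 for k in rex}
    if mc_iters > 0:
        originals = [list(p.points) for p in profiles]
        model_vals = []
        for p in profiles:
            g = _dispersion_shape(p.nu, kex, tau_convention) * scale[p.field_mhz]
            model_vals.append(
                r2_0[(p.residue_id, p.field_mhz)] + rex_ref[p.residue_id] * g
            )
        kex_samples = np.empty(mc_iters)
        r20_samples = {k: np.empty(mc_iters) for k in r2_0}
        rexref_samples = {k: np.empty(mc_iters) for k in rex_ref}
        try:
            for it in range(mc_iters):
                for p, pts, mv in zip(profiles, originals, model_vals):
                    p.points = [
                        DispersionPoint(
                            pt.nu_cpmg,
                            float(mv[i] + rng.normal(0.0, pt.sigma)),
                            pt.sigma,
                        )
                        for i, pt in enumerate(pts)
                    ]
                sub = _JointProblem(profiles, tau_convention)
                k_mc = _minimize_kex(sub, starts=(kex,), n_grid=41)
                _, r20_mc, rexref_mc = sub.solve_linear(k_mc)
                kex_samples[it] = k_mc
                for k in r2_0:
                    r20_samples[k][it] = r20_mc[k]
                for res in rex_ref:
                    rexref_samples[res][it] = rexref_mc[res]
        finally:
            for p, pts in zip(profiles, originals):
                p.points = pts
        sigma_kex = float(np.std(kex_samples))
        ci = (
            float(np.percentile(kex_samples, 2.5)),
            float(np.percentile(kex_samples, 97.5)),
        )
        sig_r20 = {k: float(np.std(v)) for k, v in r20_samples.items()}
        sig_rex = {
            (res, f): float(np.std(rexref_samples[res])) * scale[f]
            for (res, f) in rex
        }

        for res in problem.by_residue:
            rex_sd = float(np.std(rexref_samples[res]))
            lo = rex_ref[res] - 1.96 * rex_sd
            dchi2 = _chi2_without_exchange(problem, res, kex) - chi2
            if lo <= 0.0 and dchi2 < 2.0:
                flags[res].append("no_detectable_exchange")

    return ExchangeFit(
        scope=scope,
        members=sorted(problem.by_residue),
        kex=kex,
        sigma_kex=sigma_kex,
        kex_ci95=ci,
        r2_0=r2_0,
        sigma_r2_0=sig_r20,
        rex=rex,
        sigma_rex=sig_rex,
        chi2=chi2,
        dof=problem.dof,
        flags=flags,
    )


def _chi2_without_exchange(problem: _JointProblem, res: int, kex: float) -> float:
    """Total chi2 when residue ``res`` is forced flat (Rex = 0).

    The flat model per block is the weighted mean of that block's R2eff;
    the other residues keep their best linear solution at this kex.
    """
    flat = 0.0
    by_field: dict[float, list[DispersionProfile]] = {}
    for p in problem.by_residue[res]:
        by_field.setdefault(p.field_mhz, []).append(p)
    for profs in by_field.values():
        y = np.concatenate([p.r2eff for p in profs])
        w = 1.0 / np.concatenate([p.sigma for p in profs])
        mean = float(np.sum(y * w**2) / np.sum(w**2))
        flat += float(np.sum(((y - mean) * w) ** 2))
    chi_all, r2_0, rex_ref = problem.solve_linear(kex)
    chi_res = 0.0
    for p in problem.by_residue[res]:
        g = (
            _dispersion_shape(p.nu, kex, problem.tau_convention)
            * (p.field_mhz / problem.ref_field) ** 2
        )
        model = r2_0[(p.residue_id, p.field_mhz)] + rex_ref[res] * g
        chi_res += float(np.sum(((p.r2eff - model) / p.sigma) ** 2))
    return chi_all - chi_res + flat
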