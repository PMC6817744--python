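"""Seeded generators for every input type the analysis modules consume.

Each generator draws from its own independent random stream derived from
(seed, generator name), so adding a generator never shifts the draws of an
existing one and the same spec always reproduces byte-identical output.

Defaults mirror the acquisition designs of the experiments being emulated:
the relaxation delay list with its duplicated 100 ms point, the nine-point
CPMG frequency grid with the repeated 640 Hz experiment and its split
50/60 ms constant-time blocks, and Guinier-regime scattering curves.
"""

from __future__ import annotations

import zlib

import numpy as np

from .dispersion import (
    DEFAULT_T_RELAX,
    LONG_T_RELAX,
    DispersionPoint,
    DispersionProfile,
    dispersion_model,
)
from .guinier import ScatteringCurve
from .tablesio import IntensityPoint, IntensitySeries

__all__ = [
    "R1_DELAYS_S",
    "SPINLOCK_DURATIONS_S",
    "CPMG_GRID",
    "stream",
    "gen_decay_series",
    "gen_dispersion",
    "gen_guinier_curve",
    "gen_toy_pdb",
]

#: longitudinal relaxation delay list (s); 100 ms is acquired twice
R1_DELAYS_S = (0.1, 0.1, 0.2, 0.4, 0.7, 1.0, 1.3, 1.7, 2.1)
#: spin-lock duration list (s); 10 ms is acquired twice
SPINLOCK_DURATIONS_S = (0.001, 0.010, 0.010, 0.020, 0.040, 0.060, 0.100, 0.160, 0.220)
#: (nu_cpmg Hz, constant time s); 640 Hz is acquired twice; the two lowest
#: frequencies use the longer 60 ms constant-time block
CPMG_GRID = (
    (80.0, DEFAULT_T_RELAX),
    (160.0, DEFAULT_T_RELAX),
    (320.0, DEFAULT_T_RELAX),
    (480.0, DEFAULT_T_RELAX),
    (640.0, DEFAULT_T_RELAX),
    (640.0, DEFAULT_T_RELAX),
    (800.0, DEFAULT_T_RELAX),
    (66.67, LONG_T_RELAX),
    (133.33, LONG_T_RELAX),
)


def stream(seed: int, name: str) -> np.random.Generator:
    """Independent named substream of the global seed."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def gen_decay_series(
    truth_rate: float,
    amplitude: float = 100.0,
    delays=R1_DELAYS_S,
    noise_sd: float = 0.0,
    seed: int = 0,
    residue_id: int = 1,
    field_mhz: float = 700.0,
    spin_label: str = "",
) -> IntensitySeries:
    """I(t) = A*exp(-R*t) + N(0, noise_sd); duplicated delays flagged."""
    delays = np.asarray(delays, dtype=float)
    if len(delays) == 0:
        raise ValueError("delays must be non-empty")
    rng = stream(seed, "decay")
    ideal = amplitude * np.exp(-truth_rate * delays)
    noisy = ideal + (rng.normal(0.0, noise_sd, len(delays)) if noise_sd > 0 else 0.0)
    points, seen = [], set()
    for t, y in zip(delays, np.atleast_1d(noisy)):
        points.append(IntensityPoint(float(t), float(y), t in seen))
        seen.add(float(t))
    return IntensitySeries(residue_id, spin_label, field_mhz, points, "relaxation")


def gen_dispersion(
    truth: dict,
    fields=(600.0, 850.0),
    grid=CPMG_GRID,
    noise_sd: float = 0.0,
    seed: int = 0,
    tau_convention: str = "reciprocal",
) -> list[DispersionProfile]:
    """Dispersion profiles drawn from the two-site fast-exchange model.

    ``truth`` holds ``kex`` (shared, s^-1), ``rex`` mapping residue ->
    exchange amplitude at the reference (lowest) field, and ``r2_0`` mapping
    residue -> baseline rate, either a scalar (shared across fields) or a
    {field: value} map.  Rex at other fields is scaled by the squared field
    ratio.  Point sigmas are set to ``noise_sd`` (or 0.1 s^-1 when
    noiseless, as a placeholder weight).
    """
    kex = float(truth["kex"])
    rex_map: dict[int, float] = truth["rex"]
    r20_map = truth["r2_0"]
    ref = min(fields)
    rng = stream(seed, "dispersion")
    sigma = noise_sd if noise_sd > 0 else 0.1

    profiles = []
    for res in sorted(rex_map):
        for f in fields:
            r20 = r20_map[res]
            if isinstance(r20, dict):
                r20 = r20[f]
            rex = rex_map[res] * (f / ref) ** 2
            for T in sorted({t for _, t in grid}, reverse=True):
                nus = [nu for nu, t in grid if t == T]
                pts = []
                for nu in nus:
                    val = dispersion_model(nu, float(r20), rex, kex, tau_convention)
                    if noise_sd > 0:
                        val += rng.normal(0.0, noise_sd)
                    pts.append(DispersionPoint(float(nu), float(val), sigma))
                profiles.append(DispersionProfile(res, float(f), float(T), pts))
    return profiles


def gen_guinier_curve(
    Rg: float,
    I0: float = 1000.0,
    q_grid=None,
    noise_rel: float = 0.0,
    seed: int = 0,
) -> ScatteringCurve:
    """I(q) = I0*exp(-q^2 Rg^2/3)*(1+eps), eps ~ N(0, noise_rel)."""
    if q_grid is None:
        q_grid = np.linspace(0.01, 0.06, 60)
    q = np.asarray(q_grid, dtype=float)
    ideal = I0 * np.exp(-(q**2) * Rg**2 / 3.0)
    if noise_rel > 0:
        rng = stream(seed, "guinier")
        I = ideal * (1.0 + rng.normal(0.0, noise_rel, len(q)))
        sigma = ideal * noise_rel
    else:
        I, sigma = ideal, None
    return ScatteringCurve(q, I, sigma)


def gen_toy_pdb(residues, seed: int = 0, chain_id: str = "A") -> str:
    """Minimal synthetic PDB text with prescribed per-atom B-factors.

    ``residues`` is a list of (residue_number, residue_name, atoms) where
    ``atoms`` is a list of B values or (B, occupancy, altloc) triples.
    Coordinates are arbitrary jittered positions; the B and occupancy
    columns are what downstream consumers read.
    """
    rng = stream(seed, "toypdb")
    lines = []
    serial = 1
    for resnum, resname, atoms in residues:
        for i, spec in enumerate(atoms):
            if isinstance(spec, (tuple, list)):
                b, occ, alt = spec
            else:
                b, occ, alt = spec, 1.0, " "
            x, y, z = rng.normal(0.0, 5.0, 3)
            name = f"C{i + 1}'" if i < 9 else f"O{i - 8}'"
            lines.append(
                f"ATOM  {serial:5d} {name:<4s}{alt:1s}{resname:>3s} {chain_id}"
                f"{resnum:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
                f"           C"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
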