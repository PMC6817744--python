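"""Composite chemical-shift perturbations between apo and ligand-bound states.

The composite change for a 1H/15N pair is the empirical weighted norm

    d_comp = sqrt(dH^2 + (dN/6.5)^2)   [ppm],

the 6.5 divisor compressing the wider nitrogen shift range onto the proton
scale.  Residues with d_comp strictly above the threshold (default 0.05 ppm)
are flagged as perturbed.  Peaks observed only in the bound state (protection
from solvent exchange on binding) cannot be given a shift difference and are
reported as a categorical "appeared on binding" list instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .tablesio import ShiftRecord

__all__ = [
    "NITROGEN_SCALE",
    "DEFAULT_THRESHOLD_PPM",
    "ShiftPerturbation",
    "PerturbationResult",
    "composite_shift",
    "perturbation_table",
]

NITROGEN_SCALE = 6.5
DEFAULT_THRESHOLD_PPM = 0.05


@dataclass(frozen=True)
class ShiftPerturbation:
    residue_id: int
    atom_class: str
    d_comp: float          # ppm, >= 0
    above_threshold: bool  # strictly greater than threshold
    threshold: float


@dataclass
class PerturbationResult:
    perturbations: list[ShiftPerturbation]
    appeared_on_binding: list[tuple[int, str]]   # bound-only (residue, atom_class)
    lost_on_binding: list[tuple[int, str]]       # apo-only


def composite_shift(dH: float, dN: float) -> float:
    """sqrt(dH^2 + (dN/6.5)^2); invariant under sign flips of either input."""
    return math.hypot(dH, dN / NITROGEN_SCALE)


def perturbation_table(
    apo: list[ShiftRecord],
    bound: list[ShiftRecord],
    threshold: float = DEFAULT_THRESHOLD_PPM,
) -> PerturbationResult:
    """Match apo/bound records on (residue, atom_class) and score each pair.

    Unmatched records are routed to the categorical appeared/lost lists
    rather than being assigned a pseudo-perturbation.
    """
    apo_map = {(r.residue_id, r.atom_class): r for r in apo}
    bound_map = {(r.residue_id, r.atom_class): r for r in bound}

    perturbations = []
    for key in sorted(apo_map.keys() & bound_map.keys()):
        a, b = apo_map[key], bound_map[key]
        d = composite_shift(b.delta_H - a.delta_H, b.delta_N - a.delta_N)
        perturbations.append(
            ShiftPerturbation(key[0], key[1], d, d > threshold, threshold)
        )
    return PerturbationResult(
        perturbations=perturbations,
        appeared_on_binding=sorted(bound_map.keys() - apo_map.keys()),
        lost_on_binding=sorted(apo_map.keys() - bound_map.keys()),
    )
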