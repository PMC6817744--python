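"""Per-residue B-factor statistics from crystallographic coordinate files.

Room-temperature B-factors report the spatial extent of thermal motion and
static disorder; averaged per residue and per secondary-structure region
they complement the temporal picture from spin relaxation.  Parsing is done
with gemmi (PDB or mmCIF); averaging is occupancy-weighted over non-hydrogen
atoms, so alternate conformers contribute in proportion to their occupancy.
Waters, ions and free ligands are excluded from the RNA residue tables and
reported separately.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "ResidueB",
    "ResidueBTable",
    "RegionMap",
    "default_region_map",
    "per_residue_bfactor",
    "region_average",
    "delta_b",
]

#: residue names treated as nucleic-acid polymer residues
RNA_RESNAMES = frozenset({"A", "C", "G", "U", "DA", "DC", "DG", "DT", "DU", "I"})


@dataclass(frozen=True)
class ResidueB:
    chain_id: str
    residue_number: int
    residue_name: str
    mean_B: float     # Angstrom^2, occupancy-weighted
    atom_count: int


@dataclass
class ResidueBTable:
    entries: list[ResidueB]
    source_label: str = ""
    hetero: list[ResidueB] = field(default_factory=list)  # ligands/ions, reported apart

    def by_residue(self) -> dict[int, float]:
        """residue_number -> mean of mean_B over chains carrying it."""
        acc: dict[int, list[float]] = {}
        for e in self.entries:
            acc.setdefault(e.residue_number, []).append(e.mean_B)
        return {k: float(np.mean(v)) for k, v in sorted(acc.items())}

    def overall_mean(self) -> float:
        """Unweighted mean of the per-residue means (all RNA residues)."""
        if not self.entries:
            raise ValueError("empty residue table")
        return float(np.mean([e.mean_B for e in self.entries]))


@dataclass
class RegionMap:
    """Named secondary-structure regions -> residue-number sets."""

    regions: dict[str, set[int]]

    @classmethod
    def from_json(cls, path) -> "RegionMap":
        raw = json.loads(Path(path).read_text())
        return cls({name: _expand(spec) for name, spec in raw.items()})


def _expand(spec) -> set[int]:
    """Region spec: list of residue numbers and/or [start, stop] ranges."""
    out: set[int] = set()
    for item in spec:
        if isinstance(item, list):
            lo, hi = item
            out.update(range(int(lo), int(hi) + 1))
        else:
            out.add(int(item))
    return out


def default_region_map() -> RegionMap:
    """Default helix/loop/junction map for the rA71 construct (editable)."""
    with resources.files("riboflex.data").joinpath("regions.json").open() as fh:
        raw = json.load(fh)
    return RegionMap({name: _expand(spec) for name, spec in raw.items()})


def _read_structure(source) -> gemmi.Structure:
    if isinstance(source, gemmi.Structure):
        return source
    text = str(source)
    if "\n" in text or text.lstrip().startswith(("ATOM", "HETATM", "CRYST1", "HEADER")):
        return gemmi.read_pdb_string(text)
    return gemmi.read_structure(text)


def per_residue_bfactor(
    source,
    chain_filter: str | None = None,
    source_label: str = "",
) -> ResidueBTable:
    """Occupancy-weighted per-residue mean B over non-hydrogen atoms.

    ``source`` is a file path, PDB-format text, or a parsed gemmi Structure.
    Waters are dropped; non-RNA residues (ligands, ions) go to the table's
    ``hetero`` list.  ``chain_filter`` restricts to one chain and raises a
    ``KeyError`` listing available chains when absent.
    """
    st = _read_structure(source)
    if len(st) == 0:
        raise ValueError("coordinate file contains no models")
    model = st[0]
    chains = [ch.name for ch in model]
    if chain_filter is not None and chain_filter not in chains:
        raise KeyError(
            f"chain {chain_filter!r} not found; available chains: {', '.join(chains)}"
        )

    entries: list[ResidueB] = []
    hetero: list[ResidueB] = []
    for chain in model:
        if chain_filter is not None and chain.name != chain_filter:
            continue
        for res in chain:
            if res.is_water():
                continue
            wsum = bsum = 0.0
            count = 0
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                occ = atom.occ if atom.occ > 0 else 1.0
                wsum += occ
                bsum += occ * atom.b_iso
                count += 1
            if count == 0:
                continue
            entry = ResidueB(
                chain.name, res.seqid.num, res.name.strip(), bsum / wsum, count
            )
            (entries if entry.residue_name in RNA_RESNAMES else hetero).append(entry)
    return ResidueBTable(entries=entries, source_label=source_label, hetero=hetero)


def region_average(
    table: ResidueBTable, regions: RegionMap
) -> dict[str, tuple[float, float, int]]:
    """Per-region (mean, SD, n) of residue-mean B-factors.

    Regions with no residues present in the table are skipped.  Residues
    listed in a region but missing from the table are simply absent from
    that region's average (common: disordered termini).
    """
    by_res = table.by_residue()
    out: dict[str, tuple[float, float, int]] = {}
    for name, members in regions.regions.items():
        vals = [by_res[r] for r in sorted(members) if r in by_res]
        if not vals:
            continue
        arr = np.asarray(vals)
        out[name] = (float(arr.mean()), float(arr.std()), len(vals))
    return out


def delta_b(a: ResidueBTable, b: ResidueBTable) -> dict[int, float]:
    """Per-residue mean-B difference a - b on the shared residue numbers."""
    am, bm = a.by_residue(), b.by_residue()
    common = sorted(am.keys() & bm.keys())
    if not common:
        raise ValueError("residue tables share no residue numbers")
    return {r: am[r] - bm[r] for r in common}
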