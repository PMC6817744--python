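"""Delimited-text I/O for peak-height series, chemical-shift tables and results.

All tables are tab-separated UTF-8 with ``#`` comment lines and a required
named header row.  Residue numbers use the construct's own numbering
(rA71 spans residues 13-84) verbatim; no re-indexing is performed anywhere.

Relaxation-delay series and CPMG series share one reader: the name of the
x-axis column (``delay_s`` vs ``nu_cpmg_hz``) distinguishes the experiment.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "ATOM_CLASSES",
    "IntensityPoint",
    "IntensitySeries",
    "ShiftRecord",
    "ResultBundle",
    "TableFormatError",
    "TableParseError",
    "TableIntegrityError",
    "read_intensity_table",
    "read_shift_table",
    "write_results",
]

#: closed set of nitrogen/imino spin classes appearing in the shift tables
ATOM_CLASSES = frozenset({"imino_HN", "N1", "N3", "N7", "N9"})

STATE_LABELS = frozenset({"apo", "bound"})


class TableFormatError(ValueError):
    """A table is structurally malformed (missing column, bad header)."""


class TableParseError(ValueError):
    """A cell could not be parsed; the message carries the row number."""


class TableIntegrityError(ValueError):
    """Semantically invalid content (duplicates, closed-set violations)."""


class IntensityPoint(NamedTuple):
    delay: float        # seconds (or Hz for CPMG series; see IntensitySeries.kind)
    intensity: float    # arbitrary units
    is_replicate: bool  # True for repeats of an earlier identical x-value


@dataclass
class IntensitySeries:
    """Peak heights vs relaxation delay (or vs CPMG frequency) for one residue.

    ``kind`` is ``"relaxation"`` when the x-axis is a delay in seconds and
    ``"cpmg"`` when it is a refocusing frequency nu_cpmg in Hz.  Replicate
    points (the acquisition design repeats one x-value, e.g. the 100 ms R1
    delay or the 640 Hz CPMG point) are flagged so noise can be estimated
    from the pair differences.
    """

    residue_id: int
    spin_label: str
    field_mhz: float
    points: list[IntensityPoint] = field(default_factory=list)
    kind: str = "relaxation"

    @property
    def x(self) -> np.ndarray:
        return np.array([p.delay for p in self.points], dtype=float)

    @property
    def intensities(self) -> np.ndarray:
        return np.array([p.intensity for p in self.points], dtype=float)

    @property
    def is_replicate(self) -> np.ndarray:
        return np.array([p.is_replicate for p in self.points], dtype=bool)

    def replicate_pairs(self) -> list[tuple[float, float, float]]:
        """(x, intensity, replicate intensity) for each duplicated x-value."""
        first: dict[float, float] = {}
        pairs = []
        for p in self.points:
            if p.is_replicate and p.delay in first:
                pairs.append((p.delay, first[p.delay], p.intensity))
            elif not p.is_replicate:
                first[p.delay] = p.intensity
        return pairs


@dataclass(frozen=True)
class ShiftRecord:
    residue_id: int
    atom_class: str
    delta_H: float  # ppm
    delta_N: float  # ppm
    state_label: str  # "apo" | "bound"


@dataclass
class ResultBundle:
    """Named result tables plus run metadata, serialized deterministically."""

    run_metadata: dict = field(default_factory=dict)
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)


def _require_columns(df: pd.DataFrame, required: set[str], path) -> None:
    missing = required - set(df.columns)
    if missing:
        raise TableFormatError(
            f"{path}: missing required column(s): {', '.join(sorted(missing))}"
        )


def _read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


def _numeric(df: pd.DataFrame, col: str, path) -> np.ndarray:
    # cell-wise float() parsing: exact round trip of repr-formatted values
    out = np.empty(len(df), dtype=float)
    for i, v in enumerate(df[col]):
        try:
            out[i] = float(v)
        except (TypeError, ValueError):
            raise TableParseError(
                f"{path}: non-numeric value {v!r} in column {col!r} "
                f"at data row {i + 1}"
            ) from None
    return out


def read_intensity_table(path, dialect: dict | None = None) -> list[IntensitySeries]:
    """Read a peak-height table into one series per (residue, field).

    The header must declare ``residue``, ``field_mhz``, ``intensity`` and an
    x-axis column: ``delay_s`` for relaxation series or ``nu_cpmg_hz`` for
    CPMG series.  An optional ``spin_label`` column is carried through.  Row
    order is preserved; a row repeating an earlier x-value within its series
    is flagged as a replicate.
    """
    df = _read_tsv(path)
    if "delay_s" in df.columns:
        xcol, kind = "delay_s", "relaxation"
    elif "nu_cpmg_hz" in df.columns:
        xcol, kind = "nu_cpmg_hz", "cpmg"
    else:
        raise TableFormatError(
            f"{path}: missing required column: need 'delay_s' or 'nu_cpmg_hz'"
        )
    _require_columns(df, {"residue", "field_mhz", "intensity"}, path)

    residue = _numeric(df, "residue", path).astype(int)
    field_mhz = _numeric(df, "field_mhz", path)
    xvals = _numeric(df, xcol, path)
    inten = _numeric(df, "intensity", path)
    if (xvals < 0).any():
        raise TableIntegrityError(f"{path}: negative value in column {xcol!r}")
    labels = (
        df["spin_label"].fillna("").to_numpy()
        if "spin_label" in df.columns
        else np.full(len(df), "", dtype=object)
    )

    series: dict[tuple[int, float], IntensitySeries] = {}
    for i in range(len(df)):
        key = (int(residue[i]), float(field_mhz[i]))
        if key not in series:
            series[key] = IntensitySeries(
                residue_id=key[0],
                spin_label=str(labels[i]),
                field_mhz=key[1],
                kind=kind,
            )
        s = series[key]
        seen = any(p.delay == xvals[i] for p in s.points)
        s.points.append(IntensityPoint(float(xvals[i]), float(inten[i]), seen))
    return list(series.values())


def read_shift_table(path) -> list[ShiftRecord]:
    """Read apo/bound chemical-shift records; validates the atom-class set."""
    df = _read_tsv(path)
    _require_columns(df, {"residue", "atom_class", "dH_ppm", "dN_ppm", "state"}, path)
    residue = _numeric(df, "residue", path).astype(int)
    dh = _numeric(df, "dH_ppm", path)
    dn = _numeric(df, "dN_ppm", path)

    records: list[ShiftRecord] = []
    seen: set[tuple[int, str, str]] = set()
    for i in range(len(df)):
        atom = str(df["atom_class"].iloc[i])
        state = str(df["state"].iloc[i])
        if atom not in ATOM_CLASSES:
            raise TableIntegrityError(
                f"{path}: unknown atom_class {atom!r} at data row {i + 1}; "
                f"allowed classes: {', '.join(sorted(ATOM_CLASSES))}"
            )
        if state not in STATE_LABELS:
            raise TableIntegrityError(
                f"{path}: unknown state {state!r} at data row {i + 1}; "
                f"allowed: apo, bound"
            )
        key = (int(residue[i]), atom, state)
        if key in seen:
            raise TableIntegrityError(
                f"{path}: duplicate record for residue {key[0]}, "
                f"atom_class {atom}, state {state}"
            )
        seen.add(key)
        records.append(ShiftRecord(int(residue[i]), atom, float(dh[i]), float(dn[i]), state))
    return records


def write_intensity_table(series_list: list[IntensitySeries], path) -> None:
    """Inverse of :func:`read_intensity_table` (round-trips exactly)."""
    kind = series_list[0].kind if series_list else "relaxation"
    xcol = "delay_s" if kind == "relaxation" else "nu_cpmg_hz"
    rows = []
    for s in series_list:
        for p in s.points:
            rows.append(
                {
                    "residue": s.residue_id,
                    "spin_label": s.spin_label,
                    "field_mhz": s.field_mhz,
                    xcol: p.delay,
                    "intensity": p.intensity,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_shift_table(records: list[ShiftRecord], path) -> None:
    rows = [
        {
            "residue": r.residue_id,
            "atom_class": r.atom_class,
            "dH_ppm": r.delta_H,
            "dN_ppm": r.delta_N,
            "state": r.state_label,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_results(bundle: ResultBundle, out_dir) -> dict[str, str]:
    """Write a bundle's tables and metadata; return {filename: sha256}.

    File naming is deterministic (sorted table names); identical bundles
    produce byte-identical files and hence identical checksums.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    meta_path = out / "run_metadata.json"
    meta_path.write_text(
        json.dumps(bundle.run_metadata, sort_keys=True, indent=1) + "\n",
        encoding="utf-8",
    )
    manifest[meta_path.name] = _sha256(meta_path)

    for name in sorted(bundle.tables):
        fpath = out / f"{name}.tsv"
        bundle.tables[name].to_csv(fpath, sep="\t", index=False, lineterminator="\n")
        manifest[fpath.name] = _sha256(fpath)

    (out / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1) + "\n", encoding="utf-8"
    )
    return manifest
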