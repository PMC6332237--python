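"""CSV and MGF input/output for feature tables, libraries and spectra.

Feature table CSV dialect (one row per full-scan feature)::

    feature_id, rt_min, mz, intensity,
    mz_a1..mz_a4, ab_a1..ab_a4,   # optional envelope: A+1..A+4 peaks
    msms_id                        # optional link to an MGF spectrum

The main ``mz`` column is the monoisotopic (A) peak with abundance 100;
``mz_a1..4``/``ab_a1..4`` carry the higher isotopologues.  Library CSV
columns: ``name, formula, class, epimer_pair, uv_maxima`` where
``epimer_pair`` is ``group:label`` (e.g. ``rugulovasine:A``) and
``uv_maxima`` is ``;``-separated nm values.  MS/MS peak lists use MGF
via pyteomics (PEPMASS = precursor m/z, CHARGE=1+).
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd
from pyteomics import mgf as _mgf

from .formula import FormulaParseError, parse_formula
from .isotopes import IsotopePattern
from .library import LibraryEntry
from .screen import Feature, LibraryRowError

__all__ = [
    "read_feature_csv",
    "write_feature_csv",
    "read_library_csv",
    "write_library_csv",
    "read_mgf",
    "write_mgf",
]

_ENV_COLS = [f"mz_a{i}" for i in range(1, 5)] + [f"ab_a{i}" for i in range(1, 5)]

PathLike = Union[str, Path]


def write_feature_csv(features: Sequence[Feature], path: PathLike) -> None:
    rows = []
    for i, f in enumerate(features):
        row: Dict[str, object] = {
            "feature_id": f.feature_id or f"F{i:04d}",
            "rt_min": round(f.rt_min, 3),
            "mz": round(f.mz, 5),
            "intensity": round(f.intensity, 1),
            "msms_id": f.msms_id or "",
        }
        if f.envelope is not None:
            higher = [p for p in f.envelope.peaks if p[0] > f.mz + 0.5][:4]
            for k, (m, a) in enumerate(higher, start=1):
                row[f"mz_a{k}"] = round(m, 5)
                row[f"ab_a{k}"] = round(a, 3)
        rows.append(row)
    cols = ["feature_id", "rt_min", "mz", "intensity"] + _ENV_COLS + ["msms_id"]
    pd.DataFrame(rows).reindex(columns=cols).to_csv(path, index=False)


def read_feature_csv(path: PathLike) -> List[Feature]:
    df = pd.read_csv(path, dtype={"feature_id": str, "msms_id": str})
    feats: List[Feature] = []
    for _, row in df.iterrows():
        envelope = None
        peaks: List[Tuple[float, float]] = [(float(row["mz"]), 100.0)]
        for k in range(1, 5):
            mc, ac = f"mz_a{k}", f"ab_a{k}"
            if mc in df.columns and pd.notna(row.get(mc)) and pd.notna(row.get(ac)):
                peaks.append((float(row[mc]), float(row[ac])))
        if len(peaks) > 1:
            envelope = IsotopePattern.from_rows(peaks)
        msms_id = row.get("msms_id")
        if pd.isna(msms_id) or msms_id == "":
            msms_id = None
        feats.append(
            Feature(
                rt_min=float(row["rt_min"]),
                mz=float(row["mz"]),
                intensity=float(row["intensity"]),
                envelope=envelope,
                msms_id=msms_id,
                feature_id=str(row["feature_id"]),
            )
        )
    return feats


def write_library_csv(entries: Sequence[LibraryEntry], path: PathLike) -> None:
    rows = []
    for e in entries:
        pair = f"{e.epimer_group}:{e.epimer_label}" if e.epimer_group else ""
        rows.append(
            {
                "name": e.name,
                "formula": e.formula.to_string(),
                "class": e.compound_class,
                "epimer_pair": pair,
                "uv_maxima": ";".join(str(v) for v in e.uv_maxima_nm),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_library_csv(
    path: PathLike,
) -> Tuple[List[LibraryEntry], List[LibraryRowError]]:
    """Parse a library CSV; bad rows are collected, not fatal.

    Returns (entries, row_errors); each error carries its 1-based data
    row number so the offending line can be fixed.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    entries: List[LibraryEntry] = []
    errors: List[LibraryRowError] = []
    seen_names = set()
    for idx, row in df.iterrows():
        rownum = int(idx) + 1
        try:
            name = row["name"].strip()
            if not name:
                raise ValueError("missing compound name")
            if name in seen_names:
                raise ValueError(f"duplicate compound name {name!r}")
            formula = parse_formula(row["formula"])
            pair = row.get("epimer_pair", "")
            group, label = ("", "")
            if pair:
                group, _, label = pair.partition(":")
            uv = tuple(
                int(v) for v in row.get("uv_maxima", "").split(";") if v.strip()
            )
            entries.append(
                LibraryEntry(
                    name=name,
                    formula=formula,
                    compound_class=row.get("class", "") or "unclassified",
                    epimer_group=group,
                    epimer_label=label,
                    uv_maxima_nm=uv,
                )
            )
            seen_names.add(name)
        except (KeyError, ValueError, FormulaParseError) as exc:
            errors.append(LibraryRowError(rownum, str(exc)))
    return entries, errors


def write_mgf(
    spectra: Dict[str, Dict[str, object]],
    path: PathLike,
) -> None:
    """Write MS/MS spectra to MGF.

    ``spectra`` maps spectrum id -> {"precursor_mz": float,
    "peaks": [(mz, intensity), ...]}.
    """
    entries = []
    for sid in sorted(spectra):
        spec = spectra[sid]
        peaks = sorted(spec["peaks"])
        entries.append(
            {
                "m/z array": [m for m, _ in peaks],
                "intensity array": [i for _, i in peaks],
                "params": {
                    "title": sid,
                    "pepmass": float(spec["precursor_mz"]),
                    "charge": "1+",
                },
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


def read_mgf(path: PathLike) -> Dict[str, Dict[str, object]]:
    """Read an MGF file into {spectrum id: {precursor_mz, peaks}}."""
    out: Dict[str, Dict[str, object]] = {}
    with _mgf.MGF(str(path)) as reader:
        for i, spec in enumerate(reader):
            params = spec.get("params", {})
            sid = str(params.get("title", f"spectrum{i}"))
            pepmass = params.get("pepmass", (0.0,))
            out[sid] = {
                "precursor_mz": float(pepmass[0]),
                "peaks": list(
                    zip(
                        (float(m) for m in spec["m/z array"]),
                        (float(x) for x in spec["intensity array"]),
                    )
                ),
            }
    return out
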