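"""End-to-end screening pipeline: assign → isotope re-rank → series
link → dereplicate → epimer labels → MS/MS annotation.

A :class:`RunConfig` captures every tolerance and path of a run and
round-trips through YAML; a :class:`Report` is a plain-dict artifact
with fixed-precision floats (m/z 4 decimals, ppm 2) so that re-running
an identical config on identical inputs reproduces it byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import yaml

from . import __version__
from .assign import ElementBounds, enumerate_formulas, rerank_with_isotopes
from .formula import Formula, parse_formula
from .fragments import annotate_products, epimer_diagnostic
from .isotopes import classify_halogens
from .library import LibraryEntry, default_library
from .screen import Feature, assign_epimers, dereplicate, link_series
from .synth import SyntheticDataset, generate, scenario_presets

__all__ = ["RunConfig", "Report", "PipelineStageError", "run_screen"]


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and offending record."""

    def __init__(self, stage: str, record: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on {record}: {cause}")
        self.stage = stage
        self.record = record
        self.cause = cause


@dataclass
class RunConfig:
    """All knobs of one screening run.

    Tolerances default to the dereplication conventions of
    high-resolution positive-ESI screening: ±5 ppm formula window,
    3 mDa substitution-delta tolerance, ±5 ppm MS/MS matching.
    """

    window_ppm: float = 5.0
    delta_tol_mda: float = 3.0
    msms_tol_ppm: float = 5.0
    max_cl: int = 2
    max_br: int = 1
    w_mass: float = 0.4
    w_iso: float = 0.6
    rt_coelution_min: float = 0.1
    element_bounds: Dict[str, List[int]] = field(
        default_factory=lambda: {
            "C": [0, 30],
            "H": [0, 40],
            "N": [0, 6],
            "O": [0, 8],
            "Cl": [0, 4],
            "Br": [0, 2],
        }
    )
    seed: int = 0
    scenario: Optional[str] = None  # synthesize inputs from a preset
    features_csv: Optional[str] = None
    msms_mgf: Optional[str] = None
    library_csv: Optional[str] = None
    verbose: bool = False

    def bounds(self) -> ElementBounds:
        return ElementBounds({el: (lo, hi) for el, (lo, hi) in self.element_bounds.items()})

    # -- serialization ------------------------------------------------------
    def to_yaml(self, path: Optional[str | Path] = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "RunConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        data = yaml.safe_load(text) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "element_bounds" in data:
            data["element_bounds"] = {
                el: list(v) for el, v in data["element_bounds"].items()
            }
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


@dataclass
class Report:
    """Screening report; ``data`` is a JSON-ready nested dict."""

    data: Dict[str, object]

    def to_json(self, path: Optional[str | Path] = None) -> str:
        text = json.dumps(self.data, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @property
    def features(self) -> List[Dict[str, object]]:
        return self.data["features"]  # type: ignore[return-value]

    @property
    def identified(self) -> List[Dict[str, object]]:
        return [f for f in self.features if f["matches"]]

    @property
    def unknowns(self) -> List[Dict[str, object]]:
        return [f for f in self.features if not f["matches"]]


def _r(x: Optional[float], nd: int) -> Optional[float]:
    return None if x is None else round(float(x), nd)


def _load_inputs(
    config: RunConfig,
) -> Tuple[List[Feature], Dict[str, Dict[str, object]], List[LibraryEntry]]:
    from .io import read_feature_csv, read_library_csv, read_mgf

    if config.scenario:
        ds: SyntheticDataset = generate(scenario_presets(config.scenario, seed=config.seed))
        features, msms = ds.features, ds.msms
    else:
        features = read_feature_csv(config.features_csv) if config.features_csv else []
        msms = read_mgf(config.msms_mgf) if config.msms_mgf else {}
    if config.library_csv:
        library, row_errors = read_library_csv(config.library_csv)
        for err in row_errors:
            warnings.warn(str(err), stacklevel=2)
    else:
        library = default_library()
    return features, msms, library


def run_screen(config: RunConfig) -> Report:
    """Execute the full screening chain and return the report.

    Stage order: formula assignment, isotope re-ranking + halogen
    call, substitution-series linking, library dereplication, epimer
    labelling of co-matched pairs, MS/MS loss annotation.  A stage
    failure raises :class:`PipelineStageError` naming the stage and
    offending record.
    """
    stage = "load"
    try:
        features, msms, library = _load_inputs(config)
    except Exception as exc:  # noqa: BLE001 - reported with stage context
        raise PipelineStageError(stage, "inputs", exc) from exc

    if not features:
        warnings.warn("empty feature table: writing empty report", stacklevel=2)
        return Report(
            {
                "features": [],
                "series_links": [],
                "meta": _meta(config, 0),
            }
        )

    bounds = config.bounds()
    records: List[Dict[str, object]] = []
    feats_sorted = sorted(
        features, key=lambda f: (f.feature_id or "", f.rt_min, f.mz)
    )

    # assignment + isotope re-rank + halogen call, per feature
    for f in feats_sorted:
        rec_id = f.feature_id or f"{f.rt_min:.3f}:{f.mz:.4f}"
        try:
            stage = "assign"
            cands = enumerate_formulas(f.mz, config.window_ppm, bounds)
            stage = "isotope_rerank"
            cands = rerank_with_isotopes(
                cands, f.envelope, config.window_ppm, config.w_mass, config.w_iso
            )
            top = cands[0] if cands else None
            stage = "halogen_call"
            call = None
            if f.envelope is not None and len(f.envelope) >= 2:
                call = classify_halogens(f.envelope, config.max_cl, config.max_br)
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError(stage, f"feature {rec_id}", exc) from exc
        records.append(
            {
                "feature_id": rec_id,
                "rt_min": _r(f.rt_min, 3),
                "mz": _r(f.mz, 4),
                "intensity": _r(f.intensity, 1),
                "top_formula": top.ion.to_string() if top else None,
                "top_ppm": _r(top.ppm, 2) if top else None,
                "top_iso_score": _r(top.iso_score, 4) if top else None,
                "n_candidates": len(cands),
                "halogen_call": [call.n_cl, call.n_br] if call else None,
                "halogen_score": _r(call.score, 4) if call else None,
                "matches": [],
                "epimer_label": None,
                "msms": None,
                "_feature": f,
            }
        )

    # substitution-series links
    stage = "link_series"
    try:
        links = link_series(feats_sorted, config.delta_tol_mda)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(stage, "feature table", exc) from exc
    link_rows = [
        {
            "light": l.light.feature_id or f"{l.light.mz:.4f}",
            "heavy": l.heavy.feature_id or f"{l.heavy.mz:.4f}",
            "delta": l.delta.name,
            "nominal_da": l.delta.nominal_da,
            "observed_delta": _r(l.observed_delta, 4),
            "error_mda": _r(l.error_mda, 2),
        }
        for l in links
    ]

    # dereplication
    stage = "dereplicate"
    try:
        matches = dereplicate(feats_sorted, library, config.window_ppm)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(stage, "feature table", exc) from exc
    by_id = {r["feature_id"]: r for r in records}
    for m in matches:
        rec = by_id[m.feature.feature_id or f"{m.feature.rt_min:.3f}:{m.feature.mz:.4f}"]
        rec["matches"] = [
            {"name": e.name, "formula": e.formula.to_string(), "ppm": _r(p, 2)}
            for e, p in zip(m.entries, m.ppm_errors)
        ]

    # epimer labels on co-matched A/B pairs
    stage = "epimers"
    try:
        groups: Dict[str, List[Feature]] = {}
        for m in matches:
            for e in m.entries:
                if e.epimer_group:
                    groups.setdefault(e.epimer_group, [])
                    if m.feature not in groups[e.epimer_group]:
                        groups[e.epimer_group].append(m.feature)
        for group, feats in sorted(groups.items()):
            labels = assign_epimers(feats)
            for f in feats:
                key = f.feature_id or f"{f.rt_min:.3f}:{f.mz:.4f}"
                rec = by_id[key]
                label = labels[key]
                rec["epimer_label"] = label
                if label in ("A", "B") and rec["matches"]:
                    rec["matches"] = [
                        mm
                        for mm in rec["matches"]
                        if not mm["name"].endswith(("A", "B"))
                        or mm["name"].endswith(label)
                    ]
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(stage, "epimer groups", exc) from exc

    # MS/MS annotation
    stage = "msms_annotate"
    for rec in records:
        f: Feature = rec.pop("_feature")
        if not f.msms_id or f.msms_id not in msms:
            continue
        try:
            prec_formula: Optional[Formula] = None
            if rec["matches"]:
                prec_formula = parse_formula(rec["matches"][0]["formula"]).protonated()
            elif rec["top_formula"]:
                prec_formula = parse_formula(rec["top_formula"], 1)
            if prec_formula is None:
                continue
            spec = msms[f.msms_id]
            anns = annotate_products(
                prec_formula, list(spec["peaks"]), tol_ppm=config.msms_tol_ppm
            )
            rec["msms"] = {
                "precursor_formula": prec_formula.to_string(),
                "epimer_diagnostic": epimer_diagnostic(anns),
                "annotations": [
                    {
                        "mz": _r(a.mz_observed, 4),
                        "formula": a.ion.to_string() if a.ion else None,
                        "losses": "+".join(a.losses),
                        "class": a.species_class,
                        "ppm": _r(a.ppm, 2),
                    }
                    for a in anns
                ],
            }
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError(stage, f"spectrum {f.msms_id}", exc) from exc

    for rec in records:
        rec.pop("_feature", None)

    return Report(
        {
            "features": records,
            "series_links": link_rows,
            "meta": _meta(config, len(records)),
        }
    )


def _meta(config: RunConfig, n_features: int) -> Dict[str, object]:
    return {
        "config_digest": config.digest(),
        "seed": config.seed,
        "n_features": n_features,
        "tolerances": {
            "window_ppm": config.window_ppm,
            "delta_tol_mda": config.delta_tol_mda,
            "msms_tol_ppm": config.msms_tol_ppm,
        },
        "version": __version__,
    }
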