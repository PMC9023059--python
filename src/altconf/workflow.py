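"""End-to-end ensemble analysis: filter → align → score → stats → landscape.

``run_analysis`` consumes a directory of predicted models (inference happens
elsewhere; see :mod:`altconf.protocol`) plus two experimental reference
structures, and writes a reproducible report bundle:

* ``outliers.json`` — coclustering report, kept/excluded model ids
* ``per_model.csv`` — TM-scores to both references, PC1/PC2, kept flag
* ``per_residue.csv`` — displacement, RMSF, mean pLDDT, confidence-kept flag
* ``landscape.json`` — variance fractions, reference projections, mask
* ``selection.json`` — top-1/3/10 extreme models on both PC1 sides
* ``config.json`` / ``log.txt`` — resolved configuration and stage log

Stages fail independently: an error is recorded with its stage name and the
bundle keeps every earlier output.  Reruns with identical inputs are
byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from altconf.ensemble_stats import (
    OutlierReport,
    ResidueProfile,
    confidence_filter,
    displacement_profile,
    filter_misfolded,
    profile_correlation,
    rmsf_profile,
)
from altconf.errors import AltconfError, DomainError
from altconf.landscape import (
    fit_landscape,
    pc_tm_correlation,
    project_reference,
    secondary_structure_mask,
    select_extremes,
)
from altconf.structures import StructureModel, correspond, read_pdb, truncate
from altconf.superpose import align_ensemble, tm_score

_FLOAT_FMT = "%.6f"


@dataclass
class WorkflowConfig:
    """Resolved, fully serializable settings of one analysis run."""

    target: str
    ref1_path: str
    ref1_chain: str = "A"
    ref2_path: str = ""
    ref2_chain: str = "A"
    truncations: list[tuple[int, int]] = field(default_factory=list)
    plddt_threshold: float = 75.0
    apply_confidence_filter: bool = True
    linkage_cutoff: float = 5.0
    min_cluster: int = 3
    mask_residues: list[int] | None = None
    top_k: tuple[int, ...] = (1, 3, 10)
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "WorkflowConfig":
        raw = json.loads(text)
        raw["truncations"] = [tuple(t) for t in raw.get("truncations", [])]
        raw["top_k"] = tuple(raw.get("top_k", (1, 3, 10)))
        return cls(**raw)


@dataclass
class RunReport:
    """In-memory result bundle of :func:`run_analysis`."""

    outliers: OutlierReport | None = None
    per_model: pd.DataFrame | None = None
    per_residue: pd.DataFrame | None = None
    landscape_summary: dict | None = None
    selection: dict | None = None
    correlation_r2: float | None = None
    errors: list[tuple[str, str]] = field(default_factory=list)
    log: list[str] = field(default_factory=list)


def _load_models(ensemble_dir: Path) -> list[StructureModel]:
    paths = sorted(ensemble_dir.glob("*.pdb"))
    models = []
    for p in paths:
        models.append(read_pdb(str(p), chain="A", is_prediction=True))
    if len(models) < 3:
        raise DomainError(f"ensemble directory holds {len(models)} models; >= 3 required")
    return models


def _remap_profile(profile: ResidueProfile, pairs: list[tuple[int, int]]) -> ResidueProfile:
    """Reindex a profile from the a-frame to the b-frame of a residue map."""
    lut = dict(pairs)
    return ResidueProfile({lut[i]: v for i, v in profile.values.items() if i in lut})


def run_analysis(
    config: WorkflowConfig,
    ensemble_dir: str | Path,
    out_dir: str | Path | None = None,
) -> RunReport:
    """Run the full analysis on an existing model ensemble.

    Every stage that fails is recorded in ``report.errors`` as
    (stage, message); later stages that depend on it are skipped, earlier
    outputs are retained and still written to ``out_dir``.
    """
    report = RunReport()
    ensemble_dir = Path(ensemble_dir)

    def log(msg: str) -> None:
        report.log.append(msg)

    log(f"config seed={config.seed} plddt_threshold={config.plddt_threshold} "
        f"linkage_cutoff={config.linkage_cutoff} min_cluster={config.min_cluster}")

    # --- load ---------------------------------------------------------
    try:
        models = _load_models(ensemble_dir)
        log(f"loaded {len(models)} models from {ensemble_dir.name}")
        ref1 = read_pdb(config.ref1_path, chain=config.ref1_chain, model_id="ref1")
        ref2 = (
            read_pdb(config.ref2_path, chain=config.ref2_chain, model_id="ref2")
            if config.ref2_path
            else None
        )
        if config.truncations:
            ref1 = truncate(ref1, config.truncations)
            if ref2 is not None:
                ref2 = truncate(ref2, config.truncations)
    except (AltconfError, OSError) as exc:
        report.errors.append(("load", str(exc)))
        return report

    # --- misfold exclusion -------------------------------------------
    kept_models = models
    try:
        report.outliers = filter_misfolded(
            models, linkage_cutoff=config.linkage_cutoff, min_cluster=config.min_cluster
        )
        kept_ids = set(report.outliers.kept)
        kept_models = [m for m in models if m.model_id in kept_ids]
        log(f"coclustering kept {len(kept_models)}, excluded {len(report.outliers.excluded)}")
    except AltconfError as exc:
        report.errors.append(("filter_misfolded", str(exc)))

    # --- structure-based alignment -----------------------------------
    try:
        aligned = align_ensemble(kept_models, "mean")
    except AltconfError as exc:
        report.errors.append(("align_ensemble", str(exc)))
        _write_bundle(report, config, out_dir)
        return report

    # --- TM-scores ----------------------------------------------------
    tm1: dict[str, float] = {}
    tm2: dict[str, float] = {}
    try:
        map1 = correspond(ref1, aligned[0])
        for m in aligned:
            tm1[m.model_id] = tm_score(ref1, m, map1).score
        if ref2 is not None:
            map2 = correspond(ref2, aligned[0])
            for m in aligned:
                tm2[m.model_id] = tm_score(ref2, m, map2).score
        log(f"TM-scores computed against {'2 references' if ref2 else '1 reference'}")
    except AltconfError as exc:
        report.errors.append(("tm_score", str(exc)))

    # --- per-residue statistics --------------------------------------
    disp_model_frame = None
    rmsf = None
    try:
        rmsf = rmsf_profile(aligned)
        plddt_vals: dict[int, list[float]] = {}
        for m in aligned:
            if m.plddt is not None:
                for rid, v in zip(m.residue_ids, m.plddt):
                    plddt_vals.setdefault(int(rid), []).append(float(v))
        mean_plddt = ResidueProfile({i: float(np.mean(v)) for i, v in plddt_vals.items()})
        if ref2 is not None:
            disp = displacement_profile(ref1, ref2, correspond(ref1, ref2))
            disp_model_frame = _remap_profile(disp, correspond(ref1, aligned[0]).pairs)
            rmsf_f, disp_f = rmsf, disp_model_frame
            if config.apply_confidence_filter and len(mean_plddt):
                rmsf_f = confidence_filter(rmsf, mean_plddt, config.plddt_threshold)
                disp_f = confidence_filter(disp_model_frame, mean_plddt, config.plddt_threshold)
            report.correlation_r2 = profile_correlation(disp_f, rmsf_f, "r_squared")
            log(f"displacement-RMSF r^2 = {report.correlation_r2:.4f}")
        rows = []
        for rid in rmsf.indices():
            rid = int(rid)
            pl = mean_plddt.values.get(rid, float("nan"))
            rows.append({
                "residue": rid,
                "displacement": (disp_model_frame.values.get(rid, float("nan"))
                                 if disp_model_frame else float("nan")),
                "rmsf": rmsf.values[rid],
                "mean_plddt": pl,
                "kept_flag": int(not config.apply_confidence_filter
                                 or (pl == pl and pl > config.plddt_threshold)),
            })
        report.per_residue = pd.DataFrame(rows)
    except AltconfError as exc:
        report.errors.append(("ensemble_stats", str(exc)))

    # --- landscape ----------------------------------------------------
    try:
        mask = (np.asarray(config.mask_residues, dtype=int)
                if config.mask_residues else secondary_structure_mask(aligned[0]))
        # references must cover the mask: restrict to mapped residues
        for ref in (ref1, ref2):
            if ref is None:
                continue
            pairs = dict(correspond(aligned[0], ref).pairs)
            mask = np.array([r for r in mask if int(r) in pairs], dtype=int)
        if len(mask) == 0:
            raise DomainError("mask empty after restriction to reference coverage")
        scape = fit_landscape(aligned, include_mask=mask)
        project_reference(scape, ref1, correspond(aligned[0], ref1))
        if ref2 is not None:
            project_reference(scape, ref2, correspond(aligned[0], ref2))
        scape.orient("ref1")
        report.landscape_summary = {
            "variance_fractions": [float(v) for v in scape.variance_fractions[:10]],
            "pc1_variance_fraction": float(scape.variance_fractions[0]),
            "reference_projections": {
                k: [float(x) for x in v[:2]] for k, v in scape.reference_projections.items()
            },
            "mask_residues": [int(r) for r in scape.mask_residues],
        }
        selection: dict[str, dict] = {}
        for side in ("low", "high"):
            per_k = {}
            for k in config.top_k:
                kk = min(k, len(scape.projections))
                ids = select_extremes(scape, kk, side)
                entry = {"models": ids}
                if tm1:
                    nearest = []
                    for mid in ids:
                        cands = [tm1[mid]] + ([tm2[mid]] if tm2 else [])
                        nearest.append(max(cands))
                    entry["mean_tm_to_nearest_ref"] = float(np.mean(nearest))
                per_k[f"top_{k}"] = entry
            selection[side] = per_k
        report.selection = selection
        if tm1:
            try:
                selection["pc1_tm_pearson_ref1"] = pc_tm_correlation(scape, tm1)
                if tm2:
                    selection["pc1_tm_pearson_ref2"] = pc_tm_correlation(scape, tm2)
            except AltconfError as exc:
                log(f"PC1-TM correlation unavailable: {exc}")
        pc = {mid: p for mid, p in scape.projections.items()}
        report.per_model = pd.DataFrame([
            {
                "model_id": m.model_id,
                "tm_to_ref1": tm1.get(m.model_id, float("nan")),
                "tm_to_ref2": tm2.get(m.model_id, float("nan")),
                "pc1": float(pc[m.model_id][0]) if m.model_id in pc else float("nan"),
                "pc2": (float(pc[m.model_id][1])
                        if m.model_id in pc and len(pc[m.model_id]) > 1 else float("nan")),
                "kept_flag": int(report.outliers is None
                                 or m.model_id in set(report.outliers.kept)),
            }
            for m in models
        ])
        log(f"landscape: PC1 fraction {scape.variance_fractions[0]:.3f}")
    except AltconfError as exc:
        report.errors.append(("landscape", str(exc)))
        if report.per_model is None and tm1:
            report.per_model = pd.DataFrame([
                {"model_id": m.model_id,
                 "tm_to_ref1": tm1.get(m.model_id, float("nan")),
                 "tm_to_ref2": tm2.get(m.model_id, float("nan")),
                 "pc1": float("nan"), "pc2": float("nan"),
                 "kept_flag": int(report.outliers is None
                                  or m.model_id in set(report.outliers.kept))}
                for m in models
            ])

    _write_bundle(report, config, out_dir)
    return report


def _write_bundle(report: RunReport, config: WorkflowConfig, out_dir: str | Path | None) -> None:
    if out_dir is None:
        return
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json() + "\n")
    (out / "log.txt").write_text("\n".join(report.log) + "\n")
    if report.outliers is not None:
        (out / "outliers.json").write_text(json.dumps({
            "kept": report.outliers.kept,
            "excluded": [list(e) for e in report.outliers.excluded],
            "cluster_labels": report.outliers.cluster_labels,
        }, indent=2, sort_keys=True) + "\n")
    if report.per_model is not None:
        report.per_model.to_csv(out / "per_model.csv", index=False, float_format=_FLOAT_FMT)
    if report.per_residue is not None:
        report.per_residue.to_csv(out / "per_residue.csv", index=False, float_format=_FLOAT_FMT)
    if report.landscape_summary is not None:
        (out / "landscape.json").write_text(
            json.dumps(report.landscape_summary, indent=2, sort_keys=True) + "\n")
    if report.selection is not None:
        (out / "selection.json").write_text(
            json.dumps(report.selection, indent=2, sort_keys=True) + "\n")
    if report.correlation_r2 is not None:
        (out / "correlation.json").write_text(
            json.dumps({"displacement_rmsf_r_squared": report.correlation_r2},
                       indent=2, sort_keys=True) + "\n")
    if report.errors:
        (out / "errors.json").write_text(
            json.dumps([list(e) for e in report.errors], indent=2) + "\n")
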