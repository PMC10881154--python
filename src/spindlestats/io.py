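"""CSV/JSON readers and writers for annotation tables, plus the pipeline driver.

All tabular inputs are UTF-8 CSV with a header row and "." decimal
separator, matching spreadsheet-style exports from image-annotation tools.
Readers validate every row (angle domain, non-negative counts, positive
lengths) and attach the offending row number to parse errors; nothing is
silently coerced.  Machine outputs store percentages unrounded and embed
the seed and a config hash so reruns are reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

import pandas as pd

from . import __version__
from .angle_geometry import (
    AngleSample,
    BasementMembraneTrace,
    DivisionTrack,
    PoleAnnotation,
    bin_angle,
    classify_reintegration,
    distribution_summary,
    spindle_angle,
    t0_t60_resolution,
)
from .cohort import TumorRecord, summarize_cohort
from .morphometry import SectionCounts, condition_means, summarize_animals
from .randomization import RandomizationConfig, randomization_score

__all__ = [
    "ParseError",
    "RunConfig",
    "read_angles",
    "read_traces",
    "read_counts",
    "read_tumors",
    "read_tracks",
    "write_annotations",
    "write_traces",
    "write_counts",
    "write_tumors",
    "write_tracks",
    "run_pipeline",
]


class ParseError(ValueError):
    """Malformed input file; message carries the file and row number."""


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")


def _row_err(path: str, idx: int, msg: str) -> ParseError:
    # +2: header line plus 1-based indexing
    return ParseError(f"{path}, row {idx + 2}: {msg}")


def read_traces(path: str | Path) -> dict[str, BasementMembraneTrace]:
    """Trace CSV: trace_id, point_index, x, y (µm)."""
    df = pd.read_csv(path)
    _require_columns(df, ["trace_id", "point_index", "x", "y"], str(path))
    traces = {}
    for tid, grp in df.groupby("trace_id", sort=False):
        grp = grp.sort_values("point_index")
        try:
            traces[str(tid)] = BasementMembraneTrace(
                points=tuple(zip(grp["x"].astype(float), grp["y"].astype(float)))
            )
        except ValueError as e:
            raise ParseError(f"{path}: trace {tid}: {e}") from e
    return traces


def read_angles(
    path: str | Path, traces: dict[str, BasementMembraneTrace] | None = None
) -> list[PoleAnnotation]:
    """Angle annotation CSV: division_id, condition, mouse_id, ax, ay, bx, by,
    and either ref_dx/ref_dy or trace_id."""
    df = pd.read_csv(path)
    _require_columns(df, ["division_id", "condition", "mouse_id", "ax", "ay", "bx", "by"], str(path))
    has_ref = "ref_dx" in df.columns and "ref_dy" in df.columns
    has_trace = "trace_id" in df.columns
    out = []
    for idx, row in df.iterrows():
        ref = None
        trace = None
        if has_ref and pd.notna(row.get("ref_dx")) and pd.notna(row.get("ref_dy")):
            ref = (float(row["ref_dx"]), float(row["ref_dy"]))
        elif has_trace and pd.notna(row.get("trace_id")):
            tid = str(row["trace_id"])
            if traces is None or tid not in traces:
                raise _row_err(str(path), idx, f"unknown trace_id {tid!r}")
            trace = traces[tid]
        else:
            raise _row_err(str(path), idx, "no reference direction or trace_id")
        try:
            out.append(
                PoleAnnotation(
                    division_id=str(row["division_id"]),
                    pole_a=(float(row["ax"]), float(row["ay"])),
                    pole_b=(float(row["bx"]), float(row["by"])),
                    reference=ref,
                    trace=trace,
                    condition=str(row["condition"]),
                    mouse_id=str(row["mouse_id"]),
                )
            )
        except ValueError as e:
            raise _row_err(str(path), idx, str(e)) from e
    return out


def read_counts(
    counts_path: str | Path, geometry_path: str | Path
) -> list[SectionCounts]:
    """Counts CSV (section_id, condition, mouse_id, layer, marker_class, count)
    joined with a geometry CSV (section_id, bm_length_um, tissue_span_um)."""
    cdf = pd.read_csv(counts_path)
    gdf = pd.read_csv(geometry_path)
    _require_columns(
        cdf, ["section_id", "condition", "mouse_id", "layer", "marker_class", "count"],
        str(counts_path),
    )
    _require_columns(gdf, ["section_id", "bm_length_um", "tissue_span_um"], str(geometry_path))
    geom = gdf.set_index(gdf["section_id"].astype(str))
    out = []
    for sid, grp in cdf.groupby("section_id", sort=False):
        sid = str(sid)
        if sid not in geom.index:
            raise ParseError(f"{counts_path}: section {sid} missing from geometry table")
        counts: dict[tuple[str, str], int] = {}
        for idx, row in grp.iterrows():
            c = row["count"]
            if c < 0 or c != int(c):
                raise _row_err(str(counts_path), idx, f"invalid count {c}")
            counts[(str(row["layer"]), str(row["marker_class"]))] = int(c)
        try:
            out.append(
                SectionCounts(
                    section_id=sid,
                    condition=str(grp["condition"].iloc[0]),
                    mouse_id=str(grp["mouse_id"].iloc[0]),
                    bm_length=float(geom.loc[sid, "bm_length_um"]),
                    tissue_span=float(geom.loc[sid, "tissue_span_um"]),
                    counts=counts,
                )
            )
        except ValueError as e:
            raise ParseError(f"{counts_path}: section {sid}: {e}") from e
    return out


def read_tumors(path: str | Path) -> list[TumorRecord]:
    """Tumor CSV: mouse_id, genotype, site, tumor_index, volume_mm3,
    eyelids_affected.  One row per tumor; tumor-free mice have a single row
    with empty tumor_index/volume."""
    df = pd.read_csv(path)
    _require_columns(df, ["mouse_id", "genotype", "site", "tumor_index", "volume_mm3"], str(path))
    out = []
    for (mid, gt, site), grp in df.groupby(["mouse_id", "genotype", "site"], sort=False):
        vols = []
        for idx, row in grp.iterrows():
            if pd.notna(row["volume_mm3"]):
                v = float(row["volume_mm3"])
                if v < 0:
                    raise _row_err(str(path), idx, f"negative volume {v}")
                vols.append(v)
        eyelids = None
        if "eyelids_affected" in grp.columns and pd.notna(grp["eyelids_affected"].iloc[0]):
            eyelids = int(grp["eyelids_affected"].iloc[0])
        try:
            out.append(
                TumorRecord(
                    mouse_id=str(mid), genotype=str(gt), site=str(site),
                    volumes=tuple(vols), eyelids_affected=eyelids,
                )
            )
        except ValueError as e:
            raise ParseError(f"{path}: mouse {mid}: {e}") from e
    return out


def read_tracks(
    angles_path: str | Path, frames_path: str | Path
) -> list[DivisionTrack]:
    """Live tracks: per-division CSV (division_id, condition, angle_t0,
    angle_t60) plus long-format frames CSV (division_id, daughter_id, frame,
    layer)."""
    adf = pd.read_csv(angles_path)
    fdf = pd.read_csv(frames_path)
    _require_columns(adf, ["division_id", "angle_t0"], str(angles_path))
    _require_columns(fdf, ["division_id", "daughter_id", "frame", "layer"], str(frames_path))
    frames_by_div: dict[str, dict[str, dict[int, str]]] = {}
    for idx, row in fdf.iterrows():
        layer = str(row["layer"])
        if layer not in ("basal", "suprabasal"):
            raise _row_err(str(frames_path), idx, f"unknown layer {layer!r}")
        frames_by_div.setdefault(str(row["division_id"]), {}).setdefault(
            str(row["daughter_id"]), {}
        )[int(row["frame"])] = layer
    out = []
    for idx, row in adf.iterrows():
        did = str(row["division_id"])
        layers = {}
        for daughter, fr in frames_by_div.get(did, {}).items():
            n = max(fr) + 1
            if set(fr) != set(range(n)):
                raise ParseError(
                    f"{frames_path}: division {did} daughter {daughter}: "
                    "frames not contiguous from 0"
                )
            layers[daughter] = tuple(fr[i] for i in range(n))
        t60 = float(row["angle_t60"]) if "angle_t60" in adf.columns and pd.notna(row.get("angle_t60")) else None
        try:
            out.append(
                DivisionTrack(
                    division_id=did,
                    angle_t0=float(row["angle_t0"]),
                    angle_t60=t60,
                    daughter_layers=layers,
                    condition=str(row["condition"]) if "condition" in adf.columns else "",
                )
            )
        except ValueError as e:
            raise _row_err(str(angles_path), idx, str(e)) from e
    return out


# -- writers (inverse dialects of the readers) -------------------------------

def write_traces(traces: dict[str, BasementMembraneTrace], path: str | Path) -> None:
    rows = [
        {"trace_id": tid, "point_index": i, "x": x, "y": y}
        for tid, tr in traces.items()
        for i, (x, y) in enumerate(tr.points)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_annotations(anns: Iterable[PoleAnnotation], path: str | Path,
                      trace_ids: dict[str, str] | None = None) -> None:
    rows = []
    for a in anns:
        row: dict[str, Any] = {
            "division_id": a.division_id, "condition": a.condition,
            "mouse_id": a.mouse_id,
            "ax": a.pole_a[0], "ay": a.pole_a[1],
            "bx": a.pole_b[0], "by": a.pole_b[1],
        }
        if a.reference is not None:
            row["ref_dx"], row["ref_dy"] = a.reference
        elif trace_ids is not None:
            row["trace_id"] = trace_ids[a.division_id]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_counts(sections: Iterable[SectionCounts], counts_path: str | Path,
                 geometry_path: str | Path) -> None:
    crows, grows = [], []
    for s in sections:
        grows.append({"section_id": s.section_id, "bm_length_um": s.bm_length,
                      "tissue_span_um": s.tissue_span})
        for (layer, marker), c in s.counts.items():
            crows.append({"section_id": s.section_id, "condition": s.condition,
                          "mouse_id": s.mouse_id, "layer": layer,
                          "marker_class": marker, "count": c})
    pd.DataFrame(crows).to_csv(counts_path, index=False)
    pd.DataFrame(grows).to_csv(geometry_path, index=False)


def write_tumors(records: Iterable[TumorRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        if r.volumes:
            for i, v in enumerate(r.volumes):
                rows.append({"mouse_id": r.mouse_id, "genotype": r.genotype,
                             "site": r.site, "tumor_index": i, "volume_mm3": v,
                             "eyelids_affected": r.eyelids_affected})
        else:
            rows.append({"mouse_id": r.mouse_id, "genotype": r.genotype,
                         "site": r.site, "tumor_index": None, "volume_mm3": None,
                         "eyelids_affected": r.eyelids_affected})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_tracks(tracks: Iterable[DivisionTrack], angles_path: str | Path,
                 frames_path: str | Path) -> None:
    arows, frows = [], []
    for t in tracks:
        arows.append({"division_id": t.division_id, "condition": t.condition,
                      "angle_t0": t.angle_t0, "angle_t60": t.angle_t60})
        for daughter, layers in t.daughter_layers.items():
            for f, layer in enumerate(layers):
                frows.append({"division_id": t.division_id, "daughter_id": daughter,
                              "frame": f, "layer": layer})
    pd.DataFrame(arows).to_csv(angles_path, index=False)
    pd.DataFrame(frows).to_csv(frames_path, index=False)


# -- pipeline ----------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run over annotation tables."""

    out_dir: str = "results"
    seed: int = 0
    angles_path: str | None = None
    traces_path: str | None = None
    counts_path: str | None = None
    geometry_path: str | None = None
    tumors_path: str | None = None
    track_angles_path: str | None = None
    track_frames_path: str | None = None
    n_reps: int = 100_000
    alpha_levels: tuple[float, ...] = (0.05, 0.01)
    ks_mode: str = "asymp"
    planar_threshold: float = 20.0
    reintegration_window_h: float = 6.0

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _summary_to_dict(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _summary_to_dict(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _summary_to_dict(v) for k, v in obj.items()}
    return obj


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Run every applicable stage and write a result bundle under cfg.out_dir.

    Stages with no configured input are skipped with a notice in the
    manifest rather than an error.  Returns the manifest dict; per-stage
    JSON/CSV files are written alongside it.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "stages": {},
        "notices": [],
    }

    if cfg.angles_path:
        traces = read_traces(cfg.traces_path) if cfg.traces_path else None
        anns = read_angles(cfg.angles_path, traces)
        rows = []
        for a in anns:
            ang = spindle_angle(a)
            rows.append({"division_id": a.division_id, "condition": a.condition,
                         "mouse_id": a.mouse_id, "angle_deg": ang,
                         "orientation": bin_angle(ang)})
        df = pd.DataFrame(rows)
        df.to_csv(out / "angles.csv", index=False)
        bins, scores = {}, {}
        for cond, grp in df.groupby("condition", sort=False):
            sample = AngleSample(condition=str(cond), angles=tuple(grp["angle_deg"]))
            bins[str(cond)] = _summary_to_dict(distribution_summary(sample))
            res = randomization_score(
                sample,
                RandomizationConfig(
                    n_reps=cfg.n_reps, alpha_levels=cfg.alpha_levels,
                    seed=cfg.seed, ks_mode=cfg.ks_mode,  # type: ignore[arg-type]
                ),
            )
            scores[str(cond)] = _summary_to_dict(res)
        (out / "bin_summaries.json").write_text(json.dumps(bins, indent=2))
        (out / "randomization_scores.json").write_text(json.dumps(scores, indent=2))
        manifest["stages"]["angles"] = {"n_divisions": len(df), "conditions": sorted(bins)}
    else:
        manifest["notices"].append("angles stage skipped: no input configured")

    if cfg.counts_path and cfg.geometry_path:
        sections = read_counts(cfg.counts_path, cfg.geometry_path)
        animals = summarize_animals(sections)
        conds = condition_means(animals)
        (out / "morphometry.json").write_text(json.dumps({
            "per_animal": {f"{c}/{m}": _summary_to_dict(s) for (c, m), s in animals.items()},
            "per_condition": {c: _summary_to_dict(s) for c, s in conds.items()},
            "aggregation": "mean of per-animal values (animal = unit of replication)",
        }, indent=2))
        manifest["stages"]["morphometry"] = {"n_sections": len(sections),
                                             "n_animals": len(animals)}
    else:
        manifest["notices"].append("morphometry stage skipped: no input configured")

    if cfg.tumors_path:
        records = read_tumors(cfg.tumors_path)
        summary: dict[str, Any] = {}
        for gt in sorted({r.genotype for r in records}):
            grp = [r for r in records if r.genotype == gt]
            for site in sorted({r.site for r in grp}):
                summary[f"{gt}/{site}"] = _summary_to_dict(summarize_cohort(grp, site))
        (out / "cohorts.json").write_text(json.dumps(summary, indent=2))
        manifest["stages"]["tumors"] = {"n_mice": len({r.mouse_id for r in records})}
    else:
        manifest["notices"].append("tumors stage skipped: no input configured")

    if cfg.track_angles_path and cfg.track_frames_path:
        tracks = read_tracks(cfg.track_angles_path, cfg.track_frames_path)
        rows = []
        for t in tracks:
            res = t0_t60_resolution(t, cfg.planar_threshold)
            reint = None
            if any(v and v[0] == "suprabasal" for v in t.daughter_layers.values()):
                reint = classify_reintegration(t, cfg.reintegration_window_h)
            rows.append({"division_id": t.division_id, "condition": t.condition,
                         "angle_t0": t.angle_t0, "angle_t60": t.angle_t60,
                         "resolution": res, "reintegration": reint})
        pd.DataFrame(rows).to_csv(out / "track_classes.csv", index=False)
        manifest["stages"]["tracks"] = {"n_tracks": len(tracks)}
    else:
        manifest["notices"].append("tracks stage skipped: no input configured")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
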