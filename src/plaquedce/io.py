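"""File I/O: NIfTI dynamic series with JSON protocol sidecars, contour and
cohort CSVs, roster CSVs, V-V PNGs, and JSON/text study reports."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AcquisitionProtocol, ScanRecord
from .kinetics import DCESeries, KineticMap
from .repro import COHORT_COLUMNS, SchemaError, validate_cohort

__all__ = [
    "write_series", "read_series",
    "write_cohort_csv", "read_cohort_csv",
    "write_contours_csv", "read_contours_csv",
    "write_roster_csv", "read_roster_csv",
    "write_kinetic_map", "write_vv_png",
    "write_report",
]


# --------------------------------------------------------------------------
# dynamic series (NIfTI + JSON sidecar)

def write_series(series: DCESeries, path: str | Path) -> Path:
    """Write a 4D series as NIfTI (x, y, z, t axis order) with the
    acquisition protocol in a ``.json`` sidecar next to it."""
    import nibabel as nib

    path = Path(path)
    proto = series.protocol
    # internal (slices, rows, cols, frames) -> NIfTI (cols, rows, slices, frames)
    vol = np.transpose(series.data, (2, 1, 0, 3)).astype(np.float32)
    affine = np.diag([proto.pixel_size, proto.pixel_size, proto.slice_thickness, 1.0])
    img = nib.Nifti1Image(vol, affine)
    img.header.set_zooms((proto.pixel_size, proto.pixel_size,
                          proto.slice_thickness, proto.frame_interval))
    nib.save(img, str(path))
    sidecar = path.with_suffix("").with_suffix(".json") if path.suffix == ".gz" \
        else path.with_suffix(".json")
    sidecar.write_text(json.dumps(dataclasses.asdict(proto), indent=2))
    return path


def read_series(path: str | Path) -> DCESeries:
    import nibabel as nib

    path = Path(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"protocol sidecar not found: {sidecar}")
    proto = AcquisitionProtocol(**json.loads(sidecar.read_text()))
    vol = np.asanyarray(nib.load(str(path)).dataobj, dtype=float)
    data = np.transpose(vol, (2, 1, 0, 3))
    return DCESeries(data=data, protocol=proto)


# --------------------------------------------------------------------------
# cohort tables

def write_cohort_csv(table: pd.DataFrame, path: str | Path) -> Path:
    validate_cohort(table, require_areas="area1" in table.columns)
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def read_cohort_csv(path: str | Path, require_areas: bool = False) -> pd.DataFrame:
    table = pd.read_csv(path)
    return validate_cohort(table, require_areas=require_areas)


# --------------------------------------------------------------------------
# contours

def write_contours_csv(contours: dict[str, np.ndarray], path: str | Path) -> Path:
    """Write named polygons as CSV rows (contour, vertex, x_mm, y_mm)."""
    rows = []
    for name, poly in contours.items():
        poly = np.asarray(poly, dtype=float)
        for i, (x, y) in enumerate(poly):
            rows.append({"contour": name, "vertex": i, "x_mm": x, "y_mm": y})
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_contours_csv(path: str | Path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path)
    for col in ("contour", "vertex", "x_mm", "y_mm"):
        if col not in df.columns:
            raise SchemaError(f"contour table is missing required column {col!r}")
    out = {}
    for name, grp in df.groupby("contour"):
        grp = grp.sort_values("vertex")
        out[str(name)] = grp[["x_mm", "y_mm"]].to_numpy(float)
    return out


# --------------------------------------------------------------------------
# roster

_ROSTER_COLUMNS = ("subject_id", "scan_index", "vendor", "site_id",
                   "frame_interval_actual", "n_frames_actual",
                   "contrast_injected", "slab_centered_on_bifurcation",
                   "quality_score")


def write_roster_csv(roster: list[ScanRecord], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame([dataclasses.asdict(r) for r in roster]).to_csv(path, index=False)
    return path


def read_roster_csv(path: str | Path) -> list[ScanRecord]:
    df = pd.read_csv(path)
    for col in _ROSTER_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"roster table is missing required column {col!r}")
    return [ScanRecord(subject_id=str(r.subject_id), scan_index=int(r.scan_index),
                       vendor=str(r.vendor), site_id=str(r.site_id),
                       frame_interval_actual=float(r.frame_interval_actual),
                       n_frames_actual=int(r.n_frames_actual),
                       contrast_injected=bool(r.contrast_injected),
                       slab_centered_on_bifurcation=bool(r.slab_centered_on_bifurcation),
                       quality_score=int(r.quality_score))
            for r in df.itertuples()]


# --------------------------------------------------------------------------
# kinetic maps and rendered images

def write_kinetic_map(kmap: KineticMap, path: str | Path,
                      pixel_size: float = 0.625) -> Path:
    """Write Ktrans/vp maps as a two-volume NIfTI (last axis: 0 = Ktrans,
    1 = vp)."""
    import nibabel as nib

    path = Path(path)
    kt = np.atleast_3d(kmap.ktrans)
    vp = np.atleast_3d(kmap.vp)
    stack = np.stack([kt, vp], axis=-1)  # (slices, rows, cols, 2)
    vol = np.transpose(stack, (2, 1, 0, 3)).astype(np.float32)
    img = nib.Nifti1Image(vol, np.diag([pixel_size, pixel_size, 1.0, 1.0]))
    nib.save(img, str(path))
    return path


def write_vv_png(image: np.ndarray, path: str | Path) -> Path:
    from PIL import Image

    path = Path(path)
    arr = (np.clip(image, 0.0, 1.0) * 255).astype(np.uint8)
    Image.fromarray(arr).save(path)
    return path


# --------------------------------------------------------------------------
# study report

def _table3_block(report_dict: dict) -> str:
    """Format the per-parameter reproducibility block as a fixed-width text
    table with All / GE / Philips rows."""
    lines = []
    for param, block in report_dict.get("parameters", {}).items():
        lines.append(f"{param}")
        lines.append(f"  {'':8s}{'Mean':>8s}{'SD':>8s}{'CV':>8s}  95% CI (CV)")
        for row_name in ("All", "GE", "Philips"):
            row = block.get(row_name)
            if row is None:
                continue
            ci = row.get("ci_cv")
            ci_txt = f"({ci[0]:.0%}-{ci[1]:.0%})" if ci else ""
            lines.append(f"  {row_name:8s}{row['mean']:8.3f}{row['sd']:8.3f}"
                         f"{row['cv']:8.0%}  {ci_txt}")
        if "p_mean" in block:
            lines.append(f"  p (mean GE vs Philips) = {block['p_mean']:.2g}; "
                         f"p (SD) = {block['p_sd']:.2g}")
        lines.append("")
    return "\n".join(lines)


def write_report(report, out_dir: str | Path) -> tuple[Path, Path]:
    """Write a study report as ``report.json`` plus a readable
    ``report.txt`` summary; returns both paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    d = report if isinstance(report, dict) else report.to_dict()
    json_path = out_dir / "report.json"
    json_path.write_text(json.dumps(d, indent=2, default=_json_default))

    casc = d.get("exclusion_cascade", {})
    txt = [
        "DCE-CMR scan-rescan reproducibility study report",
        "=" * 48,
        (f"Enrolled {casc.get('enrolled', '?')}; protocol-excluded "
         f"{casc.get('excluded_protocol', '?')}; quality-excluded "
         f"{casc.get('excluded_quality', '?')}; analyzed "
         f"{casc.get('analyzed', '?')}"),
        "",
        _table3_block(d),
    ]
    if "power_table" in d:
        txt.append("Sample size per arm (pct_diff -> n):")
        for row in d["power_table"]:
            txt.append(f"  {row['parameter']:10s} {row['pct_diff']:.0%} -> "
                       f"{row['n_per_arm']}")
    txt_path = out_dir / "report.txt"
    txt_path.write_text("\n".join(txt) + "\n")
    return json_path, txt_path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
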