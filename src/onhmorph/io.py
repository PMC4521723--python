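"""Reading and writing the pipeline's file formats.

Markup comes in as one JSON file per eye/time-point; pores as a GeoJSON-
style polygon list or a binary mask image plus a similarity transform;
study series as long-format CSV. All coordinates in files are μm and
0-based (pixel inputs are converted via the per-file scale factors).
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import SimilarityTransform

from .longitudinal import StudySeries
from .pores import PoreAnnotation, PoreSet, pores_from_mask
from .types import BScanMarkup, MarkedONH, ONHParameters

__all__ = [
    "read_markup_json",
    "write_markup_json",
    "read_pore_annotations",
    "write_onh_csv",
    "write_pore_csv",
    "read_study_csv",
    "read_iop_csv",
]


def read_markup_json(path: str | Path) -> MarkedONH:
    data = json.loads(Path(path).read_text())
    bscans = [
        BScanMarkup(
            scan_angle_deg=float(b["angle_deg"]),
            bmo_points=np.asarray(b.get("bmo", []), dtype=float).reshape(-1, 3),
            alcs_points=np.asarray(b.get("alcs", []), dtype=float).reshape(-1, 3),
            ilm_polyline=np.asarray(b.get("ilm", []), dtype=float).reshape(-1, 2),
        )
        for b in data["bscans"]
    ]
    return MarkedONH(
        eye_id=str(data["eye_id"]),
        day=int(data["day"]),
        bscans=bscans,
        lateral_scale=float(data.get("lateral_scale_um_per_px", 1.0)),
        axial_scale=float(data.get("axial_scale_um_per_px", 1.0)),
    )


def write_markup_json(marked: MarkedONH, path: str | Path) -> None:
    data = {
        "eye_id": marked.eye_id,
        "day": marked.day,
        "lateral_scale_um_per_px": marked.lateral_scale,
        "axial_scale_um_per_px": marked.axial_scale,
        "bscans": [
            {
                "angle_deg": b.scan_angle_deg,
                "bmo": np.round(b.bmo_points, 4).tolist(),
                "alcs": np.round(b.alcs_points, 4).tolist(),
                "ilm": np.round(b.ilm_polyline, 4).tolist(),
            }
            for b in marked.bscans
        ],
    }
    Path(path).write_text(json.dumps(data))


def read_pore_annotations(path: str | Path) -> list[PoreAnnotation]:
    """Load pores from a polygon JSON or a mask image (PNG/TIFF).

    The JSON form is ``{"registration": {"scale":, "rotation":,
    "translation": [tx, ty]} | null, "pores": [{"id":, "polygon": [[x, y],
    ...]}, ...]}``; the mask form needs a sibling ``<stem>.transform.json``
    with the registration when one applies.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        reg = _registration(data.get("registration"))
        return [
            PoreAnnotation(pore_id=str(p.get("id", i)),
                           polygon_2d=np.asarray(p["polygon"], dtype=float),
                           registration=reg)
            for i, p in enumerate(data["pores"])
        ]
    import imageio.v3 as iio

    mask = iio.imread(path)
    reg = None
    sidecar = path.with_suffix(".transform.json")
    if sidecar.exists():
        reg = _registration(json.loads(sidecar.read_text()))
    return pores_from_mask(mask, registration=reg)


def _registration(spec: dict | None) -> SimilarityTransform | None:
    if not spec:
        return None
    return SimilarityTransform(
        scale=float(spec.get("scale", 1.0)),
        rotation=float(spec.get("rotation", 0.0)),
        translation=tuple(spec.get("translation", (0.0, 0.0))),
    )


def write_onh_csv(rows: list[tuple[str, int, ONHParameters]], path: str | Path) -> None:
    """One CSV row per eye/time-point; a flat RoC is written as ``flat``."""
    df = pd.DataFrame(
        {
            "eye_id": [eye for eye, _, _ in rows],
            "day": [day for _, day, _ in rows],
            "alcsd_um": [p.alcsd for _, _, p in rows],
            "roc_mm": ["flat" if p.roc_is_flat else p.roc for _, _, p in rows],
            "mrw_um": [p.mrw for _, _, p in rows],
            "rnflt_um": [p.rnflt if p.rnflt is not None else math.nan for _, _, p in rows],
            "n_bscans": [p.n_bscans for _, _, p in rows],
            "extrapolation_flag": [p.extrapolation_flag for _, _, p in rows],
        }
    )
    df.to_csv(path, index=False, float_format="%.6g")


def write_pore_csv(poreset: PoreSet, path: str | Path) -> None:
    poreset.to_frame().to_csv(path, index=False, float_format="%.6g")


def read_study_csv(path: str | Path) -> list[StudySeries]:
    """Long-format study CSV: eye_id, role, day, parameter, value."""
    df = pd.read_csv(path)
    series = []
    for (eye_id, role), sub in df.groupby(["eye_id", "role"], sort=True):
        wide = sub.pivot_table(index="day", columns="parameter", values="value")
        series.append(
            StudySeries(
                eye_id=str(eye_id),
                role=str(role),
                days=wide.index.to_numpy(dtype=float),
                values={c: wide[c].to_numpy(dtype=float) for c in wide.columns},
            )
        )
    return series


def read_iop_csv(path: str | Path) -> dict[str, pd.DataFrame]:
    """IOP CSV (eye_id, day, iop_mmhg) -> per-eye frames sorted by day."""
    df = pd.read_csv(path)
    return {str(eye): sub.sort_values("day").reset_index(drop=True)
            for eye, sub in df.groupby("eye_id")}
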