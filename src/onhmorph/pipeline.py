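"""Study-level orchestration: geometry → pores → statistics → onsets.

A study lives in one directory:

* ``eyes/*.json`` — markup per eye/time-point (see :mod:`onhmorph.io`),
* ``pores/<eye>_<day>.json`` — pore polygon annotations (optional),
* ``study.csv`` / ``iop.csv`` — longitudinal parameter and IOP series,
* ``config.yaml`` — thresholds and analysis options.

``run_pipeline`` writes per-time-point ONH parameters, per-pore metrics,
an onset table with dense-rank positions, KM/log-rank JSON and a run
manifest. All randomness flows from the config seed; reruns with the same
inputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geometry import fit_onh
from .io import read_markup_json, read_pore_annotations, write_onh_csv
from .longitudinal import (
    OnsetRecord,
    StudySeries,
    confidence_interval,
    cumulative_iop_difference,
    detect_first_change,
    km_logrank,
    onset_positions,
    pooled_interval,
    round_half_up,
)
from .pores import PoreSet, assign_partitions, compute_pore_metrics, lift_pores, summarize_pores

log = logging.getLogger(__name__)

__all__ = ["StudyConfig", "PipelineError", "ValidationError", "run_pipeline", "write_report"]


class PipelineError(RuntimeError):
    pass


class ValidationError(PipelineError):
    pass


@dataclass
class StudyConfig:
    input_dir: str = "."
    output_dir: str = "out"
    grid_n: int = 128
    tps_lambda: float = 0.0
    roc_flat_threshold_mm: float = 50.0
    roc_method: str = "sphere"
    ci_style: str = "sd"  # control-eye interval: 'sd' (tolerance) or 'se'
    moran_weights: str = "inverse_distance"
    n_perm: int = 999
    seed: int = 0
    alpha: float = 0.05
    bin_objective: str = "min_gap"
    round_decimals: int = 1
    laterality: dict = field(default_factory=dict)  # eye_id -> OD | OS

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must lie in (0, 1)")
        for name in ("grid_n", "roc_flat_threshold_mm", "n_perm"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _fit_all_eyes(cfg: StudyConfig, eyes_dir: Path):
    fitted = {}
    rows = []
    for path in sorted(eyes_dir.glob("*.json")):
        try:
            marked = read_markup_json(path)
        except (KeyError, ValueError, json.JSONDecodeError) as exc:
            raise ValidationError(f"{path.name}: invalid markup ({exc})") from exc
        res = fit_onh(marked, lam=cfg.tps_lambda, grid_n=cfg.grid_n,
                      flat_threshold_mm=cfg.roc_flat_threshold_mm,
                      roc_method=cfg.roc_method)
        fitted[(marked.eye_id, marked.day)] = res
        rows.append((marked.eye_id, marked.day, res.params))
        log.info("fit %s day %d: ALCSD %.1f μm, MRW %.1f μm", marked.eye_id,
                 marked.day, res.params.alcsd, res.params.mrw)
    return fitted, rows


def _pore_sets(cfg: StudyConfig, pores_dir: Path, fitted) -> list[PoreSet]:
    sets = []
    for path in sorted(pores_dir.glob("*.json")):
        eye_id, day_s = path.stem.rsplit("_", 1)
        key = (eye_id, int(day_s))
        if key not in fitted:
            raise ValidationError(f"{path.name}: no fitted geometry for {key}")
        res = fitted[key]
        annotations = read_pore_annotations(path)
        lifted = lift_pores(annotations, res.surface)
        metrics = compute_pore_metrics(lifted)
        assign_partitions(metrics, res.ellipse,
                          laterality=cfg.laterality.get(eye_id, "OD"))
        sets.append(PoreSet(eye_id=eye_id, day=int(day_s), pores=metrics))
    return sets


def _onsets(cfg: StudyConfig, series: list[StudySeries]) -> list[OnsetRecord]:
    controls = [s for s in series if s.role == "control"]
    egs = [s for s in series if s.role == "EG"]
    records: list[OnsetRecord] = []
    for eg in egs:
        animal = eg.eye_id.rsplit("-", 1)[0]
        fellow = next((c for c in controls if c.eye_id.startswith(animal)), None)
        for param, vals in eg.values.items():
            if fellow is not None and param in fellow.values \
                    and np.isfinite(fellow.values[param]).sum() >= 3:
                interval = confidence_interval(fellow.values[param], ci_style=cfg.ci_style)
            else:
                others = [c.values[param] for c in controls
                          if param in c.values and c is not fellow]
                if not others:
                    continue
                interval = pooled_interval(others, ci_style=cfg.ci_style)
                log.warning("%s/%s: no usable fellow control, pooled interval used",
                            eg.eye_id, param)
            records.append(detect_first_change(eg.days, vals, interval,
                                               eye_id=eg.eye_id, parameter=param))
    return records


def run_pipeline(config: StudyConfig) -> dict:
    """Run every available stage for a study directory; returns the output
    paths and key frames."""
    in_dir = Path(config.input_dir)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict = {"output_dir": str(out_dir)}

    eyes_dir = in_dir / "eyes"
    fitted = {}
    if eyes_dir.is_dir():
        fitted, rows = _fit_all_eyes(config, eyes_dir)
        write_onh_csv(rows, out_dir / "onh_parameters.csv")
        outputs["onh_parameters"] = str(out_dir / "onh_parameters.csv")

    pores_dir = in_dir / "pores"
    pore_sets: list[PoreSet] = []
    if pores_dir.is_dir() and fitted:
        pore_sets = _pore_sets(config, pores_dir, fitted)
        frames = [ps.to_frame().assign(eye_id=ps.eye_id) for ps in pore_sets]
        if frames:
            pd.concat(frames).to_csv(out_dir / "pores.csv", index=False,
                                     float_format="%.6g")
            outputs["pores"] = str(out_dir / "pores.csv")
            summaries = [summarize_pores(ps, grouping=g).assign(eye_id=ps.eye_id, day=ps.day)
                         for ps in pore_sets for g in ("global", "region", "sector")]
            pd.concat(summaries).to_csv(out_dir / "pore_summaries.csv", index=False,
                                        float_format="%.6g")
            outputs["pore_summaries"] = str(out_dir / "pore_summaries.csv")

    study_csv = in_dir / "study.csv"
    if study_csv.exists():
        from .io import read_iop_csv, read_study_csv

        series = read_study_csv(study_csv)
        records = _onsets(config, series)
        table = onset_positions(records)
        onset_rows = pd.DataFrame(
            {
                "eye_id": [r.eye_id for r in records],
                "parameter": [r.parameter for r in records],
                "onset_day": [r.onset_day for r in records],
                "censored": [r.censored for r in records],
                "direction": [r.direction for r in records],
                "position": [r.position for r in records],
            }
        )
        onset_rows.to_csv(out_dir / "onsets.csv", index=False)
        table.to_csv(out_dir / "onset_positions.csv", index=False, float_format="%.6g")
        outputs["onsets"] = str(out_dir / "onsets.csv")
        outputs["onset_positions"] = str(out_dir / "onset_positions.csv")
        outputs["onset_records"] = records

        params_present = {r.parameter for r in records}
        if len(params_present) >= 2 and len({r.eye_id for r in records}) >= 2:
            surv = km_logrank(records)
            km_json = {
                "pairwise": surv.pairwise.to_dict(orient="records"),
                "curves": {p: df.to_dict(orient="list") for p, df in surv.curves.items()},
                "warnings": surv.warnings,
            }
            (out_dir / "km_logrank.json").write_text(json.dumps(km_json, indent=1))
            outputs["km_logrank"] = str(out_dir / "km_logrank.json")

        iop_csv = in_dir / "iop.csv"
        if iop_csv.exists():
            iop = read_iop_csv(iop_csv)
            diffs = []
            for eg in (s for s in series if s.role == "EG"):
                animal = eg.eye_id.rsplit("-", 1)[0]
                ctl_id = next((k for k in iop if k.startswith(animal) and k != eg.eye_id), None)
                if eg.eye_id not in iop or ctl_id is None:
                    continue
                e, c = iop[eg.eye_id], iop[ctl_id]
                e, c = e[e["day"] >= 0], c[c["day"] >= 0]
                d = cumulative_iop_difference(e["day"], e["iop_mmhg"], c["day"], c["iop_mmhg"])
                d["eye_id"] = eg.eye_id
                diffs.append(d)
            if diffs:
                pd.concat(diffs).to_csv(out_dir / "cumulative_iop.csv", index=False,
                                        float_format="%.6g")
                outputs["cumulative_iop"] = str(out_dir / "cumulative_iop.csv")

    manifest = {
        "package": "onhmorph",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": config.digest(),
        "config": dataclasses.asdict(config),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    outputs["manifest"] = str(out_dir / "manifest.json")
    return outputs


# --------------------------------------------------------------------------
# report
# --------------------------------------------------------------------------

def _fmt(x, decimals: int) -> str:
    if x is None or (isinstance(x, float) and not math.isfinite(x)):
        return "—"
    return f"{round_half_up(float(x), decimals):.{decimals}f}"


def write_report(outputs: dict, path: str | Path, decimals: int = 1) -> str:
    """Human-readable summary with table-style rounding (half-up, one
    decimal by default); censored/absent cells render as an em dash."""
    lines = ["# Study report", ""]
    out_dir = Path(outputs["output_dir"])

    onh = out_dir / "onh_parameters.csv"
    if onh.exists():
        df = pd.read_csv(onh)
        lines += ["## ONH parameters", ""]
        for _, r in df.iterrows():
            roc = r["roc_mm"]
            roc_s = "flat" if str(roc) == "flat" else _fmt(float(roc), decimals)
            lines.append(
                f"- {r['eye_id']} day {int(r['day'])}: ALCSD {_fmt(r['alcsd_um'], decimals)} μm, "
                f"RoC {roc_s} mm, MRW {_fmt(r['mrw_um'], decimals)} μm "
                f"({int(r['n_bscans'])} B-scans)"
            )
        lines.append("")

    onsets = out_dir / "onsets.csv"
    if onsets.exists():
        df = pd.read_csv(onsets)
        lines += ["## First-change onsets (day post-laser, dense-rank position)", ""]
        for eye, sub in df.groupby("eye_id"):
            cells = []
            for _, r in sub.iterrows():
                if bool(r["censored"]):
                    cells.append(f"{r['parameter']}: —")
                else:
                    cells.append(f"{r['parameter']}: {int(r['onset_day'])} ({int(r['position'])})")
            lines.append(f"- {eye}: " + ", ".join(cells))
        pos = out_dir / "onset_positions.csv"
        if pos.exists():
            dfp = pd.read_csv(pos)
            lines.append("")
            lines.append("Mean onset position: " + ", ".join(
                f"{r['parameter']} {_fmt(r['mean_position'], decimals)}"
                for _, r in dfp.iterrows()))
        lines.append("")

    summaries = out_dir / "pore_summaries.csv"
    if summaries.exists():
        df = pd.read_csv(summaries)
        lines += ["## Pore summaries (mean ± SD)", ""]
        for _, r in df.iterrows():
            if int(r["n"]) == 0:
                lines.append(f"- {r['eye_id']} day {int(r['day'])} {r['group']}: —")
            else:
                lines.append(
                    f"- {r['eye_id']} day {int(r['day'])} {r['group']} (n={int(r['n'])}): "
                    f"area {_fmt(r['area_um2_mean'], decimals)} ± {_fmt(r['area_um2_sd'], decimals)} μm², "
                    f"elongation {_fmt(r['elongation_mean'], 2)} ± {_fmt(r['elongation_sd'], 2)}, "
                    f"NND {_fmt(r['nnd_um_mean'], decimals)} ± {_fmt(r['nnd_um_sd'], decimals)} μm"
                )
        lines.append("")

    text = "\n".join(lines)
    Path(path).write_text(text)
    return text
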