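"""Dataset-level pipeline: discover sessions, run every per-session
analysis, and aggregate unit counts, selective-cell proportions,
behavior and quality summaries across sessions.

Region groups follow the dataset convention: MTL = hippocampus +
amygdala (where concept cells live), MFC = dACC + pre-SMA + vmPFC
(maintenance and probe cells).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import behavior as beh
from .fixture import load_fixture
from .model import (MFC_AREAS, MTL_AREAS, AnalysisConfig, SessionRecord,
                    validate_session)
from .nwb import load_nwb_session
from .quality import quality_frame, unit_quality_metrics
from .selection import classify_session

log = logging.getLogger("sternwm")


@dataclass
class SessionOutput:
    name: str
    task: str
    subject_id: str
    unit_areas: dict[int, str]
    classification: pd.DataFrame
    behavior: Optional[beh.BehaviorSummary]
    quality: pd.DataFrame


@dataclass
class DatasetSummary:
    n_sessions: int
    n_errors: int
    units_by_area: dict[str, int]
    units_by_task: dict[str, int]
    selective: dict[str, dict]  # counts/denominators/proportions
    behavior: Optional[pd.DataFrame]
    rm_anova: Optional[dict]
    quality_summary: Optional[pd.DataFrame]

    def to_dict(self) -> dict:
        out = {
            "n_sessions": self.n_sessions,
            "n_errors": self.n_errors,
            "units_by_area": self.units_by_area,
            "units_by_task": self.units_by_task,
            "selective": self.selective,
        }
        if self.behavior is not None:
            out["behavior"] = self.behavior.to_dict(orient="records")
        if self.rm_anova is not None:
            out["rm_anova"] = self.rm_anova
        if self.quality_summary is not None:
            out["quality_summary"] = self.quality_summary.to_dict(orient="records")
        return out


def discover_sessions(input_dir: str | Path) -> list[Path]:
    """Fixture directories (containing meta.yaml) and NWB/HDF5 files."""
    d = Path(input_dir)
    found: list[Path] = []
    if (d / "meta.yaml").exists():
        found.append(d)
    for child in sorted(d.iterdir()):
        if child.is_dir() and (child / "meta.yaml").exists():
            found.append(child)
        elif child.suffix in (".nwb", ".h5", ".hdf5"):
            found.append(child)
    return found


def load_any_session(path: Path) -> SessionRecord:
    if path.is_dir():
        return load_fixture(path)
    return load_nwb_session(path)


def classification_frame(results: dict) -> pd.DataFrame:
    rows = []
    for uid in sorted(results):
        r = results[uid]
        rows.append(dict(
            unit_id=r.unit_id, is_concept=r.is_concept,
            is_maintenance=r.is_maintenance, is_probe=r.is_probe,
            preferred_image=(-1 if r.preferred_image is None else r.preferred_image),
            anova_f=r.anova_f, anova_p=r.anova_p, maxvsrest_p=r.maxvsrest_p,
            maint_p=r.maint_p, maint_nonpref_p=r.maint_nonpref_p,
            probe_vs_enc_p=r.probe_vs_enc_p, probe_vs_maint_p=r.probe_vs_maint_p))
    return pd.DataFrame(rows)


def analyze_session(session: SessionRecord, config: AnalysisConfig,
                    name: str = "session") -> SessionOutput:
    violations = validate_session(session)
    if violations:
        raise ValueError(f"{name}: session invalid: {violations[0]}")
    area_by_electrode = {e.electrode_id: e.brain_area for e in session.electrodes}
    unit_areas = {u.unit_id: area_by_electrode[u.electrode_id]
                  for u in session.units}
    results = classify_session(session, config)
    summary = (beh.behavior_by_load(session.trials)
               if session.subject.task == "sternberg" else None)
    has_wf = any(u.waveforms is not None for u in session.units)
    qual = (quality_frame(unit_quality_metrics(session, config))
            if has_wf else pd.DataFrame())
    return SessionOutput(name=name, task=session.subject.task,
                         subject_id=session.subject.subject_id,
                         unit_areas=unit_areas,
                         classification=classification_frame(results),
                         behavior=summary, quality=qual)


def _proportion(count: int, denom: int) -> float:
    return 100.0 * count / denom if denom else 0.0


def summarize_dataset(outputs: list[SessionOutput],
                      n_errors: int = 0) -> DatasetSummary:
    """Aggregate per-session outputs; proportions carry their counts and
    denominators so they stay exactly count/denominator."""
    units_by_area: dict[str, int] = {}
    units_by_task: dict[str, int] = {}
    counts = {"concept_mtl": 0, "concept_mfc": 0, "maintenance_mfc": 0,
              "probe_mfc": 0, "concept": 0, "maintenance": 0, "probe": 0}
    denom = {"mtl": 0, "mfc": 0, "all": 0}
    behav_rows = []
    qual_frames = []
    for out in outputs:
        units_by_task[out.task] = units_by_task.get(out.task, 0) + len(out.unit_areas)
        for uid, area in out.unit_areas.items():
            units_by_area[area] = units_by_area.get(area, 0) + 1
        cls = out.classification
        if len(cls) == 0:
            continue
        areas = cls["unit_id"].map(out.unit_areas)
        in_mtl = areas.isin(MTL_AREAS)
        in_mfc = areas.isin(MFC_AREAS)
        denom["mtl"] += int(in_mtl.sum())
        denom["mfc"] += int(in_mfc.sum())
        denom["all"] += len(cls)
        counts["concept"] += int(cls["is_concept"].sum())
        counts["maintenance"] += int(cls["is_maintenance"].sum())
        counts["probe"] += int(cls["is_probe"].sum())
        counts["concept_mtl"] += int((cls["is_concept"] & in_mtl).sum())
        counts["concept_mfc"] += int((cls["is_concept"] & in_mfc).sum())
        counts["maintenance_mfc"] += int((cls["is_maintenance"] & in_mfc).sum())
        counts["probe_mfc"] += int((cls["is_probe"] & in_mfc).sum())
        if out.behavior is not None:
            df = out.behavior.to_frame()
            df.insert(0, "session", out.name)
            df.insert(1, "subject", out.subject_id)
            behav_rows.append(df)
        if len(out.quality):
            qual_frames.append(out.quality)

    selective = {
        "concept_mtl": dict(count=counts["concept_mtl"], denominator=denom["mtl"],
                            pct=_proportion(counts["concept_mtl"], denom["mtl"])),
        "concept_mfc": dict(count=counts["concept_mfc"], denominator=denom["mfc"],
                            pct=_proportion(counts["concept_mfc"], denom["mfc"])),
        "maintenance_mfc": dict(count=counts["maintenance_mfc"],
                                denominator=denom["mfc"],
                                pct=_proportion(counts["maintenance_mfc"], denom["mfc"])),
        "probe_mfc": dict(count=counts["probe_mfc"], denominator=denom["mfc"],
                          pct=_proportion(counts["probe_mfc"], denom["mfc"])),
        "concept_all": dict(count=counts["concept"], denominator=denom["all"],
                            pct=_proportion(counts["concept"], denom["all"])),
        "maintenance_all": dict(count=counts["maintenance"], denominator=denom["all"],
                                pct=_proportion(counts["maintenance"], denom["all"])),
        "probe_all": dict(count=counts["probe"], denominator=denom["all"],
                          pct=_proportion(counts["probe"], denom["all"])),
    }

    behav = pd.concat(behav_rows, ignore_index=True) if behav_rows else None
    rm = None
    sessions_with_behavior = [(o.subject_id, o.behavior) for o in outputs
                              if o.behavior is not None]
    if len({s for s, _b in sessions_with_behavior}) >= 2:
        table = beh.subject_median_rt_table(sessions_with_behavior)
        if not table.isna().any().any():
            res = beh.rm_anova_rt(table.to_numpy())
            rm = dict(F=res.F, df1=res.df1, df2=res.df2, p=res.p)

    qual_summary = None
    if qual_frames:
        q = pd.concat(qual_frames, ignore_index=True)
        rows = []
        for col in ("pct_isi_below", "mean_rate_hz", "cv2", "snr_peak",
                    "snr_mean", "mean_projection_distance", "isolation_distance"):
            vals = q[col].to_numpy(float)
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                continue
            rows.append(dict(metric=col, mean=float(vals.mean()),
                             sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                             median=float(np.median(vals)), n=int(vals.size)))
        qual_summary = pd.DataFrame(rows)

    return DatasetSummary(n_sessions=len(outputs), n_errors=n_errors,
                          units_by_area=units_by_area,
                          units_by_task=units_by_task, selective=selective,
                          behavior=behav, rm_anova=rm,
                          quality_summary=qual_summary)


def run_pipeline(input_dir: str | Path, out_dir: str | Path,
                 config: AnalysisConfig | None = None) -> DatasetSummary:
    """End-to-end: load every session in ``input_dir``, analyze it, write
    per-session CSVs and a dataset ``summary.json`` to ``out_dir``.

    Unreadable sessions are logged, skipped, and counted in the summary.
    """
    cfg = config or AnalysisConfig()
    paths = discover_sessions(input_dir)
    if not paths:
        raise ValueError(f"no sessions found in {input_dir}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: list[SessionOutput] = []
    n_errors = 0
    for path in paths:
        name = path.stem if path.is_file() else path.name
        try:
            session = load_any_session(path)
            log.info("analyzing %s (task=%s, %d units, seed=%d, n_perm=%d)",
                     name, session.subject.task, len(session.units),
                     cfg.rng_seed, cfg.n_perm)
            out = analyze_session(session, cfg, name=name)
        except Exception as exc:  # noqa: BLE001 - skip-and-count contract
            log.warning("skipping %s: %s", name, exc)
            n_errors += 1
            continue
        outputs.append(out)
        out.classification.to_csv(out_dir / f"{name}_classification.csv",
                                  index=False)
        if out.behavior is not None:
            out.behavior.to_frame().to_csv(out_dir / f"{name}_behavior.csv",
                                           index=False)
        if len(out.quality):
            out.quality.to_csv(out_dir / f"{name}_quality.csv", index=False)
    if not outputs:
        raise ValueError("every session failed to load or analyze")
    summary = summarize_dataset(outputs, n_errors=n_errors)
    (out_dir / "summary.json").write_text(
        json.dumps(summary.to_dict(), indent=2, sort_keys=True))
    return summary
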