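"""End-to-end orchestration: simulate, train, analyse, report.

``run_pipeline`` takes a :class:`RunConfig`, simulates a cohort, trains the
posture and sleep models, analyses every resident-day through all layers
(daily record, sleep record, pressure summary, norm comparison, wellbeing
indices and rating), fits the living-pattern model, and writes plain tabular
reports plus a manifest into one output directory. Runs are deterministic
under a fixed config: re-running yields byte-identical tabular outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from datetime import date as _date, timedelta
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alerts import FallRiskConfig, detect_bed_exit
from .dashboard import index_levels, overall_rating, summary_table
from .frames import DEFAULT_GRID
from .patterns import classify_day, detect_pattern_change, fit_living_patterns
from .posture import PostureModel, classify_stream, fit_posture_model, train_posture_model
from .records import (NORM_DAYS, DailyRecord, compute_norm, daily_record,
                      daily_vs_norm)
from .pressure import prolonged_pressure
from .simulate import (EPOCH_S, EPOCHS_PER_DAY, DayData, default_cohort,
                       generate_posture_dataset, simulate_day, simulate_night)
from .sleep import (SleepModel, classify_sleep, fit_sleep_model,
                    movement_counts, train_sleep_model, windows_from_nights)

_FLOAT_FMT = "%.4f"


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything a pipeline run depends on, recorded in the manifest."""

    out_dir: Union[str, Path]
    n_residents: int = 24
    n_days: int = 84
    seed: int = 0
    start_date: _date = _date(2021, 8, 2)
    risk_level: str = "high"
    norm_refresh_days: int = 7         # weekly norm refresh from day 14
    cv_metrics: bool = False           # run cross-validation during training
    posture_participants: int = 31
    posture_examples_each: int = 30
    posture_empty: int = 80
    sleep_train_nights: int = 5

    @staticmethod
    def from_yaml(path: Union[str, Path]) -> "RunConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        if "start_date" in raw and isinstance(raw["start_date"], str):
            raw["start_date"] = _date.fromisoformat(raw["start_date"])
        return RunConfig(**raw)

    def to_manifest(self) -> dict:
        d = asdict(self)
        d.pop("out_dir")  # self-evident from the manifest's location
        d["start_date"] = self.start_date.isoformat()
        d["version"] = __version__
        return d


@dataclass
class _DayResult:
    record: DailyRecord
    sleep_efficiency: Optional[float]
    pp_h: float
    n_alerts: int


def _train_models(config: RunConfig) -> tuple[PostureModel, SleepModel]:
    dataset = generate_posture_dataset(
        config.posture_participants, config.posture_examples_each,
        config.posture_empty, seed=config.seed)
    if config.cv_metrics:
        posture_model, _, _ = train_posture_model(dataset, seed=config.seed)
    else:
        posture_model = fit_posture_model(dataset, seed=config.seed)
    nights = [simulate_night(8.0, seed=config.seed * 1000 + i)
              for i in range(config.sleep_train_nights)]
    X, y = windows_from_nights(nights)
    if config.cv_metrics:
        sleep_model, _, _ = train_sleep_model(X, y, seed=config.seed)
    else:
        sleep_model = fit_sleep_model(X, y, seed=config.seed)
    return posture_model, sleep_model


def analyze_day(day: DayData, posture_model: PostureModel,
                sleep_model: SleepModel,
                alert_config: Optional[FallRiskConfig] = None) -> dict:
    """Run one simulated day through every analysis layer.

    Returns the classified posture labels, alert events, movement counts,
    sleep record, daily record and pressure summary in a dict keyed by layer.
    """
    if day.stream is None:
        raise ValueError("analyze_day needs a day simulated with frames")
    labels = classify_stream(posture_model, day.stream)
    occupancy_sec = labels != "empty"
    alerts = detect_bed_exit(labels, alert_config or FallRiskConfig(),
                             timestamps=day.stream.timestamps,
                             resident_id=day.resident_id)
    counts = movement_counts(day.stream)
    epoch_occ = occupancy_sec.reshape(EPOCHS_PER_DAY, EPOCH_S).sum(axis=1) > EPOCH_S // 2
    sleep_rec = classify_sleep(sleep_model, counts, epoch_occ)
    record = daily_record(occupancy_sec, day.date,
                          total_sleep_s=sleep_rec.total_sleep_s)
    psum = prolonged_pressure(day.stream)
    return {"postures": labels, "alerts": alerts, "counts": counts,
            "sleep": sleep_rec, "record": record, "pressure": psum}


def _fmt(x: Optional[float]) -> object:
    return np.nan if x is None else x


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline and return the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        stage = "train_models"
        posture_model, sleep_model = _train_models(config)
        alert_config = FallRiskConfig.for_risk(config.risk_level)

        stage = "simulate_analyze"
        profiles = default_cohort(config.n_residents)
        per_resident: dict[str, list[_DayResult]] = {}
        archetypes: dict[str, str] = {}
        daily_rows, alert_rows = [], []
        for r_idx, profile in enumerate(profiles):
            archetypes[profile.resident_id] = profile.archetype
            results: list[_DayResult] = []
            for d_idx in range(config.n_days):
                rng = np.random.default_rng(
                    np.random.SeedSequence([config.seed, r_idx, d_idx]))
                day = simulate_day(profile, config.start_date + timedelta(days=d_idx),
                                   rng=rng, grid=DEFAULT_GRID)
                layers = analyze_day(day, posture_model, sleep_model, alert_config)
                rec: DailyRecord = layers["record"]
                results.append(_DayResult(
                    record=rec,
                    sleep_efficiency=layers["sleep"].sleep_efficiency,
                    pp_h=layers["pressure"].max_continuous_h,
                    n_alerts=len(layers["alerts"]),
                ))
                daily_rows.append({
                    "resident_id": profile.resident_id,
                    "date": rec.date.isoformat(),
                    "archetype": profile.archetype,
                    "total_in_bed_h": rec.total_in_bed_h,
                    "total_sleep_h": _fmt(rec.total_sleep_h),
                    "sleep_efficiency": _fmt(layers["sleep"].sleep_efficiency),
                    "coverage": rec.coverage,
                    "max_continuous_pressure_h": layers["pressure"].max_continuous_h,
                    "worst_continuous_area": layers["pressure"].worst_continuous_area,
                    "n_alerts": len(layers["alerts"]),
                    "slots": "".join("1" if s else "0" for s in rec.slots),
                })
                for ev in layers["alerts"]:
                    alert_rows.append({
                        "resident_id": profile.resident_id,
                        "timestamp": str(ev.timestamp),
                        "stage": ev.stage,
                    })
            per_resident[profile.resident_id] = results

        stage = "norms_indices"
        norm_rows, index_rows = [], []
        last_day_rows = []
        refresh = config.norm_refresh_days
        for rid, results in per_resident.items():
            records = [r.record for r in results]
            norms: dict[int, object] = {}
            for i in range(config.n_days):
                if i < NORM_DAYS:
                    continue
                j = NORM_DAYS + ((i - NORM_DAYS) // refresh) * refresh
                if j not in norms:
                    norms[j] = compute_norm(records[j - NORM_DAYS:j],
                                            effective_from=records[j].date)
                    norm_rows.append({
                        "resident_id": rid,
                        "effective_from": records[j].date.isoformat(),
                        "norm_score": norms[j].norm_score,
                        "avg_in_bed_h": norms[j].avg_in_bed_h,
                        "avg_sleep_h": _fmt(norms[j].avg_sleep_h),
                    })
                norm = norms[j]
                res = results[i]
                cmpn = daily_vs_norm(res.record, norm)
                idx = index_levels(cmpn.tb_diff_h, cmpn.correlation,
                                   cmpn.st_diff_h, res.sleep_efficiency,
                                   res.pp_h, res.record.total_in_bed_h)
                rating = overall_rating(idx)
                index_rows.append({
                    "resident_id": rid,
                    "date": res.record.date.isoformat(),
                    "tb_diff_h": _fmt(cmpn.tb_diff_h),
                    "cc": _fmt(cmpn.correlation),
                    "st_diff_h": _fmt(cmpn.st_diff_h),
                    "se_pct": _fmt(res.sleep_efficiency),
                    "pp_h": res.pp_h,
                    **{f"level_{k}": (v if v is not None else "")
                       for k, v in idx.levels.items()},
                    "rating": rating.rating,
                    "color": rating.color,
                })
                if i == config.n_days - 1:
                    last_day_rows.append({
                        "resident_id": rid,
                        "total_in_bed_h": res.record.total_in_bed_h,
                        "total_sleep_h": _fmt(res.record.total_sleep_h),
                        "tb_diff_h": cmpn.tb_diff_h,
                        "st_diff_h": _fmt(cmpn.st_diff_h),
                    })

        stage = "living_patterns"
        all_records = [r.record for results in per_resident.values() for r in results]
        distinct = len({r.slots.tobytes() for r in all_records})
        pattern_model = (fit_living_patterns(all_records, seed=config.seed)
                         if distinct >= 4 else None)  # too few days to cluster
        pattern_rows, change_rows = [], []
        final_patterns: dict[str, str] = {}
        for rid, results in per_resident.items():
            if pattern_model is None:
                types = [""] * len(results)
            else:
                types = [classify_day(pattern_model, r.record) for r in results]
            final_patterns[rid] = types[-1]
            for r, t in zip(results, types):
                pattern_rows.append({"resident_id": rid,
                                     "date": r.record.date.isoformat(),
                                     "pattern": t})
            if pattern_model is not None and len(types) >= 3:
                for ev in detect_pattern_change(types):
                    change_rows.append({
                        "resident_id": rid,
                        "date": results[ev.day_index].record.date.isoformat(),
                        "old": ev.old, "new": ev.new,
                    })

        stage = "write_reports"
        for row in last_day_rows:
            row["pattern"] = final_patterns[row["resident_id"]]
        norm_cols = ["resident_id", "effective_from", "norm_score",
                     "avg_in_bed_h", "avg_sleep_h"]
        index_cols = ["resident_id", "date", "tb_diff_h", "cc", "st_diff_h",
                      "se_pct", "pp_h", "level_TB", "level_CC", "level_ST",
                      "level_SE", "level_PP", "rating", "color"]
        summary_cols = ["resident_id", "pattern", "total_in_bed_h",
                        "total_sleep_h", "tb_diff_h", "st_diff_h",
                        "tb_flag_red", "st_flag_red"]
        frames = {
            "daily.csv": pd.DataFrame(daily_rows),
            "alerts.csv": pd.DataFrame(alert_rows, columns=["resident_id", "timestamp", "stage"]),
            "norms.csv": pd.DataFrame(norm_rows, columns=norm_cols),
            "indices.csv": pd.DataFrame(index_rows, columns=index_cols),
            "patterns.csv": pd.DataFrame(pattern_rows, columns=["resident_id", "date", "pattern"]),
            "pattern_changes.csv": pd.DataFrame(change_rows, columns=["resident_id", "date", "old", "new"]),
            "summary.csv": (summary_table(last_day_rows) if last_day_rows
                            else pd.DataFrame(columns=summary_cols)),
        }
        for name, df in frames.items():
            df.to_csv(out / name, index=False, float_format=_FLOAT_FMT)
        manifest = config.to_manifest()
        manifest["pattern_names"] = pattern_model.names if pattern_model else []
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    except Exception as exc:  # pragma: no cover - exercised via stage failures
        (out / "FAILED").write_text(f"stage={stage}\nerror={exc}\n")
        raise PipelineError(stage, exc) from exc
    return out
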