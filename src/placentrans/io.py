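"""Readings/config I/O and the end-to-end analysis pipeline.

Readings travel as tidy CSV (one row per basolateral draw) with the header

    condition,regime,compound,replicate,time_h,reading,unit

``reading`` is either a concentration in mg ml⁻¹ (``unit = mg_ml``) or an
instrument value converted through the per-compound linear calibration
coefficient in the experiment config.  The pipeline emits four tidy CSVs —
per-timepoint results, an apparent-permeability summary (median ± MAD with
``n.t.`` markers), %ID curves (median ± error range) and pairwise exact
tests — plus a JSON-lines run log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__ as _version
from .core import (
    Condition,
    ConfigError,
    DoseSpec,
    ExperimentConfig,
    ParseError,
    Regime,
    TranslocationSeries,
    blank_subtract,
    load_config,
    validate_series,
)
from .kinetics import (
    BELOW_LOD,
    PE_UNDEFINED,
    PermeabilityResult,
    analyze_series,
)
from .stats import mann_whitney_exact, summarize
from .synthetic import SimulatedInsert, StudyDesign

__all__ = [
    "ExperimentManifest",
    "PipelineError",
    "READINGS_COLUMNS",
    "config_from_design",
    "write_readings",
    "write_truth",
    "read_readings",
    "run_pipeline",
]

READINGS_COLUMNS = ("condition", "regime", "compound", "replicate", "time_h", "reading", "unit")
_CSV_FLOAT_FORMAT = "%.12g"
NT_MARKER = "n.t."


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message carries the stage tag."""


@dataclass(frozen=True)
class ExperimentManifest:
    """Paths and options for one pipeline run."""

    config_path: Path
    readings_path: Path
    out_dir: Path
    pm_mode: str | None = None  # override config if set

    def __post_init__(self) -> None:
        for attr in ("config_path", "readings_path", "out_dir"):
            object.__setattr__(self, attr, Path(getattr(self, attr)))
        if not self.config_path.exists():
            raise ConfigError(f"config not found: {self.config_path}")
        if not self.readings_path.exists():
            raise ConfigError(f"readings not found: {self.readings_path}")


def config_from_design(design: StudyDesign) -> ExperimentConfig:
    """Derive the experiment config that describes a synthetic study."""
    return ExperimentConfig(
        geometry=design.geometry,
        schedules={c: cd.schedule for c, cd in design.compounds.items()},
        doses={
            c: DoseSpec.from_concentration(cd.concentration_mg_ml, design.geometry, c)
            for c, cd in design.compounds.items()
        },
        lod_mg_ml={c: cd.lod_mg_ml for c, cd in design.compounds.items()},
    )


def write_readings(inserts: Sequence[SimulatedInsert], path: str | Path) -> None:
    """Write simulated inserts in the same CSV dialect the pipeline reads."""
    rows = []
    for ins in inserts:
        s = ins.series
        for t, c in zip(s.schedule.times_h, s.concentrations_mg_ml):
            rows.append(
                {
                    "condition": s.condition.value,
                    "regime": s.regime.value,
                    "compound": ins.compound,
                    "replicate": s.replicate_id,
                    "time_h": t,
                    "reading": c,
                    "unit": "mg_ml",
                }
            )
    df = pd.DataFrame(rows, columns=list(READINGS_COLUMNS))
    df.to_csv(path, index=False, float_format=_CSV_FLOAT_FORMAT)


def write_truth(inserts: Sequence[SimulatedInsert], path: str | Path) -> None:
    """Sidecar ground-truth CSV (per-event masses) for testing estimators."""
    rows = []
    for ins in inserts:
        s = ins.series
        t = ins.truth
        for i, time_h in enumerate(t.times_h):
            rows.append(
                {
                    "condition": s.condition.value,
                    "regime": s.regime.value,
                    "compound": ins.compound,
                    "replicate": s.replicate_id,
                    "time_h": time_h,
                    "apical_mass_mg": t.apical_mass_mg[i],
                    "basolateral_mass_pre_sample_mg": t.basolateral_mass_pre_sample_mg[i],
                    "withdrawn_mass_mg": t.withdrawn_mass_mg[i],
                    "net_transported_mass_mg": t.net_transported_mass_mg[i],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_CSV_FLOAT_FORMAT)


def read_readings(
    path: str | Path, config: ExperimentConfig
) -> list[TranslocationSeries]:
    """Parse, calibrate, blank-correct and LOD-flag a readings CSV.

    Row order is immaterial; duplicates of (condition, regime, compound,
    replicate, time_h) and timepoints absent from the compound's schedule
    are parse errors naming the offending line (1-based, header = line 1).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(READINGS_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")

    df = df.copy()
    df["_line"] = df.index + 2  # header occupies line 1
    for col in ("time_h", "reading"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.loc[numeric.isna(), "_line"]
        if len(bad):
            raise ParseError(
                f"{path}: unparseable number in column '{col}' at line {int(bad.iloc[0])}"
            )
        df[col] = numeric

    key_cols = ["condition", "regime", "compound", "replicate", "time_h"]
    dup = df.duplicated(subset=key_cols, keep=False)
    if dup.any():
        first = df.loc[dup, "_line"].iloc[1]
        raise ParseError(f"{path}: duplicated timepoint row at line {int(first)}")

    out: list[TranslocationSeries] = []
    group_cols = ["compound", "condition", "regime", "replicate"]
    for (compound, condition, regime, replicate), grp in sorted(
        df.groupby(group_cols, sort=True), key=lambda kv: kv[0]
    ):
        if compound not in config.doses:
            raise ParseError(f"{path}: compound {compound!r} not in config dose table")
        schedule = config.schedules[compound]
        grp = grp.sort_values("time_h")
        times = tuple(float(t) for t in grp["time_h"])
        if len(times) != len(schedule.times_h) or any(
            abs(a - b) > 1e-9 for a, b in zip(times, schedule.times_h)
        ):
            raise ParseError(
                f"{path}: series ({compound}, {condition}, {regime}, {replicate}) "
                f"timepoints {times} do not match schedule {schedule.times_h}"
            )
        readings = np.asarray(grp["reading"], dtype=float)
        units = set(grp["unit"])
        if len(units) != 1:
            raise ParseError(
                f"{path}: mixed units in series ({compound}, {condition}, {regime}, {replicate})"
            )
        unit = units.pop()
        if unit != "mg_ml":
            coef = config.calibration_mg_ml_per_unit.get(compound)
            if coef is None:
                raise ParseError(
                    f"{path}: unit {unit!r} for {compound!r} needs a calibration coefficient"
                )
            readings = readings * coef

        series = TranslocationSeries(
            geometry=config.geometry,
            schedule=schedule,
            dose=config.doses[compound],
            concentrations_mg_ml=tuple(readings),
            condition=Condition(condition),
            regime=Regime(regime),
            replicate_id=str(replicate),
        )
        if config.blank_subtract:
            series = blank_subtract(series)
        lod = config.lod_mg_ml.get(compound)
        if lod is not None and lod > 0:
            flags = tuple(c <= lod for c in series.concentrations_mg_ml)
            censored = tuple(
                0.0 if f else c for c, f in zip(series.concentrations_mg_ml, flags)
            )
            series = replace(series, concentrations_mg_ml=censored, below_lod=flags)
        findings = validate_series(series)
        if findings:
            raise ParseError(
                f"{path}: invalid series ({compound}, {condition}, {regime}, {replicate}): "
                + "; ".join(findings)
            )
        out.append(series)
    return out


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

_OUTPUT_FILES = (
    "results.csv",
    "pe_summary.csv",
    "percent_id.csv",
    "pairwise_tests.csv",
    "run_log.jsonl",
)


def _membrane_permeability(
    results: dict[tuple, PermeabilityResult],
    compound: str,
    regime: Regime,
    ref_time_h: float,
) -> tuple[float | None, dict[str, float]]:
    """Pooled-median and per-replicate membrane P from control inserts."""
    per_rep: dict[str, float] = {}
    for (cmp_, cond, reg, rep), res in results.items():
        if cmp_ == compound and reg == regime and cond is Condition.CONTROL:
            p = res.p_at_cm_s.get(ref_time_h)
            if p is not None and p > 0:
                per_rep[rep] = p
    pooled = float(np.median(list(per_rep.values()))) if per_rep else None
    return pooled, per_rep


def run_pipeline(manifest: ExperimentManifest) -> dict[str, Path]:
    """Execute kinetics → particle/permeability summaries → statistics.

    Returns a mapping of output name → path.  Any stage failure removes
    partial outputs and raises :class:`PipelineError` tagged with the stage.
    """
    out_dir = manifest.out_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs = {name: out_dir / name for name in _OUTPUT_FILES}

    log_records: list[dict] = []

    def log(event: str, **kw) -> None:
        log_records.append({"event": event, **kw})

    try:
        stage = "read"
        config = load_config(manifest.config_path)
        if manifest.pm_mode is not None:
            config = dataclasses.replace(config, pm_mode=manifest.pm_mode)
        config_hash = hashlib.sha256(manifest.config_path.read_bytes()).hexdigest()
        log(
            "start",
            version=_version,
            config=str(manifest.config_path),
            readings=str(manifest.readings_path),
            config_sha256=config_hash,
            pm_mode=config.pm_mode,
        )
        series_list = read_readings(manifest.readings_path, config)
        log("read", n_series=len(series_list))

        stage = "kinetics"
        ref_t = config.pe_reference_time_h
        results: dict[tuple, PermeabilityResult] = {}
        for s in series_list:
            key = (s.dose.compound, s.condition, s.regime, s.replicate_id)
            results[key] = analyze_series(
                s, lod_mg_ml=config.lod_mg_ml.get(s.dose.compound)
            )

        # second pass: membrane-corrected Pe for cell-bearing conditions
        pe_values: dict[tuple, float | None] = {}
        for key, res in results.items():
            compound, cond, regime, rep = key
            if cond is Condition.CONTROL:
                continue
            pooled_pm, per_rep_pm = _membrane_permeability(results, compound, regime, ref_t)
            pm = (
                per_rep_pm.get(rep, pooled_pm)
                if config.pm_mode == "per_replicate"
                else pooled_pm
            )
            if pm is None:
                pe_values[key] = None
                continue
            res_pe = analyze_series(
                res.series, p_membrane_cm_s=pm, lod_mg_ml=config.lod_mg_ml.get(compound)
            )
            results[key] = res_pe
            pe_values[key] = res_pe.pe_at_cm_s.get(ref_t)

        stage = "results"
        rows = []
        for key in sorted(results, key=lambda k: (k[0], k[1].value, k[2].value, k[3])):
            compound, cond, regime, rep = key
            res = results[key]
            s = res.series
            for i, t in enumerate(s.schedule.times_h):
                rows.append(
                    {
                        "compound": compound,
                        "condition": cond.value,
                        "regime": regime.value,
                        "replicate": rep,
                        "time_h": t,
                        "concentration_mg_ml": s.concentrations_mg_ml[i],
                        "below_lod": int(s.below_lod[i]),
                        "cumulative_mass_mg": res.cumulative_mass_mg[i],
                        "percent_id": res.percent_id[i],
                        "p_cm_s": res.p_at_cm_s.get(t, float("nan")),
                        "pe_cm_s": (
                            res.pe_at_cm_s.get(t, float("nan"))
                            if res.pe_at_cm_s.get(t) is not None
                            else float("nan")
                        ),
                        "flags": ";".join(sorted(res.flags)),
                    }
                )
        pd.DataFrame(rows).to_csv(
            outputs["results.csv"], index=False, float_format=_CSV_FLOAT_FORMAT
        )
        log("results", rows=len(rows))

        stage = "pe_summary"
        sum_rows = []
        combos = sorted(
            {(k[0], k[1], k[2]) for k in results if k[1] is not Condition.CONTROL},
            key=lambda k: (k[0], k[1].value, k[2].value),
        )
        for compound, cond, regime in combos:
            keys = [
                k
                for k in results
                if (k[0], k[1], k[2]) == (compound, cond, regime)
            ]
            n_total = len(keys)
            all_nt = all(BELOW_LOD in results[k].flags for k in keys)
            pes = [pe_values.get(k) for k in keys]
            finite = [p for p in pes if p is not None]
            n_undef = sum(1 for p in pes if p is None)
            if all_nt or not finite:
                display = NT_MARKER
                med = mad = float("nan")
            else:
                summ = summarize(finite)
                med, mad = summ.median, summ.mad
                display = f"{med * 1e6:.1f} ± {mad * 1e6:.1f}"
            sum_rows.append(
                {
                    "compound": compound,
                    "condition": cond.value,
                    "regime": regime.value,
                    "n": n_total,
                    "n_pe_undefined": n_undef,
                    "pe_median_cm_s": med,
                    "pe_mad_cm_s": mad,
                    "pe_display_1e6_cm_s": display,
                }
            )
        pd.DataFrame(sum_rows).to_csv(
            outputs["pe_summary.csv"], index=False, float_format=_CSV_FLOAT_FORMAT
        )
        log("pe_summary", rows=len(sum_rows))

        stage = "percent_id"
        pid_rows = []
        curve_combos = sorted(
            {(k[0], k[1], k[2]) for k in results},
            key=lambda k: (k[0], k[1].value, k[2].value),
        )
        for compound, cond, regime in curve_combos:
            keys = [k for k in results if (k[0], k[1], k[2]) == (compound, cond, regime)]
            times = results[keys[0]].series.schedule.times_h
            for i, t in enumerate(times):
                vals = [results[k].percent_id[i] for k in keys]
                summ = summarize(vals)
                pid_rows.append(
                    {
                        "compound": compound,
                        "condition": cond.value,
                        "regime": regime.value,
                        "time_h": t,
                        "percent_id_median": summ.median,
                        "percent_id_lower": summ.lower,
                        "percent_id_upper": summ.upper,
                        "n": summ.n,
                    }
                )
        pd.DataFrame(pid_rows).to_csv(
            outputs["percent_id.csv"], index=False, float_format=_CSV_FLOAT_FORMAT
        )
        log("percent_id", rows=len(pid_rows))

        stage = "stats"
        test_rows = []
        compounds = sorted({k[0] for k in results})
        regimes = sorted({k[2] for k in results}, key=lambda r: r.value)
        conditions = sorted({k[1] for k in results}, key=lambda c: c.value)

        def final_pct(compound, cond, regime) -> list[float]:
            return [
                results[k].percent_id[-1]
                for k in results
                if (k[0], k[1], k[2]) == (compound, cond, regime)
            ]

        for compound in compounds:
            for regime in regimes:
                control = final_pct(compound, Condition.CONTROL, regime)
                if not control:
                    continue
                for cond in conditions:
                    if cond is Condition.CONTROL:
                        continue
                    treated = final_pct(compound, cond, regime)
                    if not treated:
                        continue
                    test = mann_whitney_exact(treated, control)
                    test_rows.append(
                        {
                            "compound": compound,
                            "comparison": f"{cond.value}_vs_control",
                            "regime": regime.value,
                            "endpoint": "final_percent_id",
                            "u_statistic": test.u_statistic,
                            "p_two_sided": test.p_two_sided,
                            "n1": test.n1,
                            "n2": test.n2,
                            "method": test.method.value,
                        }
                    )
            # static vs shaken on Pe per cell condition
            for cond in conditions:
                if cond is Condition.CONTROL:
                    continue
                arms = {}
                for regime in (Regime.STATIC, Regime.SHAKEN):
                    vals = [
                        pe_values[k]
                        for k in pe_values
                        if (k[0], k[1], k[2]) == (compound, cond, regime)
                        and pe_values[k] is not None
                    ]
                    if vals:
                        arms[regime] = vals
                if len(arms) == 2:
                    test = mann_whitney_exact(arms[Regime.STATIC], arms[Regime.SHAKEN])
                    test_rows.append(
                        {
                            "compound": compound,
                            "comparison": "static_vs_shaken",
                            "regime": cond.value,
                            "endpoint": "pe",
                            "u_statistic": test.u_statistic,
                            "p_two_sided": test.p_two_sided,
                            "n1": test.n1,
                            "n2": test.n2,
                            "method": test.method.value,
                        }
                    )
        pd.DataFrame(test_rows).to_csv(
            outputs["pairwise_tests.csv"], index=False, float_format=_CSV_FLOAT_FORMAT
        )
        log("stats", rows=len(test_rows))

        stage = "log"
        log("done", outputs=[str(p) for p in outputs.values()])
        with open(outputs["run_log.jsonl"], "w", encoding="utf-8") as fh:
            for rec in log_records:
                fh.write(json.dumps(rec, sort_keys=True) + "\n")
        return outputs
    except Exception as exc:
        for p in outputs.values():
            p.unlink(missing_ok=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
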