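"""CSV schemas, readers/writers, run configuration and the chained pipeline.

Three CSV interfaces move data between stages (UTF-8, comma-separated,
header required, "." decimal, empty string for missing):

* animal table:  animal_id, group, age_wk, bed, ach_upper_um, mvd_per_mm2,
  beta, mass_g, insulin_ng_ml, glucose_mg_dl, tnf_alpha (last four optional)
* dose-response: animal_id, bed, concentration_M, diameter_um
* mechanics:     animal_id, bed, pressure_mmHg, inner_diameter_um,
                 outer_diameter_um
* standards:     age_wk, bed, ach_upper_std, mvd_std, beta_std, n_lzr

Column names carry units so files are self-describing.  Schema violations
raise :class:`~vhi.errors.SchemaError` naming file, line and column.
Floating-point output is written with 6 significant digits.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .errors import SchemaError, VHIError
from .mechanics import MMHG_TO_DYN, MechanicsSeries, compute_stress_strain, fit_exponential
from .reactivity import DoseResponseSeries, fit_logistic
from .scoring import (
    AnimalRecord,
    HealthStandard,
    compute_standards,
    compute_vhi,
    summarize_cohorts,
    time_average,
)
from .simulate import fixture_tables, generate_study
from .validity import criterion_validity, discriminant_check, newman_keuls

log = logging.getLogger("vhi")

FLOAT_FORMAT = "%.6g"

_ANIMAL_REQUIRED = ["animal_id", "group", "age_wk", "bed", "ach_upper_um", "mvd_per_mm2", "beta"]
_ANIMAL_OPTIONAL = ["mass_g", "insulin_ng_ml", "glucose_mg_dl", "tnf_alpha"]

SCHEMAS = {
    "animal": _ANIMAL_REQUIRED,
    "dose_response": ["animal_id", "bed", "concentration_M", "diameter_um"],
    "mechanics": ["animal_id", "bed", "pressure_mmHg", "inner_diameter_um", "outer_diameter_um"],
    "standards": ["age_wk", "bed", "ach_upper_std", "mvd_std", "beta_std", "n_lzr"],
}


def _read_csv(path, schema_name):
    path = Path(path)
    if not path.exists():
        raise SchemaError("file not found", path=path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise SchemaError(f"unreadable CSV: {exc}", path=path) from exc
    required = SCHEMAS[schema_name]
    for col in required:
        if col not in df.columns:
            raise SchemaError("missing required column", path=path, column=col)
    return df


def _numeric(df, col, path, required=True):
    """Coerce a column to float, reporting the first offending line."""
    if col not in df.columns:
        return pd.Series([math.nan] * len(df))
    coerced = pd.to_numeric(df[col], errors="coerce")
    bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
    if bad.any():
        i = int(bad.idxmax())
        raise SchemaError(
            f"non-numeric value {df[col][i]!r}", path=path, line=i + 2, column=col
        )
    if required and coerced.isna().any():
        i = int(coerced.isna().idxmax())
        raise SchemaError("missing value", path=path, line=i + 2, column=col)
    return coerced


def read_table(path, schema_name: str):
    """Read and validate one of the named CSV interfaces into typed records.

    Returns a list of AnimalRecord, DoseResponseSeries, MechanicsSeries or
    HealthStandard depending on ``schema_name``.  Row order (and per-animal
    observation order, sorted by the x variable) is preserved; invariant
    violations surface as SchemaError with the file and line.
    """
    if schema_name not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema_name!r}")
    df = _read_csv(path, schema_name)
    path = Path(path)

    if schema_name == "animal":
        age = _numeric(df, "age_wk", path)
        cols = {c: _numeric(df, c, path) for c in
                ["ach_upper_um", "mvd_per_mm2", "beta"]}
        opts = {c: _numeric(df, c, path, required=False) for c in _ANIMAL_OPTIONAL}
        records = []
        for i in range(len(df)):
            try:
                records.append(AnimalRecord(
                    animal_id=str(df["animal_id"][i]), group=str(df["group"][i]),
                    age_wk=int(age[i]), bed=str(df["bed"][i]),
                    ach_upper=float(cols["ach_upper_um"][i]),
                    mvd=float(cols["mvd_per_mm2"][i]), beta=float(cols["beta"][i]),
                    **{k.split("_")[0] if k != "tnf_alpha" else "tnf_alpha":
                       (None if math.isnan(opts[k][i]) else float(opts[k][i]))
                       for k in _ANIMAL_OPTIONAL},
                ))
            except VHIError as exc:
                raise SchemaError(str(exc), path=path, line=i + 2) from exc
        return records

    if schema_name == "standards":
        num = {c: _numeric(df, c, path) for c in SCHEMAS["standards"] if c != "bed"}
        out = []
        for i in range(len(df)):
            try:
                out.append(HealthStandard(
                    age_wk=int(num["age_wk"][i]), bed=str(df["bed"][i]),
                    ach_upper_std=float(num["ach_upper_std"][i]),
                    mvd_std=float(num["mvd_std"][i]),
                    beta_std=float(num["beta_std"][i]),
                    n_lzr=int(num["n_lzr"][i]),
                ))
            except VHIError as exc:
                raise SchemaError(str(exc), path=path, line=i + 2) from exc
        return out

    # per-animal grouped series
    xcol = "concentration_M" if schema_name == "dose_response" else "pressure_mmHg"
    for c in SCHEMAS[schema_name]:
        if c not in ("animal_id", "bed"):
            df[c] = _numeric(df, c, path)
    out = []
    for (animal_id, bed), sub in df.groupby(["animal_id", "bed"], sort=False):
        sub = sub.sort_values(xcol)
        try:
            if schema_name == "dose_response":
                out.append(DoseResponseSeries(
                    animal_id=str(animal_id), bed=str(bed),
                    concentrations=sub["concentration_M"].to_numpy(),
                    responses=sub["diameter_um"].to_numpy(),
                ))
            else:
                out.append(MechanicsSeries(
                    animal_id=str(animal_id), bed=str(bed),
                    pressures=sub["pressure_mmHg"].to_numpy(),
                    inner_diameters=sub["inner_diameter_um"].to_numpy(),
                    outer_diameters=sub["outer_diameter_um"].to_numpy(),
                ))
        except VHIError as exc:
            raise SchemaError(
                f"animal {animal_id!r}: {exc}", path=path,
                line=int(sub.index[0]) + 2,
            ) from exc
    return out


def write_table(df: pd.DataFrame, path) -> None:
    """Write a DataFrame in the canonical CSV dialect (6 significant digits)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def standards_frame(standards: Sequence[HealthStandard]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(s) for s in standards])


def results_frame(results) -> pd.DataFrame:
    rows = []
    for r in results:
        d = {
            "animal_id": r.animal_id, "group": r.group, "age_wk": r.age_wk,
            "bed": r.bed, "ach_score": r.ach_score, "mvd_score": r.mvd_score,
            "stiffness_score": r.stiffness_score, "vhi": r.vhi, "mode": r.mode,
        }
        if r.component_ranks is not None:
            d["ach_rank"], d["mvd_rank"], d["stiffness_rank"] = r.component_ranks
        rows.append(d)
    return pd.DataFrame(rows)


def summaries_frame(summaries) -> pd.DataFrame:
    df = pd.DataFrame([dataclasses.asdict(s) for s in summaries])
    return df


def reactivity_fits_frame(fits) -> pd.DataFrame:
    return pd.DataFrame([{
        "animal_id": f.animal_id, "bed": f.bed, "lower_bound_um": f.lower_bound,
        "upper_bound_um": f.upper_bound, "log_ec50": f.log_ec50,
        "residual_ss": f.residual_ss, "r_squared": f.r_squared,
        "converged": f.converged, "n_obs": f.n_obs,
    } for f in fits])


def mechanics_fits_frame(fits) -> pd.DataFrame:
    return pd.DataFrame([{
        "animal_id": f.animal_id, "bed": f.bed, "beta": f.beta,
        "log_intercept": f.log_intercept, "r_squared": f.r_squared,
        "acceptable": f.acceptable, "n_obs": f.n_obs,
    } for f in fits])


# ---------------------------------------------------------------------------
# run configuration and chained pipeline


@dataclass
class RunConfig:
    """Configuration of a full simulate -> fit -> score -> validate run."""

    outdir: str = "vhi_run"
    mode: str = "percentage"
    alpha: float = 0.05
    mmhg_to_dyn: float = MMHG_TO_DYN
    clamp_zero: bool = False
    seed: int = 1
    simulate: bool = True
    groups: Optional[list] = None
    ages: Optional[list] = None
    beds: Optional[list] = None
    animals_csv: Optional[str] = None
    dose_response_csv: Optional[str] = None
    mechanics_csv: Optional[str] = None
    standards_csv: Optional[str] = None
    criterion_threshold: float = -0.4

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise VHIError("alpha must be in (0, 1)")
        if self.mode not in ("percentage", "percentile"):
            raise VHIError("mode must be 'percentage' or 'percentile'")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class PipelineStageError(VHIError):
    def __init__(self, stage, cause):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def run_pipeline(config: RunConfig) -> dict:
    """Chain simulate (optional) -> fit -> score -> summarize -> validate.

    Writes all artifacts plus a manifest (inputs, config hash, seed, package
    version) under ``config.outdir`` and returns a dict of artifact paths.
    The run is a pure function of the config, so re-running with an identical
    config reproduces every file.  Any stage failure raises
    :class:`PipelineStageError` tagged with the stage name.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts = {}
    timings = {}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except VHIError as exc:
                raise PipelineStageError(name, exc) from exc
            timings[name] = round(time.perf_counter() - t0, 3)
            log.info("stage %s done in %.3fs", name, timings[name])
            return result
        return deco

    if config.simulate:
        @stage("simulate")
        def _sim():
            specs = fixture_tables(groups=config.groups, ages=config.ages, beds=config.beds)
            if not specs:
                raise VHIError("no fixture cohorts match the requested filters")
            bundle = generate_study(specs, seed=config.seed)
            write_table(bundle.animals_frame(), outdir / "animals.csv")
            write_table(bundle.dose_response_frame(), outdir / "dose_response.csv")
            write_table(bundle.mechanics_frame(), outdir / "mechanics.csv")
            return bundle
        artifacts["animals"] = str(outdir / "animals.csv")
        artifacts["dose_response"] = str(outdir / "dose_response.csv")
        artifacts["mechanics"] = str(outdir / "mechanics.csv")
    else:
        for key, p in (("animals", config.animals_csv),
                       ("dose_response", config.dose_response_csv),
                       ("mechanics", config.mechanics_csv)):
            if p is not None:
                artifacts[key] = str(p)
        if "animals" not in artifacts:
            raise PipelineStageError("read", VHIError("no animals_csv provided and simulate=False"))

    @stage("read")
    def _read():
        animals = read_table(artifacts["animals"], "animal")
        dose = (read_table(artifacts["dose_response"], "dose_response")
                if "dose_response" in artifacts else [])
        mech = (read_table(artifacts["mechanics"], "mechanics")
                if "mechanics" in artifacts else [])
        return animals, dose, mech

    animals, dose, mech = _read

    @stage("fit-reactivity")
    def _fit_dr():
        fits = [fit_logistic(s) for s in dose]
        if fits:
            write_table(reactivity_fits_frame(fits), outdir / "reactivity_fits.csv")
            artifacts["reactivity_fits"] = str(outdir / "reactivity_fits.csv")
        return fits

    @stage("fit-mechanics")
    def _fit_mech():
        fits = [fit_exponential(compute_stress_strain(s, config.mmhg_to_dyn)) for s in mech]
        if fits:
            write_table(mechanics_fits_frame(fits), outdir / "mechanics_fits.csv")
            artifacts["mechanics_fits"] = str(outdir / "mechanics_fits.csv")
        return fits

    dr_fits, mech_fits = _fit_dr, _fit_mech

    @stage("score")
    def _score():
        # fitted components replace the tabulated ones wherever raw series exist
        dr_by_id = {f.animal_id: f for f in dr_fits}
        mech_by_id = {f.animal_id: f for f in mech_fits}
        recs = []
        for r in animals:
            upd = {}
            if r.animal_id in dr_by_id:
                upd["ach_upper"] = dr_by_id[r.animal_id].upper_bound
            if r.animal_id in mech_by_id:
                upd["beta"] = mech_by_id[r.animal_id].beta
            recs.append(dataclasses.replace(r, **upd) if upd else r)
        if config.standards_csv:
            standards = read_table(config.standards_csv, "standards")
        else:
            standards = compute_standards([r for r in recs if r.group == "LZR"])
            write_table(standards_frame(standards), outdir / "standards.csv")
            artifacts["standards"] = str(outdir / "standards.csv")
        results = compute_vhi(recs, standards, mode=config.mode, clamp_zero=config.clamp_zero)
        write_table(results_frame(results), outdir / "scores.csv")
        artifacts["scores"] = str(outdir / "scores.csv")
        return recs, results

    recs, results = _score

    @stage("summarize")
    def _summarize():
        summaries = summarize_cohorts(results)
        rows = summaries_frame(summaries)
        # time-averaged (all ages compiled) row per (group, bed)
        ta = []
        for (group, bed) in sorted({(s.group, s.bed) for s in summaries}):
            ta.append(time_average([s for s in summaries
                                    if s.group == group and s.bed == bed]))
        out = pd.concat([rows, summaries_frame(ta)], ignore_index=True)
        write_table(out, outdir / "summary.csv")
        artifacts["summary"] = str(outdir / "summary.csv")
        return summaries

    summaries = _summarize

    @stage("validate")
    def _validate():
        report = {"alpha": config.alpha, "criterion": {}, "discriminant": {}, "posthoc": {}}
        rec_by_id = {r.animal_id: r for r in recs}
        for bed in sorted({r.bed for r in recs}):
            ozr = [res for res in results
                   if res.bed == bed and res.group == "OZR"
                   and rec_by_id[res.animal_id].insulin is not None]
            if len(ozr) >= 3:
                for marker in ("insulin", "tnf_alpha"):
                    vals = [getattr(rec_by_id[r.animal_id], marker) for r in ozr]
                    if any(v is None for v in vals):
                        continue
                    rep, verdict = criterion_validity(
                        ozr, vals, threshold=config.criterion_threshold,
                        biomarker_name=marker)
                    report["criterion"][f"{bed}:{marker}"] = {
                        "n": rep.n, "r": rep.r, "p_value": rep.p_value,
                        "threshold": config.criterion_threshold, "pass": verdict,
                    }
            for age in sorted({s.age_wk for s in summaries if s.bed == bed}):
                cell = [s for s in summaries if s.bed == bed and s.age_wk == age]
                have = {s.group for s in cell}
                if {"LZR", "OZR", "OZR+LNM"} <= have:
                    report["discriminant"][f"{bed}:{age}wk"] = discriminant_check(
                        [s for s in cell if s.group in ("LZR", "OZR", "OZR+LNM")])
                groups_here = [s.group for s in cell]
                data = [[res.vhi for res in results
                         if res.bed == bed and res.age_wk == age and res.group == g]
                        for g in groups_here]
                if all(len(d) >= 2 for d in data) and len(data) >= 2:
                    ph = newman_keuls(data, alpha=config.alpha, labels=groups_here)
                    report["posthoc"][f"{bed}:{age}wk"] = {
                        "anova_F": ph.anova_F, "anova_p": ph.anova_p,
                        "significant_pairs": sorted(
                            [sorted(p) for p in
                             ({a, b} for a, b, sig in ph.pairs if sig)]),
                    }
        path = outdir / "validity.json"
        path.write_text(json.dumps(report, indent=2, default=float))
        artifacts["validity"] = str(path)
        return report

    _validate

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest(),
        "seed": config.seed,
        "artifacts": artifacts,
        "stage_seconds": timings,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    artifacts["manifest"] = str(outdir / "manifest.json")
    return artifacts
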