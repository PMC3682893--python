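"""File formats, configuration and the pipeline driver.

The interchange format is a long-format CSV with one row per plated sample:

    strain,treatment,replicate,time_h,plated_volume_ml,cfu

``plated_volume_ml`` is the *effective* plated volume (plated volume times
the serial-dilution factor) — exactly the delta_t the Poisson likelihood
needs.  ``run_pipeline`` strings together simulation (optional), fitting,
strain summaries, cross-antibiotic correlations, combination classification
and the rate-determinant analysis; every stochastic stage draws from an
explicit seed recorded in the run log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .inference import (
    FitConfig,
    FitResult,
    KillCurve,
    NoSignalError,
    Observation,
    UnderdeterminedError,
    fit_replicate,
)
from .study import (
    AnalysisConfig,
    classify_combination,
    cross_antibiotic_correlations,
    parameter_determinants,
    summarize_strain,
)
from .synthetic import PlatingDesign, StudyScenario, generate_study

__all__ = [
    "CFU_COLUMNS",
    "CfuTableError",
    "PipelineConfig",
    "read_cfu_table",
    "write_cfu_table",
    "curves_to_frame",
    "fit_table",
    "run_pipeline",
]

log = logging.getLogger("persisterfit")

CFU_COLUMNS = ("strain", "treatment", "replicate", "time_h", "plated_volume_ml", "cfu")


class CfuTableError(ValueError):
    """Raised for malformed CFU tables, naming the offending cell."""


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run; round-trips through YAML."""

    output_dir: str = "results"
    input_path: str | None = None  # CSV of observed curves; None -> simulate
    fit: FitConfig = field(default_factory=FitConfig)
    scenario: StudyScenario | None = field(default_factory=StudyScenario)
    design: PlatingDesign = field(default_factory=PlatingDesign)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    verbosity: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kw = dict(raw)
        if kw.get("fit") is not None:
            kw["fit"] = FitConfig(**_tuplify(kw["fit"]))
        if kw.get("scenario") is not None:
            kw["scenario"] = StudyScenario(**_tuplify(kw["scenario"]))
        if kw.get("design") is not None:
            kw["design"] = PlatingDesign(**_tuplify(kw["design"]))
        if kw.get("analysis") is not None:
            kw["analysis"] = AnalysisConfig(**_tuplify(kw["analysis"]))
        return cls(**kw)


def _tuplify(d: dict) -> dict:
    """YAML has no tuples; convert lists (recursively) back."""
    out = {}
    for k, v in d.items():
        if isinstance(v, list):
            out[k] = tuple(_tuplify(x) if isinstance(x, dict) else tuple(x) if isinstance(x, list) else x for x in v)
        else:
            out[k] = v
    return out


def read_cfu_table(path: str | Path) -> list[KillCurve]:
    """Parse a long-format CFU CSV into per-replicate kill curves.

    Validation errors name the offending row (1-based, excluding header).
    """
    df = pd.read_csv(path)
    missing = [c for c in CFU_COLUMNS if c not in df.columns]
    if missing:
        raise CfuTableError(f"missing column(s) {missing}; expected {list(CFU_COLUMNS)}")
    for i, row in enumerate(df.itertuples(index=False), start=1):
        for col in ("time_h", "plated_volume_ml", "cfu"):
            v = getattr(row, col)
            if not np.isfinite(v):
                raise CfuTableError(f"row {i}, column {col!r}: non-numeric value {v!r}")
        if row.time_h < 0:
            raise CfuTableError(f"row {i}, column 'time_h': negative time {row.time_h}")
        if row.plated_volume_ml <= 0:
            raise CfuTableError(
                f"row {i}, column 'plated_volume_ml': non-positive volume {row.plated_volume_ml}"
            )
        if row.cfu < 0 or row.cfu != int(row.cfu):
            raise CfuTableError(f"row {i}, column 'cfu': invalid count {row.cfu}")
    keys = ["strain", "treatment", "replicate"]
    dup = df.duplicated(subset=keys + ["time_h"])
    if dup.any():
        first = int(np.argmax(dup.values)) + 1
        raise CfuTableError(f"row {first}: duplicate (strain, treatment, replicate, time_h)")
    curves = []
    for (s, trt, rep), grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("time_h")
        obs = tuple(
            Observation(t=float(r.time_h), x=int(r.cfu), delta=float(r.plated_volume_ml))
            for r in grp.itertuples(index=False)
        )
        curves.append(KillCurve(strain=str(s), treatment=str(trt), replicate=str(rep), observations=obs))
    return curves


def curves_to_frame(curves: list[KillCurve]) -> pd.DataFrame:
    rows = [
        {
            "strain": c.strain, "treatment": c.treatment, "replicate": c.replicate,
            "time_h": o.t, "plated_volume_ml": o.delta, "cfu": o.x,
        }
        for c in curves
        for o in c.observations
    ]
    return pd.DataFrame(rows, columns=list(CFU_COLUMNS))


def write_cfu_table(curves: list[KillCurve] | pd.DataFrame, path: str | Path) -> None:
    df = curves if isinstance(curves, pd.DataFrame) else curves_to_frame(curves)
    df.to_csv(path, index=False)


def fit_table(curves: list[KillCurve], config: FitConfig) -> tuple[pd.DataFrame, list[FitResult]]:
    """Fit every curve; returns a flat per-replicate table plus the fits.

    Replicates that cannot be fit (no signal / too few timepoints) appear in
    the table with converged=False and a reason flag.
    """
    rows, fits = [], []
    for curve in curves:
        base = {"strain": curve.strain, "treatment": curve.treatment, "replicate": curve.replicate}
        try:
            fit = fit_replicate(curve, config)
        except (NoSignalError, UnderdeterminedError) as exc:
            rows.append({**base, "converged": False, "flags": type(exc).__name__})
            continue
        fits.append(fit)
        o = fit.obs_hat
        fr = fit.fraction
        mech = fit.mech_hat
        rows.append(
            {
                **base,
                "converged": fit.converged,
                "loglik": fit.loglik,
                "c1": o.c1 if o else np.nan,
                "c2": o.c2 if o else np.nan,
                "lam1": o.lam1 if o else np.nan,
                "lam2": o.lam2 if o else np.nan,
                "fp_min": fr.fp_min if fr else np.nan,
                "fp_mid": fr.fp_mid if fr else np.nan,
                "fp_max": fr.fp_max if fr else np.nan,
                "fp_point": fit.fp_point if fit.fp_point is not None else np.nan,
                "F0_normal_min": 1.0 - fr.fp_max if fr else np.nan,  # normal-cell-fraction convention
                "F0_normal_max": 1.0 - fr.fp_min if fr else np.nan,
                "slow_fraction": fit.slow_fraction,
                "m": mech.m if mech else np.nan,
                "a": mech.a if mech else np.nan,
                "b": mech.b if mech else np.nan,
                "flags": ";".join(fit.flags),
            }
        )
    return pd.DataFrame(rows), fits


def _summaries_from_fits(fits: list[FitResult]) -> pd.DataFrame:
    by_key: dict[tuple[str, str], list[FitResult]] = {}
    for f in fits:
        by_key.setdefault((f.curve.strain, f.curve.treatment), []).append(f)
    rows = []
    for (s, trt), group in sorted(by_key.items()):
        summ = summarize_strain(group)
        rows.append(
            {
                "strain": s, "treatment": trt, "n_replicates": summ.n_replicates,
                "mean_log10_fp": summ.mean_log10_fp, "se_log10_fp": summ.se_log10_fp,
                "mean_slow_fraction": summ.mean_slow_fraction,
                "n_detection_limited": summ.n_detection_limited,
                "n_nonconverged": summ.n_nonconverged,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Simulate (optionally), fit, summarize, correlate and classify.

    Writes the CFU table (simulation runs), the per-replicate fit table,
    strain summaries, the correlation report, combination calls, the
    determinant correlations and a JSON run log under ``config.output_dir``.
    Identical config and seeds reproduce identical outputs.
    """
    logging.basicConfig(
        level=getattr(logging, config.verbosity.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    if config.input_path is not None:
        log.info("reading CFU table from %s", config.input_path)
        curves = read_cfu_table(config.input_path)
        truth = None
    elif config.scenario is not None:
        log.info("simulating study (seed=%d)", config.scenario.seed)
        data, truth = generate_study(config.scenario, config.design)
        write_cfu_table(data, out / "cfu_table.csv")
        truth.to_csv(out / "truth_table.csv", index=False)
        curves = read_cfu_table(out / "cfu_table.csv")
    else:
        raise ValueError("config needs either an input_path or a scenario")
    log.info("fitting %d replicate curves", len(curves))
    fit_df, fits = fit_table(curves, config.fit)
    fit_df.to_csv(out / "fit_table.csv", index=False)
    bundle["fits"] = fit_df

    summaries = _summaries_from_fits(fits)
    summaries.to_csv(out / "strain_summaries.csv", index=False)
    bundle["summaries"] = summaries

    singles = sorted(t for t in summaries["treatment"].unique() if "+" not in t)
    corrs, skipped = cross_antibiotic_correlations(summaries, config.analysis, singles)
    corr_df = pd.DataFrame(
        [
            {"treatment_1": c.pair[0], "treatment_2": c.pair[1], "rho": c.rho,
             "p_value": c.p_value, "n": c.n, "method": c.method}
            for c in corrs
        ]
    )
    corr_df.to_csv(out / "correlations.csv", index=False)
    bundle["correlations"] = corr_df

    calls = []
    pair_treatments = [t for t in summaries["treatment"].unique() if "+" in t]
    wide = summaries.pivot_table(index="strain", columns="treatment", values="mean_log10_fp")
    for trt in pair_treatments:
        t1, t2 = trt.split("+")
        for strain in wide.index:
            vals = wide.loc[strain]
            if any(pd.isna(vals.get(k)) for k in (t1, t2)):
                continue
            f_ab = 10 ** vals[trt] if not pd.isna(vals.get(trt)) else 0.0
            call = classify_combination(
                10 ** vals[t1], 10 ** vals[t2], f_ab, config.analysis,
                strain=strain, pair=(t1, t2),
            )
            calls.append(
                {"strain": strain, "pair": trt, "f_A": call.f_A, "f_B": call.f_B,
                 "f_AB": call.f_AB, "label": call.label,
                 "d_coincident": call.d_coincident, "d_independent": call.d_independent}
            )
    call_df = pd.DataFrame(calls)
    call_df.to_csv(out / "combination_calls.csv", index=False)
    bundle["combination_calls"] = call_df

    det_df = pd.DataFrame()
    mech_rows = fit_df.dropna(subset=["fp_mid", "a", "b", "m"]) if "a" in fit_df else pd.DataFrame()
    if len(mech_rows) >= 3:
        dets = parameter_determinants(
            mech_rows.rename(columns={"fp_mid": "fp"})[["fp", "a", "b", "m"]], config.analysis
        )
        det_df = pd.DataFrame(
            [{"rate": c.pair[1], "rho": c.rho, "p_value": c.p_value, "n": c.n} for c in dets]
        )
    det_df.to_csv(out / "determinants.csv", index=False)
    bundle["determinants"] = det_df

    run_log = {
        "version": __version__,
        "fit_seed": config.fit.seed,
        "analysis_seed": config.analysis.seed,
        "scenario_seed": config.scenario.seed if config.scenario else None,
        "n_curves": len(curves),
        "n_converged": int(fit_df["converged"].sum()) if "converged" in fit_df else 0,
        "skipped_correlations": skipped,
        "note": "fp is the persister fraction; the normal-cell fraction convention "
                "is F0 = 1 - fp (columns F0_normal_*)",
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2))
    bundle["run_log"] = run_log
    if truth is not None:
        bundle["truth"] = truth
    return bundle
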