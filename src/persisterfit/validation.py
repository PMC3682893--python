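"""End-to-end validation experiments for the whole pipeline.

Each function regenerates its inputs from a seed, runs the package's own
machinery, and returns summary numbers: closed-form vs numerical-integration
agreement, stochastic-simulation agreement, identifiability coverage,
persister-fraction recovery, model selection, combination classification and
study-level correlation discrimination.  These are the quantitative checks
behind the claims the package makes about itself; the test suite asserts
thresholds on their outputs and the reproduction script reports them.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.integrate import solve_ivp

from .inference import FitConfig, compare_single_exponential, fit_replicate
from .model import (
    InitialState,
    MechanisticParams,
    feasible_fp_interval,
    mech_to_obs,
    obs_to_mech,
    total_cfu,
)
from .study import AnalysisConfig, classify_combination, spearman
from .synthetic import (
    PlatingDesign,
    StudyScenario,
    generate_study,
    simulate_kill_curve,
    simulate_stochastic,
    switching_rate_for_fraction,
)

__all__ = [
    "RATE_RANGES",
    "closed_form_agreement",
    "stochastic_oracle_agreement",
    "identifiability_coverage",
    "fraction_recovery",
    "model_selection_accuracy",
    "combination_classifier_accuracy",
    "study_discrimination",
]

# log-uniform draw ranges for randomized model checks (per hour / fraction)
RATE_RANGES = {"m": (0.1, 5.0), "a": (1e-6, 0.1), "b": (1e-6, 0.5), "fp": (1e-6, 0.2)}

#: fast multi-start configuration used for the large study sweeps
STUDY_FIT = FitConfig(n_starts=3, algorithms=("bfgs",))


def _draw_params(rng: np.random.Generator):
    vals = {
        k: math.exp(rng.uniform(math.log(lo), math.log(hi)))
        for k, (lo, hi) in RATE_RANGES.items()
    }
    return MechanisticParams(vals["m"], vals["a"], vals["b"]), InitialState(1e7, vals["fp"])


def closed_form_agreement(n_draws: int = 1000, seed: int = 0) -> dict:
    """Max relative deviation of the closed-form total from adaptive ODE
    integration (LSODA, rtol 1e-11) over random parameter draws, t in [0, 48] h."""
    rng = np.random.default_rng(seed)
    tt = np.linspace(0.0, 48.0, 9)
    worst = 0.0
    for _ in range(n_draws):
        mech, init = _draw_params(rng)

        def rhs(t, y):
            return [-(mech.m + mech.a) * y[0] + mech.b * y[1], mech.a * y[0] - mech.b * y[1]]

        sol = solve_ivp(rhs, [0, 48], [init.n0, init.p0], t_eval=tt,
                        method="LSODA", rtol=1e-11, atol=1e-290)
        ref = sol.y.sum(axis=0)
        total = np.asarray(total_cfu(mech_to_obs(mech, init), tt))
        worst = max(worst, float(np.max(np.abs(total - ref) / ref)))
    return {"max_rel_error": worst, "n": n_draws}


def stochastic_oracle_agreement(
    n_runs: int = 1000, n_total: int = 10_000, fp: float = 0.01, seed: int = 0,
    mech: MechanisticParams | None = None,
) -> dict:
    """Ensemble-mean deviation of the exact event simulator from the closed
    form, in standard-error units, at the sampling-schedule times."""
    mech = mech or MechanisticParams(2.0, 0.01, 0.05)
    tt = np.array(PlatingDesign().schedule)
    p0 = int(round(fp * n_total))
    n0 = n_total - p0
    ss = np.random.SeedSequence(seed).spawn(n_runs)
    tot = np.empty((n_runs, len(tt)))
    for i in range(n_runs):
        n, p = simulate_stochastic(mech, n0, p0, tt, np.random.default_rng(ss[i]))
        tot[i] = n + p
    closed = np.asarray(total_cfu(mech_to_obs(mech, InitialState(float(n_total), fp)), tt))
    se = tot.std(axis=0, ddof=1) / math.sqrt(n_runs)
    z = np.abs(tot.mean(axis=0) - closed) / np.maximum(se, 1e-12)
    return {"max_abs_z": float(z.max()), "n": n_runs}


def identifiability_coverage(n_draws: int = 1000, seed: int = 0) -> dict:
    """Over random mechanisms: does the feasible interval contain the
    generating fp, and does the inverse map at the true fp return the rates?"""
    rng = np.random.default_rng(seed)
    covered = 0
    worst_rel = 0.0
    for _ in range(n_draws):
        mech, init = _draw_params(rng)
        obs = mech_to_obs(mech, init)
        iv = feasible_fp_interval(obs)
        if iv.contains(init.fp, atol=1e-9):
            covered += 1
        back = obs_to_mech(obs, init.fp)
        for est, true in ((back.m, mech.m), (back.a, mech.a), (back.b, mech.b)):
            worst_rel = max(worst_rel, abs(est - true) / max(true, 1e-300))
    return {"coverage": covered / n_draws, "max_rel_error": worst_rel, "n": n_draws}


def fraction_recovery(
    n_per_fp: int = 50,
    fps: tuple[float, ...] = (1e-4, 1e-3, 1e-2, 1e-1),
    seed: int = 0,
    config: FitConfig | None = None,
) -> dict:
    """Recovery of log10 fp from seeded Poisson curves on the 9-point schedule.

    Fixed study conditions: kill rate m = 2 /h, exit rate b = 0.01 /h,
    N0 = 5e7 CFU/ml, entry rate a set by the growth-phase balance at each fp.
    """
    design = PlatingDesign()
    errors = []
    ss = np.random.SeedSequence(seed).spawn(len(fps) * n_per_fp)
    k = 0
    for fp in fps:
        b, m = 0.01, 2.0
        mech = MechanisticParams(m, switching_rate_for_fraction(fp, b, 2.0), b)
        init = InitialState(5e7, fp)
        for _ in range(n_per_fp):
            curve = simulate_kill_curve(mech, init, design, np.random.default_rng(ss[k]))
            k += 1
            fit = fit_replicate(curve, config or FitConfig(seed=0))
            errors.append(abs(math.log10(fit.fp_point) - math.log10(fp)))
    errors = np.asarray(errors)
    return {
        "fraction_within_0p3": float(np.mean(errors <= 0.3)),
        "median_abs_log10_error": float(np.median(errors)),
        "n": len(errors),
    }


def model_selection_accuracy(n_runs: int = 50, seed: int = 0,
                             config: FitConfig | None = None) -> dict:
    """Fraction of correct biphasic/monophasic calls under each regime."""
    config = config or FitConfig(n_starts=4)
    design = PlatingDesign()
    ss = np.random.SeedSequence(seed).spawn(2 * n_runs)
    # monophasic truth: no persisters, single exponential kill
    mono = MechanisticParams(2.0, 0.0, 0.0)
    mono_init = InitialState(5e7, 0.0)
    # biphasic truth: 1% persisters, slow exit
    fp = 0.01
    bi = MechanisticParams(2.0, switching_rate_for_fraction(fp, 0.01, 2.0), 0.01)
    bi_init = InitialState(5e7, fp)
    correct_mono = correct_bi = 0
    for i in range(n_runs):
        c = simulate_kill_curve(mono, mono_init, design, np.random.default_rng(ss[i]))
        if not compare_single_exponential(c, config).biphasic:
            correct_mono += 1
        c = simulate_kill_curve(bi, bi_init, design, np.random.default_rng(ss[n_runs + i]))
        if compare_single_exponential(c, config).biphasic:
            correct_bi += 1
    return {
        "single_exponential_correct": correct_mono / n_runs,
        "biexponential_correct": correct_bi / n_runs,
        "n": n_runs,
    }


def combination_classifier_accuracy(
    n_per_hypothesis: int = 300, noise_log10: float = 0.15, seed: int = 0
) -> dict:
    """Label accuracy on noisy synthetic (f_A, f_B, f_AB) triples.

    Single-drug fractions are log-uniform on [1e-3, 0.1] (the well-measured
    range in which combination assays are run); measurement noise of
    ``noise_log10`` decades perturbs each fraction.
    """
    rng = np.random.default_rng(seed)
    cfg = AnalysisConfig()
    acc = {}
    for hyp in ("exclusive", "independent", "coincident"):
        hits = 0
        for _ in range(n_per_hypothesis):
            f_a, f_b = 10 ** rng.uniform(-3, -1, 2)
            if hyp == "exclusive":
                f_ab = 0.0
            elif hyp == "independent":
                f_ab = f_a * f_b
            else:
                f_ab = min(f_a, f_b)
            noisy = [
                v * 10 ** (noise_log10 * rng.standard_normal()) if v > 0 else 0.0
                for v in (f_a, f_b, f_ab)
            ]
            if classify_combination(noisy[0], noisy[1], noisy[2], cfg).label == hyp:
                hits += 1
        acc[hyp] = hits / n_per_hypothesis
    acc["n"] = n_per_hypothesis
    return acc


def _study_rhos(scenario: StudyScenario, fit_config: FitConfig, analysis: AnalysisConfig):
    """Fit every replicate of a simulated study; pairwise Spearman rho of
    per-strain mean log10 fractions."""
    design = PlatingDesign()
    data, _ = generate_study(scenario, design)
    rhos = []
    log_fp = {}
    for (strain, trt), grp in data.groupby(["strain", "treatment"]):
        vals = []
        for _, rep in grp.groupby("replicate"):
            from .inference import KillCurve, Observation

            rep = rep.sort_values("time_h")
            curve = KillCurve(
                strain, trt, "r",
                tuple(Observation(r.time_h, int(r.cfu), r.plated_volume_ml)
                      for r in rep.itertuples()),
            )
            fit = fit_replicate(curve, fit_config)
            if fit.converged and fit.fp_point and fit.fp_point > 0:
                vals.append(math.log10(fit.fp_point))
        if vals:
            log_fp[(strain, trt)] = float(np.mean(vals))
    for t1, t2 in itertools.combinations(scenario.antibiotics, 2):
        xs, ys = [], []
        for s in {k[0] for k in log_fp}:
            if (s, t1) in log_fp and (s, t2) in log_fp:
                xs.append(log_fp[(s, t1)])
                ys.append(log_fp[(s, t2)])
        rhos.append(spearman(xs, ys, analysis, pair=(t1, t2)).rho)
    return rhos


def study_discrimination(
    n_studies: int = 20, seed: int = 0, fit_config: FitConfig | None = None
) -> dict:
    """Contrast the shared-fraction and independent-fraction study designs.

    Under the multidrug-tolerance (shared) design every strain keeps one
    characteristic fraction across antibiotics, so all pairwise rho should be
    strongly positive; under the independent design rho should stay inside
    the small-sample null band (|rho| < 0.58, the two-sided 5% critical value
    at n = 12).
    """
    fit_config = fit_config or STUDY_FIT
    analysis = AnalysisConfig(seed=seed)
    out: dict = {"n": n_studies}
    for model in ("shared", "independent"):
        per_study = []
        for j in range(n_studies):
            sc = StudyScenario(
                n_strains=12, n_replicates=6, fraction_model=model,
                seed=(seed * 1_000_003 + j) % (2**31 - 1),
            )
            per_study.append(_study_rhos(sc, fit_config, analysis))
        flat = [r for rhos in per_study for r in rhos]
        if model == "shared":
            out["shared_all_rho_above_0p7"] = float(
                np.mean([all(r > 0.7 for r in rhos) for rhos in per_study])
            )
            out["shared_min_rho"] = float(min(flat))
        else:
            out["independent_rho_within_null_band"] = float(
                np.mean([abs(r) < 0.58 for r in flat])
            )
            out["independent_studies_all_within_band"] = float(
                np.mean([all(abs(r) < 0.58 for r in rhos) for rhos in per_study])
            )
    return out
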