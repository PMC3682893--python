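"""Synthetic kill-curve data with the error structure the fitter assumes.

The generator emulates a standard persister time-kill experiment: cultures
grown into exponential phase, antibiotic added at t = 0, hourly CFU samples
for the first 4 h (serial dilution, 5 ul spot plating) plus late samples near
20/24/28/48 h (100-500 ul plated directly), six biological replicates, and
persister fractions spanning below 1e-5 to above 0.1.  Counts are pure
Poisson draws around the deterministic two-state mean — exactly the sampling
model the likelihood assumes.  An exact event-driven (Gillespie) simulator of
the underlying jump process is included as an independent stochastic oracle
for the closed-form mean.

All randomness flows from a single scenario seed through
numpy.random.SeedSequence spawning, so identical seeds reproduce
byte-identical datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inference import KillCurve, Observation
from .model import InitialState, MechanisticParams, mech_to_obs, total_cfu

__all__ = [
    "PlatingDesign",
    "StudyScenario",
    "COMBINATION_HYPOTHESES",
    "design_dilutions",
    "simulate_kill_curve",
    "simulate_stochastic",
    "generate_study",
]

COMBINATION_HYPOTHESES = ("exclusive", "independent", "coincident")


@dataclass(frozen=True)
class PlatingDesign:
    """Sampling schedule and dilution/plating rules.

    schedule : sampling times in hours after drug addition
    culture_volume : culture volume per replicate (ml)
    spot_volume : early-phase spot-plate volume (ml)
    late_plated_volumes : allowed direct plating volumes late in the curve (ml)
    target_count_range : desired colonies per plate
    max_dilution_exponent : serial dilutions allowed up to 10^-k
    late_threshold_h : times at/after this use the late plating rule
    """

    schedule: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0, 20.0, 24.0, 28.0, 48.0)
    culture_volume: float = 1.5
    spot_volume: float = 0.005
    late_plated_volumes: tuple[float, ...] = (0.1, 0.2, 0.5)
    target_count_range: tuple[float, float] = (10.0, 300.0)
    max_dilution_exponent: int = 8
    late_threshold_h: float = 8.0

    def __post_init__(self) -> None:
        ts = self.schedule
        if ts[0] != 0.0 or any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("schedule must start at 0 and increase strictly")
        if self.spot_volume <= 0 or min(self.late_plated_volumes) <= 0:
            raise ValueError("plating volumes must be positive")
        if self.target_count_range[0] >= self.target_count_range[1]:
            raise ValueError("target count range must be nonempty")

    def allowed_deltas(self, t: float) -> np.ndarray:
        """Allowed effective plated volumes at time t, descending."""
        if t >= self.late_threshold_h:
            bases = self.late_plated_volumes
        else:
            bases = (self.spot_volume,)
        ks = np.arange(self.max_dilution_exponent + 1)
        vals = np.unique(np.outer(np.asarray(bases), 10.0 ** (-ks)).ravel())
        return vals[::-1]


@dataclass(frozen=True)
class StudyScenario:
    """Design of a simulated multi-strain, multi-antibiotic persister study.

    fraction_model : "shared" draws one fp per strain reused for every
        antibiotic (the multidrug-tolerance hypothesis); "independent" draws
        fp per strain x antibiotic (the no-shared-mechanism hypothesis).
    combination_hypothesis : generative rule for antibiotic pairs —
        exclusive (fp_AB = 0), independent (fp_AB = fp_A * fp_B) or
        coincident (fp_AB = min(fp_A, fp_B)).
    growth_rate : pre-treatment exponential growth rate (per hour) used to
        back out the normal->persister switching rate a from fp via the
        growth-phase balance a ~= fp (growth_rate + b) / (1 - fp).
    """

    n_strains: int = 12
    antibiotics: tuple[str, ...] = ("ampicillin", "ciprofloxacin", "nalidixic_acid")
    pairs: tuple[tuple[str, str], ...] = ()
    n_replicates: int = 6
    fraction_model: str = "independent"
    combination_hypothesis: str = "coincident"
    fp_range: tuple[float, float] = (1e-5, 0.1)
    m_range: tuple[float, float] = (0.5, 5.0)
    b_range: tuple[float, float] = (1e-4, 0.1)
    N0_range: tuple[float, float] = (1e7, 1e8)
    growth_rate: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fraction_model not in ("shared", "independent"):
            raise ValueError(f"unknown fraction_model {self.fraction_model!r}")
        if self.combination_hypothesis not in COMBINATION_HYPOTHESES:
            raise ValueError(
                f"unknown combination hypothesis {self.combination_hypothesis!r}; "
                f"expected one of {COMBINATION_HYPOTHESES}"
            )
        for rng_ in (self.fp_range, self.m_range, self.b_range, self.N0_range):
            if rng_[0] <= 0 or rng_[1] < rng_[0]:
                raise ValueError(f"parameter range must be positive and ordered: {rng_}")
        for pair in self.pairs:
            if any(ab not in self.antibiotics for ab in pair):
                raise ValueError(f"pair {pair} references an unknown antibiotic")


def design_dilutions(obs, design: PlatingDesign) -> np.ndarray:
    """Effective plated volume delta_t for each scheduled time.

    At each time the expected concentration N(t) is evaluated and the largest
    allowed delta with expected count N(t)*delta at or below the upper target
    is chosen; when even the largest delta undershoots the lower target (the
    detection-limit regime at late times) that largest delta is used anyway.
    Deterministic in its inputs.
    """
    lo, hi = design.target_count_range
    out = np.empty(len(design.schedule))
    for i, t in enumerate(design.schedule):
        N = float(total_cfu(obs, t))
        cands = design.allowed_deltas(t)
        chosen = cands[-1]  # most dilute fallback for huge N
        for dl in cands:  # descending: first not overshooting wins
            if N * dl <= hi:
                chosen = dl
                break
        out[i] = chosen
    return out


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_kill_curve(
    mech: MechanisticParams,
    init: InitialState,
    design: PlatingDesign,
    seed,
    strain: str = "sim",
    treatment: str = "drug",
    replicate: str = "r1",
) -> KillCurve:
    """Poisson CFU counts around the deterministic two-state mean."""
    rng = _as_rng(seed)
    obs = mech_to_obs(mech, init)
    deltas = design_dilutions(obs, design)
    means = np.asarray(total_cfu(obs, np.asarray(design.schedule))) * deltas
    counts = rng.poisson(means)
    observations = tuple(
        Observation(t=t, x=int(x), delta=float(dl))
        for t, x, dl in zip(design.schedule, counts, deltas)
    )
    return KillCurve(
        strain=strain, treatment=treatment, replicate=replicate, observations=observations
    )


def simulate_stochastic(
    mech: MechanisticParams, n0: int, p0: int, t_grid, seed
) -> tuple[np.ndarray, np.ndarray]:
    """Exact event-driven simulation of the two-state jump process.

    Three event types with propensities m*n (death of a normal cell), a*n
    (normal -> persister) and b*p (persister -> normal); the ensemble mean
    converges to the closed-form trajectory.  Returns integer (n, p) at each
    grid time.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t_grid) <= 0) or t_grid[0] < 0:
        raise ValueError("t_grid must be nonnegative and strictly increasing")
    rng = _as_rng(seed)
    m, a, b = mech.m, mech.a, mech.b
    n, p = int(n0), int(p0)
    out_n = np.empty(len(t_grid), dtype=np.int64)
    out_p = np.empty(len(t_grid), dtype=np.int64)
    t = 0.0
    i = 0
    exp_sampler = rng.exponential
    uni = rng.random
    ma = m + a
    while i < len(t_grid):
        rate = ma * n + b * p
        if rate <= 0.0:
            break
        t_next = t + exp_sampler() / rate
        while i < len(t_grid) and t_grid[i] < t_next:
            out_n[i], out_p[i] = n, p
            i += 1
        if i >= len(t_grid):
            break
        t = t_next
        u = uni() * rate
        if u < m * n:
            n -= 1
        elif u < ma * n:
            n -= 1
            p += 1
        else:
            p -= 1
            n += 1
    out_n[i:], out_p[i:] = n, p
    return out_n, out_p


def switching_rate_for_fraction(fp: float, b: float, growth_rate: float) -> float:
    """Normal->persister rate a sustaining fraction fp during growth.

    At balanced exponential growth (rate g) the persister inflow a*n matches
    the outflow (b + g)*p, giving a = fp (g + b) / (1 - fp) for the
    quasi-stationary fraction.
    """
    if not 0.0 <= fp < 1.0:
        raise ValueError(f"fp must be in [0, 1), got {fp}")
    return fp * (growth_rate + b) / (1.0 - fp)


def _pair_label(pair: tuple[str, str]) -> str:
    return "+".join(pair)


def generate_study(
    scenario: StudyScenario, design: PlatingDesign | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full strain x treatment x replicate study.

    Returns ``(data, truth)``: a long-format CFU table (one row per plated
    sample; columns strain, treatment, replicate, time_h, plated_volume_ml,
    cfu) and a truth table of the generating parameters per strain x
    treatment.  Combination treatments derive fp from the pair's hypothesis
    and take the kill rate of the more lethal drug.
    """
    design = design or PlatingDesign()
    root = np.random.SeedSequence(scenario.seed)
    ss_params, ss_curves = root.spawn(2)
    rng = np.random.default_rng(ss_params)

    def log_uniform(lohi, size=None):
        lo, hi = lohi
        return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))

    strains = [f"S{i + 1:02d}" for i in range(scenario.n_strains)]
    truth_rows = []
    params: dict[tuple[str, str], tuple[MechanisticParams, InitialState]] = {}

    shared_fp = {s: log_uniform(scenario.fp_range) for s in strains}
    for s in strains:
        for ab in scenario.antibiotics:
            fp = shared_fp[s] if scenario.fraction_model == "shared" else log_uniform(scenario.fp_range)
            m = log_uniform(scenario.m_range)
            b = log_uniform(scenario.b_range)
            N0 = log_uniform(scenario.N0_range)
            a = switching_rate_for_fraction(fp, b, scenario.growth_rate)
            params[(s, ab)] = (MechanisticParams(m=m, a=a, b=b), InitialState(N0=N0, fp=fp))
        for pair in scenario.pairs:
            mA, iA = params[(s, pair[0])]
            mB, iB = params[(s, pair[1])]
            hyp = scenario.combination_hypothesis
            if hyp == "exclusive":
                fp_ab = 0.0
            elif hyp == "independent":
                fp_ab = iA.fp * iB.fp
            else:  # coincident: the more lethal drug's persisters survive
                fp_ab = min(iA.fp, iB.fp)
            m_ab = max(mA.m, mB.m)  # more lethal drug dominates the kill
            b_ab = (mA if mA.m >= mB.m else mB).b
            a_ab = switching_rate_for_fraction(fp_ab, b_ab, scenario.growth_rate)
            N0_ab = log_uniform(scenario.N0_range)
            params[(s, _pair_label(pair))] = (
                MechanisticParams(m=m_ab, a=a_ab, b=b_ab),
                InitialState(N0=N0_ab, fp=fp_ab),
            )

    treatments = list(scenario.antibiotics) + [_pair_label(p) for p in scenario.pairs]
    n_curves = len(strains) * len(treatments) * scenario.n_replicates
    curve_seeds = ss_curves.spawn(n_curves)
    rows = []
    k = 0
    for s in strains:
        for trt in treatments:
            mech, init = params[(s, trt)]
            truth_rows.append(
                {
                    "strain": s, "treatment": trt, "fp": init.fp, "F0_normal": 1.0 - init.fp,
                    "m": mech.m, "a": mech.a, "b": mech.b, "N0": init.N0,
                    "hypothesis": scenario.combination_hypothesis if "+" in trt else "",
                }
            )
            for r in range(1, scenario.n_replicates + 1):
                curve = simulate_kill_curve(
                    mech, init, design, np.random.default_rng(curve_seeds[k]),
                    strain=s, treatment=trt, replicate=f"r{r}",
                )
                k += 1
                for o in curve.observations:
                    rows.append(
                        {
                            "strain": s, "treatment": trt, "replicate": f"r{r}",
                            "time_h": o.t, "plated_volume_ml": o.delta, "cfu": o.x,
                        }
                    )
    data = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    return data, truth
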