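"""Study-level statistics over per-replicate persister-fraction fits.

Aggregates replicate fits into strain x treatment summaries (on the log10
scale, since persister fractions span four orders of magnitude), tests for
cross-antibiotic correlation of persister fractions with Spearman rank
correlations and permutation p-values, classifies combination-treatment
fractions against the exclusive / independent / coincident hypotheses, and
correlates fractions with the underlying switching and death rates.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .inference import FitResult

__all__ = [
    "StrainSummary",
    "CorrelationResult",
    "CombinationCall",
    "AnalysisConfig",
    "summarize_strain",
    "spearman",
    "cross_antibiotic_correlations",
    "classify_combination",
    "parameter_determinants",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the study-level statistics.

    n_permutations : Monte-Carlo permutations for Spearman p-values
    exact_max_n : exhaustive permutation enumeration at or below this n
    tau_log10 : combination-classification tolerance (log10 units)
    detection_bound : fraction below which a combination count is treated as
        no surviving persisters (exclusive)
    seed : RNG seed for Monte-Carlo permutations
    """

    n_permutations: int = 10_000
    exact_max_n: int = 7
    tau_log10: float = 0.5
    detection_bound: float = 1e-7
    seed: int = 0


@dataclass(frozen=True)
class StrainSummary:
    strain: str
    treatment: str
    n_replicates: int
    mean_log10_fp: float | None
    se_log10_fp: float | None
    mean_slow_fraction: float | None
    n_detection_limited: int = 0
    n_nonconverged: int = 0

    @property
    def available(self) -> bool:
        return self.mean_log10_fp is not None


@dataclass(frozen=True)
class CorrelationResult:
    pair: tuple[str, str]
    rho: float
    p_value: float
    n: int
    method: str  # "exact-permutation" | "monte-carlo"
    seed: int | None = None
    flag: str | None = None


@dataclass(frozen=True)
class CombinationCall:
    strain: str
    pair: tuple[str, str]
    f_A: float
    f_B: float
    f_AB: float
    label: str  # exclusive | independent | coincident | ambiguous
    d_coincident: float
    d_independent: float


def summarize_strain(fits: list[FitResult]) -> StrainSummary:
    """Mean and SE of log10 persister fraction across converged replicates.

    Detection-limited replicates contribute their rule-of-three upper bound
    (and are counted in the flag); nonconverged replicates are dropped.
    """
    if not fits:
        raise ValueError("summarize_strain needs at least one fit")
    strain = fits[0].curve.strain
    treatment = fits[0].curve.treatment
    vals: list[float] = []
    slow: list[float] = []
    n_dl = n_nc = 0
    for f in fits:
        if not f.converged or f.fp_point is None or f.fp_point <= 0:
            n_nc += 1
            continue
        if "detection_limit" in f.flags:
            n_dl += 1
        vals.append(math.log10(f.fp_point))
        if f.slow_fraction is not None and f.slow_fraction > 0:
            slow.append(f.slow_fraction)
    if not vals:
        return StrainSummary(strain, treatment, 0, None, None, None, n_dl, n_nc)
    arr = np.asarray(vals)
    se = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) >= 2 else None
    return StrainSummary(
        strain=strain,
        treatment=treatment,
        n_replicates=len(arr),
        mean_log10_fp=float(arr.mean()),
        se_log10_fp=se,
        mean_slow_fraction=float(np.mean(slow)) if slow else None,
        n_detection_limited=n_dl,
        n_nonconverged=n_nc,
    )


def _rank_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    """Pearson correlation of (average) ranks — Spearman's rho with ties."""
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    den = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
    if den == 0.0:
        return math.nan
    return float(rxc @ ryc) / den


def spearman(
    xs, ys, config: AnalysisConfig | None = None, pair: tuple[str, str] = ("x", "y")
) -> CorrelationResult:
    """Spearman rank correlation with a permutation p-value.

    rho uses average ranks on ties.  The two-sided p-value counts
    permutations of one vector with |rho| at least the observed |rho|:
    exhaustively over all n! orderings when n <= config.exact_max_n,
    otherwise by seeded Monte-Carlo with the add-one estimator
    (1 + #extreme) / (1 + B).  A constant vector leaves rho undefined and
    returns a flagged result.
    """
    config = config or AnalysisConfig()
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("xs and ys must be equal-length 1-d sequences")
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    rx, ry = rankdata(x), rankdata(y)
    rho = _rank_rho(rx, ry)
    if math.isnan(rho):
        return CorrelationResult(pair, math.nan, math.nan, n, "undefined", None, "constant-input")
    tol = 1e-12
    if n <= config.exact_max_n:
        count = total = 0
        for perm in itertools.permutations(range(n)):
            r = _rank_rho(rx, ry[list(perm)])
            total += 1
            if abs(r) >= abs(rho) - tol:
                count += 1
        return CorrelationResult(pair, rho, count / total, n, "exact-permutation")
    rng = np.random.default_rng(config.seed)
    B = config.n_permutations
    perms = np.stack([rng.permutation(ry) for _ in range(B)])
    rxc = rx - rx.mean()
    pc = perms - perms.mean(axis=1, keepdims=True)
    den = np.sqrt(float(rxc @ rxc)) * np.sqrt((pc * pc).sum(axis=1))
    rhos = (pc @ rxc) / den
    k = int(np.sum(np.abs(rhos) >= abs(rho) - tol))
    return CorrelationResult(pair, rho, (1 + k) / (1 + B), n, "monte-carlo", config.seed)


def _summary_frame(summaries) -> pd.DataFrame:
    if isinstance(summaries, pd.DataFrame):
        return summaries
    return pd.DataFrame(
        [
            {
                "strain": s.strain,
                "treatment": s.treatment,
                "mean_log10_fp": s.mean_log10_fp,
                "se_log10_fp": s.se_log10_fp,
            }
            for s in summaries
        ]
    )


def cross_antibiotic_correlations(
    summaries, config: AnalysisConfig | None = None, treatments: list[str] | None = None
) -> tuple[list[CorrelationResult], list[str]]:
    """Pairwise Spearman correlation of strain persister fractions.

    For each unordered treatment pair, strains with a summary in both
    treatments are matched on their mean log10 fraction; pairs with fewer
    than 3 complete strains are skipped with a logged reason.  Returns
    (results, skipped-messages).
    """
    config = config or AnalysisConfig()
    df = _summary_frame(summaries).dropna(subset=["mean_log10_fp"])
    if treatments is None:
        treatments = sorted(t for t in df["treatment"].unique() if "+" not in t)
    results: list[CorrelationResult] = []
    skipped: list[str] = []
    wide = df.pivot_table(index="strain", columns="treatment", values="mean_log10_fp")
    for t1, t2 in itertools.combinations(treatments, 2):
        if t1 not in wide.columns or t2 not in wide.columns:
            skipped.append(f"{t1} vs {t2}: treatment missing from summaries")
            continue
        sub = wide[[t1, t2]].dropna()
        if len(sub) < 3:
            skipped.append(f"{t1} vs {t2}: only {len(sub)} complete strain pairs")
            continue
        results.append(spearman(sub[t1].values, sub[t2].values, config, pair=(t1, t2)))
    return results, skipped


def classify_combination(
    f_A: float,
    f_B: float,
    f_AB: float,
    config: AnalysisConfig | None = None,
    strain: str = "",
    pair: tuple[str, str] = ("A", "B"),
) -> CombinationCall:
    """Classify a combination-treatment persister fraction.

    Hypotheses for simultaneous treatment with drugs A and B:
    exclusive — no cell persists in both, f_AB ~ 0 (below detection);
    independent — persistence mechanisms co-occur at random,
    f_AB ~ f_A * f_B; coincident — persisters of the more lethal drug also
    persist in the other, f_AB ~ min(f_A, f_B).  The call is the nearer
    hypothesis on the log10 scale when within tau, else ambiguous; a
    below-detection f_AB is exclusive regardless of distances.
    """
    config = config or AnalysisConfig()
    if f_A <= 0 or f_B <= 0:
        raise ValueError("single-drug fractions must be positive to classify")
    if f_AB < 0:
        raise ValueError("combination fraction must be >= 0")
    if f_A <= config.detection_bound or f_B <= config.detection_bound:
        raise ValueError("single-drug fractions must exceed the detection bound")
    if f_AB > 0:
        d_coin = abs(math.log10(f_AB) - math.log10(min(f_A, f_B)))
        d_ind = abs(math.log10(f_AB) - math.log10(f_A * f_B))
    else:
        d_coin = d_ind = math.inf
    if f_AB <= config.detection_bound:
        label = "exclusive"
    elif min(d_coin, d_ind) > config.tau_log10:
        label = "ambiguous"
    else:
        label = "coincident" if d_coin <= d_ind else "independent"
    return CombinationCall(
        strain=strain, pair=pair, f_A=f_A, f_B=f_B, f_AB=f_AB,
        label=label, d_coincident=d_coin, d_independent=d_ind,
    )


def parameter_determinants(
    table: pd.DataFrame, config: AnalysisConfig | None = None
) -> list[CorrelationResult]:
    """Correlate persister fractions with the mechanistic rates.

    ``table`` holds one row per strain x treatment with columns fp, a, b, m
    (natural scale).  Returns Spearman correlations of log10(fp) against
    log10(a), log10(b) and log10(m) pooled across strains and treatments —
    the structure behind asking whether the entry rate into the persister
    state, the exit rate, or the kill rate drives the fraction.
    """
    config = config or AnalysisConfig()
    sub = table[["fp", "a", "b", "m"]].astype(float)
    sub = sub[(sub > 0).all(axis=1)]
    if len(sub) < 3:
        raise ValueError(f"need at least 3 positive parameter rows, got {len(sub)}")
    lfp = np.log10(sub["fp"].values)
    out = []
    for var in ("a", "b", "m"):
        lv = np.log10(sub[var].values)
        if np.allclose(lv, lv[0]) or np.allclose(lfp, lfp[0]):
            out.append(
                CorrelationResult(("fp", var), math.nan, math.nan, len(sub),
                                  "undefined", None, "constant-input")
            )
        else:
            out.append(spearman(lfp, lv, config, pair=("fp", var)))
    return out
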