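"""Do strains keep a characteristic persister fraction across antibiotics?

Aggregates the per-replicate fits into strain x antibiotic means of
log10 fraction and computes pairwise Spearman correlations with seeded
Monte-Carlo permutation p-values.  The shared design should show strong
positive correlations for every antibiotic pair; the independent design
should show correlations inside the small-sample null band — the
signature distinguishing a single multidrug-tolerance mechanism from
antibiotic-specific persistence.

Writes strain_summaries_<design>.csv and correlations_<design>.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from persisterfit import AnalysisConfig, cross_antibiotic_correlations

OUT = Path(__file__).resolve().parent.parent / "results"


def summarize(fit_df: pd.DataFrame) -> pd.DataFrame:
    ok = fit_df[fit_df.converged & (fit_df.fp_point > 0)].copy()
    ok["log10_fp"] = np.log10(ok["fp_point"])
    g = ok.groupby(["strain", "treatment"])["log10_fp"]
    return (
        g.agg(
            n_replicates="count",
            mean_log10_fp="mean",
            se_log10_fp=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan,
        )
        .reset_index()
    )


def main() -> None:
    cfg = AnalysisConfig(seed=0)
    for model in ("shared", "independent"):
        fit_df = pd.read_csv(OUT / f"fit_table_{model}.csv")
        summ = summarize(fit_df)
        summ.to_csv(OUT / f"strain_summaries_{model}.csv", index=False)
        results, skipped = cross_antibiotic_correlations(summ, cfg)
        rows = [
            {"treatment_1": c.pair[0], "treatment_2": c.pair[1], "rho": c.rho,
             "p_value": c.p_value, "n": c.n, "method": c.method}
            for c in results
        ]
        pd.DataFrame(rows).to_csv(OUT / f"correlations_{model}.csv", index=False)
        print(f"{model} design:")
        for c in results:
            print(
                f"  {c.pair[0]} vs {c.pair[1]}: rho = {c.rho:+.2f}, "
                f"p = {c.p_value:.3f}, N = {c.n}"
            )
        for msg in skipped:
            print(f"  skipped: {msg}")


if __name__ == "__main__":
    main()
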