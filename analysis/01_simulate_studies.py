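"""Simulate the two competing study designs.

Generates two 12-strain, 3-antibiotic, 6-replicate kill-curve studies with
identical plating design but opposite persister-fraction structure:

* ``shared``      — each strain has one characteristic fraction across all
                    antibiotics (what multidrug tolerance through a single
                    mechanism such as dormancy would produce);
* ``independent`` — fractions are drawn separately per strain x antibiotic
                    (no shared mechanism).

Writes cfu_table_<design>.csv and truth_table_<design>.csv under results/.
"""

from pathlib import Path

from persisterfit import PlatingDesign, StudyScenario, generate_study

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20130204


def main() -> None:
    OUT.mkdir(exist_ok=True)
    design = PlatingDesign()
    for model in ("shared", "independent"):
        scenario = StudyScenario(fraction_model=model, seed=SEED)
        data, truth = generate_study(scenario, design)
        data.to_csv(OUT / f"cfu_table_{model}.csv", index=False)
        truth.to_csv(OUT / f"truth_table_{model}.csv", index=False)
        lo, hi = truth["fp"].min(), truth["fp"].max()
        print(
            f"{model}: {truth['strain'].nunique()} strains x "
            f"{truth['treatment'].nunique()} antibiotics, "
            f"{len(data)} plated samples; true fractions span "
            f"{lo:.2e} .. {hi:.2e}"
        )


if __name__ == "__main__":
    main()
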