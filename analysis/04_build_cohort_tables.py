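"""Run the volume-level pipeline end to end for both cohorts: per-subject
tractograms and metric maps -> virtual dissection -> trilinear tract means
-> cohort tables.

Every subject gets an independent anatomy realisation (fresh streamline
jitter), as in a study where tractography and ROI dissection are done per
participant.  Writes results/cohort/{neonates,adults}.tsv and the
per-subject dissection recovery report.
"""

from pathlib import Path

from slf_maturation import pipeline

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    out = ROOT / "cohort"
    out.mkdir(parents=True, exist_ok=True)
    result = pipeline.run_synthetic_study(seed=SEED)
    result.neonate_table.to_csv(out / "neonates.tsv", sep="\t", index=False)
    result.adult_table.to_csv(out / "adults.tsv", sep="\t", index=False)
    result.recovery.to_csv(out / "dissection_recovery.tsv", sep="\t", index=False)
    for name, table in (
        ("neonate", result.neonate_table),
        ("adult", result.adult_table),
    ):
        lr = [c for c in table.columns if c.endswith("_LR")]
        print(
            f"{name}: {len(table)} subjects, {len(lr)} averaged tract-metric "
            f"columns; SLF_II NDI mean = {table['SLF_II_NDI_LR'].mean():.3f}"
        )
    print(
        f"dissection: worst per-subject recovery "
        f"{result.recovery.recovery_pct.min():.1f}%, contaminants admitted "
        f"{result.recovery.contaminants_admitted.sum()}"
    )
    print(f"wrote cohort tables to {out}")


if __name__ == "__main__":
    main()
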