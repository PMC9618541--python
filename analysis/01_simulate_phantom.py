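"""Generate the synthetic study data: phantom ROI labels, whole-phantom
tractograms for both protocols (with ground-truth provenance), and the
two-cohort tract-mean tables.

Writes everything under results/phantom/.
"""

import json
from pathlib import Path

from slf_maturation import io_formats as iof
from slf_maturation import synthetic_data as sd

OUT = Path(__file__).resolve().parent.parent / "results" / "phantom"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    layout, labels = sd.make_phantom(seed=SEED)
    iof.write_volume(labels, OUT / "labels.nii.gz")
    with open(OUT / "label_ids.json", "w") as fh:
        json.dump(layout.label_ids, fh, indent=2)

    for protocol in ("adult", "neonate"):
        tractogram, provenance = sd.simulate_tractogram(
            layout, sd.default_bundle_mix(protocol), seed=SEED
        )
        iof.write_tck(tractogram, OUT / f"tractogram_{protocol}.tck")
        with open(OUT / f"provenance_{protocol}.json", "w") as fh:
            json.dump({"bundle": provenance}, fh)
        print(
            f"{protocol}: {len(tractogram)} streamlines "
            f"({sum(1 for p in provenance if p.startswith(('callosal', 'arcuate')))}"
            " contaminants)"
        )

    neo, adult = sd.simulate_cohort_tables(seed=SEED)
    neo.to_csv(OUT / "neonates_direct.tsv", sep="\t", index=False)
    adult.to_csv(OUT / "adults_direct.tsv", sep="\t", index=False)
    print(
        f"cohort tables: {len(neo)} neonates "
        f"({neo.age.min():.1f}-{neo.age.max():.1f} wk PMA), "
        f"{len(adult)} adults ({adult.age.min():.1f}-{adult.age.max():.1f} y)"
    )
    print(f"wrote phantom data to {OUT}")


if __name__ == "__main__":
    main()
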