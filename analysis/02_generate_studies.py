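#!/usr/bin/env python
"""Generate the synthetic xenograft studies used by the fits.

Emulates caliper-measured HCT116-like subcutaneous xenograft arms:
cohorts of 12 animals, lognormal inter-animal variation of the growth
constant, treatment starting once the cohort mean reaches 200 mm^3,
weekly dosing, twice-weekly measurements with 10% proportional noise.

Writes one dataset per study (recovery + two model-selection studies)
under results/studies/<name>/, each with per-arm TSV files and a
ground-truth JSON sidecar.
"""

from pathlib import Path

import angiosched as ang

OUT = Path(__file__).resolve().parent.parent / "results" / "studies"


def main():
    ds, truth, _ = ang.studies.make_recovery_study(seed=11)
    ang.save_study(OUT / "recovery", ds, truth)
    print("recovery study (threshold truth):")
    for d in ds:
        rx = truth["arms"][d.arm]["treatment_start_day"]
        print(f"  {d.arm:8s} n={d.n_animals} treatment from day {rx}; "
              f"final mean {d.volumes[-1]:.0f} mm^3")

    for variant in ("threshold", "continuous"):
        ds, truth, _ = ang.studies.make_selection_study(variant, seed=21)
        ang.save_study(OUT / f"selection_{variant}", ds, truth)
        print(f"selection study ({variant} truth): folfox arm final mean "
              f"{[d for d in ds if d.arm == 'folfox'][0].volumes[-1]:.0f} "
              "mm^3")
    print("wrote", OUT)


if __name__ == "__main__":
    main()
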