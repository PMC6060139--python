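#!/usr/bin/env python
"""Treatment predictions from the recovery best fit.

Uses the least-squares particle of the recovery posterior (from
03_fit_recovery.py, re-fitting if absent) to predict interventions the
study never ran:

* a bvz x FOLFOX dose grid (percent tumour reduction vs vehicle at the
  study horizon) — the dose heatmap;
* a three-week treatment break after two combination cycles, showing
  regrowth during the washout and renewed decline on resumption.

Writes results/predictions/.
"""

import json
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

import angiosched as ang
from angiosched.simulate import SimConfig

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "predictions"
FAST = SimConfig(fast=True)


def best_fit_params():
    path = ROOT / "fits" / "recovery" / "best_fit.json"
    if path.exists():
        d = json.loads(path.read_text())["params"]
    else:
        pops, *_ = ang.studies.run_recovery(progress=True)
        d = ang.best_fit(pops[-1]).as_dict()
    growth = ang.GrowthParams(lambda1=d["lambda1"], lambda2=d["lambda2"],
                              c=d["c"], d=d["d"], alpha=d["alpha"],
                              kf=d["Kf"])
    chemo = ang.ChemoResponse("threshold", alpha2=d["alpha2"], hill=d["p1"])
    pk = {ang.Drug.BVZ: ang.PKParams(d["Bk12"], d["Bk21"], d["Bke"]),
          ang.Drug.FOLFOX: ang.PKParams(d["Fk12"], d["Fk21"], d["Fke"])}
    return growth, chemo, pk


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    growth, chemo, pk = best_fit_params()
    v0, k0 = 200.0, 1000.0  # enrolment-sized tumour, K = 5 V

    grid = ang.dose_heatmap(growth, chemo, pk,
                            np.linspace(0, 20, 6), np.linspace(0, 112, 6),
                            ang.ts2_schedule(horizon=45.0), v0, k0, FAST)
    grid.to_csv(OUT / "dose_heatmap.tsv", sep="\t")
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(grid.to_numpy(), origin="lower", aspect="auto",
                   extent=[0, 112, 0, 20], cmap="viridis")
    fig.colorbar(im, label="% tumour reduction vs vehicle")
    ax.set_xlabel("FOLFOX dose (mg)")
    ax.set_ylabel("bvz dose (mg)")
    fig.tight_layout()
    fig.savefig(OUT / "dose_heatmap.png", dpi=120)
    plt.close(fig)
    print("dose grid (% reduction):")
    print(grid.round(1).to_string())

    sched = ang.ts2_schedule(n_cycles=6, horizon=60.0)
    base = ang.simulate(growth, chemo, sched, pk, v0, k0, FAST)
    broken = ang.break_forecast(growth, chemo, pk, sched, 14.5, 21.0,
                                v0, k0, FAST)
    base.to_csv(OUT / "uninterrupted.tsv")
    broken.to_csv(OUT / "three_week_break.tsv")
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(base.times, base.v, label="uninterrupted")
    ax.plot(broken.times, broken.v, label="3-week break after 2 cycles")
    ax.axvspan(14.5, 35.5, alpha=0.15, color="grey", label="break")
    ax.set_xlabel("day")
    ax.set_ylabel("tumour volume (mm$^3$)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(OUT / "treatment_break.png", dpi=120)
    plt.close(fig)
    print(f"\nfinal volume uninterrupted: {base.v[-1]:.0f} mm^3; "
          f"with 3-week break: {broken.v[-1]:.0f} mm^3 "
          f"(at day {broken.times[-1]:.0f})")
    print("wrote", OUT)


if __name__ == "__main__":
    main()
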