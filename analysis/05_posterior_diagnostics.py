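#!/usr/bin/env python
"""Posterior diagnostics of the recovery fit.

Reads the populations written by 03_fit_recovery.py (re-running the
fit if they are absent) and computes:

* precision-based relative sensitivities (inverse weighted posterior
  covariance, diagonal scaled by the squared posterior mean) — which
  parameters the data pin down; the growth constant should rank top;
* per-parameter Kolmogorov-Smirnov shifts between the prior generation
  and the final posterior — how far the data moved each marginal;
* the posterior correlation structure (e.g. the recruitment/inhibition
  ridge between c and d).

Writes tables and a marginal-posterior figure under
results/fits/recovery/.
"""

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

import angiosched as ang
from angiosched.inference import Population

FITDIR = Path(__file__).resolve().parent.parent / "results" / "fits" / \
    "recovery"


def load_or_run():
    gen_files = sorted(FITDIR.glob("population_gen*.tsv"))
    if gen_files:
        pops = [Population.from_csv(p, generation=i)
                for i, p in enumerate(gen_files)]
        return pops
    pops, *_ = ang.studies.run_recovery(progress=True)
    FITDIR.mkdir(parents=True, exist_ok=True)
    return pops


def main():
    pops = load_or_run()
    prior_gen, posterior = pops[0], pops[-1]
    names = ang.PriorSpec().names(1)

    sens = ang.sensitivities(posterior, "threshold")
    sens_tab = sens.scores.sort_values(ascending=False).rename("score")
    sens_tab.to_csv(FITDIR / "sensitivities.tsv", sep="\t")
    print("relative sensitivities (top constrains the fit most):")
    print(sens_tab.head(6).to_string())

    shifts = {p: ang.posterior_shift(prior_gen, posterior, p, "threshold")
              for p in names}
    shift_tab = pd.Series(shifts).sort_values(ascending=False) \
        .rename("ks_prior_to_posterior")
    shift_tab.to_csv(FITDIR / "prior_posterior_ks.tsv", sep="\t")
    print("\nKS shift from prior (how much the data moved each marginal):")
    print(shift_tab.head(6).to_string())

    # weighted posterior correlations
    sel = posterior.m == 1
    th, w = posterior.theta[sel], posterior.weights[sel]
    w = w / w.sum()
    mu = w @ th
    xc = th - mu
    cov = (xc * w[:, None]).T @ xc
    sd = np.sqrt(np.diag(cov))
    corr = pd.DataFrame(cov / np.outer(sd, sd), index=names, columns=names)
    corr.to_csv(FITDIR / "posterior_correlations.tsv", sep="\t")
    print(f"\ncorr(c, d) = {corr.loc['c', 'd']:.2f} "
          "(recruitment/inhibition ridge)")

    fig, axes = plt.subplots(2, 7, figsize=(18, 5))
    for ax, p in zip(axes.ravel(), names):
        x, wx = posterior.marginal(p, "threshold")
        ax.hist(x, weights=wx, bins=30, density=True, alpha=0.7)
        lo, hi = ang.PriorSpec().ranges[p]
        ax.axhline(1.0 / (hi - lo), color="grey", ls="--", lw=0.8)
        ax.set_title(p, fontsize=8)
        ax.tick_params(labelsize=6)
    fig.suptitle("marginal posteriors (dashed: prior density)")
    fig.tight_layout()
    fig.savefig(FITDIR / "posteriors.png", dpi=120)
    print("\nwrote diagnostics to", FITDIR)


if __name__ == "__main__":
    main()
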