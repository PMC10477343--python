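#!/usr/bin/env python
"""Fit both strain models to the synthetic flask datasets.

First recovers the four promoter Hill parameters from the dose-response
grid (these stay fixed in the flask fit, as they came from a separate
reporter strain), then runs the normalized least-squares flask fit per
strain and reports each recovered parameter against its generating value.

Run 02_generate_flasks.py first.
"""

from pathlib import Path

from hisicc import hill_fit, load_flasks, ta1415_model, ta2445_model
from hisicc.datasets import load_promoter
from hisicc.fitting import FREE_DEFAULT, fit_parameters
from hisicc.params import save_model

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 2026


def truth_of(model, name):
    return (getattr(model.shared, name) if hasattr(model.shared, name)
            else getattr(model.quorum, name))


def main() -> None:
    promoter = load_promoter(OUT / "promoter_grid.csv")
    hf = hill_fit(promoter)
    print("promoter Hill fit (truth in parentheses):")
    q = ta2445_model().quorum
    for name in ("K_A", "K_u", "n_A", "n_u"):
        print(f"  {name} = {getattr(hf, name):.4g} ({getattr(q, name):.4g})")

    for strain, template in (("TA1415", ta1415_model()),
                             ("TA2445", ta2445_model())):
        flasks = load_flasks(OUT / f"flasks_{strain}.csv")
        fit = fit_parameters(flasks, template, n_starts=4, seed=SEED)
        print(f"\n{strain}: objective V = {fit.cost:.4g}, "
              f"{fit.nfev} evaluations, converged={fit.success}")
        for name in FREE_DEFAULT[strain]:
            t = truth_of(template, name)
            est = fit.theta[name]
            print(f"  {name:7s} = {est:10.4g}  (truth {t:.4g}, "
                  f"rel err {abs(est - t) / abs(t):.1%})")
        save_model(fit.model, OUT / f"fitted_params_{strain}.yaml")
        print(f"  wrote {OUT / f'fitted_params_{strain}.yaml'}")


if __name__ == "__main__":
    main()
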