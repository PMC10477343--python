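#!/usr/bin/env python
"""Model-based optimization of the IPTG input for both strains.

Sweeps the feasible input region (0-15 h addition time for TA1415,
0.01-1.0 mM for TA2445), refines the optimum, writes the sweep tables and
a figure of the two yield-versus-input curves, and prints the optima.
With the published parameter values this lands at ~9.35 h and ~0.044 mM.
"""

import json
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt

from hisicc import optimize_input, ta1415_model, ta2445_model

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    for ax, model, unit in ((axes[0], ta1415_model(), "h"),
                            (axes[1], ta2445_model(), "mM")):
        opt = optimize_input(model)
        opt.sweep.to_csv(OUT / f"input_sweep_{model.strain}.csv", index=False)
        (OUT / f"optimum_{model.strain}.json").write_text(json.dumps(
            {"strain": model.strain, "u_opt": opt.u_opt,
             "yield_opt": opt.yield_opt}, indent=2))
        print(f"{model.strain}: optimal input {opt.u_opt:.4g} {unit}, "
              f"predicted final IPA {opt.yield_opt:.2f} mM")
        ax.plot(opt.sweep["input_value"], opt.sweep["final_ipa_mM"], "-")
        ax.axvline(opt.u_opt, ls=":", color="r")
        if model.strain == "TA2445":
            ax.set_xscale("log")
        ax.set_xlabel(f"IPTG input ({unit})")
        ax.set_ylabel("final IPA (mM)")
        ax.set_title(model.strain)
    fig.tight_layout()
    fig.savefig(OUT / "input_sweeps.png", dpi=150)
    print(f"wrote {OUT / 'input_sweeps.png'}")


if __name__ == "__main__":
    main()
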