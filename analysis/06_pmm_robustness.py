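#!/usr/bin/env python
"""Robustness of the two control architectures to growth-rate mismatch.

With each strain's IPTG input frozen at the model optimum, the simulated
"true" process is given growth parameters k1*, k2* that deviate from the
controller model's k1, k2 by factors 0.5-1.5 (11x11 grid).  The final IPA
yield per grid point, normalized by the matched-model optimum IPA_opt,
shows how much yield each architecture loses when the cells grow faster or
slower than predicted.  The quorum-sensing strain (TA2445) senses the
actual cell density and shifts its toggle activation accordingly, so its
surface stays near 1 in the faster-growth quadrant where the open-loop
strain (TA1415) loses yield.

Run 05_optimize_inputs.py first.
"""

import json
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt

from hisicc import compare_strains, pmm_surface, ta1415_model, ta2445_model
from hisicc.pmm import quadrant_summary

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    surfaces = {}
    for model in (ta1415_model(), ta2445_model()):
        u_opt = json.loads(
            (OUT / f"optimum_{model.strain}.json").read_text())["u_opt"]
        s = pmm_surface(model, u_opt)
        s.to_frame().to_csv(OUT / f"pmm_surface_{model.strain}.csv", index=False)
        surfaces[model.strain] = s
        print(f"{model.strain}: IPA_opt = {s.ipa_opt:.2f} mM at fixed input "
              f"{u_opt:.4g}; surface range "
              f"{s.normalized.min():.3f}-{s.normalized.max():.3f} of optimum")

    comparison = compare_strains(surfaces["TA1415"], surfaces["TA2445"])
    comparison.to_csv(OUT / "pmm_comparison.csv", index=False)
    summary = quadrant_summary(comparison, ("TA1415", "TA2445"))
    print("\nmean normalized yield by mismatch quadrant:")
    print(summary.to_string(index=False))

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.8),
                             subplot_kw={"projection": "3d"})
    for ax, (strain, s) in zip(axes, surfaces.items()):
        import numpy as np
        r1, r2 = np.meshgrid(s.ratios_k1, s.ratios_k2, indexing="ij")
        ax.plot_surface(r1, r2, s.yields, cmap="viridis")
        ax.scatter([1.0], [1.0], [s.ipa_opt], color="r", s=25)
        ax.set_xlabel("k1*/k1")
        ax.set_ylabel("k2*/k2")
        ax.set_zlabel("final IPA (mM)")
        ax.set_title(strain)
    fig.tight_layout()
    fig.savefig(OUT / "pmm_surfaces.png", dpi=150)
    print(f"\nwrote {OUT / 'pmm_surfaces.png'}")


if __name__ == "__main__":
    main()
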