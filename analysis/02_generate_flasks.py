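#!/usr/bin/env python
"""Generate the synthetic flask datasets used by the fitting and validation
steps: 5 IPTG input conditions x 3 flasks per strain, sampled every 3 h,
with 5% multiplicative measurement noise plus a small additive floor.

Also generates the promoter dose-response grid (AHL x IPTG) emulating the
GFP-reporter measurements behind the quorum-sensing Hill parameters.
"""

from pathlib import Path

from hisicc import PipelineConfig, generate_promoter_grid, run_pipeline, ta2445_model
from hisicc.datasets import save_promoter

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 2026


def main() -> None:
    for strain in ("TA1415", "TA2445"):
        cfg = PipelineConfig(strain=strain, out_dir=OUT, seed=SEED)
        artifacts = run_pipeline(cfg, stages=["generate"])
        print(f"{strain}: wrote {artifacts['generate']}")

    promoter = generate_promoter_grid(ta2445_model().quorum, noise_cv=0.05,
                                      seed=SEED)
    path = OUT / "promoter_grid.csv"
    save_promoter(promoter, path)
    print(f"promoter dose-response grid ({len(promoter.data)} wells): {path}")


if __name__ == "__main__":
    main()
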