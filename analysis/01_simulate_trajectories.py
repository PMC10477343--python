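#!/usr/bin/env python
"""Simulate both strain models under their five experimental IPTG inputs.

Writes noiseless state and observation trajectories for TA1415 (IPTG added
at 0, 6, 9, 12, 15 h) and TA2445 (constant IPTG at 0.01-1.0 mM) to
results/trajectories_<strain>.csv, and prints the final IPA yield per
condition.  These are the model curves that overlay the flask measurements.
"""

from pathlib import Path

from hisicc import PipelineConfig, run_pipeline

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    for strain in ("TA1415", "TA2445"):
        cfg = PipelineConfig(strain=strain, out_dir=OUT, seed=0)
        artifacts = run_pipeline(cfg, stages=["simulate"])
        print(f"{strain}: wrote {artifacts['simulate']}")
        import pandas as pd
        df = pd.read_csv(artifacts["simulate"], comment="#")
        finals = df.groupby("input_value").last()
        unit = "h" if strain == "TA1415" else "mM"
        for u, row in finals.iterrows():
            print(f"  input {u:g} {unit}: final OD600 {row['OD600']:.2f}, "
                  f"final IPA {row['IPA_mM']:.1f} mM")


if __name__ == "__main__":
    main()
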