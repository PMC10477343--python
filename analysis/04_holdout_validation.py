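#!/usr/bin/env python
"""Hold-out validation of both fitted models on the synthetic flask data.

Each flask under the three middle IPTG input conditions is held out in
turn; the model is refitted on the remaining 12 flasks (warm-started from
the all-data fit) and the held-out timecourse is scored with R² per
channel.  The generalization criterion is R² >= 0.5 for every held-out
flask and channel.

Run 02_generate_flasks.py and 03_fit_parameters.py first.
"""

from pathlib import Path

from hisicc import load_flasks, load_model, ta1415_model, ta2445_model
from hisicc.fitting import FREE_DEFAULT
from hisicc.validation import holdout_validate, rounds_to_frame

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    for strain, template in (("TA1415", ta1415_model()),
                             ("TA2445", ta2445_model())):
        flasks = load_flasks(OUT / f"flasks_{strain}.csv")
        fitted = load_model(OUT / f"fitted_params_{strain}.yaml")
        warm = {name: (getattr(fitted.shared, name)
                       if hasattr(fitted.shared, name)
                       else getattr(fitted.quorum, name))
                for name in FREE_DEFAULT[strain]}
        rounds = holdout_validate(flasks, template, warm_start=warm)
        df = rounds_to_frame(rounds)
        df.to_csv(OUT / f"validation_{strain}.csv", index=False)
        worst = df["r_squared"].min()
        print(f"{strain}: {len(rounds)} hold-out rounds, "
              f"{len(df)} R² values; min R² = {worst:.3f} "
              f"({'meets' if worst >= 0.5 else 'FAILS'} the 0.5 criterion)")
        for r in rounds:
            print(f"  {r.flask_id} (input {r.input_value:g}): "
                  f"R² OD600 {r.r2_od600:.3f}, IPA {r.r2_ipa:.3f}")


if __name__ == "__main__":
    main()
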