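"""Build the discretionary-salt scenarios.

"calculated": 90% of urinary-sodium-derived total salt for adults, with
child salt scaled from region-mean adult salt by energy; "recommended":
the WHO 5 g/d for adults, energy-scaled for children.  Prints the group
means next to the reference design values.
"""

import argparse
from pathlib import Path

import pandas as pd

import saltfort as sf
from saltfort.pipeline import _write_csv


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    survey = pd.read_csv(args.out / "survey.csv")
    scenarios = [sf.build_scenario(survey, name)
                 for name in ("calculated", "recommended")]
    table = pd.concat([s.salt for s in scenarios], ignore_index=True)
    _write_csv(table, args.out / "salt_scenarios.csv")

    merged = table.merge(survey[["participant_id", "region", "life_stage"]],
                         on="participant_id")
    means = (merged.groupby(["region", "life_stage", "scenario"])
             ["discretionary_salt_g_d"].mean().round(1).unstack())
    design = sf.REFERENCE_SALT_G_D.set_index(["region", "life_stage"])
    print("group-mean discretionary salt (g/d), simulated vs reference design:")
    print(means.join(design, rsuffix="_design").to_string())


if __name__ == "__main__":
    main()
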