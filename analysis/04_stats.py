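#!/usr/bin/env python
"""Condition statistics on the unique contributions.

Selects, per regressor, the electrodes showing a prediction gain over the
conditions where the process is expected, averages delta r over them per
participant and condition, and runs the 2x2 repeated-measures ANOVA
(visual contact x musical input) with Bonferroni correction across the
four regressors.
"""

import argparse
import importlib.util as _ilu
from pathlib import Path

import pandas as pd

from dyadtrf.pipeline import run_pipeline

_spec = _ilu.spec_from_file_location(
    "sim01", Path(__file__).with_name("01_simulate.py"))
_sim01 = _ilu.module_from_spec(_spec)
_spec.loader.exec_module(_sim01)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=_sim01.DEFAULT_RUN)
    args = parser.parse_args()

    run_dir = run_pipeline(_sim01.config_for(args.seed), stages=["stats"],
                           out_dir=args.out)
    anova = pd.read_csv(run_dir / "stats" / "anova.csv")
    print("2x2 repeated-measures ANOVA on delta r "
          "(Bonferroni x4 across regressors):")
    print(anova[["regressor", "effect", "F", "df1", "df2", "p", "p_bonf"]]
          .round(4).to_string(index=False))
    electrodes = pd.read_csv(run_dir / "stats" / "electrodes.csv")
    counts = electrodes.groupby("regressor")["channel"].count()
    print("\nelectrodes with a prediction gain per regressor:")
    print(counts.to_string())


if __name__ == "__main__":
    main()
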