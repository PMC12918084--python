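#!/usr/bin/env python
"""Assemble the target-population post-stratification frame.

Reads the CSV inputs written by 01_generate_inputs.py and combines three
blocks under mutual independence: the joint of the resident-survey covariates
estimated directly from target microdata, the labour-force-block joint raked
(IPF) to the local margins, and the deprivation-quintile margin pooled from
the LSOA decile table.  Writes results/frame.csv (11,520 cells with weights)
and results/comparison.csv (source-vs-target proportions per covariate
level, the data behind dumbbell plots).
"""

from pathlib import Path

import pandas as pd

from healthmrp.pipeline import build_frame, compare_demographics, read_margins_csv
from healthmrp.schema import default_schema
from healthmrp.synthetic import SourceSurvey

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    schema = default_schema()
    inputs = ROOT / "results" / "inputs"
    target = pd.read_csv(inputs / "target_microdata.csv", dtype=str)
    lfs = pd.read_csv(inputs / "lfs_microdata.csv", dtype=str)
    margins = read_margins_csv(inputs / "lfs_margins.csv", schema)
    lsoa = pd.read_csv(inputs / "lsoa_imd.csv")

    frame, deviation = build_frame(schema, target, lfs, margins, lsoa)
    frame.to_csv(ROOT / "results" / "frame.csv")
    print(f"frame: {frame.cell_index.n_cells} cells, "
          f"weights sum {frame.weights.sum():.12f}, "
          f"raking margin deviation {deviation:.2e}")

    survey = SourceSurvey.from_csv(inputs / "source_survey.csv", schema)
    comparison = compare_demographics(survey, frame)
    comparison.to_csv(ROOT / "results" / "comparison.csv", index=False)
    lit = comparison[comparison["outcome"] == "literacy"]
    biggest = lit.reindex(lit["difference"].abs().sort_values(ascending=False).index)
    print("largest source-vs-target gaps (literacy subsample):")
    for _, row in biggest.head(5).iterrows():
        print(f"  {row['variable']}={row['level']:10s} source {row['source_prop']:.2f} "
              f"target {row['target_prop']:.2f}  diff {row['difference']:+.2f}")


if __name__ == "__main__":
    main()
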