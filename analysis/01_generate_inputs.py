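#!/usr/bin/env python
"""Generate the synthetic study inputs from a known ground truth.

Writes the full input set to results/inputs/: a source skills survey
(n = 4000, three binary outcomes on nested subsamples), target-borough
microdata (n = 3000 over age/sex/ethnicity/working/home-ownership),
labour-force microdata (n = 3000 over the remaining covariates, drawn from a
deliberately non-local joint) with the local margins raking must hit, and a
164-LSOA deprivation-decile population table.  The generating parameters are
saved alongside so later stages can be checked against them.
"""

from pathlib import Path

from healthmrp.synthetic import OUTCOMES, make_default_bundle

SEED = 42
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    bundle = make_default_bundle(SEED)
    paths = bundle.write(ROOT / "results" / "inputs")

    survey = bundle.source_survey
    print(f"seed {SEED}: wrote {len(paths)} input files to {ROOT / 'results/inputs'}")
    print(f"source survey: {len(survey.data)} records")
    for o in OUTCOMES:
        sub = survey.subsample(o)
        print(f"  {o:9s} subsample n={len(sub):5d}  "
              f"prevalence(not literate)={sub[o].mean():.3f}")
    print(f"target microdata: {len(bundle.target_microdata)} records; "
          f"LFS microdata: {len(bundle.lfs_microdata)} records; "
          f"LSOA table: {len(bundle.lsoa_table)} rows")


if __name__ == "__main__":
    main()
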