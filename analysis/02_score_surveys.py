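#!/usr/bin/env python
"""Score the cohort's questionnaires and the feasibility survey.

Reads surveys.tsv and feasibility_items.tsv from step 01, writes scale
scores (scores.tsv), per-scale Cronbach alpha at baseline, and the
feasibility composites.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from dyadmind import io as dio
from dyadmind.survey_scoring import SCALES, cronbach_alpha, feasibility_composites, score_scale


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    responses = dio.read_surveys(args.out / "surveys.tsv")
    rows = [
        {
            "dyad_id": r.dyad_id,
            "respondent": r.respondent,
            "scale_id": r.scale_id,
            "timepoint": r.timepoint,
            "score": score_scale(r, SCALES[r.scale_id]),
        }
        for r in responses
    ]
    scores = pd.DataFrame(rows)
    scores.to_csv(args.out / "scores.tsv", sep="\t", index=False)

    print("baseline scale reliability (Cronbach alpha):")
    for scale_id in sorted({r.scale_id for r in responses}):
        items = np.array(
            [r.items for r in responses if r.scale_id == scale_id and r.timepoint == "pre"]
        )
        print(f"  {scale_id}: alpha={cronbach_alpha(items):.2f} (n={len(items)})")

    feas = pd.read_csv(args.out / "feasibility_items.tsv", sep="\t", index_col=0)
    comps = pd.DataFrame(
        [feasibility_composites(row.to_numpy()) for _, row in feas.iterrows()]
    )
    comps.to_csv(args.out / "feasibility_composites.tsv", sep="\t", index=False)
    print(
        f"feasibility (n={len(comps)} parents): positive {comps.positive_avg.mean():.2f}, "
        f"negative {comps.negative_avg.mean():.2f}, overall {comps.overall_avg.mean():.2f}"
    )


if __name__ == "__main__":
    main()
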