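#!/usr/bin/env python
"""Assemble the outcome battery over the scored cohort.

Reads scores.tsv from step 02, builds paired samples per measure and
comparison (pre vs post, pre vs follow-up), runs the full battery (MAD
outlier screening, normality routing, one-sided tests, paired Cohen d,
95% CI, BH-FDR within the parental self-report family), and writes the
summary table plus a plain-text report.
"""

import argparse
from pathlib import Path

import pandas as pd

from dyadmind.stats_report import MeasurePlan, PairedSample, outcome_table, render_report

#: Hypothesized improvement direction and FDR family per measure.
PLANS = [
    MeasurePlan("cdi_child", "decrease", family="child", respondent="child"),
    MeasurePlan("cdi_parent", "decrease", family="child"),
    MeasurePlan("dass_stress", "decrease", family="parent_self_report"),
    MeasurePlan("gad7", "decrease", family="parent_self_report"),
    MeasurePlan("phq9", "decrease", family="parent_self_report"),
    MeasurePlan("maas", "increase", family="mindfulness"),
]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    scores = pd.read_csv(args.out / "scores.tsv", sep="\t")
    samples = []
    for (scale_id, respondent), grp in scores.groupby(["scale_id", "respondent"]):
        wide = grp.pivot_table(index="dyad_id", columns="timepoint", values="score")
        for comparison in ("post", "followup"):
            if comparison not in wide:
                continue
            samples.append(
                PairedSample(
                    measure=scale_id,
                    pre=tuple(wide["pre"]),
                    after=tuple(wide[comparison]),
                    respondent=respondent,
                    comparison=comparison,
                )
            )
    table = outcome_table(samples, PLANS)
    table.to_csv(args.out / "outcomes.tsv", sep="\t", index=False)
    report = render_report(table)
    (args.out / "outcomes_report.txt").write_text(report)
    print(report)


if __name__ == "__main__":
    main()
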