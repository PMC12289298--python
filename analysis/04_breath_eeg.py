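#!/usr/bin/env python
"""Attention-to-breath neural analysis for one synthetic cohort.

Simulates 41 participants (pre: DMN alpha boosted during mind-wandering;
post: boost removed), runs each session through the full pipeline (clean,
epoch to the 4 s before each tap, minimum-norm source projection, alpha
power, network ROI averages, MAD consistency split, low-minus-high
differential), and reports the paired pre/post contrast per network.
"""

import argparse
from pathlib import Path

import numpy as np

from dyadmind.studies import _simulate_cohort_contrast
from dyadmind.synthetic_data import default_roi_set, make_synthetic_leadfield


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--n-participants", type=int, default=41)
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    lead_field = make_synthetic_leadfield()
    roi = default_roi_set(lead_field.source_labels)
    rng = np.random.default_rng(args.seed)
    contrast = _simulate_cohort_contrast(
        rng, args.n_participants, fs=100.0, duration_s=300.0,
        boost_active_post=False, lead_field=lead_field, roi=roi,
    )
    contrast.to_csv(args.out / "neural_contrast.tsv", sep="\t", index_label="network")
    print("post - pre change in the low-vs-high consistency alpha differential:")
    for net, row in contrast.iterrows():
        print(
            f"  {net}: mean change {row.mean_change:+.4f}, d={row.d:+.2f}, "
            f"z={abs(row.z):.2f}, one-sided p={row.p:.3g} (n={int(row.n)})"
        )
    print("expected: DMN significantly reduced, FPN/CON unchanged")


if __name__ == "__main__":
    main()
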