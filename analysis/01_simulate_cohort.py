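#!/usr/bin/env python
"""Generate the synthetic study inputs: dyad cohort surveys, training logs,
feasibility responses, and one example breath-tap + EEG recording.

Writes delimited text under the output directory; later analysis steps read
these files. All downstream quantities are fully determined by --seed.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from dyadmind import io as dio
from dyadmind.synthetic_data import (
    EffectConfig,
    LatentAttentionProfile,
    generate_cohort,
    generate_feasibility_responses,
    make_synthetic_leadfield,
    simulate_breath_run,
    simulate_eeg,
    simulate_training_course,
    state_gains,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--n-dyads", type=int, default=24)
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(args.seed).generate_state(8) % (2**31)

    cohort = generate_cohort(EffectConfig(n_dyads=args.n_dyads, seed=int(seeds[0])))
    dio.write_surveys([r for d in cohort for r in d.surveys], args.out / "surveys.tsv")
    demo = pd.DataFrame(
        {
            "dyad_id": [d.dyad_id for d in cohort],
            "child_age": [d.child_age for d in cohort],
            "parent_age": [d.parent_age for d in cohort],
            "child_sex": [d.child_sex for d in cohort],
            "parent_sex": [d.parent_sex for d in cohort],
            "affluence_score": [d.affluence_score for d in cohort],
        }
    )
    demo.to_csv(args.out / "demographics.tsv", sep="\t", index=False)

    # per-dyad training courses: skill drawn around a competent pair
    rng = np.random.default_rng(int(seeds[1]))
    logs = []
    for d in cohort:
        log = simulate_training_course(
            skill_child=float(np.clip(rng.normal(0.75, 0.1), 0.2, 1.0)),
            skill_parent=float(np.clip(rng.normal(0.85, 0.08), 0.2, 1.0)),
            n_sessions=30,
            seed=int(rng.integers(2**31)),
        )
        log.insert(0, "dyad_id", d.dyad_id)
        logs.append(log.drop(columns=["passes"]))
    pd.concat(logs).to_csv(args.out / "training_logs.tsv", sep="\t", index=False)

    feas = generate_feasibility_responses(args.n_dyads, seed=int(seeds[2]))
    pd.DataFrame(feas, columns=[f"item_{i}" for i in range(16)]).to_csv(
        args.out / "feasibility_items.tsv", sep="\t", index_label="parent"
    )

    # one worked example of the neural raw data (10 s only, to keep it small)
    lf = make_synthetic_leadfield()
    dio.write_leadfield(lf, args.out / "leadfield.tsv")
    series, states = simulate_breath_run(
        LatentAttentionProfile(), duration_s=10, block_duration_s=10, seed=int(seeds[3])
    )
    eeg = simulate_eeg(series, states, lf, state_gains("pre", 0.35), noise_sd=4.5,
                       fs=100.0, seed=int(seeds[4]))
    dio.write_taps(series, args.out / "example_taps.tsv")
    dio.write_eeg_text(eeg, args.out / "example_eeg.tsv")

    print(f"wrote cohort of {args.n_dyads} dyads to {args.out}/")
    print(f"  training: mean final level "
          f"{pd.concat(logs).groupby('dyad_id').level_end.max().mean():.1f} of 10")


if __name__ == "__main__":
    main()
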