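#!/usr/bin/env python
"""Generate the synthetic wing datasets used by the downstream analysis scripts.

Emulates the reference study design: 140 reference wings (two species x two
sexes, n = 50/50/20/20) with realistic centroid-size overlap and separated
mean shapes; 16 "field" test wings from other collection rounds; and
double-digitization sets (same user, different users) for repeatability.
Writes landmark tables under results/data/.
"""

import argparse
from pathlib import Path

from wingmorph import write_landmark_table
from wingmorph.synthetic_data import (
    simulate_reference_dataset,
    simulate_replicated_digitization,
    study_design_spec,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    out = ROOT / "results" / "data"
    out.mkdir(parents=True, exist_ok=True)

    reference = simulate_reference_dataset(study_design_spec(seed=args.seed))
    write_landmark_table(reference, out / "reference.tsv")
    print(f"reference: {len(reference)} wings, k={reference.k} -> {out / 'reference.tsv'}")

    tests = simulate_reference_dataset(study_design_spec(seed=args.seed + 54, n_scale=0.1))
    write_landmark_table(tests, out / "tests.tsv")
    print(f"test specimens: {len(tests)} wings -> {out / 'tests.tsv'}")

    # 10 wings per species digitized twice; inter-user run has larger error
    subset = reference.subset(list(range(10)) + list(range(100, 110)))
    intra = simulate_replicated_digitization(
        subset, error_sd=0.004, m=2, seed=args.seed + 100, user_ids=["u1", "u1"]
    )
    write_landmark_table(intra, out / "replicated_intra.tsv")
    inter = simulate_replicated_digitization(
        subset, error_sd=0.005, m=2, seed=args.seed + 101, user_ids=["u1", "u2"]
    )
    write_landmark_table(inter, out / "replicated_inter.tsv")
    print(f"replicated digitizations: {len(intra)} configs each (intra, inter)")


if __name__ == "__main__":
    main()
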