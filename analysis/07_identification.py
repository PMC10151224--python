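#!/usr/bin/env python
"""Identification of new field specimens against the frozen reference morphospace.

Each test wing is superimposed onto the reference consensus, projected into
the reference PC basis, and assigned to the closest reference group by
Mahalanobis distance; a joint UPGMA tree shows where the tests fall among the
reference wings.  Expected: essentially all test specimens are assigned to
their generating (species, sex) group.
"""

from pathlib import Path

from wingmorph import (
    generalized_procrustes,
    identify_test_specimens,
    read_landmark_table,
    shape_pca,
)
from wingmorph.classification import assignment_table

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    out = ROOT / "results"
    reference = read_landmark_table(out / "data" / "reference.tsv")
    tests = read_landmark_table(out / "data" / "tests.tsv")
    aligned = generalized_procrustes(reference)
    pca = shape_pca(aligned)
    records, tree = identify_test_specimens(aligned, pca, tests)

    assignment_table(records).to_csv(
        out / "assignments.tsv", sep="\t", index=False, float_format="%.4g"
    )
    (out / "combined_tree.nwk").write_text(tree.to_newick() + "\n", encoding="utf-8")

    correct = sum(r.assigned_group == r.true_group for r in records)
    for r in records:
        flag = "" if r.assigned_group == r.true_group else "   <-- misassigned"
        print(f"{r.specimen_id:12s} -> {r.assigned_group[0]} ({r.assigned_group[1]}){flag}")
    print(f"\n{correct}/{len(records)} test specimens assigned to their true group")
    print(f"wrote {out / 'assignments.tsv'} and {out / 'combined_tree.nwk'}")


if __name__ == "__main__":
    main()
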