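#!/usr/bin/env python
"""Wing shape: PCA morphospace, discriminant factors, Mahalanobis distances, allometry.

Expected pattern: all four (species, sex) groups separate in shape — every
pairwise Mahalanobis distance is large and significant after Bonferroni
correction — while allometry (regression of PC1 on centroid size) explains
almost none of the shape variation.
"""

from pathlib import Path

import pandas as pd

from wingmorph import (
    allometry_regression,
    discriminant_analysis,
    generalized_procrustes,
    mahalanobis_pairwise_test,
    read_landmark_table,
    shape_pca,
)
from wingmorph.shape_analysis import distance_table

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    out = ROOT / "results"
    aligned = generalized_procrustes(read_landmark_table(out / "data" / "reference.tsv"))
    pca = shape_pca(aligned)
    dfa = discriminant_analysis(pca, aligned.group_labels)
    print(
        "morphospace: "
        + ", ".join(f"PC{i+1} {f*100:.1f}%" for i, f in enumerate(pca.variance_fractions[:3]))
    )
    print(
        "discriminant space: "
        + ", ".join(f"DF{i+1} {f*100:.1f}%" for i, f in enumerate(dfa.variance_fractions))
    )

    scores = pd.DataFrame(
        {
            "specimen_id": aligned.specimen_ids,
            "species": [s for s, _ in aligned.group_labels],
            "sex": [x for _, x in aligned.group_labels],
            "PC1": pca.scores[:, 0],
            "PC2": pca.scores[:, 1],
            "DF1": dfa.scores[:, 0],
            "DF2": dfa.scores[:, 1],
        }
    )
    scores.to_csv(out / "factor_scores.tsv", sep="\t", index=False, float_format="%.6g")

    maha = mahalanobis_pairwise_test(pca, aligned.group_labels, n_perm=1000, seed=12)
    tab = distance_table(maha)
    tab.to_csv(out / "mahalanobis.tsv", sep="\t")
    print("\nMahalanobis distances (below diagonal) and adjusted p (above):")
    print(tab.to_string())

    allo = allometry_regression(aligned, pca)
    allo_df = pd.DataFrame(
        [
            {"species": a.species, "n": a.n, "slope": a.slope,
             "r_squared_pct": round(a.r_squared_percent, 1), "p": a.p}
            for a in allo
        ]
    )
    allo_df.to_csv(out / "allometry.tsv", sep="\t", index=False, float_format="%.4g")
    print("\nallometry (PC1 ~ CS, sexes pooled within species):")
    print(allo_df.to_string(index=False))
    print(f"wrote factor_scores.tsv, mahalanobis.tsv, allometry.tsv under {out}")


if __name__ == "__main__":
    main()
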