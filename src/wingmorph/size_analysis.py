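"""Centroid-size summaries and permutation inference among (species, sex) groups.

The omnibus comparison is a one-way ANOVA on centroid size whose F statistic
is referred to a permutation null (group labels shuffled without
replacement); pairwise contrasts use the absolute mean difference as the
permutation statistic, with Bonferroni adjustment over all pairwise
comparisons.  p-values use the add-one convention (b + 1) / (B + 1), so they
can never be exactly zero.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .superimposition import AlignedDataset


@dataclass
class PairwiseSizeResult:
    group_a: tuple[str, str]
    group_b: tuple[str, str]
    mean_difference: float
    raw_p: float
    adjusted_p: float


@dataclass
class SizeTestResult:
    f_statistic: float
    f_p: float                     # permutation p of the omnibus F
    pairwise: list[PairwiseSizeResult]
    letters: dict[tuple[str, str], str]
    n_perm: int
    alpha: float

    def pairwise_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group_a": [f"{p.group_a[0]} ({p.group_a[1]})" for p in self.pairwise],
                "group_b": [f"{p.group_b[0]} ({p.group_b[1]})" for p in self.pairwise],
                "mean_difference": [p.mean_difference for p in self.pairwise],
                "raw_p": [p.raw_p for p in self.pairwise],
                "adjusted_p": [p.adjusted_p for p in self.pairwise],
            }
        )


def size_summary(aligned: AlignedDataset) -> pd.DataFrame:
    """Per-group n, mean, max, min, variance (n-1 denominator), sd of centroid size.

    Rows are ordered by (species, sex).  A single-specimen group reports its
    variance and sd as missing, never zero.
    """
    cs = aligned.centroid_sizes
    labels = aligned.group_labels
    rows = []
    for g in aligned.groups:
        vals = cs[[i for i, lab in enumerate(labels) if lab == g]]
        n = len(vals)
        var = float(np.var(vals, ddof=1)) if n > 1 else np.nan
        rows.append(
            {
                "species": g[0],
                "sex": g[1],
                "n": n,
                "mean": float(np.mean(vals)),
                "max": float(np.max(vals)),
                "min": float(np.min(vals)),
                "variance": var,
                "sd": float(np.sqrt(var)) if n > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def _f_statistic(cs: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    grand = cs.mean()
    ss_between = 0.0
    ss_within = 0.0
    for g in range(n_groups):
        vals = cs[codes == g]
        ss_between += len(vals) * (vals.mean() - grand) ** 2
        ss_within += np.sum((vals - vals.mean()) ** 2)
    df_b = n_groups - 1
    df_w = len(cs) - n_groups
    return (ss_between / df_b) / (ss_within / df_w)


def _assign_letters(
    groups: list[tuple[str, str]], different: set[frozenset]
) -> dict[tuple[str, str], str]:
    """Compact letter display: groups sharing no letter differ significantly.

    Insert-and-absorb: start with one letter covering all groups; for each
    significantly different pair, split every letter containing both; drop
    letter sets that are subsets of another.
    """
    letter_sets: list[frozenset] = [frozenset(groups)]
    for pair in sorted(different, key=lambda p: sorted(p)):
        a, b = sorted(pair)
        split = []
        for s in letter_sets:
            if a in s and b in s:
                split.extend([s - {a}, s - {b}])
            else:
                split.append(s)
        maximal: list[frozenset] = []
        for s in split:
            if s and not any(s < t for t in split) and s not in maximal:
                maximal.append(s)
        letter_sets = maximal
    letter_sets.sort(key=lambda s: sorted(s))
    out: dict[tuple[str, str], str] = {}
    for idx, s in enumerate(letter_sets):
        letter = chr(ord("a") + idx)
        for g in s:
            out[g] = out.get(g, "") + letter
    return out


def cs_anova_permutation(
    aligned: AlignedDataset,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> SizeTestResult:
    """Omnibus one-way ANOVA on centroid size with permutation inference.

    The omnibus F and each pairwise |mean difference| are referred to nulls
    built by shuffling group labels ``n_perm`` times; pairwise p-values are
    Bonferroni-multiplied by the number of pairs (capped at 1).  Significance
    letters are assigned so that groups sharing no letter differ at ``alpha``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    cs = aligned.centroid_sizes
    groups = aligned.groups
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    code_of = {g: i for i, g in enumerate(groups)}
    codes = np.array([code_of[g] for g in aligned.group_labels])
    for g_i, g in enumerate(groups):
        if np.sum(codes == g_i) < 2:
            raise ValueError(f"group {g} has fewer than 2 specimens")

    rng = np.random.default_rng(seed)
    f_obs = _f_statistic(cs, codes, len(groups))
    means = np.array([cs[codes == i].mean() for i in range(len(groups))])
    pairs = list(itertools.combinations(range(len(groups)), 2))
    obs_diffs = np.array([abs(means[a] - means[b]) for a, b in pairs])

    f_exceed = 0
    pair_exceed = np.zeros(len(pairs), dtype=int)
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if _f_statistic(cs, perm, len(groups)) >= f_obs:
            f_exceed += 1
        pm = np.array([cs[perm == i].mean() for i in range(len(groups))])
        for pi, (a, b) in enumerate(pairs):
            if abs(pm[a] - pm[b]) >= obs_diffs[pi]:
                pair_exceed[pi] += 1

    f_p = (f_exceed + 1) / (n_perm + 1)
    n_pairs = len(pairs)
    pairwise = []
    different: set[frozenset] = set()
    for pi, (a, b) in enumerate(pairs):
        raw = (pair_exceed[pi] + 1) / (n_perm + 1)
        adj = min(1.0, raw * n_pairs)
        pairwise.append(
            PairwiseSizeResult(groups[a], groups[b], float(obs_diffs[pi]), raw, adj)
        )
        if adj < alpha:
            different.add(frozenset((groups[a], groups[b])))
    letters = _assign_letters(groups, different)
    return SizeTestResult(
        f_statistic=float(f_obs),
        f_p=float(f_p),
        pairwise=pairwise,
        letters=letters,
        n_perm=n_perm,
        alpha=alpha,
    )
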