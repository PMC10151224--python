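"""Digitization precision via Procrustes ANOVA.

Replicate digitizations of the same wings are superimposed jointly; the
one-way random-effects (model II) ANOVA is then applied to the pooled
Procrustes tangent coordinates, summing sums of squares over all 2k
coordinates.  The repeatability index is the among-specimen share of the
total variance,

    R = s2_among / (s2_among + MS_within),
    s2_among = (MS_among - MS_within) / m,

with m replicates per specimen; its complement is the measurement error.  A
negative among-specimen variance component is floored at zero (with a
warning), so R stays in [0, 100] percent.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

from .landmark_io import LandmarkDataset
from .superimposition import generalized_procrustes

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class ProcrustesAnovaResult:
    ms_among: float
    ms_within: float
    variance_among: float           # s2_among, floored at 0
    repeatability_percent: float
    measurement_error_percent: float
    n_specimens: int
    m_replicates: int

    def passes(self, threshold: float = 90.0) -> bool:
        """Whether the index clears a re-digitization threshold (percent)."""
        return self.repeatability_percent >= threshold


def repeatability_from_mean_squares(
    ms_among: float, ms_within: float, m: int
) -> ProcrustesAnovaResult:
    """Repeatability index from precomputed mean squares (m replicates)."""
    if m < 2:
        raise ValueError("need m >= 2 replicates")
    s2_among = (ms_among - ms_within) / m
    if s2_among < 0:
        logger.warning("negative among-specimen variance component (%.3e); floored at 0", s2_among)
        s2_among = 0.0
    total = s2_among + ms_within
    rep = 100.0 * s2_among / total if total > 0 else 100.0
    return ProcrustesAnovaResult(
        ms_among=float(ms_among),
        ms_within=float(ms_within),
        variance_among=float(s2_among),
        repeatability_percent=float(rep),
        measurement_error_percent=float(100.0 - rep),
        n_specimens=0,
        m_replicates=m,
    )


def procrustes_anova_repeatability(replicated: LandmarkDataset) -> ProcrustesAnovaResult:
    """Procrustes ANOVA repeatability of a balanced replicated dataset.

    Every specimen_id must appear with the same number m >= 2 of replicates.
    All n x m configurations are superimposed jointly; sums of squares of the
    tangent shape coordinates are partitioned into among-specimen
    (df = n - 1) and within-specimen / among-replicate (df = n (m - 1))
    components, summed over all 2k coordinates.
    """
    by_specimen: dict[str, list[int]] = defaultdict(list)
    for i, c in enumerate(replicated):
        by_specimen[c.specimen_id].append(i)
    counts = {len(v) for v in by_specimen.values()}
    if len(counts) != 1:
        raise ValueError(f"unbalanced replicate counts: {sorted(counts)} (balanced design required)")
    m = counts.pop()
    if m < 2:
        raise ValueError("need m >= 2 replicates per specimen")
    n = len(by_specimen)
    if n < 2:
        raise ValueError("need >= 2 specimens")

    aligned = generalized_procrustes(replicated)
    V = aligned.shape_variables                      # (n*m, 2k)
    grand = V.mean(axis=0)
    ss_among = 0.0
    ss_within = 0.0
    for idx in by_specimen.values():
        sub = V[idx]
        mu = sub.mean(axis=0)
        ss_among += m * float(np.sum((mu - grand) ** 2))
        ss_within += float(np.sum((sub - mu) ** 2))
    ms_among = ss_among / (n - 1)
    ms_within = ss_within / (n * (m - 1))
    result = repeatability_from_mean_squares(ms_among, ms_within, m)
    result.n_specimens = n
    return result
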