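"""Temporal pattern classification and miRNA-target anticorrelation.

Endosperm trajectories over the consecutive 7-, 10- and 15-DAP stages
are reduced to two fold-change steps and classified into one-step-up,
one-step-down, two-step-up-down, two-step-down-up, or flat.  Endosperm
versus kernel enrichment is a simple ratio of tissue means, and the
miRNA-target relationship is a pooled Pearson correlation over predicted
interaction pairs restricted to expressed targets (FPKM >= 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

PATTERN_CLASSES = ("one-step-up", "one-step-down", "two-step-up-down",
                   "two-step-down-up", "flat")

#: Default fold-change calling a step "up" (or its reciprocal "down").
STEP_FOLD_THRESHOLD = 1.5
STEP_PSEUDOCOUNT = 1.0

#: Targets below this FPKM in every stage are dropped before correlation.
EXPRESSED_FPKM = 1.0


@dataclass(frozen=True)
class PatternCall:
    mirna_id: str
    pattern: str                      # one of PATTERN_CLASSES
    fold_7_10: float
    fold_10_15: float


@dataclass(frozen=True)
class EnrichmentResult:
    mirna_id: str
    endosperm_mean: float
    kernel_mean: float
    fold: float


def classify_temporal_pattern(values_7_10_15, mirna_id: str = "",
                              fold_threshold: float = STEP_FOLD_THRESHOLD,
                              pseudocount: float = STEP_PSEUDOCOUNT
                              ) -> PatternCall:
    """Classify one endosperm trajectory (7, 10, 15 DAP; crosses combined).

    Each step is "up" if its fold-change is >= the threshold, "down" if
    <= its reciprocal, else level.  A single sustained direction (the
    other step level or same-direction) is one-step; opposite directions
    are the two-step peak/trough classes; two level steps are flat.
    """
    v = [float(x) for x in values_7_10_15]
    if len(v) != 3:
        raise ValueError("need exactly the 7-, 10- and 15-DAP values")
    if any(x < 0 for x in v):
        raise ValueError("negative expression values")
    if fold_threshold <= 1.0:
        raise ValueError("fold_threshold must exceed 1")

    def step(x: float, y: float) -> tuple[str, float]:
        fold = (y + pseudocount) / (x + pseudocount)
        if fold >= fold_threshold:
            return "up", fold
        if fold <= 1.0 / fold_threshold:
            return "down", fold
        return "level", fold

    s1, f1 = step(v[0], v[1])
    s2, f2 = step(v[1], v[2])
    if s1 == "up" and s2 == "down":
        pattern = "two-step-up-down"
    elif s1 == "down" and s2 == "up":
        pattern = "two-step-down-up"
    elif "up" in (s1, s2):
        pattern = "one-step-up"
    elif "down" in (s1, s2):
        pattern = "one-step-down"
    else:
        pattern = "flat"
    return PatternCall(mirna_id, pattern, f1, f2)


def endosperm_enrichment(kernel_mean: float, endosperm_mean: float,
                         mirna_id: str = "", eps: float = 0.1
                         ) -> EnrichmentResult:
    """Endosperm / kernel expression ratio with an epsilon floor."""
    fold = (endosperm_mean + eps) / (kernel_mean + eps)
    return EnrichmentResult(mirna_id, endosperm_mean, kernel_mean, fold)


def profile_target_correlation(mirna_vectors: dict[str, np.ndarray],
                               target_vectors: dict[str, np.ndarray],
                               interactions: list[tuple[str, str]],
                               expressed_fpkm: float = EXPRESSED_FPKM,
                               per_gene_means: bool = False
                               ) -> tuple[float, float, int]:
    """Pearson correlation between miRNAs and their predicted targets.

    Stage-matched (miRNA RPM, target FPKM) values are pooled over all
    interaction pairs; targets never reaching ``expressed_fpkm`` in any
    stage are dropped first.  With ``per_gene_means=True`` each
    interaction contributes a single (mean, mean) point instead of one
    point per stage.  Returns (r, two-sided p from the t transform with
    n - 2 df, number of pooled points).
    """
    xs, ys = [], []
    for mid, gid in interactions:
        if mid not in mirna_vectors or gid not in target_vectors:
            continue
        t = np.asarray(target_vectors[gid], dtype=float)
        if t.max() < expressed_fpkm:
            continue
        m = np.asarray(mirna_vectors[mid], dtype=float)
        if m.shape != t.shape:
            raise ValueError(f"stage vectors differ in length for {mid}/{gid}")
        if per_gene_means:
            xs.append(m.mean())
            ys.append(t.mean())
        else:
            xs.extend(m)
            ys.extend(t)
    x = np.asarray(xs)
    y = np.asarray(ys)
    if x.size < 3:
        raise ValueError("need at least 3 pooled points for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance vector: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), int(x.size)
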