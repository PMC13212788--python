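"""Confidence-weighted ROC analysis, Youden operating point, CV aggregation.

The voxel-wise classifier is scored with a sample-weighted ROC AUC (the
weighted Mann-Whitney statistic): each voxel contributes its confidence
weight w_vox, so voxels whose reference label is uncertain count less.

    AUC = sum_{i in pos} sum_{j in neg} w_i w_j (1[s_i > s_j] + 1/2 1[s_i = s_j])
          / (sum_pos w_i * sum_neg w_j)

Ties use the standard 1/2 convention; scaling all weights by a positive
constant leaves the AUC unchanged, and unit weights reduce it to the
classical Mann-Whitney AUC.  Zone-stratified evaluation reports the whole
prostate, peripheral zone (PZ) and transitional zone (TZ) separately, and
repeated cross-validation results are pooled into mean, SD and a normal
approximation 95% CI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RocResult",
    "weighted_roc_auc",
    "youden_point",
    "zone_stratified_eval",
    "repeated_cv_aggregate",
]


@dataclass
class RocResult:
    auc: float
    sens: np.ndarray = field(default_factory=lambda: np.array([]))
    spec: np.ndarray = field(default_factory=lambda: np.array([]))
    thresholds: np.ndarray = field(default_factory=lambda: np.array([]))
    n_pos_eff: float = 0.0
    n_neg_eff: float = 0.0


def weighted_roc_auc(
    scores: np.ndarray, labels: np.ndarray, weights: np.ndarray | None = None
) -> RocResult:
    """Weighted Mann-Whitney AUC and the weighted ROC curve.

    Computed by sorting scores once and accumulating weighted cumulative
    counts; exactly equal to the O(n^2) pairwise definition, including the
    half-credit tie convention.  Requires both classes with positive weight.
    """
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels).ravel().astype(bool)
    w = np.ones_like(s) if weights is None else np.asarray(weights, dtype=float).ravel()
    if s.shape != y.shape or s.shape != w.shape:
        raise ValueError("scores, labels, weights must have the same length")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    wp = w[y].sum()
    wn = w[~y].sum()
    if wp <= 0 or wn <= 0:
        raise ValueError("both classes must be present with positive weight")

    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    wy = np.where(y, w, 0.0)[order]
    wn_arr = np.where(~y, w, 0.0)[order]

    # group tied scores
    boundary = np.empty(s_sorted.size, dtype=bool)
    boundary[0] = True
    boundary[1:] = s_sorted[1:] != s_sorted[:-1]
    grp = np.cumsum(boundary) - 1
    n_grp = grp[-1] + 1
    gp = np.bincount(grp, weights=wy, minlength=n_grp)
    gn = np.bincount(grp, weights=wn_arr, minlength=n_grp)
    cum_p = np.cumsum(gp)
    cum_n = np.cumsum(gn)
    # pairs won: positives above each negative group; ties get half credit
    auc = float(np.sum(gn * (cum_p - gp) + 0.5 * gn * gp) / (wp * wn))

    thresholds = s_sorted[boundary]
    sens = cum_p / wp
    spec = 1.0 - cum_n / wn
    return RocResult(
        auc=auc, sens=sens, spec=spec, thresholds=thresholds,
        n_pos_eff=float(wp), n_neg_eff=float(wn),
    )


def youden_point(roc: RocResult) -> tuple[float, float, float]:
    """(sensitivity, specificity, threshold) maximizing J = sens + spec - 1.

    Ties in J are broken toward higher sensitivity.
    """
    j = roc.sens + roc.spec - 1.0
    best = np.flatnonzero(j == j.max())
    i = best[np.argmax(roc.sens[best])]
    return float(roc.sens[i]), float(roc.spec[i]), float(roc.thresholds[i])


def zone_stratified_eval(
    scores: np.ndarray,
    labels: np.ndarray,
    weights: np.ndarray,
    prostate_mask: np.ndarray,
    pz_mask: np.ndarray,
    tz_mask: np.ndarray,
) -> dict[str, RocResult | None]:
    """AUC over the whole prostate and per zone; a single-class zone is None."""
    out: dict[str, RocResult | None] = {}
    for name, m in (("whole", prostate_mask), ("pz", pz_mask), ("tz", tz_mask)):
        sel = m & np.isfinite(scores)
        try:
            out[name] = weighted_roc_auc(scores[sel], labels[sel], weights[sel])
        except ValueError:
            out[name] = None
    return out


def repeated_cv_aggregate(aucs) -> dict[str, float]:
    """Mean, SD and normal-approximation 95% CI over repeat x fold AUCs."""
    a = np.asarray(list(aucs), dtype=float)
    if a.size < 2:
        raise ValueError("need at least 2 AUC values to aggregate")
    mean = float(a.mean())
    sd = float(a.std(ddof=1))
    half = 1.96 * sd / np.sqrt(a.size)
    return {
        "mean": mean, "sd": sd, "n": int(a.size),
        "ci_low": mean - half, "ci_high": mean + half,
    }
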