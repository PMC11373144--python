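"""Zero-out feature importance, IQR outlier calling, and the knockdown test.

A trained classifier's reliance on one TF is measured by occlusion: among the
events that carry at least one occupancy change for that TF, zero the TF's
entries (the whole promoter column for positional input), re-run inference,
and report the fraction of hard labels that flip (N_changed / N_total).
Candidate regulators are the TFs whose ratio is an upper outlier under the
interquartile-range rule Q3 + 1.5*IQR.  The knockdown validation compares
per-gene |delta Z_psi| between target and non-target genes with a two-sided
Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import sparse, stats

from .models import Classifier, Features, FLAT, POSITIONAL


@dataclass(frozen=True)
class ImportanceScore:
    tf_id: str
    n_total: int
    n_changed: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_changed <= self.n_total:
            raise ValueError("need 0 <= n_changed <= n_total")

    @property
    def ratio(self) -> float:
        """Output-changing ratio; NaN when no event carries the TF."""
        if self.n_total == 0:
            return float("nan")
        return self.n_changed / self.n_total


def _zero_tf(feats: Features, tf_index: int) -> Features:
    if feats.kind == FLAT:
        data = feats.data.copy()
        data[:, tf_index] = 0.0
        return Features(data)
    if isinstance(feats.data, np.ndarray):
        data = feats.data.copy()
        data[:, :, tf_index] = 0.0
        return Features(data)
    zeroed = []
    for m in feats.data:
        m = sparse.lil_matrix(m, dtype=m.dtype)
        m[:, tf_index] = 0
        zeroed.append(m.tocsr())
    return Features(zeroed)


def _carries_tf(feats: Features, tf_index: int) -> np.ndarray:
    if feats.kind == FLAT:
        return feats.data[:, tf_index] != 0
    if isinstance(feats.data, np.ndarray):
        return feats.data[:, :, tf_index].any(axis=1)
    return np.array([m[:, tf_index].nnz > 0 for m in feats.data])


def zero_out_importance(
    model: Classifier, features, tf_index: int, tf_id: str | None = None
) -> ImportanceScore:
    """Occlude one TF and count flipped predictions among events carrying it.

    Each TF is perturbed from the unperturbed input, one at a time, so an
    event contributes to a TF's count independently of every other TF.
    """
    feats = Features(features)
    if feats.signature != model.signature:
        raise ValueError("features do not match the model's signature")
    n_feat = (
        feats.signature[1] if feats.kind == FLAT else feats.signature[1][1]
    )
    if not 0 <= tf_index < n_feat:
        raise ValueError(f"TF index {tf_index} outside the feature signature")
    mask = _carries_tf(feats, tf_index)
    n_total = int(mask.sum())
    if n_total == 0:
        return ImportanceScore(tf_id=tf_id or str(tf_index), n_total=0, n_changed=0)
    sub = feats.subset(np.nonzero(mask)[0])
    before = model.predict(sub)
    after = model.predict(_zero_tf(sub, tf_index))
    return ImportanceScore(
        tf_id=tf_id or str(tf_index),
        n_total=n_total,
        n_changed=int((before != after).sum()),
    )


def importance_table(
    model: Classifier, features, tf_ids: Sequence[str], min_support: int = 1
):
    """Zero-out importance for every TF; returns a tidy DataFrame with the
    outlier flag from :func:`iqr_outliers`.

    ``min_support`` excludes TFs with fewer than that many carrying events
    from the outlier call (their ratios are binomial noise that masks true
    outliers); they still appear in the table with outlier=False.
    """
    import pandas as pd

    feats = Features(features)
    scores = [
        zero_out_importance(model, feats, i, tf_id=tf)
        for i, tf in enumerate(tf_ids)
    ]
    ratios = {
        s.tf_id: s.ratio for s in scores if s.n_total >= max(min_support, 1)
    }
    flagged = set(iqr_outliers(ratios))
    return pd.DataFrame(
        {
            "tf": [s.tf_id for s in scores],
            "n_total": [s.n_total for s in scores],
            "n_changed": [s.n_changed for s in scores],
            "ratio": [s.ratio for s in scores],
            "outlier": [s.tf_id in flagged for s in scores],
        }
    ).set_index("tf")


def iqr_outliers(scores: dict[str, float] | Sequence[float]) -> list:
    """Keys (or indices) whose value exceeds Q3 + 1.5*(Q3 - Q1), sorted by
    descending value; quartiles by linear interpolation between order
    statistics."""
    if isinstance(scores, dict):
        keys = list(scores.keys())
        values = np.array([scores[k] for k in keys], dtype=float)
    else:
        values = np.asarray(scores, dtype=float)
        keys = list(range(len(values)))
    if len(values) < 4:
        raise ValueError("IQR outlier rule needs >= 4 scores")
    q1, q3 = np.percentile(values, [25, 75])
    cut = q3 + 1.5 * (q3 - q1)
    out = [(k, v) for k, v in zip(keys, values) if v > cut]
    out.sort(key=lambda kv: -kv[1])
    return [k for k, _ in out]


@dataclass(frozen=True)
class KnockdownResult:
    statistic: float      # standardized rank-sum (z)
    pvalue: float
    direction: int        # sign of median(target) - median(non-target)
    n_targets: int
    n_nontargets: int


def knockdown_shift_test(
    delta_z_targets: Sequence[float], delta_z_nontargets: Sequence[float]
) -> KnockdownResult:
    """Two-sided Wilcoxon rank-sum test on |delta Z_psi| of target vs
    non-target genes: normal approximation with tie correction and
    continuity correction.
    """
    x = np.asarray(delta_z_targets, dtype=float)
    y = np.asarray(delta_z_nontargets, dtype=float)
    if len(x) < 5 or len(y) < 5:
        raise ValueError("each group needs >= 5 values")
    n1, n2 = len(x), len(y)
    n = n1 + n2
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    w = ranks[:n1].sum()                      # rank sum of the target group
    mu = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / ((n) * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var == 0:
        return KnockdownResult(statistic=0.0, pvalue=1.0, direction=0,
                               n_targets=n1, n_nontargets=n2)
    diff = w - mu
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)  # continuity correction
    p = float(min(2.0 * stats.norm.sf(abs(z)), 1.0))
    p = max(p, np.nextafter(0, 1))
    direction = int(np.sign(np.median(x) - np.median(y)))
    return KnockdownResult(statistic=float(z), pvalue=p, direction=direction,
                           n_targets=n1, n_nontargets=n2)
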