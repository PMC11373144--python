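"""Cross-validation schemes, decontamination, and performance metrics.

Three splits probe different generalisation questions for promoter-splicing
pairs: event-wise (random 10% holdout + 10-fold CV; the same gene may appear
on both sides), tissue-wise (leave one tissue out, with test samples removed
when their feature vector occurs bit-identically in the training data — the
"identical features" decontamination), and gene-wise (90/10 split of gene
ids, keeping all of a gene's pairs together).  The contrast between schemes
is the point: near-identical per-gene features across tissues let event-wise
CV reward memorisation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

EVENT_WISE, TISSUE_WISE, GENE_WISE = "event_wise", "tissue_wise", "gene_wise"


@dataclass
class CVSplit:
    scheme: str
    fold: str
    train_idx: np.ndarray
    test_idx: np.ndarray
    n_removed: int = 0

    def __post_init__(self) -> None:
        if np.intersect1d(self.train_idx, self.test_idx).size:
            raise ValueError("train and test indices overlap")


@dataclass(frozen=True)
class MetricSet:
    f1: float
    auroc: float
    auprc: float
    accuracy: float
    n_test: int


def split_event_wise(n_samples: int, seed: int) -> tuple[np.ndarray, list[CVSplit]]:
    """10% random holdout plus a 10-fold partition of the rest.

    Returns (holdout indices, folds); each fold's test set is one of the ten
    parts, its training set the other nine (the holdout belongs to neither).
    """
    if n_samples < 20:
        raise ValueError("need >= 20 samples for a 10% holdout and 10 folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_samples)
    n_hold = int(round(0.1 * n_samples))
    holdout, rest = perm[:n_hold], perm[n_hold:]
    parts = np.array_split(rest, 10)
    folds = []
    for k, part in enumerate(parts):
        train = np.concatenate([p for j, p in enumerate(parts) if j != k])
        folds.append(
            CVSplit(scheme=EVENT_WISE, fold=f"fold{k}", train_idx=np.sort(train),
                    test_idx=np.sort(part))
        )
    return np.sort(holdout), folds


def _row_keys(features: np.ndarray) -> list[bytes]:
    arr = np.ascontiguousarray(features)
    return [arr[i].tobytes() for i in range(len(arr))]


def split_tissue_wise(
    tissues: Sequence[str], features: np.ndarray
) -> list[CVSplit]:
    """Leave-one-tissue-out with identical-feature decontamination.

    For each tissue T, test samples are T's samples whose full feature vector
    does not occur bit-identically among the training (non-T) samples; the
    number removed is recorded on the split.
    """
    tissues = np.asarray(tissues)
    uniq = sorted(set(tissues.tolist()))
    if len(uniq) < 2:
        raise ValueError("tissue-wise CV needs >= 2 tissues")
    keys = _row_keys(np.asarray(features))
    splits = []
    for t in uniq:
        test_mask = tissues == t
        train_idx = np.nonzero(~test_mask)[0]
        train_keys = {keys[i] for i in train_idx}
        test_all = np.nonzero(test_mask)[0]
        clean = np.array([i for i in test_all if keys[i] not in train_keys], dtype=int)
        splits.append(
            CVSplit(scheme=TISSUE_WISE, fold=t, train_idx=train_idx,
                    test_idx=clean, n_removed=int(len(test_all) - len(clean)))
        )
    return splits


def split_gene_wise(genes: Sequence[str], seed: int) -> CVSplit:
    """Random 90/10 split of gene ids; all of a gene's samples stay together."""
    genes = np.asarray(genes)
    uniq = np.array(sorted(set(genes.tolist())))
    if len(uniq) < 10:
        raise ValueError("gene-wise CV needs >= 10 genes")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(uniq))
    n_test = int(round(0.1 * len(uniq)))
    test_genes = set(uniq[perm[:n_test]].tolist())
    test_mask = np.array([g in test_genes for g in genes])
    return CVSplit(
        scheme=GENE_WISE, fold="holdout",
        train_idx=np.nonzero(~test_mask)[0], test_idx=np.nonzero(test_mask)[0],
    )


def compute_metrics(labels: Sequence[int], scores: Sequence[float]) -> MetricSet:
    """F1/accuracy at threshold 0.5; AUROC (rank statistic, ties averaged);
    AUPRC by step-wise precision-recall integration.

    With a single class in ``labels`` the ranking metrics are undefined and
    reported as NaN.
    """
    from sklearn.metrics import (
        accuracy_score,
        average_precision_score,
        f1_score,
        roc_auc_score,
    )

    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    pred = (s >= 0.5).astype(int)
    both = np.unique(y).size == 2
    return MetricSet(
        f1=float(f1_score(y, pred, zero_division=0)),
        auroc=float(roc_auc_score(y, s)) if both else float("nan"),
        auprc=float(average_precision_score(y, s)) if both else float("nan"),
        accuracy=float(accuracy_score(y, pred)),
        n_test=int(len(y)),
    )


def group_accuracy_breakdown(
    predictions: Mapping[str, tuple[np.ndarray, np.ndarray, Sequence[str]]],
    gene_groups: Mapping[str, str],
) -> pd.DataFrame:
    """Accuracy and gene counts per (tissue, splicing-form group).

    ``predictions`` maps tissue -> (labels, predicted labels, gene ids of the
    tissue's test samples); ``gene_groups`` maps gene -> group label from
    classify_gene_group.  Empty (tissue, group) cells are absent from the
    output.
    """
    rows = []
    for tissue, (y, pred, genes) in predictions.items():
        y, pred = np.asarray(y), np.asarray(pred)
        groups = np.array([gene_groups[g] for g in genes])
        for grp in sorted(set(groups.tolist())):
            mask = groups == grp
            rows.append(
                dict(tissue=tissue, group=grp, n=int(mask.sum()),
                     accuracy=float((y[mask] == pred[mask]).mean()))
            )
    return pd.DataFrame(rows)
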