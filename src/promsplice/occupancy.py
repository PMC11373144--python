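"""Per-(gene, tissue) TF occupancy encoding and tissue-specificity scoring.

An occupancy profile records, for one gene in one tissue, which TFs have at
least one retained binding site in the open promoter window (a binary vector
over TFs) and where those sites sit (a binary 2500 x n_TF positional matrix,
rows indexed by TSS-relative position -2000..+499 on the gene's strand).
Sites of TFs that are not expressed in the tissue (TPM <= 1) contribute
nothing: occupancy is defined as an expressed TF with an accessible motif.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .motifscan import MotifHit

WINDOW_LENGTH = 2500
TPM_EXPRESSED = 1.0


@dataclass
class ExpressionTable:
    """TF x tissue TPM matrix."""

    tpm: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.tpm.values < 0).any():
            raise ValueError("TPM entries must be non-negative")

    def expressed(self, tissue: str) -> pd.Series:
        """Boolean mask of TFs with TPM > 1 in ``tissue``."""
        return self.tpm[tissue] > TPM_EXPRESSED


@dataclass
class OccupancyProfile:
    """Binary occupancy of one gene's promoter in one tissue.

    ``positional`` is stored sparse (sites are rare relative to 2500 x n_TF);
    ``vector`` is the per-TF any-site summary and always consistent with it.
    """

    gene_id: str
    tissue: str
    tf_order: tuple[str, ...]
    vector: np.ndarray
    positional: sparse.csr_matrix

    @property
    def n_tf(self) -> int:
        return len(self.tf_order)

    def positional_dense(self) -> np.ndarray:
        return np.asarray(self.positional.todense(), dtype=np.int8)

    def check(self) -> None:
        col_any = np.asarray((self.positional.sum(axis=0) > 0)).ravel()
        if not np.array_equal(col_any.astype(np.int8), self.vector.astype(np.int8)):
            raise AssertionError("vector inconsistent with positional matrix")


def build_profile(
    hits: Iterable[MotifHit],
    expr: ExpressionTable,
    tissue: str,
    gene_id: str,
    tf_order: Sequence[str],
    strand: str = "+",
    window_length: int = WINDOW_LENGTH,
) -> OccupancyProfile:
    """Assemble an occupancy profile from promoter-window-relative hits.

    Hits must already be restricted to the open promoter window and carry
    coordinates relative to the window's genomic (plus-strand) orientation,
    0 .. window_length.  For minus-strand genes the positional axis is flipped
    so that row 0 always means TSS-relative -2000.  Sites of TFs with
    TPM <= 1 in ``tissue`` are dropped.
    """
    tf_index = {tf: i for i, tf in enumerate(tf_order)}
    expressed = expr.expressed(tissue).to_dict()
    n_tf = len(tf_order)
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    for h in hits:
        if h.start < 0 or h.end > window_length:
            raise ValueError(
                f"hit {h.start}-{h.end} extends outside the promoter window"
            )
        if h.tf_id not in tf_index:
            raise KeyError(f"unknown TF {h.tf_id}")
        if not expressed.get(h.tf_id, False):
            continue
        start, end = h.start, h.end
        if strand == "-":
            start, end = window_length - h.end, window_length - h.start
        footprint = np.arange(start, end)
        rows.append(footprint)
        cols.append(np.full(len(footprint), tf_index[h.tf_id]))
    if rows:
        r = np.concatenate(rows)
        c = np.concatenate(cols)
        coo = sparse.coo_matrix(
            (np.ones(len(r), dtype=np.int8), (r, c)), shape=(window_length, n_tf)
        )
        csr = coo.tocsr()
        csr.data = np.ones_like(csr.data)  # overlapping hits stay binary
    else:
        csr = sparse.csr_matrix((window_length, n_tf), dtype=np.int8)
    vector = np.zeros(n_tf, dtype=np.int8)
    vector[np.unique(csr.indices)] = 1 if csr.nnz else 0
    return OccupancyProfile(
        gene_id=gene_id,
        tissue=tissue,
        tf_order=tuple(tf_order),
        vector=vector,
        positional=csr,
    )


@dataclass(frozen=True)
class TauScore:
    tf_id: str
    tau: float
    n_expressed: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.tau <= 1.0 + 1e-12:
            raise ValueError("tau must lie in [0, 1]")


def tau(
    expression_row: np.ndarray | pd.Series,
    mode: str = "expressed_only",
    tf_id: str = "",
) -> TauScore:
    """Tissue-specificity index tau = sum(1 - x_i/max x) / (n - 1).

    mode "expressed_only" evaluates the formula over the tissues where the TF
    is expressed (TPM > 1), the convention used when n counts expressing
    tissues; "all_tissues" uses every tissue.  A TF expressed in a single
    tissue under "expressed_only" gets tau = 1 by convention (the formula's
    n - 1 denominator is undefined at n = 1, and a one-tissue TF is maximally
    specific).
    """
    x = np.asarray(expression_row, dtype=float)
    if np.all(x <= 0):
        raise ValueError("expression row has no positive entry")
    n_expressed = int((x > TPM_EXPRESSED).sum())
    if mode == "expressed_only":
        sel = x[x > TPM_EXPRESSED]
        if len(sel) == 0:
            # expressed nowhere at TPM > 1 but has signal; treat as singleton
            return TauScore(tf_id=tf_id, tau=1.0, n_expressed=0)
        if len(sel) == 1:
            return TauScore(tf_id=tf_id, tau=1.0, n_expressed=1)
        xs = sel
    elif mode == "all_tissues":
        xs = x
    else:
        raise ValueError(f"unknown mode {mode!r}")
    xhat = xs / xs.max()
    value = float((1.0 - xhat).sum() / (len(xs) - 1))
    return TauScore(tf_id=tf_id, tau=min(value, 1.0), n_expressed=n_expressed)


def classify_specificity(
    tau_scores: Sequence[TauScore], cutoff: float = 0.8
) -> dict[str, str]:
    """Label each TF tissue-specific (tau >= cutoff) or ubiquitous."""
    return {
        s.tf_id: ("tissue-specific" if s.tau >= cutoff else "ubiquitous")
        for s in tau_scores
    }


def read_tpm(path) -> ExpressionTable:
    return ExpressionTable(pd.read_csv(path, sep="\t", index_col=0))


def write_tpm(expr: ExpressionTable, path) -> None:
    expr.tpm.to_csv(path, sep="\t", float_format="%.6f")
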