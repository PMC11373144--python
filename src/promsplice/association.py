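"""Per-TF 2x2 contingency statistics for occupancy vs splicing.

Two experiments share this machinery: within one tissue, TFBS presence in the
promoter against the exclusion/inclusion splice form; and across tissue pairs,
TFBS occupancy change (XOR bit) against splicing-phase change
(concordance/discordance).  Effect size is the odds ratio (Haldane-Anscombe
0.5 correction when a cell is empty), significance the Pearson chi-squared
test without continuity correction, Bonferroni-adjusted across the TFs tested,
significant at adjusted p < 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import splicing

ADJ_P_SIGNIFICANT = 1e-3

ONE_SIDED, BOTH_SIDED, SINGLETON = "one-sided", "both-sided", "singleton"


@dataclass(frozen=True)
class ContingencyTable:
    """Counts (a, b / c, d): rows = TF condition, columns = splicing condition.

    Row 1 = TFBS present (or occupancy changed), row 2 = absent (unchanged);
    column 1 = exclusion (or discordance), column 2 = inclusion (concordance).
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("empty table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass
class AssociationResult:
    tf_id: str
    table: ContingencyTable
    odds_ratio: float
    log2_or: float
    chi2: float
    pvalue: float
    adj_pvalue: float
    significant: bool
    valid: bool  # False when an expected cell is zero (chi2 undefined)


def chi2_test(t: ContingencyTable) -> tuple[float, float]:
    """Pearson chi-squared, df=1, no continuity correction.

    Raises ValueError when any expected cell is zero (a degenerate margin);
    callers flag such TFs instead of testing them.
    """
    arr = t.as_array()
    expected = stats.contingency.expected_freq(arr)
    if np.any(expected == 0):
        raise ValueError("expected cell count of zero: chi-squared undefined")
    chi2, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return float(chi2), float(p)


def odds_ratio(t: ContingencyTable) -> float:
    """(a*d)/(b*c); with any empty cell, 0.5 is first added to all four."""
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def bonferroni(pvalues: Sequence[float], m: int | None = None) -> np.ndarray:
    """min(1, m*p); m defaults to the number of p-values supplied."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = len(p)
    return np.minimum(1.0, m * p)


def tabulate_form_association(
    forms: Mapping[str, str],
    vectors: Mapping[str, np.ndarray],
    tf_index: int,
) -> ContingencyTable:
    """2x2 of TFBS presence vs exclusion/inclusion over the genes of one tissue.

    ``forms`` maps gene -> splice form for one tissue; only genes labelled
    exclusion or inclusion (and present in ``vectors``) are counted.
    """
    a = b = c = d = 0
    for gene, form in forms.items():
        if form not in (splicing.EXCLUSION, splicing.INCLUSION):
            continue
        if gene not in vectors:
            continue
        present = bool(vectors[gene][tf_index])
        if form == splicing.EXCLUSION:
            a += present
            c += not present
        else:
            b += present
            d += not present
    return ContingencyTable(a=a, b=b, c=c, d=d)


def tabulate_delta_association(events: Sequence, tf_index: int) -> ContingencyTable:
    """2x2 of occupancy change (XOR bit) vs phase change over delta events."""
    a = b = c = d = 0
    for e in events:
        changed = bool(e.delta_vector[tf_index])
        discordant = e.label == splicing.DISCORDANCE
        if changed:
            a += discordant
            b += not discordant
        else:
            c += discordant
            d += not discordant
    return ContingencyTable(a=a, b=b, c=c, d=d)


def associate(
    tables: Mapping[str, ContingencyTable],
) -> pd.DataFrame:
    """Run chi2 + OR + Bonferroni over per-TF tables; returns a tidy frame.

    TFs whose table has a zero expected cell are kept with valid=False and
    p = NaN; m for Bonferroni counts only the TFs actually tested.
    """
    rows = []
    testable = {}
    for tf, t in tables.items():
        try:
            chi2, p = chi2_test(t)
            testable[tf] = (chi2, p)
        except ValueError:
            testable[tf] = None
    m = sum(v is not None for v in testable.values())
    for tf, t in tables.items():
        res = testable[tf]
        orv = odds_ratio(t)
        if res is None:
            rows.append(
                dict(tf=tf, a=t.a, b=t.b, c=t.c, d=t.d, odds_ratio=orv,
                     log2_or=np.log2(orv), chi2=np.nan, pvalue=np.nan,
                     adj_pvalue=np.nan, significant=False, valid=False)
            )
        else:
            chi2, p = res
            adj = min(1.0, m * p)
            rows.append(
                dict(tf=tf, a=t.a, b=t.b, c=t.c, d=t.d, odds_ratio=orv,
                     log2_or=np.log2(orv), chi2=chi2, pvalue=p,
                     adj_pvalue=adj, significant=adj < ADJ_P_SIGNIFICANT,
                     valid=True)
            )
    return pd.DataFrame(rows).set_index("tf")


def classify_gene_group(forms: Sequence[str | float]) -> str:
    """singleton / one-sided / both-sided from a gene's per-tissue forms.

    Only exclusion/inclusion labels count as "having a form"; a gene with a
    form in exactly one tissue is a singleton, with both forms somewhere
    both-sided, otherwise (same single form in >= 2 tissues) one-sided.
    """
    formed = [
        f for f in forms
        if isinstance(f, str) and f in (splicing.EXCLUSION, splicing.INCLUSION)
    ]
    if not formed:
        raise ValueError("gene has no tissue with a non-intermediate form")
    if len(formed) == 1:
        return SINGLETON
    if len(set(formed)) == 2:
        return BOTH_SIDED
    return ONE_SIDED
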