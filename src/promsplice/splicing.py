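"""From PSI tables to splice-form labels, Z-scores, phases and delta events.

PSI (percent spliced-in) of a gene's first cassette exon lies in [0, 1].
Splice forms use the fixed cutoffs exclusion (PSI < 0.2) / inclusion
(PSI > 0.8).  For the paired-tissue analysis PSI is standardised per gene
(Z-score over the tissues where the gene is observed), the top and bottom 20%
of each gene's Z values are called the high / low splicing phase, and every
unordered tissue pair in which both tissues carry a non-middle phase becomes a
delta event: the XOR of the two occupancy encodings plus |delta Z|, labelled
concordance when the phases agree and discordance when they differ.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

EXCLUSION_MAX = 0.2
INCLUSION_MIN = 0.8
PSI_RANGE_MIN = 0.2
MIN_TISSUES = 3
PHASE_FRACTION = 0.2

EXCLUSION, INCLUSION, INTERMEDIATE = "exclusion", "inclusion", "intermediate"
LOW, HIGH, MIDDLE = "low", "high", "middle"
CONCORDANCE, DISCORDANCE = "concordance", "discordance"


@dataclass
class PsiTable:
    """Gene x tissue PSI matrix; NaN marks a gene not observed in a tissue."""

    psi: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.psi.values
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals) < -1e-9 or np.nanmax(vals) > 1 + 1e-9:
                raise ValueError("PSI entries must lie in [0, 1]")


@dataclass
class ZPsiTable:
    """Per-gene z-scored PSI plus the phase call for every entry."""

    z: pd.DataFrame
    phase: pd.DataFrame  # entries in {low, high, middle} or NaN


def label_splice_form(psi: float) -> str | None:
    """exclusion (< 0.2), inclusion (> 0.8) or intermediate; None if missing."""
    if psi is None or (isinstance(psi, float) and np.isnan(psi)):
        return None
    if not 0.0 <= psi <= 1.0:
        raise ValueError("PSI must lie in [0, 1]")
    if psi < EXCLUSION_MAX:
        return EXCLUSION
    if psi > INCLUSION_MIN:
        return INCLUSION
    return INTERMEDIATE


def splice_form_table(table: PsiTable) -> pd.DataFrame:
    """Element-wise splice-form labels (NaN where PSI is missing)."""
    psi = table.psi
    forms = pd.DataFrame(INTERMEDIATE, index=psi.index, columns=psi.columns, dtype=object)
    forms = forms.where(~(psi < EXCLUSION_MAX), EXCLUSION)
    forms = forms.where(~(psi > INCLUSION_MIN), INCLUSION)
    return forms.where(psi.notna(), np.nan)


def filter_genes(table: PsiTable) -> list[str]:
    """Genes with PSI range > 0.2 and observations in >= 3 tissues."""
    psi = table.psi
    n_obs = psi.notna().sum(axis=1)
    rng = psi.max(axis=1) - psi.min(axis=1)
    keep = (n_obs >= MIN_TISSUES) & (rng > PSI_RANGE_MIN)
    return list(psi.index[keep])


def z_transform(psi_row: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Per-gene Z = (PSI - mean) / sd over non-missing tissues.

    Population (n-denominator) standard deviation; missing stays missing.
    """
    is_series = isinstance(psi_row, pd.Series)
    x = np.asarray(psi_row, dtype=float)
    obs = ~np.isnan(x)
    sd = float(np.std(x[obs]))  # population sd
    if sd == 0:
        raise ValueError("zero standard deviation: row must pass the range filter")
    z = (x - np.mean(x[obs])) / sd
    if is_series:
        return pd.Series(z, index=psi_row.index)
    return z


def assign_phase(z_row: pd.Series) -> pd.Series:
    """Call the top 20% of a gene's Z values "high" and the bottom 20% "low".

    The tail size is k = floor(0.2 * n) with a minimum of 1 per tail; entries
    are ranked by a stable sort on (value, tissue order), so boundary ties
    resolve deterministically.  Requires >= 3 non-missing values.
    """
    obs_mask = z_row.notna()
    values = z_row[obs_mask]
    n = len(values)
    if n < MIN_TISSUES:
        raise ValueError("phase assignment needs >= 3 non-missing values")
    k = max(int(np.floor(PHASE_FRACTION * n)), 1)
    order = np.argsort(values.values, kind="stable")
    phases = np.array([MIDDLE] * n, dtype=object)
    phases[order[:k]] = LOW
    phases[order[n - k :]] = HIGH
    out = pd.Series(np.nan, index=z_row.index, dtype=object)
    out[values.index] = phases
    return out


def z_psi_table(table: PsiTable) -> ZPsiTable:
    """Filter, z-transform and phase-call the whole PSI table."""
    genes = filter_genes(table)
    psi = table.psi.loc[genes]
    z = psi.apply(z_transform, axis=1)
    phase = z.apply(assign_phase, axis=1)
    return ZPsiTable(z=z, phase=phase)


@dataclass
class DeltaEvent:
    """One gene, one unordered tissue pair: what changed between them.

    ``delta_vector`` is the XOR of the two per-TF occupancy bits; the
    positional XOR is available through :meth:`delta_positional` (computed
    from the two stored profiles, kept sparse).
    """

    gene_id: str
    tissue_a: str
    tissue_b: str
    delta_vector: np.ndarray
    delta_z: float
    label: str
    _profile_a: "object" = None
    _profile_b: "object" = None

    def delta_positional(self):
        """Sparse 2500 x n_TF XOR of the two positional matrices."""
        a, b = self._profile_a.positional, self._profile_b.positional
        return (a != b).astype(np.int8)

    def delta_positional_dense(self) -> np.ndarray:
        return np.asarray(self.delta_positional().todense(), dtype=np.int8)


def build_delta_events(
    profiles: Mapping[tuple[str, str], "object"],
    zpsi: ZPsiTable,
) -> list[DeltaEvent]:
    """Enumerate all unordered tissue pairs per gene with two non-middle
    phases, XOR their occupancy encodings and record |delta Z|.

    ``profiles`` maps (gene_id, tissue) to an OccupancyProfile.  Events whose
    delta vector is all zero are retained: an unchanged promoter with an
    unchanged (or changed) phase is an informative observation.
    """
    events: list[DeltaEvent] = []
    tissues = list(zpsi.z.columns)
    for gene in zpsi.z.index:
        phases = zpsi.phase.loc[gene]
        labelled = [
            t for t in tissues
            if isinstance(phases[t], str) and phases[t] in (LOW, HIGH)
            and (gene, t) in profiles
        ]
        for i, ta in enumerate(labelled):
            for tb in labelled[i + 1 :]:
                pa, pb = profiles[(gene, ta)], profiles[(gene, tb)]
                delta_vec = np.bitwise_xor(pa.vector, pb.vector)
                label = CONCORDANCE if phases[ta] == phases[tb] else DISCORDANCE
                dz = abs(float(zpsi.z.loc[gene, ta]) - float(zpsi.z.loc[gene, tb]))
                events.append(
                    DeltaEvent(
                        gene_id=gene,
                        tissue_a=ta,
                        tissue_b=tb,
                        delta_vector=delta_vec.astype(np.int8),
                        delta_z=dz,
                        label=label,
                        _profile_a=pa,
                        _profile_b=pb,
                    )
                )
    return events


def events_frame(events: Sequence[DeltaEvent]) -> pd.DataFrame:
    """Tabular view (gene, tissue_a, tissue_b, label, delta_z)."""
    return pd.DataFrame(
        {
            "gene": [e.gene_id for e in events],
            "tissue_a": [e.tissue_a for e in events],
            "tissue_b": [e.tissue_b for e in events],
            "label": [e.label for e in events],
            "delta_z": [e.delta_z for e in events],
        }
    )


def read_psi(path) -> PsiTable:
    return PsiTable(pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"]))


def write_psi(table: PsiTable, path) -> None:
    table.psi.to_csv(path, sep="\t", float_format="%.6f", na_rep="NA")
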