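"""End-to-end assembly: bundle -> occupancy profiles -> datasets.

Thin orchestration over the analysis modules, used by the scripts and tests:
scan every promoter with every motif, keep hits inside open chromatin within
the promoter window, gate by TF expression, build delta events, and expose
the two supervised datasets (within-tissue splice form; cross-tissue phase
change) as feature containers for the classifiers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import association, models, occupancy, splicing
from .motifscan import MotifHit, batch_scan_scores, encode_sequence, SCORE_QUANTUM
from .occupancy import ExpressionTable, OccupancyProfile
from .splicing import DeltaEvent, PsiTable, ZPsiTable
from .synthetic_data import SyntheticBundle


def scan_bundle(bundle: SyntheticBundle, p_threshold: float = 1e-3) -> dict[str, list[MotifHit]]:
    """All PWM hits per gene on its promoter-window sequence, both strands.

    Vectorised over genes: one scoring pass per (PWM, strand) for the whole
    gene x position matrix.
    """
    genes = list(bundle.genes.index)
    encoded = np.stack([encode_sequence(bundle.promoter_sequences[g]) for g in genes])
    hits: dict[str, list[MotifHit]] = {g: [] for g in genes}
    for pwm in bundle.pwms:
        support, probs = pwm._score_distribution()
        sf = np.cumsum(probs[::-1])[::-1]
        threshold = pwm.score_threshold(p_threshold)
        for strand, scores in batch_scan_scores(encoded, pwm).items():
            gi, starts = np.nonzero(scores >= threshold)
            for g_idx, start in zip(gi, starts):
                q = int(np.rint(scores[g_idx, start] / SCORE_QUANTUM))
                p = float(sf[min(max(q - support[0], 0), len(sf) - 1)])
                hits[genes[g_idx]].append(
                    MotifHit(
                        tf_id=pwm.id,
                        seq_id=genes[g_idx],
                        start=int(start),
                        end=int(start) + pwm.length,
                        strand=strand,
                        score=float(scores[g_idx, start]),
                        pvalue=max(p, np.nextafter(0, 1)),
                    )
                )
    for g in genes:
        hits[g].sort(key=lambda h: (h.start, h.tf_id, h.strand))
    return hits


def build_profiles(
    bundle: SyntheticBundle,
    hits: dict[str, list[MotifHit]] | None = None,
    p_threshold: float = 1e-3,
) -> dict[tuple[str, str], OccupancyProfile]:
    """Occupancy profile for every (gene, tissue): hits restricted to the
    tissue's open-chromatin peaks, gated by TPM > 1, strand-flipped."""
    from .motifscan import restrict_to_open_promoter

    if hits is None:
        hits = scan_bundle(bundle, p_threshold)
    expr = ExpressionTable(bundle.tpm)
    tf_order = sorted(bundle.tf_ids)
    window = (0, bundle.config.promoter_length)
    profiles: dict[tuple[str, str], OccupancyProfile] = {}
    for tissue in bundle.tissues:
        for g in bundle.genes.index:
            kept = restrict_to_open_promoter(hits[g], bundle.peaks[tissue][g], window)
            profiles[(g, tissue)] = occupancy.build_profile(
                kept,
                expr,
                tissue,
                gene_id=g,
                tf_order=tf_order,
                strand=bundle.genes.loc[g, "strand"],
                window_length=bundle.config.promoter_length,
            )
    return profiles


def delta_events(
    bundle: SyntheticBundle,
    profiles: dict[tuple[str, str], OccupancyProfile] | None = None,
) -> tuple[list[DeltaEvent], ZPsiTable]:
    if profiles is None:
        profiles = build_profiles(bundle)
    zpsi = splicing.z_psi_table(PsiTable(bundle.psi))
    return splicing.build_delta_events(profiles, zpsi), zpsi


def event_labels(events) -> np.ndarray:
    return np.array([1 if e.label == splicing.DISCORDANCE else 0 for e in events])


def flat_delta_features(events) -> models.Features:
    return models.Features(np.stack([e.delta_vector for e in events]).astype(np.float32))


def positional_delta_features(events) -> models.Features:
    return models.Features([e.delta_positional() for e in events])


def informative_tf_mask(events) -> np.ndarray:
    """TFs with >= 1 occupancy change anywhere in the event set — the feature
    subset the delta models actually see (mirrors a motif-corpus reduction to
    the changing features)."""
    return np.stack([e.delta_vector for e in events]).any(axis=0)


def form_dataset(
    bundle: SyntheticBundle,
    profiles: dict[tuple[str, str], OccupancyProfile],
) -> pd.DataFrame:
    """Within-tissue splice-form samples: one row per (gene, tissue) with a
    non-intermediate form; columns gene, tissue, label (1 = inclusion)."""
    forms = splicing.splice_form_table(PsiTable(bundle.psi))
    rows = []
    for tissue in bundle.tissues:
        for g in bundle.genes.index:
            f = forms.loc[g, tissue]
            if f in (splicing.EXCLUSION, splicing.INCLUSION):
                rows.append(
                    dict(gene=g, tissue=tissue, label=int(f == splicing.INCLUSION))
                )
    return pd.DataFrame(rows)


def form_features(
    samples: pd.DataFrame,
    profiles: dict[tuple[str, str], OccupancyProfile],
) -> np.ndarray:
    return np.stack(
        [
            profiles[(r.gene, r.tissue)].vector
            for r in samples.itertuples(index=False)
        ]
    ).astype(np.float32)


def delta_association(events, tf_order) -> pd.DataFrame:
    """Per-TF occupancy-change vs phase-change enrichment over delta events."""
    tables = {
        tf: association.tabulate_delta_association(events, i)
        for i, tf in enumerate(tf_order)
    }
    return association.associate(tables)


def subsample_one_event_per_gene(events, seed: int):
    """One randomly chosen delta event per gene.

    Events of one gene share tissues and occupancy, which under-disperses
    pooled contingency counts; sampling one pair per gene restores
    cross-observation independence (used for null-calibration checks).
    """
    import collections

    rng = np.random.default_rng(seed)
    by_gene = collections.defaultdict(list)
    for e in events:
        by_gene[e.gene_id].append(e)
    return [v[rng.integers(len(v))] for _, v in sorted(by_gene.items())]


def knockdown_delta_z(
    control: SyntheticBundle, perturbed: SyntheticBundle
) -> pd.Series:
    """Per-gene mean |delta Z_psi| between the control and perturbed PSI,
    standardised with the control's per-gene statistics."""
    psi_c, psi_p = control.psi, perturbed.psi
    sd = psi_c.std(axis=1, ddof=0)
    ok = sd > 0
    dz = (psi_p.sub(psi_c.mean(axis=1), axis=0)).div(sd, axis=0) - (
        psi_c.sub(psi_c.mean(axis=1), axis=0)
    ).div(sd, axis=0)
    return dz[ok].abs().mean(axis=1)
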