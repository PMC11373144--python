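"""Self-contained synthetic datasets with a planted promoter->splicing signal.

The generator emits everything the analysis consumes — promoter sequences,
per-tissue open-chromatin peaks, JASPAR-style motifs, a TF x tissue TPM table
and a gene x tissue PSI table — with the statistical structure the method
assumes:

* sharp motifs whose consensus words are implanted at known promoter sites;
* open chromatin that is largely conserved across tissues (each site's
  openness is shared across all tissues with probability
  ``occupancy_conservation``, otherwise redrawn per tissue), reproducing the
  near-identical per-gene occupancy profiles that contaminate naive
  cross-validation;
* bimodal PSI: a per-gene inclusion propensity on the log-odds scale, a
  per-tissue wobble, observation noise, and — for a chosen causal TF subset —
  a contribution of realized causal occupancy scaled by ``effect_size``
  (log-odds per occupancy change), which plants the dependence of
  splicing-phase change on occupancy change;
* a fraction of genes observed in exactly one tissue (singletons).

Ground truth (causal TFs, site table, per-(gene, tissue) causal occupancy)
rides along in the bundle so downstream recovery can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .motifscan import BASES, PWM, write_fasta, write_jaspar_pfms, read_fasta, read_jaspar_pfms

_RC = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic study.

    Defaults mirror the real study's conditions where it states them
    (15 tissues, 2500 bp promoter window); the remaining rates are fixed at
    values that give realistic site densities and PSI behaviour (see the
    methods note).
    """

    n_genes: int = 300
    n_tissues: int = 15
    n_tfs: int = 50
    n_causal_tfs: int = 5
    motif_length: int = 8
    promoter_length: int = 2500
    effect_size: float = 2.0
    occupancy_conservation: float = 0.85
    psi_noise_sd: float = 0.05
    singleton_fraction: float = 0.05
    seed: int = 0
    # secondary rates
    site_prob: float = 0.15          # P(a non-causal TF has a site in a gene)
    causal_site_prob: float = 0.5    # causal TFs bind more promoters
    wobble_scale: float = 0.35       # Exp scale of per-gene tissue wobble (logit)
    open_prob: float = 0.5           # P(a site is open, baseline / redrawn)
    peak_pad: int = 10               # bp of open chromatin flanking a site
    tissue_specific_frac: float = 0.3  # fraction of non-causal TFs tissue-specific
    psi_dropout: float = 0.05        # P(a non-singleton entry is unobserved)
    interaction_distance: int | None = None  # plant a co-located pair rule
    positional_effect: bool = False  # causal sites act only near the TSS
    proximal_window: int = 600       # bp upstream of the TSS that counts

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_tissues", "n_tfs", "n_causal_tfs",
                     "motif_length", "promoter_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("occupancy_conservation", "psi_noise_sd",
                     "singleton_fraction", "site_prob", "causal_site_prob",
                     "open_prob", "tissue_specific_frac", "psi_dropout"):
            v = getattr(self, name)
            if name == "psi_noise_sd":
                if v < 0:
                    raise ValueError("psi_noise_sd must be non-negative")
                continue
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_causal_tfs > self.n_tfs:
            raise ValueError("n_causal_tfs must not exceed n_tfs")
        if self.n_tissues < 3:
            raise ValueError(
                "n_tissues must be >= 3: the PSI filter discards genes "
                "observed in fewer than three tissues"
            )


@dataclass
class SyntheticBundle:
    """Everything the pipeline reads, plus ground truth."""

    config: SimConfig
    genes: pd.DataFrame          # index gene_id; chrom, tss, strand
    promoter_sequences: dict[str, str]
    peaks: dict[str, dict[str, list[tuple[int, int]]]]  # tissue -> gene -> intervals
    pwms: list[PWM]
    tpm: pd.DataFrame            # TF x tissue
    psi: pd.DataFrame            # gene x tissue, NaN = unobserved
    truth: dict = field(default_factory=dict)

    @property
    def tissues(self) -> list[str]:
        return list(self.tpm.columns)

    @property
    def tf_ids(self) -> list[str]:
        return [p.id for p in self.pwms]


def _make_pwms(rng: np.random.Generator, cfg: SimConfig) -> tuple[list[PWM], list[str]]:
    pwms, consensi = [], []
    for i in range(cfg.n_tfs):
        word = rng.integers(0, 4, size=cfg.motif_length)
        counts = np.ones((4, cfg.motif_length))
        counts[word, np.arange(cfg.motif_length)] = 197.0
        pwms.append(PWM(id=f"TF{i:03d}", name=f"TF{i:03d}", counts=counts))
        consensi.append("".join(BASES[b] for b in word))
    return pwms, consensi


def generate_dataset(config: SimConfig) -> SyntheticBundle:
    """Draw one synthetic study; deterministic given ``config.seed``."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    tissues = [f"tissue{j:02d}" for j in range(cfg.n_tissues)]
    pwms, consensi = _make_pwms(rng, cfg)
    tf_ids = [p.id for p in pwms]
    L = cfg.motif_length

    causal = list(rng.choice(cfg.n_tfs, size=cfg.n_causal_tfs, replace=False))
    causal_set = set(int(c) for c in causal)

    # --- TPM: causal TFs ubiquitous; a fraction of the rest tissue-specific
    tpm = np.empty((cfg.n_tfs, cfg.n_tissues))
    specific = np.zeros(cfg.n_tfs, dtype=bool)
    for f in range(cfg.n_tfs):
        if f not in causal_set and rng.random() < cfg.tissue_specific_frac:
            specific[f] = True
            k = int(rng.integers(1, max(2, cfg.n_tissues // 4) + 1))
            on = rng.choice(cfg.n_tissues, size=k, replace=False)
            row = np.full(cfg.n_tissues, 0.1) * np.exp(rng.normal(0, 0.3, cfg.n_tissues))
            row[on] = np.exp(rng.normal(2.5, 0.5, k))
            tpm[f] = row
        else:
            tpm[f] = np.exp(rng.normal(2.5, 0.5)) * np.exp(rng.normal(0, 0.3, cfg.n_tissues))
    tpm_df = pd.DataFrame(tpm, index=tf_ids, columns=tissues)
    expressed = tpm > 1.0  # (n_tfs, n_tissues)

    # --- site layout: one slot grid per promoter keeps footprints apart
    slot_w = max(L + 2 * cfg.peak_pad + 4, 50)
    n_slots = cfg.promoter_length // slot_w
    pair = tuple(int(c) for c in causal[:2]) if cfg.interaction_distance else None

    site_rows = []          # gene, tf, start, end
    colocated: dict[str, bool] = {}
    base = np.array(list("ACGT"))
    sequences: dict[str, str] = {}
    strands = rng.choice(["+", "-"], size=cfg.n_genes)

    site_p = np.full(cfg.n_tfs, cfg.site_prob)
    site_p[list(causal_set)] = cfg.causal_site_prob
    has_site = rng.random((cfg.n_genes, cfg.n_tfs)) < site_p[None, :]
    if pair is not None:
        for f in pair:
            has_site[:, f] = rng.random(cfg.n_genes) < 0.9

    for gi, g in enumerate(genes):
        tf_here = np.nonzero(has_site[gi])[0]
        if len(tf_here) > n_slots:
            tf_here = rng.choice(tf_here, size=n_slots, replace=False)
            mask = np.zeros(cfg.n_tfs, dtype=bool)
            mask[tf_here] = True
            has_site[gi] = mask
        slots = list(rng.permutation(n_slots)[: len(tf_here)])
        slot_of = dict(zip(tf_here.tolist(), slots))
        start_of = {f: s * slot_w + (slot_w - L) // 2 for f, s in slot_of.items()}
        if pair is not None and pair[0] in slot_of and pair[1] in slot_of:
            # co-located: the pair's sites sit side by side inside one peak
            # (footprints within one kernel span); otherwise >= 5 slots apart
            coloc = bool(rng.random() < 0.5)
            colocated[g] = coloc
            if coloc:
                start_of[pair[1]] = start_of[pair[0]] + L + 4
            elif abs(slot_of[pair[1]] - slot_of[pair[0]]) < 5:
                free = sorted(set(range(n_slots)) - set(slot_of.values()))
                far = [s for s in free if abs(s - slot_of[pair[0]]) >= 5]
                if far:
                    slot_of[pair[1]] = far[0]
                    start_of[pair[1]] = far[0] * slot_w + (slot_w - L) // 2
        seq = base[rng.integers(0, 4, size=cfg.promoter_length)]
        for f in slot_of:
            start = start_of[f]
            word = consensi[f]
            if rng.random() < 0.5:
                word = _revcomp(word)
            seq[start : start + L] = list(word)
            site_rows.append((g, tf_ids[f], start, start + L))
        sequences[g] = "".join(seq)

    sites = pd.DataFrame(site_rows, columns=["gene", "tf", "start", "end"])

    # --- openness per site x tissue, conserved with prob occupancy_conservation
    n_sites = len(sites)
    shared = rng.random(n_sites) < cfg.occupancy_conservation
    baseline = rng.random(n_sites) < cfg.open_prob
    open_mat = np.empty((n_sites, cfg.n_tissues), dtype=bool)
    open_mat[shared] = baseline[shared][:, None]
    open_mat[~shared] = rng.random(((~shared).sum(), cfg.n_tissues)) < cfg.open_prob
    if pair is not None:
        # the interaction pair shares one accessibility state per gene (one
        # peak's worth of chromatin), co-located or not: flat change bits are
        # then identically distributed in both gene classes and only the
        # positional arrangement separates them
        pair_tfs = {tf_ids[f] for f in pair}
        by_gene_site: dict[str, list[int]] = {}
        for si, row in enumerate(sites.itertuples(index=False)):
            if row.tf in pair_tfs:
                by_gene_site.setdefault(row.gene, []).append(si)
        for g, sis in by_gene_site.items():
            if len(sis) == 2:
                open_mat[sis[1]] = open_mat[sis[0]]

    peaks: dict[str, dict[str, list[tuple[int, int]]]] = {
        t: {g: [] for g in genes} for t in tissues
    }
    for si, row in enumerate(sites.itertuples(index=False)):
        ps = max(row.start - cfg.peak_pad, 0)
        pe = min(row.end + cfg.peak_pad, cfg.promoter_length)
        for tj, t in enumerate(tissues):
            if open_mat[si, tj]:
                peaks[t][row.gene].append((ps, pe))
    for t in tissues:
        for g in genes:
            peaks[t][g] = _merge_intervals(peaks[t][g])

    # --- realized causal occupancy: open site AND expressed TF
    tf_pos = {tf: i for i, tf in enumerate(tf_ids)}
    causal_occ = np.zeros((cfg.n_genes, cfg.n_tissues))
    gene_pos = {g: i for i, g in enumerate(genes)}
    # alternating effect signs: causal factors act as enhancers or silencers
    # of exon inclusion (knocked-down regulators shift usage both ways)
    causal_sign = {int(c): (1.0 if k % 2 == 0 else -1.0) for k, c in enumerate(causal)}
    # TSS-proximal gate: under positional_effect a causal site contributes
    # only when it lies within proximal_window bp upstream of the TSS (or
    # downstream of it); position measured TSS-relative on the gene's strand
    proximal_cut = cfg.promoter_length - 500 - cfg.proximal_window
    for si, row in enumerate(sites.itertuples(index=False)):
        f = tf_pos[row.tf]
        if f not in causal_set:
            continue
        gi = gene_pos[row.gene]
        if cfg.positional_effect:
            if strands[gi] == "+":
                tss_pos = row.start
            else:
                tss_pos = cfg.promoter_length - row.end
            if tss_pos < proximal_cut:
                continue
        causal_occ[gi] += causal_sign[f] * (open_mat[si] & expressed[f])

    if pair is not None:
        gate = np.array([colocated.get(g, False) for g in genes], dtype=float)
    else:
        gate = np.ones(cfg.n_genes)

    # --- PSI: bimodal logit with planted causal contribution
    mu = rng.choice([-1.0, 1.0], size=cfg.n_genes) * (2.2 + rng.exponential(0.8, cfg.n_genes))
    wobble_sd = rng.exponential(cfg.wobble_scale, size=cfg.n_genes)
    wobble = rng.normal(0.0, 1.0, (cfg.n_genes, cfg.n_tissues)) * wobble_sd[:, None]
    centred = causal_occ - causal_occ.mean(axis=1, keepdims=True)
    logit = mu[:, None] + wobble + cfg.effect_size * gate[:, None] * centred
    psi = 1.0 / (1.0 + np.exp(-logit))
    psi = np.clip(psi + rng.normal(0.0, cfg.psi_noise_sd, psi.shape), 0.0, 1.0)

    # --- missingness: singletons observed once; sporadic dropout elsewhere
    observed = rng.random(psi.shape) >= cfg.psi_dropout
    n_singleton = int(round(cfg.singleton_fraction * cfg.n_genes))
    singleton_idx = rng.choice(cfg.n_genes, size=n_singleton, replace=False)
    for gi in singleton_idx:
        observed[gi] = False
        observed[gi, rng.integers(cfg.n_tissues)] = True
    psi = np.where(observed, psi, np.nan)
    psi_df = pd.DataFrame(psi, index=genes, columns=tissues)

    genes_df = pd.DataFrame(
        {
            "chrom": "chr1",
            "tss": [100_000 + 10_000 * i for i in range(cfg.n_genes)],
            "strand": strands,
        },
        index=pd.Index(genes, name="gene"),
    )

    truth = {
        "causal_tfs": [tf_ids[int(c)] for c in causal],
        "causal_signs": {tf_ids[c]: s for c, s in causal_sign.items()},
        "sites": sites,
        "site_open": open_mat,
        "causal_occupancy": pd.DataFrame(causal_occ, index=genes, columns=tissues),
        "colocated": colocated,
        "singletons": [genes[int(i)] for i in singleton_idx],
    }
    return SyntheticBundle(
        config=cfg,
        genes=genes_df,
        promoter_sequences=sequences,
        peaks=peaks,
        pwms=pwms,
        tpm=tpm_df,
        psi=psi_df,
        truth=truth,
    )


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not ivs:
        return []
    ivs = sorted(ivs)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def generate_knockdown(
    bundle: SyntheticBundle,
    tf: str,
    shift: float,
    noise_sd: float | None = None,
    seed: int | None = None,
) -> SyntheticBundle:
    """Perturbed copy emulating an shRNA knockdown of ``tf``.

    Target genes (>= 1 planted site of ``tf``) have their PSI moved by
    ``shift`` control standard deviations, signed away from the nearer PSI
    boundary per gene — knocked-down factors can raise or lower exon usage.
    ``noise_sd`` (default: the bundle's psi_noise_sd) adds fresh observation
    noise to every gene, so a zero-shift run is an exchangeable null; with
    noise_sd=0 non-target PSI is returned bit-for-bit unchanged.
    """
    sites = bundle.truth["sites"]
    targets = set(sites.loc[sites["tf"] == tf, "gene"])
    if not targets:
        raise ValueError(f"{tf} has no target gene (no planted site)")
    if noise_sd is None:
        noise_sd = bundle.config.psi_noise_sd
    rng = np.random.default_rng(
        bundle.config.seed + 1_000_003 if seed is None else seed
    )
    psi = bundle.psi.copy()
    obs = psi.notna()
    noise = rng.normal(0.0, noise_sd, psi.shape) if noise_sd > 0 else 0.0
    new = psi.values + noise
    sd = np.nanstd(psi.values, axis=1)
    mean = np.nanmean(psi.values, axis=1)
    is_target = psi.index.isin(targets)
    sign = np.where(mean > 0.5, -1.0, 1.0)
    delta = np.where(is_target, sign * shift * sd, 0.0)
    new = new + delta[:, None]
    if noise_sd > 0 or shift != 0:
        new = np.clip(new, 0.0, 1.0)
    new = np.where(obs.values, new, np.nan)
    out_psi = pd.DataFrame(new, index=psi.index, columns=psi.columns)
    kd = replace(bundle.config)  # same config; bundle copies share immutables
    truth = dict(bundle.truth)
    truth["knockdown"] = {"tf": tf, "shift": shift, "targets": sorted(targets)}
    return SyntheticBundle(
        config=kd,
        genes=bundle.genes,
        promoter_sequences=bundle.promoter_sequences,
        peaks=bundle.peaks,
        pwms=bundle.pwms,
        tpm=bundle.tpm,
        psi=out_psi,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# on-disk form


def write_bundle(bundle: SyntheticBundle, directory) -> None:
    """BED peaks per tissue, JASPAR PFMs, FASTA promoters, TSV tables,
    truth.json sidecar; round-trips through :func:`read_bundle`."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_fasta(bundle.promoter_sequences, d / "promoters.fa")
    write_jaspar_pfms(bundle.pwms, d / "motifs.jaspar")
    bundle.tpm.to_csv(d / "tpm.tsv", sep="\t", float_format="%.6f")
    bundle.psi.to_csv(d / "psi.tsv", sep="\t", float_format="%.6f", na_rep="NA")
    bundle.genes.to_csv(d / "genes.tsv", sep="\t")
    (d / "peaks").mkdir(exist_ok=True)
    for tissue, per_gene in bundle.peaks.items():
        rows = [
            (g, s, e)
            for g, ivs in sorted(per_gene.items())
            for s, e in ivs
        ]
        pd.DataFrame(rows, columns=["chrom", "start", "end"]).to_csv(
            d / "peaks" / f"{tissue}.bed", sep="\t", header=False, index=False
        )
    truth = bundle.truth
    payload = {
        "causal_tfs": truth.get("causal_tfs", []),
        "singletons": truth.get("singletons", []),
        "colocated": truth.get("colocated", {}),
        "config": {
            k: v for k, v in vars(bundle.config).items()
        },
    }
    (d / "truth.json").write_text(json.dumps(payload, indent=1))
    truth.get("sites", pd.DataFrame()).to_csv(d / "sites.tsv", sep="\t", index=False)


def read_bundle(directory) -> SyntheticBundle:
    d = Path(directory)
    payload = json.loads((d / "truth.json").read_text())
    cfg = SimConfig(**payload["config"])
    tpm = pd.read_csv(d / "tpm.tsv", sep="\t", index_col=0)
    psi = pd.read_csv(d / "psi.tsv", sep="\t", index_col=0, na_values=["NA"])
    genes = pd.read_csv(d / "genes.tsv", sep="\t", index_col=0)
    peaks: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for bed in sorted((d / "peaks").glob("*.bed")):
        per_gene: dict[str, list[tuple[int, int]]] = {g: [] for g in genes.index}
        try:
            df = pd.read_csv(bed, sep="\t", header=None, names=["chrom", "start", "end"])
        except pd.errors.EmptyDataError:
            df = pd.DataFrame(columns=["chrom", "start", "end"])
        for row in df.itertuples(index=False):
            per_gene.setdefault(row.chrom, []).append((int(row.start), int(row.end)))
        peaks[bed.stem] = per_gene
    truth = {
        "causal_tfs": payload["causal_tfs"],
        "singletons": payload["singletons"],
        "colocated": payload["colocated"],
        "sites": pd.read_csv(d / "sites.tsv", sep="\t")
        if (d / "sites.tsv").stat().st_size > 1
        else pd.DataFrame(),
    }
    return SyntheticBundle(
        config=cfg,
        genes=genes,
        promoter_sequences=read_fasta(d / "promoters.fa"),
        peaks=peaks,
        pwms=read_jaspar_pfms(d / "motifs.jaspar"),
        tpm=tpm,
        psi=psi,
        truth=truth,
    )
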