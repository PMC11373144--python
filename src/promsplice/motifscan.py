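"""PWM scanning of promoter open-chromatin sequence.

Replaces an external motif-scanning step: position frequency matrices are
converted to log-odds scores against a background base composition, every
window of the promoter sequence is scored on both strands, and a window is
reported as a hit when the probability of an equal-or-better score under the
background model falls below a per-window threshold (default 1e-3, the lenient
setting appropriate when the scanned sequence is already restricted to open
chromatin).

The p-value is computed exactly on a score lattice: column scores are rounded
to 1e-3 bits and the distribution of the total score of a random L-mer under
the background is built by dynamic programming (one convolution per column).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = {0: 3, 1: 2, 2: 1, 3: 0}

#: score lattice granularity in bits
SCORE_QUANTUM = 1e-3
#: pseudocount added to each PFM cell before normalisation
PSEUDOCOUNT = 0.25

UNIFORM_BACKGROUND = np.full(4, 0.25)


@dataclass
class PWM:
    """A position frequency matrix with its scoring machinery.

    Parameters
    ----------
    id : str
        Motif identifier (e.g. a JASPAR accession).
    name : str
        TF name.
    counts : (4, L) array
        Non-negative base counts, rows ordered A, C, G, T.
    background : (4,) array
        Background base probabilities; must sum to 1.
    """

    id: str
    name: str
    counts: np.ndarray
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError("counts must be a 4 x L matrix (rows A,C,G,T)")
        if self.length < 4:
            raise ValueError("motif length must be >= 4")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if np.any(self.counts.sum(axis=0) == 0):
            raise ValueError("PFM has an all-zero column")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must sum to 1")
        self._lattice_cache: tuple[np.ndarray, np.ndarray] | None = None

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        """(4, L) log2 odds of base frequency vs background, with pseudocount."""
        freq = self.counts + PSEUDOCOUNT
        freq = freq / freq.sum(axis=0, keepdims=True)
        return np.log2(freq / self.background[:, None])

    @property
    def lattice_log_odds(self) -> np.ndarray:
        """Integer log-odds in units of SCORE_QUANTUM bits."""
        return np.rint(self.log_odds / SCORE_QUANTUM).astype(np.int64)

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.counts, axis=0))

    @property
    def max_score(self) -> float:
        return float(self.lattice_log_odds.max(axis=0).sum() * SCORE_QUANTUM)

    @property
    def min_score(self) -> float:
        return float(self.lattice_log_odds.min(axis=0).sum() * SCORE_QUANTUM)

    def _score_distribution(self) -> tuple[np.ndarray, np.ndarray]:
        """Support (lattice units, offset by minimum) and probabilities of the
        total score of a random L-mer under the background model."""
        if self._lattice_cache is not None:
            return self._lattice_cache
        lo = self.lattice_log_odds
        col_min = lo.min(axis=0)
        col_max = lo.max(axis=0)
        span = int((col_max - col_min).sum())
        dist = np.zeros(span + 1)
        dist[0] = 1.0
        filled = 0
        for j in range(self.length):
            width = int(col_max[j] - col_min[j])
            new = np.zeros(filled + width + 1)
            for b in range(4):
                off = int(lo[b, j] - col_min[j])
                new[off : off + filled + 1] += self.background[b] * dist[: filled + 1]
            filled += width
            dist[: filled + 1] = new
        probs = dist[: filled + 1]
        base = int(col_min.sum())
        support = base + np.arange(filled + 1)
        self._lattice_cache = (support, probs)
        return self._lattice_cache

    def score_threshold(self, p_threshold: float) -> float:
        """Smallest lattice score whose p-value is below ``p_threshold``."""
        support, probs = self._score_distribution()
        sf = np.cumsum(probs[::-1])[::-1]
        ok = np.nonzero(sf < p_threshold)[0]
        if len(ok) == 0:
            return np.inf
        return float(support[ok[0]] * SCORE_QUANTUM)


@dataclass(frozen=True)
class MotifHit:
    """A PWM match on one strand of a sequence, 0-based half-open."""

    tf_id: str
    seq_id: str
    start: int
    end: int
    strand: str
    score: float
    pvalue: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("start must be < end")
        if not 0.0 < self.pvalue <= 1.0:
            raise ValueError("pvalue must be in (0, 1]")


@dataclass(frozen=True)
class PromoterWindow:
    """Strand-aware promoter window [-2000, +500) around a TSS.

    ``tss`` is 1-based genomic; ``start``/``end`` give the window as a 0-based
    half-open genomic interval of length 2500 regardless of strand.
    """

    gene_id: str
    chrom: str
    tss: int
    strand: str

    UPSTREAM: int = 2000
    DOWNSTREAM: int = 500

    @property
    def start(self) -> int:
        if self.strand == "+":
            return self.tss - 1 - self.UPSTREAM
        return self.tss - self.DOWNSTREAM

    @property
    def end(self) -> int:
        return self.start + self.UPSTREAM + self.DOWNSTREAM

    @property
    def length(self) -> int:
        return self.UPSTREAM + self.DOWNSTREAM


def encode_sequence(sequence: str) -> np.ndarray:
    """Map A/C/G/T to 0..3 and anything else (N) to -1."""
    arr = np.frombuffer(sequence.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def score_pvalue(pwm: PWM, score: float) -> float:
    """P(random L-mer scores >= ``score``) under the PWM's background model.

    The query score is rounded onto the same 1e-3-bit lattice used for the
    dynamic-programming distribution, so enumeration over rounded word scores
    reproduces the result exactly.
    """
    if not np.isfinite(score):
        raise ValueError("score must be finite")
    support, probs = pwm._score_distribution()
    q = int(np.rint(score / SCORE_QUANTUM))
    if q <= support[0]:
        return 1.0
    if q > support[-1]:
        return 0.0
    return float(probs[q - support[0] :].sum())


def _window_scores(encoded: np.ndarray, lattice_lo: np.ndarray) -> np.ndarray:
    """Lattice score of every window; windows containing N get -inf."""
    L = lattice_lo.shape[1]
    n = len(encoded) - L + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for j in range(L):
        col = encoded[j : j + n]
        invalid = col < 0
        bad |= invalid
        safe = np.where(invalid, 0, col)
        scores += lattice_lo[safe, j]
    out = scores.astype(float) * SCORE_QUANTUM
    out[bad] = -np.inf
    return out


def reverse_complement_lattice(lattice_lo: np.ndarray) -> np.ndarray:
    return lattice_lo[::-1, ::-1]


def scan(sequence: str, pwm: PWM, p_threshold: float = 1e-3) -> list[MotifHit]:
    """Report every window of ``sequence``, on both strands, whose score has
    background p-value below ``p_threshold``.

    Windows containing a non-ACGT base are skipped.  A sequence shorter than
    the motif yields an empty list.
    """
    if not 0.0 < p_threshold <= 1.0:
        raise ValueError("p_threshold must be in (0, 1]")
    encoded = encode_sequence(sequence)
    return scan_encoded(encoded, pwm, "seq", p_threshold)


def scan_encoded(
    encoded: np.ndarray, pwm: PWM, seq_id: str, p_threshold: float = 1e-3
) -> list[MotifHit]:
    """Scan an integer-encoded sequence (see :func:`encode_sequence`)."""
    L = pwm.length
    lo = pwm.lattice_log_odds
    support, probs = pwm._score_distribution()
    sf = np.cumsum(probs[::-1])[::-1]
    hits: list[MotifHit] = []
    for strand, lattice in (("+", lo), ("-", reverse_complement_lattice(lo))):
        scores = _window_scores(encoded, lattice)
        for start in np.nonzero(np.isfinite(scores))[0]:
            q = int(np.rint(scores[start] / SCORE_QUANTUM))
            p = 1.0 if q <= support[0] else float(sf[max(q - support[0], 0)]) if q <= support[-1] else 0.0
            if p < p_threshold or p_threshold >= 1.0:
                hits.append(
                    MotifHit(
                        tf_id=pwm.id,
                        seq_id=seq_id,
                        start=int(start),
                        end=int(start) + L,
                        strand=strand,
                        score=float(scores[start]),
                        pvalue=max(p, np.nextafter(0, 1)),
                    )
                )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def batch_scan_scores(encoded: np.ndarray, pwm: PWM) -> dict[str, np.ndarray]:
    """Window lattice scores for a (n_seq, seq_len) encoded matrix, per strand.

    Vectorised over sequences: one shifted gather-add per motif column.
    """
    if encoded.ndim != 2:
        raise ValueError("encoded must be 2-D (n_seq, seq_len)")
    lo = pwm.lattice_log_odds
    out = {}
    for strand, lattice in (("+", lo), ("-", reverse_complement_lattice(lo))):
        L = lattice.shape[1]
        n = encoded.shape[1] - L + 1
        scores = np.zeros((encoded.shape[0], max(n, 0)), dtype=np.int64)
        bad = np.zeros_like(scores, dtype=bool)
        for j in range(L):
            col = encoded[:, j : j + n]
            invalid = col < 0
            bad |= invalid
            scores += lattice[np.where(invalid, 0, col), j]
        fscores = scores.astype(float) * SCORE_QUANTUM
        fscores[bad] = -np.inf
        out[strand] = fscores
    return out


def restrict_to_open_promoter(
    hits: Sequence[MotifHit],
    peaks: Sequence[tuple[int, int]],
    window: tuple[int, int] | PromoterWindow,
) -> list[MotifHit]:
    """Keep hits fully contained in the intersection of a peak with the
    promoter window; output sorted by start.

    Coordinates of hits, peaks and window must share one system (genomic, or
    promoter-relative as in the synthetic pipeline).
    """
    if isinstance(window, PromoterWindow):
        wstart, wend = window.start, window.end
    else:
        wstart, wend = window
    clipped = [
        (max(ps, wstart), min(pe, wend))
        for ps, pe in peaks
        if min(pe, wend) > max(ps, wstart)
    ]
    kept = [
        h
        for h in hits
        if any(h.start >= ps and h.end <= pe for ps, pe in clipped)
    ]
    kept.sort(key=lambda h: h.start)
    return kept


# ---------------------------------------------------------------------------
# I/O


def read_jaspar_pfms(path) -> list[PWM]:
    """Read JASPAR plain-text PFMs (``>ID NAME`` then four A/C/G/T rows)."""
    from Bio import motifs

    with open(path) as fh:
        records = motifs.parse(fh, "jaspar")
    out = []
    for m in records:
        counts = np.array([m.counts[b] for b in BASES], dtype=float)
        out.append(PWM(id=m.matrix_id or m.name, name=m.name, counts=counts))
    return out


def write_jaspar_pfms(pwms: Sequence[PWM], path) -> None:
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.id} {p.name}\n")
            for bi, base in enumerate(BASES):
                row = " ".join(f"{v:.0f}" for v in p.counts[bi])
                fh.write(f"{base} [ {row} ]\n")


def write_hits_bed6(hits: Sequence[MotifHit], path, score_cap: float = 1000.0) -> None:
    """Hits as BED6; the score column is -log10(p), capped."""
    with open(path, "w") as fh:
        for h in hits:
            score = min(-np.log10(h.pvalue), score_cap)
            fh.write(
                f"{h.seq_id}\t{h.start}\t{h.end}\t{h.tf_id}\t{score:.3f}\t{h.strand}\n"
            )


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
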