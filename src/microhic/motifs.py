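"""PWM motif scanning with exact p-values, boundary enrichment, and
promoter scanning.

Scoring follows the standard log-odds convention: a window of width w
scores sum_pos log2(p_base(pos) / bg_base), evaluated on both strands.
The p-value of a score is the upper-tail mass of the exact null score
distribution under the 0-order background, computed by dynamic
programming over positions with per-position scores discretized to a
fixed grid (1e-3 in log2 units) — the same discretized scores are used
for the observed windows, so observed and null scores live on one grid.

Boundary enrichment is the descriptive statistic used to rank motifs: the
proportion of globule boundaries containing at least one hit (>= 1 bp
overlap), ranked in descending order with ties broken by motif id.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import GeneRecord, GenomicInterval, PWM

__all__ = [
    "MotifHit",
    "BoundaryEnrichment",
    "score_pvalue_table",
    "scan_pwm",
    "boundary_enrichment",
    "promoter_scan",
]

GRID = 1e-3  # log2 score discretization


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    chrom: str
    start: int
    end: int
    strand: str
    score: float
    p_value: float


@dataclass
class BoundaryEnrichment:
    motif_id: str
    n_hit_boundaries: int
    n_boundaries: int
    proportion: float
    rank: int = 0


def _int_scores(pwm: PWM) -> np.ndarray:
    """(width, 4) log-odds scores on the integer grid."""
    return np.round(pwm.log_odds() / GRID).astype(np.int64)


def score_pvalue_table(pwm: PWM) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of the discretized window score.

    Returns (scores, tail) where ``tail[k]`` is P(score >= scores[k])
    under the 0-order background.  Computed by DP: the distribution over
    integer scores is convolved one motif position at a time.
    """
    s_int = _int_scores(pwm)
    bg = pwm.background
    cur_lo = int(s_int[0].min())
    cur_hi = int(s_int[0].max())
    cur = np.zeros(cur_hi - cur_lo + 1)
    for b in range(4):
        cur[s_int[0, b] - cur_lo] += bg[b]
    for pos in range(1, pwm.width):
        nlo = cur_lo + int(s_int[pos].min())
        nhi = cur_hi + int(s_int[pos].max())
        nxt = np.zeros(nhi - nlo + 1)
        for b in range(4):
            sh = int(s_int[pos, b])
            nxt[cur_lo + sh - nlo: cur_lo + sh - nlo + len(cur)] += bg[b] * cur
        cur, cur_lo, cur_hi = nxt, nlo, nhi
    scores = (np.arange(cur_lo, cur_hi + 1)) * GRID
    tail = np.cumsum(cur[::-1])[::-1]
    return scores, np.minimum(tail, 1.0)


_ENC = np.full(256, -1, dtype=np.int8)
for _k, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _k
    _ENC[ord(_b.lower())] = _k


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


def estimate_background(seqs: dict[str, str]) -> np.ndarray:
    """0-order base frequencies over all scanned sequence."""
    counts = np.zeros(4)
    for s in seqs.values():
        e = _encode(s)
        counts += np.bincount(e[e >= 0], minlength=4)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    return counts / counts.sum()


def _scan_strand(enc: np.ndarray, s_int: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Discretized window scores; windows with non-ACGT are masked."""
    w = s_int.shape[0]
    n = len(enc) - w + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    total = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    safe = np.where(enc >= 0, enc, 0)
    for pos in range(w):
        total += s_int[pos][safe[pos: pos + n]]
        bad |= enc[pos: pos + n] < 0
    return total, ~bad


def scan_pwm(
    pwm: PWM,
    seqs: dict[str, str],
    p_max: float = 1e-4,
    background: np.ndarray | None = None,
) -> list[MotifHit]:
    """Scan both strands of every sequence; report hits with p <= p_max.

    Unless ``background`` is given, the 0-order background is estimated
    from the scanned sequences themselves.  Scanning is invariant to
    FASTA line wrapping and case.
    """
    if background is None:
        background = estimate_background(seqs)
    pwm = pwm.with_background(background)
    w = pwm.width
    scores_grid, tail = score_pvalue_table(pwm)
    int_lo = int(round(scores_grid[0] / GRID))
    # score threshold for p <= p_max
    ok = tail <= p_max
    if not np.any(ok):
        return []
    thr_idx = int(np.argmax(ok))
    hits: list[MotifHit] = []
    fwd = _int_scores(pwm)
    rev = _int_scores(pwm.reverse_complement())
    for chrom, seq in seqs.items():
        if len(seq) < w:
            raise ValueError(f"motif wider than sequence {chrom}")
        enc = _encode(seq)
        for strand, s_int in (("+", fwd), ("-", rev)):
            total, valid = _scan_strand(enc, s_int)
            idx = total - int_lo
            np.clip(idx, 0, len(tail) - 1, out=idx)
            sel = np.nonzero(valid & (idx >= thr_idx))[0]
            for off in sel:
                hits.append(
                    MotifHit(pwm.motif_id, chrom, int(off), int(off) + w, strand,
                             float(total[off] * GRID), float(tail[idx[off]]))
                )
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return hits


class _HitIndex:
    """Per-chromosome sorted hit intervals for fast overlap queries."""

    def __init__(self, hits: list[MotifHit]):
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        by_chrom: dict[str, list[MotifHit]] = {}
        for h in hits:
            by_chrom.setdefault(h.chrom, []).append(h)
        for chrom, hh in by_chrom.items():
            s = np.array(sorted(h.start for h in hh))
            self._starts[chrom] = s
            # constant width per motif, so ends are starts + w
            self._ends[chrom] = s + (hh[0].end - hh[0].start)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        s = self._starts.get(chrom)
        if s is None:
            return False
        w = int(self._ends[chrom][0] - s[0])
        lo = np.searchsorted(s, start - w + 1, side="left")
        hi = np.searchsorted(s, end, side="left")
        return hi > lo


def boundary_enrichment(
    hits_by_motif: dict[str, list[MotifHit]],
    boundaries: list[GenomicInterval],
) -> list[BoundaryEnrichment]:
    """Proportion of boundaries containing >= 1 hit, per motif, ranked.

    A boundary "contains" a motif when any hit overlaps it by >= 1 bp.
    Descending by proportion; ties broken by motif id.
    """
    if not boundaries:
        raise ValueError("no boundaries given")
    out = []
    for motif_id, hits in hits_by_motif.items():
        index = _HitIndex(hits)
        n_hit = sum(1 for b in boundaries if index.overlaps(b.chrom, b.start, b.end))
        out.append(BoundaryEnrichment(motif_id, n_hit, len(boundaries),
                                      n_hit / len(boundaries)))
    out.sort(key=lambda e: (-e.proportion, e.motif_id))
    for r, e in enumerate(out, 1):
        e.rank = r
    return out


def promoter_interval(gene: GeneRecord, chrom_length: int,
                      upstream_bp: int = 1500) -> GenomicInterval | None:
    """The ``upstream_bp`` region 5' of the gene on its strand, truncated
    at chromosome edges; None if the gene is unstranded or the promoter
    is empty."""
    if gene.strand == "+":
        start, end = max(0, gene.start - upstream_bp), gene.start
    elif gene.strand == "-":
        start, end = gene.end, min(chrom_length, gene.end + upstream_bp)
    else:
        return None
    if start >= end:
        return None
    return GenomicInterval(gene.chrom, start, end, gene.strand, f"{gene.id}_promoter")


def promoter_scan(
    hits_by_motif: dict[str, list[MotifHit]],
    genes: list[GeneRecord],
    layout,
    upstream_bp: int = 1500,
) -> tuple[dict[str, dict[str, bool]], list[str]]:
    """Per-gene presence of each motif in the 1.5-kb (default) promoter.

    Returns (table, warnings): ``table[gene_id][motif_id]`` is True when
    at least one hit overlaps the promoter; unstranded genes are skipped
    with a warning.
    """
    lengths = layout.lengths
    table: dict[str, dict[str, bool]] = {}
    notes: list[str] = []
    indexes = {m: _HitIndex(hits) for m, hits in hits_by_motif.items()}
    for g in genes:
        prom = promoter_interval(g, lengths[g.chrom], upstream_bp)
        if prom is None:
            notes.append(f"gene {g.id or g} has no strand or empty promoter; skipped")
            continue
        table[g.id] = {
            m: idx.overlaps(prom.chrom, prom.start, prom.end)
            for m, idx in indexes.items()
        }
    return table, notes
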