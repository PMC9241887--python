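"""Insulation-score computation, boundary calling and globule segmentation.

The insulation score of bin *i* is the mean contact count in the w-by-w
square upstream-by-downstream of the bin,

    raw(i) = mean{ M[a, b] : i-w <= a <= i-1,  i+1 <= b <= i+w },

restricted to one chromosome; squares are never truncated — bins within
``w`` of a chromosome end are masked invalid.  The reported track is
log2(raw / chromosome mean of raw over valid bins), so self-interacting
domains appear as plateaus and their junctions as local minima.
Boundaries are local minima whose depth relative to both flanking local
maxima exceeds a strength threshold; globules are the intervals between
consecutive boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import ranksums

from .genome import BinTable, ContactMatrix, GenomeLayout, GenomicInterval

__all__ = [
    "InsulationTrack",
    "GlobuleSet",
    "insulation_score",
    "call_boundaries",
    "segment_globules",
    "globule_bin_stats",
    "boundary_f1",
]


@dataclass
class InsulationTrack:
    bin_table: BinTable
    window_bins: int
    raw: np.ndarray          # mean count in the off-diagonal square
    normalized: np.ndarray   # log2(raw / chrom mean of raw), NaN where invalid
    valid: np.ndarray        # False within window of chromosome ends


@dataclass
class GlobuleSet:
    """Boundaries and the self-interacting domains they delimit."""

    boundaries: list[tuple[str, int, float]]     # (chrom, global bin, strength)
    globules: list[GenomicInterval]
    labels: np.ndarray                           # per-bin: 'boundary'|'interior'|'edge'
    bin_table: BinTable

    @property
    def boundary_bins(self) -> np.ndarray:
        return np.array([b for _, b, _ in self.boundaries], dtype=np.int64)

    def sizes_kb(self) -> np.ndarray:
        return np.array([(g.end - g.start) / 1000.0 for g in self.globules])

    def boundary_intervals(self) -> list[GenomicInterval]:
        bt = self.bin_table
        return [
            GenomicInterval(chrom, int(bt.start[b]), int(bt.end[b]), id=f"boundary_{k}")
            for k, (chrom, b, _) in enumerate(self.boundaries)
        ]


def insulation_score(matrix: ContactMatrix, w_bp: int) -> InsulationTrack:
    """Insulation track at window ``w_bp`` (must be >= 2 bins)."""
    bt = matrix.bin_table
    res = bt.resolution
    w = w_bp // res
    if w_bp < 2 * res:
        raise ValueError(f"window {w_bp} bp is below 2 bins at {res} bp resolution")
    n = bt.n_bins
    raw = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    norm = np.full(n, np.nan)
    for nm in bt.layout.names:
        glo, ghi = bt.chrom_range(nm)
        n_c = ghi - glo
        if n_c < 2 * w + 1:
            continue  # chromosome too short: all-invalid
        m = matrix.cis_dense(nm)
        # summed-area table for O(1) square sums
        sat = np.zeros((n_c + 1, n_c + 1))
        sat[1:, 1:] = np.cumsum(np.cumsum(m, axis=0), axis=1)
        idx = np.arange(w, n_c - w)
        a0, a1 = idx - w, idx            # rows [i-w, i)
        b0, b1 = idx + 1, idx + w + 1    # cols [i+1, i+w]
        sq = sat[a1, b1] - sat[a0, b1] - sat[a1, b0] + sat[a0, b0]
        raw[glo + idx] = sq / (w * w)
        valid[glo + idx] = True
        mean_raw = np.nanmean(raw[glo + idx])
        if mean_raw > 0:
            with np.errstate(divide="ignore"):
                norm[glo + idx] = np.log2(raw[glo + idx] / mean_raw)
        else:
            valid[glo + idx] = False
            raw[glo + idx] = np.nan
            norm[glo + idx] = np.nan
    return InsulationTrack(bt, w, raw, norm, valid)


def _local_minima(v: np.ndarray) -> list[int]:
    """Indices of local minima in a 1-D array; plateau -> leftmost bin;
    run endpoints are never minima."""
    n = len(v)
    minima = []
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        # plateau v[i..j]; check strict descent on the left, ascent on right
        if v[i - 1] > v[i] and j + 1 < n and v[j + 1] > v[i]:
            minima.append(i)
        i = j + 1
    return minima


def call_boundaries(track: InsulationTrack, min_strength: float = 0.1,
                    smooth_bins: int = 5) -> list[tuple[str, int, float]]:
    """Local minima of the normalized insulation score with strength
    >= ``min_strength`` (log2 units).

    The normalized track is first smoothed by a centered moving average
    over ``smooth_bins`` bins within each valid run (1 disables it);
    this suppresses shot-noise minima at realistic read depths.
    Strength is the smaller of the rises to the flanking local maxima
    (segment maxima between consecutive minima, run edges included);
    minima at the edges of a valid run are discarded.
    """
    bt = track.bin_table
    out: list[tuple[str, int, float]] = []
    half = max(smooth_bins, 1) // 2
    for nm in bt.layout.names:
        glo, ghi = bt.chrom_range(nm)
        val = track.valid[glo:ghi]
        score = track.normalized[glo:ghi]
        if half > 0:
            score = score.copy()
            for k in np.nonzero(val)[0]:
                lo = max(k - half, 0)
                hi = min(k + half + 1, len(score))
                seg = track.normalized[glo + lo: glo + hi][val[lo:hi]]
                score[k] = seg.mean()
        # contiguous valid runs
        i = 0
        n_c = ghi - glo
        while i < n_c:
            if not val[i]:
                i += 1
                continue
            j = i
            while j < n_c and val[j]:
                j += 1
            v = score[i:j]
            mins = _local_minima(v)
            anchors = [0] + mins + [len(v) - 1]
            for k, m in enumerate(mins):
                left_max = v[anchors[k]: m + 1].max()
                right_max = v[m: anchors[k + 2] + 1].max()
                strength = float(min(left_max, right_max) - v[m])
                if strength >= min_strength:
                    out.append((nm, glo + i + m, strength))
            i = j
    out.sort(key=lambda r: r[1])
    return out


def segment_globules(
    boundaries: list[tuple[str, int, float]],
    bin_table: BinTable,
    layout: GenomeLayout,
    track: InsulationTrack | None = None,
) -> GlobuleSet:
    """Partition chromosomes into globules between consecutive boundaries.

    Boundary bins are excluded from globule interiors; chromosome ends
    close the first and last globule.  Per-bin labels are 'boundary',
    'interior', or 'edge' for bins masked invalid by the insulation
    window (when a track is given).
    """
    labels = np.full(bin_table.n_bins, "interior", dtype=object)
    if track is not None:
        labels[~track.valid] = "edge"
    globules: list[GenomicInterval] = []
    per_chrom: dict[str, list[int]] = {nm: [] for nm in layout.names}
    for chrom, b, _ in boundaries:
        per_chrom[chrom].append(b)
        labels[b] = "boundary"
    k = 0
    for nm, L in layout.chromosomes:
        glo, ghi = bin_table.chrom_range(nm)
        bs = sorted(per_chrom[nm])
        edges = [glo - 1] + bs + [ghi]
        for a, b in zip(edges[:-1], edges[1:]):
            lo_bin, hi_bin = a + 1, b  # bins strictly between boundaries
            if hi_bin <= lo_bin:
                continue
            start = int(bin_table.start[lo_bin])
            end = int(bin_table.end[hi_bin - 1])
            globules.append(GenomicInterval(nm, start, end, id=f"globule_{k}"))
            k += 1
    return GlobuleSet(list(boundaries), globules, labels, bin_table)


def boundary_f1(called: np.ndarray, truth: np.ndarray, tol_bins: int = 1) -> float:
    """F1 score of called vs true boundary bins at +/- ``tol_bins``.

    Greedy one-to-one matching: each called bin may claim one true bin
    within the tolerance and vice versa.
    """
    called = np.sort(np.asarray(called, dtype=np.int64))
    truth = np.sort(np.asarray(truth, dtype=np.int64))
    if len(called) == 0 or len(truth) == 0:
        return 0.0
    used = np.zeros(len(truth), dtype=bool)
    tp = 0
    for c in called:
        k = np.searchsorted(truth, c)
        best, best_d = -1, tol_bins + 1
        for cand in (k - 1, k, k + 1):
            if 0 <= cand < len(truth) and not used[cand]:
                dd = abs(int(truth[cand]) - int(c))
                if dd < best_d:
                    best, best_d = cand, dd
        if best >= 0 and best_d <= tol_bins:
            used[best] = True
            tp += 1
    precision = tp / len(called)
    recall = tp / len(truth)
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def globule_bin_stats(
    globules: GlobuleSet,
    genes=None,
    fasta: dict[str, str] | None = None,
):
    """Compare boundary vs interior bins: genes per bin, mean expression
    per bin, and GC fraction per bin, with two-sided Wilcoxon rank-sum
    p-values.  A comparison with fewer than 2 bins per class reports a
    p-value of None.
    """
    bt = globules.bin_table
    n = bt.n_bins
    gene_count = np.zeros(n)
    expr_sum = np.zeros(n)
    expr_n = np.zeros(n)
    if genes:
        for g in genes:
            lo, hi = bt.chrom_range(g.chrom)
            b0 = lo + g.start // bt.resolution
            b1 = lo + (g.end - 1) // bt.resolution
            for b in range(b0, min(b1, hi - 1) + 1):
                gene_count[b] += 1
                if g.expression is not None:
                    expr_sum[b] += g.expression
                    expr_n[b] += 1
    with np.errstate(invalid="ignore"):
        expr_mean = np.where(expr_n > 0, expr_sum / np.maximum(expr_n, 1), 0.0)
    gc = None
    if fasta is not None:
        gc = np.zeros(n)
        for nm in bt.layout.names:
            seq = fasta[nm].upper()
            lo, hi = bt.chrom_range(nm)
            for b in range(lo, hi):
                s = seq[bt.start[b]: bt.end[b]]
                acgt = sum(s.count(c) for c in "ACGT")
                gc[b] = (s.count("G") + s.count("C")) / acgt if acgt else np.nan

    is_b = globules.labels == "boundary"
    is_i = globules.labels == "interior"

    def compare(x):
        xb, xi = x[is_b], x[is_i]
        xb, xi = xb[~np.isnan(xb)], xi[~np.isnan(xi)]
        p = None
        if len(xb) >= 2 and len(xi) >= 2:
            p = float(ranksums(xb, xi).pvalue)
        return {
            "boundary_median": float(np.median(xb)) if len(xb) else None,
            "interior_median": float(np.median(xi)) if len(xi) else None,
            "p_value": p,
        }

    out = {
        "gene_density": compare(gene_count),
        "expression": compare(expr_mean),
    }
    if gc is not None:
        out["gc"] = compare(gc)
    return out
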