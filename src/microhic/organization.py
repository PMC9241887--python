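"""Centromere calling from trans-contact profiles, aggregate chromosome
analysis (ACA), and Rabl-type classification.

In a Rabl nuclear configuration centromeres cluster at one pole, so the
per-bin count of inter-chromosomal (trans) contacts peaks sharply at
each centromere.  Centromeres are therefore called, per chromosome, as
the contiguous run of bins around the trans-contact maximum whose
smoothed signal stays above half the chromosome maximum — after
excluding chromosome-end bins, where telomere bundling produces a
competing trans peak.

ACA rescales each chromosome arm to a fixed number of slots and
aggregates the contact signal over every ordered chromosome pair and
both arm orientations, yielding an isochromosome-by-isochromosome map
in which Rabl features appear as an enriched center (cen-cen) and
enriched corners (tel-tel).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import ContactMatrix

__all__ = [
    "TransProfile",
    "AcaMap",
    "trans_profile",
    "call_centromeres",
    "aca",
    "classify_rabl",
]


@dataclass
class TransProfile:
    """Per-bin total trans contact counts with end-bin exclusion."""

    counts: np.ndarray
    smoothed: np.ndarray
    excluded: np.ndarray        # True for bins within end_exclusion of an end
    end_exclusion_bp: int
    bin_table: object


@dataclass
class AcaMap:
    """Aggregated 2F x 2F isochromosome map with corner enrichment scores."""

    map: np.ndarray             # full aggregation (cis + trans blocks)
    trans_map: np.ndarray       # trans blocks only, used for corner scores
    F: int
    cen_score: float
    tel_score: float
    label: str = ""


def trans_profile(matrix: ContactMatrix, end_exclusion_bp: int | None = None,
                  smooth_bins: int = 5) -> TransProfile:
    """Per-bin sum of contacts to other chromosomes.

    Each trans pair contributes to both of its bins, so the profile sums
    to twice the total trans count.  Bins within ``end_exclusion_bp`` of
    either chromosome end are flagged excluded (not deleted); smoothing
    is a centered moving average over ``smooth_bins`` bins within each
    chromosome.
    """
    bt = matrix.bin_table
    if end_exclusion_bp is None:
        end_exclusion_bp = max(2 * bt.resolution, 40_000)
    row, col, data = matrix.triplets()
    cid = bt.chrom_id()
    tr = cid[row] != cid[col]
    counts = np.zeros(bt.n_bins)
    np.add.at(counts, row[tr], data[tr])
    np.add.at(counts, col[tr], data[tr])

    excluded = np.zeros(bt.n_bins, dtype=bool)
    smoothed = np.zeros(bt.n_bins)
    half = smooth_bins // 2
    for nm, L in bt.layout.chromosomes:
        glo, ghi = bt.chrom_range(nm)
        n_c = ghi - glo
        k = min(-(-end_exclusion_bp // bt.resolution), n_c)
        excluded[glo: glo + k] = True
        excluded[ghi - k: ghi] = True
        if excluded[glo:ghi].all():
            raise ValueError(
                f"end exclusion of {end_exclusion_bp} bp removes all of {nm}"
            )
        c = counts[glo:ghi]
        csum = np.cumsum(np.concatenate([[0.0], c]))
        idx = np.arange(n_c)
        lo = np.maximum(idx - half, 0)
        hi = np.minimum(idx + half + 1, n_c)
        smoothed[glo:ghi] = (csum[hi] - csum[lo]) / (hi - lo)
    return TransProfile(counts, smoothed, excluded, end_exclusion_bp, bt)


def call_centromeres(profile: TransProfile, run_fraction: float = 0.5
                     ) -> tuple[dict[str, tuple[int, int]], list[str]]:
    """Per chromosome: the contiguous non-excluded run around the trans
    maximum whose smoothed value stays >= ``run_fraction`` of the
    chromosome maximum, returned as a bp interval.

    Returns (calls, warnings); chromosomes with a flat profile
    (max/median < 2) or no signal are flagged.
    """
    bt = profile.bin_table
    calls: dict[str, tuple[int, int]] = {}
    notes: list[str] = []
    for nm, L in bt.layout.chromosomes:
        glo, ghi = bt.chrom_range(nm)
        ok = ~profile.excluded[glo:ghi]
        s = np.where(ok, profile.smoothed[glo:ghi], -np.inf)
        if not np.any(np.isfinite(s)) or np.nanmax(s) <= 0:
            notes.append(f"{nm}: no trans signal, no centromere call")
            continue
        peak = int(np.argmax(s))  # argmax is leftmost on ties
        thr = run_fraction * s[peak]
        lo = peak
        while lo - 1 >= 0 and ok[lo - 1] and s[lo - 1] >= thr:
            lo -= 1
        hi = peak
        n_c = ghi - glo
        while hi + 1 < n_c and ok[hi + 1] and s[hi + 1] >= thr:
            hi += 1
        med = float(np.median(profile.smoothed[glo:ghi][ok]))
        if med > 0 and s[peak] / med < 2.0:
            notes.append(f"{nm}: flat trans profile (max/median "
                         f"{s[peak] / med:.2f} < 2), call uncertain")
        calls[nm] = (int(bt.start[glo + lo]), int(bt.end[glo + hi]))
    return calls, notes


def _arm_rescale_matrix(n_left: int, n_right: int, F: int) -> np.ndarray:
    """(2F, n) weighted-average matrix mapping a chromosome's bins onto
    2F arm slots; slot F-1 and F are centromere-proximal."""
    n = n_left + n_right
    R = np.zeros((2 * F, n))

    def fill(rows, cols, reverse):
        m = len(cols)
        if m == 0:
            return
        # linear overlap of m bins onto F slots
        edges = np.linspace(0, m, F + 1)
        for s in range(F):
            a, b = edges[s], edges[s + 1]
            first, last = int(np.floor(a)), int(np.ceil(b))
            for k in range(first, min(last, m)):
                ov = min(b, k + 1) - max(a, k)
                if ov > 0:
                    col = cols[m - 1 - k] if reverse else cols[k]
                    R[rows[s], col] += ov
        for s in range(F):
            tot = R[rows[s]].sum()
            if tot > 0:
                R[rows[s]] /= tot

    # left arm: telomere at slot 0, centromere side at slot F-1
    fill(list(range(F)), list(range(n_left)), reverse=False)
    # right arm: centromere side at slot F, telomere at slot 2F-1
    fill(list(range(F, 2 * F)), list(range(n_left, n)), reverse=False)
    return R


def aca(matrix: ContactMatrix, centromeres: dict[str, tuple[int, int]],
        F: int = 20, corner_k: int = 3) -> AcaMap:
    """Aggregate chromosome analysis.

    Every chromosome's bin axis is split at its centromere midpoint and
    each arm rescaled to ``F`` slots; the contact signal of every
    ordered chromosome pair, in both arm orientations, is accumulated
    into one symmetric 2F x 2F map with the centromere slots adjacent at
    the center.  Corner scores are taken on the trans-only aggregation:
    cen = mean of the central 2k x 2k block, tel = mean of the four
    k x k corner blocks, each divided by the whole trans-map mean.
    """
    bt = matrix.bin_table
    names = bt.layout.names
    R: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for nm in names:
        if nm not in centromeres:
            raise ValueError(f"no centromere for chromosome {nm}")
        glo, ghi = bt.chrom_range(nm)
        n_c = ghi - glo
        cs, ce = centromeres[nm]
        mid_bin = int(((cs + ce) // 2) // bt.resolution)
        mid_bin = min(max(mid_bin, 1), n_c - 1)
        fwd = _arm_rescale_matrix(mid_bin, n_c - mid_bin, F)
        # reversed presentation: arms swap, bin axis reversed
        rev = _arm_rescale_matrix(n_c - mid_bin, mid_bin, F)[:, ::-1]
        R[nm] = (fwd, rev)

    full = np.zeros((2 * F, 2 * F))
    trans_only = np.zeros((2 * F, 2 * F))
    n_full = 0
    n_trans = 0
    sym = matrix.to_symmetric()
    for a in names:
        lo_a, hi_a = bt.chrom_range(a)
        for b in names:
            lo_b, hi_b = bt.chrom_range(b)
            block = sym[lo_a:hi_a, lo_b:hi_b].toarray()
            for Ra in R[a]:
                for Rb in R[b]:
                    agg = Ra @ block @ Rb.T
                    full += agg
                    n_full += 1
                    if a != b:
                        trans_only += agg
                        n_trans += 1
    full /= n_full
    full = (full + full.T) / 2.0
    if n_trans:
        trans_only /= n_trans
        trans_only = (trans_only + trans_only.T) / 2.0

    k = corner_k
    base = trans_only if n_trans else full
    whole = base.mean()
    if whole <= 0:
        cen_score = tel_score = float("nan")
    else:
        cen_score = float(base[F - k: F + k, F - k: F + k].mean() / whole)
        corners = [base[:k, :k], base[:k, -k:], base[-k:, :k], base[-k:, -k:]]
        tel_score = float(np.mean([c.mean() for c in corners]) / whole)
    return AcaMap(full, trans_only, F, cen_score, tel_score)


def classify_rabl(aca_map: AcaMap, cen_threshold: float = 1.5) -> str:
    """'type_I_rabl' iff the cen-cen corner score >= cen_threshold
    (inclusive), else 'non_rabl'."""
    label = "type_I_rabl" if aca_map.cen_score >= cen_threshold else "non_rabl"
    aca_map.label = label
    return label
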