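"""Contact-matrix summaries: distance-decay curves, cis/trans partition,
and a random-walk replicate-reproducibility score.

The reproducibility score re-implements the random-walk concordance idea
behind GenomeDISCO: each replicate's cis matrix is converted to a
row-stochastic transition matrix, raised to a small power ``t``, and the
two smoothed matrices are compared by a normalized elementwise L1
distance.  The score is 1 for identical matrices and is invariant to a
global rescaling of counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import ContactMatrix

__all__ = ["DecayCurve", "decay_curve", "cis_trans_summary",
           "reproducibility_score", "rebin"]


def rebin(matrix: ContactMatrix, coarse_resolution: int) -> ContactMatrix:
    """Aggregate a contact matrix to a coarser resolution (must be a
    multiple of the current one)."""
    from .genome import BinTable

    bt = matrix.bin_table
    if coarse_resolution % bt.resolution != 0:
        raise ValueError("coarse resolution must be a multiple of the fine one")
    coarse = BinTable(bt.layout, coarse_resolution)
    # fine global index -> coarse global index, via (chrom, start)
    fine_to_coarse = np.empty(bt.n_bins, dtype=np.int64)
    for nm in bt.layout.names:
        flo, fhi = bt.chrom_range(nm)
        clo, _ = coarse.chrom_range(nm)
        fine_to_coarse[flo:fhi] = clo + bt.start[flo:fhi] // coarse_resolution
    row, col, data = matrix.triplets()
    return ContactMatrix(coarse, fine_to_coarse[row], fine_to_coarse[col], data)


@dataclass
class DecayCurve:
    """Mean cis contact probability as a function of genomic distance.

    ``contact_probability[k]`` is the mean observed count per possible
    pair in distance stratum ``k``, divided by the total cis read count
    (so it is a per-pair contact probability); ``mass`` is the fraction
    of all cis reads falling in the stratum and sums to 1.
    """

    distance_bp: np.ndarray
    contact_probability: np.ndarray
    mass: np.ndarray
    n_possible: np.ndarray
    n_reads: np.ndarray

    def fit_slope(self, d_min: float | None = None, d_max: float | None = None) -> float:
        """Log-log slope of contact probability vs distance (least squares)."""
        keep = (self.contact_probability > 0) & (self.distance_bp > 0)
        if d_min is not None:
            keep &= self.distance_bp >= d_min
        if d_max is not None:
            keep &= self.distance_bp <= d_max
        x = np.log(self.distance_bp[keep].astype(float))
        y = np.log(self.contact_probability[keep])
        slope, _ = np.polyfit(x, y, 1)
        return float(slope)


def decay_curve(matrix: ContactMatrix, log_binning: bool = False,
                bins_per_decade: int = 8) -> DecayCurve:
    """Distance-decay curve over cis pairs (diagonal excluded).

    With ``log_binning`` distances are grouped into geometric strata
    (``bins_per_decade`` per decade); otherwise each bin distance is its
    own stratum.  Strata with zero possible pairs are omitted.
    """
    bt = matrix.bin_table
    res = bt.resolution
    row, col, data = matrix.triplets()
    cid = bt.chrom_id()
    cis = (cid[row] == cid[col]) & (row != col)
    if not np.any(cis):
        raise ValueError("matrix has no off-diagonal cis entries")
    d = (col[cis] - row[cis]).astype(np.int64)
    counts = data[cis]
    total_cis = counts.sum()

    max_d = max(bt.n_bins_of(nm) - 1 for nm in bt.layout.names)
    # possible pairs at each bin distance
    n_possible_d = np.zeros(max_d + 1, dtype=np.int64)
    for nm in bt.layout.names:
        n_c = bt.n_bins_of(nm)
        dd = np.arange(1, n_c)
        n_possible_d[dd] += n_c - dd
    sum_d = np.zeros(max_d + 1)
    np.add.at(sum_d, d, counts)

    dist = np.arange(1, max_d + 1)
    if log_binning:
        edges = np.unique(
            np.round(10 ** np.arange(0, np.log10(max_d) + 1.0 / bins_per_decade,
                                     1.0 / bins_per_decade)).astype(np.int64)
        )
        stratum = np.searchsorted(edges, dist, side="right") - 1
    else:
        stratum = dist - 1
    n_strata = stratum.max() + 1
    poss = np.zeros(n_strata)
    reads = np.zeros(n_strata)
    dsum = np.zeros(n_strata)
    np.add.at(poss, stratum, n_possible_d[1:])
    np.add.at(reads, stratum, sum_d[1:])
    np.add.at(dsum, stratum, dist.astype(float) * n_possible_d[1:])
    keep = poss > 0
    mean_dist = dsum[keep] / poss[keep] * res
    prob = reads[keep] / poss[keep] / total_cis
    mass = reads[keep] / total_cis
    return DecayCurve(mean_dist, prob, mass, poss[keep].astype(np.int64),
                      reads[keep])


def cis_trans_summary(matrix: ContactMatrix):
    """Totals of cis and trans reads plus per-chromosome cis/trans shares."""
    bt = matrix.bin_table
    row, col, data = matrix.triplets()
    cid = bt.chrom_id()
    cis = cid[row] == cid[col]
    total_cis = float(data[cis].sum())
    total_trans = float(data[~cis].sum())
    per_chrom = {}
    for k, nm in enumerate(bt.layout.names):
        on = (cid[row] == k) | (cid[col] == k)
        c = float(data[on & cis].sum())
        t = float(data[on & ~cis].sum())
        per_chrom[nm] = {"cis": c, "trans": t}
    return total_cis, total_trans, per_chrom


def _transition_power(m: np.ndarray, keep: np.ndarray, t: int) -> np.ndarray:
    sub = m[np.ix_(keep, keep)]
    rowsum = sub.sum(axis=1, keepdims=True)
    rowsum[rowsum == 0] = 1.0
    p = sub / rowsum
    return np.linalg.matrix_power(p, t)


def reproducibility_score(m1: ContactMatrix, m2: ContactMatrix, t_steps: int = 3) -> float:
    """Random-walk concordance between two replicates, in [0, 1].

    Per chromosome the cis matrices are restricted to bins with nonzero
    degree in either replicate (union rule), row-normalized, raised to
    the ``t_steps`` power, and compared by an elementwise L1 distance
    divided by the number of retained bins; the score is the mean over
    chromosomes of ``1 - d/2`` clipped to [0, 1].
    """
    if not m1.bin_table.same_table(m2.bin_table):
        raise ValueError("matrices use different bin tables")
    scores = []
    for nm in m1.bin_table.layout.names:
        a = m1.cis_dense(nm)
        b = m2.cis_dense(nm)
        keep = (a.sum(axis=1) > 0) | (b.sum(axis=1) > 0)
        n_keep = int(keep.sum())
        if n_keep == 0:
            continue
        pa = _transition_power(a, keep, t_steps)
        pb = _transition_power(b, keep, t_steps)
        d = np.abs(pa - pb).sum() / n_keep
        scores.append(min(max(1.0 - d / 2.0, 0.0), 1.0))
    if not scores:
        raise ValueError("no chromosome with nonzero contacts")
    return float(np.mean(scores))
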