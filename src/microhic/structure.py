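"""3D genome reconstruction by metric multidimensional scaling.

Contact counts are converted to "wish" distances with the standard
power-law transfer delta = count^(-1/exponent) (exponent 3 by default),
rescaled so the median nearest-neighbour distance is 1.  Coordinates
are then fitted by weighted SMACOF majorization of the stress

    sigma(X) = sum_{observed ij} w_ij (||x_i - x_j|| - delta_ij)^2,
    w_ij = delta_ij^(-2),

starting from a deterministic classical-scaling configuration on
shortest-path-completed distances; unobserved pairs carry zero weight
in the stress (missing is not far).  Majorization guarantees a
non-increasing stress at every accepted iteration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, shortest_path

from .genome import ContactMatrix, GenomeLayout

__all__ = [
    "WishDistances",
    "Structure3D",
    "counts_to_wish_distances",
    "mds_embed",
    "structure_metrics",
]


@dataclass
class WishDistances:
    """Target distances on observed (count > 0) bin pairs."""

    i: np.ndarray
    j: np.ndarray
    delta: np.ndarray
    n_bins: int
    bin_table: object = None


@dataclass
class Structure3D:
    """Per-bin 3D coordinates with the optimization trace."""

    coords: np.ndarray            # (n_bins, 3); NaN for unembedded bins
    stress: float
    stress_trace: list[float]
    n_iter: int
    converged: bool
    embedded: np.ndarray          # bool mask of embedded bins
    bin_table: object = None


def counts_to_wish_distances(matrix: ContactMatrix, exponent: float = 3.0) -> WishDistances:
    """delta_ij = c_ij^(-1/exponent) on pairs with c > 0, rescaled so the
    median nearest-neighbour (adjacent cis bin) distance equals 1."""
    if exponent <= 0:
        raise ValueError("exponent must be positive")
    row, col, data = matrix.triplets()
    keep = (data > 0) & (row != col)
    row, col, data = row[keep], col[keep], data[keep]
    if len(row) == 0:
        raise ValueError("matrix has no off-diagonal contacts")
    delta = data.astype(float) ** (-1.0 / exponent)
    bt = matrix.bin_table
    cid = bt.chrom_id()
    nn = (cid[row] == cid[col]) & (col - row == 1)
    scale = np.median(delta[nn]) if np.any(nn) else np.median(delta)
    return WishDistances(row, col, delta / scale, bt.n_bins, bt)


def _classical_init(wd: WishDistances, nodes: np.ndarray) -> np.ndarray:
    """Classical MDS on shortest-path-completed wish distances."""
    remap = -np.ones(wd.n_bins, dtype=np.int64)
    remap[nodes] = np.arange(len(nodes))
    i, j = remap[wd.i], remap[wd.j]
    keep = (i >= 0) & (j >= 0)
    n = len(nodes)
    g = sp.coo_matrix((wd.delta[keep], (i[keep], j[keep])), shape=(n, n)).tocsr()
    g = g.maximum(g.T)
    D = shortest_path(g, method="auto", directed=False)
    finite_max = np.nanmax(D[np.isfinite(D)])
    D[~np.isfinite(D)] = finite_max
    D2 = D**2
    Jc = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * Jc @ D2 @ Jc
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:3]
    lam = np.maximum(vals[order], 0.0)
    X = vecs[:, order] * np.sqrt(lam)[None, :]
    if X.shape[1] < 3:
        X = np.pad(X, ((0, 0), (0, 3 - X.shape[1])))
    return X


def mds_embed(
    wd: WishDistances,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-6,
    init: np.ndarray | None = None,
) -> Structure3D:
    """Weighted SMACOF embedding of the wish distances into 3D.

    The distance graph's largest connected component is embedded (a
    disconnected graph is flagged via the ``embedded`` mask); the start
    configuration is deterministic (classical scaling on shortest-path
    completed distances), so the result does not depend on ``seed``.
    Stress is non-increasing across iterations by construction.
    """
    n_all = wd.n_bins
    g = sp.coo_matrix((np.ones(len(wd.i)), (wd.i, wd.j)), shape=(n_all, n_all))
    n_comp, labels = connected_components(g, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        nodes = np.nonzero(labels == np.argmax(sizes))[0]
    else:
        nodes = np.arange(n_all)
    remap = -np.ones(n_all, dtype=np.int64)
    remap[nodes] = np.arange(len(nodes))
    ii, jj = remap[wd.i], remap[wd.j]
    keep = (ii >= 0) & (jj >= 0)
    ii, jj, delta = ii[keep], jj[keep], wd.delta[keep]
    n = len(nodes)

    w = delta**-2.0
    # Laplacian V of the weights; fixed across iterations
    V = sp.coo_matrix(
        (np.concatenate([-w, -w]), (np.concatenate([ii, jj]), np.concatenate([jj, ii]))),
        shape=(n, n),
    ).toarray()
    np.fill_diagonal(V, -V.sum(axis=1))
    # pseudo-inverse via the centering trick: (V + 11'/n)^-1 - 11'/n
    ones = np.full((n, n), 1.0 / n)
    V_pinv = np.linalg.inv(V + ones) - ones

    X = _classical_init(wd, nodes) if init is None else np.asarray(init)[nodes]

    def stress_and_dists(X):
        diff = X[ii] - X[jj]
        d = np.sqrt((diff**2).sum(axis=1))
        return float(np.sum(w * (d - delta) ** 2)), d

    s, d = stress_and_dists(X)
    trace = [s]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > 0, w * delta / d, 0.0)
        # B(X) X  (Guttman transform), assembled sparsely
        BX = np.zeros_like(X)
        contrib = ratio[:, None] * (X[ii] - X[jj])
        np.add.at(BX, ii, contrib)
        np.add.at(BX, jj, -contrib)
        X_new = V_pinv @ BX
        s_new, d_new = stress_and_dists(X_new)
        if s_new > s + 1e-12 * max(s, 1.0):
            converged = True  # majorization floor reached (numerical)
            break
        X, d = X_new, d_new
        rel = (s - s_new) / max(s, 1e-300)
        s = s_new
        trace.append(s)
        if rel < tol:
            converged = True
            break

    coords = np.full((n_all, 3), np.nan)
    coords[nodes] = X
    embedded = np.zeros(n_all, dtype=bool)
    embedded[nodes] = True
    return Structure3D(coords, s, trace, it, converged, embedded, wd.bin_table)


def _pairwise_mean_dist(points: np.ndarray) -> float:
    n = len(points)
    if n < 2:
        return float("nan")
    diff = points[:, None, :] - points[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    iu = np.triu_indices(n, k=1)
    return float(d[iu].mean())


def structure_metrics(
    structure: Structure3D,
    layout: GenomeLayout,
    seed: int = 0,
    n_draws: int = 100,
) -> dict:
    """Clustering and clothes-pin geometry summaries of an embedding.

    * centromere (telomere) clustering ratio: mean pairwise distance
      among centromeric (telomeric) bins divided by the mean of the same
      statistic over ``n_draws`` random equal-size bin sets (< 1 means
      clustered);
    * per-chromosome clothes-pin score: distance between the centromere
      centroid and the telomere centroid divided by the chromosome's
      radius of gyration (large means centromere and telomeres sit at
      opposite ends of the fold).
    """
    bt = structure.bin_table
    if not layout.centromeres:
        raise ValueError("layout carries no centromere annotation")
    rng = np.random.default_rng(seed)
    res = bt.resolution
    cen_bins: list[int] = []
    tel_bins: list[int] = []
    for nm, L in layout.chromosomes:
        glo, ghi = bt.chrom_range(nm)
        cs, ce = layout.centromeres[nm]
        cen_bins.extend(range(glo + cs // res, glo + min(-(-ce // res), ghi - glo)))
        te_b = max(1, layout.telomere_extent // res)
        tel_bins.extend(range(glo, glo + te_b))
        tel_bins.extend(range(ghi - te_b, ghi))
    cen_bins = np.array([b for b in cen_bins if structure.embedded[b]])
    tel_bins = np.array([b for b in sorted(set(tel_bins)) if structure.embedded[b]])
    emb = np.nonzero(structure.embedded)[0]

    def ratio(bins):
        if len(bins) < 2:
            return float("nan")
        obs = _pairwise_mean_dist(structure.coords[bins])
        null = [
            _pairwise_mean_dist(structure.coords[rng.choice(emb, len(bins), replace=False)])
            for _ in range(n_draws)
        ]
        return obs / float(np.mean(null))

    metrics = {
        "centromere_clustering_ratio": ratio(cen_bins),
        "telomere_clustering_ratio": ratio(tel_bins),
        "clothespin": {},
    }
    for nm, L in layout.chromosomes:
        glo, ghi = bt.chrom_range(nm)
        bins = np.arange(glo, ghi)[structure.embedded[glo:ghi]]
        if len(bins) < 2:
            continue
        xyz = structure.coords[bins]
        rg = float(np.sqrt(((xyz - xyz.mean(axis=0)) ** 2).sum(axis=1).mean()))
        cs, ce = layout.centromeres[nm]
        cb = np.array([b for b in range(glo + cs // res, glo + min(-(-ce // res), ghi - glo))
                       if structure.embedded[b]])
        te_b = max(1, layout.telomere_extent // res)
        tb = np.array([b for b in list(range(glo, glo + te_b)) + list(range(ghi - te_b, ghi))
                       if structure.embedded[b]])
        if len(cb) == 0 or len(tb) == 0 or rg == 0:
            continue
        c_cent = structure.coords[cb].mean(axis=0)
        t_cent = structure.coords[tb].mean(axis=0)
        metrics["clothespin"][nm] = float(np.linalg.norm(c_cent - t_cent) / rg)
    return metrics
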