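"""Synthetic Rabl-structured Hi-C data with full ground truth.

The generator emulates a small multi-chromosome fungal genome: eight
chromosomes of 1.8-5.9 Mb, power-law intra-chromosomal distance decay,
planted self-interacting domains of 2-80 kb separated by single-bin
boundaries, centromere-centromere and telomere-telomere trans-contact
bundling (the Rabl configuration), Poisson count sampling with paired
replicates, telomeric (TTAGGGG)n repeats, uniformly placed genes with
1.5-kb promoters, and a consensus motif planted into a controlled
fraction of domain boundaries.

The expected intensity over bin pairs is

    cis:    lambda_ij  ~  (|i-j| + d0)^(-alpha) * beta^[same domain] * loop fold
    trans:  lambda_ij  ~  eps * (1 + k_c c_i c_j + k_t t_i t_j)

with c, t in [0, 1] indicator weights for centromeric / telomeric bins
(1 inside the interval, decaying linearly to 0 over one flanking bin),
eps expressed relative to the 1-bin cis expectation, and the whole field
scaled so that the expected total count equals ``n_pairs``.  Counts are
independent Poisson draws given lambda.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genome import BinTable, ContactMatrix, GenomeLayout, GeneRecord, GenomicInterval, revcomp

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "ExpectedIntensity",
    "simulate_genome",
    "simulate_truth",
    "expected_intensity",
    "sample_contacts",
    "sample_replicates",
    "plant_boundary_motifs",
    "simulate_dataset",
]

TELOMERE_UNIT = "TTAGGGG"


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the synthetic Hi-C generator (defaults = study-like)."""

    n_chrom: int = 8
    chrom_length_range: tuple[int, int] = (1_800_000, 5_900_000)
    resolution: int = 2_000
    alpha: float = 1.0              # distance-decay exponent
    d0_bins: int = 1                # decay offset, in bins
    domain_size_range: tuple[int, int] = (2_000, 80_000)
    domain_boost: float = 2.0       # intra-domain enrichment beta
    cen_strength: float = 4.0       # centromere bundling k_c
    tel_strength: float = 2.0       # telomere bundling k_t
    trans_baseline: float = 0.02    # eps, relative to the 1-bin cis weight
    n_pairs: int = 1_000_000
    loops: tuple[tuple[tuple[int, int], float], ...] = ()  # ((i, j), fold), cis only
    n_random_loops: int = 0          # convenience: plant this many random cis loops
    loop_fold: float = 8.0
    loop_distance_bins: tuple[int, int] = (5, 100)
    gc: float = 0.5
    motif_consensus: str = "TGCATTAGCGTC"
    motif_boundary_fraction: float = 0.6
    telomere_copies: int = 5
    telomere_extent: int = 40_000
    centromere_width: int = 30_000
    genes_per_mb: float = 100.0
    gene_length: int = 1_500
    promoter_length: int = 1_500
    omit_last_3prime_telomere: bool = False

    def __post_init__(self) -> None:
        if min(self.domain_boost, self.cen_strength, self.tel_strength) < 0:
            raise ValueError("enrichment strengths must be >= 0")
        if not (0.0 <= self.motif_boundary_fraction <= 1.0):
            raise ValueError("motif_boundary_fraction must be in [0, 1]")
        if self.n_pairs <= 0:
            raise ValueError("n_pairs must be positive")


@dataclass
class GroundTruth:
    """Everything the generator planted, for recovery scoring."""

    params: SimulationParams
    layout: GenomeLayout                       # includes true centromeres
    bin_table: BinTable
    domains: list[GenomicInterval]             # planted self-interacting domains
    boundary_bins: np.ndarray                  # global bin indices of junction bins
    domain_id: np.ndarray                      # per-bin domain label, -1 = none
    cen_weight: np.ndarray                     # per-bin centromere weight c_i
    tel_weight: np.ndarray                     # per-bin telomere weight t_i
    loops: dict[tuple[int, int], float] = field(default_factory=dict)
    genes: list[GeneRecord] = field(default_factory=list)
    motif_boundary_bins: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))


def _seed_seq(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *key]))


def _linear_flank(n_bins: int, lo_bin: int, hi_bin: int) -> np.ndarray:
    """Weight 1 on bins [lo_bin, hi_bin), 0.5 on the single flanking bin."""
    w = np.zeros(n_bins)
    w[lo_bin:hi_bin] = 1.0
    if lo_bin - 1 >= 0:
        w[lo_bin - 1] = max(w[lo_bin - 1], 0.5)
    if hi_bin < n_bins:
        w[hi_bin] = max(w[hi_bin], 0.5)
    return w


def simulate_truth(params: SimulationParams, seed: int) -> GroundTruth:
    """Build the layout, centromeres, domain tiling and gene set (no sequence)."""
    rng = _seed_seq(seed, 1)
    lo, hi = params.chrom_length_range
    res = params.resolution
    names = [f"chr{'I' * 0 or _roman(k + 1)}" for k in range(params.n_chrom)]
    if params.n_chrom == 1:
        lengths = [int(hi)]
    else:
        # deterministic spread across the range plus jitter, snapped to bins
        base = np.linspace(lo, hi, params.n_chrom)
        jitter = rng.uniform(-0.03, 0.03, params.n_chrom) * (hi - lo)
        lengths = [int(res * round(x / res)) for x in np.clip(base + jitter, lo, hi)]
    rng.shuffle(lengths)

    centromeres: dict[str, tuple[int, int]] = {}
    for name, L in zip(names, lengths):
        mid = rng.uniform(0.3, 0.7) * L
        start = int(res * round((mid - params.centromere_width / 2) / res))
        start = max(res, min(start, L - params.centromere_width - res))
        centromeres[name] = (start, start + params.centromere_width)

    layout = GenomeLayout(tuple(zip(names, lengths)), centromeres,
                          telomere_extent=params.telomere_extent)
    bt = BinTable(layout, res)
    n = bt.n_bins

    domain_id = np.full(n, -1, dtype=np.int64)
    boundary_bins: list[int] = []
    domains: list[GenomicInterval] = []
    next_id = 0
    dmin, dmax = params.domain_size_range
    dmin_b = max(1, dmin // res)
    dmax_b = max(dmin_b, dmax // res)
    for name, L in layout.chromosomes:
        glo, _ = bt.chrom_range(name)
        cs, ce = centromeres[name]
        cs_b, ce_b = cs // res, -(-ce // res)
        n_c = bt.n_bins_of(name)
        for arm_lo, arm_hi in ((0, cs_b), (ce_b, n_c)):
            pos = arm_lo
            first = True
            while arm_hi - pos >= dmin_b:
                if not first:
                    boundary_bins.append(glo + pos)  # junction bin
                    pos += 1
                    if arm_hi - pos < dmin_b:
                        boundary_bins.pop()
                        pos -= 1
                        break
                size = int(rng.integers(dmin_b, dmax_b + 1))
                size = min(size, arm_hi - pos)
                domain_id[glo + pos: glo + pos + size] = next_id
                domains.append(
                    GenomicInterval(name, pos * res, min((pos + size) * res, L),
                                    id=f"domain_{next_id}")
                )
                next_id += 1
                pos += size
                first = False

    cen_w = np.zeros(n)
    tel_w = np.zeros(n)
    for name, L in layout.chromosomes:
        glo, ghi = bt.chrom_range(name)
        n_c = ghi - glo
        cs, ce = centromeres[name]
        cen_w[glo:ghi] = _linear_flank(n_c, cs // res, -(-ce // res))
        te_b = max(1, params.telomere_extent // res)
        t = np.zeros(n_c)
        t[:te_b] = 1.0
        t[-te_b:] = 1.0
        if te_b < n_c:
            t[te_b] = max(t[te_b], 0.5)
            t[-te_b - 1] = max(t[-te_b - 1], 0.5)
        tel_w[glo:ghi] = t

    loops = dict(params.loops)
    if params.n_random_loops > 0:
        dlo, dhi = params.loop_distance_bins
        while len(loops) < len(params.loops) + params.n_random_loops:
            nm = names[int(rng.integers(params.n_chrom))]
            glo, ghi = bt.chrom_range(nm)
            d = int(rng.integers(dlo, dhi + 1))
            if ghi - glo <= d:
                continue
            i = glo + int(rng.integers(ghi - glo - d))
            loops.setdefault((i, i + d), params.loop_fold)

    genes = _place_genes(params, layout, rng)
    return GroundTruth(
        params=params, layout=layout, bin_table=bt,
        domains=domains, boundary_bins=np.array(sorted(boundary_bins), dtype=np.int64),
        domain_id=domain_id, cen_weight=cen_w, tel_weight=tel_w,
        loops=loops, genes=genes,
    )


def _roman(k: int) -> str:
    vals = [(10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I")]
    out = ""
    for v, s in vals:
        while k >= v:
            out += s
            k -= v
    return out


def _place_genes(params: SimulationParams, layout: GenomeLayout,
                 rng: np.random.Generator) -> list[GeneRecord]:
    genes: list[GeneRecord] = []
    gl = params.gene_length
    pad = params.promoter_length
    k = 0
    for name, L in layout.chromosomes:
        n_genes = int(round(L * params.genes_per_mb / 1e6))
        span = gl + 200  # gene + minimal spacer
        usable = L - 2 * pad - n_genes * span
        if usable <= 0:
            raise ValueError(
                f"chromosome {name} too small for {n_genes} genes with promoters"
            )
        gaps = rng.multinomial(usable, np.full(n_genes + 1, 1.0 / (n_genes + 1)))
        pos = pad
        for gi in range(n_genes):
            pos += gaps[gi]
            strand = "+" if rng.random() < 0.5 else "-"
            expr = float(rng.lognormal(0.0, 1.0))
            genes.append(GeneRecord(name, pos, pos + gl, strand,
                                    f"gene_{k:05d}", expr))
            k += 1
            pos += span
    return genes


def simulate_genome(
    params: SimulationParams, seed: int
) -> tuple[GenomeLayout, dict[str, str], list[GeneRecord], GroundTruth]:
    """Ground truth plus an i.i.d. genome sequence with telomeric repeats.

    The 5' end of each chromosome starts with ``telomere_copies`` tandem
    TTAGGGG units; the 3' end carries the reverse complement (CCCCTAA)n,
    optionally omitted on the last chromosome to emulate an incomplete
    assembly end.
    """
    truth = simulate_truth(params, seed)
    rng = _seed_seq(seed, 2)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    p = np.array([(1 - params.gc) / 2, params.gc / 2, params.gc / 2, (1 - params.gc) / 2])
    seqs: dict[str, str] = {}
    names = truth.layout.names
    for name, L in truth.layout.chromosomes:
        idx = rng.choice(4, size=L, p=p)
        seq = bases[idx].tobytes().decode()
        head = TELOMERE_UNIT * params.telomere_copies
        tail = revcomp(TELOMERE_UNIT) * params.telomere_copies
        seq = head + seq[len(head):]
        if not (params.omit_last_3prime_telomere and name == names[-1]):
            seq = seq[: L - len(tail)] + tail
        seqs[name] = seq
    return truth.layout, seqs, truth.genes, truth


class ExpectedIntensity:
    """Expected contact intensity lambda over all bin pairs.

    cis intensities are held per chromosome as banded vectors (one band
    per bin distance); the trans field is an exact three-component
    mixture (uniform + centromere + telomere bundling), so the full
    trans matrix is never materialized.  ``lambda_at`` evaluates any
    pair exactly; the field is normalized so the total over all pairs
    (i <= j) equals ``params.n_pairs``.
    """

    def __init__(self, truth: GroundTruth, params: SimulationParams | None = None):
        params = params or truth.params
        self.truth = truth
        self.params = params
        bt = truth.bin_table
        self._cis_bands: dict[str, np.ndarray] = {}
        self._band_offsets: dict[str, np.ndarray] = {}
        d0 = params.d0_bins
        alpha = params.alpha
        beta = params.domain_boost
        z_cis = 0.0
        for name, _ in truth.layout.chromosomes:
            glo, ghi = bt.chrom_range(name)
            n_c = ghi - glo
            dom = truth.domain_id[glo:ghi]
            w = np.empty(n_c * (n_c + 1) // 2)
            offsets = np.empty(n_c + 1, dtype=np.int64)
            pos = 0
            for d in range(n_c):
                offsets[d] = pos
                m = n_c - d
                band = np.full(m, (d + d0) ** (-alpha))
                same = (dom[:m] == dom[d:]) & (dom[:m] >= 0)
                band[same] *= beta
                w[pos: pos + m] = band
                pos += m
            offsets[n_c] = pos
            self._cis_bands[name] = w
            self._band_offsets[name] = offsets
            z_cis += w.sum()
        # planted loops multiply the cis weight of their pair
        cid = bt.chrom_id()
        for (i, j), fold in truth.loops.items():
            i, j = (i, j) if i <= j else (j, i)
            if cid[i] != cid[j]:
                raise ValueError("planted loops must be cis pairs")
            name = bt.chrom[i]
            glo, _ = bt.chrom_range(name)
            li, d = i - glo, j - i
            off = self._band_offsets[name]
            k = off[d] + li
            z_cis += self._cis_bands[name][k] * (fold - 1.0)
            self._cis_bands[name][k] *= fold

        # Trans field: a read-mass mixture.  The uniform background
        # carries eps x the total cis weight; centromere and telomere
        # bundling carry k_c and k_t times the uniform mass, spread over
        # the c_i*c_j / t_i*t_j products.  This keeps the trans share of
        # reads resolution-independent (~= eps*(1+k_c+k_t) of cis) and
        # concentrates bundled reads enough to emulate Rabl maps.
        names = truth.layout.names
        self._chrom_names = names
        nb = {nm: bt.n_bins_of(nm) for nm in names}
        C = {nm: truth.cen_weight[slice(*bt.chrom_range(nm))].sum() for nm in names}
        T = {nm: truth.tel_weight[slice(*bt.chrom_range(nm))].sum() for nm in names}
        pairs = [(names[a], names[b])
                 for a in range(len(names)) for b in range(a + 1, len(names))]
        np_u = sum(nb[a] * nb[b] for a, b in pairs)
        np_c = sum(C[a] * C[b] for a, b in pairs)
        np_t = sum(T[a] * T[b] for a, b in pairs)
        eps = params.trans_baseline
        self._w_uniform = eps * z_cis / np_u if np_u else 0.0
        cen_mass = params.cen_strength * eps * z_cis if np_c else 0.0
        tel_mass = params.tel_strength * eps * z_cis if np_t else 0.0
        self._cen_coef = cen_mass / np_c if np_c else 0.0
        self._tel_coef = tel_mass / np_t if np_t else 0.0
        self._block_w: dict[tuple[str, str], np.ndarray] = {}
        z_trans = 0.0
        for a, b in pairs:
            comp = np.array([
                self._w_uniform * nb[a] * nb[b],
                self._cen_coef * C[a] * C[b],
                self._tel_coef * T[a] * T[b],
            ])
            self._block_w[(a, b)] = comp
            z_trans += comp.sum()
        self._z = z_cis + z_trans
        self.scale = params.n_pairs / self._z
        self.z_cis = z_cis
        self.z_trans = z_trans

    def total(self) -> float:
        """Sum of lambda over all pairs i <= j (equals n_pairs exactly)."""
        return self.scale * self._z

    @property
    def total_cis(self) -> float:
        return self.scale * self.z_cis

    @property
    def total_trans(self) -> float:
        return self.scale * self.z_trans

    def lambda_at(self, i, j) -> np.ndarray:
        """Exact lambda for global bin pairs (vectorized)."""
        i = np.atleast_1d(np.asarray(i, dtype=np.int64))
        j = np.atleast_1d(np.asarray(j, dtype=np.int64))
        lo = np.minimum(i, j)
        hi = np.maximum(i, j)
        bt = self.truth.bin_table
        cid = bt.chrom_id()
        out = np.empty(len(lo))
        cis = cid[lo] == cid[hi]
        for k in np.nonzero(cis)[0]:
            name = bt.chrom[lo[k]]
            glo, _ = bt.chrom_range(name)
            d = hi[k] - lo[k]
            off = self._band_offsets[name]
            out[k] = self._cis_bands[name][off[d] + (lo[k] - glo)]
        tr = self.truth
        kt = np.nonzero(~cis)[0]
        out[kt] = (
            self._w_uniform
            + self._cen_coef * tr.cen_weight[lo[kt]] * tr.cen_weight[hi[kt]]
            + self._tel_coef * tr.tel_weight[lo[kt]] * tr.tel_weight[hi[kt]]
        )
        return out * self.scale


def expected_intensity(truth: GroundTruth, params: SimulationParams | None = None) -> ExpectedIntensity:
    return ExpectedIntensity(truth, params)


def sample_contacts(intensity: ExpectedIntensity, seed: int) -> ContactMatrix:
    """Independent Poisson draw per bin pair with mean lambda_ij."""
    rng = _seed_seq(seed, 3)
    bt = intensity.truth.bin_table
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    for name in intensity._chrom_names:
        glo, ghi = bt.chrom_range(name)
        n_c = ghi - glo
        lam = intensity._cis_bands[name] * intensity.scale
        counts = rng.poisson(lam)
        nz = np.nonzero(counts)[0]
        if len(nz) == 0:
            continue
        off = intensity._band_offsets[name]
        d = np.searchsorted(off, nz, side="right") - 1
        i = nz - off[d]
        rows.append(glo + i)
        cols.append(glo + i + d)
        vals.append(counts[nz].astype(float))

    # trans by Poissonization of the exact mixture
    blocks = list(intensity._block_w.items())
    if blocks:
        comp_w = intensity.scale * np.concatenate([w for _, w in blocks])
        tot = comp_w.sum()
        if tot > 0:
            k_total = rng.poisson(tot)
            alloc = rng.multinomial(k_total, comp_w / tot)
            tr = intensity.truth
            for bi, ((na, nbm), _) in enumerate(blocks):
                lo_a, hi_a = bt.chrom_range(na)
                lo_b, hi_b = bt.chrom_range(nbm)
                for ci in range(3):
                    k = alloc[bi * 3 + ci]
                    if k == 0:
                        continue
                    if ci == 0:
                        i = rng.integers(lo_a, hi_a, size=k)
                        j = rng.integers(lo_b, hi_b, size=k)
                    else:
                        w_attr = tr.cen_weight if ci == 1 else tr.tel_weight
                        wa = w_attr[lo_a:hi_a]
                        wb = w_attr[lo_b:hi_b]
                        i = lo_a + rng.choice(hi_a - lo_a, size=k, p=wa / wa.sum())
                        j = lo_b + rng.choice(hi_b - lo_b, size=k, p=wb / wb.sum())
                    rows.append(i)
                    cols.append(j)
                    vals.append(np.ones(k))

    if rows:
        return ContactMatrix(bt, np.concatenate(rows), np.concatenate(cols),
                             np.concatenate(vals))
    return ContactMatrix(bt)


def sample_replicates(
    intensity: ExpectedIntensity, seed1: int, seed2: int
) -> tuple[ContactMatrix, ContactMatrix]:
    """Two independent Poisson replicates of the same intensity field."""
    return sample_contacts(intensity, seed1), sample_contacts(intensity, seed2)


def plant_boundary_motifs(
    seqs: dict[str, str],
    truth: GroundTruth,
    consensus: str | None = None,
    fraction: float | None = None,
    seed: int = 0,
) -> tuple[dict[str, str], np.ndarray]:
    """Insert a consensus motif into a controlled fraction of boundary bins.

    Exactly ``round(fraction * n_boundaries)`` boundary bins receive one
    consensus instance at a uniformly chosen offset inside the bin.
    Returns the edited sequences and the chosen global boundary bin ids.
    """
    p = truth.params
    consensus = consensus if consensus is not None else p.motif_consensus
    fraction = fraction if fraction is not None else p.motif_boundary_fraction
    rng = _seed_seq(seed, 4)
    bt = truth.bin_table
    n_pick = int(round(fraction * len(truth.boundary_bins)))
    picked = np.sort(rng.choice(truth.boundary_bins, size=n_pick, replace=False))
    out = dict(seqs)
    w = len(consensus)
    for b in picked:
        chrom = bt.chrom[b]
        start, end = int(bt.start[b]), int(bt.end[b])
        if end - start < w:
            raise ValueError("motif consensus longer than boundary bin")
        off = int(rng.integers(start, end - w + 1))
        s = out[chrom]
        out[chrom] = s[:off] + consensus + s[off + w:]
    truth.motif_boundary_bins = picked
    return out, picked


def simulate_dataset(params: SimulationParams, seed: int, with_sequence: bool = True):
    """One-call generator: truth, intensity, one contact matrix and,
    optionally, the motif-planted genome sequence."""
    if with_sequence:
        _, seqs, _, truth = simulate_genome(params, seed)
        if params.motif_boundary_fraction > 0 and len(params.motif_consensus):
            seqs, _ = plant_boundary_motifs(seqs, truth, seed=seed)
    else:
        truth = simulate_truth(params, seed)
        seqs = None
    lam = expected_intensity(truth, params)
    matrix = sample_contacts(lam, seed)
    return truth, lam, matrix, seqs
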