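"""Core genomic domain types: chromosome layouts, bin tables, contact
matrices, genes/intervals and position weight matrices.

Conventions used throughout the package:

* coordinates are 0-based, half-open ``[start, end)`` internally;
* pairs files are 1-based and converted on read;
* contact matrices store only the upper triangle (``i <= j``) of a
  genome-wide symmetric matrix keyed by global bin index;
* strand is carried for genes only — contacts are strandless.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "GenomeLayout",
    "BinTable",
    "ContactMatrix",
    "GenomicInterval",
    "GeneRecord",
    "PWM",
    "FormatError",
]


class FormatError(ValueError):
    """Raised when an on-disk file violates its format contract."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome set with optional centromere annotation.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    centromeres
        Optional map ``name -> (start, end)`` in bp; each interval must lie
        strictly inside its chromosome.
    telomere_extent
        Width in bp treated as the chromosome-end (telomeric) region by
        analyses that need one.
    """

    chromosomes: tuple[tuple[str, int], ...]
    centromeres: dict[str, tuple[int, int]] = field(default_factory=dict)
    telomere_extent: int = 40_000

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise FormatError("duplicate chromosome names in layout")
        for name, length in self.chromosomes:
            if length <= 0:
                raise FormatError(f"chromosome {name!r} has non-positive length {length}")
        lengths = dict(self.chromosomes)
        for name, (start, end) in self.centromeres.items():
            if name not in lengths:
                raise FormatError(f"centromere on unknown chromosome {name!r}")
            if not (0 < start < end < lengths[name]):
                raise FormatError(
                    f"centromere {name}:{start}-{end} not strictly inside chromosome"
                )

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def length_of(self, name: str) -> int:
        return self.lengths[name]

    def with_centromeres(self, centromeres: dict[str, tuple[int, int]]) -> "GenomeLayout":
        return GenomeLayout(self.chromosomes, dict(centromeres), self.telomere_extent)


class BinTable:
    """Fixed-width tiling of a genome layout into bins.

    Bins tile each chromosome in order; every bin has width ``resolution``
    except possibly the last per chromosome, which is truncated at the
    chromosome end.  Bins carry a global integer index across chromosomes.
    """

    def __init__(self, layout: GenomeLayout, resolution: int):
        if resolution <= 0:
            raise ValueError(f"resolution must be positive, got {resolution}")
        self.layout = layout
        self.resolution = int(resolution)
        chroms: list[str] = []
        starts: list[np.ndarray] = []
        offsets: dict[str, tuple[int, int]] = {}
        pos = 0
        for name, length in layout.chromosomes:
            n = -(-length // resolution)  # ceil
            chroms.extend([name] * n)
            starts.append(np.arange(n, dtype=np.int64) * resolution)
            offsets[name] = (pos, pos + n)
            pos += n
        self.n_bins = pos
        self.chrom = np.array(chroms)
        self.start = np.concatenate(starts) if starts else np.empty(0, dtype=np.int64)
        lengths = layout.lengths
        self.end = np.minimum(
            self.start + resolution,
            np.array([lengths[c] for c in chroms], dtype=np.int64),
        )
        self._range = offsets

    def __len__(self) -> int:
        return self.n_bins

    def chrom_range(self, name: str) -> tuple[int, int]:
        """Global ``[lo, hi)`` bin-index range of a chromosome."""
        return self._range[name]

    def n_bins_of(self, name: str) -> int:
        lo, hi = self._range[name]
        return hi - lo

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global index of the bin containing 0-based position ``pos``."""
        lo, hi = self._range[chrom]
        idx = lo + pos // self.resolution
        if not (lo <= idx < hi):
            raise ValueError(f"position {chrom}:{pos} outside chromosome")
        return idx

    def chrom_id(self) -> np.ndarray:
        """Integer chromosome id per bin (order of the layout)."""
        ids = np.empty(self.n_bins, dtype=np.int32)
        for i, name in enumerate(self.layout.names):
            lo, hi = self._range[name]
            ids[lo:hi] = i
        return ids

    def same_table(self, other: "BinTable") -> bool:
        return (
            self.resolution == other.resolution
            and self.layout.chromosomes == other.layout.chromosomes
        )


def make_bins(layout: GenomeLayout, resolution: int) -> BinTable:
    """Tile ``layout`` into bins of ``resolution`` bp (last bin truncated)."""
    return BinTable(layout, resolution)


class ContactMatrix:
    """Genome-wide symmetric sparse contact matrix over a bin table.

    Only the upper triangle (``i <= j`` in global bin indices) is stored;
    queries are symmetric.  Counts are non-negative.
    """

    def __init__(self, bin_table: BinTable, i=None, j=None, counts=None):
        self.bin_table = bin_table
        n = bin_table.n_bins
        if i is None:
            i = np.empty(0, dtype=np.int64)
            j = np.empty(0, dtype=np.int64)
            counts = np.empty(0, dtype=np.float64)
        i = np.asarray(i, dtype=np.int64)
        j = np.asarray(j, dtype=np.int64)
        counts = np.asarray(counts, dtype=np.float64)
        if np.any(counts < 0):
            raise ValueError("contact counts must be non-negative")
        if len(i) and (i.min() < 0 or j.max() >= n):
            raise ValueError("bin indices outside bin table")
        lo = np.minimum(i, j)
        hi = np.maximum(i, j)
        m = sp.coo_matrix((counts, (lo, hi)), shape=(n, n)).tocsr()
        m.sum_duplicates()
        m.eliminate_zeros()
        self._upper = m

    @classmethod
    def from_upper_csr(cls, bin_table: BinTable, upper: sp.csr_matrix) -> "ContactMatrix":
        obj = cls.__new__(cls)
        obj.bin_table = bin_table
        upper = sp.triu(upper).tocsr()
        upper.eliminate_zeros()
        obj._upper = upper
        return obj

    @property
    def upper(self) -> sp.csr_matrix:
        """Upper-triangular CSR view (i <= j)."""
        return self._upper

    def to_symmetric(self) -> sp.csr_matrix:
        u = self._upper
        return u + sp.triu(u, k=1).T

    def triplets(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        coo = self._upper.tocoo()
        order = np.lexsort((coo.col, coo.row))
        return coo.row[order], coo.col[order], coo.data[order]

    def get(self, i: int, j: int) -> float:
        lo, hi = (i, j) if i <= j else (j, i)
        return float(self._upper[lo, hi])

    @property
    def total(self) -> float:
        return float(self._upper.sum())

    def _cis_mask(self, row: np.ndarray, col: np.ndarray) -> np.ndarray:
        cid = self.bin_table.chrom_id()
        return cid[row] == cid[col]

    @property
    def total_cis(self) -> float:
        row, col, data = self.triplets()
        return float(data[self._cis_mask(row, col)].sum())

    @property
    def total_trans(self) -> float:
        row, col, data = self.triplets()
        return float(data[~self._cis_mask(row, col)].sum())

    def cis_dense(self, chrom: str) -> np.ndarray:
        """Dense symmetric cis submatrix of one chromosome."""
        lo, hi = self.bin_table.chrom_range(chrom)
        sub = self._upper[lo:hi, lo:hi].toarray()
        return sub + np.triu(sub, k=1).T


_STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    id: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in _STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneRecord(GenomicInterval):
    """A gene locus; ``expression`` is an optional abundance value."""

    expression: float | None = None


class PWM:
    """Position weight matrix over A, C, G, T.

    Built from a count (PFM) or probability matrix; a pseudocount is added
    to counts before normalization.  Rows are positions, columns A/C/G/T.
    """

    ALPHABET = "ACGT"

    def __init__(
        self,
        motif_id: str,
        probs: np.ndarray,
        background: np.ndarray | None = None,
        pseudocount: float = 0.25,
    ):
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] < 1:
            raise ValueError("PWM matrix must be (width, 4) with width >= 1")
        sums = probs.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("PWM rows must each sum to 1")
        self.motif_id = motif_id
        self.probs = probs
        self.pseudocount = pseudocount
        if background is None:
            background = np.full(4, 0.25)
        background = np.asarray(background, dtype=float)
        if not np.isclose(background.sum(), 1.0, atol=1e-6):
            raise ValueError("background must sum to 1")
        self.background = background

    @classmethod
    def from_counts(
        cls,
        motif_id: str,
        counts: np.ndarray,
        background: np.ndarray | None = None,
        pseudocount: float = 0.25,
    ) -> "PWM":
        counts = np.asarray(counts, dtype=float) + pseudocount
        probs = counts / counts.sum(axis=1, keepdims=True)
        return cls(motif_id, probs, background, pseudocount)

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def with_background(self, background: np.ndarray) -> "PWM":
        return PWM(self.motif_id, self.probs, background, self.pseudocount)

    def log_odds(self) -> np.ndarray:
        """(width, 4) log2 odds vs the background, with probability floor."""
        p = np.maximum(self.probs, 1e-10)
        b = np.maximum(self.background, 1e-10)
        return np.log2(p / b[None, :])

    def reverse_complement(self) -> "PWM":
        return PWM(
            self.motif_id,
            self.probs[::-1, ::-1].copy(),
            self.background[::-1].copy(),
            self.pseudocount,
        )


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgtNn", "TGCAtgcaNn"))[::-1]
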