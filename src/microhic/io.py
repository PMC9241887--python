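"""Readers and writers for the on-disk formats the pipeline touches.

Formats: chrom.sizes (2-column TSV), valid-pairs text (4 whitespace
columns, 1-based positions), contact-matrix triplet TSV (with a header
naming the resolution), BED3/BED6, GFF-lite (9 columns, ``gene`` features
only), FASTA (via Biopython) and JASPAR position frequency matrices.
All writers and readers round-trip: ``read(write(x)) == x`` on valid
objects.
"""

from __future__ import annotations

import re

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import (
    BinTable,
    ContactMatrix,
    FormatError,
    GeneRecord,
    GenomeLayout,
    GenomicInterval,
    PWM,
)

__all__ = [
    "read_chromsizes",
    "write_chromsizes",
    "read_pairs",
    "write_pairs",
    "read_matrix",
    "write_matrix",
    "read_bed",
    "write_bed",
    "read_gff_genes",
    "write_gff_genes",
    "read_fasta",
    "write_fasta",
    "read_jaspar",
    "write_jaspar",
]


def read_chromsizes(path) -> GenomeLayout:
    """Read a two-column (name, length) chrom.sizes file."""
    chroms: list[tuple[str, int]] = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            name, length_s = parts
            try:
                length = int(length_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer length {length_s!r}")
            if length <= 0:
                raise FormatError(f"{path}:{lineno}: non-positive length for {name!r}")
            if name in seen:
                raise FormatError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            seen.add(name)
            chroms.append((name, length))
    return GenomeLayout(tuple(chroms))


def write_chromsizes(layout: GenomeLayout, path) -> None:
    with open(path, "w") as fh:
        for name, length in layout.chromosomes:
            fh.write(f"{name}\t{length}\n")


def read_pairs(path, bin_table: BinTable) -> tuple[ContactMatrix, int]:
    """Bin a valid-pairs text file (``chrom1 pos1 chrom2 pos2``, 1-based).

    Returns the contact matrix and the number of pairs rejected because a
    chromosome was not in the bin table's layout.
    """
    known = set(bin_table.layout.names)
    idx1: list[int] = []
    idx2: list[int] = []
    rejected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            c1, p1s, c2, p2s = parts
            try:
                p1, p2 = int(p1s), int(p2s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer position")
            if c1 not in known or c2 not in known:
                rejected += 1
                continue
            try:
                idx1.append(bin_table.bin_index(c1, p1 - 1))
                idx2.append(bin_table.bin_index(c2, p2 - 1))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}")
    counts = np.ones(len(idx1))
    return ContactMatrix(bin_table, np.array(idx1, dtype=np.int64),
                         np.array(idx2, dtype=np.int64), counts), rejected


def write_pairs(pairs, path) -> None:
    """Write ``(chrom1, pos1, chrom2, pos2)`` tuples (1-based positions)."""
    with open(path, "w") as fh:
        for c1, p1, c2, p2 in pairs:
            fh.write(f"{c1}\t{p1}\t{c2}\t{p2}\n")


def write_matrix(matrix: ContactMatrix, path) -> None:
    """Write triplet text: header line naming the resolution, then
    ``bin_i<TAB>bin_j<TAB>count`` rows (upper triangle, sorted)."""
    i, j, data = matrix.triplets()
    with open(path, "w") as fh:
        fh.write(f"# resolution={matrix.bin_table.resolution}\n")
        for a, b, c in zip(i, j, data):
            c_str = f"{int(c)}" if float(c).is_integer() else repr(float(c))
            fh.write(f"{a}\t{b}\t{c_str}\n")


def read_matrix(path, bin_table: BinTable) -> ContactMatrix:
    i: list[int] = []
    j: list[int] = []
    data: list[float] = []
    resolution = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = re.search(r"resolution=(\d+)", line)
                if m:
                    resolution = int(m.group(1))
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            i.append(int(parts[0]))
            j.append(int(parts[1]))
            data.append(float(parts[2]))
    if resolution is not None and resolution != bin_table.resolution:
        raise FormatError(
            f"{path}: resolution {resolution} does not match bin table "
            f"({bin_table.resolution})"
        )
    return ContactMatrix(bin_table, np.array(i, dtype=np.int64),
                         np.array(j, dtype=np.int64), np.array(data))


def write_bed(intervals, path, scores=None) -> None:
    """Write BED3 (or BED6 when intervals carry id/strand or scores given)."""
    with open(path, "w") as fh:
        for k, iv in enumerate(intervals):
            if scores is not None or iv.id or iv.strand != ".":
                score = 0.0 if scores is None else scores[k]
                name = iv.id or "."
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_bed(path) -> list[GenomicInterval]:
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 and parts[3] != "." else ""
            strand = parts[5] if len(parts) > 5 else "."
            out.append(GenomicInterval(chrom, start, end, strand, name))
    return out


def write_gff_genes(genes, path, source: str = "microhic") -> None:
    """Write GeneRecords as GFF-lite ``gene`` features (1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.id}"
            if g.expression is not None:
                attrs += f";expression={g.expression:g}"
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


def read_gff_genes(path) -> list[GeneRecord]:
    """Read ``gene`` features from a 9-column GFF-lite file."""
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns")
            if parts[2] != "gene":
                continue
            chrom, start, end, strand = parts[0], int(parts[3]) - 1, int(parts[4]), parts[6]
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            expr = attrs.get("expression")
            genes.append(
                GeneRecord(
                    chrom, start, end,
                    strand if strand in "+-" else ".",
                    attrs.get("ID", ""),
                    float(expr) if expr is not None else None,
                )
            )
    return genes


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into an ordered name -> uppercase sequence map."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    # Biopython wraps at 60; acceptable — scanning is wrap-invariant.


_JASPAR_ROW = re.compile(r"^([ACGT])\s*\[?\s*([\d.\s]+?)\s*\]?\s*$")


def read_jaspar(path, pseudocount: float = 0.25) -> list[PWM]:
    """Read JASPAR-style PFMs (4 count rows per motif) into PWMs."""
    motifs: list[PWM] = []
    motif_id = None
    rows: dict[str, list[float]] = {}

    def flush():
        nonlocal rows, motif_id
        if motif_id is not None and rows:
            if set(rows) != set("ACGT"):
                raise FormatError(f"motif {motif_id}: missing base rows")
            counts = np.array([rows[b] for b in "ACGT"], dtype=float).T
            motifs.append(PWM.from_counts(motif_id, counts, pseudocount=pseudocount))
        rows = {}

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                motif_id = line[1:].split()[0]
                continue
            m = _JASPAR_ROW.match(line)
            if m:
                base, values = m.group(1), m.group(2)
                rows[base] = [float(v) for v in values.split()]
    flush()
    return motifs


def write_jaspar(pwms, path, scale: float = 100.0) -> None:
    """Write PWMs back as JASPAR PFMs (probabilities scaled to counts)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id}\n")
            counts = pwm.probs * scale
            for bi, base in enumerate("ACGT"):
                vals = " ".join(f"{v:g}" for v in counts[:, bi])
                fh.write(f"{base} [ {vals} ]\n")
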