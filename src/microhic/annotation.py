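"""Gene-level annotation of the Hi-C results: boundary/interior gene
assignment, mapping of significant contacts onto genes, hub-gene
ranking, and telomeric-repeat detection."""

from __future__ import annotations

import re

import pandas as pd

from .genome import GeneRecord, revcomp
from .insulation import GlobuleSet

__all__ = [
    "assign_genes_to_globules",
    "map_contacts_to_genes",
    "hub_ranking",
    "telomere_repeat_scan",
]


def assign_genes_to_globules(genes: list[GeneRecord], globules: GlobuleSet
                             ) -> tuple[dict[str, str], dict[str, int]]:
    """Label each gene 'boundary', 'interior' or 'spanning' by the classes
    of the bins it overlaps.  Returns (labels, summary counts)."""
    bt = globules.bin_table
    res = bt.resolution
    labels: dict[str, str] = {}
    for g in genes:
        if g.chrom not in bt.layout.lengths:
            raise ValueError(f"gene {g.id} on unknown chromosome {g.chrom}")
        lo, hi = bt.chrom_range(g.chrom)
        b0 = lo + g.start // res
        b1 = min(lo + (g.end - 1) // res, hi - 1)
        classes = set(globules.labels[b0: b1 + 1])
        classes.discard("edge")
        if classes == {"boundary"}:
            labels[g.id] = "boundary"
        elif "boundary" in classes:
            labels[g.id] = "spanning"
        else:
            labels[g.id] = "interior"
    summary = {
        lab: sum(1 for v in labels.values() if v == lab)
        for lab in ("boundary", "interior", "spanning")
    }
    return labels, summary


def map_contacts_to_genes(contacts, genes: list[GeneRecord], bin_table
                          ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Assign each significant contact to every gene overlapping either
    anchor bin (>= 1 bp overlap).

    Returns a per-gene table of distinct cis/trans contact counts and a
    summary with the numbers of genes having cis, trans, or both kinds
    of interaction, plus the count of contacts touching no gene.
    """
    records = contacts.records if hasattr(contacts, "records") else contacts
    res = bin_table.resolution
    # genes sorted per chromosome for binary search over starts
    per_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        per_chrom.setdefault(g.chrom, []).append(g)
    for v in per_chrom.values():
        v.sort(key=lambda g: g.start)

    def genes_in(chrom: str, start: int, end: int) -> list[str]:
        out = []
        for g in per_chrom.get(chrom, []):
            if g.start < end and start < g.end:
                out.append(g.id)
            elif g.start >= end:
                break
        return out

    cis_counts: dict[str, int] = {}
    trans_counts: dict[str, int] = {}
    intergenic = 0
    for row in records.itertuples(index=False):
        touched: set[str] = set()
        for b in (int(row.bin_i), int(row.bin_j)):
            chrom = bin_table.chrom[b]
            touched.update(genes_in(chrom, int(bin_table.start[b]),
                                    int(bin_table.end[b])))
        if not touched:
            intergenic += 1
            continue
        target = cis_counts if row.kind == "cis" else trans_counts
        for gid in touched:
            target[gid] = target.get(gid, 0) + 1

    all_ids = sorted(set(cis_counts) | set(trans_counts))
    table = pd.DataFrame({
        "gene_id": all_ids,
        "cis": [cis_counts.get(g, 0) for g in all_ids],
        "trans": [trans_counts.get(g, 0) for g in all_ids],
    })
    summary = {
        "genes_with_cis": int((table["cis"] > 0).sum()),
        "genes_with_trans": int((table["trans"] > 0).sum()),
        "genes_with_both": int(((table["cis"] > 0) & (table["trans"] > 0)).sum()),
        "intergenic_contacts": intergenic,
    }
    return table, summary


def hub_ranking(per_gene: pd.DataFrame, top_n: int = 10) -> dict[str, pd.DataFrame]:
    """Top-``top_n`` genes by cis and by trans contact count (ties broken
    by gene id)."""
    out = {}
    for kind in ("cis", "trans"):
        ranked = per_gene.sort_values([kind, "gene_id"], ascending=[False, True])
        out[kind] = ranked.head(top_n).reset_index(drop=True)[["gene_id", kind]]
    return out


def telomere_repeat_scan(
    seqs: dict[str, str],
    unit: str = "TTAGGGG",
    min_copies: int = 3,
    window_bp: int = 5000,
) -> dict[str, dict[str, bool]]:
    """Detect tandem telomeric repeats at chromosome ends.

    The first ``window_bp`` of each chromosome is searched for
    >= ``min_copies`` tandem copies of ``unit``; the last ``window_bp``
    for tandem copies of its reverse complement.  Windows larger than
    the chromosome are clipped.
    """
    pat5 = re.compile(f"(?:{re.escape(unit.upper())}){{{min_copies},}}")
    pat3 = re.compile(f"(?:{re.escape(revcomp(unit).upper())}){{{min_copies},}}")
    out: dict[str, dict[str, bool]] = {}
    for name, seq in seqs.items():
        s = seq.upper()
        w = min(window_bp, len(s))
        out[name] = {
            "five_prime": bool(pat5.search(s[:w])),
            "three_prime": bool(pat3.search(s[-w:])),
        }
    return out
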