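"""End-to-end orchestration: one call simulates a Rabl-structured Hi-C
dataset and runs every analysis stage to a summary report.

All outputs are plain text and fully determined by (config, seed);
re-running with the same inputs reproduces every file byte-identically.
Logging goes to stderr and a run log; the log file carries no
information the report does not.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import numpy as np
import yaml

from . import io as mio
from .annotation import (assign_genes_to_globules, hub_ranking,
                         map_contacts_to_genes, telomere_repeat_scan)
from .genome import GenomicInterval, PWM
from .insulation import (boundary_f1, call_boundaries, insulation_score,
                         segment_globules)
from .matrix_ops import cis_trans_summary, decay_curve, rebin, reproducibility_score
from .motifs import boundary_enrichment, promoter_scan, scan_pwm
from .organization import aca, call_centromeres, classify_rabl, trans_profile
from .significance import (cis_significance, filter_significant,
                           fit_distance_prior, records_to_table,
                           trans_significance)
from .simulate import (SimulationParams, expected_intensity,
                       plant_boundary_motifs, sample_contacts, simulate_genome)
from .structure import counts_to_wish_distances, mds_embed, structure_metrics

log = logging.getLogger("microhic")

DEMO_CONFIG = {
    "simulation": {
        "n_chrom": 4,
        "chrom_length_range": [400_000, 800_000],
        "resolution": 2_000,
        "n_pairs": 400_000,
        "telomere_extent": 20_000,
        "centromere_width": 20_000,
        "n_random_loops": 20,
    },
    "coarse_resolution": 10_000,
    "insulation_window_bins": 10,
    "min_boundary_strength": 0.1,
    "q_max": 0.01,
    "min_count": 3,
    "aca_F": 20,
    "cen_threshold": 1.5,
    "mds_exponent": 3.0,
    "motif_p_max": 1e-4,
}


def load_config(path=None) -> dict:
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEMO_CONFIG.items()}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for k, v in user.items():
            if k == "simulation" and isinstance(v, dict):
                cfg["simulation"].update(v)
            else:
                cfg[k] = v
    return cfg


def consensus_pwm(consensus: str, motif_id: str = "planted", p: float = 0.97) -> PWM:
    """PWM concentrated on a consensus sequence."""
    w = len(consensus)
    probs = np.full((w, 4), (1 - p) / 3)
    for k, base in enumerate(consensus.upper()):
        probs[k, "ACGT".index(base)] = p
    return PWM(motif_id, probs)


def _params_from_config(cfg: dict) -> SimulationParams:
    sim = dict(cfg.get("simulation", {}))
    for key in ("chrom_length_range", "domain_size_range"):
        if key in sim:
            sim[key] = tuple(sim[key])
    if "loops" in sim:
        sim["loops"] = tuple((tuple(p), f) for p, f in sim["loops"])
    return SimulationParams(**sim)


def run_all(config: dict | None, seed: int, outdir) -> dict:
    """Execute simulate -> bin -> decay -> reproducibility -> insulation ->
    globules -> significance -> centromeres -> aca -> embed -> motifs ->
    annotate, writing all outputs plus a manifest and a report."""
    cfg = config or load_config()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    manifest: list[str] = []
    report: dict = {"seed": seed}
    stage = "config"
    try:
        params = _params_from_config(cfg)
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=True)
        manifest.append("config.yaml")

        stage = "simulate"
        log.info("simulating genome and Hi-C contacts (seed=%d)", seed)
        layout, seqs, genes, truth = simulate_genome(params, seed)
        if params.motif_boundary_fraction > 0:
            seqs, planted = plant_boundary_motifs(seqs, truth, seed=seed)
        lam = expected_intensity(truth, params)
        matrix = sample_contacts(lam, seed)
        rep2 = sample_contacts(lam, seed + 1_000_003)
        mio.write_chromsizes(layout, outdir / "genome.chrom.sizes")
        mio.write_fasta(seqs, outdir / "genome.fa")
        mio.write_gff_genes(genes, outdir / "genes.gff")
        mio.write_bed(truth.domains, outdir / "true_domains.bed")
        bt = truth.bin_table
        mio.write_bed(
            [GenomicInterval(bt.chrom[b], int(bt.start[b]), int(bt.end[b]),
                             id=f"true_boundary_{k}")
             for k, b in enumerate(truth.boundary_bins)],
            outdir / "true_boundaries.bed")
        mio.write_bed(
            [GenomicInterval(nm, s, e, id=f"true_centromere_{nm}")
             for nm, (s, e) in layout.centromeres.items()],
            outdir / "true_centromeres.bed")
        mio.write_matrix(matrix, outdir / "matrix.tsv")
        manifest += ["genome.chrom.sizes", "genome.fa", "genes.gff",
                     "true_domains.bed", "true_boundaries.bed",
                     "true_centromeres.bed", "matrix.tsv"]

        stage = "decay"
        curve = decay_curve(matrix, log_binning=True)
        _write_tsv(outdir / "decay.tsv",
                   ["distance_bp", "contact_probability", "mass"],
                   zip(curve.distance_bp, curve.contact_probability, curve.mass))
        manifest.append("decay.tsv")
        total_cis, total_trans, _ = cis_trans_summary(matrix)
        report["decay_slope"] = round(curve.fit_slope(), 4)
        report["total_cis"] = total_cis
        report["total_trans"] = total_trans

        stage = "reproducibility"
        coarse_res = int(cfg["coarse_resolution"])
        m_coarse = rebin(matrix, coarse_res)
        r_coarse = rebin(rep2, coarse_res)
        report["reproducibility"] = round(
            reproducibility_score(m_coarse, r_coarse), 4)

        stage = "insulation"
        w_bins = int(cfg["insulation_window_bins"])
        track = insulation_score(matrix, w_bins * params.resolution)
        _write_tsv(outdir / "insulation.tsv",
                   ["chrom", "start", "end", "raw", "normalized", "valid"],
                   ((bt.chrom[b], bt.start[b], bt.end[b],
                     _fmt(track.raw[b]), _fmt(track.normalized[b]),
                     int(track.valid[b])) for b in range(bt.n_bins)))
        manifest.append("insulation.tsv")

        stage = "call-globules"
        bounds = call_boundaries(track, float(cfg["min_boundary_strength"]))
        globs = segment_globules(bounds, bt, layout, track)
        mio.write_bed(globs.boundary_intervals(), outdir / "boundaries.bed",
                      scores=[s for _, _, s in bounds])
        mio.write_bed(globs.globules, outdir / "globules.bed")
        manifest += ["boundaries.bed", "globules.bed"]
        sizes = globs.sizes_kb()
        report["n_globules"] = len(globs.globules)
        report["globule_size_kb_min"] = float(sizes.min()) if len(sizes) else None
        report["globule_size_kb_max"] = float(sizes.max()) if len(sizes) else None
        report["boundary_f1_vs_truth"] = round(
            boundary_f1(globs.boundary_bins, truth.boundary_bins), 4)

        stage = "significance"
        prior = fit_distance_prior(matrix)
        cis_rec = cis_significance(matrix, prior)
        trans_rec = trans_significance(matrix)
        import pandas as pd
        allrec = pd.concat([cis_rec, trans_rec], ignore_index=True)
        sig = filter_significant(allrec, float(cfg["q_max"]), int(cfg["min_count"]))
        records_to_table(sig.records, matrix).to_csv(
            outdir / "significant_contacts.tsv", sep="\t", index=False)
        manifest.append("significant_contacts.tsv")
        report["n_cis_significant"] = sig.n_cis
        report["n_trans_significant"] = sig.n_trans

        stage = "centromeres"
        profile = trans_profile(m_coarse)
        calls, notes = call_centromeres(profile)
        mio.write_bed(
            [GenomicInterval(nm, s, e, id=f"centromere_{nm}")
             for nm, (s, e) in calls.items()],
            outdir / "centromeres.bed")
        manifest.append("centromeres.bed")
        errs = []
        for nm, (s, e) in calls.items():
            ts, te = layout.centromeres[nm]
            errs.append(abs((s + e) / 2 - (ts + te) / 2) / coarse_res)
        report["centromere_max_error_bins"] = round(max(errs), 2) if errs else None
        report["centromere_warnings"] = notes

        stage = "aca"
        amap = aca(m_coarse, calls, F=int(cfg["aca_F"]))
        label = classify_rabl(amap, float(cfg["cen_threshold"]))
        np.savetxt(outdir / "aca_map.tsv", amap.map, delimiter="\t", fmt="%.6g")
        manifest.append("aca_map.tsv")
        report["aca_cen_score"] = round(amap.cen_score, 3)
        report["aca_tel_score"] = round(amap.tel_score, 3)
        report["rabl_class"] = label

        stage = "embed"
        wd = counts_to_wish_distances(m_coarse, float(cfg["mds_exponent"]))
        struct = mds_embed(wd, seed=seed)
        cbt = m_coarse.bin_table
        _write_tsv(outdir / "structure.tsv",
                   ["chrom", "start", "end", "x", "y", "z"],
                   ((cbt.chrom[b], cbt.start[b], cbt.end[b],
                     _fmt(struct.coords[b, 0]), _fmt(struct.coords[b, 1]),
                     _fmt(struct.coords[b, 2])) for b in range(cbt.n_bins)))
        manifest.append("structure.tsv")
        d_emb = np.sqrt(((struct.coords[wd.i] - struct.coords[wd.j]) ** 2).sum(axis=1))
        ok = np.isfinite(d_emb)
        report["embedding_stress"] = round(struct.stress, 6)
        report["embedding_distance_correlation"] = round(
            float(np.corrcoef(d_emb[ok], wd.delta[ok])[0, 1]), 4)
        smet = structure_metrics(struct, layout.with_centromeres(layout.centromeres),
                                 seed=seed)
        report["centromere_clustering_ratio"] = round(
            smet["centromere_clustering_ratio"], 4)
        report["telomere_clustering_ratio"] = round(
            smet["telomere_clustering_ratio"], 4)

        stage = "scan-motifs"
        pwm = consensus_pwm(params.motif_consensus)
        hits = scan_pwm(pwm, seqs, float(cfg["motif_p_max"]))
        _write_tsv(outdir / "motif_hits.tsv",
                   ["motif", "chrom", "start", "end", "strand", "score", "p_value"],
                   ((h.motif_id, h.chrom, h.start, h.end, h.strand,
                     f"{h.score:.3f}", f"{h.p_value:.3g}") for h in hits))
        manifest.append("motif_hits.tsv")
        enr = boundary_enrichment({pwm.motif_id: hits}, globs.boundary_intervals())
        report["planted_motif_boundary_proportion"] = round(enr[0].proportion, 4)
        prom_table, _ = promoter_scan({pwm.motif_id: hits}, genes, layout)
        report["n_genes_with_promoter_motif"] = sum(
            1 for v in prom_table.values() if v[pwm.motif_id])

        stage = "annotate"
        _, gene_summary = assign_genes_to_globules(genes, globs)
        report["genes_boundary"] = gene_summary["boundary"]
        report["genes_interior"] = gene_summary["interior"]
        report["genes_spanning"] = gene_summary["spanning"]
        per_gene, contact_summary = map_contacts_to_genes(sig, genes, bt)
        report.update(contact_summary)
        hubs = hub_ranking(per_gene)
        report["top_cis_genes"] = hubs["cis"]["gene_id"].tolist()[:3]
        report["top_trans_genes"] = hubs["trans"]["gene_id"].tolist()[:3]

        stage = "telomeres"
        telo = telomere_repeat_scan(seqs)
        report["telomere_ends_present"] = sum(
            int(v["five_prime"]) + int(v["three_prime"]) for v in telo.values())

        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        manifest.append("report.json")
        with open(outdir / "manifest.txt", "w") as fh:
            fh.write("\n".join(manifest) + "\n")
        log.info("pipeline complete: %d outputs", len(manifest))
        return report
    except Exception:
        log.error("stage %r failed", stage)
        raise RuntimeError(f"pipeline stage {stage!r} failed") from sys.exc_info()[1]
    finally:
        log.removeHandler(handler)
        handler.close()


def _fmt(x) -> str:
    return "nan" if not np.isfinite(x) else f"{x:.6g}"


def _write_tsv(path, header, rows) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for r in rows:
            fh.write("\t".join(str(c) for c in r) + "\n")
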