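"""Insulation scores, boundary calling and globule segmentation."""

import numpy as np
import pytest

import microhic as mh
from conftest import random_contact_matrix
from microhic.insulation import (InsulationTrack, boundary_f1,
                                 call_boundaries, globule_bin_stats,
                                 insulation_score, segment_globules)


def brute_force_insulation(dense, w):
    """Independent double-loop oracle for the w x w square mean."""
    n = dense.shape[0]
    raw = np.full(n, np.nan)
    for i in range(w, n - w):
        total = 0.0
        for a in range(i - w, i):
            for b in range(i + 1, i + w + 1):
                total += dense[a, b]
        raw[i] = total / (w * w)
    return raw


def make_track(values, resolution=1000):
    """An InsulationTrack with a given normalized score vector."""
    values = np.asarray(values, dtype=float)
    layout = mh.GenomeLayout((("c", len(values) * resolution),))
    bt = mh.make_bins(layout, resolution)
    return InsulationTrack(bt, 2, values.copy(), values.copy(),
                           np.isfinite(values))


class TestInsulationScore:
    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(50):
            m = random_contact_matrix(rng, n_bins=30, density=0.4)
            w = int(rng.integers(2, 6))
            track = insulation_score(m, w * 1000)
            oracle = brute_force_insulation(m.cis_dense("c0"), w)
            np.testing.assert_allclose(track.raw[track.valid],
                                       oracle[track.valid], atol=1e-12)
            assert np.array_equal(track.valid, np.isfinite(oracle))

    def test_constant_matrix_normalizes_to_zero(self):
        layout = mh.GenomeLayout((("c", 30_000),))
        bt = mh.make_bins(layout, 1000)
        iu = np.triu_indices(30)
        m = mh.ContactMatrix(bt, iu[0], iu[1], np.full(len(iu[0]), 4.0))
        track = insulation_score(m, 3000)
        np.testing.assert_allclose(track.normalized[track.valid], 0.0,
                                   atol=1e-12)

    def test_two_block_minimum_at_junction(self):
        # two dense diagonal blocks, zero across: strict minimum at junction
        n, cut = 20, 10
        layout = mh.GenomeLayout((("c", n * 1000),))
        bt = mh.make_bins(layout, 1000)
        iu = np.triu_indices(n)
        same_block = (iu[0] < cut) == (iu[1] < cut)
        m = mh.ContactMatrix(bt, iu[0][same_block], iu[1][same_block],
                             np.full(int(same_block.sum()), 5.0))
        track = insulation_score(m, 3000)
        v = track.normalized
        j = int(np.nanargmin(v))
        # the two junction-flanking bins tie (both squares all-cross);
        # argmin picks the leftmost
        assert j in (cut - 1, cut)
        others = v[track.valid & ~np.isin(np.arange(n), [cut - 1, cut])]
        assert v[j] < others.min()

    def test_window_too_small_rejected(self, rng):
        m = random_contact_matrix(rng)
        with pytest.raises(ValueError):
            insulation_score(m, 1500)

    def test_short_chromosome_all_invalid(self):
        layout = mh.GenomeLayout((("c", 5000),))
        bt = mh.make_bins(layout, 1000)
        m = mh.ContactMatrix(bt, [0, 1], [1, 2], [1.0, 1.0])
        track = insulation_score(m, 3000)
        assert not track.valid.any()


class TestBoundaryCalling:
    def test_monotone_track_no_boundaries(self):
        track = make_track(np.linspace(0, 1, 30))
        assert call_boundaries(track, smooth_bins=1) == []

    def test_v_shape_strength(self):
        v = np.concatenate([np.linspace(0.5, 0.0, 11),
                            np.linspace(0.0, 0.5, 11)[1:]])
        track = make_track(v)
        calls = call_boundaries(track, min_strength=0.1, smooth_bins=1)
        assert len(calls) == 1
        chrom, b, strength = calls[0]
        assert b == 10
        assert strength == pytest.approx(0.5)

    def test_shallow_minimum_filtered(self):
        v = np.concatenate([np.linspace(0.05, 0.0, 6),
                            np.linspace(0.0, 0.05, 6)[1:]])
        track = make_track(v)
        assert call_boundaries(track, min_strength=0.1, smooth_bins=1) == []

    def test_two_block_junction_called(self):
        n, cut = 20, 10
        layout = mh.GenomeLayout((("c", n * 1000),))
        bt = mh.make_bins(layout, 1000)
        iu = np.triu_indices(n)
        same = (iu[0] < cut) == (iu[1] < cut)
        m = mh.ContactMatrix(bt, iu[0][same], iu[1][same],
                             np.full(int(same.sum()), 5.0))
        track = insulation_score(m, 3000)
        calls = call_boundaries(track, min_strength=0.1, smooth_bins=1)
        assert len(calls) == 1
        assert calls[0][1] in (cut - 1, cut)  # leftmost of the tied pair

    def test_count_non_increasing_in_strength(self, small_matrix):
        track = insulation_score(small_matrix, 10 * 5000)
        counts = [len(call_boundaries(track, s))
                  for s in (0.0, 0.05, 0.1, 0.2, 0.4, 0.8)]
        assert counts == sorted(counts, reverse=True)

    def test_plateau_leftmost(self):
        v = np.array([1.0, 0.5, 0.0, 0.0, 0.0, 0.5, 1.0])
        track = make_track(v)
        calls = call_boundaries(track, min_strength=0.1, smooth_bins=1)
        assert len(calls) == 1 and calls[0][1] == 2


class TestSegmentation:
    def test_single_boundary_arithmetic(self):
        layout = mh.GenomeLayout((("c", 40_000),))
        bt = mh.make_bins(layout, 2000)  # 20 bins
        globs = segment_globules([("c", 10, 0.5)], bt, layout)
        sizes = sorted(globs.sizes_kb())
        assert sizes == [18.0, 20.0]

    def test_zero_boundaries_whole_chromosome(self, small_truth):
        layout = small_truth.layout
        bt = small_truth.bin_table
        globs = segment_globules([], bt, layout)
        assert len(globs.globules) == len(layout.chromosomes)
        for g, (nm, L) in zip(globs.globules, layout.chromosomes):
            assert (g.start, g.end) == (0, L)

    def test_bin_conservation(self, small_matrix, small_truth):
        track = insulation_score(small_matrix, 10 * 5000)
        bounds = call_boundaries(track)
        globs = segment_globules(bounds, small_truth.bin_table,
                                 small_truth.layout, track)
        n_b = (globs.labels == "boundary").sum()
        n_i = (globs.labels == "interior").sum()
        n_e = (globs.labels == "edge").sum()
        assert n_b + n_i + n_e == small_truth.bin_table.n_bins
        assert n_b == len(bounds)

    def test_noiseless_recovery(self):
        """Boundaries recovered from the rounded intensity field itself
        (no sampling noise) with F1 >= 0.9 at +/-1 bin, at the working
        conditions (2-kb bins, 2-80 kb domains)."""
        small_params = mh.SimulationParams()
        truth = mh.simulate_truth(small_params, 42)
        lam = mh.expected_intensity(truth)
        bt = truth.bin_table
        rows, cols, vals = [], [], []
        for nm, _ in truth.layout.chromosomes:
            glo, ghi = bt.chrom_range(nm)
            lamv = lam._cis_bands[nm] * lam.scale
            off = lam._band_offsets[nm]
            nz = np.nonzero(np.round(lamv))[0]
            d = np.searchsorted(off, nz, side="right") - 1
            i = nz - off[d]
            rows.append(glo + i)
            cols.append(glo + i + d)
            vals.append(np.round(lamv[nz]))
        m = mh.ContactMatrix(bt, np.concatenate(rows), np.concatenate(cols),
                             np.concatenate(vals))
        track = insulation_score(m, 10 * small_params.resolution)
        calls = call_boundaries(track, smooth_bins=1)
        f1 = boundary_f1(np.array([b for _, b, _ in calls]),
                         truth.boundary_bins)
        assert f1 >= 0.9


class TestGlobuleBinStats:
    def _globules(self, labels, resolution=2000):
        layout = mh.GenomeLayout((("c", len(labels) * resolution),))
        bt = mh.make_bins(layout, resolution)
        return mh.insulation.GlobuleSet(
            [("c", i, 0.5) for i, l in enumerate(labels) if l == "boundary"],
            [], np.array(labels, dtype=object), bt)

    def test_empty_gene_set(self):
        globs = self._globules(["interior"] * 10 + ["boundary"] * 3)
        out = globule_bin_stats(globs, genes=[])
        assert out["gene_density"]["boundary_median"] == 0.0

    def test_too_few_bins_p_undefined(self):
        globs = self._globules(["interior"] * 10 + ["boundary"])
        out = globule_bin_stats(globs, genes=[])
        assert out["gene_density"]["p_value"] is None

    def test_shuffled_labels_null_calibrated(self, rng):
        """With labels assigned at random, the rank-sum p-value exceeds
        0.05 in >= 90% of seeds."""
        n = 300
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            labels = np.where(r.random(n) < 0.2, "boundary", "interior")
            globs = self._globules(list(labels))
            genes = [
                mh.GeneRecord("c", int(s), int(s) + 500, "+", f"g{k}",
                              float(r.lognormal()))
                for k, s in enumerate(r.choice(n * 2000 - 500, 150,
                                               replace=False))
            ]
            out = globule_bin_stats(globs, genes=genes)
            if out["gene_density"]["p_value"] > 0.05:
                hits += 1
        assert hits >= 0.9 * n_seeds

    def test_planted_density_difference_detected(self, rng):
        """Doubled gene density on boundary bins yields p < 0.05 at
        500 bins per class."""
        n = 1000
        labels = np.array(["interior"] * 500 + ["boundary"] * 500,
                          dtype=object)
        globs = self._globules(list(labels))
        genes = []
        k = 0
        for b in range(n):
            lam = 2.0 if labels[b] == "boundary" else 1.0
            for _ in range(rng.poisson(lam)):
                s = b * 2000 + int(rng.integers(0, 1500))
                genes.append(mh.GeneRecord("c", s, s + 400, "+", f"g{k}"))
                k += 1
        out = globule_bin_stats(globs, genes=genes)
        assert out["gene_density"]["p_value"] < 0.05

    def test_gc_comparison(self):
        globs = self._globules(["interior"] * 5 + ["boundary"] * 5,
                               resolution=100)
        fasta = {"c": "ACGT" * 125 + "GGCC" * 125}
        out = globule_bin_stats(globs, genes=[], fasta=fasta)
        assert out["gc"]["boundary_median"] == pytest.approx(1.0)
        assert out["gc"]["interior_median"] == pytest.approx(0.5)
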