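"""Synthetic-data generator: determinism, planted features, and the
statistical structure of the expected intensity field."""

import numpy as np
import pytest

import microhic as mh
from microhic.simulate import TELOMERE_UNIT, plant_boundary_motifs
from microhic.genome import revcomp


class TestGenomeSimulation:
    def test_same_seed_identical(self, small_params):
        _, s1, g1, t1 = mh.simulate_genome(small_params, 7)
        _, s2, g2, t2 = mh.simulate_genome(small_params, 7)
        assert s1 == s2
        assert g1 == g2
        assert np.array_equal(t1.boundary_bins, t2.boundary_bins)

    def test_different_seed_differs(self, small_params):
        _, s1, _, _ = mh.simulate_genome(small_params, 7)
        _, s2, _, _ = mh.simulate_genome(small_params, 8)
        assert s1 != s2

    def test_telomere_repeats_planted(self, small_params):
        _, seqs, _, _ = mh.simulate_genome(small_params, 7)
        head = TELOMERE_UNIT * small_params.telomere_copies
        tail = revcomp(TELOMERE_UNIT) * small_params.telomere_copies
        for seq in seqs.values():
            assert seq.startswith(head)
            assert seq.endswith(tail)

    def test_omitted_3prime_telomere(self, small_params):
        from dataclasses import replace

        p = replace(small_params, omit_last_3prime_telomere=True)
        layout, seqs, _, _ = mh.simulate_genome(p, 7)
        tail = revcomp(TELOMERE_UNIT) * p.telomere_copies
        names = layout.names
        assert not seqs[names[-1]].endswith(tail)
        assert seqs[names[0]].endswith(tail)

    def test_gc_content_within_3_sd(self):
        p = mh.SimulationParams(n_chrom=1, chrom_length_range=(1_000_000, 1_000_000),
                                gc=0.5, telomere_copies=0)
        _, seqs, _, _ = mh.simulate_genome(p, 3)
        seq = next(iter(seqs.values()))
        L = len(seq)
        gc = (seq.count("G") + seq.count("C")) / L
        sd = np.sqrt(0.25 / L)
        assert abs(gc - 0.5) < 3 * sd

    def test_domains_and_boundaries_disjoint(self, small_truth):
        # boundary bins carry no domain label; domains do not overlap
        assert np.all(small_truth.domain_id[small_truth.boundary_bins] == -1)
        for a, b in zip(small_truth.domains, small_truth.domains[1:]):
            if a.chrom == b.chrom:
                assert a.end <= b.start

    def test_genes_non_overlapping_with_promoter_room(self, small_truth):
        by_chrom = {}
        for g in small_truth.genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        lengths = small_truth.layout.lengths
        for nm, gg in by_chrom.items():
            gg.sort(key=lambda g: g.start)
            for a, b in zip(gg, gg[1:]):
                assert a.end <= b.start
            assert gg[0].start >= 1500
            assert gg[-1].end <= lengths[nm] - 1500


class TestExpectedIntensity:
    def test_distance_ratio_closed_form(self, small_intensity, small_truth):
        # same-domain pairs at 1 vs 3 bins: lambda ratio = (3+1)/(1+1) = 2
        dom = small_truth.domain_id
        found = False
        for i in range(len(dom) - 3):
            if dom[i] >= 0 and dom[i] == dom[i + 1] == dom[i + 3]:
                l1 = small_intensity.lambda_at(i, i + 1)[0]
                l3 = small_intensity.lambda_at(i, i + 3)[0]
                assert l1 / l3 == pytest.approx(2.0)
                found = True
                break
        assert found

    def test_total_normalized_to_n(self, small_intensity, small_params):
        assert small_intensity.total() == pytest.approx(
            small_params.n_pairs, rel=1e-9)
        # exhaustive check: banded cis sums + analytic trans total
        assert (small_intensity.total_cis + small_intensity.total_trans
                == pytest.approx(small_params.n_pairs, rel=1e-9))

    def test_uniform_trans_when_no_bundling(self, small_params):
        from dataclasses import replace

        p = replace(small_params, cen_strength=0.0, tel_strength=0.0)
        truth = mh.simulate_truth(p, 5)
        lam = mh.expected_intensity(truth)
        cid = truth.bin_table.chrom_id()
        rng = np.random.default_rng(1)
        i = rng.integers(0, truth.bin_table.n_bins, 200)
        j = rng.integers(0, truth.bin_table.n_bins, 200)
        tr = cid[i] != cid[j]
        vals = lam.lambda_at(i[tr], j[tr])
        assert np.allclose(vals, vals[0])

    def test_lambda_at_matches_band_storage(self, small_intensity, small_truth):
        bt = small_truth.bin_table
        rng = np.random.default_rng(2)
        glo, ghi = bt.chrom_range(bt.layout.names[0])
        i = rng.integers(glo, ghi - 5, 50)
        j = i + rng.integers(1, 5, 50)
        lam = small_intensity.lambda_at(i, j)
        assert np.all(lam > 0)

    def test_loop_boost(self, small_params):
        from dataclasses import replace

        truth0 = mh.simulate_truth(small_params, 9)
        pair = (int(truth0.boundary_bins[0]) + 2, int(truth0.boundary_bins[0]) + 30)
        p = replace(small_params, loops=((pair, 8.0),))
        truth = mh.simulate_truth(p, 9)
        lam0 = mh.expected_intensity(truth0)
        lam = mh.expected_intensity(truth)
        r = (lam.lambda_at(*pair)[0] / lam.scale) / (
            lam0.lambda_at(*pair)[0] / lam0.scale)
        assert r == pytest.approx(8.0)

    def test_trans_loop_rejected(self, small_params):
        from dataclasses import replace

        truth = mh.simulate_truth(small_params, 9)
        bt = truth.bin_table
        j = bt.chrom_range(bt.layout.names[1])[0] + 1
        p = replace(small_params, loops=(((0, int(j)), 8.0),))
        with pytest.raises(ValueError, match="cis"):
            mh.expected_intensity(mh.simulate_truth(p, 9))


class TestSampling:
    def test_zero_lambda_zero_counts(self, small_intensity, small_matrix):
        # sampled support is a subset of positive-lambda pairs
        row, col, data = small_matrix.triplets()
        lam = small_intensity.lambda_at(row[:500], col[:500])
        assert np.all(lam > 0)

    def test_deterministic_given_seed(self, small_intensity):
        m1 = mh.sample_contacts(small_intensity, 5)
        m2 = mh.sample_contacts(small_intensity, 5)
        assert (m1.upper != m2.upper).nnz == 0

    def test_poisson_mean_monte_carlo(self):
        # empirical per-pair mean over 200 draws within 3 sd of lambda
        p = mh.SimulationParams(
            n_chrom=2, chrom_length_range=(40_000, 60_000), resolution=5_000,
            n_pairs=2_000, telomere_extent=10_000, centromere_width=10_000,
            domain_size_range=(10_000, 30_000))
        truth = mh.simulate_truth(p, 1)
        lam = mh.expected_intensity(truth)
        pairs = [(0, 1), (0, 3), (2, 5)]
        sums = np.zeros(len(pairs))
        n_rep = 200
        for s in range(n_rep):
            m = mh.sample_contacts(lam, 1000 + s)
            for k, (i, j) in enumerate(pairs):
                sums[k] += m.get(i, j)
        for k, (i, j) in enumerate(pairs):
            expect = lam.lambda_at(i, j)[0]
            sd = np.sqrt(expect / n_rep)
            assert abs(sums[k] / n_rep - expect) < 3.5 * sd

    def test_replicates_positively_correlated(self, small_intensity):
        m1, m2 = mh.sample_replicates(small_intensity, 1, 2)
        r1, c1, d1 = m1.triplets()
        # compare counts on pairs observed in replicate 1
        d2 = np.array([m2.get(i, j) for i, j in zip(r1[:2000], c1[:2000])])
        assert np.corrcoef(d1[:2000], d2)[0, 1] > 0.1

    def test_trans_masses_match_intensity(self, small_params, small_truth,
                                          small_intensity, small_matrix):
        """Realized trans read masses per region class match the exact
        lambda field within sampling error (20%)."""
        truth, lam, m = small_truth, small_intensity, small_matrix
        bt = truth.bin_table
        cid = bt.chrom_id()
        # enumerate every trans pair (small fixture)
        n = bt.n_bins
        iu = np.triu_indices(n, 1)
        tr = cid[iu[0]] != cid[iu[1]]
        ti, tj = iu[0][tr], iu[1][tr]
        expect = lam.lambda_at(ti, tj)
        cc = truth.cen_weight[ti] * truth.cen_weight[tj]
        tt = truth.tel_weight[ti] * truth.tel_weight[tj]
        row, col, data = m.triplets()
        trm = cid[row] != cid[col]
        row, col, data = row[trm], col[trm], data[trm]
        occ = truth.cen_weight[row] * truth.cen_weight[col]
        ott = truth.tel_weight[row] * truth.tel_weight[col]
        for mask_e, mask_o in [
            (cc > 0.5, occ > 0.5),
            (tt > 0.5, ott > 0.5),
            ((cc < 1e-9) & (tt < 1e-9), (occ < 1e-9) & (ott < 1e-9)),
        ]:
            assert data[mask_o].sum() == pytest.approx(
                expect[mask_e].sum(), rel=0.2)
        # bundled classes carry multiples of the uniform per-pair rate
        assert expect[cc > 0.5].mean() > 3 * expect[
            (cc < 1e-9) & (tt < 1e-9)].mean()


class TestDecayRecovery:
    def test_power_law_slope_recovered(self):
        """Regression of log mean count on log distance recovers -alpha
        within 0.1 at >= 5e5 pairs."""
        p = mh.SimulationParams(n_pairs=600_000, resolution=10_000)
        truth = mh.simulate_truth(p, 13)
        m = mh.sample_contacts(mh.expected_intensity(truth), 13)
        curve = mh.decay_curve(m, log_binning=True)
        slope = curve.fit_slope()
        assert -1.1 < slope < -0.9


class TestMotifPlanting:
    def test_fraction_one_every_boundary(self, small_params):
        from dataclasses import replace

        p = replace(small_params, telomere_copies=2)
        _, seqs, _, truth = mh.simulate_genome(p, 3)
        seqs2, picked = plant_boundary_motifs(seqs, truth, fraction=1.0, seed=3)
        assert len(picked) == len(truth.boundary_bins)
        bt = truth.bin_table
        for b in picked:
            chrom = bt.chrom[b]
            window = seqs2[chrom][bt.start[b]: bt.end[b]]
            assert p.motif_consensus in window

    def test_fraction_zero_unchanged(self, small_params):
        _, seqs, _, truth = mh.simulate_genome(small_params, 3)
        seqs2, picked = plant_boundary_motifs(seqs, truth, fraction=0.0, seed=3)
        assert len(picked) == 0
        assert seqs2 == seqs

    def test_fractional_count(self, small_params):
        _, seqs, _, truth = mh.simulate_genome(small_params, 3)
        _, picked = plant_boundary_motifs(seqs, truth, fraction=0.6, seed=3)
        assert len(picked) == round(0.6 * len(truth.boundary_bins))

    def test_consensus_wider_than_bin_rejected(self, small_params):
        _, seqs, _, truth = mh.simulate_genome(small_params, 3)
        with pytest.raises(ValueError):
            plant_boundary_motifs(seqs, truth, consensus="A" * 6000,
                                  fraction=1.0, seed=3)
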