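import numpy as np
import pandas as pd
import pytest
from scipy import stats

import nucleoidscope as ns
from nucleoidscope.contacts import make_bins
from nucleoidscope.structure import Track


class TestBinCoverage:
    def test_low_mapq_reads_filtered(self, small_layout):
        bins = make_bins(small_layout, 10_000)
        reads = pd.DataFrame(
            {"chrom": ["chr1"] * 3, "start": [1, 100, 200], "length": [100] * 3,
             "mapq": [0, 30, 29]}
        )
        cov = ns.bin_coverage(reads, bins, mapq_min=30, binsize=10_000)
        assert cov.values.sum() == 0  # threshold is strictly above 30

    def test_mapq_threshold_is_strict(self, small_layout):
        bins = make_bins(small_layout, 10_000)
        reads = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [1, 1], "length": [50, 50],
             "mapq": [30, 31]}
        )
        cov = ns.bin_coverage(reads, bins, binsize=10_000)
        assert cov.values.sum() == 50  # only MAPQ 31 survives

    def test_boundary_spanning_read_splits_by_overlap(self, small_layout):
        bins = make_bins(small_layout, 10_000)
        reads = pd.DataFrame(
            {"chrom": ["chr1"], "start": [9_941], "length": [100], "mapq": [60]}
        )
        cov = ns.bin_coverage(reads, bins, binsize=10_000)
        assert cov.values[0] == 60 and cov.values[1] == 40

    def test_per_base_track_input(self, small_layout):
        bins = make_bins(small_layout, 10_000)
        track = {"chr1": np.ones(800_000)}
        cov = ns.bin_coverage(track, bins, binsize=10_000)
        assert np.allclose(cov.chrom_values("chr1"), 10_000)
        assert np.allclose(cov.chrom_values("chr2"), 0)


class TestSavgolSmooth:
    def test_polynomial_signal_reproduced_exactly(self, small_layout):
        bins = make_bins(small_layout, 10_000)
        x = np.arange(len(bins), dtype=float)
        poly = 0.5 * x**3 - 2 * x**2 + x - 7
        tr = Track(bins=bins, values=poly, kind="coverage", binsize=10_000)
        sm = ns.savgol_smooth(tr, 21, 3, circular=False)
        assert np.max(np.abs(sm.values - poly)) < 1e-6 * np.max(np.abs(poly))

    def test_constant_track_unchanged(self, small_layout):
        bins = make_bins(small_layout, 10_000)
        tr = Track(bins=bins, values=np.full(len(bins), 3.3), kind="coverage", binsize=10_000)
        sm = ns.savgol_smooth(tr)
        assert np.allclose(sm.values, 3.3)

    def test_noise_variance_reduced(self, small_layout, rng):
        bins = make_bins(small_layout, 10_000)
        noise = rng.standard_normal(len(bins))
        tr = Track(bins=bins, values=noise, kind="coverage", binsize=10_000)
        sm = ns.savgol_smooth(tr)
        assert np.var(sm.values) < np.var(noise)

    def test_window_larger_than_chromosome_rejected(self, small_layout):
        bins = make_bins(small_layout, 10_000)
        tr = Track(bins=bins, values=np.zeros(len(bins)), kind="coverage", binsize=10_000)
        with pytest.raises(ValueError):
            ns.savgol_smooth(tr, window=101, order=3)

    def test_even_window_rejected(self, small_layout):
        bins = make_bins(small_layout, 10_000)
        tr = Track(bins=bins, values=np.zeros(len(bins)), kind="coverage", binsize=10_000)
        with pytest.raises(ValueError, match="odd"):
            ns.savgol_smooth(tr, window=20, order=3)


class TestContactTranscriptionCorrelation:
    def test_identical_tracks_correlate_perfectly(self, wt_balanced):
        fire = ns.fire_score(wt_balanced)
        cov = Track(
            bins=fire.bins, values=np.nan_to_num(fire.values), kind="coverage",
            binsize=fire.binsize,
        )
        rep = ns.contact_transcription_correlation(wt_balanced, cov)
        assert rep.pearson_r == pytest.approx(1.0, abs=1e-9)

    def test_sign_invariant_under_affine_rescale(self, wt_balanced, layout):
        fire = ns.fire_score(wt_balanced)
        coup = ns.CouplingParams(k_fire=1.0, seed=81)
        _, cov = ns.simulate_transcription(layout, fire.values, coup, 10_000)
        t1 = Track(bins=fire.bins, values=cov, kind="coverage", binsize=10_000)
        t2 = Track(bins=fire.bins, values=5.0 * cov + 11.0, kind="coverage", binsize=10_000)
        r1 = ns.contact_transcription_correlation(wt_balanced, t1).pearson_r
        r2 = ns.contact_transcription_correlation(wt_balanced, t2).pearson_r
        assert r1 == pytest.approx(r2, abs=1e-9)

    def test_coupled_simulation_recovers_positive_correlation(self, wt_balanced, layout):
        fire = ns.fire_score(wt_balanced)
        coup = ns.CouplingParams(k_fire=1.0, seed=82)
        _, cov = ns.simulate_transcription(layout, fire.values, coup, 10_000)
        rep = ns.contact_transcription_correlation(
            wt_balanced, Track(bins=fire.bins, values=cov, kind="coverage", binsize=10_000)
        )
        assert rep.pearson_r > 0.3
        assert set(rep.per_chrom) == {"chr1", "chr2"}

    def test_short_range_signal_variant(self, wt_balanced, layout):
        fire = ns.fire_score(wt_balanced)
        coup = ns.CouplingParams(k_fire=1.0, seed=83)
        _, cov = ns.simulate_transcription(layout, fire.values, coup, 10_000)
        rep = ns.contact_transcription_correlation(
            wt_balanced,
            Track(bins=fire.bins, values=cov, kind="coverage", binsize=10_000),
            signal_kind="short_range_sum",
        )
        assert rep.signal_kind == "short_range_sum"
        assert rep.pearson_r > 0.2


class TestVariantContactEnrichment:
    def test_pvalue_respects_add_one_bound(self, wt_sim):
        _, observed, _ = wt_sim
        var = pd.DataFrame({"chrom": ["chr1"] * 3, "pos": [10_500, 400_000, 2_000_000]})
        rep = ns.variant_contact_enrichment(var, observed, n_perm=200, seed=1)
        assert rep.p_perm >= 1 / 201

    def test_null_pvalues_superuniform(self, small_layout):
        """With exchangeable variant placement the permutation p-value is
        (super)uniform: its empirical CDF must not exceed the diagonal by
        more than Monte-Carlo error."""
        true, _, _ = ns.simulate_contact_map(
            small_layout,
            ns.ContactModelParams(
                beta_cid=1.0, gamma_arm=1.0, delta_prophage=1.0, rho_ori2crts=1.0,
                bias_amplitude=0.3, n_pairs=300_000, seed=84,
            ),
            10_000,
        )
        rng = np.random.default_rng(85)
        pvals = []
        for rep_i in range(200):
            bins_sel = rng.choice(true.n_bins, 10, replace=False)
            var = pd.DataFrame(
                {
                    "chrom": true.bins["chrom"].to_numpy()[bins_sel],
                    "pos": true.bins["start"].to_numpy()[bins_sel] + 1,
                }
            )
            pvals.append(
                ns.variant_contact_enrichment(var, true, n_perm=199, seed=int(rng.integers(2**31))).p_perm
            )
        pvals = np.sort(pvals)
        ecdf = np.arange(1, 201) / 200
        assert np.max(ecdf - pvals) < 0.12  # KS-style band at n=200, alpha~0.01
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_variants_in_top_decile_detected(self, layout):
        power = 0
        for seed in range(10):
            _, observed, _ = ns.simulate_contact_map(layout, ns.wt_params(seed=700 + seed), 10_000)
            marg = observed.marginals()
            top = np.argsort(marg)[-52:]
            rng = np.random.default_rng(800 + seed)
            chosen = rng.choice(top, 30, replace=False)
            var = pd.DataFrame(
                {
                    "chrom": observed.bins["chrom"].to_numpy()[chosen],
                    "pos": observed.bins["start"].to_numpy()[chosen] + 5_000,
                }
            )
            rep = ns.variant_contact_enrichment(var, observed, n_perm=1000, seed=900 + seed)
            power += rep.p_perm < 0.05
        assert power >= 9

    def test_no_usable_variant_rejected(self, wt_sim):
        _, observed, _ = wt_sim
        with pytest.raises(ValueError):
            ns.variant_contact_enrichment(
                pd.DataFrame({"chrom": ["chrX"], "pos": [1]}), observed
            )


class TestCrtsScan:
    def test_verbatim_planted_motif_found_exactly(self):
        seq = ns.random_sequence(100_000, seed=90)
        motif = ns.random_sequence(150, seed=91)
        planted = seq[:30_000] + motif + seq[30_150:]
        hit = ns.crts_scan(planted, motif, ori1=0, ter1=50_000)
        assert hit.position == 30_001
        assert hit.identity == 1.0
        assert hit.strand == "+"

    def test_relative_position_two_fifths(self):
        seq = ns.random_sequence(200_000, seed=92)
        motif = ns.random_sequence(150, seed=93)
        ori1, ter1 = 0, 100_000
        pos = int(0.4 * (ter1 - ori1))
        planted = seq[:pos] + motif + seq[pos + 150:]
        hit = ns.crts_scan(planted, motif, ori1, ter1)
        assert hit.relative_replichore_position == pytest.approx(0.4, abs=150 / 100_000)

    def test_reverse_complement_found_on_minus_strand(self):
        comp = str.maketrans("ACGT", "TGCA")
        seq = ns.random_sequence(50_000, seed=94)
        motif = ns.random_sequence(60, seed=95)
        rc = motif.translate(comp)[::-1]
        planted = seq[:20_000] + rc + seq[20_060:]
        hit = ns.crts_scan(planted, motif, ori1=0, ter1=25_000)
        assert hit.position == 20_001
        assert hit.strand == "-"
        assert hit.identity == 1.0

    def test_short_motif_and_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            ns.crts_scan("ACGT" * 100, "ACGT", 0, 100)
        with pytest.raises(ValueError):
            ns.crts_scan("", "A" * 30, 0, 100)


class TestAnnotateRegions:
    def test_reported_prophage_genes_overlap_query_region(self):
        genes = ns.load_region_genes("chr1").assign(chrom="chr1")
        out = ns.annotate_regions([("chr1", 1_390_000, 1_405_000)], genes)
        assert out["n_genes"].iloc[0] == 5
        assert set(out["genes"].iloc[0]) == set(genes["gene_id"])

    def test_empty_region_gives_empty_list(self):
        genes = ns.load_region_genes("chr2").assign(chrom="chr2")
        out = ns.annotate_regions([("chr2", 1, 1_000)], genes)
        assert out["n_genes"].iloc[0] == 0
        assert out["genes"].iloc[0] == []

    def test_deg_status_counted(self):
        genes = ns.load_region_genes("chr2").assign(chrom="chr2")
        deg = pd.DataFrame(
            {"gene_id": genes["gene_id"],
             "direction": np.where(genes["differential_expression"] == "Up", "up", "down")}
        )
        out = ns.annotate_regions([("chr2", 190_000, 230_000)], genes, deg)
        assert out["n_up"].iloc[0] == 6
        assert out["n_down"].iloc[0] == 1


class TestEndToEndTriad:
    def test_depleted_region_variants_and_downregulation_cooccur(self, layout):
        """The full mutant-vs-WT synthetic contrast reproduces the
        qualitative triad: a down differential region, a variant cluster
        inside it, and depressed expression of the genes it contains."""
        hits = 0
        for seed in range(10):
            wt, _, _ = ns.simulate_contact_map(layout, ns.wt_params(seed=1000 + seed), 10_000)
            mut, _, _ = ns.simulate_contact_map(layout, ns.mutant_params(seed=2000 + seed), 10_000)
            regions = ns.differential_regions(ns.differential_map(wt, mut))
            down = [r for r in regions if r.direction == "down"]
            if not down:
                continue
            region = max(down, key=lambda r: r.n_bins)
            variants = ns.simulate_variants(
                layout, 6, cluster=(layout.prophage_regions[0], 111), seed=3000 + seed
            )
            clusters = ns.variant_cluster_scan(variants, max_gap=5_000)
            top = clusters[0]
            inside = (
                top.chrom == region.chrom
                and top.start >= region.start
                and top.end <= region.end
            )
            # expression: genes in the region get a 4-fold knock-down
            coup = ns.CouplingParams(gene_count=800, seed=4000 + seed)
            genes, ca, cb = ns.simulate_expression_pair(layout, coup)
            in_region = (
                (genes["chrom"] == region.chrom)
                & (genes["end"] >= region.start)
                & (genes["start"] <= region.end)
            ).to_numpy()
            fc = np.where(in_region, 0.25, 1.0)
            genes2, ca2, cb2 = ns.simulate_expression_pair(layout, coup, fc)
            res = ns.call_degs(genes2, ca2, cb2)
            mean_l2 = res.loc[in_region, "log2_fold_change"].mean()
            if inside and mean_l2 < 0:
                hits += 1
        assert hits >= 9
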