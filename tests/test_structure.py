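import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import nucleoidscope as ns
from nucleoidscope.contacts import ContactMatrix, make_bins
from nucleoidscope.structure import Track


def _matrix_from_dense(layout, dense, binsize=10_000):
    bins = make_bins(layout, binsize)
    return ContactMatrix(
        bins=bins, counts=sp.csr_matrix(dense), binsize=binsize, layout=layout
    )


class TestDirectionalityIndex:
    def test_symmetric_matrix_gives_zero_track(self, small_layout):
        bins = make_bins(small_layout, 10_000)
        n = len(bins)
        di = ns.directionality_index(
            _matrix_from_dense(small_layout, np.full((n, n), 3.0)), 100_000
        )
        assert np.allclose(di.values, 0.0)

    def test_hand_evaluated_formula(self):
        # A=10, B=0: sign -, (10-5)^2/5 + (0-5)^2/5 = 10 -> DI = -10
        A, B = 10.0, 0.0
        E = (A + B) / 2
        di = np.sign(B - A) * ((A - E) ** 2 + (B - E) ** 2) / E
        lay = ns.make_genome_layout({"chr1": 300_000}, crts_rel=None, circular=False)
        n = 30
        M = np.zeros((n, n))
        M[10, 9] = M[9, 10] = 10.0  # only upstream contact for bin 10
        di_track = ns.directionality_index(_matrix_from_dense(lay, M), 10_000)
        assert di_track.values[10] == pytest.approx(di) == pytest.approx(-10.0)

    def test_antisymmetric_under_genome_reversal(self, small_layout):
        true, _, _ = ns.simulate_contact_map(
            small_layout, ns.ContactModelParams(n_pairs=200_000, seed=61), 10_000
        )
        di = ns.directionality_index(true, 50_000)
        for name in small_layout.names:
            sl = true.chrom_slice(name)
            D = true.dense()
            rev = D[sl, sl][::-1, ::-1]
            mat_rev = ContactMatrix(
                bins=make_bins(
                    ns.make_genome_layout(
                        {name: small_layout.length(name)}, crts_rel=None
                    ),
                    10_000,
                ),
                counts=sp.csr_matrix(rev),
                binsize=10_000,
                layout=ns.make_genome_layout({name: small_layout.length(name)}, crts_rel=None),
            )
            di_rev = ns.directionality_index(mat_rev, 50_000)
            assert np.allclose(di_rev.values, -di.values[sl][::-1], atol=1e-9)

    def test_scale_below_binsize_rejected(self, wt_balanced):
        with pytest.raises(ValueError):
            ns.directionality_index(wt_balanced, 5_000)


class TestCidBorders:
    def test_zero_track_yields_no_borders(self, small_layout):
        bins = make_bins(small_layout, 10_000)
        di = Track(bins=bins, values=np.zeros(len(bins)), kind="DI", binsize=10_000)
        assert ns.call_cid_borders(di, min_amplitude=0.5) == []

    def test_infinite_amplitude_yields_no_borders(self, wt_balanced):
        di = ns.directionality_index(wt_balanced)
        assert ns.call_cid_borders(di, min_amplitude=np.inf) == []

    def test_all_nan_track_rejected(self, small_layout):
        bins = make_bins(small_layout, 10_000)
        di = Track(bins=bins, values=np.full(len(bins), np.nan), kind="DI", binsize=10_000)
        with pytest.raises(ValueError):
            ns.call_cid_borders(di)

    def test_planted_borders_recovered_within_two_bins(self, layout, wt_balanced):
        """All ten planted borders found within +/-2 bins with at most one
        spurious border per chromosome at the default amplitude."""
        di = ns.directionality_index(wt_balanced)
        called = ns.call_cid_borders(di)
        planted = ns.default_cid_borders(layout)
        tol = 2 * 10_000
        spurious = {name: 0 for name in layout.names}
        matched = 0
        for chrom, pos in called:
            near = [
                b for b in planted[chrom]
                if layout.circular_distance(chrom, pos - 1, b) <= tol
            ]
            if near:
                matched += 1
            else:
                spurious[chrom] += 1
        recovered = set()
        for chrom, pos in called:
            for b in planted[chrom]:
                if layout.circular_distance(chrom, pos - 1, b) <= tol:
                    recovered.add((chrom, b))
        assert len(recovered) == 10
        assert all(v <= 1 for v in spurious.values())


class TestFireScore:
    def test_constant_matrix_gives_zero_z(self, small_layout):
        bins = make_bins(small_layout, 10_000)
        n = len(bins)
        z = ns.fire_score(_matrix_from_dense(small_layout, np.full((n, n), 2.0)))
        assert np.allclose(z.values, 0.0)

    def test_z_scores_standardized_per_chromosome(self, wt_balanced):
        z = ns.fire_score(wt_balanced)
        for name in ("chr1", "chr2"):
            v = z.chrom_values(name)
            live = np.isfinite(v)
            assert np.nanmean(v[live]) == pytest.approx(0.0, abs=1e-9)
            assert np.nanstd(v[live]) == pytest.approx(1.0, abs=1e-9)

    def test_masked_bins_propagate_nan(self, wt_balanced):
        z = ns.fire_score(wt_balanced)
        assert np.isnan(z.values[wt_balanced.mask]).all()
        assert np.isfinite(z.values[~wt_balanced.mask]).all()

    def test_cid_interiors_score_above_borders(self, layout):
        """Bins well inside CIDs interact locally more than border bins."""
        diffs = []
        for seed in range(5):
            _, obs, _ = ns.simulate_contact_map(layout, ns.wt_params(seed=70 + seed), 10_000)
            bal = ns.ice_normalize(obs)
            z = ns.fire_score(bal)
            borders = ns.default_cid_borders(layout)
            border_bins, interior_bins = [], []
            for name in layout.names:
                sl = bal.chrom_slice(name)
                starts = bal.bins["start"].to_numpy()[sl]
                for k, s in enumerate(starts):
                    dmin = min(
                        layout.circular_distance(name, s, b) for b in borders[name]
                    )
                    if dmin <= 10_000:
                        border_bins.append(sl.start + k)
                    elif dmin >= 50_000:
                        interior_bins.append(sl.start + k)
            diffs.append(
                np.nanmean(z.values[interior_bins]) - np.nanmean(z.values[border_bins])
            )
        assert np.mean(diffs) > 0

    def test_window_below_binsize_rejected(self, wt_balanced):
        with pytest.raises(ValueError):
            ns.fire_score(wt_balanced, window=5_000)


class TestDifferentialMap:
    def test_identical_matrices_give_zero(self, wt_sim):
        true, _, _ = wt_sim
        diff = ns.differential_map(true, true)
        v = diff.values[np.isfinite(diff.values)]
        assert np.allclose(v, 0.0)

    def test_depth_invariance(self, small_layout):
        true, _, _ = ns.simulate_contact_map(
            small_layout, ns.ContactModelParams(n_pairs=100_000, seed=62), 10_000
        )
        doubled = ContactMatrix(
            bins=true.bins.copy(), counts=sp.csr_matrix(true.dense() * 2),
            binsize=true.binsize, layout=small_layout,
        )
        diff = ns.differential_map(true, doubled)
        v = diff.values[np.isfinite(diff.values)]
        assert np.allclose(v, 0.0, atol=1e-12)

    def test_antisymmetric_in_arguments(self, wt_sim, mutant_sim):
        a, b = wt_sim[0], mutant_sim[0]
        d1 = ns.differential_map(a, b)
        d2 = ns.differential_map(b, a)
        m = np.isfinite(d1.values)
        assert np.allclose(d1.values[m], -d2.values[m], atol=1e-12)

    def test_planted_depletion_is_negative_in_region(self, wt_sim, mutant_sim):
        diff = ns.differential_map(wt_sim[0], mutant_sim[0])
        sel = (
            (diff.bins["chrom"] == "chr1")
            & (diff.bins["start"] >= 1_300_000)
            & (diff.bins["start"] < 1_500_000)
        ).to_numpy()
        region_cells = diff.values[sel, :]
        assert np.nanmean(region_cells) < 0

    def test_bin_mismatch_rejected(self, wt_sim, small_layout):
        other, _, _ = ns.simulate_contact_map(
            small_layout, ns.ContactModelParams(n_pairs=1_000, seed=1), 10_000
        )
        with pytest.raises(ValueError):
            ns.differential_map(wt_sim[0], other)


class TestDifferentialRegions:
    def test_zero_map_yields_nothing(self, small_layout):
        n = len(make_bins(small_layout, 10_000))
        a = _matrix_from_dense(small_layout, np.full((n, n), 2.0))
        regions = ns.differential_regions(ns.differential_map(a, a))
        assert regions == []

    def test_planted_depletion_recovered_with_high_jaccard(self, wt_sim, mutant_sim):
        diff = ns.differential_map(wt_sim[0], mutant_sim[0])
        regions = ns.differential_regions(diff)
        down = [r for r in regions if r.direction == "down"]
        assert len(down) == 1
        r = down[0]
        inter = max(0, min(r.end, 1_500_000) - max(r.start - 1, 1_300_000))
        union = max(r.end, 1_500_000) - min(r.start - 1, 1_300_000)
        assert inter / union >= 0.7
        assert r.mean_log2 <= -0.3

    def test_zero_threshold_partitions_by_sign(self, wt_sim, mutant_sim):
        diff = ns.differential_map(wt_sim[0], mutant_sim[0])
        regions = ns.differential_regions(diff, threshold=0.0, min_run=1)
        marginal = np.nanmean(diff.values, axis=1)
        n_binned = sum(r.n_bins for r in regions)
        assert n_binned == int(np.isfinite(marginal).sum())


class TestRegionPairScore:
    def test_identical_matrices_score_zero(self, wt_sim):
        a = wt_sim[0]
        _, _, ratio = ns.region_pair_score(
            a, a, ("chr1", 615_001, 665_000), ("chr2", 1, 25_000)
        )
        assert ratio == pytest.approx(0.0, abs=1e-12)

    def test_weakened_tether_scores_negative(self, wt_sim, mutant_sim):
        """Mutant halves the ori2-crtS multiplier: both the ori2-crtS
        block and its symmetric ter1-ter2 companion lose contact
        probability."""
        wt, mut = wt_sim[0], mutant_sim[0]
        _, _, crts_ratio = ns.region_pair_score(
            wt, mut, ("chr1", 615_001, 665_000), ("chr2", 1, 25_000)
        )
        _, _, ter_ratio = ns.region_pair_score(
            wt, mut, ("chr1", 1_575_001, 1_625_000), ("chr2", 975_001, 1_025_000)
        )
        assert crts_ratio < 0
        assert ter_ratio < 0

    def test_empty_block_rejected(self, wt_sim):
        with pytest.raises(ValueError, match="empty"):
            ns.region_pair_score(
                wt_sim[0], wt_sim[0], ("chr9", 1, 100), ("chr1", 1, 100)
            )
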