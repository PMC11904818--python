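"""Region extraction/sampling and random-region Pearson correlation."""

import numpy as np
import pytest
from scipy import stats

from spatniche.niche_correlation import (
    CorrelationParams,
    RegionProfiles,
    correlate_gene_sets,
    extract_region,
    sample_regions,
    spatial_aggregation_map,
)
from spatniche.synthdata import hex_grid_geometry
from spatniche.qc_norm import normalize_log_cpm

from conftest import make_count_matrix


def _grid_counts(geom, rng, n_genes=30):
    counts = rng.integers(0, 20, size=(len(geom), n_genes)) + 1
    m = make_count_matrix(counts, obs_kind="spot")
    m.obs_ids = geom.barcodes.copy()
    return m


class TestExtractRegion:
    def test_region_size_one_is_seed(self):
        geom = hex_grid_geometry("S", 6, 6)
        seed = geom.barcodes[7]
        assert extract_region(geom, seed, 1) == (seed,)

    def test_contains_seed_with_exact_size(self):
        geom = hex_grid_geometry("S", 8, 8)
        for seed in geom.barcodes[::13]:
            members = extract_region(geom, seed, 25)
            assert len(members) == 25 and seed in members

    def test_matches_brute_force_distance_sort(self):
        geom = hex_grid_geometry("S", 6, 10)  # 60-spot toy grid with hex ties
        for seed in geom.barcodes[::7]:
            members = extract_region(geom, seed, 12)
            i = list(geom.barcodes).index(seed)
            d2 = (geom.pxl_row - geom.pxl_row[i]) ** 2 + (geom.pxl_col - geom.pxl_col[i]) ** 2
            order = sorted(range(len(geom)), key=lambda j: (d2[j], str(geom.barcodes[j])))
            expected = tuple(geom.barcodes[j] for j in order[:12])
            assert members == expected

    def test_excludes_out_of_tissue(self):
        geom = hex_grid_geometry("S", 6, 6)
        geom.in_tissue[::2] = 0
        seed = geom.barcodes[1]
        members = extract_region(geom, seed, 10)
        out = set(geom.barcodes[geom.in_tissue == 0])
        assert not (set(members) & out)

    def test_too_few_spots_rejected(self):
        geom = hex_grid_geometry("S", 5, 5)
        with pytest.raises(ValueError):
            extract_region(geom, geom.barcodes[0], 26)


class TestSampleRegions:
    def test_seed_determinism(self, rng):
        geom = hex_grid_geometry("S", 10, 10)
        m = _grid_counts(geom, rng)
        p = CorrelationParams(n_regions_per_sample=20, region_size=9, seed=5)
        a = sample_regions(geom, m, p)
        b = sample_regions(geom, m, p)
        assert [r.members for r in a.regions] == [r.members for r in b.regions]
        assert np.array_equal(a.matrix, b.matrix)

    def test_zero_regions_empty(self, rng):
        geom = hex_grid_geometry("S", 6, 6)
        m = _grid_counts(geom, rng)
        out = sample_regions(geom, m, CorrelationParams(n_regions_per_sample=0))
        assert len(out) == 0 and out.matrix.shape[0] == 0

    def test_all_regions_sized_and_seeded(self, rng):
        geom = hex_grid_geometry("S", 12, 12)
        m = _grid_counts(geom, rng)
        p = CorrelationParams(n_regions_per_sample=50, region_size=25, seed=1)
        out = sample_regions(geom, m, p)
        for r in out.regions:
            assert len(r.members) == 25 and r.seed_spot in r.members

    def test_seed_spots_uniform_chi_square(self, rng):
        geom = hex_grid_geometry("S", 8, 8)  # 64 spots
        m = _grid_counts(geom, rng)
        counts = {b: 0 for b in geom.barcodes}
        for s in range(40):
            out = sample_regions(
                geom, m, CorrelationParams(n_regions_per_sample=32, region_size=1), seed=s
            )
            for r in out.regions:
                counts[r.seed_spot] += 1
        observed = np.array(list(counts.values()))
        chi2 = ((observed - observed.mean()) ** 2 / observed.mean()).sum()
        # 63 dof; generous upper bound on the uniformity statistic
        assert chi2 < stats.chi2.ppf(0.999, 63)

    def test_profile_is_logcpm_of_summed_counts(self, rng):
        geom = hex_grid_geometry("S", 6, 6)
        m = _grid_counts(geom, rng)
        p = CorrelationParams(n_regions_per_sample=3, region_size=4, seed=2)
        out = sample_regions(geom, m, p)
        r = out.regions[0]
        rows = [list(m.obs_ids).index(b) for b in r.members]
        summed = np.asarray(m.values[rows].sum(axis=0)).ravel()
        expected = np.log2(summed / summed.sum() * 1e6 + 1)
        assert np.allclose(r.profile, expected)

    def test_oversampling_flags_replacement(self, rng):
        geom = hex_grid_geometry("S", 5, 6)
        m = _grid_counts(geom, rng)
        out = sample_regions(
            geom, m, CorrelationParams(n_regions_per_sample=100, region_size=5), seed=3
        )
        assert out.with_replacement and len(out) == 100


class TestCorrelateGeneSets:
    def _profiles(self, mat, genes):
        n = mat.shape[0]
        return RegionProfiles(
            regions=[None] * n,
            gene_ids=np.asarray(genes, dtype=object),
            matrix=np.asarray(mat, dtype=float),
            sample_ids=np.array(["S"] * n, dtype=object),
        )

    def test_gene_with_itself_r_one(self, rng):
        mat = rng.normal(size=(50, 2))
        prof = self._profiles(mat, ["a", "b"])
        recs = correlate_gene_sets(prof, ["a"], ["a"])
        assert recs[0].r == pytest.approx(1.0)

    def test_constant_gene_undefined(self, rng):
        mat = np.column_stack([np.full(30, 2.0), rng.normal(size=30)])
        prof = self._profiles(mat, ["const", "x"])
        recs = correlate_gene_sets(prof, ["const"], ["x"])
        assert not recs[0].defined
        assert not recs[0].passes_standard and not recs[0].passes_strict

    def test_p_matches_t_transform_closed_form(self, rng):
        # fixed 10-point toy pair: p must equal the closed form to 1e-10
        x = np.array([1.0, 2, 3, 4, 5, 6, 7, 8, 9, 10])
        y = np.array([2.0, 1, 4, 3, 7, 5, 8, 6, 10, 9])
        pad = rng.normal(size=(10, 1))
        prof = self._profiles(np.column_stack([x, y, pad]), ["a", "b", "z"])
        rec = correlate_gene_sets(prof, ["a"], ["b"])[0]
        r_ref, p_ref = stats.pearsonr(x, y)
        assert rec.r == pytest.approx(r_ref, abs=1e-12)
        assert rec.p_value == pytest.approx(p_ref, abs=1e-10)

    def test_symmetry_of_r(self, rng):
        mat = rng.normal(size=(40, 2))
        prof = self._profiles(mat, ["a", "b"])
        fwd = correlate_gene_sets(prof, ["a"], ["b"])[0]
        rev = correlate_gene_sets(prof, ["b"], ["a"])[0]
        assert fwd.r == rev.r

    def test_bivariate_normal_recovery(self):
        # rho = 0.7 at n = 200 regions: within 0.1 for >= 95% of 50 seeds
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            z = rng.multivariate_normal([0, 0], [[1, 0.7], [0.7, 1]], size=200)
            prof = self._profiles(z, ["a", "b"])
            r = correlate_gene_sets(prof, ["a"], ["b"])[0].r
            hits += abs(r - 0.7) <= 0.1
        assert hits >= 48

    def test_stratified_r_reported(self, rng):
        mat = rng.normal(size=(60, 2))
        prof = self._profiles(mat, ["a", "b"])
        prof.sample_ids = np.array(["S1"] * 30 + ["S2"] * 30, dtype=object)
        recs = correlate_gene_sets(
            prof, ["a"], ["b"], sample_conditions={"S1": "TB", "S2": "Duroc"}
        )
        assert set(recs[0].r_by_group) == {"TB", "Duroc"}

    def test_empty_intersection_rejected(self, rng):
        prof = self._profiles(rng.normal(size=(10, 1)), ["a"])
        with pytest.raises(ValueError):
            correlate_gene_sets(prof, ["missing"], ["a"])

    def test_q_values_bh_monotone(self, rng):
        mat = rng.normal(size=(80, 6))
        prof = self._profiles(mat, list("abcdef"))
        recs = correlate_gene_sets(prof, ["a", "b", "c"], ["d", "e", "f"])
        defined = sorted((r.p_value, r.q_value) for r in recs if r.defined)
        qs = [q for _, q in defined]
        assert all(b >= a - 1e-12 for a, b in zip(qs, qs[1:]))
        assert all(q >= p - 1e-12 for p, q in defined)


class TestSpatialAggregationMap:
    def test_unknown_gene_rejected(self, rng):
        geom = hex_grid_geometry("S", 6, 6)
        m = _grid_counts(geom, rng)
        with pytest.raises(KeyError):
            spatial_aggregation_map(m, geom, ("g0", "nope"))

    def test_constant_gene_constant_column(self, rng):
        geom = hex_grid_geometry("S", 6, 6)
        counts = np.ones((len(geom), 3), dtype=int) * [5, 7, 9]
        m = make_count_matrix(counts, obs_kind="spot")
        m.obs_ids = geom.barcodes.copy()
        df = spatial_aggregation_map(m, geom, ("g0", "g1"))
        assert df["g0"].nunique() == 1

    def test_values_match_hand_join(self, rng):
        geom = hex_grid_geometry("S", 5, 5)
        m = _grid_counts(geom, rng, n_genes=4)
        df = spatial_aggregation_map(m, geom, ("g1", "g2"))
        expr = np.asarray(normalize_log_cpm(m).todense())
        row = df[df["barcode"] == m.obs_ids[3]].iloc[0]
        assert row["g1"] == pytest.approx(expr[3, 1])
        assert row["g2"] == pytest.approx(expr[3, 2])
        assert row["pxl_row_in_fullres"] == geom.pxl_row[3]
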