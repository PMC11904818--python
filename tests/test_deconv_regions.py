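"""Signature building, NNLS deconvolution, region classification, region DE."""

import numpy as np
import pandas as pd
import pytest

from spatniche.deconv_regions import (
    RegionParams,
    build_signatures,
    classify_regions,
    deconvolve_spots,
    region_de,
)
from spatniche.types import ProportionMap, SignatureMatrix

from conftest import make_count_matrix


def _labels(m, values):
    return pd.Series(np.asarray(values, dtype=object), index=pd.Index(m.obs_ids))


class TestBuildSignatures:
    def test_single_type_mean_cpm(self):
        counts = np.array([[10, 30, 60], [20, 60, 120]])
        m = make_count_matrix(counts)
        sig = build_signatures(m, _labels(m, ["T", "T"]), top_k_markers=0)
        # both nuclei have identical CPM, so the signature is that profile
        assert np.allclose(sig.values[0], [1e5, 3e5, 6e5])

    def test_duplicating_nuclei_leaves_mean_unchanged(self, rng):
        counts = rng.integers(1, 20, size=(6, 5))
        m1 = make_count_matrix(counts)
        m2 = make_count_matrix(np.vstack([counts, counts]), prefix="D")
        lab = ["A", "A", "A", "B", "B", "B"]
        s1 = build_signatures(m1, _labels(m1, lab), top_k_markers=0)
        s2 = build_signatures(m2, _labels(m2, lab + lab), top_k_markers=0)
        assert np.allclose(s1.values, s2.values)

    def test_three_nucleus_hand_mean(self):
        counts = np.array([[8, 2], [6, 4], [4, 6]])  # libraries all 10
        m = make_count_matrix(counts)
        sig = build_signatures(m, _labels(m, ["T", "T", "T"]), top_k_markers=0)
        assert np.allclose(sig.values[0], [6e5, 4e5])

    def test_missing_label_rejected(self):
        m = make_count_matrix([[1, 2], [3, 4]])
        with pytest.raises(ValueError, match="missing"):
            build_signatures(m, pd.Series({"OBS0": "A"}), top_k_markers=0)

    def test_marker_subset_restricts_genes(self, small_reference):
        ref, labels, _ = small_reference
        sig = build_signatures(ref, labels, top_k_markers=5)
        assert sig.values.shape[1] < ref.n_genes
        assert sig.values.shape[0] == 4


class TestDeconvolveSpots:
    def _toy_signatures(self):
        values = np.array([[100.0, 0.0, 50.0], [0.0, 100.0, 50.0]])
        return SignatureMatrix(
            values=values,
            celltypes=np.array(["A", "B"], dtype=object),
            gene_ids=np.array(["g0", "g1", "g2"], dtype=object),
        )

    def test_pure_spot_recovers_unit_proportion(self):
        sig = self._toy_signatures()
        spots = make_count_matrix([[100, 0, 50]], obs_kind="spot")
        pm = deconvolve_spots(spots, sig)
        assert pm.values[0, 0] == pytest.approx(1.0, abs=1e-9)
        assert pm.residual[0] == pytest.approx(0.0, abs=1e-9)

    def test_noiseless_mixture_recovered(self):
        sig = self._toy_signatures()
        # 0.6*A + 0.4*B of equal-mass signatures -> counts [60, 40, 50]
        spots = make_count_matrix([[60, 40, 50]], obs_kind="spot")
        pm = deconvolve_spots(spots, sig)
        assert pm.values[0] == pytest.approx([0.6, 0.4], abs=1e-6)

    def test_all_zero_spot_uniform_and_flagged(self):
        sig = self._toy_signatures()
        spots = make_count_matrix([[0, 0, 0], [100, 0, 50]], obs_kind="spot")
        pm = deconvolve_spots(spots, sig)
        assert pm.values[0] == pytest.approx([0.5, 0.5])
        assert pm.flagged[0] and not pm.flagged[1]

    def test_no_shared_genes_rejected(self):
        sig = SignatureMatrix(
            values=np.array([[1.0]]),
            celltypes=np.array(["A"], dtype=object),
            gene_ids=np.array(["zz"], dtype=object),
        )
        spots = make_count_matrix([[1, 2]], obs_kind="spot")
        with pytest.raises(ValueError, match="shared"):
            deconvolve_spots(spots, sig)

    def test_rows_sum_to_one_and_nonnegative(self, rng):
        sig = self._toy_signatures()
        spots = make_count_matrix(rng.integers(0, 50, size=(20, 3)) + 1, obs_kind="spot")
        pm = deconvolve_spots(spots, sig)
        assert np.allclose(pm.values.sum(axis=1), 1.0, atol=1e-9)
        assert (pm.values >= 0).all()

    def test_gene_order_permutation_equivariant(self, rng):
        sig = self._toy_signatures()
        counts = rng.integers(1, 50, size=(5, 3))
        spots = make_count_matrix(counts, obs_kind="spot")
        pm1 = deconvolve_spots(spots, sig)
        perm = [2, 0, 1]
        sig2 = SignatureMatrix(
            values=sig.values[:, perm],
            celltypes=sig.celltypes,
            gene_ids=sig.gene_ids[perm],
        )
        pm2 = deconvolve_spots(spots, sig2)
        assert np.allclose(pm1.values, pm2.values, atol=1e-9)


class TestClassifyRegions:
    def _pm(self, props):
        props = np.asarray(props, dtype=float)
        values = np.column_stack([props, 1.0 - props])
        return ProportionMap(
            values=values,
            barcodes=np.array([f"S-S{i:03d}x{0:03d}" for i in range(len(props))], dtype=object),
            celltypes=np.array(["FAPs", "rest"], dtype=object),
        )

    def _geom(self, n):
        from spatniche.types import SpotGeometry

        return SpotGeometry(
            barcodes=np.array([f"S-S{i:03d}x{0:03d}" for i in range(n)], dtype=object),
            in_tissue=np.ones(n, dtype=int),
            array_row=np.arange(n),
            array_col=np.zeros(n, dtype=int) + np.arange(n) % 2,
            pxl_row=np.arange(n, dtype=float),
            pxl_col=np.zeros(n),
        )

    def test_quantile_count_matches_sort_oracle(self):
        props = np.round(np.arange(1, 101) / 100.0, 2)
        labels = classify_regions(self._pm(props), self._geom(100), RegionParams())
        # brute force: threshold is the order statistic at floor(0.75 * 99)
        thr = sorted(props)[int(np.floor(0.75 * 99))]
        assert (labels == "high").sum() == sum(1 for p in props if p >= thr) == 26
        assert (labels == "low").sum() == sum(1 for p in props if p <= sorted(props)[24])

    def test_zero_high_quantile_everything_high(self):
        props = np.linspace(0.1, 0.9, 20)
        labels = classify_regions(
            self._pm(props), self._geom(20), RegionParams(high_quantile=0.0, low_quantile=0.0)
        )
        assert (labels == "high").all()

    def test_constant_proportions_all_intermediate(self):
        with pytest.warns(UserWarning):
            labels = classify_regions(
                self._pm(np.full(10, 0.5)), self._geom(10), RegionParams()
            )
        assert (labels == "intermediate").all()

    def test_monotone_rescaling_invariance(self):
        props = np.linspace(0.05, 0.95, 40)
        l1 = classify_regions(self._pm(props), self._geom(40), RegionParams())
        l2 = classify_regions(self._pm(props**2), self._geom(40), RegionParams())
        assert (l1 == l2).all()

    def test_out_of_tissue_excluded_from_quantiles(self):
        geom = self._geom(10)
        geom.in_tissue[5:] = 0
        props = np.linspace(0.1, 1.0, 10)
        labels = classify_regions(self._pm(props), geom, RegionParams())
        assert len(labels) == 5

    def test_missing_celltype_rejected(self):
        with pytest.raises(KeyError):
            classify_regions(
                self._pm([0.5]), self._geom(1), RegionParams(target_celltype="nope")
            )


class TestRegionDE:
    def _spots(self, rng, n=20, g=50):
        counts = rng.integers(0, 10, size=(n, g)) + 1
        counts[: n // 2, 0] += 40  # planted high-region gene
        return make_count_matrix(counts, obs_kind="spot")

    def test_planted_gene_detected_up(self, rng):
        m = self._spots(rng)
        high = list(m.obs_ids[:10])
        low = list(m.obs_ids[10:])
        recs = region_de(m, high, low)
        rec0 = next(r for r in recs if r.gene_id == "g0")
        assert rec0.passes_filter and rec0.direction == "up"

    def test_overlapping_classes_rejected(self, rng):
        m = self._spots(rng)
        ids = list(m.obs_ids)
        with pytest.raises(ValueError, match="both classes"):
            region_de(m, ids[:10], ids[5:15])

    def test_small_class_rejected(self, rng):
        m = self._spots(rng)
        ids = list(m.obs_ids)
        with pytest.raises(ValueError, match=">= 3"):
            region_de(m, ids[:2], ids[10:])

    def test_shuffled_labels_near_alpha(self, rng):
        counts = rng.integers(0, 12, size=(40, 400)) + 1
        m = make_count_matrix(counts, obs_kind="spot")
        ids = list(m.obs_ids)
        perm = rng.permutation(40)
        recs = region_de(m, [ids[i] for i in perm[:20]], [ids[i] for i in perm[20:]])
        frac = np.mean([r.p_value < 0.05 for r in recs])
        assert 0.01 <= frac <= 0.10
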