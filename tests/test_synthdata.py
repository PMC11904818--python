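"""Synthetic-data generator: determinism, moments, geometry, planted structure."""

import numpy as np
import pytest

from spatniche.synthdata import (
    ReferenceSpec,
    SpatialSpec,
    expected_signatures,
    hex_grid_geometry,
    simulate_location_table,
    simulate_reference,
    simulate_study,
    simulate_visium,
    StudySpec,
)
from spatniche.markers_de import DEParams, find_markers
from spatniche.qc_norm import normalize_log_cpm


SMALL = dict(
    n_celltypes=3,
    n_genes=120,
    n_nuclei_per_type=40,
    markers_per_type=8,
    seed=11,
)


class TestSimulateReference:
    def test_seed_determinism(self):
        a, la, ta = simulate_reference(ReferenceSpec(**SMALL))
        b, lb, tb = simulate_reference(ReferenceSpec(**SMALL))
        assert a == b
        assert (la == lb).all()
        assert ta.signatures.equals(tb.signatures)

    def test_different_seed_differs(self):
        a, _, _ = simulate_reference(ReferenceSpec(**SMALL))
        b, _, _ = simulate_reference(ReferenceSpec(**{**SMALL, "seed": 12}))
        assert a != b

    def test_infeasible_spec_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            ReferenceSpec(n_celltypes=5, n_genes=40, markers_per_type=10)

    def test_marker_blocks_disjoint_and_elevated(self):
        spec = ReferenceSpec(**SMALL)
        sig = expected_signatures(spec)
        elevated = sig.to_numpy() > spec.baseline_mean * 1.5
        mito = spec.mito_gene_count
        marker_cols = elevated[:, mito:].any(axis=0)
        # each marker gene is elevated in exactly one cell type
        assert elevated[:, mito:][:, marker_cols].sum(axis=0).max() == 1
        assert marker_cols.sum() == spec.n_celltypes * spec.markers_per_type

    def test_nb_moments_match_closed_form(self):
        # empirical per-gene mean of NB(5, size=2) within 3 standard errors
        spec = ReferenceSpec(
            n_celltypes=1,
            n_genes=200,
            n_nuclei_per_type=10000,
            markers_per_type=1,
            marker_log2fc=0.0,
            baseline_mean=5.0,
            dispersion=2.0,
            mito_gene_count=0,
            seed=5,
            low_quality_fraction=0.0,
            high_mito_fraction=0.0,
        )
        m, _, _ = simulate_reference(spec)
        x = np.asarray(m.values.todense(), dtype=float)
        se = np.sqrt((5.0 + 5.0**2 / 2.0) / spec.n_nuclei_per_type)
        within = np.abs(x.mean(axis=0) - 5.0) <= 3.0 * se
        assert within.mean() >= 0.99
        # variance close to NB variance mean + mean^2/size
        v = x.var(axis=0)
        assert np.median(v) == pytest.approx(17.5, rel=0.1)

    def test_null_fold_change_spec_yields_no_markers(self):
        spec = ReferenceSpec(
            **{**SMALL, "marker_log2fc": 0.0, "low_quality_fraction": 0.0,
               "high_mito_fraction": 0.0, "n_nuclei_per_type": 100}
        )
        m, labels, _ = simulate_reference(spec)
        recs = find_markers(
            normalize_log_cpm(m), labels.to_numpy(), DEParams(), gene_ids=m.gene_ids
        )
        assert sum(r.passes_filter and r.q_value < 0.05 for r in recs) == 0

    def test_counts_nonnegative_integers(self):
        m, _, _ = simulate_reference(ReferenceSpec(**SMALL))
        assert m.values.data.min() >= 0
        assert np.array_equal(m.values.data, np.round(m.values.data))


class TestHexGeometry:
    def test_parity_constant(self):
        g = hex_grid_geometry("S", 6, 5)
        assert len(set((g.array_row + g.array_col) % 2)) == 1

    def test_neighbour_distance_uniform(self):
        from spatniche.synthdata import HEX_PITCH_PX

        g = hex_grid_geometry("S", 4, 4)
        # adjacent same-row spots and diagonal spots both at one pitch
        d_row = np.hypot(g.pxl_row[1] - g.pxl_row[0], g.pxl_col[1] - g.pxl_col[0])
        assert d_row == pytest.approx(HEX_PITCH_PX)


class TestSimulateVisium:
    def _signatures(self):
        return expected_signatures(
            ReferenceSpec(
                **SMALL, celltypes=("FAPs", "myofibers_type1", "myofibers_type2")
            )
        )

    def test_seed_determinism(self):
        spec = SpatialSpec(grid_rows=8, grid_cols=8, seed=3)
        a = simulate_visium(spec, self._signatures())
        b = simulate_visium(spec, self._signatures())
        assert a[0] == b[0]
        assert a[2].proportions.equals(b[2].proportions)

    def test_true_proportions_rows_sum_to_one(self):
        spec = SpatialSpec(grid_rows=8, grid_cols=8, seed=3)
        _, _, truth = simulate_visium(spec, self._signatures())
        assert np.allclose(truth.proportions.to_numpy().sum(axis=1), 1.0, atol=1e-9)

    def test_zero_amplitude_constant_proportions(self):
        spec = SpatialSpec(grid_rows=6, grid_cols=6, proportion_amplitude=0.0, seed=3)
        _, _, truth = simulate_visium(spec, self._signatures())
        p = truth.proportions.to_numpy()
        assert np.allclose(p, p[0], atol=1e-12)

    def test_planted_gene_absent_rejected(self):
        spec = SpatialSpec(
            grid_rows=6, grid_cols=6, planted_pairs=(("NOPE", "ALSO_NOPE", 0.5),)
        )
        with pytest.raises(ValueError, match="NOPE"):
            simulate_visium(spec, self._signatures())

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError):
            SpatialSpec(planted_pairs=(("a", "b", 1.5),))

    def test_grid_too_small_rejected(self):
        with pytest.raises(ValueError):
            SpatialSpec(grid_rows=4, grid_cols=4)

    def test_library_sizes_near_target(self):
        spec = SpatialSpec(grid_rows=10, grid_cols=10, reads_per_spot=5000, seed=2)
        m, _, _ = simulate_visium(spec, self._signatures())
        libs = m.library_sizes()
        assert abs(libs.mean() - 5000) / 5000 < 0.05


class TestLocationTable:
    GENES = [f"G{i}" for i in range(1000)]

    def test_zero_fraction_only_planted(self):
        table = simulate_location_table(
            self.GENES, 0.0, seed=1, always_secreted=["G1", "G2"]
        )
        secreted = {g for g, l in table.items() if any("Secreted" in s for s in l)}
        assert secreted == {"G1", "G2"}

    def test_full_fraction_all_secreted(self):
        table = simulate_location_table(self.GENES[:50], 1.0, seed=1)
        assert all(any("Secreted" in s for s in l) for l in table.values())

    def test_fraction_within_one_gene(self):
        table = simulate_location_table(self.GENES, 0.1, seed=1)
        n_secreted = sum(any("Secreted" in s for s in l) for l in table.values())
        assert abs(n_secreted - 100) <= 1

    def test_every_gene_assigned_one_entry(self):
        table = simulate_location_table(self.GENES[:30], 0.2, seed=1)
        assert set(table) == set(self.GENES[:30])
        assert all(len(l) == 1 for l in table.values())


class TestSimulateStudy:
    def test_study_determinism_and_structure(self):
        spec = StudySpec(seed=4)
        spec.reference = ReferenceSpec(**SMALL, celltypes=("FAPs", "myofibers_type1", "myofibers_type2"))
        for sid in spec.spatial:
            spec.spatial[sid].grid_rows = 10
            spec.spatial[sid].grid_cols = 10
            spec.spatial[sid].planted_pairs = ()
        spec.condition_effects = {"TB": {}, "Duroc": {}}
        a = simulate_study(spec)
        b = simulate_study(spec)
        assert a.reference == b.reference
        assert set(a.spatial) == {"TB", "Duroc"}
        assert (a.labels == b.labels).all()
        assert a.locations == b.locations
        # per-condition nuclei carry their condition
        assert set(a.conditions) == {"TB", "Duroc"}
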