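"""Compartment grid, GLUT1 region segmentation, zonation call and TIL
pattern cascade."""

import numpy as np
import pandas as pd
import pytest

from mifspatial.cell_io import PanelConfig
from mifspatial.phenotyping import assign_phenotypes, call_positivity
from mifspatial.regions import (
    call_metabolic_zonation,
    classify_compartments,
    classify_til_pattern,
    region_tcell_proportion,
    segment_glut_regions,
)
from mifspatial.synthetic import SimulationConfig, simulate_sample

from conftest import make_table

MARKERS4 = ("SOX10", "CD3", "CD31", "GLUT1")


def _proc(rows, panel):
    t = assign_phenotypes(call_positivity(make_table(rows, panel.markers), panel))
    return classify_compartments(t, panel)


class TestCompartments:
    def test_no_melanoma_all_outside(self, small_panel):
        t, grid = _proc(
            [{"x": 100.0, "y": 100.0, "CD3_intensity": 9.0}], small_panel
        )
        assert (grid.compartment == 0).all()
        assert t.cells["compartment"].tolist() == ["outside"]

    def test_single_melanoma_tumor_disc(self, small_panel):
        t, grid = _proc(
            [{"x": 500.0, "y": 500.0, "SOX10_intensity": 9.0}], small_panel
        )
        tumor = grid.compartment == 1
        assert tumor.any()
        centers = grid.centers()[tumor.ravel()]
        d = np.linalg.norm(centers - [500.0, 500.0], axis=1)
        assert d.max() <= small_panel.tumor_bin_radius_um + 1e-9
        # peritumor band surrounds the tumor bins
        assert (grid.compartment == 2).any()

    def test_compartments_partition_cells(self, sim_sample):
        _, table, _, _ = sim_sample
        counts = table.cells["compartment"].value_counts()
        assert counts.sum() == len(table)
        assert set(counts.index) <= {"tumor", "peritumor", "outside"}

    def test_simulated_nest_melanoma_mostly_tumor(self, sim_sample):
        _, table, _, _ = sim_sample
        mel = table.cells[table.cells["phenotype"] == "melanoma"]
        assert (mel["compartment"] == "tumor").mean() >= 0.95


class TestGlutRegions:
    def _uniform_rows(self, glut: bool):
        rng = np.random.default_rng(3)
        return [
            {"x": float(x), "y": float(y), "SOX10_intensity": 9.0,
             "GLUT1_intensity": 9.0 if glut else 0.1}
            for x, y in rng.uniform(0, 600, size=(300, 2))
        ]

    def test_all_glut1_positive(self, small_panel):
        t, grid = _proc(self._uniform_rows(True), small_panel)
        t, grid = segment_glut_regions(t, grid, small_panel)
        tumor = grid.compartment == 1
        assert (grid.glut[tumor] == 1).all()

    def test_all_glut1_negative(self, small_panel):
        t, grid = _proc(self._uniform_rows(False), small_panel)
        t, grid = segment_glut_regions(t, grid, small_panel)
        tumor = grid.compartment == 1
        assert (grid.glut[tumor] == 2).all()

    def test_half_plane_boundary_recovered(self, small_panel):
        """GLUT1+ melanoma right of x=1000: the recovered region border
        lies within one bin width of the true line."""
        rng = np.random.default_rng(4)
        rows = [
            {"x": float(x), "y": float(y), "SOX10_intensity": 9.0,
             "GLUT1_intensity": 9.0 if x > 1000 else 0.1}
            for x, y in rng.uniform(0, 2000, size=(4000, 2))
        ]
        t, grid = _proc(rows, small_panel)
        t, grid = segment_glut_regions(t, grid, small_panel)
        tumor = grid.compartment == 1
        centers = grid.centers().reshape(grid.ny, grid.nx, 2)
        pos = tumor & (grid.glut == 1)
        neg = tumor & (grid.glut == 2)
        b = small_panel.grid_bin_um
        assert centers[pos][:, 0].min() > 1000 - 2 * b
        assert centers[neg][:, 0].max() < 1000 + 2 * b

    def test_idempotent_and_deterministic(self, small_panel):
        t, grid = _proc(self._uniform_rows(True), small_panel)
        t1, g1 = segment_glut_regions(t, grid, small_panel)
        t2, g2 = segment_glut_regions(t1, g1, small_panel)
        np.testing.assert_array_equal(g1.glut, g2.glut)
        assert t1.cells["region"].tolist() == t2.cells["region"].tolist()

    def test_no_melanoma_in_tumor_bins_rejected(self, small_panel):
        t, grid = _proc(
            [{"x": 0.0, "y": 0.0, "CD3_intensity": 9.0}], small_panel
        )
        with pytest.raises(ValueError, match="QC"):
            segment_glut_regions(t, grid, small_panel)


class TestRegionProportion:
    def test_direct_count_oracle(self, small_panel):
        """Vectorized proportions equal an explicit per-row recount."""
        rng = np.random.default_rng(5)
        rows = [
            {"x": float(x), "y": float(y),
             "SOX10_intensity": 9.0 if rng.uniform() < 0.7 else 0.0,
             "CD3_intensity": 0.0 if rng.uniform() < 0.7 else 9.0,
             "GLUT1_intensity": 9.0 if x > 300 else 0.1}
            for x, y in rng.uniform(0, 600, size=(150, 2))
        ]
        # guarantee some melanoma so segmentation is defined
        rows += [{"x": 10.0 * i, "y": 300.0, "SOX10_intensity": 9.0,
                  "GLUT1_intensity": 9.0 if 10 * i > 300 else 0.1}
                 for i in range(60)]
        t, grid = _proc(rows, small_panel)
        t, grid = segment_glut_regions(t, grid, small_panel)
        rp = region_tcell_proportion(t, grid)
        for label, got in (("glut1_pos", rp.prop_pos), ("glut1_neg", rp.prop_neg)):
            sub = t.cells[t.cells["region"] == label]
            assert got == pytest.approx(
                (sub["phenotype"] == "tcell").sum() / len(sub)
            )

    def test_no_tcells_zero_proportions(self, small_panel):
        rng = np.random.default_rng(6)
        rows = [{"x": float(x), "y": float(y), "SOX10_intensity": 9.0,
                 "GLUT1_intensity": 9.0 if x > 300 else 0.1}
                for x, y in rng.uniform(0, 600, size=(300, 2))]
        t, grid = _proc(rows, small_panel)
        t, grid = segment_glut_regions(t, grid, small_panel)
        rp = region_tcell_proportion(t, grid)
        assert rp.defined
        assert rp.prop_pos == 0.0 and rp.prop_neg == 0.0


class TestZonation:
    def _sample(self, seed, zonal):
        meta, table, _ = simulate_sample(SimulationConfig(seed=seed, zonation=zonal))
        panel = PanelConfig()
        t = assign_phenotypes(call_positivity(table, panel))
        return t, panel

    def test_uniform_positivity_not_zonal(self):
        t, panel = self._sample(31, zonal=False)
        z = call_metabolic_zonation(t, panel)
        assert z.defined and not z.is_zonal

    def test_zonal_generator_called_zonal(self):
        t, panel = self._sample(32, zonal=True)
        z = call_metabolic_zonation(t, panel)
        assert z.defined and z.is_zonal
        assert z.trend >= 0.7 and z.fraction_range >= 0.10

    def test_decreasing_gradient_not_zonal(self, small_panel):
        """Positivity concentrated near vessels must not be called zonal
        (the call requires an increasing trend)."""
        rng = np.random.default_rng(7)
        rows = [{"x": 500.0, "y": 500.0, "CD31_intensity": 9.0}]
        for x, y in rng.uniform(0, 1000, size=(800, 2)):
            d = np.hypot(x - 500.0, y - 500.0)
            rows.append({
                "x": float(x), "y": float(y), "SOX10_intensity": 9.0,
                "GLUT1_intensity": 9.0 if d < 200 else 0.1,
            })
        t = assign_phenotypes(call_positivity(
            make_table(rows, MARKERS4), small_panel))
        z = call_metabolic_zonation(t, small_panel)
        assert z.defined and not z.is_zonal
        assert z.trend < 0

    def test_too_few_melanoma_undefined(self, small_panel):
        t = assign_phenotypes(call_positivity(make_table(
            [{"x": 0.0, "y": 0.0, "SOX10_intensity": 9.0},
             {"x": 5.0, "y": 0.0, "CD31_intensity": 9.0}], MARKERS4
        ), small_panel))
        z = call_metabolic_zonation(t, small_panel)
        assert not z.defined


class TestTilPattern:
    def test_zero_tcells_absent(self, small_panel):
        rng = np.random.default_rng(8)
        rows = [{"x": float(x), "y": float(y), "SOX10_intensity": 9.0}
                for x, y in rng.uniform(0, 600, size=(200, 2))]
        t, grid = _proc(rows, small_panel)
        call = classify_til_pattern(t, grid, small_panel)
        assert call.pattern == 0

    def test_all_tcells_outside_tumor_peritumoral(self, small_panel):
        rng = np.random.default_rng(9)
        rows = [{"x": float(x), "y": float(y), "SOX10_intensity": 9.0}
                for x, y in rng.uniform(0, 400, size=(200, 2))]
        # a dense cuff of T-cells in the band outside the tumor bins
        rows += [{"x": float(x), "y": float(y), "CD3_intensity": 9.0}
                 for x, y in rng.uniform(480, 580, size=(200, 2))]
        t, grid = _proc(rows, small_panel)
        call = classify_til_pattern(t, grid, small_panel)
        assert call.pattern == 1
        assert call.intratumoral_share < 0.2

    @pytest.mark.parametrize("mode,expected", [
        ("absent", 0), ("peritumoral", 1), ("perivascular", 2), ("infiltrative", 3),
    ])
    def test_generator_modes_recovered(self, mode, expected, panel):
        hits = 0
        for seed in range(8):
            meta, table, _ = simulate_sample(
                SimulationConfig(seed=600 + seed, til_pattern=mode))
            t = assign_phenotypes(call_positivity(table, panel))
            t, grid = classify_compartments(t, panel)
            hits += classify_til_pattern(t, grid, panel).pattern == expected
        assert hits >= 6
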