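"""Scene generator: population sampling, emission model, voxelization."""

import numpy as np
import pytest

from opmflow.scene import (PHASE_ORDER, PhaseLabel, ScenePopulation,
                           draw_phase_counts, emission_density,
                           sample_population, voxelize)

from conftest import make_cell


class TestSamplePopulation:
    def test_empty_population(self, geometry):
        pop = sample_population(0, geometry, seed=0)
        assert len(pop) == 0
        assert pop.concentration == 0.0

    def test_negative_n_rejected(self, geometry):
        with pytest.raises(ValueError):
            sample_population(-1, geometry)

    def test_malformed_fractions_rejected(self, geometry):
        with pytest.raises(ValueError):
            sample_population(10, geometry, phase_fractions={"interphase": 0.5})

    def test_degenerate_fractions_all_interphase(self, geometry):
        pop = sample_population(50, geometry,
                                phase_fractions={"interphase": 1.0}, seed=3)
        assert all(c.phase is PhaseLabel.INTERPHASE for c in pop.cells)

    def test_seed_determinism(self, geometry):
        a = sample_population(200, geometry, seed=7)
        b = sample_population(200, geometry, seed=7)
        assert np.array_equal(a.positions, b.positions)
        assert all(x.phase == y.phase and np.array_equal(x.orientation, y.orientation)
                   for x, y in zip(a.cells, b.cells))

    def test_phase_counts_match_replayed_multinomial(self, geometry):
        """Per-phase counts equal an independent multinomial draw replayed
        from the same recorded random stream (with the documented
        odd-telophase parity rule)."""
        n = 10_000
        fractions = {"interphase": 0.95, "prophase": 0.027, "metaphase": 0.008,
                     "anaphase": 0.002, "telophase": 0.013}
        seed = 123
        pop = sample_population(n, geometry, phase_fractions=fractions, seed=seed)
        p = np.array([fractions[ph.value] for ph in PHASE_ORDER])
        expected = draw_phase_counts(np.random.default_rng(seed), n, p)
        observed = np.array([sum(1 for c in pop.cells if c.phase is ph)
                             for ph in PHASE_ORDER])
        assert np.array_equal(observed, expected)

    def test_concentration_consistency(self, geometry):
        pop = sample_population(2000, geometry, seed=1)
        vol_ml = geometry.segment_volume_ml
        assert pop.concentration == pytest.approx(2000 / vol_ml, rel=1e-2)

    def test_positions_respect_channel_interior(self, geometry):
        pop = sample_population(500, geometry, seed=2)
        pos, r = pop.positions, pop.radii
        assert np.all(pos[:, 2] >= r - 1e-9)
        assert np.all(pos[:, 2] <= geometry.height_h - r + 1e-9)
        margin = geometry.side_margin
        assert np.all(pos[:, 0] >= margin)
        assert np.all(pos[:, 0] <= geometry.width_w - margin)

    def test_telophase_cells_form_mutual_pairs(self, geometry):
        pop = sample_population(400, geometry,
                                phase_fractions={"interphase": 0.6, "telophase": 0.4},
                                seed=5)
        telo = {c.id: c for c in pop.cells if c.phase is PhaseLabel.TELOPHASE}
        assert len(telo) % 2 == 0 and len(telo) > 0
        for c in telo.values():
            assert c.partner_id in telo
            assert telo[c.partner_id].partner_id == c.id
        # partner separation ≈ 1.2 × mean diameter
        seps = [np.linalg.norm(c.center - telo[c.partner_id].center)
                for c in telo.values()]
        assert np.allclose(seps, 12.0, atol=1e-6)

    def test_csv_roundtrip(self, tmp_path, geometry):
        pop = sample_population(30, geometry, seed=9)
        pop.save(tmp_path / "pop.csv")
        back = ScenePopulation.load(tmp_path / "pop.csv")
        assert np.allclose(back.positions, pop.positions)
        assert [c.phase for c in back.cells] == [c.phase for c in pop.cells]


def _grid_integral(cell, channel, step=0.15):
    """Midpoint-rule integral of the emission density over the cell support."""
    reach = cell.cell_radius * 2.2
    g = np.arange(-reach, reach, step) + step / 2.0
    X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
    pts = cell.center + np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    return emission_density(cell, pts, channel).sum() * step ** 3


class TestEmissionDensity:
    @pytest.mark.parametrize("phase", list(PhaseLabel))
    @pytest.mark.parametrize("channel", ["cyto", "dna"])
    def test_budget_conservation(self, phase, channel):
        rng = np.random.default_rng(0)
        q = rng.normal(size=4)
        cell = make_cell([0.0, 0.0, 0.0], phase=phase, orientation=q / np.linalg.norm(q))
        est = _grid_integral(cell, channel)
        assert est == pytest.approx(cell.budgets[channel], rel=0.005)

    def test_metaphase_support_is_oblate_ellipsoid(self):
        cell = make_cell([0.0, 0.0, 0.0], phase=PhaseLabel.METAPHASE)
        a = cell.nuclear_radius
        c = 0.35 * a
        # identity orientation: short axis along z
        outside = np.array([[a * 1.05, 0, 0], [0, a * 1.05, 0], [0, 0, c * 1.05],
                            [a * 0.9, a * 0.9, 0]])
        inside = np.array([[a * 0.9, 0, 0], [0, 0, c * 0.9], [0, a * 0.9, 0]])
        assert np.all(emission_density(cell, outside, "dna") == 0)
        assert np.all(emission_density(cell, inside, "dna") > 0)

    def test_anaphase_halves_are_balanced(self):
        rng = np.random.default_rng(4)
        q = rng.normal(size=4)
        cell = make_cell([0.0, 0.0, 0.0], phase=PhaseLabel.ANAPHASE,
                         orientation=q / np.linalg.norm(q))
        axis = cell.spindle_axis
        g = np.arange(-9.0, 9.0, 0.15) + 0.075
        X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        vals = emission_density(cell, pts, "dna")
        side = (pts @ axis) > 0
        up, down = vals[side].sum(), vals[~side].sum()
        assert up == pytest.approx(down, rel=0.01)

    def test_point_outside_bounds_is_zero_not_error(self):
        cell = make_cell([0.0, 0.0, 0.0])
        assert emission_density(cell, [[1e4, 1e4, 1e4]], "dna") == 0

    def test_unknown_channel_rejected(self):
        cell = make_cell([0.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            emission_density(cell, [[0, 0, 0]], "gfp")


class TestVoxelize:
    def test_empty_scene_all_zero(self, geometry):
        scene = ScenePopulation([], geometry, 0.0, 0)
        vol = voxelize(scene, (1.0, 1.0, 1.0), ((0, 20), (0, 20), (0, 20)))
        assert vol.data.sum() == 0

    def test_single_cell_dna_budget_conserved(self, geometry):
        cell = make_cell([10.0, 10.0, 10.0], radius=5.0)
        scene = ScenePopulation([cell], geometry, 0.0, 0)
        vol = voxelize(scene, (0.4, 0.4, 0.4), ((0, 20), (0, 20), (0, 20)),
                       channels=("dna",), supersample=3)
        assert vol.channel("dna").sum() == pytest.approx(cell.budgets["dna"], rel=0.01)

    def test_bbox_outside_channel_rejected(self, geometry):
        scene = ScenePopulation([], geometry, 0.0, 0)
        with pytest.raises(ValueError):
            voxelize(scene, (1, 1, 1), ((0, 10), (0, 10), (-50, 10)))

    def test_metaphase_plate_orientation_recovered(self, geometry):
        """Principal eigenvector of the voxelized metaphase plate aligns with
        the cell's set orientation within 3 degrees."""
        from opmflow.mitotic import principal_axes
        rng = np.random.default_rng(8)
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        cell = make_cell([15.0, 15.0, 15.0], phase=PhaseLabel.METAPHASE,
                         orientation=q)
        scene = ScenePopulation([cell], geometry, 0.0, 0)
        vol = voxelize(scene, (0.3, 0.3, 0.3), ((5, 25), (5, 25), (5, 25)),
                       channels=("dna",), supersample=2)
        img = vol.channel("dna")
        zz, yy, xx = np.nonzero(img > 0)
        coords = np.column_stack([xx, yy, zz]) * 0.3 + np.array([5, 5, 5]) + 0.15
        region = principal_axes(coords, img[zz, yy, xx])
        short_axis = region.eigvecs[:, 2]
        cos = abs(float(short_axis @ cell.spindle_axis))
        assert np.degrees(np.arccos(min(cos, 1.0))) < 3.0
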