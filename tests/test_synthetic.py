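"""Generators: area preservation, ground truth, and reproducibility."""

import numpy as np
import pytest

from tubekin import geometry as g
from tubekin.synthetic import (
    CellFieldSpec,
    Constriction,
    ConstrictingTubeFlow,
    PulseSpec,
    TubeSpec,
    make_calcium_movie,
    make_cell_tessellation,
    make_constricting_tube,
    make_fold_outcomes,
    make_nuclei_pairs,
    make_sphere_sequence,
)


def material_cell_areas(surface):
    """Areas of the quad lattice cells (triangle pairs) of a generated tube."""
    fa = g.face_areas(surface.vertices, surface.faces)
    return fa[::2] + fa[1::2]


class TestConstrictingTube:
    def test_static_cylinder_is_rigid_with_zero_fields(self):
        spec = TubeSpec(R0=25.0, L0=150.0, constrictions=[], n_s=32, n_phi=16, n_t=5)
        seq, fields, _ = make_constricting_tube(spec)
        for k in range(1, len(seq)):
            assert np.allclose(seq[k].vertices, seq[0].vertices, atol=1e-9)
        assert np.abs(fields.vn).max() < 1e-9
        assert np.abs(fields.div).max() < 1e-9
        assert np.abs(fields.residual).max() < 1e-9
        # H is the cylinder value, not zero
        assert np.allclose(fields.H, 1.0 / 50.0, atol=1e-9)

    def test_deep_constriction_preserves_material_cell_areas(self, tube_seq):
        # depth ramps to 0.6*R0; per-material-cell area drift stays <= 1e-3
        seq, _, _ = tube_seq
        a0 = material_cell_areas(seq[0])
        for k in (5, 12, len(seq) - 1):
            drift = np.abs(material_cell_areas(seq[k]) / a0 - 1.0)
            assert drift.max() <= 1e-3

    def test_vertex_count_and_connectivity_constant(self, tube_seq):
        seq, _, _ = tube_seq
        for surf in seq.surfaces:
            assert surf.n_vertices == seq[0].n_vertices
            assert np.array_equal(surf.faces, seq[0].faces)

    def test_analytic_fields_satisfy_incompressibility_identity(self, tube_seq):
        _, fields, _ = tube_seq
        assert np.abs(fields.div - 2.0 * fields.H * fields.vn).max() < 1e-12

    def test_analytic_divergence_against_flux_oracle(self, tube_seq):
        # independent (1/r) d(r v_s)/dl quadrature oracle vs the
        # area-conservation construction
        _, _, flow = tube_seq
        u = np.linspace(10.0, 190.0, 400)
        for t in (5.0, 15.0):
            _, _, div = flow.analytic_fields(t, u)
            oracle = flow.divergence_by_flux(t, u)
            scale = np.abs(div).max()
            assert np.abs(div - oracle)[20:-20].max() < 0.05 * scale

    def test_neck_closure_fails_naming_timestep(self):
        # two overlapping constrictions jointly exceed R0
        spec = TubeSpec(
            R0=30.0,
            L0=200.0,
            constrictions=[
                Constriction(95.0, 20.0, 15.0),
                Constriction(105.0, 20.0, 15.0),
            ],
            n_s=32,
            n_phi=16,
            n_t=20,
        )
        with pytest.raises(RuntimeError, match="timestep"):
            make_constricting_tube(spec)

    def test_depth_invariant_enforced(self):
        with pytest.raises(ValueError, match="depth"):
            TubeSpec(constrictions=[Constriction(100.0, 35.0, 10.0)])

    def test_mesh_resolution_invariant_enforced(self):
        with pytest.raises(ValueError, match="resolution"):
            TubeSpec(n_s=8)

    def test_analytic_fields_consistent_under_refinement(self):
        # analytic fields are a property of the flow, not the mesh: doubling
        # the resolution reproduces them at shared marker labels
        kw = dict(
            R0=30.0,
            L0=200.0,
            constrictions=[Constriction(100.0, 15.0, 12.0)],
            n_phi=16,
            n_t=6,
        )
        u = np.linspace(20.0, 180.0, 50)
        coarse = ConstrictingTubeFlow(TubeSpec(n_s=32, **kw))
        fine = ConstrictingTubeFlow(TubeSpec(n_s=64, **kw))
        for t in (2.0, 5.0):
            Hc, vnc, dc = coarse.analytic_fields(t, u)
            Hf, vnf, df = fine.analytic_fields(t, u)
            assert np.allclose(Hc, Hf, rtol=1e-6, atol=1e-12)
            assert np.allclose(vnc, vnf, rtol=1e-6, atol=1e-12)
            assert np.allclose(dc, df, rtol=1e-6, atol=1e-12)

    def test_byte_reproducible(self):
        spec = TubeSpec(
            R0=30.0,
            L0=200.0,
            constrictions=[Constriction(100.0, 12.0, 15.0)],
            n_s=32,
            n_phi=16,
            n_t=5,
            seed=42,
        )
        a, _, _ = make_constricting_tube(spec)
        b, _, _ = make_constricting_tube(spec)
        for sa, sb in zip(a.surfaces, b.surfaces):
            assert sa.vertices.tobytes() == sb.vertices.tobytes()


class TestSphereSequence:
    def test_static_sphere_zero_velocity_and_volume(self, sphere_static):
        seq, fields = sphere_static
        assert np.abs(fields.velocity).max() < 1e-9
        assert g.enclosed_volume(seq[0]) == pytest.approx(4188.79, rel=0.01)

    def test_shrinking_sphere_residual_closed_form(self, shrinking_sphere):
        seq, fields = shrinking_sphere
        for k, t in enumerate(seq.times):
            R = 10.0 * (1.0 - 0.01 * t)
            assert np.allclose(fields.residual[k], -2.0 * 0.1 / R, rtol=1e-3)
            assert np.abs(fields.div[k]).max() == 0.0

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            make_sphere_sequence(lambda t: 1.0 - t, n_t=3, dt=1.0)


class TestCellTessellation:
    def test_isotropic_profile_yields_near_unit_aspect(self, cylinder_surface):
        from tubekin.cells import measure_cells, weighted_mean_aspect

        spec = CellFieldSpec(n_cells=400, aspect_profile=1.0, jitter=0.02, seed=3)
        recs = measure_cells(make_cell_tessellation(spec, cylinder_surface), cylinder_surface)
        assert weighted_mean_aspect(recs) == pytest.approx(1.0, abs=0.05)

    def test_circumferential_population_exceeds_two(self, measured_circumferential):
        from tubekin.cells import weighted_mean_aspect

        assert weighted_mean_aspect(measured_circumferential) > 2.0

    def test_realized_aspect_within_ten_percent_of_target(
        self, measured_circumferential
    ):
        from tubekin.cells import weighted_mean_aspect

        assert weighted_mean_aspect(measured_circumferential) == pytest.approx(
            2.5, rel=0.10
        )

    def test_two_population_profile_recovered(self, cylinder_surface):
        from tubekin.cells import measure_cells, weighted_mean_aspect

        prof = lambda s: 1.0 + 1.5 * np.exp(-((np.asarray(s) - 100.0) ** 2) / (2 * 30.0**2))
        spec = CellFieldSpec(n_cells=600, aspect_profile=prof, jitter=0.08, seed=5)
        recs = measure_cells(make_cell_tessellation(spec, cylinder_surface), cylinder_surface)
        near = [r for r in recs if abs(r.s - 100.0) < 25.0]
        far = [r for r in recs if abs(r.s - 100.0) > 60.0]
        assert weighted_mean_aspect(near) > weighted_mean_aspect(far) + 0.5

    def test_polygons_simple_and_non_overlapping(self, circumferential_cells):
        import shapely.geometry as sgeom

        polys = [sgeom.Polygon(c.polygon_chart) for c in circumferential_cells]
        assert all(p.is_valid and p.is_simple for p in polys)
        # pairwise overlap of a Voronoi partition is boundary-only
        rng = np.random.default_rng(0)
        idx = rng.choice(len(polys), 40, replace=False)
        for i in idx:
            for j in idx:
                if i < j:
                    inter = polys[i].intersection(polys[j]).area
                    assert inter < 1e-6 * max(polys[i].area, polys[j].area)

    def test_too_many_cells_rejected(self, cylinder_surface):
        spec = CellFieldSpec(n_cells=1000, mean_area=100.0, seed=0)
        with pytest.raises(ValueError, match="exceeds"):
            make_cell_tessellation(spec, cylinder_surface)

    def test_seeded_reproducibility(self, cylinder_surface):
        spec = CellFieldSpec(n_cells=200, aspect_profile=2.0, jitter=0.1, seed=9)
        a = make_cell_tessellation(spec, cylinder_surface)
        b = make_cell_tessellation(spec, cylinder_surface)
        assert len(a) == len(b)
        for ca, cb in zip(a, b):
            assert ca.polygon_chart.tobytes() == cb.polygon_chart.tobytes()


class TestNucleiPairs:
    def test_zero_drift_separation_stationary(self):
        df = make_nuclei_pairs(20, 0.0, 30.0, seed=1)
        from tubekin.cells import nuclei_pair_motion

        out = nuclei_pair_motion(df)
        assert abs(out["rate_um_per_h"]) < 0.2

    def test_initial_separation_below_pairing_threshold(self):
        df = make_nuclei_pairs(40, 5.0, 60.0, seed=2)
        t0 = df[df["t"] == 0.0]
        for pid, grp in t0.groupby("pair_id"):
            xyz = grp.sort_values("layer")[["x", "y", "z"]].to_numpy()
            assert np.linalg.norm(xyz[0] - xyz[1]) < 5.0

    def test_drift_rate_recovered(self):
        from tubekin.cells import nuclei_pair_motion

        df = make_nuclei_pairs(81, 5.0, 60.0, seed=11, noise_sd=0.3)
        out = nuclei_pair_motion(df)
        assert out["rate_um_per_h"] == pytest.approx(5.0, abs=0.5)


class TestCalciumMovie:
    def test_zero_amplitude_is_background_plus_noise(self):
        spec = PulseSpec(
            frame_shape=(16, 32), n_frames=12, amplitude=0.0,
            background_level=20.0, noise_sd=0.0, seed=1,
        )
        stack, truth = make_calcium_movie(spec)
        assert np.allclose(stack.frames, 20.0)

    def test_pulse_duration_and_truth_table(self):
        spec = PulseSpec(
            frame_shape=(24, 64), n_frames=30, pulse_rate=3.0,
            amplitude=50.0, duration=1, noise_sd=0.0, seed=4,
        )
        stack, truth = make_calcium_movie(spec)
        assert (truth["frame"] >= 0).all() and (truth["frame"] < 30).all()
        # a pulse of duration 1 leaves no residue two frames later
        if len(truth):
            f = int(truth.iloc[0]["frame"])
            if f + 2 < 30:
                x = int(round(truth.iloc[0]["ap_px"]))
                y = int(round(truth.iloc[0]["circ_px"]))
                y = min(max(y, 0), 23)
                x = min(max(x, 0), 63)
                later = stack.frames[f + 2, y, x]
                others = truth[(truth.frame <= f + 2) & (truth.frame >= f + 1)]
                if others.empty:
                    assert later < 20.0 + 1e-9 + 50.0 * 0.05

    def test_seeded_reproducibility(self):
        spec = PulseSpec(seed=7)
        a, ta = make_calcium_movie(spec)
        b, tb = make_calcium_movie(spec)
        assert a.frames.tobytes() == b.frames.tobytes()
        assert ta.equals(tb)

    def test_triplet_interval_invariant(self):
        with pytest.raises(ValueError, match="triplet_interval"):
            PulseSpec(triplet_interval=20.0)


class TestFoldOutcomes:
    def test_certain_success_gives_zero_se(self):
        from tubekin.stats import proportion_se

        df = make_fold_outcomes(1.0, 50, seed=0)
        p_hat = float(df["success"].mean())
        assert p_hat == 1.0
        assert proportion_se(p_hat, 50) == 0.0

    def test_counts_in_range_and_success_consistent(self):
        df = make_fold_outcomes(0.5, 130, seed=3)
        assert df["folds"].between(0, 3).all()
        assert (df["success"] == (df["folds"] == 3)).all()
        assert len(df) == 130

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            make_fold_outcomes(1.5, 10, seed=0)
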