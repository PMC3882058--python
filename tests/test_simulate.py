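"""Synthetic-data generators: walk model, image rendering, plate counts."""

import numpy as np
import pytest

import chemoscreen as cs
from chemoscreen.config import ConfigurationError


class TestSimulateTracks:
    def test_fully_biased_walk_moves_purely_upward(self):
        tracks = cs.simulate_tracks(
            cs.SimConfig(seed=1, n_cells=10, bias=1.0, persistence=0.0)
        )
        for t in tracks:
            assert np.allclose(np.diff(t.x), 0.0)
            assert np.all(np.diff(t.y) >= 0.0)
            assert cs.upward_directionality(t) == pytest.approx(1.0)

    def test_zero_motility_keeps_cells_at_start(self):
        tracks = cs.simulate_tracks(
            cs.SimConfig(seed=2, n_cells=10, motility_factor=0.0)
        )
        for t in tracks:
            assert cs.path_length(t) == 0.0
            assert np.allclose(t.x, t.x[0]) and np.allclose(t.y, t.y[0])

    def test_unbiased_walk_has_no_mean_upward_drift(self):
        tracks = cs.simulate_tracks(cs.SimConfig(seed=3, n_cells=200, bias=0.0))
        values = np.array([cs.upward_directionality(t) for t in tracks])
        se = values.std(ddof=1) / np.sqrt(values.size)
        assert abs(values.mean()) < 3.0 * se

    def test_shapes_and_channel_confinement(self):
        config = cs.SimConfig(seed=4, n_cells=50, n_frames=25, channel_width=100.0)
        tracks = cs.simulate_tracks(config)
        assert len(tracks) == 50
        for t in tracks:
            assert len(t) == 25
            assert np.all((t.x >= 0.0) & (t.x <= 100.0))
            assert t.y[0] == 0.0

    def test_identical_seed_is_bit_reproducible_and_seeds_differ(self):
        config = cs.SimConfig(seed=5, n_cells=20)
        a = cs.simulate_tracks(config)
        b = cs.simulate_tracks(config)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.x, tb.x)
            np.testing.assert_array_equal(ta.y, tb.y)
        c = cs.simulate_tracks(cs.SimConfig(seed=6, n_cells=20))
        assert not np.array_equal(a[0].x, c[0].x)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"bias": 1.5},
            {"bias": -0.1},
            {"persistence": 1.0},
            {"dt": 0.0},
            {"n_frames": 1},
            {"motility_factor": 2.0},
            {"step_scale": float("nan")},
        ],
    )
    def test_out_of_range_parameters_raise_configuration_error(self, kwargs):
        with pytest.raises(ConfigurationError):
            cs.SimConfig(seed=0, n_cells=5, **kwargs)


class TestRenderStack:
    def test_static_cell_peak_sits_at_its_centre(self):
        track = cs.Track(0, np.arange(5), np.full(5, 20.0), np.full(5, 30.0))
        stack, truth = cs.render_stack(
            [track], cs.CellImageSpec(radius=4.0), shape=(64, 64)
        )
        assert stack.shape[0] == 5
        for frame in stack:
            row, col = np.unravel_index(np.argmax(frame), frame.shape)
            assert (col, row) == (20, 30)
        assert (truth[["x_px", "y_px"]].to_numpy() == [20.0, 30.0]).all()

    def test_two_distant_cells_give_two_components(self):
        # oracle: direct pixel count on the rendered array
        radius = 4.0
        t1 = cs.Track(0, np.arange(3), np.full(3, 15.0), np.full(3, 20.0))
        t2 = cs.Track(1, np.arange(3), np.full(3, 45.0), np.full(3, 20.0))  # 30 px > 4*radius
        spec = cs.CellImageSpec(radius=radius, peak_intensity=100.0, background=10.0)
        stack, _ = cs.render_stack([t1, t2], spec, shape=(48, 64))
        from skimage import measure

        midway = (100.0 + 10.0) / 2.0
        for frame in stack:
            labels = measure.label(frame > midway)
            assert labels.max() == 2

    def test_empty_track_set_renders_pure_background(self):
        spec = cs.CellImageSpec(background=7.0, peak_intensity=50.0)
        stack, truth = cs.render_stack([], spec, shape=(32, 32))
        assert np.all(stack == 7.0)
        assert truth.empty

    def test_out_of_bounds_cells_raise_listing_track_ids(self):
        inside = cs.Track("ok", np.arange(2), [10.0, 10.0], [10.0, 10.0])
        outside = cs.Track("bad", np.arange(2), [10.0, 500.0], [10.0, 10.0])
        with pytest.raises(ValueError, match="bad"):
            cs.render_stack([inside, outside], shape=(64, 64))

    def test_rendering_is_deterministic_given_seed(self):
        tracks = cs.simulate_tracks(cs.SimConfig(seed=8, n_cells=5))
        spec = cs.CellImageSpec(radius=4.0, noise_sd=2.0)
        a, _ = cs.render_stack(tracks, spec, seed=9)
        b, _ = cs.render_stack(tracks, spec, seed=9)
        np.testing.assert_array_equal(a, b)


class TestRenderPolarizedCell:
    def test_unpolarized_cell_is_reflection_symmetric(self):
        spec = cs.CellImageSpec(radius=10.0, polarity_ratio=1.0, orientation=np.pi / 2)
        image, _ = cs.render_polarized_cell(spec)
        np.testing.assert_allclose(image, image[::-1, :], atol=1e-12)

    def test_leading_to_trailing_ratio_tracks_polarity_ratio(self):
        spec = cs.CellImageSpec(radius=12.0, polarity_ratio=10.0, orientation=0.0)
        image, line = cs.render_polarized_cell(spec)
        profile = cs.extract_profile(image, line)
        a, b, _ = cs.section_means(profile)
        assert a / b == pytest.approx(10.0, rel=0.05)

    def test_rotating_orientation_by_pi_swaps_sections(self):
        # same transection line, cell polarity reversed: a and b swap
        fwd = cs.CellImageSpec(radius=10.0, polarity_ratio=6.0, orientation=0.3)
        rev = cs.CellImageSpec(radius=10.0, polarity_ratio=6.0,
                               orientation=0.3 + np.pi)
        img_f, line_f = cs.render_polarized_cell(fwd)
        img_r, _ = cs.render_polarized_cell(rev)
        a_f, b_f, _ = cs.section_means(cs.extract_profile(img_f, line_f))
        a_r, b_r, _ = cs.section_means(cs.extract_profile(img_r, line_f))
        assert a_f == pytest.approx(b_r, rel=1e-6)
        assert b_f == pytest.approx(a_r, rel=1e-6)

    def test_each_cells_own_line_always_runs_trailing_to_leading(self):
        # the ground-truth line flips with the orientation, so sections
        # measured along it are orientation-independent
        for theta in (0.3, 0.3 + np.pi):
            spec = cs.CellImageSpec(radius=10.0, polarity_ratio=6.0,
                                    orientation=theta)
            image, line = cs.render_polarized_cell(spec)
            a, b, _ = cs.section_means(cs.extract_profile(image, line))
            assert a > b

    def test_polarity_ratio_below_one_is_rejected(self):
        with pytest.raises(ConfigurationError, match="orientation"):
            cs.CellImageSpec(polarity_ratio=0.5)

    def test_ground_truth_line_spans_the_cell(self):
        spec = cs.CellImageSpec(radius=8.0, orientation=0.0)
        _, ((x0, y0), (x1, y1)) = cs.render_polarized_cell(spec)
        assert x1 - x0 == pytest.approx(16.0)
        assert y0 == y1


class TestSimulatePlate:
    def test_full_inhibition_zeroes_inhibitor_wells(self):
        spec = cs.PlateSpec(
            n_wells=20, seed=1, inhibitor_wells=frozenset({10, 11}),
            inhibitor_effect=0.0,
        )
        plate = cs.simulate_plate(spec)
        inhibited = plate[plate["well"].isin(["W0011", "W0012"])]
        assert (inhibited["count"] == 0).all()

    def test_inert_wells_average_the_control_mean(self):
        spec = cs.PlateSpec(n_wells=400, seed=2, control_mean=10.0,
                            larvae_per_well=3)
        counts = cs.simulate_plate(spec)["count"].to_numpy()
        se = counts.std(ddof=1) / np.sqrt(counts.size)
        assert abs(counts.mean() - 10.0) < 3.0 * se

    def test_zero_wells_gives_empty_table(self):
        plate = cs.simulate_plate(cs.PlateSpec(n_wells=0, seed=3))
        assert plate.empty
        assert list(plate.columns) == ["well", "condition", "replicate", "count"]

    def test_layout_and_determinism(self):
        spec = cs.PlateSpec(n_wells=12, seed=4, n_vehicle_wells=2,
                            larvae_per_well=3)
        plate = cs.simulate_plate(spec)
        assert len(plate) == 36
        assert set(plate.loc[plate["condition"] == "vehicle", "well"]) == {
            "W0001", "W0002"
        }
        again = cs.simulate_plate(spec)
        assert plate.equals(again)

    def test_inhibitor_wells_must_be_extract_wells(self):
        with pytest.raises(ConfigurationError):
            cs.PlateSpec(n_wells=12, inhibitor_wells=frozenset({0}),
                         n_vehicle_wells=2)

    def test_overdispersed_counts_have_inflated_variance(self):
        base = dict(n_wells=2000, control_mean=10.0, larvae_per_well=3,
                    n_vehicle_wells=0)
        poisson = cs.simulate_plate(cs.PlateSpec(seed=5, dispersion=1.0, **base))
        nb = cs.simulate_plate(cs.PlateSpec(seed=5, dispersion=3.0, **base))
        assert nb["count"].var() > 2.0 * poisson["count"].var()


class TestSimulateScreen:
    def test_truth_map_marks_exactly_the_planted_inhibitors(self):
        table, truth = cs.simulate_screen(n_extracts=100, n_inhibitors=3, seed=6)
        planted = [c for c, eff in truth.items() if eff < 1.0]
        assert len(planted) == 3
        assert len(truth) == 100
        assert set(table["condition"]) == set(truth) | {"vehicle"}

    def test_confirmation_plates_carry_candidates_and_vehicle(self):
        plates = cs.simulate_confirmation_plates(
            ["extract_0001", "extract_0002"], {"extract_0001": 0.0},
            n_replicates=3, seed=7,
        )
        assert len(plates) == 3
        for plate in plates:
            conditions = set(plate["condition"])
            assert conditions == {"vehicle", "extract_0001", "extract_0002"}
            assert (plate.loc[plate["condition"] == "extract_0001", "count"] == 0).all()
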