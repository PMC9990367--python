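import numpy as np
import pytest

from fretflux.cohort import CohortSpec, GroupSpec, generate_cohort
from fretflux.kinetics import ConcentrationSeries, KineticParams
from fretflux.protocols import get_protocol
from fretflux.render import EllipseCell, NoiseModel, ScenePhantom, render_movie
from fretflux.sensors import LACONIC


class TestRenderMovie:
    def test_noiseless_single_cell_ratio_exact(self, noiseless_movie, single_cell_scene):
        cell_mask = single_cell_scene.foreground_mask()
        expected = LACONIC.forward(1.0)
        for i in range(noiseless_movie.n_frames):
            num = noiseless_movie.numerator[i][cell_mask].mean()
            den = noiseless_movie.denominator[i][cell_mask].mean()
            assert abs(num / den - expected) < 1e-9

    def test_same_seed_bitwise_identical(self, constant_series, single_cell_scene):
        nm = NoiseModel(seed=42, drift_sd=0.5)
        a = render_movie(constant_series, LACONIC, single_cell_scene, nm, 2.0)
        b = render_movie(constant_series, LACONIC, single_cell_scene, nm, 2.0)
        assert np.array_equal(a.numerator, b.numerator)
        assert np.array_equal(a.denominator, b.denominator)
        assert np.array_equal(a.metadata["drift_truth"], b.metadata["drift_truth"])

    def test_series_too_short_rejected(self, single_cell_scene):
        t = np.arange(0.0, 5.0, 1.0)
        short = ConcentrationSeries(t=t, lac_in=np.ones_like(t), glc_in=np.ones_like(t))
        with pytest.raises(ValueError, match="duration"):
            render_movie(short, LACONIC, single_cell_scene, NoiseModel.none(), 10.0,
                         duration=60.0)

    def test_cells_outside_frame_rejected(self):
        with pytest.raises(ValueError, match="inside the frame"):
            ScenePhantom(shape=(32, 32), cells=(EllipseCell(2.0, 2.0, 5.0, 5.0, 100.0),))

    def test_mosaic_frame_ratio_is_brightness_weighted_mixture(self):
        """One knockout and one wild-type cell of equal brightness: the
        whole-frame ratio is the midpoint of the two sensor ratios."""
        t = np.arange(0.0, 11.0, 1.0)
        ko = ConcentrationSeries(t=t, lac_in=np.full_like(t, 4.0), glc_in=np.ones_like(t))
        wt = ConcentrationSeries(t=t, lac_in=np.full_like(t, 0.5), glc_in=np.ones_like(t))
        scene = ScenePhantom(
            shape=(64, 64),
            cells=(
                EllipseCell(20.0, 20.0, 5.0, 5.0, 100.0, knockout=True),
                EllipseCell(44.0, 44.0, 5.0, 5.0, 100.0, knockout=False),
            ),
            background=2.0,
        )
        movie = render_movie(ko, LACONIC, scene, NoiseModel.none(), 1.0, control_series=wt)
        from fretflux.pipeline import process_movie

        trace, _, _ = process_movie(movie, window=1)
        r_ko, r_wt = LACONIC.forward(4.0), LACONIC.forward(0.5)
        # both cells have the same pixel count and brightness by symmetry
        assert trace.r[0] == pytest.approx((r_ko + r_wt) / 2, rel=1e-3)


class TestGenerateCohort:
    def test_counts_and_schema(self, mct_block):
        spec = CohortSpec(groups=(GroupSpec("a", 2, 2), GroupSpec("b", 2, 2)), seed=1)
        cohort = generate_cohort(spec, mct_block, LACONIC)
        assert len(cohort) == 8
        assert len(cohort.truth) == 8
        assert set(cohort.truth["group"]) == {"a", "b"}
        assert cohort.truth["stack_id"].is_unique

    def test_seeded_determinism(self, mct_block):
        spec = CohortSpec(groups=(GroupSpec("a", 2, 2),), seed=9)
        c1 = generate_cohort(spec, mct_block, LACONIC)
        c2 = generate_cohort(spec, mct_block, LACONIC)
        assert c1.truth.equals(c2.truth)
        for r1, r2 in zip(c1.records, c2.records):
            assert np.array_equal(r1.trace.r, r2.trace.r)

    def test_zero_mice_rejected(self):
        with pytest.raises(ValueError):
            GroupSpec("a", 0, 2)
        with pytest.raises(ValueError):
            GroupSpec("a", 2, 0)

    def test_degenerate_mosaic_uses_control_kinetics(self, mct_block):
        """mosaic_fraction = 0: every cell is wild type, so the trace is
        driven entirely by the control parameter series despite the
        group's knockout overrides."""
        spec = CohortSpec(
            groups=(
                GroupSpec("ko", 2, 2, {"lac_prod_frac": 2.0, "mct_vmax": 0.1},
                          mosaic_fraction=0.0),
            ),
            seed=3,
        )
        cohort = generate_cohort(spec, mct_block, LACONIC, trace_noise_sd=0.0)
        for rec in cohort.records:
            assert rec.ko_weight == 0.0
            # the rendered ratio equals the wild-type series through the sensor
            expected = LACONIC.forward(
                np.interp(rec.trace.t, rec.control_series.t, rec.control_series.lac_in)
            )
            from fretflux.pipeline import temporal_smooth

            assert np.allclose(rec.trace.r, temporal_smooth(expected, 11), atol=1e-12)

    def test_mosaic_knockout_count_is_seeded_binomial(self, mct_block):
        spec = CohortSpec(
            groups=(GroupSpec("ko", 5, 4, {"lac_prod_frac": 1.5}, mosaic_fraction=0.6),),
            seed=21,
        )
        cohort = generate_cohort(spec, mct_block, LACONIC, n_cells=50)
        counts = cohort.truth["n_knockout"].to_numpy()
        assert counts.min() >= 0 and counts.max() <= 50
        # with p = 0.6 and n = 50 the mean count concentrates near 30
        assert abs(counts.mean() - 30.0) < 4.0

    def test_rendered_cohort_produces_movies(self, mct_block):
        prot = get_protocol("mct_block", duration=150.0)
        spec = CohortSpec(groups=(GroupSpec("a", 1, 1),), seed=5)
        cohort = generate_cohort(
            spec, prot, LACONIC, render=True, frame_rate=1.0,
            n_cells=5, scene_shape=(64, 64),
        )
        movie = cohort.records[0].movie
        assert movie is not None
        assert movie.n_frames == 151
        assert movie.metadata["protocol"] == "mct_block"

    def test_duplicate_group_names_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            CohortSpec(groups=(GroupSpec("a", 1, 1), GroupSpec("a", 1, 1)))
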