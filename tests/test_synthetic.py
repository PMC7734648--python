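"""Synthetic-data generators: determinism, ground truth, planted structure."""

import numpy as np
import pytest
from scipy import stats

from necroptodyn import kinetics as kn
from necroptodyn.synthetic import (
    CountLaw,
    FishSceneSpec,
    MixtureSpec,
    SceneSpec,
    make_death_time_samples,
    make_fish_images,
    make_movie,
    make_trace_fixtures,
)

BIMODAL = MixtureSpec((0.5, 0.5), (6.0, 18.0), (1.5, 1.5))


class TestDeathTimeSamples:
    def test_unimodal_and_bimodal_samples(self):
        uni = make_death_time_samples(MixtureSpec((1.0,), (8.0,), (2.0,)), 300, seed=0)
        bi = make_death_time_samples(MixtureSpec((0.5, 0.5), (4.0, 16.0), (1.0, 1.0)), 300, seed=0)
        assert kn.dip_test(uni.times, n_boot=1000, seed=1).p_unimodal > 0.05
        assert kn.dip_test(bi.times, n_boot=1000, seed=1).p_unimodal < 0.05

    def test_seed_determinism(self):
        a = make_death_time_samples(BIMODAL, 100, seed=5).times
        b = make_death_time_samples(BIMODAL, 100, seed=5).times
        assert np.array_equal(a, b)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            MixtureSpec((0.5, 0.6), (1.0, 2.0), (0.1, 0.1))


class TestTraceFixtures:
    def test_planted_step_crosses_threshold_at_death_frame(self):
        spec = SceneSpec(n_cells=20, duration_hours=4.0, death_time_law=BIMODAL,
                         noise_sigma=0.0, seed=1,
                         frame_interval_min=1.5)
        spec = SceneSpec(n_cells=20, duration_hours=24.0, death_time_law=BIMODAL,
                         noise_sigma=0.0, seed=1)
        traces, gt = make_trace_fixtures(spec)
        thr = gt.recommended_threshold
        for i, f in enumerate(gt.death_frames):
            if f < 0:
                assert np.all(traces[i] <= thr)
            else:
                assert np.all(traces[i, :f] <= thr)
                assert np.all(traces[i, f:] > thr)

    def test_noise_runs_capped_below_persistence_rule(self):
        """Even with heavy noise, pre-death above-threshold runs are <= 5
        frames, so a 6-frame persistence rule never fires early."""
        spec = SceneSpec(n_cells=30, duration_hours=24.0, death_time_law="none",
                         noise_sigma=400.0, pi_step_amplitude=600.0, seed=2)
        traces, gt = make_trace_fixtures(spec)
        _, table = kn.call_deaths(traces, threshold=gt.recommended_threshold, min_run=6)
        assert table.data["censored"].all()

    def test_exact_recovery_with_noise(self):
        spec = SceneSpec(n_cells=50, duration_hours=24.0, death_time_law=BIMODAL,
                         noise_sigma=30.0, seed=3)
        traces, gt = make_trace_fixtures(spec)
        _, table = kn.call_deaths(traces, threshold=gt.recommended_threshold, min_run=6)
        rec = table.data["death_frame"].to_numpy()
        assert np.array_equal(rec, gt.death_frames)

    def test_determinism(self):
        spec = SceneSpec(n_cells=10, death_time_law=BIMODAL, seed=9)
        a, _ = make_trace_fixtures(spec)
        b, _ = make_trace_fixtures(spec)
        assert np.array_equal(a, b)


class TestMovie:
    def test_empty_scene(self):
        movie, gt = make_movie(SceneSpec(n_cells=0, field_size=64, duration_hours=0.1,
                                         frame_interval_min=1.5))
        assert gt.death_frames.size == 0
        assert movie.nuclear.shape[1:] == (64, 64)

    def test_static_censored_scene(self):
        spec = SceneSpec(n_cells=20, field_size=256, duration_hours=0.5,
                         motion_sigma=0.0, death_time_law="none", seed=0)
        movie, gt = make_movie(spec)
        assert np.all(gt.death_frames == -1)
        # static: centroids identical across frames
        assert np.allclose(gt.centroids[0], gt.centroids[-1])

    def test_inclusive_endpoint_grid(self):
        spec = SceneSpec(n_cells=1, field_size=64, duration_hours=24.0, frame_interval_min=1.5)
        assert spec.n_frames == 961

    def test_packing_limit_error_names_limit(self):
        with pytest.raises(ValueError, match="packing limit"):
            make_movie(SceneSpec(n_cells=5000, field_size=128, duration_hours=0.05))

    def test_planted_death_histogram_matches_direct_sampling(self):
        """Planted death times reproduce the mixture within sampling error.

        Planting (shared by movies and trace fixtures) rounds mixture draws
        to the frame grid and censors beyond the observation window; the
        same transformation is applied to an independent direct sample
        before comparing binned counts.
        """
        spec = SceneSpec(n_cells=300, duration_hours=24.0, death_time_law=BIMODAL, seed=11)
        _, gt = make_trace_fixtures(spec)
        planted = gt.death_times_hours[np.isfinite(gt.death_times_hours)]
        direct = make_death_time_samples(BIMODAL, 3000, seed=123).times
        dt_h = spec.frame_interval_min / 60.0
        direct = np.round(direct / dt_h) * dt_h
        direct = direct[(direct >= 0) & (direct <= spec.duration_hours)]
        bins = np.arange(0.0, 24.1, 2.0)
        obs = np.histogram(planted, bins=bins)[0]
        ref = np.histogram(direct, bins=bins)[0]
        _, p, _, _ = stats.chi2_contingency(np.vstack([obs + 1, ref + 1]))
        assert p > 0.01

    def test_divisions_spawn_daughters(self):
        spec = SceneSpec(n_cells=30, field_size=512, duration_hours=2.0,
                         division_rate=0.5, seed=4)
        _, gt = make_movie(spec)
        daughters = gt.parents >= 0
        assert daughters.sum() == len(gt.division_times_hours)
        assert daughters.sum() > 0
        assert np.all(gt.birth_frames[daughters] > 0)


class TestFishImages:
    def test_responder_fraction_binomial(self):
        spec = FishSceneSpec(n_cells=500, field_size=1536, seed=0)
        _, gt = make_fish_images(spec)
        se = np.sqrt(0.76 * 0.24 / 500)
        assert abs(gt.responder.mean() - 0.76) < 4 * se

    def test_background_only_channel(self):
        laws = {
            "A20": {"responder": CountLaw("constant", 0.0), "nonresponder": CountLaw("constant", 0.0)},
        }
        spec = FishSceneSpec(n_cells=10, field_size=256, responder_fraction=1.0,
                             count_laws=laws, noise_sigma=0.0, seed=1)
        imgs, gt = make_fish_images(spec)
        assert len(gt.spots) == 0
        assert np.all(imgs.transcripts["A20"] == spec.background)

    def test_noiseless_planted_spots_are_local_maxima(self):
        """Without noise, detected maxima equal the analytically expected
        count: planted spots, merged where two Gaussians are closer than
        twice the PSF sigma (the exact one-maximum criterion for equal
        amplitudes)."""
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial import cKDTree

        from necroptodyn.smfish import detect_spots, dog_filter

        laws = {"A20": {"responder": CountLaw("constant", 4.0), "nonresponder": CountLaw("constant", 4.0)}}
        spec = FishSceneSpec(n_cells=10, field_size=512, count_laws=laws,
                             noise_sigma=0.0, cell_area_mean=1200.0, seed=2)
        imgs, gt = make_fish_images(spec)
        cand = detect_spots(dog_filter(imgs.transcripts["A20"].astype(float)))
        pts = gt.spots[["x", "y"]].to_numpy()
        assert len(pts) == 40
        clusters = fcluster(linkage(pts, "single"), t=2.0 * spec.psf_sigma,
                            criterion="distance")
        n_resolvable = len(np.unique(clusters))
        assert abs(len(cand) - n_resolvable) <= 1
        # every detected maximum lies near a planted spot
        tree = cKDTree(pts)
        d, _ = tree.query(cand[["x", "y"]].to_numpy())
        assert np.all(d <= 2.0)

    def test_psf_must_be_diffraction_limited(self):
        with pytest.raises(ValueError, match="diffraction"):
            FishSceneSpec(psf_sigma=6.0, nucleus_radius=5.0)

    def test_determinism(self):
        spec = FishSceneSpec(n_cells=20, field_size=384, seed=7)
        a, _ = make_fish_images(spec)
        b, _ = make_fish_images(spec)
        assert np.array_equal(a.transcripts["A20"], b.transcripts["A20"])
        assert np.array_equal(a.nuclear, b.nuclear)
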