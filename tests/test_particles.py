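"""Drift correction, particle picking, symmetrization, average/std maps."""

import numpy as np
import pytest

from conftest import interior_dimer
from gatekit.movie import (Movie, MovieConfig, dimer_centers, read_movie,
                           render_window, simulate_afm_movie, write_movie)
from gatekit.particles import (ParticleStack, average_and_std,
                               iterative_average, pick_particles,
                               register_frames, symmetrize_c2)


def _stack(windows):
    import pandas as pd
    w = np.asarray(windows, dtype=float)
    recs = pd.DataFrame({"frame": np.zeros(len(w), dtype=int),
                         "row": 0.0, "col": 0.0, "score": 1.0})
    return ParticleStack(w, recs)


class TestAverageAndStd:
    def test_identical_particles_zero_std(self):
        w = np.ones((5, 9, 9)) * 1.3
        avg, std = average_and_std(_stack(w))
        assert np.allclose(avg.data, 1.3)
        assert np.all(std.data == 0.0)

    def test_two_particle_mean_and_std(self):
        w = np.stack([np.zeros((3, 3)), np.full((3, 3), 2.0)])
        avg, std = average_and_std(_stack(w))
        assert np.allclose(avg.data, 1.0)
        assert np.allclose(std.data, 1.0)  # population std

    def test_matches_brute_force_loops(self, rng):
        w = rng.normal(size=(7, 5, 5))
        avg, std = average_and_std(_stack(w))
        for i in range(5):
            for j in range(5):
                pix = [w[p, i, j] for p in range(7)]
                assert avg.data[i, j] == pytest.approx(np.mean(pix))
                assert std.data[i, j] == pytest.approx(np.std(pix))

    def test_single_particle_rejected(self):
        with pytest.raises(ValueError, match="2 particles"):
            average_and_std(_stack(np.zeros((1, 3, 3))))


class TestSymmetrizeC2:
    def test_symmetric_input_unchanged(self, rng):
        half = rng.normal(size=(9, 9))
        sym = 0.5 * (half + np.rot90(half, 2))
        assert np.allclose(symmetrize_c2(sym), sym)

    def test_idempotent(self, rng):
        m = rng.normal(size=(11, 11))
        once = symmetrize_c2(m)
        assert np.allclose(symmetrize_c2(once), once)

    def test_impulse_splits_into_point_symmetric_pair(self):
        m = np.zeros((9, 9))
        m[2, 5] = 4.0
        sym = symmetrize_c2(m)
        assert sym[2, 5] == pytest.approx(2.0)
        assert sym[6, 3] == pytest.approx(2.0)
        assert sym.sum() == pytest.approx(4.0)

    def test_commutes_with_rot180(self, rng):
        m = rng.normal(size=(9, 9))
        assert np.allclose(symmetrize_c2(np.rot90(m, 2)),
                           np.rot90(symmetrize_c2(m), 2))

    def test_even_size_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            symmetrize_c2(np.zeros((8, 8)))


class TestRegistration:
    def test_identical_frames_zero_shift(self, static_movie):
        _, movie, _ = static_movie
        _, drifts = register_frames(movie)
        assert np.allclose(drifts, 0.0, atol=1e-9)

    def test_integer_drift_recovered(self):
        cfg = MovieConfig(n_frames=6, noise_sigma=0.0, tau_open=1e6,
                          tau_closed=1e-9, drift_per_frame=(0.25, 0.0),
                          seed=1)  # exactly 1 px/frame along x
        movie, _ = simulate_afm_movie(cfg)
        _, drifts = register_frames(movie)
        assert np.allclose(drifts[:, 1], np.arange(6), atol=0.05)
        assert np.array_equal(np.round(drifts[:, 1]), np.arange(6))
        assert np.allclose(drifts[:, 0], 0.0, atol=0.05)

    def test_subpixel_drift_recovered(self):
        cfg = MovieConfig(n_frames=6, noise_sigma=0.05, tau_open=1e6,
                          tau_closed=1e-9, drift_per_frame=(0.075, 0.0),
                          seed=2)  # 0.3 px/frame, SNR ~ 25
        movie, _ = simulate_afm_movie(cfg)
        _, drifts = register_frames(movie)
        err = np.abs(drifts[:, 1] - 0.3 * np.arange(6))
        assert err.max() <= 0.15

    def test_flat_frames_identity_with_warning(self, caplog):
        movie = Movie(np.zeros((3, 32, 32)), 0.25, 0.2)
        with caplog.at_level("WARNING"):
            _, drifts = register_frames(movie)
        assert np.allclose(drifts, 0.0)
        assert any("flat" in r.message for r in caplog.records)


class TestPickParticles:
    def test_reference_pasted_at_known_positions(self, rng):
        ref = rng.normal(size=(9, 9)) + 5.0
        frame = np.zeros((64, 64))
        spots = [(15, 20), (40, 45), (30, 10)]
        for (r, c) in spots:
            frame[r - 4:r + 5, c - 4:c + 5] = ref
        movie = Movie(frame[None], 1.0, 1.0)
        stack = pick_particles(movie, ref, threshold=0.9)
        got = sorted(zip(np.round(stack.records.row).astype(int),
                         np.round(stack.records.col).astype(int)))
        assert got == sorted(spots)
        assert (stack.records.score > 0.99).all()

    def test_pure_noise_frame_yields_empty_stack(self, rng, caplog):
        movie = Movie(rng.normal(size=(1, 64, 64)), 1.0, 1.0)
        ref = rng.normal(size=(11, 11))
        with caplog.at_level("WARNING"):
            stack = pick_particles(movie, ref, threshold=0.9)
        assert stack.n_particles == 0

    def test_synthetic_movie_recall(self):
        """>= 90% of interior ground-truth dimer sites recovered."""
        cfg = MovieConfig(n_frames=20, noise_sigma=0.05, seed=4,
                          shape_px=(128, 128))
        movie, truth = simulate_afm_movie(cfg)
        dc = dimer_centers(truth)
        c0 = dc[dc.frame == 0].iloc[5]
        ref = render_window(cfg, c0.col_px * cfg.pixel_size,
                            c0.row_px * cfg.pixel_size, 37)
        stack = pick_particles(movie, symmetrize_c2(ref), threshold=0.6)
        k = 37
        found = total = 0
        for (frame, grp) in dc.groupby("frame"):
            picks = stack.records[stack.records.frame == frame]
            for _, site in grp.iterrows():
                # only sites whose window fits inside the frame count
                if not (k // 2 + 2 <= site.row_px < 128 - k // 2 - 2
                        and k // 2 + 2 <= site.col_px < 128 - k // 2 - 2):
                    continue
                total += 1
                if picks.empty:
                    continue
                d = np.hypot(picks.row - site.row_px,
                             picks.col - site.col_px)
                found += (d.min() < 2.0)
        assert total > 50
        assert found / total >= 0.90

    def test_even_reference_rejected(self):
        movie = Movie(np.zeros((1, 32, 32)), 1.0, 1.0)
        with pytest.raises(ValueError, match="odd"):
            pick_particles(movie, np.zeros((8, 8)), 0.7)


class TestIterativeAverage:
    def test_noiseless_crystal_reproduces_template(self, static_movie):
        cfg, movie, truth = static_movie
        d0 = interior_dimer(truth, movie.shape)
        k = 37
        tmpl = render_window(cfg, d0.col_px * cfg.pixel_size,
                             d0.row_px * cfg.pixel_size, k)
        i, j = int(round(d0.row_px)), int(round(d0.col_px))
        seed_win = movie.frames[0][i - k // 2:i + k // 2 + 1,
                                   j - k // 2:j + k // 2 + 1]
        avg, std, stack, diag = iterative_average(movie, seed_win,
                                                  rounds=2, threshold=0.7)
        assert np.max(np.abs(avg.data - tmpl)) < 0.01 * cfg.rim_height
        assert std.data.max() < 0.01 * cfg.rim_height

    def test_true_template_seed_is_fixed_point(self, static_movie):
        cfg, movie, truth = static_movie
        d0 = interior_dimer(truth, movie.shape)
        tmpl = render_window(cfg, d0.col_px * cfg.pixel_size,
                             d0.row_px * cfg.pixel_size, 37)
        _, _, s1, _ = iterative_average(movie, tmpl, rounds=1, threshold=0.7)
        _, _, s2, _ = iterative_average(movie, tmpl, rounds=2, threshold=0.7)
        a = sorted(map(tuple, np.round(
            s1.records[["frame", "row", "col"]].values, 2)))
        b = sorted(map(tuple, np.round(
            s2.records[["frame", "row", "col"]].values, 2)))
        assert a == b

    def test_second_round_does_not_lose_particles(self):
        counts1, counts2 = [], []
        for seed in range(10):
            cfg = MovieConfig(n_frames=8, noise_sigma=0.25, seed=seed)
            movie, truth = simulate_afm_movie(cfg)
            d0 = interior_dimer(truth, movie.shape)
            k = 37
            i, j = int(round(d0.row_px)), int(round(d0.col_px))
            seed_win = movie.frames[0][i - k // 2:i + k // 2 + 1,
                                       j - k // 2:j + k // 2 + 1]
            try:
                _, _, s1, _ = iterative_average(movie, seed_win, rounds=1,
                                                threshold=0.55)
                _, _, s2, _ = iterative_average(movie, seed_win, rounds=2,
                                                threshold=0.55)
            except RuntimeError:
                continue
            counts1.append(s1.n_particles)
            counts2.append(s2.n_particles)
        assert len(counts1) >= 8
        assert np.mean(counts2) >= np.mean(counts1)

    def test_std_map_peaks_in_loop_region_not_rim(self):
        """A gating loop toggling position dominates the std map while the
        static rim stays quiet (the mobile-domain signature)."""
        cfg = MovieConfig(n_frames=60, noise_sigma=0.02, tau_open=0.2,
                          tau_closed=0.2, seed=6)
        movie, truth = simulate_afm_movie(cfg)
        d0 = interior_dimer(truth, movie.shape)
        k = 37
        tmpl = render_window(cfg, d0.col_px * cfg.pixel_size,
                             d0.row_px * cfg.pixel_size, k)
        avg, std, _, _ = iterative_average(movie, tmpl, rounds=2,
                                           threshold=0.5)
        i_max, j_max = np.unravel_index(np.argmax(std.data), std.data.shape)
        # loop positions of both dimer partners: between offset_closed (on
        # the molecule center) and offset_open (extended along +/-x)
        half = k // 2
        mol_dx = 1.875 / cfg.pixel_size
        loop_reach = (1.875 + cfg.loop_offset_open[0]) / cfg.pixel_size
        assert abs(i_max - half) <= 4  # on the dimer axis row
        assert abs(j_max - half) <= loop_reach + 3
        # static rim top/bottom stays comparatively quiet
        rim_rows = std.data[[half - int(np.ceil(
            cfg.rim_radius / cfg.pixel_size)), half + int(np.ceil(
                cfg.rim_radius / cfg.pixel_size))], half]
        assert std.data[i_max, j_max] > 2.0 * rim_rows.max()

    def test_empty_pick_aborts_with_diagnostics(self):
        movie = Movie(np.zeros((3, 48, 48)), 0.25, 0.2)
        with pytest.raises(RuntimeError, match="empty pick"):
            iterative_average(movie, np.ones((9, 9)), rounds=2,
                              threshold=0.7)


class TestTranslationEquivariance:
    def test_integer_shift_of_all_frames_leaves_average_unchanged(self):
        cfg = MovieConfig(n_frames=4, noise_sigma=0.0, tau_open=1e6,
                          tau_closed=1e-9, seed=9)
        movie, truth = simulate_afm_movie(cfg)
        shift = 2
        shifted = Movie(np.roll(movie.frames, shift, axis=2),
                        cfg.pixel_size, cfg.frame_interval)
        d0 = interior_dimer(truth, movie.shape)
        k = 37
        tmpl = render_window(cfg, d0.col_px * cfg.pixel_size,
                             d0.row_px * cfg.pixel_size, k)
        avg_a, _, _, _ = iterative_average(movie, tmpl, rounds=1,
                                           threshold=0.7)
        avg_b, _, _, _ = iterative_average(shifted, tmpl, rounds=1,
                                           threshold=0.7)
        assert np.allclose(avg_a.data, avg_b.data, atol=1e-6)


def test_movie_tiff_roundtrip(tmp_path, static_movie):
    _, movie, _ = static_movie
    f = tmp_path / "movie.tif"
    write_movie(movie, f)
    back = read_movie(f)
    assert back.frames.shape == movie.frames.shape
    assert np.allclose(back.frames, movie.frames, atol=1e-6)
    assert back.pixel_size == movie.pixel_size
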