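"""Spot detection, trajectory linking, MSD computation and the three
mobility models (free, bimodal CDF, confined)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hdlmem import spt, synthetic
from hdlmem.spt import Localization, MsdCurve, Trajectory


def _render_emitters(shape, centers_px, photons, bg, rng, psf_fwhm_px=3.0):
    sig = psf_fwhm_px / 2.3548
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    img = np.full(shape, float(bg))
    for (r0, c0) in centers_px:
        img += photons / (2 * np.pi * sig**2) * np.exp(
            -((yy - r0) ** 2 + (xx - c0) ** 2) / (2 * sig**2)
        )
    return rng.poisson(img).astype(float)


class TestDetectSpots:
    def test_noise_frames_rarely_trigger(self):
        """At a 5-sigma threshold an empty frame should detect nothing in
        >= 95% of realizations."""
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            frame = rng.normal(100.0, 5.0, (64, 64))
            hits += bool(spt.detect_spots(frame, threshold=5.0))
        assert hits <= 2

    def test_localization_precision_at_1000_photons(self):
        errs = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            r0, c0 = 15.5 + rng.uniform(-1, 1, 2)
            frame = _render_emitters((32, 32), [(r0, c0)], 1000, 10, rng)
            locs = spt.detect_spots(frame, threshold=5.0, pixel_size=100.0)
            assert len(locs) == 1
            errs.append(
                np.hypot(locs[0].x - (c0 + 0.5) * 0.1, locs[0].y - (r0 + 0.5) * 0.1) * 1e3
            )
        assert np.sqrt(np.mean(np.square(errs))) <= 40.0  # nm

    def test_well_separated_emitters_counted_exactly(self):
        rng = np.random.default_rng(3)
        frame = _render_emitters((80, 80), [(20.0, 20.0), (70.0, 70.0)], 2000, 10, rng)
        locs = spt.detect_spots(frame, threshold=5.0, pixel_size=100.0)
        assert len(locs) == 2

    def test_overlap_policy(self):
        """Spots closer than one PSF FWHM: 'merge' keeps the brighter
        candidate; 'drop' never reports more than 'merge' does.  (A pair
        below the two-maximum resolution limit appears as one spot under
        either policy.)"""
        rng = np.random.default_rng(4)
        frame = _render_emitters((40, 40), [(20.0, 20.0), (20.0, 22.9)], 4000, 10, rng)
        merged = spt.detect_spots(frame, threshold=5.0, pixel_size=100.0, overlap="merge")
        dropped = spt.detect_spots(frame, threshold=5.0, pixel_size=100.0, overlap="drop")
        assert len(merged) == 1
        assert len(dropped) <= len(merged)


class TestLinking:
    def test_single_emitter_full_length(self):
        frames = [[Localization(1.0, 1.0, f)] for f in range(15)]
        trajs = spt.link_trajectories(frames, max_disp=0.5)
        assert len(trajs) == 1 and len(trajs[0]) == 15

    def test_distant_emitters_never_swapped(self):
        frames = [
            [Localization(1.0, 1.0, f), Localization(11.0, 11.0, f)] for f in range(10)
        ]
        trajs = spt.link_trajectories(frames, max_disp=0.5)
        assert len(trajs) == 2
        for tr in trajs:
            assert np.ptp(tr.x) < 1e-9 and len(tr) == 10

    def test_brownian_steps_linked_correctly(self):
        """>= 95% of true steps of a sparse Brownian ensemble are recovered."""
        rng = np.random.default_rng(5)
        n_part, n_frames = 20, 25
        pos = rng.uniform(5, 95, (n_part, 2))
        truth = [pos.copy()]
        step = np.sqrt(2 * 0.5 * 0.02)  # D=0.5 um^2/s at 20 ms frames
        frames = []
        for f in range(n_frames):
            frames.append([Localization(p[0], p[1], f) for p in pos])
            pos = pos + rng.normal(0, step, (n_part, 2))
            truth.append(pos.copy())
        trajs = spt.link_trajectories(frames, max_disp=0.6)
        n_links = sum(len(t) - 1 for t in trajs)
        assert n_links >= 0.95 * n_part * (n_frames - 1)
        # every link in every trajectory must be a true step (no swaps)
        full = [t for t in trajs if len(t) == n_frames]
        for tr in full:
            d0 = np.hypot(tr.x[0] - truth[0][:, 0], tr.y[0] - truth[0][:, 1])
            k = int(np.argmin(d0))
            for i, f in enumerate(tr.frames):
                assert np.hypot(tr.x[i] - truth[f][k, 0], tr.y[i] - truth[f][k, 1]) < 1e-9


class TestMsd:
    def test_static_points_without_noise_are_zero(self):
        trajs = [Trajectory(np.full(20, 3.0), np.full(20, 4.0), np.arange(20))]
        msd = spt.compute_msd(trajs, n_values=[1, 2, 3])
        assert np.allclose(msd.msd, 0.0)

    def test_noise_floor_closed_form(self):
        trajs, _ = synthetic.gen_trajectory_mixture(
            n_traj=200, fractions=(1, 0, 0), sigma_xy=30.0, seed=1
        )
        msd = spt.compute_msd(trajs, n_values=[1, 2, 3, 4])
        assert np.allclose(msd.msd, 3.6e-3, rtol=0.08)

    def test_brownian_closed_form(self):
        trajs, _ = synthetic.gen_trajectory_mixture(
            n_traj=400, fractions=(0, 0, 1), d_free=1.0, sigma_xy=30.0, seed=2
        )
        msd = spt.compute_msd(trajs, n_values=[1])
        assert msd.t_lag[0] == pytest.approx(0.02)
        assert msd.msd[0] == pytest.approx(4 * 1.0 * 0.02 + 3.6e-3, rel=0.03)

    def test_non_overlapping_pair_count(self):
        trajs = [Trajectory(np.arange(10.0), np.zeros(10), np.arange(10))]
        msd = spt.compute_msd(trajs, n_values=[3])
        assert msd.n_pairs[0] == 3  # i = 0, 3, 6
        msd_ov = spt.compute_msd(trajs, n_values=[3], windowing="overlapping")
        assert msd_ov.n_pairs[0] == 7

    def test_excessive_lag_omitted_with_warning(self):
        import warnings as w

        trajs = [Trajectory(np.arange(5.0), np.zeros(5), np.arange(5))]
        with w.catch_warnings():
            w.simplefilter("always")
            msd = spt.compute_msd(trajs, n_values=[1, 10])
        assert msd.t_lag.size == 1


class TestFreeDiffusionFit:
    def test_exact_on_analytic_line(self):
        t = np.array([0.02, 0.04, 0.06, 0.08])
        msd = MsdCurve(t, 4 * 1.0 * t + 4 * 0.03**2, np.full(4, 1000))
        fit = spt.fit_free_diffusion(msd)
        assert fit.d == pytest.approx(1.0, abs=1e-9)
        assert fit.sigma_xy == pytest.approx(30.0, abs=1e-6)

    def test_generator_recovery_at_paper_value(self):
        trajs, _ = synthetic.gen_trajectory_mixture(
            n_traj=200, fractions=(0, 0, 1), d_free=9.6, sigma_xy=30.0, seed=4
        )
        fit = spt.fit_free_diffusion(spt.compute_msd(trajs))
        assert fit.d == pytest.approx(9.6, rel=0.05)

    def test_immobile_flag_on_negative_slope(self):
        t = np.array([0.02, 0.04, 0.06])
        msd = MsdCurve(t, np.array([0.004, 0.0039, 0.0038]), np.full(3, 500))
        fit = spt.fit_free_diffusion(msd)
        assert fit.d == 0.0 and "immobile" in fit.flags


class TestBimodalCdf:
    def test_single_component_collapses_to_monomodal(self):
        rng = np.random.default_rng(0)
        sq = {0.02: rng.exponential(0.01, 2000)}
        with pytest.warns(UserWarning, match="monomodal"):
            fit = spt.fit_bimodal_cdf(sq)
        assert fit.model == "monomodal"
        assert fit.msd1[0] == pytest.approx(0.01, rel=0.1)

    def test_mixture_alpha_recovery(self):
        trajs, _ = synthetic.gen_trajectory_mixture(
            n_traj=300, fractions=(0.7, 0.3, 0.0), seed=11
        )
        fit = spt.fit_bimodal_cdf(spt.square_displacements(trajs, [1, 2, 3]))
        assert fit.alpha == pytest.approx(0.70, abs=0.05)

    def test_two_brownian_populations_slopes(self):
        rng = np.random.default_rng(1)
        lags = np.array([0.02, 0.04, 0.06])
        sq = {}
        for t in lags:
            m1, m2 = 4 * 0.05 * t, 4 * 1.0 * t
            sq[t] = np.concatenate(
                [rng.exponential(m1, 3000), rng.exponential(m2, 3000)]
            )
        fit = spt.fit_bimodal_cdf(sq)
        d1 = np.polyfit(lags, fit.msd1, 1)[0] / 4
        d2 = np.polyfit(lags, fit.msd2, 1)[0] / 4
        assert d1 == pytest.approx(0.05, rel=0.1)
        assert d2 == pytest.approx(1.0, rel=0.1)
        assert fit.alpha == pytest.approx(0.5, abs=0.05)

    @given(scale=st.floats(0.1, 50.0))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_scale_equivariance(self, scale):
        rng = np.random.default_rng(7)
        sq = {
            0.02: np.concatenate(
                [rng.exponential(0.004, 1500), rng.exponential(0.08, 1500)]
            )
        }
        base = spt.fit_bimodal_cdf(sq)
        scaled = spt.fit_bimodal_cdf({k: v * scale for k, v in sq.items()})
        assert scaled.alpha == pytest.approx(base.alpha, abs=0.02)
        assert scaled.msd1[0] == pytest.approx(base.msd1[0] * scale, rel=0.05)
        assert scaled.msd2[0] == pytest.approx(base.msd2[0] * scale, rel=0.05)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="< 100"):
            spt.fit_bimodal_cdf({0.02: np.ones(50)})


class TestConfinedFit:
    def test_exact_on_model_curve(self):
        t = np.linspace(0.02, 1.0, 30)
        msd = MsdCurve(t, spt.confined_msd_model(t, 0.1, 0.2), np.full(30, 1000))
        fit = spt.fit_confined(msd, fit_offset=False)
        assert fit.d == pytest.approx(0.1, rel=1e-6)
        assert fit.radius == pytest.approx(0.2, rel=1e-6)

    def test_long_lag_plateau_equals_r_squared(self):
        assert spt.confined_msd_model(np.inf, 0.1, 0.2) == pytest.approx(0.04)
        t = np.geomspace(0.02, 50.0, 40)
        curve = spt.confined_msd_model(t, 0.05, 0.15)
        assert curve[-1] == pytest.approx(0.15**2, rel=1e-6)

    def test_reflected_walk_radius_recovery(self):
        trajs, _ = synthetic.gen_trajectory_mixture(
            n_traj=300, fractions=(0, 1, 0), radius=0.15, d_conf=0.1,
            sigma_xy=30.0, n_frames=30, seed=8,
        )
        msd = spt.compute_msd(trajs, n_values=list(range(1, 15)))
        fit = spt.fit_confined(msd)
        assert fit.model == "confined"
        assert fit.radius == pytest.approx(0.15, rel=0.15)

    def test_linear_msd_flagged_free(self):
        t = np.linspace(0.02, 0.2, 10)
        msd = MsdCurve(t, 4 * 0.5 * t, np.full(10, 1000))
        fit = spt.fit_confined(msd)
        assert "looks_free" in fit.flags


class TestClassify:
    def test_pure_immobile(self):
        trajs, _ = synthetic.gen_trajectory_mixture(
            n_traj=100, fractions=(1, 0, 0), sigma_xy=30.0, seed=1
        )
        fractions, _ = spt.classify_mobility(trajs, sigma_xy=30.0)
        assert fractions[0] >= 0.97

    def test_mixture_recovery(self):
        trajs, _ = synthetic.gen_trajectory_mixture(
            n_traj=300, fractions=(0.7, 0.3, 0.0), seed=2
        )
        fractions, labels = spt.classify_mobility(trajs, sigma_xy=30.0)
        assert fractions[0] == pytest.approx(0.7, abs=0.05)
        assert fractions[1] == pytest.approx(0.3, abs=0.05)
        assert "unclassified" not in labels

    def test_pure_free_mostly_free(self):
        """Free ensembles classify predominantly free; single-trajectory
        TAMSD noise leaves a small spurious-confinement rate."""
        trajs, _ = synthetic.gen_trajectory_mixture(
            n_traj=150, fractions=(0, 0, 1), d_free=1.0, sigma_xy=30.0, seed=3
        )
        fractions, _ = spt.classify_mobility(trajs, sigma_xy=30.0)
        assert fractions[2] >= 0.85 and fractions[0] == 0.0

    def test_short_trajectories_unclassified(self):
        trajs = [Trajectory([0.0, 0.01], [0.0, 0.0], [0, 1])]
        fractions, labels = spt.classify_mobility(trajs, sigma_xy=30.0)
        assert labels == ["unclassified"]
        assert np.isnan(fractions[0])
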