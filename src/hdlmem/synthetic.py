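"""Synthetic-data generators with recorded ground truth.

Every input the analysis pipeline consumes can be generated here, together
with a :class:`SyntheticTruth` recording the parameters and seed, so that
each analysis operation can be exercised against a known answer:

* TCSPC decay sets over the 400-550 nm emission band (10 nm steps) with a
  Gaussian IRF (78 ps FWHM) and Poisson counting noise, following a
  continuous-relaxation emission model whose band maximum shifts as
  ``nu(t) = nu_inf + (nu0 - nu_inf) exp(-t/tau_shift)``;
* excitation spectrum pairs (Em 440/490 nm) with a known GP;
* trajectory mixtures (immobile / confined-in-a-disc / free Brownian) with
  isotropic localization noise;
* FCS intensity traces from particle-based 2-d diffusion through a Gaussian
  focus in a periodic box, with optional two-state triplet blinking;
* two-channel phase-separated bilayer images (pixel-intensity or countable
  point-emitter mode) with Poisson shot noise plus Gaussian read noise;
* GUV z-stacks showing an equatorial membrane ring.

All randomness comes from one ``numpy.random.default_rng(seed)`` per
dataset; identical seed and parameters reproduce outputs bit-identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fcs import IntensityTrace
from .spt import Localization, Trajectory
from .tdfs import DecayCurve, InstrumentResponse

__all__ = [
    "SyntheticTruth",
    "RelaxationModel",
    "CameraNoise",
    "gen_tdfs_dataset",
    "gen_gp_spectra",
    "gen_trajectory_mixture",
    "gen_fcs_trace",
    "gen_two_phase_image",
    "gen_guv_image",
]


@dataclass
class SyntheticTruth:
    """Ground-truth record paired with one generated dataset."""

    dataset_id: str
    parameters: dict
    seed: int
    extras: dict = field(default_factory=dict, repr=False)


@dataclass
class RelaxationModel:
    """Continuous solvent-relaxation emission model.

    The emission band is a Gaussian in wavenumber of width ``band_fwhm``
    whose maximum relaxes mono-exponentially from ``nu0`` to ``nu_inf``
    with time constant ``tau_shift``; the total emitted intensity decays
    with ``fluor_lifetime``.
    """

    nu0: float = 23_800.0  # cm^-1
    nu_inf: float = 21_800.0  # cm^-1
    tau_shift: float = 2.0  # ns
    fluor_lifetime: float = 4.0  # ns
    band_fwhm: float = 3000.0  # cm^-1

    def __post_init__(self) -> None:
        if not (self.nu0 > self.nu_inf > 0):
            raise ValueError("non-physical model: require nu0 > nu_inf > 0")
        if self.tau_shift <= 0 or self.fluor_lifetime <= 0:
            raise ValueError("tau_shift and fluor_lifetime must be positive")

    def nu_t(self, t: np.ndarray) -> np.ndarray:
        return self.nu_inf + (self.nu0 - self.nu_inf) * np.exp(-np.asarray(t, float) / self.tau_shift)


@dataclass
class CameraNoise:
    """Poisson shot noise + Gaussian read noise camera model."""

    offset: float = 100.0  # counts
    read_sd: float = 2.0  # counts rms
    gain: float = 1.0  # counts per photon

    def apply(self, photons: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        shot = rng.poisson(np.clip(photons, 0, None)).astype(float)
        return self.gain * shot + self.offset + rng.normal(0.0, self.read_sd, photons.shape)


# ---------------------------------------------------------------------------
# TDFS


@dataclass
class TdfsDataset:
    decays: list
    irf: InstrumentResponse
    steady_state: pd.DataFrame
    truth: SyntheticTruth


def gen_tdfs_dataset(
    model: RelaxationModel,
    irf_fwhm: float = 78.0,  # ps
    wavelength_grid: np.ndarray | None = None,
    peak_counts: int = 5000,
    seed: int = 0,
    n_bins: int = 4096,
    bin_width: float = 0.0125,  # ns
    irf_t0: float = 2.0,  # ns
    background_counts: float = 5.0,  # dark counts per bin at the peak-count level
    jacobian: bool = True,
) -> TdfsDataset:
    """Generate per-wavelength TCSPC decays + IRF + steady-state spectrum.

    Each decay is a Poisson realization of the relaxation model convolved
    with a Gaussian IRF; the expectation is scaled so the peak bin equals
    ``peak_counts`` (emulating acquisition until a target peak count).
    The steady-state spectrum (1 nm steps) is the time integral of the same
    emission model.  With ``jacobian=True`` the per-wavelength intensities
    include the nm->cm^-1 density conversion factor.
    """
    if wavelength_grid is None:
        wavelength_grid = np.arange(400.0, 551.0, 10.0)
    wavelength_grid = np.asarray(wavelength_grid, dtype=float)
    if np.any(np.diff(wavelength_grid) <= 0):
        raise ValueError("wavelength grid must be strictly increasing")
    if peak_counts < 1000:
        raise ValueError("peak_counts must be >= 1000")
    rng = np.random.default_rng(seed)

    t = np.arange(n_bins) * bin_width
    sd_band = model.band_fwhm / 2.3548
    nu_of_t = model.nu_t(t)

    def emission(lams: np.ndarray) -> np.ndarray:
        """Ideal per-wavelength decay surface, shape (n_lambda, n_t)."""
        nu_l = 1e7 / lams
        band = np.exp(-((nu_l[:, None] - nu_of_t[None, :]) ** 2) / (2 * sd_band**2))
        out = band * np.exp(-t[None, :] / model.fluor_lifetime)
        if jacobian:
            out = out * (1e7 / lams[:, None] ** 2)
        return out

    # Gaussian IRF profile centered at irf_t0
    irf_sd = irf_fwhm * 1e-3 / 2.3548
    irf_profile = np.exp(-((t - irf_t0) ** 2) / (2 * irf_sd**2))
    irf_counts = rng.poisson(irf_profile / irf_profile.max() * 10_000)
    irf = InstrumentResponse(time_axis=t, counts=irf_counts, fwhm_ps=irf_fwhm)

    kernel = irf_profile / irf_profile.sum()
    ideal = emission(wavelength_grid)
    decays = []
    for i, lam in enumerate(wavelength_grid):
        conv = np.convolve(kernel, ideal[i])[: t.size]
        expect = conv / conv.max() * peak_counts + background_counts
        decays.append(
            DecayCurve(
                emission_wavelength=float(lam),
                time_axis=t,
                counts=rng.poisson(expect),
            )
        )

    lam_ss = np.arange(wavelength_grid[0], wavelength_grid[-1] + 0.5, 1.0)
    i_ss = emission(lam_ss).sum(axis=1) * bin_width
    steady_state = pd.DataFrame({"wavelength_nm": lam_ss, "intensity": i_ss})

    truth = SyntheticTruth(
        dataset_id=f"tdfs-{seed}",
        parameters={
            "nu0_cm-1": model.nu0,
            "nu_inf_cm-1": model.nu_inf,
            "delta_nu_cm-1": model.nu0 - model.nu_inf,
            "tau_shift_ns": model.tau_shift,
            "fluor_lifetime_ns": model.fluor_lifetime,
            "band_fwhm_cm-1": model.band_fwhm,
            "irf_fwhm_ps": irf_fwhm,
            "peak_counts": peak_counts,
            "jacobian": jacobian,
        },
        seed=seed,
    )
    return TdfsDataset(decays=decays, irf=irf, steady_state=steady_state, truth=truth)


# ---------------------------------------------------------------------------
# Laurdan GP spectra


def gen_gp_spectra(
    gp_true: float,
    lambda_ex_grid: np.ndarray | None = None,
    noise_sd: float = 0.02,
    seed: int = 0,
    band_center: float = 360.0,
    band_sd: float = 25.0,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Two excitation spectra (Em 440 / 490 nm) with known GP.

    Before noise the intensity ratio satisfies
    ``I440/I490 = (1 + gp_true) / (1 - gp_true)`` at every excitation
    wavelength; multiplicative Gaussian noise of fractional sd ``noise_sd``
    is then applied independently to each point.
    """
    if not -1.0 <= gp_true <= 1.0:
        raise ValueError("gp_true must lie in [-1, 1]")
    if abs(gp_true) == 1.0 and noise_sd > 0:
        raise ValueError("|gp_true| = 1 with noise is ill-defined (zero channel)")
    if lambda_ex_grid is None:
        lambda_ex_grid = np.arange(320.0, 421.0, 2.0)
    lam = np.asarray(lambda_ex_grid, dtype=float)
    rng = np.random.default_rng(seed)
    shape = np.exp(-((lam - band_center) ** 2) / (2 * band_sd**2))
    i440 = shape * (1.0 + gp_true)
    i490 = shape * (1.0 - gp_true)
    if noise_sd > 0:
        i440 = i440 * (1.0 + noise_sd * rng.standard_normal(lam.size))
        i490 = i490 * (1.0 + noise_sd * rng.standard_normal(lam.size))
    truth = SyntheticTruth(
        dataset_id=f"gp-{seed}",
        parameters={"gp_true": gp_true, "noise_sd": noise_sd},
        seed=seed,
    )
    return (
        pd.DataFrame({"lambda_ex_nm": lam, "intensity": i440}),
        pd.DataFrame({"lambda_ex_nm": lam, "intensity": i490}),
        truth,
    )


# ---------------------------------------------------------------------------
# Trajectories


def gen_trajectory_mixture(
    n_traj: int = 200,
    fractions: tuple[float, float, float] = (0.7, 0.3, 0.0),
    d_free: float = 1.0,  # um^2/s
    d_conf: float = 0.1,  # um^2/s
    radius: float = 0.15,  # um
    sigma_xy: float = 30.0,  # nm
    t_ill: float = 5.0,  # ms
    t_delay: float = 15.0,  # ms
    n_frames: int = 50,
    field_um: float = 20.0,
    seed: int = 0,
) -> tuple[list[Trajectory], SyntheticTruth]:
    """Mixture of immobile / confined / free trajectories with noise.

    ``fractions`` gives (immobile, confined, free) and must sum to 1.
    Immobile particles are static points; confined particles perform a
    reflected Brownian walk inside a disc of the given radius; free
    particles are unbounded Brownian walks.  All positions receive
    isotropic Gaussian localization noise of sd ``sigma_xy``.
    """
    fr = np.asarray(fractions, dtype=float)
    if not np.isclose(fr.sum(), 1.0):
        raise ValueError("fractions must sum to 1")
    if not 5.0 <= sigma_xy <= 100.0:
        raise ValueError("sigma_xy must be in the 5-100 nm range")
    if radius <= 0 and fr[1] > 0:
        raise ValueError("radius must be positive when the confined fraction is > 0")
    rng = np.random.default_rng(seed)
    counts = np.floor(fr * n_traj).astype(int)
    while counts.sum() < n_traj:  # distribute rounding remainder
        counts[np.argmax(fr * n_traj - counts)] += 1

    frame_dt = (t_ill + t_delay) * 1e-3  # s
    sig_um = sigma_xy * 1e-3
    trajs, labels = [], []
    frames = np.arange(n_frames)

    def noise(n):
        return rng.normal(0.0, sig_um, (n, 2))

    for _ in range(counts[0]):  # immobile
        p0 = rng.uniform(0, field_um, 2)
        pos = np.tile(p0, (n_frames, 1)) + noise(n_frames)
        trajs.append(Trajectory(pos[:, 0], pos[:, 1], frames, t_ill, t_delay))
        labels.append("immobile")

    if counts[1]:
        # substeps small enough for faithful reflection at the disc edge
        n_sub = max(1, int(np.ceil(64.0 * d_conf * frame_dt / radius**2)))
        dt_sub = frame_dt / n_sub
        step_sd = np.sqrt(2.0 * d_conf * dt_sub)
        for _ in range(counts[1]):
            center = rng.uniform(0, field_um, 2)
            p = np.zeros(2)
            pos = np.empty((n_frames, 2))
            pos[0] = p
            for k in range(1, n_frames):
                for _s in range(n_sub):
                    p = p + rng.normal(0.0, step_sd, 2)
                    r = np.hypot(*p)
                    if r > radius:  # radial reflection
                        p *= (2.0 * radius - r) / r
                pos[k] = p
            pos = pos + center + noise(n_frames)
            trajs.append(Trajectory(pos[:, 0], pos[:, 1], frames, t_ill, t_delay))
            labels.append("confined")

    step_sd_free = np.sqrt(2.0 * d_free * frame_dt)
    for _ in range(counts[2]):  # free
        p0 = rng.uniform(0, field_um, 2)
        steps = rng.normal(0.0, step_sd_free, (n_frames, 2))
        steps[0] = 0.0
        pos = p0 + np.cumsum(steps, axis=0) + noise(n_frames)
        trajs.append(Trajectory(pos[:, 0], pos[:, 1], frames, t_ill, t_delay))
        labels.append("free")

    truth = SyntheticTruth(
        dataset_id=f"spt-{seed}",
        parameters={
            "fractions": tuple(fr),
            "d_free_um2_s": d_free,
            "d_conf_um2_s": d_conf,
            "radius_um": radius,
            "sigma_xy_nm": sigma_xy,
            "t_ill_ms": t_ill,
            "t_delay_ms": t_delay,
            "n_frames": n_frames,
            "n_traj": n_traj,
        },
        seed=seed,
        extras={"labels": labels},
    )
    return trajs, truth


# ---------------------------------------------------------------------------
# FCS traces


def _triplet_states(rng, n_bins, dt, duration, triplet_frac, tau_triplet, n_particles):
    """Per-particle two-state (bright/dark) telegraph processes.

    Dwell times are exponential with correlation time ``tau_triplet`` and
    stationary dark fraction ``triplet_frac``.  Returns a boolean (n_bins,
    n_particles) bright matrix.  Cost scales with duration/tau_triplet, so
    this is intended for short traces.
    """
    k_total = 1.0 / tau_triplet
    mean_bright = 1.0 / (triplet_frac * k_total)  # dwell in bright state
    mean_dark = 1.0 / ((1.0 - triplet_frac) * k_total)
    t_bins = (np.arange(n_bins) + 0.5) * dt
    bright = np.empty((n_bins, n_particles), dtype=bool)
    n_sw = int(duration * k_total * 1.5) + 50
    for j in range(n_particles):
        start_bright = rng.random() > triplet_frac
        means = np.empty(n_sw)
        means[0::2] = mean_bright if start_bright else mean_dark
        means[1::2] = mean_dark if start_bright else mean_bright
        switches = np.cumsum(rng.exponential(means))
        parity = np.searchsorted(switches, t_bins) % 2
        bright[:, j] = (parity == 0) if start_bright else (parity == 1)
    return bright


def gen_fcs_trace(
    d_true: float = 9.6,  # um^2/s
    n_particles: float = 5.0,  # mean number in the focal area
    w0: float = 0.25,  # um
    triplet_frac: float = 0.0,
    tau_triplet: float = 5e-6,  # s
    duration: float = 10.0,  # s
    dt: float = 50e-6,  # s
    brightness: float = 30_000.0,  # counts/s per particle at beam centre
    seed: int = 0,
    chunk: int = 50_000,
) -> tuple[IntensityTrace, SyntheticTruth]:
    """Photon-count trace of 2-d diffusion through a Gaussian focus.

    Particles diffuse in a periodic square box of side 10 w0; the detected
    rate is ``brightness * sum_i exp(-2 r_i^2 / w0^2)`` and counts per bin
    are Poisson.  The particle density is ``n_particles / (pi w0^2)`` so the
    fitted correlation amplitude is 1/n_particles.  Optional two-state
    triplet blinking multiplies each particle's emission by a telegraph
    process (only meaningful when ``dt < tau_triplet``).
    """
    if w0 <= 0:
        raise ValueError("w0 must be positive")
    n_bins = int(round(duration / dt))
    if n_bins < 100_000:
        raise ValueError("duration/dt must be >= 1e5 samples")
    if triplet_frac > 0 and dt >= tau_triplet:
        warnings.warn("dt >= tau_triplet: triplet blinking unresolvable", stacklevel=2)
    rng = np.random.default_rng(seed)

    box = 10.0 * w0
    m_total = max(1, int(round(n_particles * box**2 / (np.pi * w0**2))))
    pos = rng.uniform(0.0, box, (m_total, 2))
    step_sd = np.sqrt(2.0 * d_true * dt)
    center = box / 2.0

    bright = None
    if triplet_frac > 0 and dt < tau_triplet:
        bright = _triplet_states(
            rng, n_bins, dt, duration, triplet_frac, tau_triplet, m_total
        )

    counts = np.empty(n_bins, dtype=np.int64)
    start = 0
    pos = pos.astype(np.float32)
    while start < n_bins:
        n = min(chunk, n_bins - start)
        steps = rng.standard_normal((n, m_total, 2), dtype=np.float32)
        steps *= np.float32(step_sd)
        np.cumsum(steps, axis=0, out=steps)
        path = np.mod(pos[None, :, :] + steps, np.float32(box))
        # minimal-image distance to the focus at the box centre
        d = np.mod(path - np.float32(center) + np.float32(box / 2), np.float32(box))
        d -= np.float32(box / 2)
        w = np.exp(-2.0 * (d[..., 0] ** 2 + d[..., 1] ** 2) / np.float32(w0**2))
        if bright is not None:
            w = w * bright[start : start + n]
        rate = brightness * w.sum(axis=1, dtype=np.float64)
        counts[start : start + n] = rng.poisson(rate * dt)
        pos = path[-1]
        start += n

    truth = SyntheticTruth(
        dataset_id=f"fcs-{seed}",
        parameters={
            "d_um2_s": d_true,
            "n_particles": n_particles,
            "w0_um": w0,
            "triplet_frac": triplet_frac,
            "tau_triplet_s": tau_triplet,
            "duration_s": duration,
            "dt_s": dt,
            "tau_d_s": w0**2 / (4.0 * d_true),
        },
        seed=seed,
    )
    return IntensityTrace(dt=dt, counts=counts), truth


# ---------------------------------------------------------------------------
# Two-phase bilayer images


def _labels_from_geometry(mask_geometry, shape) -> np.ndarray:
    if isinstance(mask_geometry, np.ndarray):
        labels = mask_geometry.astype(np.uint8)
        if set(np.unique(labels)) - {1, 2}:
            raise ValueError("geometry array must contain labels {1, 2} only")
        return labels
    kind = mask_geometry[0]
    labels = np.full(shape, 2, dtype=np.uint8)
    if kind == "split":
        frac = mask_geometry[1]
        labels[:, : int(round(shape[1] * frac))] = 1
    elif kind == "disc":
        cy, cx, r = mask_geometry[1:]
        yy, xx = np.mgrid[: shape[0], : shape[1]]
        labels[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = 1
        labels = 3 - labels  # disc = ordered domain (phase 2) in L_d sea
    else:
        raise ValueError(f"unknown geometry {kind!r}")
    if (labels == 1).sum() == 0 or (labels == 2).sum() == 0:
        raise ValueError("both phase regions must have non-zero area")
    return labels


@dataclass
class TwoPhaseImage:
    channel_marker: np.ndarray
    channel_signal: np.ndarray
    pixel_size: float
    truth: SyntheticTruth


def gen_two_phase_image(
    mask_geometry=("split", 0.5),
    density1: float = 1.0,  # signal channel, per um^2 in phase 1 (L_d)
    density2: float = 0.333,  # signal channel, per um^2 in phase 2
    mode: str = "point-emitters",
    psf_fwhm: float = 300.0,  # nm
    pixel_size: float = 100.0,  # nm
    shape: tuple[int, int] = (384, 384),
    noise: CameraNoise | None = None,
    marker_levels: tuple[float, float] = (1000.0, 100.0),
    photons_per_spot: float = 800.0,
    seed: int = 0,
) -> TwoPhaseImage:
    """Two-channel image of a phase-separated bilayer with known densities.

    Channel 1 carries the L_d marker (bright in phase 1); channel 2 carries
    the particle signal at per-phase densities ``density1``/``density2``.
    In ``"pixel-intensity"`` mode the densities are expected photon counts
    per um^2 spread uniformly over the phase; in ``"point-emitters"`` mode
    they are countable diffraction-limited spots per um^2 with
    ``photons_per_spot`` photons each.
    """
    from scipy.ndimage import gaussian_filter

    if density1 < 0 or density2 < 0:
        raise ValueError("densities must be non-negative")
    rng = np.random.default_rng(seed)
    noise = CameraNoise() if noise is None else noise
    labels = _labels_from_geometry(mask_geometry, shape)
    px_um = pixel_size * 1e-3
    px_area = px_um**2
    sigma_px = psf_fwhm / 2.3548 / pixel_size

    marker_mean = np.where(labels == 1, marker_levels[0], marker_levels[1]).astype(float)
    marker = noise.apply(gaussian_filter(marker_mean, sigma_px), rng)

    emitters = None
    if mode == "pixel-intensity":
        signal_mean = np.where(labels == 1, density1, density2) * px_area
        signal = noise.apply(gaussian_filter(signal_mean, sigma_px), rng)
    elif mode == "point-emitters":
        photons = np.zeros(shape, dtype=float)
        emitters = []
        half = int(np.ceil(4 * sigma_px))
        win = np.arange(-half, half + 1)
        for phase, dens in ((1, density1), (2, density2)):
            pix = np.argwhere(labels == phase)
            area_um2 = pix.shape[0] * px_area
            n_spots = rng.poisson(dens * area_um2)
            if n_spots == 0:
                continue
            choice = pix[rng.integers(0, pix.shape[0], n_spots)]
            sub = rng.uniform(-0.5, 0.5, (n_spots, 2))
            centers = choice + sub  # (row, col), pixel units
            for (r0, c0) in centers:
                ri = int(round(r0))
                ci = int(round(c0))
                rr = ri + win
                cc = ci + win
                ok_r = (rr >= 0) & (rr < shape[0])
                ok_c = (cc >= 0) & (cc < shape[1])
                g_r = np.exp(-((rr[ok_r] - r0) ** 2) / (2 * sigma_px**2))
                g_c = np.exp(-((cc[ok_c] - c0) ** 2) / (2 * sigma_px**2))
                stamp = np.outer(g_r, g_c)
                stamp *= photons_per_spot / (2 * np.pi * sigma_px**2)
                photons[np.ix_(rr[ok_r], cc[ok_c])] += stamp
                emitters.append((float((c0 + 0.5) * px_um), float((r0 + 0.5) * px_um), phase))
        signal = noise.apply(photons, rng)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    truth = SyntheticTruth(
        dataset_id=f"pslb-{seed}",
        parameters={
            "density1_um-2": density1,
            "density2_um-2": density2,
            "kp_true": (density1 / density2) if density2 > 0 else np.inf,
            "mode": mode,
            "pixel_size_nm": pixel_size,
            "psf_fwhm_nm": psf_fwhm,
            "camera_offset": noise.offset,
            "read_sd": noise.read_sd,
        },
        seed=seed,
        extras={"labels": labels, "emitters": emitters},
    )
    return TwoPhaseImage(
        channel_marker=marker, channel_signal=signal, pixel_size=pixel_size, truth=truth
    )


# ---------------------------------------------------------------------------
# GUV z-stacks


@dataclass
class GuvImage:
    stack: np.ndarray  # (z, y, x) membrane channel
    truth: SyntheticTruth


def gen_guv_image(
    radius: float = 10.0,  # um
    ring_density: float = 500.0,  # mean counts per ring pixel
    interior_density: float = 0.0,
    pixel_size: float = 200.0,  # nm
    z_step: float = 500.0,  # nm
    n_slices: int = 21,
    noise: CameraNoise | None = None,
    ring_sigma_px: float = 1.2,
    shape: tuple[int, int] | None = None,
    seed: int = 0,
) -> GuvImage:
    """Z-stack of a spherical vesicle membrane (annulus per slice).

    Slice at height z shows a ring of radius sqrt(R^2 - z^2) with a
    Gaussian radial profile of per-pixel peak amplitude ``ring_density``;
    the enclosed disc carries ``interior_density``.  The equatorial slice
    (largest circumference) is the one with maximal ring signal.
    """
    rng = np.random.default_rng(seed)
    noise = CameraNoise() if noise is None else noise
    r_px = radius * 1e3 / pixel_size
    if r_px < 10:
        raise ValueError("radius must span >= 10 pixels")
    if shape is None:
        n = int(np.ceil(2.6 * r_px))
        shape = (n, n)
    if 2 * r_px >= min(shape):
        raise ValueError("vesicle exceeds the field of view")
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)

    zs = (np.arange(n_slices) - (n_slices - 1) / 2.0) * z_step * 1e-3  # um
    stack = np.empty((n_slices,) + shape)
    eq_index = int(np.argmin(np.abs(zs)))
    for i, z in enumerate(zs):
        if abs(z) >= radius:
            mean = np.zeros(shape)
        else:
            rz_px = np.sqrt(radius**2 - z**2) * 1e3 / pixel_size
            ring = ring_density * np.exp(-((dist - rz_px) ** 2) / (2 * ring_sigma_px**2))
            mean = ring + np.where(dist < rz_px - 2 * ring_sigma_px, interior_density, 0.0)
        stack[i] = noise.apply(mean, rng)

    ring_mask = np.abs(dist - r_px) <= 1.5
    truth = SyntheticTruth(
        dataset_id=f"guv-{seed}",
        parameters={
            "radius_um": radius,
            "ring_density": ring_density,
            "interior_density": interior_density,
            "pixel_size_nm": pixel_size,
            "z_step_nm": z_step,
            "n_slices": n_slices,
            "equatorial_index": eq_index,
            "camera_offset": noise.offset,
        },
        seed=seed,
        extras={"ring_mask": ring_mask, "center_px": (cy, cx)},
    )
    return GuvImage(stack=stack, truth=truth)
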