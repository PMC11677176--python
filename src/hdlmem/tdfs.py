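"""Time-dependent fluorescence shift (TDFS) analysis.

Fits TCSPC emission decays by iterative reconvolution with the measured
instrument response, reconstructs time-resolved emission spectra (TRES)
from the fitted decays and the steady-state emission spectrum, and derives
the two scalar descriptors of solvent relaxation:

* the total spectral shift ``delta_nu = nu(0) - nu(inf)`` (probe-environment
  polarity / hydrogen-bond-network level), and
* the integrated relaxation time ``tau_r = int_0^inf (nu(t) - nu(inf)) /
  delta_nu dt`` (local mobility of the hydrated glycerol region).

``nu(0)`` is treated as a calibration constant (default 23,800 cm^-1 for
Laurdan in phosphatidylcholine bilayers); its independent estimation is out
of scope here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, least_squares
from scipy.signal import fftconvolve

__all__ = [
    "DecayCurve",
    "InstrumentResponse",
    "MultiExpFit",
    "TRES",
    "TdfsResult",
    "fit_decay_reconvolution",
    "reconstruct_tres",
    "compute_delta_nu",
    "compute_tau_r",
    "NU0_DEFAULT",
]

#: Time-zero TRES maximum for Laurdan in PC bilayers, cm^-1 (calibration constant).
NU0_DEFAULT = 23_800.0

#: Stated intrinsic uncertainties of the TDFS readouts.
DELTA_NU_UNCERTAINTY = 50.0  # cm^-1
TAU_R_UNCERTAINTY = 0.05  # ns


@dataclass
class DecayCurve:
    """Photon-counting decay at one emission wavelength.

    Parameters
    ----------
    emission_wavelength : float
        Emission wavelength in nm.
    time_axis : ndarray
        Uniform, strictly increasing time grid in ns.
    counts : ndarray
        Non-negative photon counts per bin.
    """

    emission_wavelength: float
    time_axis: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.time_axis.ndim != 1 or self.time_axis.size < 2:
            raise ValueError("time_axis must be a 1-d grid with >= 2 points")
        dt = np.diff(self.time_axis)
        if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("time_axis must be strictly increasing and uniform")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.counts.shape != self.time_axis.shape:
            raise ValueError("counts and time_axis must have equal length")

    @property
    def bin_width(self) -> float:
        return float(self.time_axis[1] - self.time_axis[0])

    @property
    def peak_count(self) -> float:
        return float(self.counts.max())


@dataclass
class InstrumentResponse:
    """Measured instrument response function (IRF) of the TCSPC setup."""

    time_axis: np.ndarray
    counts: np.ndarray
    fwhm_ps: float = 78.0

    def __post_init__(self) -> None:
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("IRF counts must be non-negative")

    @property
    def bin_width(self) -> float:
        return float(self.time_axis[1] - self.time_axis[0])

    def normalized(self) -> np.ndarray:
        """Baseline-subtracted, unit-area IRF profile."""
        c = self.counts.astype(float)
        n_base = max(4, c.size // 50)
        baseline = float(np.median(c[:n_base]))
        prof = np.clip(c - baseline, 0.0, None)
        s = prof.sum()
        if s <= 0:
            raise ValueError("IRF has no signal above baseline")
        return prof / s


@dataclass
class MultiExpFit:
    """Multi-exponential reconvolution fit of one decay.

    ``model(t) = sum_i amplitudes[i] * exp(-t / lifetimes[i])`` is the
    IRF-free impulse response; the fitted curve is its convolution with the
    (shifted) IRF plus a constant background.  Amplitudes may be negative
    (rise terms on the red edge of a relaxing emission band); the total
    time-integral stays positive for a physical decay.
    """

    amplitudes: np.ndarray
    lifetimes: np.ndarray
    time_shift: float
    background: float
    chi2_reduced: float
    emission_wavelength: float | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.amplitudes = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        self.lifetimes = np.atleast_1d(np.asarray(self.lifetimes, dtype=float))
        order = np.argsort(self.lifetimes)
        self.lifetimes = self.lifetimes[order]
        self.amplitudes = self.amplitudes[order]
        if np.any(self.lifetimes <= 0):
            raise ValueError("lifetimes must be positive")
        if not 1 <= self.lifetimes.size <= 4:
            raise ValueError("1-4 exponential components supported")

    @property
    def n_components(self) -> int:
        return int(self.lifetimes.size)

    def model(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.sum(
            self.amplitudes[:, None] * np.exp(-t[None, :] / self.lifetimes[:, None]),
            axis=0,
        )

    @property
    def integral(self) -> float:
        """Analytic integral of the impulse response over [0, inf)."""
        return float(np.sum(self.amplitudes * self.lifetimes))

    @property
    def mean_lifetime(self) -> float:
        """Amplitude-weighted mean lifetime, ns."""
        a = self.amplitudes
        return float(np.sum(a * self.lifetimes) / np.sum(a))


@dataclass
class TRES:
    """Reconstructed time-resolved emission spectra.

    ``intensity[i, j]`` is the spectral density at ``time_axis[i]`` and
    ``wavenumber_axis[j]`` (cm^-1, ascending).  ``nu_t`` and ``fwhm_t`` hold
    the per-time band maximum position and width from a line-shape fit.
    """

    wavenumber_axis: np.ndarray
    time_axis: np.ndarray
    intensity: np.ndarray
    nu_t: np.ndarray
    fwhm_t: np.ndarray
    jacobian_applied: bool = True

    def population(self) -> np.ndarray:
        """Per-time integral of the spectrum over the wavenumber axis."""
        return np.trapezoid(self.intensity, self.wavenumber_axis, axis=1)

    def support_time(self, frac: float = 0.01) -> float:
        """Latest time at which the emitting population still exceeds
        ``frac`` of its maximum.  Beyond this point the reconstruction
        extrapolates the fitted decays without photon support and the band
        position becomes unreliable."""
        pop = self.population()
        above = np.flatnonzero(pop >= frac * pop.max())
        return float(self.time_axis[above[-1]]) if above.size else float(self.time_axis[-1])


@dataclass
class TdfsResult:
    """Scalar TDFS readouts with their intrinsic uncertainties."""

    nu0: float
    nu_inf: float
    delta_nu: float
    tau_r: float
    uncertainty_delta_nu: float = DELTA_NU_UNCERTAINTY
    uncertainty_tau_r: float = TAU_R_UNCERTAINTY
    flags: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Reconvolution fitting


def _reconvolved(
    irf_norm: np.ndarray,
    t: np.ndarray,
    amplitudes: np.ndarray,
    lifetimes: np.ndarray,
    shift: float,
    background: float,
) -> np.ndarray:
    """Background + (shifted IRF) x multi-exponential, on the decay grid."""
    dt = t[1] - t[0]
    # sub-bin IRF shift by linear interpolation (positive shift delays the IRF)
    bins = np.arange(irf_norm.size)
    shifted = np.interp(bins - shift / dt, bins, irf_norm, left=0.0, right=0.0)
    trel = t - t[0]
    impulse = np.sum(
        amplitudes[:, None] * np.exp(-trel[None, :] / lifetimes[:, None]), axis=0
    )
    conv = fftconvolve(shifted, impulse)[: t.size] * dt
    return background + conv


def _fit_fixed_n(decay, irf_norm, n, weights, taus0=None):
    """Variable-projection fit: lifetimes and IRF shift are the nonlinear
    parameters; amplitudes and background are solved linearly at each step.
    Amplitudes may be negative (red-edge rise terms)."""
    t = decay.time_axis
    counts = decay.counts.astype(float)
    dt = decay.bin_width
    bg0 = float(np.median(counts[: max(4, counts.size // 50)]))
    ipk = int(np.argmax(counts))
    tail_t = t[ipk:] - t[ipk]
    tail_c = np.clip(counts[ipk:] - bg0, 0, None)
    tau_est = max(float(np.sum(tail_t * tail_c) / max(tail_c.sum(), 1.0)), 5 * dt)
    if taus0 is None:
        taus0 = np.array([tau_est]) if n == 1 else np.geomspace(tau_est / 4.0, tau_est * 1.5, n)
    bins = np.arange(irf_norm.size)
    trel = t - t[0]
    wc = counts * weights

    def design(p):
        taus = np.exp(p[:n])
        shifted = np.interp(bins - p[n] / dt, bins, irf_norm, left=0.0, right=0.0)
        cols = np.empty((t.size, n + 1))
        for i, tau in enumerate(taus):
            impulse = np.exp(-trel / tau)
            cols[:, i] = fftconvolve(shifted, impulse)[: t.size] * dt
        cols[:, n] = 1.0  # constant background
        return cols

    def solve(p):
        a = design(p) * weights[:, None]
        coef, *_ = np.linalg.lstsq(a, wc, rcond=None)
        return coef, a @ coef - wc

    def resid(p):
        return solve(p)[1]

    p0 = np.concatenate([np.log(taus0), [0.0]])
    lo = np.concatenate([np.full(n, np.log(dt / 4)), [-20 * dt]])
    hi = np.concatenate([np.full(n, np.log(10 * (t[-1] - t[0]))), [20 * dt]])
    sol = least_squares(resid, p0, bounds=(lo, hi), method="trf", max_nfev=200)
    # second pass with Pearson weights (sigma^2 from the fitted model):
    # Neyman weighting from raw counts biases reduced chi-square upward in
    # low-count bins
    coef, _ = solve(sol.x)
    model = design(sol.x) @ coef
    weights = 1.0 / np.sqrt(np.clip(model, 1.0, None))
    wc = counts * weights
    sol = least_squares(resid, sol.x, bounds=(lo, hi), method="trf", max_nfev=200)
    coef, _ = solve(sol.x)
    params = {
        "amplitudes": coef[:n],
        "lifetimes": np.exp(sol.x[:n]),
        "shift": float(sol.x[n]),
        "background": float(coef[n]),
    }
    # report the Pearson chi-square of the final model (variance from the
    # model, not from the possibly stale optimisation weights)
    model = design(sol.x) @ coef
    ndof = max(counts.size - (2 * n + 2), 1)
    chi2 = float(np.sum((counts - model) ** 2 / np.clip(model, 1.0, None)) / ndof)
    return params, chi2


def fit_decay_reconvolution(
    decay: DecayCurve,
    irf: InstrumentResponse,
    n_components: int | None = None,
    max_components: int = 3,
    improvement: float = 0.05,
) -> MultiExpFit:
    """Fit a decay with a multi-exponential model by iterative reconvolution.

    The model is ``background + (shifted IRF) (x) sum_i a_i exp(-t/tau_i)``
    with Poisson weighting (sigma = sqrt(max(counts, 1))).  When
    ``n_components`` is None the component count is chosen automatically:
    a component is added (up to ``max_components``) only while it improves
    reduced chi-square by more than ``improvement`` (guarding against
    over-parameterisation).  Nearly degenerate lifetime pairs trigger a
    refit with one component fewer.
    """
    if not np.isclose(decay.bin_width, irf.bin_width, rtol=1e-6):
        raise ValueError("decay and IRF must share one bin width")
    if n_components is not None and not 1 <= n_components <= 4:
        raise ValueError("n_components must be in 1-4")

    irf_norm = irf.normalized()
    counts = decay.counts.astype(float)
    weights = 1.0 / np.sqrt(np.clip(counts, 1.0, None))

    ns = [n_components] if n_components is not None else list(
        range(1, max_components + 1)
    )
    best = None
    prev_taus = None
    for n in ns:
        # warm start: reuse the previous lifetimes plus one faster component
        taus0 = None
        if prev_taus is not None and prev_taus.size == n - 1:
            taus0 = np.sort(np.append(prev_taus, prev_taus.min() / 3.0))
        params, chi2 = _fit_fixed_n(decay, irf_norm, n, weights, taus0=taus0)
        prev_taus = params["lifetimes"]
        if best is None or chi2 < best[2] * (1.0 - improvement):
            best = (n, params, chi2)
    n, params, chi2 = best
    amps, taus = params["amplitudes"], params["lifetimes"]

    # collapse nearly degenerate lifetimes (only same-sign amplitude pairs:
    # an opposite-sign pair with close lifetimes encodes a genuine rise)
    if n > 1:
        order = np.argsort(taus)
        taus_s, amps_s = taus[order], amps[order]
        same_sign = np.sign(amps_s[1:]) == np.sign(amps_s[:-1])
        if np.any((taus_s[1:] / taus_s[:-1] < 1.2) & same_sign):
            warnings.warn(
                "degenerate lifetimes; reducing component count", stacklevel=2
            )
            n -= 1
            params, chi2 = _fit_fixed_n(decay, irf_norm, n, weights)
            amps, taus = params["amplitudes"], params["lifetimes"]

    fit = MultiExpFit(
        amplitudes=amps,
        lifetimes=taus,
        time_shift=params["shift"],
        background=params["background"],
        chi2_reduced=chi2,
        emission_wavelength=decay.emission_wavelength,
    )
    # degenerate when the exponential model barely improves on a pure
    # background description (no real signal)
    bg_only = float(np.median(counts))
    chi2_bg = float(np.sum(((counts - bg_only) * weights) ** 2) / max(counts.size - 1, 1))
    if chi2_bg - chi2 < 0.05 * chi2_bg:
        fit.degenerate = True
    return fit


# ---------------------------------------------------------------------------
# TRES reconstruction


def _lognormal_line(nu, h, nu_p, width, asym):
    """Asymmetric log-normal band; reduces to a Gaussian of FWHM ``width``
    as ``asym -> 0``.  Maximum value ``h`` at ``nu_p``."""
    arg = 1.0 + 2.0 * asym * (nu - nu_p) / width
    out = np.zeros_like(np.asarray(nu, dtype=float))
    ok = arg > 0
    a = np.where(np.abs(asym) < 1e-8, 1e-8, asym)
    out[ok] = h * np.exp(-np.log(2.0) * (np.log(arg[ok]) / a) ** 2)
    return out


def _fit_band(nu: np.ndarray, y: np.ndarray, lineshape: str = "gaussian") -> tuple[float, float]:
    """Return (peak position, FWHM) of one spectral slice.

    Default is a symmetric Gaussian band fit: on the 16-point spectral grid
    with a partially covered blue wing the extra asymmetry degree of freedom
    of a log-normal line is poorly constrained and amplifies reconstruction
    systematics in the extracted maximum (``lineshape="lognormal"`` remains
    available for genuinely skewed bands).  Fallback: parabolic fit of the
    log-intensity about the maximum.
    """
    imax = int(np.argmax(y))
    h0 = float(y[imax])
    nu_p0 = float(nu[imax])
    # moment-based width guess
    w = np.clip(y, 0, None)
    if w.sum() > 0:
        mu = float(np.sum(nu * w) / w.sum())
        sd = float(np.sqrt(np.sum((nu - mu) ** 2 * w) / w.sum()))
    else:
        sd = (nu[-1] - nu[0]) / 4
    width0 = max(2.3548 * sd, (nu[1] - nu[0]) * 2)
    try:
        if lineshape == "gaussian":
            popt, _ = curve_fit(
                lambda x, h, c, fwhm: h * np.exp(-((x - c) ** 2) * 2.7726 / fwhm**2),
                nu,
                y,
                p0=[h0, nu_p0, width0],
                bounds=([0, nu[0] - width0, width0 / 10], [np.inf, nu[-1] + width0, width0 * 10]),
                maxfev=2000,
            )
        else:
            popt, _ = curve_fit(
                _lognormal_line,
                nu,
                y,
                p0=[h0, nu_p0, width0, 0.01],
                bounds=(
                    [0, nu[0] - width0, width0 / 10, -0.9],
                    [np.inf, nu[-1] + width0, width0 * 10, 0.9],
                ),
                maxfev=2000,
            )
        return float(popt[1]), float(abs(popt[2]))
    except (RuntimeError, ValueError):
        pass
    # parabolic fallback on log intensity around the maximum
    lo, hi = max(imax - 2, 0), min(imax + 3, nu.size)
    xs, ys = nu[lo:hi], np.log(np.clip(y[lo:hi], 1e-300, None))
    coef = np.polyfit(xs, ys, 2)
    if coef[0] >= 0:
        return nu_p0, width0
    nu_p = -coef[1] / (2 * coef[0])
    fwhm = 2.3548 / np.sqrt(-2 * coef[0])
    return float(nu_p), float(fwhm)


def default_time_grid(t_min: float = 1e-3, t_max: float = 50.0, n: int = 200) -> np.ndarray:
    """Logarithmic TRES time grid, ns (resolves sub-ns and ns relaxation)."""
    return np.geomspace(t_min, t_max, n)


def reconstruct_tres(
    fits: dict[float, MultiExpFit] | list[MultiExpFit],
    steady_state,
    time_grid: np.ndarray | None = None,
    jacobian: bool = True,
    chi2_max: float = 2.5,
    lineshape: str = "gaussian",
) -> TRES:
    """Reconstruct TRES from per-wavelength decay fits and the steady-state
    emission spectrum.

    For each wavelength the fitted (IRF-free) decay is normalised to unit
    time-integral and scaled by the steady-state intensity:
    ``S(lambda, t) = I_ss(lambda) * D_fit(lambda, t) / int D_fit dt``.
    Intensities are then mapped to a wavenumber density; by default the
    lambda^2 Jacobian is applied (``jacobian=False`` gives the uncorrected
    convention).  The band maximum ``nu(t)`` and FWHM(t) are extracted per
    time slice by a log-normal line-shape fit.

    Parameters
    ----------
    fits
        Mapping wavelength (nm) -> MultiExpFit, or a list of fits whose
        ``emission_wavelength`` is set.
    steady_state
        ``(wavelength_nm, intensity)`` table: a pandas DataFrame with those
        columns or a 2-column array.
    """
    if not isinstance(fits, dict):
        fits = {f.emission_wavelength: f for f in fits}
    ss = np.asarray(
        steady_state[["wavelength_nm", "intensity"]]
        if hasattr(steady_state, "columns")
        else steady_state,
        dtype=float,
    )
    usable = {}
    for lam, fit in sorted(fits.items()):
        if fit.chi2_reduced > chi2_max or fit.degenerate:
            warnings.warn(
                f"excluding decay at {lam} nm (chi2_red={fit.chi2_reduced:.2f})",
                stacklevel=2,
            )
            continue
        usable[lam] = fit
    if len(usable) < 5:
        raise ValueError(
            f"only {len(usable)} usable wavelengths (< 5); cannot reconstruct TRES"
        )

    lams = np.array(sorted(usable))
    if not (ss[:, 0].min() <= lams.min() and ss[:, 0].max() >= lams.max()):
        raise ValueError("steady-state spectrum does not cover the decay wavelengths")
    i_ss = np.interp(lams, ss[:, 0], ss[:, 1])

    t = default_time_grid() if time_grid is None else np.asarray(time_grid, float)
    # rows: time, cols: wavelength
    s_lambda = np.empty((t.size, lams.size))
    for j, lam in enumerate(lams):
        fit = usable[lam]
        s_lambda[:, j] = i_ss[j] * fit.model(t) / fit.integral

    nu = 1e7 / lams  # cm^-1, descending with wavelength
    s_nu = s_lambda * (lams**2 / 1e7) if jacobian else s_lambda
    order = np.argsort(nu)
    nu_axis = nu[order]
    intensity = s_nu[:, order]

    nu_t = np.empty(t.size)
    fwhm_t = np.empty(t.size)
    for i in range(t.size):
        nu_t[i], fwhm_t[i] = _fit_band(nu_axis, intensity[i], lineshape=lineshape)

    return TRES(
        wavenumber_axis=nu_axis,
        time_axis=t,
        intensity=intensity,
        nu_t=nu_t,
        fwhm_t=fwhm_t,
        jacobian_applied=jacobian,
    )


# ---------------------------------------------------------------------------
# Scalar TDFS readouts


def compute_delta_nu(
    tres: TRES,
    nu0: float = NU0_DEFAULT,
    slope_tol: float = 10.0,
    support_frac: float = 0.1,
) -> tuple[float, float, list]:
    """Total spectral shift ``delta_nu = nu0 - nu(inf)``.

    ``nu(inf)`` is the fully-relaxed band position, estimated inside the
    data-supported time window (population >= 1% of its maximum; beyond it
    the reconstruction extrapolates without photon support).  The primary
    estimator is the asymptote of a mono-exponential relaxation fit to
    ``nu(t)``, which removes the residual tail that a plain late-time mean
    would retain.  When that fit fails or implies an unresolved relaxation
    (fitted time constant longer than half the window), the earliest
    window ``[t*, 2 t*]`` with slope below ``slope_tol`` cm^-1/ns is used
    instead; with no such window the result is flagged ``"no_plateau"``
    and is a lower bound.  Returns ``(delta_nu, nu_inf, flags)``.
    """
    flags: list = []
    t_sup = tres.support_time(support_frac)
    keep = tres.time_axis <= t_sup
    t, nu_t = tres.time_axis[keep], tres.nu_t[keep]

    # fit the asymptote on the tail only, where the slowest relaxation
    # component dominates (keeps multi-exponential relaxations unbiased)
    tail = t >= t_sup / 4.0
    if tail.sum() < 6:
        tail = np.ones_like(t, dtype=bool)
    est = _exp_asymptote(t[tail], nu_t[tail])
    nu_inf = None
    if est is not None and est[1] < t_sup / 2.0:
        nu_inf = est[0]
    else:
        for i in range(t.size - 3):
            j = int(np.searchsorted(t, 2.0 * t[i]))
            if j >= t.size:
                break
            if j - i < 3:
                continue
            window = slice(i, j + 1)
            slope = float(np.polyfit(t[window], nu_t[window], 1)[0])
            if abs(slope) < slope_tol:
                nu_inf = float(np.mean(nu_t[window]))
                flags.append("plateau_window")
                break
    if nu_inf is None:
        nu_inf = float(np.mean(nu_t[-5:]))
        flags.append("no_plateau")
        warnings.warn(
            "relaxation unresolved within the observed window; "
            "delta_nu is a lower bound",
            stacklevel=2,
        )
    if nu0 < nu_t[0] - 2 * DELTA_NU_UNCERTAINTY:
        flags.append("nu0_below_observed")
        warnings.warn(
            f"nu0={nu0:.0f} cm^-1 is below the observed nu(t=0)={nu_t[0]:.0f}",
            stacklevel=2,
        )
    return nu0 - nu_inf, nu_inf, flags


def _exp_asymptote(t: np.ndarray, nu_t: np.ndarray) -> tuple[float, float] | None:
    """``(asymptote, time constant)`` of a mono-exponential relaxation fit
    to ``nu(t)``, or None when the fit fails."""

    def model(tt, nu_inf, amp, tau):
        return nu_inf + amp * np.exp(-tt / tau)

    span = float(nu_t[0] - nu_t[-1])
    try:
        popt, _ = curve_fit(
            model, t, nu_t,
            p0=[nu_t[-1], max(span, 1.0), max(t[-1] / 5.0, t[1])],
            maxfev=5000,
        )
    except (RuntimeError, ValueError):
        return None
    return float(popt[0]), float(abs(popt[2]))


def compute_tau_r(
    tres: TRES,
    nu_inf: float,
    delta_nu: float,
    cut_level: float = 0.01,
    tail_warn_frac: float = 0.2,
    support_frac: float = 0.1,
) -> tuple[float, list]:
    """Integrated relaxation time ``tau_r`` (ns).

    Trapezoidal integral of the normalised shift correlation
    ``c(t) = (nu(t) - nu(inf)) / delta_nu`` over the data-supported window
    up to the point where ``|c|`` falls below ``cut_level``, plus an
    exponential-tail extrapolation fitted to the final decade of ``c``.
    Returns ``(tau_r, flags)``; flag ``"tail_unreliable"`` is set when the
    extrapolated tail exceeds ``tail_warn_frac`` of the total.
    """
    if delta_nu <= 0:
        raise ValueError("delta_nu must be positive to normalise the correlation")
    keep = tres.time_axis <= tres.support_time(support_frac)
    t = np.concatenate([[0.0], tres.time_axis[keep]])
    c = (np.concatenate([[tres.nu_t[0]], tres.nu_t[keep]]) - nu_inf) / delta_nu

    below = np.flatnonzero(np.abs(c) < cut_level)
    i_cut = int(below[0]) if below.size else c.size - 1
    i_cut = max(i_cut, 2)
    core = float(np.trapezoid(c[: i_cut + 1], t[: i_cut + 1]))

    # exponential tail from the decaying region c in [cut_level, 0.2]
    sel = (c[: i_cut + 1] > cut_level) & (c[: i_cut + 1] < 0.2)
    tail = 0.0
    if sel.sum() >= 3 and c[i_cut] > 0:
        slope = np.polyfit(t[: i_cut + 1][sel], np.log(c[: i_cut + 1][sel]), 1)[0]
        if slope < 0:
            tau_tail = -1.0 / slope
            tail = float(c[i_cut] * tau_tail)
    total = core + tail
    flags: list = []
    if total > 0 and tail / total > tail_warn_frac:
        flags.append("tail_unreliable")
        warnings.warn(
            f"tail extrapolation is {100 * tail / total:.0f}% of tau_r",
            stacklevel=2,
        )
    return total, flags


def analyze_tdfs(
    decays: list[DecayCurve],
    irf: InstrumentResponse,
    steady_state,
    nu0: float = NU0_DEFAULT,
    jacobian: bool = True,
    n_components: int | None = None,
) -> TdfsResult:
    """Full TDFS chain: reconvolution fits -> TRES -> delta_nu and tau_r."""
    fits = [fit_decay_reconvolution(d, irf, n_components=n_components) for d in decays]
    tres = reconstruct_tres(fits, steady_state, jacobian=jacobian)
    delta_nu, nu_inf, flags = compute_delta_nu(tres, nu0=nu0)
    tau_r, flags2 = compute_tau_r(tres, nu_inf, delta_nu)
    return TdfsResult(
        nu0=nu0,
        nu_inf=nu_inf,
        delta_nu=delta_nu,
        tau_r=tau_r,
        flags=flags + flags2,
    )
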