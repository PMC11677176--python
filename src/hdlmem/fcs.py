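"""Fluorescence correlation spectroscopy on membrane (2-d) diffusion.

The intensity autocorrelation ``G(tau) = <dI(t) dI(t+tau)> / <I>^2`` is
computed with a multi-tau scheme (quasi-logarithmic lag spacing) and fitted
with the standard one-component 2-d diffusion + triplet model

    G(tau) = (1/N) * (1 + tau/tau_D)^-1
             * (1 + T/(1-T) * exp(-tau/tau_T)) + G_inf

yielding the mean number of molecules N in the focus, the diffusion time
tau_D, and — given the beam waist w0 — the lateral diffusion constant
``D = w0^2 / (4 tau_D)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "IntensityTrace",
    "CorrelationCurve",
    "FcsFit",
    "autocorrelate",
    "fit_2d_triplet",
    "aggregate_sample",
]

#: Default beam waist (um), typical for a high-NA water objective at ~640 nm.
W0_DEFAULT = 0.25


@dataclass
class IntensityTrace:
    """Binned photon-count time trace."""

    dt: float  # bin width, s
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def duration(self) -> float:
        return float(self.counts.size * self.dt)


@dataclass
class CorrelationCurve:
    """Normalized fluctuation autocorrelation with per-lag block SE."""

    lag_axis: np.ndarray  # s, strictly increasing, quasi-log spaced
    g_values: np.ndarray
    se: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.lag_axis) <= 0):
            raise ValueError("lags must be strictly increasing")


@dataclass
class FcsFit:
    """Fitted 2-d diffusion + triplet model parameters."""

    n_mean: float
    tau_d: float  # s
    triplet_frac: float
    tau_triplet: float  # s
    g_inf: float
    w0: float  # um
    chi2_reduced: float
    fit_se: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    @property
    def d(self) -> float:
        """Lateral diffusion constant, um^2/s (= w0^2 / (4 tau_D))."""
        return self.w0**2 / (4.0 * self.tau_d)


# ---------------------------------------------------------------------------
# Multi-tau correlation


def _multitau_raw(x: np.ndarray, m: int = 16) -> tuple[np.ndarray, np.ndarray]:
    """Multi-tau autocorrelation of one block.

    Returns (lags_in_bins, <x(t) x(t+lag)> / (<x_left><x_right>)) using the
    symmetric normalization that is unbiased for finite blocks.
    """
    x = x.astype(float)
    lags, g = [], []
    level = 0
    binwidth = 1
    while True:
        n = x.size
        ks = np.arange(1, m + 1) if level == 0 else np.arange(m // 2 + 1, m + 1)
        if n < 2 * m:
            break
        for k in ks:
            a, b = x[: n - k], x[k:]
            denom = a.mean() * b.mean()
            if denom <= 0:
                g.append(0.0)
            else:
                g.append(float(np.dot(a, b) / (n - k) / denom) - 1.0)
            lags.append(k * binwidth)
        # coarsen by pairwise averaging for the next level
        if n % 2:
            x = x[:-1]
        x = 0.5 * (x[::2] + x[1::2])
        binwidth *= 2
        level += 1
    return np.array(lags, dtype=float), np.array(g)


def autocorrelate(
    trace: IntensityTrace,
    m: int = 16,
    n_blocks: int = 10,
    min_bins: int = 100_000,
) -> CorrelationCurve:
    """Multi-tau autocorrelation with block-splitting standard errors.

    The trace is split into ``n_blocks`` contiguous blocks; the correlation
    of each block is computed independently and the returned curve is their
    mean with SE = sd/sqrt(n_blocks).  Lags longer than a tenth of a block
    are discarded (they are not estimable within a block).
    """
    counts = trace.counts
    if counts.size < min_bins:
        raise ValueError(f"trace has {counts.size} bins; >= {min_bins} required")
    if counts.mean() == 0:
        raise ValueError("mean intensity is zero")
    block_len = counts.size // n_blocks
    gs = []
    lags = None
    for b in range(n_blocks):
        lag_b, g_b = _multitau_raw(counts[b * block_len : (b + 1) * block_len], m=m)
        if lags is None:
            lags = lag_b
        gs.append(g_b[: lags.size])
    gmat = np.vstack(gs)
    keep = lags <= block_len / 10
    lags, gmat = lags[keep], gmat[:, keep]
    g_mean = gmat.mean(axis=0)
    g_se = gmat.std(axis=0, ddof=1) / np.sqrt(n_blocks)
    return CorrelationCurve(lag_axis=lags * trace.dt, g_values=g_mean, se=g_se)


# ---------------------------------------------------------------------------
# Model fitting


def _model_2d_triplet(tau, n_mean, tau_d, t_frac, tau_t, g_inf):
    g = (1.0 / n_mean) / (1.0 + tau / tau_d)
    if t_frac > 0:
        g = g * (1.0 + t_frac / (1.0 - t_frac) * np.exp(-tau / tau_t))
    return g + g_inf


def fit_2d_triplet(
    curve: CorrelationCurve,
    w0: float = W0_DEFAULT,
    fit_triplet: bool = True,
    fit_range: tuple[float, float] = (10e-6, 1.0),
) -> FcsFit:
    """Fit the one-component 2-d diffusion (+ triplet) model.

    Weighted least squares with inverse block-SE weights; the offset
    ``G_inf`` is floated.  When the fitted triplet time collides with the
    diffusion time (separation < 10x) the triplet term is disabled with a
    warning and the fit repeated.
    """
    sel = (curve.lag_axis >= fit_range[0]) & (curve.lag_axis <= fit_range[1])
    tau = curve.lag_axis[sel]
    g = curve.g_values[sel]
    se = curve.se[sel]
    if tau.size < 8:
        raise ValueError("too few lags inside the fit range")
    if np.log10(tau[-1] / tau[0]) < 2.0:
        warnings.warn("correlation spans < 2 decades of lag; fit may be ill-posed", stacklevel=2)
    w = 1.0 / np.clip(se, max(1e-6, np.median(se) * 1e-3), None)

    g0 = max(float(np.mean(g[: max(3, tau.size // 20)])), 1e-6)
    # diffusion-time guess: lag where g first drops below half its amplitude
    half = np.flatnonzero(g < g0 / 2)
    tau_d0 = float(tau[half[0]]) if half.size else float(np.sqrt(tau[0] * tau[-1]))

    def _fit(with_triplet: bool):
        if with_triplet:
            p0 = [1.0 / g0, tau_d0, 0.1, min(5e-6, tau_d0 / 100), 0.0]
            lo = [1e-3, tau[0] / 10, 0.0, tau[0] / 100, -np.inf]
            hi = [np.inf, tau[-1] * 10, 0.8, tau[-1], np.inf]
        else:
            p0 = [1.0 / g0, tau_d0, 0.0]
            lo = [1e-3, tau[0] / 10, -np.inf]
            hi = [np.inf, tau[-1] * 10, np.inf]

        def resid(p):
            if with_triplet:
                model = _model_2d_triplet(tau, p[0], p[1], p[2], p[3], p[4])
            else:
                model = _model_2d_triplet(tau, p[0], p[1], 0.0, 1.0, p[2])
            return (model - g) * w

        sol = least_squares(resid, p0, bounds=(lo, hi), x_scale="jac")
        ndof = max(tau.size - len(p0), 1)
        return sol, float(np.sum(sol.fun**2) / ndof)

    flags = []
    if fit_triplet:
        sol, chi2 = _fit(True)
        n_mean, tau_d, t_frac, tau_t, g_inf = sol.x
        if t_frac > 1e-3 and tau_d / tau_t < 10.0:
            warnings.warn(
                "triplet time within 10x of the diffusion time; disabling triplet",
                stacklevel=2,
            )
            flags.append("triplet_disabled")
            sol, chi2 = _fit(False)
            n_mean, tau_d, g_inf = sol.x
            t_frac, tau_t = 0.0, np.nan
    else:
        sol, chi2 = _fit(False)
        n_mean, tau_d, g_inf = sol.x
        t_frac, tau_t = 0.0, np.nan

    return FcsFit(
        n_mean=float(n_mean),
        tau_d=float(tau_d),
        triplet_frac=float(t_frac),
        tau_triplet=float(tau_t),
        g_inf=float(g_inf),
        w0=w0,
        chi2_reduced=chi2,
        flags=flags,
    )


def aggregate_sample(
    fits: list[FcsFit],
    vesicle_ids: list,
    replicate_ids: list | None = None,
) -> dict:
    """Per-sample diffusion summary following the replicate structure
    (several traces per vesicle, >= 5 vesicles, 3 technical replicates).

    Traces are first averaged within each (replicate, vesicle); the sample
    mean and SE are then taken across vesicles and replicates.  ``n`` is
    the total number of measurements (traces).
    """
    if not fits:
        raise ValueError("no fits to aggregate")
    if replicate_ids is None:
        replicate_ids = [0] * len(fits)
    ds = np.array([f.d for f in fits])
    keys = list(zip(replicate_ids, vesicle_ids))
    uniq = sorted(set(keys))
    per_vesicle = np.array([ds[[i for i, k in enumerate(keys) if k == u]].mean() for u in uniq])
    flags = []
    if per_vesicle.size < 2:
        flags.append("single_vesicle_se_undefined")
        se = np.nan
    else:
        se = float(per_vesicle.std(ddof=1) / np.sqrt(per_vesicle.size))
    return {
        "mean_d": float(per_vesicle.mean()),
        "se_d": se,
        "n": len(fits),
        "n_vesicles": per_vesicle.size,
        "flags": flags,
    }
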