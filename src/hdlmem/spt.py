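"""Single-particle tracking: localization, linking, and mobility analysis.

Trajectories of membrane-bound particles are decomposed with three models:

* free (Brownian) diffusion, ``msd = 4 D t_lag + 4 sigma_xy^2`` — a weighted
  linear fit yielding the lateral diffusion constant D and the localization
  precision sigma_xy;
* a bimodal mixture, fitted on the cumulative distribution of square
  displacements, ``cdf = 1 - alpha exp(-sd/msd1) - (1-alpha) exp(-sd/msd2)``,
  yielding the fraction alpha of the slow component and per-lag msd1/msd2;
* confined diffusion inside an impermeable circle of radius R,
  ``msd = R^2 (1 - exp(-4 D t_lag / R^2))``.

Time lags follow ``t_lag = n (t_ill + t_delay)`` with illumination time
t_ill and inter-frame delay t_delay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, least_squares

__all__ = [
    "Localization",
    "Trajectory",
    "MsdCurve",
    "DiffusionFit",
    "detect_spots",
    "link_trajectories",
    "compute_msd",
    "fit_free_diffusion",
    "fit_bimodal_cdf",
    "fit_confined",
    "classify_mobility",
    "square_displacements",
]


@dataclass
class Localization:
    """Single-molecule position (um) with localization precision (nm)."""

    x: float
    y: float
    frame: int
    precision: float = np.nan
    amplitude: float = np.nan
    saturated: bool = False


@dataclass
class Trajectory:
    """Time-ordered 2-d positions of one particle.

    ``x``/``y`` in um, ``frames`` strictly increasing integer indices,
    ``t_ill``/``t_delay`` in ms.  The frame period is ``t_ill + t_delay``.
    """

    x: np.ndarray
    y: np.ndarray
    frames: np.ndarray
    t_ill: float = 5.0
    t_delay: float = 15.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.frames = np.asarray(self.frames, dtype=int)
        if self.x.size < 2:
            raise ValueError("a trajectory needs >= 2 points")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return int(self.x.size)

    @property
    def frame_time(self) -> float:
        """Frame period in seconds."""
        return (self.t_ill + self.t_delay) * 1e-3


@dataclass
class MsdCurve:
    """Ensemble mean square displacement vs time lag."""

    t_lag: np.ndarray  # s
    msd: np.ndarray  # um^2
    n_pairs: np.ndarray

    def __post_init__(self) -> None:
        self.t_lag = np.asarray(self.t_lag, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)


@dataclass
class DiffusionFit:
    """Result of one mobility-model fit."""

    model: str  # "free" | "confined" | "bimodal" | "monomodal"
    d: float = np.nan  # um^2/s
    sigma_xy: float = np.nan  # nm
    alpha: float = np.nan
    msd1: np.ndarray | None = None  # um^2 per t_lag (slow component)
    msd2: np.ndarray | None = None  # um^2 per t_lag (fast component)
    t_lag: np.ndarray | None = None
    radius: float = np.nan  # um
    fit_se: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Localization


def _gauss2d(coords, amp, x0, y0, sigma, offset):
    x, y = coords
    return (amp * np.exp(-((x - x0) ** 2 + (y - y0) ** 2) / (2 * sigma**2)) + offset).ravel()


def detect_spots(
    frame: np.ndarray,
    threshold: float = 5.0,
    pixel_size: float = 100.0,
    psf_fwhm: float = 300.0,
    overlap: str = "drop",
    saturation: float | None = None,
) -> list[Localization]:
    """Detect diffraction-limited spots and localize them by 2-d Gaussian fit.

    Local maxima of the smoothed image exceeding
    ``background + threshold * sd`` (robust estimates) are refined on a
    cutout with a symmetric 2-d Gaussian; sub-pixel centres are returned in
    um (pixel centres at half-integer pixel coordinates) and the precision
    (nm) comes from the fit covariance of the centre.  Spots closer than one
    PSF FWHM are merged or dropped according to ``overlap``.
    """
    from scipy.ndimage import gaussian_filter, maximum_filter

    if frame.ndim != 2:
        raise ValueError("detect_spots expects a single-channel 2-d frame")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    img = frame.astype(float)
    sigma_px = psf_fwhm / 2.3548 / pixel_size
    smooth = gaussian_filter(img, sigma_px)
    bg = float(np.median(smooth))
    sd = 1.4826 * float(np.median(np.abs(smooth - bg)))
    if sd == 0:
        sd = float(np.std(smooth)) or 1.0
    level = bg + threshold * sd

    size = max(3, int(round(3 * sigma_px)) | 1)
    is_max = (smooth == maximum_filter(smooth, size=size)) & (smooth > level)
    # filter-padding artifacts concentrate at the border; a fit window must
    # fit inside the frame anyway
    margin = max(2, int(round(2 * sigma_px)))
    is_max[:margin, :] = is_max[-margin:, :] = False
    is_max[:, :margin] = is_max[:, -margin:] = False
    peaks = np.argwhere(is_max)

    # overlap handling on candidate peaks
    if peaks.shape[0] > 1:
        min_sep_px = psf_fwhm / pixel_size
        keep = np.ones(len(peaks), dtype=bool)
        d2 = np.sum((peaks[:, None, :] - peaks[None, :, :]) ** 2, axis=-1)
        close = (d2 < min_sep_px**2) & ~np.eye(len(peaks), dtype=bool)
        if overlap == "drop":
            keep &= ~close.any(axis=1)
        else:  # merge: keep the brighter member of each close pair
            amps = smooth[peaks[:, 0], peaks[:, 1]]
            for i, j in zip(*np.nonzero(np.triu(close))):
                keep[j if amps[i] >= amps[j] else i] = False
        peaks = peaks[keep]

    half = max(4, int(round(3 * sigma_px)))
    locs: list[Localization] = []
    for r, c in peaks:
        r0, r1 = max(r - half, 0), min(r + half + 1, img.shape[0])
        c0, c1 = max(c - half, 0), min(c + half + 1, img.shape[1])
        patch = img[r0:r1, c0:c1]
        yy, xx = np.mgrid[r0:r1, c0:c1]
        p0 = [float(img[r, c] - bg), float(c), float(r), sigma_px, bg]
        try:
            popt, pcov = curve_fit(
                _gauss2d, (xx, yy), patch.ravel(), p0=p0,
                bounds=(
                    [0, c0 - 1, r0 - 1, sigma_px / 4, -np.inf],
                    [np.inf, c1, r1, sigma_px * 4, np.inf],
                ),
                maxfev=400,
            )
        except (RuntimeError, ValueError):
            continue
        amp, x0, y0 = popt[0], popt[1], popt[2]
        prec_px = float(np.sqrt(max(pcov[1, 1], 0.0) + max(pcov[2, 2], 0.0)) / np.sqrt(2))
        locs.append(
            Localization(
                x=(x0 + 0.5) * pixel_size * 1e-3,
                y=(y0 + 0.5) * pixel_size * 1e-3,
                frame=0,
                precision=prec_px * pixel_size,
                amplitude=float(amp),
                saturated=bool(saturation is not None and patch.max() >= saturation),
            )
        )
    return locs


# ---------------------------------------------------------------------------
# Linking


def link_trajectories(
    locs_per_frame: list[list[Localization]],
    max_disp: float,
    t_ill: float = 5.0,
    t_delay: float = 15.0,
) -> list[Trajectory]:
    """Greedy nearest-neighbour frame-to-frame linking.

    Links longer than ``max_disp`` (um) are rejected; when a detection has
    several track ends (or a track end several detections) within
    ``max_disp``, all involved links are dropped as ambiguous.  No gap
    closing: a track not extended in a frame is terminated.
    """
    active: list[dict] = []
    done: list[dict] = []
    n_ambiguous = 0
    for fi, locs in enumerate(locs_per_frame):
        pts = np.array([[l.x, l.y] for l in locs]) if locs else np.empty((0, 2))
        if active and len(pts):
            ends = np.array([[tr["x"][-1], tr["y"][-1]] for tr in active])
            d = np.sqrt(((ends[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
            cand = d <= max_disp
            amb_rows = cand.sum(axis=1) > 1
            amb_cols = cand.sum(axis=0) > 1
            n_ambiguous += int(amb_rows.sum() + amb_cols.sum())
            cand[amb_rows, :] = False
            cand[:, amb_cols] = False
            linked_tracks, linked_dets = set(), set()
            for i, j in zip(*np.nonzero(cand)):
                if i in linked_tracks or j in linked_dets:
                    continue
                tr = active[i]
                tr["x"].append(pts[j, 0])
                tr["y"].append(pts[j, 1])
                tr["frames"].append(fi)
                linked_tracks.add(i)
                linked_dets.add(j)
            done.extend(tr for i, tr in enumerate(active) if i not in linked_tracks)
            active = [tr for i, tr in enumerate(active) if i in linked_tracks]
            new = [j for j in range(len(pts)) if j not in linked_dets and not amb_cols[j]]
        else:
            done.extend(active)
            active = []
            new = list(range(len(pts)))
        for j in new:
            active.append({"x": [pts[j, 0]], "y": [pts[j, 1]], "frames": [fi]})
    done.extend(active)
    trajs = [
        Trajectory(tr["x"], tr["y"], tr["frames"], t_ill=t_ill, t_delay=t_delay)
        for tr in done
        if len(tr["x"]) >= 2
    ]
    for tr in trajs:
        tr.n_ambiguous = n_ambiguous  # diagnostic, shared count
    return trajs


# ---------------------------------------------------------------------------
# MSD analysis


def _pairs_for_lag(n_points: int, n: int, windowing: str) -> np.ndarray:
    if windowing == "overlapping":
        return np.arange(0, n_points - n)
    return np.arange(0, n_points - n, n)  # i = 1, 1+n, 1+2n, ... (0-based)


def compute_msd(
    trajs: list[Trajectory],
    n_values: list[int] | None = None,
    windowing: str = "non-overlapping",
) -> MsdCurve:
    """Ensemble MSD over trajectories at lags ``t_lag = n (t_ill + t_delay)``.

    The default non-overlapping windowing pairs positions at indices
    ``i = 1, 1+n, 1+2n, ...`` so that squared displacements entering one lag
    are independent; ``windowing="overlapping"`` uses all pairs.
    """
    if not trajs:
        raise ValueError("no trajectories")
    max_len = max(len(tr) for tr in trajs)
    if n_values is None:
        n_values = list(range(1, max_len))
    frame_time = trajs[0].frame_time
    t_lag, msd, n_pairs = [], [], []
    for n in n_values:
        acc, cnt = 0.0, 0
        for tr in trajs:
            if len(tr) <= n:
                continue
            idx = _pairs_for_lag(len(tr), n, windowing)
            dx = tr.x[idx + n] - tr.x[idx]
            dy = tr.y[idx + n] - tr.y[idx]
            acc += float(np.sum(dx * dx + dy * dy))
            cnt += idx.size
        if cnt == 0:
            warnings.warn(f"lag n={n} exceeds all trajectory lengths; omitted", stacklevel=2)
            continue
        t_lag.append(n * frame_time)
        msd.append(acc / cnt)
        n_pairs.append(cnt)
    return MsdCurve(np.array(t_lag), np.array(msd), np.array(n_pairs))


def square_displacements(
    trajs: list[Trajectory],
    n_values: list[int],
    windowing: str = "overlapping",
) -> dict[float, np.ndarray]:
    """Pooled square displacements per time lag (for the bimodal CDF fit)."""
    frame_time = trajs[0].frame_time
    out: dict[float, np.ndarray] = {}
    for n in n_values:
        chunks = []
        for tr in trajs:
            if len(tr) <= n:
                continue
            idx = _pairs_for_lag(len(tr), n, windowing)
            dx = tr.x[idx + n] - tr.x[idx]
            dy = tr.y[idx + n] - tr.y[idx]
            chunks.append(dx * dx + dy * dy)
        if chunks:
            out[n * frame_time] = np.concatenate(chunks)
    return out


def fit_free_diffusion(msd: MsdCurve, n_fit_points: int = 4) -> DiffusionFit:
    """Weighted linear fit of ``msd = 4 D t_lag + 4 sigma_xy^2``.

    The first ``n_fit_points`` lags are used (bias/variance compromise);
    weights are sqrt(n_pairs).  A negative intercept is clamped to zero and
    flagged; a negative slope returns D = 0 with the ``immobile`` flag.
    """
    if msd.t_lag.size < 2:
        raise ValueError("need >= 2 lags for the linear MSD fit")
    k = min(n_fit_points, msd.t_lag.size)
    t, y, w = msd.t_lag[:k], msd.msd[:k], np.sqrt(msd.n_pairs[:k].astype(float))
    coef, cov = np.polyfit(t, y, 1, w=w, cov="unscaled" if k > 2 else False) if k > 2 else (
        np.polyfit(t, y, 1, w=w),
        np.full((2, 2), np.nan),
    )
    slope, intercept = float(coef[0]), float(coef[1])
    flags = []
    if slope < 0:
        flags.append("immobile")
        d = 0.0
    else:
        d = slope / 4.0
    if intercept < 0:
        flags.append("negative_intercept")
        sigma_nm = 0.0
    else:
        sigma_nm = np.sqrt(intercept / 4.0) * 1e3
    se = {}
    if np.all(np.isfinite(cov)):
        se = {"d": float(np.sqrt(cov[0, 0]) / 4.0), "intercept": float(np.sqrt(cov[1, 1]))}
    return DiffusionFit(model="free", d=d, sigma_xy=sigma_nm, fit_se=se, flags=flags)


def _bimodal_cdf(sd, alpha, m1, m2):
    return 1.0 - alpha * np.exp(-sd / m1) - (1.0 - alpha) * np.exp(-sd / m2)


def fit_bimodal_cdf(
    sq_disp: dict[float, np.ndarray],
    min_samples: int = 100,
) -> DiffusionFit:
    """Fit the two-component square-displacement CDF (mixture model).

    ``cdf(sd) = 1 - alpha exp(-sd/msd1) - (1-alpha) exp(-sd/msd2)`` with one
    shared ``alpha`` across lags and per-lag ``msd1 < msd2``.  If the two
    components are closer than a factor 2 the fit collapses to a monomodal
    exponential with a warning.
    """
    lags = sorted(sq_disp)
    samples = [np.sort(np.asarray(sq_disp[t], dtype=float)) for t in lags]
    for t, s in zip(lags, samples):
        if s.size < min_samples:
            raise ValueError(f"lag {t:g}s has {s.size} < {min_samples} samples")
    n_lag = len(lags)

    # quantile-based inits: slow component near the 25% point, fast near 90%
    m1_0 = np.array([max(np.quantile(s, 0.25), 1e-9) for s in samples])
    m2_0 = np.array([max(np.quantile(s, 0.9), 2e-9) for s in samples])

    def resid(p):
        alpha = p[0]
        m1 = np.exp(p[1 : 1 + n_lag])
        m2 = np.exp(p[1 + n_lag :])
        out = []
        for s, a, b in zip(samples, m1, m2):
            ecdf = (np.arange(s.size) + 0.5) / s.size
            out.append(_bimodal_cdf(s, alpha, a, b) - ecdf)
        return np.concatenate(out)

    p0 = np.concatenate([[0.5], np.log(m1_0), np.log(m2_0)])
    lo = np.concatenate([[0.0], np.full(2 * n_lag, -50.0)])
    hi = np.concatenate([[1.0], np.full(2 * n_lag, 50.0)])
    sol = least_squares(resid, p0, bounds=(lo, hi), x_scale="jac")
    alpha = float(sol.x[0])
    m1 = np.exp(sol.x[1 : 1 + n_lag])
    m2 = np.exp(sol.x[1 + n_lag :])
    if np.mean(m1) > np.mean(m2):  # enforce msd1 < msd2
        m1, m2 = m2, m1
        alpha = 1.0 - alpha

    flags = []
    if np.mean(m2) / max(np.mean(m1), 1e-30) < 2.0:
        warnings.warn("components separated by < 2x; collapsing to monomodal", stacklevel=2)
        flags.append("monomodal")

        def resid1(p):
            out = []
            for s, lm in zip(samples, p):
                ecdf = (np.arange(s.size) + 0.5) / s.size
                out.append(1.0 - np.exp(-s / np.exp(lm)) - ecdf)
            return np.concatenate(out)

        sol1 = least_squares(resid1, np.log((m1_0 + m2_0) / 2))
        m = np.exp(sol1.x)
        return DiffusionFit(
            model="monomodal", alpha=1.0, msd1=m, msd2=m,
            t_lag=np.array(lags), flags=flags,
        )
    return DiffusionFit(
        model="bimodal", alpha=alpha, msd1=m1, msd2=m2,
        t_lag=np.array(lags), flags=flags,
    )


def confined_msd_model(t_lag, d, radius, offset=0.0):
    """Approximate MSD for diffusion in an impermeable circle of radius R."""
    return radius**2 * (1.0 - np.exp(-4.0 * d * t_lag / radius**2)) + offset


def fit_confined(
    msd: MsdCurve,
    fit_offset: bool = True,
    curvature_ratio: float = 0.7,
) -> DiffusionFit:
    """Nonlinear fit of the confined-diffusion MSD model.

    ``msd = R^2 (1 - exp(-4 D t_lag / R^2)) [+ 4 sigma_xy^2]``; the optional
    offset absorbs the localization-noise floor.  The curve must show
    saturation (late-lag/early-lag slope ratio < ``curvature_ratio``),
    otherwise the data are flagged as free; a failed fit falls back to the
    free model.
    """
    flags = []
    t, y = msd.t_lag, msd.msd
    if t.size >= 4:
        early = (y[1] - y[0]) / (t[1] - t[0])
        late = (y[-1] - y[-2]) / (t[-1] - t[-2])
        if early > 0 and late / early >= curvature_ratio:
            flags.append("looks_free")
    plateau = float(np.mean(y[-max(2, t.size // 5):]))
    r0 = np.sqrt(max(plateau, 1e-12))
    d0 = max((y[1] - y[0]) / (4 * (t[1] - t[0])), 1e-6) if t.size > 1 else 0.01
    try:
        if fit_offset:
            popt, pcov = curve_fit(
                confined_msd_model, t, y, p0=[d0, r0, 0.0],
                bounds=([0, 1e-6, 0], [np.inf, np.inf, plateau]), maxfev=5000,
            )
            d, radius, offset = popt
        else:
            popt, pcov = curve_fit(
                lambda tt, d, r: confined_msd_model(tt, d, r), t, y,
                p0=[d0, r0], bounds=([0, 1e-6], [np.inf, np.inf]), maxfev=5000,
            )
            d, radius = popt
            offset = 0.0
    except (RuntimeError, ValueError):
        warnings.warn("confined fit failed; falling back to free model", stacklevel=2)
        out = fit_free_diffusion(msd)
        out.flags.append("confined_fit_failed")
        return out
    se = {}
    if np.all(np.isfinite(pcov)):
        errs = np.sqrt(np.diag(pcov))
        se = {"d": float(errs[0]), "radius": float(errs[1])}
    return DiffusionFit(
        model="confined", d=float(d), radius=float(radius),
        sigma_xy=float(np.sqrt(max(offset, 0) / 4) * 1e3), fit_se=se, flags=flags,
    )


def classify_mobility(
    trajs: list[Trajectory],
    sigma_xy: float,
    n_lags: int = 3,
    tol: float = 0.5,
    min_points: int = 8,
    decision_margin: float = 6.0,
) -> tuple[tuple[float, float, float], list[str]]:
    """Classify each trajectory as immobile / confined / free.

    A trajectory is immobile when its mean MSD over the first ``n_lags``
    lags does not exceed the localization-noise floor ``4 sigma_xy^2`` by
    more than ``tol`` (fractional).  Otherwise confined and free fits on
    the per-trajectory MSD are compared by small-sample-corrected AIC.
    Trajectories shorter than ``min_points`` go to the ``unclassified``
    bucket.  Returns ``((f_immobile, f_confined, f_free), labels)``;
    fractions are over classified trajectories.
    """
    noise_floor = 4.0 * (sigma_xy * 1e-3) ** 2
    labels = []
    for tr in trajs:
        if len(tr) < min_points:
            labels.append("unclassified")
            continue
        max_lag = min(len(tr) - 1, max(n_lags * 4, len(tr) // 2))
        msd = compute_msd([tr], list(range(1, max_lag + 1)), windowing="overlapping")
        if np.mean(msd.msd[:n_lags]) <= noise_floor * (1.0 + tol):
            labels.append("immobile")
            continue
        # both candidate models share the known noise floor as intercept, so
        # a plateau above 4 sigma^2 can only be explained by confinement
        t, y = msd.t_lag, msd.msd - noise_floor
        n = t.size
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                (d_c, r_c), _ = curve_fit(
                    lambda tt, d, r: confined_msd_model(tt, d, r), t, y,
                    p0=[max(y[0] / (4 * t[0]), 1e-6), np.sqrt(max(np.mean(y[-3:]), 1e-9))],
                    bounds=([0, 1e-6], [np.inf, np.inf]), maxfev=2000,
                )
            except (RuntimeError, ValueError):
                labels.append("free")
                continue
        d_f = max(float(np.sum(t * y) / np.sum(t * t)) / 4.0, 0.0)  # slope-only free fit
        rss_c = float(np.sum((confined_msd_model(t, d_c, r_c) - y) ** 2))
        rss_f = float(np.sum((4 * d_f * t - y) ** 2))
        # two gates against spurious confinement: the confined model nests
        # the free one (R -> inf), so demand (a) a decisive AICc improvement
        # and (b) a plateau well below the lag-1 free extrapolation
        decisive = _aicc(rss_c, n, 2) < _aicc(rss_f, n, 1) - decision_margin
        slope0 = max(float(np.mean(y[:2] / t[:2])), 1e-12)
        plateau_small = r_c**2 < 0.33 * slope0 * t[-1]
        labels.append("confined" if decisive and plateau_small else "free")
    counts = {k: labels.count(k) for k in ("immobile", "confined", "free")}
    total = sum(counts.values())
    if total == 0:
        return (np.nan, np.nan, np.nan), labels
    return (
        counts["immobile"] / total,
        counts["confined"] / total,
        counts["free"] / total,
    ), labels


def _aicc(rss: float, n: int, k: int) -> float:
    aic = n * np.log(max(rss, 1e-300) / n) + 2 * k
    denom = n - k - 1
    return aic + (2 * k * (k + 1) / denom if denom > 0 else np.inf)
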