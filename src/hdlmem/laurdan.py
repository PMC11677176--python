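"""Laurdan excitation generalized polarization (GP).

GP_EX(lambda_EX) = (I440 - I490) / (I440 + I490), computed pointwise from
two excitation spectra recorded at emission 440 nm and 490 nm.  GP reports
on lipid packing and glycerol-region mobility: higher GP means a more
ordered, less mobile environment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GpSpectrum", "compute_gp_ex", "summarize_gp"]


@dataclass
class GpSpectrum:
    """Pointwise excitation-GP spectrum with a scalar summary."""

    lambda_ex_axis: np.ndarray
    gp_values: np.ndarray  # NaN where masked
    summary_gp: float
    summary_se: float

    def __post_init__(self) -> None:
        finite = self.gp_values[np.isfinite(self.gp_values)]
        if finite.size and (np.any(finite > 1.0 + 1e-12) or np.any(finite < -1.0 - 1e-12)):
            raise ValueError("GP values must lie in [-1, 1]")


def _as_spectrum(spec) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(spec, "columns"):
        cols = list(spec.columns)
        lam = np.asarray(spec[cols[0]], dtype=float)
        inten = np.asarray(spec[cols[1]], dtype=float)
    else:
        arr = np.asarray(spec, dtype=float)
        lam, inten = arr[:, 0], arr[:, 1]
    return lam, inten


def compute_gp_ex(spec440, spec490, noise_floor_frac: float = 0.01) -> GpSpectrum:
    """Compute the excitation-GP spectrum from the Em=440 and Em=490 spectra.

    Both spectra must share one excitation-wavelength grid.  Points whose
    denominator ``I440 + I490`` falls below ``noise_floor_frac`` of its
    maximum are masked (NaN) to avoid +-1 artifacts at the spectrum edges.
    The scalar summary is the default-range mean (see ``summarize_gp``).
    """
    lam4, i440 = _as_spectrum(spec440)
    lam9, i490 = _as_spectrum(spec490)
    if lam4.shape != lam9.shape or not np.allclose(lam4, lam9):
        raise ValueError("excitation spectra must share one wavelength grid")
    denom = i440 + i490
    floor = noise_floor_frac * float(np.max(denom))
    gp = np.full_like(denom, np.nan, dtype=float)
    ok = denom > floor
    if not ok.any():
        raise ValueError("all points fall below the denominator noise floor")
    gp[ok] = (i440[ok] - i490[ok]) / denom[ok]
    gp[ok] = np.clip(gp[ok], -1.0, 1.0)
    spectrum = GpSpectrum(lambda_ex_axis=lam4, gp_values=gp, summary_gp=np.nan, summary_se=np.nan)
    spectrum.summary_gp, spectrum.summary_se = _range_mean(spectrum, None)
    return spectrum


def _range_mean(gp: GpSpectrum, lambda_range: tuple[float, float] | None):
    lam = gp.lambda_ex_axis
    if lambda_range is None:
        # default summary window (near-UV Laurdan excitation band)
        lo, hi = 340.0, 400.0
        sel = (lam >= lo) & (lam <= hi)
        if not sel.any():  # grid does not reach the default window: use all
            sel = np.ones_like(lam, dtype=bool)
    else:
        lo, hi = lambda_range
        sel = (lam >= lo) & (lam <= hi)
        if not sel.any():
            raise ValueError(f"range {lambda_range} nm does not intersect the grid")
    vals = gp.gp_values[sel]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no unmasked GP points in the requested range")
    mean = float(np.mean(vals))
    se = float(np.std(vals, ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
    return mean, se


def summarize_gp(
    gp: GpSpectrum, lambda_range: tuple[float, float] | None = None
) -> tuple[float, float]:
    """Scalar GP +- SE: unweighted mean of unmasked points in the range
    (default 340-400 nm excitation)."""
    return _range_mean(gp, lambda_range)
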