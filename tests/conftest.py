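import warnings

import numpy as np
import pytest

from hdlmem import synthetic, tdfs


@pytest.fixture(autouse=True)
def _quiet_warnings():
    """Analysis code warns liberally (exclusions, degeneracies); tests assert
    on warnings explicitly where they matter."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def tdfs_dataset():
    """One full synthetic TDFS dataset (16 decays, IRF, spectrum), shared
    across tests because decay fitting dominates runtime."""
    return synthetic.gen_tdfs_dataset(synthetic.RelaxationModel(), seed=1)


@pytest.fixture(scope="session")
def tdfs_fits(tdfs_dataset):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return [
            tdfs.fit_decay_reconvolution(d, tdfs_dataset.irf)
            for d in tdfs_dataset.decays
        ]


def analytic_tres(nu0=23_800.0, nu_inf=21_800.0, taus=((2.0, 1.0),), band_fwhm=3000.0,
                  fluor_lifetime=4.0):
    """Noise-free TRES surface on the experimental wavelength grid.

    ``taus`` is a list of (time constant ns, weight) pairs for the shift
    relaxation; the band is a Gaussian in wavenumber.
    """
    lam = np.arange(400.0, 551.0, 10.0)
    nu_axis = np.sort(1e7 / lam)
    t = tdfs.default_time_grid()
    w = np.array([wt for _, wt in taus])
    tt = np.array([tau for tau, _ in taus])
    nu_true = nu_inf + (nu0 - nu_inf) * np.sum(
        w[:, None] * np.exp(-t[None, :] / tt[:, None]), axis=0
    )
    sd = band_fwhm / 2.3548
    intensity = np.exp(-t[:, None] / fluor_lifetime) * np.exp(
        -((nu_axis[None, :] - nu_true[:, None]) ** 2) / (2 * sd * sd)
    )
    nu_fit = np.empty(t.size)
    fwhm = np.empty(t.size)
    for i in range(t.size):
        nu_fit[i], fwhm[i] = tdfs._fit_band(nu_axis, intensity[i])
    return tdfs.TRES(nu_axis, t, intensity, nu_fit, fwhm)
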