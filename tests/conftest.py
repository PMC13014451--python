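import numpy as np
import pytest
from scipy import stats

import permeakit as pk


@pytest.fixture(scope="session")
def thermo310():
    return pk.ThermoState(310.0)


@pytest.fixture(scope="session")
def flat_landscape():
    """Flat free energy, constant diffusivity, wide domain (free diffusion)."""
    return pk.LandscapeSpec(g_terms=(), d_base=0.1, z_min=0.0, z_max=1000.0)


@pytest.fixture(scope="session")
def membrane_landscape():
    return pk.default_membrane_landscape()


@pytest.fixture(scope="session")
def full_window_set(membrane_landscape, thermo310):
    """71 umbrella windows at 1 Å spacing, k = 2.5 kcal/mol/Å², 310 K,
    2×10⁵ retained samples each, on the cisplatin-like membrane landscape."""
    return pk.generate_window_set(membrane_landscape, thermo310, seed=20240)


def exact_harmonic_windows(thermo, a=0.2, center=5.0, spring_k=2.0,
                           bias_centers=(4.0, 6.0), n=100_000):
    """Windows sampled exactly (inverse-CDF, no dynamics) from the biased
    Boltzmann density of the harmonic free energy G(z) = ½·a·(z−center)².

    The biased density is Gaussian with precision β(a+k) and mean
    (a·center + k·z0)/(a+k), so stratified normal quantiles sample it
    exactly.
    """
    beta = thermo.beta
    windows = []
    quantiles = (np.arange(n) + 0.5) / n
    rng = np.random.default_rng(2718)
    for z0 in bias_centers:
        var = 1.0 / (beta * (a + spring_k))
        mean = (a * center + spring_k * z0) / (a + spring_k)
        z = stats.norm.ppf(quantiles, loc=mean, scale=np.sqrt(var))
        rng.shuffle(z)  # samples are i.i.d.; present them in random order
        times = 0.1 * np.arange(1, n + 1)
        windows.append(pk.WindowTrajectory(z0, spring_k, times, z))
    return windows


def harmonic_boltzmann_oracle(thermo, bin_edges, a=0.2, center=5.0):
    """Per-bin free energy of the harmonic G by direct Boltzmann inversion of
    the analytic unbiased density: G_b = −kT·ln ∫_bin exp(−βG) dz."""
    beta = thermo.beta
    sigma = np.sqrt(1.0 / (beta * a))
    cdf = stats.norm.cdf(bin_edges, loc=center, scale=sigma)
    p = np.diff(cdf)
    with np.errstate(divide="ignore"):
        return -np.log(p) / beta


@pytest.fixture(scope="session")
def two_window_fixture(thermo310):
    return exact_harmonic_windows(thermo310)


def brute_force_pairs(coords_a, coords_b, cutoff, box=None):
    """O(N²) oracle: (i, j, distance) for all pairs within cutoff."""
    delta = coords_a[:, None, :] - coords_b[None, :, :]
    if box is not None:
        delta -= box * np.round(delta / box)
    d = np.sqrt((delta**2).sum(axis=-1))
    ii, jj = np.nonzero(d <= cutoff)
    return ii, jj, d[ii, jj]
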