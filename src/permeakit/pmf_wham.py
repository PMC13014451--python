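"""Potential-of-mean-force reconstruction from umbrella windows.

Standard WHAM self-consistency: with per-window histograms n_i(z_b), window
sample counts N_i and harmonic biases w_i(z) = ½k_i(z−z₀ᵢ)²,

    p(z_b) = Σ_i n_i(z_b) / Σ_i N_i · exp(β(f_i − w_i(z_b)))
    f_i    = −β⁻¹ · ln Σ_b p(z_b) · exp(−β·w_i(z_b))

iterated until the window shift constants f_i stop moving.  The free-energy
profile is G = −β⁻¹·ln p, shifted so its minimum over a chosen bulk reference
region is zero.  Bins no window ever visited carry no free energy: they are
dropped from the profile, never interpolated.

Uncertainties come from a moving-block bootstrap within each window (window
samples are autocorrelated, so naive resampling would understate the error).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_io import PermeakitError, Profile, ThermoState, WindowTrajectory

logger = logging.getLogger("permeakit")


@dataclass
class PMFResult:
    """Reconstructed free-energy profile with WHAM bookkeeping."""

    profile: Profile                     # G(z), kcal/mol
    reference_region: tuple[float, float]
    window_free_energies: np.ndarray     # per-window shifts f_i, kcal/mol
    converged: bool
    iterations: int


@dataclass
class PMFLandmarks:
    """Interface minima, core maximum, and barrier heights of a PMF."""

    min_right: tuple[float, float]  # (z Å, G kcal/mol)
    max: tuple[float, float]
    min_left: tuple[float, float]
    dG_right: float
    dG_left: float


def _bin_edges(windows: Sequence[WindowTrajectory], bin_width: float):
    zmin = min(float(np.min(w.z_values)) for w in windows)
    zmax = max(float(np.max(w.z_values)) for w in windows)
    # align edges on multiples of bin_width so the grid is stable under
    # resampling (bootstrap replicates share the original bin layout)
    lo = np.floor(zmin / bin_width) * bin_width
    n_bins = int(np.ceil((zmax - lo) / bin_width)) + 1
    return lo + bin_width * np.arange(n_bins + 1)


def _check_overlap(counts: np.ndarray, windows, min_counts: int = 10):
    order = np.argsort([w.bias_center for w in windows])
    for a, b in zip(order[:-1], order[1:]):
        shared = np.minimum(counts[a], counts[b]).sum()
        if shared < min_counts:
            logger.warning(
                "weak histogram overlap between windows at %.2f and %.2f Å "
                "(%d shared counts)", windows[a].bias_center,
                windows[b].bias_center, int(shared),
            )


def wham_solve(
    windows: Sequence[WindowTrajectory],
    thermo: ThermoState,
    bin_width: float = 0.2,
    tolerance: float = 1e-7,
    max_iter: int = 100_000,
    reference_region: tuple[float, float] | None = None,
    bin_edges: np.ndarray | None = None,
    check_overlap: bool = True,
) -> PMFResult:
    """Solve the WHAM equations for a set of harmonic umbrella windows.

    Parameters
    ----------
    reference_region : (z_lo, z_hi) over which min G is pinned to 0; defaults
        to the last 10% of the sampled z range (bulk side).
    bin_edges : optional pre-computed edges (used by the bootstrap so every
        replicate shares one grid).
    """
    if len(windows) < 1:
        raise PermeakitError("wham_solve needs at least one window")
    beta = thermo.beta
    if bin_edges is None:
        bin_edges = _bin_edges(windows, bin_width)
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    n_win, n_bins = len(windows), len(centers)

    counts = np.zeros((n_win, n_bins))
    for i, w in enumerate(windows):
        counts[i], _ = np.histogram(w.z_values, bins=bin_edges)
    if check_overlap and n_win > 1:
        _check_overlap(counts, windows)

    n_total = counts.sum(axis=0)                      # per-bin total counts
    n_i = counts.sum(axis=1)                          # per-window sample count
    bias = np.array([w.bias_energy(centers) for w in windows])  # (n_win, n_bins)
    boltz = np.exp(-beta * bias)                      # exp(−βw_i(z_b))

    occupied = n_total > 0
    f = np.zeros(n_win)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # p_b = Σ n_ib / Σ N_i exp(βf_i) exp(−βw_ib); gauge-fix f_0 = 0
        denom = (n_i[:, None] * np.exp(beta * f)[:, None] * boltz).sum(axis=0)
        p = np.where(occupied, n_total / np.maximum(denom, 1e-300), 0.0)
        z_i = boltz @ p                               # Σ_b p_b exp(−βw_ib)
        f_new = -np.log(np.maximum(z_i, 1e-300)) / beta
        f_new -= f_new[0]
        delta = float(np.max(np.abs(f_new - f)))
        f = f_new
        if delta < tolerance:
            converged = True
            break
    if not converged:
        logger.warning("WHAM did not converge in %d iterations (Δf=%.3g)",
                       max_iter, delta)

    g = np.full(n_bins, np.nan)
    g[occupied] = -np.log(p[occupied]) / beta
    if reference_region is None:
        zmax = centers[occupied].max()
        zmin = centers[occupied].min()
        reference_region = (zmax - 0.1 * (zmax - zmin), zmax)
    ref_mask = occupied & (centers >= reference_region[0]) \
        & (centers <= reference_region[1])
    if not ref_mask.any():
        raise PermeakitError(
            f"reference region {reference_region} has no occupied bins"
        )
    g -= np.nanmin(g[ref_mask])

    profile = Profile(centers[occupied], g[occupied], unit="kcal/mol")
    return PMFResult(profile, tuple(reference_region), f, converged, it)


def bootstrap_pmf(
    windows: Sequence[WindowTrajectory],
    thermo: ThermoState,
    n_boot: int = 50,
    block_length: int = 200,
    seed: int = 0,
    bin_width: float = 0.2,
    tolerance: float = 1e-6,
    max_iter: int = 50_000,
    reference_region: tuple[float, float] | None = None,
) -> Profile:
    """Per-bin standard error of G via moving-block bootstrap.

    Within each window, contiguous blocks of ``block_length`` samples are
    resampled with replacement to preserve autocorrelation; WHAM is re-solved
    per replicate and the per-bin standard deviation over replicates returned
    (on the bins the original solution occupies).
    """
    if n_boot < 20:
        raise PermeakitError("n_boot must be ≥ 20 for a usable error estimate")
    for w in windows:
        if block_length >= w.n_samples:
            raise PermeakitError(
                f"block_length {block_length} ≥ window length {w.n_samples}"
            )
    edges = _bin_edges(windows, bin_width)
    base = wham_solve(windows, thermo, bin_width, tolerance, max_iter,
                      reference_region, bin_edges=edges, check_overlap=False)
    base_z = base.profile.z_grid
    rng = np.random.default_rng(seed)
    replicates = np.full((n_boot, len(base_z)), np.nan)
    for r in range(n_boot):
        resampled = []
        for w in windows:
            n = w.n_samples
            n_blocks = int(np.ceil(n / block_length))
            starts = rng.integers(0, n - block_length + 1, size=n_blocks)
            idx = (starts[:, None] + np.arange(block_length)).ravel()[:n]
            resampled.append(WindowTrajectory(
                w.bias_center, w.spring_k, w.times, w.z_values[idx],
            ))
        # replicates may leave tail bins empty; solve with the replicate's
        # own reference, interpolate onto the base grid, then re-pin on the
        # base reference region so every replicate shares the base gauge
        rep = wham_solve(resampled, thermo, bin_width, tolerance, max_iter,
                         None, bin_edges=edges, check_overlap=False)
        g_rep = np.interp(base_z, rep.profile.z_grid, rep.profile.values)
        ref_lo, ref_hi = base.reference_region
        ref_mask = (base_z >= ref_lo) & (base_z <= ref_hi)
        if not ref_mask.any():
            ref_mask = slice(None)
        g_rep = g_rep - g_rep[ref_mask].min()
        replicates[r] = g_rep
    se = np.std(replicates, axis=0, ddof=1)
    return Profile(base_z, se, unit="kcal/mol")


def extract_landmarks(
    pmf: Profile | PMFResult,
    interface_right_region: tuple[float, float] = (50.0, 65.0),
    core_region: tuple[float, float] = (30.0, 50.0),
    interface_left_region: tuple[float, float] = (15.0, 30.0),
) -> PMFLandmarks:
    """Locate the interface minima and core barrier of a PMF.

    ``min_right``/``min_left`` are the argmin of G over the two interface
    regions, ``max`` the argmax over the core region; barrier heights are the
    exact differences max.G − min.G.  Ties break toward the region center.
    """
    profile = pmf.profile if isinstance(pmf, PMFResult) else pmf
    z, g = profile.z_grid, profile.values

    def pick(region, mode):
        lo, hi = region
        mask = (z >= lo) & (z <= hi)
        if not mask.any():
            raise PermeakitError(f"region {region} outside profile support")
        zz, gg = z[mask], g[mask]
        best = gg.max() if mode == "max" else gg.min()
        ties = np.flatnonzero(gg == best)
        center = 0.5 * (lo + hi)
        j = ties[np.argmin(np.abs(zz[ties] - center))]
        return (float(zz[j]), float(gg[j]))

    min_right = pick(interface_right_region, "min")
    gmax = pick(core_region, "max")
    min_left = pick(interface_left_region, "min")
    return PMFLandmarks(
        min_right=min_right, max=gmax, min_left=min_left,
        dG_right=gmax[1] - min_right[1],
        dG_left=gmax[1] - min_left[1],
    )
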