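"""Position-dependent diffusivity and solubility-diffusion permeability.

The local diffusion coefficient is estimated per umbrella window from the
restrained fluctuations (Hummer's estimator):

    D = var(z)² / ∫₀^τc C_zz(t) dt        with  C_zz(t) = ⟨δz(0)·δz(t)⟩

which is exact for an Ornstein–Uhlenbeck process (C = var·e^{−t/τ},
∫C = var·τ, hence D = var/τ).  The autocorrelation integral is truncated at
the first zero crossing of C_zz, where the noise-dominated tail begins.

Permeability follows the inhomogeneous solubility-diffusion model:

    1/P = R_eff = ∫ exp(β·G(z)) / D(z) dz

integrated across the membrane with z in cm and D in cm²/s, so P is in cm/s
and the local resistance R(z) in s/cm².  The exponential is accumulated in
log space, never by clipping G.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .core_io import (
    PermeakitError, Profile, ThermoState, WindowTrajectory, convert_diffusivity,
)

logger = logging.getLogger("permeakit")

_CM_PER_ANGSTROM = 1e-8


@dataclass
class AutocorrelationSeries:
    """Positional autocorrelation of one window's z(t)."""

    lags: np.ndarray          # ps, starting at 0, uniform
    C_zz: np.ndarray          # Å²
    truncation_lag: float     # ps, first zero crossing (or last lag)

    @property
    def variance(self) -> float:
        """C_zz at lag 0, Å²."""
        return float(self.C_zz[0])

    @property
    def integral_timescale(self) -> float:
        """∫C_zz dt / var up to the truncation lag, ps."""
        return self.integral / self.variance if self.variance > 0 else 0.0

    @property
    def integral(self) -> float:
        """Trapezoidal ∫₀^τc C_zz(t) dt, Å²·ps."""
        mask = self.lags <= self.truncation_lag
        return float(np.trapezoid(self.C_zz[mask], self.lags[mask]))


@dataclass
class DiffusivityProfile:
    """D(z) interpolated from per-window estimates."""

    profile: Profile                       # Å²/ps on the analysis grid
    window_records: list[dict] = field(default_factory=list)
    # each record: bias_center, mean_z, variance, acf_integral, D (Å²/ps)

    def as_cm2_s(self) -> Profile:
        return Profile(
            self.profile.z_grid,
            convert_diffusivity(1.0, "A2/ps", "cm2/s") * self.profile.values,
            unit="cm2/s",
        )


@dataclass
class PermeabilityResult:
    """Permeability and resistance from the solubility-diffusion integral.

    ``log10_P``/``log10_R_eff`` stay finite even when the barrier is so high
    that P underflows (or R_eff overflows) a double.
    """

    P: float                  # cm/s
    R_eff: float              # s/cm
    log10_P: float
    log10_R_eff: float
    R_profile: Profile        # R(z), s/cm²
    z_in: float
    z_out: float
    log_integrand: Profile    # βG(z) − ln D(z) (D in cm²/s), dimensionless


def autocorrelation(
    z_series: np.ndarray, dt: float, max_lag: float,
) -> AutocorrelationSeries:
    """Biased (fixed 1/n) positional autocorrelation up to ``max_lag`` ps.

    δz = z − mean(z); C_zz(t_k) = (1/n)·Σ_i δz(i)·δz(i+k).  The fixed 1/n
    normalization at every lag keeps the estimator positive-semidefinite.
    """
    z = np.asarray(z_series, dtype=float)
    n = len(z)
    n_lags = int(round(max_lag / dt)) + 1
    if n_lags > n:
        raise PermeakitError(
            f"max_lag {max_lag} ps exceeds the series span {(n - 1) * dt} ps"
        )
    if n < 2 * (n_lags - 1) and n_lags > 1:
        raise PermeakitError("series too short for the requested max_lag")
    dz = z - z.mean()
    # full autocorrelation via FFT, then biased normalization
    acf = signal.fftconvolve(dz, dz[::-1], mode="full")[n - 1: n - 1 + n_lags]
    acf /= n
    lags = dt * np.arange(n_lags)
    neg = np.flatnonzero(acf < 0)
    trunc = lags[neg[0] - 1] if len(neg) and neg[0] > 0 else lags[-1]
    return AutocorrelationSeries(lags=lags, C_zz=acf, truncation_lag=float(trunc))


def window_diffusivity(
    window: WindowTrajectory,
    dt: float | None = None,
    max_lag_fraction: float = 0.05,
) -> tuple[float, float]:
    """Hummer estimate (mean_z, D) for one restrained window, D in Å²/ps.

    D = var(z)²/∫C_zz dt with the integral truncated at the first zero
    crossing.  Raises when the window has no variance or a non-positive
    autocorrelation integral (pathological series).
    """
    dt = window.dt if dt is None else dt
    z = window.z_values
    if np.var(z) <= 0:
        raise PermeakitError("window has zero positional variance")
    max_lag = max(max_lag_fraction * (len(z) - 1) * dt, dt)
    acf = autocorrelation(z, dt, max_lag)
    integral = acf.integral
    if integral <= 0:
        raise PermeakitError("non-positive autocorrelation integral")
    d = acf.variance**2 / integral
    return float(np.mean(z)), float(d)


def diffusivity_profile(
    windows: list[WindowTrajectory],
    z_grid: np.ndarray | None = None,
    max_lag_fraction: float = 0.05,
) -> DiffusivityProfile:
    """Per-window D estimates interpolated onto an analysis grid.

    Windows whose estimator fails (zero variance, non-positive ACF integral)
    are excluded with a warning; the gaps are filled by linear interpolation
    between usable neighbours, constant beyond the outermost windows.
    """
    records = []
    for w in windows:
        try:
            mean_z, d = window_diffusivity(w, max_lag_fraction=max_lag_fraction)
        except PermeakitError as exc:
            logger.warning("window at %.2f Å excluded from D(z): %s",
                           w.bias_center, exc)
            continue
        acf = autocorrelation(
            w.z_values, w.dt,
            max(max_lag_fraction * (w.n_samples - 1) * w.dt, w.dt),
        )
        records.append({
            "bias_center": w.bias_center, "mean_z": mean_z,
            "variance": acf.variance, "acf_integral": acf.integral, "D": d,
        })
    if len(records) < 2:
        raise PermeakitError("need at least two usable windows for D(z)")
    records.sort(key=lambda r: r["mean_z"])
    mz = np.array([r["mean_z"] for r in records])
    dd = np.array([r["D"] for r in records])
    if z_grid is None:
        z_grid = mz
    d_interp = np.interp(np.asarray(z_grid, dtype=float), mz, dd)
    return DiffusivityProfile(
        profile=Profile(np.asarray(z_grid, dtype=float), d_interp, unit="A2/ps"),
        window_records=records,
    )


def permeability(
    pmf: Profile,
    d_profile: Profile | DiffusivityProfile,
    thermo: ThermoState,
    z_in: float,
    z_out: float,
) -> PermeabilityResult:
    """Solubility-diffusion permeability P and resistance R_eff = 1/P.

    ``pmf`` carries G(z) in kcal/mol referenced to 0 in bulk; ``d_profile``
    carries D(z) in Å²/ps (a DiffusivityProfile is accepted directly).  Both
    are linearly interpolated onto the PMF grid restricted to
    [z_in, z_out]; the resistance integral uses the trapezoidal rule with z
    in cm.
    """
    if isinstance(d_profile, DiffusivityProfile):
        d_profile = d_profile.profile
    if not z_in < z_out:
        raise PermeakitError("z_in must be < z_out")
    mask = (pmf.z_grid >= z_in) & (pmf.z_grid <= z_out)
    if mask.sum() < 2:
        raise PermeakitError("fewer than 2 PMF points inside [z_in, z_out]")
    z = pmf.z_grid[mask]
    g = pmf.values[mask]
    d_a2ps = d_profile.interp(z)
    if np.any(d_a2ps <= 0):
        raise PermeakitError("D(z) must be positive on the integration grid")
    d_cm2s = convert_diffusivity(1.0, "A2/ps", "cm2/s") * d_a2ps

    log_r = thermo.beta * g - np.log(d_cm2s)       # ln R(z), R in s/cm²
    shift = float(np.max(log_r))                   # log-space guard
    log_reff = shift + np.log(np.trapezoid(np.exp(log_r - shift),
                                           z * _CM_PER_ANGSTROM))
    with np.errstate(over="ignore", under="ignore"):
        r_eff = float(np.exp(log_reff))            # may overflow to inf
        p = float(np.exp(-log_reff))               # may underflow to 0
        r_vals = np.exp(np.minimum(log_r, 709.0))  # display profile only
    return PermeabilityResult(
        P=p, R_eff=r_eff,
        log10_P=float(-log_reff / np.log(10.0)),
        log10_R_eff=float(log_reff / np.log(10.0)),
        R_profile=Profile(z, r_vals, unit="s/cm^2"),
        z_in=float(z_in), z_out=float(z_out),
        log_integrand=Profile(z, log_r, unit="dimensionless"),
    )
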