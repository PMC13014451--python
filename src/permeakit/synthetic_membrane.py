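"""Desk-scale surrogate for umbrella-sampling input data.

Generates biased 1-D overdamped Langevin trajectories of a permeant on a
configurable membrane-shaped free-energy landscape G(z) with
position-dependent diffusivity D(z), a steered (constant-velocity pull)
pass for window seeding, and labeled toy membrane snapshots for the
structural analyses.

The dynamics are overdamped Itô Euler–Maruyama:

    z ← z + [ −β·D(z)·(G′(z) + U′_bias(z)) + D′(z) ]·dt + √(2·D(z)·dt)·ξ

with ξ ~ N(0,1), U_bias = ½k(z−z₀)² and reflecting boundaries at the domain
edges.  The D′(z) spurious-drift term is required for the correct stationary
(Boltzmann) density whenever D varies with position; omitting it biases
long-run histograms and is therefore part of the generator's contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .core_io import Frame, PermeakitError, ThermoState, WindowTrajectory


@dataclass(frozen=True)
class GaussianTerm:
    """One Gaussian feature: height·exp(−(z−center)²/(2·width²)).

    Negative height makes a well, positive a barrier (for G terms) or a
    local enhancement (for D terms).
    """

    center: float   # Å
    height: float   # kcal/mol for G terms; dimensionless fraction for D terms
    width: float    # Å (Gaussian sigma)


@dataclass(frozen=True)
class LandscapeSpec:
    """Ground-truth free energy G(z) and diffusivity D(z) on a bounded domain.

    G(z) = Σ Gaussian terms; D(z) = D_base·(1 + Σ Gaussian terms), clipped
    below at 0.05·D_base so D stays strictly positive.  Boundaries reflect.
    """

    g_terms: tuple[GaussianTerm, ...]
    d_terms: tuple[GaussianTerm, ...] = ()
    d_base: float = 0.1          # Å²/ps (≈1e-5 cm²/s, bulk-water scale)
    z_min: float = 0.0
    z_max: float = 70.0

    def __post_init__(self):
        if not self.z_min < self.z_max:
            raise PermeakitError("landscape domain must have z_min < z_max")
        if self.d_base <= 0:
            raise PermeakitError("d_base must be positive")

    def _terms_arrays(self, terms):
        if not terms:
            return (np.zeros(0), np.zeros(0), np.ones(0))
        c = np.array([t.center for t in terms], dtype=float)
        h = np.array([t.height for t in terms], dtype=float)
        w = np.array([t.width for t in terms], dtype=float)
        if np.any(w <= 0):
            raise PermeakitError("Gaussian widths must be positive")
        return c, h, w

    def free_energy(self, z) -> np.ndarray:
        """G(z) in kcal/mol."""
        z = np.asarray(z, dtype=float)
        c, h, w = self._terms_arrays(self.g_terms)
        out = np.zeros_like(z, dtype=float)
        for ci, hi, wi in zip(c, h, w):
            out += hi * np.exp(-((z - ci) ** 2) / (2 * wi**2))
        return out

    def free_energy_grad(self, z) -> np.ndarray:
        """dG/dz in kcal/mol/Å."""
        z = np.asarray(z, dtype=float)
        c, h, w = self._terms_arrays(self.g_terms)
        out = np.zeros_like(z, dtype=float)
        for ci, hi, wi in zip(c, h, w):
            out += hi * np.exp(-((z - ci) ** 2) / (2 * wi**2)) * (-(z - ci) / wi**2)
        return out

    def diffusivity(self, z) -> np.ndarray:
        """D(z) in Å²/ps, clipped at 0.05·D_base."""
        z = np.asarray(z, dtype=float)
        c, h, w = self._terms_arrays(self.d_terms)
        mod = np.ones_like(z, dtype=float)
        for ci, hi, wi in zip(c, h, w):
            mod += hi * np.exp(-((z - ci) ** 2) / (2 * wi**2))
        return np.maximum(self.d_base * mod, 0.05 * self.d_base)

    def diffusivity_grad(self, z) -> np.ndarray:
        """dD/dz in Å/ps (zero where the clip is active)."""
        z = np.asarray(z, dtype=float)
        c, h, w = self._terms_arrays(self.d_terms)
        mod = np.ones_like(z, dtype=float)
        grad = np.zeros_like(z, dtype=float)
        for ci, hi, wi in zip(c, h, w):
            g = np.exp(-((z - ci) ** 2) / (2 * wi**2))
            mod += hi * g
            grad += hi * g * (-(z - ci) / wi**2)
        clipped = self.d_base * mod <= 0.05 * self.d_base
        out = self.d_base * grad
        out[clipped] = 0.0
        return out


def default_membrane_landscape() -> LandscapeSpec:
    """Double-interface membrane landscape for a cisplatin-like permeant.

    Interfacial wells of depth 0.8 kcal/mol at 57.3 Å and 22.4 Å, a core
    barrier of 16.0 kcal/mol at 40.0 Å (all relative to bulk water at ~70 Å,
    z measured from the system center of mass), bulk diffusivity 0.1 Å²/ps
    (1e-5 cm²/s) dipping at the interfaces and mildly reduced in the core.
    """
    return LandscapeSpec(
        g_terms=(
            GaussianTerm(57.3, -0.8, 2.0),
            GaussianTerm(40.0, 16.0, 4.5),
            GaussianTerm(22.4, -0.8, 2.0),
        ),
        d_terms=(
            GaussianTerm(57.3, -0.7, 3.0),
            GaussianTerm(22.4, -0.7, 3.0),
            GaussianTerm(40.0, -0.4, 6.0),
        ),
        d_base=0.1,
        z_min=0.0,
        z_max=70.0,
    )


@dataclass(frozen=True)
class PullSchedule:
    """Constant-velocity pull used to seed umbrella windows."""

    start: float            # Å
    end: float              # Å
    velocity: float = 0.972  # Å/ns
    spring_k: float = 2.5    # kcal/mol/Å²
    spacing: float = 1.0     # Å between emitted seeds

    def __post_init__(self):
        if self.velocity <= 0:
            raise PermeakitError("pull velocity must be > 0")
        if self.spacing <= 0:
            raise PermeakitError("seed spacing must be > 0")

    @property
    def n_seeds(self) -> int:
        return int(abs(self.end - self.start) / self.spacing) + 1


# ---------------------------------------------------------------------------
# jitted propagators


@njit(cache=True)
def _gauss_sum(z, centers, heights, widths):
    s = 0.0
    for i in range(centers.shape[0]):
        d = z - centers[i]
        s += heights[i] * np.exp(-d * d / (2.0 * widths[i] * widths[i]))
    return s


@njit(cache=True)
def _gauss_grad(z, centers, heights, widths):
    s = 0.0
    for i in range(centers.shape[0]):
        d = z - centers[i]
        w2 = widths[i] * widths[i]
        s += heights[i] * np.exp(-d * d / (2.0 * w2)) * (-d / w2)
    return s


@njit(cache=True)
def _propagate(
    z0, n_steps, dt, stride, beta, bias_center, spring_k,
    gc, gh, gw, dc, dh, dw, d_base, z_min, z_max, noise,
):
    """Euler–Maruyama propagation; returns `n_steps // stride` samples."""
    n_out = n_steps // stride
    out = np.empty(n_out)
    z = z0
    d_floor = 0.05 * d_base
    k = 0
    for step in range(n_steps):
        dmod = 1.0 + _gauss_sum(z, dc, dh, dw)
        d = d_base * dmod
        if d <= d_floor:
            d = d_floor
            dgrad = 0.0
        else:
            dgrad = d_base * _gauss_grad(z, dc, dh, dw)
        force = _gauss_grad(z, gc, gh, gw) + spring_k * (z - bias_center)
        z = z + (-beta * d * force + dgrad) * dt \
            + np.sqrt(2.0 * d * dt) * noise[step]
        # reflecting boundaries
        if z < z_min:
            z = 2.0 * z_min - z
        if z > z_max:
            z = 2.0 * z_max - z
        if z < z_min:
            z = z_min
        if (step + 1) % stride == 0:
            out[k] = z
            k += 1
    return out


@njit(cache=True)
def _propagate_pull(
    z0, n_steps, dt, stride_check, beta, center0, vel, spring_k,
    gc, gh, gw, dc, dh, dw, d_base, z_min, z_max, grid, noise,
):
    """Steered pass with moving bias center; records z at grid crossings."""
    seeds = np.empty(grid.shape[0])
    taken = np.zeros(grid.shape[0], dtype=np.bool_)
    z = z0
    d_floor = 0.05 * d_base
    direction = 1.0 if vel >= 0 else -1.0
    for step in range(n_steps):
        t = step * dt
        center = center0 + vel * t
        dmod = 1.0 + _gauss_sum(z, dc, dh, dw)
        d = d_base * dmod
        if d <= d_floor:
            d = d_floor
            dgrad = 0.0
        else:
            dgrad = d_base * _gauss_grad(z, dc, dh, dw)
        force = _gauss_grad(z, gc, gh, gw) + spring_k * (z - center)
        z = z + (-beta * d * force + dgrad) * dt \
            + np.sqrt(2.0 * d * dt) * noise[step]
        if z < z_min:
            z = 2.0 * z_min - z
        if z > z_max:
            z = 2.0 * z_max - z
        if z < z_min:
            z = z_min
        for g in range(grid.shape[0]):
            if not taken[g] and direction * (center - grid[g]) >= 0.0:
                seeds[g] = z
                taken[g] = True
    for g in range(grid.shape[0]):
        if not taken[g]:
            seeds[g] = z
    return seeds


def _check_stability(landscape: LandscapeSpec, thermo: ThermoState, dt: float):
    zz = np.linspace(landscape.z_min, landscape.z_max, 4001)
    dmax = float(np.max(landscape.diffusivity(zz)))
    gmax = float(np.max(np.abs(landscape.free_energy_grad(zz))))
    drift = thermo.beta * dmax * gmax * dt
    if drift >= 0.1:
        raise PermeakitError(
            f"unstable integration: β·D·max|G'|·dt = {drift:.3f} Å ≥ 0.1 Å; "
            "reduce dt"
        )


def _term_arrays(terms):
    if not terms:
        return np.zeros(0), np.zeros(0), np.ones(0)
    return (
        np.array([t.center for t in terms], dtype=float),
        np.array([t.height for t in terms], dtype=float),
        np.array([t.width for t in terms], dtype=float),
    )


def simulate_window(
    landscape: LandscapeSpec,
    bias_center: float,
    spring_k: float,
    thermo: ThermoState,
    n_steps: int = 2_000_000,
    dt: float = 0.01,
    sample_stride: int = 10,
    seed: int = 0,
    z0: float | None = None,
) -> WindowTrajectory:
    """Simulate one harmonically restrained window; deterministic per seed.

    Defaults retain 2×10⁵ samples (2e6 steps, stride 10, dt 0.01 ps).
    """
    _check_stability(landscape, thermo, dt)
    if n_steps < sample_stride:
        raise PermeakitError("n_steps must be at least sample_stride")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(n_steps)
    gc, gh, gw = _term_arrays(landscape.g_terms)
    dc, dh, dw = _term_arrays(landscape.d_terms)
    start = float(np.clip(bias_center if z0 is None else z0,
                          landscape.z_min, landscape.z_max))
    samples = _propagate(
        start, n_steps, dt, sample_stride, thermo.beta, bias_center, spring_k,
        gc, gh, gw, dc, dh, dw, landscape.d_base,
        landscape.z_min, landscape.z_max, noise,
    )
    times = dt * sample_stride * np.arange(1, len(samples) + 1)
    return WindowTrajectory(bias_center, spring_k, times, samples)


def seed_windows(
    landscape: LandscapeSpec,
    schedule: PullSchedule,
    thermo: ThermoState,
    dt: float = 0.01,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """One steered pass; emit (bias_center, start_z) at each grid crossing.

    The bias center moves as z₀(t) = start + v·t and the instantaneous
    permeant position is captured each time the center crosses a grid point
    spaced by the schedule's spacing.
    """
    _check_stability(landscape, thermo, dt)
    sgn = 1.0 if schedule.end >= schedule.start else -1.0
    grid = schedule.start + sgn * schedule.spacing * np.arange(schedule.n_seeds)
    vel_ps = sgn * schedule.velocity * 1e-3  # Å/ns → Å/ps
    if schedule.start == schedule.end:
        return [(schedule.start, schedule.start)]
    span = abs(schedule.end - schedule.start)
    n_steps = int(np.ceil(span / (abs(vel_ps) * dt))) + 1
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(n_steps)
    gc, gh, gw = _term_arrays(landscape.g_terms)
    dc, dh, dw = _term_arrays(landscape.d_terms)
    start = float(np.clip(schedule.start, landscape.z_min, landscape.z_max))
    seeds = _propagate_pull(
        start, n_steps, dt, 1, thermo.beta, schedule.start, vel_ps,
        schedule.spring_k, gc, gh, gw, dc, dh, dw, landscape.d_base,
        landscape.z_min, landscape.z_max, grid, noise,
    )
    return [(float(g), float(s)) for g, s in zip(grid, seeds)]


def generate_window_set(
    landscape: LandscapeSpec,
    thermo: ThermoState,
    centers: np.ndarray | None = None,
    spring_k: float = 2.5,
    n_steps: int = 2_000_000,
    dt: float = 0.01,
    sample_stride: int = 10,
    seed: int = 0,
    use_pull_seeding: bool = False,
) -> list[WindowTrajectory]:
    """Simulate a full umbrella set (default 71 windows at 1 Å spacing)."""
    if centers is None:
        centers = np.arange(0.0, 71.0, 1.0)
    centers = np.asarray(centers, dtype=float)
    starts: dict[float, float] = {}
    if use_pull_seeding:
        sched = PullSchedule(
            start=float(centers.max()), end=float(centers.min()),
            spring_k=spring_k,
            spacing=float(abs(np.diff(np.sort(centers))[0])) if len(centers) > 1 else 1.0,
        )
        for c, s in seed_windows(landscape, sched, thermo, dt=dt, seed=seed):
            starts[round(c, 9)] = s
    rng = np.random.default_rng(seed)
    window_seeds = rng.integers(0, 2**31 - 1, size=len(centers))
    windows = []
    for c, s in zip(centers, window_seeds):
        windows.append(simulate_window(
            landscape, float(c), spring_k, thermo,
            n_steps=n_steps, dt=dt, sample_stride=sample_stride,
            seed=int(s), z0=starts.get(round(float(c), 9)),
        ))
    return windows


# ---------------------------------------------------------------------------
# toy membrane frames


@dataclass(frozen=True)
class SlabSpec:
    """Geometry of the toy membrane slab along z."""

    core_center: float = 40.0      # Å
    core_half_width: float = 17.0  # Å: OL/CHL band is |z−core_center| < this
    head_shell_width: float = 3.0  # Å thickness of each interface shell
    n_tail: int = 60               # OL + CHL pseudo-atoms
    n_head: int = 40               # PC/PE/PS/PG pseudo-atoms (both shells)
    box_xy: float = 40.0           # Å lateral box
    z_extent: float = 80.0         # Å total box height


def generate_toy_frames(
    n_frames: int,
    n_water: int,
    slab: SlabSpec | None = None,
    drug_z: float = 70.0,
    seed: int = 0,
) -> list[Frame]:
    """Labeled point-particle membrane snapshots with a single DRG particle.

    OL/CHL pseudo-atoms are uniform in the hydrophobic band, headgroup
    pseudo-atoms (PC/PE/PS/PG) sit in two interface shells, water fills the
    remaining z range, and the drug is fixed at ``drug_z``.  Overlaps are
    allowed (point particles); ground-truth pair distances are recoverable
    by brute force.
    """
    if slab is None:
        slab = SlabSpec()
    rng = np.random.default_rng(seed)
    lo = slab.core_center - slab.core_half_width
    hi = slab.core_center + slab.core_half_width
    frames = []
    head_labels = ["PC", "PE", "PS", "PG"]
    tail_labels = ["OL", "CHL"]
    for _ in range(n_frames):
        elements, labels, coords = [], [], []

        def xy(n):
            return rng.uniform(0, slab.box_xy, size=(n, 2))

        # hydrophobic band
        tz = rng.uniform(lo, hi, size=slab.n_tail)
        txy = xy(slab.n_tail)
        for i in range(slab.n_tail):
            elements.append("C")
            labels.append(tail_labels[i % 2])
            coords.append([txy[i, 0], txy[i, 1], tz[i]])
        # two interface head shells
        half = slab.n_head // 2
        for shell_base, n in ((hi, half), (lo - slab.head_shell_width,
                                           slab.n_head - half)):
            hz = rng.uniform(shell_base, shell_base + slab.head_shell_width, size=n)
            hxy = xy(n)
            for i in range(n):
                elements.append("P")
                labels.append(head_labels[i % 4])
                coords.append([hxy[i, 0], hxy[i, 1], hz[i]])
        # water outside the slab
        if n_water:
            wz = np.empty(n_water)
            filled = 0
            while filled < n_water:
                cand = rng.uniform(0, slab.z_extent, size=n_water - filled)
                keep = cand[(cand < lo - slab.head_shell_width) |
                            (cand > hi + slab.head_shell_width)]
                wz[filled:filled + len(keep)] = keep
                filled += len(keep)
            wxy = xy(n_water)
            for i in range(n_water):
                elements.append("O")
                labels.append("WAT")
                coords.append([wxy[i, 0], wxy[i, 1], wz[i]])
        # the permeant
        elements.append("Pt")
        labels.append("DRG")
        coords.append([slab.box_xy / 2, slab.box_xy / 2, drug_z])
        frames.append(Frame(
            elements, labels, np.array(coords),
            box=np.array([slab.box_xy, slab.box_xy, slab.z_extent]),
        ))
    return frames
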