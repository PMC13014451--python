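# Methods

This note defines the models and estimators implemented in permeakit, the
numerical choices behind them, and their known limitations. Internal units
throughout: kcal/mol for energies, Å for lengths, ps for times,
k_B = 0.0019872041 kcal/mol/K (k_BT = 0.6160 kcal/mol at 310 K).

## 1. Umbrella windows and WHAM (`pmf_wham`)

**Model.** Each umbrella window *i* restrains the permeant's membrane-normal
coordinate z with a harmonic bias w_i(z) = ½k(z − z_i)². The unbiased
probability density p(z) on a histogram grid is recovered by iterating the
WHAM self-consistency equations:

    p(z_b) = Σ_i n_i(z_b) / Σ_i N_i exp[β(f_i − w_i(z_b))]
    f_i    = −β⁻¹ ln Σ_b p(z_b) exp[−β w_i(z_b)]

with G(z_b) = −β⁻¹ ln p(z_b), pinned so that the minimum of G over a
bulk-water reference region is zero.

**Numerical choices.**

- Histogram bins (default width 0.2 Å) are aligned to multiples of the bin
  width so that results do not depend on the sample extrema.
- Bins with zero total counts are *masked out*, never interpolated: an empty
  bin carries no information and log(0) would otherwise poison the
  iteration. The returned profile simply omits those grid points.
- The window free energies f_i are gauge-fixed (f_0 = 0) during iteration;
  convergence is declared when the largest change in any f_i falls below the
  tolerance (default 10⁻⁷ kcal/mol). Adding a constant to every bias leaves
  G unchanged (verified as a test invariant).
- A window-overlap check warns when adjacent histograms share too little
  support, the classic failure mode of stratified sampling.
- Default reference region: the last 10 % of the sampled range, or an
  explicit interval such as (65, 70) Å for the synthetic membrane, where the
  permeant is in bulk water.

**Errors.** Standard errors come from a moving-block bootstrap
(default block length 200 samples, ≥20 replicates): blocks of each window's
time series are resampled with replacement, preserving short-range
autocorrelation. Each replicate PMF is solved on the original bin edges,
interpolated onto the base grid, and re-pinned on the base reference region
before the per-bin standard deviation is taken — re-pinning removes the
arbitrary gauge that would otherwise inflate the error band.

**Landmarks.** `extract_landmarks` reports the minima over the two
interfacial regions (defaults 15–30 Å and 50–65 Å), the maximum over the
core region (30–50 Å), and the barrier heights ΔG = G_max − G_min from
either side. Ties break toward the region center.

## 2. Diffusivity and permeability (`permeation_kinetics`)

**Local diffusivity.** For each restrained window the position
autocorrelation C_zz(t) = ⟨δz(0) δz(t)⟩ is computed by FFT with the biased
(fixed 1/n) normalization, which keeps the estimator positive-semidefinite.
The local diffusion coefficient is

    D = var(z)² / ∫₀^τc C_zz(t) dt.

For an Ornstein–Uhlenbeck process (a harmonically restrained overdamped
particle) C = var·e^{−t/τ} and ∫C = var·τ, so D = var/τ exactly — this is
the oracle used in the test suite, and it also fixes the reading of the
estimator: the alternative var/(2∫C) would be wrong by a factor of two on
the same oracle.

- The integral is truncated at the *first zero crossing* of C_zz: beyond
  it, the true correlation is below the noise floor and the integral would
  otherwise random-walk.
- Maximum lag defaults to 5 % of the window length.
- Windows where the estimator fails (zero variance, non-positive integral)
  are excluded with a warning; D(z) is linearly interpolated between the
  surviving windows' mean positions and held constant beyond the outermost
  ones.

**Permeability.** The inhomogeneous solubility-diffusion model:

    1/P = R_eff = ∫_{z_in}^{z_out} exp(βG(z)) / D(z) dz,

with z in cm and D in cm²/s (1 Å²/ps = 10⁻⁴ cm²/s), so P is in cm/s and the
local resistance R(z) in s/cm². The integrand is accumulated in log space
with a max-shift, so the result is exact to floating precision for any
barrier height; `log10_P` and `log10_R_eff` remain finite even when P
itself underflows a double (βG ≳ 700). P·R_eff = 1 by construction, to
machine precision.

## 3. Synthetic ground truth (`synthetic_membrane`)

**Landscape.** G(z) and D(z) are sums of Gaussian terms
h·exp(−(z−c)²/2w²) over a [0, 70] Å domain. The default
(`default_membrane_landscape`) reproduces the cisplatin-like case:
interfacial wells of −0.8 kcal/mol at 22.4 and 57.3 Å (width 2 Å), a core
barrier of +16.0 kcal/mol at 40.0 Å (width 4.5 Å), base diffusivity
0.1 Å²/ps with dips at the interfaces and core. D is clipped at 5 % of the
base value.

**Dynamics.** Overdamped (high-friction) Langevin dynamics in the Itô
convention:

    z ← z + [−βD(z)(G′(z) + w′(z)) + D′(z)]·dt + √(2 D(z) dt)·ξ

with reflecting boundaries. The D′ term is the spurious-drift correction
required for the scheme to sample the correct stationary density when D
varies with position; a χ² test of the stationary density under strongly
varying D guards it. A stability precondition (βD·max|G′|·dt < 0.1 Å)
rejects unsafe time steps. Kernels are numba-compiled; a full 71-window
study runs in ~15 s on one CPU.

**Defaults as package choices.** 71 windows at 1 Å spacing, spring constant
2.5 kcal mol⁻¹ Å⁻², 310 K, time step 0.01 ps, sample stride 10, and 2×10⁵
retained samples per window after discarding the first half of each series
as equilibration. These sizes are chosen so that the WHAM reconstruction
error (≈0.1 kcal/mol RMSD) is small compared to the 0.5 kcal/mol acceptance
tolerance while the whole study stays desk-scale. Initial window
configurations can also be seeded from a steered pull
(default velocity 0.972 Å/ns) via `seed_windows`.

**What the generator does and does not emulate.** It reproduces the
*statistics* that the estimators consume — biased stationary densities,
window autocorrelation times, position-dependent mobility — on a known
landscape. It does not emulate lipid degrees of freedom, membrane
deformation, orthogonal slow modes, or finite-size artifacts of real
all-atom simulations; conclusions about those cannot be drawn from it.

## 4. Structural profiles (`trajectory_profiles`)

All pair queries use the minimum-image convention when a frame carries an
orthorhombic box, and a KD-tree fast path whose results are tested for
exact equality against an O(N²) brute-force oracle.

- **Contacts** (cutoff 7.0 Å): the native pair set is defined by the
  reference frame; per-frame native/non-native tallies are frame-averaged
  and rounded for reporting, with raw means retained.
- **Hydration** (threshold 3.0 Å): water oxygens within the threshold of
  any probe atom; per-window means carry a ±1σ frame-to-frame band. A
  fully solvated small platinum complex holds ~13 first-shell waters, the
  bulk anchor used in the tests.
- **Hydrogen bonds**: geometric criterion, heavy-donor–acceptor distance
  ≤ 3.5 Å and D–H···A angle at the hydrogen ≥ 135°, with donor/acceptor
  role tallies for the probe.
- **RDF**: ideal-gas normalized (g ≡ 1 for uncorrelated particles);
  r_max must not exceed half the smallest box length; open frames require
  an explicit reference volume.
- **Electron density**: per-component profiles along z, each atom
  contributing its element's electron count (Pt = 78) to its bin; the
  profile integral times the lateral area recovers the total electron count
  exactly, and components sum to the total by construction.

## 5. MM-GBSA energetics (`mmgbsa_energetics`)

Single-trajectory end-state decomposition, every Δ term being
complex − receptor − ligand:

    ΔG_total = ΔE_int + ΔE_ele + ΔE_vdW + ΔG_GB + ΔG_SA

- Component geometries are extracted from the complex, so ΔE_int ≡ 0
  exactly (single-trajectory convention), and the gas-phase Δ terms reduce
  to the receptor–ligand cross sums.
- Coulomb: k_e = 332.0637 kcal·Å/mol/e². Lennard-Jones: Lorentz–Berthelot
  mixing (arithmetic σ, geometric ε).
- Polar solvation: the Still pairwise generalized-Born form
  f_GB = √(r² + R_iR_j e^{−r²/4R_iR_j}) including self terms, with
  ε_in = 1, ε_out = 78.5 by default. A single ion reduces exactly to the
  Born formula (−81.97 kcal/mol for q = 1e, R = 2 Å, ε 1→80). Born radii
  are inputs (default σ/2), not computed self-consistently.
- Nonpolar solvation: G_SA = γ·SASA with γ = 0.0072 kcal/mol/Å², SASA by
  Shrake–Rupley point sampling (960 golden-spiral points, probe 1.4 Å;
  an isolated sphere is exact to <0.5 %).
- The conformational-entropy term −TΔS is reported as the explicit string
  `"omitted"` — it is genuinely not computed, and must never silently enter
  a sum.

## 6. Known limitations

- Published landmark tables for these systems round the barrier-height
  columns independently of the (z, G) columns, so exact differences
  G_max − G_min can disagree with quoted ΔG values by 0.1 kcal/mol. The
  package always reports the exact difference.
- Published permeability/resistance pairs are likewise not always mutually
  reciprocal at two significant figures; permeakit enforces P·R_eff = 1 to
  machine precision for everything it computes.
- WHAM error bars assume the moving-block bootstrap captures the window
  autocorrelation; block length (default 200 samples) should exceed the
  correlation time.
- The diffusivity estimator assumes the restrained coordinate is locally
  harmonic and overdamped; strongly anharmonic or inertial windows bias it.
- Generalized-Born energies are only as good as the supplied Born radii;
  no self-consistent radius model is included.
- Unit round trips between Å²/ps and cm²/s are exact to ≤1 ulp, not
  bitwise, because 10⁻⁴ is not representable in binary floating point.
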