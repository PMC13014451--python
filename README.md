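# permeakit

Analysis toolkit for passive membrane permeation of small solutes —
umbrella-sampling free-energy profiles, position-dependent diffusivities,
solubility-diffusion permeabilities, structural trajectory profiles, and
MM-GBSA end-state energetics. The numbers and defaults are tuned to the
textbook problem of cisplatin and its Pt(IV) prodrugs crossing a
phospholipid bilayer, but every estimator is generic.

## The science

A drug crossing a lipid bilayer experiences a one-dimensional free-energy
landscape G(z) along the membrane normal: shallow attractive wells at the
two head-group interfaces and a large barrier in the hydrophobic core.
Hydrophilic platinum drugs such as cisplatin face core barriers well above
10 kcal/mol, which is why their passive permeabilities are tiny (~10⁻⁹ cm/s)
and why lipophilic axial ligands on Pt(IV) prodrugs — which lower the core
barrier — raise permeability by orders of magnitude.

permeakit covers the full analysis chain:

1. **Umbrella sampling → PMF.** Harmonically restrained windows along z are
   combined with the weighted histogram analysis method (WHAM),
   self-consistently removing the bias
   w_i(z) = ½k(z − z_i)². Statistical error bands come from a moving-block
   bootstrap over each window's time series. Landmark extraction reports the
   interface minima, the core maximum, and the translocation barriers
   ΔG = G_max − G_min from either side.

2. **Restrained fluctuations → D(z).** The local diffusion coefficient per
   window is estimated from the positional variance and autocorrelation of
   the restrained coordinate,

       D = var(z)² / ∫₀^τc C_zz(t) dt,

   which is exact for an Ornstein–Uhlenbeck process. The integral is
   truncated at the first zero crossing of C_zz, where the tail becomes
   noise-dominated.

3. **G(z), D(z) → permeability.** The inhomogeneous solubility-diffusion
   model gives the permeability coefficient through the local resistance
   R(z):

       1/P = R_eff = ∫ exp(G(z)/k_BT) / D(z) dz,

   with z in cm and D in cm²/s so P is in cm/s. The exponential is handled
   in log space, so arbitrarily high barriers never overflow
   (`log10_P`/`log10_R_eff` stay finite even when P underflows a double).

4. **Synthetic ground truth.** Because converged all-atom umbrella sampling
   is not recomputable at desk scale, the package includes an overdamped
   Langevin generator on an analytic Gaussian-term landscape (wells
   −0.8 kcal/mol at 22.4 / 57.3 Å, core barrier +16.0 kcal/mol at 40.0 Å —
   the cisplatin case — with a matching position-dependent diffusivity).
   Every estimator can therefore be validated against known ground truth.

5. **Structural profiles.** Native/non-native contact counts, hydration-shell
   populations, geometric hydrogen bonds, radial distribution functions and
   per-component electron-density profiles over labeled frames
   (water, lipid head groups, tails, cholesterol, drug, ions).

6. **MM-GBSA energetics.** Single-trajectory end-state decomposition
   ΔG_total = ΔE_MM + ΔG_GB + ΔG_SA with pairwise Coulomb, Lennard-Jones
   (Lorentz–Berthelot), the Still generalized-Born form, and Shrake–Rupley
   surface areas. The conformational-entropy term is carried as an explicit
   `"omitted"` marker, never a silent zero.

Internal units: kcal/mol, Å, ps; k_B = 0.0019872041 kcal/mol/K.

## Worked example

Reconstruct the cisplatin-like permeation problem end to end from synthetic
umbrella windows:

```python
import permeakit as pk

thermo = pk.ThermoState(310.0)
landscape = pk.default_membrane_landscape()
windows = pk.generate_window_set(landscape, thermo, seed=7)

pmf = pk.wham_solve(windows, thermo, reference_region=(65.0, 70.0))
landmarks = pk.extract_landmarks(pmf.profile)
d_profile = pk.diffusivity_profile(windows, z_grid=pmf.profile.z_grid)
perm = pk.permeability(pmf.profile, d_profile, thermo, 15.0, 65.0)

print(f"converged: {pmf.converged} after {pmf.iterations} iterations")
print(f"core barrier:    {landmarks.max[1]:6.2f} kcal/mol at z = {landmarks.max[0]:.1f} A")
print(f"interface wells: {landmarks.min_left[1]:6.2f} (z = {landmarks.min_left[0]:.1f} A), "
      f"{landmarks.min_right[1]:6.2f} (z = {landmarks.min_right[0]:.1f} A)")
print(f"dG_right = {landmarks.dG_right:.2f} kcal/mol, dG_left = {landmarks.dG_left:.2f} kcal/mol")
print(f"P     = {perm.P:.2e} cm/s")
print(f"R_eff = {perm.R_eff:.2e} s/cm")
```

Output (about 25 s on one CPU):

```
converged: True after 18810 iterations
core barrier:     16.09 kcal/mol at z = 40.1 A
interface wells:  -0.64 (z = 22.1 A),  -0.81 (z = 57.3 A)
dG_right = 16.89 kcal/mol, dG_left = 16.73 kcal/mol
P     = 1.25e-09 cm/s
R_eff = 7.98e+08 s/cm
```

The reconstructed barrier (16.09 kcal/mol) recovers the ground-truth
16.0 kcal/mol, and the permeability lands in the ~10⁻⁹ cm/s regime expected
for a barrier of that height — with P·R_eff = 1 holding to machine
precision.

The same pipeline is available from the command line:

```sh
permeakit synth --seed 7 --out scratch/windows      # windows + ground truth
permeakit pmf --manifest scratch/windows/manifest.tsv --out scratch/run
permeakit kinetics --manifest scratch/windows/manifest.tsv --out scratch/run
```

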