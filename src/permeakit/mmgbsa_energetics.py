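"""End-state free-energy bookkeeping (MM-GBSA) with a minimal nonbonded
evaluator for toy complex/receptor/ligand systems.

ΔG_total = ΔE_MM + ΔG_sol, with ΔE_MM = ΔE_int + ΔE_ele + ΔE_vdW and
ΔG_sol = ΔG_GB + ΔG_SA.  Each Δ term is complex − receptor − ligand.  The
single-trajectory convention (component geometries extracted from the
complex) makes ΔE_int identically zero.  The conformational-entropy term
−TΔS is carried as an explicit "omitted" marker, never a silent zero.

The evaluator provides pairwise Coulomb, Lennard-Jones (Lorentz–Berthelot
mixing), the Still pairwise Generalized Born form (Born radii are inputs),
and Shrake–Rupley point-sampled solvent-accessible surface area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import Frame, PermeakitError

#: Coulomb constant, kcal·Å/mol/e²
KE = 332.0637

#: nonpolar surface coefficient, kcal/mol/Å², and offset, kcal/mol
GAMMA_SA = 0.0072
BETA_SA = 0.0

DEFAULT_EPS_IN = 1.0
DEFAULT_EPS_OUT = 78.5


@dataclass
class EnergyComponents:
    """One system's energy ledger (complex, receptor, or ligand)."""

    E_int: float = 0.0
    E_ele: float = 0.0
    E_vdW: float = 0.0
    G_GB: float = 0.0
    G_SA: float = 0.0


@dataclass
class EnergyDecomposition:
    """The MM-GBSA Δ-term ledger: every Δ is complex − receptor − ligand."""

    dE_int: float
    dE_ele: float
    dE_vdW: float
    dG_GB: float
    dG_SA: float
    TdS: str = "omitted"

    @property
    def dE_MM(self) -> float:
        return self.dE_int + self.dE_ele + self.dE_vdW

    @property
    def dG_sol(self) -> float:
        return self.dG_GB + self.dG_SA

    @property
    def dG_gas(self) -> float:
        return self.dE_MM

    @property
    def dG_total(self) -> float:
        return self.dE_MM + self.dG_sol


def _require_charges(frame: Frame) -> np.ndarray:
    if frame.charges is None:
        raise PermeakitError("frame carries no charges")
    return frame.charges


def _distances(coords: np.ndarray) -> np.ndarray:
    delta = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((delta**2).sum(axis=-1))


def coulomb_energy(frame: Frame, dielectric_in: float = DEFAULT_EPS_IN) -> float:
    """Pairwise Coulomb energy Σ_{i<j} k_e·q_i·q_j/(ε_in·r_ij), kcal/mol."""
    q = _require_charges(frame)
    if frame.n_atoms < 2:
        return 0.0
    r = _distances(frame.coords)
    iu = np.triu_indices(frame.n_atoms, k=1)
    if np.any(r[iu] == 0):
        raise PermeakitError("coincident atoms in Coulomb evaluation")
    return float(KE / dielectric_in * np.sum(q[iu[0]] * q[iu[1]] / r[iu]))


def lj_energy(frame: Frame, sigma: np.ndarray, epsilon: np.ndarray) -> float:
    """12-6 Lennard-Jones energy with Lorentz–Berthelot combining, kcal/mol.

    σ_ij = (σ_i+σ_j)/2 (arithmetic), ε_ij = √(ε_i·ε_j) (geometric).
    """
    sigma = np.asarray(sigma, dtype=float)
    epsilon = np.asarray(epsilon, dtype=float)
    n = frame.n_atoms
    if n < 2:
        return 0.0
    r = _distances(frame.coords)
    iu = np.triu_indices(n, k=1)
    rij = r[iu]
    if np.any(rij == 0):
        raise PermeakitError("coincident atoms in LJ evaluation")
    sij = 0.5 * (sigma[iu[0]] + sigma[iu[1]])
    eij = np.sqrt(epsilon[iu[0]] * epsilon[iu[1]])
    sr6 = (sij / rij) ** 6
    return float(np.sum(4.0 * eij * (sr6**2 - sr6)))


def gb_energy(
    frame: Frame,
    born_radii: np.ndarray,
    eps_in: float = DEFAULT_EPS_IN,
    eps_out: float = DEFAULT_EPS_OUT,
) -> float:
    """Still pairwise Generalized Born polar solvation energy, kcal/mol.

    G_GB = −½·k_e·(1/ε_in − 1/ε_out)·Σ_{i,j} q_i·q_j / f_GB with
    f_GB = √(r² + R_i·R_j·exp(−r²/(4·R_i·R_j))); self terms (i == j, r = 0,
    f_GB = R_i) are included, which for a single ion reduces to the Born
    formula.  Born radii are supplied, not computed self-consistently.
    """
    q = _require_charges(frame)
    R = np.asarray(born_radii, dtype=float)
    if np.any(R <= 0):
        raise PermeakitError("Born radii must be positive")
    r2 = ((frame.coords[:, None, :] - frame.coords[None, :, :]) ** 2).sum(axis=-1)
    rr = R[:, None] * R[None, :]
    f_gb = np.sqrt(r2 + rr * np.exp(-r2 / (4.0 * rr)))
    prefac = -0.5 * KE * (1.0 / eps_in - 1.0 / eps_out)
    return float(prefac * np.sum(q[:, None] * q[None, :] / f_gb))


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack([np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi),
                            np.cos(phi)])


def sasa(
    frame: Frame,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> tuple[float, np.ndarray]:
    """Shrake–Rupley solvent-accessible surface area.

    Each atom's accessible sphere (radius r_i + probe) is sampled with a
    golden-spiral point set; a point is exposed when outside every other
    atom's expanded sphere.  Returns (total, per-atom) areas in Å².
    """
    if n_sphere_points < 10:
        raise PermeakitError("n_sphere_points must be ≥ 10")
    radii = np.asarray(radii, dtype=float)
    if len(radii) != frame.n_atoms:
        raise PermeakitError("one radius per atom required")
    expanded = radii + probe_radius
    unit = _sphere_points(n_sphere_points)
    per_atom = np.zeros(frame.n_atoms)
    coords = frame.coords
    for i in range(frame.n_atoms):
        pts = coords[i] + expanded[i] * unit
        exposed = np.ones(n_sphere_points, dtype=bool)
        for j in range(frame.n_atoms):
            if j == i:
                continue
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            exposed &= d2 > expanded[j] ** 2
            if not exposed.any():
                break
        frac = exposed.sum() / n_sphere_points
        per_atom[i] = frac * 4.0 * np.pi * expanded[i] ** 2
    return float(per_atom.sum()), per_atom


def sa_energy(total_sasa: float, gamma: float = GAMMA_SA,
              b: float = BETA_SA) -> float:
    """Nonpolar solvation term G_SA = γ·SASA + b, kcal/mol."""
    return gamma * total_sasa + b


def evaluate_components(
    frame: Frame,
    sigma: np.ndarray,
    epsilon: np.ndarray,
    born_radii: np.ndarray | None = None,
    eps_in: float = DEFAULT_EPS_IN,
    eps_out: float = DEFAULT_EPS_OUT,
    gamma: float = GAMMA_SA,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> EnergyComponents:
    """Full energy ledger for one system.

    Born radii default to σ/2 (intrinsic LJ radius) when not given.  E_int
    is zero by the single-trajectory convention.
    """
    sigma = np.asarray(sigma, dtype=float)
    if born_radii is None:
        born_radii = sigma / 2.0
    total_area, _ = sasa(frame, np.asarray(born_radii, dtype=float),
                         probe_radius, n_sphere_points)
    return EnergyComponents(
        E_int=0.0,
        E_ele=coulomb_energy(frame, eps_in),
        E_vdW=lj_energy(frame, sigma, epsilon),
        G_GB=gb_energy(frame, born_radii, eps_in, eps_out),
        G_SA=sa_energy(total_area, gamma),
    )


def mmgbsa_decompose(
    complex_: EnergyComponents,
    receptor: EnergyComponents,
    ligand: EnergyComponents,
) -> EnergyDecomposition:
    """Δ-term ledger: ΔX = X(complex) − X(receptor) − X(ligand)."""
    def d(attr):
        return getattr(complex_, attr) - getattr(receptor, attr) \
            - getattr(ligand, attr)

    return EnergyDecomposition(
        dE_int=d("E_int"), dE_ele=d("E_ele"), dE_vdW=d("E_vdW"),
        dG_GB=d("G_GB"), dG_SA=d("G_SA"),
    )


def split_frame(frame: Frame, ligand_label: str = "DRG"):
    """Single-trajectory split of a complex frame into (receptor, ligand).

    Geometries are extracted from the complex unchanged, so gas-phase
    internal energies cancel exactly in the decomposition.
    """
    lig_idx = frame.select(ligand_label)
    if len(lig_idx) == 0:
        raise PermeakitError(f"ligand label {ligand_label!r} absent")
    rec_idx = np.array([i for i in range(frame.n_atoms)
                        if frame.labels[i] != ligand_label], dtype=int)

    def sub(idx):
        return Frame(
            [frame.elements[i] for i in idx],
            [frame.labels[i] for i in idx],
            frame.coords[idx],
            charges=None if frame.charges is None else frame.charges[idx],
            radii=None if frame.radii is None else frame.radii[idx],
            box=frame.box,
        ), idx

    return sub(rec_idx), sub(lig_idx)
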