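"""Domain types, units, and file I/O shared by every analysis stage.

Internal unit system: energies in kcal/mol, lengths in Å, times in ps,
temperature in K.  Diffusivities are held in Å²/ps internally and converted
to cm²/s only when results are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

logger = logging.getLogger("permeakit")

#: Boltzmann constant, kcal mol^-1 K^-1
KB = 0.0019872041

#: closed vocabulary of component labels: water, phospholipid headgroups
#: (phosphatidyl-choline/-ethanolamine/-serine/-glycerol), oleoyl tails,
#: cholesterol, the permeant drug, and monoatomic ions
COMPONENT_LABELS = frozenset(
    {"WAT", "PC", "PE", "PS", "PG", "OL", "CHL", "DRG", "ION"}
)

#: residue-name → component-label map for PDB input
PDB_RESIDUE_MAP = {
    "HOH": "WAT", "WAT": "WAT", "TIP": "WAT", "SPC": "WAT", "T3P": "WAT",
    "PC": "PC", "POPC": "PC", "DOPC": "PC",
    "PE": "PE", "POPE": "PE",
    "PS": "PS", "POPS": "PS",
    "PG": "PG", "POPG": "PG",
    "OL": "OL", "OLE": "OL",
    "CHL": "CHL", "CLR": "CHL", "CHOL": "CHL",
    "DRG": "DRG", "LIG": "DRG",
    "ION": "ION", "NA": "ION", "CL": "ION", "K": "ION", "MG": "ION",
}


class PermeakitError(RuntimeError):
    """Fatal condition in input data or preconditions."""


@dataclass(frozen=True)
class ThermoState:
    """Thermodynamic state: temperature and the derived inverse energy β.

    β = 1/(k_B·T) in mol/kcal, with k_B = 0.0019872041 kcal/mol/K.
    """

    temperature: float

    def __post_init__(self):
        if not self.temperature > 0:
            raise PermeakitError(f"temperature must be > 0 K, got {self.temperature}")

    @property
    def kT(self) -> float:
        """Thermal energy k_B·T in kcal/mol."""
        return KB * self.temperature

    @property
    def beta(self) -> float:
        """Inverse thermal energy 1/(k_B·T) in mol/kcal."""
        return 1.0 / (KB * self.temperature)


@dataclass
class WindowTrajectory:
    """One umbrella window: z(t) series under a harmonic bias.

    The bias potential is U(z) = ½·spring_k·(z − bias_center)².
    ``times``/``z_values`` hold the retained (post-equilibration) samples.
    """

    bias_center: float          # Å
    spring_k: float             # kcal mol^-1 Å^-2
    times: np.ndarray           # ps, strictly increasing, uniform step
    z_values: np.ndarray        # Å
    equilibrated_fraction: float = 0.0  # fraction already discarded

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.z_values = np.asarray(self.z_values, dtype=float)
        if self.times.shape != self.z_values.shape:
            raise PermeakitError("times and z_values must have equal length")
        if len(self.times) < 2:
            raise PermeakitError("window series needs at least 2 samples")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise PermeakitError("window times must be strictly increasing")
        if np.max(np.abs(dt - dt[0])) > 1e-9 * max(abs(dt[0]), 1.0):
            raise PermeakitError("window time step must be uniform")

    @property
    def n_samples(self) -> int:
        return len(self.z_values)

    @property
    def dt(self) -> float:
        """Sampling interval in ps."""
        return float(self.times[1] - self.times[0])

    def bias_energy(self, z: np.ndarray) -> np.ndarray:
        """Harmonic bias w(z) = ½k(z−z₀)² in kcal/mol."""
        return 0.5 * self.spring_k * (np.asarray(z) - self.bias_center) ** 2


@dataclass
class Frame:
    """A labeled atomic snapshot.

    ``elements`` and ``labels`` are per-atom; ``coords`` is (N, 3) in Å.
    ``charges`` (e) and ``radii`` (Å) are optional per-atom arrays; ``box``
    is optional orthorhombic box lengths (3,) in Å.
    """

    elements: list[str]
    labels: list[str]
    coords: np.ndarray
    charges: np.ndarray | None = None
    radii: np.ndarray | None = None
    box: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = len(self.coords)
        if len(self.elements) != n or len(self.labels) != n:
            raise PermeakitError("elements/labels/coords length mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise PermeakitError("non-finite coordinates in frame")
        bad = set(self.labels) - COMPONENT_LABELS
        if bad:
            raise PermeakitError(f"unknown component labels: {sorted(bad)}")
        if self.charges is not None:
            self.charges = np.asarray(self.charges, dtype=float)
        if self.radii is not None:
            self.radii = np.asarray(self.radii, dtype=float)
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,) or np.any(self.box <= 0):
                raise PermeakitError("box must be 3 positive orthorhombic lengths")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def select(self, label: str) -> np.ndarray:
        """Indices of atoms carrying a component label."""
        return np.array([i for i, l in enumerate(self.labels) if l == label], dtype=int)


@dataclass
class Profile:
    """A quantity sampled on a strictly increasing z grid (Å)."""

    z_grid: np.ndarray
    values: np.ndarray
    unit: str
    stderr: np.ndarray | None = None

    def __post_init__(self):
        self.z_grid = np.asarray(self.z_grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.z_grid.shape != self.values.shape:
            raise PermeakitError("z_grid and values must have equal length")
        if np.any(np.diff(self.z_grid) <= 0):
            raise PermeakitError("z_grid must be strictly increasing")
        if np.any(np.isnan(self.values)):
            raise PermeakitError("profile values contain NaN")
        if self.stderr is not None:
            self.stderr = np.asarray(self.stderr, dtype=float)
            if self.stderr.shape != self.values.shape:
                raise PermeakitError("stderr length mismatch")

    def interp(self, z: np.ndarray) -> np.ndarray:
        """Linear interpolation, constant extrapolation beyond the ends."""
        return np.interp(np.asarray(z, dtype=float), self.z_grid, self.values)


@dataclass
class RunConfig:
    """Run configuration for the pipeline stages."""

    temperature: float = 310.0
    manifest: str | None = None
    frames: str | None = None
    bin_width: float = 0.2                 # Å, WHAM histogram bins
    wham_tolerance: float = 1e-7           # kcal/mol on window shifts
    wham_max_iter: int = 100_000
    n_bootstrap: int = 50
    block_length: int = 200
    seed: int = 0
    z_in: float = 15.0                     # Å, permeability integration bounds
    z_out: float = 65.0
    equilibrated_fraction: float = 0.5
    hydration_cutoff: float = 3.0          # Å
    contact_cutoff: float = 7.0            # Å
    hbond_distance: float = 3.5            # Å heavy–heavy
    hbond_angle: float = 135.0             # degrees at H
    reference_region: tuple[float, float] = (65.0, 70.0)
    output_dir: str = "."

    def __post_init__(self):
        if not self.z_in < self.z_out:
            raise PermeakitError("z_in must be < z_out")
        for name in ("hydration_cutoff", "contact_cutoff", "hbond_distance"):
            if getattr(self, name) <= 0:
                raise PermeakitError(f"{name} must be > 0")

    @property
    def thermo(self) -> ThermoState:
        return ThermoState(self.temperature)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "reference_region" in data:
            data["reference_region"] = tuple(data["reference_region"])
        return cls(**data)


# ---------------------------------------------------------------------------
# window manifest / series I/O


def read_window_series(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column (time_ps, z_angstrom) series; '#' comments allowed."""
    path = Path(path)
    if not path.exists():
        raise PermeakitError(f"series file not found: {path}")
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.size == 0:
        raise PermeakitError(f"empty series file: {path}")
    if data.shape[1] < 2:
        raise PermeakitError(f"series file {path} must have 2 columns")
    return data[:, 0], data[:, 1]


def read_window_manifest(
    path: str | Path,
    equilibrated_fraction: float = 0.5,
    min_retained: int = 100,
) -> list[WindowTrajectory]:
    """Load umbrella windows from a TSV manifest.

    The manifest has columns ``window_id  bias_center  spring_k  series_path``
    (header row required; '#' comments allowed); series paths are resolved
    relative to the manifest location.  The leading ``equilibrated_fraction``
    of each series is discarded as equilibration.
    """
    path = Path(path)
    if not path.exists():
        raise PermeakitError(f"manifest not found: {path}")
    windows: list[WindowTrajectory] = []
    with open(path) as fh:
        header = None
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if header is None:
                header = [f.strip().lower() for f in fields]
                required = {"window_id", "bias_center", "spring_k", "series_path"}
                if not required.issubset(header):
                    raise PermeakitError(
                        f"manifest missing columns {sorted(required - set(header))}"
                    )
                idx = {name: header.index(name) for name in required}
                continue
            wid = fields[idx["window_id"]]
            center = float(fields[idx["bias_center"]])
            k = float(fields[idx["spring_k"]])
            series = path.parent / fields[idx["series_path"]]
            if not series.exists():
                raise PermeakitError(f"window {wid}: series file not found: {series}")
            times, z = read_window_series(series)
            if np.any(np.diff(times) <= 0):
                raise PermeakitError(f"window {wid}: non-monotone times")
            n_skip = int(len(times) * equilibrated_fraction)
            times, z = times[n_skip:], z[n_skip:]
            if len(z) < min_retained:
                raise PermeakitError(
                    f"window {wid}: too few samples after equilibration discard "
                    f"({len(z)} < {min_retained})"
                )
            windows.append(
                WindowTrajectory(center, k, times, z,
                                 equilibrated_fraction=equilibrated_fraction)
            )
    if not windows:
        raise PermeakitError(f"manifest {path} contains no windows")
    return windows


def write_window_set(
    windows: Sequence[WindowTrajectory], out_dir: str | Path,
    manifest_name: str = "manifest.tsv",
) -> Path:
    """Write windows as series files plus a TSV manifest; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / manifest_name
    with open(manifest, "w") as mh:
        mh.write("window_id\tbias_center\tspring_k\tseries_path\n")
        for i, w in enumerate(windows):
            name = f"window_{i:03d}.dat"
            with open(out_dir / name, "w") as sh:
                sh.write("# time_ps z_angstrom\n")
                for t, z in zip(w.times, w.z_values):
                    sh.write(f"{float(t)!r} {float(z)!r}\n")
            mh.write(f"{i}\t{float(w.bias_center)!r}\t{float(w.spring_k)!r}"
                     f"\t{name}\n")
    return manifest


# ---------------------------------------------------------------------------
# frame I/O (extended XYZ with component label column; minimal PDB)


def _parse_xyz(path: Path) -> list[Frame]:
    frames: list[Frame] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError:
            raise PermeakitError(f"{path}:{i + 1}: expected atom count")
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        box = None
        if "box=" in comment.lower():
            tok = comment.lower().split("box=")[1].split()[0]
            box = np.array([float(v) for v in tok.split(",")])
        elements, labels, coords = [], [], []
        charges: list[float] = []
        have_charge = None
        for j in range(n):
            ln = i + 2 + j
            if ln >= len(lines):
                raise PermeakitError(f"{path}: truncated frame at line {ln + 1}")
            parts = lines[ln].split()
            if len(parts) < 5:
                raise PermeakitError(
                    f"{path}:{ln + 1}: need 'element x y z label [charge]'"
                )
            elements.append(parts[0])
            coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
            labels.append(parts[4])
            if have_charge is None:
                have_charge = len(parts) >= 6
            if have_charge:
                charges.append(float(parts[5]))
        frames.append(Frame(
            elements, labels, np.array(coords),
            charges=np.array(charges) if have_charge else None, box=box,
        ))
        i += 2 + n
    return frames


def _parse_pdb(path: Path) -> list[Frame]:
    frames: list[Frame] = []
    elements: list[str] = []
    labels: list[str] = []
    coords: list[list[float]] = []
    residues: list[tuple] = []       # per-atom (resname, chain, resseq, line)
    box = None

    def flush():
        nonlocal elements, labels, coords, residues
        if coords:
            # unknown residues are accepted as ION only when monoatomic
            from collections import Counter
            unknown = [i for i, l in enumerate(labels) if l is None]
            sizes = Counter(residues[i][:3] for i in unknown)
            for i in unknown:
                resname, _, _, lineno = residues[i]
                if sizes[residues[i][:3]] > 1:
                    raise PermeakitError(
                        f"{path}:{lineno}: unknown polyatomic residue "
                        f"{resname!r}")
                labels[i] = "ION"
            frames.append(Frame(elements, labels, np.array(coords), box=box))
            elements, labels, coords, residues = [], [], [], []

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            rec = line[:6].strip()
            if rec == "CRYST1":
                box = np.array([float(line[6:15]), float(line[15:24]),
                                float(line[24:33])])
            elif rec in ("ATOM", "HETATM"):
                try:
                    name = line[12:16].strip()
                    resname = line[17:21].strip()
                    chain = line[21:22]
                    resseq = line[22:26].strip()
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                except (ValueError, IndexError):
                    raise PermeakitError(f"{path}:{lineno}: malformed ATOM record")
                element = line[76:78].strip() if len(line) >= 78 else ""
                if not element:
                    element = "".join(c for c in name if c.isalpha())[:2].capitalize()
                    if len(element) > 1 and element[1].isupper():
                        element = element[0]
                elements.append(element)
                labels.append(PDB_RESIDUE_MAP.get(resname.upper()))
                coords.append([x, y, z])
                residues.append((resname, chain, resseq, lineno))
            elif rec in ("END", "ENDMDL"):
                flush()
    flush()
    return frames


def read_frames(path: str | Path, fmt: str | None = None) -> list[Frame]:
    """Read labeled frames from extended XYZ or minimal PDB.

    XYZ dialect: per-atom line ``element x y z label [charge]``; optional
    ``box=Lx,Ly,Lz`` token in the comment line.  PDB: residue names map to
    component labels through a fixed table; unknown residues are accepted as
    ION only when monoatomic.
    """
    path = Path(path)
    if fmt is None:
        fmt = "pdb" if path.suffix.lower() == ".pdb" else "xyz"
    if fmt == "xyz":
        return _parse_xyz(path)
    if fmt == "pdb":
        return _parse_pdb(path)
    raise PermeakitError(f"unknown frame format {fmt!r}")


def write_frames_xyz(frames: Sequence[Frame], path: str | Path) -> None:
    """Write frames in the extended XYZ dialect read_frames consumes."""
    with open(path, "w") as fh:
        for frame in frames:
            fh.write(f"{frame.n_atoms}\n")
            comment = "permeakit frame"
            if frame.box is not None:
                comment += " box=" + ",".join(f"{float(v)!r}" for v in frame.box)
            fh.write(comment + "\n")
            for i in range(frame.n_atoms):
                x, y, z = (float(v) for v in frame.coords[i])
                line = f"{frame.elements[i]} {x!r} {y!r} {z!r} {frame.labels[i]}"
                if frame.charges is not None:
                    line += f" {float(frame.charges[i])!r}"
                fh.write(line + "\n")


# ---------------------------------------------------------------------------
# unit conversion

_DIFFUSIVITY_FACTORS = {
    ("A2/ps", "cm2/s"): 1e-4,
    ("cm2/s", "A2/ps"): 1e4,
}

_UNIT_ALIASES = {
    "a2/ps": "A2/ps", "å2/ps": "A2/ps", "ang2/ps": "A2/ps", "a^2/ps": "A2/ps",
    "cm2/s": "cm2/s", "cm^2/s": "cm2/s",
}


def convert_diffusivity(value: float, from_unit: str, to_unit: str) -> float:
    """Convert diffusivities between Å²/ps and cm²/s (1 Å²/ps = 1e-4 cm²/s)."""
    try:
        f = _UNIT_ALIASES[from_unit.lower()]
        t = _UNIT_ALIASES[to_unit.lower()]
    except KeyError as exc:
        raise PermeakitError(f"unknown diffusivity unit: {exc.args[0]!r}")
    if f == t:
        return value
    return value * _DIFFUSIVITY_FACTORS[(f, t)]
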