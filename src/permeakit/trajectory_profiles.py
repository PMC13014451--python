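"""Structural analyses over labeled frames.

Native/non-native contact counts, hydration-shell populations with ±1σ
bands, geometric hydrogen bonds, radial distribution functions, and
per-component electron-density profiles.  All pair queries honor the
minimum-image convention when a frame carries an orthorhombic box and fall
back to open boundaries otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .core_io import Frame, PermeakitError, Profile

#: electrons per neutral element
ELECTRON_COUNT = {
    "H": 1, "C": 6, "N": 7, "O": 8, "P": 15, "S": 16, "Cl": 17,
    "K": 19, "Na": 11, "Mg": 12, "Pt": 78,
}


def _pair_distances(a: np.ndarray, b: np.ndarray,
                    box: np.ndarray | None) -> np.ndarray:
    """(len(a), len(b)) distance matrix, minimum image if box given."""
    delta = a[:, None, :] - b[None, :, :]
    if box is not None:
        delta -= box * np.round(delta / box)
    return np.sqrt((delta**2).sum(axis=-1))


def _neighbor_pairs(a: np.ndarray, b: np.ndarray, cutoff: float,
                    box: np.ndarray | None):
    """(i, j, distance) arrays for pairs within cutoff; KD-tree fast path."""
    if box is not None:
        # cKDTree periodic mode needs wrapped coordinates
        aw = np.mod(a, box)
        bw = np.mod(b, box)
        ta = cKDTree(aw, boxsize=box)
        tb = cKDTree(bw, boxsize=box)
    else:
        aw, bw = a, b
        ta, tb = cKDTree(a), cKDTree(b)
    pairs = ta.query_ball_tree(tb, cutoff)
    ii, jj = [], []
    for i, js in enumerate(pairs):
        ii.extend([i] * len(js))
        jj.extend(js)
    ii = np.array(ii, dtype=int)
    jj = np.array(jj, dtype=int)
    if len(ii) == 0:
        return ii, jj, np.zeros(0)
    delta = aw[ii] - bw[jj]
    if box is not None:
        delta -= box * np.round(delta / box)
    return ii, jj, np.sqrt((delta**2).sum(axis=-1))


@dataclass
class ContactReport:
    """Per-component-label contact statistics, frame-averaged.

    ``native_count``/``nonnative_count`` are rounded to the nearest integer
    (the raw frame averages are kept in ``native_mean``/``nonnative_mean``);
    ``mean_min_distance`` is the mean distance over contacting pairs.
    """

    per_label: dict[str, dict] = field(default_factory=dict)

    def native(self, label: str) -> int:
        return self.per_label.get(label, {}).get("native_count", 0)

    def nonnative(self, label: str) -> int:
        return self.per_label.get(label, {}).get("nonnative_count", 0)

    def mean_distance(self, label: str) -> float:
        return self.per_label.get(label, {}).get("mean_min_distance", np.nan)


@dataclass
class HBondReport:
    """Hydrogen-bond tallies per partner component label."""

    per_label: dict[str, dict] = field(default_factory=dict)
    probe_as_donor: int = 0
    probe_as_acceptor: int = 0

    @property
    def total(self) -> int:
        return sum(rec["count"] for rec in self.per_label.values())


@dataclass
class DensityProfile:
    """Per-component electron density along z, e/Å³."""

    z_grid: np.ndarray                     # bin centers, Å
    bin_width: float
    area: float                            # Å²
    per_component: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def total(self) -> np.ndarray:
        return sum(self.per_component.values())


def count_contacts(
    frames: Sequence[Frame],
    probe_label: str,
    reference_frame: Frame,
    cutoff: float = 7.0,
) -> ContactReport:
    """Native/non-native contacts of the probe with every other component.

    The native pair set is every probe–partner atom pair within ``cutoff``
    in ``reference_frame``.  Per frame, a pair within cutoff that belongs to
    the native set counts as native, otherwise non-native; counts are
    averaged over frames and rounded for reporting.
    """
    ref_probe = reference_frame.select(probe_label)
    if len(ref_probe) == 0:
        raise PermeakitError(f"probe label {probe_label!r} absent from reference")
    ref_other = np.array(
        [i for i in range(reference_frame.n_atoms)
         if reference_frame.labels[i] != probe_label], dtype=int)
    ii, jj, _ = _neighbor_pairs(
        reference_frame.coords[ref_probe], reference_frame.coords[ref_other],
        cutoff, reference_frame.box)
    native_set = set(zip(ref_probe[ii], ref_other[jj]))

    stats: dict[str, dict] = {}
    n_frames = len(frames)
    for frame in frames:
        probe = frame.select(probe_label)
        if len(probe) == 0:
            raise PermeakitError(f"probe label {probe_label!r} absent from frame")
        other = np.array([i for i in range(frame.n_atoms)
                          if frame.labels[i] != probe_label], dtype=int)
        if len(other) == 0:
            continue
        ii, jj, dist = _neighbor_pairs(frame.coords[probe],
                                       frame.coords[other],
                                       cutoff, frame.box)
        for a, b, d in zip(probe[ii], other[jj], dist):
            label = frame.labels[b]
            rec = stats.setdefault(label, {"native": 0, "nonnative": 0,
                                           "dist_sum": 0.0, "n_pairs": 0})
            if (a, b) in native_set:
                rec["native"] += 1
            else:
                rec["nonnative"] += 1
            rec["dist_sum"] += d
            rec["n_pairs"] += 1

    report = ContactReport()
    for label, rec in stats.items():
        nat = rec["native"] / n_frames
        non = rec["nonnative"] / n_frames
        report.per_label[label] = {
            "native_count": int(round(nat)),
            "nonnative_count": int(round(non)),
            "native_mean": nat,
            "nonnative_mean": non,
            "mean_min_distance": rec["dist_sum"] / rec["n_pairs"],
        }
    return report


def hydration_count(frame: Frame, probe_label: str,
                    threshold: float = 3.0) -> int:
    """Water oxygens within ``threshold`` Å of any probe atom (one frame)."""
    probe = frame.select(probe_label)
    if len(probe) == 0:
        raise PermeakitError(f"probe label {probe_label!r} absent")
    wat = [i for i in frame.select("WAT")
           if frame.elements[i].upper().startswith("O")]
    if not wat:
        return 0
    d = _pair_distances(frame.coords[np.array(wat)], frame.coords[probe],
                        frame.box)
    return int(np.sum(d.min(axis=1) <= threshold))


def hydration_profile(
    frames_by_window: Mapping[float, Sequence[Frame]],
    probe_label: str,
    threshold: float = 3.0,
) -> Profile:
    """Mean hydration-shell population per window with a ±1σ band.

    Keys of ``frames_by_window`` are bias centers (Å); per window the count
    of water oxygens within ``threshold`` of any probe atom is averaged over
    frames, with the frame-to-frame standard deviation as the band.
    """
    centers = sorted(frames_by_window)
    means, sigmas = [], []
    for c in centers:
        counts = [hydration_count(f, probe_label, threshold)
                  for f in frames_by_window[c]]
        means.append(float(np.mean(counts)))
        sigmas.append(float(np.std(counts)))
    return Profile(np.array(centers, dtype=float), np.array(means),
                   unit="molecules", stderr=np.array(sigmas))


def hydrogen_bonds(
    frame: Frame,
    donors: Sequence[tuple[int, int]],
    acceptors: Sequence[int],
    d_max: float = 3.5,
    angle_min: float = 135.0,
    probe_label: str = "DRG",
) -> HBondReport:
    """Geometric hydrogen bonds: heavy–acceptor ≤ d_max and D–H···A angle
    (at the hydrogen) ≥ angle_min degrees.

    ``donors`` are (heavy_atom_index, hydrogen_index) pairs; ``acceptors``
    are heavy-atom indices.  Role tallies count bonds where the probe
    component supplies the donor vs the acceptor.
    """
    report = HBondReport()
    coords = frame.coords
    for heavy, h in donors:
        if h >= frame.n_atoms or not frame.elements[h].upper().startswith("H"):
            raise PermeakitError(f"donor ({heavy},{h}): index {h} is not a hydrogen")
        for acc in acceptors:
            if acc == heavy:
                continue
            dvec = coords[acc] - coords[heavy]
            if frame.box is not None:
                dvec -= frame.box * np.round(dvec / frame.box)
            dist = float(np.linalg.norm(dvec))
            if dist > d_max:
                continue
            v1 = coords[heavy] - coords[h]
            v2 = coords[acc] - coords[h]
            if frame.box is not None:
                v1 -= frame.box * np.round(v1 / frame.box)
                v2 -= frame.box * np.round(v2 / frame.box)
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if angle < angle_min:
                continue
            donor_label = frame.labels[heavy]
            acc_label = frame.labels[acc]
            partner = acc_label if donor_label == probe_label else donor_label
            rec = report.per_label.setdefault(
                partner, {"count": 0, "dist_sum": 0.0, "angle_sum": 0.0,
                          "as_donor": 0, "as_acceptor": 0})
            rec["count"] += 1
            rec["dist_sum"] += dist
            rec["angle_sum"] += angle
            if donor_label == probe_label:
                rec["as_donor"] += 1
                report.probe_as_donor += 1
            if acc_label == probe_label:
                rec["as_acceptor"] += 1
                report.probe_as_acceptor += 1
    for rec in report.per_label.values():
        rec["mean_distance"] = rec["dist_sum"] / rec["count"]
        rec["mean_angle"] = rec["angle_sum"] / rec["count"]
    return report


def rdf(
    frames: Sequence[Frame],
    label_a: str,
    label_b: str,
    r_max: float = 15.0,
    bin_width: float = 0.1,
    volume: float | None = None,
) -> Profile:
    """Radial distribution function g(r) between two component labels.

    Normalized so an ideal gas gives g ≡ 1.  With a periodic box, distances
    use the minimum image and ``r_max`` must not exceed half the smallest
    box length; for open frames an explicit reference ``volume`` (Å³) must
    supply the mean partner density.
    """
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    hist = np.zeros(len(centers))
    norm = 0.0
    for frame in frames:
        ia = frame.select(label_a)
        ib = frame.select(label_b)
        if len(ia) == 0:
            raise PermeakitError(f"label {label_a!r} absent from frame")
        if len(ib) == 0:
            continue
        if frame.box is not None:
            if r_max > 0.5 * float(frame.box.min()):
                raise PermeakitError("r_max exceeds half the smallest box length")
            vol = float(np.prod(frame.box))
        else:
            if volume is None:
                raise PermeakitError("open frames need an explicit reference volume")
            vol = volume
        d = _pair_distances(frame.coords[ia], frame.coords[ib], frame.box)
        if label_a == label_b:
            np.fill_diagonal(d, np.inf)
        h, _ = np.histogram(d.ravel(), bins=edges)
        hist += h
        rho_b = (len(ib) - (1 if label_a == label_b else 0)) / vol
        norm += len(ia) * rho_b
    if norm == 0:
        return Profile(centers, np.zeros_like(centers), unit="dimensionless")
    shell = (4.0 / 3.0) * np.pi * (edges[1:]**3 - edges[:-1]**3)
    return Profile(centers, hist / (norm * shell), unit="dimensionless")


def electron_density(
    frames: Sequence[Frame],
    z_bins: np.ndarray,
    area: float | None = None,
) -> DensityProfile:
    """Per-component electron density along z, frame-averaged.

    Each atom contributes its element's electron count to the z bin holding
    it; densities are electrons / (area × bin height), e/Å³.  ``area``
    defaults to the lateral box cross-section when frames carry a box.
    """
    z_bins = np.asarray(z_bins, dtype=float)
    if area is None:
        if frames and frames[0].box is not None:
            area = float(frames[0].box[0] * frames[0].box[1])
        else:
            raise PermeakitError("area required when frames carry no box")
    widths = np.diff(z_bins)
    centers = 0.5 * (z_bins[:-1] + z_bins[1:])
    per_comp: dict[str, np.ndarray] = {}
    for frame in frames:
        for el in set(frame.elements):
            key = el.capitalize()
            if key not in ELECTRON_COUNT:
                raise PermeakitError(f"no electron count for element {el!r}")
        for label in set(frame.labels):
            idx = frame.select(label)
            weights = np.array([ELECTRON_COUNT[frame.elements[i].capitalize()]
                                for i in idx], dtype=float)
            h, _ = np.histogram(frame.coords[idx, 2], bins=z_bins,
                                weights=weights)
            acc = per_comp.setdefault(label, np.zeros(len(centers)))
            acc += h
    n_frames = len(frames)
    for label in per_comp:
        per_comp[label] = per_comp[label] / (area * widths * n_frames)
    return DensityProfile(z_grid=centers, bin_width=float(widths[0]),
                          area=area, per_component=per_comp)
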