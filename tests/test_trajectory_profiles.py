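"""Contacts, hydration, hydrogen bonds, RDF and electron density.

Every spatial query is checked against a brute-force all-pairs oracle, plus
closed-form constructions (delta shells, ideal gas, uniform slabs).
"""

import numpy as np
import pytest

import permeakit as pk
from permeakit.core_io import PermeakitError
from permeakit.trajectory_profiles import ELECTRON_COUNT

from conftest import brute_force_pairs


def water_frame(positions, extra=(), box=None):
    """Frame with WAT oxygens at given positions plus extra (el, label, xyz)."""
    elements = ["O"] * len(positions)
    labels = ["WAT"] * len(positions)
    coords = list(positions)
    for el, label, xyz in extra:
        elements.append(el)
        labels.append(label)
        coords.append(xyz)
    return pk.Frame(elements, labels, np.array(coords, dtype=float),
                    box=None if box is None else np.asarray(box, float))


def shell_positions(center, radius, n):
    """n points on an exact sphere of given radius (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    unit = np.column_stack([np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi), np.cos(phi)])
    return center + radius * unit


class TestContacts:
    def test_no_contacts(self):
        f = water_frame([[50.0, 0, 0]], extra=[("Pt", "DRG", [0.0, 0, 0])])
        rep = pk.count_contacts([f], "DRG", f, cutoff=7.0)
        assert rep.native("WAT") == 0 and rep.nonnative("WAT") == 0

    def test_constructed_native_nonnative_split(self):
        """5 waters within cutoff in the reference stay native; 3 waters
        present only in the later frame are non-native."""
        drg = ("Pt", "DRG", [0.0, 0.0, 0.0])
        near5 = shell_positions(np.zeros(3), 2.0, 5)
        far3_ref = shell_positions(np.zeros(3), 50.0, 3)   # outside cutoff
        ref = water_frame(np.vstack([near5, far3_ref]), extra=[drg])
        moved = shell_positions(np.zeros(3), 2.5, 3)
        frame = water_frame(np.vstack([near5, moved]), extra=[drg])
        rep = pk.count_contacts([frame], "DRG", ref, cutoff=7.0)
        assert rep.native("WAT") == 5
        assert rep.nonnative("WAT") == 3
        assert rep.mean_distance("WAT") == pytest.approx(
            (5 * 2.0 + 3 * 2.5) / 8)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        box = np.array([20.0, 20.0, 20.0])
        labels = ["DRG"] * 3 + ["WAT"] * 80 + ["PC"] * 40 + ["OL"] * 40
        elements = ["Pt"] * 3 + ["O"] * 80 + ["P"] * 40 + ["C"] * 40
        frames = [
            pk.Frame(elements, labels, rng.uniform(0, 20, (163, 3)), box=box)
            for _ in range(20)
        ]
        ref = frames[0]
        cutoff = 5.0
        rep = pk.count_contacts(frames, "DRG", ref, cutoff=cutoff)

        # oracle: O(N²) with minimum image
        probe = ref.select("DRG")
        other = np.array([i for i in range(ref.n_atoms)
                          if ref.labels[i] != "DRG"])
        ii, jj, _ = brute_force_pairs(ref.coords[probe], ref.coords[other],
                                      cutoff, box)
        native = set(zip(probe[ii], other[jj]))
        per_label = {}
        for fr in frames:
            ii, jj, dd = brute_force_pairs(fr.coords[probe], fr.coords[other],
                                           cutoff, box)
            for a, b, d in zip(probe[ii], other[jj], dd):
                rec = per_label.setdefault(fr.labels[b],
                                           {"nat": 0, "non": 0, "ds": 0.0,
                                            "np": 0})
                rec["nat" if (a, b) in native else "non"] += 1
                rec["ds"] += d
                rec["np"] += 1
        for label, rec in per_label.items():
            assert rep.native(label) == round(rec["nat"] / len(frames))
            assert rep.nonnative(label) == round(rec["non"] / len(frames))
            assert rep.mean_distance(label) == pytest.approx(
                rec["ds"] / rec["np"], rel=1e-12)

    def test_missing_probe_fatal(self):
        f = water_frame([[0.0, 0, 0]])
        with pytest.raises(PermeakitError):
            pk.count_contacts([f], "DRG", f)


class TestHydration:
    def test_shell_of_12_at_2p5_angstrom(self):
        drg = ("Pt", "DRG", [10.0, 10.0, 10.0])
        f = water_frame(shell_positions(np.array([10.0, 10, 10]), 2.5, 12),
                        extra=[drg])
        assert pk.hydration_count(f, "DRG", threshold=3.0) == 12
        assert pk.hydration_count(f, "DRG", threshold=0.1) == 0

    def test_bulk_solvation_shell_of_13(self):
        """13 waters at 2.8 Å — the bulk-water first-shell population of a
        small hydrated platinum complex — are all inside the 3 Å threshold."""
        drg = ("Pt", "DRG", [0.0, 0.0, 0.0])
        f = water_frame(shell_positions(np.zeros(3), 2.8, 13), extra=[drg])
        prof = pk.hydration_profile({70.0: [f]}, "DRG", threshold=3.0)
        assert prof.values[0] == 13.0
        assert prof.stderr[0] == 0.0

    def test_mean_and_sigma_over_alternating_frames(self):
        drg = ("Pt", "DRG", [0.0, 0.0, 0.0])
        f4 = water_frame(shell_positions(np.zeros(3), 2.0, 4), extra=[drg])
        f6 = water_frame(shell_positions(np.zeros(3), 2.0, 6), extra=[drg])
        prof = pk.hydration_profile({40.0: [f4, f6, f4, f6]}, "DRG")
        assert prof.values[0] == pytest.approx(5.0)
        assert prof.stderr[0] == pytest.approx(1.0)

    def test_no_water_gives_zero_not_error(self):
        f = pk.Frame(["Pt"], ["DRG"], np.zeros((1, 3)))
        prof = pk.hydration_profile({0.0: [f]}, "DRG")
        assert prof.values[0] == 0.0

    def test_counts_oxygens_not_hydrogens(self):
        g = pk.Frame(["O", "H", "H", "Pt"], ["WAT", "WAT", "WAT", "DRG"],
                     np.array([[2.0, 0, 0], [2.5, 0.8, 0], [2.5, -0.8, 0],
                               [0.0, 0, 0]]))
        assert pk.hydration_count(g, "DRG") == 1


class TestHydrogenBonds:
    def _oho(self, angle_deg, oo=2.8):
        """Water donor O–H aimed at an acceptor O; D–H···A angle as given."""
        oh = 1.0
        d = np.array([0.0, 0.0, 0.0])
        h = np.array([oh, 0.0, 0.0])
        theta = np.radians(180.0 - angle_deg)
        a = h + (oo - oh) * np.array([np.cos(theta), np.sin(theta), 0.0])
        return pk.Frame(["O", "H", "O"], ["DRG", "DRG", "WAT"],
                        np.vstack([d, h, a]))

    def test_linear_bond_detected(self):
        f = self._oho(180.0)
        rep = pk.hydrogen_bonds(f, donors=[(0, 1)], acceptors=[2])
        assert rep.total == 1
        assert rep.probe_as_donor == 1
        assert rep.per_label["WAT"]["mean_angle"] == pytest.approx(180.0)

    def test_bent_geometry_rejected(self):
        rep = pk.hydrogen_bonds(self._oho(90.0), donors=[(0, 1)],
                                acceptors=[2])
        assert rep.total == 0

    def test_long_bond_rejected(self):
        rep = pk.hydrogen_bonds(self._oho(180.0, oo=4.0), donors=[(0, 1)],
                                acceptors=[2], d_max=3.5)
        assert rep.total == 0

    def test_acceptor_role_tally(self):
        f = pk.Frame(["O", "H", "O"], ["WAT", "WAT", "DRG"],
                     np.array([[0.0, 0, 0], [1.0, 0, 0], [2.8, 0, 0]]))
        rep = pk.hydrogen_bonds(f, donors=[(0, 1)], acceptors=[2])
        assert rep.probe_as_acceptor == 1
        assert rep.probe_as_donor == 0

    def test_missing_hydrogen_fatal(self):
        f = self._oho(180.0)
        with pytest.raises(PermeakitError, match="not a hydrogen"):
            pk.hydrogen_bonds(f, donors=[(0, 2)], acceptors=[1])


class TestRDF:
    def test_ideal_gas_is_unity(self):
        rng = np.random.default_rng(23)
        box = np.array([40.0, 40.0, 40.0])
        frames = []
        for _ in range(20):
            coords = np.vstack([rng.uniform(0, 40, (50, 3)),
                                rng.uniform(0, 40, (4000, 3))])
            frames.append(pk.Frame(["Pt"] * 50 + ["O"] * 4000,
                                   ["DRG"] * 50 + ["WAT"] * 4000, coords,
                                   box=box))
        g = pk.rdf(frames, "DRG", "WAT", r_max=16.0, bin_width=0.5)
        window = (g.z_grid >= 5.0) & (g.z_grid <= 15.0)
        assert np.all(g.values[window] > 0.95)
        assert np.all(g.values[window] < 1.05)

    def test_delta_shell(self):
        drg = ("Pt", "DRG", [20.0, 20.0, 20.0])
        f = water_frame(shell_positions(np.array([20.0, 20, 20]), 3.05, 64),
                        extra=[drg], box=[40.0, 40.0, 40.0])
        g = pk.rdf([f], "DRG", "WAT", r_max=10.0, bin_width=0.2)
        occupied = g.values > 0
        assert occupied.sum() == 1
        assert g.z_grid[occupied][0] == pytest.approx(3.1, abs=0.1)

    def test_zero_partners_zero_profile(self):
        f = pk.Frame(["Pt"], ["DRG"], np.array([[20.0, 20, 20]]),
                     box=np.array([40.0, 40, 40]))
        g = pk.rdf([f], "DRG", "WAT", r_max=10.0)
        np.testing.assert_array_equal(g.values, 0.0)

    def test_r_max_beyond_half_box_fatal(self):
        f = pk.Frame(["Pt"], ["DRG"], np.array([[5.0, 5, 5]]),
                     box=np.array([10.0, 10, 10]))
        with pytest.raises(PermeakitError, match="half"):
            pk.rdf([f], "DRG", "DRG", r_max=8.0)

    def test_open_frames_need_volume(self):
        f = water_frame([[1.0, 0, 0]], extra=[("Pt", "DRG", [0.0, 0, 0])])
        with pytest.raises(PermeakitError, match="volume"):
            pk.rdf([f], "DRG", "WAT")
        g = pk.rdf([f], "DRG", "WAT", r_max=5.0, volume=1000.0)
        assert g.values.max() > 0


class TestRigidMotionInvariance:
    def test_contacts_hydration_invariant(self):
        rng = np.random.default_rng(31)
        coords = rng.uniform(-5, 5, (60, 3))
        labels = ["DRG"] + ["WAT"] * 40 + ["PC"] * 19
        elements = ["Pt"] + ["O"] * 40 + ["P"] * 19
        f = pk.Frame(elements, labels, coords)
        # random rotation (QR of a Gaussian matrix) + translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        g = pk.Frame(elements, labels, coords @ q.T + np.array([7.0, -3.0, 11.0]))
        rep_f = pk.count_contacts([f], "DRG", f, cutoff=4.0)
        rep_g = pk.count_contacts([g], "DRG", g, cutoff=4.0)
        for label in rep_f.per_label:
            assert rep_f.native(label) == rep_g.native(label)
            assert rep_f.mean_distance(label) == pytest.approx(
                rep_g.mean_distance(label), rel=1e-9)
        assert pk.hydration_count(f, "DRG") == pk.hydration_count(g, "DRG")


class TestElectronDensity:
    def test_single_oxygen_bin(self):
        f = pk.Frame(["O"], ["WAT"], np.array([[5.0, 5.0, 0.5]]))
        dens = pk.electron_density([f], np.arange(0.0, 11.0, 1.0), area=100.0)
        assert dens.per_component["WAT"][0] == pytest.approx(0.08)
        assert np.all(dens.per_component["WAT"][1:] == 0.0)

    def test_uniform_slab_flat(self):
        rng = np.random.default_rng(5)
        n = 40_000
        coords = np.column_stack([rng.uniform(0, 10, n), rng.uniform(0, 10, n),
                                  rng.uniform(0, 20, n)])
        f = pk.Frame(["O"] * n, ["WAT"] * n, coords,
                     box=np.array([10.0, 10.0, 20.0]))
        dens = pk.electron_density([f], np.arange(0.0, 21.0, 1.0))
        vals = dens.per_component["WAT"]
        assert np.std(vals) / np.mean(vals) < 0.05

    def test_component_partition_identity(self):
        rng = np.random.default_rng(6)
        labels = ["WAT"] * 30 + ["PC"] * 20 + ["DRG"] * 1
        elements = ["O"] * 30 + ["P"] * 20 + ["Pt"]
        f = pk.Frame(elements, labels, rng.uniform(0, 10, (51, 3)))
        bins = np.arange(0.0, 11.0, 1.0)
        dens = pk.electron_density([f], bins, area=100.0)
        all_at = pk.Frame(elements, ["WAT"] * 51, f.coords)
        total = pk.electron_density([all_at], bins, area=100.0)
        np.testing.assert_allclose(dens.total, total.per_component["WAT"],
                                   atol=1e-12)

    def test_integral_conserves_electron_count(self):
        rng = np.random.default_rng(8)
        elements = ["O"] * 25 + ["P"] * 10 + ["Pt"] * 2
        labels = ["WAT"] * 25 + ["PC"] * 10 + ["DRG"] * 2
        f = pk.Frame(elements, labels, rng.uniform(0, 10, (37, 3)))
        bins = np.arange(0.0, 10.5, 0.5)
        dens = pk.electron_density([f], bins, area=77.0)
        integral = np.sum(dens.total * 77.0 * 0.5)
        expected = sum(ELECTRON_COUNT[e] for e in elements)
        assert integral == pytest.approx(expected, rel=1e-6)

    def test_unknown_element_fatal(self):
        f = pk.Frame(["Xx"], ["ION"], np.zeros((1, 3)))
        with pytest.raises(PermeakitError, match="Xx"):
            pk.electron_density([f], np.arange(0.0, 2.0, 1.0), area=1.0)
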