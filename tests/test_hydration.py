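import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hmgclamp.hydration import (AtomSelector, HBondCriteria, SiteDefinition,
                                WaterBarcode, assign_bridge, box_to_full_numbering,
                                build_barcode, crystal_solvent_summary,
                                distance_trace, is_hbond, residency_stats)
from hmgclamp.structures import read_structure, Trajectory
from hmgclamp.synth import ToyTrajectoryConfig, gen_toy_trajectory

from conftest import make_atoms, make_model

CRIT = HBondCriteria()


class TestHBond:
    def test_short_contact_good_angle(self):
        d = np.array([0.0, 0.0, 0.0])
        a = np.array([2.8, 0.0, 0.0])
        h = np.array([0.95, 0.02, 0.0])  # nearly linear D-H...A
        assert is_hbond(d, a, CRIT, hydrogen=h)

    def test_long_contact_rejected_regardless_of_angle(self):
        d = np.array([0.0, 0.0, 0.0])
        a = np.array([5.0, 0.0, 0.0])
        h = np.array([1.0, 0.0, 0.0])
        assert not is_hbond(d, a, CRIT, hydrogen=h)

    def test_inclusive_boundaries(self):
        # build a triangle with D-H...A angle exactly 130 degrees at the
        # hydrogen and the heavy-atom distance exactly at the 3.5 A cutoff
        h = np.zeros(3)
        d = np.array([1.0, 0.0, 0.0])
        ang = math.radians(130.0)
        # |HA| solving |DA| = 3.5 by the law of cosines
        r = (2 * math.cos(ang)
             + math.sqrt(4 * math.cos(ang) ** 2 + 4 * (3.5 ** 2 - 1))) / 2
        a = r * np.array([math.cos(ang), math.sin(ang), 0.0])
        assert np.linalg.norm(d - a) == pytest.approx(3.5, abs=1e-12)
        assert is_hbond(d, a, CRIT, hydrogen=h)

    def test_heavy_atom_fallback(self):
        d, a = np.zeros(3), np.array([3.2, 0, 0])
        assert is_hbond(d, a, CRIT)  # no hydrogen supplied
        assert is_hbond(d, a, HBondCriteria(use_hydrogens=False),
                        hydrogen=np.array([0.0, 1.0, 0.0]))

    @settings(derandomize=True, max_examples=30)
    @given(theta=st.floats(0, math.pi), phi=st.floats(0, 2 * math.pi),
           tx=st.floats(-50, 50))
    def test_rigid_motion_invariance(self, theta, phi, tx):
        d = np.array([0.0, 0.0, 0.0])
        a = np.array([3.0, 0.4, 0.0])
        h = np.array([0.9, 0.3, 0.1])
        ct, st_, cp, sp = (math.cos(theta), math.sin(theta),
                           math.cos(phi), math.sin(phi))
        rz = np.array([[cp, -sp, 0], [sp, cp, 0], [0, 0, 1]])
        rx = np.array([[1, 0, 0], [0, ct, -st_], [0, st_, ct]])
        R = rz @ rx
        t = np.array([tx, 1.0, -2.0])
        before = is_hbond(d, a, CRIT, hydrogen=h)
        after = is_hbond(R @ d + t, R @ a + t, CRIT, hydrogen=R @ h + t)
        assert before == after

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            HBondCriteria(max_DA_dist=0.0)
        with pytest.raises(ValueError):
            HBondCriteria(min_DHA_angle=190.0)


def _site():
    return SiteDefinition(
        protein_side_chain=(AtomSelector(chain="A", resnum=72, name="OH"),),
        protein_backbone=(AtomSelector(chain="A", resnum=5, name="O"),),
        dna_backbone=(AtomSelector(chain="B", resnum=7, name="OP1"),),
        criteria=HBondCriteria(use_hydrogens=False), min_partners=2)


def _partners():
    return [
        dict(name="OH", resname="TYR", resnum=72, chain="A",
             x=2.8, y=0.0, z=0.0),
        dict(name="O", resname="ILE", resnum=5, chain="A",
             x=0.0, y=2.8, z=0.0),
        dict(name="OP1", resname="DC", resnum=7, chain="B",
             x=-2.8, y=0.0, z=0.0),
    ]


class TestAssignBridge:
    def test_one_water_motif(self):
        model = make_model(_partners() + [
            dict(name="O", resname="HOH", resnum=1, chain="W",
                 x=0.0, y=0.0, z=0.0, record="HETATM")])
        motif, ids = assign_bridge(model, _site())
        assert motif == "one_water"
        assert ids == ["W:1"]

    def test_two_water_motif(self):
        # w1 bonded only to the Tyr hydroxyl, w2 only to the phosphate
        # oxygen, and w1-w2 within hydrogen-bonding distance of each other
        model = make_model(_partners() + [
            dict(name="O", resname="HOH", resnum=1, chain="W",
                 x=1.0, y=-2.62, z=0.0, record="HETATM"),
            dict(name="O", resname="HOH", resnum=2, chain="W",
                 x=-1.0, y=-2.62, z=0.0, record="HETATM")])
        motif, ids = assign_bridge(model, _site())
        assert motif == "two_water"
        assert set(ids) == {"W:1", "W:2"}

    def test_no_water_in_range(self):
        model = make_model(_partners() + [
            dict(name="O", resname="HOH", resnum=1, chain="W",
                 x=20.0, y=20.0, z=20.0, record="HETATM")])
        assert assign_bridge(model, _site())[0] == "none"

    def test_one_water_takes_precedence(self):
        # the central water bridges alone, and also forms a two-water
        # pattern with a second water bonded to the phosphate; the
        # single-water motif must win
        model = make_model(_partners() + [
            dict(name="O", resname="HOH", resnum=1, chain="W",
                 x=0.0, y=0.0, z=0.0, record="HETATM"),
            dict(name="O", resname="HOH", resnum=2, chain="W",
                 x=-2.0, y=-2.0, z=0.0, record="HETATM")])
        motif, ids = assign_bridge(model, _site())
        assert motif == "one_water"
        assert ids == ["W:1"]

    def test_unresolvable_selector_is_config_error(self):
        model = make_model(_partners())
        bad = SiteDefinition(
            protein_side_chain=(AtomSelector(chain="Z", resnum=1,
                                             name="XX"),),
            protein_backbone=(), dna_backbone=_site().dna_backbone,
            criteria=HBondCriteria(use_hydrogens=False))
        with pytest.raises(ValueError):
            assign_bridge(model, bad)


def _brute_force_barcode(traj, site):
    """Independent per-frame re-scan with plain Python loops."""
    atoms = traj.atoms
    crit = site.criteria
    prot_rows = [i for i, r in atoms.iterrows()
                 if (r["chain"], r["resnum"], r["name"]) in
                 [("A", 72, "OH"), ("A", 5, "O")]]
    dna_rows = [i for i, r in atoms.iterrows()
                if (r["chain"], r["resnum"], r["name"]) == ("B", 7, "OP1")]
    wat_rows = [(i, f"{r['chain']}:{r['resnum']}")
                for i, r in atoms.iterrows() if r["resname"] == "HOH"]
    occupants = []
    for f in range(traj.n_frames):
        xyz = traj.coords[f]
        best = None
        # 1-water scan
        for i, wid in wat_rows:
            np_b = sum(np.linalg.norm(xyz[i] - xyz[p]) <= crit.max_DA_dist
                       for p in prot_rows)
            nd_b = sum(np.linalg.norm(xyz[i] - xyz[p]) <= crit.max_DA_dist
                       for p in dna_rows)
            if np_b + nd_b >= site.min_partners and np_b >= 1 and nd_b >= 1:
                best = wid
                break
        if best is None:
            # 2-water scan: report the protein-proximal member
            for ii, (i, wi) in enumerate(wat_rows):
                for j, wj in wat_rows[ii + 1:]:
                    if np.linalg.norm(xyz[i] - xyz[j]) > crit.max_DA_dist:
                        continue
                    npi = sum(np.linalg.norm(xyz[i] - xyz[p])
                              <= crit.max_DA_dist for p in prot_rows)
                    npj = sum(np.linalg.norm(xyz[j] - xyz[p])
                              <= crit.max_DA_dist for p in prot_rows)
                    ndi = sum(np.linalg.norm(xyz[i] - xyz[p])
                              <= crit.max_DA_dist for p in dna_rows)
                    ndj = sum(np.linalg.norm(xyz[j] - xyz[p])
                              <= crit.max_DA_dist for p in dna_rows)
                    if (npi + ndi) >= 1 and (npj + ndj) >= 1 \
                            and (npi + npj) >= 1 and (ndi + ndj) >= 1:
                        dpi = min(np.linalg.norm(xyz[i] - xyz[p])
                                  for p in prot_rows)
                        dpj = min(np.linalg.norm(xyz[j] - xyz[p])
                                  for p in prot_rows)
                        best = wi if dpi <= dpj else wj
                        break
                if best is not None:
                    break
        occupants.append(best)
    return occupants


class TestBarcode:
    def test_stationary_water_single_segment(self):
        cfg = ToyTrajectoryConfig(n_frames=40, n_waters=1,
                                  escape_probability=0.0, seed=0)
        traj, _ = gen_toy_trajectory(cfg)
        bc = build_barcode(traj, cfg.site_definition(), gap_tolerance=0)
        assert bc.segments == ((0, 39, "W:1"),)

    def test_exchange_creates_boundary(self):
        cfg = ToyTrajectoryConfig(n_frames=60, n_waters=6,
                                  escape_probability=0.15, seed=5)
        traj, truth = gen_toy_trajectory(cfg)
        bc = build_barcode(traj, cfg.site_definition(), gap_tolerance=0)
        assert list(bc.occupants) == truth.params["occupants"]
        assert [tuple(s) for s in bc.segments] == \
            [tuple(s) for s in truth.params["segments"]]

    def test_empty_trajectory(self):
        cfg = ToyTrajectoryConfig(n_frames=1, n_waters=1, seed=0)
        traj, _ = gen_toy_trajectory(cfg)
        empty = Trajectory(atoms=traj.atoms, coords=traj.coords[:0])
        bc = build_barcode(empty, cfg.site_definition())
        assert bc.occupants == ()
        assert bc.segments == ()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_rescan(self, seed):
        rng = np.random.default_rng(seed)
        cfg = ToyTrajectoryConfig(
            n_frames=int(rng.integers(10, 51)),
            n_waters=int(rng.integers(2, 21)),
            escape_probability=float(rng.uniform(0, 0.5)),
            seed=seed + 1000)
        traj, _ = gen_toy_trajectory(cfg)
        site = cfg.site_definition()
        bc = build_barcode(traj, site, gap_tolerance=0)
        assert list(bc.occupants) == _brute_force_barcode(traj, site)

    def test_reversal_reverses_segments(self):
        cfg = ToyTrajectoryConfig(n_frames=50, n_waters=5,
                                  escape_probability=0.2, seed=9)
        traj, _ = gen_toy_trajectory(cfg)
        site = cfg.site_definition()
        fwd = build_barcode(traj, site, gap_tolerance=0)
        rev = build_barcode(Trajectory(atoms=traj.atoms,
                                       coords=traj.coords[::-1]),
                            site, gap_tolerance=0)
        n = traj.n_frames
        expect = tuple(sorted(((n - 1 - e, n - 1 - s, w)
                               for s, e, w in fwd.segments)))
        assert tuple(sorted(rev.segments)) == expect

    def test_gap_tolerance_monotonicity(self):
        cfg = ToyTrajectoryConfig(n_frames=120, n_waters=4,
                                  escape_probability=0.3, seed=2)
        traj, _ = gen_toy_trajectory(cfg)
        site = cfg.site_definition()
        counts = [len(build_barcode(traj, site, gap_tolerance=g).segments)
                  for g in (0, 1, 2, 5, 10)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestResidency:
    def test_seven_distinct_occupants(self):
        # segment occupant sequence a b c a d e f g -> 7 distinct waters
        ids = ["a", "b", "c", "a", "d", "e", "f", "g"]
        occupants, segments = [], []
        start = 0
        for k, wid in enumerate(ids):
            occupants += [wid] * 5
            segments.append((start, start + 4, wid))
            start += 5
        bc = WaterBarcode(occupants=tuple(occupants),
                          segments=tuple(segments), frame_dt=100.0)
        stats = residency_stats(bc)
        assert stats.n_distinct_occupants == 7
        assert stats.occupancy_fraction == 1.0

    def test_empty_barcode(self):
        bc = WaterBarcode(occupants=(None,) * 10, segments=(), frame_dt=100.0)
        stats = residency_stats(bc)
        assert stats.occupancy_fraction == 0.0
        assert stats.first_occupancy_time_ns is None
        assert stats.dwell_times_ns == ()

    def test_occupancy_fraction_and_units(self):
        occ = tuple(["W:1"] * 40 + [None] * 60)
        bc = WaterBarcode(occupants=occ, segments=((0, 39, "W:1"),),
                          frame_dt=10.0)
        stats = residency_stats(bc)
        assert stats.occupancy_fraction == pytest.approx(0.4)
        assert stats.dwell_times_ns[0] == pytest.approx(0.4)  # 40 x 10 ps


class TestDistanceTrace:
    def test_constant_distance(self):
        cfg = ToyTrajectoryConfig(n_frames=8, n_waters=1, seed=0)
        traj, _ = gen_toy_trajectory(cfg)
        d = distance_trace(traj,
                           AtomSelector(chain="A", resnum=72, name="OH"),
                           AtomSelector(chain="B", resnum=7, name="OP1"))
        assert np.allclose(d, 5.6)  # partners sit 2.8 A either side

    def test_three_four_five(self):
        atoms = make_atoms([
            dict(name="A1", resname="UNK", resnum=1, chain="A",
                 x=0.0, y=0.0, z=0.0),
            dict(name="A2", resname="UNK", resnum=2, chain="A",
                 x=3.0, y=4.0, z=0.0)])
        traj = Trajectory(atoms=atoms,
                          coords=atoms[["x", "y", "z"]].to_numpy()[None])
        d = distance_trace(traj, AtomSelector(name="A1"),
                           AtomSelector(name="A2"))
        assert d[0] == pytest.approx(5.0)

    def test_matches_brute_force_norm(self):
        rng = np.random.default_rng(4)
        atoms = make_atoms([
            dict(name="A1", resname="UNK", resnum=1, chain="A",
                 x=0.0, y=0.0, z=0.0),
            dict(name="A2", resname="UNK", resnum=2, chain="A",
                 x=1.0, y=0.0, z=0.0)])
        coords = rng.uniform(-5, 5, size=(10, 2, 3))
        traj = Trajectory(atoms=atoms, coords=coords)
        d = distance_trace(traj, AtomSelector(name="A1"),
                           AtomSelector(name="A2"))
        expect = [math.dist(coords[f, 0], coords[f, 1]) for f in range(10)]
        assert np.allclose(d, expect)

    def test_ambiguous_selector_lists_matches(self):
        cfg = ToyTrajectoryConfig(n_frames=2, n_waters=3, seed=0)
        traj, _ = gen_toy_trajectory(cfg)
        with pytest.raises(ValueError, match="HOH"):
            distance_trace(traj, AtomSelector(chain="W"),
                           AtomSelector(chain="A", resnum=72, name="OH"))


class TestSolventSummary:
    def test_counts_and_means(self, synthetic_crystal):
        model = read_structure(str(synthetic_crystal))
        summary = crystal_solvent_summary(model)
        assert summary.n_waters == 3
        assert summary.mean_b_water == pytest.approx(20.0)
        assert summary.mean_b_protein == pytest.approx(12.0)
        assert summary.mean_b_dna == pytest.approx(22.0)
        assert summary.dna_b_higher_than_protein
        assert summary.n_waters_near_complex == 2  # one water is far away
        assert summary.chain_atom_counts["S"] == 3


def test_box_numbering_offset():
    assert box_to_full_numbering(72) == 127
    assert box_to_full_numbering(5) == 60
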