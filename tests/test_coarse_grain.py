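"""Bead maps, bead trajectories, internal coordinates and elasticity."""
import numpy as np
import pytest
from scipy.stats import spearmanr

from mdflex import (
    BOLTZMANN_KCAL,
    BeadMap,
    BeadTrajectory,
    MDFlexError,
    bead_trajectory,
    eg_stator_bead_map,
    harmonic_angle_samples,
    hinged_rod_trajectory,
    internal_coordinates,
    load_bead_map,
    spring_constants,
)
from mdflex.coarse_grain import BeadMapError

from conftest import make_structure, make_trajectory


def _enumerate_tsv(path):
    """Independent oracle: expand the TSV residue ranges with plain python."""
    residues = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        chains = [c for c in header[1:] if c.lower() != "domain"]
        for line in fh:
            cells = line.rstrip("\n").split("\t")
            for chain, cell in zip(chains, cells[1:]):
                if cell.strip() in ("-", ""):
                    continue
                for part in cell.split(","):
                    if "-" in part:
                        lo, hi = part.split("-")
                        residues.setdefault(chain, set()).update(
                            range(int(lo), int(hi) + 1)
                        )
                    else:
                        residues.setdefault(chain, set()).add(int(part))
    return residues


class TestBeadMap:
    def test_stator_table_bead_and_residue_counts(self):
        """The shipped 15-bead stator table assigns every G residue 21-120
        (100 residues, no gaps) and 184 of the 186 E residues 3-188, with
        E:14-15 unassigned — cross-checked by direct range enumeration."""
        from importlib import resources

        bm = eg_stator_bead_map()
        assert bm.n_beads == 15
        assert bm.labels == [f"P{i}" for i in range(1, 16)]

        ref = resources.files("mdflex.data").joinpath("eg_stator_beads.tsv")
        with resources.as_file(ref) as p:
            oracle = _enumerate_tsv(p)
        assert bm.residues("G") == oracle["G"] == set(range(21, 121))
        assert len(bm.residues("E")) == len(oracle["E"]) == 184
        assert bm.residues("E") == oracle["E"]
        assert bm.unassigned_report() == {"E": [14, 15]}

    def test_stator_domain_tags(self):
        bm = eg_stator_bead_map()
        assert [bm.domain(f"P{i}") for i in (1, 4)] == ["head", "head"]
        assert bm.domain("P5") == "neck"
        assert all(bm.domain(f"P{i}") == "tail" for i in range(6, 16))

    def test_overlapping_assignment_rejected(self):
        with pytest.raises(BeadMapError):
            BeadMap(
                ["A", "B"],
                {"A": [("X", 40, 55)], "B": [("X", 50, 60)]},
            )

    def test_empty_bead_rejected(self):
        with pytest.raises(BeadMapError):
            BeadMap(["A"], {"A": []})

    def test_malformed_range_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("bead\tX\nA\t10-\n")
        with pytest.raises(BeadMapError):
            load_bead_map(p)

    def test_tsv_roundtrip(self, tmp_path):
        bm = eg_stator_bead_map()
        p = tmp_path / "rt.tsv"
        bm.to_tsv(p)
        back = load_bead_map(p)
        assert back.labels == bm.labels
        assert back.domains == bm.domains
        for label in bm.labels:
            assert back.residues("E") == bm.residues("E")
            assert back.residues("G") == bm.residues("G")


class TestBeadTrajectory:
    def test_single_atom_beads_equal_atom_coordinates(self):
        s = make_structure(3, seed=1)
        traj = make_trajectory(s, s.coords[None].repeat(2, axis=0))
        bm = BeadMap(
            ["B1", "B2", "B3"],
            {f"B{i + 1}": [("A", i + 1, i + 1)] for i in range(3)},
        )
        bt = bead_trajectory(traj, bm)
        assert np.allclose(bt.centers[0], s.coords)

    def test_equal_mass_pair_gives_midpoint(self):
        s = make_structure(4, seed=2)
        traj = make_trajectory(s, s.coords[None].repeat(2, axis=0))
        bm = BeadMap(["B1", "B2"], {"B1": [("A", 1, 2)], "B2": [("A", 3, 4)]})
        bt = bead_trajectory(traj, bm)
        assert np.allclose(bt.centers[0, 0], s.coords[:2].mean(axis=0))
        assert np.allclose(bt.centers[0, 1], s.coords[2:].mean(axis=0))

    def test_mass_weighted_centers_match_brute_force(self):
        rng = np.random.default_rng(5)
        s = make_structure(20, seed=3)
        s.masses[:] = rng.uniform(1.0, 16.0, 20)
        frames = rng.normal(size=(4, 20, 3)) * 5
        traj = make_trajectory(s, frames)
        bm = BeadMap(
            ["B1", "B2"], {"B1": [("A", 1, 7)], "B2": [("A", 8, 20)]}
        )
        bt = bead_trajectory(traj, bm)
        for f in range(4):
            for b, (lo, hi) in enumerate([(0, 7), (7, 20)]):
                num = np.zeros(3)
                den = 0.0
                for a in range(lo, hi):
                    num += s.masses[a] * frames[f, a]
                    den += s.masses[a]
                assert np.allclose(bt.centers[f, b], num / den, atol=1e-6)

    def test_missing_residue_in_topology_raises(self):
        s = make_structure(3, seed=1)
        traj = make_trajectory(s, s.coords[None].repeat(2, axis=0))
        bm = BeadMap(["B1"], {"B1": [("A", 10, 12)]})
        with pytest.raises(BeadMapError):
            bead_trajectory(traj, bm)


class TestInternalCoordinates:
    def test_fifteen_beads_give_13_angles_12_dihedrals(self):
        rng = np.random.default_rng(0)
        bt = BeadTrajectory(
            rng.normal(size=(5, 15, 3)) * 10, [f"P{i + 1}" for i in range(15)]
        )
        series = internal_coordinates(bt)
        assert sum(1 for s in series if s.kind == "angle") == 13
        assert sum(1 for s in series if s.kind == "dihedral") == 12

    def test_collinear_beads_give_pi_and_flag_dihedral(self):
        centers = np.array([[[0, 0, 0], [0, 0, 1], [0, 0, 2], [0, 0, 3.0]]])
        bt = BeadTrajectory(centers, ["a", "b", "c", "d"])
        series = internal_coordinates(bt)
        angle = [s for s in series if s.kind == "angle"][0]
        dihedral = [s for s in series if s.kind == "dihedral"][0]
        assert angle.values[0] == pytest.approx(np.pi)
        assert dihedral.degenerate[0]

    @pytest.mark.parametrize(
        "last,expected", [([1.0, 0, 2], 0.0), ([-1.0, 0, 2], np.pi)]
    )
    def test_planar_cis_trans_dihedral(self, last, expected):
        centers = np.array(
            [[[1.0, 0, -1], [0, 0, 0], [0, 0, 1], last]]
        )
        bt = BeadTrajectory(centers, ["a", "b", "c", "d"])
        dihedral = [s for s in internal_coordinates(bt) if s.kind == "dihedral"][0]
        assert abs(dihedral.values[0]) == pytest.approx(expected, abs=1e-10)

    def test_too_few_beads_raise(self):
        bt = BeadTrajectory(np.zeros((2, 2, 3)), ["a", "b"])
        with pytest.raises(MDFlexError):
            internal_coordinates(bt)


class TestSpringConstants:
    def test_known_variance_arithmetic(self):
        """σ² = 0.02 rad² at 310 K gives k = kBT/(2σ²) = 15.40 kcal/mol/rad²
        (kBT at 310 K is 0.61603 kcal/mol)."""
        from mdflex.coarse_grain import InternalCoordinateSeries

        rng = np.random.default_rng(1)
        vals = rng.normal(1.5, np.sqrt(0.02), size=200_000)
        vals = 1.5 + (vals - vals.mean()) * np.sqrt(0.02) / vals.std(ddof=1)
        s = InternalCoordinateSeries(
            "angle", 1, ("a", "b", "c"), vals, np.zeros(vals.size, dtype=bool)
        )
        prof = spring_constants([s], temperature=310.0)
        assert BOLTZMANN_KCAL * 310.0 == pytest.approx(0.61603, abs=1e-5)
        assert prof.k[0] == pytest.approx(15.40, abs=0.01)

    def test_large_variance_limit_is_zero_stiffness(self):
        from mdflex.coarse_grain import InternalCoordinateSeries

        rng = np.random.default_rng(2)
        s = InternalCoordinateSeries(
            "angle", 1, ("a", "b", "c"),
            rng.uniform(-1e3, 1e3, 10_000), np.zeros(10_000, dtype=bool),
        )
        prof = spring_constants([s], temperature=310.0)
        assert prof.k[0] < 1e-5

    def test_zero_variance_is_an_error(self):
        from mdflex.coarse_grain import InternalCoordinateSeries

        s = InternalCoordinateSeries(
            "angle", 1, ("a", "b", "c"), np.full(10, 1.2), np.zeros(10, dtype=bool)
        )
        with pytest.raises(MDFlexError):
            spring_constants([s])

    def test_boltzmann_samples_recover_planted_k(self):
        """Equipartition inversion of harmonic Boltzmann samples returns the
        planted constant within 3% at 1e5 samples."""
        from mdflex.coarse_grain import InternalCoordinateSeries

        for k_true, wrap in [(5.0, False), (40.0, False), (12.0, True)]:
            samples = harmonic_angle_samples(
                k_true, n=100_000, seed=7, wrap=wrap,
                theta0=np.pi if wrap else 1.9,
            )
            kind = "dihedral" if wrap else "angle"
            beads = ("a", "b", "c", "d") if wrap else ("a", "b", "c")
            s = InternalCoordinateSeries(
                kind, 1, beads, samples, np.zeros(samples.size, dtype=bool)
            )
            prof = spring_constants([s], temperature=310.0)
            assert prof.k[0] == pytest.approx(k_true, rel=0.03)

    def test_frame_duplication_leaves_k_unchanged(self):
        bt1 = hinged_rod_trajectory(
            angle_k=np.array([10.0, 25.0, 6.0]), dihedral_k=np.array([8.0, 15.0]),
            n_frames=5000, seed=9,
        )
        bt2 = BeadTrajectory(
            np.concatenate([bt1.centers, bt1.centers]), bt1.labels
        )
        k1 = spring_constants(internal_coordinates(bt1)).k
        k2 = spring_constants(internal_coordinates(bt2)).k
        assert np.allclose(k1, k2, rtol=1e-3)

    def test_invariant_under_global_rigid_motion(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(4)
        bt = hinged_rod_trajectory(
            angle_k=np.array([10.0, 20, 30]), dihedral_k=np.array([5.0, 8]),
            n_frames=300, seed=1,
        )
        moved = bt.centers.copy()
        for f in range(moved.shape[0]):
            rot = Rotation.random(random_state=np.random.RandomState(f))
            moved[f] = rot.apply(moved[f]) + rng.uniform(-40, 40, 3)
        bt2 = BeadTrajectory(moved, bt.labels)
        k1 = spring_constants(internal_coordinates(bt)).k
        k2 = spring_constants(internal_coordinates(bt2)).k
        assert np.allclose(k1, k2, rtol=1e-9)

    def test_hinged_rod_profile_recovers_planted_stiffnesses(self):
        """Planted per-angle/dihedral constants recovered within 10% at 1e4
        frames, and the stiffness ordering is reproduced exactly."""
        angle_k = np.array([8.0, 30.0, 2.0, 90.0, 15.0, 50.0])
        dihedral_k = np.array([4.0, 60.0, 10.0, 25.0, 1.5])
        # θ0 placed > 3σ from the angle-range boundaries so that the
        # truncation of the Boltzmann tails does not bias the variances
        bt = hinged_rod_trajectory(
            angle_k=angle_k, dihedral_k=dihedral_k, n_frames=10_000,
            theta0=2.0, seed=3,
        )
        prof = spring_constants(internal_coordinates(bt), temperature=310.0)
        got_a = prof.subset("angle")["k_kcal_mol_rad2"].to_numpy()
        got_d = prof.subset("dihedral")["k_kcal_mol_rad2"].to_numpy()
        assert np.allclose(got_a, angle_k, rtol=0.10)
        assert np.allclose(got_d, dihedral_k, rtol=0.10)
        planted = np.concatenate([angle_k, dihedral_k])
        rho = spearmanr(planted, np.concatenate([got_a, got_d])).statistic
        assert rho == pytest.approx(1.0)

    def test_neck_domain_classification(self):
        bm = eg_stator_bead_map()
        rng = np.random.default_rng(0)
        bt = BeadTrajectory(
            rng.normal(size=(50, 15, 3)) * 10, bm.labels, domains=bm.domains
        )
        prof = spring_constants(internal_coordinates(bt), domains=bm.domains)
        t = prof.table
        # angle #3 = P3-P4-P5 involves the neck bead
        assert t[(t["kind"] == "angle") & (t["index"] == 3)]["domain"].iloc[0] == "neck"
        assert t[(t["kind"] == "angle") & (t["index"] == 1)]["domain"].iloc[0] == "head"
        assert t[(t["kind"] == "angle") & (t["index"] == 13)]["domain"].iloc[0] == "tail"
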