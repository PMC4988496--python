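"""Kabsch superposition, RMSD/RMSF analysis and hinge detection."""
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mdflex import (
    DegenerateGeometryError,
    average_structure,
    detect_hinges,
    gaussian_mode_ensemble,
    kabsch_superpose,
    rmsd_series,
    rmsf_profile,
    select,
)
from mdflex.superpose import FlexibilityProfile, align_trajectory, apply_fit

from conftest import make_structure, make_trajectory


def grid_rmsd_oracle(mobile, reference, levels=4, n=14):
    """Brute-force minimum RMSD over rotations: nested Euler-angle grid with
    optimal translation (centroid matching) at every candidate."""
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)
    center = np.zeros(3)
    span = np.pi
    best = np.inf
    for _ in range(levels):
        ax = [np.linspace(c - span, c + span, n) for c in center]
        grid = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1).reshape(-1, 3)
        rots = Rotation.from_euler("zyx", grid)
        rotated = np.einsum("rij,aj->rai", rots.as_matrix(), mob)
        rmsds = np.sqrt(np.mean(np.sum((rotated - ref) ** 2, axis=2), axis=1))
        k = int(np.argmin(rmsds))
        best = min(best, float(rmsds[k]))
        center = grid[k]
        span = 2.2 * span / n
    return best


class TestKabsch:
    def test_identical_coordinates(self, small_structure):
        x = small_structure.coords
        rot, trans, rmsd = kabsch_superpose(x, x)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(rot, np.eye(3), atol=1e-10)

    def test_translation_invariance(self, small_structure):
        x = small_structure.coords
        _, _, rmsd = kabsch_superpose(x, x + np.array([5.0, -3.0, 2.0]))
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_matches_rotation_grid_brute_force(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            mob = rng.uniform(-8, 8, size=(5, 3))
            ref = rng.uniform(-8, 8, size=(5, 3))
            _, _, rmsd = kabsch_superpose(mob, ref)
            assert rmsd == pytest.approx(grid_rmsd_oracle(mob, ref), abs=1e-3)

    def test_never_improper_and_symmetric(self):
        """Over 100 random pairs (including near-planar ones): det(R) = +1
        and the minimum RMSD is symmetric in mobile/reference."""
        rng = np.random.default_rng(9)
        for i in range(100):
            n = int(rng.integers(3, 12))
            a = rng.normal(size=(n, 3)) * 5
            b = rng.normal(size=(n, 3)) * 5
            if i % 3 == 0:  # squash to near-planar
                a[:, 2] *= 1e-4
                b[:, 2] *= 1e-4
            rot, _, r_ab = kabsch_superpose(a, b)
            _, _, r_ba = kabsch_superpose(b, a)
            assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-8)
            assert r_ab == pytest.approx(r_ba, abs=1e-8)

    def test_superposed_rmsd_never_exceeds_raw_rmsd(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            a = rng.normal(size=(7, 3)) * 4
            b = rng.normal(size=(7, 3)) * 4
            _, _, fitted = kabsch_superpose(a, b)
            raw = np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1)))
            assert fitted <= raw + 1e-12

    def test_mass_weighting_changes_optimum(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(6, 3)) * 5
        b = rng.normal(size=(6, 3)) * 5
        w = np.array([10.0, 1, 1, 1, 1, 1])
        _, _, rw = kabsch_superpose(a, b, weights=w)
        _, _, ru = kabsch_superpose(a, b)
        assert not np.isclose(rw, ru)

    def test_too_few_atoms(self):
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_is_degenerate(self):
        line = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(line, line)


class TestRmsdSeries:
    def test_frames_equal_reference_are_zero(self, small_structure):
        traj = make_trajectory(
            small_structure, np.repeat(small_structure.coords[None], 4, axis=0)
        )
        sel = select(small_structure, "all")
        series = rmsd_series(traj, small_structure, sel)
        assert np.allclose(series.rmsd, 0.0, atol=1e-10)

    def test_rigidly_rotated_copies_are_zero(self, small_structure):
        rng = np.random.default_rng(8)
        frames = np.stack(
            [
                Rotation.random(random_state=np.random.RandomState(i)).apply(
                    small_structure.coords
                )
                + rng.uniform(-5, 5, 3)
                for i in range(6)
            ]
        )
        traj = make_trajectory(small_structure, frames)
        series = rmsd_series(traj, small_structure, select(small_structure, "all"))
        assert np.allclose(series.rmsd, 0.0, atol=1e-8)

    def test_single_atom_displacement_closed_form(self):
        """Displacing one of N atoms by d gives raw RMSD d/√N; the optimal
        fit can only lower that, and must agree with the grid oracle."""
        s = make_structure(30, seed=21)
        d = 0.8
        frame = s.coords.copy()
        frame[2, 0] += d
        traj = make_trajectory(s, frame[None].repeat(2, axis=0))
        series = rmsd_series(traj, s, select(s, "all"))
        raw = d / np.sqrt(s.n_atoms)
        assert series.rmsd[0] <= raw + 1e-12
        assert series.rmsd[0] == pytest.approx(raw, rel=0.05)
        assert series.rmsd[0] == pytest.approx(
            grid_rmsd_oracle(frame, s.coords), abs=1e-3
        )

    def test_exclusion_removes_atoms_from_fit_and_measure(self):
        s = make_structure(8, seed=5)
        frame = s.coords.copy()
        frame[0] += 50.0  # huge excursion on the excluded atom
        traj = make_trajectory(s, frame[None].repeat(2, axis=0))
        sel = select(s, "all")
        excl = select(s, "resid 1")
        series = rmsd_series(traj, s, sel, exclude=excl)
        assert np.allclose(series.rmsd, 0.0, atol=1e-10)

    def test_empty_effective_selection_raises(self, small_structure):
        traj = make_trajectory(
            small_structure, small_structure.coords[None].repeat(2, axis=0)
        )
        sel = select(small_structure, "all")
        with pytest.raises(Exception):
            rmsd_series(traj, small_structure, sel, exclude=sel)


class TestAverageStructure:
    def test_rigid_trajectory_recovers_frame0(self, small_structure):
        rng = np.random.default_rng(1)
        frames = np.stack(
            [
                Rotation.random(random_state=np.random.RandomState(i)).apply(
                    small_structure.coords
                )
                + rng.uniform(-3, 3, 3)
                for i in range(5)
            ]
        )
        traj = make_trajectory(small_structure, frames)
        avg = average_structure(traj)
        _, _, rmsd = kabsch_superpose(avg, small_structure.coords)
        assert rmsd == pytest.approx(0.0, abs=1e-8)

    def test_two_aligned_frames_give_midpoint(self):
        s = make_structure(150, seed=4)
        base = s.coords
        delta = np.zeros_like(base)
        delta[1, 2] = 0.05  # one-atom wobble; the fit absorbs only O(1/N)
        traj = make_trajectory(s, np.stack([base + delta, base - delta]))
        avg = average_structure(traj)
        assert np.allclose(avg, base, atol=1e-3)

    def test_gaussian_ensemble_mean_recovery(self):
        """Mean of a planted Gaussian ensemble recovered within 3 SEM."""
        s = make_structure(30, seed=2)
        sigma, n = 0.1, 2000
        rng = np.random.default_rng(0)
        frames = s.coords[None] + rng.normal(scale=sigma, size=(n, 30, 3))
        traj = make_trajectory(s, frames)
        avg = average_structure(traj, max_iter=5)
        _, _, rmsd = kabsch_superpose(avg, s.coords)
        sem = sigma / np.sqrt(n)
        assert rmsd < 3 * sem * np.sqrt(3)


class TestRmsf:
    def test_rigid_trajectory_is_zero(self, small_structure):
        traj = make_trajectory(
            small_structure, small_structure.coords[None].repeat(3, axis=0)
        )
        prof = rmsf_profile(traj, select(small_structure, "all"))
        assert np.allclose(prof.rmsf, 0.0, atol=1e-10)

    def test_two_frame_single_atom_displacement(self):
        s = make_structure(200, seed=6)
        d = 0.2
        up, down = s.coords.copy(), s.coords.copy()
        up[0, 1] += d
        down[0, 1] -= d
        traj = make_trajectory(s, np.stack([up, down]))
        prof = rmsf_profile(traj, select(s, "all"))
        # the fit absorbs O(1/N) of the motion; at N=200 that is < 1%
        assert prof.rmsf[0] == pytest.approx(d, rel=0.01)
        assert np.all(prof.rmsf[1:] < d / 50)

    def test_isotropic_noise_gives_sigma_sqrt3(self):
        s = make_structure(40, seed=3)
        sigma, n = 0.25, 2000
        rng = np.random.default_rng(17)
        frames = s.coords[None] + rng.normal(scale=sigma, size=(n, 40, 3))
        traj = make_trajectory(s, frames)
        prof = rmsf_profile(traj, select(s, "all"))
        assert np.mean(prof.rmsf) == pytest.approx(sigma * np.sqrt(3), rel=0.05)

    def test_invariant_under_global_rigid_motion(self, stator):
        structure, traj = stator
        sel = select(structure, "name CA")
        base = rmsf_profile(traj, sel)
        rng = np.random.default_rng(23)
        moved_frames = np.stack(
            [
                Rotation.random(random_state=np.random.RandomState(i)).apply(f)
                + rng.uniform(-30, 30, 3)
                for i, f in enumerate(traj.frames)
            ]
        )
        moved = make_trajectory(structure, moved_frames)
        prof = rmsf_profile(moved, sel)
        assert np.allclose(prof.rmsf, base.rmsf, atol=1e-6)


def _profile_from_values(values, chain="A"):
    n = len(values)
    return FlexibilityProfile(
        atom_indices=np.arange(n),
        rmsf=np.asarray(values, dtype=float),
        mean_coords=np.zeros((n, 3)),
        chain_ids=np.array([chain] * n, dtype=object),
        res_ids=np.arange(1, n + 1),
        atom_names=np.array(["CA"] * n, dtype=object),
    )


class TestDetectHinges:
    def test_monotone_profile_has_no_interior_hinge(self):
        prof = _profile_from_values(np.linspace(1.0, 5.0, 40))
        assert detect_hinges(prof, smooth_window=3, min_len=4) == []

    def test_v_shape_flat_bottom_is_detected_exactly(self):
        values = np.concatenate(
            [np.linspace(5, 1.2, 15), np.full(6, 0.5), np.linspace(1.2, 5, 15)]
        )
        prof = _profile_from_values(values)
        hinges = detect_hinges(prof, smooth_window=1, percentile=10, min_len=4)
        assert len(hinges) == 1
        assert (hinges[0].start, hinges[0].end) == (16, 21)

    def test_window_larger_than_chain_raises(self):
        prof = _profile_from_values(np.ones(6))
        with pytest.raises(Exception):
            detect_hinges(prof, smooth_window=50, min_len=2)

    def test_hinged_rod_pivot_neighbourhood_detected(self):
        """A soft bending angle between a long and a short rigid arm is a
        pivot. Under a single global superposition the displacement node —
        the low-RMSF dip — forms in the residues immediately flanking the
        pivot (the fit redistributes part of the swing), so the check is
        that a detected hinge interval lies within a few residues of the
        planted soft-angle vertex."""
        from mdflex import beads_as_calpha, hinged_rod_trajectory

        n_beads = 40
        angle_k = np.full(n_beads - 2, 300.0)
        angle_k[29] = 0.8  # soft angle with vertex at bead 31 (resid 31)
        bt = hinged_rod_trajectory(
            angle_k=angle_k,
            dihedral_k=np.full(n_beads - 3, 300.0),
            n_frames=500,
            seed=2,
        )
        structure, traj = beads_as_calpha(bt)
        prof = rmsf_profile(traj, select(structure, "all"))
        hinges = detect_hinges(prof, smooth_window=3, percentile=60, min_len=2)
        vertex = 31
        assert any(
            h.start - 3 <= vertex <= h.end + 3 for h in hinges
        ), f"no hinge near the planted pivot: {hinges}"


def test_align_trajectory_applies_fit_to_all_atoms(small_structure):
    rot = Rotation.from_euler("z", 0.7).as_matrix()
    frames = np.stack([small_structure.coords, apply_fit(small_structure.coords, rot, np.array([1.0, 2, 3]))])
    traj = make_trajectory(small_structure, frames)
    aligned = align_trajectory(traj, small_structure.coords)
    assert np.allclose(aligned.frames[1], small_structure.coords, atol=1e-8)
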