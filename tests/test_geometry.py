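"""In-line attack angles, guanidinium proximity, peptide reach."""

import numpy as np
import pytest

from poc.ensemble import Atom, Ensemble, Frame
from poc.geometry import (
    DistanceReport,
    GeometryError,
    MissingAtomError,
    ScissileSite,
    bond_angle,
    dihedral,
    guanidinium_distances,
    inline_probability,
    max_reach,
    productive_fraction,
    reach_classify,
    theta_series,
    weighted_average_distance,
)
from poc.sequences import SiteLabel
from poc.synthetic import EnsembleSpec, simulate_ensemble


def arccos_oracle(p1, p2, p3):
    v1 = np.asarray(p1) - np.asarray(p2)
    v2 = np.asarray(p3) - np.asarray(p2)
    return np.degrees(
        np.arccos(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    )


def atan2_oracle(p1, p2, p3, p4):
    p1, p2, p3, p4 = map(np.asarray, (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    return np.degrees(np.arctan2(np.dot(m1, n2), np.dot(n1, n2)))


class TestPrimitives:
    def test_collinear_points_give_180(self):
        assert bond_angle((0, 0, 0), (1, 0, 0), (2, 0, 0)) == pytest.approx(180.0)

    def test_right_angle(self):
        assert bond_angle((1, 0, 0), (0, 0, 0), (0, 1, 0)) == pytest.approx(90.0)

    def test_zero_length_vector_rejected(self):
        with pytest.raises(GeometryError):
            bond_angle((0, 0, 0), (0, 0, 0), (1, 0, 0))

    def test_angle_matches_independent_oracle_on_random_triples(self, rng):
        for _ in range(20):
            pts = rng.normal(size=(3, 3)) * 5
            assert bond_angle(*pts) == pytest.approx(arccos_oracle(*pts), abs=1e-9)

    def test_planar_cis_and_trans_dihedrals(self):
        cis = [(1, 1, 0), (1, 0, 0), (-1, 0, 0), (-1, 1, 0)]
        trans = [(1, 1, 0), (1, 0, 0), (-1, 0, 0), (-1, -1, 0)]
        assert dihedral(*cis) == pytest.approx(0.0, abs=1e-12)
        assert dihedral(*trans) == pytest.approx(180.0)

    def test_dihedral_matches_independent_oracle_on_random_quadruples(self, rng):
        for _ in range(20):
            pts = rng.normal(size=(4, 3)) * 5
            assert dihedral(*pts) == pytest.approx(atan2_oracle(*pts), abs=1e-9)

    def test_degenerate_dihedral_rejected(self):
        with pytest.raises(GeometryError):
            dihedral((0, 0, 0), (0, 0, 0), (1, 0, 0), (2, 1, 0))


def site_frame(theta_deg, attack_res=63, extra=()):
    """Single frame holding one scissile triple at the requested angle."""
    t = np.radians(theta_deg)
    atoms = [
        Atom(attack_res, "SYN", "O2'", "O", (3 * np.cos(t), 3 * np.sin(t), 0.0)),
        Atom(attack_res + 1, "SYN", "P", "P", (0.0, 0.0, 0.0)),
        Atom(attack_res + 1, "SYN", "O5'", "O", (1.6, 0.0, 0.0)),
    ]
    atoms.extend(extra)
    return Frame(atoms=tuple(atoms))


class TestThetaSeries:
    def test_collinear_triple_reads_180(self):
        ens = Ensemble(frames=[site_frame(180.0)])
        assert theta_series(ens, ScissileSite(63))[0] == pytest.approx(180.0)

    def test_prescribed_angles_recovered(self):
        angles = [10.0, 90.0, 155.0, 160.0, 179.0]
        ens = Ensemble(frames=[site_frame(a) for a in angles])
        assert np.allclose(theta_series(ens, ScissileSite(63)), angles, atol=1e-6)

    def test_missing_o2_prime_is_a_named_error(self):
        frame = Frame(atoms=(
            Atom(64, "SYN", "P", "P", (0.0, 0.0, 0.0)),
            Atom(64, "SYN", "O5'", "O", (1.6, 0.0, 0.0)),
        ))
        with pytest.raises(MissingAtomError, match="O2'"):
            theta_series(Ensemble(frames=[frame]), ScissileSite(63))


class TestInlineProbability:
    def test_all_above_threshold(self):
        assert inline_probability([160.0] * 5) == 1.0

    def test_exact_planted_ratio(self):
        series = [160.0] * 30 + [120.0] * 70
        assert inline_probability(series) == 0.30

    def test_threshold_is_strict(self):
        assert inline_probability([155.0] * 10) == 0.0

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            inline_probability([])


def proximity_ensemble(n_near, n_far, d_near=3.0, d_far=20.0):
    """Frames whose single arginine sits at a controlled distance from the
    scissile triple (same distance to O2' and P by symmetric placement)."""
    frames = []
    for k in range(n_near + n_far):
        d = d_near if k < n_near else d_far
        o2 = np.array([0.0, 3.0, 0.0])  # site_frame(90.0) places O2' here
        p = np.zeros(3)
        mid = 0.5 * (o2 + p)
        h = np.sqrt(d * d - 2.25)
        center = mid + np.array([0.0, 0.0, h])
        extra = [Atom(201, "ARG", n, "N", tuple(center)) for n in ("NE", "NH1", "NH2")]
        frames.append(site_frame(90.0, extra=extra))
    return Ensemble(frames=frames)


class TestGuanidiniumDistances:
    def test_single_nitrogen_equidistant_fixture(self):
        ens = proximity_ensemble(1, 0, d_near=3.0)
        rep = guanidinium_distances(ens, [201], ScissileSite(63))
        assert rep.distances.shape == (1, 1, 2)
        assert rep.distances[0, 0] == pytest.approx([3.0, 3.0], abs=1e-9)

    def test_matches_brute_force_all_pairs_oracle(self, rng):
        spec = EnsembleSpec(
            sites=(63,), n_frames=10, planted_productive=((63, 4),), seed=5
        )
        ens, _ = simulate_ensemble(spec)
        rep = guanidinium_distances(ens, spec.arg_residues, ScissileSite(63))
        topo = ens.topology
        by_key = {k: i for i, k in enumerate(topo)}
        o2, p = by_key[(63, "SYN", "O2'")], by_key[(64, "SYN", "P")]
        for f in range(ens.n_frames):
            for a, res in enumerate(spec.arg_residues):
                n_idx = [by_key[(res, "ARG", n)] for n in ("NE", "NH1", "NH2")]
                for t, target in enumerate((o2, p)):
                    expected = min(
                        np.linalg.norm(ens.coords[f, i] - ens.coords[f, target])
                        for i in n_idx
                    )
                    assert rep.distances[f, a, t] == pytest.approx(expected, abs=1e-12)

    def test_missing_guanidinium_atoms_rejected(self):
        ens = Ensemble(frames=[site_frame(90.0)])
        with pytest.raises(MissingAtomError):
            guanidinium_distances(ens, [201], ScissileSite(63))


class TestProductiveFraction:
    def test_mode_separation_single_vs_dyad(self):
        ens = proximity_ensemble(5, 0, d_near=3.0)
        rep = guanidinium_distances(ens, [201], ScissileSite(63))
        assert productive_fraction(rep, mode="single") == 1.0
        assert productive_fraction(rep, mode="dyad") == 0.0

    def test_exact_planted_ratio(self):
        ens = proximity_ensemble(12, 88)
        rep = guanidinium_distances(ens, [201], ScissileSite(63))
        assert productive_fraction(rep) == 0.12

    def test_zero_cutoff_never_productive(self):
        ens = proximity_ensemble(3, 0)
        rep = guanidinium_distances(ens, [201], ScissileSite(63))
        assert productive_fraction(rep, cutoff=0.0) == 0.0

    def test_monotone_in_cutoff_and_dyad_below_single(self):
        spec = EnsembleSpec(
            sites=(63,), n_frames=40, planted_productive=((63, 10),), seed=9
        )
        ens, _ = simulate_ensemble(spec)
        rep = guanidinium_distances(ens, spec.arg_residues, ScissileSite(63))
        cutoffs = [0.0, 2.0, 4.0, 6.0, 12.0, 30.0, 60.0]
        singles = [productive_fraction(rep, c, "single") for c in cutoffs]
        dyads = [productive_fraction(rep, c, "dyad") for c in cutoffs]
        assert singles == sorted(singles)
        assert dyads == sorted(dyads)
        assert all(d <= s for d, s in zip(dyads, singles))


class TestWeightedAverage:
    def test_constant_observations(self):
        ens = proximity_ensemble(4, 0, d_near=5.0)
        rep = guanidinium_distances(ens, [201], ScissileSite(63))
        assert weighted_average_distance(rep) == pytest.approx(5.0, abs=1e-9)

    def test_two_observation_mean(self):
        rep = DistanceReport(
            site=ScissileSite(63),
            arg_residues=(201,),
            distances=np.array([[[4.0, 6.0]]]),
        )
        assert weighted_average_distance(rep) == pytest.approx(5.0)

    def test_matches_brute_force_mean_and_histogram_mean(self, rng):
        spec = EnsembleSpec(sites=(63,), n_frames=50, planted_productive=((63, 7),), seed=3)
        ens, _ = simulate_ensemble(spec)
        rep = guanidinium_distances(ens, spec.arg_residues, ScissileSite(63))
        assert weighted_average_distance(rep) == pytest.approx(
            float(np.mean(rep.distances)), abs=1e-9
        )
        edges, counts = rep.histogram()
        assert counts.sum() == rep.distances.size


class TestRigidInvariance:
    def test_statistics_unchanged_by_rigid_motion(self, rng):
        from scipy.spatial.transform import Rotation

        spec = EnsembleSpec(
            sites=(63,), n_frames=20,
            planted_inline=((63, 8),), planted_productive=((63, 5),), seed=11,
        )
        ens, _ = simulate_ensemble(spec)
        site = ScissileSite(63)
        theta0 = theta_series(ens, site)
        rep0 = guanidinium_distances(ens, spec.arg_residues, site)

        moved = []
        for f, frame in enumerate(ens.frames):
            R = Rotation.random(random_state=f).as_matrix()
            shift = rng.uniform(-30, 30, size=3)
            atoms = tuple(
                Atom(a.residue_number, a.residue_name, a.atom_name, a.element,
                     tuple(R @ np.array(a.xyz) + shift))
                for a in frame.atoms
            )
            moved.append(Frame(atoms=atoms, frame_index=f))
        ens_m = Ensemble(frames=moved)
        assert np.allclose(theta_series(ens_m, site), theta0, atol=1e-6)
        rep_m = guanidinium_distances(ens_m, spec.arg_residues, site)
        assert np.allclose(rep_m.distances, rep0.distances, atol=1e-6)
        assert productive_fraction(rep_m) == productive_fraction(rep0)


class TestReach:
    def test_peptide_plus_linker(self):
        assert max_reach(36.5, 8.6) == pytest.approx(45.1)

    def test_distant_site_unreachable(self):
        # a site 54 Å from the conjugation point exceeds the 45.1 Å reach
        frame = Frame(atoms=(
            Atom(62, "SYN", "P", "P", (0.0, 0.0, 0.0)),
            Atom(35, "SYN", "P", "P", (54.0, 0.0, 0.0)),
        ))
        [a] = reach_classify(frame, 62, [SiteLabel.from_str("C34-U35")], max_reach(36.5, 8.6))
        assert a.distance_A == pytest.approx(54.0)
        assert not a.reachable

    def test_boundary_distance_is_reachable(self):
        frame = Frame(atoms=(
            Atom(62, "SYN", "P", "P", (0.0, 0.0, 0.0)),
            Atom(64, "SYN", "P", "P", (45.1, 0.0, 0.0)),
        ))
        [a] = reach_classify(frame, 62, [SiteLabel.from_str("C63-A64")], 45.1)
        assert a.reachable

    def test_missing_phosphorus_is_named_error(self):
        frame = Frame(atoms=(Atom(62, "SYN", "P", "P", (0.0, 0.0, 0.0)),))
        with pytest.raises(MissingAtomError):
            reach_classify(frame, 62, [SiteLabel.from_str("C63-A64")], 45.1)
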