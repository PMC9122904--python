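"""Coil sampling, scoring, cavity geometry, selection and occupancy."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize

from chaperkit.tail import (BOND_LENGTH, CLASH_RADIUS, CavityAxis,
                            CavityPlane, LabelCloud, TailEnsemble,
                            boltzmann_resample, build_cavity_plane,
                            filter_d26_inside, fit_plane, label_occupancy,
                            make_energy_fn, metropolis_trajectory,
                            pair_energy, resample_frames, sample_coil,
                            score_ensemble, select_topk, signed_distance)
from chaperkit.tail import (BJERRUM_LENGTH, DEBYE_LENGTH, ELEC_STRENGTH,
                            SOFT_K)


@pytest.fixture(scope="module")
def coils(scaffold):
    return sample_coil(120, "S" * 28, scaffold, seed=7)


class TestSampling:
    def test_requested_count_and_determinism(self, scaffold):
        a = sample_coil(25, "S" * 28, scaffold, seed=3)
        b = sample_coil(25, "S" * 28, scaffold, seed=3)
        assert len(a) == 25
        assert np.array_equal(a.coords, b.coords)
        c = sample_coil(25, "S" * 28, scaffold, seed=4)
        assert not np.array_equal(a.coords, c.coords)

    def test_bond_lengths_and_anchoring(self, coils, scaffold):
        d = np.linalg.norm(np.diff(coils.coords, axis=2), axis=3)
        assert np.allclose(d, BOND_LENGTH)
        for k, ch in enumerate(scaffold.chain_ids):
            anchor = scaffold.bead(ch, scaffold.anchor_residue)
            d_anchor = np.linalg.norm(coils.coords[:, k, -1] - anchor,
                                      axis=1)
            assert np.allclose(d_anchor, BOND_LENGTH)

    def test_self_avoidance(self, coils):
        flat = coils.coords.reshape(len(coils), -1, 3)
        n = flat.shape[1]
        iu, ju = np.triu_indices(n, k=2)
        same = (iu // 28) == (ju // 28)
        d = np.linalg.norm(flat[:, iu] - flat[:, ju], axis=2)
        assert d[:, same].min() >= CLASH_RADIUS - 1e-9
        cross = ~same & (np.abs(iu - ju) >= 1)
        assert d[:, cross].min() >= CLASH_RADIUS - 1e-9

    def test_invalid_arguments_rejected(self, scaffold):
        with pytest.raises(ValueError):
            sample_coil(0, "S" * 28, scaffold)
        with pytest.raises(ValueError):
            sample_coil(5, "", scaffold)

    def test_end_to_end_scaling_consistent_with_saw_exponent(self, scaffold):
        # RMS end-to-end distance ~ N^nu with nu between 0.5 and 0.7
        lengths = [7, 14, 28]
        rms = []
        for L in lengths:
            ens = sample_coil(400, "S" * L, scaffold, seed=11)
            e2e = np.linalg.norm(ens.coords[:, :, 0] - ens.coords[:, :, -1],
                                 axis=2)
            rms.append(np.sqrt(np.mean(e2e**2)))
        nu = np.polyfit(np.log(lengths), np.log(rms), 1)[0]
        assert 0.5 <= nu <= 0.7


class TestScoring:
    def test_neutral_tail_has_zero_electrostatics(self, scaffold, coils):
        ens = coils.subset(np.arange(20))
        ens.charges = {}
        neutral_scaffold_energy = score_ensemble(ens, scaffold).copy()
        # soft-sphere-only energies are non-negative; for non-clashing
        # conformers they vanish
        assert (neutral_scaffold_energy >= 0).all()
        assert (neutral_scaffold_energy < 1e-9).sum() > 0

    def test_pair_energy_hand_formula(self):
        d = 6.5
        expected = (-ELEC_STRENGTH * BJERRUM_LENGTH *
                    np.exp(-d / DEBYE_LENGTH) / d)
        assert pair_energy(-1, 1, d) == pytest.approx(expected, rel=1e-12)
        d2 = 3.5  # inside the clash radius
        expected2 = (ELEC_STRENGTH * BJERRUM_LENGTH *
                     np.exp(-d2 / DEBYE_LENGTH) / d2 +
                     SOFT_K * (CLASH_RADIUS - d2) ** 2)
        assert pair_energy(1, 1, d2) == pytest.approx(expected2, rel=1e-12)

    def test_acidic_bead_favoured_near_positive_cavity(self, scaffold,
                                                       coils):
        minus = coils.subset(np.arange(len(coils)))
        minus.charges = {26: -1}
        plus = coils.subset(np.arange(len(coils)))
        plus.charges = {26: 1}
        e_minus = score_ensemble(minus, scaffold)
        e_plus = score_ensemble(plus, scaffold).copy()
        assert (e_minus <= e_plus).all()
        assert (e_minus < e_plus).any()

    def test_single_state_energy_matches_batch_scorer(self, scaffold,
                                                      coils):
        ens = coils.subset(np.arange(10))
        batch = score_ensemble(ens, scaffold)
        f = make_energy_fn(scaffold, ens.charges, 2, 28)
        single = np.array([f(ens.coords[i]) for i in range(10)])
        assert np.allclose(batch, single, atol=1e-10)


class TestCavityPlane:
    def test_designed_scaffold_plane_exact(self, scaffold):
        plane = build_cavity_plane(scaffold)
        assert plane.rms_residual < 1e-12
        assert np.allclose(np.abs(plane.normal), [0, 0, 1])
        sd = signed_distance(plane, plane.defining_points)
        assert np.allclose(sd, 0.0, atol=1e-12)

    def test_cavity_centroid_on_negative_side(self, scaffold):
        plane = build_cavity_plane(scaffold)
        assert signed_distance(
            plane, scaffold.concave_centroid()[None])[0] < 0

    def test_generic_points_match_bruteforce_minimisation(self, rng):
        pts = rng.uniform(-10, 10, (4, 3))
        centroid, normal, resid = fit_plane(pts)

        def objective(x):
            th, ph, d = x
            n = np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph),
                          np.cos(th)])
            return np.mean((pts @ n - d) ** 2)

        best = np.inf
        for th0 in np.linspace(0.1, 3.0, 6):
            for ph0 in np.linspace(0, 6.0, 6):
                r = minimize(objective, [th0, ph0, 0.0], method="Nelder-Mead",
                             options={"xatol": 1e-10, "fatol": 1e-14,
                                      "maxiter": 5000})
                best = min(best, r.fun)
        assert abs(resid - np.sqrt(best)) < 1e-6

    def test_collinear_points_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]],
                       dtype=float)
        with pytest.raises(ValueError):
            fit_plane(pts)


def ensemble_with_d26(positions, energies=None):
    n = len(positions)
    coords = np.zeros((n, 1, 28, 3))
    coords[:, 0, 25, :] = positions
    return TailEnsemble(coords,
                        np.arange(n, dtype=float) if energies is None
                        else np.asarray(energies, dtype=float),
                        np.arange(n))


class TestCavityFilter:
    PLANE = CavityPlane(np.zeros(3), np.array([0.0, 0.0, 1.0]),
                        np.zeros((4, 3)))

    def test_solvent_side_kept_boundary_kept(self):
        ens = ensemble_with_d26([[0, 0, 10.0], [0, 0, 0.0], [0, 0, -1.0]])
        kept, removed = filter_d26_inside(ens, self.PLANE)
        assert removed == 1
        assert set(kept.ids) == {0, 1}  # exactly-on-plane is kept

    def test_matches_bruteforce_loop(self, rng):
        pos = rng.uniform(-5, 5, (1000, 3))
        ens = ensemble_with_d26(pos)
        kept, removed = filter_d26_inside(ens, self.PLANE)
        expected = [i for i in range(1000) if pos[i, 2] >= 0]
        assert list(kept.ids) == expected
        assert removed == 1000 - len(expected)

    def test_either_vs_both_mode(self, rng):
        coords = np.zeros((4, 2, 28, 3))
        # (chainA z, chainB z) per conformer
        zz = [(1, 1), (1, -1), (-1, 1), (-1, -1)]
        for i, (za, zb) in enumerate(zz):
            coords[i, 0, 25, 2] = za
            coords[i, 1, 25, 2] = zb
        ens = TailEnsemble(coords, np.zeros(4), np.arange(4))
        kept_either, _ = filter_d26_inside(ens, self.PLANE, mode="either")
        kept_both, _ = filter_d26_inside(ens, self.PLANE, mode="both")
        assert list(kept_either.ids) == [0]
        assert list(kept_both.ids) == [0, 1, 2]


class TestTopK:
    def test_lowest_three(self):
        ens = ensemble_with_d26(np.zeros((4, 3)), energies=[5, 1, 3, 2])
        top, flagged = select_topk(ens, k=3)
        assert list(top.energies) == [1, 2, 3]
        assert not flagged

    def test_k_equal_to_size_identity(self):
        ens = ensemble_with_d26(np.zeros((4, 3)), energies=[5, 1, 3, 2])
        top, flagged = select_topk(ens, k=4)
        assert sorted(top.ids) == [0, 1, 2, 3]

    def test_small_ensemble_flagged(self):
        ens = ensemble_with_d26(np.zeros((2, 3)), energies=[1, 2])
        _, flagged = select_topk(ens, k=3)
        assert flagged

    def test_matches_sort_oracle_and_tie_break(self, rng):
        e = rng.integers(0, 5, 50).astype(float)  # many ties
        ens = ensemble_with_d26(np.zeros((50, 3)), energies=e)
        top, _ = select_topk(ens, k=7)
        oracle = sorted(range(50), key=lambda i: (e[i], i))[:7]
        assert sorted(top.ids) == sorted(oracle)
        assert list(top.energies) == sorted(e)[:7]


class TestResampleFrames:
    def make_traj(self, n):
        traj = TailEnsemble(np.zeros((n, 1, 28, 3)), np.zeros(n),
                            np.arange(n))
        traj.label_positions = np.arange(n, dtype=float).reshape(n, 1, 1) \
            * np.ones((n, 1, 3))
        return traj

    def test_full_length_identity(self):
        cloud = resample_frames(self.make_traj(1000), n=1000)
        assert np.array_equal(cloud.frame_indices, np.arange(1000))

    def test_every_second_frame(self):
        cloud = resample_frames(self.make_traj(2000), n=1000)
        assert np.array_equal(cloud.frame_indices, np.arange(0, 2000, 2))

    @given(m=st.integers(10, 5000), frac=st.floats(0.05, 1.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_index_oracle_no_duplicates(self, m, frac):
        n = max(int(m * frac), 1)
        cloud = resample_frames(self.make_traj(m), n=n)
        oracle = np.floor(np.arange(n) * m / n).astype(int)
        assert np.array_equal(cloud.frame_indices, oracle)
        assert len(np.unique(cloud.frame_indices)) == n
        assert (np.diff(cloud.frame_indices) > 0).all()

    def test_short_trajectory_rejected(self):
        with pytest.raises(ValueError):
            resample_frames(self.make_traj(10), n=11)


class TestOccupancy:
    PLANE = CavityPlane(np.zeros(3), np.array([0.0, 0.0, 1.0]),
                        np.zeros((4, 3)))
    AXIS = CavityAxis(np.array([0.0, 0.0, -5.0]),
                      np.array([1.0, 0.0, 0.0]))

    def test_all_positions_at_centroid(self):
        pos = np.tile(self.AXIS.point, (50, 1, 1)).reshape(50, 1, 3)
        occ = label_occupancy(LabelCloud(pos, np.arange(50)), self.PLANE,
                              self.AXIS)
        assert occ["in_cavity_fraction"] == 1.0
        assert occ["median_radial_distance"] == 0.0

    def test_mirrored_cloud_complements(self, rng):
        pos = rng.uniform(-3, 3, (200, 1, 3)) + np.array([0, 0, 4.0])
        cloud = LabelCloud(pos, np.arange(200))
        mirrored = LabelCloud(pos * np.array([1, 1, -1.0]), np.arange(200))
        f1 = label_occupancy(cloud, self.PLANE, self.AXIS)
        f2 = label_occupancy(mirrored, self.PLANE, self.AXIS)
        assert f1["in_cavity_fraction"] + f2["in_cavity_fraction"] == \
            pytest.approx(1.0)

    def test_radial_displacement_scores_five_angstrom(self, rng):
        base = np.zeros((500, 1, 3))
        base[:, 0, 0] = rng.uniform(-10, 10, 500)  # along the axis
        base[:, 0, 2] = -5.0
        shifted = base.copy()
        shifted[:, 0, 1] += 5.0  # displace radially
        occ = label_occupancy(LabelCloud(shifted, np.arange(500)),
                              self.PLANE, self.AXIS,
                              reference=LabelCloud(base, np.arange(500)))
        assert occ["edge_relocation_score"] == pytest.approx(5.0, abs=1e-9)

    def test_degenerate_axis_rejected(self):
        with pytest.raises(ValueError):
            CavityAxis(np.zeros(3), np.zeros(3))


class TestThermalSampling:
    def test_metropolis_preserves_bonds_and_is_deterministic(self, scaffold):
        init = sample_coil(1, "S" * 28, scaffold, seed=5)
        t1 = metropolis_trajectory(scaffold, init, n_frames=40,
                                   steps_per_frame=3, burn_in_frames=5,
                                   seed=9)
        t2 = metropolis_trajectory(scaffold, init, n_frames=40,
                                   steps_per_frame=3, burn_in_frames=5,
                                   seed=9)
        assert np.array_equal(t1.coords, t2.coords)
        d = np.linalg.norm(np.diff(t1.coords, axis=2), axis=3)
        assert np.allclose(d, BOND_LENGTH, atol=1e-9)

    def test_boltzmann_resample_low_temperature_limit(self, scaffold):
        ens = sample_coil(30, "S" * 28, scaffold, seed=6)
        score_ensemble(ens, scaffold)
        cold = boltzmann_resample(ens, 10, kt=1e-6, seed=0)
        assert np.allclose(cold.energies, ens.energies.min())
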