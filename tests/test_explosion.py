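"""Initial-condition sampling and Coulomb-explosion trajectory physics."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import ceikit as ck
from ceikit import units
from ceikit.explosion import InitialConditionSpec, IntegratorConfig, propagate_event

K_EV_ANG = 14.399645  # e^2/(4 pi eps0), eV·Å


def two_body(m1, m2, q1, q2, r0, rel_tol=1e-9, termination_fraction=1e-6):
    positions = np.array([[0.0, 0.0, 0.0], [r0, 0.0, 0.0]])
    velocities = np.zeros((2, 3))
    return propagate_event(
        positions,
        velocities,
        np.array([m1, m2]),
        np.array([q1, q2]),
        IntegratorConfig(rel_tol=rel_tol, termination_fraction=termination_fraction),
        return_diagnostics=True,
    )


class TestSampling:
    def test_degenerate_spec_reproduces_equilibrium_at_rest(self):
        g = ck.fixture_geometry("cis_dce")
        spec = InitialConditionSpec(sigma=0.0, e_kin_total=0.0, n_samples=3, seed=0)
        pos, vel = ck.sample_initial_conditions(g, spec)
        assert np.allclose(pos, g.positions[None])
        assert np.all(vel == 0.0)

    def test_net_momentum_removed_and_kinetic_energy_exact(self):
        g = ck.fixture_geometry("trans_dce")
        spec = InitialConditionSpec(sigma=0.25, e_kin_total=0.5, n_samples=200, seed=3)
        _, vel = ck.sample_initial_conditions(g, spec)
        p_net = (g.masses[None, :, None] * vel).sum(axis=1)
        assert np.abs(p_net).max() < 1e-12
        ke = 0.5 * units.U_ANGFS_SQ_TO_EV * (g.masses[None, :, None] * vel**2).sum(axis=(1, 2))
        assert np.allclose(ke, 0.5, atol=1e-12)

    @pytest.mark.parametrize("mode, expected_sd", [("component", 0.25), ("radial", 0.25 / np.sqrt(3))])
    def test_displacement_spread_matches_sampling_mode(self, mode, expected_sd):
        g = ck.fixture_geometry("cis_dce")
        spec = InitialConditionSpec(sigma=0.25, e_kin_total=0.5, n_samples=10_000, seed=7, sigma_mode=mode)
        pos, _ = ck.sample_initial_conditions(g, spec)
        sd = (pos - g.positions[None]).std()
        assert sd == pytest.approx(expected_sd, abs=0.01)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            InitialConditionSpec(sigma=-0.1)
        with pytest.raises(ValueError):
            InitialConditionSpec(e_kin_total=-1.0)
        with pytest.raises(ValueError):
            InitialConditionSpec(n_samples=0)
        with pytest.raises(ValueError):
            InitialConditionSpec(sigma_mode="spherical")


class TestCoulombPotential:
    def test_unit_charges_at_one_angstrom(self):
        pe = ck.coulomb_potential_energy(np.array([[0, 0, 0], [1.0, 0, 0]]), [1, 1])
        assert pe == pytest.approx(K_EV_ANG, abs=1e-6)

    def test_unit_charges_at_1p44_angstrom(self):
        pe = ck.coulomb_potential_energy(np.array([[0, 0, 0], [1.44, 0, 0]]), [1, 1])
        assert pe == pytest.approx(9.99975, abs=1e-4)

    def test_far_separation_limit(self):
        pe = ck.coulomb_potential_energy(np.array([[0, 0, 0], [1e6, 0, 0]]), [1, 1])
        assert pe < 1e-4

    def test_coincident_atoms_raise(self):
        with pytest.raises(ValueError, match="singular"):
            ck.coulomb_potential_energy(np.zeros((2, 3)), [1, 1])


class TestPropagation:
    def test_two_body_kinetic_energy_release(self):
        event, diag = two_body(34.96885, 34.96885, 1, 1, 1.44)
        _, total = ck.kinetic_energy_release(event)
        assert total == pytest.approx(9.99975, rel=2e-6)
        per_fragment, _ = ck.kinetic_energy_release(event)
        assert per_fragment == pytest.approx([total / 2, total / 2], rel=1e-9)
        # momenta anti-parallel
        cosang = np.dot(event.momenta[0], event.momenta[1]) / (
            np.linalg.norm(event.momenta[0]) * np.linalg.norm(event.momenta[1])
        )
        assert np.arccos(np.clip(cosang, -1, 1)) == pytest.approx(np.pi, abs=1e-6)

    def test_energy_conservation_audit(self):
        g = ck.fixture_geometry("cis_dce")
        spec = InitialConditionSpec(n_samples=1, seed=5)
        pos, vel = ck.sample_initial_conditions(g, spec)
        _, diag = propagate_event(
            pos[0], vel[0], g.masses, np.ones(6), IntegratorConfig(rel_tol=1e-9),
            return_diagnostics=True,
        )
        assert diag["energy_drift_rel"] < 1e-6

    def test_charge_scaling_law(self):
        g = ck.fixture_geometry("cis_dce")
        base = propagate_event(g.positions, np.zeros((6, 3)), g.masses, np.ones(6))
        doubled = propagate_event(g.positions, np.zeros((6, 3)), g.masses, 2 * np.ones(6))
        ratio = np.linalg.norm(doubled.momenta, axis=1) / np.linalg.norm(base.momenta, axis=1)
        assert np.allclose(ratio, 2.0, rtol=1e-6)

    def test_rotational_equivariance(self):
        g = ck.fixture_geometry("twisted_dce")
        R = Rotation.from_rotvec([0.3, -0.8, 0.5]).as_matrix()
        cfg = IntegratorConfig(rel_tol=1e-12)
        base = propagate_event(g.positions, np.zeros((6, 3)), g.masses, np.ones(6), cfg)
        rotated = propagate_event(g.positions @ R.T, np.zeros((6, 3)), g.masses, np.ones(6), cfg)
        expected = base.momenta @ R.T
        scale = np.linalg.norm(base.momenta)
        assert np.abs(rotated.momenta - expected).max() / scale < 1e-9

    def test_mirror_symmetric_geometry_gives_mirror_symmetric_momenta(self):
        # cis-DCE equilibrium at rest: x -> -x maps H1<->H2, C1<->C2, Cl1<->Cl2
        g = ck.fixture_geometry("cis_dce")
        event = propagate_event(
            g.positions, np.zeros((6, 3)), g.masses, np.ones(6), IntegratorConfig(rel_tol=1e-10)
        )
        swap = [1, 0, 3, 2, 5, 4]
        mirrored = event.momenta[swap] * np.array([-1.0, 1.0, 1.0])
        scale = np.linalg.norm(event.momenta)
        assert np.abs(event.momenta - mirrored).max() / scale < 1e-6

    def test_nonpositive_energy_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            propagate_event(np.zeros((2, 3)) + [[0, 0, 0], [1, 0, 0]], np.zeros((2, 3)),
                            np.array([1.0, 1.0]), np.array([0, 0]))

    def test_step_cap_raises_trajectory_error(self):
        with pytest.raises(ck.explosion.TrajectoryError, match="max_steps"):
            two_body_cfg = IntegratorConfig(rel_tol=1e-12, termination_fraction=1e-10, max_steps=50)
            propagate_event(
                np.array([[0.0, 0, 0], [1.44, 0, 0]]), np.zeros((2, 3)),
                np.array([35.0, 35.0]), np.array([1, 1]), two_body_cfg,
            )


class TestEnsemble:
    def test_ensemble_is_deterministic_and_momentum_free(self):
        g = ck.fixture_geometry("cis_dce")
        channel = ck.FragmentationChannel.all_singly_charged(g)
        spec = InitialConditionSpec(n_samples=50, seed=9)
        e1 = ck.simulate_ensemble(g, channel, spec)
        e2 = ck.simulate_ensemble(g, channel, spec)
        assert np.array_equal(e1.momenta, e2.momenta)
        assert len(e1) == 50
        assert len(np.unique(e1.event_ids)) == 50
        assert np.linalg.norm(e1.momenta.sum(axis=1), axis=1).max() < 1e-6
        assert set(e1.labels) == {"cis_dce"}

    def test_default_sample_count_is_20000(self):
        assert InitialConditionSpec().n_samples == 20_000

    def test_kinetic_energy_release_total_matches_initial_energy(self, cis_small):
        g = ck.fixture_geometry("cis_dce")
        spec = InitialConditionSpec(n_samples=1, seed=11)
        pos, vel = ck.sample_initial_conditions(g, spec)
        pe0 = ck.coulomb_potential_energy(pos[0], np.ones(6))
        _, total = ck.kinetic_energy_release(cis_small[0])
        # all events share the spec: compare this event's KER to its own budget
        event, diag = propagate_event(
            pos[0], vel[0], g.masses, np.ones(6), return_diagnostics=True
        )
        _, ker = ck.kinetic_energy_release(event)
        assert ker == pytest.approx(pe0 + 0.5, rel=2e-4)

    def test_zero_momenta_have_zero_ker(self):
        event = ck.ExplosionEvent(np.zeros((2, 3)), ("H", "H"), [1, 1], [1.008, 1.008])
        per_frag, total = ck.kinetic_energy_release(event)
        assert total == 0.0 and np.all(per_frag == 0.0)
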