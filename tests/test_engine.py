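"""Langevin engine: force-energy consistency, SHAKE, integrator limits,
determinism."""

import numpy as np
import pytest

from nrrgo.constants import KB, KCAL_TO_MD
from nrrgo.engine import (EngineError, SimState, apply_shake,
                          compute_energy_forces, langevin_step, pack_model,
                          run_equilibrium)
from nrrgo.gomodel import CGTopology, NativeContact


def _dimer(k=1.0, r0=4.0, sep=4.5, m=(100.0, 100.0), restraint=True):
    contacts = [] if restraint else [NativeContact(0, 1, r0, 1.5, "sidechain")]
    return CGTopology(
        n_beads=2, masses=np.array(m), bonds=[], angles=[], dihedrals=[],
        contacts=contacts, repulsive_radii=np.zeros(2),
        harmonic_restraints=[(0, 1, r0, k)] if restraint else [],
        author_resids=np.array([1, 2]), sequence="AA",
        native_coords=np.array([[0.0, 0, 0], [sep, 0, 0]]))


class TestEnergyForces:
    def test_contact_minimum_has_zero_force(self):
        top = _dimer(restraint=False)          # single native contact at 4 A
        coords = np.array([[0.0, 0, 0], [4.0, 0, 0]])
        rep, f = compute_energy_forces(top, coords)
        assert np.abs(f).max() < 1e-10
        assert rep.contact == pytest.approx(-1.5, rel=1e-4)  # well depth

    def test_forces_are_exact_gradients(self, hairpin_top, hairpin_packed, rng):
        top, p = hairpin_top, hairpin_packed
        x = top.native_coords + 0.05 * rng.standard_normal((top.n_beads, 3))
        rep, f = compute_energy_forces(top, x, packed=p)
        h = 1e-6
        num = np.zeros_like(f)
        for i in range(top.n_beads):
            for d in range(3):
                xp, xm = x.copy(), x.copy()
                xp[i, d] += h
                xm[i, d] -= h
                num[i, d] = -(compute_energy_forces(top, xp, packed=p)[0].total
                              - compute_energy_forces(top, xm, packed=p)[0].total) / (2 * h)
        assert np.abs(num - f).max() / np.abs(f).max() < 1e-6

    def test_total_is_sum_of_components(self, hairpin_top, rng):
        x = hairpin_top.native_coords + 0.1 * rng.standard_normal(
            (hairpin_top.n_beads, 3))
        rep, _ = compute_energy_forces(hairpin_top, x)
        parts = rep.angle + rep.dihedral + rep.contact + rep.repulsion + rep.restraint
        assert rep.total == pytest.approx(parts, rel=1e-12)

    def test_nonfinite_coords_rejected(self, hairpin_top):
        x = hairpin_top.native_coords.copy()
        x[0, 0] = np.nan
        with pytest.raises(ValueError):
            compute_energy_forces(hairpin_top, x)

    def test_native_state_near_local_minimum(self, hairpin_top, hairpin_packed):
        """Overdamped T=0 relaxation from the native coordinates releases
        less than 1 kT(300K)."""
        e0 = compute_energy_forces(hairpin_top, hairpin_top.native_coords,
                                   packed=hairpin_packed)[0].total
        traj = run_equilibrium(hairpin_top, T=0.0, n_steps=5000, save_every=5000,
                               seed=0, gamma=50.0, packed=hairpin_packed)
        e1 = compute_energy_forces(hairpin_top, traj.frames[-1],
                                   packed=hairpin_packed)[0].total
        assert e0 - e1 < KB * 300.0
        assert e1 <= e0 + 1e-9


class TestShake:
    def test_satisfied_coords_unchanged(self, hairpin_top):
        x = hairpin_top.native_coords
        out = apply_shake(hairpin_top, x, x.copy())
        np.testing.assert_allclose(out, x, atol=1e-9)

    def test_two_body_mass_weighted_projection(self):
        top = CGTopology(
            n_beads=2, masses=np.array([50.0, 150.0]),
            bonds=[(0, 1, 4.0)], angles=[], dihedrals=[], contacts=[],
            repulsive_radii=np.zeros(2), harmonic_restraints=[],
            author_resids=np.array([1, 2]), sequence="AA",
            native_coords=np.array([[0.0, 0, 0], [4.0, 0, 0]]))
        ref = top.native_coords
        stretched = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        out = apply_shake(top, ref, stretched, tol=1e-10)
        # bond restored; displacements inversely proportional to masses
        assert np.linalg.norm(out[1] - out[0]) == pytest.approx(4.0, abs=1e-9)
        d0 = np.abs(out[0, 0] - stretched[0, 0])
        d1 = np.abs(out[1, 0] - stretched[1, 0])
        assert d0 / d1 == pytest.approx(150.0 / 50.0, rel=1e-6)

    def test_residual_below_tolerance_on_all_frames(self, hairpin_top,
                                                    hairpin_packed):
        from nrrgo import _kernels as K
        p = hairpin_packed
        traj = run_equilibrium(hairpin_top, T=300.0, n_steps=20000,
                               save_every=200, seed=3, packed=p)
        worst = max(K.max_bond_residual(fr, p[2], p[3], p[4])
                    for fr in traj.frames)
        assert worst < 1e-6


class TestIntegrator:
    def test_nve_energy_conservation(self):
        """gamma=0, T=0 on a harmonic dimer: symplectic -> no secular drift."""
        top = _dimer()
        v0 = np.array([[0.2, 0, 0], [-0.2, 0, 0]])
        traj = run_equilibrium(top, T=0.0, n_steps=100000, save_every=1000,
                               seed=1, gamma=0.0, velocities0=v0)
        e = traj.metadata["energy_series"]
        tot = e[:, :5].sum(axis=1) + e[:, 5]
        m = len(tot)
        drift = abs(np.mean(tot[-m // 10:]) - np.mean(tot[:m // 10]))
        assert drift / abs(np.mean(tot)) < 1e-4

    def test_zero_friction_step_is_velocity_verlet(self):
        top = _dimer()
        x0 = top.native_coords.copy()
        v0 = np.array([[0.1, 0, 0], [-0.1, 0, 0]])
        st = langevin_step(top, SimState(x0.copy(), v0.copy(), 0.0, seed=5),
                           dt=0.01, gamma=0.0, T=0.0)
        # hand-computed velocity Verlet step
        def force(x):
            return compute_energy_forces(top, x)[1]
        dt = 0.01
        a0 = force(x0) * KCAL_TO_MD / 100.0
        x1 = x0 + dt * v0 + 0.5 * dt * dt * a0
        a1 = force(x1) * KCAL_TO_MD / 100.0
        v1 = v0 + 0.5 * dt * (a0 + a1)
        np.testing.assert_allclose(st.coords, x1, atol=1e-12)
        np.testing.assert_allclose(st.velocities, v1, atol=1e-12)

    def test_ou_velocity_autocorrelation(self):
        """Free bead: VACF decays with time constant 1/gamma."""
        top = CGTopology(n_beads=1, masses=np.array([100.0]), bonds=[],
                         angles=[], dihedrals=[], contacts=[],
                         repulsive_radii=np.zeros(1), harmonic_restraints=[],
                         author_resids=np.array([1]), sequence="A",
                         native_coords=np.zeros((1, 3)))
        gamma, dt = 1.0, 0.01
        traj = run_equilibrium(top, T=300.0, n_steps=60000, save_every=1,
                               seed=4, gamma=gamma, save_velocities=True)
        v = traj.velocities[:, 0, :]
        maxlag = 300
        ac = np.array([np.mean(np.sum(v[:len(v) - k] * v[k:], axis=1))
                       for k in range(maxlag)])
        ac /= ac[0]
        lags = np.arange(maxlag) * dt
        sel = lags < 2.0 / gamma
        tau = -1.0 / np.polyfit(lags[sel],
                                np.log(np.clip(ac[sel], 1e-8, None)), 1)[0]
        assert tau == pytest.approx(1.0 / gamma, rel=0.15)

    def test_equipartition_with_constrained_dof(self, hairpin_top,
                                                hairpin_packed):
        T = 300.0
        traj = run_equilibrium(hairpin_top, T=T, n_steps=40000, save_every=20,
                               seed=9, packed=hairpin_packed)
        e = traj.metadata["energy_series"]
        ke = e[len(e) // 4:, 5]
        ndof = 3 * hairpin_top.n_beads - len(hairpin_top.bonds)
        expect = 0.5 * ndof * KB * T
        # crude decorrelation: ~20-frame correlation length
        neff = len(ke) / 20.0
        se = ke.std() / np.sqrt(neff)
        assert abs(ke.mean() - expect) < 3 * se + 0.02 * expect

    def test_overdamped_zero_t_energy_nonincreasing(self, hairpin_top, rng):
        x0 = hairpin_top.native_coords + 0.3 * rng.standard_normal(
            (hairpin_top.n_beads, 3))
        traj = run_equilibrium(hairpin_top, T=0.0, n_steps=2000, save_every=100,
                               seed=2, gamma=50.0, coords0=x0)
        e = traj.metadata["energy_series"][:, :5].sum(axis=1)
        assert (np.diff(e) <= 1e-6).all()

    def test_zero_steps_returns_input_frame(self, hairpin_top):
        traj = run_equilibrium(hairpin_top, T=300.0, n_steps=0, save_every=10,
                               seed=1)
        assert traj.n_frames == 1
        np.testing.assert_array_equal(traj.frames[0], hairpin_top.native_coords)

    def test_bitwise_determinism(self, hairpin_top, hairpin_packed):
        t1 = run_equilibrium(hairpin_top, T=300.0, n_steps=2000, save_every=100,
                             seed=42, packed=hairpin_packed)
        t2 = run_equilibrium(hairpin_top, T=300.0, n_steps=2000, save_every=100,
                             seed=42, packed=hairpin_packed)
        assert (t1.frames == t2.frames).all()
        t3 = run_equilibrium(hairpin_top, T=300.0, n_steps=2000, save_every=100,
                             seed=43, packed=hairpin_packed)
        assert not (t1.frames == t3.frames).all()

    def test_instability_guard(self, hairpin_top):
        v0 = np.zeros((hairpin_top.n_beads, 3))
        v0[0, 0] = 500.0      # 5 A in one 10 fs step
        with pytest.raises(EngineError, match="instability|guard"):
            run_equilibrium(hairpin_top, T=0.0, n_steps=10, save_every=1,
                            seed=1, gamma=0.0, velocities0=v0)
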