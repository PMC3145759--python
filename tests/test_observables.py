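"""Native fractions, superposition, RMSF/covariance, B-factor conversion."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from nrrgo.gomodel import NativeContact
from nrrgo.observables import (ContactSubsets, bfactor_to_rmsf,
                               covariance_map, end_to_end, native_fraction,
                               rmsf_profile, rmsf_to_bfactor, superpose)


def _contacts(pairs, r0=5.0):
    return [NativeContact(i, j, r0, 1.0, "sidechain") for i, j in pairs]


class TestNativeFraction:
    def test_native_coords_give_unity(self, hairpin_top):
        q = native_fraction(hairpin_top.native_coords, hairpin_top.contacts,
                            hairpin_top.author_resids,
                            subsets={"half": ((1, 8), None)})
        assert q["Q_total"] == 1.0
        assert q["half"] == 1.0

    def test_fully_extended_gives_zero(self, hairpin_top):
        n = hairpin_top.n_beads
        x = np.zeros((n, 3))
        x[:, 0] = 4.0 * np.arange(n)
        q = native_fraction(x, hairpin_top.contacts, hairpin_top.author_resids)
        assert q["Q_total"] == 0.0

    def test_matches_brute_force_on_random_sets(self, rng):
        n = 30
        pairs = [(i, j) for i in range(n) for j in range(i + 4, n)]
        idx = rng.choice(len(pairs), size=40, replace=False)
        contacts = _contacts([pairs[k] for k in idx])
        x = rng.standard_normal((n, 3)) * 6
        q = native_fraction(x, contacts, tolerance=1.0)["Q_total"]
        formed = sum(np.linalg.norm(x[c.bead_i] - x[c.bead_j]) <= c.r_native + 1.0
                     for c in contacts)
        assert q == pytest.approx(formed / len(contacts))

    def test_rigid_motion_invariance(self, hairpin_top, rng):
        x = hairpin_top.native_coords + 0.2 * rng.standard_normal(
            (hairpin_top.n_beads, 3))
        rot = Rotation.random(random_state=3).as_matrix()
        q1 = native_fraction(x, hairpin_top.contacts, hairpin_top.author_resids)
        q2 = native_fraction(x @ rot.T + np.array([5.0, -3.0, 2.0]),
                             hairpin_top.contacts, hairpin_top.author_resids)
        assert q1["Q_total"] == pytest.approx(q2["Q_total"])

    def test_empty_subset_is_undefined(self, hairpin_top):
        q = native_fraction(hairpin_top.native_coords, hairpin_top.contacts,
                            hairpin_top.author_resids,
                            subsets={"nowhere": ((900, 950), None)})
        assert np.isnan(q["nowhere"])

    def test_partitioned_subsets_recombine_to_total(self, two_domain):
        _s, top, info = two_domain
        cs = ContactSubsets(top.contacts, top.author_resids, info["subsets"])
        x = top.native_coords * 1.05      # break some contacts
        formed = cs.formed(x)
        q = cs.fractions(x)
        for name, mask in cs.masks.items():
            if name == "Q_total" or not mask.sum():
                continue
            assert q[name] == pytest.approx(formed[mask].mean())


class TestSuperpose:
    def test_identity(self, rng):
        x = rng.standard_normal((10, 3))
        rot, trans, rmsd = superpose(x, x)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-10)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_recovers_known_rotation(self, rng):
        x = rng.standard_normal((12, 3)) * 3
        R = Rotation.random(random_state=7).as_matrix()
        moved = x @ R.T + np.array([1.0, 2.0, 3.0])
        rot, trans, rmsd = superpose(moved, x)
        np.testing.assert_allclose(rot @ R, np.eye(3), atol=1e-10)
        assert rmsd < 1e-10

    def test_agrees_with_scipy_kabsch(self, rng):
        """Independent oracle: scipy's Rotation.align_vectors on centered
        point sets gives the same optimal RMSD."""
        a = rng.standard_normal((15, 3)) * 2
        b = rng.standard_normal((15, 3)) * 2
        _rot, _t, rmsd = superpose(a, b)
        ac, bc = a - a.mean(0), b - b.mean(0)
        _srot, srssd = Rotation.align_vectors(bc, ac, return_sensitivity=False)
        fitted = _srot.apply(ac)
        srmsd = np.sqrt(np.mean(np.sum((fitted - bc) ** 2, axis=1)))
        assert rmsd == pytest.approx(srmsd, rel=1e-9)

    def test_two_point_swap_matches_independent_fit(self):
        """Four coplanar beads with two swapped: optimal rmsd agrees with an
        independently computed Kabsch fit."""
        ref = np.array([[0.0, 0, 0], [2.0, 0, 0], [0, 2.0, 0], [2.0, 2.0, 0]])
        mob = ref.copy()
        mob[[0, 1]] = mob[[1, 0]]
        _r, _t, rmsd = superpose(mob, ref)
        ac, bc = mob - mob.mean(0), ref - ref.mean(0)
        import warnings
        with warnings.catch_warnings():
            # coplanar points: scipy warns that the rotation is not unique,
            # but the optimal rssd is
            warnings.simplefilter("ignore", UserWarning)
            srot, _ = Rotation.align_vectors(bc, ac)
        srmsd = np.sqrt(np.mean(np.sum((srot.apply(ac) - bc) ** 2, axis=1)))
        assert rmsd == pytest.approx(srmsd, rel=1e-9)
        unaligned = np.sqrt(np.mean(np.sum((mob - ref) ** 2, axis=1)))
        assert rmsd <= unaligned + 1e-12

    def test_collinear_selection_is_error(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="degenerate|collinear"):
            superpose(line, line)


class TestFluctuations:
    def test_frozen_trajectory_zero_rmsf(self, rng):
        fr = np.repeat(rng.standard_normal((1, 8, 3)), 10, axis=0)
        prof = rmsf_profile(fr, fr[0])
        np.testing.assert_allclose(prof.rmsf, 0.0, atol=1e-12)

    def test_gaussian_jitter_limit(self, rng):
        """Independent isotropic jitter of width sigma -> RMSF -> sigma*sqrt(3).

        Enough beads are used that the 6 rigid-body degrees of freedom the
        superposition absorbs are a small correction (factor
        sqrt(1 - 6/(3n)) ~ 0.5% at n = 80)."""
        n = 80
        base = rng.standard_normal((n, 3)) * 8
        sigma = 0.3
        frames = base[None] + sigma * rng.standard_normal((4000, n, 3))
        prof = rmsf_profile(frames, base, use_fraction=1.0)
        np.testing.assert_allclose(prof.rmsf, sigma * np.sqrt(3), rtol=0.05)

    def test_rigid_motion_removed_by_alignment(self, rng):
        base = rng.standard_normal((9, 3)) * 5
        frames = []
        for k in range(40):
            R = Rotation.from_euler("z", 5.0 * k, degrees=True).as_matrix()
            frames.append(base @ R.T + k * np.array([0.1, 0.2, 0.0]))
        prof = rmsf_profile(np.array(frames), base, use_fraction=1.0)
        np.testing.assert_allclose(prof.rmsf, 0.0, atol=1e-8)

    def test_too_few_frames_error(self, rng):
        fr = rng.standard_normal((1, 5, 3))
        with pytest.raises(ValueError):
            rmsf_profile(fr, fr[0])


class TestCovariance:
    def test_frozen_trajectory_zero_matrix(self, rng):
        fr = np.repeat(rng.standard_normal((1, 6, 3)), 5, axis=0)
        cov = covariance_map(fr, fr[0])
        np.testing.assert_allclose(cov, 0.0, atol=1e-12)

    def test_diagonal_equals_rmsf_squared(self, rng):
        base = rng.standard_normal((7, 3)) * 6
        frames = base[None] + 0.2 * rng.standard_normal((500, 7, 3))
        cov = covariance_map(frames, base, use_fraction=1.0)
        prof = rmsf_profile(frames, base, use_fraction=1.0)
        np.testing.assert_allclose(np.diag(cov), prof.rmsf ** 2, rtol=1e-8)

    def test_shared_displacement_couples_offdiagonal(self, rng):
        # enough beads that superposition barely redistributes the motion
        n = 24
        base = rng.standard_normal((n, 3)) * 10
        frames = []
        for _ in range(2000):
            d = 0.3 * rng.standard_normal(3)
            fr = base.copy()
            fr[2] += d
            fr[10] += d     # beads 2 and 10 move together
            frames.append(fr)
        cov = covariance_map(np.array(frames), base, use_fraction=1.0)
        assert cov[2, 10] == pytest.approx(cov[2, 2], rel=0.25)
        assert abs(cov[2, 3]) < 0.3 * cov[2, 2]

    def test_symmetric_and_psd(self, hairpin_top, hairpin_packed):
        from nrrgo.engine import run_equilibrium
        traj = run_equilibrium(hairpin_top, T=300.0, n_steps=5000,
                               save_every=50, seed=6, packed=hairpin_packed)
        cov = covariance_map(traj.frames, hairpin_top.native_coords)
        np.testing.assert_allclose(cov, cov.T, atol=1e-10)
        assert np.linalg.eigvalsh(cov).min() >= -1e-8


class TestBfactor:
    def test_zero_maps_to_zero(self):
        assert bfactor_to_rmsf(0.0) == 0.0

    def test_closed_form_value(self):
        # 8 pi^2 / 3 = 26.3189...: a B-factor of that size is 1 A RMSF
        assert bfactor_to_rmsf(8 * np.pi ** 2 / 3) == pytest.approx(1.0,
                                                                    abs=1e-12)
        assert bfactor_to_rmsf(26.3189) == pytest.approx(1.0, abs=1e-4)

    def test_roundtrip_identity(self, rng):
        r = rng.random(20) * 3
        np.testing.assert_allclose(bfactor_to_rmsf(rmsf_to_bfactor(r)), r,
                                   rtol=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            bfactor_to_rmsf(-1.0)
        with pytest.raises(ValueError):
            rmsf_to_bfactor(np.array([-0.1]))


class TestEndToEnd:
    def test_values(self):
        x = np.array([[0.0, 0, 0], [1.0, 0, 0], [4.0, 4.0, 2.0]])
        assert end_to_end(x, 0, 0) == 0.0
        assert end_to_end(x, 0, 1) == 1.0
        assert end_to_end(x, 0, 2) == 6.0
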