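"""Go-model construction: contacts, flavoring, topology assembly,
thermal calibration."""

import copy
import json

import numpy as np
import pytest

from nrrgo.gomodel import (CGTopology, GoModelOptions, NativeContact,
                           assign_contact_energies, build_native_contacts,
                           build_topology, calibrate_energy_scale,
                           load_contact_weights)
from nrrgo.structure import ChainStructure, Residue
from nrrgo.toys import (ToySpec, make_toy_structure, make_two_domain_shielded,
                        make_two_state_benchmark)


def _extended_chain(n=20):
    """Straight chain, side chains all on one side: no |i-j|>=4 pair within
    any detection cutoff."""
    res = []
    for k in range(n):
        ca = np.array([3.8 * k, 0.0, 1.0 * (k % 2)])
        atoms = [("CA", "C", ca),
                 ("N", "N", ca + np.array([-1.2, 0.0, 0.35])),
                 ("C", "C", ca + np.array([1.2, 0.0, 0.35])),
                 ("O", "O", ca + np.array([1.4, 0.0, -0.9])),
                 ("CB", "C", ca + np.array([0.0, 2.0, 0.0]))]
        res.append(Residue(k + 1, "AVL"[k % 3], ca, atoms, 10.0))
    return ChainStructure(res, [], [])


class TestBuildNativeContacts:
    def test_extended_chain_has_no_contacts(self):
        assert build_native_contacts(_extended_chain()) == []

    @pytest.mark.parametrize("kind", ["hairpin", "two_domain_shielded"])
    def test_designed_plan_recovered_exactly(self, kind):
        s, plan = make_toy_structure(ToySpec(topology_kind=kind))
        got = sorted((c.bead_i, c.bead_j) for c in build_native_contacts(s))
        assert got == sorted((i, j) for i, j, _e in plan)

    def test_short_range_pairs_excluded(self, hairpin):
        for c in build_native_contacts(hairpin[0]):
            assert abs(c.bead_i - c.bead_j) >= 4

    def test_r_native_is_ca_distance(self, hairpin):
        s, _ = hairpin
        ca = s.ca_coords()
        for c in build_native_contacts(s):
            assert c.r_native == pytest.approx(
                np.linalg.norm(ca[c.bead_i] - ca[c.bead_j]))

    def test_hbond_origin_on_sheet_fixture(self):
        s, _info = make_two_domain_shielded()
        origins = {c.origin for c in build_native_contacts(s)}
        assert origins == {"backbone_hbond"}

    def test_sidechain_origin_wins_on_hairpin(self, hairpin):
        origins = {c.origin for c in build_native_contacts(hairpin[0])}
        assert origins == {"sidechain"}


class TestAssignContactEnergies:
    def test_all_alanine_uniform(self):
        contacts = [NativeContact(0, 5, 6.0, 1.0, "sidechain"),
                    NativeContact(1, 6, 6.0, 1.0, "sidechain")]
        out = assign_contact_energies(contacts, "A" * 8, baseline=1.3)
        assert out[0].epsilon == pytest.approx(out[1].epsilon)
        assert out[0].epsilon == pytest.approx(1.3)

    def test_mean_sidechain_epsilon_equals_baseline(self, hairpin):
        s, _ = hairpin
        out = assign_contact_energies(build_native_contacts(s), s.sequence(),
                                      baseline=0.85)
        eps = [c.epsilon for c in out if c.origin == "sidechain"]
        assert np.mean(eps) == pytest.approx(0.85, rel=1e-12)
        assert np.std(eps) > 0   # flavoring actually differentiates pairs

    def test_backbone_and_ion_depths(self):
        contacts = [NativeContact(0, 5, 6.0, 1.0, "backbone_hbond"),
                    NativeContact(1, 9, 4.0, 1.0, "ion_coordination")]
        out = assign_contact_energies(contacts, "A" * 10,
                                      backbone_epsilon=0.9, ion_epsilon=2.0)
        assert out[0].epsilon == pytest.approx(0.9)
        assert out[1].epsilon == pytest.approx(2.0)

    def test_unknown_residue_is_error(self):
        contacts = [NativeContact(1, 5, 6.0, 1.0, "sidechain")]
        with pytest.raises(ValueError, match="alphabet"):
            assign_contact_energies(contacts, "AXAAAA")

    def test_weight_table_shape(self):
        w = load_contact_weights()
        assert w.shape == (20, 20)


class TestBuildTopology:
    def test_five_bead_counting(self):
        s = _extended_chain(5)
        top = build_topology(s, [])
        assert len(top.bonds) == 4
        assert len(top.angles) == 3
        assert len(top.dihedrals) == 2
        assert top.n_beads == 5

    def test_bond_lengths_native(self, hairpin_top, hairpin):
        ca = hairpin[0].ca_coords()
        for i, j, length in hairpin_top.bonds:
            assert length == pytest.approx(np.linalg.norm(ca[i] - ca[j]))

    def test_chain_break_removes_one_bond(self):
        s, _ = make_toy_structure(ToySpec())
        contacts = build_native_contacts(s)
        full = build_topology(s, contacts)
        broken = build_topology(s, contacts, GoModelOptions(
            break_s1=True, s1_break_resids=(8, 9)))
        assert len(broken.bonds) == len(full.bonds) - 1
        assert broken.n_beads == full.n_beads
        assert broken.chain_break == (8, 9)

    def test_chain_break_missing_resids_error(self, hairpin):
        s, _ = hairpin
        with pytest.raises(ValueError, match="break"):
            build_topology(s, [], GoModelOptions(break_s1=True,
                                                 s1_break_resids=(1622, 1670)))

    def test_disulfide_and_ion_modifications(self):
        s, _ = make_toy_structure(ToySpec(cysteine_pairs=[(2, 13)],
                                          ion_near_residue=5))
        opts = GoModelOptions(min_ion_coordinators=1)
        top = build_topology(s, build_native_contacts(s), opts)
        assert top.n_beads == 17          # 16 residues + 1 calcium bead
        ks = sorted(k for _i, _j, _r, k in top.harmonic_restraints)
        assert ks == [pytest.approx(0.1), pytest.approx(1.0)]  # tether + SS
        ion_contacts = [c for c in top.contacts
                        if c.origin == "ion_coordination"]
        assert len(ion_contacts) == 1
        assert all(c.epsilon == pytest.approx(2.0) for c in ion_contacts)
        assert top.repulsive_radii[-1] == pytest.approx(2.0)
        assert top.masses[-1] == pytest.approx(40.08)

    def test_underscoordinated_ion_not_retained(self):
        s, _ = make_toy_structure(ToySpec(ion_near_residue=5))
        top = build_topology(s, build_native_contacts(s))   # needs >= 4
        assert top.metadata["n_ion_beads"] == 0

    def test_deterministic_serialization(self):
        s, _ = make_toy_structure(ToySpec())
        c = build_native_contacts(s)
        t1 = build_topology(s, c).to_json()
        t2 = build_topology(s, c).to_json()
        assert t1 == t2
        top = CGTopology.from_json(t1)
        assert top.to_json() == t1

    def test_validate_rejects_contact_on_excluded_pair(self, hairpin):
        s, _ = hairpin
        top = build_topology(s, build_native_contacts(s))
        bad = copy.deepcopy(top)
        bad.contacts.append(NativeContact(0, 1, 3.9, 1.0, "sidechain"))
        with pytest.raises(ValueError, match="contact and excluded"):
            bad.validate()

    def test_domain_subset_contacts_are_subset_of_full(self):
        s, info = make_two_domain_shielded()
        full = {(s.resids()[c.bead_i], s.resids()[c.bead_j])
                for c in build_native_contacts(s)}
        lo, hi = info["subsets"]["beta:core"][1]   # the core block
        sub = s.subset(lo, hi)
        part = {(sub.resids()[c.bead_i], sub.resids()[c.bead_j])
                for c in build_native_contacts(sub)}
        assert part == {(a, b) for a, b in full if lo <= a <= hi and lo <= b <= hi}


class TestCalibration:
    def _estimator(self, noise=0.0):
        def est(benchlike):
            return benchlike.tm() + noise, 1.0
        return est

    def test_fixed_point_returns_unit_scale(self):
        b = make_two_state_benchmark(2.0, 1.0, np.exp(2.0 / (0.0019872041 * 350)))
        out = calibrate_energy_scale(b, b.tm(), self._estimator(), tol=5.0)
        assert out.energy_scale == pytest.approx(1.0)
        assert out.metadata["calibration_iterations"] == 1

    def test_closed_form_scale_recovery(self):
        b = make_two_state_benchmark(2.0, 1.0, np.exp(2.0 / (0.0019872041 * 350)))
        # Tm(scale) = scale * Tm(1): reaching 420 K needs scale 1.2
        out = calibrate_energy_scale(b, 420.0, self._estimator(), tol=1.0)
        assert out.energy_scale == pytest.approx(420.0 / b.tm(), rel=1e-6)
        assert out.metadata["tm_estimate"] == pytest.approx(420.0, abs=1.0)

    def test_nonconvergence_error_carries_history(self):
        b = make_two_state_benchmark(2.0, 1.0, np.exp(2.0 / (0.0019872041 * 350)))

        def stuck(_b):
            return 100.0, 1.0    # estimator ignores the scale: cannot converge
        with pytest.raises(RuntimeError, match="history"):
            calibrate_energy_scale(b, 350.0, stuck, tol=5.0, max_iter=3)
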