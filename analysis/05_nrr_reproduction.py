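#!/usr/bin/env python
"""Scaled reproduction of the Notch1 NRR mechanical-unfolding analysis.

Requires the crystal structure of the human Notch1 negative regulatory
region at data/3ETO.pdb (PDB entry 3ETO; not redistributed here).

Stages (each prints its findings and writes under results/05_nrr/):
 1. structure checks: residue span 1449-1727 with the excised S1 loop
    (1623-1669), ten disulfides (3 per LNR module + 1 in HD), three
    calcium sites with 6-7 coordinating oxygens, native end-to-end ~35 A;
 2. Tm calibration of the sequence-flavored model to 350 K by replica
    exchange + WHAM, then a 300 K equilibrium run reporting C-alpha RMSD
    (expected to fluctuate around ~3 A) and the RMSF profile against the
    crystal-B-factor conversion;
 3. S1-broken constant-velocity pulling ensemble at the scaled-down
    preset (100 A/ns, 10 replicates; the unfolding pathway is insensitive
    to speed over 0.1-100 A/ns, which is what licenses the scaled preset),
    reporting the averaged force profile, its peaks, and the subdomain
    rupture order (LNR-A:HD, LNR-B:HD, LNR-C:HD, HD-beta5, HDN:HDC);
 4. HD-domain-only replica exchange and the F(Q, Q_beta5) surface near Tm.

At these scaled settings the whole script is hours of compute on one
CPU; the full published protocol (1 A/ns, 60 replicates of 500 ns;
1 us REX) is cluster-scale.
"""

import sys
from pathlib import Path

import numpy as np

from nrrgo.engine import pack_model, run_equilibrium
from nrrgo.gomodel import (GoModelOptions, assign_contact_energies,
                           build_native_contacts, build_topology,
                           calibrate_energy_scale)
from nrrgo.observables import (ContactSubsets, bfactor_to_rmsf, end_to_end,
                               rmsf_profile, superpose)
from nrrgo.pulling import (PullProtocol, average_force_profile,
                           detect_force_peaks, run_smd, unfolding_order)
from nrrgo.remd import (make_temperature_ladder, remd_tm_estimator, run_remd,
                        wham_free_energy)
from nrrgo.structure import (SubdomainScheme, detect_disulfides,
                             detect_ion_coordination, read_structure)

ROOT = Path(__file__).resolve().parent.parent
NRR = ROOT / "data" / "3ETO.pdb"
OUT = ROOT / "results" / "05_nrr"
SEED = 1

# native-contact subsets monitored during pulling (author numbering);
# LNR-A:HD counts all contacts the first 40 residues make with HD
PULL_SUBSETS = {
    "LNR-A:HD": ((1449, 1488), (1568, 1727)),
    "LNR-B:HD": ((1491, 1522), (1568, 1727)),
    "LNR-C:HD": ((1529, 1562), (1568, 1727)),
    "HD-beta5": ((1721, 1727), None),
    "HDN:HDC": ((1568, 1622), (1670, 1727)),
}


def structure_checks(s):
    scheme = SubdomainScheme.notch1_nrr()
    resids = s.resids()
    print(f"residue span {resids.min()}-{resids.max()}, "
          f"gaps at {[(resids[i], resids[i+1]) for i in s.segment_breaks]}")
    pairs = detect_disulfides(s)
    by_dom = {}
    for p in pairs:
        by_dom.setdefault(scheme.primary_label(p.resid_i), []).append(p)
    print(f"{len(pairs)} disulfides: "
          + ", ".join(f"{k}:{len(v)}" for k, v in sorted(by_dom.items())))
    sites = detect_ion_coordination(s)
    print(f"{len(sites)} calcium sites with "
          f"{[len(x.coordinating_residues) for x in sites]} coordinators")
    d = end_to_end(s.ca_coords(), 0, s.n_residues - 1)
    print(f"native end-to-end distance {d:.1f} A")


def main():
    if not NRR.exists():
        print(f"ERROR: {NRR} not found.\nDownload PDB entry 3ETO "
              "(https://www.rcsb.org/structure/3ETO) into data/ first.")
        return 2
    OUT.mkdir(parents=True, exist_ok=True)
    s = read_structure(NRR.read_text(), "A")
    structure_checks(s)

    # --- model + thermal calibration ---------------------------------
    contacts = assign_contact_energies(build_native_contacts(s), s.sequence())
    top = build_topology(s, contacts)
    ladder = make_temperature_ladder(250.0, 450.0, 8)
    est = remd_tm_estimator(ladder, cycle_ps=10.0, n_cycles=400, seed=SEED)
    cal = calibrate_energy_scale(top, 350.0, est, tol=15.0, max_iter=8)
    print(f"calibrated scale {cal.energy_scale:.3f} "
          f"(Tm {cal.metadata['tm_estimate']:.0f} K)")
    packed = pack_model(cal)

    # --- 300 K equilibrium: RMSD ~3 A, RMSF vs B-factors --------------
    traj = run_equilibrium(cal, T=300.0, n_steps=1000000, save_every=2000,
                           seed=SEED + 1, packed=packed)
    prot = slice(0, s.n_residues)
    rmsds = [superpose(fr[prot], cal.native_coords[prot])[2]
             for fr in traj.frames[len(traj.frames) // 5:]]
    print(f"300 K equilibrium C-alpha RMSD: mean {np.mean(rmsds):.1f} A "
          f"(range {np.min(rmsds):.1f}-{np.max(rmsds):.1f})")
    prof = rmsf_profile(traj.frames[:, prot], cal.native_coords[prot])
    bf = bfactor_to_rmsf([r.b_factor for r in s.residues])
    import pandas as pd
    pd.DataFrame({"residue_id": np.arange(1, s.n_residues + 1),
                  "author_resid": s.resids(), "rmsf_model_A": prof.rmsf,
                  "rmsf_from_bfactor_A": bf}).to_csv(
        OUT / "rmsf.tsv", sep="\t", index=False)

    # --- S1-broken pulling ensemble, scaled preset --------------------
    broken = build_topology(s, contacts, GoModelOptions(break_s1=True))
    broken.energy_scale = cal.energy_scale
    bp = pack_model(broken)
    runs = []
    for k in range(10):
        pp = PullProtocol(speed=100.0, spring_k=1.0, max_extension=260.0,
                          save_every=500, seed=SEED * 1000 + k)
        _t, rec = run_smd(broken, pp, T=300.0, subsets=PULL_SUBSETS,
                          packed=bp)
        rec.to_csv(OUT / f"pull_{k:02d}.csv", index=False)
        runs.append(rec)
        print(f"  pull {k}: final extension "
              f"{rec.end_to_end_A.iloc[-1]:.0f} A")
    profile = average_force_profile(runs, bin_width=1.0, running_window=50)
    profile.to_csv(OUT / "force_profile.tsv", sep="\t", index=False)
    peaks = detect_force_peaks(profile, min_prominence=5.0,
                               min_separation=10.0)
    print("force peaks:", [(round(e), round(h)) for e, h in peaks])
    order = unfolding_order(runs)
    print("rupture order:")
    print(order.to_string(index=False))
    order.to_json(OUT / "unfolding_order.json", orient="records", indent=1)

    # --- HD-domain folding surface ------------------------------------
    hd = s.subset(1568, 1727)
    hd_contacts = assign_contact_energies(build_native_contacts(hd),
                                          hd.sequence())
    hd_top = build_topology(hd, hd_contacts)
    hd_top.energy_scale = cal.energy_scale
    hd_ladder = make_temperature_ladder(300.0, 400.0, 8)
    run = run_remd(hd_top, hd_ladder, cycle_ps=10.0, n_cycles=1000,
                   seed=SEED + 5, packed=pack_model(hd_top))
    cs = ContactSubsets(hd_top.contacts, hd_top.author_resids,
                        {"Q_beta5": ((1721, 1727), None)})
    q = np.array([[d["Q_total"], d["Q_beta5"]]
                  for d in (cs.fractions(c) for c in run.coords)])
    surf = wham_free_energy(run, q, {"Q": np.linspace(0, 1, 51),
                                     "Q_beta5": np.linspace(0, 1, 26)},
                            target_T=350.0)
    surf.to_table().to_csv(OUT / "hd_free_energy_Q_Qbeta5.tsv", sep="\t",
                           index=False)
    print(f"HD F(Q, Q_beta5) at 350 K written "
          f"({np.isfinite(surf.free_energy).sum()} occupied bins); look for "
          "an intermediate basin at low Q_beta5 with high residual Q")
    return 0


if __name__ == "__main__":
    sys.exit(main())
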