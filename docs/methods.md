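# Methods

## Scope and model

The package studies force- and temperature-induced unfolding of the Notch1
negative regulatory region (NRR) — three protective LNR modules wrapped
around the heterodimerization (HD) domain — with a topology-based
coarse-grained model, and ships synthetic fixtures that reproduce the
fold's protector/protected architecture so the entire pipeline is testable
without the crystal structure.

### Energy function

One bead per residue at the C-alpha position; residue masses; calcium ions
as neutral beads of mass 40.08 amu and repulsive radius 2 Å.

* **Bonds**: virtual bonds between consecutive residues, fixed at native
  lengths by SHAKE (no energy term; the worst bond-length residual is
  reported with every energy evaluation).  The covalent connection across
  the excised S1 loop (author numbering 1622→1670 in the 3ETO construct)
  is a bond like any other and is deleted when the model is built with
  `break_s1`, which is required to observe heterodimer dissociation under
  load.
* **Angles**: harmonic in the angle, k = 20 kcal/mol/rad² (config-exposed),
  minima at native values.  Near-straight angles are handled by a floor on
  sin θ in the gradient; native angles are never exactly 180° for
  realistic (or realistically zigzagged synthetic) chains.
* **Pseudo-torsions**: native-structure-independent cosine series
  Σₙ Aₙ(1 + cos(nφ − δₙ)), n = 1..4, keyed by the Gly/Pro/other class of
  the central residue pair.  The class table
  (`data/dihedral_flavors.tsv`) is a labeled reconstruction — the original
  knowledge-based tables are not tabulated in any resource available to
  this package — with a uniform fallback for tests.  Its absolute scale is
  absorbed by the thermal calibration below.
* **Native contacts**: pairs |i−j| ≥ 4 with side-chain heavy atoms within
  4.5 Å, or a backbone N···O ≤ 3.5 Å with the C=O···N angle ≥ 90°
  (side-chain origin wins when both hold).  Potential
  ε[13x¹² − 18x¹⁰ + 4x⁶], x = r₀/r: minimum −ε at the native Cα distance
  r₀ and a low desolvation-style barrier (~0.01 ε) outside the well.
  Truncated and energy-shifted to zero at the 25 Å non-bonded cutoff.
* **Flavoring**: side-chain contact depths proportional to a pairwise
  weight table, normalized so their mean equals 1 energy unit before
  global calibration.  The shipped table (`data/contact_weights.tsv`) is
  the outer product of the Miyazawa per-residue contact-energy scale (as
  distributed in Biopython) — a standard one-parameter factorization of
  pairwise contact statistics, labeled as a reconstruction in the file
  header.  Only relative magnitudes matter downstream.  Backbone
  hydrogen-bond contacts get a uniform 1.0; calcium-coordination contacts
  get 2.0 kcal/mol.
* **Disulfides**: harmonic Cα–Cα restraints at native separation,
  k = 1.0 kcal/mol/Å².  **Ion tethers**: one weak restraint per retained
  ion to its closest coordinating residue, k = 0.1 kcal/mol/Å² ("weak":
  strong enough to prevent escape during hot or pulled trajectories,
  weak enough not to perturb coordination; the value is not dictated by
  anything and is config-exposed).
* **Non-native pairs**: purely repulsive ε_rep(σ/r)¹², ε_rep = 0.1
  kcal/mol, σ the mean of the bead radii (4.0 Å Cα, 2.0 Å Ca); only 1-2
  and 1-3 pairs are excluded.  Evaluated over a precomputed all-pairs
  list rather than a Verlet neighbor list — at a few hundred beads the
  O(N²) pass inside the compiled kernel is cheaper than list upkeep and
  cannot miss pairs.

Ions found in the structure are retained as model beads when they have at
least 4 coordinating oxygens (backbone O or Asp OD1/OD2 within 3.2 Å);
which crystal ions count as "bound" is otherwise ambiguous, and the choice
is logged.

### Thermal calibration

All flavored terms (contacts, angles, torsions) carry a single global
scale.  Because that scale multiplies the energy linearly, the melting
temperature is exactly proportional to it, so calibration iterates
`scale *= T_target/T_measured` with a replica-exchange/WHAM Tm estimator
until within tolerance — one iteration up to estimator noise.  Desk-scale
estimator settings (8 replicas spread exponentially over 150–550 K, 5 ps
exchange cycles, 250 cycles, first 20% discarded) have ~15 K seed-to-seed
noise on the 16-residue hairpin, so the shipped calibrations use a ±20 K
tolerance; all replicas start folded, because at these run lengths melting
equilibrates much faster than refolding (folded starts give the
lower-variance, slightly Tm-inflating estimate — the bias shrinks with
cycle count).  The production anchor for the NRR model is Tm = 350 K,
which makes it stably folded at 300 K.

### Dynamics

BAOAB Langevin splitting; SHAKE (Gauss–Seidel sweeps, absolute residual
tolerance 10⁻⁸ Å in-run, 500 sweep cap) after each position half-drift,
velocity projection (RATTLE) after every kick and thermostat substep.
γ = 0, T = 0 reduces exactly to velocity Verlet.  Defaults: 10 fs step,
γ = 0.1 ps⁻¹.  Units: kcal/mol, Å, ps, amu, K;
kB = 0.0019872041 kcal/mol/K; 1 kcal/(mol·Å) = 69.4786 pN.  Energy in
integrator units via 1 kcal/mol = 418.4 amu Å²/ps².  An instability guard
aborts any run in which a bead moves more than 1 Å in a single step.
Trajectories are bit-reproducible for a fixed seed on one platform; the
integrator statistics (NVE drift measured as the difference between early
and late mean total energy, equipartition with 3N − n_bonds degrees of
freedom, Ornstein–Uhlenbeck velocity-autocorrelation time 1/γ) are
verified in the test suite.

### Pulling

One virtual spring per terminal bead (default 1.0 kcal/mol/Å² ≈ 69.5
pN/Å — stiff-spring regime; the original instrument constant is unstated,
and peak heights do shift with stiffness and speed, so force magnitudes
are treated as protocol-dependent).  Anchors sit symmetrically about the
instantaneous midpoint along the instantaneous end-to-end axis and
separate at constant speed, which avoids net translation without
constraining rotation.  The reported force is the axial spring component
on the pulled bead averaged over each save interval.  Production mirrors
the published protocol (300 K, 1.0 Å/ns, 60 replicates); the desk-scale
preset (100–150 Å/ns, ~10 replicates) leans on the demonstrated
insensitivity of the unfolding pathway to pulling speed over 0.1–100 Å/ns.
Rupture order is quantified as the extension at which each monitored
contact subset first drops below half its native fraction (median over
replicates); subsets that never cross are "retained".

### Replica exchange and WHAM

Exponential temperature ladders (Tᵢ = Tmin·(Tmax/Tmin)^(i/(n−1)));
neighbor swaps over alternating even/odd pairs each cycle with acceptance
min(1, exp[(βᵢ − βⱼ)(Eᵢ − Eⱼ)]); velocities rescaled by √(T_new/T_old);
the per-cycle temperature multiset is asserted.  WHAM solves the standard
multi-temperature self-consistency on the sampled energies (log-sum-exp
throughout, residual tolerance 10⁻⁸ on the per-temperature free energies)
once, then reweights to any target temperature: free-energy surfaces over
one or two reaction coordinates (min-shifted to zero; empty bins reported
missing, not zero), folded-fraction melting curves (folded ≡ Q ≥ 0.5,
threshold config-exposed), Tm by linear interpolation of the 0.5 crossing
with a split-half uncertainty, and heat-capacity curves as an independent
Tm estimator.  A single-temperature input degenerates exactly to
−kT ln(histogram).

## Synthetic fixtures

The generators emulate the statistical structure the analysis assumes —
a stable native topology, designed detector targets, a shielded
"cleavage-strand" architecture — not NRR energetics:

* **Hairpin** (default 16 residues): two zigzagged antiparallel strands
  (3.8 Å Cα step, 1 Å zigzag so native angles are β-strand-like ~150°,
  5.6 Å strand separation); facing pairs are realized as side-chain
  contacts by pointing 1.5 Å pseudo-side-chain atoms at each other, with
  designed margins so the detectors recover exactly the planned pair list.
  Optional cysteine pairs place SG atoms exactly 2.05 Å apart along the
  pair axis; an optional calcium sits 2.4 Å from one backbone O.
* **Two-domain shielded sheet** (46 residues): a six-strand serpentine
  meander; strands 0–1 are the "protector", strand 2 the shielded
  terminal-strand analog, strands 3–5 the core.  Cross-strand contacts are
  designed backbone hydrogen bonds; interface well depths are graded
  (1.8 / 2.6 / 3.6 kcal/mol) so the fold is stable at 300 K and pulling
  the termini must rupture protector:core, then beta:core, then core:core.
  Geometric serial loading and the energetic grading force the same
  order, making the designed schedule a usable oracle for the
  rupture-order statistic.
* **Helix bundle**: two packed ideal helices, qualitative only.
* **Two-level benchmark**: folded level (E = 0, degeneracy g_f) and
  unfolded level (E = dE, degeneracy g_u) with exact
  Tm = dE/(k ln(g_u/g_f)), ΔF(T) and i.i.d. Boltzmann sampling — the
  closed-form oracle for WHAM, melting curves and calibration.

What passing on these fixtures does **not** show: quantitative NRR
energetics (peak heights in pN, absolute Tm transferability), crystal-
packing artifacts, or anything about real side-chain packing — the
fixtures validate mechanisms and bookkeeping, not Notch biology.  The
quantitative reproduction analyses require the 3ETO structure
(`analysis/05_nrr_reproduction.py`) and, at the published protocol sizes,
cluster-scale compute; the script runs a scaled preset (10 pulls at
100 Å/ns; ~10⁶-step equilibrium; 10³ REX cycles) and labels its outputs
accordingly.

## Problem sizes used in the shipped runs

Test-suite and acceptance-script simulations are desk-scale by design:
16–46-bead fixtures, 10⁴–3×10⁵-step trajectories, 8-replica ladders with
250–400 cycles, 8–10-replicate pulling ensembles.  These sizes were chosen
so each statistic resolves its oracle (e.g. Tm noise ~15 K, OU
autocorrelation fit within 15%, rupture order deterministic in ≥ 8/10
seeds) while any individual stage stays in the minutes range on one CPU.

## Known limitations

* The flavoring tables are reconstructions (see above); consequently
  per-contact energetics differ from the original builder's in detail,
  and only the calibrated ensemble behavior is comparable.
* Tm estimation from folded starts is biased upward at short run lengths;
  the calibration inherits that bias at desk scale.
* No electrostatics, no explicit solvent, no multi-chain complexes, no
  constant-force (clamp) pulling mode, no mmCIF input.
* Force peak heights depend on spring stiffness and pulling speed;
  cross-protocol comparisons should use positions and ordering, not
  absolute pN values.
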