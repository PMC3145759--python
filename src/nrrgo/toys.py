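"""Synthetic structures and analytic benchmarks.

Small single-chain structures with C-alpha + minimal backbone/side-chain
decoration, built so that the contact/disulfide/ion detectors recover an
exactly known plan, plus a discrete two-level system with a closed-form
partition function.  The two-domain fixture mimics the protector/protected
architecture of the Notch NRR fold (a "protector" subchain packing over the
terminal strand of a "core" subchain) so that pulling-order machinery can be
validated end to end without any real structure.

Geometry is deterministic given the spec; strands are ideal (3.8 A C-alpha
step, 5.6 A strand separation), with backbone O/N placed to realize
designed cross-strand hydrogen bonds and one pseudo side-chain atom per
residue placed either toward a designed partner or out of plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import KB
from .structure import ChainStructure, Residue, Ion

__all__ = ["ToySpec", "make_toy_structure", "make_two_domain_shielded",
           "make_two_state_benchmark", "TwoStateBenchmark"]

_SEQ_CYCLE = "AVLSTIEKFDNQMY"   # mixed composition for flavoring paths
_CLASH_LIMIT = 1.5              # A, any closer heavy-atom pair = infeasible


@dataclass
class ToySpec:
    n_residues: int = 16
    topology_kind: str = "hairpin"     # hairpin | helix_bundle | two_domain_shielded
    contact_plan: list | None = None   # [(i, j, epsilon)] internal indices
    cysteine_pairs: list = field(default_factory=list)
    ion_near_residue: int | None = None
    seed: int = 0
    start_resid: int = 1
    ca_step: float = 3.8
    strand_sep: float = 5.6

    def __post_init__(self):
        if self.contact_plan:
            for i, j, _e in self.contact_plan:
                if abs(i - j) < 4:
                    raise ValueError(f"planned contact ({i},{j}) violates |i-j| >= 4")


def _residue(idx: int, aa: str, ca: np.ndarray, atoms: list,
             start_resid: int) -> Residue:
    return Residue(start_resid + idx, aa, ca, [("CA", "C", ca)] + atoms, 10.0)


def _default_sequence(n: int, spec: ToySpec) -> list:
    seq = [_SEQ_CYCLE[i % len(_SEQ_CYCLE)] for i in range(n)]
    for i, j in spec.cysteine_pairs:
        seq[i] = seq[j] = "C"
    return seq


def _check_feasible(residues: list, ions: list):
    pts, owner = [], []
    for k, r in enumerate(residues):
        for _nm, _el, xyz in r.heavy_atoms:
            pts.append(xyz)
            owner.append(k)
    pts = np.array(pts)
    from scipy.spatial import cKDTree
    tree = cKDTree(pts)
    for a, b in tree.query_pairs(_CLASH_LIMIT):
        if abs(owner[a] - owner[b]) > 1:
            raise ValueError(
                f"infeasible toy plan: atoms of residues {owner[a]} and "
                f"{owner[b]} clash ({np.linalg.norm(pts[a]-pts[b]):.2f} A)")
    for ion in ions:
        d = np.min(np.linalg.norm(pts - ion.xyz, axis=1))
        if d < _CLASH_LIMIT:
            raise ValueError("infeasible toy plan: ion clashes with chain")


def _hairpin(spec: ToySpec):
    """Antiparallel two-strand hairpin; facing pairs (i, n-1-i) with
    |i-j| >= 4 are realized as side-chain contacts (pseudo side-chain atoms
    pointed at each other across the 5.6 A strand gap)."""
    n = spec.n_residues
    if n < 10 or n % 2:
        raise ValueError("hairpin needs an even n_residues >= 10")
    L = (n - 2) // 2
    a, D = spec.ca_step, spec.strand_sep
    seq = _default_sequence(n, spec)

    plan = spec.contact_plan
    if plan is None:
        plan = [(i, n - 1 - i, 1.0) for i in range(L) if (n - 1 - i) - i >= 4]
    planned = {}
    for i, j, e in plan:
        planned[min(i, j)] = (max(i, j), e)

    # strands zigzag in z (beta-strand-like virtual angles ~150 deg; exactly
    # straight strands would put native angles at 180 deg)
    zig = 1.0
    ca = np.zeros((n, 3))
    for i in range(L):
        ca[i] = (a * i, 0.0, zig * (i % 2))
    x_end = a * (L - 1)
    ca[L] = (x_end + 2.9, 0.28 * D, 1.6)
    ca[L + 1] = (x_end + 2.9, 0.72 * D, -1.6)
    for k in range(L + 2, n):
        ca[k] = (a * (n - 1 - k), D, zig * (k % 2))

    in_plan = set()
    for i, (j, _e) in planned.items():
        in_plan.add(i)
        in_plan.add(j)
    cys = {i for pair in spec.cysteine_pairs for i in pair}

    cys_partner = {}
    for i, j in spec.cysteine_pairs:
        cys_partner[i], cys_partner[j] = j, i

    residues = []
    for k in range(n):
        p = ca[k]
        atoms = [("N", "N", p + np.array([-1.2, 0.0, 0.35])),
                 ("C", "C", p + np.array([1.2, 0.0, 0.35])),
                 ("O", "O", p + np.array([1.4, 0.0, -0.9]))]
        toward = +1.0 if p[1] < D / 2 else -1.0   # unit +y for strand 1
        if k in cys:
            # SG on the line to the partner C-alpha, so the pair sits
            # exactly 2.05 A apart
            axis = ca[cys_partner[k]] - p
            d = np.linalg.norm(axis)
            atoms.append(("SG", "S", p + axis * ((d - 2.05) / (2 * d))))
        elif k in in_plan and k < L or (k in in_plan and k >= L + 2):
            atoms.append(("CB", "C", p + np.array([0.0, toward * 1.5, 0.0])))
        else:
            atoms.append(("CB", "C", p + np.array([0.0, 0.0, 2.0])))
        residues.append(_residue(k, seq[k], p, atoms, spec.start_resid))

    ions = []
    if spec.ion_near_residue is not None:
        o_xyz = residues[spec.ion_near_residue].atom("O")
        ions.append(Ion("Ca", o_xyz + np.array([0.0, 0.0, -2.4])))
    _check_feasible(residues, ions)
    s = ChainStructure(residues, ions, [])
    return s, [(i, j, e) for i, j, e in plan]


def _helix_bundle(spec: ToySpec):
    """Two packed ideal helices joined by a loop; qualitative fixture (the
    recovered contact plan is whatever the detector finds)."""
    n = spec.n_residues
    if n < 16:
        raise ValueError("helix bundle needs n_residues >= 16")
    L = (n - 3) // 2
    seq = _default_sequence(n, spec)
    ca = np.zeros((n, 3))
    axis_sep = 9.0
    for i in range(L):
        th = math.radians(100.0) * i
        ca[i] = (2.3 * math.cos(th), 2.3 * math.sin(th), 1.5 * i)
    zt = 1.5 * (L - 1)
    for k, frac in enumerate(((0.25, 2.0), (0.5, 3.0), (0.75, 2.0)), start=0):
        ca[L + k] = (axis_sep * frac[0], frac[1], zt + 2.0)
    for k in range(L + 3, n):
        i = k - (L + 3)
        th = math.radians(100.0) * i + math.pi
        ca[k] = (axis_sep + 2.3 * math.cos(th), 2.3 * math.sin(th), zt - 1.5 * i)
    residues = []
    for k in range(n):
        p = ca[k]
        # side chains point toward the other helix axis
        ax = axis_sep if k < L else 0.0
        d = np.array([ax - p[0], 0.0, 0.0])
        d = d / max(np.linalg.norm(d), 1e-9)
        atoms = [("N", "N", p + np.array([-0.8, 0.8, 0.5])),
                 ("C", "C", p + np.array([0.8, -0.8, 0.5])),
                 ("O", "O", p + np.array([0.9, -1.0, -0.7])),
                 ("CB", "C", p + d * 1.8)]
        residues.append(_residue(k, seq[k], p, atoms, spec.start_resid))
    _check_feasible(residues, [])
    return ChainStructure(residues, [], []), None


def make_toy_structure(spec: ToySpec):
    """Deterministic toy structure for the given spec.

    Returns ``(structure, contact_plan)``; the plan is the exact pair list
    (with designed well depths) that the contact builder recovers on the
    structure, or None for qualitative kinds.
    """
    if spec.topology_kind == "hairpin":
        return _hairpin(spec)
    if spec.topology_kind == "helix_bundle":
        return _helix_bundle(spec)
    if spec.topology_kind == "two_domain_shielded":
        s, info = make_two_domain_shielded(spec)
        return s, info["contact_plan"]
    raise ValueError(f"unknown topology_kind {spec.topology_kind!r}")


# strand roles in the two-domain fixture
_STRANDS = 6
_SLEN = 6
_TURN = 2


def make_two_domain_shielded(spec: ToySpec | None = None):
    """Serpentine six-strand sheet mimicking the NRR's protector/protected
    architecture.

    Strands 0-1 form the "protector", strand 2 the shielded terminal-strand
    analog ("beta"), strands 3-5 the "core".  Cross-strand contacts are
    realized as designed backbone hydrogen bonds; interface well depths are
    graded (protector:core weakest, core:core strongest) so that pulling the
    termini apart must rupture protector:core, then beta:core, then
    core:core, in that order.

    Returns ``(structure, info)`` where info carries the contact plan, the
    monitored subset definitions (author-resid range pairs) and the designed
    rupture order.
    """
    spec = spec or ToySpec(topology_kind="two_domain_shielded")
    n = _STRANDS * _SLEN + (_STRANDS - 1) * _TURN    # 46
    a, D = spec.ca_step, spec.strand_sep
    seq = _default_sequence(n, spec)

    def strand_of(idx):
        return idx // (_SLEN + _TURN), idx % (_SLEN + _TURN)

    zig = 1.0
    ca = np.zeros((n, 3))
    for idx in range(n):
        s, t = strand_of(idx)
        y = D * s
        if t < _SLEN:
            x = a * t if s % 2 == 0 else a * (_SLEN - 1) - a * t
            ca[idx] = (x, y, zig * (t % 2))
        else:   # two turn residues bulging past the strand end
            bulge = 3.2 if s % 2 == 0 else -3.2
            x0 = a * (_SLEN - 1) if s % 2 == 0 else 0.0
            frac = 0.3 if t == _SLEN else 0.7
            ca[idx] = (x0 + bulge, y + frac * D, 1.2 if t == _SLEN else -1.2)

    # designed cross-strand pairs: same-x residues of adjacent strands
    # graded so the fold is stable at 300 K and rupture order is forced:
    # protector interfaces weakest, core:core strongest
    iface_eps = {0: 1.8, 1: 1.8, 2: 2.6, 3: 3.6, 4: 3.6}
    if spec.contact_plan is not None:
        plan = list(spec.contact_plan)
    else:
        plan = []
        for s in range(_STRANDS - 1):
            for t in range(_SLEN):
                i = s * (_SLEN + _TURN) + t
                j = (s + 1) * (_SLEN + _TURN) + (_SLEN - 1 - t)
                if j - i >= 4:
                    plan.append((i, j, iface_eps[s]))

    residues = []
    for idx in range(n):
        s, t = strand_of(idx)
        p = ca[idx]
        dirx = 1.0 if s % 2 == 0 else -1.0
        atoms = [("N", "N", p + np.array([-1.0 * dirx, -1.0, 0.0])),
                 ("C", "C", p + np.array([1.0 * dirx, 0.4, 0.0])),
                 ("O", "O", p + np.array([1.0 * dirx, 1.55, 0.0])),
                 ("CB", "C", p + np.array([0.0, 0.0, 2.0 if idx % 2 else -2.0]))]
        residues.append(_residue(idx, seq[idx], p, atoms, spec.start_resid))

    ions = []
    if spec.ion_near_residue is not None:
        o_xyz = residues[spec.ion_near_residue].atom("O")
        ions.append(Ion("Ca", o_xyz + np.array([0.0, 0.0, 2.4])))
    _check_feasible(residues, ions)
    s0 = spec.start_resid
    blk = _SLEN + _TURN

    def rng(s_first, s_last):
        return (s0 + s_first * blk, s0 + min(s_last * blk + blk, n) - 1)

    subsets = {
        "protector:core": (rng(0, 1), rng(2, 5)),
        "beta:core": (rng(2, 2), rng(3, 5)),
        "core:core": (rng(3, 3), rng(4, 5)),
    }
    info = {
        "contact_plan": plan,
        "subsets": subsets,
        "expected_order": ["protector:core", "beta:core", "core:core"],
        "termini": (0, n - 1),
    }
    return ChainStructure(residues, ions, []), info


@dataclass
class TwoStateBenchmark:
    """Two-level system: folded level at E = 0 with degeneracy g_folded,
    unfolded at E = dE with degeneracy g_unfolded.

    Exact: folded fraction p_f(T) = g_f / (g_f + g_u e^{-dE/kT});
    Tm = dE / (k ln(g_u/g_f));  dF(T) = F_u - F_f = dE - kT ln(g_u/g_f)
    (positive below Tm).  ``sample`` draws i.i.d. Boltzmann configurations
    and reports (energy, Q) with Q = 1 for folded, 0 for unfolded.
    """
    dE: float
    g_folded: float
    g_unfolded: float
    energy_scale: float = 1.0   # calibration hook: scales dE
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.dE <= 0:
            raise ValueError("dE must be positive")
        if self.g_folded < 1 or self.g_unfolded < 1:
            raise ValueError("degeneracies must be >= 1")
        if self.g_unfolded <= self.g_folded:
            raise ValueError("no melting temperature exists for "
                             "g_unfolded <= g_folded")

    @property
    def effective_dE(self) -> float:
        return self.dE * self.energy_scale

    def tm(self) -> float:
        return self.effective_dE / (KB * math.log(self.g_unfolded / self.g_folded))

    def folded_fraction(self, T: float) -> float:
        w_u = self.g_unfolded * math.exp(-self.effective_dE / (KB * T))
        return self.g_folded / (self.g_folded + w_u)

    def delta_f(self, T: float) -> float:
        return self.effective_dE - KB * T * math.log(self.g_unfolded / self.g_folded)

    def sample(self, T: float, n: int, rng: np.random.Generator):
        p_f = self.folded_fraction(T)
        folded = rng.random(n) < p_f
        energies = np.where(folded, 0.0, self.effective_dE)
        q = folded.astype(float)
        return energies, q


def make_two_state_benchmark(dE: float, g_folded: float,
                             g_unfolded: float) -> TwoStateBenchmark:
    return TwoStateBenchmark(dE, g_folded, g_unfolded)
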