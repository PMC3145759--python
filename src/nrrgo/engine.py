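"""Langevin dynamics engine for coarse-grained topologies.

Public surface: :func:`compute_energy_forces`, :func:`apply_shake`,
:func:`langevin_step`, :func:`run_equilibrium`, plus the
:class:`SimState` / :class:`Trajectory` / :class:`EnergyReport` containers.

Integrator: BAOAB splitting with SHAKE applied after each position
half-drift and velocity projection (RATTLE) after each kick/thermostat
substep.  With friction gamma = 0 and T = 0 the scheme reduces to
velocity Verlet.  Defaults mirror the production protocol: 10 fs time
step, friction 0.1 ps^-1.  Non-bonded interactions are truncated (and
energy-shifted to zero) at the topology cutoff, 25 A by default.

Non-native pairs are evaluated with a precomputed all-pairs list rather
than a Verlet neighbor list: at a few hundred beads the O(N^2) pass
inside the compiled kernel is faster than list maintenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .constants import KB, KCAL_TO_MD
from .gomodel import CGTopology

logger = logging.getLogger("nrrgo.engine")

__all__ = ["SimState", "Trajectory", "EnergyReport", "pack_model",
           "compute_energy_forces", "apply_shake", "langevin_step",
           "run_equilibrium", "maxwell_velocities"]

_STATUS_MSG = {
    K.UNSTABLE: "instability guard tripped (per-step displacement > limit)",
    K.SHAKE_FAIL: "SHAKE/RATTLE failed to converge",
    K.SPRING_RUNAWAY: "pulling spring extension ran away",
    K.NONFINITE: "non-finite energy (bead overlap?)",
}


class EngineError(RuntimeError):
    pass


@dataclass
class SimState:
    coords: np.ndarray             # (n,3) A
    velocities: np.ndarray         # (n,3) A/ps
    time: float = 0.0              # ps
    seed: int = 0
    step: int = 0

    def __post_init__(self):
        if not (np.isfinite(self.coords).all() and np.isfinite(self.velocities).all()):
            raise ValueError("non-finite state")
        if self.coords.shape != self.velocities.shape:
            raise ValueError("coords/velocities shape mismatch")


@dataclass
class Trajectory:
    times: np.ndarray              # (m,) ps, strictly increasing
    frames: np.ndarray             # (m, n, 3) A
    velocities: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.times) != len(self.frames):
            raise ValueError("times/frames length mismatch")
        if len(self.times) > 1 and not (np.diff(self.times) > 0).all():
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def write_xyz(self, path, labels=None):
        n = self.frames.shape[1]
        labels = labels or (["CA"] * n)
        with open(path, "w") as fh:
            for t, fr in zip(self.times, self.frames):
                fh.write(f"{n}\nt= {t:.3f} ps\n")
                for lab, (x, y, z) in zip(labels, fr):
                    fh.write(f"{lab} {x:.4f} {y:.4f} {z:.4f}\n")

    def write_pdb(self, path):
        """Multi-model C-alpha-only PDB trace."""
        with open(path, "w") as fh:
            for m, fr in enumerate(self.frames, start=1):
                fh.write(f"MODEL     {m:4d}\n")
                for i, (x, y, z) in enumerate(fr, start=1):
                    fh.write(f"ATOM  {i:5d}  CA  GLY A{i:4d}    "
                             f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n")
                fh.write("ENDMDL\n")


@dataclass
class EnergyReport:
    constraint_residual: float     # A, max |bond - native|
    angle: float
    dihedral: float
    contact: float
    repulsion: float
    restraint: float

    @property
    def total(self) -> float:
        return self.angle + self.dihedral + self.contact + self.repulsion + self.restraint


def pack_model(top: CGTopology) -> tuple:
    """Flatten a CGTopology into the plain arrays the kernels take.

    The global energy scale is baked into contact, angle and dihedral
    amplitudes here (restraints and repulsion stay absolute).
    """
    s = top.energy_scale
    bi = np.array([b[0] for b in top.bonds], dtype=np.int64)
    bj = np.array([b[1] for b in top.bonds], dtype=np.int64)
    br0 = np.array([b[2] for b in top.bonds], dtype=np.float64)

    ai = np.array([a[0] for a in top.angles], dtype=np.int64)
    aj = np.array([a[1] for a in top.angles], dtype=np.int64)
    ak = np.array([a[2] for a in top.angles], dtype=np.int64)
    at0 = np.array([a[3] for a in top.angles], dtype=np.float64)
    akk = s * np.array([a[4] for a in top.angles], dtype=np.float64)

    di = np.array([d[0] for d in top.dihedrals], dtype=np.int64)
    dj = np.array([d[1] for d in top.dihedrals], dtype=np.int64)
    dk = np.array([d[2] for d in top.dihedrals], dtype=np.int64)
    dl = np.array([d[3] for d in top.dihedrals], dtype=np.int64)
    damp = s * np.array([d[4] for d in top.dihedrals], dtype=np.float64).reshape(-1, 4)
    ddel = np.array([d[5] for d in top.dihedrals], dtype=np.float64).reshape(-1, 4)

    ci = np.array([c.bead_i for c in top.contacts], dtype=np.int64)
    cj = np.array([c.bead_j for c in top.contacts], dtype=np.int64)
    cr0 = np.array([c.r_native for c in top.contacts], dtype=np.float64)
    ceps = s * np.array([c.epsilon for c in top.contacts], dtype=np.float64)
    y = cr0 / top.cutoff
    cshift = ceps * (13.0 * y ** 12 - 18.0 * y ** 10 + 4.0 * y ** 6)

    # non-native repulsive pairs: everything not excluded, not a contact
    n = top.n_beads
    excl = top.exclusions()
    cpairs = {(min(c.bead_i, c.bead_j), max(c.bead_i, c.bead_j))
              for c in top.contacts}
    rad = np.asarray(top.repulsive_radii, dtype=np.float64)
    rlist = [(i, j) for i in range(n) for j in range(i + 1, n)
             if (i, j) not in excl and (i, j) not in cpairs]
    ri = np.array([p[0] for p in rlist], dtype=np.int64)
    rj = np.array([p[1] for p in rlist], dtype=np.int64)
    rsig = 0.5 * (rad[ri] + rad[rj]) if len(rlist) else np.empty(0)
    rshift = top.repulsion_epsilon * (rsig / top.cutoff) ** 12 \
        if len(rlist) else np.empty(0)

    hi = np.array([h[0] for h in top.harmonic_restraints], dtype=np.int64)
    hj = np.array([h[1] for h in top.harmonic_restraints], dtype=np.int64)
    hr0 = np.array([h[2] for h in top.harmonic_restraints], dtype=np.float64)
    hk = np.array([h[3] for h in top.harmonic_restraints], dtype=np.float64)

    masses = np.asarray(top.masses, dtype=np.float64)
    return (masses, 1.0 / masses,
            bi, bj, br0,
            ai, aj, ak, at0, akk,
            di, dj, dk, dl, damp, ddel,
            ci, cj, cr0, ceps, cshift,
            ri, rj, np.asarray(rsig, dtype=np.float64),
            float(top.repulsion_epsilon), np.asarray(rshift, dtype=np.float64),
            hi, hj, hr0, hk,
            float(top.cutoff) ** 2)


def _force_args(p):
    (_m, _im, _bi, _bj, _br0, ai, aj, ak, at0, akk, di, dj, dk, dl, damp,
     ddel, ci, cj, cr0, ceps, cshift, ri, rj, rsig, rep_eps, rshift,
     hi, hj, hr0, hk, cutoff2) = p
    return (ai, aj, ak, at0, akk, di, dj, dk, dl, damp, ddel,
            ci, cj, cr0, ceps, cshift, ri, rj, rsig, rep_eps, rshift,
            hi, hj, hr0, hk, cutoff2)


def compute_energy_forces(top: CGTopology, coords: np.ndarray,
                          packed: tuple | None = None):
    """Energy components and exact-negative-gradient forces (kcal/mol/A)."""
    coords = np.ascontiguousarray(coords, dtype=np.float64)
    if not np.isfinite(coords).all():
        raise ValueError("non-finite coordinates")
    p = packed if packed is not None else pack_model(top)
    f = np.zeros_like(coords)
    ea, ed, ec, er, eh = K.energy_forces(coords, f, *_force_args(p))
    tot = ea + ed + ec + er + eh
    if not np.isfinite(tot):
        raise EngineError("non-finite energy (overlapping beads?)")
    resid = K.max_bond_residual(coords, p[2], p[3], p[4])
    return EnergyReport(resid, ea, ed, ec, er, eh), f


def apply_shake(top: CGTopology, coords_ref: np.ndarray, coords_new: np.ndarray,
                tol: float = 1e-6, max_iter: int = 500,
                packed: tuple | None = None) -> np.ndarray:
    """Return ``coords_new`` projected so every virtual bond has its native
    length within ``tol`` (A)."""
    if tol <= 0:
        raise ValueError("tol must be positive")
    p = packed if packed is not None else pack_model(top)
    out = np.array(coords_new, dtype=np.float64, copy=True)
    ref = np.ascontiguousarray(coords_ref, dtype=np.float64)
    it = K.shake(out, ref, p[2], p[3], p[4], p[1], tol, max_iter)
    if it < 0:
        raise EngineError(f"SHAKE did not converge in {max_iter} iterations")
    logger.debug("SHAKE converged in %d sweeps", it)
    return out


def maxwell_velocities(top: CGTopology, T: float, rng: np.random.Generator,
                       packed: tuple | None = None) -> np.ndarray:
    """Maxwell-Boltzmann draw, RATTLE-projected onto the bond constraints."""
    p = packed if packed is not None else pack_model(top)
    n = top.n_beads
    if T <= 0:
        return np.zeros((n, 3))
    sig = np.sqrt(KB * T * KCAL_TO_MD / np.asarray(top.masses))
    v = rng.standard_normal((n, 3)) * sig[:, None]
    x = np.ascontiguousarray(top.native_coords, dtype=np.float64)
    K.rattle(v, x, p[2], p[3], p[4], p[1], 1e-10, 500)
    return v


def _run(top, state, n_steps, save_every, dt, gamma, T,
         packed=None, save_velocities=False, pull=None,
         shake_tol=1e-8, shake_maxiter=500, guard=1.0):
    """Shared driver for equilibrium and pulling runs; returns raw arrays."""
    p = packed if packed is not None else pack_model(top)
    masses, invm, bi, bj, br0 = p[0], p[1], p[2], p[3], p[4]
    x = np.array(state.coords, dtype=np.float64, copy=True)
    v = np.array(state.velocities, dtype=np.float64, copy=True)
    n = top.n_beads
    nfr = 1 + (n_steps // save_every if save_every > 0 else 0)
    frames = np.zeros((nfr, n, 3))
    vel_frames = np.zeros((nfr, n, 3) if save_velocities else (1, n, 3))
    times = np.zeros(nfr)
    exts = np.zeros(nfr)
    pforces = np.zeros(nfr)
    e_series = np.zeros((nfr, 6))
    if pull is None:
        pull_args = (0, 0, 0, 0.0, 0.0, 0.0, np.inf, 20.0)
    else:
        pull_args = pull
    kT_md = KB * max(T, 0.0) * KCAL_TO_MD
    status, nw, bad, steps = K.run_md(
        x, v, invm, masses, dt, gamma, kT_md, n_steps,
        max(save_every, 1), int(state.seed) & 0x7FFFFFFF,
        bi, bj, br0, *_force_args(p),
        shake_tol, shake_maxiter, guard,
        *pull_args,
        frames, vel_frames, 1 if save_velocities else 0,
        times, exts, pforces, e_series)
    if status not in (K.OK,):
        raise EngineError(f"{_STATUS_MSG.get(status, status)} at step {steps}"
                          + (f" (bead {bad})" if bad >= 0 else ""))
    return (x, v, frames[:nw], vel_frames[:nw] if save_velocities else None,
            times[:nw], exts[:nw], pforces[:nw], e_series[:nw], steps)


def langevin_step(top: CGTopology, state: SimState, dt: float, gamma: float,
                  T: float, packed: tuple | None = None) -> SimState:
    """One BAOAB step.  gamma = 0, T = 0 is a velocity-Verlet step."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if gamma < 0 or T < 0:
        raise ValueError("gamma and T must be non-negative")
    sub = SimState(state.coords, state.velocities, state.time,
                   seed=(state.seed * 2654435761 + state.step + 1) % (2 ** 31),
                   step=0)
    x, v, *_ = _run(top, sub, 1, 1, dt, gamma, T, packed=packed)
    return SimState(x, v, state.time + dt, state.seed, state.step + 1)


def run_equilibrium(top: CGTopology, T: float, n_steps: int, save_every: int,
                    seed: int, coords0: np.ndarray | None = None,
                    velocities0: np.ndarray | None = None,
                    dt: float = 0.01, gamma: float = 0.1,
                    save_velocities: bool = False,
                    packed: tuple | None = None,
                    return_state: bool = False):
    """Equilibrium Langevin run; reproducible for a fixed seed.

    ``n_steps = 0`` returns a single-frame trajectory of the input coords.
    """
    packed = packed if packed is not None else pack_model(top)
    x0 = top.native_coords if coords0 is None else coords0
    if velocities0 is None:
        rng = np.random.default_rng(seed)
        v0 = maxwell_velocities(top, T, rng, packed=packed)
    else:
        v0 = velocities0
    state = SimState(np.asarray(x0, float), np.asarray(v0, float), 0.0,
                     seed=seed)
    if n_steps == 0:
        traj = Trajectory(np.zeros(1), np.asarray(x0, float)[None, :, :],
                          metadata={"temperature": T, "seed": seed,
                                    "protocol": "equilibrium",
                                    "save_every": save_every, "dt": dt,
                                    "gamma": gamma})
        return (traj, state) if return_state else traj
    x, v, frames, vels, times, _exts, _pf, e_series, steps = _run(
        top, state, n_steps, save_every, dt, gamma, T, packed=packed,
        save_velocities=save_velocities)
    meta = {"temperature": T, "seed": seed, "protocol": "equilibrium",
            "save_every": save_every, "dt": dt, "gamma": gamma,
            "energy_series": e_series}
    traj = Trajectory(times, frames, velocities=vels, metadata=meta)
    if return_state:
        return traj, SimState(x, v, times[-1], seed=seed, step=steps)
    return traj
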