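"""Temperature replica exchange and multi-histogram (WHAM) reweighting.

Replicas run Langevin segments at the rungs of an exponentially spaced
temperature ladder; neighbor swaps are attempted after every segment with
the Metropolis criterion min(1, exp[(1/kT_i - 1/kT_j)(E_i - E_j)]) over
alternating even/odd pairs, rescaling velocities by sqrt(T_new/T_old) on
acceptance.  WHAM combines the per-temperature samples into free-energy
surfaces over one or two reaction coordinates at any target temperature,
a folded-fraction melting curve, and a Tm estimate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .constants import KB
from .engine import SimState, pack_model, maxwell_velocities, _run
from .observables import ContactSubsets

logger = logging.getLogger("nrrgo.remd")

__all__ = ["TemperatureLadder", "ReplicaRun", "FreeEnergySurface",
           "make_temperature_ladder", "attempt_exchange", "run_remd",
           "wham_free_energy", "melting_curve", "heat_capacity_curve",
           "remd_tm_estimator"]


@dataclass
class TemperatureLadder:
    temperatures: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.temperatures, dtype=float)
        if len(t) < 2 or not (np.diff(t) > 0).all():
            raise ValueError("ladder must be >= 2 strictly increasing temperatures")
        self.temperatures = t

    def __len__(self):
        return len(self.temperatures)


def make_temperature_ladder(t_min: float, t_max: float, n: int) -> TemperatureLadder:
    """Exponential (geometric) spacing: T_i = t_min (t_max/t_min)^(i/(n-1))."""
    if not (t_max > t_min > 0):
        raise ValueError("need t_max > t_min > 0")
    if n < 2:
        raise ValueError("need n >= 2")
    i = np.arange(n)
    return TemperatureLadder(t_min * (t_max / t_min) ** (i / (n - 1)))


def attempt_exchange(e_i: float, t_i: float, e_j: float, t_j: float,
                     rng: np.random.Generator) -> bool:
    """Metropolis temperature-swap decision for one neighbor pair."""
    delta = (1.0 / (KB * t_i) - 1.0 / (KB * t_j)) * (e_i - e_j)
    if delta >= 0:
        return True
    return rng.random() < math.exp(delta)


@dataclass
class ReplicaRun:
    ladder: TemperatureLadder
    records: pd.DataFrame          # cycle, replica, temperature, energy
    coords: np.ndarray             # (n_samples, n_beads, 3) aligned with records
    exchange_log: pd.DataFrame     # cycle, pair_low_rung, accepted
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        lad = np.sort(self.ladder.temperatures)
        for cyc, grp in self.records.groupby("cycle"):
            if not np.allclose(np.sort(grp["temperature"].to_numpy()), lad):
                raise ValueError(f"temperature multiset broken at cycle {cyc}")

    def acceptance_rate(self) -> float:
        if len(self.exchange_log) == 0:
            return float("nan")
        return float(self.exchange_log["accepted"].mean())


def run_remd(top, ladder: TemperatureLadder, cycle_ps: float, n_cycles: int,
             seed: int, coords0=None, dt: float = 0.01, gamma: float = 0.1,
             packed=None) -> ReplicaRun:
    """Replica-exchange run: alternating dynamics segments of ``cycle_ps``
    and neighbor-swap sweeps (even pairs on even cycles, odd on odd).

    One potential-energy/coordinate sample is recorded per replica per
    cycle (at segment end).  ``n_cycles = 0`` returns the initial states
    with an empty exchange log.
    """
    packed = packed if packed is not None else pack_model(top)
    temps = ladder.temperatures
    R = len(temps)
    rng = np.random.default_rng(seed)
    n = top.n_beads
    x0 = np.asarray(top.native_coords if coords0 is None else coords0, float)
    states = []
    rep_temp = np.arange(R)        # replica -> rung index
    for r in range(R):
        xr = x0 if x0.ndim == 2 else x0[r]
        v = maxwell_velocities(top, temps[r], rng, packed=packed)
        states.append(SimState(np.array(xr), v, 0.0,
                               seed=int(rng.integers(2 ** 31))))
    steps_per_cycle = max(int(round(cycle_ps / dt)), 1)

    rec_rows, xch_rows, snap = [], [], []
    if n_cycles == 0:
        for r in range(R):
            rec_rows.append({"cycle": 0, "replica": r,
                             "temperature": temps[rep_temp[r]],
                             "energy": float("nan")})
            snap.append(states[r].coords)
        return ReplicaRun(ladder, pd.DataFrame(rec_rows), np.array(snap),
                          pd.DataFrame(columns=["cycle", "pair_low_rung",
                                                "accepted"]),
                          {"cycle_ps": cycle_ps, "seed": seed})

    energies = np.zeros(R)
    for cyc in range(n_cycles):
        for r in range(R):
            T_r = temps[rep_temp[r]]
            sub = SimState(states[r].coords, states[r].velocities, 0.0,
                           seed=int(rng.integers(2 ** 31)))
            try:
                x, v, _fr, _vf, _t, _e, _p, e_series, _s = _run(
                    top, sub, steps_per_cycle, steps_per_cycle, dt, gamma,
                    T_r, packed=packed)
            except Exception as exc:
                raise RuntimeError(f"replica {r} (rung {rep_temp[r]}) failed "
                                   f"at cycle {cyc}: {exc}") from exc
            states[r] = SimState(x, v, 0.0, seed=states[r].seed)
            energies[r] = e_series[-1, :5].sum()
            rec_rows.append({"cycle": cyc, "replica": r,
                             "temperature": T_r, "energy": energies[r]})
            snap.append(np.array(x))
        # exchange sweep over alternating neighbor pairs of the ladder
        start = cyc % 2
        rung_to_rep = np.empty(R, dtype=int)
        rung_to_rep[rep_temp] = np.arange(R)
        for k in range(start, R - 1, 2):
            ri, rj = rung_to_rep[k], rung_to_rep[k + 1]
            acc = attempt_exchange(energies[ri], temps[k],
                                   energies[rj], temps[k + 1], rng)
            xch_rows.append({"cycle": cyc, "pair_low_rung": k,
                             "accepted": acc})
            if acc:
                rep_temp[ri], rep_temp[rj] = k + 1, k
                fac_i = math.sqrt(temps[k + 1] / temps[k])
                states[ri].velocities *= fac_i
                states[rj].velocities /= fac_i
    run = ReplicaRun(ladder, pd.DataFrame(rec_rows), np.array(snap),
                     pd.DataFrame(xch_rows),
                     {"cycle_ps": cycle_ps, "n_cycles": n_cycles,
                      "seed": seed, "dt": dt, "gamma": gamma})
    logger.info("REMD: %d cycles, exchange acceptance %.2f",
                n_cycles, run.acceptance_rate())
    return run


@dataclass
class FreeEnergySurface:
    axes: dict                     # name -> bin edges
    free_energy: np.ndarray        # kcal/mol, min-shifted to 0; NaN = empty
    occupancy: np.ndarray          # unweighted sample counts per bin
    temperature: float
    wham_iterations: int
    converged: bool

    def __post_init__(self):
        finite = np.isfinite(self.free_energy)
        if finite.any():
            if (self.occupancy[finite] <= 0).any():
                raise ValueError("finite bin with zero occupancy")
            if abs(np.nanmin(self.free_energy)) > 1e-9:
                raise ValueError("minimum not shifted to zero")

    def to_table(self) -> pd.DataFrame:
        names = list(self.axes)
        centers = [0.5 * (e[:-1] + e[1:]) for e in self.axes.values()]
        if len(names) == 1:
            return pd.DataFrame({names[0]: centers[0],
                                 "free_energy_kcal": self.free_energy,
                                 "occupancy": self.occupancy})
        g0, g1 = np.meshgrid(centers[0], centers[1], indexing="ij")
        return pd.DataFrame({names[0]: g0.ravel(), names[1]: g1.ravel(),
                             "free_energy_kcal": self.free_energy.ravel(),
                             "occupancy": self.occupancy.ravel()})


class _WhamSolution:
    """Converged WHAM self-consistency state, reusable for reweighting to
    any target temperature."""

    def __init__(self, energies, sample_temps, tol, max_iter):
        self.energies = np.asarray(energies, dtype=float)
        temps = np.asarray(sample_temps, dtype=float)
        self.uniq = np.unique(temps)
        betas = 1.0 / (KB * self.uniq)
        counts = np.array([(temps == t).sum() for t in self.uniq], dtype=float)
        f = np.zeros(len(self.uniq))               # dimensionless free energies
        bE = betas[None, :] * self.energies[:, None]    # (S, K)
        logN = np.log(counts)
        it, resid = 0, np.inf
        for it in range(1, max_iter + 1):
            # log denominator per sample: ln sum_l N_l exp(f_l - beta_l E_s)
            logden = logsumexp(logN[None, :] + f[None, :] - bE, axis=1)
            newf = -logsumexp(-bE.T - logden[None, :], axis=1)
            newf = newf - newf[0]
            resid = float(np.max(np.abs(newf - f)))
            f = newf
            if resid < tol:
                break
        self.iterations = it
        self.residual = resid
        self.converged = resid < tol
        self._logden = logsumexp(logN[None, :] + f[None, :] - bE, axis=1)

    def log_weights(self, target_T):
        return -self.energies / (KB * target_T) - self._logden

    def weights(self, target_T):
        logw = self.log_weights(target_T)
        w = np.exp(logw - logw.max())
        return w / w.sum()


def _wham_log_weights(energies, sample_temps, target_T, tol, max_iter):
    """Back-compat shim: returns (log-weights at target_T, iterations,
    converged, final residual)."""
    sol = _WhamSolution(energies, sample_temps, tol, max_iter)
    return sol.log_weights(target_T), sol.iterations, sol.converged, sol.residual


def wham_free_energy(run, coords_values, bins, target_T: float,
                     tol: float = 1e-8, max_iter: int = 100000,
                     discard_fraction: float = 0.2,
                     energies=None, sample_temps=None) -> FreeEnergySurface:
    """Free-energy surface over one or two reaction coordinates at
    ``target_T`` from multi-temperature samples.

    ``run`` may be a :class:`ReplicaRun` (its records supply energies and
    sampling temperatures; the first ``discard_fraction`` of cycles is
    dropped as equilibration) or None with ``energies``/``sample_temps``
    given explicitly.  ``coords_values`` is (S,) or (S, 2) aligned with the
    samples; ``bins`` a dict name -> bin edge array.

    Raises on non-convergence.  With a single sampling temperature the
    result reduces to -kT ln(histogram) + const.
    """
    if run is not None:
        rec = run.records
        ncyc = int(rec["cycle"].max()) + 1
        keep = rec["cycle"] >= int(math.floor(ncyc * discard_fraction))
        energies = rec.loc[keep, "energy"].to_numpy()
        sample_temps = rec.loc[keep, "temperature"].to_numpy()
        coords_values = np.asarray(coords_values)[keep.to_numpy()]
    else:
        energies = np.asarray(energies, dtype=float)
        sample_temps = np.asarray(sample_temps, dtype=float)
        coords_values = np.asarray(coords_values)
    logw, iters, converged, resid = _wham_log_weights(
        energies, sample_temps, target_T, tol, max_iter)
    if not converged:
        raise RuntimeError(f"WHAM did not converge in {max_iter} iterations "
                           f"(last residual {resid:.2e})")
    w = np.exp(logw - logw.max())
    w /= w.sum()

    vals = np.atleast_2d(np.asarray(coords_values, dtype=float).T).T
    names = list(bins)
    edges = [np.asarray(bins[nm], dtype=float) for nm in names]
    if vals.shape[1] != len(names):
        raise ValueError("coords_values/bins dimensionality mismatch")
    hist_w, _ = np.histogramdd(vals, bins=edges, weights=w)
    hist_n, _ = np.histogramdd(vals, bins=edges)
    with np.errstate(divide="ignore"):
        fe = -KB * target_T * np.log(hist_w)
    fe[hist_n == 0] = np.nan
    fe = fe - np.nanmin(fe)
    if len(names) == 1:
        fe, hist_n = fe.ravel(), hist_n.ravel()
    return FreeEnergySurface({nm: e for nm, e in zip(names, edges)},
                             fe, hist_n, target_T, iters, converged)


def melting_curve(energies, sample_temps, q_values, t_grid,
                  q_threshold: float = 0.5, tol: float = 1e-8,
                  max_iter: int = 100000):
    """Folded fraction (Q >= threshold) versus temperature by WHAM
    reweighting, plus the Tm where it crosses 0.5.

    Returns (DataFrame[T_K, folded_fraction], tm, tm_uncertainty); the
    uncertainty is the spread between the estimates from the two halves of
    the samples.  Tm is NaN when the curve never crosses 0.5 inside the grid.
    """
    energies = np.asarray(energies, dtype=float)
    sample_temps = np.asarray(sample_temps, dtype=float)
    folded = np.asarray(q_values, dtype=float) >= q_threshold

    def curve(e, st, fl):
        sol = _WhamSolution(e, st, tol, max_iter)
        if not sol.converged:
            raise RuntimeError(
                f"WHAM did not converge (residual {sol.residual:.2e})")
        return np.array([float(sol.weights(T)[fl].sum()) for T in t_grid])

    def crossing(fr):
        below = np.nonzero(fr < 0.5)[0]
        above = np.nonzero(fr >= 0.5)[0]
        if len(below) == 0 or len(above) == 0:
            return float("nan")
        k = below[0]
        if k == 0:
            return float(t_grid[0])
        t0, t1 = t_grid[k - 1], t_grid[k]
        f0, f1 = fr[k - 1], fr[k]
        return float(t0 + (0.5 - f0) * (t1 - t0) / (f1 - f0))

    fr = curve(energies, sample_temps, folded)
    tm = crossing(fr)
    half = len(energies) // 2
    tms = []
    for sl in (slice(0, half), slice(half, None)):
        try:
            tms.append(crossing(curve(energies[sl], sample_temps[sl],
                                      folded[sl])))
        except RuntimeError:
            pass
    tms = [t for t in tms if np.isfinite(t)]
    err = float(max(abs(t - tm) for t in tms)) if tms else float("nan")
    df = pd.DataFrame({"T_K": np.asarray(t_grid, dtype=float),
                       "folded_fraction": fr})
    return df, tm, err


def heat_capacity_curve(energies, sample_temps, t_grid, tol: float = 1e-8,
                        max_iter: int = 100000) -> pd.DataFrame:
    """Heat capacity Cv(T) = (<E^2> - <E>^2) / (k T^2) by WHAM reweighting;
    its peak is an independent melting-temperature estimator."""
    energies = np.asarray(energies, dtype=float)
    sol = _WhamSolution(energies, sample_temps, tol, max_iter)
    if not sol.converged:
        raise RuntimeError(f"WHAM did not converge (residual {sol.residual:.2e})")
    rows = []
    for T in t_grid:
        w = sol.weights(T)
        e1 = float(np.dot(w, energies))
        e2 = float(np.dot(w, energies ** 2))
        rows.append({"T_K": float(T), "Cv": (e2 - e1 * e1) / (KB * T * T)})
    return pd.DataFrame(rows)


def remd_tm_estimator(ladder: TemperatureLadder, cycle_ps: float,
                      n_cycles: int, seed: int, subsets=None,
                      q_threshold: float = 0.5, t_grid=None,
                      discard_fraction: float = 0.2, dt: float = 0.01,
                      mixed_start: bool = False):
    """Build a ``tm_estimator(topology) -> (tm, err)`` closure for
    :func:`nrrgo.gomodel.calibrate_energy_scale`.

    Runs replica exchange on the topology, computes per-sample Q, and reads
    Tm off the WHAM melting curve.  All replicas start folded by default
    (melting equilibrates much faster than refolding at desk-scale run
    lengths, so folded starts give the lower-variance estimate; the
    residual bias is upward and shrinks with n_cycles).  With
    ``mixed_start`` the upper half of the ladder instead starts from a
    heat-denatured configuration, which improves overlap when refolding is
    fast enough.
    """
    if t_grid is None:
        t_grid = np.linspace(ladder.temperatures[0],
                             ladder.temperatures[-1], 101)

    def estimator(top):
        packed = pack_model(top)
        x0 = np.asarray(top.native_coords, dtype=float)
        starts = np.repeat(x0[None], len(ladder), axis=0)
        if mixed_start:
            from .engine import run_equilibrium
            hot = run_equilibrium(top, float(ladder.temperatures[-1] * 2.0),
                                  4000, 4000, seed + 17, packed=packed)
            for r in range(len(ladder) // 2, len(ladder)):
                starts[r] = hot.frames[-1]
        run = run_remd(top, ladder, cycle_ps, n_cycles, seed,
                       coords0=starts, dt=dt, packed=packed)
        cs = ContactSubsets(top.contacts, top.author_resids)
        q = np.array([cs.fractions(c)["Q_total"] for c in run.coords])
        ncyc = int(run.records["cycle"].max()) + 1
        keep = (run.records["cycle"] >= int(ncyc * discard_fraction)).to_numpy()
        _df, tm, err = melting_curve(run.records["energy"].to_numpy()[keep],
                                     run.records["temperature"].to_numpy()[keep],
                                     q[keep], t_grid, q_threshold)
        if math.isnan(tm):
            fr_ends = _df["folded_fraction"].iloc[[0, -1]].to_numpy()
            raise RuntimeError(
                f"melting curve never crosses 0.5 inside the ladder "
                f"(folded fraction {fr_ends[0]:.2f} -> {fr_ends[1]:.2f})")
        return tm, err

    return estimator
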