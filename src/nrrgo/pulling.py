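"""Constant-velocity steered dynamics (virtual-spring pulling on the
terminal beads), force-extension bookkeeping, force-peak detection and
rupture-order statistics.

Pulling geometry: one spring on each terminal bead; the two anchor points
sit symmetrically about the instantaneous midpoint along the instantaneous
terminal-terminal axis and separate at the protocol speed.  The recorded
applied force is the axial spring-force component on the pulled bead,
averaged over each save interval and reported in pN
(1 kcal/mol/A = 69.4786 pN).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .constants import PN_PER_KCAL_MOL_A
from .engine import SimState, Trajectory, pack_model, maxwell_velocities, _run
from .gomodel import CGTopology
from .observables import ContactSubsets

logger = logging.getLogger("nrrgo.pulling")

__all__ = ["PullProtocol", "run_smd", "average_force_profile",
           "detect_force_peaks", "unfolding_order"]


@dataclass
class PullProtocol:
    speed: float = 1.0                 # A/ns
    spring_k: float = 1.0              # kcal/mol/A^2 (~69.5 pN/A)
    attachment: tuple = (0, -1)        # (bead_N, bead_C); -1 = last protein bead
    max_extension: float = 150.0       # A, end-to-end stop
    seed: int = 0
    save_every: int = 100              # steps
    dt: float = 0.01                   # ps
    gamma: float = 0.1                 # 1/ps
    spring_runaway: float = 20.0       # A, per-spring extension error bound

    def __post_init__(self):
        if self.speed <= 0 or self.spring_k <= 0:
            raise ValueError("speed and spring_k must be positive")


def run_smd(top: CGTopology, protocol: PullProtocol, T: float = 300.0,
            coords0: np.ndarray | None = None, subsets: dict | None = None,
            packed=None):
    """One constant-velocity pulling run.

    Returns ``(Trajectory, records)`` where records is a DataFrame with
    time_ps, end_to_end_A, force_pN and (when ``subsets`` given) per-subset
    native fractions evaluated on the saved frames.
    """
    packed = packed if packed is not None else pack_model(top)
    if top.chain_break is None and {1622, 1670} <= set(top.author_resids.tolist()):
        logger.warning("pulling a heterodimer-capable chain without the S1 "
                       "break; dissociation cannot be observed")
    n_prot = int((top.author_resids >= 0).sum())
    bead_n, bead_c = protocol.attachment
    bead_n = bead_n % n_prot
    bead_c = bead_c % n_prot
    x0 = np.asarray(top.native_coords if coords0 is None else coords0, float)
    d0 = float(np.linalg.norm(x0[bead_c] - x0[bead_n]))
    speed_ps = protocol.speed / 1000.0          # A/ns -> A/ps
    n_steps = int(math.ceil((protocol.max_extension - d0 + 5.0)
                            / (speed_ps * protocol.dt)))
    rng = np.random.default_rng(protocol.seed)
    v0 = maxwell_velocities(top, T, rng, packed=packed)
    state = SimState(x0, v0, 0.0, seed=protocol.seed)
    pull = (1, bead_n, bead_c, protocol.spring_k, speed_ps, d0,
            protocol.max_extension, protocol.spring_runaway)
    x, v, frames, _vels, times, exts, pf, e_series, steps = _run(
        top, state, n_steps, protocol.save_every, protocol.dt, protocol.gamma,
        T, packed=packed, pull=pull)
    meta = {"temperature": T, "seed": protocol.seed, "protocol": "smd",
            "save_every": protocol.save_every, "dt": protocol.dt,
            "gamma": protocol.gamma, "speed_A_per_ns": protocol.speed,
            "spring_k": protocol.spring_k, "energy_series": e_series}
    traj = Trajectory(times, frames, metadata=meta)
    rec = pd.DataFrame({
        "time_ps": times,
        "end_to_end_A": exts,
        "force_pN": pf * PN_PER_KCAL_MOL_A,
    })
    if subsets is not None:
        cs = ContactSubsets(top.contacts, top.author_resids, subsets)
        qrows = [cs.fractions(fr) for fr in frames]
        qdf = pd.DataFrame(qrows)
        rec = pd.concat([rec, qdf], axis=1)
    return traj, rec


def average_force_profile(records: list, bin_width: float = 1.0,
                          running_window: int = 50) -> pd.DataFrame:
    """Bin force against end-to-end distance, average across runs.

    Returns a DataFrame with bin centers, per-bin mean force, standard
    error across runs, sample count, and the ``running_window``-point
    running average of the mean trace.  Bins no run visited are missing
    (NaN), never zero.
    """
    if not records:
        raise ValueError("need at least one record")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo = min(r["end_to_end_A"].min() for r in records)
    hi = max(r["end_to_end_A"].max() for r in records)
    edges = np.arange(math.floor(lo / bin_width) * bin_width,
                      hi + bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    per_run = np.full((len(records), len(centers)), np.nan)
    for k, r in enumerate(records):
        idx = np.clip(np.digitize(r["end_to_end_A"].to_numpy(), edges) - 1,
                      0, len(centers) - 1)
        sums = np.zeros(len(centers))
        cnts = np.zeros(len(centers))
        np.add.at(sums, idx, r["force_pN"].to_numpy())
        np.add.at(cnts, idx, 1.0)
        with np.errstate(invalid="ignore"):
            per_run[k] = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    import warnings
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)   # all-NaN bins
        mean = np.nanmean(per_run, axis=0)
        nruns = np.sum(~np.isnan(per_run), axis=0)
        sem = np.nanstd(per_run, axis=0, ddof=0) / np.sqrt(np.maximum(nruns, 1))
    df = pd.DataFrame({"end_to_end_A": centers, "force_pN": mean,
                       "sem_pN": sem, "n_runs": nruns})
    df["running_avg_pN"] = (df["force_pN"]
                            .rolling(running_window, min_periods=1,
                                     center=True).mean())
    return df


def detect_force_peaks(profile: pd.DataFrame, min_prominence: float = 5.0,
                       min_separation: float = 5.0,
                       column: str = "running_avg_pN") -> list:
    """Local maxima of the smoothed force trace, sorted by extension.

    Returns ``[(extension A, height pN), ...]`` for peaks above the
    prominence threshold and at least ``min_separation`` A apart.
    """
    good = profile[column].notna().to_numpy()
    y = profile.loc[good, column].to_numpy()
    x = profile.loc[good, "end_to_end_A"].to_numpy()
    if len(y) < 3:
        return []
    bin_width = float(np.median(np.diff(x))) if len(x) > 1 else 1.0
    distance = max(int(math.ceil(min_separation / bin_width)), 1)
    idx, _props = find_peaks(y, prominence=min_prominence, distance=distance)
    return [(float(x[i]), float(y[i])) for i in idx]


def unfolding_order(runs: list, subsets: list | None = None,
                    q_threshold: float = 0.5) -> pd.DataFrame:
    """Rupture order: for each monitored subset, the extension at which its
    native fraction first drops below ``q_threshold`` (median over runs).

    ``runs`` are per-run DataFrames from :func:`run_smd` containing
    end_to_end_A and one column per subset.  A subset whose median
    first-crossing never happens is reported as retained (extension NaN).
    Rows are sorted by crossing extension, retained subsets last.
    """
    if not runs:
        raise ValueError("need at least one run")
    if subsets is None:
        subsets = [c for c in runs[0].columns
                   if c not in ("time_ps", "end_to_end_A", "force_pN",
                                "Q_total")]
    rows = []
    for name in subsets:
        crossings = []
        for r in runs:
            q = r[name].to_numpy()
            ext = r["end_to_end_A"].to_numpy()
            below = np.nonzero(q < q_threshold)[0]
            crossings.append(ext[below[0]] if len(below) else np.inf)
        med = float(np.median(crossings))
        rows.append({"subset": name,
                     "half_loss_extension_A": med if np.isfinite(med) else np.nan,
                     "retained": not np.isfinite(med)})
    df = pd.DataFrame(rows)
    return (df.sort_values(["retained", "half_loss_extension_A"],
                           na_position="last")
            .reset_index(drop=True))
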