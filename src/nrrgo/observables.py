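"""Trajectory observables: native-contact fractions, superposition,
RMSF/covariance, B-factor conversion and end-to-end distance.

Native-contact criterion: a contact is formed when the inter-C-alpha
distance is no more than ``tolerance`` (default 1.0 A) greater than its
native distance.  Q values are per-subset fractions; subsets are defined
by author-resid range pairs matched against the contact list (the second
range may be None, meaning "any partner").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ContactSubsets", "native_fraction", "contact_fraction_series",
           "superpose", "rmsf_profile", "FluctuationProfile",
           "bfactor_to_rmsf", "rmsf_to_bfactor", "covariance_map",
           "end_to_end"]

_B_COEF = 8.0 * np.pi ** 2 / 3.0      # B = (8 pi^2 / 3) * RMSF^2


class ContactSubsets:
    """Precomputed masks mapping named residue-range pairs onto a contact
    list, for fast per-frame Q evaluation."""

    def __init__(self, contacts, author_resids, subsets=None,
                 tolerance: float = 1.0, include_ion_contacts: bool = False):
        if tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        keep = [c for c in contacts
                if include_ion_contacts or c.origin != "ion_coordination"]
        self.ci = np.array([c.bead_i for c in keep], dtype=int)
        self.cj = np.array([c.bead_j for c in keep], dtype=int)
        self.r0 = np.array([c.r_native for c in keep], dtype=float)
        self.tolerance = tolerance
        author = np.asarray(author_resids)
        ri, rj = author[self.ci], author[self.cj]
        self.masks = {"Q_total": np.ones(len(keep), dtype=bool)}
        for name, (range_a, range_b) in (subsets or {}).items():
            in_a_i = (ri >= range_a[0]) & (ri <= range_a[1])
            in_a_j = (rj >= range_a[0]) & (rj <= range_a[1])
            if range_b is None:
                mask = in_a_i | in_a_j
            else:
                in_b_i = (ri >= range_b[0]) & (ri <= range_b[1])
                in_b_j = (rj >= range_b[0]) & (rj <= range_b[1])
                mask = (in_a_i & in_b_j) | (in_a_j & in_b_i)
            self.masks[name] = mask

    def formed(self, coords: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(coords[self.ci] - coords[self.cj], axis=1)
        return d <= self.r0 + self.tolerance

    def fractions(self, coords: np.ndarray) -> dict:
        """Q per subset; empty subsets are undefined (NaN), not 0."""
        formed = self.formed(coords)
        out = {}
        for name, mask in self.masks.items():
            tot = int(mask.sum())
            out[name] = float(formed[mask].sum()) / tot if tot else float("nan")
        return out


def native_fraction(coords, contacts, author_resids=None, subsets=None,
                    tolerance: float = 1.0) -> dict:
    """Fraction of native contacts formed, total and per named subset."""
    if author_resids is None:
        author_resids = np.arange(np.asarray(coords).shape[0])
    cs = ContactSubsets(contacts, author_resids, subsets, tolerance)
    return cs.fractions(np.asarray(coords, dtype=float))


def contact_fraction_series(frames, times, contacts, author_resids,
                            subsets=None, tolerance: float = 1.0) -> pd.DataFrame:
    cs = ContactSubsets(contacts, author_resids, subsets, tolerance)
    rows = [cs.fractions(fr) for fr in frames]
    df = pd.DataFrame(rows)
    df.insert(0, "time_ps", np.asarray(times, dtype=float))
    return df


def superpose(mobile: np.ndarray, ref: np.ndarray, selection=None):
    """Least-squares rigid-body superposition (Kabsch).

    Returns ``(rotation (3,3), translation (3,), rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``ref`` over the
    selection; rmsd is the post-fit value over the selection.
    """
    mobile = np.asarray(mobile, dtype=float)
    ref = np.asarray(ref, dtype=float)
    sel = np.arange(len(ref)) if selection is None else np.asarray(selection)
    if len(sel) < 3:
        raise ValueError("need at least 3 selected beads")
    pm, pr = mobile[sel], ref[sel]
    cm, cr = pm.mean(axis=0), pr.mean(axis=0)
    am, ar = pm - cm, pr - cr
    if np.linalg.matrix_rank(ar, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) selection")
    h = am.T @ ar
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cr - rot @ cm
    fitted = pm @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - pr) ** 2, axis=1))))
    return rot, trans, rmsd


def _aligned_frames(frames, ref, selection, use_fraction):
    frames = np.asarray(frames, dtype=float)
    if not 0 < use_fraction <= 1:
        raise ValueError("use_fraction must be in (0, 1]")
    m = len(frames)
    start = m - max(int(round(m * use_fraction)), 1)
    frames = frames[start:]
    if len(frames) < 2:
        raise ValueError("need at least 2 frames after discard")
    out = np.empty_like(frames)
    target = np.asarray(ref, dtype=float)
    # iterated mean: align to ref, average, re-align to the mean (2 rounds)
    for _round in range(2):
        for k, fr in enumerate(frames):
            rot, trans, _ = superpose(fr, target, selection)
            out[k] = fr @ rot.T + trans
        target = out.mean(axis=0)
    return out, target


@dataclass
class FluctuationProfile:
    rmsf: np.ndarray            # (n,) A
    align_selection: object
    source: str                 # "trajectory" | "crystal_bfactors"

    def __post_init__(self):
        if (self.rmsf < 0).any():
            raise ValueError("negative RMSF")


def rmsf_profile(frames, ref, align_selection=None,
                 use_fraction: float = 0.8) -> FluctuationProfile:
    """Per-residue RMSF about the (iterated) mean structure after per-frame
    superposition; by default only the final 80% of frames are used."""
    aligned, mean = _aligned_frames(frames, ref, align_selection, use_fraction)
    dev = aligned - mean[None]
    rmsf = np.sqrt(np.mean(np.sum(dev ** 2, axis=2), axis=0))
    return FluctuationProfile(rmsf, align_selection, "trajectory")


def bfactor_to_rmsf(b):
    """RMSF (A) from a crystallographic B-factor via B = 8 pi^2 RMSF^2 / 3."""
    b = np.asarray(b, dtype=float)
    if (b < 0).any():
        raise ValueError("negative B-factor")
    return np.sqrt(b / _B_COEF)


def rmsf_to_bfactor(rmsf):
    rmsf = np.asarray(rmsf, dtype=float)
    if (rmsf < 0).any():
        raise ValueError("negative RMSF")
    return _B_COEF * rmsf ** 2


def covariance_map(frames, ref, align_selection=None,
                   use_fraction: float = 0.8) -> np.ndarray:
    """Residue-residue covariance C_ij = <dr_i . dr_j> (A^2) after
    superposition; diagonal equals RMSF^2."""
    aligned, mean = _aligned_frames(frames, ref, align_selection, use_fraction)
    dev = aligned - mean[None]
    return np.einsum("mia,mja->ij", dev, dev) / len(dev)


def end_to_end(coords, bead_n: int, bead_c: int) -> float:
    coords = np.asarray(coords, dtype=float)
    return float(np.linalg.norm(coords[bead_c] - coords[bead_n]))
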