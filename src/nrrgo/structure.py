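"""Structure ingestion and annotation for the auto-inhibited Notch NRR fold.

Reads a single protein chain from PDB text into :class:`ChainStructure`,
detects disulfide bridges and bound calcium sites, and assigns the
LNR-A/LNR-B/LNR-C/HD subdomain scheme used throughout the analysis.

All user-facing residue identifiers are author numbering (1449-1727 for
the human Notch1 NRR); a contiguous 0-based internal index is kept for
arrays, with an explicit bidirectional map (the "compressed residue ID"
1..N used in fluctuation plots is ``internal index + 1``).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd

from .constants import BACKBONE_ATOMS, THREE_TO_ONE, ONE_TO_THREE

logger = logging.getLogger("nrrgo.structure")

__all__ = [
    "Residue", "Ion", "ChainStructure", "DisulfidePair", "IonSite",
    "SubdomainScheme", "read_structure", "write_structure",
    "detect_disulfides", "detect_ion_coordination", "assign_subdomains",
]


@dataclass
class Residue:
    author_resid: int
    aa: str                       # one-letter code
    ca_xyz: np.ndarray            # (3,) A
    heavy_atoms: list             # [(atom_name, element, xyz (3,))]
    b_factor: float               # A^2, from the C-alpha record

    def atom(self, name: str):
        for nm, _el, xyz in self.heavy_atoms:
            if nm == name:
                return xyz
        return None

    def sidechain_atoms(self):
        return [(nm, el, xyz) for nm, el, xyz in self.heavy_atoms
                if nm not in BACKBONE_ATOMS]


@dataclass
class Ion:
    element: str
    xyz: np.ndarray


@dataclass
class ChainStructure:
    residues: list[Residue]
    ions: list[Ion] = field(default_factory=list)
    segment_breaks: list[int] = field(default_factory=list)

    def __post_init__(self):
        resids = [r.author_resid for r in self.residues]
        if any(b >= a for a, b in zip(resids[1:], resids[:-1])):
            raise ValueError("residues must be strictly ordered by author resid")
        if any(r.b_factor < 0 for r in self.residues):
            raise ValueError("negative B-factor")

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def ca_coords(self) -> np.ndarray:
        return np.array([r.ca_xyz for r in self.residues], dtype=float)

    def resids(self) -> np.ndarray:
        return np.array([r.author_resid for r in self.residues], dtype=int)

    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def index_of(self, author_resid: int) -> int:
        """Author resid -> 0-based internal index."""
        try:
            return self._index_map()[author_resid]
        except KeyError:
            raise KeyError(f"residue {author_resid} not in structure") from None

    def author_of(self, index: int) -> int:
        return self.residues[index].author_resid

    def _index_map(self) -> dict:
        if not hasattr(self, "_imap"):
            self._imap = {r.author_resid: i for i, r in enumerate(self.residues)}
        return self._imap

    def subset(self, lo: int, hi: int) -> "ChainStructure":
        """New ChainStructure keeping author resids in [lo, hi]; ions kept
        only if within 5 A of a kept residue atom."""
        kept = [r for r in self.residues if lo <= r.author_resid <= hi]
        ions = []
        if kept:
            pts = np.array([xyz for r in kept for _n, _e, xyz in r.heavy_atoms])
            for ion in self.ions:
                if np.min(np.linalg.norm(pts - ion.xyz, axis=1)) <= 5.0:
                    ions.append(ion)
        resids = [r.author_resid for r in kept]
        breaks = [i for i in range(len(kept) - 1) if resids[i + 1] != resids[i] + 1]
        return ChainStructure(kept, ions, breaks)


@dataclass
class DisulfidePair:
    resid_i: int
    resid_j: int
    sg_distance: float

    def __post_init__(self):
        if self.resid_i == self.resid_j:
            raise ValueError("disulfide between a residue and itself")


@dataclass
class IonSite:
    ion_index: int
    coordinating_residues: list   # [(author_resid, atom_name, distance A)]


@dataclass
class SubdomainScheme:
    """Named author-numbered residue ranges (inclusive).

    ``primary`` ranges must not overlap; every residue outside them is a
    linker.  ``secondary`` ranges (HDN/HDC/beta5 by default) may nest.
    """
    primary: dict
    secondary: dict

    @classmethod
    def notch1_nrr(cls) -> "SubdomainScheme":
        return cls(
            primary={
                "LNR-A": (1449, 1480),
                "LNR-B": (1491, 1522),
                "LNR-C": (1529, 1562),
                "HD": (1568, 1727),
            },
            secondary={
                "HDN": (1568, 1622),
                "HDC": (1670, 1727),
                "beta5": (1721, 1727),
            },
        )

    def validate(self):
        items = sorted(self.primary.items(), key=lambda kv: kv[1][0])
        for (na, (_, hia)), (nb, (lob, _)) in zip(items, items[1:]):
            if lob <= hia:
                raise ValueError(f"overlapping primary ranges {na} and {nb}")

    def primary_label(self, resid: int) -> str:
        for name, (lo, hi) in self.primary.items():
            if lo <= resid <= hi:
                return name
        return "linker"

    def secondary_labels(self, resid: int) -> list:
        return [name for name, (lo, hi) in self.secondary.items()
                if lo <= resid <= hi]

    def range_of(self, name: str) -> tuple:
        if name in self.primary:
            return self.primary[name]
        return self.secondary[name]


def read_structure(pdb_text: str, chain_id: str = "A") -> ChainStructure:
    """Parse one chain of a PDB file into a :class:`ChainStructure`.

    Keeps ATOM records with blank or 'A' altloc, records HETATM calcium
    ions, skips waters, hydrogens and anisotropic records, and flags
    author-numbering discontinuities (e.g. the excised S1 loop).

    Raises ``ValueError`` for a residue without a C-alpha or with an
    unknown residue name.
    """
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise ValueError("empty PDB input")
    model = st[0]
    chain = model.find_chain(chain_id)
    if chain is None:
        raise ValueError(f"chain {chain_id!r} not found")

    residues: list[Residue] = []
    ions: list[Ion] = []
    for res in chain:
        name = res.name.strip()
        if name == "HOH":
            continue
        if name == "CA" or (len(res) == 1 and res[0].element.name == "Ca"):
            ions.append(Ion("Ca", np.array(res[0].pos.tolist())))
            continue
        if res.het_flag == "H" and name not in THREE_TO_ONE:
            logger.info("ignoring hetero residue %s %d", name, res.seqid.num)
            continue
        if name not in THREE_TO_ONE:
            raise ValueError(f"unknown residue name {name!r} at resid {res.seqid.num}")
        heavy, ca, bfac = [], None, 0.0
        for atom in res:
            if atom.element.is_hydrogen:
                continue
            if atom.altloc not in ("\0", "", "A"):
                continue
            xyz = np.array(atom.pos.tolist())
            if atom.name == "CA":
                ca, bfac = xyz, atom.b_iso
            heavy.append((atom.name, atom.element.name, xyz))
        if ca is None:
            raise ValueError(f"residue {res.seqid.num} ({name}) has no C-alpha")
        residues.append(Residue(res.seqid.num, THREE_TO_ONE[name], ca, heavy,
                                max(bfac, 0.0)))
    if not residues:
        raise ValueError(f"no protein residues with C-alpha in chain {chain_id!r}")

    resids = [r.author_resid for r in residues]
    breaks = [i for i in range(len(resids) - 1) if resids[i + 1] != resids[i] + 1]
    for i in breaks:
        logger.info("numbering discontinuity between %d and %d",
                    resids[i], resids[i + 1])
    return ChainStructure(residues, ions, breaks)


def write_structure(s: ChainStructure, chain_id: str = "A") -> str:
    """Serialize a ChainStructure back to PDB text (round-trip partner of
    :func:`read_structure`)."""
    st = gemmi.Structure()
    st.name = "nrrgo"
    model = gemmi.Model("1")
    chain = gemmi.Chain(chain_id)
    for r in s.residues:
        res = gemmi.Residue()
        res.name = ONE_TO_THREE[r.aa]
        res.seqid = gemmi.SeqId(r.author_resid, " ")
        for nm, el, xyz in r.heavy_atoms:
            at = gemmi.Atom()
            at.name = nm
            at.element = gemmi.Element(el)
            at.pos = gemmi.Position(*map(float, xyz))
            at.b_iso = r.b_factor if nm == "CA" else 0.0
            at.occ = 1.0
            res.add_atom(at)
        chain.add_residue(res)
    for k, ion in enumerate(s.ions, start=1):
        res = gemmi.Residue()
        res.name = "CA"
        res.seqid = gemmi.SeqId(9000 + k, " ")
        res.het_flag = "H"
        at = gemmi.Atom()
        at.name = "CA"
        at.element = gemmi.Element("Ca")
        at.pos = gemmi.Position(*map(float, ion.xyz))
        at.occ = 1.0
        res.add_atom(at)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    buf = io.StringIO()
    buf.write(st.make_pdb_string())
    return buf.getvalue()


def detect_disulfides(s: ChainStructure, cutoff: float = 2.5) -> list[DisulfidePair]:
    """SG-SG pairs of cysteines within ``cutoff`` A.

    A cysteine within the cutoff of two partners is ambiguous and raises.
    Pairs are returned sorted by the lower resid; detection is symmetric
    in atom order and rigid-motion invariant (distances only).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    sgs = [(r.author_resid, r.atom("SG")) for r in s.residues
           if r.aa == "C" and r.atom("SG") is not None]
    partners: dict[int, list] = {rid: [] for rid, _ in sgs}
    for a in range(len(sgs)):
        for b in range(a + 1, len(sgs)):
            d = float(np.linalg.norm(sgs[a][1] - sgs[b][1]))
            if d <= cutoff:
                partners[sgs[a][0]].append((sgs[b][0], d))
                partners[sgs[b][0]].append((sgs[a][0], d))
    for rid, ps in partners.items():
        if len(ps) > 1:
            raise ValueError(
                f"ambiguous disulfide bonding: CYS {rid} within {cutoff} A of "
                f"{[p[0] for p in ps]}")
    pairs = []
    for rid, ps in partners.items():
        for other, d in ps:
            if rid < other:
                pairs.append(DisulfidePair(rid, other, d))
    return sorted(pairs, key=lambda p: p.resid_i)


def detect_ion_coordination(s: ChainStructure, coord_cutoff: float = 3.2) -> list[IonSite]:
    """Coordinating oxygens (backbone O, Asp OD1/OD2) within ``coord_cutoff``
    of each ion.  Ions with no coordinator are dropped with a warning."""
    if coord_cutoff <= 0:
        raise ValueError("coord_cutoff must be positive")
    sites = []
    for k, ion in enumerate(s.ions):
        coords = []
        for r in s.residues:
            candidates = [("O", r.atom("O"))]
            if r.aa == "D":
                candidates += [("OD1", r.atom("OD1")), ("OD2", r.atom("OD2"))]
            for nm, xyz in candidates:
                if xyz is None:
                    continue
                d = float(np.linalg.norm(xyz - ion.xyz))
                if d <= coord_cutoff:
                    coords.append((r.author_resid, nm, d))
        if not coords:
            logger.warning("ion %d has no coordinating oxygen within %.2f A; dropped",
                           k, coord_cutoff)
            continue
        sites.append(IonSite(k, sorted(coords, key=lambda c: c[2])))
    return sites


def assign_subdomains(s: ChainStructure, scheme: SubdomainScheme | None = None) -> pd.DataFrame:
    """Per-residue label table: exactly one primary label per residue
    (linkers labeled ``linker``), secondary labels comma-joined."""
    scheme = scheme or SubdomainScheme.notch1_nrr()
    scheme.validate()
    rows = []
    for r in s.residues:
        rows.append({
            "resid": r.author_resid,
            "aa": r.aa,
            "primary_label": scheme.primary_label(r.author_resid),
            "secondary_labels": ",".join(scheme.secondary_labels(r.author_resid)),
        })
    return pd.DataFrame(rows, columns=["resid", "aa", "primary_label", "secondary_labels"])
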