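"""Coarse-grained structure representation and PDB input/output.

Proteins are reduced to three sites per residue (CA, CB, O) in the style of
one-bead-side-chain models such as AWSEM; DNA is reduced to three sites per
nucleotide (P = phosphate, S = sugar, B = base) following the 3SPN2 mapping.
All lengths are in angstroms.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import is_aa

__all__ = [
    "CGSite",
    "CGSystem",
    "MembraneSlab",
    "StructureError",
    "read_pdb",
    "write_pdb",
    "make_helix_fixture",
    "make_cys_toy",
    "make_dna_fixture",
    "AMINO_ACIDS",
    "NUCLEOTIDES",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDES = "acgt"  # lowercase to keep them distinct from Ala/Cys/Gly/Thr

PROTEIN_ROLES = ("CA", "CB", "O")
DNA_ROLES = ("P", "S", "B")

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}

_NUC_RESNAMES = {
    "DA": "a", "DC": "c", "DG": "g", "DT": "t",
    "A": "a", "C": "c", "G": "g", "T": "t", "U": "t",
}
_NUC_ONE_TO_RESNAME = {"a": "DA", "c": "DC", "g": "DG", "t": "DT"}

# atom used as the base site proxy, by nucleotide
_BASE_PROXY = {"a": "N9", "g": "N9", "c": "N1", "t": "N1"}


class StructureError(ValueError):
    """Raised when a structure violates the coarse-grained model's contract."""


@dataclass(frozen=True)
class CGSite:
    """One coarse-grained interaction site.

    ``site_role`` is CA/CB/O for protein residues and P/S/B for nucleotides.
    ``residue_index`` is the author residue number within its chain.
    """

    chain_id: str
    residue_index: int
    residue_type: str
    site_role: str
    position: tuple[float, float, float]

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise StructureError(f"non-finite or malformed position {self.position!r}")
        is_protein = self.residue_type in AMINO_ACIDS
        is_dna = self.residue_type in NUCLEOTIDES
        if not (is_protein or is_dna):
            raise StructureError(f"unknown residue type {self.residue_type!r}")
        if is_protein and self.site_role not in PROTEIN_ROLES:
            raise StructureError(
                f"site role {self.site_role!r} invalid on protein residue "
                f"{self.chain_id}{self.residue_index}"
            )
        if is_dna and self.site_role not in DNA_ROLES:
            raise StructureError(
                f"site role {self.site_role!r} invalid on nucleotide "
                f"{self.chain_id}{self.residue_index}"
            )


@dataclass(frozen=True)
class MembraneSlab:
    """Implicit membrane: the slab |z| < zm centered on z = 0.

    Parameters
    ----------
    zm : half-thickness of the slab in A (burial region boundary).
    b : boundary of the contact-switch region in A (1.5 nm).
    eta : steepness of the contact switch, 1/A (10 / nm).
    k_m : steepness of the burial switch, 1/A.
    """

    zm: float = 15.0
    b: float = 15.0
    eta: float = 1.0
    k_m: float = 1.0

    def __post_init__(self):
        if min(self.zm, self.b, self.eta, self.k_m) <= 0:
            raise ValueError("all membrane slab parameters must be positive")


class CGSystem:
    """A coarse-grained structure: protein residues plus optional DNA.

    Per-site metadata is kept in parallel lists, with all coordinates in a
    single ``(n_sites, 3)`` array so that rigid-body moves and integrators can
    operate on one contiguous block.
    """

    def __init__(self, sites: Sequence[CGSite]):
        sites = list(sites)
        self._chain = [s.chain_id for s in sites]
        self._resindex = np.array([s.residue_index for s in sites], dtype=int)
        self._restype = [s.residue_type for s in sites]
        self._role = [s.site_role for s in sites]
        self.coords = np.array(
            [s.position for s in sites], dtype=float
        ).reshape(len(sites), 3)
        self._build_tables()

    # -- construction ------------------------------------------------------
    def _build_tables(self) -> None:
        protein: dict[tuple[str, int], dict[str, int]] = {}
        dna: dict[tuple[str, int], dict[str, int]] = {}
        order_p: list[tuple[str, int]] = []
        order_d: list[tuple[str, int]] = []
        types: dict[tuple[str, int], str] = {}
        for k in range(len(self._role)):
            key = (self._chain[k], int(self._resindex[k]))
            table, order = (
                (protein, order_p) if self._restype[k] in AMINO_ACIDS else (dna, order_d)
            )
            if key not in table:
                table[key] = {}
                order.append(key)
                types[key] = self._restype[k]
            elif types[key] != self._restype[k]:
                raise StructureError(f"conflicting residue types at {key}")
            if self._role[k] in table[key]:
                raise StructureError(f"duplicate {self._role[k]} site at {key}")
            table[key][self._role[k]] = k

        # protein residue table
        self.res_keys: list[tuple[str, int]] = order_p
        self.res_types: list[str] = [types[k] for k in order_p]
        ica, icb, io_, cb_sub = [], [], [], []
        last_by_chain: dict[str, int] = {}
        for key in order_p:
            chain, idx = key
            if chain in last_by_chain and idx <= last_by_chain[chain]:
                raise StructureError(
                    f"residue indices not strictly increasing in chain {chain!r} at {idx}"
                )
            last_by_chain[chain] = idx
            roles = protein[key]
            if "CA" not in roles:
                raise StructureError(f"protein residue {chain}{idx} is missing CA")
            ica.append(roles["CA"])
            if "CB" in roles:
                icb.append(roles["CB"])
                cb_sub.append(False)
            else:
                # glycine (or a reduced model without CB): CA stands in for CB
                icb.append(roles["CA"])
                cb_sub.append(True)
            io_.append(roles.get("O", -1))
        self._ica = np.array(ica, dtype=int)
        self._icb = np.array(icb, dtype=int)
        self._io = np.array(io_, dtype=int)
        self.cb_is_ca = np.array(cb_sub, dtype=bool)

        # sequence coordinates: ordinal position within the chain, and the
        # author residue number (used for sequence-separation rules)
        ordinal = np.empty(len(order_p), dtype=int)
        seqpos = np.empty(len(order_p), dtype=int)
        chain_code = np.empty(len(order_p), dtype=int)
        chain_ids = sorted({c for c, _ in order_p})
        counter: dict[str, int] = {}
        for n, (chain, idx) in enumerate(order_p):
            counter[chain] = counter.get(chain, -1) + 1
            ordinal[n] = counter[chain]
            seqpos[n] = idx
            chain_code[n] = chain_ids.index(chain)
        self.res_ordinal = ordinal
        self.res_seqpos = seqpos
        self.res_chain_code = chain_code

        # DNA nucleotide table
        self.nuc_keys: list[tuple[str, int]] = order_d
        self.nuc_types: list[str] = [types[k] for k in order_d]
        self._inuc = {role: [] for role in DNA_ROLES}
        for key in order_d:
            for role in DNA_ROLES:
                if role in dna[key]:
                    self._inuc[role].append(dna[key][role])
        self._protein_lookup = protein

    # -- basic views -------------------------------------------------------
    @property
    def L(self) -> int:
        """Number of protein residues."""
        return len(self.res_keys)

    @property
    def n_sites(self) -> int:
        return self.coords.shape[0]

    @property
    def sequence(self) -> str:
        return "".join(self.res_types)

    def sites(self) -> Iterable[CGSite]:
        for k in range(self.n_sites):
            yield CGSite(
                self._chain[k], int(self._resindex[k]), self._restype[k],
                self._role[k], tuple(self.coords[k]),
            )

    def ca_positions(self) -> np.ndarray:
        return self.coords[self._ica]

    def cb_positions(self) -> np.ndarray:
        """Side-chain site positions (CA substituted where no CB exists)."""
        return self.coords[self._icb]

    def cb_site_indices(self) -> np.ndarray:
        return self._icb.copy()

    def ca_site_indices(self) -> np.ndarray:
        return self._ica.copy()

    def residue_sites(self, chain_id: str, residue_index: int) -> dict[str, int]:
        """Map role -> site index for one protein residue."""
        return dict(self._protein_lookup[(chain_id, residue_index)])

    def cb_position(self, chain_id: str, residue_index: int) -> np.ndarray:
        roles = self._protein_lookup[(chain_id, residue_index)]
        return self.coords[roles.get("CB", roles["CA"])]

    @property
    def dna_phosphates(self) -> np.ndarray:
        """Positions of DNA phosphate sites, shape (n_P, 3)."""
        return self.coords[self._inuc["P"]] if self._inuc["P"] else np.empty((0, 3))

    def dna_site_positions(self) -> np.ndarray:
        """All DNA site positions (P, S and B), for excluded-volume terms."""
        idx = sum((self._inuc[r] for r in DNA_ROLES), [])
        return self.coords[idx] if idx else np.empty((0, 3))

    @property
    def has_dna(self) -> bool:
        return bool(self.nuc_keys)

    def cysteine_residues(self) -> np.ndarray:
        """Indices (into the residue table) of cysteines."""
        return np.array([n for n, t in enumerate(self.res_types) if t == "C"], dtype=int)

    def sequence_separation(self, i: int, j: int) -> int | None:
        """Separation between residues i and j (residue-table indices).

        Returns None for interchain pairs, which are treated as unboundedly
        separated by every energy term.
        """
        if self.res_chain_code[i] != self.res_chain_code[j]:
            return None
        return abs(int(self.res_seqpos[i]) - int(self.res_seqpos[j]))

    # -- geometry ----------------------------------------------------------
    def copy(self) -> "CGSystem":
        new = object.__new__(CGSystem)
        new.__dict__.update(self.__dict__)
        new.coords = self.coords.copy()
        return new

    def with_coords(self, coords: np.ndarray) -> "CGSystem":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != self.coords.shape:
            raise ValueError("coordinate array shape mismatch")
        new = self.copy()
        new.coords = coords.copy()
        return new

    def translated(self, vec) -> "CGSystem":
        return self.with_coords(self.coords + np.asarray(vec, dtype=float))

    def rotated(self, R: np.ndarray, center=None) -> "CGSystem":
        c = np.zeros(3) if center is None else np.asarray(center, dtype=float)
        return self.with_coords((self.coords - c) @ np.asarray(R).T + c)


# ---------------------------------------------------------------------------
# PDB input / output
# ---------------------------------------------------------------------------

def _pick_atom(residue, name):
    """Return the coordinates of `name`, honoring altloc '' or 'A' only."""
    if name not in residue:
        return None
    atom = residue[name]
    if atom.is_disordered():
        for alt in atom.disordered_get_id_list():
            if alt in (" ", "A"):
                return atom.disordered_get(alt).get_coord()
        return None
    if atom.get_altloc() not in (" ", "A"):
        return None
    return atom.get_coord()


def read_pdb(path) -> CGSystem:
    """Read a PDB file and map it to coarse-grained sites.

    First model only; altloc blank or 'A'; HETATM, waters and hydrogens are
    ignored. Protein residues contribute CA, CB and O sites (glycine's CB is
    substituted by its CA); nucleotides contribute P (phosphorus), S (C4')
    and B (N1/N9) sites.
    """
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("cg", str(path))
    except Exception as exc:  # Bio.PDB raises assorted exception types
        raise StructureError(f"cannot parse PDB file {path}: {exc}") from exc
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise StructureError(f"no models in {path}")

    sites: list[CGSite] = []
    for chain in model:
        for residue in chain:
            hetflag, resseq, _ = residue.get_id()
            if hetflag.strip():
                continue  # HETATM / water
            resname = residue.get_resname().strip()
            if is_aa(residue, standard=True) and resname in _THREE_TO_ONE:
                one = _THREE_TO_ONE[resname]
                ca = _pick_atom(residue, "CA")
                if ca is None:
                    raise StructureError(
                        f"protein residue {chain.id}{resseq} ({resname}) is missing CA"
                    )
                sites.append(CGSite(chain.id, resseq, one, "CA", tuple(ca)))
                cb = _pick_atom(residue, "CB")
                if cb is not None:
                    sites.append(CGSite(chain.id, resseq, one, "CB", tuple(cb)))
                o = _pick_atom(residue, "O")
                if o is not None:
                    sites.append(CGSite(chain.id, resseq, one, "O", tuple(o)))
            elif resname in _NUC_RESNAMES:
                one = _NUC_RESNAMES[resname]
                p = _pick_atom(residue, "P")
                if p is not None:  # 5' terminal nucleotides lack P
                    sites.append(CGSite(chain.id, resseq, one, "P", tuple(p)))
                s = _pick_atom(residue, "C4'")
                if s is not None:
                    sites.append(CGSite(chain.id, resseq, one, "S", tuple(s)))
                b = _pick_atom(residue, _BASE_PROXY[one])
                if b is not None:
                    sites.append(CGSite(chain.id, resseq, one, "B", tuple(b)))
    if not sites:
        raise StructureError(f"no protein or DNA residues found in {path}")
    return CGSystem(sites)


_ROLE_ATOM = {"CA": "CA", "CB": "CB", "O": "O", "P": "P", "S": "C4'", "B": "N9"}


def _pdb_atom_line(serial, name, resname, chain, resseq, xyz, element):
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:5d} {name_field}{'':1s}{resname:>3s} {chain:1s}"
        f"{resseq:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
    )


def _model_lines(cg: CGSystem, serial_start: int = 1) -> list[str]:
    lines = []
    serial = serial_start
    for k in range(cg.n_sites):
        role = cg._role[k]
        rtype = cg._restype[k]
        if rtype in AMINO_ACIDS:
            resname = _ONE_TO_THREE[rtype]
        else:
            resname = _NUC_ONE_TO_RESNAME[rtype]
        atom = _ROLE_ATOM[role]
        if role == "B":
            atom = _BASE_PROXY[rtype]
        element = ("P" if atom == "P" else "N" if atom.startswith("N")
                   else "O" if atom == "O" else "C")
        lines.append(
            _pdb_atom_line(serial, atom, resname, cg._chain[k],
                           int(cg._resindex[k]), cg.coords[k], element)
        )
        serial += 1
    return lines


def write_pdb(cg: CGSystem, path, *, models: Sequence[np.ndarray] | None = None) -> None:
    """Write a CGSystem (or a trajectory of coordinate frames) as PDB.

    With ``models`` given, each coordinate array becomes one MODEL record
    (multi-model PDB trajectory).
    """
    out = io.StringIO()
    if models is None:
        out.write("\n".join(_model_lines(cg)))
        out.write("\nEND\n")
    else:
        for m, coords in enumerate(models, start=1):
            frame = cg.with_coords(coords)
            out.write(f"MODEL     {m:4d}\n")
            out.write("\n".join(_model_lines(frame)))
            out.write("\nENDMDL\n")
        out.write("END\n")
    Path(path).write_text(out.getvalue())


def read_pdb_models(path) -> list[CGSystem]:
    """Read every model of a multi-model PDB as a list of CGSystems."""
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("traj", str(path))
    frames = []
    base = read_pdb(path)
    for model in structure.get_models():
        coords = []
        for chain in model:
            for residue in chain:
                if residue.get_id()[0].strip():
                    continue
                for atom in residue:
                    if atom.get_altloc() in (" ", "A"):
                        coords.append(atom.get_coord())
        coords = np.asarray(coords, dtype=float)
        if coords.shape == base.coords.shape:
            frames.append(base.with_coords(coords))
    return frames


# ---------------------------------------------------------------------------
# Synthetic fixtures
# ---------------------------------------------------------------------------

def make_helix_fixture(
    n_res: int,
    z_offset: float = 0.0,
    axis=(0.0, 0.0, 1.0),
    sequence: str | None = None,
    chain_id: str = "A",
) -> CGSystem:
    """Ideal alpha-helix: 1.5 A rise and 100 degrees of twist per residue.

    The helix runs along ``axis`` with its CA centroid at the origin, then the
    whole chain is shifted by ``z_offset`` along the global z axis. CB sites
    are placed 1.53 A radially outward from each CA; carbonyl O sites sit
    between consecutive CA positions. Deterministic in its arguments.
    """
    if n_res < 4:
        raise ValueError("a helix fixture needs at least 4 residues")
    if sequence is None:
        sequence = "A" * n_res
    if len(sequence) != n_res:
        raise ValueError("sequence length must equal n_res")
    if any(c not in AMINO_ACIDS for c in sequence):
        raise ValueError("sequence must use one-letter amino-acid codes")

    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    # orthonormal frame (u, v, axis)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, axis)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)

    radius, rise, twist = 2.3, 1.5, math.radians(100.0)
    t = np.arange(n_res)
    radial = np.outer(np.cos(t * twist), u) + np.outer(np.sin(t * twist), v)
    ca = radius * radial + np.outer(t * rise, axis)
    ca -= ca.mean(axis=0)
    cb = ca + 1.53 * radial
    o = np.empty_like(ca)
    o[:-1] = 0.5 * (ca[:-1] + ca[1:]) + 0.6 * radial[:-1]
    o[-1] = ca[-1] + (ca[-1] - ca[-2]) * 0.5 + 0.6 * radial[-1]

    shift = np.array([0.0, 0.0, z_offset])
    sites = []
    for n in range(n_res):
        aa = sequence[n]
        sites.append(CGSite(chain_id, n + 1, aa, "CA", tuple(ca[n] + shift)))
        if aa != "G":
            sites.append(CGSite(chain_id, n + 1, aa, "CB", tuple(cb[n] + shift)))
        sites.append(CGSite(chain_id, n + 1, aa, "O", tuple(o[n] + shift)))
    return CGSystem(sites)


def make_dna_fixture(n_bp: int, rise: float = 3.38, twist_deg: float = 36.0,
                     center=(0.0, 0.0, 0.0), axis_offset: float = 0.0,
                     chain_ids=("D", "E")) -> CGSystem:
    """Idealized B-DNA duplex: two antiparallel strands of n_bp nucleotides.

    Each nucleotide carries P (r = 8.9 A), S (r = 8.0 A) and B (r = 4.0 A)
    sites on a helix of the given rise and twist along z; the 5' terminal
    nucleotide of each strand has no phosphate, as in real structures. The
    duplex axis passes through ``center`` (shifted by ``axis_offset`` in x).
    Alternating a/t sequence. Deterministic.
    """
    if n_bp < 2:
        raise ValueError("a duplex fixture needs at least 2 base pairs")
    center = np.asarray(center, dtype=float) + np.array([axis_offset, 0.0, 0.0])
    twist = math.radians(twist_deg)
    sites: list[CGSite] = []
    for strand, (chain, phase) in enumerate(zip(chain_ids, (0.0, math.pi * 0.85))):
        for k in range(n_bp):
            # strand 2 runs antiparallel: base pair k pairs with n_bp-1-k
            bp = k if strand == 0 else n_bp - 1 - k
            ang = bp * twist + phase
            z = bp * rise
            nuc = "a" if (bp + strand) % 2 == 0 else "t"
            def ring(radius):
                return tuple(center + np.array(
                    [radius * math.cos(ang), radius * math.sin(ang), z]))
            if k > 0:  # 5' terminus lacks P
                sites.append(CGSite(chain, k + 1, nuc, "P", ring(8.9)))
            sites.append(CGSite(chain, k + 1, nuc, "S", ring(8.0)))
            sites.append(CGSite(chain, k + 1, nuc, "B", ring(4.0)))
    return CGSystem(sites)


def make_cys_toy(
    cys_positions: Sequence, spacer: int = 5, chain_id: str = "A"
) -> CGSystem:
    """A toy chain whose cysteine CB sites sit exactly at given positions.

    Consecutive cysteines are separated in sequence by ``spacer`` alanine
    residues, so every cysteine pair has sequence separation > 1. Filler CAs
    are laid out on a two-segment detour between consecutive cysteines with
    near-3.8 A virtual-bond spacing, so the chain is also usable with
    backbone springs in toy dynamics.
    """
    positions = [np.asarray(p, dtype=float) for p in cys_positions]
    for n, p in enumerate(positions):
        for q in positions[:n]:
            if np.linalg.norm(p - q) < 1e-9:
                raise ValueError("cysteine positions must be pairwise distinct")
    if spacer < 2:
        raise ValueError("spacer must be >= 2 so cysteine pairs have separation > 1")

    sites: list[CGSite] = []
    if not positions:
        # cysteine-free control chain
        for n in range(4):
            base = np.array([3.8 * n, 0.0, 0.0])
            sites.append(CGSite(chain_id, n + 1, "A", "CA", tuple(base)))
            sites.append(CGSite(chain_id, n + 1, "A", "CB", tuple(base + (0, 1.5, 0))))
        return CGSystem(sites)

    def filler_path(a, b, count):
        """`count` points between CA anchors a and b, spaced ~3.8 A along a
        tent-shaped detour long enough to accommodate them."""
        d = np.linalg.norm(b - a)
        seg = max(3.8 * (count + 1) / 2.0, d / 2.0 + 0.1)
        # offset direction orthogonal to a->b
        u = (b - a) / max(d, 1e-9)
        ref = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(u, ref)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        v = np.cross(u, ref)
        v /= np.linalg.norm(v)
        apex = 0.5 * (a + b) + v * math.sqrt(max(seg * seg - (d / 2) ** 2, 0.0))
        pts = []
        total = count + 1  # bonds along the path
        for m in range(1, count + 1):
            t = m / total
            if t <= 0.5:
                pts.append(a + (apex - a) * (2 * t))
            else:
                pts.append(apex + (b - apex) * (2 * t - 1))
        return pts

    resseq = 1
    ca_anchor_prev = None
    for n, p in enumerate(positions):
        ca = p + np.array([1.53, 0.0, 0.0])
        if n > 0:
            for base in filler_path(ca_anchor_prev, ca, spacer):
                sites.append(CGSite(chain_id, resseq, "A", "CA", tuple(base)))
                sites.append(CGSite(chain_id, resseq, "A", "CB",
                                    tuple(base + np.array([0.0, 0.0, 1.5]))))
                resseq += 1
        sites.append(CGSite(chain_id, resseq, "C", "CA", tuple(ca)))
        sites.append(CGSite(chain_id, resseq, "C", "CB", tuple(p)))
        resseq += 1
        ca_anchor_prev = ca
    return CGSystem(sites)
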