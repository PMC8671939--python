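"""Coordinate models, residue-range backbone superposition and RMSD.

Structures are read through gemmi (PDB and mmCIF), keeping author residue
numbering, waters and ligands.  Alternate conformations are resolved to a
single conformer per atom (highest occupancy, ties broken toward altloc
"A").  Superposition is the least-squares optimal rigid rotation (Kabsch,
via SVD with reflection correction) over backbone atoms paired by
(chain, residue number, atom name) within a residue interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

BACKBONE_ATOMS = ("N", "CA", "C", "O")

WATER_NAMES = {"HOH", "WAT", "H2O", "DOD"}

STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


class StructureError(ValueError):
    """Parsing or selection failure on a coordinate model."""


@dataclass(frozen=True)
class AtomRecord:
    chain: str
    res_name: str
    res_seq: int
    icode: str
    atom_name: str
    element: str
    pos: tuple[float, float, float]
    occupancy: float = 1.0

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.pos, dtype=float)

    @property
    def is_water(self) -> bool:
        return self.res_name in WATER_NAMES

    @property
    def is_standard(self) -> bool:
        return self.res_name in STANDARD_RESIDUES

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain, self.res_seq, self.icode)

    def label(self) -> str:
        ic = self.icode.strip()
        return f"{self.chain}/{self.res_name}{self.res_seq}{ic}/{self.atom_name}"


@dataclass
class StructureModel:
    """A flat, altloc-resolved view of one model of a structure."""

    identifier: str
    atoms: list[AtomRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index: dict[tuple[str, int, str, str], AtomRecord] = {}
        for a in self.atoms:
            self._index[(a.chain, a.res_seq, a.icode, a.atom_name)] = a

    # -- selections --------------------------------------------------------

    def get_atom(self, chain: str, res_seq: int, atom_name: str,
                 icode: str = "") -> AtomRecord | None:
        return self._index.get((chain, res_seq, icode, atom_name))

    def residues(self) -> dict[tuple[str, int, str], list[AtomRecord]]:
        out: dict[tuple[str, int, str], list[AtomRecord]] = {}
        for a in self.atoms:
            out.setdefault(a.residue_key, []).append(a)
        return out

    def residue_atoms(self, chain: str, res_seq: int,
                      icode: str = "") -> list[AtomRecord]:
        return [a for a in self.atoms
                if a.residue_key == (chain, res_seq, icode)]

    def het_residues(self) -> list[tuple[str, int, str]]:
        """Non-standard, non-water residue names present (ligands)."""
        seen, out = set(), []
        for a in self.atoms:
            if not a.is_standard and not a.is_water:
                key = (a.chain, a.res_seq, a.res_name)
                if key not in seen:
                    seen.add(key)
                    out.append(key)
        return out

    def find_residues_by_name(self, res_name: str) -> list[tuple[str, int, str]]:
        seen, out = set(), []
        for a in self.atoms:
            if a.res_name == res_name:
                key = (a.chain, a.res_seq, a.icode)
                if key not in seen:
                    seen.add(key)
                    out.append(key)
        return out

    def waters(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.is_water and a.element == "O"]

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.element != "H"]


def _resolve_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """One conformer per atom name: highest occupancy, ties toward 'A'."""
    by_name: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = by_name.get(atom.name)
        if prev is None:
            by_name[atom.name] = atom
            continue
        key_new = (atom.occ, -ord(atom.altloc or "A"))
        key_old = (prev.occ, -ord(prev.altloc or "A"))
        if key_new > key_old:
            by_name[atom.name] = atom
    return list(by_name.values())


def read_structure(path: str | Path, fmt: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file into a flat model (first model only).

    Author residue numbering is preserved; waters and ligands are kept;
    alternate locations are resolved per the highest-occupancy policy.
    """
    path = Path(path)
    try:
        if fmt is None:
            st = gemmi.read_structure(str(path))
        else:
            coor = {"pdb": gemmi.CoorFormat.Pdb,
                    "mmcif": gemmi.CoorFormat.Mmcif}[fmt.lower()]
            st = gemmi.read_structure(str(path), format=coor)
    except (RuntimeError, ValueError, KeyError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    st.setup_entities()
    model = st[0]
    atoms: list[AtomRecord] = []
    for chain in model:
        for residue in chain:
            for atom in _resolve_altlocs(residue):
                atoms.append(
                    AtomRecord(
                        chain=chain.name,
                        res_name=residue.name,
                        res_seq=residue.seqid.num,
                        icode=(residue.seqid.icode or "").strip(),
                        atom_name=atom.name,
                        element=atom.element.name.upper(),
                        pos=(atom.pos.x, atom.pos.y, atom.pos.z),
                        occupancy=atom.occ,
                    )
                )
    if not atoms:
        raise StructureError(f"{path}: no atoms")
    return StructureModel(identifier=path.stem, atoms=atoms)


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Superposition:
    rotation: np.ndarray      # 3x3, proper (det = +1)
    translation: np.ndarray   # applied after rotation
    rmsd: float               # A, over the paired atoms after transform
    n_atoms: int
    residue_range: tuple[int, int]
    atom_names: tuple[str, ...]
    unpaired: tuple[str, ...] = ()

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper rotation/translation mapping P onto Q, plus RMSD.

    Solves min_R,t ||R p_i + t - q_i||^2 by SVD of the covariance of the
    centred point sets; a reflection in the least-squares solution is
    corrected by flipping the smallest singular direction.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 2 or p.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    h = (p - pc).T @ (q - qc)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = qc - rot @ pc
    moved = p @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - q) ** 2, axis=1))))
    return rot, trans, rmsd


def superpose(
    model_a: StructureModel,
    model_b: StructureModel,
    residue_range: tuple[int, int],
    atom_names: tuple[str, ...] = BACKBONE_ATOMS,
) -> Superposition:
    """Superpose ``model_a`` onto ``model_b`` over a residue interval.

    Atoms are paired by (chain, residue number, atom name) intersection
    over the inclusive range; residues present in only one model are
    reported as unpaired.  Requires >= 3 paired atoms.
    """
    lo, hi = residue_range
    pa, pb, unpaired = [], [], []
    chains_a = {a.chain for a in model_a.atoms}
    chains_b = {b.chain for b in model_b.atoms}
    for chain in sorted(chains_a & chains_b):
        for res_seq in range(lo, hi + 1):
            for name in atom_names:
                a = model_a.get_atom(chain, res_seq, name)
                b = model_b.get_atom(chain, res_seq, name)
                if a is not None and b is not None:
                    pa.append(a.xyz)
                    pb.append(b.xyz)
                elif a is not None or b is not None:
                    which = model_a.identifier if b is None else model_b.identifier
                    unpaired.append(f"{chain}/{res_seq}/{name} only in {which}")
    if len(pa) < 3:
        raise StructureError(
            f"only {len(pa)} paired atoms in range {lo}-{hi}; need >= 3"
            + (f" (chains in common: {sorted(chains_a & chains_b)})" if not unpaired else "")
        )
    rot, trans, rmsd = kabsch(np.array(pa), np.array(pb))
    return Superposition(
        rotation=rot, translation=trans, rmsd=rmsd, n_atoms=len(pa),
        residue_range=(lo, hi), atom_names=tuple(atom_names),
        unpaired=tuple(unpaired),
    )


def measure_distance(model: StructureModel, atom_ref_a: str, atom_ref_b: str) -> float:
    """Euclidean distance (A) between two atoms given as "chain/resnum/atom"."""
    a = _resolve_atom_ref(model, atom_ref_a)
    b = _resolve_atom_ref(model, atom_ref_b)
    return float(np.linalg.norm(a.xyz - b.xyz))


def _resolve_atom_ref(model: StructureModel, ref: str) -> AtomRecord:
    parts = ref.split("/")
    if len(parts) != 3:
        raise StructureError(
            f"atom reference {ref!r} must be chain/resnum/atom_name"
        )
    chain, res, name = parts
    try:
        res_seq = int("".join(c for c in res if c.isdigit() or c == "-"))
    except ValueError as exc:
        raise StructureError(f"cannot parse residue in {ref!r}") from exc
    atom = model.get_atom(chain, res_seq, name)
    if atom is None:
        candidates = [a.label() for a in model.residue_atoms(chain, res_seq)]
        raise StructureError(
            f"atom {ref!r} not found; atoms at that residue: {candidates or 'none'}"
        )
    return atom


def write_pdb(path: str | Path, model: StructureModel) -> None:
    """Write the flat model back out as a minimal PDB file."""
    st = gemmi.Structure()
    st.name = model.identifier
    md = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for a in model.atoms:
        ch = chains.get(a.chain)
        if ch is None:
            ch = gemmi.Chain(a.chain)
            chains[a.chain] = ch
        res = None
        if len(ch) > 0:
            last = ch[len(ch) - 1]
            if last.seqid.num == a.res_seq and last.name == a.res_name:
                res = last
        if res is None:
            res = gemmi.Residue()
            res.name = a.res_name
            res.seqid = gemmi.SeqId(a.res_seq, a.icode or " ")
            if a.is_water or not a.is_standard:
                res.het_flag = "H"
            else:
                res.het_flag = "A"
            ch.add_residue(res)
            res = ch[len(ch) - 1]
        atom = gemmi.Atom()
        atom.name = a.atom_name
        atom.element = gemmi.Element(a.element)
        atom.pos = gemmi.Position(*a.pos)
        atom.occ = a.occupancy
        res.add_atom(atom)
    for ch in chains.values():
        md.add_chain(ch)
    st.add_model(md)
    st.setup_entities()
    st.write_pdb(str(path))
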