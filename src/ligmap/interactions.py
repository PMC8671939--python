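"""Geometric protein-ligand interaction detection.

Detectors for the interaction classes that describe a ligand in a binding
pocket: hydrogen bonds, salt bridges, cation-pi contacts (with the
T-shaped vs stacked distinction), CH-pi contacts, bridging waters, and
generic pocket contacts.  All criteria are distance/angle cutoffs on heavy
atoms; when hydrogens are absent (typical for crystal structures at
moderate resolution) distance-only criteria are used.

Ligand chemistry (ring atom sets, donors/acceptors, named atoms) is
declarative, keyed by het code, and never perceived from connectivity.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structures import AtomRecord, StructureModel, StructureError

# ---------------------------------------------------------------------------
# Chemistry tables for standard residues
# ---------------------------------------------------------------------------

#: Side-chain heavy-atom hydrogen-bond donors.
SIDECHAIN_DONORS: dict[str, tuple[str, ...]] = {
    "ARG": ("NE", "NH1", "NH2"),
    "ASN": ("ND2",),
    "GLN": ("NE2",),
    "HIS": ("ND1", "NE2"),
    "LYS": ("NZ",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TRP": ("NE1",),
    "TYR": ("OH",),
}

#: Side-chain hydrogen-bond acceptors.
SIDECHAIN_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "ASN": ("OD1",),
    "ASP": ("OD1", "OD2"),
    "GLN": ("OE1",),
    "GLU": ("OE1", "OE2"),
    "HIS": ("ND1", "NE2"),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
}

#: Cationic side-chain groups (atoms whose centroid locates the charge).
CATIONIC_GROUPS: dict[str, tuple[str, ...]] = {
    "ARG": ("NE", "CZ", "NH1", "NH2"),
    "LYS": ("NZ",),
}

#: Anionic side-chain oxygens.
ANIONIC_ATOMS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}

#: sp2 carbons with no attached hydrogen: excluded as CH-pi donors.
_NON_CH_CARBONS: dict[str, tuple[str, ...]] = {
    "ASP": ("CG",),
    "ASN": ("CG",),
    "GLU": ("CD",),
    "GLN": ("CD",),
    "ARG": ("CZ",),
    "PHE": ("CG",),
    "TYR": ("CG", "CZ"),
    "TRP": ("CG", "CD2", "CE2"),
    "HIS": ("CG",),
}

#: Aromatic ring atom sets of standard residues.
PROTEIN_RINGS: dict[str, dict[str, tuple[str, ...]]] = {
    "PHE": {"ring": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")},
    "TYR": {"ring": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")},
    "HIS": {"ring": ("CG", "ND1", "CD2", "CE1", "NE2")},
    "TRP": {
        "pyrrole": ("CG", "CD1", "CD2", "NE1", "CE2"),
        "benzene": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    },
}


@dataclass(frozen=True)
class LigandChemistry:
    """Declarative chemistry for one het code."""

    res_name: str
    donors: tuple[str, ...] = ()
    acceptors: tuple[str, ...] = ()
    #: ring label -> ordered ring atom names (>= 5 atoms each)
    rings: dict[str, tuple[str, ...]] = field(default_factory=dict)
    #: semantic atom labels, e.g. {"c7_hydroxyl_o": "O4"}
    named_atoms: dict[str, str] = field(default_factory=dict)


#: Shipped registry.  Real het codes from deposited entries are added via
#: ``load_ligand_config`` because component-dictionary atom nomenclature
#: must be confirmed against each file.  "LIG" is the synthetic benzene-
#: bearing test ligand emitted by the simulators.
LIGAND_CHEMISTRY: dict[str, LigandChemistry] = {
    "LIG": LigandChemistry(
        res_name="LIG",
        donors=("O1",),
        acceptors=("O1", "O2"),
        rings={"benzene": ("C1", "C2", "C3", "C4", "C5", "C6")},
        named_atoms={"hydroxyl_o": "O1", "bridging_o": "O2"},
    ),
}


def load_ligand_config(path: str | Path) -> dict[str, LigandChemistry]:
    """Load/override ligand chemistry from a JSON file.

    Layout: ``{"UCN": {"donors": [...], "acceptors": [...],
    "rings": {"label": [...]}, "named_atoms": {...}}}``.
    """
    data = json.loads(Path(path).read_text())
    out = dict(LIGAND_CHEMISTRY)
    for code, entry in data.items():
        out[code] = LigandChemistry(
            res_name=code,
            donors=tuple(entry.get("donors", ())),
            acceptors=tuple(entry.get("acceptors", ())),
            rings={k: tuple(v) for k, v in entry.get("rings", {}).items()},
            named_atoms=dict(entry.get("named_atoms", {})),
        )
    return out


# ---------------------------------------------------------------------------
# Interactions and criteria
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Interaction:
    kind: str  # hbond | salt_bridge | cation_pi | ch_pi | water_bridge | pocket_contact
    partner_a: str
    partner_b: str
    metrics: dict[str, float] = field(default_factory=dict)
    geometry_class: str | None = None

    def __str__(self) -> str:
        m = ", ".join(f"{k}={v:.2f}" for k, v in self.metrics.items())
        cls = f" [{self.geometry_class}]" if self.geometry_class else ""
        return f"{self.kind}: {self.partner_a} -- {self.partner_b} ({m}){cls}"


@dataclass(frozen=True)
class InteractionCriteria:
    hbond_max_distance: float = 3.5        # donor-acceptor heavy atoms, A
    hbond_min_angle: float = 120.0         # D-H...A, deg, if H present
    salt_bridge_max_distance: float = 4.0  # cationic N to anionic O, A
    cation_pi_max_distance: float = 6.0    # cation centroid to ring centroid
    cation_pi_stacked_max_angle: float = 30.0
    cation_pi_tshaped_min_angle: float = 60.0
    ch_pi_max_distance: float = 4.5        # carbon to ring centroid
    ch_pi_min_elevation: float = 30.0      # deg above ring plane
    water_bridge_max_distance: float = 3.5
    pocket_cutoff: float = 4.5
    ring_planarity_tolerance: float = 0.25  # max out-of-plane deviation, A


# ---------------------------------------------------------------------------
# Ring geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RingDefinition:
    """A specific aromatic ring in a specific residue of a model."""

    res_name: str
    label: str
    atom_names: tuple[str, ...]
    chain: str
    res_seq: int

    def __post_init__(self) -> None:
        if len(self.atom_names) < 5:
            raise ValueError("a ring needs >= 5 atoms")

    def site(self) -> str:
        return f"{self.chain}/{self.res_name}{self.res_seq}/{self.label}"


@dataclass(frozen=True)
class RingGeometry:
    centroid: np.ndarray
    normal: np.ndarray  # unit vector
    max_deviation: float  # worst out-of-plane distance, A


def ring_geometry(model: StructureModel, ring: RingDefinition) -> RingGeometry:
    """Centroid and unit normal of a ring by best-fit plane (SVD)."""
    coords = []
    for name in ring.atom_names:
        atom = model.get_atom(ring.chain, ring.res_seq, name)
        if atom is None:
            raise StructureError(f"ring atom {name} missing in {ring.site()}")
        coords.append(atom.xyz)
    xyz = np.array(coords)
    centroid = xyz.mean(axis=0)
    _, _, vt = np.linalg.svd(xyz - centroid)
    normal = vt[2] / np.linalg.norm(vt[2])
    deviations = np.abs((xyz - centroid) @ normal)
    return RingGeometry(centroid, normal, float(deviations.max()))


def ligand_rings(
    model: StructureModel,
    het_code: str,
    chemistry: dict[str, LigandChemistry] | None = None,
) -> list[RingDefinition]:
    """Instantiate the configured rings of a het code found in the model."""
    chem = (chemistry or LIGAND_CHEMISTRY).get(het_code)
    if chem is None:
        raise StructureError(
            f"no chemistry configured for het code {het_code!r}; "
            f"known: {sorted((chemistry or LIGAND_CHEMISTRY))}"
        )
    rings = []
    for chain, res_seq, _ in model.find_residues_by_name(het_code):
        for label, names in chem.rings.items():
            rings.append(RingDefinition(het_code, label, names, chain, res_seq))
    return rings


# ---------------------------------------------------------------------------
# Helper selections
# ---------------------------------------------------------------------------

def _polar_atoms(model: StructureModel,
                 chemistry: dict[str, LigandChemistry],
                 role: str) -> list[AtomRecord]:
    """Donor or acceptor heavy atoms across protein and configured ligands."""
    table = SIDECHAIN_DONORS if role == "donor" else SIDECHAIN_ACCEPTORS
    out = []
    for a in model.atoms:
        if a.is_water:
            continue
        if a.is_standard:
            if role == "donor" and a.atom_name == "N" and a.res_name != "PRO":
                out.append(a)
            elif role == "acceptor" and a.atom_name == "O":
                out.append(a)
            elif a.atom_name in table.get(a.res_name, ()):
                out.append(a)
        else:
            chem = chemistry.get(a.res_name)
            if chem is not None:
                names = chem.donors if role == "donor" else chem.acceptors
                if a.atom_name in names:
                    out.append(a)
    return out


def _attached_hydrogens(model: StructureModel, donor: AtomRecord) -> list[AtomRecord]:
    return [
        a for a in model.residue_atoms(donor.chain, donor.res_seq, donor.icode)
        if a.element == "H" and np.linalg.norm(a.xyz - donor.xyz) < 1.3
    ]


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle at vertex b in degrees."""
    v1, v2 = a - b, c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))


# ---------------------------------------------------------------------------
# Detectors
# ---------------------------------------------------------------------------

def detect_hbonds(
    model: StructureModel,
    criteria: InteractionCriteria = InteractionCriteria(),
    chemistry: dict[str, LigandChemistry] | None = None,
) -> list[Interaction]:
    """Hydrogen bonds by donor-acceptor heavy-atom distance.

    When the donor carries explicit hydrogens the D-H...A angle must also
    exceed the configured minimum; otherwise the distance criterion alone
    is used (heavy-atom-only crystal structures).
    """
    chem = chemistry or LIGAND_CHEMISTRY
    donors = _polar_atoms(model, chem, "donor")
    acceptors = _polar_atoms(model, chem, "acceptor")
    hits = []
    for d in donors:
        for a in acceptors:
            if d.residue_key == a.residue_key:
                continue
            dist = float(np.linalg.norm(d.xyz - a.xyz))
            if dist > criteria.hbond_max_distance or dist < 0.5:
                continue
            metrics = {"distance": dist}
            hydrogens = _attached_hydrogens(model, d)
            if hydrogens:
                best = max(
                    _angle_deg(d.xyz, h.xyz, a.xyz) for h in hydrogens
                )
                if best < criteria.hbond_min_angle:
                    continue
                metrics["angle"] = best
            hits.append(Interaction("hbond", d.label(), a.label(), metrics))
    return hits


def detect_salt_bridges(
    model: StructureModel,
    criteria: InteractionCriteria = InteractionCriteria(),
) -> list[Interaction]:
    """Cationic-N to anionic-O contacts; one hit per residue pair (min dist)."""
    cations = [
        a for a in model.atoms
        if a.atom_name in CATIONIC_GROUPS.get(a.res_name, ()) and a.element == "N"
    ]
    anions = [
        a for a in model.atoms
        if a.atom_name in ANIONIC_ATOMS.get(a.res_name, ())
    ]
    best: dict[tuple, tuple[float, AtomRecord, AtomRecord]] = {}
    for c in cations:
        for an in anions:
            dist = float(np.linalg.norm(c.xyz - an.xyz))
            if dist > criteria.salt_bridge_max_distance:
                continue
            key = (c.residue_key, an.residue_key)
            if key not in best or dist < best[key][0]:
                best[key] = (dist, c, an)
    return [
        Interaction("salt_bridge", c.label(), an.label(), {"distance": dist})
        for dist, c, an in sorted(best.values(), key=lambda t: t[0])
    ]


def _classify_cation_pi(theta: float, criteria: InteractionCriteria) -> str:
    if theta <= criteria.cation_pi_stacked_max_angle:
        return "stacked/axial"
    if theta >= criteria.cation_pi_tshaped_min_angle:
        return "T-shaped/edge"
    return "intermediate"


def detect_cation_pi(
    model: StructureModel,
    rings: list[RingDefinition],
    criteria: InteractionCriteria = InteractionCriteria(),
) -> list[Interaction]:
    """Cation-to-ring contacts classified by the normal/approach angle.

    theta is the angle between the ring normal and the centroid-to-cation
    vector, folded to [0, 90] deg: small theta means the cation sits over
    the ring face (stacked), large theta means an in-plane, T-shaped/edge
    approach.  Non-planar rings are skipped with a warning entry removed.
    """
    groups: dict[tuple, list[AtomRecord]] = {}
    for a in model.atoms:
        if a.atom_name in CATIONIC_GROUPS.get(a.res_name, ()):
            groups.setdefault(a.residue_key, []).append(a)
    hits = []
    for ring in rings:
        geom = ring_geometry(model, ring)
        if geom.max_deviation > criteria.ring_planarity_tolerance:
            continue  # non-planar ring: skip
        for key, atoms in groups.items():
            centroid = np.mean([a.xyz for a in atoms], axis=0)
            vec = centroid - geom.centroid
            dist = float(np.linalg.norm(vec))
            if dist > criteria.cation_pi_max_distance:
                continue
            cosang = abs(np.dot(vec / dist, geom.normal))
            theta = math.degrees(math.acos(np.clip(cosang, 0.0, 1.0)))
            label = f"{atoms[0].chain}/{atoms[0].res_name}{atoms[0].res_seq}/+"
            hits.append(
                Interaction(
                    "cation_pi", label, ring.site(),
                    {"distance": dist, "theta": theta},
                    geometry_class=_classify_cation_pi(theta, criteria),
                )
            )
    return sorted(hits, key=lambda i: i.metrics["distance"])


def detect_ch_pi(
    model: StructureModel,
    rings: list[RingDefinition],
    criteria: InteractionCriteria = InteractionCriteria(),
) -> list[Interaction]:
    """C-H...pi contacts: a CH carbon close to and above a ring face."""
    hits = []
    for ring in rings:
        geom = ring_geometry(model, ring)
        if geom.max_deviation > criteria.ring_planarity_tolerance:
            continue
        for a in model.atoms:
            if a.element != "C" or not a.is_standard:
                continue
            if (a.chain, a.res_seq) == (ring.chain, ring.res_seq):
                continue
            if a.atom_name in ("C",) + _NON_CH_CARBONS.get(a.res_name, ()):
                continue
            vec = a.xyz - geom.centroid
            dist = float(np.linalg.norm(vec))
            if dist > criteria.ch_pi_max_distance or dist < 0.5:
                continue
            sinang = abs(np.dot(vec / dist, geom.normal))
            elevation = math.degrees(math.asin(np.clip(sinang, 0.0, 1.0)))
            if elevation < criteria.ch_pi_min_elevation:
                continue
            hits.append(
                Interaction(
                    "ch_pi", a.label(), ring.site(),
                    {"distance": dist, "elevation": elevation},
                )
            )
    return sorted(hits, key=lambda i: i.metrics["distance"])


def detect_water_bridges(
    model: StructureModel,
    criteria: InteractionCriteria = InteractionCriteria(),
    chemistry: dict[str, LigandChemistry] | None = None,
    report_distances_to: list[str] | None = None,
) -> list[Interaction]:
    """Waters H-bonded to >= 2 polar atoms of distinct residues.

    Each bridge reports the individual leg distances and their spread
    (max - min; 0 means a perfectly equidistant bridge).  Distances from
    the bridging water to additional named atoms ("chain/resnum/atom",
    e.g. a ligand oxygen just beyond H-bond range) are reported on request.
    """
    from .structures import _resolve_atom_ref

    chem = chemistry or LIGAND_CHEMISTRY
    polar = [
        a for a in _polar_atoms(model, chem, "donor")
        + _polar_atoms(model, chem, "acceptor")
    ]
    # de-duplicate atoms present in both donor and acceptor sets
    uniq: dict[tuple, AtomRecord] = {
        (a.residue_key, a.atom_name): a for a in polar
    }
    extras = [(ref, _resolve_atom_ref(model, ref)) for ref in (report_distances_to or [])]
    hits = []
    for w in model.waters():
        partners = []
        for a in uniq.values():
            dist = float(np.linalg.norm(w.xyz - a.xyz))
            if dist <= criteria.water_bridge_max_distance:
                partners.append((dist, a))
        if len({a.residue_key for _, a in partners}) < 2:
            continue
        partners.sort(key=lambda t: t[0])
        legs = [d for d, _ in partners]
        metrics = {f"leg_{i + 1}": d for i, d in enumerate(legs)}
        metrics["spread"] = max(legs) - min(legs)
        for ref, atom in extras:
            metrics[f"dist_to[{ref}]"] = float(np.linalg.norm(w.xyz - atom.xyz))
        partner_names = " + ".join(a.label() for _, a in partners)
        hits.append(Interaction("water_bridge", w.label(), partner_names, metrics))
    return hits


def ligand_pocket_residues(
    model: StructureModel,
    ligand_selector: str,
    cutoff: float = 4.5,
) -> list[tuple[tuple[str, int, str], str, float]]:
    """Protein residues with any heavy atom within ``cutoff`` of the ligand.

    ``ligand_selector`` is a het code (e.g. "LIG") or "chain/resnum".
    Returns (residue key, residue name, min distance) sorted by distance.
    """
    if "/" in ligand_selector:
        chain, res = ligand_selector.split("/")
        lig_atoms = [
            a for a in model.residue_atoms(chain, int(res)) if a.element != "H"
        ]
    else:
        lig_atoms = [
            a for a in model.heavy_atoms() if a.res_name == ligand_selector
        ]
    if not lig_atoms:
        available = [f"{c}/{n}{s}" for c, s, n in model.het_residues()]
        raise StructureError(
            f"ligand {ligand_selector!r} not found; het residues present: "
            f"{available or 'none'}"
        )
    lig_xyz = np.array([a.xyz for a in lig_atoms])
    best: dict[tuple, tuple[str, float]] = {}
    for a in model.heavy_atoms():
        if not a.is_standard:
            continue
        dmin = float(np.min(np.linalg.norm(lig_xyz - a.xyz, axis=1)))
        if dmin > cutoff:
            continue
        key = a.residue_key
        if key not in best or dmin < best[key][1]:
            best[key] = (a.res_name, dmin)
    return sorted(
        ((key, name, d) for key, (name, d) in best.items()),
        key=lambda t: t[2],
    )


def write_interactions_tsv(path, interactions: list[Interaction]) -> None:
    with open(path, "w") as fh:
        fh.write("kind\tpartner_a\tpartner_b\tgeometry_class\tmetrics\n")
        for i in interactions:
            metrics = ";".join(f"{k}={v:.3f}" for k, v in i.metrics.items())
            fh.write(
                f"{i.kind}\t{i.partner_a}\t{i.partner_b}\t"
                f"{i.geometry_class or ''}\t{metrics}\n"
            )
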