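"""Shared fixtures: the AGP2 construct and hand-built coordinate models."""

from __future__ import annotations

import math

import numpy as np
import pytest

from ligmap import agp2
from ligmap.sequences import Construct, cleave_construct
from ligmap.structures import AtomRecord, StructureModel


@pytest.fixture(scope="session")
def agp2_construct() -> Construct:
    return Construct(
        raw_sequence=agp2.AGP2_FL_RAW_SEQUENCE,
        tag_region=agp2.AGP2_TAG_REGION,
        extension=agp2.AGP2_EXTENSION,
        mature_offset=agp2.AGP2_MATURE_OFFSET,
        stop_position=agp2.AGP2_STOP_POSITION,
    )


@pytest.fixture(scope="session")
def agp2_mature(agp2_construct) -> str:
    return cleave_construct(agp2_construct).mature_sequence


def _atom(chain, res_name, res_seq, name, pos, element=None):
    if element is None:
        element = name[0]
    return AtomRecord(
        chain=chain, res_name=res_name, res_seq=res_seq, icode="",
        atom_name=name, element=element,
        pos=(float(pos[0]), float(pos[1]), float(pos[2])),
    )


def make_model(atoms, identifier="fixture") -> StructureModel:
    return StructureModel(identifier, list(atoms))


@pytest.fixture
def binding_site_model() -> StructureModel:
    """A small hand-built pocket around a benzene-bearing ligand "LIG".

    Geometry (ligand ring in the z=0 plane, centred at the origin):

    * LIG benzene C1-C6, radius 1.39 A; hydroxyl O1 at (2.5, 0, 0);
      "bridging" O2 at (0, 3.0, 2.0).
    * ARG 90 guanidinium group centred in the ring plane 4.5 A from the
      ring centroid -> T-shaped cation-pi; its NH1 sits 2.9 A from
      GLU 64 OE1 -> salt bridge.
    * PHE 112 CE1 carbon 3.6 A directly above the ring centroid -> CH-pi.
    * SER 114 OG and SER 125 OG flank a water oxygen at 2.8 A each
      (equidistant bridge); the water sits ~3.8 A from LIG O2.
    * SER 147 OG 2.8 A from LIG O1 -> hydrogen bond.
    """
    atoms = []
    for i in range(6):
        ang = math.radians(60 * i)
        atoms.append(_atom("A", "LIG", 201, f"C{i + 1}",
                           (1.39 * math.cos(ang), 1.39 * math.sin(ang), 0.0)))
    atoms.append(_atom("A", "LIG", 201, "O1", (2.5, 0.0, 0.0)))
    atoms.append(_atom("A", "LIG", 201, "O2", (0.0, 3.0, 2.0)))

    # ARG 90 guanidinium: 4-atom centroid (4.5, 0, 0.3), near in-plane
    for name, off in (("NE", (-0.6, -0.6, 0.0)), ("CZ", (0.0, 0.0, 0.0)),
                      ("NH1", (0.6, 0.6, 0.0)), ("NH2", (0.0, 0.0, 1.2))):
        atoms.append(_atom("A", "ARG", 90, name,
                           (4.5 + off[0], off[1], off[2])))
    # GLU 64 OE1 exactly 2.9 A from ARG NH1 at (5.1, 0.6, 0)
    atoms.append(_atom("A", "GLU", 64, "OE1", (8.0, 0.6, 0.0)))
    atoms.append(_atom("A", "GLU", 64, "OE2", (8.6, 1.6, 0.0)))

    # PHE 112 CE1 directly above ring centroid
    atoms.append(_atom("A", "PHE", 112, "CE1", (0.0, 0.0, 3.6)))

    # water bridge between SER 114 OG and SER 125 OG; 3.8 A from LIG O2
    w = np.array([0.0, 6.8, 2.0])
    atoms.append(_atom("A", "SER", 114, "OG", tuple(w + [2.8, 0.0, 0.0])))
    atoms.append(_atom("A", "SER", 125, "OG", tuple(w + [-2.8, 0.0, 0.0])))
    atoms.append(_atom("W", "HOH", 301, "O", tuple(w)))

    # SER 147 OG H-bonded to LIG O1
    atoms.append(_atom("A", "SER", 147, "OG", (2.5, 2.8, 0.0)))
    return make_model(atoms, "binding_site")


MINIMAL_PDB = """\
CRYST1   50.000   50.000   50.000  90.00  90.00  90.00 P 1           1
ATOM      1  N   ALA A  11      11.000  10.000  10.000  1.00 20.00           N
ATOM      2  CA  ALA A  11      12.000  10.500  10.200  1.00 20.00           C
ATOM      3  C   ALA A  11      13.000  11.000  10.400  1.00 20.00           C
ATOM      4  O   ALA A  11      13.500  12.000  10.600  1.00 20.00           O
ATOM      5  N   GLY A  12      14.000  10.000  11.000  1.00 20.00           N
ATOM      6  CA  GLY A  12      15.000  10.500  11.200  1.00 20.00           C
ATOM      7  C   GLY A  12      16.000  11.000  11.400  1.00 20.00           C
ATOM      8  O   GLY A  12      16.500  12.000  11.600  1.00 20.00           O
ATOM      9  N   SER A  13      17.000  10.000  12.000  1.00 20.00           N
ATOM     10  CA  SER A  13      18.000  10.500  12.200  1.00 20.00           C
ATOM     11  C   SER A  13      19.000  11.000  12.400  1.00 20.00           C
ATOM     12  O   SER A  13      19.500  12.000  12.600  1.00 20.00           O
TER
END
"""


@pytest.fixture
def minimal_pdb(tmp_path):
    path = tmp_path / "minimal.pdb"
    path.write_text(MINIMAL_PDB)
    return path
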