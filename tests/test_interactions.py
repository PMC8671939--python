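"""Geometric interaction detectors on a hand-built binding-site model."""

import math

import numpy as np
import pytest

from ligmap.interactions import (
    InteractionCriteria,
    LigandChemistry,
    RingDefinition,
    detect_cation_pi,
    detect_ch_pi,
    detect_hbonds,
    detect_salt_bridges,
    detect_water_bridges,
    ligand_pocket_residues,
    ligand_rings,
    load_ligand_config,
    ring_geometry,
)
from ligmap.structures import AtomRecord, StructureError, StructureModel

CRITERIA = InteractionCriteria()


def _atom(chain, res_name, res_seq, name, pos, element=None):
    return AtomRecord(chain, res_name, res_seq, "", name,
                      element or name[0], tuple(float(v) for v in pos))


def benzene(chain="A", res_name="LIG", res_seq=201, z=0.0):
    return [
        _atom(chain, res_name, res_seq, f"C{i + 1}",
              (1.39 * math.cos(math.radians(60 * i)),
               1.39 * math.sin(math.radians(60 * i)), z))
        for i in range(6)
    ]


def ring_def(res_seq=201):
    return RingDefinition("LIG", "benzene",
                          ("C1", "C2", "C3", "C4", "C5", "C6"), "A", res_seq)


class TestRingGeometry:
    def test_centroid_and_unit_normal(self):
        model = StructureModel("m", benzene())
        geom = ring_geometry(model, ring_def())
        assert geom.centroid == pytest.approx([0, 0, 0], abs=1e-12)
        assert np.linalg.norm(geom.normal) == pytest.approx(1.0)
        assert abs(geom.normal[2]) == pytest.approx(1.0)
        assert geom.max_deviation == pytest.approx(0.0, abs=1e-12)

    def test_fewer_than_five_atoms_rejected(self):
        with pytest.raises(ValueError):
            RingDefinition("LIG", "bad", ("C1", "C2", "C3", "C4"), "A", 1)

    def test_nonplanar_ring_skipped_by_detectors(self):
        atoms = benzene()
        bent = atoms[0]
        atoms[0] = _atom("A", "LIG", 201, "C1",
                         (bent.pos[0], bent.pos[1], 1.5))
        atoms.append(_atom("A", "ARG", 1, "NZ", (0, 0, 4.0), "N"))
        atoms.append(_atom("A", "LYS", 1, "NZ", (0, 0, 4.0), "N"))
        model = StructureModel("m", atoms)
        assert detect_cation_pi(model, [ring_def()], CRITERIA) == []


class TestHbonds:
    def test_pair_at_2p8_detected(self):
        model = StructureModel("m", [
            _atom("A", "SER", 1, "OG", (0, 0, 0)),
            _atom("A", "ASN", 2, "OD1", (2.8, 0, 0)),
        ])
        hits = detect_hbonds(model, CRITERIA)
        assert any(h.metrics["distance"] == pytest.approx(2.8) for h in hits)

    def test_pair_at_4p2_not_detected(self):
        model = StructureModel("m", [
            _atom("A", "SER", 1, "OG", (0, 0, 0)),
            _atom("A", "ASN", 2, "OD1", (4.2, 0, 0)),
        ])
        assert detect_hbonds(model, CRITERIA) == []

    def test_angle_criterion_applies_when_hydrogens_present(self):
        # donor H pointing away from the acceptor: D-H...A angle ~ 0
        model = StructureModel("m", [
            _atom("A", "SER", 1, "OG", (0, 0, 0)),
            _atom("A", "SER", 1, "HG", (-0.95, 0, 0), "H"),
            _atom("A", "ASN", 2, "OD1", (2.8, 0, 0)),
        ])
        assert detect_hbonds(model, CRITERIA) == []
        # H between donor and acceptor: angle 180
        model2 = StructureModel("m", [
            _atom("A", "SER", 1, "OG", (0, 0, 0)),
            _atom("A", "SER", 1, "HG", (0.95, 0, 0), "H"),
            _atom("A", "ASN", 2, "OD1", (2.8, 0, 0)),
        ])
        hits = detect_hbonds(model2, CRITERIA)
        assert hits and hits[0].metrics["angle"] == pytest.approx(180.0)

    def test_ligand_hydroxyl_to_serine(self, binding_site_model):
        hits = detect_hbonds(binding_site_model, CRITERIA)
        labels = {(h.partner_a, h.partner_b) for h in hits}
        assert ("A/SER147/OG", "A/LIG201/O1") in labels


class TestSaltBridges:
    def test_arg_glu_pair_detected_with_min_distance(self, binding_site_model):
        hits = detect_salt_bridges(binding_site_model, CRITERIA)
        arg_glu = [h for h in hits if "ARG90" in h.partner_a and "GLU64" in h.partner_b]
        assert len(arg_glu) == 1  # one hit per residue pair
        assert arg_glu[0].metrics["distance"] == pytest.approx(2.9, abs=1e-6)

    def test_pair_at_6a_not_detected(self):
        model = StructureModel("m", [
            _atom("A", "ARG", 1, "NH1", (0, 0, 0), "N"),
            _atom("A", "GLU", 2, "OE1", (6.0, 0, 0)),
        ])
        assert detect_salt_bridges(model, CRITERIA) == []


class TestCationPi:
    def test_axial_cation_is_stacked(self):
        atoms = benzene() + [_atom("A", "LYS", 10, "NZ", (0, 0, 4.0), "N")]
        hits = detect_cation_pi(StructureModel("m", atoms), [ring_def()], CRITERIA)
        assert len(hits) == 1
        assert hits[0].geometry_class == "stacked/axial"
        assert hits[0].metrics["distance"] == pytest.approx(4.0)

    def test_in_plane_cation_is_t_shaped(self):
        atoms = benzene() + [_atom("A", "LYS", 10, "NZ", (4.5, 0, 0), "N")]
        hits = detect_cation_pi(StructureModel("m", atoms), [ring_def()], CRITERIA)
        assert hits[0].geometry_class == "T-shaped/edge"
        assert hits[0].metrics["theta"] == pytest.approx(90.0)

    def test_guanidinium_edge_approach_in_pocket(self, binding_site_model):
        rings = ligand_rings(binding_site_model, "LIG")
        hits = detect_cation_pi(binding_site_model, rings, CRITERIA)
        arg = [h for h in hits if "ARG90" in h.partner_a]
        assert arg and arg[0].geometry_class == "T-shaped/edge"

    def test_beyond_cutoff_ignored(self):
        atoms = benzene() + [_atom("A", "LYS", 10, "NZ", (0, 0, 6.5), "N")]
        assert detect_cation_pi(StructureModel("m", atoms), [ring_def()], CRITERIA) == []


class TestChPi:
    def test_carbon_above_centroid_detected(self, binding_site_model):
        rings = ligand_rings(binding_site_model, "LIG")
        hits = detect_ch_pi(binding_site_model, rings, CRITERIA)
        assert any("PHE112" in h.partner_a for h in hits)
        phe = next(h for h in hits if "PHE112" in h.partner_a)
        assert phe.metrics["distance"] == pytest.approx(3.6)
        assert phe.metrics["elevation"] == pytest.approx(90.0)

    def test_in_plane_carbon_rejected(self):
        atoms = benzene() + [_atom("A", "LEU", 10, "CD1", (3.6, 0, 0))]
        assert detect_ch_pi(StructureModel("m", atoms), [ring_def()], CRITERIA) == []

    def test_carbonyl_carbon_not_a_donor(self):
        atoms = benzene() + [_atom("A", "GLY", 10, "C", (0, 0, 3.6))]
        assert detect_ch_pi(StructureModel("m", atoms), [ring_def()], CRITERIA) == []


class TestWaterBridges:
    def test_equidistant_serine_bridge(self, binding_site_model):
        hits = detect_water_bridges(binding_site_model, CRITERIA)
        assert len(hits) == 1
        bridge = hits[0]
        assert "SER114" in bridge.partner_b and "SER125" in bridge.partner_b
        assert bridge.metrics["spread"] == pytest.approx(0.0, abs=1e-9)
        assert bridge.metrics["leg_1"] == pytest.approx(2.8)

    def test_distance_to_named_nonbonded_atom_reported(self, binding_site_model):
        hits = detect_water_bridges(binding_site_model, CRITERIA,
                                    report_distances_to=["A/201/O2"])
        assert hits[0].metrics["dist_to[A/201/O2]"] == pytest.approx(3.8, abs=1e-6)

    def test_single_partner_is_no_bridge(self):
        model = StructureModel("m", [
            _atom("A", "SER", 1, "OG", (0, 0, 0)),
            _atom("W", "HOH", 50, "O", (2.8, 0, 0)),
        ])
        assert detect_water_bridges(model, CRITERIA) == []


class TestPocket:
    def test_nearby_residue_listed_with_min_distance(self, binding_site_model):
        pocket = ligand_pocket_residues(binding_site_model, "LIG", cutoff=4.5)
        names = {f"{name}{key[1]}" for key, name, _ in pocket}
        assert {"ARG90", "PHE112", "SER147"} <= names
        dists = [d for _, _, d in pocket]
        assert dists == sorted(dists)

    def test_tiny_cutoff_gives_empty_list(self, binding_site_model):
        assert ligand_pocket_residues(binding_site_model, "LIG", cutoff=0.1) == []

    def test_missing_ligand_error_names_het_residues(self, binding_site_model):
        with pytest.raises(StructureError, match="LIG"):
            ligand_pocket_residues(binding_site_model, "XYZ")


class TestSelfAudit:
    def test_every_reported_metric_respects_its_cutoff(self, binding_site_model):
        """Detectors never emit a hit outside their own configured cutoffs."""
        rings = ligand_rings(binding_site_model, "LIG")
        for hit in detect_hbonds(binding_site_model, CRITERIA):
            assert hit.metrics["distance"] <= CRITERIA.hbond_max_distance
        for hit in detect_salt_bridges(binding_site_model, CRITERIA):
            assert hit.metrics["distance"] <= CRITERIA.salt_bridge_max_distance
        for hit in detect_cation_pi(binding_site_model, rings, CRITERIA):
            assert hit.metrics["distance"] <= CRITERIA.cation_pi_max_distance
        for hit in detect_ch_pi(binding_site_model, rings, CRITERIA):
            assert hit.metrics["distance"] <= CRITERIA.ch_pi_max_distance
            assert hit.metrics["elevation"] >= CRITERIA.ch_pi_min_elevation

    def test_detectors_idempotent(self, binding_site_model):
        first = detect_hbonds(binding_site_model, CRITERIA)
        second = detect_hbonds(binding_site_model, CRITERIA)
        assert first == second


def test_ligand_config_override(tmp_path):
    cfg = tmp_path / "ligands.json"
    cfg.write_text('{"UCN": {"rings": {"central": ["C1","C2","C3","C4","C5","C6"]},'
                   ' "donors": ["O4"], "acceptors": ["O4"],'
                   ' "named_atoms": {"c7_hydroxyl_o": "O4"}}}')
    chem = load_ligand_config(cfg)
    assert "LIG" in chem  # shipped entries preserved
    assert chem["UCN"].rings["central"][0] == "C1"
    assert chem["UCN"].named_atoms["c7_hydroxyl_o"] == "O4"
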