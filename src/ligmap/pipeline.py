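"""End-to-end orchestration of the analysis stages.

A single plain-text config drives the five analysis stages (sequence
report, chemical-shift mapping, relaxation profiling, structure
comparison + interactions, thermodynamics).  Threshold keys carry their
units in the name; the defaults reproduce the AGP2-UCN-01 analysis
parameters exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

from . import agp2, csp, interactions, relaxation, sequences, structures, thermo

_BOOL = {"true": True, "false": False}


@dataclass
class PipelineConfig:
    # stage toggles
    run_seq: bool = True
    run_csp: bool = True
    run_relax: bool = True
    run_compare: bool = True
    run_interactions: bool = True
    run_thermo: bool = True
    # inputs
    construct_config: str = ""
    free_peaks: str = ""
    bound_peaks: str = ""
    decays: str = ""
    noe: str = ""
    structure_ref: str = ""
    structure_alt: str = ""
    interactions_model: str = ""
    ligand_het_code: str = "LIG"
    # chemical-shift mapping parameters
    range_h_ppm: float = agp2.CSP_RANGE_H_PPM
    range_n_ppm: float = agp2.CSP_RANGE_N_PPM
    gate_h_ppm: float = agp2.CSP_GATE_H_PPM
    gate_n_ppm: float = agp2.CSP_GATE_N_PPM
    height_floor_fraction: float = agp2.CSP_HEIGHT_FLOOR_FRACTION
    match_strategy: str = "global"
    # superposition
    superpose_start: int = agp2.SUPERPOSITION_RANGE[0]
    superpose_end: int = agp2.SUPERPOSITION_RANGE[1]
    superpose_atoms: str = "N,CA,C,O"
    # interaction cutoffs
    hbond_max_a: float = 3.5
    salt_bridge_max_a: float = 4.0
    cation_pi_max_a: float = 6.0
    ch_pi_max_a: float = 4.5
    water_bridge_max_a: float = 3.5
    pocket_cutoff_a: float = 4.5
    # thermodynamics
    kd_a_nm: float = agp2.KD_STAUROSPORINE_NM
    kd_b_nm: float = agp2.KD_UCN01_NM
    temperature_k: float = agp2.DEFAULT_TEMPERATURE_K
    tm_free_c: float = agp2.TM_FREE_C
    tm_bound_c: float = agp2.TM_BOUND_C
    # misc
    out_dir: str = "ligmap_out"
    seed: int = 0

    # -- plain-text round trip -------------------------------------------

    def dump(self) -> str:
        lines = []
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if isinstance(value, bool):
                value = "true" if value else "false"
            lines.append(f"{f.name} = {value}")
        return "\n".join(lines) + "\n"

    @classmethod
    def load(cls, text: str) -> "PipelineConfig":
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in fields:
                raise ValueError(f"unknown config key {key!r}")
            ftype = fields[key].type
            if ftype == "bool":
                kwargs[key] = _BOOL[val.lower()]
            elif ftype == "int":
                kwargs[key] = int(val)
            elif ftype == "float":
                kwargs[key] = float(val)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    @classmethod
    def load_file(cls, path: str | Path) -> "PipelineConfig":
        return cls.load(Path(path).read_text())

    def interaction_criteria(self) -> interactions.InteractionCriteria:
        return interactions.InteractionCriteria(
            hbond_max_distance=self.hbond_max_a,
            salt_bridge_max_distance=self.salt_bridge_max_a,
            cation_pi_max_distance=self.cation_pi_max_a,
            ch_pi_max_distance=self.ch_pi_max_a,
            water_bridge_max_distance=self.water_bridge_max_a,
            pocket_cutoff=self.pocket_cutoff_a,
        )


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages and write a consolidated report.

    Each stage writes its own TSV under ``out_dir``; a ``report.json``
    collects summaries, parameters, the seed, and per-stage status.  A
    stage whose input is missing is skipped with an explicit error entry
    rather than aborting the run.  Stage inputs are checksummed before
    and after the run to guarantee no stage mutates another's inputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "parameters": {
            f.name: getattr(config, f.name) for f in dataclasses.fields(config)
        },
        "seed": config.seed,
        "stages": {},
        "errors": [],
    }
    inputs = [
        Path(p) for p in (
            config.construct_config, config.free_peaks, config.bound_peaks,
            config.decays, config.noe, config.structure_ref,
            config.structure_alt, config.interactions_model,
        ) if p and Path(p).exists()
    ]
    checksums_before = {str(p): _checksum(p) for p in inputs}

    def stage(name, enabled, paths, fn):
        if not enabled:
            report["stages"][name] = {"status": "disabled"}
            return
        missing = [p for p in paths if not p or not Path(p).exists()]
        if missing:
            report["stages"][name] = {"status": "skipped"}
            report["errors"].append(f"{name}: missing input(s) {missing}")
            return
        try:
            report["stages"][name] = {"status": "ok", **fn()}
        except Exception as exc:  # stage isolation: one failure never aborts the run
            report["stages"][name] = {"status": "failed"}
            report["errors"].append(f"{name}: {exc}")

    # -- sequence ---------------------------------------------------------
    def do_seq():
        construct = sequences.load_construct_config(config.construct_config)
        rep = sequences.construct_report(construct)
        (out / "sequence_report.json").write_text(json.dumps(
            {
                "mature_length": rep["mature_length"],
                "sequons": [s.position for s in rep["sequons"]],
                "cysteines": rep["cysteines"],
                "residues_removed": rep.get("residues_removed"),
            }, indent=2))
        return {
            "mature_length": rep["mature_length"],
            "n_sequons": len(rep["sequons"]),
            "n_cysteines": len(rep["cysteines"]),
            "residues_removed": rep.get("residues_removed"),
        }

    stage("seq", config.run_seq, [config.construct_config], do_seq)

    # -- chemical-shift mapping ------------------------------------------
    def do_csp():
        from .peaks import read_peaklist
        free = read_peaklist(config.free_peaks)
        bound = read_peaklist(config.bound_peaks)
        gates = csp.GateSpec(config.gate_h_ppm, config.gate_n_ppm,
                             config.height_floor_fraction)
        free_f, _ = csp.filter_by_height(free, gates.height_floor_fraction)
        bound_f, _ = csp.filter_by_height(bound, gates.height_floor_fraction)
        weight = csp.compute_weight(config.range_h_ppm, config.range_n_ppm)
        mapping = csp.reverse_assign(free_f, bound_f, weight, gates,
                                     strategy=config.match_strategy)
        profile = csp.minimal_shift_profile(mapping, bound_f)
        csp.write_mapping_tsv(out / "csp_mapping.tsv", mapping)
        csp.write_profile_tsv(out / "csp_profile.tsv", profile)
        return {
            "weight": weight.weight,
            "n_matched": len(mapping.pairs),
            "n_bound_only": len(mapping.unmatched_bound),
            "n_unmatched_free": len(mapping.unmatched_free),
        }

    stage("csp", config.run_csp, [config.free_peaks, config.bound_peaks], do_csp)

    # -- relaxation -------------------------------------------------------
    def do_relax():
        decays = relaxation.read_decays_tsv(config.decays)
        noe = relaxation.read_noe_tsv(config.noe) if config.noe else None
        results = relaxation.analyse_relaxation(decays, noe)
        profile = relaxation.mobility_profile(results)
        relaxation.write_results_tsv(out / "relaxation.tsv", results, profile)
        return {
            "n_residues": len(results),
            "fast_motion_residues": profile.fast_motion_residues,
            "low_t2_patches": profile.low_t2_patches,
        }

    stage("relax", config.run_relax, [config.decays], do_relax)

    # -- structure comparison --------------------------------------------
    def do_compare():
        ref = structures.read_structure(config.structure_ref)
        alt = structures.read_structure(config.structure_alt)
        sup = structures.superpose(
            ref, alt,
            (config.superpose_start, config.superpose_end),
            tuple(config.superpose_atoms.split(",")),
        )
        return {"rmsd_a": sup.rmsd, "n_atoms": sup.n_atoms}

    stage("compare", config.run_compare,
          [config.structure_ref, config.structure_alt], do_compare)

    # -- interactions -----------------------------------------------------
    def do_interactions():
        model = structures.read_structure(config.interactions_model)
        criteria = config.interaction_criteria()
        found = interactions.detect_hbonds(model, criteria)
        found += interactions.detect_salt_bridges(model, criteria)
        try:
            rings = interactions.ligand_rings(model, config.ligand_het_code)
        except structures.StructureError:
            rings = []
        if rings:
            found += interactions.detect_cation_pi(model, rings, criteria)
            found += interactions.detect_ch_pi(model, rings, criteria)
        found += interactions.detect_water_bridges(model, criteria)
        interactions.write_interactions_tsv(out / "interactions.tsv", found)
        return {"n_interactions": len(found),
                "by_kind": {k: sum(1 for i in found if i.kind == k)
                            for k in sorted({i.kind for i in found})}}

    stage("interactions", config.run_interactions,
          [config.interactions_model], do_interactions)

    # -- thermodynamics ---------------------------------------------------
    def do_thermo():
        aff = thermo.AffinityPair(config.kd_a_nm, config.kd_b_nm,
                                  config.temperature_k)
        tm = thermo.ThermalPair(config.tm_free_c, config.tm_bound_c)
        return {
            "ddg_kj_mol": thermo.delta_delta_g(aff),
            "fold_change": thermo.fold_change(aff),
            "delta_tm_c": thermo.delta_tm(tm),
        }

    stage("thermo", config.run_thermo, [], do_thermo)

    # input integrity audit
    checksums_after = {str(p): _checksum(p) for p in inputs}
    if checksums_after != checksums_before:
        report["errors"].append("input files were modified during the run")
    report["ok"] = not report["errors"]
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
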