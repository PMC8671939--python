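"""Ground-truth-bearing synthetic inputs for every pipeline stage.

The generators emulate the statistical structure the analyses assume:

* paired bound/free amide peak lists where binding-pocket residues carry
  large chemical-shift perturbations (some beyond the matching gates),
  the rest of the chain shifts only slightly, a fraction of free-state
  peaks is lost to exchange broadening, and heights are log-normal;
* mono-exponential T1/T2 decay series on the experimental delay
  schedules with Gaussian noise, plus NOE intensity pairs, with uniform
  core dynamics and mobile termini;
* rigid-body-transformed, noise-perturbed copies of an idealised
  backbone with a known expected RMSD.

Everything is driven by one seeded generator: a fixed seed gives
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from . import agp2
from .peaks import Peak, write_peaklist_tsv
from .relaxation import RelaxSeries
from .structures import AtomRecord, StructureModel, write_pdb

_AA_CHOICES = "ACDEFGHIKLMNQRSTVWY"  # no proline: prolines give no amide peak


@dataclass(frozen=True)
class SimulationSpec:
    """Study-scale defaults for all three generators."""

    seed: int = 0
    # -- peak lists -------------------------------------------------------
    n_residues: int = 160           # observable amides of a ~170-aa construct
    pocket_fraction: float = 0.1    # fraction of residues in the binding site
    beyond_gate_fraction: float = 0.5  # pocket shifts too large to match
    core_sigma_h: float = 0.01      # ppm, small shifts of non-pocket residues
    core_sigma_n: float = 0.05      # ppm
    pocket_dh_range: tuple[float, float] = (0.03, 0.09)   # within-gate pocket
    pocket_dn_range: tuple[float, float] = (0.2, 0.6)
    dropout_fraction: float = 0.3   # free peaks lost to exchange broadening
    height_median: float = 1e5
    height_sigma: float = 0.6       # log-normal sigma of peak heights
    gate_h: float = agp2.CSP_GATE_H_PPM
    gate_n: float = agp2.CSP_GATE_N_PPM
    # -- relaxation -------------------------------------------------------
    core_t1_s: float = 0.85
    core_t2_s: float = 0.07
    core_noe: float = 0.80
    n_terminal: int = 3             # mobile residues at each terminus
    terminal_ratio_scale: float = 0.5  # T1/T2 at termini relative to core
    terminal_noe_scale: float = 0.5
    noise_fraction: float = 0.02    # Gaussian noise as a fraction of I0
    i0: float = 1000.0
    t1_delays_ms: tuple[float, ...] = tuple(agp2.T1_DELAYS_MS)
    t2_delays_ms: tuple[float, ...] = tuple(agp2.T2_DELAYS_MS)
    # -- structures -------------------------------------------------------
    n_structure_residues: int = 125  # 4 backbone atoms each -> 500 atoms
    coord_sigma: float = 0.3         # A, isotropic per-atom noise
    max_translation: float = 20.0    # A

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# Peak lists
# ---------------------------------------------------------------------------

@dataclass
class PeakListTruth:
    """Ground truth for scoring a recovered mapping."""

    mapping: dict[str, str]            # bound id -> free id (surviving pairs)
    pocket_residues: list[int]
    beyond_gate_residues: list[int]    # perturbed past at least one gate
    dropped_free_residues: list[int]


def simulate_peaklists(
    spec: SimulationSpec,
) -> tuple[list[Peak], list[Peak], PeakListTruth]:
    """Paired bound (assigned) and free (unassigned) peak lists.

    Bound shifts are drawn over realistic amide ranges (1H 6.5-11 ppm,
    15N 105-135 ppm).  Free = bound + per-residue perturbation: pocket
    residues get large shifts, a configured fraction of them beyond the
    matching gates; everything else gets small shifts.  Dropout then
    removes a fraction of free peaks.
    """
    rng = spec.rng()
    n = spec.n_residues
    residues = np.arange(1, n + 1)
    shift_h = rng.uniform(6.5, 11.0, n)
    shift_n = rng.uniform(105.0, 135.0, n)
    aa = rng.choice(list(_AA_CHOICES), n)
    heights = spec.height_median * rng.lognormal(0.0, spec.height_sigma, n)

    n_pocket = int(round(spec.pocket_fraction * n))
    pocket = sorted(rng.choice(residues, size=n_pocket, replace=False).tolist())
    n_beyond = int(round(spec.beyond_gate_fraction * n_pocket))
    beyond = sorted(rng.choice(pocket, size=n_beyond, replace=False).tolist()) if pocket else []

    dh = rng.normal(0.0, spec.core_sigma_h, n)
    dn = rng.normal(0.0, spec.core_sigma_n, n)
    for res in pocket:
        i = res - 1
        sign_h, sign_n = rng.choice([-1.0, 1.0], 2)
        if res in beyond:
            # past at least the 1H gate by construction
            dh[i] = sign_h * rng.uniform(1.5, 4.0) * spec.gate_h
            dn[i] = sign_n * rng.uniform(1.0, 2.0) * spec.gate_n
        else:
            dh[i] = sign_h * rng.uniform(*spec.pocket_dh_range)
            dn[i] = sign_n * rng.uniform(*spec.pocket_dn_range)

    bound = [
        Peak(
            id=f"b{res}",
            shift_h=float(shift_h[i]),
            shift_n=float(shift_n[i]),
            height=float(heights[i]),
            assignment=f"{aa[i]}{res}",
        )
        for i, res in enumerate(residues)
    ]
    keep = rng.uniform(size=n) >= spec.dropout_fraction
    free = [
        Peak(
            id=f"f{res}",
            shift_h=float(shift_h[i] + dh[i]),
            shift_n=float(shift_n[i] + dn[i]),
            height=float(heights[i] * rng.lognormal(0.0, 0.1)),
        )
        for i, res in enumerate(residues)
        if keep[i]
    ]
    truth = PeakListTruth(
        mapping={f"b{res}": f"f{res}" for i, res in enumerate(residues) if keep[i]},
        pocket_residues=pocket,
        beyond_gate_residues=beyond,
        dropped_free_residues=[int(r) for i, r in enumerate(residues) if not keep[i]],
    )
    return bound, free, truth


# ---------------------------------------------------------------------------
# Relaxation
# ---------------------------------------------------------------------------

@dataclass
class RelaxTruth:
    t1_s: dict[int, float]
    t2_s: dict[int, float]
    noe: dict[int, float]
    terminal_residues: list[int]


def simulate_relaxation(
    spec: SimulationSpec,
    n_residues: int | None = None,
) -> tuple[list[RelaxSeries], dict[int, tuple[float, float, float, float]], RelaxTruth]:
    """T1/T2 decay tables on the experimental delay grids, plus NOE pairs.

    Core residues share one (T1, T2, NOE) triple; the first and last
    ``n_terminal`` residues are scaled toward fast internal motion (lower
    T1/T2 ratio and NOE).  Gaussian noise is added at ``noise_fraction``
    of the reference intensity.
    """
    rng = spec.rng()
    n = n_residues if n_residues is not None else 60
    s = np.sqrt(spec.terminal_ratio_scale)
    terminal = [r for r in range(1, n + 1)
                if r <= spec.n_terminal or r > n - spec.n_terminal]
    t1_truth, t2_truth, noe_truth = {}, {}, {}
    for res in range(1, n + 1):
        if res in terminal:
            t1_truth[res] = spec.core_t1_s * s
            t2_truth[res] = spec.core_t2_s / s
            noe_truth[res] = spec.core_noe * spec.terminal_noe_scale
        else:
            t1_truth[res] = spec.core_t1_s
            t2_truth[res] = spec.core_t2_s
            noe_truth[res] = spec.core_noe

    series: list[RelaxSeries] = []
    noe_pairs: dict[int, tuple[float, float, float, float]] = {}
    sigma = spec.noise_fraction * spec.i0
    for res in range(1, n + 1):
        for experiment, delays, tau in (
            ("T1", spec.t1_delays_ms, t1_truth[res]),
            ("T2", spec.t2_delays_ms, t2_truth[res]),
        ):
            t = np.asarray(delays) / 1000.0
            y = spec.i0 * np.exp(-t / tau)
            if sigma > 0:
                y = y + rng.normal(0.0, sigma, len(t))
            series.append(
                RelaxSeries(res, tuple(delays), tuple(float(v) for v in y), experiment)
            )
        i_ref = spec.i0 + (rng.normal(0.0, sigma) if sigma > 0 else 0.0)
        i_sat = noe_truth[res] * spec.i0 + (rng.normal(0.0, sigma) if sigma > 0 else 0.0)
        noe_pairs[res] = (float(i_sat), float(i_ref), sigma, sigma)

    truth = RelaxTruth(t1_truth, t2_truth, noe_truth, terminal)
    return series, noe_pairs, truth


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------

def _ideal_backbone(n_residues: int) -> list[AtomRecord]:
    """Idealised helical backbone (N, CA, C, O per residue) as chain A."""
    atoms = []
    radius, rise, twist = 2.3, 1.5, np.deg2rad(100.0)
    offsets = {
        "N": np.array([-0.8, -0.9, -0.4]),
        "CA": np.zeros(3),
        "C": np.array([0.9, 0.7, 0.5]),
        "O": np.array([1.1, 1.7, 0.9]),
    }
    for i in range(n_residues):
        ang = i * twist
        ca = np.array([radius * np.cos(ang), radius * np.sin(ang), rise * i])
        for name, off in offsets.items():
            pos = ca + off
            atoms.append(
                AtomRecord(
                    chain="A", res_name="ALA", res_seq=i + 1, icode="",
                    atom_name=name, element="C" if name.startswith("C") else name[0],
                    pos=(float(pos[0]), float(pos[1]), float(pos[2])),
                )
            )
    return atoms


def simulate_structures(
    spec: SimulationSpec,
) -> tuple[StructureModel, StructureModel, dict]:
    """Reference backbone and a noisy, rigidly transformed copy.

    The copy is perturbed by isotropic Gaussian noise (sigma =
    ``coord_sigma``) and then moved by a random proper rigid transform.
    For n atoms with per-coordinate noise sigma, the expected RMSD after
    optimal superposition approaches sigma * sqrt(3).
    """
    rng = spec.rng()
    ref = StructureModel("synthetic_ref", _ideal_backbone(spec.n_structure_residues))
    coords = np.array([a.xyz for a in ref.atoms])
    noisy = coords + rng.normal(0.0, spec.coord_sigma, coords.shape)
    rot = Rotation.random(random_state=rng).as_matrix()
    trans = rng.uniform(-spec.max_translation, spec.max_translation, 3)
    moved = noisy @ rot.T + trans
    atoms = [
        AtomRecord(
            chain=a.chain, res_name=a.res_name, res_seq=a.res_seq, icode=a.icode,
            atom_name=a.atom_name, element=a.element,
            pos=(float(x), float(y), float(z)),
        )
        for a, (x, y, z) in zip(ref.atoms, moved)
    ]
    copy = StructureModel("synthetic_moved", atoms)
    transform = {"rotation": rot, "translation": trans, "sigma": spec.coord_sigma}
    return ref, copy, transform


# ---------------------------------------------------------------------------
# File emission (same dialects the analysis consumes)
# ---------------------------------------------------------------------------

def write_simulation_bundle(spec: SimulationSpec, out_dir: str | Path) -> dict[str, Path]:
    """Generate and write every stage's inputs; returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = f"seed = {spec.seed}"
    paths: dict[str, Path] = {}

    bound, free, _ = simulate_peaklists(spec)
    paths["bound"] = out / "bound_peaks.tsv"
    paths["free"] = out / "free_peaks.tsv"
    write_peaklist_tsv(paths["bound"], bound, header)
    write_peaklist_tsv(paths["free"], free, header)

    series, noe_pairs, _ = simulate_relaxation(spec)
    paths["decays"] = out / "decays.tsv"
    with open(paths["decays"], "w") as fh:
        fh.write(f"# {header}\nresidue\texperiment\tdelay_ms\tintensity\n")
        for s in series:
            for d, y in zip(s.delays_ms, s.intensities):
                fh.write(f"{s.residue}\t{s.experiment}\t{d:g}\t{y:.4f}\n")
    paths["noe"] = out / "noe.tsv"
    with open(paths["noe"], "w") as fh:
        fh.write(f"# {header}\nresidue\ti_sat\ti_ref\tsigma_sat\tsigma_ref\n")
        for res, (i_sat, i_ref, s_sat, s_ref) in sorted(noe_pairs.items()):
            fh.write(f"{res}\t{i_sat:.4f}\t{i_ref:.4f}\t{s_sat:.4f}\t{s_ref:.4f}\n")

    ref, moved, _ = simulate_structures(spec)
    paths["structure_ref"] = out / "structure_ref.pdb"
    paths["structure_moved"] = out / "structure_moved.pdb"
    write_pdb(paths["structure_ref"], ref)
    write_pdb(paths["structure_moved"], moved)
    return paths
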