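"""Reference constants for the AGP2-UCN-01 system.

Human alpha-1-acid glycoprotein variant 2 (AGP2) is a plasma lipocalin whose
eight-stranded beta-barrel binds the staurosporine derivative UCN-01
(7-hydroxystaurosporine) with low-nanomolar affinity.  The constants below
describe the recombinant expression construct used for NMR work (His6-tag,
3C protease site, "GP" cloning scar, C149R substitution, C-terminal
truncation at Glu173) and the analysis parameters of the chemical-shift
mapping and relaxation experiments.
"""

from __future__ import annotations

# Full-length expression construct: His6-tag + 3C site, cleaved after
# LEVLFQ to leave a "GP" extension ahead of mature residue 1 (Gln).
# The mature portion carries the C149R substitution.
AGP2_FL_RAW_SEQUENCE = (
    "MAHHHHHHSSGLEVLFQ"  # cleavable N-terminal segment (tag + 3C site)
    "GP"                 # extension left after cleavage
    "QIPLCANLVPVPITNATLDRITGKWFYIASAFRNEEYNKSVQEIQATFFYFTPNKTEDTIFLREYQTRQ"
    "NQCFYNSSYLNVQRENGTVSRYEGGREHVAHLLFLRDTKTLMFGSYLDDEKNWGLSFYADKPETTKEQL"
    "GEFYEALDCLRIPRSDVMYTDWKKDKCEPLEKQHEKERKQEEGES"
)

#: 1-based inclusive interval of the cleavable tag within the raw sequence.
AGP2_TAG_REGION = (1, 17)

#: Residues left after cleavage but before mature position 1.
AGP2_EXTENSION = "GP"

#: Index (1-based) in the raw sequence of mature residue 1.
AGP2_MATURE_OFFSET = 20

#: The truncated NMR construct stops at Glu173 (mature numbering); the
#: residue at this position and everything C-terminal of it are absent.
AGP2_STOP_POSITION = 173

#: Mature length of AGP1/AGP2 (both variants).
AGP2_MATURE_LENGTH = 183

# ---------------------------------------------------------------------------
# Chemical-shift mapping parameters (free vs UCN-01-bound TROSY-HSQC)
# ---------------------------------------------------------------------------

#: Assigned-peak chemical-shift ranges used to derive the 15N weighting.
CSP_RANGE_H_PPM = 4.504
CSP_RANGE_N_PPM = 30.616

#: Per-dimension matching gates for the reverse minimal-shift assignment.
CSP_GATE_H_PPM = 0.1
CSP_GATE_N_PPM = 0.68

#: Peaks are only counted above this fraction of the tallest resonance
#: (His172 in the bound spectrum, putative His172 in the free spectrum).
CSP_HEIGHT_FLOOR_FRACTION = 0.05

# ---------------------------------------------------------------------------
# 15N relaxation delay schedules (ms)
# ---------------------------------------------------------------------------

T1_DELAYS_MS = (10, 50, 100, 200, 400, 600, 800, 1000, 1200, 1500, 1800, 2000, 2500)
T2_DELAYS_MS = (10, 48, 64, 80, 96, 128, 160, 192, 240, 320)

# ---------------------------------------------------------------------------
# Structure comparison
# ---------------------------------------------------------------------------

#: Backbone residue interval used for superposition against earlier
#: ligand-bound AGP2 structures.
SUPERPOSITION_RANGE = (11, 167)

# ---------------------------------------------------------------------------
# Affinity and thermal stability
# ---------------------------------------------------------------------------

#: Dissociation constants (nM): UCN-01 is the high-affinity eutomer,
#: staurosporine lacks the lactam C7 hydroxyl.
KD_UCN01_NM = 3.5
KD_STAUROSPORINE_NM = 88.0

#: Melting temperatures (deg C) of the truncated construct without and with
#: a 2-fold excess of UCN-01.
TM_FREE_C = 61.9
TM_BOUND_C = 75.6

#: Default temperature (K) for binding free-energy comparisons.
DEFAULT_TEMPERATURE_K = 298.0
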