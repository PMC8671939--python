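"""Scalar binding-affinity and thermal-stability comparisons.

Two ligands' dissociation constants compare through the binding
free-energy difference ddG = R T ln(Kd_a / Kd_b); a positive value means
ligand *a* binds more weakly.  Thermal stabilisation on ligand binding is
the plain melting-temperature shift dTm = Tm_bound - Tm_free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

R_J_PER_MOL_K = 8.314  # gas constant


@dataclass(frozen=True)
class AffinityPair:
    """Two dissociation constants at one temperature."""

    kd_a: float  # nM
    kd_b: float  # nM
    temperature: float = 298.0  # K

    def __post_init__(self) -> None:
        if self.kd_a <= 0 or self.kd_b <= 0:
            raise ValueError("dissociation constants must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (K)")


@dataclass(frozen=True)
class ThermalPair:
    tm_free: float   # deg C
    tm_bound: float  # deg C

    def __post_init__(self) -> None:
        if not (math.isfinite(self.tm_free) and math.isfinite(self.tm_bound)):
            raise ValueError("melting temperatures must be finite")


def delta_delta_g(pair: AffinityPair) -> float:
    """Binding free-energy difference R T ln(kd_a/kd_b) in kJ/mol.

    Antisymmetric under swapping the two ligands; the Kd unit cancels in
    the ratio.
    """
    return R_J_PER_MOL_K * pair.temperature * math.log(pair.kd_a / pair.kd_b) / 1000.0


def fold_change(pair: AffinityPair) -> float:
    """Affinity fold-change kd_a / kd_b (reciprocal under swap)."""
    return pair.kd_a / pair.kd_b


def delta_tm(pair: ThermalPair) -> float:
    """Melting-temperature shift on binding, tm_bound - tm_free (deg C)."""
    return pair.tm_bound - pair.tm_free
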