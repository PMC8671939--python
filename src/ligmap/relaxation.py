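"""Per-residue 15N relaxation fitting and backbone mobility profiling.

Longitudinal (T1) and transverse (T2) relaxation decays are fit to a
two-parameter mono-exponential I(t) = I0 * exp(-t / T); the steady-state
heteronuclear NOE is the saturated/reference intensity ratio.  A depressed
T1/T2 ratio together with a depressed NOE marks fast (sub-nanosecond)
internal motion, typically at chain termini; a contiguous patch of
depressed T2 marks slower (us-ms) exchange.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import trim_mean

_T_BOUNDS_S = (1e-3, 100.0)  # physically sensible window for amide 15N T1/T2


@dataclass(frozen=True)
class RelaxSeries:
    """One residue's relaxation decay (delays in ms)."""

    residue: int
    delays_ms: tuple[float, ...]
    intensities: tuple[float, ...]
    experiment: str = "T1"  # "T1" | "T2"

    def __post_init__(self) -> None:
        if len(self.delays_ms) != len(self.intensities):
            raise ValueError("delays and intensities differ in length")
        if any(d <= 0 for d in self.delays_ms):
            raise ValueError("delays must be strictly positive")


@dataclass(frozen=True)
class ExponentialFit:
    """Mono-exponential fit result; times in seconds."""

    i0: float
    t: float
    i0_err: float
    t_err: float
    ok: bool = True
    message: str = ""


@dataclass
class RelaxResult:
    residue: int
    t1: float | None = None     # s
    t2: float | None = None     # s
    t1_err: float = 0.0
    t2_err: float = 0.0
    noe: float | None = None
    noe_err: float = 0.0

    @property
    def ratio(self) -> float | None:
        if self.t1 is None or self.t2 is None or self.t2 == 0:
            return None
        return self.t1 / self.t2

    @property
    def complete(self) -> bool:
        return self.t1 is not None and self.t2 is not None and self.noe is not None


def fit_exponential(series: RelaxSeries) -> ExponentialFit:
    """Nonlinear least-squares fit of I(t) = I0 exp(-t/T).

    Delays are converted ms -> s so T is returned in seconds.  Parameter
    uncertainties come from the residual-scaled covariance.  A fit that
    fails to converge, or lands outside (1 ms, 100 s), returns a
    flagged-failure result rather than raising.
    """
    if len(set(series.delays_ms)) < 3:
        raise ValueError(
            f"residue {series.residue}: need >= 3 distinct delays for a fit"
        )
    t_s = np.asarray(series.delays_ms, dtype=float) / 1000.0
    y = np.asarray(series.intensities, dtype=float)
    if np.allclose(y, y[0]):
        raise ValueError(f"residue {series.residue}: intensities are constant")

    # deterministic initial guess: I0 from the tallest point, T from the
    # delay whose intensity is nearest I0/e
    i0_guess = float(np.max(np.abs(y)))
    t_guess = float(t_s[np.argmin(np.abs(np.abs(y) - i0_guess / math.e))])
    t_guess = min(max(t_guess, _T_BOUNDS_S[0]), _T_BOUNDS_S[1])

    def model(t, i0, tau):
        return i0 * np.exp(-t / tau)

    try:
        popt, pcov = curve_fit(
            model, t_s, y, p0=[i0_guess, t_guess], maxfev=10000
        )
    except RuntimeError as exc:
        return ExponentialFit(math.nan, math.nan, math.nan, math.nan, False, str(exc))
    i0, tau = popt
    if not (_T_BOUNDS_S[0] < tau < _T_BOUNDS_S[1]) or not np.all(np.isfinite(pcov)):
        return ExponentialFit(
            i0, tau, math.nan, math.nan, False,
            f"fitted T = {tau:.4g} s outside ({_T_BOUNDS_S[0]} s, {_T_BOUNDS_S[1]} s)",
        )
    errs = np.sqrt(np.diag(pcov))
    return ExponentialFit(float(i0), float(tau), float(errs[0]), float(errs[1]))


def compute_hetnoe(
    i_sat: float,
    i_ref: float,
    sigma_sat: float = 0.0,
    sigma_ref: float = 0.0,
) -> tuple[float, float]:
    """Steady-state heteronuclear NOE ratio with first-order error.

    ratio = I_sat / I_ref; negative ratios are allowed (flexible tails).
    The error propagates the two intensity uncertainties to first order:
    sigma^2 = (sigma_sat/I_ref)^2 + (I_sat sigma_ref / I_ref^2)^2.
    """
    if i_ref == 0:
        raise ValueError("reference intensity is zero")
    ratio = i_sat / i_ref
    err = math.hypot(sigma_sat / i_ref, i_sat * sigma_ref / i_ref**2)
    return ratio, abs(err)


@dataclass(frozen=True)
class MobilityCriteria:
    """Thresholds for flagging fast motion and low-T2 exchange patches.

    Fractions are relative to the trimmed mean over all complete residues
    ("core" values).  A residue is fast-motion when BOTH its T1/T2 ratio
    and its NOE fall below the respective fraction of core.
    """

    ratio_fraction: float = 0.75
    noe_fraction: float = 0.75
    t2_patch_fraction: float = 0.75
    min_patch_length: int = 4
    trim_proportion: float = 0.1


@dataclass
class MobilityProfile:
    core_ratio: float
    core_noe: float
    core_t2: float
    fast_motion_residues: list[int] = field(default_factory=list)
    low_t2_patches: list[tuple[int, int]] = field(default_factory=list)

    @property
    def has_exchange_patch(self) -> bool:
        return bool(self.low_t2_patches)


def mobility_profile(
    results: list[RelaxResult],
    criteria: MobilityCriteria = MobilityCriteria(),
) -> MobilityProfile:
    """Flag fast-motion residues and contiguous depressed-T2 patches."""
    complete = sorted(
        (r for r in results if r.complete), key=lambda r: r.residue
    )
    if len(complete) < 5:
        raise ValueError("need >= 5 residues with complete T1/T2/NOE results")
    ratios = np.array([r.ratio for r in complete])
    noes = np.array([r.noe for r in complete])
    t2s = np.array([r.t2 for r in complete])
    core_ratio = float(trim_mean(ratios, criteria.trim_proportion))
    core_noe = float(trim_mean(noes, criteria.trim_proportion))
    core_t2 = float(trim_mean(t2s, criteria.trim_proportion))

    fast = [
        r.residue
        for r, ratio, noe in zip(complete, ratios, noes)
        if ratio < criteria.ratio_fraction * core_ratio
        and noe < criteria.noe_fraction * core_noe
    ]

    # contiguous (in residue numbering) runs of depressed T2
    low = [
        r.residue for r, t2 in zip(complete, t2s)
        if t2 < criteria.t2_patch_fraction * core_t2
    ]
    patches: list[tuple[int, int]] = []
    run_start = None
    prev = None
    for res in low:
        if run_start is None:
            run_start = prev = res
            continue
        if res == prev + 1:
            prev = res
        else:
            if prev - run_start + 1 >= criteria.min_patch_length:
                patches.append((run_start, prev))
            run_start = prev = res
    if run_start is not None and prev - run_start + 1 >= criteria.min_patch_length:
        patches.append((run_start, prev))

    return MobilityProfile(core_ratio, core_noe, core_t2, fast, patches)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_decays_tsv(path: str | Path) -> list[RelaxSeries]:
    """Read decay tables: columns residue, experiment, delay_ms, intensity."""
    df = pd.read_csv(path, sep="\t", comment="#")
    series = []
    for (residue, experiment), grp in df.groupby(["residue", "experiment"], sort=True):
        grp = grp.sort_values("delay_ms")
        series.append(
            RelaxSeries(
                residue=int(residue),
                delays_ms=tuple(grp["delay_ms"].astype(float)),
                intensities=tuple(grp["intensity"].astype(float)),
                experiment=str(experiment),
            )
        )
    return series


def read_noe_tsv(path: str | Path) -> dict[int, tuple[float, float, float, float]]:
    """Read NOE pairs: columns residue, i_sat, i_ref [, sigma_sat, sigma_ref]."""
    df = pd.read_csv(path, sep="\t", comment="#")
    out = {}
    for row in df.itertuples(index=False):
        out[int(row.residue)] = (
            float(row.i_sat),
            float(row.i_ref),
            float(getattr(row, "sigma_sat", 0.0) or 0.0),
            float(getattr(row, "sigma_ref", 0.0) or 0.0),
        )
    return out


def analyse_relaxation(
    decays: list[RelaxSeries],
    noe_pairs: dict[int, tuple[float, float, float, float]] | None = None,
) -> list[RelaxResult]:
    """Fit all decays and merge with NOE ratios into per-residue results."""
    by_res: dict[int, RelaxResult] = {}
    for series in decays:
        res = by_res.setdefault(series.residue, RelaxResult(series.residue))
        fit = fit_exponential(series)
        if not fit.ok:
            continue
        if series.experiment.upper() == "T1":
            res.t1, res.t1_err = fit.t, fit.t_err
        elif series.experiment.upper() == "T2":
            res.t2, res.t2_err = fit.t, fit.t_err
    if noe_pairs:
        for residue, (i_sat, i_ref, s_sat, s_ref) in noe_pairs.items():
            res = by_res.setdefault(residue, RelaxResult(residue))
            res.noe, res.noe_err = compute_hetnoe(i_sat, i_ref, s_sat, s_ref)
    return [by_res[r] for r in sorted(by_res)]


def write_results_tsv(path: str | Path, results: list[RelaxResult],
                      profile: MobilityProfile | None = None) -> None:
    flags = set(profile.fast_motion_residues) if profile else set()
    with open(path, "w") as fh:
        fh.write("residue\tT1_s\tT1_err\tT2_s\tT2_err\tNOE\tNOE_err\tratio\tflags\n")
        for r in results:
            def fmt(x):
                return "" if x is None else f"{x:.4f}"
            flag = "fast-motion" if r.residue in flags else ""
            fh.write(
                f"{r.residue}\t{fmt(r.t1)}\t{r.t1_err:.4f}\t{fmt(r.t2)}\t"
                f"{r.t2_err:.4f}\t{fmt(r.noe)}\t{r.noe_err:.4f}\t"
                f"{fmt(r.ratio)}\t{flag}\n"
            )
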