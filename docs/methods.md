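# Methods

`ligmap` re-implements, as a tested library, the computational analyses
used to characterise how the plasma lipocalin AGP2 binds the kinase
inhibitor UCN-01 (7-hydroxystaurosporine): reverse minimal chemical-shift
mapping of HSQC peak lists, ¹⁵N relaxation fitting with mobility
profiling, residue-range backbone superposition, geometric interaction
detection around a bound ligand, construct bookkeeping, and scalar
binding thermodynamics. This note records the models, the defaults, the
numerical choices, and what the synthetic generators do and do not
emulate.

## Reverse minimal chemical-shift mapping (`csp`)

When only the ligand-bound state of a protein yields an assignable
spectrum, per-residue perturbations are estimated in reverse: each
unassigned free-state peak is matched to an assigned bound-state peak
and the distance of the accepted match is a *lower bound* on the true
perturbation — hence "minimal shift".

**Distance.** The combined shift is the weighted Euclidean
`d = sqrt(Δδ_H² + (w·Δδ_N)²)` with `w = range_H / range_N`, the ratio of
the assigned-peak shift ranges in the two dimensions. For the AGP2
assignments those ranges are 4.504 ppm (¹H) and 30.616 ppm (¹⁵N), giving
`w = 0.147`. The source study cites the combined-shift convention without
printing the formula; the weighted Euclidean form is the standard
realisation of that convention and reproduces the printed weighting's
units (¹H ppm per ¹⁵N ppm).

**Gates.** Candidate pairs must satisfy *per-dimension* rectangular
gates (defaults 0.1 ppm in ¹H, 0.68 ppm in ¹⁵N) before any distance
ranking; a pair outside either gate is never matched no matter how small
its weighted distance. Gate comparisons are inclusive (≤); the boundary
case is measure-zero on real data.

**Matching.** Default strategy is distance-ordered global greedy: all
gated cross-list pairs are sorted by weighted distance and accepted in
order, skipping pairs whose bound or free member is already used. This
realises "closest peaks assigned first, then progressively more distant
free peaks to the closest remaining bound peak" in a single ordering. A
free-peak-sequential variant (each free peak, in order of its best gated
distance, claims the nearest remaining bound peak) is available via
`strategy="sequential"`; on well-separated data the two agree. Ties are
broken lexicographically on (bound id, free id) for determinism. Every
returned mapping is self-audited: one-to-one in both directions, and
every accepted pair re-checked against the gates.

**Height floor.** Peaks are counted only if *strictly more than* a
configured fraction (default 5%) of the tallest peak of their own
spectrum; the reference peak id is reported so the tallest-resonance
assumption can be inspected.

**Output.** Matched bound peaks get Δδ_min; unmatched bound peaks are
reported categorically as `bound-only` (candidate large-shift or
exchange-broadened residues) and never given an imputed shift value;
residues without a bound peak are `unobserved`.

## ¹⁵N relaxation (`relaxation`)

Decays are fit to the two-parameter mono-exponential
`I(t) = I₀·exp(−t/T)` by nonlinear least squares; no baseline offset is
modelled, which is the standard treatment for amide ¹⁵N T1/T2 series.
Delays are taken in ms and converted internally, so T is always in
seconds. Initial guesses are deterministic: I₀ from the tallest point, T
from the delay whose intensity is nearest I₀/e. A fit that does not
converge or lands outside (1 ms, 100 s) returns a flagged-failure
record rather than raising, so one bad residue cannot abort a profile.
Uncertainties come from the residual-scaled covariance of the
least-squares solution; the Monte-Carlo check in the test suite shows
the covariance errors track the empirical scatter at the 2% noise level.

The heteronuclear NOE is the plain saturated/reference intensity ratio
with first-order error propagation; negative ratios (highly flexible
tails) are allowed.

**Mobility profile.** Core values are the 10%-trimmed means of T1/T2,
NOE and T2 over all residues with complete results. A residue is flagged
*fast-motion* only when both its T1/T2 ratio and its NOE fall below 75%
of core — requiring both suppresses single-parameter outliers. A
contiguous run of ≥ 4 residues with T2 below 75% of core is reported as
a candidate µs–ms exchange patch; the analysis reports the absence of
such patches just as meaningfully as their presence. The 75% fractions
and minimum patch length are configuration defaults, chosen because the
underlying finding is qualitative; they separate a 50%-of-core terminus
from core scatter cleanly in the recovery tests.

## Structures (`structures`, `interactions`)

PDB and mmCIF files are read through gemmi; author residue numbering is
authoritative and never remapped, waters and ligands are retained, and
alternate conformations are resolved per atom to the highest-occupancy
conformer (ties toward altloc "A"). Hydrogens are optional; all
detectors fall back to distance-only criteria when they are absent, as
is typical for crystal structures near 1.8 Å resolution.

**Superposition.** Atoms are paired by (chain, residue number, atom
name) over an inclusive residue interval; default atom set is backbone
N, CA, C, O (the published comparison states only "backbone residues",
so CA-only is available via the atom-set argument). The optimal rotation
is computed by the Kabsch SVD construction with reflection correction;
the test suite cross-checks it against an independent quaternion
(Horn) implementation to 1e-9 and asserts RMSD invariance under random
proper rigid transforms.

**Interaction detectors.** All criteria are configurable; defaults
follow common literature conventions:

| interaction  | criterion (defaults) |
|---|---|
| hydrogen bond | donor–acceptor heavy atoms ≤ 3.5 Å; D–H···A ≥ 120° when H present |
| salt bridge | cationic N (Arg NE/NH1/NH2, Lys NZ) to anionic O (Asp/Glu carboxylate) ≤ 4.0 Å; one hit per residue pair at the minimum distance |
| cation-π | cationic-group centroid to ring centroid ≤ 6.0 Å; θ = angle(ring normal, centroid→cation), folded to [0°, 90°]: ≤ 30° stacked/axial, ≥ 60° T-shaped/edge, else intermediate |
| CH-π | CH carbon to ring centroid ≤ 4.5 Å and elevation above the ring plane ≥ 30°; carbonyl and other non-CH sp² carbons excluded |
| water bridge | water O within 3.5 Å of ≥ 2 polar atoms of distinct residues; leg distances and their spread reported, plus on-request distances to named atoms just beyond H-bond range |
| pocket contact | any protein heavy atom within 4.5 Å of any ligand heavy atom |

Ring centroids and normals come from an SVD plane fit; rings failing a
0.25 Å out-of-plane tolerance are skipped. Ligand chemistry (ring atom
sets, donors/acceptors, semantic atom names) is declarative and keyed by
het code. Because component-dictionary atom nomenclature must be
confirmed against each deposited file, the shipped registry contains the
synthetic test ligand plus a JSON override loader
(`load_ligand_config`) for real het codes; perception from connectivity
was deliberately avoided to keep the geometry module free of
cheminformatics dependencies.

## Sequences (`sequences`)

Constructs are modelled in raw (pre-cleavage) coordinates with a
cleavable tag interval, an optional post-cleavage extension, and an
optional stop position. Mature numbering is 1-based and *unshifted* by
the extension: a "GP" protease scar is labelled −1, 0 so that mature
positions (Cys5, Glu64, Arg90, …) match the literature numbering. The
tag interval in the configuration is authoritative over any prose count
of tag residues; for the AGP2 construct the printed tag segment is 17
residues. Sequon scanning implements N-X-S/T with X ≠ P via an
overlapping-window scan; `count_differences` is a strict Hamming count
on pre-aligned equal-length sequences (the AGP1/AGP2 mature alignment is
gapless at 183 residues) and refuses unequal lengths rather than
aligning.

## Thermodynamics (`thermo`)

`ΔΔG = R·T·ln(Kd_a/Kd_b)` in kJ/mol with R = 8.314 J·mol⁻¹·K⁻¹ and a
default T of 298 K (the temperature of the NMR work; the published
energy band does not state its temperature, and the result moves < 1%
over any plausible lab temperature). Fold change is the plain Kd ratio;
ΔTm is the plain difference of melting temperatures.

## Synthetic data (`synthetic`)

One seeded `numpy` generator drives all three simulators; a fixed seed
gives bit-identical output files, and the seed is recorded in every
file header.

* **Peak lists** — bound shifts uniform over amide ranges (¹H 6.5–11,
  ¹⁵N 105–135 ppm); 160 residues by default (the observable amides of a
  ~170-residue construct); 10% of residues are "pocket" residues with
  large perturbations, half of them beyond the matching gates; everyone
  else gets small Gaussian shifts (σ 0.01/0.05 ppm); 30% of free peaks
  are dropped, emulating exchange-broadened free-state resonances;
  heights are log-normal.
* **Relaxation** — decays on the experimental delay grids (13 T1 delays
  10–2500 ms; 10 T2 delays 10–320 ms), core values T1 0.85 s, T2 70 ms,
  NOE 0.80 (typical for a ~20 kDa protein at 700 MHz), three mobile
  residues at each terminus with the T1/T2 ratio and NOE at 50% of core,
  2% Gaussian noise.
* **Structures** — an idealised helical backbone (125 residues × 4
  backbone atoms), perturbed by isotropic Gaussian noise (σ 0.3 Å) and a
  random proper rigid transform; for n atoms the post-fit RMSD
  expectation is √3·σ.

What the generators do *not* emulate: peak overlap and lineshape
effects, spectral noise ridges, chemical-exchange line broadening as a
physical process (dropout is a proxy), relaxation-delay cross-talk, and
real protein geometry (the synthetic backbone is not stereochemically
valid, only metrically useful). Passing the recovery tests therefore
demonstrates correctness of the algorithms under the stated statistical
assumptions, not robustness to pathological real spectra.

## Problem sizes

The test suite and the acceptance script use 60-residue peak lists for
recovery checks, 50×50 lists for oracle equivalence, 200 Monte-Carlo
replicates for estimator calibration, and 500-atom point sets for
superposition checks — sizes at which the brute-force oracles remain
exact and the statistical assertions are stable across seeds.

## Known limitations

* Checks against deposited crystallographic entries (backbone RMSDs
  between ligand complexes; specific H-bond distances) require the PDB
  files to be supplied locally under `data/structures/`; the package
  ships no coordinates for them.
* The matching step is greedy, not globally optimal assignment
  (Hungarian); this is deliberate, since the mapped quantity is defined
  by the greedy procedure itself.
* No model-free (Lipari–Szabo) analysis, spectral-density mapping, or
  exchange-regime modelling; no peak picking from raw spectra; no
  sequence alignment.
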