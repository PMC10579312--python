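# Methods

This note documents the models, rules and numerical choices behind
`somatlas`, the reasoning where the design was genuinely open, and what
the synthetic-data tests do and do not demonstrate about real spectra.

## Scope and assumptions

The pipeline starts from exported, centroided peak lists (m/z, intensity,
S/N); it does not process raw transients, profile spectra or perform peak
picking. All ions are treated as singly charged — appropriate for small
molecules below ~1000 Da in ESI/APPI, where multiply charged species are
rare and assumed rejected upstream. The elemental space is
{C, H, N, O, S, Na, Mg, Cl}; isotopologues beyond the ¹³C and ³⁴S
companions are out of scope, as is any isomer-level structure annotation.
No hard mass window is imposed: the instrument's acquisition range is
treated as a property of the data, not of the software.

## Mass arithmetic

Monoisotopic atomic masses: C 12 (exact), H 1.0078250319, N 14.0030740052,
O 15.9949146221, S 31.9720707, Na 22.98976928, Mg 23.9850417,
Cl 34.96885268 Da; electron mass 0.00054858 Da. Ion conversions include
the electron mass, e.g. M([M−H]⁻) = m/z + 1.0078250 − 0.0005486 and
M(M⁺•) = m/z + 0.0005486; the neutral→ion→neutral round trip is exact to
< 1e−9 Da for every supported ion type.

Two nominal-mass conventions coexist deliberately. For a *measured* mass
the only option is rounding to the nearest integer, and that is what the
per-nominal-mass spectral profiles use. For a *known composition* the
nominal mass is the sum of integer atomic masses — the standard
definition — and it is exact under elemental substitution: a CH₄→O
exchange preserves it identically (both units are nominally 16) while
shifting the exact mass by 36.3855 mDa. Rounding the monoisotopic mass
would misclassify hydrogen-rich formulas above ~600 Da, whose cumulative
mass defect exceeds +0.5 (e.g. C38H69NO5 = 619.5176 Da rounds to 620
while its substitution partner C37H65NO6 = 619.4812 Da rounds to 619).
The 36.3855 mDa spacing is computed from the atomic-mass table; a widely
quoted rounded figure of 36.3845 mDa differs from the exact value by
1 µDa.

## Senior validation and conservative filter rules

A candidate neutral passes the Senior/cyclomatic-number check iff its
DBE = 1 + Σnᵢ(vᵢ−2)/2 is a non-negative integer, its odd-valence atom
count (H, N, Na, Cl) is even, and Σnᵢvᵢ ≥ 2(Σnᵢ−1). Valences are C 4,
H 1, N 3, O 2, S 2 (divalent sulfur), Na 1, Cl 1 and Mg 4 (coordination
number).

The default element bounds and ratio filters are this package's
"conservative filter rules"; every one of them is configurable:

| rule | default | rationale |
|---|---|---|
| C | 1–100 | covers the <1000 Da small-molecule regime |
| H | 0–200, H/C ∈ [0.4, 3.2] | valence-feasible saturation range; H/C < 0.4 implies fullerene-like cores not observed in SOM |
| N | 0–5 | meteoritic CHNO/CHNOS rarely exceeds N4 |
| O | 0–40, O/C ≤ 1.2 | carboxyl/hydroxyl-rich end of the van Krevelen plane |
| S | 0–9; S ≥ 4 only for pure CHS with DBE ≤ 1 | mixed families carry S1–S3; higher S counts occur as saturated polysulfur (S3–S9) chains |
| Na | 0–1; Na/Mg-bearing neutrals need O ≥ 2 | sodiated neutrals are salts of O-bearing acids (the observed Na families are all CHO(N/S)Na) |
| Mg | 0–0 (opt-in) | Mg-organics are searchable (valence 4) but reported absent in the target spectra; enabling them reintroduces sub-µDa ambiguities (see below) |
| Cl | 0–0 in neutrals | chlorine reaches these spectra as an adduct, not as a constituent |

The S/C ≤ 0.8 and N/C ≤ 1.3 caps are retained as coarse guards; the
joint rules above are the binding ones.

### Why the rules are this tight: micro-Dalton coincidences

The CHNOS(+Na, Mg, Cl) space contains elemental substitutions whose mass
differences are far below the width of a ±0.2 ppm window (40–280 µDa over
120–700 Da):

* [M−H]⁻ / [M+Cl]⁻ ion-type switches: −4C+4H+4N−7O+2S (+13 µDa) and
  +11C−4N−7O (−21 µDa) relative to the Cl+H adduct offset;
* Mg+Na+4N+8O ≈ 5C+11H+5S to < 1 µDa — double-metal compositions are
  indistinguishable from organosulfur by mass at any realistic accuracy;
* 14C+7O ≈ 24H+8S (54 µDa), 13C+6N ≈ 16H+10O+2S (43 µDa),
  Na+5O ≈ 6C−H+S (96 µDa).

Under permissive bounds these coincidences produce 7–20% wrong primary
assignments on synthetic spectra with 0.05 ppm mass error. The rule set
above eliminates every class that involves an implausible composition
(double metals, O-free salts, S-rich mixed formulas, N ≥ 6,
fullerene-like H/C) while keeping the emulated population fully inside
the filters. Measured on ten independent seeds (4399 planted formulas,
0.05 ppm jitter, 0.2 ppm window): 99.98% recovered as primary, zero
assignments on rejection-sampled noise peaks. The residual failures are
genuine: e.g. a −21C+12H+13O+S neighbour at −140 µDa can outcompete the
true formula above ~650 Da after a >2.5σ jitter excursion, and a Cl
adduct of one population member can collide with the deprotonated ion of
another. These ambiguities are properties of the composition space, not
of the software; resolving them in real data requires isotope or series
evidence.

### Adduct and salt corroboration

An adduct hypothesis ([M+Cl]⁻, [M+Na]⁺) is retained only when the same
neutral is also visible through the mode's primary channel ([M−H]⁻ resp.
[M+H]⁺) within 0.25 ppm elsewhere in the peak list, and a Na-bearing
neutral only when its free acid (Na→H) is present. Adducts and salts
accompany the main ionization product in electrospray, so an
uncorroborated adduct is overwhelmingly more likely a near-isobar of a
different composition. The 0.25 ppm partner window is ~5σ of the typical
jitter, so genuine partners are essentially never rejected. Both rules
are on by default and can be disabled (`require_adduct_partner=False`).

### Tie-breaking and isotope verification

Among surviving candidates of a peak, the primary is the lowest
|ppm error| (ties broken lexicographically for determinism). Isotope
verification searches the +1.0033548 Da ¹³C companion (and +1.9957959 Da
³⁴S when S ≥ 1); a companion within a factor-2 band of n_C × 0.0107
(n_S × 0.0442) confirms, a companion far outside contradicts, and an
*absent* companion contradicts only when it should have been obvious
(n_C ≥ 10 at parent S/N ≥ 30). After verification, a confirmed candidate
within 0.02 ppm of the best error is promoted over an unverified one.

## Enumeration

Candidate formulas are enumerated by vectorising over all heteroatom
combinations inside the bounds (pre-filtered by the C-dependent ratio
rules and sorted by H-free partial mass, cached per bounds object) and
solving the hydrogen count per branch; at sub-ppm windows at most one H
value fits per branch. The enumeration is exact — the test suite checks
set equality against an independent exhaustive nested-loop oracle on 100
random masses — and monotone in the tolerance.

## Descriptors

Xc uses the corrected ring-and-double-bond count d = DBE − m·O − n·S with
π-bond fractions m = n = 0.5 by default (configurable): Xc = (3d − 2)/d
when d > 0 and DBE > 0, else 0. Kendrick mass defects use the CH₂ base
(K = m × 14/14.0156500; KMD = round(K) − K), under which CH₂ homologues
share a defect exactly. Family labels concatenate the present
hetero-elements in the order C, H, N, O, S with a Na (or Cl) suffix;
Mg-bearing formulas are labelled `Mg-organic`. Homologous-series
detection walks maximal chains under exact repeated addition of the step
(CH₂ by default); chains are disjoint per step and reported at length
≥ 2.

## Mass-difference networks

The canonical network is formula-based: an undirected edge joins two
compositions iff their elemental difference equals a catalogue delta
exactly, which removes all tolerance ambiguity and is verified in the
tests to reproduce the all-pairs exact-mass-difference search at 1e−6 Da.
The default catalogue holds 13 differences (CH₂, H₂, O, H₂O, CO₂, HCN,
NH, NH₃, S, SO, SO₂, SO₃, SO₄); a 12-entry variant without CO₂ is
available because published transformation lists sometimes omit it.
"Addition" and "removal" collapse to one undirected edge; the deltas are
elementally distinct, so each pair carries exactly one label. Statistics
report per-transformation counts and percentages (to 0.1%), plus grouped
shares for the top-4 (CH₂, H₂, O, H₂O), the nitrogen set (HCN, NH, NH₃)
and the sulfur set (S…SO₄). A mass-based variant connects raw peaks whose
m/z difference matches a catalogue mass within a ppm tolerance
(evaluated against the larger m/z), enabling network construction before
any assignment.

## Multivariate protocol

Intensity matrices are assembled by exact elemental identity of the
primary assignments; a formula absent from a sample is 0 (detection
semantics — no imputation). Preprocessing is log₁₀(1 + x) — the +1 offset
handles true zeros and is configurable in spirit by supplying
pre-transformed data — followed by column mean-centering and
unit-variance scaling; zero-variance columns are dropped and recorded,
and the stored record reapplies the identical transform to new samples.

PCA is fitted by NIPALS with Gram-Schmidt re-orthogonalisation of each
loading against its predecessors (tolerance 1e−10 on the relative score
change, cap 500 sweeps). If the score vector has not settled at the cap
but the component's explained sum of squares has (relative change
< 1e−9), the component is accepted: that is the signature of a
(near-)degenerate eigenvalue pair, where any basis of the shared subspace
is equally valid; a genuinely unstable component raises an error naming
it. Components are oriented so the largest-|value| loading is positive,
making scores reproducible bit-for-bit under a fixed seed.

Q² uses row-wise K-fold cross-validation (7 contiguous blocks by
default): each fold refits NIPALS on the kept rows and reconstructs the
left-out rows from the fold loadings; Q²(cum at k) = 1 − PRESS(k)/TSS.
Row-wise PCA cross-validation carries a known small optimism of order
k/p (projection onto k directions always removes some variance of a
held-out row), so on pure noise Q² sits near +k/p rather than exactly
≤ 0 — about +0.025 for k = 2, p = 80. Element-wise CV would remove this
bias at substantially higher cost; the row-wise scheme is the one the
standard chemometrics packages use and is kept for comparability. The
"valid component" heuristic — retain component i while Q²(i) > 0 — is an
approximation, as is the whole CV scheme relative to proprietary
implementations whose exact rules are unpublished.

The work/prediction protocol fits preprocessing and PCA on the work
samples only, cross-validates Q² within the work set, projects the
prediction samples through the stored transform and loadings, and (when
class labels exist) classifies each held-out sample to the class with
the nearest mean PC1 training score.

## Synthetic data: what it emulates, what it does not

The generator emulates the structural features that drive every pipeline
stage: family proportions (largest-remainder quotas, so the sampled mix
is exact; defaults put ~52% in N-bearing families, 27% CHO, 15% CHOS,
4% CH, 2% CHS, loosely mimicking meteoritic SOM), CH₂ homologous series,
saturated polysulfur chains S3–S9 (capped at C17 so the chains stay below
the mass where the 54 µDa 14C+7O/24H+8S coincidence enters a 0.2 ppm
window), a 120–700 Da mass range, Gaussian ppm mass error (0.05 ppm
default), log-normal intensities (ln-scale µ = 14, σ = 1.2 — only
relative abundances matter, and a two-parameter heavy-tailed positive
model is the simplest adequate choice), S/N proportional to intensity
with a floor at the export threshold 3, and noise peaks placed by
rejection against the enumeration oracle (≥ 0.5 ppm from every bounded
composition, for a clean false-positive measurement).

Two-class studies mirror a 36-sample design split 25 work / 11
prediction: class B multiplies a planted 10% discriminating-formula
subset by a fold-change (4 by default) under multiplicative log-normal
noise (σ = 0.25 in ln units); sample classes, the split and all draws
derive from one seed.

Not modelled: isotopic fine structure beyond the ¹³C/³⁴S companions,
resolution and peak-shape effects, ionization suppression, calibration
drift within a spectrum, solvent-dependent extraction selectivity, and
correlated (series-wise) intensity structure. Passing tests therefore
demonstrate correctness of the algorithms under realistic mass-accuracy
and population structure — not robustness to every instrumental artefact
of real spectra.

## Problem sizes

The test suite and the acceptance script use populations of 100–1500
formulas, peak lists of ~500 peaks, 36-sample studies and 20-replicate
classification experiments; these sizes give stable statistics for every
asserted property while keeping a full run in the minutes range on one
CPU. Real datasets two orders of magnitude larger (tens of thousands of
formulas) are handled by the same code paths; the enumeration grid and
the network construction are the only O(heavy) steps and both are
vectorised or hash-based.

## Known limitations

* Unique assignment from mass alone degrades above ~650 Da where
  sub-window near-isobars exist even under the conservative rules;
  isotope or homologous-series evidence is then required.
* The Q² scheme's k/p optimism (above).
* The edge TSV export stores edges only, so isolated nodes do not survive
  a round trip (GraphML preserves all nodes).
* Xc is reported for the neutral composition; for radical cations (M⁺•)
  the even-electron parity rule is waived but descriptors still refer to
  the neutral.
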