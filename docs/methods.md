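# Methods

This note documents the models behind each module, the defaults that matter,
what the synthetic-data generators do and do not emulate, and the numerical
choices a maintainer would want to know.

## Tetrad genetics

### Assay model

Three spore-expressed fluorophores mark chromosome VIII: red at *CEN8* and
green at *ARG4* on one homolog, blue at *THR1* on the other. Each spore
inherits one chromatid, so its colour triple identifies the chromatid's
allelic composition exactly (the 8 possible triples map bijectively onto the
8 chromatid classes). A tetrad is classified per interval by the number of
recombinant chromatids: 0 → PD, 2 → TT, 4 → NPD. Under 2:2 segregation of
every marker this count is always even; tetrads violating 2:2 are flagged
aberrant and excluded from all denominators.

The pattern {two triple-bright spores, two dark spores} is genuinely
ambiguous: it is produced both by meiosis-I nondisjunction (two disomic, two
nullisomic spores) and by a four-chromatid double crossover in the
*ARG4*–*THR1* interval. `tally()` therefore takes an `ambiguous=` policy:

* `"nd"` (default) — count as nondisjunction. In real strains segregation
  failure dominates this pattern; the cost is a small deflation of the
  second interval's map distance (~0.2 cM at 4.2 cM, because true NPDs are
  removed from the tally).
* `"npd"` — count as interval-1 PD / interval-2 NPD. Correct when
  nondisjunction is known absent, e.g. simulations generated without it.
* `"exclude"` — drop the pattern everywhere (sensitivity analysis).

### Perkins distance and its standard error

cM = 100(6·NPD + TT)/(2(PD + NPD + TT)) corrects tetratype-based distances
for double crossovers assuming no chromatid interference. Writing t = TT/n,
p = NPD/n, the estimate is 50(t + 6p) and the multinomial delta method gives

    se = 50 sqrt[(t(1 − t) + 36 p(1 − p) − 12 t p)/n].

The estimator carries a small inherent downward bias from triple and higher
crossovers it cannot see: under the Poisson no-interference model its
expectation at a true 11.63 cM is 11.49 (−1.2%), and −0.2% at 4.22 cM.
Recovery tests therefore allow 3 Monte-Carlo SE plus 2% of the true
distance; at the simulation sizes used (2×10⁵ tetrads) the Monte-Carlo SE is
~0.07 cM.

### Simulator

Per meiosis, crossover counts in each interval are Poisson with mean
m = 2d/100 per bivalent — a map distance of d cM is d/100 Morgans per
chromatid, and each crossover involves two of the four chromatids. Each
chiasma exchanges everything distal to its interval between one chromatid
currently carrying homolog-1 content and one carrying homolog-2 content at
that point (distal to an earlier exchange a chromatid follows the other
homolog's axis; pairing by centromere identity instead would distort
inter-interval patterns). There is no chiasma or chromatid interference.
With probability `nd_prob` a meiosis instead yields the nondisjunction
pattern. Strain presets (`WT_TETRAD_CONDITIONS`, deletion-strain analogues)
encode the published wild-type distances (11.63, 4.22 cM), ~60% residual
crossovers and elevated nondisjunction (1.15%, 2.73%) for the deletion
strains.

Not emulated: crossover interference (real yeast shows it; the Perkins
formula is the standard estimator under its absence, and an interference
model would need a gamma-renewal process along the bivalent), spore death,
scoring errors. Passing recovery tests therefore validates the estimators
under the no-interference model, not the biology of interference.

## Contingency statistics

Fisher's exact test is two-tailed by the probability-mass rule (sum of
hypergeometric probabilities of all margin-preserving tables no more likely
than the observed one); the implementation delegates to scipy and the test
suite pins it against an exact rational-arithmetic enumeration over every
2×2 table with n ≤ 40. The G test is G = 2 Σ O ln(O/E) with df = (r−1)(c−1)
and a chi-square upper tail; cells with O = 0 contribute nothing, and no
Williams or continuity correction is applied (none is specified for the
analyses this reproduces). Proportion intervals default to Wald — matching
the symmetric "mean ± 95% CI" presentation of nondisjunction frequencies —
with Wilson available (`method="wilson"`) where small counts make Wald
undercover. Reversion frequencies aggregate by the mean across cultures
(matching a mean ± SD presentation); a median rule is available for
jackpot-prone data.

## Footprint mapping

The detected fragments carry the N-terminal tag, so each band is an
N-terminal prefix of the protein; its apparent molecular weight locates the
cleavage site.

* **Peak picking**: morphological-opening baseline subtraction (window 15%
  of the trace), Savitzky–Golay smoothing (window 1% of the trace by
  default, polynomial order 2), scipy `find_peaks` with a prominence
  threshold relative to the tallest smoothed signal (5% default), and
  sub-sample refinement by a local quadratic through the three samples
  around each maximum. Equal Gaussian bands closer than ~2σ produce a
  single maximum; that is the physical resolution limit, not a setting.
* **Calibration**: least-squares quartic of migration on molecular weight
  (in kDa, not log kDa), requiring ≥ 5 markers. A quartic fitted across a
  wide, sparse MW range can oscillate, so fits that are not strictly
  monotone over the marker range are rejected rather than silently
  inverted; inversion on the accepted range is by bisection.
* **Residue assignment**: fragment mass is matched against tag mass +
  cumulative **average** residue masses of the actual sequence (average,
  not monoisotopic, because SDS-PAGE resolves nothing near isotopic
  precision). Per-site uncertainty propagates the calibration residual RMS
  through the local slope of the migration law, floored at 5 residues — the
  assay's stated precision class is 5–10 residues regardless of fit
  quality.
* **Candidate residues**: lysines/arginines within ±12 residues of a site
  (the window that covers the published site→mutation pairings), optionally
  filtered by K/R conservation across a supplied alignment.

The lane simulator generates band centres under migration = a − b·ln(MW) —
deliberately *not* a quartic — so calibration robustness to a merely smooth
monotone truth is exercised; a custom law (e.g. an exact quartic for
round-trip identity tests) can be supplied. The default simulated ladder is
the 20–120 kDa marker set: a quartic across the additional sparse gap to a
220 kDa band is non-monotone (the guard rejects it), and all fragments of
an ~88 kDa tagged protein fall within 20–120 kDa.

## AFM volumetrics

Background is a least-squares plane refitted iteratively on below-threshold
pixels plus a median offset, making volumes invariant to any added plane;
the robust SD is 1.4826×MAD. Pixels above median + 3 robust SD (with a tiny
absolute floor so round-off never seeds components on noise-free images) are
grouped with 8-connectivity; detections under 4 px are dropped; masks are
grown by 3 px (without overlapping neighbours) before integrating
volume = Σ(height − background)·pixel area, so the sub-threshold skirt of
each particle is captured — on noise-free synthetic fields total volume is
conserved to well under 2%. Particles touching the field edge are flagged
and excluded from summaries. Classes: sub-threshold < 40 nm³ (speckle floor;
the upstream analysis states no floor, so this is a package choice), monomer
[40, 170), dimer [170, 350] inclusive on both bounds per the published
window, multimer > 350 nm³. Class fractions are reported among non-edge,
above-floor particles.

The predicted condensed volume V_c = (M₀/N₀)(V₁ + d·V₂) evaluates, for a
175 kDa heterodimer with the stated constants, to 331.3 nm³. Shape-scored
dimer configurations (extended / one-arm folded / semi-condensed /
condensed) are accepted as pre-scored counts and compared by G test; the
scoring itself was manual upstream and is not reimplemented.

The field simulator uses rotationally symmetric Gaussian caps (analytic
volume 2πσ²h₀) with rejection placement; it does not emulate AFM tip
convolution, scan-line noise, or drift beyond what plane subtraction
removes, so segmentation performance on real images will be somewhat worse
than on synthetic fields.

## Binding and kinetics

Hill fits target the series on its native scale — the unbound fraction, as
gel quantification of the free band yields directly — with the saturating
bound fraction fixed at 1 (binding in these assays runs >90% to completion);
`free_amplitude=True` frees it. K is parameterised as the half-saturation
constant so it carries concentration units. Initialisation: K from the
interpolated half-max crossing, n from the log-log slope of the odds
f/(1−f) near half-max; bounds n ∈ (0, 6], K > 0; Levenberg-style least
squares via scipy `curve_fit`, SEs from the covariance (local curvature).
Titrations that do not bracket half-maximal binding are rejected as
non-identifiable rather than fitted. Michaelis–Menten fits are analogous;
k_cat = V_max when rates are per-enzyme, else V_max divided by the supplied
enzyme concentration, and a substrate range that never reaches 2·K_m
triggers a warning since K_m is then poorly constrained. Competition series
are normalised as 100(1 − bound/bound_ref), clipped to [0, 100] with a flag
when noise pushes a point outside.

The titration simulator adds i.i.d. Gaussian noise to the exact curve
(truncated to [0,1] for fractions). Its default binding grid is a two-fold
EMSA-style dilution series, 12.5–400 nM, concentrated around the
tens-of-nM half-saturation range these assays occupy. At the simulated
conditions used in tests (10 points, 3% noise) the Hill-slope estimator's
sampling SD is ~0.12 — the information limit of such a titration — which is
why slope-recovery checks are stated in units of the fitted SE.

## Reversion assays

Revertant counts per culture are Poisson(frequency × CFU). Luria–Delbrück
jackpot dynamics are deliberately not modelled: the estimand throughout is
the reversion *frequency* (revertants per CFU), not a mutation rate, and the
published comparisons are frequency-based. Simulated fluctuation data will
therefore under-disperse relative to real cultures; the median aggregation
rule exists for exactly that gap.

## Problem sizes and determinism

All generators are bit-reproducible given a seed and return truth records
sufficient to score their estimators. Default validation sizes — 2×10⁵
tetrads for distance recovery, 10⁵ for nondisjunction and classifier
checks, 10⁶ for the small-distance expansion check, 40–60 particles per AFM
field, 10-point titrations, 6 cultures — were chosen so each check's
Monte-Carlo error is comfortably below the tolerance it tests.
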