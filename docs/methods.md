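# Methods

This note documents the models, numerical choices and limitations behind
`glycotrait`: what each stage computes, which parameters matter, what the
synthetic-data generator does and does not emulate, and where the design
was genuinely open.

## Mass and isotope engine

Compositions count five residue classes — hexose (C₆H₁₀O₅), HexNAc
(C₈H₁₃NO₅), deoxyhexose (C₆H₁₀O₄), lactonized NeuAc (NeuAc − H₂O,
α2,3-linkage proxy) and ethyl-esterified NeuAc (NeuAc + C₂H₄, α2,6 proxy).
The reported m/z is the monoisotopic mass of the residues + H₂O + Na minus
one electron, i.e. the singly charged `[M+Na]+` cation. Element masses and
isotope abundances are IUPAC representative values pinned in one table in
`chem.py`. All 19 reference calibrant m/z values reproduce within 0.9 mDa;
the largest deviation (H9N8, −0.8 mDa) is consistent with rounding in the
printed value. Whether the electron mass is subtracted is a ~0.5 mDa
convention; it is subtracted here because that matches the printed values
slightly better at 3-decimal precision.

Isotopic patterns are aggregated by extra-neutron count (unit-mass
isotopologues) and computed by element-wise convolution with
exponentiation-by-squaring; truncated patterns keep guard terms so the
retained fractions are unbiased. The average isotopologue spacing used for
peak windows is 1.00235 Da; the exact per-formula spacing varies by
< 0.01 Da over this mass range, far below the ±0.24 Da integration
half-window. Composition search over a bounded box (default H ≤ 12, N ≤ 10,
F, L, E ≤ 6) is exhaustive — ~50k candidates in milliseconds — and returns
hits sorted by |ppm|. The search is by mass only; it does not impose
biosynthetic plausibility (a match like F3L3E3 is reported if it fits the
window).

## Spectrum processing

The chain mirrors the established composition-level workflow with these
numerical choices:

- **Smoothing** — Savitzky–Golay, order 2, window = nearest odd point count
  spanning 0.06 Da (minimum 5 points), 4 cycles. Total ion current is
  preserved to within 1%.
- **Baseline** — tophat (grey opening) with a 3 Da structuring element:
  much wider than the ~0.2 Da peaks, much narrower than baseline structure.
  The opening follows the *lower* envelope of the noise, so a pedestal of
  roughly +3σ of the noise survives subtraction. All S/N values are
  therefore measured as apex height above the local background level, and
  extraction integrates background-subtracted intensities; the level and
  noise (1.4826 × MAD) are estimated on disjoint 20-Da tiles and linearly
  interpolated between tile centres (an O(n) equivalent of a sliding
  window; width configurable).
- **Peak picking** — local maxima at S/N ≥ 3, apex refined by a parabola
  through the top three points. The picker expects a smoothed,
  baseline-corrected spectrum; on raw noisy input a single physical peak
  can yield several ripple maxima.
- **Recalibration** — calibrants are matched to the nearest picked peak
  within 100 ppm, restricted to peaks with S/N ≥ 9 (absent calibrants must
  not latch onto noise maxima), then a 3rd-degree polynomial of theoretical
  on observed m/z is least-squares fitted with one outlier-rejection refit
  (drop |residual| > max(2.5 × SD, 1 ppm)). At least five matched
  calibrants are required; fewer is a hard error. On noiseless input with a
  known cubic distortion the residuals at the calibrants are < 1 ppm.
- **Extraction** — the first three isotopologues are integrated in
  ±3σ windows (σ default 0.08 Da) and the summed area divided by
  (p₀+p₁+p₂). Three-isotope truncation is itself the mitigation against
  overlapping envelopes of heavier neighbours; no deconvolution is
  attempted. A ±3σ window captures 99.7% of a Gaussian peak, making the
  corrected area conserve the true area to ≲ 1% on clean data (a ±2σ
  window would clip 4.5% systematically).
- **QC** — all quoted inequalities are strict: spectrum pass requires
  summed analyte area > 1×10⁵ *and* > 50% of that area at S/N > 9; analyte
  pass requires S/N > 6, |ppm| < 20 and quality score criterion. The
  quality score is the mean absolute deviation between observed and
  theoretical first-three isotopologue fractions, so *smaller* is better;
  the default accepts QS ≤ 0.10. Because the printed criterion reads
  "quality score > 0.10" while deviation scores conventionally pass when
  small, the direction is configurable (`QCThresholds.qs_pass_below`).
- **Replicates** — technical replicates are averaged onto the first
  replicate's m/z grid before peak picking (averaging vs summing differs
  only by a factor that the final rescaling to 100% removes).

## Derived traits

Every trait lives in a declarative registry as a numerator/denominator pair
of abundance weights, so alternates can be swapped without touching the
pipeline. Classification: N=2 ∧ H≥5 high-mannose, N=2 ∧ H≤4 paucimannose,
N=3 ∧ H≥5 hybrid, otherwise complex (N<2 is not a valid N-glycan). For
complex species, antennae = N−2 floored at 1 and galactoses =
min(H−3, antennae) floored at 0; a bisecting GlcNAc is indistinguishable
from an antenna at composition level and is counted as one — a known
confound. Hybrid species contribute to "all"-denominators but not to
complex-only traits. Undefined subsets yield NaN (missing), never 0.

Sialylation is emitted in two forms: per-antenna over complex species
(`Sia23`, `Sia26`, the registry default form) and per-glycan over the whole
profile (`Sia23Glycans`, `Sia26Glycans` — the fraction of total abundance
carrying at least one L or E). The generator targets and the group
contrasts use the per-glycan form, because only in that form are the
printed group values internally consistent (α2,3 ≤ overall sialylation).

A structural consequence of the antenna/galactose counting worth knowing:
complex compositions with H > N are always fully galactosylated
(H > N ⇒ H−3 ≥ N−2), so galactosylation-per-antenna below 100% is
attainable *only* through HexNAc≥Hex species. The two traits are therefore
intrinsically coupled at the composition level.

## Synthetic-data generator

The generator emulates the 16-cell-line study design: two groups (8+8 by
default), 3 technical replicates, spectra over m/z 1000–5000.

**Profiles.** Per-sample values of eight targetable traits (high-mannose,
multi-fucosylation, overall/α2,3/α2,6 sialylation per-glycan,
galactosylation per antenna, HexNAc≥Hex, HexNAc≥7) are drawn from
truncated normals around group targets (default between-sample SD
4.5 pp), with order constraints repaired at draw time (overall sialylation
clipped into [max(s23, s26), s23+s26]; gal-per-antenna drawn inside the
interval the drawn HexNAc≥Hex share admits). Abundances over a ~100-species
library (high-mannose H5–10N2, two hybrid species at a fixed 3% share, and
complex species spanning 0–4 fucoses, bisected, branched and sialylated
variants with L+E never exceeding the galactose count) are then solved by
non-negative least squares: every targeted trait is a ratio of linear forms
in the abundances, so trait = target is a linear constraint, and the NNLS
objective keeps the solution near a random Dirichlet base profile for
between-sample variety. Achieved traits match the drawn values within 1 pp;
the rare draws (~1–2%) that remain infeasible through higher-order
couplings are projected onto the feasible set, with the achieved vector
recorded as the effective draw. Stored truth is always the achieved
profile and its traits.

**Trait SD calibration.** The 4.5 pp SD was set by a design-time power
calculation: with exact Mann–Whitney at n=8/8 and Bonferroni over the 15
emitted traits, the weakest designed contrast (α2,3-sialylation, 12 pp)
then reaches corrected significance in ≳85% of cohorts — matching a study
outcome in which all five headline contrasts were significant — while the
7 pp HexNAc≥7 trend stays mostly non-significant. A larger SD (e.g. 8 pp)
would drop the weakest contrast's power to ~35%, inconsistent with that
outcome.

**Preset group targets** encode the reported contrasts: multi-fucosylation
54/33, overall sialylation 21/36 (lower in the high group, per the
narrative direction), α2,3-sialylation 11/23, α2,6 12/18,
galactosylation-per-antenna 72/85, HexNAc≥7 27/20, high-mannose 30/30.
HexNAc≥Hex group means are not printed (only ">2-fold higher"); they are
set to 26/12. Because of the gal/HexNAc coupling above, the low group's
*achieved* gal-per-antenna mean settles at ~88–90% rather than the nominal
85% — with a >2-fold-lower HexNAc≥Hex share, 85% is not jointly attainable
under these counting rules. All recovery checks compare against the stored
truth, not the nominal preset.

**Spectra.** Each composition contributes Gaussian peaks (σ = 0.08 Da,
≈ FWHM 0.19 Da, resolution ~10⁴ at m/z 2000) at its first five
isotopologue positions, shifted by a cubic miscalibration polynomial
(default ~10–40 ppm — well inside the 100 ppm calibrant-matching window),
with areas = intensity_scale × abundance × isotopic fraction over a
decaying-exponential baseline plus Gaussian noise (SD 200 at an
analyte-area scale of 2×10⁶, so a 0.1% species has S/N ≈ 25 and spectra
pass the 1×10⁵ total-intensity QC with margin). Replicates are independent
noise realizations of the same profile. Not emulated: detector dead time,
matrix clusters, peak-shape asymmetry, chemical noise correlated with
analytes, and spot-to-spot intensity drift — so passing roundtrip tests
demonstrate the correctness of the processing chain, not its robustness to
every real-data pathology.

**Expression matrix.** Genes × samples log2 values, Gaussian around
per-group means (base 6.0, SD 0.5 log2 units). Differential defaults encode
the reported directionality and magnitudes: FUT3 5.7×, FUT6 2.7×, GMDS
3.7×, LGALS4 23×, HNF1A/HNF4A/B4GALNT3/MGAT4A/B3GNT3/B3GNT8 up;
FUT8/ST3GAL3/4/6 down (trend); everything else null. CDX1 itself is
generated around the log2 group means of the measured cell-line table
(ratio of linear group means ≈ 65).

## Statistics

Trait contrasts: two-sided Mann–Whitney U, exact for group sizes ≤ 10
without ties (the exact implementation is verified against full enumeration
of all labelings for n ≤ 6), normal approximation with tie correction
otherwise; Bonferroni family = number of traits tested. Genes: Welch t-test
by default (the pooled-variance variant is a flag), fold change =
2^(Δ mean log2), Bonferroni over the tested panel; genes absent from the
matrix are reported as missing rather than dropped. Trait–gene association:
per-pair OLS with slope, intercept, R² and two-sided slope p. PCA:
mean-centred, unit-variance scaled by default, full SVD, component signs
fixed so the largest-|loading| element is positive. The CDX1 summary is the
ratio of arithmetic group means on the linear scale (not the mean of
per-sample ratios).

Under a null design (identical group targets) the trait test's type-I error
over 1000 simulated cohorts stays within 2 Monte-Carlo SEs of α = 0.05; the
exact test's attainable size at n=8/8 is 0.0499.

## Problem sizes

Defaults are sized for a laptop-class single core: the full
simulate → render → process roundtrip of a 16-sample, 3-replicate cohort at
0.02 Da sampling takes a few seconds; the 100-cohort detection-rate and
1000-cohort type-I summaries in `scripts/acceptance.py` complete in about
two minutes. The detection-rate and type-I summaries operate on generated
profiles directly (the spectral layer's fidelity is established separately
by the roundtrip recovery check, which shows sub-0.5 pp median trait
error), keeping the Monte-Carlo loops cheap.

## Known limitations

- Composition-level identification only: no structural (linkage/branch)
  assignment, no MS/MS, no distinction of α2,8- from α2,3-linked sialic
  acids (both lactonize), no type-1 vs type-2 chains, no O-acetylation.
- Bisecting GlcNAc vs antennal GlcNAc vs LacdiNAc are indistinguishable;
  antennae counting treats them identically.
- No deconvolution of overlapping isotope envelopes beyond three-isotope
  truncation.
- The synthetic composition library (~100 species) is smaller than a real
  cell-line glycome (hundreds of species); the generator's trait couplings
  (notably gal-per-antenna vs HexNAc≥Hex) are properties of the counting
  rules, not of biology.
- Vendor raw formats are out of scope; spectra enter as two-column xy text.
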