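# Methods

## The model

A DOM sample is a composition: per-sample signal intensities of assigned
molecular formulas are normalized to the sum of all assigned-peak
intensities in that sample, so each molecule carries a relative abundance
*I<sub>i</sub>* and each sample's abundances sum to one. A zero means the
molecule was not detected in that sample and is treated as a real
observation of absence, not as missing data. The normalization denominator
is the whole-sample total and is never recomputed after subsetting:
downstream weighted means normalize internally, so re-closure would only
change nothing (the indicator) or silently change meaning (occupancy).

**MER.** The response of molecule *i* to a covariate (water temperature at
sampling by default — any numeric metadata column can be selected) is the
Spearman rank correlation ρ of its relative abundance against the
covariate. Rank correlation is used because peak intensities are strongly
skewed and only monotone association is claimed; it also makes MER a
unitless effect size that can be compared across regions and studies. Ties
receive average ranks; two-sided p-values use the t approximation with
n − 2 degrees of freedom, with an exact permutation test (all n!
orderings) below n = 10. A constant abundance or covariate leaves ρ
undefined; such records are flagged and skipped downstream. Low-occurrence
molecules inflate type-I error, so molecules detected in fewer than
⌈n/3⌉ of the fitting samples are dropped (for 80% partitions of 150- and
180-sample designs this gives cutoffs of 40 and 48 samples). Zeros of
retained molecules enter the correlation; excluding them is an option
(`include_zeros=False`). No multiple-testing correction is applied by
default, matching the indicator's definition of "significant" as an
unadjusted p ≤ 0.05 per molecule; a user can post-filter the returned
p-values if their application needs familywise control.

**iCER.** The compositional response of a sample is the
relative-abundance-weighted mean of the MERs of molecules present in it,
iCER = Σ(MER·I)/Σ(I) ∈ [−1, 1]. Because iCER consumes MERs, the two are
computed on statistically independent data: each replicate partitions the
samples uniformly at random 80:20 (|train| = round(0.8·n)), fits MERs on
the training partition only — the occupancy cutoff recomputed from the
training size — and scores iCER for the held-out samples. Per-sample iCER
is the arithmetic mean over the replicates in which the sample was held
out; replicates where a sample shares no MER-carrying molecule are
skipped, not zero-filled. 999 replicates is the default; each replicate's
RNG derives from (master seed, replicate index), so partial reruns
reproduce the split sequence. Both variants are always computed: iCER from
all MERs and from significant-only MERs; the latter is the default for
reporting because significantly responsive molecules dominate the
composition and give steeper, better-resolved temperature relationships.
Splits are plain uniform (not stratified by design cells): the resampling
scheme's only job is independence, and stratification options were left
out to keep the scheme identical to the published one.

**Sensitivity.** Per nutrient level (≥ 3 samples), the OLS slope of iCER
against the covariate measures warming sensitivity; the OLS slope of those
slopes against nutrient concentration measures how eutrophication
modulates it. The summary percentage is defined here as
100 · (slope-of-slopes) / (mean per-level slope) per mg N L⁻¹. This
definition is this package's documented choice; the percentage printed by
other analyses of this design may be normalized differently.

## Molecular traits and classes

Fifteen traits per formula: neutral monoisotopic mass (IUPAC element
masses; a measured m/z-derived mass can be supplied instead), carbon
number, DBE = 1 + (2C − H + N + P)/2 (CHNOPS convention: O and S
contribute zero), DBE − O and (DBE − O)/C, modified aromaticity index
AI_mod = (1 + C − 0.5·O − S − 0.5·H)/(C − 0.5·O − S − N − P) clamped to 0
when negative or the denominator is non-positive, DBE − AI (subtracting
AI_mod by default; the unmodified index is a switch, since which one the
trait list intends is ambiguous), NOSC, GFE = 60.3 − 28.5·NOSC, the
CH2-base Kendrick defect round(KM) − KM with KM = mass·14/14.01565, and
the five element/C ratios. Compound classes partition the van Krevelen
plane with aromaticity precedence: condensed aromatics (AI_mod ≥ 0.67),
aromatics ([0.5, 0.67)), fatty acids & carbohydrates (H/C > 2.0 or
O/C ≥ 0.9), peptides (1.5 ≤ H/C ≤ 2.0, O/C < 0.9, N > 0), aliphatics
(same, N = 0), then high-O (O/C ≥ 0.5) vs low-O unsaturated. Comparisons
are exact rationals-as-floats: benzene's AI_mod = 2/3 falls below 0.67 and
classifies as aromatic; implementations that round to 3 decimals before
comparing would place it on the boundary.

Formula plausibility re-checks the elemental-ratio assignment criteria
(0.333 ≤ H/C ≤ 2.25, O/C ≤ 1, N/C < 0.5, S/C < 0.2, P/C < 0.1,
(S+P)/C < 0.2) with the printed boundary senses. The nitrogen rule and
integer-DBE checks belong to m/z-based assignment, which this package does
not perform, and are deliberately not re-applied. Oxygen-free formulas are
accepted by default and can be flagged (`require_oxygen=True`).

## Continuum, transferability, gas rates

**Removal continuum.** Within each sign group, molecules sort by |MER|
(ties broken by molecule id) into equal-count bins — 100 by default, i.e.
1% of the group per bin; remainders go to the lowest-index bins, and a
group smaller than the bin count falls back to one molecule per bin.
Scenario k retains bins k..B and reports: % removed, % significant,
mean/median MER, the signed MER of smallest magnitude retained, per-trait
means ± s.e. (across molecules) for GFE, AI_mod, H/C, O/C and NOSC, and
per-class richness percentages (summing to 100). All molecules with
defined MERs participate, significant or not — the analysis needs the full
effect-size continuum. Robustness to bin width is checked by comparing
curves interpolated along the |lowest retained MER| axis.

**Transferability.** Agreement between two independently fitted MER tables
is Pearson r and the OLS slope of group-B MERs on group-A MERs over their
shared molecules (identity = exact elemental composition via molecule id),
overall and per compound class with ≥ 3 members; fit significance is the
one-sided F test (equivalent to the slope t test for simple OLS).
Intra-regionally, all C(n, n/2) labeled assignments of the nutrient levels
to groups A and B are enumerated (252 for 10 levels — labeled, so a split
and its mirror both count); MERs are fitted on each group's full sample
set, not on 80% sub-partitions, because transferability needs each group's
complete MER range rather than an out-of-sample contract.

**Gas release rates.** R = dc/dt · V/M_v · M_w/m with V in litres,
M_v = 22.4 L mol⁻¹ and M_w the molar mass of carbon; since ppm is 10⁻⁶
mol fraction and the result is in µg, the two factors cancel and R is in
µg C g⁻¹ d⁻¹. The incubation design re-flushes the headspace with N₂
after each sampling, so each measurement is a per-interval accumulation;
the default fit regresses per-interval concentration on interval duration
(with intercept, so a constant concentration profile over unequal
intervals fits a zero slope). Cumulative-sum and raw-series fits are
provided for designs without flushing. Negative fitted rates (net uptake)
are allowed and flagged. Both a cumulative mass flux and the final
interval concentration are reported, since either may be meant by "flux".

## Synthetic data

The generator's defaults are the study designs: field = 16 elevations
(5 + 6 + 5 across three regions, the printed elevations) × 10 nutrient
levels (0–36 mg N L⁻¹, the printed series) × 3 replicates = 480 samples,
with water temperature declining linearly with elevation inside each
region's measured range (11.4–21.1, 10.4–23.0, 19.6–25.2 °C); lab =
3 climate-zone inocula × 7 temperatures (5–35 °C) × 4 replicates = 84
samples, gas sampling on days 5/12/19/26/33.

Molecules (default 300 — enough for stable bin/continuum statistics while
keeping the full 999-replicate pipeline interactive on one core) draw
valid CHNOPS compositions; 75% are warm-accumulating, 15% warm-depleting,
10% null by default, with target |ρ| uniform on (0.3, 0.9). Latent
log-intensity is baseline + β·t + noise with t the standardized
temperature and β = ρ/√(1 − ρ²)·σ, so the latent rank correlation matches
the target; σ = 0.4 (lognormal multiplicative noise) and 5% random dropout
by default. Closure subtracts a common drift −d log Σ/dt from every
molecule's share trend; the generator balances this drift by giving the
minority-trend group compensating baseline mass, so planted signs survive
the compositional normalization (first-order, at the gradient's centre).
Warm-accumulating molecules are drawn preferentially from high-GFE
compositions (Gumbel-max weighted sampling), reproducing the
field-experiment regime in which warming selects for thermodynamically
less favorable molecules; a negative linkage reproduces the lab-direction
regime. Gas series invert the rate equation with a planted rate
base + coupling·(T − 5) and multiplicative noise of σ = 0.005 — the order
of gas-chromatography replicate precision; the slope fit amplifies
concentration error roughly threefold because only the first sampling
interval differs in length.

What passing tests on this generator do show: the estimators recover
monotone abundance–temperature structure, planted signs and magnitudes,
the indicator's identities, and the pipeline's independence contract.
What they do not show: behavior under ionization-efficiency bias,
correlated molecule families (shared biochemical origin), heavy
zero-inflation beyond the occupancy cutoff, instrument drift between
batches, or non-monotone (unimodal) temperature responses — real FT-ICR
data contain all of these.

## Numerical conventions and degenerate inputs

Spearman ρ is computed as Pearson correlation of average ranks and clipped
to [−1, 1] against floating-point overshoot; |ρ| = 1 maps to p = 0 rather
than a degenerate t. Constant vectors yield NaN ρ, excluded everywhere
downstream. Weighted means reject all-zero weights. An intensity column
of zeros yields zero relative abundance (not NaN). round(0.8·n) uses
banker's rounding (Python `round`). Bin remainders, tie-breaks and split
sub-seeding are all deterministic so that identical seeds give
byte-identical outputs.

## Limitations

Single-covariate responses only (a multivariate extension is out of
scope); no partial correlations; no cross-laboratory harmonization of
MERs; no spectrum processing or formula assignment — inputs are
already-assigned formula tables; the percentage definition of nutrient
sensitivity is one documented choice among several plausible ones.
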