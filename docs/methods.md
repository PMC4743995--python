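# Methods

This note documents the models, conventions and design choices behind
`osmo`, stage by stage, and what the synthetic-data tests do and do not
establish about real data.

## Dose-response model

Growth inhibition is modelled as a three-parameter Hill curve on
relative growth rates, `r(c) = top / (1 + (c/k)^h)` with `top ∈ [0.8,
1.2]`, `k > 0` (mM NaCl) and `h > 0`. The bottom asymptote is fixed at
zero because rates are normalised to the unstressed control; `top`
absorbs residual normalisation error. With this form the half-maximal
concentration equals `k`, and `IC_f = k (f/(1−f))^{1/h}` for any
inhibition fraction `f ∈ (0,1)` — strictly increasing in `f`, so
IC10 ≤ IC25 ≤ IC50 always holds.

Fitting uses bounded Levenberg–Marquardt (trust-region reflective) with
an analytic Jacobian and a small multi-start grid: `k` starts at a
half-maximum crossing estimated from the data plus the extremes of the
tested range, `h` at {0.8, 2, 4}. The best residual sum of squares wins;
an IC50 beyond the tested concentration range is reported but flagged
not-determined.

Maximum exponential growth rates are the largest slope of a least-squares
line through ln(OD) over a sliding window. The window defaults to 8
consecutive points for a single curve. When whole replicate series are
fitted (`estimate_ic_from_curves`), the window is instead sized to span
4 hours of data whatever the sampling interval: the maximum over many
short overlapping windows is upward-biased under multiplicative noise,
and a fixed time span keeps the bias negligible at 10-minute sampling
while still sitting inside a typical exponential phase. Replicates are
fitted separately — each replicate's rates normalised to its own
unstressed curve — and IC values averaged across replicate fits
(reported as mean ± SD), rather than pooling points into one fit.

Human cell lines are handled by the same sigmoid applied to normalised
72-h endpoint cell counts; `fit_linear_calibration` maps a fluorescence
readout to cell counts with a positive-slope line fitted on the longest
low-count prefix whose linear R² reaches 0.999, which excludes the
saturated top of the signal range.

## Accurate-mass annotation

Negative-ionisation centroids are matched against expected ion m/z
within an absolute tolerance (default 0.005 Da, not ppm). Two species
per compound are considered: the deprotonated molecular ion
(neutral monoisotopic mass − 1.00727646688 Da, a proton — not a neutral
hydrogen, so electron mass is treated correctly at this tolerance) and
the single-¹³C isotopologue (+1.0033548378 Da). Monoisotopic masses come
from a bundled IUPAC/CODATA constant table so windows are reproducible
across environments. The mass index is sorted and queried by binary
search; tests prove equivalence to an all-pairs linear scan.

Ambiguity (several compounds within tolerance of one feature) is flagged
and propagated, never auto-resolved, and every matching feature becomes
its own row in the merged metabolite table — duplicate metabolite names
therefore denote different ions of the same compound. ¹³C rows are kept
as independent measurements, not summed into the monoisotopic row.
Compounds are routed to one extract phase by octanol/water logP
(≤ 0 → polar, > 0 → nonpolar); a compound annotated only in the wrong
phase is excluded.

## Differential analysis

Quantile normalisation forces all sample columns onto the mean
distribution of order statistics. It is applied separately per organism
and extract phase, since its purpose is correcting biomass variation
within one experiment. Ties receive the mean of the target values over
the tied ranks (this preserves column sums; exact idempotence and equal
column multisets hold for tie-free data). Columns with missing entries
are mapped through quantile interpolation onto the same reference.

Technical replicates are averaged into their biological replicate before
any statistics, so n = 4 for microbes and 3 for human lines. The log₂
fold-change is log₂(mean stressed) − log₂(mean control) over biological
replicates; the test is a two-sided pooled-variance Student t on log₂
intensities. Degenerate zero-variance comparisons with equal means get
p = 1 by convention. Fold-changes from non-positive means become missing
values, never imputed zeros.

q-values follow the Storey–Tibshirani recipe: π₀(λ) = #{p > λ}/(m(1−λ))
on λ = 0, 0.05, …, 0.90, smoothed with a cubic smoothing spline
(`scipy.interpolate.splrep` default smoothing) and read off at λ = 0.90,
clamped to (0, 1]; q is π₀·m·p(i)/i with monotonicity enforced from the
largest p downward, so p-value order is preserved and π₀ = 1 reduces
exactly to Benjamini–Hochberg. The multiple-testing family is all ions ×
all stress levels within one organism. A record is differential when
|log₂FC| ≥ 1 and q < 0.05; a metabolite is differential for an organism
when any stress level qualifies.

Baseline Z-scores compare unstressed abundances across organisms:
organism means at IC0, by default on log₂ normalised intensities
(configurable), standardised per metabolite with the across-organism
sample SD; zero-variance rows get Z = 0 and a flag, |Z| < 1 is tagged
"small".

## Comparative structure

PCA is the SVD of the column-centered fold-change matrix with missing
values imputed to 0 (= unchanged vs control) — a complete matrix is
required for the decomposition. Distances, in contrast, are
pairwise-complete Cityblock sums so that imputation cannot dilute them.
Cladograms use average linkage by default (configurable single /
complete / average / ward); Newick branch lengths are half the
merge-height gaps, making leaf-to-leaf path lengths equal the cophenetic
distances. Average linkage is monotone, so merge heights never invert.

Jukes-Cantor distances use the mismatch fraction p over columns where
both sequences are un-gapped; p ≥ 3/4 is past the model's saturation
point and flagged undefined. The association between metabolic and
phylogenetic distance structures is assessed by a Mantel test: Pearson R
over the upper triangle, with a permutation null (relabeling one matrix;
one-sided for positive association) as the primary p-value. A t
statistic on R with n(n−1)/2 − 2 df is reported alongside, labeled
approximate — distance pairs are not independent, so it is optimistic
and is never treated as the primary inference.

## Screens

The four-way ANOVA fits a main-effects-only linear model of the
IC50-level log₂ fold-changes on taxonomy group, habitat, cell-wall class
and salt-tolerance class (low: IC50 < 500 mM; medium: 500–1000 mM,
boundaries inclusive; high: > 1000 mM). Designs are unbalanced, so each
factor's p-value uses added-last (partial) sums of squares: the F test
compares the full model against the model with that factor dropped, with
degrees of freedom from matrix ranks, which transparently handles
aliased factors (zero added df → untestable). Analysis is complete-case
per metabolite; a factor left with one populated level is marked
untestable. An exactly constant response short-circuits to F = 0 rather
than dividing floating-point noise. Hits need factor p < 0.01 and
|group mean log₂FC| > 1 in at least one of that factor's groups;
per-factor lists are ranked by p and truncated to 40 for reporting, with
the hit union counted before truncation.

The tolerance screen computes, per metabolite over the organisms where
it was detected, Pearson's R between IC50-level log₂ fold-changes and
organism IC50, and the upper quartile x₀.₇₅ of |log₂FC| with the linear
order-statistic interpolation convention (position 1 + 0.75(n−1)). Hits
need detection in strictly more than 10 species, x₀.₇₅ > 1 and |R| >
0.5, with the sign of R separating correlating from anticorrelating
metabolites. The screen is invariant to organism ordering and to any
common rescaling of the IC50 units.

## Synthetic-data generator

The generator emulates the study design: 16 organisms (taxonomy groups
cycling through two proteobacterial classes, firmicutes, actinobacteria,
fungi and human, giving twelve microbes, two fungi and two human lines),
IC50 drawn log-uniformly over 150–1500 mM, four stress levels, 4
(microbes) or 3 (human) biological × 2 technical replicates, two extract
phases, growth curves for an unstressed control plus twelve salt
concentrations log-spaced over 50–2500 mM in duplicate, sampled every 10
minutes for 24 h as capped exponential curves. Habitat and cell-wall
labels are drawn independently of taxonomy (apart from the human lines,
which are animal-associated and wall-less) so that every ANOVA factor
retains its own degrees of freedom; in real panels these factors are
strongly confounded with taxonomy, and the ANOVA's added-last convention
is exactly what exposes that confounding.

Intensities are log-normal around per-(compound, organism) baselines
(log₂ mean 14, SD 2) with biological CV 20% and technical CV 10% —
values typical for flow-injection TOF intensities; noise is
multiplicative to keep positivity. Features sit at the expected ion m/z
plus uniform jitter within ±0.004 Da (strictly inside the 0.005 Da
annotation tolerance, so recall is 100% by construction); decoy features
that match no library mass within 0.006 Da are added at 10× the number
of true features, echoing the ~17,000-feature / ~10³-annotation ratio of
real spectra. The default library holds 120 compounds — an order of
magnitude below a real per-species KEGG list, chosen so a full
multi-study acceptance run completes in minutes; library size does not
enter any statistical contract.

Planted effects are written on the log₂ scale into a ground-truth
registry: osmoprotectant accumulation (≥ 1.2 log₂ units at IC50, graded
1/3 and 2/3 at IC10/IC25), species-specific shifts, factor-specific
offsets (|offset| ∈ [2.5, 3.5], planted only on identifiable levels —
at least two member organisms, and not the human-aliased taxonomy/wall
levels, where attribution to one factor is impossible by construction),
and tolerance-correlated responses whose IC50-level fold-change is
linear in organism IC50 with Gaussian noise (SD 0.45), calibrated to
|R| ≈ 0.8 and x₀.₇₅ ≈ 1.5. Everything else is null. All outputs are
pure functions of (config, seed).

What passing tests show — and do not. Parameter recovery on this
generator demonstrates that the pipeline's statistics are implemented
correctly and are jointly powerful enough at the study's replicate
structure and noise level. The generator does not model isotope-pattern
intensity ratios, ionisation suppression, batch effects, missing-not-at-
random dropout, or correlated metabolite panels; recovery rates here
therefore do not predict sensitivity on real spectra, where annotation
ambiguity and matrix effects dominate.

## Numerical conventions and edge cases

- Mass arithmetic uses the bundled constant table (≥ 6 decimals);
  proton mass 1.00727646688 Da, ¹³C−¹²C 1.0033548378 Da.
- Tolerance-class boundaries 500 and 1000 mM are assigned to "medium".
- Quantile normalisation raises on an all-missing column; q-value
  estimation requires ≥ 10 p-values for the spline (π₀ is forced to 1
  for smaller families).
- Mantel permutation p uses the (count + 1)/(n_perm + 1) estimator;
  permutations are seeded.
- Clustering ties break deterministically by label order of the
  condensed distance matrix.
- Problem sizes in the shipped acceptance run: 12 replicate studies at
  the default design, 100 rate-level dose-response fits, a 2000-ion null
  study, and 10 tree-structured Mantel replicates at 999 permutations.

## Known limitations

- Only the two stated negative-mode ion species are considered; no
  adduct search, isotope-pattern scoring or positive mode.
- The Hill inhibition curve is monotone; hormetic (growth-stimulating)
  low-salt responses would be mis-fit.
- The t approximation for distance-matrix correlation is reported but
  approximate; the permutation p is the defensible one.
- The four-way ANOVA fits main effects only — interactions are out of
  scope — and cannot attribute effects carried by levels that are
  aliased across factors (e.g. a human-only response).
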