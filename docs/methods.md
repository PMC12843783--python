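# Methods

This note documents the models, numerical choices and limitations of
`riverdom`'s analysis chain, and what the synthetic-data generator does
and does not emulate.

## EEM preprocessing

An EEM is stored as an excitation × emission intensity grid with
strictly increasing wavelength axes (nm) and a boolean mask for excised
cells.  The preprocessing chain is:

1. **Blank subtraction.**  A pure-water blank EEM is subtracted cell by
   cell.  Negative residuals are retained rather than clipped — the
   nonnegativity constraint belongs to the PARAFAC loadings, not the
   data, and clipping would bias low-signal regions upward.
2. **Inner-filter correction (optional, off by default).**  Each cell is
   multiplied by `10^((A(ex)+A(em))/2)` with absorbance A (per cm,
   1 cm path) linearly interpolated; extrapolation outside the
   absorbance spectrum is an error.  The correction is optional because
   many campaigns record no absorbance; blank subtraction alone then
   accounts only for the instrument background.
3. **Raman normalisation.**  Intensities are divided by the trapezoidal
   area under the blank's water Raman peak at Ex 350 nm over
   Em 371–428 nm, giving Raman units (R.U.).  Band endpoints are
   interpolated onto the native emission grid, so the constant-blank
   area over that window is exactly 57 nm·counts per unit intensity.
4. **Scatter excision.**  Cells with |em − ex| ≤ w1 (first-order
   Rayleigh), |em − 2·ex| ≤ w2 (second order), or emission within
   ±15 nm of the Raman ridge are excised; the ridge is located at a
   constant 3400 cm⁻¹ shift below the excitation line
   (1/em = 1/ex − 3400·10⁻⁷ nm⁻¹), which at Ex 350 nm falls at
   ≈ 397 nm, inside the 371–428 nm normalisation window.  Default
   half-widths w1 = w2 = 10 nm; all widths are configurable since
   instruments differ.  The anti-Stokes region em < ex is always
   masked.  `fill="mask"` marks cells missing; `fill="interpolate"`
   replaces them by linear interpolation along emission (rows left with
   fewer than two good cells fall back to masking with a warning).
   Interpolated filling is used only where a complete surface is needed
   (the wavelength-ratio indices); the PARAFAC stage always works on
   masked data.

## PARAFAC

The sample × ex × em tensor is modelled as a sum of F nonnegative
rank-one components.  Fitting is alternating least squares:

- each mode update solves row-wise nonnegative least squares via the
  Cholesky square-root reformulation of the normal equations, so the
  per-row cost is independent of the mode dimensions;
- missing cells (excised scatter) are handled by expectation-
  maximisation: the objective is the SSE over observed cells only, and
  model values are imputed into missing cells between sweeps;
- components that collapse to zero (a known absorbing state of
  nonnegative ALS) are reinitialised randomly — without this safeguard
  overfactored fits tend to park surplus components at zero instead of
  revealing their instability.  A reinitialisation can transiently
  raise the SSE; in healthy fits it never triggers and the objective is
  non-increasing;
- `n_starts` random initialisations are run (default 10; the pipeline
  preset uses 4) and the best observed-cell SSE kept.  Iteration stops
  when the relative SSE change drops below `tol` (default 1e-8) or
  `max_iter` (default 2500) is reached.  EM with heavily masked data
  converges slowly; the pipeline preset caps iterations at 800, which
  in practice changes loadings by far less than the split-half
  uncertainty.

The fitted model is canonicalised: emission and excitation loading
columns are scaled to unit maximum with all scale absorbed into the
score matrix, and components are ordered by emission then excitation
peak position.  In this form a score is directly the component's
maximum fluorescence intensity (Fmax) in that sample, and percent
abundance is Fmax normalised to 100 within the sample.

**CORCONDIA** computes the least-squares Tucker core G of the
(model-imputed) data against the fitted loadings via pseudo-inverses
and returns `100·(1 − Σ(g − t)²/F)` with t the superdiagonal identity
core.  The model is canonicalised first, which makes the diagnostic
invariant to any joint rescaling of the loadings that leaves the fitted
tensor unchanged.  Values near 100 support the trilinear model at that
rank; overfactored fits collapse far below zero because near-degenerate
loadings amplify the pseudo-inverses.  Exactly singular loadings raise
an error advising rank reduction.

**Split-half validation** splits samples into two halves (alternating
by sorted sample id, or randomly), fits each independently, matches
components greedily by emission-mode Tucker congruence (ties broken on
excitation), and reports the per-mode minimum congruence; the
validation flag requires both minima above 0.95.

**Component typing** labels a component protein-like when its emission
peak lies below 380 nm and humic-like at or above it (the ≥ convention
at the boundary); the threshold sits between tyrosine/tryptophan-type
emissions (≤ ~335 nm) and humic-type emissions (≥ ~395 nm).  Excitation
peaks are all local maxima at ≥ 50% of the loading maximum.  Flat
loadings are "unresolved".

With scatter masked, excitation loadings in the region where all
emissions below the excitation line are missing are only weakly
constrained by data; reported excitation peaks of a fit on heavily
masked stacks should be read together with the split-half congruence.

## Fluorescence indices

FI and BIX are bilinear-interpolated intensity ratios at
(Ex 370, Em 470/520) and (Ex 310, Em 380/430).  HIX is computed in the
bounded form `A(435–480) / (A(435–480) + A(300–345))` (trapezoidal
areas on the native grid) so that higher values mean greater
humification; the orientation is configurable because the two
conventions circulate in the literature with opposite directions.  The
excitation wavelength for HIX defaults to 254 nm (the conventional
choice) and is configurable.  All three indices are invariant to global
scaling of the EEM.  Interpretation labels: FI < 1.4 terrestrial,
> 1.9 autochthonous, otherwise mixed; BIX > 0.8 endogenous; HIX level
cut defaults to 0.8.

## Two-dimensional correlation spectroscopy

For band signals along an ordered perturbation series, the dynamic
matrix Ỹ subtracts each band's series mean;
Φ = ỸᵀỸ/(m−1) and Ψ = ỸᵀNỸ/(m−1) with the Hilbert–Noda matrix
N[j,k] = 1/(π(k−j)), zero on the diagonal.  Sequential order follows
Noda's sign rules per band pair (Φ > 0 with Ψ > 0: band 1 first;
Φ > 0 with Ψ < 0: band 2 first; Φ < 0 reverses the reading;
|Ψ| at or below `zero_tol`·max|Ψ| — default 0.05, plus a roundoff
floor — is simultaneous).  Pairwise votes are aggregated by Copeland
score with ties grouped as simultaneous; cyclic precedences are
flagged.

The sign rules presuppose overlapping, same-direction band responses.
For fully separated pulse responses the synchronous cross-peaks turn
negative and the reversal rule produces contradictory (cyclic)
precedences — the implementation reports the cycle rather than hiding
it, and the test suite pins this behaviour against a brute-force rule
application.  The perturbation variable is a user choice (default:
sample order from the manifest) and is recorded in the output metadata,
since the inferred sequence is only meaningful relative to it.

## Microbiome summaries

Shannon diversity is reported in nats over nonzero proportions; Chao1
uses the bias-corrected form `S_obs + F1(F1−1)/(2(F2+1))`, which is
defined even without doubletons.  Rarefaction subsamples without
replacement, averaging observed richness over `reps` draws per depth;
depths beyond a sample's total are omitted with a warning.  Taxa–DOM
correlation tables use Spearman rank correlation (robust for
compositional abundances; Pearson available), with exact permutation
p-values when 8 or fewer samples are shared — at such sizes the
t-approximation misplaces the p = 0.05 boundary.  Stars follow raw p
(* < 0.05, ** < 0.01); a Benjamini–Hochberg column is included as a
side-channel but deliberately not used for the stars, matching common
reporting practice in this field.

## Co-occurrence network

Edges are pairwise Spearman correlations passing |r| > 0.5 (strict) and
p < 0.05 (raw; a BH-corrected variant sits behind a flag).  Scope is
either all pairs or the OTU–component bipartite subset.  Isolated
features are excluded from the node set.  Summaries report node/edge
counts, percent negative edges (1 decimal), per-phylum node shares
(2 decimals) and the combined share of a named phylum set; comparisons
report absolute and percent changes (percent rounded to the nearest
integer).  Keystone taxa are operationalised as hub nodes: degree at or
above the 80th percentile of the degree distribution and betweenness at
or below the 20th percentile — i.e. well-connected nodes inside
cohesive clusters rather than fragile bridges.  Both quantiles are
configurable and both metrics are reported for every node.

## Path model

Latent-variable SEM is approximated by composite path analysis: each
composite is the mean of its z-scored indicators, re-standardized
(single-indicator composites are the indicator's z-score), and the
humification composite is the raw fluorescence-intensity ratio of the
protein-like to the humic-like block, standardized afterwards.  Note
this ratio *decreases* with humification; the sign convention is kept
as stated so coefficients remain comparable with ratio-based reports,
and an HIX-based alternative can be substituted.  Each endogenous
composite is regressed on its parents by OLS in topological order;
because composites are standardized the coefficients are standardized
path coefficients with classical standard errors.  This estimator has
identical path semantics to ML-SEM for recursive systems at the cost of
ignoring measurement error, and unlike a commercial SEM fit it is fully
reproducible and testable.  No global fit indices (CFI/RMSEA) are
computed.  Seasonal presets encode the two hypothesis structures
(protein block D1/D4/D5/D6 with single-indicator microbial-humic D2 and
humic D3; the analogous W-component blocks).

## Synthetic data

The generator emulates the statistical structure the chain assumes:

- **EEMs** are exactly trilinear mixtures of Gaussian-profile
  fluorophores (configurable peak sets matching the classic
  tyrosine/tryptophan/fulvic peak positions), plus optional scatter
  ridges (first-order Rayleigh at 4× peak signal, second order at 1×,
  Raman ridge at 0.5× with 8 nm emission width at the 3400 cm⁻¹ shift)
  and iid Gaussian noise, default 1% of the maximum clean signal.
  Scores are log-normal (meanlog 0, sdlog 0.5) — nonnegative with
  realistic right skew.
- **OTU tables** draw multinomial counts at fixed depth from log-normal
  latent abundances; a linked taxon's log-abundance is shifted by
  sign·strength·(standardized component score).  Taxonomy comes from a
  fixed dummy backbone of eight phyla common in temperate river water.
- **Chemistry** variables are exponential-link linear combinations of
  standardized component scores plus noise, keeping concentrations
  positive.

Default sizes used by the recovery fixtures and the acceptance script:
20 samples (30 for network recovery), 3 components, excitation grid
220–450 nm step 10, emission 250–550 nm step 5, 40 taxa at 20,000
reads, 10 seeds per Monte-Carlo summary.  These sizes give stable
medians while keeping a full run in minutes on one core.

What the generator does **not** emulate: non-Gaussian or
concentration-dependent fluorophore shapes, inner-filter distortion,
wavelength-dependent (heteroscedastic-in-band) instrument noise beyond
the scatter ridges, taxon–taxon ecological interactions, sequencing
error or compositional zero-inflation beyond multinomial sampling.
Passing recovery tests therefore demonstrate correctness of the
algorithms under the assumed generative model, not robustness to every
artifact of real field data.

## Numerical details and degenerate inputs

- NNLS Gram matrices carry a 1e-12 relative ridge for numerical safety.
- Tucker congruence of a zero vector is defined as 0.
- Percent abundance of an all-zero sample row is reported missing.
- Constant bands are excluded from 2D-COS sequencing and flagged.
- Constant features are rejected by the network builder; constant
  indicators by the composite builder.
- Collinear path-model parents (condition number > 1e8) are an error.
- All generators and stochastic stages take explicit integer seeds;
  identical seeds reproduce datasets and reports bit-identically.
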