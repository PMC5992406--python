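# Methods

This note records the models, algorithms and numerical conventions behind
`nirspeclib`, the choices made where the published workflow leaves the
design open, and what the synthetic-data tests do and do not establish.

## Preprocessing chain

Order is fixed: replicate averaging → Savitzky–Golay first derivative →
vector normalization. The derivative removes additive baselines and
linear drift; the normalization removes multiplicative scatter.

* **SG derivative.** 17-point window. The polynomial order is not part of
  the published recipe; order 2 is used (the canonical choice for a
  first-derivative filter, and exact on quadratics — tested). Filter
  coefficients are divided by the grid spacing so outputs are
  d(absorbance)/d(cm⁻¹); this scale is immaterial after normalization but
  keeps units meaningful. Half a window (8 points) is dropped at each
  end instead of padding: fabricated edge values would perturb the
  similarity index. The grid is trimmed accordingly (canonical grid
  4,000–12,000 cm⁻¹ at 4 cm⁻¹ → 4,032–11,968 after the derivative).
* **Vector normalization.** Centre to zero mean, scale to unit Euclidean
  norm, computed over the active wavenumber region. Whether the original
  software also mean-centres is not documented; the centred variant is
  the default and the step is configurable. A useful consequence of the
  centre-and-scale form: it is invariant to positive affine maps of its
  input, so features extracted from an already-normalized spectrum equal
  features extracted from the bare derivative — region extraction and
  normalization commute with storage format.

## Similarity index r_T

r_T = Cov(y₁,y₂)/(σ₁σ₂) over 4,200–10,000 cm⁻¹, population (1/n)
moments (the convention cancels in the ratio; fixed for
reproducibility), computed on preprocessed spectra (the state the models
consume), stored as a ratio in [−1,1] and reported in percent. The
reference spectrum is the mean preprocessed spectrum of the *plain
tablets* only; whether dispersible/chewable tablets should join the
reference class is a policy choice exposed as `reference_form`.

## Calibration-set selection (library route)

Entries are sorted ascending by r_T (ties broken by sample_id, so the
whole pipeline is deterministic without a seed). The selection anchors
at the library entry nearest the *median* target r_T and grows outward,
alternating sides, accepting an entry when its r_T differs from the
last accepted entry on that side by at least the spacing (default
1.25 percentage points — the midpoint of the workable 1.0–1.5 band).
The sweep stops once the selection covers the target r_T range and
holds ≥ `n_min` (30) entries.

Two repair rules cover the boundary cases the published description
leaves open:

* **Coverage repair.** If a side exhausts within one spacing of a target
  bound, the outermost accepted entry is *replaced* by the entry
  bracketing the bound. The gap to its inward neighbour can only grow,
  so all adjacent gaps still respect the spacing. A sub-spacing endpoint
  is force-included (and flagged) only when nothing beyond the anchor
  was accepted on that side.
* **Shortfalls are flagged, not fixed.** If the library cannot yield
  `n_min` entries at the configured spacing, the result carries a
  `shortfall` flag; entries are never padded in below the spacing. The
  degenerate case (spacing wider than the library span) additionally
  admits the library's extreme entries as endpoints, mirroring how a
  practitioner would at least bound the span.

The 2/3–1/3 calibration/test split is a deterministic interleave over
the r_T-sorted selection (every third entry → test) with both extreme
entries forced into calibration, so both sets span the same r_T range
and no seed is needed. Endpoint forcing and interleaving are design
choices; the published workflow does not state how its split was drawn.

## Conventional route

Ward agglomerative clustering (Euclidean distance) of all preprocessed
spectra, tree cut at 19 groups; per cluster, three members are drawn
with a seeded generator — two to calibration, one to validation;
clusters smaller than three contribute to calibration only (coverage
takes priority — unstated in the source workflow).

## PLS1 and rank selection

Single-response PLS by iterative latent-variable extraction with
X-deflation (NIPALS form; exact in one step per component for a single
response). The regression vector is b = W(PᵀW)⁻¹q. At full rank on
full-column-rank data this equals ordinary least squares (tested to
1e-8 against a normal-equations solve).

Rank is chosen by leave-one-out cross-validation: PRESS(r) for
r = 1..min(10, n−2, p), then the smallest rank whose
PRESS(r)/PRESS(r*) ≤ F₁₋α(n, n) with α = 0.25 (the prevailing
parsimony convention for PRESS-based rank choice; the exact rule used
by the original instrument software is unpublished, so α and the rule
are configurable). The rank cap of 10 reflects that practical models of
this kind use 2–6 latent variables and guards against overfitting
runaway on small sets. Rank is re-selected after every transfer round,
since the parsimony decision depends on the training composition.

PCA scores (for score plots) use the SVD of mean-centred calibration
features with the sign of each axis fixed so its largest-magnitude
loading is positive.

## Validation metrics

Differᵢ = yᵢ,true − yᵢ,pred; PRESS = ΣDifferᵢ²;
RMSEP or RMSECV = √(PRESS/M) (test-set vs leave-one-out mode);
R² = (1 − PRESS/Σ(yᵢ−ȳ)²)·100; fractions of samples with
|Differ| > 5% and < 1% (the conventional reporting thresholds), and
mean |Differ|. The identities PRESS = M·RMSEP² and the R² formula are
asserted exactly in the test suite.

## Optimization by transfer

Each round predicts the test set and moves every sample with
|Differ| > 5% (configurable) into calibration, then re-selects rank and
refits. The loop stops when clean, after 5 rounds, or when a transfer
would shrink the test set below 20% of the combined set — the published
workflow never bounds the shrinkage, but a validation set that vanishes
validates nothing. When the floor binds, only the worst offenders are
moved and the stop is recorded in the transfer log.

## Synthetic library generator

The generator emulates the statistical structure the method assumes,
not the physics of diffuse reflectance:

* Pure-component spectra are sums of Gaussian bands on the canonical
  grid. Amoxicillin bands sit at 8,300–9,500, 5,300–6,500 and
  4,200–4,800 cm⁻¹ (its known absorption regions); water near 5,200 and
  7,000 cm⁻¹; clavulanate in between. Excipients come in four classes
  built as a shared *family base* (tablet-like vs granule-like) plus
  class-specific bands (weight 0.7), so within-family spectral
  distances always stay below between-family ones and the two families
  are cleanly separable — the qualitative tablet/granule split real
  libraries show.
* A sample is a Beer–Lambert linear mixture: content fractions times
  component spectra, remainder to the form's excipient class, the
  excipient blended with a small manufacturer-specific variant
  (weight 0.07) emulating house-to-house excipient differences.
* Assays are drawn uniformly per dosage form within wide, overlapping
  sub-ranges of the global ranges (amoxicillin 4.77–57.86%, clavulanate
  1.03–20.17%, water 0.24–9.30%); tablets concentrated, suspensions
  dilute. This composition spread is what fans each form across a broad
  r_T band, so a 150-entry library supports roughly 25–40 selections at
  1.25% spacing.
* Replicates add: baseline offset ~ N(0, 0.02 AU), slope
  ~ N(0, 3·10⁻⁶ AU/cm⁻¹), scatter factor ~ N(1, 0.02), pointwise noise
  ~ N(0, 0.005·σ_signal). The artifact magnitudes are typical FT-NIR
  diffuse-reflectance drift/scatter scales; all are applied *before*
  preprocessing so the derivative/normalization chain is genuinely
  exercised. Default library composition is 74/78/10/96/120 per form
  (the heterogeneous multi-manufacturer mix); pipeline-level tests use
  a balanced 30-per-form 150-entry library, since a class with only a
  handful of members cannot support per-class validation at that scale.
* All randomness flows from one seed; per-sample substreams come from a
  SHA-256 hash of the sample id, so any sample regenerates
  independently.

**What a green test establishes — and what it does not.** The generator
is linear in composition by construction, its class structure is
Gaussian-band-based, and its artifacts are the ones the preprocessing
chain is designed to remove. Green pipeline tests therefore establish
that the implementation is faithful and that the workflow recovers
content under the method's own assumptions; they say nothing about
particle-size effects, non-linear matrix interactions, instrument line
shapes, or the published accuracy tables, which depend on undeposited
commercial spectra.

**Statistical margin.** Across a survey of 21 generator seeds at the
default noise, the pipeline's held-out mean |Differ| for amoxicillin was
0.4–1.7% (19/21 seeds ≤ 1.5%) and the two routes agreed within a factor
2.2 at worst. The fixed-seed pipeline tests sit comfortably inside the
typical range; the occasional marginal seed reflects the small test
sets (≈10 held-out samples), not a systematic bias.

## Degenerate inputs and tolerances

Zero-variance spectra are rejected wherever a variance enters a
denominator (normalization, r_T), naming the offending sample.
Correlation values are clipped to [−1, 1] against numeric overshoot.
Gap comparisons in the selection use an absolute slack of 1e-9
percentage points. Oracle equivalences are asserted at 1e-8 (PLS vs
least squares), 1e-10 (LOOCV vs literal loop), exact partitions (Ward
vs brute-force agglomeration) and 1e-12 (r_T bounds).
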