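# Methods

This note documents the models, algorithms and design choices behind
`dx2quant`, in the spirit of a statistics package's methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## smFISH quantification model

The assay images each transcript as a diffraction-limited focus in one of
two probe channels: red (C2, exons shared by both isoforms — so every
transcript) and green (C1, the skipped exon — so only the full-length
transcript). Because the probe sets differ in size and hybridization
efficiency, the raw red/green signal ratio carries unknown per-channel
efficiencies α (red) and β (green):

    Red/Green = α([FL] + [DX2]) / (β[FL]),
    [DX2]/[FL] = C · Red/Green − 1, with C = β/α.

The conversion is affine with slope C, so without a calibration experiment
the ratio is *semiquantitative*: `CalibrationModel.relative_only()` makes
this explicit and `isoform_ratio` refuses to convert. With a supplied C,
negative results (ratio below the floor 1/C) are unphysical and are clamped
to zero with a warning rather than propagated.

Processing steps and their parameters:

- **Thresholding.** Configurable: Otsu per channel (default; parameter-free)
  or a fixed intensity value (used by the exact tests). A constant-intensity
  image has no Otsu threshold and yields an empty mask. A mask covering more
  than half the image triggers a saturation warning, not an error.
- **Size-based noise removal.** Connected components (8-connected by
  default, matching the common `bwlabel` convention; 4-connectivity by
  flag) below `min_size` (foci default 4 px², nuclei default 200 px² at the
  simulator's scale) are discarded as speckle.
- **Aggregation.** The image-level ratio supports two modes because "the
  average pixel area" of a channel is ambiguous between mean object area
  and total area. The default is `total_area` (Σ red areas / Σ green
  areas): total area equals mean object area × count and therefore tracks
  transcript abundance; `mean_object_area` is provided for comparison.
  Summaries across images average the per-image ratios rather than pooling
  sums, matching how multi-image box plots are normally reported.
- **Single-cell assignment.** Nuclei are thresholded DAPI components with
  sequential ids in raster order; each focus goes to the nucleus with the
  nearest *centroid* (not boundary), ties to the lower id. Cells with zero
  green area keep an undefined per-cell ratio: they are retained and
  flagged, and excluded from ratio summaries. Border-touching cells are
  kept.

## Synthetic smFISH fields

The generator emulates the geometry that matters to the quantification
loop, not optics. Defaults (one 512×512 px field): 12 cells, nucleus radii
uniform in 12–18 px, Poisson(8) red and Poisson(4) green foci per cell,
isotropic Gaussian spots (σ = 1.5 px, amplitude 600) over a constant
background of 100 with additive Gaussian noise (SD 5, clipped at zero;
Poisson shot noise by flag). Foci centres are uniform over the cytoplasmic
annulus between 1× and 2× the nucleus radius. Nuclei are placed by
rejection sampling with centre separation at least twice the annulus outer
radius (plus 2 px), which makes every focus *provably* nearest to its own
nucleus — single-cell ground truth is unambiguous by construction, and a
field too crowded to satisfy this raises a placement error rather than
degrading silently.

What this does **not** model: PSF optics, 3-D stacks, photobleaching,
autofluorescence texture, overlapping cells, or chromatic misregistration.
Passing tests therefore demonstrate correctness of the measurement chain
(thresholding → size filter → areas → assignment → ratios) under a known
forward model, not robustness to real-microscope artefacts. Because spot
parameters are identical across channels, the expected red/green area
ratio equals the planted foci-count ratio; with overlapping spots the
thresholded union area is slightly subadditive, which cancels in the ratio
to first order and is covered by the 10% recovery tolerance at 30 fields.
No acquisition-noise statistics were available to fit; the defaults are
free parameters chosen to resemble sparse confocal fields, not estimates
of any particular instrument.

## Junction counting

Junctions are extracted by walking the CIGAR: M/D/=/X consume reference, N
emits (last consumed base, first base after the gap), insertions and clips
consume nothing. The gene model places the exon-1 donor at chr7:6009499
with acceptors 6015145 (exon 2, full-length) and 6017814 (exon 3,
skipping); printed spans are interpreted as exon *flanks* (1-based), giving
implied N lengths of 5645 and 8314. Whether such printed coordinates denote
exon flanks or intron boundaries is a genuine ambiguity; the flank
convention is the documented choice and all coordinates are configuration,
not constants. Classification allows a configurable ± tolerance on both
junction ends, validated so the two classes can never overlap. Multi-gap
reads count once, by their first matching junction. Default filters exclude
unmapped, secondary and supplementary records; `min_mapq` defaults to 0 and
duplicates are not removed — explicit defaults where upstream pipelines
are silent. Reads on another reference are refused (distinct class), never
counted as unspliced. "chr7" and "7" naming is normalized by option.

The read simulator places each junction at a seeded-random offset with at
least one matched base per side and exactly the model-implied N length, so
`simulate → quantify` is exact (not statistical) for any seed — the basis
of the roundtrip tests.

## Survival statistics

- **Quantile cutoff.** Linear-interpolation (type-7) quantiles by default —
  the common software default — and configurable, because a first-quartile
  cutoff value depends on the estimator. Labels: high = ratio ≥ cutoff.
- **Kaplan–Meier.** Product-limit estimator over distinct event times;
  median = smallest event time with S ≤ 0.5, else "not reached". Median
  confidence limits use the log-log (Greenwood) pointwise envelope crossing
  0.5, in the Brookmeyer–Crowley spirit, since printed medians-with-CIs
  rarely name a method.
- **Log-rank.** k-group observed-minus-expected with the multivariate
  hypergeometric covariance accumulated over pooled event times; chi-square
  on k−1 df.
- **Cox PH.** Newton–Raphson on the partial likelihood to gradient norm
  < 1e−8 with step-halving; Breslow ties by default (Efron by flag);
  covariates centred for conditioning; Wald CI exp(β ± 1.96·SE). The score
  test at β = 0 is reported and, for a single binary covariate with Breslow
  ties, equals the log-rank chi-square — an identity the tests verify to
  1e−6. Monotone likelihood (complete separation) is detected by a
  diverging coefficient (|β| > 30 after centring) or a collapsed
  information matrix (SE > 1000) and raised as a convergence error with a
  diagnostic rather than returned as a huge finite estimate.
- **Exact R×C Fisher.** Depth-first enumeration of all tables with the
  observed margins; p = total probability of tables whose multivariate
  hypergeometric probability is ≤ that of the observed table, compared in
  log space with relative tolerance 1e−7 (floating-point equality of table
  probabilities is otherwise ill-defined). The enumerator checks that the
  probabilities it visits sum to 1 (warning beyond 1e−6) and aborts past a
  configurable table budget (default 5×10⁶), pointing to Monte-Carlo
  permutation as the standard fallback for larger tables. For 2×2 tables
  it matches the classic conditional test (cross-checked against an
  independent enumeration and `scipy.stats.fisher_exact` in the tests).
- **Mann–Whitney U.** Midrank U; exact two-sided p by full enumeration of
  group assignments when n₁+n₂ ≤ 12 (ties honoured), otherwise the normal
  approximation with tie and continuity corrections.

Significance conventions: p < 0.05 for survival/contingency tests, FDR
q < 0.10 for gene sets.

## Gene-set scoring

Per-gene statistics are Welch two-sample t (high minus low); zero-variance
genes get t = 0 with a flag. A set's statistic is a one-sample t of its
members' gene-level t values against the mean t of *all* genes, two-sided p
on (m−1) df, BH-adjusted across sets. This is a deliberate, documented
simplification of the GAGE scheme (which compares one-on-one sample
pairs): it preserves the reported quantity — per-gene two-sample t
statistics summarized per pathway with an FDR q — in a desk-testable form.
The continuous-ratio differential-expression model (negative-binomial GLM
on counts) is out of scope; the implemented contrast is the dichotomized
high/low group comparison. Gene-set membership is user-supplied (GMT); no
database access at build or test time.

The expression simulator draws background genes i.i.d. N(0,1) in both
groups and shifts perturbed-set members by the stated effect (in SD units)
in the high group. Default study conditions follow the dichotomized AML
analysis scale: 16 vs 6 samples, 25 sets of 20 genes over 1000 genes.
Under the null the set p-values are approximately uniform (member t values
are mildly heavy-tailed and share the global-mean centring, both
negligible at these sizes); the acceptance checks measure ~5% of null sets
at p < 0.05 over 1000 simulated sets and ≥95% detection (q < 0.10) of a
2-SD planted set across 20 seeds.

## Problem sizes and determinism

Simulation-based checks use 30 fields of 512×512 px for ratio recovery, 10
fields for assignment accuracy, 100 reads for the junction roundtrip, 30
synthetic cohorts of 51 patients for hazard-ratio recovery, and 40 + 20
expression simulations for calibration and power — sizes at which the
Monte-Carlo error is comfortably inside each stated tolerance. Every
stochastic path takes an explicit integer seed (NumPy `default_rng`;
multi-run sub-seeds via `SeedSequence`), so identical configurations
reproduce bit-identical outputs on one platform.

## Known limitations

- No absolute isoform quantification without a measured calibration
  constant C; cross-cell-line ratio values from real micrographs depend on
  unpublished threshold settings and are not reproducible desk-side.
- The image pipeline is 2-D, single-plane, and assumes well-separated
  cells; dense tissue would need watershed-style segmentation it does not
  provide.
- Junction counting implements exactly the two-junction rule — no EM
  deconvolution of multi-isoform mixtures, no PSI models, no alignment.
- The Fisher enumerator is exact but exponential in principle; very large
  sparse tables require the Monte-Carlo fallback it suggests.
- The gene-set statistic is a group-contrast simplification, not a
  re-implementation of the original GAGE pairwise scheme.
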