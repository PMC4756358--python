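# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `ramanmap`. Everything quantitative stated here is computed
by the test suite or by `scripts/acceptance.py`; nothing is asserted that
the code does not itself measure.

## Data model

A dataset is a set of spectra on one strictly increasing wavenumber axis
(fingerprint window 460–1800 cm⁻¹, ≥ 16 points) with one metadata row per
spectrum (subject, dose in Gy, tissue section, mapping region, stage
position in µm). Quality-control flags (`cosmic_ray`, `saturated`,
`manual_exclude`, `degenerate`) never remove a spectrum from the container;
flagged spectra are excluded from every downstream statistic but kept for
audit, and each stage logs its decisions to a provenance list. Spectra are
kept in a canonical order — lexicographic by (subject, map, y, x) — so
score tables and reports do not depend on input file order. Processing
state advances only along raw → baseline_subtracted → aligned → normalized.

On-disk formats are plain text: long-format spectra tables
(`spectrum_id, wavenumber, intensity`), metadata tables, band tables and
wide matrices, comma- or tab-separated with `#` comments. Floats are
written with 17 significant digits and parsed with round-trip precision, so
write→read is bit-identical. Spectra whose private axes deviate from the
dataset axis by less than 0.5 cm⁻¹ (configurable) are linearly resampled
onto it and the fact is logged; larger deviations are data errors.

## Preprocessing

### Artifact flagging

Cosmic-ray spikes are narrow (1–2 channel) high-amplitude detector events.
Per spectrum we compute the second difference and its modified z-score
(0.6745·(d₂ − median)/MAD); any point beyond the threshold (default 8)
flags the spectrum. A single spike of amplitude *a* contributes ≈ 2*a* to
the second difference while smooth Raman bands (widths of several channels)
contribute ≈ amplitude/σ² per channel², so spikes ≥ 20× the noise SD are
detected with ≥ 95% sensitivity at ≤ 1% false positives on clean spectra
(measured each run by the acceptance script). One caveat follows from the
same arithmetic: on *essentially noiseless* data the MAD approaches the
curvature of the sharpest band and any sharp peak can trip the detector —
the criterion assumes detector noise is not negligible, which holds for
real acquisitions and the generator's defaults.

Saturation is flagged when ≥ `saturation_run` (default 5) consecutive
points sit at or above the detector ceiling. A constant spectrum, or one
with zero second-difference MAD that is not explained by saturation, is
flagged `degenerate`. A manual include/exclude list is applied last, so an
analyst can reproduce a hand-curated exclusion set exactly.

### Baseline removal

The broad background from substrate and tissue autofluorescence is
estimated per spectrum by iterated zero-order Savitzky–Golay filtering
(a moving average over ±`window_halfwidth`, default 60 cm⁻¹): filter the
working spectrum, pull every point above the estimate down to
`estimate + ρ·(point − estimate)` (default ρ = 0, i.e. full clipping),
refilter, and repeat for `n_iterations` (default 100) or until the
estimate changes by < 10⁻⁶ (relative). The subtraction is exact by
construction: baseline + corrected = input at every point.

Boundary handling matters more than it looks. A one-sided (truncated)
average on an edge where the spectrum rises toward the boundary sits below
the data; the clip step then ratchets the working spectrum down, and
because clipping is one-directional the error grows and diffuses inward by
one half-width per iteration — on the generator's own noiseless spectra
this reached ~10% of the baseline range after 100 iterations. We therefore
extend each end by a fitted line before filtering, with one asymmetric
trimmed refit (points above the first fit by more than the residual RMS are
dropped): a Raman band anywhere inside the edge window would otherwise
lever the slope — and if that band is dose-responsive (glycogen has a band
at 482 cm⁻¹, 22 points from the axis start) the edge error becomes
proportional to the biological signal itself. With the trimmed extension
the filter is exact on ramps, recovers a cubic background under 5×-range
peaks to 0.25% RMS in peak-free regions with peak areas preserved to < 1%,
and leaves < 0.1% mean residue in the band-free 1750–1800 cm⁻¹ window of
noiseless simulated tissue spectra.

Known bias: with ρ = 0 the clip descends into the noise floor, leaving the
converged baseline ≈ 1 noise SD below the true background everywhere (a
well-known property of clipping estimators). This common-mode offset is
small at realistic noise (3% of peak amplitude) and largely cancels in
mean-centered PCA; raising ρ trades it against slower peak rejection.

### Wavenumber alignment

Acquisition drift is rigid and below 1 cm⁻¹. Each baseline-corrected
spectrum is aligned by fitting a Gaussian plus constant over
1003 ± 10 cm⁻¹ (the phenylalanine ring-breathing band present in
essentially all tissue spectra), shifting by linear re-interpolation at
`axis + δ`, and repeating for exactly two passes. Noiseless rigid shifts
in ±0.9 cm⁻¹ are removed to < 0.05 cm⁻¹; at SNR 20 the residual stays
≤ 0.25 cm⁻¹ in ≥ 95% of replicates. Offsets beyond 1 cm⁻¹ on the first
pass warn but still align (counts are aggregated in the provenance log).
A failed fit (no positive-amplitude peak) flags the spectrum and excludes
it. The reference center is fixed at 1003.0 cm⁻¹ while the band table
lists phenylalanine at 1004 cm⁻¹ (both values circulate in the
literature); in simulation this produces a uniform ≈ −1 cm⁻¹ registration
offset for all spectra, which cancels in every relative quantity and is
absorbed by the 6 cm⁻¹ annotation tolerance.

### Normalization

Division by the trapezoidal integral over the full axis (area = 1 to
1e-12), proxying the amount of biological material in the sampling volume.
Non-positive areas flag the spectrum instead of dividing. Order is fixed:
flag → baseline → align → normalize; normalizing an interpolated trace is
well defined, and the reverse order differs only at interpolation error
level. The chain reports per-stage exclusion counts with the invariant
input = survivors + excluded.

## Chemometrics

PCA is computed by SVD of the mean-centered matrix of surviving normalized
spectra. Explained-variance ratios are singular values squared over total
centered sum of squares; loadings are orthonormal to 1e-10 and
reconstruction at full rank is exact to 1e-8 relative. Signs are made
deterministic by orienting each component so its largest-magnitude loading
element is positive; the applied signs are recorded, and `orient_to` can
flip a component to match an external convention (e.g. presenting the
glycogen cluster as negative). Channels are not variance-scaled: spectra
are already area-normalized and autoscaling would inflate empty regions.

Dose relevance of each component is measured by the Kruskal–Wallis
chi-square statistic of its scores grouped by dose (midranks, tie
correction, dof = groups − 1; the all-tied degenerate case is defined as
H = 0, p = 1). Components are reported sorted by H together with the
3rd-to-2nd ratio, the drop-off screen used to decide how many components
carry dose structure. Pairwise group comparisons use the two-sided
Wilcoxon rank-sum test: exact enumeration when both n ≤ 10 without ties,
otherwise the tie-corrected normal approximation with continuity
correction. Both statistics are implemented over `scipy.stats` and are
verified in the test suite against independent brute-force oracles (full
enumeration of rank assignments; hand rank computation) on every group
composition of N ≤ 9, to 1e-12.

Group summaries follow Tukey box-plot conventions: median, quartiles by
the linear-interpolation quantile rule (stated because reported
percentiles depend on it), notch half-width 1.57·IQR/√n (normal
approximation to the 95% CI on the median), whiskers at the most extreme
points within 1.5·IQR of the quartiles, and the fraction of strictly
negative scores. Per-subject analysis compares subjects within a dose
pairwise by Wilcoxon at α = 0.05 and reports the connected components of
the "not significantly different" graph as equivalence classes — the
package's formalization of tumours "segregating into k unique
distributions". With hundreds of spectra per subject this test is
pseudoreplicated (spectra within a tumour are not independent), exactly as
in the emulated workflow; the classes describe the data, not
subject-level inference.

Loading annotation finds local extrema whose |value| exceeds the 0.75
quantile of |loading| and matches them to band-table centers within
6 cm⁻¹. An entity is assigned to a side only when ≥ 2 of its bands match
extrema of that sign (single fingerprint bands are too degenerate between
biomolecules); ≥ 2 matches on both sides reports `mixed`. Cross-study
comparison is the Pearson correlation of two loadings after linear
interpolation onto the overlap of their axes.

## Spatial maps

Scores of one mapping region are placed on its acquisition lattice
(row-major, y down, origin at min(x), min(y), default step 15 µm). Stage
jitter within half a step snaps to the lattice; larger offsets and two
spectra in one cell are errors, not silent fixes. Cells whose spectrum was
excluded are masked — the analog of hatched "no data" pixels in published
score maps — and flattening the unmasked cells recovers exactly the input
(spectrum, score) pairs. Heterogeneity summaries report per-map IQR/range
and the spread of per-map medians per subject. Grids are written as CSV
(NaN for masked) with a JSON sidecar; PNG rendering (grayscale, dark =
negative) is an optional thin layer.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
with full ground truth, so that recovery can be verified rather than
assumed. Design defaults mirror the emulated study: doses (0, 5, 15) Gy,
4 subjects per dose, 5 mapping regions per subject cycling over 3
sections, 8×8 spectra per region at 15 µm — 3840 spectra, bracketing the
~6.6k of a real study while running in about a minute.

Each entity's basis spectrum is a unit-area sum of Gaussians (σ = 4 cm⁻¹)
at its band-table centers. Per spectrum, the marker entity's weight
(glycogen by default) is

w_glycogen = w₀ · exp(subject effect + spatial field) · (1 + β·dose),

with all other entities fixed at their base weights. The per-subject
effect (log-normal, SD 0.15) and the per-map spatial field
(kernel-smoothed white noise, correlation length 2 px, SD 0.35) act on the
marker only: the emulated biology places inter-tumour and intra-tumour
variability in expression of the radiation-response signature itself, and
independent per-entity subject effects would create dose-constant subject
clusters in non-marker directions that the pooled-spectrum KW ranking —
pseudoreplicated by design — can spuriously promote above the marker
component. β defaults to 0.06 per Gy (glycogen ×1.3 at 5 Gy, ×1.9 at
15 Gy): no published effect size exists on the concentration scale, so the
default was chosen once as a moderate effect that is detectable but leaves
realistic overlap between groups. The multiplicative (log-scale) form
keeps weights positive by construction.

The clean signal (weights × bases) is stacked on a cubic-polynomial
fluorescence background with amplitude 5× the mean peak height and 10%
log-normal per-spectrum variation, rigidly drifted by
Uniform(−0.9, 0.9) cm⁻¹ via linear interpolation, and corrupted with
Gaussian noise (3% of mean peak amplitude), cosmic spikes (3% of spectra,
1–2 channels, 10–100× noise) and saturation (2% of spectra, scaled over a
global detector ceiling and clipped, guaranteeing a plateau). A single
`numpy` Generator seeded from the config drives every draw, so
(config, seed) reproduces the dataset bit-identically, and the returned
ground truth (weights, baselines, clean signals, shifts, artifact labels,
fields, ceiling) is the oracle for every pipeline test.

`truth_contrast` returns the marker basis minus the mean-weight-weighted
average of the other bases, scaled to unit L2 norm (unit signed area is
ill-conditioned for a vector with balancing lobes; correlation only uses
the direction). This is the spectral direction along which the injected
effect moves the data, and recovered dose-related loadings are validated
against it: at default conditions the top-KW component correlates with it
at |r| ≈ 0.97.

What the generator does not emulate — and what passing tests therefore do
not show about real tissue: physical Raman cross-sections and instrument
response, shot-noise statistics (noise is additive Gaussian), fluorescence
photobleaching kinetics, spectral contributions of histology beyond the
configured entities, and non-rigid wavenumber distortion.

## Pipeline, determinism and problem sizes

`run_pipeline` executes simulate/load → flag → baseline → align →
normalize → PCA → KW ranking → group/subject statistics → annotation →
truth/external correlation → score maps, and writes loadings, scores, EVR,
KW table, per-map grids, a provenance log and a JSON+text report with a
SHA-256 manifest of outputs. Reports contain no timestamps and all
computation is seeded, so identical config+seed reproduces every output
byte for byte. Stage outputs are rewritten each run; the config hash in
the report (paths excluded) identifies the analysis that produced them.

Test-suite problem sizes are chosen to exercise each property at the
smallest scale where it is meaningful: the end-to-end recovery and spatial
round-trip run at the full default design (3840 spectra); null calibration
of the dose comparison runs 200 replicates of a two-dose,
2-subjects-per-dose, 5×5-single-map design with no injected effect or
subject/spatial structure, testing the fixed first component so the check
is a pure type-I-error calibration (selecting the top-ranked component
under the null would be a selection-biased test); determinism is exercised
on a reduced design since it is scale-independent.

## Limitations

- The KW/Wilcoxon statistics on pooled spectra inherit pseudoreplication
  from the emulated workflow; p-values overstate subject-level evidence.
- No multiple-testing correction is applied across components (reported
  as-is, matching the emulated analysis).
- The baseline estimator's noise-floor bias (≈ 1σ at ρ = 0) and its
  partial absorption of very broad or densely overlapping band clusters
  are inherent to zero-order clipping methods; both are documented above
  and bounded by the recovery tests.
- Spike detection assumes non-negligible detector noise (see above).
- Supervised classification, derivative-spectrum analysis, scatter
  correction and map inpainting are out of scope.
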