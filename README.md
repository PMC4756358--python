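# ramanmap

Chemometric detection of radiation-induced biochemical change in Raman
microspectroscopy maps of tumour tissue.

External-beam radiotherapy alters tumour metabolism — most prominently a
dose-dependent accumulation of glycogen — and these changes leave
fingerprints in the 460–1800 cm⁻¹ Raman spectrum. `ramanmap` implements the
full analysis chain used to detect such responses in hyperspectral tissue
maps collected across dose groups (e.g. 0/5/15 Gy, several subjects per
dose, several mapping regions per subject):

1. **Preprocessing** — automated artifact flagging (cosmic-ray spikes via a
   modified z-score on the second difference, saturation plateaus),
   iterative zero-order Savitzky–Golay (moving-average) baseline removal
   with clipping, wavenumber recalibration by Gaussian fitting of the
   phenylalanine 1003 cm⁻¹ ring-breathing band (two interpolation passes),
   and normalization to the total area under the corrected spectrum.
2. **Chemometrics** — mean-centered PCA by SVD; components ranked for dose
   relevance by the chi-square statistic *H* of a Kruskal–Wallis test on
   their scores grouped by dose,

   H = [12 / (N(N+1))] · Σᵢ nᵢ (R̄ᵢ − (N+1)/2)² / (1 − Σ(t³−t)/(N³−N)),

   two-sided Wilcoxon rank-sum comparisons between dose groups (exact
   enumeration for n ≤ 10 without ties, tie-corrected normal approximation
   with continuity correction otherwise), Tukey box statistics with notch
   half-width 1.57·IQR/√n, negative-score proportions and percentiles, and
   per-subject (per-tumour) segregation into score-distribution classes.
3. **Band annotation** — loading extrema are matched against a built-in
   table of biomolecular Raman bands (glycogen 482/850/940/1042/1083/1129/
   1385 cm⁻¹, protein Amide I/III and CH, lipid CC/CH/ester, nucleobases,
   phenylalanine, tryptophan, choline); an entity is assigned to a loading
   side only when ≥ 2 of its bands co-occur on that side.
4. **Spatial mapping** — per-region rasterization of PC scores onto the
   15 µm acquisition lattice with masked pixels for excluded spectra, and
   intra-/inter-region heterogeneity summaries.
5. **Synthetic tissue-map generator** — a fully seeded, ground-truthed
   simulator of the whole study design (biomolecular basis spectra on a
   fluorescence background, calibration drift < 1 cm⁻¹, spikes, saturation,
   dose-dependent and spatially patchy glycogen enrichment, per-subject
   random effects) so that every stage, and the end-to-end dose-response
   claim, is testable without access to instrument data.

## Worked example

Run the whole pipeline on a simulated study (3 dose groups × 4 subjects ×
2 maps of 5×5 spectra) from the command line:

```bash
ramanmap run --seed 7 --out demo/
```

or in Python:

```python
import ramanmap as rm
from ramanmap.synthetic import SimulationConfig

cfg = rm.RunConfig(seed=7, out_dir="demo",
                   simulation=SimulationConfig(subjects_per_dose=4,
                                               maps_per_subject=2,
                                               grid_rows=5, grid_cols=5))
report = rm.run_pipeline(cfg)
```

which prints (`demo/report.txt`, abridged):

```
spectra: n_input=600, n_cosmic_ray=20, n_saturated=13, ... n_survivors=570

explained variance: PC1 51.7%, PC2 4.2%, PC3 1.5%, PC4 0.7%, PC5 0.5%

Kruskal-Wallis ranking (chi-square, dose groups):
  PC1: chi2 = 211.3, p = 1.3e-46
  PC4: chi2 = 4.9, p = 0.0879
  ...
PC1:
  0.0 Gy: n=191, median=-5.631e-03 +/- 5.9e-04, negative fraction 85%
  5.0 Gy: n=188, median=-1.192e-03 +/- 8.1e-04, negative fraction 61%
  15.0 Gy: n=191, median=4.268e-03 +/- 1.1e-03, negative fraction 24%
  Wilcoxon 0_vs_5Gy: p = 2.79e-13 *
  Wilcoxon 0_vs_15Gy: p = 1.55e-42 *
  5Gy subject classes: [['S100', 'S101', 'S102'], ['S103']]

top-PC loading vs simulation truth contrast: |r| = 0.971
```

Reading this: 30 of 600 spectra were excluded as artifacts; PC1 carries
half the variance and is by far the most dose-related component (KW
chi-square 211 vs < 5 for the rest); its scores separate every dose pair
significantly and shift monotonically with dose (here glycogen loads
*positively* on PC1, so irradiated groups shift positive — the sign record
lets you flip the convention); within the 5 Gy group one tumour expresses
the signature differently from the other three; and the recovered loading
matches the simulator's injected glycogen-vs-rest contrast at |r| = 0.97.

Stage-level commands (`simulate`, `preprocess`, `pca`, `rank`, `stats`,
`annotate`, `correlate`, `map`) expose the same steps individually over
plain CSV files; see `ramanmap --help`.

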