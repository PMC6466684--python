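# Methods

## Forward model (synthetic spectra)

Absorbance is Beer–Lambert linear mixing: each macromolecular pool
(protein, lipid, carbohydrate, silica) owns a fixed set of Gaussian bands
(center ν₀ in cm⁻¹, width σ in cm⁻¹, relative extinction ε ≥ 0), and a
cell with mass fractions *f* (% DW) at optical scale *s* produces

    A(ν) = s · Σ_pools (f_pool/100) · Σ_bands ε · exp(−(ν − ν₀)²/(2σ²))
           + baseline(ν) + η(ν)

with a per-spectrum linear baseline ramp (endpoints uniform on
±0.01 absorbance by default) and i.i.d. Gaussian noise η (sd 0.002 by
default). Default band centers are the diagnostic bands of phytoplankton
biomass — Amide I/II at 1658/1544 (protein), CH₂ stretches at 2915/2848
and ester C=O at 1740 (lipid), the C–O–C cluster at 1153/1108/1080/1020
(carbohydrate), one broad Si–O envelope at 1075 (frustule silica). Widths
are 12–25 cm⁻¹ (60 for the amorphous silica envelope); amide extinctions
exceed the lipid carbonyl's, as in condensed-phase IR. The noise defaults
were chosen once as a plausible bench-top noise floor (peak absorbance of a
whole cell is O(1); 0.002 absorbance ≈ 0.2 % of a strong band) and are not
derived from any published measurement.

The wavenumber grid spans 700–4000 cm⁻¹ at 2 cm⁻¹ spacing. The
instrument's 4 cm⁻¹ figure is an *instrumental resolution*, not a point
spacing; 2 cm⁻¹ sampling gives the 9-point derivative filter ≥ 4 points
per band half-width. Grids are stored ascending; descending display is a
plotting convention only.

### Composition sampling

Bulk calibration replicates and single cells draw each pool from a normal
truncated at zero (exact truncated-normal sampling, not clipping); if the
resulting pool sum exceeds 100 % DW the row is jointly rescaled to 100.
This keeps every generated composition physically valid at the cost of a
known distortion: for populations whose pool means already sum to
~100 % DW (e.g. the cyanobacterium at either temperature), about half of
the draws are rescaled, which drags the effective mean and the density
mode of the dominant pool a few % DW below the nominal generating mean.
Per-cell optical-path/biomass scaling is lognormal with unit mean and
CV = 0.15; because no intensity normalization is applied anywhere in the
chain (see below), predicted per-cell values inherit this multiplicative
spread and a further ≈1 % downward mode shift. The single-cell
mode-recovery tests therefore use a tolerance of 1.5 KDE bandwidths, which
absorbs both effects at the default settings; a green test establishes
that calibration transfer recovers population structure to within the
smoothing scale, not that the mode is unbiased.

The generator emulates the *statistical* structure of a measurement
campaign (replicate scatter, mixture populations, noise, baseline, path
length). It does not emulate instrument physics — interferograms,
apodization, atmospheric lines, Mie scattering on curved cells — nor
overlapping absorbers beyond the four pools (nucleic acids in the
950–1200 cm⁻¹ window are subsumed in band overlap). Green tests say the
chemometric pipeline is correct under linear mixing; they cannot certify
robustness to scattering artifacts real microspectroscopy exhibits.

## Preprocessing

Operations move a `SpectrumSet` along `raw → cut → second_derivative →
centered`; the state machine rejects reprocessing. Cutting keeps the
closed intervals 3019–2819 and 1800–950 cm⁻¹ (100 + 426 = 526 points on
the default grid). The Savitzky–Golay second derivative (window 9,
quadratic) is applied per segment, never across the inter-segment gap, and
is taken with respect to wavenumber (divided by spacing²) so features are
grid-invariant. Edge points without a full window are dropped — each
segment loses 8 points, leaving 510 features — rather than padded, to
avoid fabricated boundary values entering the regression. The raw
derivative sign is kept (absorption bands appear as minima). No vector,
SNV or EMSC normalization is applied: the modeled workflow states none,
so per-cell scale variation flows through to the predictions by design.

## PLS1 calibration

One model per pool (PLS1, not PLS2), orthogonal-scores NIPALS exactly as
in the README. X and y are centered inside the fit (means stored on the
model); neither is variance-scaled. (PᵀW) systems are solved densely
rather than by explicit inversion. If deflation exhausts Xᵀy before the
requested A components — which happens on noise-free synthetic data,
where the centered spectra have rank ≈ 4 — extraction stops early with a
warning and the achieved count is recorded; no directions are fabricated.
Explained variance per component is ‖t_a p_aᵀ‖²_F/‖X_c‖²_F (X block) and
q_a²‖t_a‖²/‖y_c‖² (y block); both are reported and labeled, since a
single "% variance explained" figure is ambiguous between the blocks.

Default A = 7, user-overridable. Requesting A > min(n−1, p) is an error.

## Validation

RMSEC and RMSEP use denominator *n* (no degrees-of-freedom correction);
the choice is arbitrary but applied consistently so the hand oracles in
the tests are exact. LOOCV re-estimates the centering and the fit inside
each fold — reusing the full-set mean would leak the held-out sample and
bias RMSEP low. Range cutting and the SG derivative are per-spectrum
operations, hence fold-invariant and done once. R² is reported both as
1 − SS_res/SS_tot and as squared Pearson correlation (`R2_corr`), labeled,
because calibration plots in the field use either convention.

## Density estimation and modes

Gaussian KDE evaluated on a 512-point uniform grid extending 3 bandwidths
past the data range, floored at 0 % DW; mass of kernels falling below zero
is reported (`truncated_mass`), not renormalized, and the integral
invariant (1 ± 0.01) accommodates it. The default bandwidth is the
0.9·min(sd, IQR/1.34)·n^(−1/5) rule of thumb — the default of the
environment such analyses are usually run in; the wording "the SD of the
Gaussian kernel is the bandwidth" is self-referential for a Gaussian
kernel, so both the rule and an explicit user bandwidth are supported.
Edge cases: IQR = 0 falls back to the sd (never a zero bandwidth); all
values identical falls back to max(|x₁|, 1)·10⁻³ with a warning.

Modes are local maxima with topographic prominence ≥ 5 % of the global
maximum (configurable); a secondary-mode report needs *some* prominence
criterion and 5 % suppresses sampling ripples at n ≈ 200 without hiding
genuinely balanced bimodality. Modes are returned sorted by height.

## PCA

SVD of the centered derivative matrix; scores are projections, loadings
right-singular vectors, explained-variance fractions from squared singular
values. Signs are fixed so each loading's largest-magnitude element is
positive, making score plots reproducible across BLAS implementations.

## Numerical/edge choices

- Degenerate NIPALS direction threshold: ‖X_aᵀy_a‖ ≤ 1e−12 · ‖Xᵀy_c‖.
- Composition-table validity allows a 1e−9 % DW rounding slack on the
  ≤ 100 % sum for generator output; external assay tables may pass a
  larger explicit tolerance.
- Re-cutting an already-cut set with the same ranges is the identity;
  all other state rewinds are errors.
- Seeding: every generator accepts an integer seed or a
  `numpy.random.Generator`; the end-to-end study derives per-stage
  streams from one `SeedSequence`, making outputs bit-reproducible from
  (config, seed).

## Known limitations

- Calibration statistics on the default synthetic design (R² ≈ 1,
  RMSEP < 1 % DW) are cleaner than real campaigns, where biological
  matrix effects and scattering dominate; the synthetic noise model is
  deliberately simple.
- Mode locations of pools whose population means sum to ~100 % DW are
  biased low by the renormalization (see above).
- No scatter/atmospheric correction, no JCAMP-DX/OPUS readers, no formal
  multimodality tests (dip/Silverman), no 2-D KDE, no VIP scores.
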