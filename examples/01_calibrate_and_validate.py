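"""Calibrate PLS1 composition models on a synthetic bulk campaign.

Simulates the bench-top measurement of 3 phytoplankton cultures x 2 growth
temperatures x 5 replicates (30 spectra), preprocesses them (range cut,
9-point quadratic Savitzky-Golay second derivative, mean centering), fits a
7-component PLS1 model per macromolecular pool, and prints the model
summary table: calibration R^2, RMSEC, leave-one-out RMSEP (all in % of
cell dry weight) and the most predictive wavenumbers.
"""

from ftircell import generate_calibration_set, validate_calibration

raw, compositions = generate_calibration_set(rng=1)
print(f"calibration campaign: {raw.n_spectra} bulk spectra, "
      f"{raw.n_points} grid points each\n")

report = validate_calibration(raw, compositions, n_components=7)
print(report.to_table().to_string(index=False))

print("""
R2 ~ 1 and RMSEC near zero say the linear forward model is essentially
noise-limited on this synthetic set; RMSEP (the honest, held-out error, in
% of dry weight) is the figure of merit for predicting unknown cells. The
top predictor bands sit on the expected chemistry: Amide I/II for protein,
CH2 stretches for lipid, the C-O-C cluster for carbohydrate.""")
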