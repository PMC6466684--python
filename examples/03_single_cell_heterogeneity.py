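"""Single-cell calibration transfer and population heterogeneity.

Calibrates on bulk spectra, then predicts per-cell protein content for two
simulated cyanobacterium populations grown at 15 and 25 degC - the warm
population carries a genuine bimodal protein distribution (two phenotypes).
Kernel density estimates with rule-of-thumb bandwidth summarize each
population; detected modes are printed.
"""

from ftircell import (DEFAULT_CALIBRATION_DESIGN, MixtureComponent,
                      PopulationSpec, cut_ranges, find_modes,
                      generate_calibration_set, generate_population,
                      kde_gaussian, predict, savgol_second_derivative,
                      validate_calibration)

raw, table = generate_calibration_set(rng=10)
report = validate_calibration(raw, table)
protein_model = report.models["protein"]

cold = PopulationSpec.from_condition(DEFAULT_CALIBRATION_DESIGN[0],
                                     n_cells=200)   # 15 degC, unimodal
warm = PopulationSpec(
    macromolecules={
        "protein": (MixtureComponent(0.5, 30.0, 3.0),
                    MixtureComponent(0.5, 50.0, 3.0)),   # two phenotypes
        "lipid": (MixtureComponent(1.0, 44.7, 12.7),),
        "carbohydrate": (MixtureComponent(1.0, 10.6, 1.8),),
    },
    n_cells=200, species="M. aeruginosa", temperature_C=25.0)

for label, spec, seed in [("15 degC", cold, 101), ("25 degC", warm, 102)]:
    cells, truth = generate_population(spec, rng=seed)
    deriv = savgol_second_derivative(cut_ranges(cells))
    predicted = predict(protein_model, deriv.absorbance)
    est = kde_gaussian(predicted)
    modes = find_modes(est)
    desc = "; ".join(f"{m.location:.1f}% DW (height {m.height:.3f})"
                     for m in modes)
    print(f"{label}: bandwidth {est.bandwidth:.2f}% DW, "
          f"{len(modes)} mode(s): {desc}")

print("""
One mode at 15 degC versus two at 25 degC: the density estimate resolves
coexisting phenotypes that a population-average assay would blur into a
single intermediate value.""")
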