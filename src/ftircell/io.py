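"""File formats, run configuration and the end-to-end mock-community study.

Spectra travel as wide CSV (first column ``wavenumber_cm-1``, one column
per spectrum id, ``#``-prefixed header comments carrying the processing
state) with a ``*.meta.csv`` sidecar for per-spectrum metadata. Fitted
models are JSON; density estimates CSV; the whole study is driven by a
:class:`RunConfig` that round-trips through YAML.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from .preprocess import (DEFAULT_RANGES, DEFAULT_SG_POLYORDER,
                         DEFAULT_SG_WINDOW, cut_ranges,
                         savgol_second_derivative)
from .population import DensityEstimate, find_modes, kde_gaussian, pca
from .pls import predict, save_model
from .spectra import SpectrumSet, WavenumberGrid, make_meta
from .synth import (DEFAULT_CALIBRATION_DESIGN, NoiseParams, PopulationSpec,
                    SpeciesCondition, build_band_library,
                    generate_calibration_set, generate_population)
from .validation import ValidationReport, validate_calibration


class FormatError(ValueError):
    """Malformed spectra/composition file."""


# ---------------------------------------------------------------------------
# spectra CSV
# ---------------------------------------------------------------------------

def _split_segments(wavenumbers: np.ndarray) -> list[np.ndarray]:
    """Recover disjoint uniform segments from a concatenated axis."""
    d = np.diff(wavenumbers)
    # offending row index counts the header as row 1
    for i, step in enumerate(d):
        if step == 0:
            raise FormatError(f"duplicated wavenumber at row {i + 3}")
        if step < 0:
            raise FormatError(f"non-monotone wavenumber at row {i + 3}")
    if wavenumbers.size == 1:
        return [wavenumbers]
    spacing = d.min()
    breaks = np.nonzero(d > spacing * 1.5)[0] + 1
    return np.split(wavenumbers, breaks)


def write_spectra_csv(sset: SpectrumSet, path) -> None:
    path = Path(path)
    wide = pd.DataFrame(sset.absorbance.T, columns=sset.ids())
    wide.insert(0, "wavenumber_cm-1", sset.wavenumbers)
    with open(path, "w") as fh:
        fh.write(f"# state: {sset.state}\n")
        wide.to_csv(fh, index=False)
    sset.meta.to_csv(path.with_suffix(".meta.csv"), index=False)


def read_spectra_csv(path) -> SpectrumSet:
    path = Path(path)
    state = "raw"
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            if "state:" in line:
                state = line.split("state:", 1)[1].strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        wide = pd.read_csv(fh)
    if wide.columns[0] != "wavenumber_cm-1":
        raise FormatError("first column must be 'wavenumber_cm-1'")
    wavenumbers = wide.iloc[:, 0].to_numpy(float)
    segments = _split_segments(wavenumbers)
    ids = list(wide.columns[1:])
    absorbance = wide.iloc[:, 1:].to_numpy(float).T
    meta_path = path.with_suffix(".meta.csv")
    if meta_path.exists():
        meta = pd.read_csv(meta_path)
        if list(meta["id"].astype(str)) != [str(i) for i in ids]:
            raise FormatError("metadata sidecar ids do not match columns")
    else:
        meta = make_meta(ids)
    return SpectrumSet(segments=segments, absorbance=absorbance, meta=meta,
                       state=state)


def write_composition_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_composition_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    out = table.set_index("id", drop=False)
    out.index.name = None
    return out


def write_density_csv(est: DensityEstimate, path) -> None:
    pd.DataFrame({"value_pctDW": est.eval_grid,
                  "density": est.density}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

RESPONSES = ("protein", "lipid", "carbohydrate")


@dataclass
class RunConfig:
    """Everything needed to reproduce a study bit-for-bit."""

    seed: int = 0
    grid_low: float = 700.0
    grid_high: float = 4000.0
    grid_spacing: float = 2.0
    band_overrides: dict[str, list[tuple[float, float, float]]] | None = None
    design: tuple[SpeciesCondition, ...] = DEFAULT_CALIBRATION_DESIGN
    n_replicates: int = 5
    calibration_noise: NoiseParams = field(default_factory=NoiseParams)
    population_noise: NoiseParams = field(default_factory=NoiseParams)
    n_cells: int = 200
    cell_scale_cv: float = 0.15
    ranges: tuple[tuple[float, float], ...] = DEFAULT_RANGES
    sg_window: int = DEFAULT_SG_WINDOW
    sg_polyorder: int = DEFAULT_SG_POLYORDER
    n_components: int = 7
    kde_grid_n: int = 512
    kde_cut: float = 3.0
    kde_bandwidth: float | None = None
    mode_prominence_frac: float = 0.05

    def grid(self) -> WavenumberGrid:
        return WavenumberGrid.default(self.grid_low, self.grid_high,
                                      self.grid_spacing)

    def populations(self) -> list[PopulationSpec]:
        """Default mock-community populations: one unimodal population per
        calibration condition (species x temperature)."""
        return [PopulationSpec.from_condition(
            cond, n_cells=self.n_cells, cell_scale_cv=self.cell_scale_cv,
            noise=self.population_noise) for cond in self.design]

    # -- YAML round trip ---------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = {
            "seed": self.seed,
            "grid": {"low": self.grid_low, "high": self.grid_high,
                     "spacing": self.grid_spacing},
            "band_overrides": self.band_overrides,
            "design": [{"species": c.species,
                        "temperature_C": c.temperature_C,
                        "means": c.means, "sds": c.sds}
                       for c in self.design],
            "n_replicates": self.n_replicates,
            "calibration_noise": asdict(self.calibration_noise),
            "population_noise": asdict(self.population_noise),
            "n_cells": self.n_cells,
            "cell_scale_cv": self.cell_scale_cv,
            "preprocessing": {"ranges": [list(r) for r in self.ranges],
                              "sg_window": self.sg_window,
                              "sg_polyorder": self.sg_polyorder},
            "n_components": self.n_components,
            "kde": {"grid_n": self.kde_grid_n, "cut": self.kde_cut,
                    "bandwidth": self.kde_bandwidth,
                    "prominence_frac": self.mode_prominence_frac},
        }
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        g = d.get("grid", {})
        pp = d.get("preprocessing", {})
        kde = d.get("kde", {})
        design = tuple(
            SpeciesCondition(c["species"], c["temperature_C"],
                             dict(c["means"]), dict(c["sds"]))
            for c in d["design"]) if "design" in d \
            else DEFAULT_CALIBRATION_DESIGN

        def _noise(key):
            nd = d.get(key)
            if nd is None:
                return NoiseParams()
            return NoiseParams(additive_sd=nd["additive_sd"],
                               baseline_range=tuple(nd["baseline_range"]))

        return cls(
            seed=d.get("seed", 0),
            grid_low=g.get("low", 700.0), grid_high=g.get("high", 4000.0),
            grid_spacing=g.get("spacing", 2.0),
            band_overrides=d.get("band_overrides"),
            design=design,
            n_replicates=d.get("n_replicates", 5),
            calibration_noise=_noise("calibration_noise"),
            population_noise=_noise("population_noise"),
            n_cells=d.get("n_cells", 200),
            cell_scale_cv=d.get("cell_scale_cv", 0.15),
            ranges=tuple(tuple(r) for r in pp.get("ranges", DEFAULT_RANGES)),
            sg_window=pp.get("sg_window", DEFAULT_SG_WINDOW),
            sg_polyorder=pp.get("sg_polyorder", DEFAULT_SG_POLYORDER),
            n_components=d.get("n_components", 7),
            kde_grid_n=kde.get("grid_n", 512),
            kde_cut=kde.get("cut", 3.0),
            kde_bandwidth=kde.get("bandwidth"),
            mode_prominence_frac=kde.get("prominence_frac", 0.05))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# end-to-end study
# ---------------------------------------------------------------------------

@dataclass
class StudyResult:
    """In-memory results of :func:`run_mock_community_study`."""

    config: RunConfig
    report: ValidationReport
    calibration_table: pd.DataFrame
    predictions: dict[tuple[str, float], pd.DataFrame]
    densities: dict[tuple[str, float, str], DensityEstimate]
    pca_by_species: dict[str, Any]
    outdir: Path | None = None


def _population_key(spec: PopulationSpec) -> tuple[str, float]:
    return (spec.species, float(spec.temperature_C))


def run_mock_community_study(config: RunConfig,
                             outdir=None,
                             populations: Sequence[PopulationSpec] | None
                             = None) -> StudyResult:
    """Execute the full calibration-transfer study.

    Stages: simulate the bulk calibration campaign; preprocess and calibrate
    one PLS1 model per macromolecular pool; validate each by LOOCV; simulate
    each single-cell population; preprocess single cells with the *training*
    mean; predict per-cell contents; estimate densities, call modes, and run
    a per-species PCA. All randomness derives from ``config.seed``; writes
    artifacts under ``outdir`` when given.
    """
    grid = config.grid()
    library = build_band_library(config.band_overrides)
    pops = list(populations) if populations is not None \
        else config.populations()
    seeds = np.random.SeedSequence(config.seed).spawn(1 + len(pops))

    # -- calibration ------------------------------------------------------
    cal_raw, cal_table = generate_calibration_set(
        config.design, config.n_replicates, library, grid,
        config.calibration_noise, np.random.default_rng(seeds[0]))
    report = validate_calibration(
        cal_raw, cal_table, RESPONSES, config.n_components,
        config.ranges, config.sg_window, config.sg_polyorder)
    training_mean = np.asarray(
        report.models[RESPONSES[0]].preprocessing["training_mean"])

    # -- single-cell populations ------------------------------------------
    predictions: dict[tuple[str, float], pd.DataFrame] = {}
    densities: dict[tuple[str, float, str], DensityEstimate] = {}
    deriv_by_pop: dict[tuple[str, float], SpectrumSet] = {}
    for spec, seed in zip(pops, seeds[1:]):
        cells_raw, truth = generate_population(
            spec, library, grid, np.random.default_rng(seed))
        # predict on uncentered derivative features: each model stores its
        # training mean and centers internally, so centering here would
        # subtract it twice
        deriv = savgol_second_derivative(
            cut_ranges(cells_raw, config.ranges), config.sg_window,
            config.sg_polyorder)
        centered = deriv._advance("centered",
                                  deriv.segments,
                                  deriv.absorbance - training_mean)
        deriv_by_pop[_population_key(spec)] = centered
        table = truth.copy()
        for name in RESPONSES:
            table[f"{name}_pred"] = predict(report.models[name],
                                            deriv.absorbance)
        predictions[_population_key(spec)] = table
        for name in RESPONSES:
            est = kde_gaussian(table[f"{name}_pred"].to_numpy(),
                               bandwidth=config.kde_bandwidth,
                               grid_n=config.kde_grid_n, cut=config.kde_cut)
            find_modes(est, config.mode_prominence_frac)
            densities[(spec.species, float(spec.temperature_C), name)] = est

    # -- PCA per species, temperatures pooled ------------------------------
    pca_by_species: dict[str, Any] = {}
    for species in dict.fromkeys(spec.species for spec in pops):
        sets = [v for (sp, _t), v in deriv_by_pop.items() if sp == species]
        X = np.vstack([s.absorbance for s in sets])
        Xc = X - X.mean(axis=0)
        if Xc.shape[0] >= 2:
            pca_by_species[species] = pca(Xc, n_components=5)

    result = StudyResult(config=config, report=report,
                         calibration_table=cal_table,
                         predictions=predictions, densities=densities,
                         pca_by_species=pca_by_species)
    if outdir is not None:
        result.outdir = Path(outdir)
        _write_study(result, cal_raw)
    return result


def _write_study(result: StudyResult, cal_raw: SpectrumSet) -> None:
    out = result.outdir
    for sub in ("models", "predictions", "densities", "pca"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    write_spectra_csv(cal_raw, out / "calibration_spectra.csv")
    write_composition_csv(result.calibration_table,
                          out / "calibration_compositions.csv")
    for name, model in result.report.models.items():
        save_model(model, out / "models" / f"{name}.json")
    result.report.save_json(out / "validation_report.json")
    result.report.to_table().to_csv(out / "model_summary.csv", index=False)
    for (species, temp), table in result.predictions.items():
        slug = f"{species.replace(' ', '_').replace('.', '')}_{temp:g}C"
        table.to_csv(out / "predictions" / f"{slug}.csv", index=False)
    modes: dict[str, Any] = {}
    for (species, temp, name), est in result.densities.items():
        slug = (f"{species.replace(' ', '_').replace('.', '')}_{temp:g}C_"
                f"{name}")
        write_density_csv(est, out / "densities" / f"{slug}.csv")
        modes[slug] = {"bandwidth": est.bandwidth,
                       "modes": [m._asdict() for m in est.modes]}
    with open(out / "modes.json", "w") as fh:
        json.dump(modes, fh, indent=1)
    for species, res in result.pca_by_species.items():
        slug = species.replace(" ", "_").replace(".", "")
        pd.DataFrame(res.scores,
                     columns=[f"PC{i + 1}"
                              for i in range(res.scores.shape[1])]
                     ).to_csv(out / "pca" / f"{slug}_scores.csv", index=False)
    log = {"seed": result.config.seed,
           "config_hash": result.config.config_hash(),
           "n_populations": len(result.predictions)}
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1)
    result.config.to_yaml(out / "config.yaml")
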