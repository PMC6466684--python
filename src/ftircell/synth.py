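"""Synthetic FTIR spectrum generator with known macromolecular ground truth.

The forward model is Beer-Lambert linear mixing: each macromolecular pool
(protein, lipid, carbohydrate, silica) contributes a fixed set of Gaussian
absorption bands, scaled by its mass fraction, summed, then degraded by a
per-spectrum linear baseline ramp and additive white noise. Single cells
additionally carry a lognormal optical-path/biomass scale factor.

Default band centers are the diagnostic phytoplankton bands: CH2 stretches
at 2915/2848 and the ester C=O at 1740 cm^-1 (lipids), Amide I/II at
1658/1544 cm^-1 (proteins), the C-O-C / C-O cluster at 1153, 1108, 1080 and
1020 cm^-1 (carbohydrates), and one broad Si-O band for diatom frustule
silica. Amide extinctions exceed the lipid C=O extinction, as in condensed
phase IR of biomass.

Default composition statistics are the wet-chemistry reference values for
three phytoplankton cultures (a cyanobacterium, a green alga, a diatom)
grown at 15 and 25 degC, with n = 5 biological replicates each; they are
encoded in :data:`DEFAULT_CALIBRATION_DESIGN`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .spectra import SpectrumSet, WavenumberGrid, make_meta

COMPONENTS = ("protein", "lipid", "carbohydrate", "silica")
ORGANIC_POOLS = ("protein", "lipid", "carbohydrate")


class ConfigurationError(ValueError):
    """Invalid generator configuration (unknown component, bad design)."""


class Band(NamedTuple):
    """One Gaussian absorption band."""
    center: float          # cm^-1
    width: float           # Gaussian sigma, cm^-1
    extinction: float      # relative, dimensionless, >= 0


@dataclass(frozen=True)
class BandLibrary:
    """Absorption bands per macromolecular component."""

    bands: dict[str, tuple[Band, ...]]

    def __post_init__(self) -> None:
        for name, blist in self.bands.items():
            if name not in COMPONENTS:
                raise ConfigurationError(f"unknown component {name!r}")
            for b in blist:
                if b.width <= 0:
                    raise ConfigurationError(f"{name}: band width must be > 0")
                if b.extinction < 0:
                    raise ConfigurationError(f"{name}: extinction must be >= 0")

    def __getitem__(self, component: str) -> tuple[Band, ...]:
        return self.bands.get(component, ())

    def centers(self, component: str) -> list[float]:
        return [b.center for b in self[component]]


# widths (sigma) chosen in the 12-25 cm^-1 range typical of condensed-phase
# biomass bands; broad amorphous silica envelope is wider.
_DEFAULT_BANDS: dict[str, tuple[Band, ...]] = {
    "protein": (
        Band(1658.0, 25.0, 1.00),   # Amide I
        Band(1544.0, 22.0, 0.65),   # Amide II
    ),
    "lipid": (
        Band(2915.0, 14.0, 0.70),   # asym CH2 stretch
        Band(2848.0, 12.0, 0.45),   # sym CH2 stretch
        Band(1740.0, 15.0, 0.35),   # ester C=O (< Amide I/II extinction)
    ),
    "carbohydrate": (
        Band(1153.0, 14.0, 0.40),
        Band(1108.0, 14.0, 0.35),
        Band(1080.0, 16.0, 0.50),
        Band(1020.0, 18.0, 0.55),
    ),
    "silica": (
        Band(1075.0, 60.0, 0.60),   # broad Si-O-Si stretch envelope
    ),
}


def build_band_library(
    overrides: Mapping[str, Sequence[tuple[float, float, float]]] | None = None,
) -> BandLibrary:
    """Return the default band library, with optional per-component edits.

    ``overrides`` maps component name -> list of ``(center, width,
    extinction)`` tuples that fully replace that component's defaults (an
    empty list removes the component's absorbance). Unknown component names
    raise :class:`ConfigurationError`.
    """
    bands = dict(_DEFAULT_BANDS)
    if overrides:
        for name, blist in overrides.items():
            if name not in COMPONENTS:
                raise ConfigurationError(f"unknown component {name!r}")
            bands[name] = tuple(Band(*b) for b in blist)
    return BandLibrary(bands=bands)


@dataclass(frozen=True)
class NoiseParams:
    """Measurement degradation applied to every rendered spectrum.

    additive_sd : absorbance units; white Gaussian noise per grid point.
    baseline_range : endpoints of a per-spectrum linear ramp are drawn
        uniformly from this interval (absorbance units). The second
        derivative step annihilates any such ramp exactly.
    """

    additive_sd: float = 0.002
    baseline_range: tuple[float, float] = (-0.01, 0.01)

    @classmethod
    def none(cls) -> "NoiseParams":
        return cls(additive_sd=0.0, baseline_range=(0.0, 0.0))


def as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def _pure_component_matrix(library: BandLibrary,
                           grid: WavenumberGrid) -> np.ndarray:
    """Absorbance of each unit-fraction component on the grid [4 x n]."""
    nu = grid.values
    out = np.zeros((len(COMPONENTS), nu.size))
    for i, comp in enumerate(COMPONENTS):
        for band in library[comp]:
            out[i] += band.extinction * np.exp(
                -0.5 * ((nu - band.center) / band.width) ** 2)
    return out


def render_spectrum(
    composition: Mapping[str, float] | pd.Series,
    library: BandLibrary,
    grid: WavenumberGrid,
    scale: float = 1.0,
    noise: NoiseParams | None = None,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Render one absorbance spectrum from a composition (% dry weight).

    A(nu) = scale * sum_c (f_c / 100) * sum_bands eps * gauss(nu)
            + baseline(nu) + additive noise

    Mass fractions enter as percentages and are divided by 100, so a whole
    cell at unit scale has absorbance of order the extinction coefficients.
    With ``noise=None`` (or all-zero noise) the output is a deterministic
    linear function of the composition.
    """
    if scale < 0:
        raise ValueError("scale must be >= 0")
    nu = grid.values
    spectrum = np.zeros(nu.size)
    pure = _pure_component_matrix(library, grid)
    for i, comp in enumerate(COMPONENTS):
        f = float(composition.get(comp, 0.0) if isinstance(composition, Mapping)
                  else composition.get(comp, 0.0))
        if f < 0:
            raise ValueError(f"negative {comp} fraction")
        spectrum += (f / 100.0) * pure[i]
    spectrum *= scale
    if noise is not None and (noise.additive_sd > 0
                              or noise.baseline_range != (0.0, 0.0)):
        gen = as_rng(rng)
        lo, hi = noise.baseline_range
        if hi > lo:
            e0, e1 = gen.uniform(lo, hi, size=2)
            spectrum = spectrum + np.linspace(e0, e1, nu.size)
        if noise.additive_sd > 0:
            spectrum = spectrum + gen.normal(0.0, noise.additive_sd, nu.size)
    return spectrum


# ---------------------------------------------------------------------------
# composition sampling
# ---------------------------------------------------------------------------

def _draw_truncated_normal(mean: float, sd: float, size: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Normal(mean, sd) truncated at zero; degenerate when sd == 0."""
    if sd == 0:
        return np.full(size, float(mean))
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size,
                               random_state=rng)


def _renormalize(comp: np.ndarray) -> np.ndarray:
    """Jointly rescale rows whose component sum exceeds 100% DW."""
    total = comp.sum(axis=1)
    over = total > 100.0
    if np.any(over):
        comp = comp.copy()
        comp[over] *= (100.0 / total[over])[:, None]
    return comp


def check_composition_table(table: pd.DataFrame,
                            tol: float = 1e-9) -> None:
    """Validate a composition table (% DW fractions, sum <= 100 + tol).

    The default ``tol`` only absorbs floating-point rounding of the
    generators' joint renormalization; pass a larger value (a few % DW) for
    externally measured tables whose assays carry independent errors.
    """
    for comp in COMPONENTS:
        if comp in table and (table[comp] < 0).any():
            raise ValueError(f"negative {comp} fraction in composition table")
    present = [c for c in COMPONENTS if c in table]
    total = table[present].sum(axis=1)
    if (total > 100.0 + tol).any():
        raise ValueError("composition fractions sum above 100% DW")


# ---------------------------------------------------------------------------
# calibration design (bulk cultures)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesCondition:
    """Mean/SD composition of one species at one growth temperature."""

    species: str
    temperature_C: float
    means: dict[str, float]     # % DW per component
    sds: dict[str, float]       # % DW per component

    def __post_init__(self) -> None:
        for comp, m in self.means.items():
            if comp not in COMPONENTS:
                raise ConfigurationError(f"unknown component {comp!r}")
            if not 0.0 <= m <= 100.0:
                raise ConfigurationError(
                    f"{self.species} {comp} mean {m} outside [0, 100] % DW")
        for comp, s in self.sds.items():
            if s < 0:
                raise ConfigurationError("SDs must be >= 0")


#: Reference biochemistry (% DW, mean and SD of n = 5 biological replicates)
#: of the three calibration cultures at the two growth temperatures.
DEFAULT_CALIBRATION_DESIGN: tuple[SpeciesCondition, ...] = (
    SpeciesCondition("M. aeruginosa", 15.0,
                     {"protein": 26.9, "lipid": 38.4, "carbohydrate": 34.6},
                     {"protein": 9.9, "lipid": 9.1, "carbohydrate": 19.7}),
    SpeciesCondition("M. aeruginosa", 25.0,
                     {"protein": 44.6, "lipid": 44.7, "carbohydrate": 10.6},
                     {"protein": 11.6, "lipid": 12.7, "carbohydrate": 1.8}),
    SpeciesCondition("A. obliquus", 15.0,
                     {"protein": 46.4, "lipid": 38.8, "carbohydrate": 14.7},
                     {"protein": 13.8, "lipid": 16.9, "carbohydrate": 3.7}),
    SpeciesCondition("A. obliquus", 25.0,
                     {"protein": 36.7, "lipid": 46.6, "carbohydrate": 16.6},
                     {"protein": 6.4, "lipid": 9.3, "carbohydrate": 2.8}),
    SpeciesCondition("A. granulata", 15.0,
                     {"protein": 16.5, "lipid": 33.7, "carbohydrate": 5.8,
                      "silica": 43.8},
                     {"protein": 8.0, "lipid": 14.8, "carbohydrate": 0.2,
                      "silica": 11.4}),
    SpeciesCondition("A. granulata", 25.0,
                     {"protein": 21.7, "lipid": 35.4, "carbohydrate": 4.0,
                      "silica": 38.8},
                     {"protein": 6.2, "lipid": 6.7, "carbohydrate": 1.4,
                      "silica": 8.8}),
)


def generate_calibration_set(
    design: Sequence[SpeciesCondition] = DEFAULT_CALIBRATION_DESIGN,
    n_replicates: int = 5,
    library: BandLibrary | None = None,
    grid: WavenumberGrid | None = None,
    noise: NoiseParams | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[SpectrumSet, pd.DataFrame]:
    """Simulate the bulk calibration measurement campaign.

    One spectrum per (species x temperature x replicate); replicate
    compositions are truncated-at-zero normal draws around the design
    means/SDs, jointly renormalized so organics + silica never exceed
    100% DW. Deterministic given the seed.

    Returns the raw :class:`SpectrumSet` and the ground-truth composition
    table (the stand-in for the wet-chemistry reference assays).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if not design:
        raise ValueError("empty calibration design")
    library = library or build_band_library()
    grid = grid or WavenumberGrid.default()
    noise = NoiseParams() if noise is None else noise
    gen = as_rng(rng)

    rows, spectra, meta_rows = [], [], []
    for cond in design:
        comp = np.zeros((n_replicates, len(COMPONENTS)))
        for j, name in enumerate(COMPONENTS):
            comp[:, j] = _draw_truncated_normal(
                cond.means.get(name, 0.0), cond.sds.get(name, 0.0),
                n_replicates, gen)
        comp = _renormalize(comp)
        for r in range(n_replicates):
            sid = f"{cond.species}_{cond.temperature_C:g}C_rep{r + 1}"
            c = dict(zip(COMPONENTS, comp[r]))
            spectra.append(render_spectrum(c, library, grid, 1.0, noise, gen))
            rows.append({"id": sid, "species": cond.species,
                         "temperature_C": cond.temperature_C, "level": "bulk",
                         **c})
            meta_rows.append(sid)
    table = pd.DataFrame(rows).set_index("id", drop=False)
    table.index.name = None
    meta = make_meta(meta_rows,
                     species=list(table["species"]),
                     temperature_C=list(table["temperature_C"]),
                     level="bulk")
    sset = SpectrumSet(segments=[grid.values], absorbance=np.vstack(spectra),
                       meta=meta, state="raw")
    check_composition_table(table)
    return sset, table


# ---------------------------------------------------------------------------
# single-cell populations
# ---------------------------------------------------------------------------

class MixtureComponent(NamedTuple):
    weight: float   # mixing fraction, weights per pool sum to 1
    mean: float     # % DW
    sd: float       # % DW


@dataclass(frozen=True)
class PopulationSpec:
    """Statistical description of a single-cell population.

    Each macromolecular pool follows a (possibly one-component) mixture of
    truncated-at-zero normals; unimodal populations use one component,
    heterogeneous ones two. ``cell_scale_cv`` is the coefficient of
    variation of the lognormal per-cell optical-path/biomass factor.
    """

    macromolecules: dict[str, tuple[MixtureComponent, ...]]
    n_cells: int = 200
    cell_scale_cv: float = 0.15
    noise: NoiseParams = field(default_factory=NoiseParams)
    species: str = ""
    temperature_C: float = float("nan")

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.cell_scale_cv < 0:
            raise ValueError("cell_scale_cv must be >= 0")
        for pool, comps in self.macromolecules.items():
            if pool not in COMPONENTS:
                raise ConfigurationError(f"unknown component {pool!r}")
            w = sum(c.weight for c in comps)
            if abs(w - 1.0) > 1e-12:
                raise ValueError(
                    f"{pool} mixture weights sum to {w}, expected 1")
            for c in comps:
                if c.sd < 0 or c.mean < 0:
                    raise ValueError(f"{pool}: means and sds must be >= 0")

    @classmethod
    def unimodal(cls, means: Mapping[str, float], sds: Mapping[str, float],
                 **kwargs) -> "PopulationSpec":
        macro = {pool: (MixtureComponent(1.0, float(m),
                                         float(sds.get(pool, 0.0))),)
                 for pool, m in means.items()}
        return cls(macromolecules=macro, **kwargs)

    @classmethod
    def from_condition(cls, cond: SpeciesCondition,
                       **kwargs) -> "PopulationSpec":
        kwargs.setdefault("species", cond.species)
        kwargs.setdefault("temperature_C", cond.temperature_C)
        return cls.unimodal(cond.means, cond.sds, **kwargs)


def generate_population(
    spec: PopulationSpec,
    library: BandLibrary | None = None,
    grid: WavenumberGrid | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[SpectrumSet, pd.DataFrame]:
    """Simulate single-cell spectra for one population.

    Per cell: draw each pool from its mixture (truncated at zero), jointly
    renormalize if the sum exceeds 100% DW, draw a lognormal scale with
    unit mean and CV ``spec.cell_scale_cv``, render with noise. Returns the
    raw spectra and the ground-truth per-cell composition table (which also
    records the drawn scale).
    """
    library = library or build_band_library()
    grid = grid or WavenumberGrid.default()
    gen = as_rng(rng)
    n = spec.n_cells

    comp = np.zeros((n, len(COMPONENTS)))
    for j, pool in enumerate(COMPONENTS):
        comps = spec.macromolecules.get(pool)
        if not comps:
            continue
        weights = np.array([c.weight for c in comps])
        choice = gen.choice(len(comps), size=n, p=weights)
        for k, c in enumerate(comps):
            idx = choice == k
            comp[idx, j] = _draw_truncated_normal(c.mean, c.sd,
                                                  int(idx.sum()), gen)
    comp = _renormalize(comp)

    if spec.cell_scale_cv > 0:
        sigma2 = np.log1p(spec.cell_scale_cv ** 2)
        # unit-mean lognormal: E[scale] = exp(mu + sigma^2/2) = 1
        scales = gen.lognormal(mean=-sigma2 / 2.0,
                               sigma=np.sqrt(sigma2), size=n)
    else:
        scales = np.ones(n)

    ids = [f"{spec.species or 'cell'}_{spec.temperature_C:g}C_cell{i + 1}"
           if spec.species else f"cell{i + 1}" for i in range(n)]
    spectra = np.empty((n, grid.n_points))
    rows = []
    for i in range(n):
        c = dict(zip(COMPONENTS, comp[i]))
        spectra[i] = render_spectrum(c, library, grid, float(scales[i]),
                                     spec.noise, gen)
        rows.append({"id": ids[i], "species": spec.species,
                     "temperature_C": spec.temperature_C,
                     "level": "single-cell", **c, "scale": float(scales[i])})
    table = pd.DataFrame(rows).set_index("id", drop=False)
    table.index.name = None
    meta = make_meta(ids, species=spec.species,
                     temperature_C=spec.temperature_C, level="single-cell")
    sset = SpectrumSet(segments=[grid.values], absorbance=spectra,
                       meta=meta, state="raw")
    check_composition_table(table)
    return sset, table
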