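"""Forward model for synthetic Raman data with known ground truth.

Generates (a) aqueous fumarate solution spectra and dilution series with
the 1277/1401/1652 cm^-1 triplet at a stated sensitivity, (b) single-cell
hyperspectral phantoms with five compartments (substrate, nucleus,
membrane, cytoplasm, mitochondria), cellular background bands,
cytochrome-C confounders, a fluorescence baseline, Gaussian noise and
cosmic-ray spikes, (c) kidney-tissue phantoms for two Fh1 genotypes, and
(d) labelled line-scan spectra for classifier training.

All bands are Gaussian.  The solution-fumarate 1401 cm^-1 band is
calibrated so that its flat-baseline area over 1399-1419 cm^-1 equals
sensitivity x concentration x dwell (default 19.2 counts cm^-1 s^-1
mM^-1); the residual out-of-window tail of the Gaussian is absorbed into
that calibration, making generator/integrator round trips exact by
construction.  Confounding signal near 1401 cm^-1 is rendered as the
cytochrome-C oxidised/reduced pair (weak 1388/1401 cm^-1 bands), scaled
in fumarate-equivalent mM, so that apparent concentration maps obey
apparent = true + confounder.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict

import numpy as np

from .calibrate import CalibrationSeries
from .classify import LabelledSpectra
from .core import (
    DEFAULT_NOISE_FLOOR,
    DEFAULT_SENSITIVITY,
    REFERENCE_DWELL,
    SpectralMap,
    Spectrum,
    default_axis,
)
from .preprocess import band_auc

__all__ = [
    "BandComponent",
    "ComponentLibrary",
    "PhantomConfig",
    "CompartmentSpec",
    "GroundTruth",
    "build_component_library",
    "generate_solution_spectrum",
    "generate_calibration_series",
    "generate_cell_phantom",
    "generate_tissue_phantom",
    "generate_linescan_dataset",
    "cell_phantom_config",
    "COMPARTMENTS",
    "TABLE1_APPARENT_MM",
]

COMPARTMENTS = ("substrate", "nucleus", "membrane", "cytoplasm", "mitochondria")

#: Apparent per-compartment fumarate concentrations (mM) per cell line,
#: mean values of the reference compartment table.
TABLE1_APPARENT_MM = {
    "WT": {"substrate": 2, "nucleus": 4, "membrane": 4,
           "cytoplasm": 6, "mitochondria": 10},
    "KO1": {"substrate": 4, "nucleus": 8, "membrane": 8,
            "cytoplasm": 11, "mitochondria": 11},
    "KO19": {"substrate": 3, "nucleus": 9, "membrane": 14,
             "cytoplasm": 24, "mitochondria": 37},
}


# ---------------------------------------------------------------------------
# Band components and library
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BandComponent:
    """One Gaussian band: centre (cm^-1), sigma (cm^-1) and integrated
    area per unit weight per second (counts cm^-1 s^-1; for metabolite
    bands the unit weight is 1 mM)."""

    center: float
    width_sigma: float
    area_per_unit: float

    def __post_init__(self) -> None:
        if not self.width_sigma > 0:
            raise ValueError("band width_sigma must be positive")
        if self.area_per_unit < 0:
            raise ValueError("band area_per_unit must be >= 0")

    def render(self, wavenumbers: np.ndarray) -> np.ndarray:
        """Counts per channel for unit weight and 1 s dwell."""
        g = np.exp(-0.5 * ((wavenumbers - self.center) / self.width_sigma) ** 2)
        return self.area_per_unit / (self.width_sigma * np.sqrt(2 * np.pi)) * g


@dataclass
class ComponentLibrary:
    """Named sets of bands.  ``components[name]`` renders per unit weight
    per second; metabolite components are scaled in mM."""

    components: dict[str, tuple[BandComponent, ...]]
    sensitivity: float = DEFAULT_SENSITIVITY
    variant: str = "none"

    def __contains__(self, name: str) -> bool:
        return name in self.components

    def render(self, name: str, wavenumbers: np.ndarray) -> np.ndarray:
        if name not in self.components:
            raise KeyError(
                f"unknown component {name!r}; available: "
                f"{sorted(self.components)}"
            )
        out = np.zeros_like(wavenumbers, dtype=float)
        for band in self.components[name]:
            out += band.render(wavenumbers)
        return out

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "variant": self.variant,
            "components": {
                name: [asdict(b) for b in bands]
                for name, bands in self.components.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ComponentLibrary":
        comps = {
            name: tuple(BandComponent(**b) for b in bands)
            for name, bands in d["components"].items()
        }
        return cls(comps, sensitivity=float(d.get("sensitivity",
                                                  DEFAULT_SENSITIVITY)),
                   variant=str(d.get("variant", "none")))


def _window_fraction(center: float, sigma: float,
                     wavenumbers: np.ndarray) -> float:
    """Fraction of a unit-area Gaussian recovered by the flat-baseline
    band integral on the given grid (trapezoid, standard windows)."""
    band = BandComponent(center, sigma, 1.0)
    spec = Spectrum(wavenumbers, band.render(wavenumbers), dwell=1.0)
    return band_auc(spec)


def build_component_library(variant: str = "none",
                            sensitivity: float = DEFAULT_SENSITIVITY,
                            wavenumbers: np.ndarray | None = None
                            ) -> ComponentLibrary:
    """Build the default component library.

    ``variant='13C4'`` replaces the 1401 cm^-1 solution band by the
    isotopologue band at 1373 cm^-1 (same cross-section).  The relative
    areas of the 1277 and 1652 companions (0.9x and 1.4x the 1401 band)
    are cosmetic defaults; only the 1401 band is quantitative.
    """
    if variant not in ("none", "13C4"):
        raise ValueError(
            f"unknown isotope variant {variant!r}; allowed: 'none', '13C4'"
        )
    wn = default_axis() if wavenumbers is None else np.asarray(wavenumbers,
                                                               dtype=float)
    # calibrate the quantitative band against the flat-baseline integral
    frac = _window_fraction(1401.0, 4.0, wn)
    unit_area = sensitivity / frac  # raw Gaussian area per mM per s
    quant_center = 1373.0 if variant == "13C4" else 1401.0
    fumarate_solution = (
        BandComponent(1277.0, 5.0, 0.9 * unit_area),
        BandComponent(quant_center, 4.0, unit_area),
        BandComponent(1652.0, 6.0, 1.4 * unit_area),
    )
    fumarate_powder = tuple(
        BandComponent(c, 5.0, a * unit_area)
        for c, a in ((913.0, 0.8), (1296.0, 0.9), (1431.0, 1.0), (1657.0, 1.2))
    )
    # cytochrome-C redox pair: weak 1388/1401 bands confounding the
    # fumarate window; calibrated so 1 unit == 1 fumarate-equivalent mM
    pair = (
        BandComponent(1388.0, 4.0, 1.0),
        BandComponent(1401.0, 4.0, 1.0),
    )
    pair_frac = sum(_window_fraction(b.center, b.width_sigma, wn) for b in pair)
    pair_area = sensitivity / pair_frac
    cytc_redox = tuple(BandComponent(b.center, b.width_sigma, pair_area)
                       for b in pair)
    # prominent resonance-enhanced cytochrome-C marker bands (mitochondria)
    cytc_marker = (
        BandComponent(748.0, 5.0, 16000.0),
        BandComponent(1127.0, 5.0, 14000.0),
        BandComponent(1585.0, 5.0, 18000.0),
    )
    # background component areas give band heights of order 100-400
    # counts at the 0.3 s reference dwell, comparable to real cell scans
    components = {
        "fumarate_solution": fumarate_solution,
        "fumarate_powder": fumarate_powder,
        "cytc_redox": cytc_redox,
        "cytc_marker": cytc_marker,
        "protein": (
            BandComponent(1260.0, 10.0, 16000.0),  # amide III
            BandComponent(1660.0, 12.0, 28000.0),  # amide I
        ),
        "phe": (
            BandComponent(1003.0, 4.0, 9000.0),    # phenylalanine
        ),
        "lipid": (
            BandComponent(1445.0, 9.0, 24000.0),   # CH2 deformation
        ),
        "lipid_twist": (
            BandComponent(1301.0, 7.0, 12000.0),   # acyl-chain twist
        ),
        "dna": (
            BandComponent(785.0, 6.0, 16000.0),    # DNA backbone/base marker
        ),
        "water": (
            BandComponent(1640.0, 25.0, 12000.0),  # water bend, broad
        ),
        "quartz": (
            BandComponent(490.0, 30.0, 6000.0),    # substrate, weak
        ),
        "tissue_marker": (
            BandComponent(1130.0, 5.0, 20000.0),   # tissue outline band
        ),
    }
    return ComponentLibrary(components, sensitivity=sensitivity,
                            variant=variant)


# ---------------------------------------------------------------------------
# Solution spectra and calibration series
# ---------------------------------------------------------------------------

def generate_solution_spectrum(conc: float, dwell: float = REFERENCE_DWELL,
                               noise_sd: float = 0.0, seed: int = 0,
                               library: ComponentLibrary | None = None,
                               wavenumbers: np.ndarray | None = None,
                               offset_per_s: float = 50.0) -> Spectrum:
    """Aqueous fumarate solution spectrum at ``conc`` mM.

    counts = fumarate bands + flat water/quartz offset + Gaussian noise.
    Band and offset counts scale linearly with dwell; ``noise_sd`` is
    applied as given (counts).
    """
    if conc < 0:
        raise ValueError("concentration must be non-negative")
    if not dwell > 0:
        raise ValueError("dwell must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    lib = library if library is not None else build_component_library()
    wn = default_axis() if wavenumbers is None else np.asarray(wavenumbers,
                                                               dtype=float)
    counts = np.full(wn.shape, offset_per_s * dwell, dtype=float)
    if conc > 0:
        counts += conc * dwell * lib.render("fumarate_solution", wn)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        counts += rng.normal(0.0, noise_sd, size=wn.shape)
    return Spectrum(wn, counts, dwell=dwell,
                    meta={"source": "synthetic-solution", "conc_mm": conc,
                          "seed": seed})


def generate_calibration_series(concs, replicates: int = 3,
                                dwell: float = REFERENCE_DWELL,
                                noise_sd: float | None = None,
                                seed: int = 0,
                                library: ComponentLibrary | None = None,
                                wavenumbers: np.ndarray | None = None,
                                keep_spectra: bool = True
                                ) -> CalibrationSeries:
    """Dilution series of band-AUC intensities (counts cm^-1 s^-1).

    ``noise_sd=None`` uses the experimental noise floor scaled as
    sqrt(dwell / 0.3 s) from the reference dwell.
    """
    concs = list(concs)
    if not concs:
        raise ValueError("concentration list must be non-empty")
    if any(c < 0 for c in concs):
        raise ValueError("concentrations must be non-negative")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if noise_sd is None:
        noise_sd = DEFAULT_NOISE_FLOOR * np.sqrt(dwell / REFERENCE_DWELL)
    lib = library if library is not None else build_component_library()
    wn = default_axis() if wavenumbers is None else np.asarray(wavenumbers,
                                                               dtype=float)
    rng = np.random.default_rng(seed)
    conc_col, inten_col, spectra = [], [], []
    for c in concs:
        base = generate_solution_spectrum(c, dwell=dwell, noise_sd=0.0,
                                          library=lib, wavenumbers=wn)
        for _ in range(replicates):
            counts = base.counts
            if noise_sd > 0:
                counts = counts + rng.normal(0.0, noise_sd, size=wn.shape)
            spec = base.with_counts(counts)
            conc_col.append(c)
            inten_col.append(band_auc(spec))
            if keep_spectra:
                spectra.append(spec)
    return CalibrationSeries.from_arrays(
        conc_col, inten_col, dwell=dwell, band="1401",
        spectra=spectra if keep_spectra else None)


# ---------------------------------------------------------------------------
# Phantom configuration
# ---------------------------------------------------------------------------

@dataclass
class CompartmentSpec:
    """Per-compartment generator parameters.

    ``weights`` are unit weights of background library components;
    ``fumarate_mm``/``confounder_mm`` are (mean, sd) in mM (the
    confounder in fumarate-equivalent mM); ``cytc_marker`` is the weight
    of the resonance cytochrome-C marker bands.
    """

    weights: dict[str, float]
    fumarate_mm: tuple[float, float] = (0.0, 0.0)
    confounder_mm: tuple[float, float] = (0.0, 0.0)
    cytc_marker: float = 0.0

    def __post_init__(self) -> None:
        if self.fumarate_mm[1] < 0 or self.confounder_mm[1] < 0:
            raise ValueError("concentration SDs must be >= 0")


def _default_compartments() -> dict[str, CompartmentSpec]:
    return {
        "substrate": CompartmentSpec(
            weights={"quartz": 1.0, "water": 0.4}),
        "nucleus": CompartmentSpec(
            weights={"dna": 2.8, "protein": 1.0, "phe": 1.0, "lipid": 0.3,
                     "lipid_twist": 0.3, "water": 0.5},
            cytc_marker=0.1),
        "membrane": CompartmentSpec(
            weights={"lipid": 2.2, "lipid_twist": 2.2, "protein": 0.4,
                     "phe": 0.4, "water": 0.3},
            cytc_marker=0.1),
        "cytoplasm": CompartmentSpec(
            weights={"protein": 1.5, "phe": 1.5, "lipid": 0.6,
                     "lipid_twist": 0.6, "water": 0.5},
            cytc_marker=0.4),
        "mitochondria": CompartmentSpec(
            weights={"protein": 1.0, "phe": 1.0, "lipid": 1.0,
                     "lipid_twist": 1.0, "water": 0.4},
            cytc_marker=2.0),
    }


@dataclass
class PhantomConfig:
    """Configuration of a single-cell (or tissue) phantom.

    Geometry is parametric (ellipse nucleus, annular membrane rim,
    seeded mitochondrial blobs) so that ground truth is exact.  Defaults
    reproduce the cell area-scan acquisition: 0.5 um step, 0.3 s dwell,
    noise floor 7.5 counts at that dwell.
    """

    shape: tuple[int, int] = (40, 40)
    step_um: float = 0.5
    axis_start: float = 400.0
    axis_stop: float = 1800.0
    axis_step: float = 1.0
    dwell: float = REFERENCE_DWELL
    compartments: dict[str, CompartmentSpec] = field(
        default_factory=_default_compartments)
    cell_radii: tuple[float, float] = (0.40, 0.34)   # fractions of (H, W)
    nucleus_radii: tuple[float, float] = (0.16, 0.13)
    nucleus_offset: tuple[float, float] = (-0.05, 0.04)
    membrane_rim_px: float = 1.5
    mito_blobs: int = 6
    mito_radius_px: float = 1.8
    weight_jitter: float = 0.02
    noise_floor: float = DEFAULT_NOISE_FLOOR
    baseline_amplitude: float = 40.0    # counts at the reference dwell
    cosmic_ray_rate: float = 0.01
    sensitivity: float = DEFAULT_SENSITIVITY
    isotope_variant: str = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.axis_stop <= self.axis_start or self.axis_step <= 0:
            raise ValueError("axis must be strictly increasing")
        if self.noise_floor < 0 or self.cosmic_ray_rate < 0:
            raise ValueError("noise floor and cosmic-ray rate must be >= 0")
        unknown = set(self.compartments) - set(COMPARTMENTS)
        if unknown:
            raise ValueError(f"unknown compartments {sorted(unknown)}")

    @property
    def wavenumbers(self) -> np.ndarray:
        return default_axis(self.axis_start, self.axis_stop, self.axis_step)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["compartments"] = {k: asdict(v) for k, v in self.compartments.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        d = dict(d)
        comps = {
            k: CompartmentSpec(
                weights=dict(v["weights"]),
                fumarate_mm=tuple(v.get("fumarate_mm", (0.0, 0.0))),
                confounder_mm=tuple(v.get("confounder_mm", (0.0, 0.0))),
                cytc_marker=float(v.get("cytc_marker", 0.0)),
            )
            for k, v in d.pop("compartments", {}).items()
        } or _default_compartments()
        known = {f.name for f in fields(cls)} - {"compartments"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        for key in ("shape", "cell_radii", "nucleus_radii", "nucleus_offset"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(compartments=comps, **d)


#: Fh1 cell-line presets: true fumarate means (mM) per compartment.
_PRESET_TRUE_MM = {
    "WT": {"substrate": 0, "nucleus": 0, "membrane": 0,
           "cytoplasm": 0, "mitochondria": 0},
    "KO1": {"substrate": 2, "nucleus": 4, "membrane": 4,
            "cytoplasm": 5, "mitochondria": 1},
    "KO19": {"substrate": 1, "nucleus": 5, "membrane": 10,
             "cytoplasm": 18, "mitochondria": 27},
}
#: Confounder (cytochrome-C redox pair) in fumarate-equivalent mM, equal
#: for all cell lines: it is what the FH-proficient control measures.
_PRESET_CONFOUNDER_MM = {"substrate": 2, "nucleus": 4, "membrane": 4,
                         "cytoplasm": 6, "mitochondria": 10}
#: Per-line compositional phenotype: clonal lines differ modestly in
#: lipid/protein/nucleic-acid content beyond fumarate itself (FH loss
#: reprograms metabolism and KO cells show generally higher Raman
#: intensities), and FH-deficient clones carry less respiratory-chain
#: cytochrome-C.  Multipliers on the background component weights and on
#: the mitochondrial cytochrome-C marker strength.
_PRESET_COMPOSITION = {
    "WT": {},
    "KO1": {"dna": 1.3, "lipid": 1.15, "lipid_twist": 1.25, "protein": 0.9,
            "phe": 1.2},
    "KO19": {"lipid": 1.3, "lipid_twist": 1.6, "protein": 0.9, "dna": 0.75,
             "phe": 0.8},
}
#: Biomass fraction per voxel relative to WT (applied to all biological
#: components but not to water/substrate signal): KO lines are denser,
#: giving the globally higher Raman intensities seen in their spectra.
_PRESET_BIOMASS = {"WT": 1.0, "KO1": 1.25, "KO19": 1.1}
_PRESET_CYTC_MARKER = {"WT": 1.0, "KO1": 0.75, "KO19": 0.6}
_BIO_COMPONENTS = ("protein", "phe", "lipid", "lipid_twist", "dna")


def cell_phantom_config(preset: str = "KO19", seed: int = 0,
                        rel_sd: float = 0.2, **overrides) -> PhantomConfig:
    """Phantom configuration for one of the Fh1 cell-line presets.

    True and confounder concentrations are drawn per pixel from
    N(mean, (rel_sd * mean)^2) truncated at zero; apparent compartment
    means then reproduce the reference compartment table by construction
    (apparent = true + confounder).
    """
    if preset not in _PRESET_TRUE_MM:
        raise ValueError(f"unknown preset {preset!r}; "
                         f"allowed: {sorted(_PRESET_TRUE_MM)}")
    comps = _default_compartments()
    composition = _PRESET_COMPOSITION[preset]
    for name, spec in comps.items():
        t = float(_PRESET_TRUE_MM[preset][name])
        c = float(_PRESET_CONFOUNDER_MM[name])
        spec.fumarate_mm = (t, rel_sd * t)
        spec.confounder_mm = (c, rel_sd * c)
        biomass = _PRESET_BIOMASS[preset]
        spec.weights = {
            comp: w * composition.get(comp, 1.0)
            * (biomass if comp in _BIO_COMPONENTS else 1.0)
            for comp, w in spec.weights.items()
        }
        spec.cytc_marker *= _PRESET_CYTC_MARKER[preset] * biomass
    return PhantomConfig(compartments=comps, seed=seed, **overrides)


# ---------------------------------------------------------------------------
# Ground truth and phantom rendering
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Per-pixel truth for a generated phantom."""

    labels: np.ndarray            # (H, W) int compartment ids
    label_names: tuple[str, ...]  # id -> compartment name
    concentration: np.ndarray     # (H, W) true fumarate, mM
    confounder: np.ndarray        # (H, W) fumarate-equivalent mM

    def mask(self, name: str) -> np.ndarray:
        return self.labels == self.label_names.index(name)


def _cell_geometry(config: PhantomConfig, rng: np.random.Generator
                   ) -> np.ndarray:
    """Partition the grid into the five compartments (one label/pixel)."""
    h, w = config.shape
    rows, cols = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ry, rx = config.cell_radii[0] * h, config.cell_radii[1] * w
    r_cell = np.sqrt(((rows - cy) / ry) ** 2 + ((cols - cx) / rx) ** 2)
    labels = np.zeros((h, w), dtype=int)           # substrate
    inside = r_cell <= 1.0
    labels[inside] = COMPARTMENTS.index("cytoplasm")
    # membrane: annular rim of configured thickness (in pixels, approx)
    rim = config.membrane_rim_px / min(ry, rx)
    membrane = inside & (r_cell >= 1.0 - rim)
    labels[membrane] = COMPARTMENTS.index("membrane")
    # nucleus: offset ellipse
    ny = cy + config.nucleus_offset[0] * h
    nx = cx + config.nucleus_offset[1] * w
    nry, nrx = config.nucleus_radii[0] * h, config.nucleus_radii[1] * w
    r_nuc = np.sqrt(((rows - ny) / nry) ** 2 + ((cols - nx) / nrx) ** 2)
    nucleus = (r_nuc <= 1.0) & inside & ~membrane
    labels[nucleus] = COMPARTMENTS.index("nucleus")
    # mitochondria: seeded circular blobs inside the cytoplasm
    cyto_idx = np.argwhere(labels == COMPARTMENTS.index("cytoplasm"))
    n_blobs = min(config.mito_blobs, len(cyto_idx))
    if n_blobs:
        centers = cyto_idx[rng.choice(len(cyto_idx), size=n_blobs,
                                      replace=False)]
        mito = np.zeros((h, w), dtype=bool)
        for by, bx in centers:
            d = np.sqrt((rows - by) ** 2 + (cols - bx) ** 2)
            mito |= d <= config.mito_radius_px
        mito &= labels == COMPARTMENTS.index("cytoplasm")
        labels[mito] = COMPARTMENTS.index("mitochondria")
    return labels


def _random_baseline(wn: np.ndarray, n: int, amplitude: float,
                     rng: np.random.Generator,
                     scale: np.ndarray | None = None,
                     pixel_jitter: float = 0.05) -> np.ndarray:
    """Smooth random cubic fluorescence baselines, (n, channels).

    One cubic shape is drawn per scan (fluorescence background shares
    its spectral shape across a map); ``scale`` modulates the amplitude
    per spectrum (fluorescence tracks the amount of material in the
    focal volume), with a small jitter on the coefficients.
    """
    if amplitude <= 0:
        return np.zeros((n, wn.size))
    x = (wn - wn[0]) / (wn[-1] - wn[0])
    # canonical autofluorescence shape: smooth decay towards higher
    # wavenumbers; scans share the shape with a moderate jitter
    canonical = np.array([1.0, -0.9, 0.35, -0.1])
    base_coeffs = canonical * (1.0 + 0.05 * rng.standard_normal(4))
    coeffs = base_coeffs[None, :] * (
        1.0 + pixel_jitter * rng.standard_normal((n, 4)))
    if scale is None:
        scale = np.ones(n)
    scale = scale * rng.uniform(0.9, 1.1, size=n)
    V = np.vander(x, 4, increasing=True)
    base = (coeffs * scale[:, None]) @ V.T
    return amplitude * np.clip(base, 0.0, None)


def _add_cosmic_rays(counts: np.ndarray, rate: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Single-channel spikes, 20-100x the local level, per-spectrum
    Bernoulli(rate)."""
    if rate <= 0:
        return counts
    n, c = counts.shape
    hit = rng.random(n) < rate
    for i in np.flatnonzero(hit):
        ch = rng.integers(0, c)
        local = max(abs(counts[i, ch]), 10.0)
        counts[i, ch] += local * rng.uniform(20.0, 100.0)
    return counts


def _truncated_normal(mean: np.ndarray, sd: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    draw = rng.normal(mean, sd)
    return np.clip(draw, 0.0, None)


def generate_cell_phantom(config: PhantomConfig,
                          library: ComponentLibrary | None = None
                          ) -> tuple[SpectralMap, GroundTruth]:
    """Render a single-cell phantom and its exact ground truth.

    Each pixel spectrum is the compartment-weighted sum of background
    components, plus fumarate bands at the pixel's true concentration,
    plus the cytochrome-C confounder at its fumarate-equivalent
    concentration, plus a random cubic baseline, Gaussian noise and
    cosmic-ray spikes.
    """
    wn = config.wavenumbers
    lib = library if library is not None else build_component_library(
        config.isotope_variant, config.sensitivity, wn)
    for name, spec in config.compartments.items():
        unknown = set(spec.weights) - set(lib.components)
        if unknown:
            raise ValueError(
                f"compartment {name!r} references unknown components "
                f"{sorted(unknown)}"
            )
    rng = np.random.default_rng(config.seed)
    labels = _cell_geometry(config, rng)
    h, w = config.shape
    n = h * w
    flat_labels = labels.reshape(-1)

    # per-unit component spectra (1 s dwell)
    comp_names = sorted({c for s in config.compartments.values()
                         for c in s.weights})
    comp_matrix = (np.stack([lib.render(c, wn) for c in comp_names])
                   if comp_names else np.zeros((0, wn.size)))
    fum_unit = lib.render("fumarate_solution", wn)
    conf_unit = lib.render("cytc_redox", wn)
    marker_unit = lib.render("cytc_marker", wn)

    weights = np.zeros((n, len(comp_names)))
    marker_w = np.zeros(n)
    conc = np.zeros(n)
    confounder = np.zeros(n)
    for cid, cname in enumerate(COMPARTMENTS):
        mask = flat_labels == cid
        if not mask.any():
            continue
        spec = config.compartments[cname]
        base_w = np.array([spec.weights.get(c, 0.0) for c in comp_names])
        # within-compartment variability: a common-mode focal-volume
        # factor (small pixel-to-pixel within one cell) plus a small
        # independent composition jitter
        common = 1.0 + 0.05 * rng.standard_normal((mask.sum(), 1))
        jitter = common * (1.0 + config.weight_jitter * rng.standard_normal(
            (mask.sum(), len(comp_names))))
        weights[mask] = np.clip(base_w[None, :] * jitter, 0.0, None)
        marker_w[mask] = spec.cytc_marker * np.clip(
            common[:, 0] * (1.0 + config.weight_jitter
                            * rng.standard_normal(mask.sum())),
            0.0, None)
        m, s = spec.fumarate_mm
        conc[mask] = _truncated_normal(np.full(mask.sum(), float(m)),
                                       float(s), rng)
        m, s = spec.confounder_mm
        confounder[mask] = _truncated_normal(np.full(mask.sum(), float(m)),
                                             float(s), rng)

    counts = weights @ comp_matrix
    counts += conc[:, None] * fum_unit[None, :]
    counts += confounder[:, None] * conf_unit[None, :]
    counts += marker_w[:, None] * marker_unit[None, :]
    counts *= config.dwell
    material = weights.sum(axis=1) + marker_w
    mat_scale = material / material.mean() if material.mean() > 0 \
        else np.ones(n)
    counts += _random_baseline(
        wn, n, config.baseline_amplitude * config.dwell / REFERENCE_DWELL,
        rng, scale=mat_scale)
    noise_sd = config.noise_floor * np.sqrt(config.dwell / REFERENCE_DWELL)
    if noise_sd > 0:
        counts += rng.normal(0.0, noise_sd, size=counts.shape)
    counts = _add_cosmic_rays(counts, config.cosmic_ray_rate, rng)

    smap = SpectralMap(wn, counts.reshape(h, w, wn.size),
                       step_um=config.step_um, dwell=config.dwell,
                       meta={"source": "synthetic-cell", "seed": config.seed})
    truth = GroundTruth(labels=labels, label_names=COMPARTMENTS,
                        concentration=conc.reshape(h, w),
                        confounder=confounder.reshape(h, w))
    return smap, truth


# ---------------------------------------------------------------------------
# Tissue phantoms
# ---------------------------------------------------------------------------

#: Tissue fumarate (mean, sd) mM per genotype; the Fh1-null sections
#: accumulate fumarate well above the ~8 mM LOD (up to ~40 mM), the
#: floxed controls stay below it.
_TISSUE_FUMARATE_MM = {"fl/fl": (3.0, 2.0), "-/-": (25.0, 8.0)}


def generate_tissue_phantom(genotype: str, config: PhantomConfig | None = None,
                            library: ComponentLibrary | None = None
                            ) -> tuple[SpectralMap, GroundTruth]:
    """Kidney-tissue-section phantom for one genotype.

    On-tissue pixels carry a protein/lipid matrix, the 1130 cm^-1
    outline band and fumarate per genotype; off-tissue pixels carry only
    substrate signal.  Labels: 0 = off-tissue, 1 = tissue.
    """
    if genotype not in _TISSUE_FUMARATE_MM:
        raise ValueError(
            f"unknown genotype {genotype!r}; allowed: 'fl/fl', '-/-'")
    config = config if config is not None else PhantomConfig()
    wn = config.wavenumbers
    lib = library if library is not None else build_component_library(
        config.isotope_variant, config.sensitivity, wn)
    rng = np.random.default_rng(config.seed)
    h, w = config.shape
    rows, cols = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ry, rx = config.cell_radii[0] * h, config.cell_radii[1] * w
    # irregular tissue boundary: ellipse modulated by a random harmonic
    theta = np.arctan2(rows - cy, cols - cx)
    wobble = 1.0 + 0.15 * np.sin(2 * theta + rng.uniform(0, 2 * np.pi)) \
        + 0.1 * np.sin(3 * theta + rng.uniform(0, 2 * np.pi))
    r = np.sqrt(((rows - cy) / ry) ** 2 + ((cols - cx) / rx) ** 2)
    tissue = r <= wobble
    n = h * w
    flat_tissue = tissue.reshape(-1)

    matrix = (0.8 * lib.render("protein", wn) + 0.5 * lib.render("lipid", wn)
              + 0.4 * lib.render("water", wn) + lib.render("tissue_marker", wn))
    substrate = lib.render("quartz", wn) + 0.4 * lib.render("water", wn)
    fum_unit = lib.render("fumarate_solution", wn)

    mean_mm, sd_mm = _TISSUE_FUMARATE_MM[genotype]
    conc = np.zeros(n)
    conc[flat_tissue] = _truncated_normal(
        np.full(flat_tissue.sum(), mean_mm), sd_mm, rng)

    jitter = np.clip(1.0 + config.weight_jitter
                     * rng.standard_normal(n), 0.0, None)
    counts = np.where(flat_tissue[:, None], matrix[None, :],
                      substrate[None, :]) * jitter[:, None]
    counts = counts + conc[:, None] * fum_unit[None, :]
    counts *= config.dwell
    baseline_scale = np.where(flat_tissue, 1.0, 0.4)
    counts += _random_baseline(
        wn, n, config.baseline_amplitude * config.dwell / REFERENCE_DWELL,
        rng, scale=baseline_scale)
    noise_sd = config.noise_floor * np.sqrt(config.dwell / REFERENCE_DWELL)
    if noise_sd > 0:
        counts += rng.normal(0.0, noise_sd, size=counts.shape)
    counts = _add_cosmic_rays(counts, config.cosmic_ray_rate, rng)

    smap = SpectralMap(wn, counts.reshape(h, w, wn.size),
                       step_um=config.step_um, dwell=config.dwell,
                       meta={"source": "synthetic-tissue",
                             "genotype": genotype, "seed": config.seed})
    truth = GroundTruth(labels=tissue.astype(int),
                        label_names=("off_tissue", "tissue"),
                        concentration=conc.reshape(h, w),
                        confounder=np.zeros((h, w)))
    return smap, truth


# ---------------------------------------------------------------------------
# Labelled line-scan dataset for classification
# ---------------------------------------------------------------------------

def _linescan_profile(points: int, rng: np.random.Generator) -> list[str]:
    """Compartment sequence along a line through the major cell axis:
    membrane at both ends, a central nucleus run, mitochondria scattered
    in the cytoplasm."""
    if points == 1:
        return ["cytoplasm"]
    profile = ["cytoplasm"] * points
    profile[0] = "membrane"
    profile[-1] = "membrane"
    if points >= 10:
        # fixed per-scan composition (standardised major-axis scans cross
        # anatomically similar fractions); only positions vary
        nuc_len = max(1, round(points * 0.3))
        start = (points - nuc_len) // 2 + int(rng.integers(-1, 2))
        for i in range(start, start + nuc_len):
            if 0 < i < points - 1:
                profile[i] = "nucleus"
        cyto_pos = [i for i, p in enumerate(profile) if p == "cytoplasm"]
        n_mito = min(2, len(cyto_pos))
        for i in rng.choice(cyto_pos, size=n_mito, replace=False):
            profile[i] = "mitochondria"
    return profile


def generate_linescan_dataset(n_per_class: int | dict = 30,
                              points_per_scan: int = 20,
                              presets: dict[str, PhantomConfig] | None = None,
                              dwell: float = 5.0, seed: int = 0,
                              cosmic_ray_rate: float | None = None
                              ) -> LabelledSpectra:
    """Labelled spectra from line scans through cells of the three lines.

    Defaults match the classifier acquisition: 20 steps per scan at 5 s
    dwell.  ``n_per_class`` scans per class (an int, or a mapping class
    name -> count) yields ``n_per_class * points_per_scan`` spectra per
    class, labelled WT / KO1 / KO19, in acquisition order.
    """
    if presets is None:
        presets = {name: cell_phantom_config(name, dwell=dwell)
                   for name in ("WT", "KO1", "KO19")}
    if not isinstance(n_per_class, dict):
        n_per_class = {name: int(n_per_class) for name in presets}
    if min(n_per_class.values()) < 1 or points_per_scan < 1:
        raise ValueError("n_per_class and points_per_scan must be >= 1")
    rng = np.random.default_rng(seed)
    first = next(iter(presets.values()))
    wn = first.wavenumbers
    lib = build_component_library(first.isotope_variant, first.sensitivity, wn)
    comp_names = sorted({c for cfg in presets.values()
                         for s in cfg.compartments.values()
                         for c in s.weights})
    comp_matrix = np.stack([lib.render(c, wn) for c in comp_names])
    fum_unit = lib.render("fumarate_solution", wn)
    conf_unit = lib.render("cytc_redox", wn)
    marker_unit = lib.render("cytc_marker", wn)

    X_rows, labels = [], []
    for cls_name, cfg in presets.items():
        rate = cfg.cosmic_ray_rate if cosmic_ray_rate is None \
            else cosmic_ray_rate
        for _ in range(n_per_class[cls_name]):
            profile = _linescan_profile(points_per_scan, rng)
            # focal-volume factors: one per cell (scan) times a small
            # per-point term, shared by bands and fluorescence so that
            # each is a pure scale of its spectrum
            commons = (1.0 + 0.10 * rng.standard_normal()) * (
                1.0 + 0.04 * rng.standard_normal(len(profile)))
            scan_baselines = _random_baseline(
                wn, len(profile),
                cfg.baseline_amplitude * dwell / REFERENCE_DWELL, rng,
                scale=commons)
            for point, comp in enumerate(profile):
                spec = cfg.compartments[comp]
                base_w = np.array([spec.weights.get(c, 0.0)
                                   for c in comp_names])
                common = commons[point]
                jit = np.clip(common * (1.0 + cfg.weight_jitter
                              * rng.standard_normal(len(comp_names))),
                              0.0, None)
                counts = (base_w * jit) @ comp_matrix
                m, s = spec.fumarate_mm
                conc = float(_truncated_normal(np.array(float(m)),
                                               float(s), rng))
                m, s = spec.confounder_mm
                conf = float(_truncated_normal(np.array(float(m)),
                                               float(s), rng))
                marker = spec.cytc_marker * max(
                    0.0, common * (1.0 + cfg.weight_jitter
                                   * rng.standard_normal()))
                counts = counts + conc * fum_unit + conf * conf_unit \
                    + marker * marker_unit
                counts *= dwell
                counts += scan_baselines[point]
                noise_sd = cfg.noise_floor * np.sqrt(dwell / REFERENCE_DWELL)
                if noise_sd > 0:
                    counts += rng.normal(0.0, noise_sd, size=wn.shape)
                counts = _add_cosmic_rays(counts[None, :], rate, rng)[0]
                X_rows.append(counts)
                labels.append(cls_name)
    return LabelledSpectra(np.array(X_rows), np.array(labels), wn,
                           dwell=dwell,
                           meta={"source": "synthetic-linescan",
                                 "seed": seed})
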