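"""Synthetic NIR spectral libraries for testing the calibration workflow.

The generator emulates a multi-manufacturer, multi-dosage-form library of
amoxicillin / potassium clavulanate products.  Each sample spectrum is a
Beer–Lambert-style linear mixture of pure-component spectra (amoxicillin,
clavulanate, water, and one dosage-form-family excipient class), built
from sums of Gaussian absorption bands on the canonical grid.  Amoxicillin
bands sit in the regions where the drug absorbs (8,300–9,500 cm⁻¹ C–H
overtones; 5,300–6,500 and 4,200–4,800 cm⁻¹ C=O overtones); water bands
sit near the 5,200 and 7,000 cm⁻¹ O–H combination/overtone bands.

Replicate acquisitions add the artifacts diffuse reflectance actually
shows — an additive baseline offset, a linear slope, a multiplicative
scatter factor, and pointwise noise — *before* preprocessing, so the
derivative/normalization chain is genuinely exercised.

Tablet-family and granule-family samples use different excipient classes
and different assay sub-ranges, so the two families form visibly distinct
spectral classes and each dosage form occupies its own r_T band, mirroring
the wide r_T spread a real heterogeneous library shows.

All randomness flows from the spec's single seed; per-sample substreams
are derived by stable hashing of the sample_id, so any sample can be
regenerated independently.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, ValidationError
from .library import LibraryEntry, SpectralLibrary, index_library
from .preprocess import PreprocessConfig, preprocess_spectrum
from .spectra import CANONICAL_GRID, DOSAGE_FORMS, ReferenceAssay, Spectrum

__all__ = [
    "GeneratorSpec",
    "pure_component_spectrum",
    "generate_sample",
    "generate_library",
]

#: Library composition emulating a heterogeneous multi-manufacturer library.
DEFAULT_N_PER_FORM = {
    "tablet": 74,
    "dispersible_tablet": 78,
    "chewable_tablet": 10,
    "granule": 96,
    "oral_suspension": 120,
}

#: Global assay ranges (% m/m) of the emulated library.
DEFAULT_CONCENTRATION_RANGES = {
    "amoxicillin": (4.77, 57.86),
    "clavulanate": (1.03, 20.17),
    "water": (0.24, 9.30),
}

# Per-form assay sub-ranges: strengths differ systematically by dosage
# form (tablets concentrated, suspensions dilute) but span wide,
# overlapping bands — manufacturers market many strengths of the same
# form — which spreads each form over its own broad r_T band.
FORM_ASSAY_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "tablet": {"amoxicillin": (25.0, 57.86), "clavulanate": (6.0, 20.17), "water": (0.24, 3.0)},
    "dispersible_tablet": {"amoxicillin": (20.0, 50.0), "clavulanate": (5.0, 16.0), "water": (0.5, 3.5)},
    "chewable_tablet": {"amoxicillin": (15.0, 45.0), "clavulanate": (4.0, 13.0), "water": (1.0, 4.0)},
    "granule": {"amoxicillin": (8.0, 30.0), "clavulanate": (2.0, 9.0), "water": (3.0, 7.0)},
    "oral_suspension": {"amoxicillin": (4.77, 20.0), "clavulanate": (1.03, 6.0), "water": (4.0, 9.30)},
    "capsule_granule": {"amoxicillin": (10.0, 32.0), "clavulanate": (3.0, 10.0), "water": (2.0, 6.0)},
}

#: Excipient class per dosage form; tablet-family forms share classes 0–1,
#: granule-family forms use classes 2–3 (distinct band placements).
FORM_EXCIPIENT_CLASS = {
    "tablet": 0,
    "dispersible_tablet": 0,
    "chewable_tablet": 1,
    "granule": 2,
    "oral_suspension": 3,
    "capsule_granule": 2,
}

COMPONENTS = (
    "amoxicillin",
    "clavulanate",
    "water",
    "excipient_class_0",
    "excipient_class_1",
    "excipient_class_2",
    "excipient_class_3",
)

# Band-placement windows per component (low, high, n_bands).  API and
# water windows follow the known absorption regions; excipient classes
# are built from a shared family base (tablet-family classes 0–1 vs
# granule-family classes 2–3) plus smaller class-specific bands, so
# within-family spectral distances stay well below between-family ones
# over the 4,200–10,000 cm⁻¹ similarity region.
_BAND_WINDOWS: dict[str, list[tuple[float, float, int]]] = {
    "amoxicillin": [(8300, 9500, 4), (5300, 6500, 4), (4200, 4800, 3)],
    "clavulanate": [(7800, 8300, 2), (5900, 6300, 2), (4300, 4900, 3), (6600, 7000, 2)],
    "water": [(5100, 5350, 2), (6850, 7150, 2)],
    "excipient_class_0": [(4400, 5200, 2), (6200, 7200, 2), (8200, 9200, 2)],
    "excipient_class_1": [(4300, 5100, 2), (6000, 7000, 2), (8400, 9400, 2)],
    "excipient_class_2": [(5400, 6400, 2), (7200, 8400, 2), (9400, 10600, 2)],
    "excipient_class_3": [(5600, 6600, 2), (7400, 8600, 2), (9600, 10800, 2)],
}

#: shared base windows per excipient family (tablet-like vs granule-like)
_FAMILY_BASE_WINDOWS: dict[str, list[tuple[float, float, int]]] = {
    "tablet_family": [(4400, 5200, 3), (6100, 7200, 3), (8200, 9400, 3)],
    "granule_family": [(5400, 6500, 3), (7300, 8500, 3), (9400, 10800, 3)],
}

#: weight of the class-specific bands on top of the family base spectrum
_CLASS_BAND_WEIGHT = 0.7


@dataclass(frozen=True)
class GeneratorSpec:
    """Stated world of the synthetic library.

    noise_rel_sd : float
        Pointwise Gaussian noise SD relative to the signal scale
        (default 0.5% — instrument-grade FT-NIR repeatability).
    baseline_sd, slope_sd, scatter_sd : float
        Per-replicate additive offset SD (absorbance units), linear slope
        SD (absorbance per cm⁻¹), and multiplicative scatter factor SD.
    """

    n_per_form: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_N_PER_FORM)
    )
    concentration_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CONCENTRATION_RANGES)
    )
    noise_rel_sd: float = 0.005
    baseline_sd: float = 0.02
    slope_sd: float = 3e-6
    scatter_sd: float = 0.02
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for form, count in self.n_per_form.items():
            if form not in DOSAGE_FORMS:
                raise ValidationError(f"unknown dosage form {form!r}")
            if count < 0:
                raise ValidationError(f"negative count for {form!r}")
        for analyte, (lo, hi) in self.concentration_ranges.items():
            if not (0.0 <= lo < hi <= 100.0):
                raise ValidationError(
                    f"{analyte} range ({lo}, {hi}) not within [0, 100]"
                )
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")

    def to_json(self) -> dict:
        return {
            "n_per_form": dict(self.n_per_form),
            "concentration_ranges": {
                k: list(v) for k, v in self.concentration_ranges.items()
            },
            "noise_rel_sd": self.noise_rel_sd,
            "baseline_sd": self.baseline_sd,
            "slope_sd": self.slope_sd,
            "scatter_sd": self.scatter_sd,
            "n_replicates": self.n_replicates,
            "seed": self.seed,
        }


def _substream(*parts) -> np.random.Generator:
    """Deterministic child generator from a stable hash of the parts."""
    digest = hashlib.sha256("|".join(str(p) for p in parts).encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


def pure_component_spectrum(component: str, seed: int = 0) -> Spectrum:
    """Pure-component absorbance spectrum: a nonnegative sum of Gaussians.

    Deterministic per (component, seed).  Band centers are drawn inside
    the component's characteristic windows; a broad low-amplitude
    background keeps the spectrum realistic and strictly nonnegative.
    """
    if component not in _BAND_WINDOWS:
        raise ValidationError(
            f"unknown component {component!r}; expected one of {COMPONENTS}"
        )
    rng = _substream("component", component, seed)
    grid = CANONICAL_GRID

    def _bands(windows, generator, scale=1.0):
        out = np.zeros_like(grid)
        for lo, hi, n_bands in windows:
            centers = generator.uniform(lo, hi, size=n_bands)
            heights = generator.uniform(0.3, 1.0, size=n_bands) * scale
            widths = generator.uniform(60.0, 220.0, size=n_bands)
            for c, h, w in zip(centers, heights, widths):
                out += h * np.exp(-0.5 * ((grid - c) / w) ** 2)
        return out

    if component.startswith("excipient_class_"):
        family = (
            "tablet_family"
            if component in ("excipient_class_0", "excipient_class_1")
            else "granule_family"
        )
        base_rng = _substream("family-base", family, seed)
        spectrum = _bands(_FAMILY_BASE_WINDOWS[family], base_rng)
        spectrum += _bands(_BAND_WINDOWS[component], rng, scale=_CLASS_BAND_WEIGHT)
    else:
        spectrum = _bands(_BAND_WINDOWS[component], rng)
    # broad background hump
    bg_center = rng.uniform(6000, 9000)
    spectrum += 0.15 * np.exp(-0.5 * ((grid - bg_center) / 2500.0) ** 2)
    return Spectrum(
        wavenumbers=grid.copy(),
        absorbance=spectrum,
        sample_id=f"pure:{component}",
    )


#: weight of the manufacturer-specific excipient variant in the blend;
#: adds the mild house-to-house excipient variability real libraries
#: show (kept small — the dominant spectral variation is compositional)
MANUFACTURER_EXCIPIENT_WEIGHT = 0.07


def _excipient_spectrum(exc_class: str, manufacturer: str, seed: int) -> np.ndarray:
    """Excipient blend of one manufacturer: class spectrum + house variant."""
    base = pure_component_spectrum(exc_class, seed).absorbance
    if not manufacturer:
        return base
    rng = _substream("excipient-variant", exc_class, manufacturer, seed)
    grid = CANONICAL_GRID
    variant = np.zeros_like(grid)
    centers = rng.uniform(4200, 10800, size=6)
    heights = rng.uniform(0.3, 1.0, size=6)
    widths = rng.uniform(80.0, 300.0, size=6)
    for c, h, w in zip(centers, heights, widths):
        variant += h * np.exp(-0.5 * ((grid - c) / w) ** 2)
    w = MANUFACTURER_EXCIPIENT_WEIGHT
    return (1.0 - w) * base + w * variant


def _ideal_mixture(
    form: str, assay: ReferenceAssay, seed: int, manufacturer: str = ""
) -> np.ndarray:
    f_amox = (assay.amoxicillin_pct or 0.0) / 100.0
    f_clav = (assay.clavulanate_pct or 0.0) / 100.0
    f_water = (assay.water_pct or 0.0) / 100.0
    f_exc = 1.0 - f_amox - f_clav - f_water
    if f_exc < 0:
        raise ValidationError(
            f"assay fractions exceed 100% for form {form!r}"
        )
    exc = f"excipient_class_{FORM_EXCIPIENT_CLASS[form]}"
    parts = (
        f_amox * pure_component_spectrum("amoxicillin", seed).absorbance
        + f_clav * pure_component_spectrum("clavulanate", seed).absorbance
        + f_water * pure_component_spectrum("water", seed).absorbance
        + f_exc * _excipient_spectrum(exc, manufacturer, seed)
    )
    return parts


def generate_sample(
    form: str,
    assay: ReferenceAssay,
    spec: GeneratorSpec,
    draw: np.random.Generator,
    manufacturer: str = "",
) -> tuple[list[Spectrum], ReferenceAssay]:
    """Replicate spectra for one sample of a dosage form at a given assay.

    The ideal spectrum is the linear component mixture (with the
    manufacturer's excipient blend when a manufacturer is named); each
    replicate then receives an additive baseline offset, a linear slope,
    a multiplicative scatter factor, and pointwise Gaussian noise scaled
    by the signal's standard deviation.
    """
    if form not in DOSAGE_FORMS:
        raise ValidationError(f"unknown dosage form {form!r}")
    ideal = _ideal_mixture(form, assay, spec.seed, manufacturer)
    scale = float(ideal.std())
    grid = CANONICAL_GRID
    centered_nu = grid - grid.mean()
    replicates = []
    for rep in range(spec.n_replicates):
        baseline = draw.normal(0.0, spec.baseline_sd)
        slope = draw.normal(0.0, spec.slope_sd)
        scatter = draw.normal(1.0, spec.scatter_sd)
        noise = draw.normal(0.0, spec.noise_rel_sd * scale, size=grid.size)
        values = scatter * ideal + baseline + slope * centered_nu + noise
        replicates.append(
            Spectrum(
                wavenumbers=grid.copy(),
                absorbance=values,
                dosage_form=form,
                replicate_index=rep,
            )
        )
    return replicates, assay


def _draw_assay(form: str, rng: np.random.Generator, spec: GeneratorSpec) -> ReferenceAssay:
    sub = FORM_ASSAY_RANGES[form]
    vals = {}
    for analyte, (g_lo, g_hi) in spec.concentration_ranges.items():
        lo, hi = sub.get(analyte, (g_lo, g_hi))
        lo, hi = max(lo, g_lo), min(hi, g_hi)
        vals[analyte] = float(rng.uniform(lo, hi))
    return ReferenceAssay(
        amoxicillin_pct=vals.get("amoxicillin"),
        clavulanate_pct=vals.get("clavulanate"),
        water_pct=vals.get("water"),
    )


def generate_library(spec: GeneratorSpec) -> SpectralLibrary:
    """Generate, preprocess, and r_T-index a full synthetic library.

    Per-form sample counts and assay ranges follow the spec; every
    sample's replicates are averaged and taken through the standard
    pretreatment chain; the reference spectrum is the tablet mean and the
    whole library is indexed over the default 4,200–10,000 cm⁻¹ region.
    Fully reproducible from ``spec.seed``.
    """
    if spec.n_per_form.get("tablet", 0) == 0:
        raise ConfigurationError(
            "default reference policy needs at least one tablet entry"
        )
    cfg = PreprocessConfig()
    entries: list[LibraryEntry] = []
    for form in DOSAGE_FORMS:
        count = spec.n_per_form.get(form, 0)
        for i in range(count):
            sid = f"{form}-{i:03d}"
            rng = _substream("sample", sid, spec.seed)
            manufacturer = f"mfr-{rng.integers(1, 27):02d}"
            assay = _draw_assay(form, rng, spec)
            reps, assay = generate_sample(form, assay, spec, rng, manufacturer)
            reps = [
                Spectrum(
                    wavenumbers=r.wavenumbers,
                    absorbance=r.absorbance,
                    sample_id=sid,
                    dosage_form=form,
                    manufacturer=manufacturer,
                    batch=f"batch-{i:03d}",
                    replicate_index=r.replicate_index,
                )
                for r in reps
            ]
            processed = preprocess_spectrum(reps, cfg)
            entries.append(
                LibraryEntry(spectrum=processed, assay=assay, raw_replicates=reps)
            )
    lib = SpectralLibrary(entries=entries, preprocess=cfg)
    return index_library(lib)
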