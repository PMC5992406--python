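"""Spectral library construction and r_T similarity indexing.

The library's similarity index r_T between two spectra y1(k), y2(k) is the
ratio of their covariance to the product of their standard deviations,
computed over a fixed wavenumber region (default 4,200–10,000 cm⁻¹):

    r_T = Cov(y1, y2) / (sigma_y1 * sigma_y2)

r_T ranges from −1 (inverted spectra) to +1 (identical spectra) and is
conventionally reported as a percentage.  Every entry of a
:class:`SpectralLibrary` is indexed against a single reference spectrum —
by default the mean preprocessed spectrum of the plain tablets — so that
sorting the library by r_T orders it by spectral similarity to the
tablet class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import (
    DegenerateInputError,
    EmptySelectionError,
    ValidationError,
)
from .preprocess import PreprocessConfig
from .spectra import (
    ReferenceAssay,
    Spectrum,
    WavenumberRegions,
    read_assay_manifest,
    read_spectra_table,
    write_assay_manifest,
    write_spectra_table,
)
from .spectra import RT_REGION

__all__ = [
    "LibraryEntry",
    "SpectralLibrary",
    "correlation_coefficient",
    "build_reference_spectrum",
    "index_library",
    "save_library",
    "load_library",
]


def correlation_coefficient(
    s1: Spectrum, s2: Spectrum, region: WavenumberRegions | None = None
) -> float:
    """r_T between two spectra over a wavenumber region.

    Population (1/n) moments are used; the convention cancels in the
    ratio.  Both spectra must share a common grid and have nonzero
    variance over the region.

    Returns the coefficient as a ratio in [−1, 1] (multiply by 100 for
    the conventional percentage form).
    """
    a, b = s1.ascending(), s2.ascending()
    if a.wavenumbers.shape != b.wavenumbers.shape or not np.allclose(
        a.wavenumbers, b.wavenumbers
    ):
        raise ValidationError(
            f"grid mismatch between '{s1.sample_id}' and '{s2.sample_id}'"
        )
    mask = (
        np.ones(a.n_points, dtype=bool) if region is None else region.mask(a.wavenumbers)
    )
    if mask.sum() < 2:
        raise ValidationError("correlation region selects fewer than 2 points")
    y1 = a.absorbance[mask]
    y2 = b.absorbance[mask]
    y1c = y1 - y1.mean()
    y2c = y2 - y2.mean()
    s1sd = float(np.sqrt(np.mean(y1c**2)))
    s2sd = float(np.sqrt(np.mean(y2c**2)))
    if s1sd == 0.0 or s2sd == 0.0:
        offender = s1.sample_id if s1sd == 0.0 else s2.sample_id
        raise DegenerateInputError(
            f"spectrum '{offender}': zero variance over the r_T region"
        )
    r = float(np.mean(y1c * y2c) / (s1sd * s2sd))
    # clip numeric overshoot beyond the Cauchy–Schwarz bound
    return float(np.clip(r, -1.0, 1.0))


@dataclass
class LibraryEntry:
    """One batch in the library: preprocessed spectrum, assay, r_T index.

    ``spectrum`` is the replicate-averaged, derivative-and-normalized
    spectrum on the canonical grid; ``raw_replicates`` optionally retains
    the original acquisitions.  ``r_t`` is populated by
    :func:`index_library` and stored as a ratio in [−1, 1].
    """

    spectrum: Spectrum
    assay: ReferenceAssay = field(default_factory=ReferenceAssay)
    raw_replicates: list[Spectrum] | None = None
    r_t: float | None = None

    @property
    def sample_id(self) -> str:
        return self.spectrum.sample_id

    @property
    def dosage_form(self) -> str | None:
        return self.spectrum.dosage_form

    @property
    def r_t_pct(self) -> float:
        """r_T as a percentage (the conventional reporting unit)."""
        if self.r_t is None:
            raise ValidationError(f"entry '{self.sample_id}' is not indexed")
        return 100.0 * self.r_t


@dataclass
class SpectralLibrary:
    """An indexed collection of library entries.

    All entries share the canonical grid, the reference spectrum, and the
    r_T computation region.
    """

    entries: list[LibraryEntry]
    reference_spectrum: Spectrum | None = None
    rt_region: WavenumberRegions = field(default_factory=lambda: RT_REGION)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    reference_form: str = "tablet"

    def __len__(self) -> int:
        return len(self.entries)

    def indexed_entries(self) -> list[LibraryEntry]:
        missing = [e.sample_id for e in self.entries if e.r_t is None]
        if missing:
            raise ValidationError(
                f"{len(missing)} entries not indexed (first: {missing[0]!r})"
            )
        return sorted(self.entries, key=lambda e: (e.r_t, e.sample_id))

    def rt_summary(self) -> dict[str, float]:
        """min / max / mean / median of r_T, in percent."""
        rts = np.array([e.r_t_pct for e in self.entries])
        return {
            "min": float(rts.min()),
            "max": float(rts.max()),
            "mean": float(rts.mean()),
            "median": float(np.median(rts)),
            "n": int(rts.size),
        }


def build_reference_spectrum(entries: list[LibraryEntry], form: str = "tablet") -> Spectrum:
    """Mean preprocessed spectrum of all entries of one dosage form.

    The default reference is the plain-tablet mean; whether the reference
    class should also include dispersible/chewable tablets is a policy
    choice left to the caller.
    """
    chosen = [e for e in entries if e.dosage_form == form]
    if not chosen:
        raise EmptySelectionError(f"no library entries of dosage form {form!r}")
    ref = chosen[0].spectrum
    for e in chosen[1:]:
        if not np.array_equal(e.spectrum.wavenumbers, ref.wavenumbers):
            raise ValidationError("library entries are not on a common grid")
    mean = np.mean([e.spectrum.absorbance for e in chosen], axis=0)
    return Spectrum(
        wavenumbers=ref.wavenumbers.copy(),
        absorbance=mean,
        sample_id=f"reference:{form}",
        dosage_form=form,
    )


def index_library(lib: SpectralLibrary) -> SpectralLibrary:
    """Populate every entry's r_T against the library reference spectrum.

    Builds the reference (mean spectrum of ``lib.reference_form`` entries)
    if it is not already set.  Returns the same library object for
    chaining.
    """
    if lib.reference_spectrum is None:
        lib.reference_spectrum = build_reference_spectrum(
            lib.entries, lib.reference_form
        )
    for entry in lib.entries:
        entry.r_t = correlation_coefficient(
            entry.spectrum, lib.reference_spectrum, lib.rt_region
        )
    return lib


def index_spectrum(lib: SpectralLibrary, s: Spectrum) -> float:
    """r_T of an external (preprocessed) spectrum against the library reference."""
    if lib.reference_spectrum is None:
        raise ValidationError("library has no reference spectrum; index it first")
    return correlation_coefficient(s, lib.reference_spectrum, lib.rt_region)


# ---------------------------------------------------------------------------
# serialization: directory with spectra CSV + manifest CSV + JSON index


def save_library(lib: SpectralLibrary, directory: str | Path) -> None:
    """Write a library to ``directory`` as plain-text artifacts.

    Layout: ``spectra.csv`` (preprocessed spectra, long format),
    ``manifest.csv`` (metadata + assays), ``index.json`` (r_T values in
    percent, reference provenance, r_T region, preprocessing config), and
    ``reference.csv`` (the reference spectrum).
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_spectra_table([e.spectrum for e in lib.entries], d / "spectra.csv")
    write_assay_manifest(
        (
            (
                e.sample_id,
                e.dosage_form or "",
                e.spectrum.manufacturer,
                e.spectrum.batch,
                e.assay,
            )
            for e in lib.entries
        ),
        d / "manifest.csv",
    )
    if lib.reference_spectrum is not None:
        write_spectra_table([lib.reference_spectrum], d / "reference.csv")
    index = {
        "rt_region": lib.rt_region.to_json(),
        "reference_form": lib.reference_form,
        "reference_spectrum": None
        if lib.reference_spectrum is None
        else lib.reference_spectrum.sample_id,
        "preprocess": lib.preprocess.to_json(),
        "r_t_pct": {
            e.sample_id: (None if e.r_t is None else 100.0 * e.r_t)
            for e in lib.entries
        },
    }
    (d / "index.json").write_text(json.dumps(index, indent=2, sort_keys=True))


def load_library(directory: str | Path) -> SpectralLibrary:
    """Load a library written by :func:`save_library`."""
    d = Path(directory)
    index = json.loads((d / "index.json").read_text())
    manifest = read_assay_manifest(d / "manifest.csv")
    spectra = read_spectra_table(d / "spectra.csv")
    rt_pct = index["r_t_pct"]
    entries = []
    for s in spectra:
        meta = manifest.get(s.sample_id, {})
        assay = meta.get("assay", ReferenceAssay())
        if s.dosage_form is None and meta.get("dosage_form"):
            s = replace(s, dosage_form=meta["dosage_form"])
        rt = rt_pct.get(s.sample_id)
        entries.append(
            LibraryEntry(
                spectrum=s,
                assay=assay,
                r_t=None if rt is None else rt / 100.0,
            )
        )
    reference = None
    if (d / "reference.csv").exists():
        reference = read_spectra_table(d / "reference.csv")[0]
    return SpectralLibrary(
        entries=entries,
        reference_spectrum=reference,
        rt_region=WavenumberRegions.from_json(index["rt_region"]),
        preprocess=PreprocessConfig.from_json(index["preprocess"]),
        reference_form=index.get("reference_form", "tablet"),
    )
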