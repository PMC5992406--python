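"""Spectrum containers, wavenumber regions, and table I/O.

A :class:`Spectrum` is a wavenumber grid (cm⁻¹) with absorbance values and
acquisition metadata.  Libraries of dosage-form spectra live on a canonical
uniform grid (4,000–12,000 cm⁻¹ at 4 cm⁻¹ spacing, 2,001 points) so that all
vector operations downstream — similarity indexing, derivative filtering,
region extraction — are well defined; :func:`resample_to_grid` harmonizes
arbitrary input grids onto it by piecewise-linear interpolation.

On-disk formats are plain text: a long-format CSV for spectra
(sample_id, replicate_index, wavenumber, absorbance), a manifest CSV for
per-sample metadata and reference assay values, and a read-only subset of
JCAMP-DX (simple ``XYDATA (X++(Y..Y))`` blocks).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, RangeError, ValidationError

__all__ = [
    "CANONICAL_GRID",
    "DOSAGE_FORMS",
    "TABLET_FAMILY",
    "GRANULE_FAMILY",
    "Spectrum",
    "ReferenceAssay",
    "WavenumberRegions",
    "read_spectra_table",
    "write_spectra_table",
    "read_assay_manifest",
    "write_assay_manifest",
    "resample_to_grid",
]

#: Canonical library grid: 4,000–12,000 cm⁻¹ at 4 cm⁻¹ spacing (2,001 points).
CANONICAL_GRID = np.arange(4000.0, 12000.0 + 4.0, 4.0)

DOSAGE_FORMS = (
    "tablet",
    "dispersible_tablet",
    "chewable_tablet",
    "granule",
    "oral_suspension",
    "capsule_granule",
)

#: Dosage forms whose spectra cluster with plain tablets (Fig.-2-style split).
TABLET_FAMILY = frozenset({"tablet", "dispersible_tablet", "chewable_tablet"})
GRANULE_FAMILY = frozenset({"granule", "oral_suspension", "capsule_granule"})

GRID_SPAN = (4000.0, 12000.0)


@dataclass(frozen=True)
class Spectrum:
    """A single NIR spectrum: wavenumber grid, absorbance values, metadata.

    Parameters
    ----------
    wavenumbers : ndarray
        Strictly monotonic grid in cm⁻¹; for library use the span must lie
        within 4,000–12,000 cm⁻¹.
    absorbance : ndarray
        Absorbance-like values (input units are treated as generic
        absorbance; no reflectance conversion is applied), same length.
    sample_id, dosage_form, manufacturer, batch : str
        Acquisition metadata.  ``dosage_form`` must be one of
        :data:`DOSAGE_FORMS` when given.
    replicate_index : int or None
        0-based replicate number; ``None`` for replicate-averaged spectra.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    sample_id: str = ""
    dosage_form: str | None = None
    manufacturer: str = ""
    batch: str = ""
    replicate_index: int | None = None

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "absorbance", ab)
        if wn.ndim != 1 or ab.ndim != 1 or wn.size != ab.size or wn.size < 2:
            raise ValidationError(
                f"spectrum '{self.sample_id}': wavenumbers and absorbance must "
                f"be 1-D, equal length >= 2 (got {wn.shape} / {ab.shape})"
            )
        if not (np.all(np.isfinite(wn)) and np.all(np.isfinite(ab))):
            raise ValidationError(f"spectrum '{self.sample_id}': non-finite values")
        d = np.diff(wn)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValidationError(
                f"spectrum '{self.sample_id}': wavenumber grid not strictly monotonic"
            )
        if self.dosage_form is not None and self.dosage_form not in DOSAGE_FORMS:
            raise ValidationError(
                f"spectrum '{self.sample_id}': unknown dosage form "
                f"{self.dosage_form!r}"
            )
        if self.replicate_index is not None and self.replicate_index < 0:
            raise ValidationError("replicate_index must be >= 0 or None")

    @property
    def n_points(self) -> int:
        return int(self.wavenumbers.size)

    def ascending(self) -> "Spectrum":
        """Return a copy with the grid sorted ascending."""
        if self.wavenumbers[0] < self.wavenumbers[-1]:
            return self
        return replace(
            self,
            wavenumbers=self.wavenumbers[::-1].copy(),
            absorbance=self.absorbance[::-1].copy(),
        )

    def with_values(self, wavenumbers: np.ndarray, absorbance: np.ndarray) -> "Spectrum":
        """Copy metadata onto new arrays."""
        return replace(self, wavenumbers=wavenumbers, absorbance=absorbance)

    def in_library_span(self) -> bool:
        lo, hi = GRID_SPAN
        return bool(self.wavenumbers.min() >= lo and self.wavenumbers.max() <= hi)


@dataclass(frozen=True)
class ReferenceAssay:
    """Reference-method content values (% m/m); ``None`` means not assayed."""

    amoxicillin_pct: float | None = None
    clavulanate_pct: float | None = None
    water_pct: float | None = None

    def __post_init__(self) -> None:
        for name, val in self.as_dict().items():
            if val is not None and not (0.0 <= val <= 100.0):
                raise ValidationError(f"{name}={val} outside [0, 100]")

    def as_dict(self) -> dict[str, float | None]:
        return {
            "amoxicillin_pct": self.amoxicillin_pct,
            "clavulanate_pct": self.clavulanate_pct,
            "water_pct": self.water_pct,
        }

    def get(self, analyte: str) -> float | None:
        """Value for ``analyte`` in {amoxicillin, clavulanate, water}."""
        try:
            return self.as_dict()[f"{analyte}_pct"]
        except KeyError:
            raise ValidationError(f"unknown analyte {analyte!r}") from None


@dataclass(frozen=True)
class WavenumberRegions:
    """An ordered list of non-overlapping (low, high) intervals in cm⁻¹."""

    intervals: tuple[tuple[float, float], ...]

    def __init__(self, intervals: Iterable[Sequence[float]]):
        ivs = tuple((float(a), float(b)) for a, b in intervals)
        for lo, hi in ivs:
            if not lo < hi:
                raise ValidationError(f"region ({lo}, {hi}): low must be < high")
        for (lo1, hi1) in ivs:
            for (lo2, hi2) in ivs:
                if (lo1, hi1) != (lo2, hi2) and lo1 < hi2 and lo2 < hi1:
                    raise ValidationError(
                        f"regions ({lo1}, {hi1}) and ({lo2}, {hi2}) overlap"
                    )
        object.__setattr__(self, "intervals", ivs)

    def mask(self, grid: np.ndarray) -> np.ndarray:
        """Boolean mask of grid points falling in any interval."""
        grid = np.asarray(grid, dtype=float)
        m = np.zeros(grid.shape, dtype=bool)
        for lo, hi in self.intervals:
            m |= (grid >= lo) & (grid <= hi)
        return m

    def to_json(self) -> list[list[float]]:
        return [[lo, hi] for lo, hi in self.intervals]

    @classmethod
    def from_json(cls, data: Iterable[Sequence[float]]) -> "WavenumberRegions":
        return cls(data)


# default region over which the library similarity index r_T is computed
RT_REGION = WavenumberRegions([(4200.0, 10000.0)])


# ---------------------------------------------------------------------------
# table I/O

_SPECTRA_COLUMNS = ["sample_id", "replicate_index", "wavenumber", "absorbance"]
_META_COLUMNS = ["dosage_form", "manufacturer", "batch"]


def write_spectra_table(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra to a long-format CSV.

    Columns: sample_id, replicate_index (empty for averaged spectra),
    wavenumber, absorbance, dosage_form, manufacturer, batch.
    """
    frames = []
    for s in spectra:
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": s.sample_id,
                    "replicate_index": s.replicate_index,
                    "wavenumber": s.wavenumbers,
                    "absorbance": s.absorbance,
                    "dosage_form": s.dosage_form,
                    "manufacturer": s.manufacturer,
                    "batch": s.batch,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def _read_spectra_csv(path: Path) -> list[Spectrum]:
    df = pd.read_csv(path)
    for col in ("sample_id", "wavenumber", "absorbance"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    if "replicate_index" not in df.columns:
        df["replicate_index"] = np.nan
    for col in _META_COLUMNS:
        if col not in df.columns:
            df[col] = None
    if df["wavenumber"].isna().any() or df["absorbance"].isna().any():
        raise FormatError(f"{path}: empty cells in 'wavenumber'/'absorbance'")

    out: list[Spectrum] = []
    for (sid, rep), grp in df.groupby(["sample_id", "replicate_index"], dropna=False):
        row0 = grp.iloc[0]
        form = row0["dosage_form"]
        out.append(
            Spectrum(
                wavenumbers=grp["wavenumber"].to_numpy(float),
                absorbance=grp["absorbance"].to_numpy(float),
                sample_id=str(sid),
                dosage_form=None if pd.isna(form) else str(form),
                manufacturer="" if pd.isna(row0["manufacturer"]) else str(row0["manufacturer"]),
                batch="" if pd.isna(row0["batch"]) else str(row0["batch"]),
                replicate_index=None if pd.isna(rep) else int(rep),
            )
        )
    out.sort(key=lambda s: (s.sample_id, -1 if s.replicate_index is None else s.replicate_index))
    return out


_JCAMP_NUM = re.compile(r"[+-]?\d+(?:\.\d+)?(?:[eE][+-]?\d+)?")


def _read_jcampdx(path: Path) -> list[Spectrum]:
    """Minimal JCAMP-DX reader: single ``XYDATA=(X++(Y..Y))`` block per file."""
    text = Path(path).read_text()
    fields: dict[str, str] = {}
    data_lines: list[str] = []
    in_data = False
    for line in text.splitlines():
        line = line.strip()
        if line.startswith("##"):
            key, _, val = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            val = val.strip()
            if key == "XYDATA":
                in_data = "(X++(Y..Y))" in val.replace(" ", "")
                if not in_data:
                    raise FormatError(f"{path}: unsupported XYDATA variant {val!r}")
                continue
            if key == "END":
                in_data = False
                continue
            fields[key] = val
        elif in_data and line:
            data_lines.append(line)
    if not data_lines:
        raise FormatError(f"{path}: no XYDATA block found")
    yfactor = float(fields.get("YFACTOR", 1.0))
    ys: list[float] = []
    for line in data_lines:
        nums = [float(m) for m in _JCAMP_NUM.findall(line)]
        if len(nums) < 2:
            raise FormatError(f"{path}: malformed XYDATA line {line!r}")
        # nums[0] is the line's abscissa check value; Y values follow
        ys.extend(n * yfactor for n in nums[1:])
    # reconstruct the (uniform) x grid from FIRSTX/LASTX
    n = len(ys)
    if "FIRSTX" in fields and "LASTX" in fields:
        first = float(fields["FIRSTX"])
        last = float(fields["LASTX"])
        grid = np.linspace(first, last, n)
    else:
        raise FormatError(f"{path}: FIRSTX/LASTX required for XYDATA decoding")
    title = fields.get("TITLE", Path(path).stem)
    return [Spectrum(wavenumbers=grid, absorbance=np.asarray(ys), sample_id=title)]


def read_spectra_table(path: str | Path, format: str = "csv") -> list[Spectrum]:
    """Read spectra from ``path``.

    Parameters
    ----------
    path : str or Path
    format : {"csv", "jcampdx"}
        ``csv`` expects the long format written by
        :func:`write_spectra_table`; ``jcampdx`` reads a simple
        ``(X++(Y..Y))`` XYDATA block (read-only interchange support).
    """
    p = Path(path)
    if not p.exists():
        raise FormatError(f"no such file: {p}")
    if format == "csv":
        return _read_spectra_csv(p)
    if format == "jcampdx":
        return _read_jcampdx(p)
    raise ValidationError(f"unknown format {format!r}")


def write_assay_manifest(
    rows: Iterable[tuple[str, str, str, str, ReferenceAssay]], path: str | Path
) -> None:
    """Write the per-sample manifest CSV.

    ``rows`` yields (sample_id, dosage_form, manufacturer, batch, assay);
    absent assay values are written as empty cells.
    """
    recs = []
    for sid, form, manu, batch, assay in rows:
        recs.append(
            {
                "sample_id": sid,
                "dosage_form": form,
                "manufacturer": manu,
                "batch": batch,
                **assay.as_dict(),
            }
        )
    pd.DataFrame(recs).to_csv(path, index=False)


def read_assay_manifest(path: str | Path) -> dict[str, dict]:
    """Read the manifest CSV; returns sample_id -> metadata + ReferenceAssay."""
    p = Path(path)
    if not p.exists():
        raise FormatError(f"no such file: {p}")
    df = pd.read_csv(p)
    required = ["sample_id", "dosage_form", "manufacturer", "batch"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{p}: missing required column '{col}'")
    out: dict[str, dict] = {}
    for _, row in df.iterrows():
        def _num(col: str) -> float | None:
            if col not in df.columns or pd.isna(row[col]):
                return None
            return float(row[col])

        out[str(row["sample_id"])] = {
            "dosage_form": str(row["dosage_form"]),
            "manufacturer": "" if pd.isna(row["manufacturer"]) else str(row["manufacturer"]),
            "batch": "" if pd.isna(row["batch"]) else str(row["batch"]),
            "assay": ReferenceAssay(
                amoxicillin_pct=_num("amoxicillin_pct"),
                clavulanate_pct=_num("clavulanate_pct"),
                water_pct=_num("water_pct"),
            ),
        }
    return out


def resample_to_grid(s: Spectrum, grid: np.ndarray) -> Spectrum:
    """Resample a spectrum onto ``grid`` by piecewise-linear interpolation.

    The target grid must lie within the closed span of the source grid —
    no extrapolation is ever performed.
    """
    grid = np.asarray(grid, dtype=float)
    src = s.ascending()
    lo, hi = src.wavenumbers[0], src.wavenumbers[-1]
    if grid.min() < lo or grid.max() > hi:
        raise RangeError(
            f"target grid [{grid.min()}, {grid.max()}] extends beyond source "
            f"span [{lo}, {hi}]"
        )
    values = np.interp(grid, src.wavenumbers, src.absorbance)
    return s.with_values(grid, values)
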