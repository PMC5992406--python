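"""Spectral pretreatment chain.

The modeling chain is fixed in order: replicate averaging, Savitzky–Golay
first derivative (17-point window by default), then vector normalization
(center to zero mean, scale to unit Euclidean norm) over the active
wavenumber region.  The derivative removes additive baselines and slopes;
the normalization removes multiplicative scatter.  Edge points that the SG
window cannot cover are dropped (half a window at each end) rather than
padded, so no fabricated values enter the similarity index or the model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import savgol_coeffs

from .errors import DegenerateInputError, RegionError, ValidationError
from .spectra import Spectrum, WavenumberRegions

__all__ = [
    "PreprocessConfig",
    "average_replicates",
    "sg_first_derivative",
    "vector_normalize",
    "extract_regions",
    "preprocess_spectrum",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the pretreatment chain.

    sg_window : odd int
        Savitzky–Golay window length in points (default 17).
    sg_polyorder : int
        Fitting polynomial order (default 2; the canonical choice for a
        first-derivative filter of this window).
    derivative_order : int
        Fixed at 1; only first-derivative pretreatment is supported.
    normalize : bool
        Apply vector normalization after the derivative (default True).
    regions : WavenumberRegions or None
        Active region for normalization / feature extraction; ``None``
        means the full available grid.
    """

    sg_window: int = 17
    sg_polyorder: int = 2
    derivative_order: int = 1
    normalize: bool = True
    regions: WavenumberRegions | None = None

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window < self.sg_polyorder + 2:
            raise ValidationError(
                f"sg_window must be odd and >= polyorder + 2 "
                f"(got window={self.sg_window}, polyorder={self.sg_polyorder})"
            )
        if self.derivative_order != 1:
            raise ValidationError("only first-derivative pretreatment is supported")

    def to_json(self) -> dict:
        return {
            "sg_window": self.sg_window,
            "sg_polyorder": self.sg_polyorder,
            "derivative_order": self.derivative_order,
            "normalize": self.normalize,
            "regions": None if self.regions is None else self.regions.to_json(),
        }

    @classmethod
    def from_json(cls, data: dict) -> "PreprocessConfig":
        regions = data.get("regions")
        return cls(
            sg_window=int(data.get("sg_window", 17)),
            sg_polyorder=int(data.get("sg_polyorder", 2)),
            derivative_order=int(data.get("derivative_order", 1)),
            normalize=bool(data.get("normalize", True)),
            regions=None if regions is None else WavenumberRegions.from_json(regions),
        )


def average_replicates(replicates: list[Spectrum]) -> Spectrum:
    """Pointwise arithmetic mean of replicate spectra of one sample.

    All replicates must share the same grid and sample_id; the result has
    ``replicate_index=None``.
    """
    if not replicates:
        raise ValidationError("no replicates to average")
    ref = replicates[0]
    for s in replicates[1:]:
        if s.sample_id != ref.sample_id:
            raise ValidationError(
                f"replicates from different samples: "
                f"{ref.sample_id!r} vs {s.sample_id!r}"
            )
        if s.wavenumbers.shape != ref.wavenumbers.shape or not np.array_equal(
            s.wavenumbers, ref.wavenumbers
        ):
            raise ValidationError(
                f"sample {ref.sample_id!r}: replicate grids differ"
            )
    mean = np.mean([s.absorbance for s in replicates], axis=0)
    return replace(ref, absorbance=mean, replicate_index=None)


def _check_uniform(wn: np.ndarray) -> float:
    d = np.diff(wn)
    if not np.allclose(d, d[0], rtol=1e-8, atol=1e-10 * abs(d[0])):
        raise ValidationError("Savitzky–Golay derivative requires a uniform grid")
    return float(d[0])


def sg_first_derivative(s: Spectrum, cfg: PreprocessConfig | None = None) -> Spectrum:
    """Savitzky–Golay first derivative with respect to wavenumber.

    The filter coefficients are scaled by the grid spacing so output units
    are d(absorbance)/d(cm⁻¹).  Half a window of edge points is dropped at
    each end; the returned grid is trimmed to match.
    """
    cfg = cfg or PreprocessConfig()
    src = s.ascending()
    if src.n_points < cfg.sg_window:
        raise ValidationError(
            f"spectrum has {src.n_points} points, fewer than the "
            f"{cfg.sg_window}-point SG window"
        )
    delta = _check_uniform(src.wavenumbers)
    coeffs = savgol_coeffs(cfg.sg_window, cfg.sg_polyorder, deriv=1, delta=delta)
    # np.convolve flips the kernel; savgol_coeffs is already time-reversed,
    # so 'valid' convolution applies the filter at each fully-covered point
    deriv = np.convolve(src.absorbance, coeffs, mode="valid")
    half = cfg.sg_window // 2
    grid = src.wavenumbers[half:-half]
    return src.with_values(grid, deriv)


def vector_normalize(
    s: Spectrum, regions: WavenumberRegions | None = None
) -> Spectrum:
    """Center to zero mean then scale to unit Euclidean norm.

    The mean and norm are computed over the points inside ``regions`` (the
    active region actually used downstream); points outside the region are
    transformed with the same offset and scale so the output remains a
    full-grid spectrum.
    """
    mask = (
        np.ones(s.n_points, dtype=bool)
        if regions is None
        else regions.mask(s.wavenumbers)
    )
    if mask.sum() < 2:
        raise RegionError("normalization region selects fewer than 2 points")
    vals = s.absorbance[mask]
    centered = vals - vals.mean()
    norm = float(np.linalg.norm(centered))
    if norm == 0.0:
        raise DegenerateInputError(
            f"spectrum '{s.sample_id}': zero variance over the normalization region"
        )
    out = (s.absorbance - vals.mean()) / norm
    return s.with_values(s.wavenumbers, out)


def normalize_vector(x: np.ndarray) -> np.ndarray:
    """Center-and-unit-norm a bare feature vector (same convention)."""
    x = np.asarray(x, dtype=float)
    c = x - x.mean()
    n = float(np.linalg.norm(c))
    if n == 0.0:
        raise DegenerateInputError("zero-variance feature vector")
    return c / n


def extract_regions(s: Spectrum, regions: WavenumberRegions) -> np.ndarray:
    """Concatenate the values whose wavenumber lies in each interval.

    Within each interval points are ordered by descending wavenumber
    (instrument convention); intervals contribute in their listed order.
    """
    src = s.ascending()
    parts: list[np.ndarray] = []
    for lo, hi in regions.intervals:
        m = (src.wavenumbers >= lo) & (src.wavenumbers <= hi)
        if not m.any():
            raise RegionError(
                f"region ({lo}, {hi}) cm⁻¹ selects no grid points "
                f"on [{src.wavenumbers[0]}, {src.wavenumbers[-1]}]"
            )
        parts.append(src.absorbance[m][::-1])
    return np.concatenate(parts)


def preprocess_spectrum(
    replicates: list[Spectrum] | Spectrum, cfg: PreprocessConfig | None = None
) -> Spectrum:
    """Full pretreatment: average -> SG first derivative -> vector normalize.

    Accepts either a replicate list or an already-averaged spectrum.
    """
    cfg = cfg or PreprocessConfig()
    avg = (
        replicates
        if isinstance(replicates, Spectrum)
        else average_replicates(replicates)
    )
    deriv = sg_first_derivative(avg, cfg)
    if cfg.normalize:
        return vector_normalize(deriv, cfg.regions)
    return deriv
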