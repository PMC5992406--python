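"""PLS1 regression, rank selection, cross-validation, and validation metrics.

The calibration core is single-response partial least squares (PLS1),
implemented as iterative latent-variable extraction with X-deflation
(NIPALS form; for a single response each component is exact in one step).
The number of latent variables ("rank") is chosen by a one-sided F-test on
the predicted residual error sum of squares:

    PRESS(r)      = sum_i Differ_i^2          (Differ_i = y_i,true − y_i,pred)
    RMSEP/RMSECV  = sqrt(PRESS / M)
    R^2           = (1 − PRESS / sum_i (y_i − y_mean)^2) × 100

with PRESS computed by leave-one-out cross-validation and the chosen rank
the smallest r whose PRESS(r)/PRESS(r*) ratio falls below the F quantile
(Haaland–Thomas parsimony rule).

API follows the statsmodels convention: :class:`PLS1Model` holds the data
and configuration; ``fit()`` returns a :class:`PLS1Results` carrying the
regression vector, loadings, diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import (
    DataError,
    DegenerateInputError,
    RankError,
    ValidationError,
)
from .preprocess import PreprocessConfig, extract_regions, normalize_vector, preprocess_spectrum
from .spectra import Spectrum, WavenumberRegions

__all__ = [
    "PLS1Model",
    "PLS1Results",
    "ValidationReport",
    "fit_pls1",
    "validation_metrics",
    "loocv",
    "select_rank_ftest",
    "pca_scores",
]

ANALYTES = ("amoxicillin", "clavulanate", "water")


# ---------------------------------------------------------------------------
# validation metrics


@dataclass
class ValidationReport:
    """Per-sample prediction differences and aggregate accuracy metrics.

    ``differs`` holds Differ_i = true − predicted (% content units);
    PRESS is their sum of squares; ``rmsep``/``rmsecv`` is
    sqrt(PRESS / n) depending on the validation mode (test-set vs
    leave-one-out); ``r_squared`` is the percentage of the reference-value
    variance reproduced by the predictions; the fractions count samples
    whose |Differ| exceeds 5% or stays below 1%.
    """

    n: int
    differs: np.ndarray
    press: float
    r_squared: float
    rmsep: float | None = None
    rmsecv: float | None = None
    frac_gt_5pct: float = 0.0
    frac_lt_1pct: float = 0.0
    mean_abs_differ: float = 0.0
    mode: str = "tsv"

    def to_json(self) -> dict:
        return {
            "n": self.n,
            "differs": [float(d) for d in self.differs],
            "press": self.press,
            "r_squared": self.r_squared,
            "rmsep": self.rmsep,
            "rmsecv": self.rmsecv,
            "frac_gt_5pct": self.frac_gt_5pct,
            "frac_lt_1pct": self.frac_lt_1pct,
            "mean_abs_differ": self.mean_abs_differ,
            "mode": self.mode,
        }

    def summary(self) -> str:
        rows = [
            ("Validation mode", self.mode.upper()),
            ("N samples", f"{self.n}"),
            ("R^2 (%)", f"{self.r_squared:.2f}"),
            (
                "RMSEP (%)" if self.mode == "tsv" else "RMSECV (%)",
                f"{(self.rmsep if self.mode == 'tsv' else self.rmsecv):.4f}",
            ),
            ("Mean |Differ| (%)", f"{self.mean_abs_differ:.4f}"),
            ("Samples |Differ| > 5%", f"{100 * self.frac_gt_5pct:.1f}%"),
            ("Samples |Differ| < 1%", f"{100 * self.frac_lt_1pct:.1f}%"),
        ]
        width = max(len(k) for k, _ in rows)
        return "\n".join(f"{k:<{width}}  {v}" for k, v in rows)


def validation_metrics(
    true: Sequence[float], predicted: Sequence[float], mode: str = "tsv"
) -> ValidationReport:
    """Compute the standard accuracy metrics from true and predicted values.

    mode : {"tsv", "loocv"}
        Test-set validation reports RMSEP; leave-one-out reports RMSECV.
    """
    y = np.asarray(true, dtype=float)
    yp = np.asarray(predicted, dtype=float)
    if y.shape != yp.shape or y.ndim != 1 or y.size < 1:
        raise ValidationError(
            f"true/predicted must be equal-length 1-D vectors (got {y.shape}, {yp.shape})"
        )
    if mode not in ("tsv", "loocv"):
        raise ValidationError(f"unknown validation mode {mode!r}")
    differs = y - yp
    press = float(np.sum(differs**2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 100.0 * (1.0 - press / tss) if tss > 0 else (100.0 if press == 0 else -np.inf)
    rms = float(np.sqrt(press / y.size))
    ad = np.abs(differs)
    return ValidationReport(
        n=int(y.size),
        differs=differs,
        press=press,
        r_squared=r2,
        rmsep=rms if mode == "tsv" else None,
        rmsecv=rms if mode == "loocv" else None,
        frac_gt_5pct=float(np.mean(ad > 5.0)),
        frac_lt_1pct=float(np.mean(ad < 1.0)),
        mean_abs_differ=float(ad.mean()),
        mode=mode,
    )


# ---------------------------------------------------------------------------
# PLS1 core


def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, rank: int):
    """Latent-variable extraction with X-deflation; returns W, P, q.

    For a single response the NIPALS inner loop converges in one step:
    w = X'y / ||X'y||, t = Xw, p = X't/(t't), q = y't/(t't), X <- X − t p'.
    """
    n, p = Xc.shape
    W = np.zeros((p, rank))
    P = np.zeros((p, rank))
    q = np.zeros(rank)
    X = Xc.copy()
    for a in range(rank):
        w = X.T @ yc
        wn = np.linalg.norm(w)
        if wn == 0.0:
            raise DegenerateInputError(
                f"component {a + 1}: no residual covariance between X and y"
            )
        w /= wn
        t = X @ w
        tt = float(t @ t)
        if tt == 0.0:
            raise DegenerateInputError(f"component {a + 1}: zero-variance score")
        P[:, a] = X.T @ t / tt
        q[a] = float(yc @ t) / tt
        W[:, a] = w
        X = X - np.outer(t, P[:, a])
    return W, P, q


def fit_pls1(X: np.ndarray, y: np.ndarray, rank: int) -> "PLS1Results":
    """Fit a PLS1 regression on a feature matrix (convenience wrapper)."""
    return PLS1Model(X, y).fit(rank)


class PLS1Model:
    """Single-response PLS calibration model specification.

    Parameters
    ----------
    X : ndarray, shape (n, p)
        Preprocessed feature vectors (rows = samples).
    y : ndarray, shape (n,)
        Reference assay values (% content).
    analyte : str, optional
        One of {"amoxicillin", "clavulanate", "water"}; informational.
    regions : WavenumberRegions, optional
        The wavenumber regions the features came from; retained so
        results can preprocess and predict raw spectra.
    preprocess : PreprocessConfig, optional
        The pretreatment chain used to produce the features.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        analyte: str | None = None,
        regions: WavenumberRegions | None = None,
        preprocess: PreprocessConfig | None = None,
    ):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.size:
            raise ValidationError(
                f"X must be (n, p) and y length n (got {X.shape}, {y.shape})"
            )
        if X.shape[0] < 2:
            raise ValidationError("need at least 2 training samples")
        if np.any(~np.isfinite(y)):
            raise DataError("y contains non-finite / absent values")
        if float(np.var(y)) == 0.0:
            raise DegenerateInputError("zero-variance y")
        if analyte is not None and analyte not in ANALYTES:
            raise ValidationError(f"unknown analyte {analyte!r}")
        self.X = X
        self.y = y
        self.analyte = analyte
        self.regions = regions
        self.preprocess = preprocess

    @property
    def max_rank(self) -> int:
        n, p = self.X.shape
        return min(n - 1, p)

    def fit(self, rank: int) -> "PLS1Results":
        """Extract ``rank`` latent variables and return the fitted results."""
        if not 1 <= rank <= self.max_rank:
            raise RankError(
                f"rank {rank} infeasible: must be in [1, {self.max_rank}] "
                f"for n={self.X.shape[0]}, p={self.X.shape[1]}"
            )
        x_mean = self.X.mean(axis=0)
        y_mean = float(self.y.mean())
        Xc = self.X - x_mean
        yc = self.y - y_mean
        W, P, q = _nipals_pls1(Xc, yc, rank)
        # regression vector: b = W (P'W)^{-1} q
        b = W @ np.linalg.solve(P.T @ W, q)
        return PLS1Results(
            model=self,
            rank=rank,
            x_weights=W,
            x_loadings=P,
            y_loadings=q,
            x_mean=x_mean,
            y_mean=y_mean,
            regression_vector=b,
        )

    def fit_path(self, max_rank: int) -> list["PLS1Results"]:
        """Fit all ranks 1..max_rank sharing one component extraction."""
        if not 1 <= max_rank <= self.max_rank:
            raise RankError(
                f"max_rank {max_rank} infeasible (limit {self.max_rank})"
            )
        x_mean = self.X.mean(axis=0)
        y_mean = float(self.y.mean())
        Xc = self.X - x_mean
        yc = self.y - y_mean
        W, P, q = _nipals_pls1(Xc, yc, max_rank)
        out = []
        for r in range(1, max_rank + 1):
            Wr, Pr, qr = W[:, :r], P[:, :r], q[:r]
            b = Wr @ np.linalg.solve(Pr.T @ Wr, qr)
            out.append(
                PLS1Results(
                    model=self,
                    rank=r,
                    x_weights=Wr,
                    x_loadings=Pr,
                    y_loadings=qr,
                    x_mean=x_mean,
                    y_mean=y_mean,
                    regression_vector=b,
                )
            )
        return out


@dataclass
class PLS1Results:
    """Fitted PLS1 calibration: latent structure, regression vector, metadata."""

    model: PLS1Model
    rank: int
    x_weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    x_mean: np.ndarray
    y_mean: float
    regression_vector: np.ndarray

    @property
    def analyte(self) -> str | None:
        return self.model.analyte

    @property
    def regions(self) -> WavenumberRegions | None:
        return self.model.regions

    def predict_features(self, X: np.ndarray) -> np.ndarray:
        """Predict content from already-extracted feature vectors."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.x_mean.size:
            raise ValidationError(
                f"feature length {X.shape[1]} != model's {self.x_mean.size}"
            )
        return self.y_mean + (X - self.x_mean) @ self.regression_vector

    def predict(self, s: Spectrum, preprocessed: bool = False) -> float:
        """Predict content (%) for a spectrum.

        With ``preprocessed=False`` (default) the spectrum is taken
        through the model's full pretreatment chain (derivative, region
        extraction, normalization over the model regions) before applying
        the regression vector; replicate lists should be averaged first.
        With ``preprocessed=True`` the spectrum is assumed to already be a
        derivative (normalized or not — normalization is affine-invariant,
        so it cancels) and only region extraction + normalization apply.
        """
        if self.regions is None or self.model.preprocess is None:
            raise ValidationError(
                "model carries no regions/preprocess config; "
                "use predict_features for bare vectors"
            )
        x = spectrum_features(
            s, self.regions, self.model.preprocess, preprocessed=preprocessed
        )
        return float(self.predict_features(x[None, :])[0])

    def fittedvalues(self) -> np.ndarray:
        return self.predict_features(self.model.X)

    def training_report(self) -> ValidationReport:
        return validation_metrics(self.model.y, self.fittedvalues(), mode="tsv")

    def summary(self) -> str:
        """Plain-text summary table of the fitted calibration."""
        rep = self.training_report()
        rows = [
            ("Analyte", self.analyte or "-"),
            ("Rank (latent variables)", f"{self.rank}"),
            ("Training samples", f"{self.model.X.shape[0]}"),
            ("Features", f"{self.model.X.shape[1]}"),
            ("Training R^2 (%)", f"{rep.r_squared:.2f}"),
            ("Training RMSE (%)", f"{rep.rmsep:.4f}"),
        ]
        width = max(len(k) for k, _ in rows)
        head = "PLS1 calibration results"
        return "\n".join([head, "-" * len(head)] + [f"{k:<{width}}  {v}" for k, v in rows])

    def to_json(self) -> dict:
        return {
            "analyte": self.analyte,
            "rank": self.rank,
            "x_weights": self.x_weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "regression_vector": self.regression_vector.tolist(),
            "regions": None if self.regions is None else self.regions.to_json(),
            "preprocess": None
            if self.model.preprocess is None
            else self.model.preprocess.to_json(),
        }


def spectrum_features(
    s: Spectrum,
    regions: WavenumberRegions,
    cfg: PreprocessConfig,
    preprocessed: bool = False,
) -> np.ndarray:
    """Feature vector for one spectrum: derivative, region extraction, norm.

    ``preprocessed=True`` skips the derivative step for spectra that are
    already derivatives.  Center-and-unit-norm is invariant to positive
    affine maps of its input, so whether such a spectrum was also already
    vector-normalized does not change the result.
    """
    deriv = (
        s
        if preprocessed
        else preprocess_spectrum(
            s,
            PreprocessConfig(
                sg_window=cfg.sg_window,
                sg_polyorder=cfg.sg_polyorder,
                normalize=False,
            ),
        )
    )
    vec = extract_regions(deriv, regions)
    if cfg.normalize:
        vec = normalize_vector(vec)
    return vec


# ---------------------------------------------------------------------------
# cross-validation and rank selection


def loocv(
    X: np.ndarray, y: np.ndarray, max_rank: int
) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out cross-validation across ranks 1..max_rank.

    Each sample is held out once; the model refit on the remaining n−1
    samples predicts it.  Returns (rmsecv_by_rank, press_by_rank), each of
    length ``max_rank``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValidationError("LOOCV needs at least 3 samples")
    limit = min(n - 2, X.shape[1])
    if not 1 <= max_rank <= limit:
        raise RankError(f"max_rank {max_rank} infeasible (limit {limit})")
    preds = np.zeros((n, max_rank))
    for i in range(n):
        keep = np.arange(n) != i
        sub = PLS1Model(X[keep], y[keep])
        for res in sub.fit_path(max_rank):
            preds[i, res.rank - 1] = res.predict_features(X[i][None, :])[0]
    press = np.sum((y[:, None] - preds) ** 2, axis=0)
    rmsecv = np.sqrt(press / n)
    return rmsecv, press


def select_rank_ftest(
    press_by_rank: Sequence[float], n: int, alpha: float = 0.25
) -> int:
    """Parsimonious rank choice by a one-sided F-test on PRESS.

    Let r* = argmin PRESS.  The chosen rank is the smallest r whose
    PRESS(r)/PRESS(r*) does not exceed the F quantile at probability
    1 − alpha with (n, n) degrees of freedom — i.e. the simplest model
    whose cross-validation error is not significantly worse than the
    best (Haaland–Thomas style rule, alpha = 0.25 by convention).
    """
    press = np.asarray(press_by_rank, dtype=float)
    if press.size == 0:
        raise ValidationError("empty PRESS sequence")
    if np.any(press < 0) or np.any(~np.isfinite(press)):
        raise ValidationError("PRESS values must be finite and non-negative")
    if n < 2:
        raise ValidationError("need n >= 2 for the F-test")
    best = float(press.min())
    if best == 0.0:
        return int(np.argmin(press)) + 1
    threshold = float(stats.f.ppf(1.0 - alpha, n, n))
    ratios = press / best
    passing = np.nonzero(ratios <= threshold)[0]
    return int(passing[0]) + 1


# ---------------------------------------------------------------------------
# PCA scores


def pca_scores(X: np.ndarray, n_components: int) -> np.ndarray:
    """Scores of mean-centered calibration features on the leading PCs.

    Component variances are non-increasing; the sign of each axis is
    fixed so its largest-magnitude loading is positive.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("pca_scores expects an (n >= 2, p) matrix")
    n, p = X.shape
    if not 1 <= n_components <= min(n - 1, p):
        raise RankError(
            f"n_components {n_components} infeasible for n={n}, p={p}"
        )
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    V = Vt[:n_components].T
    # deterministic sign: largest-|loading| element of each axis positive
    for j in range(n_components):
        k = int(np.argmax(np.abs(V[:, j])))
        if V[k, j] < 0:
            V[:, j] = -V[:, j]
    return Xc @ V
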