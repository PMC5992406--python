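"""End-to-end model construction: selection, fitting, validation, transfer.

Two routes build a content model from an indexed spectral library:

* ``library`` — the general spectral-library method: compute the r_T of
  the samples to be analyzed, select calibration spectra around their
  median r_T with a fixed spacing (>= 30 spectra, covering the target
  r_T range), split 2/3–1/3 into calibration and test sets, pick the PLS
  rank by LOOCV + F-test, fit, and validate on the test set;

* ``conventional`` — the universal-model method: Ward-cluster all
  library spectra into a fixed number of groups, draw two calibration
  and one validation sample per cluster, then fit and validate the same
  way.

Either route can then be *optimized by transfer*: test spectra whose
prediction difference exceeds the expected threshold are moved into the
calibration set and the model is refit (rank re-selected) until no test
sample exceeds the threshold, a round limit is hit, or the test set would
shrink below a floor.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, ValidationError
from .library import LibraryEntry, SpectralLibrary, index_spectrum
from .pls import (
    PLS1Model,
    PLS1Results,
    ValidationReport,
    loocv,
    select_rank_ftest,
    spectrum_features,
    validation_metrics,
)
from .preprocess import PreprocessConfig, preprocess_spectrum
from .selection import (
    SelectionResult,
    sample_from_clusters,
    select_for_targets,
    split_train_test,
    ward_cluster,
)
from .spectra import ReferenceAssay, Spectrum, WavenumberRegions

__all__ = [
    "PipelineConfig",
    "REGION_PRESETS",
    "build_model",
    "optimize_model",
    "evaluate",
]

#: Named wavenumber-region presets for content models (regions tuned per
#: model in practice; "model1" is the amoxicillin universal-model preset).
REGION_PRESETS: dict[str, WavenumberRegions] = {
    "model1": WavenumberRegions(
        [(8273.4, 9426.6), (7124.0, 7702.5), (5970.7, 6549.3)]
    ),
    "full": WavenumberRegions([(4200.0, 10000.0)]),
}


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one model-building run.

    analyte : {"amoxicillin", "clavulanate", "water"}
    route : {"library", "conventional"}
    spacing : float
        Adjacent-r_T spacing for the library route, percentage points
        (the workable band is about 1.0–1.5; default 1.25).
    n_groups : int
        Ward cluster count for the conventional route (default 19).
    n_min : int
        Minimum calibration-selection size for the library route (30).
    differ_threshold : float
        Prediction-difference threshold (%) above which a test sample is
        transferred during optimization (default 5.0).
    rank_policy : {"ftest", "fixed"}
        LOOCV + F-test rank selection, or a fixed rank (``rank_value``).
    """

    analyte: str = "amoxicillin"
    route: str = "library"
    spacing: float = 1.25
    n_groups: int = 19
    n_min: int = 30
    differ_threshold: float = 5.0
    max_transfer_rounds: int = 5
    regions: WavenumberRegions = field(
        default_factory=lambda: REGION_PRESETS["full"]
    )
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    seed: int = 0
    rank_policy: str = "ftest"
    rank_value: int | None = None
    max_rank: int = 10
    ftest_alpha: float = 0.25

    def __post_init__(self) -> None:
        if self.route not in ("library", "conventional"):
            raise ValidationError(f"unknown route {self.route!r}")
        if self.analyte not in ("amoxicillin", "clavulanate", "water"):
            raise ValidationError(f"unknown analyte {self.analyte!r}")
        if self.differ_threshold <= 0 or self.spacing < 0:
            raise ValidationError("thresholds must be positive")
        if self.rank_policy not in ("ftest", "fixed"):
            raise ValidationError(f"unknown rank policy {self.rank_policy!r}")
        if self.rank_policy == "fixed" and not self.rank_value:
            raise ValidationError("rank_policy='fixed' requires rank_value")

    def to_json(self) -> dict:
        return {
            "analyte": self.analyte,
            "route": self.route,
            "spacing": self.spacing,
            "n_groups": self.n_groups,
            "n_min": self.n_min,
            "differ_threshold": self.differ_threshold,
            "max_transfer_rounds": self.max_transfer_rounds,
            "regions": self.regions.to_json(),
            "preprocess": self.preprocess.to_json(),
            "seed": self.seed,
            "rank_policy": self.rank_policy,
            "rank_value": self.rank_value,
            "max_rank": self.max_rank,
            "ftest_alpha": self.ftest_alpha,
        }

    def config_hash(self) -> str:
        """Stable hash identifying this configuration (recorded in artifacts)."""
        blob = json.dumps(self.to_json(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _entry_features(entries: list[LibraryEntry], cfg: PipelineConfig) -> np.ndarray:
    return np.vstack(
        [
            spectrum_features(
                e.spectrum, cfg.regions, cfg.preprocess, preprocessed=True
            )
            for e in entries
        ]
    )


def _entry_y(entries: list[LibraryEntry], analyte: str) -> np.ndarray:
    vals = []
    for e in entries:
        v = e.assay.get(analyte)
        if v is None:
            raise DataError(
                f"sample '{e.sample_id}' has no {analyte} reference assay"
            )
        vals.append(v)
    return np.asarray(vals, dtype=float)


def _choose_rank(X: np.ndarray, y: np.ndarray, cfg: PipelineConfig) -> int:
    if cfg.rank_policy == "fixed":
        return int(cfg.rank_value)
    cap = min(cfg.max_rank, X.shape[0] - 2, X.shape[1])
    _, press = loocv(X, y, cap)
    return select_rank_ftest(press, n=X.shape[0], alpha=cfg.ftest_alpha)


def _fit(entries: list[LibraryEntry], cfg: PipelineConfig) -> PLS1Results:
    X = _entry_features(entries, cfg)
    y = _entry_y(entries, cfg.analyte)
    rank = _choose_rank(X, y, cfg)
    model = PLS1Model(
        X, y, analyte=cfg.analyte, regions=cfg.regions, preprocess=cfg.preprocess
    )
    return model.fit(rank)


def evaluate(
    results: PLS1Results,
    samples: list[tuple[Spectrum, ReferenceAssay]],
    preprocessed: bool = True,
) -> ValidationReport:
    """Predict each sample and assemble the accuracy report.

    Every sample must carry the model's analyte in its reference assay;
    a missing value raises a :class:`DataError` naming the sample.
    """
    analyte = results.analyte
    if analyte is None:
        raise ValidationError("results carry no analyte tag")
    true_vals, preds = [], []
    for s, assay in samples:
        v = assay.get(analyte)
        if v is None:
            raise DataError(f"sample '{s.sample_id}' has no {analyte} reference assay")
        true_vals.append(v)
        preds.append(results.predict(s, preprocessed=preprocessed))
    return validation_metrics(true_vals, preds, mode="tsv")


def _evaluate_entries(
    results: PLS1Results, entries: list[LibraryEntry]
) -> ValidationReport:
    return evaluate(
        results, [(e.spectrum, e.assay) for e in entries], preprocessed=True
    )


@dataclass
class BuildArtifacts:
    """Everything a model-building run produces, with provenance."""

    results: PLS1Results
    report: ValidationReport
    selection: SelectionResult | dict
    train: list[LibraryEntry]
    test: list[LibraryEntry]
    config_hash: str
    seed: int

    def to_json(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "model": self.results.to_json(),
            "report": self.report.to_json(),
            "selection": self.selection.to_json()
            if isinstance(self.selection, SelectionResult)
            else self.selection,
            "train_ids": [e.sample_id for e in self.train],
            "test_ids": [e.sample_id for e in self.test],
        }


def build_model(
    lib: SpectralLibrary,
    targets: list[Spectrum] | None,
    cfg: PipelineConfig,
) -> BuildArtifacts:
    """Build and validate a content model by the configured route.

    ``targets`` (the spectra of the samples to be analyzed, raw or
    averaged, un-preprocessed) are required for the library route and
    ignored by the conventional route.  Fully reproducible from
    (library, config): the only randomness is the conventional route's
    per-cluster draw, driven by ``cfg.seed``.
    """
    entries = lib.indexed_entries()
    usable = [e for e in entries if e.assay.get(cfg.analyte) is not None]
    if not usable:
        raise DataError(f"no library entries carry a {cfg.analyte} assay")

    if cfg.route == "library":
        if not targets:
            raise ValidationError("library route requires target spectra")
        target_rts = []
        for t in targets:
            proc = preprocess_spectrum(t, lib.preprocess)
            target_rts.append(100.0 * index_spectrum(lib, proc))
        selection = select_for_targets(
            SpectralLibrary(
                entries=usable,
                reference_spectrum=lib.reference_spectrum,
                rt_region=lib.rt_region,
                preprocess=lib.preprocess,
            ),
            target_rts,
            spacing=cfg.spacing,
            n_min=cfg.n_min,
        )
        train, test = split_train_test(selection)
        sel_artifact: SelectionResult | dict = selection
    else:
        X_all = _entry_features(usable, cfg)
        labels = ward_cluster(X_all, n_groups=cfg.n_groups)
        cal_idx, val_idx = sample_from_clusters(labels, seed=cfg.seed)
        train = [usable[i] for i in cal_idx]
        test = [usable[i] for i in val_idx]
        sel_artifact = {
            "route": "conventional",
            "n_groups": cfg.n_groups,
            "labels": [int(l) for l in labels],
            "calibration_ids": [e.sample_id for e in train],
            "validation_ids": [e.sample_id for e in test],
        }

    results = _fit(train, cfg)
    report = _evaluate_entries(results, test) if test else results.training_report()
    return BuildArtifacts(
        results=results,
        report=report,
        selection=sel_artifact,
        train=train,
        test=test,
        config_hash=cfg.config_hash(),
        seed=cfg.seed,
    )


def optimize_model(
    results: PLS1Results,
    train: list[LibraryEntry],
    test: list[LibraryEntry],
    cfg: PipelineConfig,
) -> tuple[PLS1Results, list[dict]]:
    """Optimize a model by transferring poorly predicted test spectra.

    Each round predicts the test set and moves every sample whose
    |prediction difference| exceeds ``cfg.differ_threshold`` into the
    calibration set, then re-selects the rank and refits.  Stops when no
    sample exceeds the threshold, after ``cfg.max_transfer_rounds``
    refits, or when a transfer would drop the test set below 20% of the
    combined set.  Returns the final results and a per-round transfer log.
    """
    if {e.sample_id for e in train} & {e.sample_id for e in test}:
        raise ValidationError("train and test sets overlap")
    train = list(train)
    test = list(test)
    total = len(train) + len(test)
    floor = max(1, int(np.ceil(0.2 * total)))
    log: list[dict] = []
    current = results
    for round_no in range(1, cfg.max_transfer_rounds + 1):
        report = _evaluate_entries(current, test) if test else None
        if report is None:
            break
        over = [
            e
            for e, d in zip(test, report.differs)
            if abs(d) > cfg.differ_threshold
        ]
        if not over:
            break
        if len(test) - len(over) < floor:
            # transferring all offenders would erase the validation surface;
            # move only as many as the floor allows, worst first
            budget = len(test) - floor
            if budget <= 0:
                log.append(
                    {
                        "round": round_no,
                        "transferred": [],
                        "stopped": "test-set floor reached",
                    }
                )
                break
            by_differ = sorted(
                zip(test, np.abs(report.differs)), key=lambda p: -p[1]
            )
            over = [e for e, d in by_differ if d > cfg.differ_threshold][:budget]
        over_ids = {e.sample_id for e in over}
        train.extend(over)
        test = [e for e in test if e.sample_id not in over_ids]
        current = _fit(train, cfg)
        log.append(
            {
                "round": round_no,
                "transferred": sorted(over_ids),
                "n_train": len(train),
                "n_test": len(test),
            }
        )
    return current, log
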