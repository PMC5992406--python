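"""Calibration-set construction.

Two routes are provided:

* the **library route**: sort library entries by r_T, pick spectra with a
  fixed r_T spacing (about 1.0–1.5 percentage points between adjacent
  calibration spectra), anchored at the median r_T of the samples to be
  analyzed, growing outward until the selection covers the target r_T
  range and reaches a minimum size (>= 30), then a deterministic 2/3–1/3
  train/test split;

* the **conventional route**: Ward hierarchical clustering (Euclidean
  distance) of all preprocessed spectra into a fixed number of groups
  (default 19), drawing three samples per cluster — two for calibration,
  one for validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .errors import (
    CoverageError,
    EmptySelectionError,
    SizeError,
    ValidationError,
)
from .library import LibraryEntry, SpectralLibrary

__all__ = [
    "SelectionResult",
    "select_by_spacing",
    "select_for_targets",
    "split_train_test",
    "ward_cluster",
    "sample_from_clusters",
]

#: numeric slack when comparing r_T gaps against the configured spacing
GAP_TOL = 1e-9


@dataclass
class SelectionResult:
    """Outcome of a calibration-set selection.

    ``selected`` is sorted ascending by r_T; ``adjacent_gaps`` holds the
    r_T difference (percentage points) between consecutive selected
    entries.  ``flags`` records shortfalls the selection could not fix
    (too few entries in reach, forced coverage endpoints closer than the
    spacing) without silently altering the contract.
    """

    selected: list[LibraryEntry]
    spacing: float
    adjacent_gaps: list[float] = field(default_factory=list)
    target_median_rt: float | None = None
    target_rt_range: tuple[float, float] | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.selected = sorted(
            self.selected, key=lambda e: (e.r_t_pct, e.sample_id)
        )
        self.adjacent_gaps = [
            self.selected[i + 1].r_t_pct - self.selected[i].r_t_pct
            for i in range(len(self.selected) - 1)
        ]

    @property
    def rt_values(self) -> np.ndarray:
        return np.array([e.r_t_pct for e in self.selected])

    def to_json(self) -> dict:
        return {
            "spacing": self.spacing,
            "n_selected": len(self.selected),
            "sample_ids": [e.sample_id for e in self.selected],
            "r_t_pct": [e.r_t_pct for e in self.selected],
            "adjacent_gaps": self.adjacent_gaps,
            "target_median_rt": self.target_median_rt,
            "target_rt_range": self.target_rt_range,
            "flags": list(self.flags),
        }


def _sorted_entries(entries: list[LibraryEntry]) -> list[LibraryEntry]:
    for e in entries:
        if e.r_t is None:
            raise ValidationError(f"entry '{e.sample_id}' is not indexed")
    return sorted(entries, key=lambda e: (e.r_t_pct, e.sample_id))


def select_by_spacing(
    entries: list[LibraryEntry],
    spacing: float,
    anchor: float | None = None,
) -> SelectionResult:
    """Greedy selection of entries separated by at least ``spacing`` r_T points.

    Without an anchor the sweep starts at the lowest r_T and moves upward,
    accepting an entry whenever its r_T exceeds the last accepted value by
    at least ``spacing``.  With an anchor (an r_T value in percent) the
    entry nearest the anchor is accepted first and the sweep grows outward
    alternately to higher and lower r_T, which keeps the selected median
    close to the anchor.  Deterministic: ties on r_T break by
    lexicographically smaller sample_id.
    """
    if not entries:
        raise EmptySelectionError("no entries to select from")
    if spacing < 0:
        raise ValidationError("spacing must be >= 0")
    ordered = _sorted_entries(entries)
    if anchor is None:
        chosen = [ordered[0]]
        for e in ordered[1:]:
            if e.r_t_pct - chosen[-1].r_t_pct >= spacing - GAP_TOL:
                chosen.append(e)
        return SelectionResult(selected=chosen, spacing=spacing)

    rts = np.array([e.r_t_pct for e in ordered])
    start = int(np.argmin(np.abs(rts - anchor)))
    chosen = [ordered[start]]
    up, down = start + 1, start - 1
    hi = lo = ordered[start].r_t_pct
    go_up = True
    while up < len(ordered) or down >= 0:
        moved = False
        if go_up and up < len(ordered):
            while up < len(ordered) and ordered[up].r_t_pct - hi < spacing - GAP_TOL:
                up += 1
            if up < len(ordered):
                chosen.append(ordered[up])
                hi = ordered[up].r_t_pct
                up += 1
                moved = True
        elif not go_up and down >= 0:
            while down >= 0 and lo - ordered[down].r_t_pct < spacing - GAP_TOL:
                down -= 1
            if down >= 0:
                chosen.append(ordered[down])
                lo = ordered[down].r_t_pct
                down -= 1
                moved = True
        go_up = not go_up
        if not moved and up >= len(ordered) and down < 0:
            break
    return SelectionResult(selected=chosen, spacing=spacing, target_median_rt=anchor)


def select_for_targets(
    lib: SpectralLibrary,
    target_rts: list[float],
    spacing: float = 1.25,
    n_min: int = 30,
) -> SelectionResult:
    """Select calibration entries for a set of samples to be analyzed.

    ``target_rts`` are the r_T values (percent) of the target spectra
    against the library reference.  The selection is anchored at the
    target median and grown outward alternately with the configured
    spacing, stopping once it covers the target r_T range
    [min, max] and holds at least ``n_min`` entries.  If the sweep
    exhausts the library before covering a side, the outermost library
    entry beyond the target bound is force-included (flagged, exempt from
    the spacing rule); if no library entry reaches the bound a
    :class:`CoverageError` is raised naming the uncovered side.  A
    selection smaller than ``n_min`` after the library is exhausted is
    returned with a ``shortfall`` flag rather than an error.
    """
    if not target_rts:
        raise EmptySelectionError("no target samples")
    ordered = _sorted_entries(lib.entries)
    rts = np.array([e.r_t_pct for e in ordered])
    t = np.asarray(target_rts, dtype=float)
    t_median = float(np.median(t))
    t_min, t_max = float(t.min()), float(t.max())

    if rts.max() < t_max - GAP_TOL:
        raise CoverageError(
            f"library maximum r_T {rts.max():.2f}% cannot cover target "
            f"maximum {t_max:.2f}% (upper side uncovered)"
        )
    if rts.min() > t_min + GAP_TOL:
        raise CoverageError(
            f"library minimum r_T {rts.min():.2f}% cannot cover target "
            f"minimum {t_min:.2f}% (lower side uncovered)"
        )

    start = int(np.argmin(np.abs(rts - t_median)))
    chosen_idx = [start]
    up, down = start + 1, start - 1
    hi = lo = float(rts[start])
    go_up = True

    def covered() -> bool:
        return lo <= t_min + GAP_TOL and hi >= t_max - GAP_TOL

    while not (covered() and len(chosen_idx) >= n_min):
        advanced = False
        for _ in range(2):  # try preferred side, then the other
            if go_up:
                i = up
                while i < len(ordered) and rts[i] - hi < spacing - GAP_TOL:
                    i += 1
                if i < len(ordered):
                    chosen_idx.append(i)
                    hi = float(rts[i])
                    up = i + 1
                    advanced = True
            else:
                i = down
                while i >= 0 and lo - rts[i] < spacing - GAP_TOL:
                    i -= 1
                if i >= 0:
                    chosen_idx.append(i)
                    lo = float(rts[i])
                    down = i - 1
                    advanced = True
            go_up = not go_up
            if advanced:
                break
        if not advanced:
            break

    flags: list[str] = []
    # coverage repair when the spacing sweep stopped short of a target
    # bound: replace the outermost accepted entry with the entry
    # bracketing the bound — the gap to its inward neighbour only grows,
    # so the spacing contract is preserved.  Only when the sweep accepted
    # nothing beyond the anchor on that side is a sub-spacing endpoint
    # forced (and flagged).
    if hi < t_max - GAP_TOL:
        j = int(np.nonzero(rts >= t_max - GAP_TOL)[0][0])
        top = max(chosen_idx)
        if len(chosen_idx) >= 2:
            chosen_idx.remove(top)
            chosen_idx.append(j)
        else:
            chosen_idx.append(j)
            flags.append(
                f"forced upper coverage endpoint '{ordered[j].sample_id}' "
                f"closer than spacing"
            )
    if lo > t_min + GAP_TOL:
        j = int(np.nonzero(rts <= t_min + GAP_TOL)[0][-1])
        bottom = min(chosen_idx)
        if len(chosen_idx) >= 2 and bottom != j:
            chosen_idx.remove(bottom)
            chosen_idx.append(j)
        elif j not in chosen_idx:
            chosen_idx.append(j)
            flags.append(
                f"forced lower coverage endpoint '{ordered[j].sample_id}' "
                f"closer than spacing"
            )
    # degenerate case (spacing exceeds the library span): the library's
    # extreme entries are still eligible endpoints so the selection at
    # least bounds the available r_T span; moderate shortfalls are only
    # flagged, never silently padded
    if len(chosen_idx) == 1 and n_min > 1:
        for j in (0, len(ordered) - 1):
            if j not in chosen_idx:
                chosen_idx.append(j)
                flags.append(
                    f"forced library endpoint '{ordered[j].sample_id}' "
                    f"into a degenerate selection"
                )
    if len(chosen_idx) < n_min:
        flags.append(
            f"shortfall: only {len(chosen_idx)} entries selected "
            f"(minimum requested {n_min})"
        )
    result = SelectionResult(
        selected=[ordered[i] for i in sorted(set(chosen_idx))],
        spacing=spacing,
        target_median_rt=t_median,
        target_rt_range=(t_min, t_max),
        flags=flags,
    )
    return result


def split_train_test(
    selected: SelectionResult, train_fraction: float = 2.0 / 3.0
) -> tuple[list[LibraryEntry], list[LibraryEntry]]:
    """Deterministic interleaved 2/3–1/3 split over the r_T-sorted selection.

    Every third entry goes to the test set; the minimum- and maximum-r_T
    entries are always forced into the training set so both sets span the
    same r_T range.  Interleaving (rather than a random draw) preserves
    the concentration/r_T span in both sets and needs no seed.
    """
    entries = selected.selected
    n = len(entries)
    if n < 3:
        raise SizeError(f"need >= 3 selected entries to split (got {n})")
    if not 0.0 < train_fraction < 1.0:
        raise ValidationError("train_fraction must be in (0, 1)")
    period = max(2, round(1.0 / (1.0 - train_fraction)))
    test_idx = {
        i for i in range(n) if i % period == 1 and i not in (0, n - 1)
    }
    train = [e for i, e in enumerate(entries) if i not in test_idx]
    test = [e for i, e in enumerate(entries) if i in test_idx]
    return train, test


def ward_cluster(X: np.ndarray, n_groups: int = 19) -> np.ndarray:
    """Agglomerative hierarchical clustering, Euclidean distance, Ward linkage.

    Returns 0-based cluster labels from cutting the tree at ``n_groups``
    clusters.  Labels are deterministic (scipy's linkage order).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError("ward_cluster expects a 2-D sample × feature matrix")
    n = X.shape[0]
    if not 1 <= n_groups <= n:
        raise SizeError(f"n_groups={n_groups} infeasible for n={n} samples")
    if n_groups == n:
        return np.arange(n)
    Z = linkage(X, method="ward", metric="euclidean")
    labels = fcluster(Z, t=n_groups, criterion="maxclust")
    return labels - 1


def sample_from_clusters(
    labels: np.ndarray, per_cluster: int = 3, seed: int = 0
) -> tuple[list[int], list[int]]:
    """Draw samples per cluster: two for calibration, one for validation.

    Per cluster, ``min(per_cluster, cluster size)`` members are drawn
    without replacement with a seeded generator; the first two drawn go
    to calibration and the third (when present) to validation.  Clusters
    of size 1–2 contribute to calibration only.  Returns
    (calibration indices, validation indices).
    """
    labels = np.asarray(labels)
    if labels.ndim != 1:
        raise ValidationError("labels must be 1-D")
    rng = np.random.default_rng(seed)
    calibration: list[int] = []
    validation: list[int] = []
    for lab in np.unique(labels):
        members = np.nonzero(labels == lab)[0]
        k = min(per_cluster, members.size)
        drawn = rng.choice(members, size=k, replace=False)
        calibration.extend(int(i) for i in drawn[:2])
        if k >= 3:
            validation.append(int(drawn[2]))
    return sorted(calibration), sorted(validation)
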