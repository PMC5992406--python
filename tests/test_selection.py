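"""Calibration-set selection: spacing sweep, target coverage, splits, clustering."""

import itertools

import numpy as np
import pytest

from nirspeclib import (
    LibraryEntry,
    ReferenceAssay,
    SpectralLibrary,
    sample_from_clusters,
    select_by_spacing,
    select_for_targets,
    split_train_test,
    ward_cluster,
)
from nirspeclib.errors import (
    CoverageError,
    EmptySelectionError,
    SizeError,
)

from conftest import make_spectrum


def entries_with_rt(rts, ids=None):
    ids = ids or [f"e{i:03d}" for i in range(len(rts))]
    out = []
    for sid, rt in zip(ids, rts):
        e = LibraryEntry(
            spectrum=make_spectrum([0.0, 1.0, 2.0], sample_id=sid),
            assay=ReferenceAssay(amoxicillin_pct=50.0),
            r_t=rt / 100.0,
        )
        out.append(e)
    return out


class TestSelectBySpacing:
    def test_hand_traced_greedy_sweep(self):
        entries = entries_with_rt([70.0, 70.5, 71.0, 71.5, 72.0])
        result = select_by_spacing(entries, spacing=1.0)
        assert [e.r_t_pct for e in result.selected] == pytest.approx([70.0, 71.0, 72.0])

    def test_zero_spacing_selects_everything(self):
        entries = entries_with_rt([70.0, 70.2, 70.4, 71.0])
        result = select_by_spacing(entries, spacing=0.0)
        assert len(result.selected) == 4

    def test_equal_rt_tie_breaks_lexicographic(self):
        entries = entries_with_rt([80.0, 80.0], ids=["bbb", "aaa"])
        result = select_by_spacing(entries, spacing=0.5)
        assert [e.sample_id for e in result.selected] == ["aaa"]

    def test_empty_input_rejected(self):
        with pytest.raises(EmptySelectionError):
            select_by_spacing([], spacing=1.0)

    def test_gaps_respect_spacing_and_subsequence(self):
        gen = np.random.default_rng(11)
        rts = np.sort(gen.uniform(40, 99, size=200))
        entries = entries_with_rt(rts)
        result = select_by_spacing(entries, spacing=1.5)
        assert all(g >= 1.5 - 1e-9 for g in result.adjacent_gaps)
        selected_ids = [e.sample_id for e in result.selected]
        all_ids = [e.sample_id for e in sorted(entries, key=lambda e: e.r_t_pct)]
        it = iter(all_ids)
        assert all(sid in it for sid in selected_ids)  # subsequence check

    def test_anchored_sweep_hugs_anchor(self):
        rts = np.linspace(50, 90, 81)  # 0.5% steps
        entries = entries_with_rt(rts)
        result = select_by_spacing(entries, spacing=1.0, anchor=70.0)
        assert 70.0 in [round(e.r_t_pct, 6) for e in result.selected]
        assert all(g >= 1.0 - 1e-9 for g in result.adjacent_gaps)


def library_from_rts(rts):
    return SpectralLibrary(entries=entries_with_rt(rts))


class TestSelectForTargets:
    def test_dense_library_covers_targets(self):
        gen = np.random.default_rng(5)
        rts = np.sort(gen.uniform(40, 99, size=300))  # mean gap ~0.2 < spacing/2
        lib = library_from_rts(rts)
        targets = list(rts[100:180])
        result = select_for_targets(lib, targets, spacing=1.25, n_min=30)
        sel_rts = result.rt_values
        assert sel_rts.min() <= min(targets) + 1e-9
        assert sel_rts.max() >= max(targets) - 1e-9
        assert len(result.selected) >= 30
        assert all(g >= 1.25 - 1e-9 for g in result.adjacent_gaps)
        # selected median hugs the target median within one spacing
        assert abs(np.median(sel_rts) - np.median(targets)) <= 2 * 1.25

    def test_determinism(self):
        gen = np.random.default_rng(6)
        rts = np.sort(gen.uniform(40, 99, size=200))
        lib = library_from_rts(rts)
        targets = list(rts[50:150])
        r1 = select_for_targets(lib, targets, spacing=1.25)
        r2 = select_for_targets(lib, targets, spacing=1.25)
        assert [e.sample_id for e in r1.selected] == [e.sample_id for e in r2.selected]

    def test_degenerate_small_library(self):
        # spacing larger than the library span: nearest entry + endpoints
        rts = [70.0, 71.0, 72.0, 73.0, 74.0]
        lib = library_from_rts(rts)
        result = select_for_targets(lib, [72.0], spacing=50.0, n_min=30)
        sel = sorted(e.r_t_pct for e in result.selected)
        assert sel == pytest.approx([70.0, 72.0, 74.0])
        assert any("shortfall" in f for f in result.flags)

    def test_target_above_library_max_rejected(self):
        lib = library_from_rts([70.0, 75.0, 80.0])
        with pytest.raises(CoverageError, match="upper"):
            select_for_targets(lib, [85.0], spacing=1.0)

    def test_target_below_library_min_rejected(self):
        lib = library_from_rts([70.0, 75.0, 80.0])
        with pytest.raises(CoverageError, match="lower"):
            select_for_targets(lib, [60.0], spacing=1.0)

    def test_shortfall_flagged_not_padded(self):
        rts = np.linspace(70, 80, 41)  # span 10 => at most 9 at spacing 1.25
        lib = library_from_rts(rts)
        result = select_for_targets(lib, [74.0, 76.0], spacing=1.25, n_min=30)
        assert len(result.selected) < 30
        assert any("shortfall" in f for f in result.flags)
        assert all(g >= 1.25 - 1e-9 for g in result.adjacent_gaps)


class TestSplitTrainTest:
    @pytest.mark.parametrize("n, expected_test", [(30, 10), (3, 1), (4, 1)])
    def test_split_sizes(self, n, expected_test):
        entries = entries_with_rt(np.linspace(50, 90, n))
        result = select_by_spacing(entries, spacing=0.0)
        train, test = split_train_test(result)
        assert len(test) == expected_test
        assert len(train) == n - expected_test

    def test_endpoints_always_in_train(self):
        entries = entries_with_rt(np.linspace(50, 90, 31))
        result = select_by_spacing(entries, spacing=0.0)
        train, _ = split_train_test(result)
        train_rts = [e.r_t_pct for e in train]
        assert min(train_rts) == pytest.approx(50.0)
        assert max(train_rts) == pytest.approx(90.0)

    def test_too_few_rejected(self):
        entries = entries_with_rt([50.0, 60.0])
        result = select_by_spacing(entries, spacing=0.0)
        with pytest.raises(SizeError):
            split_train_test(result)

    def test_disjoint_and_exhaustive(self):
        entries = entries_with_rt(np.linspace(50, 90, 25))
        result = select_by_spacing(entries, spacing=0.0)
        train, test = split_train_test(result)
        train_ids = {e.sample_id for e in train}
        test_ids = {e.sample_id for e in test}
        assert not train_ids & test_ids
        assert len(train_ids | test_ids) == 25


def brute_force_ward(X, n_groups):
    """Literal agglomeration with the Lance–Williams Ward update."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    clusters = {i: [i] for i in range(n)}
    d = {
        (i, j): float(np.sum((X[i] - X[j]) ** 2))
        for i, j in itertools.combinations(range(n), 2)
    }  # Ward objective uses squared Euclidean merge costs

    def dist(i, j):
        return d[(i, j) if i < j else (j, i)]

    next_label = n
    while len(clusters) > n_groups:
        keys = sorted(clusters)
        (a, b) = min(
            ((i, j) for i, j in itertools.combinations(keys, 2)),
            key=lambda p: dist(*p),
        )
        na, nb = len(clusters[a]), len(clusters[b])
        merged = clusters.pop(a) + clusters.pop(b)
        for k in list(clusters):
            nk = len(clusters[k])
            dk = (
                (na + nk) * dist(a, k) + (nb + nk) * dist(b, k) - nk * dist(a, b)
            ) / (na + nb + nk)
            d[(k, next_label) if k < next_label else (next_label, k)] = dk
        clusters[next_label] = merged
        next_label += 1
    labels = np.empty(n, dtype=int)
    for lab, (_, members) in enumerate(sorted(clusters.items())):
        labels[members] = lab
    return labels


def same_partition(a, b):
    return len({(x, y) for x, y in zip(a, b)}) == len(set(a)) == len(set(b))


class TestWardCluster:
    def test_two_separated_clouds(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (10, 3)), rng.normal(5, 0.1, (12, 3))])
        labels = ward_cluster(X, 2)
        assert same_partition(labels, [0] * 10 + [1] * 12)

    def test_full_and_root_cuts(self, rng):
        X = rng.normal(size=(6, 2))
        assert len(set(ward_cluster(X, 6))) == 6
        assert len(set(ward_cluster(X, 1))) == 1

    def test_matches_brute_force_agglomeration(self):
        # oracle: literal Lance–Williams agglomeration on tiny datasets
        for seed in range(10):
            gen = np.random.default_rng(seed)
            n = int(gen.integers(4, 9))
            X = gen.normal(size=(n, 3))
            for k in (2, 3):
                if k >= n:
                    continue
                assert same_partition(
                    ward_cluster(X, k), brute_force_ward(X, k)
                ), f"seed={seed}, k={k}"

    def test_too_many_groups_rejected(self, rng):
        with pytest.raises(SizeError):
            ward_cluster(rng.normal(size=(5, 2)), 6)


class TestSampleFromClusters:
    def test_counting_rule(self):
        labels = np.repeat(np.arange(19), 3)
        cal, val = sample_from_clusters(labels, seed=1)
        assert len(cal) == 38
        assert len(val) == 19
        assert not set(cal) & set(val)

    def test_determinism(self):
        labels = np.repeat(np.arange(5), 4)
        assert sample_from_clusters(labels, seed=7) == sample_from_clusters(labels, seed=7)

    def test_singleton_cluster_goes_to_calibration(self):
        labels = np.array([0, 0, 0, 1])  # cluster 1 is a singleton
        cal, val = sample_from_clusters(labels, seed=0)
        assert 3 in cal
        assert 3 not in val
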