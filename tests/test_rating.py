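"""Pooled ranking, condition counting, the rating rule and diagnosis.

The independent oracle for the counting/rating rule is a naive per-voxel
tally: sort (value, stable-order) pairs by hand, count the top-T per
condition, and apply ``argmax if max >= ceil(T/2 + 1)`` with ceiling
arithmetic done through the ``math`` module.
"""

import itertools
import math

import numpy as np
import pytest

from voxar.rating import (
    UNASSIGNED,
    build_rating_map,
    count_conditions,
    majority_threshold,
    pool_rank,
    pool_rank_values,
    rating_histogram,
    voxar_diagnose,
)
from voxar.report import STATUS_REFUSED
from voxar.similarity import SimilarityMap


def _sim(values):
    values = np.asarray(values, dtype=float)
    return SimilarityMap(values=values, defined=~np.isnan(values), sigma_g=2.0)


def _counts_from(counts_obj):
    return counts_obj.counts


@pytest.mark.parametrize("T,expected", [(1, 2), (3, 3), (5, 4), (7, 5), (9, 6)])
def test_majority_threshold_exact_ceiling(T, expected):
    assert majority_threshold(T) == math.ceil(T / 2 + 1) == expected


def test_pool_rank_single_atlas_per_database_t1():
    shape = (2, 1, 1)
    maps = {
        "a": [_sim(np.array([0.1, 0.9]).reshape(shape))],
        "b": [_sim(np.array([0.8, 0.2]).reshape(shape))],
        "c": [_sim(np.array([0.3, 0.4]).reshape(shape))],
    }
    p = pool_rank(maps, np.ones(shape, dtype=bool), T=1)
    assert p.top.sum(axis=0).tolist() == [1, 1]  # exactly one indicator per voxel
    counts = count_conditions(p).counts
    assert counts[:, 0].tolist() == [0, 1, 0]  # voxel 0: global max is b
    assert counts[:, 1].tolist() == [1, 0, 0]  # voxel 1: global max is a


def test_pool_rank_cardinality_nine_atlases_t7(rng):
    shape = (3, 3, 3)
    maps = {c: [_sim(rng.random(shape)) for _ in range(3)] for c in "abc"}
    p = pool_rank(maps, np.ones(shape, dtype=bool), T=7)
    counts = count_conditions(p).counts
    assert (counts.sum(axis=0) == 7).all()


def test_pool_rank_all_tied_uses_stable_condition_order():
    shape = (1, 1, 1)
    maps = {c: [_sim(np.full(shape, 0.5))] for c in ("a", "b", "c")}
    p = pool_rank(maps, np.ones(shape, dtype=bool), T=1)
    counts = count_conditions(p).counts[:, 0]
    assert counts.tolist() == [1, 0, 0]  # first condition in sorted order wins


def test_count_example_composition():
    # top-7 at a voxel = [A,A,B,A,C,A,B] -> A:4, B:2, C:1
    values = np.array([[0.9], [0.8], [0.7], [0.6], [0.5], [0.4], [0.3]])
    cond_idx = np.array([0, 0, 1, 0, 2, 0, 1])
    order = np.argsort(cond_idx, kind="stable")  # rows must be grouped by condition
    p = pool_rank_values(
        values[order], np.ones_like(values, dtype=bool)[order], cond_idx[order],
        ("A", "B", "C"), T=7,
    )
    counts = count_conditions(p).counts[:, 0]
    assert counts.tolist() == [4, 2, 1]


def test_single_condition_counts_saturate():
    values = np.tile(np.linspace(1, 0, 5).reshape(-1, 1), (1, 4))
    p = pool_rank_values(
        values, np.ones_like(values, dtype=bool), np.zeros(5, dtype=int), ("only",), T=7
    )
    counts = count_conditions(p).counts
    assert (counts[0] == 5).all()  # min(T, N) = 5


def _oracle_rating(values_at_voxel, cond_idx, T):
    """Naive tally: stable descending sort, count top-T, apply the guard."""
    order = sorted(range(len(values_at_voxel)), key=lambda i: (-values_at_voxel[i], i))
    top = order[: min(T, len(order))]
    tally: dict[int, int] = {}
    for i in top:
        tally[cond_idx[i]] = tally.get(cond_idx[i], 0) + 1
    best = max(tally, key=lambda c: (tally[c], -c))
    if tally[best] >= math.ceil(T / 2 + 1):
        return best
    return UNASSIGNED


@pytest.mark.parametrize("T", [1, 3, 5, 7, 9])
def test_rating_rule_matches_hand_tally_for_all_compositions(T):
    """For every composition of 7 pooled entries over 3 conditions the counts
    and the assignment equal the naive per-voxel oracle."""
    n_entries = 7
    for comp in itertools.product(range(3), repeat=n_entries):
        values = np.linspace(1.0, 0.4, n_entries)  # strictly decreasing, no ties
        cond_idx = np.asarray(comp)
        order = np.argsort(cond_idx, kind="stable")
        p = pool_rank_values(
            values[order].reshape(-1, 1),
            np.ones((n_entries, 1), dtype=bool),
            cond_idx[order],
            ("A", "B", "C"),
            T=T,
        )
        counts = count_conditions(p)
        expected_counts = [sum(1 for c in comp[: min(T, n_entries)] if c == k) for k in range(3)]
        assert counts.counts[:, 0].tolist() == expected_counts
        rmap = build_rating_map(counts)
        expected = _oracle_rating(values.tolist(), comp, T)
        assert rmap.labels_flat[0] == expected
        # the absolute-majority guard is never violated
        if rmap.labels_flat[0] != UNASSIGNED:
            assert counts.counts[:, 0].max() >= majority_threshold(T)


def test_rating_examples_t7():
    def rate(counts):
        values = []
        cond_idx = []
        for c, n in enumerate(counts):
            for k in range(n):
                values.append(1.0 - 0.01 * len(values))
                cond_idx.append(c)
        p = pool_rank_values(
            np.asarray(values).reshape(-1, 1),
            np.ones((len(values), 1), dtype=bool),
            np.asarray(cond_idx),
            ("A", "B", "C"),
            T=7,
        )
        return build_rating_map(count_conditions(p)).labels_flat[0]

    assert rate([5, 1, 1]) == 0  # A wins: 5 >= ceil(7/2+1) = 5
    assert rate([4, 2, 1]) == UNASSIGNED  # 4 < 5


def test_rating_t1_single_count_unassigned_under_printed_rule():
    # T=1: threshold ceil(1/2+1) = 2 exceeds the single available count,
    # so the printed rule can never assign
    p = pool_rank_values(
        np.array([[0.9]]), np.ones((1, 1), dtype=bool), np.array([0]), ("A",), T=1
    )
    rmap = build_rating_map(count_conditions(p))
    assert rmap.labels_flat[0] == UNASSIGNED


def test_rating_histogram_percentages_and_separation():
    from voxar.rating import RatingMap

    labels = np.array([0] * 6 + [1] * 4 + [UNASSIGNED] * 10, dtype=np.int16)
    rmap = RatingMap(
        labels_flat=labels, conditions=("A", "B"), roi_index=np.arange(20), shape=(20, 1, 1)
    )
    hist = rating_histogram(rmap)
    assert hist.percentages == {"A": 60.0, "B": 40.0}
    assert hist.separation == pytest.approx(20.0)
    assert hist.n_unassigned == 10
    assert abs(sum(hist.percentages.values()) - 100.0) < 1e-9

    single = RatingMap(np.zeros(5, dtype=np.int16), ("w",), np.arange(5), (5, 1, 1))
    h = rating_histogram(single)
    assert h.percentages == {"w": 100.0}

    empty = RatingMap(np.full(5, UNASSIGNED, dtype=np.int16), ("A", "B"), np.arange(5), (5, 1, 1))
    h = rating_histogram(empty)
    assert h.empty and h.percentages == {} and h.argmax() is None


def test_oracle_equivalence_on_random_grids(rng):
    """Pooled rank/count/rating equals the naive per-voxel oracle on random
    6-cube maps with 9 atlases, including undefined entries."""
    shape = (6, 6, 6)
    T = 5
    conds = ("A", "B", "C")
    values = rng.normal(size=(9, np.prod(shape)))
    defined = rng.random(values.shape) > 0.2
    cond_idx = np.repeat(np.arange(3), 3)
    p = pool_rank_values(values, defined, cond_idx, conds, T=T)
    rmap = build_rating_map(count_conditions(p))
    for v in range(values.shape[1]):
        rows = [i for i in range(9) if defined[i, v]]
        if rows:
            expected = _oracle_rating(
                [values[i, v] for i in rows], [cond_idx[i] for i in rows], T
            )
        else:
            expected = UNASSIGNED
        assert rmap.labels_flat[v] == expected


def test_voxar_diagnose_self_match_dominates(small_cohort):
    target = small_cohort[3]  # a 'switch_a' subject
    dbs = {}
    for s in small_cohort:
        dbs.setdefault(s.condition, []).append(s.image.data)
    dbs[target.condition].append(target.image.data)  # duplicate the target
    roi = np.ones(target.image.data.shape, dtype=bool)
    report = voxar_diagnose(target.image.data, dbs, roi, T=3)
    assert report.predicted == target.condition
    assert report.histogram.percentages[target.condition] > 50.0


def test_voxar_diagnose_identical_databases_is_symmetric(rng):
    """Bit-identical databases yield exactly tied pooled rankings: the
    stable tie-break interleaves the conditions, the per-condition counts
    are equal at every voxel, and no condition can reach the absolute
    majority — the diagnosis is refused rather than arbitrary."""
    imgs = [rng.normal(size=(10, 10, 10)) for _ in range(3)]
    target = rng.normal(size=(10, 10, 10))
    roi = np.ones(target.shape, dtype=bool)
    from voxar.similarity import TargetMoments

    tm = TargetMoments(target, 2.0)
    sims = {c: [tm.lncc_to(i, roi=roi) for i in imgs] for c in ("a", "b", "c")}
    counts = count_conditions(pool_rank(sims, roi, T=3)).counts
    np.testing.assert_array_equal(counts[0], counts[1])
    np.testing.assert_array_equal(counts[1], counts[2])
    report = voxar_diagnose(target, {"a": imgs, "b": list(imgs), "c": list(imgs)}, roi, T=3)
    assert report.status == STATUS_REFUSED and report.predicted is None


def test_voxar_diagnose_refuses_when_nothing_assigned(rng):
    # two databases of 1 atlas each, T=7: max count 1 < threshold 5
    a = rng.normal(size=(8, 8, 8))
    b = rng.normal(size=(8, 8, 8))
    target = rng.normal(size=(8, 8, 8))
    roi = np.ones(target.shape, dtype=bool)
    report = voxar_diagnose(target, {"a": [a], "b": [b]}, roi, T=7)
    assert report.status == STATUS_REFUSED
    assert report.predicted is None
    assert report.histogram.empty


def test_label_permutation_equivariance(rng):
    shape = (6, 6, 6)
    target = rng.normal(size=shape)
    arrs = {c: [rng.normal(size=shape) for _ in range(3)] for c in ("a", "c")}
    # one condition resembles the target so that voxels actually get assigned
    arrs["b"] = [target + 0.3 * rng.normal(size=shape) for _ in range(3)]
    roi = np.ones(shape, dtype=bool)
    base = voxar_diagnose(target, arrs, roi, T=3)
    renamed = {"x_" + c: v for c, v in arrs.items()}
    perm = voxar_diagnose(target, renamed, roi, T=3)
    assert base.predicted is not None
    assert perm.predicted == "x_" + base.predicted
    for c, pct in base.histogram.percentages.items():
        assert perm.histogram.percentages["x_" + c] == pytest.approx(pct)


def test_conservation_of_top_counts(rng):
    shape = (5, 5, 5)
    maps = {c: [_sim(rng.random(shape)) for _ in range(4)] for c in ("a", "b")}
    # knock out some voxels of one atlas
    maps["a"][0].defined[:2] = False
    maps["a"][0].values[:2] = np.nan
    T = 7
    p = pool_rank(maps, np.ones(shape, dtype=bool), T=T)
    counts = count_conditions(p).counts
    np.testing.assert_array_equal(counts.sum(axis=0), np.minimum(T, p.n_defined))
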