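import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from voxar.isa import (
    UNDEFINED_RANK,
    fuse_weighted,
    isa_diagnose,
    rank_in_database,
    rank_values,
    ranks_to_weights,
    synthesize,
)
from voxar.similarity import SimilarityMap


def _sim(values, roi=None):
    values = np.asarray(values, dtype=float)
    defined = ~np.isnan(values)
    return SimilarityMap(values=values, defined=defined, sigma_g=2.0)


def _full_roi(shape):
    return np.ones(shape, dtype=bool)


def test_single_atlas_has_rank_zero_everywhere():
    sm = _sim(np.full((3, 3, 3), 0.4))
    rf = rank_in_database([sm], _full_roi((3, 3, 3)))
    assert (rf.ranks == 0).all()


def test_rank_order_and_stable_ties():
    shape = (1, 1, 1)
    maps = [_sim(np.full(shape, v)) for v in (0.9, 0.2, 0.5)]
    rf = rank_in_database(maps, _full_roi(shape))
    assert rf.ranks[:, 0].tolist() == [0, 2, 1]

    tied = [_sim(np.full(shape, 0.5)), _sim(np.full(shape, 0.5))]
    rf = rank_in_database(tied, _full_roi(shape))
    assert rf.ranks[:, 0].tolist() == [0, 1]  # stable: list order breaks ties


def test_undefined_voxels_ranked_among_defined_only():
    shape = (2, 1, 1)
    a = np.array([0.1, np.nan]).reshape(shape)
    b = np.array([0.9, 0.3]).reshape(shape)
    rf = rank_in_database([_sim(a), _sim(b)], _full_roi(shape))
    assert rf.ranks[:, 0].tolist() == [1, 0]
    assert rf.ranks[0, 1] == UNDEFINED_RANK
    assert rf.ranks[1, 1] == 0


def test_ranks_to_weights_closed_form():
    ranks = np.array([[0], [2]], dtype=np.int32)
    w = ranks_to_weights(ranks, beta=0.5)
    assert w[0, 0] == pytest.approx(1.0)
    assert w[1, 0] == pytest.approx(np.exp(-1.0))
    # strictly decreasing in rank
    many = np.arange(6, dtype=np.int32).reshape(-1, 1)
    assert (np.diff(ranks_to_weights(many, beta=0.5), axis=0) < 0).all()
    assert ranks_to_weights(np.array([[UNDEFINED_RANK]]), beta=0.5)[0, 0] == 0.0


def test_single_atlas_synthesis_reproduces_zscored_atlas(rng):
    img = rng.normal(size=(6, 6, 6))
    roi = _full_roi(img.shape)
    weights = np.ones((1, roi.sum()))
    synth = synthesize([img], weights, roi)
    from voxar.similarity import zscore

    np.testing.assert_allclose(synth.values, zscore(img, roi).ravel(), atol=1e-12)


def test_equal_weights_give_arithmetic_mean(rng):
    a = rng.normal(size=(5, 5, 5))
    b = rng.normal(size=(5, 5, 5))
    roi = _full_roi(a.shape)
    weights = np.full((2, roi.sum()), 0.7)
    synth = synthesize([a, b], weights, roi)
    from voxar.similarity import zscore

    expected = (zscore(a, roi).ravel() + zscore(b, roi).ravel()) / 2
    np.testing.assert_allclose(synth.values, expected, atol=1e-12)


def test_hand_set_weights_fused_value():
    """Oracle: direct evaluation of the normalised weighted average with
    weights (1, e^-0.5, e^-1) and intensities (10, 20, 30)."""
    w = np.array([1.0, np.exp(-0.5), np.exp(-1.0)]).reshape(3, 1)
    v = np.array([10.0, 20.0, 30.0]).reshape(3, 1)
    fused, defined = fuse_weighted(v, w)
    assert defined.all()
    assert fused[0] == pytest.approx(16.798433321701935, abs=1e-12)


@settings(deadline=None, derandomize=True)
@given(st.integers(min_value=1, max_value=6), st.integers(min_value=0, max_value=2**31 - 1))
def test_fusion_convexity(n_atlases, seed):
    rng = np.random.default_rng(seed)
    values = rng.normal(size=(n_atlases, 20))
    weights = rng.random((n_atlases, 20))
    weights[rng.random(weights.shape) < 0.3] = 0.0
    fused, defined = fuse_weighted(values, weights)
    masked = np.where(weights > 0, values, np.nan)
    lo = np.nanmin(masked, axis=0)[defined]
    hi = np.nanmax(masked, axis=0)[defined]
    assert (fused[defined] >= lo - 1e-12).all()
    assert (fused[defined] <= hi + 1e-12).all()


def test_zero_total_weight_everywhere_rejected(rng):
    img = rng.normal(size=(4, 4, 4))
    roi = _full_roi(img.shape)
    with pytest.raises(ValueError, match="zero total weight"):
        synthesize([img], np.zeros((1, roi.sum())), roi)


def test_permuting_atlases_preserves_fusion_without_ties(rng):
    shape = (4, 4, 4)
    roi = _full_roi(shape)
    images = [rng.normal(size=shape) for _ in range(4)]
    sims = [_sim(rng.random(shape)) for _ in range(4)]
    ranks = rank_in_database(sims, roi)
    w = ranks_to_weights(ranks)
    base = synthesize(images, w, roi).values
    perm = [2, 0, 3, 1]
    ranks_p = rank_in_database([sims[i] for i in perm], roi)
    w_p = ranks_to_weights(ranks_p)
    permuted = synthesize([images[i] for i in perm], w_p, roi).values
    np.testing.assert_allclose(base, permuted, atol=1e-10)


def test_isa_diagnoses_database_containing_the_target(small_cohort):
    target = small_cohort[0]  # a 'normal' subject
    dbs = {}
    for s in small_cohort:
        dbs.setdefault(s.condition, []).append(s.image.data)
    roi = np.ones(target.image.data.shape, dtype=bool)
    report = isa_diagnose(dbs, target.image.data, roi)
    assert report.predicted == target.condition
    assert set(report.ncc_scores) == set(dbs)
    assert report.ncc_scores[target.condition] == max(report.ncc_scores.values())


def test_identical_databases_tie_broken_and_logged(rng):
    imgs = [rng.normal(size=(8, 8, 8)) for _ in range(3)]
    target = rng.normal(size=(8, 8, 8))
    roi = np.ones(target.shape, dtype=bool)
    report = isa_diagnose({"b_cond": imgs, "a_cond": list(imgs)}, target, roi)
    scores = report.ncc_scores
    assert abs(scores["a_cond"] - scores["b_cond"]) < 1e-10
    assert report.predicted == "a_cond"  # condition-name order breaks the tie
    assert any("tie" in w for w in report.warnings)


def test_isa_requires_two_conditions(rng):
    img = rng.normal(size=(4, 4, 4))
    with pytest.raises(ValueError, match="two conditions"):
        isa_diagnose({"only": [img]}, img, np.ones(img.shape, dtype=bool))


def test_rank_values_is_permutation_at_every_voxel(rng):
    values = rng.normal(size=(5, 30))
    defined = rng.random((5, 30)) > 0.3
    ranks = rank_values(values, defined)
    for v in range(30):
        col = ranks[defined[:, v], v]
        assert sorted(col.tolist()) == list(range(len(col)))
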