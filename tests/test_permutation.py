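"""Balanced subclass permutation: combinatorics, nulls, p-values."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nestedmvpa import (
    CVScheme,
    LabeledDataset,
    NullDistribution,
    SimParams,
    block_permutation_null,
    count_balanced_assignments,
    cross_validate,
    enumerate_balanced_assignments,
    generate_dataset,
    group_null,
    p_value,
    sample_balanced_assignments,
    trial_permutation_null,
)


def brute_force_balanced_count(K: int) -> int:
    """Independent oracle: enumerate subset pairs, dedupe under label swap."""
    half = K // 2
    class_a = range(K)
    class_b = range(K, 2 * K)
    seen = set()
    for a_part in itertools.combinations(class_a, half):
        for b_part in itertools.combinations(class_b, half):
            c1 = frozenset(a_part) | frozenset(b_part)
            c2 = frozenset(range(2 * K)) - c1
            seen.add(frozenset((c1, c2)))
    return len(seen)


@pytest.mark.parametrize("K,expected", [(2, 2), (4, 18), (10, 31752)])
def test_balanced_assignment_counts(K, expected):
    assert count_balanced_assignments(K) == expected
    assert count_balanced_assignments(K) == math.comb(K, K // 2) ** 2 // 2


@pytest.mark.parametrize("K", [2, 4, 6, 8])
def test_count_matches_brute_force_enumeration(K):
    assert count_balanced_assignments(K) == brute_force_balanced_count(K)
    assignments = list(enumerate_balanced_assignments(K))
    assert len(assignments) == brute_force_balanced_count(K)
    # distinct, and no assignment equals another's label swap
    keys = {frozenset((a.class1_subclasses, a.class2_subclasses)) for a in assignments}
    assert len(keys) == len(assignments)


@pytest.mark.parametrize("K", [1, 3, 5])
def test_odd_subclass_count_rejected(K):
    with pytest.raises(ValueError, match="even"):
        count_balanced_assignments(K)
    with pytest.raises(ValueError):
        list(enumerate_balanced_assignments(K))


@given(K=st.sampled_from([2, 4, 6, 8]))
@settings(max_examples=8, deadline=None, derandomize=True)
def test_every_assignment_is_balanced(K):
    """Each new class gets exactly K/2 subclasses from each original class."""
    class_a = set(range(K))
    class_b = set(range(K, 2 * K))
    for a in enumerate_balanced_assignments(K):
        assert len(a.class1_subclasses & class_a) == K // 2
        assert len(a.class1_subclasses & class_b) == K // 2
        assert a.class1_subclasses | a.class2_subclasses == class_a | class_b
        assert not a.class1_subclasses & a.class2_subclasses


def test_sampling_without_replacement_recovers_full_enumeration(rng):
    full = {a.class1_subclasses for a in enumerate_balanced_assignments(4)}
    sampled = sample_balanced_assignments(4, 18, rng)
    assert {a.class1_subclasses for a in sampled} == full
    with pytest.raises(ValueError):
        sample_balanced_assignments(4, 19, rng)


def test_assignment_relabeling_preserves_nesting(biased_data):
    subs_a = biased_data.subclasses_of(1)
    subs_b = biased_data.subclasses_of(2)
    for a in itertools.islice(
        enumerate_balanced_assignments(10, subs_a, subs_b), 5
    ):
        labels = a.labels_for(biased_data.subclass_labels)
        for sc in np.unique(biased_data.subclass_labels):
            assert len(np.unique(labels[biased_data.subclass_labels == sc])) == 1
        assert (labels == 1).sum() == (labels == 2).sum()


def test_exhaustive_flag_and_draw_counts(toy_data):
    null = block_permutation_null(toy_data, "paper_lda", CVScheme(seed=0),
                                  n_perm=50, seed=1)
    assert null.exhaustive and null.n_draws == 18  # K=4 -> all 18 assignments
    sampled = block_permutation_null(toy_data, "paper_lda", CVScheme(seed=0),
                                     n_perm=10, seed=1)
    assert not sampled.exhaustive and sampled.n_draws == 10


def test_block_null_mean_inflated_by_subclasses(biased_data):
    null = block_permutation_null(biased_data, "paper_lda", CVScheme(seed=0),
                                  n_perm=60, seed=2)
    assert null.ccrs.mean() > 0.55


def test_trial_null_centred_at_chance(biased_data):
    null = trial_permutation_null(biased_data, "paper_lda", CVScheme(seed=0),
                                  n_perm=120, seed=2)
    se = null.ccrs.std(ddof=1) / np.sqrt(null.n_draws)
    assert abs(null.ccrs.mean() - 0.5) < 4 * se + 1e-9


def test_trial_null_below_block_null_with_subclasses(biased_data):
    """Subclass structure lifts the block null above the trial null."""
    block = block_permutation_null(biased_data, "paper_lda", CVScheme(seed=0),
                                   n_perm=60, seed=3)
    trial = trial_permutation_null(biased_data, "paper_lda", CVScheme(seed=0),
                                   n_perm=60, seed=3)
    assert trial.ccrs.mean() < block.ccrs.mean() - 0.1


def test_schemes_coincide_without_subclass_variance(rng):
    """With sigma_S = 0 both null schemes are centred at the same chance level."""
    block_means, trial_means = [], []
    for _ in range(15):
        data = generate_dataset(
            SimParams(d=5, K=4, N=10, sigma_C=0, sigma_S=0, sigma_W=1,
                      seed=int(rng.integers(2**31)))
        )
        cv = CVScheme(seed=int(rng.integers(2**31)))
        block_means.append(
            block_permutation_null(data, "paper_lda", cv, 18, int(rng.integers(2**31))).ccrs.mean()
        )
        trial_means.append(
            trial_permutation_null(data, "paper_lda", cv, 18, int(rng.integers(2**31))).ccrs.mean()
        )
    assert abs(np.mean(block_means) - 0.5) < 0.02
    assert abs(np.mean(block_means) - np.mean(trial_means)) < 0.02


def test_block_permutation_rejects_unequal_subclass_counts():
    rng = np.random.default_rng(0)
    features = rng.normal(size=(60, 4))
    classes = np.repeat([1, 2], 30)
    subclasses = np.r_[np.repeat([1, 2], 15), np.repeat([3, 4, 5], 10)]
    data = LabeledDataset(features, classes, subclasses)
    with pytest.raises(ValueError, match="equal number of subclasses"):
        block_permutation_null(data, "paper_lda", CVScheme(seed=0), 10, 0)


def _null(ccrs, exhaustive=False):
    ccrs = np.asarray(ccrs, dtype=float)
    return NullDistribution(ccrs, "trial_wise", len(ccrs), exhaustive)


def test_p_value_add_one_estimator():
    null = _null(np.linspace(0.3, 0.59, 999))
    assert p_value(0.6, null) == pytest.approx(1 / 1000)
    assert p_value(0.2, null) == 1.0
    median_null = _null(np.linspace(0, 1, 1000))
    assert p_value(0.5, median_null) == pytest.approx(0.5, abs=0.01)


def test_p_value_exhaustive_convention():
    null = _null(np.linspace(0.4, 0.6, 18), exhaustive=True)
    assert p_value(0.99, null) == pytest.approx(1 / 18)
    assert p_value(0.5, null) == pytest.approx(
        np.mean(np.linspace(0.4, 0.6, 18) >= 0.5), abs=1 / 18
    )


@given(
    ccrs=st.lists(st.floats(0, 1), min_size=1, max_size=50),
    observed=st.floats(0, 1),
)
@settings(max_examples=50, deadline=None, derandomize=True)
def test_p_value_bounds(ccrs, observed):
    p = p_value(observed, _null(ccrs))
    assert 0 < p <= 1


def test_group_null_single_subject_reduces_to_subject_p(rng):
    null = _null(np.linspace(0.35, 0.75, 200))
    observed = 0.68
    p_single = p_value(observed, null)
    p_group, _ = group_null([null], [observed], n_resample=20_000, seed=4)
    assert p_group == pytest.approx(p_single, abs=0.01)


def test_group_null_degenerate_nulls():
    nulls = [_null([0.5] * 10) for _ in range(5)]
    p, dist = group_null(nulls, [0.6] * 5, n_resample=1000, seed=0)
    assert p == pytest.approx(1 / 1001)
    assert np.all(dist.ccrs == 0.5)


def test_group_null_matches_product_space_oracle(rng):
    """Resampled group p agrees with exhaustive enumeration over tiny nulls."""
    subject_nulls = [
        [0.4, 0.5, 0.65],
        [0.45, 0.55, 0.6, 0.7],
        [0.35, 0.5, 0.62, 0.58, 0.49],
    ]
    observed = [0.6, 0.58, 0.57]
    obs_mean = np.mean(observed)
    combos = [np.mean(c) for c in itertools.product(*subject_nulls)]
    exact = np.mean(np.asarray(combos) >= obs_mean)
    p, _ = group_null([_null(n) for n in subject_nulls], observed,
                      n_resample=40_000, seed=9)
    assert p == pytest.approx(exact, abs=0.01)


def test_group_null_input_validation():
    with pytest.raises(ValueError):
        group_null([], [], n_resample=10)
    with pytest.raises(ValueError):
        group_null([_null([0.5])], [0.5, 0.6], n_resample=10)
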