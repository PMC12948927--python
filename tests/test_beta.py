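import itertools

import numpy as np
import pytest
from scipy.spatial.distance import jaccard as scipy_jaccard

from slime.beta import (
    BetaResult,
    build_null,
    classify_pattern,
    jaccard_dissimilarity,
    pair_label,
    pairwise_beta,
    time_differential_bias_check,
    within_experiment_beta,
    zscore,
)
from slime.simulate import SimConfig, simulate_dataset

from conftest import make_table


# ---------------------------------------------------------------------------
# Jaccard


def test_jaccard_examples():
    assert jaccard_dissimilarity({"x", "y"}, {"x", "y"}) == 0.0
    assert jaccard_dissimilarity({"x"}, {"y"}) == 1.0
    assert jaccard_dissimilarity({"x", "y", "z"}, {"y", "z", "w"}) == pytest.approx(0.5)


def test_jaccard_both_empty_rejected():
    with pytest.raises(ValueError, match="empty"):
        jaccard_dissimilarity(set(), set())


def test_jaccard_matches_scipy_on_all_subset_pairs():
    """Independent-route check against scipy's boolean Jaccard distance."""
    universe = list(range(5))
    for mask_a in range(1, 2 ** len(universe)):
        for mask_b in range(1, 2 ** len(universe)):
            a = {u for u in universe if mask_a >> u & 1}
            b = {u for u in universe if mask_b >> u & 1}
            va = np.array([u in a for u in universe])
            vb = np.array([u in b for u in universe])
            assert jaccard_dissimilarity(a, b) == pytest.approx(scipy_jaccard(va, vb))


# ---------------------------------------------------------------------------
# null model


def test_build_null_deterministic():
    pool = [f"a{i}" for i in range(30)]
    n1 = build_null(pool[:20], pool[10:], 8, 12, n_mock=400, n_pairs=200, seed=3)
    n2 = build_null(pool[:20], pool[10:], 8, 12, n_mock=400, n_pairs=200, seed=3)
    assert np.array_equal(n1.draws, n2.draws)
    n3 = build_null(pool[:20], pool[10:], 8, 12, n_mock=400, n_pairs=200, seed=4)
    assert not np.array_equal(n1.draws, n3.draws)


def test_build_null_saturated_pool_is_degenerate():
    pool = ["a", "b", "c"]
    null = build_null(pool, pool, 3, 3, n_mock=100, n_pairs=50, seed=0)
    assert (null.draws == 0).all()
    assert null.degenerate
    result = zscore(0.5, null, "After")
    assert np.isnan(result.z)
    assert result.reason is not None


def test_build_null_mean_matches_exhaustive_enumeration():
    """Pool of 4, richness (2, 2): compare against all (C(4,2))^2 pairs."""
    universe = list("wxyz")
    exact = [
        1 - len(set(a) & set(b)) / len(set(a) | set(b))
        for a in itertools.combinations(universe, 2)
        for b in itertools.combinations(universe, 2)
    ]
    null = build_null(universe[:2], universe[1:], 2, 2, n_mock=10_000, n_pairs=1_000, seed=2)
    se = np.std(exact) / np.sqrt(null.n_pairs)
    assert null.mean == pytest.approx(np.mean(exact), abs=3 * se)
    # moments recomputable from the stored draws
    assert null.mean == pytest.approx(float(null.draws.mean()), abs=1e-12)
    assert null.sd == pytest.approx(float(null.draws.std(ddof=1)), abs=1e-12)


def test_build_null_validates_inputs():
    with pytest.raises(ValueError, match="exceeds"):
        build_null(["a"], ["b"], 3, 1, n_mock=10, n_pairs=5)
    with pytest.raises(ValueError, match="n_pairs"):
        build_null(list("abcd"), list("abcd"), 2, 2, n_mock=10, n_pairs=8)


def test_build_null_uniform_richness_rule():
    pool = [f"a{i}" for i in range(20)]
    null = build_null(pool, pool, 5, 10, n_mock=200, n_pairs=100, seed=1,
                      richness_rule="uniform")
    assert len(null.draws) == 100
    assert ((null.draws >= 0) & (null.draws <= 1)).all()


# ---------------------------------------------------------------------------
# z-scores


def test_zscore_centering_and_threshold():
    pool = [f"a{i}" for i in range(40)]
    null = build_null(pool, pool, 10, 10, n_mock=2_000, n_pairs=1_000, seed=0)
    assert zscore(null.mean, null).z == pytest.approx(0.0)
    # strict inequality: just inside the band is not significant, just outside is
    inside = zscore(null.mean - 1.9599 * null.sd, null)
    assert inside.z == pytest.approx(-1.96, abs=1e-3)
    assert not inside.significant and not inside.convergent
    outside = zscore(null.mean - 1.9601 * null.sd, null)
    assert outside.significant and outside.convergent


def test_zscore_direct_arithmetic():
    pool = ["p", "q"]
    null = build_null(pool, pool, 1, 1, n_mock=100, n_pairs=50, seed=0)
    null.draws = np.array([0.85, 0.95] * 25)  # mean 0.9, sd ~0.0505
    null.draws = (null.draws - null.draws.mean()) / null.draws.std(ddof=1) * 0.05 + 0.9
    result = zscore(0.3, null)
    assert result.z == pytest.approx((0.3 - 0.9) / 0.05)
    assert result.z == pytest.approx(-12.0)
    assert result.significant and result.convergent


# ---------------------------------------------------------------------------
# pattern classification


def _triple(zs, pair="e1~e2"):
    out = []
    for cat, z in zip(("Before", "After", "Furthest"), zs):
        if z is None:
            out.append(None)
        else:
            out.append(BetaResult(pair, cat, 0.5, z, abs(z) > 1.96))
    return out


@pytest.mark.parametrize(
    "zs, label",
    [
        ((-5, -6, -7), "persistent_convergence"),
        ((0.09, -1.30, -3.58), "progressive_convergence"),  # reported pair 2-4
        ((-0.67, -3.39, -0.32), "transient_convergence"),  # reported pair 1-2
        ((-1.25, -1.56, -0.18), "null_like"),  # reported pair 1-5
        ((-7.78, -4.01, -5.0), "persistent_convergence"),  # pairs 2-3 / 3-4 range
        ((0.5, 0.5, 0.5), "null_like"),
        ((3.2, 2.5, 4.0), "null_like"),  # significantly MORE dissimilar: not convergent
        ((-2.5, -1.0, -2.2), "null_like"),  # atypical: lapses after a significant start
        ((-1.0, -2.5, -2.2), "progressive_convergence"),
    ],
)
def test_classify_pattern_rule_table(zs, label):
    assert classify_pattern(*_triple(zs)).label == label


def test_classify_pattern_atypical_and_partial():
    atypical = classify_pattern(*_triple((-3.0, -0.5, -0.5)))
    assert atypical.label == "null_like" and atypical.atypical
    partial = classify_pattern(*_triple((None, -3.0, -3.0)))
    assert partial.partial
    assert partial.label == "progressive_convergence"


# ---------------------------------------------------------------------------
# within-experiment comparisons


def test_within_identical_consecutive_samples_strongly_negative():
    # first two samples identical, third adds pool so the null is non-degenerate
    counts = [
        [1, 1, 1, 1, 0, 0, 0, 0],
        [1, 1, 1, 1, 0, 0, 0, 0],
        [0, 0, 1, 1, 1, 1, 1, 1],
    ]
    table = make_table("e", counts, days=[-1, 3, 8])
    results = within_experiment_beta(table, n_mock=2_000, n_pairs=1_000, seed=0)
    assert results[0].observed == 0.0
    assert results[0].z < -1.96
    # observed dissimilarity 0 gives the minimum attainable z against this null
    assert results[0].z <= results[1].z


def test_within_disjoint_samples_nonnegative_z():
    counts = [
        [1, 1, 1, 0, 0, 0, 0, 0, 0],
        [0, 0, 0, 1, 1, 1, 0, 0, 0],
        [0, 0, 0, 0, 0, 0, 1, 1, 1],
    ]
    table = make_table("e", counts, days=[-1, 3, 8])
    results = within_experiment_beta(table, n_mock=2_000, n_pairs=1_000, seed=0)
    assert np.mean([r.observed for r in results]) == 1.0
    assert np.mean([r.z for r in results]) >= 0


def test_within_single_sample_empty():
    table = make_table("e", [[1, 2]], days=[0])
    assert within_experiment_beta(table) == []


def test_within_all_pairs_mode():
    table = make_table("e", [[1, 1, 0], [1, 0, 1], [0, 1, 1]], days=[-1, 3, 8])
    consecutive = within_experiment_beta(table, n_mock=200, n_pairs=100, seed=0)
    allpairs = within_experiment_beta(table, n_mock=200, n_pairs=100, seed=0, mode="all")
    assert len(consecutive) == 2
    assert len(allpairs) == 3


# ---------------------------------------------------------------------------
# Spearman bias check


def test_bias_check_flags_monotone_dependence():
    gaps = [1, 2, 3, 4, 5]
    zs = [-5.0, -4.0, -3.0, -2.0, -1.0]
    report = time_differential_bias_check(zs, gaps)
    assert report.rho == pytest.approx(1.0)
    assert report.p_value <= 0.05
    assert report.biased


def test_bias_check_insufficient_n():
    with pytest.raises(ValueError, match=">= 5"):
        time_differential_bias_check([0.1, 0.2], [1, 2])


def test_bias_check_constant_input_undefined():
    report = time_differential_bias_check([1, 2, 3, 4, 5], [2, 2, 2, 2, 2])
    assert np.isnan(report.p_value)
    assert not report.biased


def test_bias_check_type_one_rate_under_independence():
    """Independent z and gaps: bias flagged in <= 10% of 200 seeded runs."""
    rng = np.random.default_rng(123)
    flags = 0
    for _ in range(200):
        z = rng.normal(size=20)
        gaps = rng.integers(0, 30, size=20)
        if len(set(gaps.tolist())) == 1:
            continue
        flags += time_differential_bias_check(z, gaps).biased
    assert flags <= 20


# ---------------------------------------------------------------------------
# pair independence under the seeding scheme


def test_adding_an_experiment_leaves_existing_pairs_unchanged():
    cfg5 = SimConfig(seed=9)
    cfg6 = SimConfig(seed=9, n_experiments=6,
                     injections=tuple(list(SimConfig().injections) + [(0,)]),
                     refills=tuple(list(SimConfig().refills) + [()]),
                     h2_percent=(10.0, 10.0, 2.0, 2.0, 2.0, 2.0))
    ds5, ds6 = simulate_dataset(cfg5), simulate_dataset(cfg6)
    pw5 = pairwise_beta(ds5.tables, ds5.designs, n_mock=400, n_pairs=200, seed=9)
    pw6 = pairwise_beta(ds6.tables, ds6.designs, n_mock=400, n_pairs=200, seed=9)
    z5 = {(r.pair, r.category): r.z for r in pw5.results}
    z6 = {(r.pair, r.category): r.z for r in pw6.results}
    assert set(z5) <= set(z6)
    for key, z in z5.items():
        assert z == z6[key]
    assert len(pw6.patterns) == 15 and len(pw5.patterns) == 10


def test_pair_label_is_order_free():
    assert pair_label("b", "a") == pair_label("a", "b") == "a~b"


def test_expected_z_nonincreasing_in_shared_pool_fraction():
    """More engineered sharing can only depress the convergence z-score."""
    mean_z = []
    for fraction in (0.0, 0.4, 0.8):
        zs = []
        for seed in range(40):
            cfg = SimConfig(
                n_experiments=2, shared_experiments=(1, 2),
                shared_pool_fraction=fraction, global_pool_size=250,
                shared_pool_size=80, sampling_days=(-15, -1, 3, 8),
                injections=((0,), (0,)), refills=((), ()),
                h2_percent=(10.0, 10.0), depth=1_000, seed=seed,
            )
            ds = simulate_dataset(cfg)
            pw = pairwise_beta(ds.tables, ds.designs, n_mock=400, n_pairs=200, seed=seed)
            zs.extend(r.z for r in pw.results)
        mean_z.append(np.mean(zs))
    assert mean_z[0] > mean_z[1] > mean_z[2]
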