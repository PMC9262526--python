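"""Unit and oracle tests for the graded-response CAT engine."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tcmcat.cat_engine import (
    AbilityPrior,
    CATConfig,
    Item,
    ItemBank,
    administer_cat,
    element_information,
    generate_item_bank,
    item_information,
    map_estimate,
    response_probability,
    select_next_item,
)


def _random_item(rng, element=None, n_cat=4, item_id=1):
    e = int(rng.integers(0, 6)) if element is None else element
    a = float(rng.lognormal(0.2, 0.3))
    b = np.sort(rng.normal(0, 1, n_cat - 1))
    b += np.arange(n_cat - 1) * 1e-3  # guarantee strict increase
    return Item(item_id=item_id, element_index=e, discrimination=a, thresholds=tuple(b))


# ---------------------------------------------------------------------------
# response probabilities
# ---------------------------------------------------------------------------


@given(
    a=st.floats(0.2, 3.0),
    b0=st.floats(-2.0, 2.0),
    gap=st.floats(0.1, 2.0),
    th=st.floats(-4.0, 4.0),
    e=st.integers(0, 5),
)
def test_response_probability_is_a_distribution(a, b0, gap, th, e):
    item = Item(item_id=1, element_index=e, discrimination=a, thresholds=(b0, b0 + gap))
    theta = np.zeros(6)
    theta[e] = th
    p = response_probability(item, theta)
    assert p.shape == (3,)
    assert abs(p.sum() - 1.0) < 1e-12
    assert np.all(p > 0) and np.all(p < 1)


def test_cumulative_probability_half_at_threshold():
    item = Item(item_id=1, element_index=2, discrimination=1.7, thresholds=(-0.5, 0.8))
    theta = np.zeros(6)
    theta[2] = 0.8  # at the second threshold, P(X >= 2) = 1/2 exactly
    p = response_probability(item, theta)
    assert p[2] == pytest.approx(0.5, abs=1e-15)


def test_flat_item_limit_is_theta_independent():
    item = Item(item_id=1, element_index=0, discrimination=1e-9, thresholds=(-1.0, 1.0))
    t1, t2 = np.zeros(6), np.zeros(6)
    t1[0], t2[0] = -3.0, 3.0
    np.testing.assert_allclose(
        response_probability(item, t1), response_probability(item, t2), atol=1e-8
    )


def test_response_probability_rejects_nonfinite_theta():
    item = Item(item_id=1, element_index=0, discrimination=1.0, thresholds=(0.0,))
    with pytest.raises(ValueError):
        response_probability(item, np.array([np.nan, 0, 0, 0, 0, 0]))


# ---------------------------------------------------------------------------
# information
# ---------------------------------------------------------------------------


def test_item_information_between_item_structure(rng):
    for _ in range(50):
        item = _random_item(rng)
        theta = rng.normal(0, 1.5, 6)
        info = item_information(item, theta)
        e = item.element_index
        assert info[e, e] >= 0
        off = info.copy()
        off[e, e] = 0.0
        assert np.all(off == 0.0)


def test_item_information_matches_expected_negative_hessian(rng):
    """Fisher information == expected (over categories) negative second
    derivative of the log-likelihood, by central finite differences."""
    h = 1e-4
    for _ in range(10):
        item = _random_item(rng, n_cat=5)
        theta = rng.normal(0, 1, 6)
        e = item.element_index

        def logp(th_e, k):
            th = theta.copy()
            th[e] = th_e
            return np.log(response_probability(item, th)[k])

        p0 = response_probability(item, theta)
        expected = 0.0
        for k in range(item.n_categories):
            d2 = (logp(theta[e] + h, k) - 2 * logp(theta[e], k) + logp(theta[e] - h, k)) / h**2
            expected -= p0[k] * d2
        assert element_information(item, theta[e]) == pytest.approx(expected, abs=1e-4)


def test_bank_vectorized_information_matches_scalar(small_bank, rng):
    theta = rng.normal(0, 1, 6)
    vec = small_bank.information_all(theta)
    scalar = np.array(
        [element_information(it, theta[it.element_index]) for it in small_bank.items]
    )
    np.testing.assert_allclose(vec, scalar, rtol=1e-12)


# ---------------------------------------------------------------------------
# D-optimal selection
# ---------------------------------------------------------------------------


def _brute_force_select(bank, administered, theta, prior):
    """Exhaustive argmax of det(prior precision + administered + candidate)."""
    A = prior.precision.copy()
    for iid in administered:
        A += item_information(bank[iid], theta)
    best_id, best_det = None, -np.inf
    for it in bank.items:
        if it.item_id in administered:
            continue
        det = np.linalg.det(A + item_information(it, theta))
        if det > best_det:
            best_id, best_det = it.item_id, det
    return best_id


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_select_matches_exhaustive_determinant_search(small_bank, prior, seed):
    rng = np.random.default_rng(seed)
    theta = rng.normal(0, 1, 6)
    administered = []
    for _ in range(8):
        chosen = select_next_item(small_bank, administered, theta, prior)
        assert chosen == _brute_force_select(small_bank, administered, theta, prior)
        administered.append(chosen)


def test_select_tie_break_lowest_id(prior):
    items = [
        Item(item_id=i, element_index=0, discrimination=1.5, thresholds=(-0.5, 0.5))
        for i in (4, 9, 2)
    ]
    bank = ItemBank(items)
    assert select_next_item(bank, [], np.zeros(6), prior) == 2


def test_select_concentrates_on_unconstrained_element(small_bank):
    """With near-infinite prior precision on five elements, the determinant
    gain is dominated by the free coordinate, so its items are selected."""
    cov = np.eye(6) * 1e-8
    cov[3, 3] = 1.0
    prior = AbilityPrior(np.zeros(6), cov)
    administered = []
    for _ in range(3):
        chosen = select_next_item(small_bank, administered, np.zeros(6), prior)
        assert chosen == _brute_force_select(small_bank, administered, np.zeros(6), prior)
        assert small_bank[chosen].element_index == 3
        administered.append(chosen)


def test_select_exhausted_bank_raises(small_bank, prior):
    all_ids = list(small_bank.item_ids)
    with pytest.raises(ValueError):
        select_next_item(small_bank, all_ids, np.zeros(6), prior)


# ---------------------------------------------------------------------------
# MAP estimation
# ---------------------------------------------------------------------------


def test_map_with_no_items_returns_prior():
    cov = np.eye(6) * 0.7 + 0.2
    prior = AbilityPrior(np.ones(6) * 0.3, cov)
    res = map_estimate([], [], prior)
    np.testing.assert_array_equal(res.theta_hat, prior.mean)
    np.testing.assert_allclose(res.posterior_se, np.sqrt(np.diag(cov)))


def _grid_search_1d(items, responses, prior, e, lo=-3.0, hi=3.0, step=0.01):
    grid = np.arange(lo, hi + step, step)
    best, best_lp = None, -np.inf
    for g in grid:
        theta = prior.mean.copy()
        theta[e] = g
        lp = sum(
            np.log(response_probability(it, theta)[r]) for it, r in zip(items, responses)
        )
        dev = theta - prior.mean
        lp -= 0.5 * dev @ prior.precision @ dev
        if lp > best_lp:
            best, best_lp = g, lp
    return best


def test_map_matches_grid_search_one_element(prior, rng):
    items = [_random_item(rng, element=2, item_id=i) for i in (1, 2)]
    responses = [1, 2]
    res = map_estimate(items, responses, prior)
    grid_max = _grid_search_1d(items, responses, prior, e=2)
    assert res.theta_hat[2] == pytest.approx(grid_max, abs=0.02)
    # untouched elements stay at the prior mean
    np.testing.assert_allclose(np.delete(res.theta_hat, 2), 0.0, atol=1e-9)


def test_map_matches_grid_search_two_elements(prior, rng):
    items = [_random_item(rng, element=0, item_id=1), _random_item(rng, element=4, item_id=2)]
    responses = [0, 2]
    res = map_estimate(items, responses, prior)
    for e, (it, r) in zip((0, 4), zip(items, responses)):
        grid_max = _grid_search_1d([it], [r], prior, e=e)
        assert res.theta_hat[e] == pytest.approx(grid_max, abs=0.02)


def test_map_gradient_norm_below_tolerance(prior, rng):
    items = [_random_item(rng, item_id=i) for i in range(1, 11)]
    responses = [int(rng.integers(0, it.n_categories)) for it in items]
    cfg = CATConfig(newton_tol=1e-8)
    res = map_estimate(items, responses, prior, cfg)
    assert res.converged


# ---------------------------------------------------------------------------
# adaptive sessions
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def recovery_sessions(default_bank, prior, cat_config):
    """200 simulated sessions on the default bank, shared across tests."""
    rng = np.random.default_rng(11)
    truths, results = [], []
    for _ in range(200):
        th = rng.normal(0, 1, 6)
        truths.append(th)
        results.append(
            administer_cat(default_bank, true_theta=th, config=cat_config, prior=prior, rng=rng)
        )
    return np.array(truths), results


def test_session_structure_and_determinism(small_bank, prior):
    cfg = CATConfig(max_items=10)
    th = np.linspace(-1, 1, 6)
    r1 = administer_cat(small_bank, th, cfg, prior, np.random.default_rng(5))
    r2 = administer_cat(small_bank, th, cfg, prior, np.random.default_rng(5))
    assert len(r1.administered) == len(r1.responses) == 10
    assert len(set(r1.administered)) == 10
    assert r1.administered == r2.administered and r1.responses == r2.responses
    np.testing.assert_array_equal(r1.theta_hat, r2.theta_hat)
    np.testing.assert_allclose(r1.raw_cat_score, 50 + 10 * r1.theta_hat)


def test_rmse_decreases_with_more_items(recovery_sessions):
    truths, results = recovery_sessions
    th5 = np.array([r.trajectory[4]["theta_hat"] for r in results])
    th20 = np.array([r.theta_hat for r in results])
    rmse5 = np.sqrt(((th5 - truths) ** 2).mean(axis=0))
    rmse20 = np.sqrt(((th20 - truths) ** 2).mean(axis=0))
    assert np.all(rmse20 < rmse5)


def test_parameter_recovery_guard(recovery_sessions):
    truths, results = recovery_sessions
    th20 = np.array([r.theta_hat for r in results])
    assert np.all(np.abs(th20 - truths).mean(axis=0) < 0.6)


def test_posterior_se_nonincreasing_in_expectation(recovery_sessions):
    _, results = recovery_sessions
    mean_se = np.array(
        [[np.mean(step["posterior_se"]) for step in r.trajectory] for r in results]
    ).mean(axis=0)
    assert np.all(np.diff(mean_se) < 1e-6)


def test_doptimal_beats_random_selection(small_bank, prior):
    ses = {"d_optimal": [], "random": []}
    for rule in ses:
        cfg = CATConfig(max_items=12, selection_rule=rule)
        rng = np.random.default_rng(1)
        for _ in range(100):
            th = rng.normal(0, 1, 6)
            res = administer_cat(small_bank, th, cfg, prior, rng)
            ses[rule].append(np.mean(res.posterior_se))
    assert np.mean(ses["d_optimal"]) <= np.mean(ses["random"])


def test_bank_exhaustion_error(small_bank, prior):
    with pytest.raises(ValueError):
        administer_cat(small_bank, np.zeros(6), CATConfig(max_items=50), prior)


# ---------------------------------------------------------------------------
# bank generation and serialization
# ---------------------------------------------------------------------------


def test_generate_default_bank_sizes(default_bank):
    assert len(default_bank) == 215
    counts = default_bank.n_per_element()
    assert set(counts.tolist()) <= {35, 36} and counts.sum() == 215


def test_bank_thresholds_strictly_increasing(default_bank):
    for it in default_bank.items:
        assert np.all(np.diff(it.thresholds) > 0)


def test_bank_seed_reproducibility_and_roundtrip(tmp_path):
    b1 = generate_item_bank(n_items=30, seed=3)
    b2 = generate_item_bank(n_items=30, seed=3)
    assert b1.to_json() == b2.to_json()
    path = tmp_path / "bank.csv"
    b1.to_csv(path)
    b3 = ItemBank.read_csv(path)
    np.testing.assert_allclose(
        [it.discrimination for it in b1.items], [it.discrimination for it in b3.items]
    )
    assert [it.thresholds for it in b1.items] == [it.thresholds for it in b3.items]


def test_item_validation():
    with pytest.raises(ValueError):
        Item(item_id=1, element_index=0, discrimination=-1.0, thresholds=(0.0,))
    with pytest.raises(ValueError):
        Item(item_id=1, element_index=0, discrimination=1.0, thresholds=(0.5, 0.5))
    with pytest.raises(ValueError):
        generate_item_bank(n_items=3)
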