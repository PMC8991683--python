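"""Derived statistics: normalization, policy fields, matches, incidence, Welch."""

import numpy as np
import pytest
from scipy import stats as sps

import epiforage as ef
from epiforage.analysis import match_statistics
from epiforage.memory import MemoryBank, snapshot


# --------------------------------------------------------------------------
# Performance normalization
# --------------------------------------------------------------------------


def test_normalization_anchors(open_field):
    r_star = ef.optimal_average_reward(open_field)
    assert ef.normalize_performance([-2.5] * 10, open_field) == 0.0
    assert ef.normalize_performance([r_star] * 10, open_field) == pytest.approx(100.0)
    mid = (-2.5 + r_star) / 2
    assert ef.normalize_performance([mid], open_field) == pytest.approx(50.0)
    # affine and order preserving in the mean raw score
    lo = ef.normalize_performance([0.0], open_field)
    hi = ef.normalize_performance([5.0], open_field)
    assert hi > lo
    assert ef.normalize_performance([2.5], open_field) == pytest.approx((lo + hi) / 2)
    with pytest.raises(ValueError):
        ef.normalize_performance([], open_field)


# --------------------------------------------------------------------------
# Direction and entropy closed forms
# --------------------------------------------------------------------------


def test_preferred_direction_cases():
    assert np.allclose(ef.preferred_direction([0.25] * 4), (0.0, 0.0))
    assert np.allclose(ef.preferred_direction([0, 1, 0, 0]), (0.0, 1.0))  # Up
    assert np.allclose(ef.preferred_direction([1, 0, 0, 0]), (0.0, -1.0))  # Down
    assert np.allclose(ef.preferred_direction([0, 0.5, 0, 0.5]), (0.5, 0.5))
    # the mean displacement never exceeds unit length
    rng = np.random.default_rng(2)
    for _ in range(50):
        p = rng.dirichlet(np.ones(4))
        assert np.linalg.norm(ef.preferred_direction(p)) <= 1.0 + 1e-12


def test_policy_entropy_cases():
    assert ef.policy_entropy([0.25] * 4) == pytest.approx(np.log(4))
    assert ef.policy_entropy([1, 0, 0, 0]) == 0.0
    assert ef.policy_entropy([0.5, 0.5, 0, 0]) == pytest.approx(np.log(2))


# --------------------------------------------------------------------------
# Policy fields from snapshots
# --------------------------------------------------------------------------


def _toy_bank_and_snapshot(env, enc, rng, n=60):
    bank = MemoryBank(n, enc.dim)
    for s in rng.choice(env.n_states, n, replace=False):
        ef.write_event(bank, enc.table[s], int(rng.integers(4)), float(rng.normal()), state=int(s))
    return bank, snapshot(bank)


def test_average_policy_fields_idempotence(open_field, rng):
    enc = ef.successor_encoding(open_field)
    bank, snap = _toy_bank_and_snapshot(open_field, enc, rng)
    single = ef.average_policy_fields([(0, snap)], open_field, enc, window=1)
    repeated = ef.average_policy_fields([(i, snap) for i in range(4)], open_field, enc, window=4)
    assert np.allclose(single.directions, repeated.directions)
    assert np.allclose(single.entropy, repeated.entropy)
    assert np.all((single.entropy >= 0) & (single.entropy <= np.log(4) + 1e-12))
    assert np.all(np.abs(single.directions) <= 1 + 1e-12)
    with pytest.raises(ValueError):
        ef.average_policy_fields([(0, snap)], open_field, enc, window=2)
    # the field matches per-state recall + closed-form direction/entropy
    pmap = ef.policy_map(bank, open_field, enc)
    probe = 123
    assert np.allclose(single.directions[probe], ef.preferred_direction(pmap[probe]))
    assert single.entropy[probe] == pytest.approx(ef.policy_entropy(pmap[probe]))


# --------------------------------------------------------------------------
# Match statistics
# --------------------------------------------------------------------------


def _fake_result(success, n_recalls, n_exact, nonexact_sum):
    class R:
        pass

    r = R()
    r.success = np.asarray(success, dtype=bool)
    r.n_recalls = np.asarray(n_recalls)
    r.n_exact = np.asarray(n_exact)
    r.nonexact_dist_sum = np.asarray(nonexact_sum, dtype=float)
    return r


def test_match_statistics_group_arithmetic():
    r = _fake_result(
        success=[True, True, False],
        n_recalls=[4, 6, 10],
        n_exact=[4, 3, 0],
        nonexact_sum=[0.0, 1.5, 25.0],
    )
    out = match_statistics(r)
    assert out["success"].exact_pct == pytest.approx(100 * 7 / 10)
    assert out["success"].mean_nonexact_distance == pytest.approx(1.5 / 3)
    assert out["failure"].exact_pct == 0.0
    assert out["failure"].mean_nonexact_distance == pytest.approx(2.5)
    # a group with no recall events returns the undefined marker, not zero
    empty = match_statistics(_fake_result([True], [0], [0], [0.0]))
    assert np.isnan(empty["failure"].exact_pct)
    assert np.isnan(empty["failure"].mean_nonexact_distance)


def test_onehot_nonmatch_distance_is_one(ladder_runs):
    """Disjoint onehot keys: every non-exact recall sits at distance 1,
    whatever the forgetting condition."""
    for frac in (0.75, 0.25):
        r = ladder_runs[("onehot", frac, 0)]
        out = match_statistics(r)
        for group in out.values():
            if not np.isnan(group.mean_nonexact_distance):
                assert group.mean_nonexact_distance == pytest.approx(1.0)
            assert np.isnan(group.exact_pct) or 0 <= group.exact_pct <= 100


def test_successful_episodes_have_more_exact_matches(ladder_runs):
    """Finding exact or near matches in memory tracks success."""
    r = ladder_runs[("successor", 0.75, 0)]
    out = match_statistics(r)
    assert out["success"].exact_pct > out["failure"].exact_pct or np.isnan(
        out["failure"].exact_pct
    )


# --------------------------------------------------------------------------
# Trajectory sampling
# --------------------------------------------------------------------------


def test_sample_trajectories_read_only_and_bounded(open_field, rng):
    enc = ef.successor_encoding(open_field)
    _, snap = _toy_bank_and_snapshot(open_field, enc, rng, n=80)
    before = [dict(e) for e in snap["entries"]]
    lengths = ef.sample_trajectories([(0, snap), (1, snap)], open_field, enc, 5, rng)
    assert lengths.shape == (10,)
    assert np.all((lengths >= 1) & (lengths <= 250))
    assert snap["entries"] == before  # frozen bank, no writes


def test_optimal_bank_trajectory_length_matches_lambda(open_field, rng):
    """A bank whose every policy is deterministic-optimal walks straight to
    the reward: mean sampled length equals λ, the mean geodesic distance."""
    enc = ef.onehot_encoding(open_field)
    dist = ef.distances_from(open_field, open_field.reward_state)
    bank = MemoryBank(400, 400)
    for s in range(400):
        if s == open_field.reward_index:
            continue
        best = int(np.argmin([dist[open_field.next_state[s, a]] for a in range(4)]))
        ef.write_event(bank, enc.table[s], best, 50.0, state=s)
    snap = snapshot(bank)
    lengths = ef.sample_trajectories([(0, snap)], open_field, enc, 800, rng)
    lam = ef.mean_distance_to_reward(open_field)
    sem = lengths.std(ddof=1) / np.sqrt(lengths.size)
    assert abs(lengths.mean() - lam) < 4 * sem + 0.05


# --------------------------------------------------------------------------
# Forgetting incidence
# --------------------------------------------------------------------------


def test_incidence_normalization_and_difference(rng):
    tallies_a = [rng.integers(0, 20, size=30) + 1 for _ in range(4)]
    tallies_b = [rng.integers(0, 20, size=30) + 1 for _ in range(4)]
    freqs = ef.forgetting_frequencies(tallies_a)
    assert np.allclose(freqs.sum(axis=1), 1.0)
    diff = ef.incidence_difference(
        ef.forgetting_incidence(tallies_a), ef.forgetting_incidence(tallies_b)
    )
    assert diff.sum() == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError):
        ef.forgetting_frequencies([np.zeros(30)])


def test_random_rule_victims_uniform_chi_square(rng):
    """Uniform victim sampling: forgetting counts over a symmetric write
    stream pass a chi-square goodness-of-fit test against uniformity."""
    n_states, cap = 40, 10
    keys = np.eye(n_states)
    bank = MemoryBank(cap, n_states, rule="random")
    for s in rng.permutation(n_states)[:cap]:
        ef.write_event(bank, keys[s], 0, 0.0, state=int(s), rng=rng)
    for _ in range(10_000):
        s = int(rng.integers(n_states))
        ef.write_event(bank, keys[s], 0, 0.0, state=s, rng=rng)
    counts = np.bincount(np.array(bank.forget_log), minlength=n_states)
    assert counts.sum() > 5_000
    p = sps.chisquare(counts).pvalue
    assert p > 0.01


# --------------------------------------------------------------------------
# Welch's t-test
# --------------------------------------------------------------------------


def test_welch_identical_samples():
    res = ef.welch_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.t == 0.0
    assert res.p == pytest.approx(1.0)
    assert res.p_bonferroni == res.p  # m = 1


def test_welch_matches_scipy_oracle(rng):
    for _ in range(20):
        x = rng.normal(0, 1, size=int(rng.integers(3, 15)))
        y = rng.normal(0.5, 2, size=int(rng.integers(3, 15)))
        ours = ef.welch_test(x, y, tails="two")
        ref = sps.ttest_ind(x, y, equal_var=False)
        assert ours.t == pytest.approx(ref.statistic, abs=1e-10)
        assert ours.p == pytest.approx(ref.pvalue, abs=1e-10)
        assert ours.df == pytest.approx(ref.df, abs=1e-10)
        one = ef.welch_test(x, y, tails="greater")
        ref1 = sps.ttest_ind(x, y, equal_var=False, alternative="greater")
        assert one.p == pytest.approx(ref1.pvalue, abs=1e-10)


def test_welch_bonferroni_and_conventions():
    res = ef.welch_test([1.0, 1.0, 1.1], [2.0, 2.2, 2.1], m_comparisons=5)
    assert res.p_bonferroni == pytest.approx(min(1.0, 5 * res.p))
    # zero variance in both samples, equal means: t undefined -> p = 1
    res = ef.welch_test([1.0, 1.0], [1.0, 1.0])
    assert res.t == 0.0 and res.p == 1.0
    with pytest.raises(ValueError):
        ef.welch_test([1.0], [1.0, 2.0])


# --------------------------------------------------------------------------
# Policy coherence and entropy orderings (heavy fixtures)
# --------------------------------------------------------------------------


def test_forgetting_raises_policy_coherence_for_structured_keys(ladder_runs):
    """Moderate forgetting with SR keys makes neighbouring preferred
    directions agree more than unbounded memory does."""
    coh = {}
    for frac in (1.0, 0.75):
        vals = []
        for seed in (0, 1, 2):
            r = ladder_runs[("successor", frac, seed)]
            pf = ef.average_policy_fields(r.snapshots, r.env, r.encoding, window=25)
            vals.append(ef.neighbourhood_coherence(pf.directions, r.env))
        coh[frac] = np.mean(vals)
    assert coh[0.75] > coh[1.0]


def test_structured_keys_keep_low_entropy_near_reward(ladder_runs):
    """At 75% capacity, SR agents hold more confident (lower-entropy)
    policies within geodesic distance 3 of the reward than onehot agents."""
    means = {}
    for enc_kind in ("successor", "onehot"):
        vals = []
        for seed in (0, 1, 2):
            r = ladder_runs[(enc_kind, 0.75, seed)]
            near = ef.distances_from(r.env, r.env.reward_state) <= 3
            pf = ef.average_policy_fields(r.snapshots, r.env, r.encoding, window=25)
            vals.append(pf.entropy[near].mean())
        means[enc_kind] = np.mean(vals)
    assert means["successor"] < means["onehot"]
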