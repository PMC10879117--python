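"""Chain Bayesian-network proportion model: 2x2 inversion, chain
factorization against a brute-force Markov oracle, odds-ratio
estimation, form labels and the mutual-information audit."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bescope import (
    ChainProportionModel,
    SiteError,
    chain_joint,
    classify_forms,
    estimate_adjacent_or,
    joint_from_margins_or,
    mutual_information_audit,
    predict_proportions,
)
from bescope.quant import OutcomeAllele, OutcomeDistribution, pattern_string


class TestJointFromMarginsOr:
    def test_symmetric_case(self):
        j = joint_from_margins_or(0.5, 0.5, 9.0)
        assert j.p11 == pytest.approx(0.375)
        assert j.p10 == pytest.approx(0.125)
        assert j.p01 == pytest.approx(0.125)
        assert j.p00 == pytest.approx(0.375)
        assert j.odds_ratio == pytest.approx(9.0)

    def test_independence(self):
        j = joint_from_margins_or(0.3, 0.6, 1.0)
        assert j.p11 == pytest.approx(0.18)

    def test_comonotone_limit(self):
        j = joint_from_margins_or(0.4, 0.7, 1e8)
        assert j.p11 == pytest.approx(0.4, abs=1e-4)

    def test_random_draws_reproduce_margins_and_or(self):
        rng = np.random.default_rng(30)
        for _ in range(1000):
            p, q = rng.uniform(0.02, 0.98, size=2)
            c = float(np.exp(rng.uniform(-4, 4)))
            j = joint_from_margins_or(p, q, c)
            assert j.p11 + j.p10 == pytest.approx(p, abs=1e-9)
            assert j.p11 + j.p01 == pytest.approx(q, abs=1e-9)
            assert min(j.p11, j.p10, j.p01, j.p00) >= -1e-12
            lo, hi = max(0.0, p + q - 1.0), min(p, q)
            if lo + 1e-7 < j.p11 < hi - 1e-7:  # away from Frechet clipping
                assert j.odds_ratio == pytest.approx(c, rel=1e-6)

    @settings(max_examples=200, derandomize=True)
    @given(
        p=st.floats(0.01, 0.99),
        q=st.floats(0.01, 0.99),
        log_c=st.floats(-5, 5),
    )
    def test_property_valid_table_with_exact_margins(self, p, q, log_c):
        j = joint_from_margins_or(p, q, float(np.exp(log_c)))
        cells = [j.p11, j.p10, j.p01, j.p00]
        assert all(v >= -1e-12 for v in cells)
        assert sum(cells) == pytest.approx(1.0, abs=1e-9)
        assert j.p11 + j.p10 == pytest.approx(p, abs=1e-9)
        assert j.p11 + j.p01 == pytest.approx(q, abs=1e-9)
        assert max(0.0, p + q - 1.0) - 1e-12 <= j.p11 <= min(p, q) + 1e-12

    def test_domain_errors(self):
        with pytest.raises(SiteError):
            joint_from_margins_or(0.0, 0.5, 2.0)
        with pytest.raises(SiteError):
            joint_from_margins_or(0.5, 0.5, -1.0)


def brute_force_chain(marginals, odds_ratios):
    """Independent oracle: explicitly build the Markov-chain conditionals
    and enumerate the joint distribution."""
    n = len(marginals)
    conditionals = []
    for i in range(1, n):
        j = joint_from_margins_or(marginals[i - 1], marginals[i], odds_ratios[i - 1])
        p_given_1 = j.p11 / (j.p11 + j.p10)
        p_given_0 = j.p01 / (j.p01 + j.p00)
        conditionals.append((p_given_0, p_given_1))
    dist = {}
    for bits in itertools.product((0, 1), repeat=n):
        p = marginals[0] if bits[0] else 1 - marginals[0]
        for i in range(1, n):
            cond = conditionals[i - 1][bits[i - 1]]
            p *= cond if bits[i] else 1 - cond
        dist[bits] = p
    return dist


class TestChainJoint:
    def test_independence_factorizes(self):
        m = ChainProportionModel(positions=(5, 6, 7), marginals=[0.2, 0.5, 0.7],
                                 odds_ratios=[1.0, 1.0])
        for bits in itertools.product((0, 1), repeat=3):
            expected = np.prod([p if b else 1 - p
                                for b, p in zip(bits, [0.2, 0.5, 0.7])])
            assert chain_joint(m, bits) == pytest.approx(expected)

    def test_sums_to_one(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            n = int(rng.integers(1, 7))
            m = ChainProportionModel(
                positions=tuple(range(1, n + 1)),
                marginals=rng.uniform(0.05, 0.95, n),
                odds_ratios=np.exp(rng.uniform(-2, 2, max(n - 1, 0))),
            )
            total = sum(chain_joint(m, bits)
                        for bits in itertools.product((0, 1), repeat=n))
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_matches_brute_force_markov_oracle(self):
        rng = np.random.default_rng(32)
        for _ in range(10):
            marg = rng.uniform(0.1, 0.9, 3)
            ors = np.exp(rng.uniform(-1.5, 1.5, 2))
            model = ChainProportionModel(positions=(4, 6, 8), marginals=marg,
                                         odds_ratios=ors)
            oracle = brute_force_chain(list(marg), list(ors))
            for bits, expected in oracle.items():
                assert chain_joint(model, bits) == pytest.approx(expected, abs=1e-12)

    def test_specified_example_c_4_2(self):
        model = ChainProportionModel(positions=(5, 6, 7),
                                     marginals=[0.3, 0.4, 0.5],
                                     odds_ratios=[4.0, 2.0])
        oracle = brute_force_chain([0.3, 0.4, 0.5], [4.0, 2.0])
        for bits, expected in oracle.items():
            assert chain_joint(model, bits) == pytest.approx(expected, abs=1e-12)

    def test_wrong_pattern_length(self):
        model = ChainProportionModel(positions=(5, 6), marginals=[0.3, 0.4],
                                     odds_ratios=[2.0])
        with pytest.raises(SiteError, match="pattern length"):
            chain_joint(model, (1, 0, 1))


class TestPredictProportions:
    def test_single_editable_base(self):
        model = ChainProportionModel(positions=(6,), marginals=[0.3], odds_ratios=[])
        dist = predict_proportions(model, site_id="x")
        props = dist.by_pattern()
        assert props[pattern_string([6])] == pytest.approx(0.3)
        assert props[pattern_string([])] == pytest.approx(0.7)

    def test_wildtype_removal_renormalizes(self):
        model = ChainProportionModel(positions=(5, 7), marginals=[0.2, 0.4],
                                     odds_ratios=[3.0])
        dist = predict_proportions(model, remove_wildtype=True,
                                   proportion_threshold=0.05)
        assert dist.total() == pytest.approx(1.0)
        assert pattern_string([]) not in dist.by_pattern()

    def test_all_c_one_equals_bernoulli_product(self):
        marg = [0.25, 0.5, 0.8]
        model = ChainProportionModel(positions=(4, 5, 6), marginals=marg,
                                     odds_ratios=[1.0, 1.0])
        dist = predict_proportions(model)
        props = dist.by_pattern()
        for bits in itertools.product((0, 1), repeat=3):
            pat = pattern_string([p for p, b in zip((4, 5, 6), bits) if b])
            expected = np.prod([m if b else 1 - m for b, m in zip(bits, marg)])
            assert props[pat] == pytest.approx(float(expected))

    def test_enumeration_guard(self):
        model = ChainProportionModel(
            positions=tuple(range(1, 14)), marginals=[0.5] * 13,
            odds_ratios=[1.0] * 12,
        )
        with pytest.raises(SiteError, match="enumeration limit"):
            predict_proportions(model)


class TestEstimateAdjacentOr:
    def _patterns_from_chain(self, marg, c, n, seed):
        oracle = brute_force_chain(marg, [c] * (len(marg) - 1))
        rng = np.random.default_rng(seed)
        keys = list(oracle)
        counts = rng.multinomial(n, [oracle[k] for k in keys])
        positions = list(range(5, 5 + len(marg)))
        return {
            pattern_string([p for p, b in zip(positions, k) if b]): cnt / n
            for k, cnt in zip(keys, counts)
        }, positions

    def test_independent_positions_give_c_near_one(self):
        patterns, pos = self._patterns_from_chain([0.4, 0.5], 1.0, 10**5, 40)
        cs = estimate_adjacent_or({"s": patterns}, {"s": pos}, weights={"s": 10**5})
        assert cs[(5, 6)] == pytest.approx(1.0, abs=0.1)

    def test_monte_carlo_recovery_c4(self):
        patterns, pos = self._patterns_from_chain([0.4, 0.5, 0.3], 4.0, 10**5, 41)
        cs = estimate_adjacent_or({"s": patterns}, {"s": pos}, weights={"s": 10**5})
        for pair in [(5, 6), (6, 7)]:
            assert 3.6 <= cs[pair] <= 4.4

    def test_pseudocount_keeps_perfect_coupling_finite(self):
        patterns = {pattern_string([5, 6]): 0.5, pattern_string([]): 0.5}
        cs = estimate_adjacent_or({"s": patterns}, {"s": [5, 6]}, weights={"s": 1000})
        assert np.isfinite(cs[(5, 6)]) and cs[(5, 6)] > 100

    def test_unobserved_pair_defaults_to_one(self):
        cs = estimate_adjacent_or({}, {"s": [5, 6]})
        assert cs[(5, 6)] == 1.0


class TestClassifyForms:
    def _dist(self, items):
        return OutcomeDistribution(
            site_id="s",
            alleles=[OutcomeAllele(pattern=pattern_string(p), proportion=v)
                     for p, v in items],
        )

    def test_max_form_is_top_edited_allele(self):
        labels = classify_forms(self._dist([([5], 0.6), ([5, 6], 0.4)]))
        assert labels.max_form == pattern_string([5])
        assert labels.forms[pattern_string([5, 6])] == "Edited-form"

    def test_tie_break_prefers_fewer_edits_then_leftmost(self):
        labels = classify_forms(self._dist([([5, 6], 0.4), ([7], 0.4), ([6], 0.2)]))
        assert labels.max_form == pattern_string([7])
        tied_left = classify_forms(self._dist([([6], 0.5), ([5], 0.5)]))
        assert tied_left.max_form == pattern_string([5])

    def test_no_edited_allele(self):
        labels = classify_forms(self._dist([([], 1.0)]))
        assert labels.max_form is None and not labels.has_edited


class TestMutualInformation:
    def test_independent_pair_zero_bits(self):
        patterns, pos = {}, [5, 6]
        for a in (0, 1):
            for b in (0, 1):
                pat = pattern_string([p for p, x in zip(pos, (a, b)) if x])
                patterns[pat] = (0.3 if a else 0.7) * (0.6 if b else 0.4)
        audit = mutual_information_audit(patterns, pos)
        assert audit["pairwise"][(5, 6)] == pytest.approx(0.0, abs=1e-12)

    def test_perfectly_coupled_pair_one_bit(self):
        patterns = {pattern_string([5, 6]): 0.5, pattern_string([]): 0.5}
        audit = mutual_information_audit(patterns, [5, 6])
        assert audit["pairwise"][(5, 6)] == pytest.approx(1.0)

    def test_markov_chain_has_near_zero_conditional_mi(self):
        oracle = brute_force_chain([0.4, 0.5, 0.6], [10.0, 10.0])
        pos = [5, 6, 7]
        patterns = {
            pattern_string([p for p, b in zip(pos, bits) if b]): prob
            for bits, prob in oracle.items()
        }
        audit = mutual_information_audit(patterns, pos)
        # exact distribution: conditional MI(x5; x7 | x6) is identically 0
        assert audit["conditional_given_intermediate"][(5, 6, 7)] == \
            pytest.approx(0.0, abs=1e-12)
        # but the distant marginal MI is positive (carried through the chain)
        assert audit["distant"][(5, 7)] > 0.01
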