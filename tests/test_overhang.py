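"""The uniform overhang model: trimming, exceedance probability, labelling
and feature construction."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from splicesieve.core import (
    ContractViolation,
    FPReason,
    JunctionEvidence,
    JunctionKey,
)
from splicesieve.overhang import (
    OverhangSupport,
    build_feature_vector,
    exceedance_counts,
    expected_exceedance,
    label_junction,
    prob_exceed,
    trim_overhang,
)

KEY = JunctionKey("chr1", 100, 200, "+")


def evidence(raw, mismatch_positions=()):
    ev = JunctionEvidence(key=KEY)
    ev.raw_overhangs = list(raw)
    ev.mismatch_positions = list(mismatch_positions)
    # fixture convention: every listed mismatch position applies to each
    # read whose arm reaches it
    ev.trimmed_overhangs = [
        trim_overhang(r, [p for p in mismatch_positions if p <= r])
        for r in raw
    ]
    return ev


class TestTrim:
    @pytest.mark.parametrize("raw,positions,expected", [
        (20, [], 20),        # no mismatch: identity
        (20, [5, 12], 4),    # first mismatch at 5 leaves 4 matching bases
        (20, [1], 0),        # mismatch adjacent to splice site: nothing left
        (1, [1], 0),
        (7, [7], 6),
    ])
    def test_examples(self, raw, positions, expected):
        assert trim_overhang(raw, positions) == expected

    def test_position_outside_arm_rejected(self):
        with pytest.raises(ContractViolation):
            trim_overhang(10, [11])
        with pytest.raises(ContractViolation):
            trim_overhang(10, [0])


class TestProbExceed:
    def test_at_support_max_is_zero(self):
        sup = OverhangSupport(o_max=25)
        for n in (1, 5, 100):
            assert prob_exceed(25, n, sup) == 0.0

    def test_single_read_enumeration(self):
        # 25 equally likely outcomes; only o=25 exceeds 24
        assert prob_exceed(24, 1, OverhangSupport(o_max=25)) == pytest.approx(1 / 25)

    def test_against_exhaustive_enumeration(self):
        """1 - F(p)^n equals brute-force enumeration of all o_max^n outcomes."""
        for o_max in range(2, 8):
            sup = OverhangSupport(o_max=o_max)
            for n in range(1, 4):
                outcomes = list(itertools.product(range(1, o_max + 1), repeat=n))
                for p in range(1, o_max + 1):
                    frac = sum(max(o) > p for o in outcomes) / len(outcomes)
                    assert prob_exceed(p, n, sup) == pytest.approx(frac)

    def test_monte_carlo_example(self, rng):
        """p*=3, n=10 on {1..25}: virtually certain to see a longer overhang."""
        sup = OverhangSupport(o_max=25)
        p = prob_exceed(3, 10, sup)
        assert p == pytest.approx(1 - (3 / 25) ** 10)
        draws = rng.integers(1, 26, size=(200_000, 10))
        assert (draws.max(axis=1) > 3).mean() == pytest.approx(p, abs=1e-4)

    @given(st.integers(2, 40), st.data())
    @settings(max_examples=50, deadline=None)
    def test_monotonicity(self, o_max, data):
        """Increasing in n, decreasing in p_star."""
        sup = OverhangSupport(o_max=o_max)
        p_star = data.draw(st.integers(1, o_max))
        n = data.draw(st.integers(1, 50))
        assert prob_exceed(p_star, n + 1, sup) >= prob_exceed(p_star, n, sup)
        if p_star < o_max:
            assert prob_exceed(p_star + 1, n, sup) <= prob_exceed(p_star, n, sup)

    def test_out_of_support_rejected(self):
        with pytest.raises(ContractViolation):
            prob_exceed(0, 1, OverhangSupport(o_max=25))
        with pytest.raises(ContractViolation):
            prob_exceed(26, 1, OverhangSupport(o_max=25))


class TestExceedanceCounts:
    def test_examples(self):
        sup = OverhangSupport(o_max=25)
        c = exceedance_counts([10, 8], sup)
        positions = np.arange(1, 25)
        assert c[positions.tolist().index(7)] == 2
        assert c[positions.tolist().index(9)] == 1
        assert c[positions.tolist().index(10)] == 0

    def test_empty_and_maximal(self):
        sup = OverhangSupport(o_max=10)
        assert exceedance_counts([], sup).tolist() == [0] * 9
        assert exceedance_counts([10] * 5, sup).tolist() == [5] * 9

    @given(st.lists(st.integers(0, 20), max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_matches_bruteforce_and_nonincreasing(self, overhangs):
        sup = OverhangSupport(o_max=20)
        c = exceedance_counts(overhangs, sup)
        brute = [sum(o > p for o in overhangs) for p in range(1, 20)]
        assert c.tolist() == brute
        assert all(a >= b for a, b in zip(c, c[1:]))


class TestExpectedExceedance:
    @pytest.mark.parametrize("n,p,o_max,expected", [
        (100, 10, 50, 80.0),
        (100, 49, 50, 2.0),
        (77, 9, 10, 7.7),  # p just below o_max: n / |support|
    ])
    def test_uniform_expectation(self, n, p, o_max, expected):
        assert expected_exceedance(n, p, OverhangSupport(o_max=o_max)) == \
            pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ContractViolation):
            expected_exceedance(10, 50, OverhangSupport(o_max=50))


class TestFeatureVector:
    def test_observed_equals_expected_gives_zero(self):
        # one read at each admissible overhang: C_p = o_max - p = E_p exactly
        sup = OverhangSupport(o_max=12)
        ev = evidence(range(1, 13))
        fv = build_feature_vector(ev, sup)
        assert np.allclose(fv.x, 0.0)

    def test_all_trimmed_zero_is_negative_everywhere(self):
        sup = OverhangSupport(o_max=25)
        ev = evidence([5] * 10, mismatch_positions=[1] * 10)
        assert all(t == 0 for t in ev.trimmed_overhangs)
        fv = build_feature_vector(ev, sup, pseudocount=0.5)
        e = 10 * (25 - np.arange(1, 25)) / 25
        assert np.allclose(fv.x, np.log2(0.5 / (e + 0.5)))
        assert np.all(fv.x < 0)

    def test_doubled_counts_approach_plus_one(self):
        sup = OverhangSupport(o_max=12)
        # two reads at every overhang, expectation taken at single-copy n:
        # C_p = 2 E_p everywhere, so x_p -> +1 as the pseudocount vanishes
        ev = evidence(sorted(list(range(1, 13)) * 2))
        single = evidence(range(1, 13))
        c = exceedance_counts(ev.trimmed_overhangs, sup)
        e = np.array([expected_exceedance(single.n_unique, p, sup)
                      for p in range(1, 12)])
        x = np.log2((c + 1e-9) / (e + 1e-9))
        assert np.allclose(x, 1.0)

    def test_pseudocount_must_be_positive(self):
        from splicesieve.core import ConfigurationError

        with pytest.raises(ConfigurationError):
            build_feature_vector(evidence([5]), OverhangSupport(o_max=25),
                                 pseudocount=0.0)

    def test_uniform_evidence_mean_feature_shrinks_to_zero(self, rng):
        """Under the uniform model the elementwise mean feature converges to
        0 as reads per junction grow (log-ratio bias ~ 1/n)."""
        sup = OverhangSupport(o_max=25)
        bounds = {100: 0.25, 400: 0.09, 1600: 0.045}
        maxima = []
        for n_reads, bound in bounds.items():
            xs = []
            for _ in range(300):
                ev = JunctionEvidence(key=KEY)
                ev.raw_overhangs = list(rng.integers(1, 26, size=n_reads))
                ev.trimmed_overhangs = list(ev.raw_overhangs)
                xs.append(build_feature_vector(ev, sup).x)
            m = float(np.abs(np.mean(xs, axis=0)).max())
            assert m < bound
            maxima.append(m)
        assert maxima[0] > maxima[1] > maxima[2]


class TestLabelJunction:
    def test_short_overhangs_shared_mismatch_is_potential_fp(self):
        """10 reads, all overhangs <= 3, every mismatch at position 3."""
        sup = OverhangSupport(o_max=25)
        ev = evidence([3] * 10, mismatch_positions=[3] * 10)
        label = label_junction(ev, sup, alpha=0.99)
        assert label.is_potential_fp
        assert label.reason == FPReason.SINGLE_MISMATCH_RULE

    def test_single_long_read_not_flagged(self):
        """One read, overhang 24, mismatch at 24: exceedance prob 0.04."""
        sup = OverhangSupport(o_max=25)
        ev = evidence([24], mismatch_positions=[24])
        assert not label_junction(ev, sup).is_potential_fp

    def test_no_mismatch_never_single_mismatch_fp(self):
        sup = OverhangSupport(o_max=25)
        ev = evidence([2, 3, 2, 1, 3])
        assert not label_junction(ev, sup).is_potential_fp

    def test_no_matching_overhang(self):
        sup = OverhangSupport(o_max=25)
        ev = evidence([4, 7, 2], mismatch_positions=[1, 1, 1])
        ev.trimmed_overhangs = [0, 0, 0]
        label = label_junction(ev, sup)
        assert label.is_potential_fp
        assert label.reason == FPReason.NO_MATCHING_OVERHANG

    def test_longer_overhang_defuses_rule(self):
        """A single read overhanging past the mismatch position rescinds the
        single-mismatch rule."""
        sup = OverhangSupport(o_max=25)
        ev = evidence([3] * 10 + [10], mismatch_positions=[3] * 10)
        assert not label_junction(ev, sup).is_potential_fp

    @given(st.integers(1, 8), st.integers(1, 30))
    @settings(max_examples=60, deadline=None)
    def test_adding_short_read_never_unflags(self, p_star, n):
        """Monotonicity: adding a read with overhang <= p* to a flagged
        junction cannot flip it back to PRESUMED_OK."""
        sup = OverhangSupport(o_max=25)
        ev = evidence([p_star] * n, mismatch_positions=[p_star] * n)
        before = label_junction(ev, sup)
        ev.raw_overhangs.append(p_star)
        ev.trimmed_overhangs.append(p_star - 1)
        after = label_junction(ev, sup)
        if before.is_potential_fp:
            assert after.is_potential_fp

    def test_duplication_invariance(self):
        """Doubling the evidence (same reads twice) preserves the label."""
        sup = OverhangSupport(o_max=25)
        ev = evidence([3] * 6, mismatch_positions=[3] * 6)
        doubled = evidence([3] * 12, mismatch_positions=[3] * 12)
        assert label_junction(ev, sup) == label_junction(doubled, sup)
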