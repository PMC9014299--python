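"""Latent-class model: pattern probabilities, likelihood, MLE and EM."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from triangulate import (
    BinaryOutcomeMatrix,
    DegenerateDataWarning,
    FitResult,
    IdentifiabilityError,
    OperatingCharacteristics,
    PatternTable,
    fit_em,
    fit_mle,
    log_likelihood,
    pattern_probability,
    resolve_label_switching,
    simulate_binary,
    tabulate_patterns,
)
from triangulate.model import _all_patterns, _em_from, _moment_start

unit = st.floats(0.01, 0.99)


def oc_strategy(K=3):
    vec = st.tuples(*[unit] * K)
    return st.builds(OperatingCharacteristics, rho=unit, phi=vec, psi=vec)


class TestBinaryOutcomeMatrix:
    def test_rejects_non_binary_and_bad_labels(self):
        with pytest.raises(ValueError, match="0 or 1"):
            BinaryOutcomeMatrix(np.array([[0, 2, 1]]))
        with pytest.raises(ValueError, match="pair_labels"):
            BinaryOutcomeMatrix(np.zeros((2, 3)), pair_labels=("only-one",))

    def test_default_labels(self):
        m = BinaryOutcomeMatrix(np.zeros((2, 3)))
        assert m.method_labels == ("method1", "method2", "method3")
        assert len(m.pair_labels) == 2


class TestTabulatePatterns:
    def test_direct_tally(self):
        m = BinaryOutcomeMatrix(np.array([[1, 1, 1], [0, 0, 0]]))
        table = tabulate_patterns(m)
        d = table.as_dict()
        assert len(d) == 8
        assert d[(1, 1, 1)] == 1 and d[(0, 0, 0)] == 1
        assert sum(d.values()) == 2

    def test_counts_conserved_on_simulated_rows(self, interior_truth):
        ds = simulate_binary(interior_truth, 1_000, seed=3)
        assert tabulate_patterns(ds.matrix).n == 1_000


class TestPatternProbability:
    @pytest.mark.parametrize(
        "oc, pattern, expected",
        [
            (OperatingCharacteristics(1.0, (1, 1, 1), (0.5, 0.5, 0.5)), (1, 1, 1), 1.0),
            (OperatingCharacteristics(0.5, (0.5,) * 3, (0.5,) * 3), (1, 0, 1), 0.125),
            # hand evaluation: 0.3·(0.8·0.3·0.6) + 0.7·(0.1·0.8·0.3) = 0.06
            (OperatingCharacteristics(0.3, (0.8, 0.7, 0.6), (0.1, 0.2, 0.3)), (1, 0, 1), 0.06),
        ],
    )
    def test_known_values(self, oc, pattern, expected):
        assert pattern_probability(oc, pattern) == pytest.approx(expected, abs=1e-12)

    def test_dimension_mismatch(self, interior_truth):
        with pytest.raises(ValueError, match="pattern length"):
            pattern_probability(interior_truth, (1, 0))

    @given(oc=oc_strategy())
    @settings(max_examples=50, deadline=None)
    def test_probabilities_normalize(self, oc):
        total = sum(pattern_probability(oc, tuple(p)) for p in _all_patterns(3))
        assert total == pytest.approx(1.0, abs=1e-12)


class TestLogLikelihood:
    def test_certain_observation_scores_zero(self):
        oc = OperatingCharacteristics(1.0, (1, 1, 1), (0.2, 0.2, 0.2))
        table = PatternTable(np.array([0, 0, 0, 0, 0, 0, 0, 1]), K=3)
        assert log_likelihood(oc, table) == pytest.approx(0.0, abs=1e-9)

    def test_additive_in_counts(self):
        oc = OperatingCharacteristics(0.5, (0.5,) * 3, (0.5,) * 3)
        table = PatternTable(np.array([2, 0, 0, 0, 0, 0, 0, 0]), K=3)
        assert log_likelihood(oc, table) == pytest.approx(2 * np.log(0.125))

    @given(oc=oc_strategy(), counts=st.lists(st.integers(0, 50), min_size=8, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_label_swap(self, oc, counts):
        table = PatternTable(np.array(counts), K=3)
        assert log_likelihood(oc, table) == pytest.approx(
            log_likelihood(oc.swapped(), table), rel=1e-12
        )


class TestLabelSwitching:
    def _result(self, oc):
        return FitResult(oc, log_likelihood=-1.0, converged=True, n_starts=1, start_seed=0)

    def test_anti_informative_fit_is_swapped(self):
        oc = OperatingCharacteristics(0.7, (0.1, 0.2, 0.1), (0.9, 0.8, 0.9))
        out = resolve_label_switching(self._result(oc))
        assert out.label_swapped
        assert out.estimates.rho == pytest.approx(0.3)
        np.testing.assert_allclose(out.estimates.phi, [0.9, 0.8, 0.9])
        np.testing.assert_allclose(out.estimates.psi, [0.1, 0.2, 0.1])
        assert out.log_likelihood == -1.0

    def test_conventional_fit_unchanged(self, interior_truth):
        out = resolve_label_switching(self._result(interior_truth))
        assert not out.label_swapped
        assert out.estimates is interior_truth


class TestFitMLE:
    def test_requires_three_methods(self):
        with pytest.raises(IdentifiabilityError, match="K >= 3"):
            fit_mle(PatternTable(np.array([5, 5, 5, 5]), K=2))

    def test_single_pattern_warns_degenerate(self):
        table = PatternTable(np.array([0, 0, 0, 0, 0, 0, 0, 50]), K=3)
        with pytest.warns(DegenerateDataWarning):
            fit_mle(table, n_starts=3)

    def test_perfectly_separated_mixture(self):
        counts = np.zeros(8, dtype=int)
        counts[0] = 500   # (0,0,0)
        counts[7] = 500   # (1,1,1)
        fit = fit_mle(PatternTable(counts, K=3), seed=0)
        assert fit.estimates.rho == pytest.approx(0.5, abs=1e-3)
        np.testing.assert_allclose(fit.estimates.phi, 1.0, atol=1e-3)
        np.testing.assert_allclose(fit.estimates.psi, 0.0, atol=1e-3)

    def test_matches_em_oracle_on_seeded_data(self, seeded_table):
        mle = fit_mle(seeded_table, seed=1)
        em = fit_em(seeded_table, seed=1)
        np.testing.assert_allclose(
            mle.estimates.to_vector(), em.estimates.to_vector(), atol=1e-4
        )
        assert mle.log_likelihood == pytest.approx(em.log_likelihood, rel=1e-6)

    def test_estimates_satisfy_label_convention(self, seeded_table):
        fit = fit_mle(seeded_table, seed=2)
        assert np.sum(fit.estimates.phi - fit.estimates.psi) >= 0
        assert fit.log_likelihood <= 0


class TestFitEM:
    def test_loglik_nondecreasing_across_iterations(self, seeded_table):
        pats = _all_patterns(3)
        counts = seeded_table.counts.astype(float)
        start = _moment_start(seeded_table)
        lls = [
            _em_from(start, counts, pats, tol=-1.0, max_iter=i)[1] for i in range(1, 30)
        ]
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_boundary_solution_on_separated_data(self):
        counts = np.zeros(8, dtype=int)
        counts[0] = counts[7] = 500
        em = fit_em(PatternTable(counts, K=3), seed=0)
        mle = fit_mle(PatternTable(counts, K=3), seed=0)
        np.testing.assert_allclose(
            em.estimates.to_vector(), mle.estimates.to_vector(), atol=1e-3
        )


def test_estimator_bias_shrinks_with_sample_size(interior_truth):
    """Point estimates approach the truth as n grows by decades."""
    from triangulate import simulate_study

    errs = []
    for n in (1_000, 100_000):
        res = simulate_study(interior_truth, n, repeats=20, seed=9)
        errs.append(
            np.abs(res.mean.to_numpy() - interior_truth.to_vector()).mean()
        )
    assert errs[-1] < errs[0]
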