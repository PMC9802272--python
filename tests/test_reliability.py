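"""Krippendorff's alpha against a brute-force pair-enumeration oracle,
percent agreement, adjudication, and the purposive validation sampler."""

import numpy as np
import pytest

from ibdtopics import (
    CodingMatrix,
    TopicAssignment,
    ValidationSamplePlan,
    adjudicate,
    draw_validation_sample,
    krippendorff_alpha,
    percent_agreement,
    summarize_topic_reliability,
    topic_matrices,
)
from ibdtopics.lexicons import CANONICAL_TOPICS
from ibdtopics.reliability import ReliabilityError


def alpha_bruteforce(rows):
    """Independent oracle: enumerate every ordered pair of pairable values.

    Observed disagreement sums mismatching within-unit pairs weighted by
    1/(m_u - 1); expected disagreement enumerates all cross-position pairs
    of the pooled values weighted by 1/(n - 1).  alpha = 1 - D_o/D_e.
    """
    units = [[v for v in row if v is not None] for row in rows]
    units = [u for u in units if len(u) >= 2]
    pooled = [v for u in units for v in u]
    n = len(pooled)
    d_obs = 0.0
    for u in units:
        m = len(u)
        for i in range(m):
            for j in range(m):
                if i != j and u[i] != u[j]:
                    d_obs += 1.0 / (m - 1)
    d_exp = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and pooled[i] != pooled[j]:
                d_exp += 1.0 / (n - 1)
    if d_exp == 0:
        return None
    return 1.0 - d_obs / d_exp


def matrix_from_rows(rows):
    return CodingMatrix(
        unit_ids=[f"u{i}" for i in range(len(rows))],
        coders=[f"c{j}" for j in range(len(rows[0]))],
        labels=[list(r) for r in rows],
    )


class TestKrippendorffAlpha:
    def test_perfect_agreement_two_categories(self):
        rows = [(1, 1), (0, 0), (1, 1), (0, 0)]
        assert krippendorff_alpha(matrix_from_rows(rows)).alpha == pytest.approx(1.0)

    def test_four_unit_example_matches_oracle(self):
        rows = [(1, 1), (0, 0), (1, 0), (0, 0)]
        result = krippendorff_alpha(matrix_from_rows(rows))
        assert result.alpha == pytest.approx(alpha_bruteforce(rows), abs=1e-12)
        assert result.alpha == pytest.approx(1 - 14 / 30)  # hand enumeration

    def test_systematic_disagreement_is_negative(self):
        rows = [(1, 0), (0, 1)] * 8
        result = krippendorff_alpha(matrix_from_rows(rows))
        oracle = alpha_bruteforce(rows)
        assert result.alpha == pytest.approx(oracle, abs=1e-12)
        assert result.alpha < 0

    @pytest.mark.parametrize("case", range(500))
    def test_matches_bruteforce_on_random_matrices(self, case):
        rng = np.random.default_rng(20_000 + case)
        n_units = int(rng.integers(2, 13))
        n_coders = int(rng.integers(2, 4))
        n_cats = int(rng.integers(2, 4))
        rows = rng.integers(0, n_cats, size=(n_units, n_coders)).astype(object)
        # sprinkle missing values but keep something pairable
        mask = rng.random(rows.shape) < 0.2
        rows[mask] = None
        rows = [tuple(r) for r in rows]
        pairable = [r for r in rows if sum(v is not None for v in r) >= 2]
        if not pairable:
            return
        expected = alpha_bruteforce(rows)
        if expected is None:
            with pytest.warns(UserWarning):
                result = krippendorff_alpha(matrix_from_rows(rows))
            assert result.alpha is None
        else:
            result = krippendorff_alpha(matrix_from_rows(rows))
            assert result.alpha == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_unit_and_coder_permutation(self):
        rng = np.random.default_rng(7)
        rows = [tuple(rng.integers(0, 3, size=3)) for _ in range(10)]
        base = krippendorff_alpha(matrix_from_rows(rows)).alpha
        shuffled_units = [rows[i] for i in rng.permutation(len(rows))]
        swapped_coders = [(r[2], r[0], r[1]) for r in rows]
        assert krippendorff_alpha(matrix_from_rows(shuffled_units)).alpha == pytest.approx(base, abs=1e-12)
        assert krippendorff_alpha(matrix_from_rows(swapped_coders)).alpha == pytest.approx(base, abs=1e-12)

    def test_single_category_is_undefined_with_warning(self):
        with pytest.warns(UserWarning, match="undefined"):
            result = krippendorff_alpha(matrix_from_rows([(1, 1), (1, 1)]))
        assert result.alpha is None

    def test_units_with_single_label_are_excluded(self):
        rows = [(1, 1), (0, 0), (1, None), (None, 0)]
        result = krippendorff_alpha(matrix_from_rows(rows))
        assert result.n_units == 2
        assert result.alpha == pytest.approx(alpha_bruteforce(rows), abs=1e-12)

    def test_no_pairable_values_raises(self):
        with pytest.raises(ReliabilityError):
            krippendorff_alpha(matrix_from_rows([(1, None), (None, 0)]))


class TestPercentAgreement:
    @pytest.mark.parametrize("rows, expected", [
        ([(1, 1), (0, 0), (1, 0), (0, 0)], 0.75),
        ([(1, 1), (0, 0)], 1.0),
        ([(1, 0), (0, 1)], 0.0),
    ])
    def test_fraction_of_identical_units(self, rows, expected):
        assert percent_agreement(matrix_from_rows(rows)) == pytest.approx(expected)

    def test_requires_two_complete_coders(self):
        with pytest.raises(ReliabilityError, match="alpha"):
            percent_agreement(matrix_from_rows([(1, 1, 1)]))
        with pytest.raises(ReliabilityError, match="alpha"):
            percent_agreement(matrix_from_rows([(1, None)]))

    def test_agreement_one_iff_zero_observed_disagreement(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            rows = [tuple(rng.integers(0, 2, size=2)) for _ in range(8)]
            pa = percent_agreement(matrix_from_rows(rows))
            if len({v for r in rows for v in r}) < 2:
                continue  # alpha undefined there
            alpha = krippendorff_alpha(matrix_from_rows(rows)).alpha
            assert (pa == 1.0) == (alpha == pytest.approx(1.0))
            assert alpha <= 1.0 + 1e-12


class TestAdjudicate:
    def test_concordant_matrix_needs_no_resolutions(self):
        m = matrix_from_rows([("present", "present"), ("absent", "absent")])
        assert adjudicate(m) == {"u0": "present", "u1": "absent"}

    def test_resolution_applies_to_discordant_unit(self):
        m = matrix_from_rows([("present", "absent")])
        assert adjudicate(m, {"u0": "present"}) == {"u0": "present"}

    def test_unresolved_discordance_raises_with_unit_id(self):
        m = matrix_from_rows([("present", "absent"), ("present", "present")])
        with pytest.raises(ReliabilityError, match="u0"):
            adjudicate(m)

    def test_consensus_feeds_human_vs_computer_matrix(self):
        """The adjudicated column pairs with classifier output as a 2-coder matrix."""
        human = matrix_from_rows([("present", "present"), ("present", "absent")])
        consensus = adjudicate(human, {"u1": "absent"})
        computer = {"u0": "present", "u1": "absent"}
        matrix = CodingMatrix.from_labelings({"human": consensus, "computer": computer})
        assert percent_agreement(matrix) == 1.0
        assert krippendorff_alpha(matrix).alpha == pytest.approx(1.0)


def _assignments_with(topic_counts):
    """n posts per topic assigned positive, ids shared across a pool."""
    out = []
    i = 0
    for topic, (pos, total) in topic_counts.items():
        for j in range(total):
            out.append(TopicAssignment(
                post_id=f"{topic}_{j}", topics={topic} if j < pos else set()
            ))
            i += 1
    return out


class TestValidationSampler:
    def _ample_assignments(self, n=200):
        rng = np.random.default_rng(3)
        out = []
        for i in range(n * 8):
            topics = {t for t in CANONICAL_TOPICS if rng.random() < 0.5}
            out.append(TopicAssignment(post_id=f"p{i}", topics=topics))
        return out

    def test_canonical_plan_draws_960(self):
        sample = draw_validation_sample(
            self._ample_assignments(), ValidationSamplePlan(seed=5)
        )
        assert sample.total_draws == 960
        assert all(len(ids) == 60 for ids in sample.strata.values())
        assert len(sample.strata) == 16

    def test_strata_are_correctly_signed(self):
        assignments = self._ample_assignments()
        by_id = {a.post_id: a.topics for a in assignments}
        sample = draw_validation_sample(assignments, ValidationSamplePlan(seed=5))
        for (topic, stratum), ids in sample.strata.items():
            for u in ids:
                assert (topic in by_id[u]) == (stratum == "positive")

    def test_same_seed_reproduces_sample(self):
        assignments = self._ample_assignments()
        s1 = draw_validation_sample(assignments, ValidationSamplePlan(seed=9))
        s2 = draw_validation_sample(assignments, ValidationSamplePlan(seed=9))
        assert s1.strata == s2.strata
        s3 = draw_validation_sample(assignments, ValidationSamplePlan(seed=10))
        assert s1.strata != s3.strata

    def test_small_stratum_error_names_topic_and_stratum(self):
        counts = {t: (100, 200) for t in CANONICAL_TOPICS}
        counts["intimacy"] = (10, 200)
        assignments = _assignments_with(counts)
        with pytest.raises(ReliabilityError, match="intimacy.*positive"):
            draw_validation_sample(assignments, ValidationSamplePlan(seed=1))

    def test_unit_drawn_for_two_strata_appears_once(self):
        # a symptoms-positive post is also an intimacy-negative candidate,
        # so the aggregated id list must deduplicate across strata while
        # both stratum ledgers keep their full 60
        assignments = [
            TopicAssignment(post_id=f"s{i}", topics={"symptoms"}) for i in range(80)
        ] + [
            TopicAssignment(post_id=f"i{i}", topics={"intimacy"}) for i in range(80)
        ]
        plan = ValidationSamplePlan(topics=["symptoms", "intimacy"], seed=2)
        sample = draw_validation_sample(assignments, plan)
        assert sample.total_draws == 240
        assert all(len(ids) == 60 for ids in sample.strata.values())
        assert len(sample.unit_ids) == len(set(sample.unit_ids))
        assert len(sample.unit_ids) < 240  # overlap existed and was aggregated


class TestTopicReliabilitySummary:
    def test_mean_and_range_over_binary_topic_matrices(self):
        rng = np.random.default_rng(21)
        units = [f"u{i}" for i in range(60)]
        lab_a = {u: {t for t in CANONICAL_TOPICS if rng.random() < 0.4} for u in units}
        # second coder flips a few of coder a's codes
        lab_b = {
            u: {t for t in CANONICAL_TOPICS
                if (t in lab_a[u]) != (rng.random() < 0.05)}
            for u in units
        }
        matrices = topic_matrices({"a": lab_a, "b": lab_b}, units)
        summary = summarize_topic_reliability(matrices)
        alphas = [a for a in summary["per_topic_alpha"].values() if a is not None]
        assert summary["mean_alpha"] == pytest.approx(np.mean(alphas))
        assert summary["range_alpha"] == (min(alphas), max(alphas))
        assert all(a <= 1.0 for a in alphas)
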