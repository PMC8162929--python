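import math

import numpy as np
import pytest
from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss

from dreamlink.consensus import GateStatus, Outcome, OutcomeCategory
from dreamlink.io import load_control_outcomes, load_sham_facial, load_table2
from dreamlink.stats import (
    ChanceReport,
    ContingencyTable2x2,
    OutcomeCounts,
    chance_analyses,
    fisher_exact,
    fleiss_kappa,
    round1,
    summarize,
    tally,
)


def brute_force_fisher_greater(a, b, c, d):
    """Independent oracle: enumerate the hypergeometric tail directly."""
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def prob(x):
        return (
            math.comb(row1, x) * math.comb(row2, col1 - x) / math.comb(n, col1)
        )

    hi = min(row1, col1)
    return sum(prob(x) for x in range(a, hi + 1))


def table2_rows():
    df = load_table2()
    return {
        f"{r.team}|{r.task}": OutcomeCounts(
            int(r.total_trials), int(r.correct), int(r.incorrect),
            int(r.ambiguous), int(r.no_response),
        )
        for r in df.itertuples()
    }


class TestSummarize:
    def test_table2_total_row(self):
        summary = summarize(table2_rows())
        total = summary.total
        assert total.n_trials == 158
        assert total.correct == 29 and total.pct("correct") == 18.4
        assert total.incorrect == 5 and total.pct("incorrect") == 3.2
        assert total.ambiguous == 28 and total.pct("ambiguous") == 17.7
        assert total.no_response == 96 and total.pct("no_response") == 60.8

    def test_single_correct_trial(self):
        counts = tally([OutcomeCategory.CORRECT])
        assert counts.n_trials == 1
        assert counts.pct("correct") == 100.0

    def test_conservation_simulated(self):
        rng = np.random.default_rng(0)
        cats = list(OutcomeCategory)
        outcomes = [cats[i] for i in rng.integers(0, 4, size=1000)]
        counts = tally(outcomes)
        assert counts.n_trials == 1000
        assert counts.correct + counts.incorrect + counts.ambiguous + counts.no_response == 1000

    def test_empty_summary(self):
        summary = summarize({})
        assert summary.rows == () and summary.total is None

    def test_excluded_trials_skipped(self):
        outcomes = [
            Outcome(OutcomeCategory.CORRECT, GateStatus.INCLUDED),
            Outcome(OutcomeCategory.CORRECT, GateStatus.EXCLUDED_NOT_REM),
            Outcome(OutcomeCategory.NO_RESPONSE, GateStatus.EXCLUDED_NOT_SVLD),
        ]
        assert tally(outcomes).n_trials == 1

    def test_percentages_recompose(self):
        total = summarize(table2_rows()).total
        s = sum(total.pct(w) for w in ("correct", "incorrect", "ambiguous", "no_response"))
        assert 99.8 <= s <= 100.2

    def test_counts_must_sum(self):
        with pytest.raises(ValueError):
            OutcomeCounts(10, 5, 1, 1, 1)

    def test_round1_half_up(self):
        assert round1(18.35) == 18.4
        assert round1(2.25) == 2.3
        assert round1(60.759) == 60.8


class TestFleissKappa:
    def test_perfect_agreement(self):
        assert fleiss_kappa([[3, 0], [0, 3]]) == 1.0

    def test_all_same_category_every_subject(self):
        # degenerate: single category used, perfect agreement
        assert fleiss_kappa([[3, 0], [3, 0]]) == 1.0

    def test_hand_computed_small_matrix(self):
        # oracle computed by hand before implementation:
        # P_i = (1/3, 1/3, 1, 1) -> P_bar = 2/3; p_j = (.5, .5) -> P_e = .5
        # kappa = (2/3 - 1/2) / (1/2) = 1/3
        m = [[2, 1], [1, 2], [3, 0], [0, 3]]
        assert fleiss_kappa(m) == pytest.approx(1 / 3)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(1)
        m = rng.multinomial(5, [0.3, 0.4, 0.3], size=50)
        assert fleiss_kappa(m) == pytest.approx(sm_fleiss(m), abs=1e-12)

    def test_near_zero_under_independence(self):
        rng = np.random.default_rng(2)
        m = rng.multinomial(3, [1 / 3] * 3, size=1000)
        assert abs(fleiss_kappa(m)) < 0.05

    def test_unequal_raters_rejected(self):
        with pytest.raises(ValueError):
            fleiss_kappa([[3, 0], [2, 0]])

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            fleiss_kappa([[3, 0]])


class TestFisherExact:
    def test_no_association(self):
        # one-sided tail at the observed cell: P(X >= 1) = 1 - 1/6 = 5/6,
        # confirmed by the brute-force oracle; two-sided p is exactly 1
        assert fisher_exact([[1, 1], [1, 1]]) == pytest.approx(5 / 6)
        assert fisher_exact([[1, 1], [1, 1]]) == pytest.approx(
            brute_force_fisher_greater(1, 1, 1, 1)
        )
        assert fisher_exact([[1, 1], [1, 1]], sided="two-sided") == 1.0

    def test_five_zero_oracle(self):
        # brute-force tail enumeration gives 1/252
        p = fisher_exact([[5, 0], [0, 5]])
        assert p == pytest.approx(1 / 252)
        assert p == pytest.approx(brute_force_fisher_greater(5, 0, 0, 5))

    def test_paper_counts_below_bound(self):
        p = fisher_exact([[62, 96], [13, 366]])
        assert p < 0.001

    @pytest.mark.parametrize("table", [
        (3, 7, 5, 5), (10, 2, 4, 9), (1, 1, 8, 2), (0, 5, 3, 3), (6, 0, 0, 6),
    ])
    def test_against_brute_force(self, table):
        a, b, c, d = table
        assert fisher_exact([[a, b], [c, d]]) == pytest.approx(
            brute_force_fisher_greater(a, b, c, d)
        )

    def test_monotone_in_association(self):
        # fixed margins, strengthening diagonal -> decreasing one-sided p
        ps = [fisher_exact([[10 + k, 10 - k], [10 - k, 10 + k]]) for k in range(0, 11, 2)]
        assert all(q < p for p, q in zip(ps, ps[1:]))

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 0, 0, 0)


class TestChanceAnalyses:
    def _fixture_counts(self):
        ctrl = load_control_outcomes().iloc[0]
        nonlucid = OutcomeCounts(
            int(ctrl.n_trials), int(ctrl.correct), int(ctrl.incorrect),
            int(ctrl.ambiguous), int(ctrl.no_response),
        )
        lucid = summarize(table2_rows()).total
        return lucid, nonlucid

    def test_nonlucid_response_rate(self):
        _, nonlucid = self._fixture_counts()
        assert nonlucid.n_trials == 379
        assert nonlucid.responses == 13

    def test_tables_and_p(self):
        lucid, nonlucid = self._fixture_counts()
        sham = load_sham_facial().iloc[0]
        semantic = table2_rows()["France|semantic discrimination"]
        report = chance_analyses(
            lucid, nonlucid,
            sham_blocks=(int(sham.n_markers), int(sham.n_contractions)),
            stim_contraction_counts=(semantic.responses, semantic.n_trials),
        )
        assert report.lucid_table == ContingencyTable2x2(62, 96, 13, 366)
        assert report.lucid_vs_nonlucid_p < 0.001
        assert report.sham_table.c == 0 and report.sham_table.d == 28
        assert report.stimulation_vs_sham_p < 0.001

    def test_correct_only_definition_also_significant(self):
        lucid, nonlucid = self._fixture_counts()
        report = chance_analyses(lucid, nonlucid, response_definition="correct_only")
        assert report.lucid_table.a == 29
        assert report.lucid_vs_nonlucid_p < 0.001

    def test_null_p_uniformity(self):
        """Under a common response rate, the exact one-sided p is (super-)
        uniform: approximately uniform with large counts."""
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(200):
            l_resp = rng.binomial(158, 0.2)
            nl_resp = rng.binomial(379, 0.2)
            ps.append(fisher_exact([[l_resp, 158 - l_resp], [nl_resp, 379 - nl_resp]]))
        ps = np.asarray(ps)
        # no excess of small p-values beyond nominal level
        for alpha in (0.05, 0.1, 0.25):
            assert (ps <= alpha).mean() <= alpha + 0.06
        from scipy.stats import kstest

        assert kstest(ps, "uniform").pvalue > 1e-4
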