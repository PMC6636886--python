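"""The enrichment test: null probability, exact binomial tail, summaries."""

import math

import numpy as np
import pytest

from bctmoa import (
    DegenerateInputError,
    LinkStatement,
    SyntheticConfig,
    TestConfig as EnrichmentConfig,
    binomial_upper_tail_p,
    build_frequency_table,
    deduplicate_links,
    expected_link_probability,
    format_p,
    generate_corpus,
    read_significant_links_fixture,
    summarize_significant,
    test_all_links as run_link_tests,
)
from bctmoa.link_stats import LinkFrequencyTable

from conftest import restricted_weights


def brute_force_upper_tail(k: int, n: int, p0: float) -> float:
    """Independent oracle: direct summation of the binomial pmf."""
    return sum(
        math.comb(n, i) * p0**i * (1 - p0) ** (n - i) for i in range(k, n + 1)
    )


class TestExpectedLinkProbability:
    def test_saturated_marginals(self):
        assert expected_link_probability(10, 10, 10) == 1.0

    def test_zero_marginal(self):
        assert expected_link_probability(0, 7, 10) == 0.0

    def test_published_marginal_inputs(self):
        # marginals printed in the study: Problem Solving linked 177 times,
        # Beliefs about Capabilities 734 times, 2,636 links in total
        p0 = expected_link_probability(177, 734, 2636)
        assert p0 == pytest.approx((177 / 2636) * (734 / 2636), rel=0, abs=0)
        assert p0 == pytest.approx(0.01870, abs=5e-6)

    def test_zero_n_undefined(self):
        with pytest.raises(DegenerateInputError):
            expected_link_probability(0, 0, 0)

    def test_marginal_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            expected_link_probability(11, 5, 10)


class TestBinomialUpperTail:
    @pytest.mark.parametrize(
        "k,n,p0,expected",
        [
            (0, 50, 0.1, 1.0),
            (1, 1, 0.5, 0.5),
            (5, 20, 0.1, 0.04317449528446339),  # frozen from the summation oracle
        ],
    )
    def test_known_values(self, k, n, p0, expected):
        assert binomial_upper_tail_p(k, n, p0) == pytest.approx(expected, abs=1e-12)

    def test_k_above_n_rejected(self):
        with pytest.raises(ValueError):
            binomial_upper_tail_p(5, 4, 0.1)

    def test_matches_oracle_on_sample_grid(self):
        """Survival-function formulation vs direct summation, spot grid.

        (The exhaustive sweep over all k, N <= 60 lives in the acceptance
        suite; this keeps a fast guard in the unit tier.)
        """
        for n in (1, 7, 23, 41):
            for p0 in (0.01, 0.2, 0.5, 0.93):
                for k in range(0, n + 1, max(1, n // 5)):
                    assert binomial_upper_tail_p(k, n, p0) == pytest.approx(
                        brute_force_upper_tail(k, n, p0), abs=1e-12
                    )

    def test_nonincreasing_in_k(self):
        for n, p0 in [(30, 0.07), (60, 0.4)]:
            ps = [binomial_upper_tail_p(k, n, p0) for k in range(n + 1)]
            assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestTestAllLinks:
    def test_single_saturated_cell_not_significant(self):
        table = build_frequency_table([LinkStatement("A1", "1.1", "x", 14)])
        (res,) = run_link_tests(table)
        assert res.p0 == 1.0 and res.p == 1.0 and not res.significant

    def test_two_independent_cells_closed_form(self):
        stmts = [LinkStatement("A1", "1.1", "x", 14), LinkStatement("A2", "1.2", "y", 4)]
        results = run_link_tests(build_frequency_table(stmts))
        for r in results:
            assert r.p0 == pytest.approx(0.25)
            assert r.p == pytest.approx(1 - 0.75**2)  # = 0.4375
            assert r.expected_count == pytest.approx(2 * 0.25)

    def test_empty_table_empty_results(self):
        table = build_frequency_table([])
        assert run_link_tests(table) == []

    def test_planted_strong_link_flagged(self, bct_registry, moa_registry):
        """A cell at 5x the marginal product with large expected count must
        be recovered; the planted ground truth is the oracle."""
        bw, mw = restricted_weights(10, 5)
        planted_cell = (bct_registry.codes[1], moa_registry.ids[2])
        cfg = SyntheticConfig(
            n_articles=150, mean_links_per_article=10, sd_links_per_article=5,
            bct_weights=bw, moa_weights=mw, propensity={planted_cell: 5.0},
            other_rate=0.0, seed=42,
        )
        corpus, truth = generate_corpus(cfg, bct_registry, moa_registry)
        table = build_frequency_table(deduplicate_links(corpus.links))
        results = {(r.bct_code, r.moa_id): r for r in run_link_tests(table)}
        assert results[planted_cell].significant
        assert results[planted_cell].expected_count >= 20

    def test_results_invariant_to_cell_insertion_order(self):
        stmts = [
            LinkStatement(f"A{i}", code, "x", m)
            for i in range(6)
            for code, m in [("1.1", 14), ("1.2", 4), ("5.1", 1)]
        ]
        t1 = build_frequency_table(deduplicate_links(stmts))
        t2 = build_frequency_table(deduplicate_links(stmts[::-1]))
        assert run_link_tests(t1) == run_link_tests(t2)

    def test_scope_mismatch_rejected(self):
        from bctmoa import ConfigurationError

        table = build_frequency_table([LinkStatement("A1", "1.1", "x", 14)])
        with pytest.raises(ConfigurationError):
            run_link_tests(table, EnrichmentConfig(scope="all-links"))

    def test_bh_adjustment_is_more_conservative(self):
        rng = np.random.default_rng(3)
        stmts = [
            LinkStatement(f"A{i}", f"{1 + rng.integers(2)}.{1 + rng.integers(2)}",
                          "x", int(1 + rng.integers(4)))
            for i in range(120)
        ]
        table = build_frequency_table(deduplicate_links(stmts))
        raw = run_link_tests(table, EnrichmentConfig())
        adj = run_link_tests(table, EnrichmentConfig(adjust="bh"))
        assert sum(r.significant for r in adj) <= sum(r.significant for r in raw)
        assert all(a.p_adjusted >= a.p for a in adj)


class TestSummarizeSignificant:
    def test_fixture_counts(self):
        s = summarize_significant(read_significant_links_fixture())
        assert (s.n_links, s.n_bcts, s.n_moas) == (87, 51, 24)

    def test_fixture_means_and_ranges(self):
        s = summarize_significant(read_significant_links_fixture())
        assert (s.mean_moas_per_bct, s.max_moas_per_bct) == (1.71, 5)
        assert (s.mean_bcts_per_moa, s.max_bcts_per_moa) == (3.63, 8)

    def test_fixture_coverage(self):
        s = summarize_significant(read_significant_links_fixture())
        assert s.pct_bct_coverage == 55.0 and s.pct_moa_coverage == 92.0

    def test_empty_set_zero_sentinel(self):
        s = summarize_significant([])
        assert s.n_links == 0 and s.mean_moas_per_bct == 0.0

    def test_half_up_rounding_of_means(self):
        # 87 links over 24 mechanisms is exactly 3.625: half-up gives 3.63
        s = summarize_significant(read_significant_links_fixture())
        assert s.mean_bcts_per_moa == 3.63


class TestFormatP:
    @pytest.mark.parametrize(
        "p,display", [(0.0005, "<.001"), (0.008, ".008"), (0.048, ".048"), (0.5, ".500")]
    )
    def test_display_convention(self, p, display):
        assert format_p(p) == display
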