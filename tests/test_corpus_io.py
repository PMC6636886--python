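"""Three-table corpus I/O, validation, fixtures, and agreement statistics."""

from pathlib import Path

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bctmoa import (
    CodingComparison,
    Corpus,
    CorpusValidationError,
    FixtureError,
    LinkStatement,
    ReferentialIntegrityError,
    SchemaError,
    coding_agreement,
    read_corpus,
    read_significant_links_fixture,
    validate_corpus,
    write_corpus,
)

HEADERS = {
    "source.csv": "article_id,year,behavior,article_type,theory_status\n",
    "bct.csv": "article_id,bct_code\n",
    "link.csv": (
        "article_id,bct_code,moa_label_raw,moa_definition_raw,moa_category,"
        "explicitness,grouping,empirical_status\n"
    ),
}


def write_tables(tmp_path: Path, source="", bct="", link="") -> tuple[Path, Path, Path]:
    paths = []
    for name, body in (("source.csv", source), ("bct.csv", bct), ("link.csv", link)):
        p = tmp_path / name
        p.write_text(HEADERS[name] + body)
        paths.append(p)
    return tuple(paths)


class TestReadCorpus:
    def test_empty_but_headed_files(self, tmp_path):
        corpus = read_corpus(*write_tables(tmp_path))
        assert corpus.n_articles == 0 and corpus.n_links == 0

    def test_row_counts_preserved(self, tmp_path):
        paths = write_tables(
            tmp_path,
            source="A1,2001,smoking,evaluation,applied\nA2,,,,none-mentioned\n",
            bct="A1,1.1\nA1,1.2\nA2,5.1\n",
            link=(
                "A1,1.1,self-regulation,,14,2,1,1\n"
                "A1,1.2,self-efficacy,,4,1,2,1\n"
                "A2,5.1,knowledge,,1,2,1,3\n"
            ),
        )
        corpus = read_corpus(*paths)
        assert corpus.n_articles == 2 and corpus.n_links == 3
        assert corpus.bct_codings["A1"] == ["1.1", "1.2"]

    def test_orphan_article_rejected(self, tmp_path):
        paths = write_tables(
            tmp_path,
            source="A1,,,,applied\n",
            bct="A1,1.1\n",
            link="A9,1.1,something,,,2,1,1\n",
        )
        with pytest.raises(ReferentialIntegrityError):
            read_corpus(*paths)

    def test_link_without_bct_coding_rejected(self, tmp_path):
        paths = write_tables(
            tmp_path,
            source="A1,,,,applied\n",
            bct="A1,1.1\n",
            link="A1,5.1,something,,,2,1,1\n",
        )
        with pytest.raises(ReferentialIntegrityError):
            read_corpus(*paths)

    def test_unknown_bct_code_rejected(self, tmp_path):
        paths = write_tables(tmp_path, source="A1,,,,applied\n", bct="A1,77.7\n")
        with pytest.raises(CorpusValidationError, match="77.7"):
            read_corpus(*paths)

    def test_missing_column_names_the_column(self, tmp_path):
        _, bct, link = write_tables(tmp_path)
        source = tmp_path / "truncated_source.csv"
        source.write_text("article_id,year\nA1,2001\n")
        with pytest.raises(SchemaError, match="behavior"):
            read_corpus(source, bct, link)

    def test_blank_category_is_unresolved(self, tmp_path, synonym_map):
        paths = write_tables(
            tmp_path,
            source="A1,,,,applied\n",
            bct="A1,1.2\n",
            link="A1,1.2,self-efficacy,,,2,1,1\n",
        )
        corpus = read_corpus(*paths)
        assert corpus.links[0].moa_category == "UNRESOLVED"
        resolved = corpus.resolve_labels(synonym_map)
        assert resolved.links[0].moa_category == 4


class TestRoundTrip:
    def test_write_then_read_preserves_content(self, toy_corpus, tmp_path):
        paths = (tmp_path / "s.csv", tmp_path / "b.csv", tmp_path / "l.csv")
        write_corpus(toy_corpus, *paths)
        back = read_corpus(*paths)
        assert back.articles == toy_corpus.articles
        assert back.bct_codings == toy_corpus.bct_codings
        assert back.links == toy_corpus.links


class TestValidateCorpus:
    def test_valid_corpus_has_no_errors(self, toy_corpus):
        report = validate_corpus(toy_corpus)
        assert report.ok and report.errors == []

    def test_flag_range_violation(self, toy_corpus):
        bad = LinkStatement("A1", "1.1", "x", 14, explicitness=3)
        corpus = Corpus(toy_corpus.articles, toy_corpus.bct_codings,
                        toy_corpus.links + [bad])
        report = validate_corpus(corpus)
        assert report.n_flag_violations == 1 and not report.ok

    def test_duplicate_statement_is_warning_not_error(self, toy_corpus):
        corpus = Corpus(toy_corpus.articles, toy_corpus.bct_codings,
                        toy_corpus.links + [toy_corpus.links[0]])
        report = validate_corpus(corpus)
        assert report.n_duplicates == 1
        assert report.ok  # duplicates are resolved downstream, not fatal


class TestSignificantLinksFixture:
    def test_fixture_has_87_distinct_links(self):
        rows = read_significant_links_fixture()
        assert len({(r.bct_code, r.moa_id) for r in rows}) == 87

    def test_graded_tasks_beliefs_about_capabilities(self, moa_registry):
        rows = read_significant_links_fixture()
        bac = moa_registry.by_label("Beliefs about Capabilities").id
        row = next(r for r in rows if r.bct_code == "8.7" and r.moa_id == bac)
        assert row.frequency == 28 and row.p_display == "<.001" and row.censored

    def test_all_p_values_within_criterion(self):
        assert all(0 < r.p_value <= 0.05 for r in read_significant_links_fixture())

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "fixture.csv"
        p.write_text("bct_code,moa_id,frequency,p_display\n")
        with pytest.raises(FixtureError):
            read_significant_links_fixture(p)

    def test_out_of_criterion_p_rejected(self, tmp_path):
        p = tmp_path / "fixture.csv"
        p.write_text("bct_code,moa_id,frequency,p_display\n1.1,14,3,.060\n")
        with pytest.raises(FixtureError):
            read_significant_links_fixture(p)

    def test_by_bct_and_by_moa_views_reconcile(self):
        """Grouping the one link set by technique and by mechanism must
        enumerate exactly the same pairs (the two published presentations)."""
        rows = read_significant_links_fixture()
        by_bct = {
            (b, r.moa_id)
            for b in {r.bct_code for r in rows}
            for r in rows
            if r.bct_code == b
        }
        by_moa = {
            (r.bct_code, m)
            for m in {r.moa_id for r in rows}
            for r in rows
            if r.moa_id == m
        }
        assert by_bct == by_moa


class TestCodingAgreement:
    @pytest.mark.parametrize(
        "n,a,pct,pabak",
        [(100, 100, 1.0, 1.0), (100, 50, 0.5, 0.0), (100, 95, 0.95, 0.90)],
    )
    def test_closed_form(self, n, a, pct, pabak):
        out = coding_agreement(CodingComparison(n_items=n, n_agreements=a))
        assert out["percent_agreement"] == pytest.approx(pct)
        assert out["pabak"] == pytest.approx(pabak)

    def test_zero_items_rejected(self):
        with pytest.raises(ValueError):
            coding_agreement(CodingComparison(n_items=0, n_agreements=0))

    def test_agreement_bounds_rejected(self):
        with pytest.raises(ValueError):
            CodingComparison(n_items=10, n_agreements=11)

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(1, 10_000), st.data())
    def test_pabak_identity_and_bounds(self, n, data):
        a = data.draw(st.integers(0, n))
        out = coding_agreement(CodingComparison(n_items=n, n_agreements=a))
        assert out["pabak"] == 2 * out["percent_agreement"] - 1
        assert -1.0 <= out["pabak"] <= 1.0
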