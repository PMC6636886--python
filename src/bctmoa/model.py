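"""Model/Results interface over the link enrichment analysis.

:class:`LinkEnrichmentModel` is constructed from a coded corpus (or directly
from deduplicated statements / a frequency table); ``fit()`` runs the exact
binomial test on every described cell and returns a
:class:`LinkEnrichmentResults` carrying the per-link estimates, the two
published-style table views, a text ``summary()``, and plotting.

Typical use::

    corpus = read_corpus("source.csv", "bct.csv", "link.csv")
    res = LinkEnrichmentModel.from_corpus(corpus, alpha=0.05).fit()
    print(res.summary())
    res.table_by_bct()        # significant links grouped by technique
    res.plot_heatmap("out/heatmap")
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from . import link_test as lt
from .corpus_io import Corpus, LinkStatement
from .heatmap import (
    DendrogramOrder,
    PMatrix,
    TRANSFORM_RAW,
    build_p_matrix,
    cluster_orders,
    render_heatmap,
)
from .link_stats import (
    SCOPE_CATEGORIZED,
    LinkFrequencyTable,
    build_frequency_table,
    corpus_summary,
    deduplicate_links,
)
from .link_test import LinkSetSummary, LinkTestResult, TestConfig


class LinkEnrichmentModel:
    """Exact binomial enrichment of link frequencies against the
    marginal-product independence null."""

    def __init__(
        self,
        freq_table: LinkFrequencyTable,
        config: TestConfig | None = None,
        corpus: Corpus | None = None,
    ):
        self.config = config if config is not None else TestConfig(scope=freq_table.scope)
        self.freq_table = freq_table
        self.corpus = corpus

    @classmethod
    def from_corpus(
        cls,
        corpus: Corpus,
        alpha: float = 0.05,
        scope: str = SCOPE_CATEGORIZED,
        adjust: str | None = None,
    ) -> "LinkEnrichmentModel":
        """Build the model from a corpus: dedup, then tabulate at ``scope``."""
        statements = deduplicate_links(corpus.links)
        table = build_frequency_table(statements, scope=scope)
        return cls(table, TestConfig(alpha=alpha, scope=scope, adjust=adjust), corpus=corpus)

    @classmethod
    def from_statements(
        cls,
        statements: Sequence[LinkStatement],
        alpha: float = 0.05,
        scope: str = SCOPE_CATEGORIZED,
    ) -> "LinkEnrichmentModel":
        table = build_frequency_table(deduplicate_links(statements), scope=scope)
        return cls(table, TestConfig(alpha=alpha, scope=scope))

    def fit(self) -> "LinkEnrichmentResults":
        results = lt.test_all_links(self.freq_table, self.config)
        return LinkEnrichmentResults(self, results)


class LinkEnrichmentResults:
    """Fitted results: per-link counts, null probabilities, and p-values."""

    def __init__(self, model: LinkEnrichmentModel, results: list[LinkTestResult]):
        self.model = model
        self.results = results
        self._frame: pd.DataFrame | None = None

    @property
    def frame(self) -> pd.DataFrame:
        """All tested links as a labelled DataFrame."""
        if self._frame is None:
            self._frame = lt.results_to_dataframe(self.results)
        return self._frame

    @property
    def significant(self) -> list[LinkTestResult]:
        return [r for r in self.results if r.significant]

    def link_set_summary(self) -> LinkSetSummary:
        """Shape statistics of the significant link set."""
        return lt.summarize_significant(self.results)

    def table_by_bct(self, significant_only: bool = True) -> pd.DataFrame:
        """Published-style view grouped by technique (sorted code, then p)."""
        return lt.table_by_bct(self.frame, significant_only)

    def table_by_moa(self, significant_only: bool = True) -> pd.DataFrame:
        """Published-style view grouped by mechanism (sorted id, then p)."""
        return lt.table_by_moa(self.frame, significant_only)

    def p_matrix(self, transform: str = TRANSFORM_RAW) -> PMatrix:
        return build_p_matrix(self.results, transform=transform)

    def cluster(self, transform: str = TRANSFORM_RAW) -> tuple[PMatrix, DendrogramOrder]:
        matrix = self.p_matrix(transform)
        return matrix, cluster_orders(matrix)

    def plot_heatmap(
        self, out_stem: str | Path, transform: str = TRANSFORM_RAW
    ) -> dict[str, Path]:
        """Render the clustered heat map; returns the written file paths."""
        matrix, orders = self.cluster(transform)
        return render_heatmap(matrix, orders, out_stem)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    def summary(self) -> str:
        """Readable run summary in the spirit of a model results table."""
        cfg = self.model.config
        ft = self.model.freq_table
        s = self.link_set_summary()
        lines = [
            "Link Enrichment Results (one-tailed exact binomial, marginal-product null)",
            "=" * 74,
            f"scope: {ft.scope:<22} alpha: {cfg.alpha:<8} adjust: {cfg.adjust or 'none'}",
            f"links in scope (N): {ft.N:<12} tested cells: {len(self.results)}",
            f"significant links: {s.n_links} across {s.n_bcts} BCTs and {s.n_moas} MoAs",
            (
                f"MoAs per BCT: mean {s.mean_moas_per_bct}, max {s.max_moas_per_bct}; "
                f"BCTs per MoA: mean {s.mean_bcts_per_moa}, max {s.max_bcts_per_moa}"
            ),
            (
                f"coverage: {s.pct_bct_coverage:.0f}% of 93 BCTs, "
                f"{s.pct_moa_coverage:.0f}% of 26 MoAs"
            ),
        ]
        if self.model.corpus is not None:
            cs = corpus_summary(self.model.corpus)
            lines.append(
                f"corpus: {cs.n_articles} articles, {cs.n_links_total} links "
                f"(mean {cs.mean_links_per_article:.2f}/article, "
                f"SD {cs.sd_links_per_article:.2f})"
            )
        lines.append("=" * 74)
        top = self.table_by_bct().head(10)
        if len(top):
            lines.append("strongest links (by-BCT view, first 10 rows):")
            lines.append(
                top[["bct_code", "bct_label", "moa_label", "k", "p_display"]]
                .to_string(index=False)
            )
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<LinkEnrichmentResults: {len(self.results)} tested, "
            f"{len(self.significant)} significant, N={self.model.freq_table.N}>"
        )
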