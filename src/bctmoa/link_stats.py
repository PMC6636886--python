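"""Link deduplication, the BCT x MoA frequency table, and corpus descriptives.

The unit of counting throughout is the *article*: a given BCT-MoA link
contributes at most once per article regardless of how many times its
authors restate it, so the cell count k(B, M) is the number of distinct
articles describing that link. Marginals m_B and m_M are row/column sums of
the cell counts and N is the grand total; these three quantities define the
independence null used by the enrichment test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .corpus_io import Corpus, LinkStatement
from .errors import ConfigurationError
from .registry import OTHER, UNRESOLVED, MoACategory

#: Frequency-table scopes. "categorized-only" drops links whose MoA could not
#: be mapped onto the 26 constructs (the scope the enrichment test runs on);
#: "all-links" keeps every statement for descriptive totals.
SCOPE_CATEGORIZED = "categorized-only"
SCOPE_ALL = "all-links"
SCOPES = (SCOPE_CATEGORIZED, SCOPE_ALL)


def deduplicate_links(statements: Iterable[LinkStatement]) -> list[LinkStatement]:
    """Keep at most one statement per (article, BCT, MoA category).

    When duplicates disagree on coding flags, the most informative survives:
    higher explicitness first, then higher empirical status. Idempotent, and
    stable in first-appearance order.
    """
    best: dict[tuple, LinkStatement] = {}
    order: list[tuple] = []
    for s in statements:
        key = (s.article_id, s.bct_code, s.moa_category)
        if key not in best:
            best[key] = s
            order.append(key)
        else:
            cur = best[key]
            if (s.explicitness, s.empirical_status) > (cur.explicitness, cur.empirical_status):
                best[key] = s
    return [best[k] for k in order]


@dataclass
class LinkFrequencyTable:
    """Article counts per (BCT, MoA) cell with marginals and grand total."""

    cells: dict[tuple[str, MoACategory], int]
    bct_marginals: dict[str, int]
    moa_marginals: dict[MoACategory, int]
    N: int
    scope: str

    def __post_init__(self) -> None:
        total = sum(self.cells.values())
        if not (
            total == self.N
            and sum(self.bct_marginals.values()) == self.N
            and sum(self.moa_marginals.values()) == self.N
        ):
            raise ValueError("marginal sums and N must all equal the cell total")

    def k(self, bct_code: str, moa: MoACategory) -> int:
        return self.cells.get((bct_code, moa), 0)

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format view: one row per nonzero cell (bct_code, moa_id, k)."""
        rows = [
            {"bct_code": b, "moa_id": m, "k": k}
            for (b, m), k in self.cells.items()
        ]
        return pd.DataFrame(rows, columns=["bct_code", "moa_id", "k"])

    def write(self, csv_path: str | Path) -> None:
        """Export the long-format CSV plus a JSON sidecar with marginals."""
        import json

        csv_path = Path(csv_path)
        self.to_dataframe().to_csv(csv_path, index=False)
        sidecar = {
            "scope": self.scope,
            "N": self.N,
            "bct_marginals": dict(self.bct_marginals),
            "moa_marginals": {str(k): v for k, v in self.moa_marginals.items()},
        }
        csv_path.with_suffix(".json").write_text(
            json.dumps(sidecar, indent=2) + "\n", encoding="utf-8"
        )


def build_frequency_table(
    statements: Sequence[LinkStatement], scope: str = SCOPE_CATEGORIZED
) -> LinkFrequencyTable:
    """Count distinct articles per (BCT, MoA) cell and derive marginals.

    Statements should already be deduplicated; distinct articles are counted
    per cell regardless, so stray duplicates cannot inflate k. Under
    categorized-only scope, statements whose category is OTHER or UNRESOLVED
    are excluded from the cells, the marginals, *and* N.
    """
    if scope not in SCOPES:
        raise ConfigurationError(f"scope must be one of {SCOPES}, got {scope!r}")
    articles_per_cell: dict[tuple[str, MoACategory], set[str]] = {}
    for s in statements:
        if scope == SCOPE_CATEGORIZED and s.moa_category in (OTHER, UNRESOLVED):
            continue
        articles_per_cell.setdefault((s.bct_code, s.moa_category), set()).add(s.article_id)

    cells = {cell: len(arts) for cell, arts in articles_per_cell.items()}
    bct_marginals: dict[str, int] = {}
    moa_marginals: dict[MoACategory, int] = {}
    for (b, m), k in cells.items():
        bct_marginals[b] = bct_marginals.get(b, 0) + k
        moa_marginals[m] = moa_marginals.get(m, 0) + k
    return LinkFrequencyTable(
        cells=cells,
        bct_marginals=bct_marginals,
        moa_marginals=moa_marginals,
        N=sum(cells.values()),
        scope=scope,
    )


@dataclass
class CorpusSummary:
    """Descriptive statistics for a coded corpus."""

    n_articles: int = 0
    n_links_total: int = 0
    mean_links_per_article: float = 0.0
    sd_links_per_article: float = 0.0
    pct_inference_needed: float = 0.0
    pct_group_statements: float = 0.0
    pct_empirically_tested: float = 0.0
    n_bcts_coded: int = 0
    n_bcts_linked: int = 0
    n_moas_linked: int = 0

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


def corpus_summary(corpus: Corpus) -> CorpusSummary:
    """Compute corpus descriptives over deduplicated link statements.

    Links-per-article moments are taken over articles contributing at least
    one link (inclusion requires one, so normally all of them); the SD is the
    sample standard deviation. Percentages are over all retained statements;
    an empty corpus returns the zero summary rather than dividing by zero.
    """
    links = deduplicate_links(corpus.links)
    if not corpus.articles and not links:
        return CorpusSummary()

    per_article: dict[str, int] = {}
    for s in links:
        per_article[s.article_id] = per_article.get(s.article_id, 0) + 1
    counts = list(per_article.values())
    n_links = len(links)

    mean = sum(counts) / len(counts) if counts else 0.0
    if len(counts) > 1:
        sd = math.sqrt(sum((c - mean) ** 2 for c in counts) / (len(counts) - 1))
    else:
        sd = 0.0

    def pct(pred) -> float:
        return 100.0 * sum(1 for s in links if pred(s)) / n_links if n_links else 0.0

    coded = {c for codes in corpus.bct_codings.values() for c in codes}
    linked_bcts = {s.bct_code for s in links}
    linked_moas = {s.moa_category for s in links if isinstance(s.moa_category, int)}

    return CorpusSummary(
        n_articles=len(corpus.articles),
        n_links_total=n_links,
        mean_links_per_article=mean,
        sd_links_per_article=sd,
        pct_inference_needed=pct(lambda s: s.explicitness == 1),
        pct_group_statements=pct(lambda s: s.grouping == 2),
        pct_empirically_tested=pct(lambda s: s.empirical_status == 3),
        n_bcts_coded=len(coded),
        n_bcts_linked=len(linked_bcts),
        n_moas_linked=len(linked_moas),
    )
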