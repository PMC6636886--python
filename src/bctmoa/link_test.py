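"""Per-cell enrichment of BCT-MoA links against a marginal-product null.

For each described link (B, M) with article count k, the null probability of
the cell under independent use of B and M is the product of the marginal
usage rates,

    p0 = (m_B / N) * (m_M / N),

where m_B is how often B was linked to any mechanism, m_M how often M was
linked to any technique, and N the corpus-wide link total. The observed
count is referred to an exact one-tailed binomial upper tail,

    p = P(X >= k),  X ~ Binomial(N, p0),

and a link is reported when p falls below the (deliberately minimal)
threshold alpha = .05. The p-values rank links by frequency *relative* to
overall technique and mechanism usage — a rarely used pair can rank high if
its components are otherwise rare — and carry no causal weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .corpus_io import SignificantLinkRow
from .errors import ConfigurationError, DegenerateInputError
from .link_stats import SCOPE_CATEGORIZED, SCOPES, LinkFrequencyTable
from .registry import N_BCTS, N_MOAS


@dataclass(frozen=True)
class TestConfig:
    """Settings for the link enrichment test.

    alpha is the significance threshold (strict inequality, p < alpha);
    scope names the frequency-table scope the null is computed on; adjust
    optionally applies a Benjamini-Hochberg correction — an extension beyond
    the original raw-p criterion, off by default.
    """

    alpha: float = 0.05
    scope: str = SCOPE_CATEGORIZED
    adjust: str | None = None  # None or "bh"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.scope not in SCOPES:
            raise ConfigurationError(f"scope must be one of {SCOPES}")
        if self.adjust not in (None, "bh"):
            raise ConfigurationError("adjust must be None or 'bh'")


@dataclass(frozen=True)
class LinkTestResult:
    """Exact binomial test outcome for one described link."""

    bct_code: str
    moa_id: int
    k: int
    p0: float
    expected_count: float
    p: float
    significant: bool
    p_adjusted: float | None = None


def expected_link_probability(m_b: int, m_m: int, n: int) -> float:
    """Null cell probability under independence: (m_B / N) * (m_M / N)."""
    if n <= 0:
        raise DegenerateInputError("null probability undefined for N = 0")
    if not (0 <= m_b <= n and 0 <= m_m <= n):
        raise ValueError("marginals must lie in [0, N]")
    return (m_b * m_m) / (n * n)


def binomial_upper_tail_p(k: int, n: int, p0: float) -> float:
    """Exact upper-tail probability P(X >= k) for X ~ Binomial(n, p0).

    Computed through the binomial survival function (no normal
    approximation); k = 0 returns exactly 1.
    """
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("need 0 <= p0 <= 1")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p0))


def test_all_links(
    freq_table: LinkFrequencyTable, config: TestConfig | None = None
) -> list[LinkTestResult]:
    """Run the exact binomial enrichment test on every described link.

    One result per nonzero cell with a categorized mechanism; cells never
    described (k = 0) are not tested, matching the reporting convention of
    only assessing links that appear in the literature. The null for every
    cell uses the table's own marginals and N.
    """
    config = config if config is not None else TestConfig()
    if freq_table.scope != config.scope:
        raise ConfigurationError(
            f"frequency table scope {freq_table.scope!r} does not match "
            f"config scope {config.scope!r}"
        )
    tested_cells = sorted(
        (cell for cell in freq_table.cells if isinstance(cell[1], int)),
        key=lambda c: (_code_key(c[0]), c[1]),
    )
    results: list[LinkTestResult] = []
    for bct_code, moa_id in tested_cells:
        k = freq_table.cells[(bct_code, moa_id)]
        p0 = expected_link_probability(
            freq_table.bct_marginals[bct_code],
            freq_table.moa_marginals[moa_id],
            freq_table.N,
        )
        p = binomial_upper_tail_p(k, freq_table.N, p0)
        results.append(
            LinkTestResult(
                bct_code=bct_code,
                moa_id=moa_id,
                k=k,
                p0=p0,
                expected_count=freq_table.N * p0,
                p=p,
                significant=p < config.alpha,
            )
        )
    if config.adjust == "bh":
        results = _apply_bh(results, config.alpha)
    return results


def _apply_bh(results: list[LinkTestResult], alpha: float) -> list[LinkTestResult]:
    """Benjamini-Hochberg step-up adjustment (optional extension)."""
    m = len(results)
    if m == 0:
        return results
    order = np.argsort([r.p for r in results], kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank_from_last, idx in enumerate(order[::-1]):
        rank = m - rank_from_last
        prev = min(prev, results[idx].p * m / rank)
        q[idx] = prev
    return [
        LinkTestResult(
            bct_code=r.bct_code,
            moa_id=r.moa_id,
            k=r.k,
            p0=r.p0,
            expected_count=r.expected_count,
            p=r.p,
            significant=q[i] < alpha,
            p_adjusted=float(q[i]),
        )
        for i, r in enumerate(results)
    ]


def _code_key(code: str) -> tuple[int, int]:
    major, minor = code.split(".", 1)
    return (int(major), int(minor))


def format_p(p: float) -> str:
    """Display convention of the published tables: '<.001' below .001,
    otherwise three decimals without a leading zero."""
    if p < 0.001:
        return "<.001"
    return f"{p:.3f}".lstrip("0")


def _round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class LinkSetSummary:
    """Shape statistics of a set of significant links."""

    n_links: int = 0
    n_bcts: int = 0
    n_moas: int = 0
    mean_moas_per_bct: float = 0.0
    max_moas_per_bct: int = 0
    mean_bcts_per_moa: float = 0.0
    max_bcts_per_moa: int = 0
    pct_bct_coverage: float = 0.0
    pct_moa_coverage: float = 0.0

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


SummaryInput = Union[SignificantLinkRow, LinkTestResult]


def summarize_significant(rows: Sequence[SummaryInput]) -> LinkSetSummary:
    """Summarize a significant link set: counts, per-axis means and maxima,
    and coverage of the 93-technique and 26-construct spaces.

    Means are rounded half-up to two decimals, coverage percentages to whole
    percent, matching the precision of the published summaries. Accepts
    either fixture rows or test results (only significant ones are counted).
    """
    pairs: set[tuple[str, int]] = set()
    for r in rows:
        if isinstance(r, LinkTestResult) and not r.significant:
            continue
        pairs.add((r.bct_code, r.moa_id))
    if not pairs:
        return LinkSetSummary()

    by_bct: dict[str, int] = {}
    by_moa: dict[int, int] = {}
    for b, m in pairs:
        by_bct[b] = by_bct.get(b, 0) + 1
        by_moa[m] = by_moa.get(m, 0) + 1

    n_links, n_bcts, n_moas = len(pairs), len(by_bct), len(by_moa)
    return LinkSetSummary(
        n_links=n_links,
        n_bcts=n_bcts,
        n_moas=n_moas,
        mean_moas_per_bct=_round_half_up(n_links / n_bcts, 2),
        max_moas_per_bct=max(by_bct.values()),
        mean_bcts_per_moa=_round_half_up(n_links / n_moas, 2),
        max_bcts_per_moa=max(by_moa.values()),
        pct_bct_coverage=_round_half_up(100.0 * n_bcts / N_BCTS, 0),
        pct_moa_coverage=_round_half_up(100.0 * n_moas / N_MOAS, 0),
    )


def results_to_dataframe(
    results: Sequence[LinkTestResult],
    bct_registry=None,
    moa_registry=None,
) -> pd.DataFrame:
    """Tabulate results with registry labels attached."""
    from . import registry as reg

    bct_registry = bct_registry if bct_registry is not None else reg.load_bct_registry()
    moa_registry = moa_registry if moa_registry is not None else reg.load_moa_registry()
    rows = []
    for r in results:
        rows.append(
            {
                "bct_code": r.bct_code,
                "bct_label": bct_registry[r.bct_code].label,
                "moa_id": r.moa_id,
                "moa_label": moa_registry[r.moa_id].label,
                "k": r.k,
                "p0": r.p0,
                "expected_count": r.expected_count,
                "p": r.p,
                "p_display": format_p(r.p),
                "significant": r.significant,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "bct_code", "bct_label", "moa_id", "moa_label",
            "k", "p0", "expected_count", "p", "p_display", "significant",
        ],
    )


def table_by_bct(frame: pd.DataFrame, significant_only: bool = True) -> pd.DataFrame:
    """View grouped by technique: sorted by (bct_code, p)."""
    df = frame[frame["significant"]] if significant_only else frame
    keys = df["bct_code"].map(_code_key)
    return df.assign(_k=keys).sort_values(["_k", "p"]).drop(columns="_k").reset_index(drop=True)


def table_by_moa(frame: pd.DataFrame, significant_only: bool = True) -> pd.DataFrame:
    """View grouped by mechanism: sorted by (moa_id, p)."""
    df = frame[frame["significant"]] if significant_only else frame
    return df.sort_values(["moa_id", "p"]).reset_index(drop=True)
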