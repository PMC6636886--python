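"""Read, validate, and write coded corpora in the three-table schema.

A coded corpus consists of three linked CSV tables sharing an article key:

* **source** — one row per article (metadata: year, target behavior,
  article type, how theory was used);
* **bct** — one row per BCT coded in an article, whether or not it was
  linked to a mechanism;
* **link** — one row per article-level BCT–MoA link statement, carrying the
  author's raw mechanism label and three coding flags (explicitness,
  grouping, empirical status).

This module also reads the packaged transcription of the study's significant
link tables (87 links at p < .05) and computes the double-coding agreement
statistics (percent agreement and PABAK) used for reliability reporting.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import registry as reg
from .errors import (
    CorpusValidationError,
    FixtureError,
    ReferentialIntegrityError,
    SchemaError,
)
from .registry import OTHER, UNRESOLVED, BCTRegistry, MoACategory, SynonymMap

THEORY_STATUSES = ("none-mentioned", "mentioned-unspecified", "applied")

SOURCE_COLUMNS = ["article_id", "year", "behavior", "article_type", "theory_status"]
BCT_COLUMNS = ["article_id", "bct_code"]
LINK_COLUMNS = [
    "article_id",
    "bct_code",
    "moa_label_raw",
    "moa_definition_raw",
    "moa_category",
    "explicitness",
    "grouping",
    "empirical_status",
]

# Coding flag enumerations, kept as the literal numeric codes used at
# extraction time (1 = some inference needed, 2 = none; 1 = one-to-one,
# 2 = group statement; 1 = MoA not measured, 2 = measured untested, 3 = tested).
EXPLICITNESS_VALUES = (1, 2)
GROUPING_VALUES = (1, 2)
EMPIRICAL_STATUS_VALUES = (1, 2, 3)


@dataclass(frozen=True)
class ArticleRecord:
    """Metadata for one coded intervention article."""

    article_id: str
    year: int | None = None
    behavior: str = ""
    article_type: str = ""
    theory_status: str = "none-mentioned"


@dataclass(frozen=True)
class LinkStatement:
    """One article-level statement linking a BCT to a mechanism of action."""

    article_id: str
    bct_code: str
    moa_label_raw: str
    moa_category: MoACategory = UNRESOLVED
    moa_definition_raw: str = ""
    explicitness: int = 2
    grouping: int = 1
    empirical_status: int = 1

    def resolved(self, synonym_map: SynonymMap) -> "LinkStatement":
        """Return a copy with moa_category filled from the raw label."""
        if self.moa_category != UNRESOLVED:
            return self
        category = reg.resolve_moa_label(self.moa_label_raw, synonym_map)
        return LinkStatement(
            article_id=self.article_id,
            bct_code=self.bct_code,
            moa_label_raw=self.moa_label_raw,
            moa_category=category,
            moa_definition_raw=self.moa_definition_raw,
            explicitness=self.explicitness,
            grouping=self.grouping,
            empirical_status=self.empirical_status,
        )


@dataclass
class Corpus:
    """A coded corpus: articles, per-article BCT codings, link statements."""

    articles: list[ArticleRecord] = field(default_factory=list)
    bct_codings: dict[str, list[str]] = field(default_factory=dict)
    links: list[LinkStatement] = field(default_factory=list)

    @property
    def n_articles(self) -> int:
        return len(self.articles)

    @property
    def n_links(self) -> int:
        return len(self.links)

    def resolve_labels(self, synonym_map: SynonymMap) -> "Corpus":
        """Resolve every UNRESOLVED link label through the synonym map."""
        return Corpus(
            articles=list(self.articles),
            bct_codings={k: list(v) for k, v in self.bct_codings.items()},
            links=[s.resolved(synonym_map) for s in self.links],
        )


@dataclass(frozen=True)
class SignificantLinkRow:
    """One row of the packaged significant-link tables."""

    bct_code: str
    moa_id: int
    frequency: int
    p_display: str

    @property
    def p_value(self) -> float:
        """Numeric p, taking censored entries ('<.001') at their bound."""
        return float(self.p_display.lstrip("<"))

    @property
    def censored(self) -> bool:
        return self.p_display.startswith("<")


@dataclass(frozen=True)
class CodingComparison:
    """Counts from comparing two coders' decisions on the same items."""

    n_items: int
    n_agreements: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_agreements <= self.n_items:
            raise ValueError("need 0 <= n_agreements <= n_items")


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_corpus`: hard errors and soft warnings."""

    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    n_unresolved: int = 0
    n_duplicates: int = 0
    n_flag_violations: int = 0

    @property
    def ok(self) -> bool:
        return not self.errors

    def to_text(self) -> str:
        lines = [
            f"errors: {len(self.errors)}",
            f"warnings: {len(self.warnings)}",
            f"unresolved MoA labels: {self.n_unresolved}",
            f"duplicate statements: {self.n_duplicates}",
            f"flag-range violations: {self.n_flag_violations}",
        ]
        lines += [f"ERROR: {e}" for e in self.errors]
        lines += [f"WARNING: {w}" for w in self.warnings]
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        return asdict(self)


def _read_rows(path: str | Path, required: list[str], table: str) -> list[dict]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        names = set(reader.fieldnames or [])
        missing = [c for c in required if c not in names]
        if missing:
            raise SchemaError(
                f"{table} table {path} is missing column(s): {', '.join(missing)}"
            )
        return list(reader)


def _parse_category(raw: str) -> MoACategory:
    raw = raw.strip()
    if not raw:
        return UNRESOLVED
    if raw.upper() == OTHER:
        return OTHER
    if raw.upper() == UNRESOLVED:
        return UNRESOLVED
    try:
        return int(raw)
    except ValueError:
        raise CorpusValidationError(f"bad moa_category value {raw!r}") from None


def read_corpus(
    source_path: str | Path,
    bct_path: str | Path,
    link_path: str | Path,
    bct_registry: BCTRegistry | None = None,
) -> Corpus:
    """Read a corpus from its three CSV tables.

    Hard failures: a missing column (schema error), a BCT code absent from
    the taxonomy registry, a link whose article is not in the source table,
    or a link whose BCT was not coded for that article. Soft issues
    (duplicates, out-of-range flags) are left to :func:`validate_corpus`.
    """
    bct_registry = bct_registry if bct_registry is not None else reg.load_bct_registry()

    source_rows = _read_rows(source_path, SOURCE_COLUMNS, "source")
    bct_rows = _read_rows(bct_path, BCT_COLUMNS, "bct")
    link_rows = _read_rows(link_path, LINK_COLUMNS, "link")

    articles: list[ArticleRecord] = []
    seen_articles: set[str] = set()
    for i, row in enumerate(source_rows, start=2):
        aid = row["article_id"].strip()
        if aid in seen_articles:
            raise CorpusValidationError(f"duplicate article_id {aid!r} (source row {i})")
        seen_articles.add(aid)
        year_raw = (row.get("year") or "").strip()
        articles.append(
            ArticleRecord(
                article_id=aid,
                year=int(year_raw) if year_raw else None,
                behavior=(row.get("behavior") or "").strip(),
                article_type=(row.get("article_type") or "").strip(),
                theory_status=(row.get("theory_status") or "none-mentioned").strip(),
            )
        )

    bct_codings: dict[str, list[str]] = {a.article_id: [] for a in articles}
    bad_codes: list[str] = []
    for i, row in enumerate(bct_rows, start=2):
        aid, code = row["article_id"].strip(), row["bct_code"].strip()
        if aid not in seen_articles:
            raise ReferentialIntegrityError(
                f"bct table row {i} references unknown article {aid!r}"
            )
        if code not in bct_registry:
            bad_codes.append(f"bct row {i}: {code!r}")
            continue
        if code not in bct_codings[aid]:
            bct_codings[aid].append(code)

    links: list[LinkStatement] = []
    for i, row in enumerate(link_rows, start=2):
        aid, code = row["article_id"].strip(), row["bct_code"].strip()
        if aid not in seen_articles:
            raise ReferentialIntegrityError(
                f"link table row {i} references unknown article {aid!r}"
            )
        if code not in bct_registry:
            bad_codes.append(f"link row {i}: {code!r}")
            continue
        if code not in bct_codings[aid]:
            raise ReferentialIntegrityError(
                f"link table row {i}: BCT {code!r} not coded for article {aid!r}"
            )
        links.append(
            LinkStatement(
                article_id=aid,
                bct_code=code,
                moa_label_raw=(row.get("moa_label_raw") or "").strip(),
                moa_definition_raw=(row.get("moa_definition_raw") or "").strip(),
                moa_category=_parse_category(row.get("moa_category") or ""),
                explicitness=int(row.get("explicitness") or 2),
                grouping=int(row.get("grouping") or 1),
                empirical_status=int(row.get("empirical_status") or 1),
            )
        )

    if bad_codes:
        raise CorpusValidationError(
            "unknown BCT code(s): " + "; ".join(bad_codes)
        )
    return Corpus(articles=articles, bct_codings=bct_codings, links=links)


def write_corpus(
    corpus: Corpus,
    source_path: str | Path,
    bct_path: str | Path,
    link_path: str | Path,
) -> None:
    """Write a corpus back to its three CSV tables (round-trip safe)."""
    with open(source_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(SOURCE_COLUMNS)
        for a in corpus.articles:
            writer.writerow(
                [a.article_id, a.year if a.year is not None else "", a.behavior,
                 a.article_type, a.theory_status]
            )
    with open(bct_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(BCT_COLUMNS)
        for aid in (a.article_id for a in corpus.articles):
            for code in corpus.bct_codings.get(aid, []):
                writer.writerow([aid, code])
    with open(link_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(LINK_COLUMNS)
        for s in corpus.links:
            writer.writerow(
                [s.article_id, s.bct_code, s.moa_label_raw, s.moa_definition_raw,
                 s.moa_category, s.explicitness, s.grouping, s.empirical_status]
            )


def validate_corpus(corpus: Corpus) -> ValidationReport:
    """Report soft data-quality issues; a clean corpus yields zero errors.

    Flag values outside their enumerations are errors; repeated
    (article, BCT, MoA) statements are warnings (they are legal on input and
    resolved by deduplication); UNRESOLVED label counts are informational.
    """
    report = ValidationReport()
    seen: set[tuple] = set()
    for s in corpus.links:
        if s.explicitness not in EXPLICITNESS_VALUES:
            report.errors.append(
                f"article {s.article_id} link {s.bct_code}: explicitness "
                f"{s.explicitness} outside {EXPLICITNESS_VALUES}"
            )
            report.n_flag_violations += 1
        if s.grouping not in GROUPING_VALUES:
            report.errors.append(
                f"article {s.article_id} link {s.bct_code}: grouping "
                f"{s.grouping} outside {GROUPING_VALUES}"
            )
            report.n_flag_violations += 1
        if s.empirical_status not in EMPIRICAL_STATUS_VALUES:
            report.errors.append(
                f"article {s.article_id} link {s.bct_code}: empirical_status "
                f"{s.empirical_status} outside {EMPIRICAL_STATUS_VALUES}"
            )
            report.n_flag_violations += 1
        key = (s.article_id, s.bct_code, s.moa_category)
        if key in seen:
            report.warnings.append(
                f"duplicate statement {key} (resolved at deduplication)"
            )
            report.n_duplicates += 1
        seen.add(key)
        if s.moa_category == UNRESOLVED:
            report.n_unresolved += 1
    return report


def read_significant_links_fixture(
    path: str | Path | None = None,
) -> list[SignificantLinkRow]:
    """Read the packaged transcription of the study's significant-link tables.

    The same 87-link set underlies both published views (grouped by BCT and
    grouped by MoA); this fixture stores it once, in the by-BCT order.
    """
    p = Path(path) if path is not None else reg._data_path("significant_links.csv")
    rows: list[SignificantLinkRow] = []
    seen: set[tuple[str, int]] = set()
    with open(p, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"bct_code", "moa_id", "frequency", "p_display"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise FixtureError(f"fixture {p} must have columns {sorted(required)}")
        for i, raw in enumerate(reader, start=2):
            row = SignificantLinkRow(
                bct_code=raw["bct_code"].strip(),
                moa_id=int(raw["moa_id"]),
                frequency=int(raw["frequency"]),
                p_display=raw["p_display"].strip(),
            )
            if row.frequency < 1:
                raise FixtureError(f"fixture row {i}: frequency must be >= 1")
            if not 0.0 < row.p_value <= 0.05:
                raise FixtureError(
                    f"fixture row {i}: p {row.p_display!r} outside (0, .05]"
                )
            key = (row.bct_code, row.moa_id)
            if key in seen:
                raise FixtureError(f"fixture row {i}: duplicate link {key}")
            seen.add(key)
            rows.append(row)
    if not rows:
        raise FixtureError(f"fixture {p} contains no rows")
    return rows


def coding_agreement(comparison: CodingComparison) -> dict[str, float]:
    """Percent agreement and Prevalence-and-Bias-Adjusted Kappa.

    PABAK = 2 * p_o - 1, where p_o is the observed agreement proportion; it
    rescales agreement so that chance-level binary agreement (p_o = 0.5)
    scores zero regardless of category prevalence.
    """
    if comparison.n_items == 0:
        raise ValueError("agreement is undefined for zero compared items")
    p_o = comparison.n_agreements / comparison.n_items
    return {"percent_agreement": p_o, "pabak": 2.0 * p_o - 1.0}


def write_validation_report(report: ValidationReport, out_path: str | Path) -> None:
    """Write a report as line-oriented text plus a .json sidecar."""
    out_path = Path(out_path)
    out_path.write_text(report.to_text() + "\n", encoding="utf-8")
    out_path.with_suffix(".json").write_text(
        json.dumps(report.to_json_dict(), indent=2) + "\n", encoding="utf-8"
    )
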