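"""Shared fixtures: registries, a toy hand-built corpus, and CSV writers."""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pytest

from bctmoa import (
    ArticleRecord,
    Corpus,
    LinkStatement,
    load_bct_registry,
    load_moa_registry,
    load_synonym_map,
)


@pytest.fixture(scope="session")
def bct_registry():
    return load_bct_registry()


@pytest.fixture(scope="session")
def moa_registry():
    return load_moa_registry()


@pytest.fixture(scope="session")
def synonym_map(moa_registry):
    return load_synonym_map(moa_registry)


@pytest.fixture
def toy_corpus() -> Corpus:
    """Two articles, three links: the smallest corpus exercising every table."""
    articles = [
        ArticleRecord(article_id="A1", year=2005, behavior="physical activity",
                      article_type="outcome evaluation", theory_status="applied"),
        ArticleRecord(article_id="A2", year=2012, behavior="smoking",
                      article_type="development", theory_status="none-mentioned"),
    ]
    bct_codings = {"A1": ["1.1", "1.2"], "A2": ["1.1"]}
    links = [
        LinkStatement("A1", "1.1", "Behavioral Regulation", 14, explicitness=2,
                      grouping=1, empirical_status=1),
        LinkStatement("A1", "1.2", "Beliefs about Capabilities", 4, explicitness=1,
                      grouping=2, empirical_status=1),
        LinkStatement("A2", "1.1", "Behavioral Regulation", 14, explicitness=2,
                      grouping=1, empirical_status=3),
    ]
    return Corpus(articles=articles, bct_codings=bct_codings, links=links)


def write_corpus_csvs(corpus: Corpus, directory: Path) -> tuple[Path, Path, Path]:
    """Write a corpus's three tables into ``directory``; returns the paths."""
    from bctmoa import write_corpus

    paths = (directory / "source.csv", directory / "bct.csv", directory / "link.csv")
    write_corpus(corpus, *paths)
    return paths


@pytest.fixture
def toy_corpus_paths(toy_corpus, tmp_path) -> tuple[Path, Path, Path]:
    return write_corpus_csvs(toy_corpus, tmp_path)


def restricted_weights(n_bcts: int, n_moas: int) -> tuple[np.ndarray, np.ndarray]:
    """Uniform weights confined to the first n_bcts x n_moas cells, giving a
    small dense link space where per-cell expected counts are controllable."""
    bw = np.zeros(93)
    bw[:n_bcts] = 1.0
    mw = np.zeros(26)
    mw[:n_moas] = 1.0
    return bw, mw
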