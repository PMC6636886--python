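"""Registries for the BCTTv1 taxonomy and the 26-construct MoA framework.

The package ships two authoritative lookup tables as editable CSV files:

* the 93 behavior change techniques (BCTs) of BCT Taxonomy version 1,
  identified by hierarchical codes such as ``"8.7"`` (group 8, technique 7);
* the 26 mechanism-of-action (MoA) constructs used to categorize authors'
  free-text mechanism labels: the 14 Theoretical Domains Framework domains
  plus 12 constructs frequent across theories of behavior change.

Free-text MoA labels from coded articles are mapped onto the 26 constructs
through a user-extensible synonym map; labels with no mapping resolve to the
sentinel category :data:`OTHER` rather than being guessed.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping, Union

from .errors import RegistryError

#: Sentinel category for an MoA label that maps onto none of the 26 constructs.
OTHER = "OTHER"

#: Sentinel for a link whose raw label has not yet been resolved.
UNRESOLVED = "UNRESOLVED"

#: Category value type: a registry id, or one of the two sentinels.
MoACategory = Union[int, str]

_BCT_CODE_RE = re.compile(r"^\d+\.\d+$")
_MOA_SOURCES = ("TDF-domain", "theory-derived")

N_BCTS = 93
N_MOAS = 26
N_TDF_DOMAINS = 14


def _data_path(name: str) -> Path:
    return Path(str(resources.files("bctmoa").joinpath("data", name)))


@dataclass(frozen=True)
class BCTEntry:
    """One BCTTv1 technique."""

    code: str
    label: str

    @property
    def group_number(self) -> int:
        """BCTTv1 cluster index, parsed from the code prefix (1-16)."""
        return int(self.code.split(".", 1)[0])


@dataclass(frozen=True)
class MoAEntry:
    """One of the 26 mechanism-of-action constructs."""

    id: int
    label: str
    definition: str
    source: str  # "TDF-domain" or "theory-derived"


class BCTRegistry:
    """Immutable, code-indexed collection of the 93 BCTs."""

    def __init__(self, entries: list[BCTEntry]):
        self._by_code = {e.code: e for e in entries}
        self._entries = tuple(entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[BCTEntry]:
        return iter(self._entries)

    def __contains__(self, code: str) -> bool:
        return code in self._by_code

    def __getitem__(self, code: str) -> BCTEntry:
        try:
            return self._by_code[code]
        except KeyError:
            raise KeyError(f"unknown BCT code {code!r}") from None

    @property
    def codes(self) -> list[str]:
        return [e.code for e in self._entries]

    def sort_key(self, code: str) -> tuple[int, int]:
        """Numeric ordering key so '10.2' sorts after '9.1', not before '2.1'."""
        major, minor = code.split(".", 1)
        return (int(major), int(minor))


class MoARegistry:
    """Immutable, id-indexed collection of the 26 MoA constructs."""

    def __init__(self, entries: list[MoAEntry]):
        self._by_id = {e.id: e for e in entries}
        self._by_label = {normalize_label(e.label): e for e in entries}
        self._entries = tuple(entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[MoAEntry]:
        return iter(self._entries)

    def __contains__(self, moa_id: int) -> bool:
        return moa_id in self._by_id

    def __getitem__(self, moa_id: int) -> MoAEntry:
        try:
            return self._by_id[moa_id]
        except KeyError:
            raise KeyError(f"unknown MoA id {moa_id!r}") from None

    def by_label(self, label: str) -> MoAEntry:
        entry = self._by_label.get(normalize_label(label))
        if entry is None:
            raise KeyError(f"unknown MoA label {label!r}")
        return entry

    @property
    def ids(self) -> list[int]:
        return [e.id for e in self._entries]


@dataclass(frozen=True)
class SynonymMap:
    """Mapping from normalized free-text MoA labels to registry ids.

    Canonical construct labels always resolve; the ``entries`` mapping adds
    curated equivalences (e.g. "self-efficacy" -> Beliefs about Capabilities).
    """

    registry: MoARegistry
    entries: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, moa_id in self.entries.items():
            if moa_id not in self.registry:
                raise RegistryError(
                    f"synonym {label!r} maps to unknown MoA id {moa_id}"
                )


_QUOTE_CHARS = "\"'‘’“”"


def normalize_label(raw: str) -> str:
    """Normalize a free-text label: lowercase, strip quotes, collapse spaces."""
    cleaned = raw.translate({ord(c): None for c in _QUOTE_CHARS})
    return " ".join(cleaned.lower().split())


def load_bct_registry(path: str | Path | None = None) -> BCTRegistry:
    """Load the BCT registry, validating count, code format, and uniqueness.

    Parameters
    ----------
    path
        Optional alternative registry CSV (columns ``code,label``); by
        default the packaged BCTTv1 file is used, which must contain exactly
        93 techniques.
    """
    p = Path(path) if path is not None else _data_path("bct_taxonomy.csv")
    entries: list[BCTEntry] = []
    seen: set[str] = set()
    with open(p, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"code", "label"} <= set(reader.fieldnames):
            raise RegistryError(f"BCT registry {p} must have columns code,label")
        for row in reader:
            code, label = row["code"].strip(), row["label"].strip()
            if not _BCT_CODE_RE.match(code):
                raise RegistryError(f"malformed BCT code {code!r} in {p}")
            if code in seen:
                raise RegistryError(f"duplicate BCT code {code!r} in {p}")
            if not label:
                raise RegistryError(f"empty label for BCT code {code!r} in {p}")
            seen.add(code)
            entries.append(BCTEntry(code=code, label=label))
    if path is None and len(entries) != N_BCTS:
        raise RegistryError(
            f"shipped BCT registry must contain {N_BCTS} techniques, found {len(entries)}"
        )
    return BCTRegistry(entries)


def load_moa_registry(path: str | Path | None = None) -> MoARegistry:
    """Load the MoA registry (26 constructs: 14 TDF domains + 12 theory-derived)."""
    p = Path(path) if path is not None else _data_path("moa_constructs.csv")
    entries: list[MoAEntry] = []
    seen_ids: set[int] = set()
    seen_labels: set[str] = set()
    with open(p, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"id", "label", "definition", "source"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise RegistryError(f"MoA registry {p} must have columns id,label,definition,source")
        for row in reader:
            try:
                moa_id = int(row["id"])
            except ValueError:
                raise RegistryError(f"non-integer MoA id {row['id']!r} in {p}") from None
            label = row["label"].strip()
            definition = row["definition"].strip()
            source = row["source"].strip()
            if moa_id in seen_ids:
                raise RegistryError(f"duplicate MoA id {moa_id} in {p}")
            key = normalize_label(label)
            if key in seen_labels:
                raise RegistryError(f"duplicate MoA label {label!r} in {p}")
            if not definition:
                raise RegistryError(f"missing definition for MoA {label!r} in {p}")
            if source not in _MOA_SOURCES:
                raise RegistryError(
                    f"MoA source must be one of {_MOA_SOURCES}, got {source!r}"
                )
            seen_ids.add(moa_id)
            seen_labels.add(key)
            entries.append(MoAEntry(id=moa_id, label=label, definition=definition, source=source))
    if path is None:
        n_tdf = sum(e.source == "TDF-domain" for e in entries)
        if len(entries) != N_MOAS or n_tdf != N_TDF_DOMAINS:
            raise RegistryError(
                f"shipped MoA registry must contain {N_MOAS} constructs "
                f"({N_TDF_DOMAINS} TDF domains); found {len(entries)} ({n_tdf} TDF)"
            )
    return MoARegistry(entries)


def load_synonym_map(
    registry: MoARegistry | None = None, path: str | Path | None = None
) -> SynonymMap:
    """Load the curated synonym seed shipped with the package.

    The seed is deliberately small: canonical labels, typographic variants,
    and equivalences stated outright in the source frameworks (self-efficacy
    is conceptually identical to Beliefs about Capabilities). Full coder
    judgment cannot be automated; unmapped labels resolve to OTHER.
    """
    registry = registry if registry is not None else load_moa_registry()
    p = Path(path) if path is not None else _data_path("moa_synonyms.csv")
    entries: dict[str, int] = {}
    with open(p, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"label", "moa_id"} <= set(reader.fieldnames):
            raise RegistryError(f"synonym map {p} must have columns label,moa_id")
        for row in reader:
            entries[normalize_label(row["label"])] = int(row["moa_id"])
    return SynonymMap(registry=registry, entries=entries)


def resolve_moa_label(raw_label: str, synonym_map: SynonymMap) -> MoACategory:
    """Resolve a free-text MoA label to a registry id, or OTHER.

    Matching is deterministic and normalization-invariant: canonical
    construct labels match first, then curated synonyms. Anything else is
    OTHER — the resolver never guesses.
    """
    if not raw_label or not raw_label.strip():
        raise ValueError("raw_label must be nonempty")
    key = normalize_label(raw_label)
    try:
        return synonym_map.registry.by_label(key).id
    except KeyError:
        pass
    if key in synonym_map.entries:
        return synonym_map.entries[key]
    return OTHER
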