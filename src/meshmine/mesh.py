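"""MeSH descriptor parsing, tree depths, and the root-proximity penalty PWK.

MeSH is polyhierarchical: one descriptor (keyword) may carry several tree
numbers, i.e. sit under several branches at different depths. Depth counts the
single-letter category root as level 1, so a tree number with ``s``
dot-separated segments has depth ``s + 1``. Keywords close to the root are
generic ("family", "cells") and are penalized by

    PWK(T) = 2**(T - 5)  for depth T < 5,   1 otherwise,

halving the weight for each level above the fifth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Union

from lxml import etree

from ._matching import normalize_term

logger = logging.getLogger(__name__)

#: Anatomy, Organisms, Diseases, Chemicals and Drugs, Psychiatry and Psychology
DEFAULT_CATEGORIES = frozenset({"A", "B", "C", "D", "F"})

#: All top-level MeSH category letters.
VALID_CATEGORIES = frozenset("ABCDEFGHIJKLMNVZ")


@dataclass(frozen=True, order=True)
class TreePosition:
    """One location of a descriptor in the MeSH hierarchy."""

    tree_number: str

    @property
    def category(self) -> str:
        return self.tree_number[0]

    @property
    def depth(self) -> int:
        # category letter = depth 1; each dot-separated segment adds one level
        return self.tree_number.count(".") + 2


def keyword_depth(positions: Iterable[TreePosition], rule: str = "max") -> int:
    """Aggregate a multi-position keyword's depths to one value.

    MeSH places a specific term under several branches; ``max`` (default)
    takes its most specific placement, ``min`` its most generic one.
    """
    depths = [p.depth for p in positions]
    if not depths:
        raise ValueError("keyword_depth requires at least one tree position")
    if rule == "max":
        return max(depths)
    if rule == "min":
        return min(depths)
    raise ValueError(f"unknown depth rule {rule!r}; expected 'max' or 'min'")


def pwk(depth: int) -> float:
    """Depth penalty: 2**(depth-5) below depth 5, otherwise 1."""
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    return 2.0 ** (depth - 5) if depth < 5 else 1.0


@dataclass
class Dictionary:
    """Keyword -> tree positions, with per-keyword aggregated depth."""

    entries: dict[str, frozenset[TreePosition]]
    categories_kept: frozenset[str] = field(default_factory=lambda: VALID_CATEGORIES)
    depth_rule: str = "max"

    def __post_init__(self) -> None:
        self.keyword_depth: dict[str, int] = {
            kw: keyword_depth(pos, self.depth_rule) for kw, pos in self.entries.items()
        }

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, keyword: str) -> bool:
        return keyword in self.entries

    @property
    def keywords(self) -> list[str]:
        return sorted(self.entries)

    @property
    def n_positions(self) -> int:
        return sum(len(p) for p in self.entries.values())

    def pwk(self, keyword: str) -> float:
        return pwk(self.keyword_depth[keyword])

    def depth_histogram(self) -> dict[int, int]:
        hist: dict[int, int] = {}
        for d in self.keyword_depth.values():
            hist[d] = hist.get(d, 0) + 1
        return dict(sorted(hist.items()))

    def to_tabular(self, path: Union[str, Path, IO[str]]) -> None:
        """Serialize as ``keyword<TAB>treenum[;treenum...]`` lines."""
        lines = []
        for kw in sorted(self.entries):
            nums = ";".join(sorted(p.tree_number for p in self.entries[kw]))
            lines.append(f"{kw}\t{nums}\n")
        if hasattr(path, "write"):
            path.writelines(lines)
        else:
            Path(path).write_text("".join(lines), encoding="utf-8")


def _build(pairs: Iterable[tuple[str, set[str]]], depth_rule: str) -> Dictionary:
    entries: dict[str, set[TreePosition]] = {}
    for keyword, tree_numbers in pairs:
        kw = normalize_term(keyword)
        if not kw:
            continue
        entries.setdefault(kw, set()).update(TreePosition(t) for t in tree_numbers)
    frozen = {kw: frozenset(pos) for kw, pos in entries.items() if pos}
    return Dictionary(frozen, depth_rule=depth_rule)


def _parse_tabular(handle: IO[str], depth_rule: str) -> Dictionary:
    pairs = []
    for lineno, line in enumerate(handle, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"malformed tabular dictionary record at line {lineno}: {line!r}")
        keyword, nums = parts
        tree_numbers = {t.strip() for t in nums.split(";") if t.strip()}
        if not tree_numbers:
            logger.warning("descriptor %r (line %d) has no tree numbers; skipped", keyword, lineno)
            continue
        pairs.append((keyword, tree_numbers))
    return _build(pairs, depth_rule)


def _parse_xml(source, depth_rule: str) -> Dictionary:
    tree = etree.parse(source)
    pairs = []
    for idx, rec in enumerate(tree.iter("DescriptorRecord")):
        name = rec.findtext("DescriptorName/String")
        if name is None:
            raise ValueError(f"malformed DescriptorRecord at index {idx}: missing DescriptorName/String")
        tree_numbers = {t.text.strip() for t in rec.findall("TreeNumberList/TreeNumber") if t.text}
        if not tree_numbers:
            logger.warning("descriptor %r (record %d) has no tree numbers; skipped", name, idx)
            continue
        pairs.append((name, tree_numbers))
    return _build(pairs, depth_rule)


def parse_mesh(source: Union[str, Path, IO], format: str = "tabular", depth_rule: str = "max") -> Dictionary:
    """Parse MeSH descriptors from official XML or the tabular dialect.

    The tabular dialect is UTF-8, ``keyword<TAB>treenum[;treenum...]``, with
    ``#`` comment lines. Keywords are lowercased with whitespace collapsed;
    a keyword appearing on several lines unions its tree numbers.
    """
    if format == "tabular":
        if hasattr(source, "read"):
            return _parse_tabular(source, depth_rule)
        with open(source, encoding="utf-8") as handle:
            return _parse_tabular(handle, depth_rule)
    if format == "xml":
        return _parse_xml(str(source) if isinstance(source, Path) else source, depth_rule)
    raise ValueError(f"unknown dictionary format {format!r}; expected 'tabular' or 'xml'")


def filter_categories(dictionary: Dictionary, keep: Iterable[str] = DEFAULT_CATEGORIES) -> Dictionary:
    """Restrict to the given top-level categories; drop emptied keywords.

    The default keep-set {A, B, C, D, F} covers anatomy, organisms, diseases,
    chemicals and drugs, and psychiatry and psychology.
    """
    keep = frozenset(keep)
    if not keep:
        raise ValueError("keep must be non-empty")
    unknown = keep - VALID_CATEGORIES
    if unknown:
        raise ValueError(
            f"unknown category codes {sorted(unknown)}; valid codes: {''.join(sorted(VALID_CATEGORIES))}"
        )
    entries = {}
    for kw, positions in dictionary.entries.items():
        kept = frozenset(p for p in positions if p.category in keep)
        if kept:
            entries[kw] = kept
    return Dictionary(entries, categories_kept=keep, depth_rule=dictionary.depth_rule)
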