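"""Tokenization and dictionary phrase matching.

Matching is case-insensitive, token-boundary, longest-match-first and
non-overlapping: at each token position the longest registered phrase starting
there is counted and the scan resumes after it.
"""

from __future__ import annotations

import re
from collections import Counter
from typing import Iterable

_TOKEN_RE = re.compile(r"[a-z0-9]+")
_WS_RE = re.compile(r"\s+")


def normalize_term(term: str) -> str:
    """Lowercase and collapse internal whitespace runs to single spaces."""
    return _WS_RE.sub(" ", term.strip().lower())


def tokenize(text: str) -> list[str]:
    """Lowercased alphanumeric tokens; punctuation acts as a boundary."""
    return _TOKEN_RE.findall(text.lower())


class PhraseMatcher:
    """Count non-overlapping occurrences of a fixed phrase set in token runs.

    Phrases are token tuples; a multi-word phrase must appear as a contiguous
    token run. Ties at one start position resolve to the longest phrase.
    """

    def __init__(self, phrases: Iterable[str]):
        self._by_first: dict[str, list[tuple[str, ...]]] = {}
        self._names: dict[tuple[str, ...], str] = {}
        for phrase in phrases:
            norm = normalize_term(phrase)
            toks = tuple(tokenize(norm))
            if not toks:
                continue
            # first registration wins, so duplicate surface forms are harmless
            self._names.setdefault(toks, norm)
            bucket = self._by_first.setdefault(toks[0], [])
            if toks not in bucket:
                bucket.append(toks)
        for bucket in self._by_first.values():
            bucket.sort(key=len, reverse=True)

    def count(self, text: str) -> Counter[str]:
        """Occurrence counts keyed by the normalized phrase."""
        tokens = tokenize(text)
        counts: Counter[str] = Counter()
        i, n = 0, len(tokens)
        while i < n:
            bucket = self._by_first.get(tokens[i])
            if bucket:
                for cand in bucket:
                    if tuple(tokens[i:i + len(cand)]) == cand:
                        counts[self._names[cand]] += 1
                        i += len(cand)
                        break
                else:
                    i += 1
            else:
                i += 1
        return counts

    def contains(self, text: str) -> bool:
        return bool(self.count(text))
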