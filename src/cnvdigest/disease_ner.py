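"""Dictionary-based disease mention recognition and normalization.

Disease surfaces are recognized by greedy longest-match lookup against a
MEDIC-style lexicon (MeSH/OMIM concept identifiers, preferred names, and
synonyms) and normalized to the concept identifier. Matching is
case-insensitive and anchored at token boundaries (alphanumeric runs), so
"flu" never fires inside "fluid".

The matcher is deliberately deterministic; the module interface would also
accommodate a learned normalizer, but none is shipped.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

from cnvdigest.corpus_io import Sentence
from cnvdigest.errors import LexiconFormatError

__all__ = [
    "LexiconEntry",
    "DiseaseLexicon",
    "DiseaseMention",
    "load_lexicon",
    "default_lexicon",
    "find_disease_mentions",
]

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+")


def _name_key(name: str) -> tuple[str, ...]:
    """Case-folded, token-normalized lookup key for a disease name."""
    return tuple(t.casefold() for t in _TOKEN_RE.findall(name))


@dataclass(frozen=True)
class LexiconEntry:
    concept_id: str
    preferred_name: str
    synonyms: tuple[str, ...] = ()


@dataclass(frozen=True)
class DiseaseMention:
    """A disease surface span normalized to a lexicon concept.

    Offsets are sentence-relative; ``matched_name`` is the lexicon name the
    surface resolved through (preferred name or synonym).
    """

    pmid: str
    field: str
    sentence_index: int
    start: int
    end: int
    surface: str
    concept_id: str
    matched_name: str


class DiseaseLexicon:
    """A loaded disease vocabulary with a normalized lookup index.

    The index maps each normalized name to exactly one concept; when two
    concepts list the same name, the first-listed concept wins and a warning
    is emitted.
    """

    def __init__(self, entries: list[LexiconEntry]):
        if not entries:
            raise LexiconFormatError("disease lexicon contains no entries")
        seen_ids = set()
        for e in entries:
            if not (e.concept_id.startswith("MESH:") or e.concept_id.startswith("OMIM:")):
                raise LexiconFormatError(
                    f"concept id {e.concept_id!r} lacks a MESH:/OMIM: prefix"
                )
            if e.concept_id in seen_ids:
                raise LexiconFormatError(f"duplicate concept id {e.concept_id}")
            seen_ids.add(e.concept_id)
        self.entries = list(entries)
        self._index: dict[tuple[str, ...], tuple[str, str]] = {}
        for e in entries:
            for name in (e.preferred_name, *e.synonyms):
                if not name:
                    raise LexiconFormatError(f"empty name under concept {e.concept_id}")
                key = _name_key(name)
                if key in self._index:
                    prev_id, prev_name = self._index[key]
                    if prev_id != e.concept_id:
                        warnings.warn(
                            f"name {name!r} maps to both {prev_id} and "
                            f"{e.concept_id}; keeping first-listed {prev_id}",
                            stacklevel=3,
                        )
                    continue
                self._index[key] = (e.concept_id, name)
        self._max_tokens = max(len(k) for k in self._index)

    def __len__(self) -> int:
        return len(self.entries)

    def resolve(self, name: str) -> Optional[str]:
        """Concept id for a name, or None if absent."""
        hit = self._index.get(_name_key(name))
        return hit[0] if hit else None

    def lookup(self, key: tuple[str, ...]) -> Optional[tuple[str, str]]:
        return self._index.get(key)

    @property
    def max_tokens(self) -> int:
        return self._max_tokens

    def names(self) -> list[str]:
        """All resolvable names (preferred and synonyms), in entry order."""
        out = []
        for e in self.entries:
            out.append(e.preferred_name)
            out.extend(e.synonyms)
        return out


def load_lexicon(path) -> DiseaseLexicon:
    """Load a MEDIC-style TSV lexicon.

    Columns: concept id (``MESH:``/``OMIM:`` prefixed), preferred name,
    optional pipe-separated synonyms. Lines starting with ``#`` are comments.
    """
    path = Path(path)
    entries: list[LexiconEntry] = []
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise LexiconFormatError(
                f"{path}:{lineno}: expected at least 2 tab-separated columns"
            )
        concept_id, preferred = parts[0].strip(), parts[1].strip()
        synonyms = tuple(
            s.strip() for s in (parts[2].split("|") if len(parts) > 2 and parts[2] else []) if s.strip()
        )
        entries.append(LexiconEntry(concept_id, preferred, synonyms))
    return DiseaseLexicon(entries)


def default_lexicon() -> DiseaseLexicon:
    """The bundled ~20-concept synthetic fixture lexicon."""
    with resources.as_file(
        resources.files("cnvdigest.data").joinpath("disease_lexicon_synthetic.tsv")
    ) as p:
        return load_lexicon(p)


def find_disease_mentions(sentence: Sentence, lexicon: DiseaseLexicon) -> list[DiseaseMention]:
    """Greedy longest-match disease recognition over one sentence.

    Scans token positions left to right; at each position the longest
    lexicon name starting there wins, and the scan resumes after it, so
    emitted spans never overlap.
    """
    tokens = [(m.group(), m.start(), m.end()) for m in _TOKEN_RE.finditer(sentence.text)]
    keys = [t[0].casefold() for t in tokens]
    mentions: list[DiseaseMention] = []
    i = 0
    n = len(tokens)
    while i < n:
        hit = None
        for length in range(min(lexicon.max_tokens, n - i), 0, -1):
            found = lexicon.lookup(tuple(keys[i : i + length]))
            if found is not None:
                hit = (length, found)
                break
        if hit is None:
            i += 1
            continue
        length, (concept_id, matched_name) = hit
        start = tokens[i][1]
        end = tokens[i + length - 1][2]
        mentions.append(
            DiseaseMention(
                pmid=sentence.pmid,
                field=sentence.field,
                sentence_index=sentence.index,
                start=start,
                end=end,
                surface=sentence.text[start:end],
                concept_id=concept_id,
                matched_name=matched_name,
            )
        )
        i += length
    return mentions
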