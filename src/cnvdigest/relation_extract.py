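"""Sentence-level CNV-disease relation extraction via trigger words.

Candidate instances are the cross product of CNV and disease mentions
co-occurring in one sentence. Each instance is classified by searching for a
trigger term (e.g. "associated", "caused") from an editable lexicon: the
token window between the two entity spans is searched first, then the whole
sentence as a fallback; the trigger nearest the midpoint of the two entities
wins, ties breaking to the left. A pair with a trigger is ``related``;
trigger-free co-occurrences are kept with ``related=False`` so downstream
consumers can choose their own co-occurrence policy.

Trigger matching is case-insensitive with light inflection folding, so
"associate", "associated" and "association" are one family. Negation is not
modelled: "not associated" still counts as a trigger.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

from cnvdigest.cnv_ner import CnvMention
from cnvdigest.corpus_io import Sentence
from cnvdigest.disease_ner import DiseaseMention
from cnvdigest.errors import ContractViolation, LexiconFormatError

__all__ = [
    "TriggerTerm",
    "TriggerLexicon",
    "CandidateInstance",
    "RelationRecord",
    "load_triggers",
    "default_triggers",
    "fold_token",
    "generate_instances",
    "find_trigger",
    "classify_relation",
]

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+")

# Longest-first suffix strip; a stem shorter than 3 characters keeps the
# original token, so "is"/"as" are never folded into noise.
_SUFFIXES = ("ings", "ing", "ions", "ion", "ied", "ies", "ed", "es", "s", "e", "d")


def fold_token(token: str) -> str:
    """Lower-case a token and strip one inflectional suffix.

    Maps associate/associated/association onto one stem; short function
    words are left untouched.
    """
    t = token.lower()
    for suffix in _SUFFIXES:
        if t.endswith(suffix) and len(t) - len(suffix) >= 3:
            return t[: -len(suffix)]
    return t


def _fold_phrase(phrase: str) -> tuple[str, ...]:
    return tuple(fold_token(t) for t in _TOKEN_RE.findall(phrase))


@dataclass(frozen=True)
class TriggerTerm:
    surface: str
    category: str  # verb | noun | preposition
    stem: tuple[str, ...]


class TriggerLexicon:
    """Trigger terms indexed by folded stem.

    Terms that fold to the same stem (cause/caused/causes) collapse into one
    entry; the first-listed surface is kept as the representative.
    """

    _CATEGORIES = {"verb", "noun", "preposition"}

    def __init__(self, terms: list[tuple[str, str]]):
        if not terms:
            raise LexiconFormatError("trigger lexicon contains no terms")
        self.terms: list[TriggerTerm] = []
        self._stems: dict[tuple[str, ...], TriggerTerm] = {}
        for surface, category in terms:
            if category not in self._CATEGORIES:
                raise LexiconFormatError(f"unknown trigger category {category!r}")
            stem = _fold_phrase(surface)
            if not stem:
                raise LexiconFormatError(f"trigger term {surface!r} has no tokens")
            if stem in self._stems:
                continue
            term = TriggerTerm(surface=surface, category=category, stem=stem)
            self._stems[stem] = term
            self.terms.append(term)
        self._max_tokens = max(len(s) for s in self._stems)

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, surface: str) -> bool:
        return _fold_phrase(surface) in self._stems

    @property
    def max_tokens(self) -> int:
        return self._max_tokens

    def match_stem(self, stem: tuple[str, ...]) -> Optional[TriggerTerm]:
        return self._stems.get(stem)

    def without(self, surface: str) -> "TriggerLexicon":
        """A copy with one term family removed (for ablation)."""
        drop = _fold_phrase(surface)
        kept = [(t.surface, t.category) for t in self.terms if t.stem != drop]
        return TriggerLexicon(kept)


def load_triggers(path) -> TriggerLexicon:
    """Load a trigger lexicon: one term per line, optional tab-separated
    category (defaults to ``verb``); ``#`` lines are comments."""
    path = Path(path)
    terms: list[tuple[str, str]] = []
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        surface = parts[0].strip()
        category = parts[1].strip() if len(parts) > 1 and parts[1].strip() else "verb"
        if not surface:
            raise LexiconFormatError(f"{path}:{lineno}: empty trigger term")
        terms.append((surface, category))
    return TriggerLexicon(terms)


def default_triggers() -> TriggerLexicon:
    """The bundled default trigger lexicon."""
    with resources.as_file(
        resources.files("cnvdigest.data").joinpath("triggers_default.txt")
    ) as p:
        return load_triggers(p)


@dataclass(frozen=True)
class CandidateInstance:
    """One co-occurring CNV-disease mention pair within a sentence."""

    sentence: Sentence
    cnv: CnvMention
    disease: DiseaseMention


@dataclass(frozen=True)
class RelationRecord:
    """One classified sentence-level CNV-disease pair.

    ``related`` is true exactly when a trigger was found; ``trigger`` then
    carries the matched sentence surface. Offsets are sentence-relative and
    support evidence highlighting.
    """

    pmid: str
    field: str
    sentence_index: int
    sentence_text: str
    cnv_id: str
    cnv_start: int
    cnv_end: int
    cnv_surface: str
    disease_id: str
    disease_start: int
    disease_end: int
    disease_surface: str
    polarity: str
    trigger: Optional[str]
    related: bool

    def to_dict(self) -> dict:
        return {
            "pmid": self.pmid,
            "field": self.field,
            "sentence_index": self.sentence_index,
            "sentence_text": self.sentence_text,
            "cnv_id": self.cnv_id,
            "cnv_start": self.cnv_start,
            "cnv_end": self.cnv_end,
            "cnv_surface": self.cnv_surface,
            "disease_id": self.disease_id,
            "disease_start": self.disease_start,
            "disease_end": self.disease_end,
            "disease_surface": self.disease_surface,
            "polarity": self.polarity,
            "trigger": self.trigger,
            "related": self.related,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RelationRecord":
        return cls(**d)


def _same_sentence(sentence: Sentence, mention) -> bool:
    return (
        mention.pmid == sentence.pmid
        and mention.field == sentence.field
        and mention.sentence_index == sentence.index
    )


def generate_instances(
    sentence: Sentence,
    cnvs: list[CnvMention],
    diseases: list[DiseaseMention],
) -> list[CandidateInstance]:
    """Cross product of CNV and disease mentions in one sentence.

    Ordered by (cnv.start, disease.start). Pairs whose spans overlap each
    other are dropped (a mention cannot be evidence for itself).
    """
    for m in (*cnvs, *diseases):
        if not _same_sentence(sentence, m):
            raise ContractViolation("mention does not belong to the given sentence")
    instances = [
        CandidateInstance(sentence=sentence, cnv=c, disease=d)
        for c in sorted(cnvs, key=lambda m: m.start)
        for d in sorted(diseases, key=lambda m: m.start)
        if c.end <= d.start or d.end <= c.start
    ]
    instances.sort(key=lambda inst: (inst.cnv.start, inst.disease.start))
    return instances


def _trigger_matches(text: str, triggers: TriggerLexicon) -> list[tuple[int, int, str]]:
    """All (start, end, surface) trigger occurrences in *text*."""
    tokens = [(m.group(), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]
    stems = [fold_token(t[0]) for t in tokens]
    out: list[tuple[int, int, str]] = []
    n = len(tokens)
    for i in range(n):
        for length in range(min(triggers.max_tokens, n - i), 0, -1):
            if triggers.match_stem(tuple(stems[i : i + length])) is not None:
                start, end = tokens[i][1], tokens[i + length - 1][2]
                out.append((start, end, text[start:end]))
                break
    return out


def find_trigger(
    instance: CandidateInstance, triggers: TriggerLexicon
) -> Optional[tuple[str, int]]:
    """Locate the trigger evidence for an instance, if any.

    Returns ``(surface, start_offset)`` of the chosen trigger or ``None``.
    The gap between the two entity spans is searched first; only if it holds
    no trigger is the whole sentence searched. Among candidates, the one
    whose midpoint is nearest the midpoint of the two entities wins, with
    ties broken toward the left. Matches overlapping either entity span are
    ignored.
    """
    text = instance.sentence.text
    cnv, dis = instance.cnv, instance.disease
    matches = [
        m
        for m in _trigger_matches(text, triggers)
        if (m[1] <= cnv.start or m[0] >= cnv.end)
        and (m[1] <= dis.start or m[0] >= dis.end)
    ]
    if not matches:
        return None
    gap_lo = min(cnv.end, dis.end)
    gap_hi = max(cnv.start, dis.start)
    between = [m for m in matches if m[0] >= gap_lo and m[1] <= gap_hi]
    pool = between if between else matches
    target = ((cnv.start + cnv.end) / 2 + (dis.start + dis.end) / 2) / 2
    best = min(pool, key=lambda m: (abs((m[0] + m[1]) / 2 - target), m[0]))
    return (best[2], best[0])


def classify_relation(
    instance: CandidateInstance,
    trigger_result: Optional[tuple[str, int]],
    polarity: Optional[str] = None,
) -> RelationRecord:
    """Build the relation record for an instance.

    ``related`` is true iff a trigger was found. Polarity defaults to the
    CNV mention's own (keyword-window) polarity.
    """
    if polarity is None:
        polarity = instance.cnv.polarity
    return RelationRecord(
        pmid=instance.sentence.pmid,
        field=instance.sentence.field,
        sentence_index=instance.sentence.index,
        sentence_text=instance.sentence.text,
        cnv_id=instance.cnv.locus.canonical_id,
        cnv_start=instance.cnv.start,
        cnv_end=instance.cnv.end,
        cnv_surface=instance.cnv.surface,
        disease_id=instance.disease.concept_id,
        disease_start=instance.disease.start,
        disease_end=instance.disease.end,
        disease_surface=instance.disease.surface,
        polarity=polarity,
        trigger=trigger_result[0] if trigger_result else None,
        related=trigger_result is not None,
    )
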