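"""De-duplication, association summaries, and the three query perspectives.

Relation records are keyed by (pmid, field, sentence index, CNV id, disease
id); de-duplication keeps one record per key and emits them in sorted key
order, which also makes parallel and serial runs byte-identical. Summaries
count evidence per (CNV, disease) pair at two granularities — sentences and
articles — and rankings order partners by article count first (the displayed
order), sentence count second, then lexicographic id.

Manual curation of extraction errors is replaced by a declarative exclusion
list: (pmid, cnv_id, disease_id) patterns with ``*`` wildcards, applied
before summarization and fully replayable.
"""

from __future__ import annotations

from collections import Counter, OrderedDict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from cnvdigest.cnv_ner import cytoband_overlaps, parse_cytoband
from cnvdigest.errors import ConfigError, CytobandParseError
from cnvdigest.relation_extract import RelationRecord

__all__ = [
    "AssociationRecord",
    "CorpusStats",
    "ExclusionPattern",
    "record_key",
    "sort_key",
    "deduplicate",
    "load_exclusions",
    "apply_exclusions",
    "summarize",
    "top_k",
    "query_by_pmid",
    "common_partners",
]

_FIELD_ORDER = {"title": 0, "abstract": 1}


def record_key(rec: RelationRecord) -> tuple:
    """De-duplication identity of a record."""
    return (rec.pmid, rec.field, rec.sentence_index, rec.cnv_id, rec.disease_id)


def sort_key(rec: RelationRecord) -> tuple:
    """Deterministic output order: article, then reading order, then pair."""
    return (
        rec.pmid,
        _FIELD_ORDER.get(rec.field, 2),
        rec.sentence_index,
        rec.cnv_id,
        rec.disease_id,
    )


@dataclass(frozen=True)
class AssociationRecord:
    """Aggregated evidence for one (CNV, disease) pair."""

    cnv_id: str
    disease_id: str
    n_sentences: int
    n_articles: int
    pmids: tuple[str, ...]
    polarity_counts: dict

    def to_dict(self) -> dict:
        return {
            "cnv_id": self.cnv_id,
            "disease_id": self.disease_id,
            "n_sentences": self.n_sentences,
            "n_articles": self.n_articles,
            "pmids": list(self.pmids),
            "polarity_counts": dict(self.polarity_counts),
        }


@dataclass(frozen=True)
class CorpusStats:
    """Corpus-level tallies over related records."""

    n_relation_sentences: int
    n_distinct_cnvs: int
    n_distinct_diseases: int
    n_articles: int

    def to_dict(self) -> dict:
        return {
            "n_relation_sentences": self.n_relation_sentences,
            "n_distinct_cnvs": self.n_distinct_cnvs,
            "n_distinct_diseases": self.n_distinct_diseases,
            "n_articles": self.n_articles,
        }


def deduplicate(records: Iterable[RelationRecord]) -> list[RelationRecord]:
    """One record per key, first occurrence kept, sorted output order.

    Idempotent and invariant under permutation of equal-keyed duplicates'
    survivors (the first occurrence in input order is retained).
    """
    seen: dict[tuple, RelationRecord] = {}
    for rec in records:
        seen.setdefault(record_key(rec), rec)
    return sorted(seen.values(), key=sort_key)


@dataclass(frozen=True)
class ExclusionPattern:
    """A (pmid, cnv_id, disease_id) filter; ``*`` wildcards any field."""

    pmid: str = "*"
    cnv_id: str = "*"
    disease_id: str = "*"

    def matches(self, rec: RelationRecord) -> bool:
        return (
            (self.pmid == "*" or self.pmid == rec.pmid)
            and (self.cnv_id == "*" or self.cnv_id == rec.cnv_id)
            and (self.disease_id == "*" or self.disease_id == rec.disease_id)
        )


def load_exclusions(path) -> list[ExclusionPattern]:
    """Read an exclusion list: three tab-separated columns per line
    (pmid, cnv_id, disease_id), ``*`` as wildcard, ``#`` comments."""
    path = Path(path)
    patterns: list[ExclusionPattern] = []
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.rstrip("\n").split("\t")]
        if len(parts) != 3 or any(not p for p in parts):
            raise ConfigError(
                f"{path}:{lineno}: exclusion pattern needs exactly 3 non-empty columns"
            )
        patterns.append(ExclusionPattern(*parts))
    return patterns


def apply_exclusions(
    records: Iterable[RelationRecord], exclusion_list: Sequence[ExclusionPattern]
) -> tuple[list[RelationRecord], int]:
    """Drop records matching any pattern; returns (kept, n_removed)."""
    kept: list[RelationRecord] = []
    removed = 0
    for rec in records:
        if any(p.matches(rec) for p in exclusion_list):
            removed += 1
        else:
            kept.append(rec)
    return kept, removed


def summarize(
    records: Iterable[RelationRecord],
) -> tuple[list[AssociationRecord], CorpusStats]:
    """Aggregate related records into per-pair associations and corpus stats.

    Conservation: the association sentence counts sum to the number of
    related input records. Input should already be de-duplicated.
    """
    related = [r for r in records if r.related]
    by_pair: "OrderedDict[tuple[str, str], list[RelationRecord]]" = OrderedDict()
    for rec in sorted(related, key=sort_key):
        by_pair.setdefault((rec.cnv_id, rec.disease_id), []).append(rec)

    associations: list[AssociationRecord] = []
    for (cnv_id, disease_id), recs in by_pair.items():
        pmids = tuple(sorted({r.pmid for r in recs}))
        polarity_counts = Counter(r.polarity for r in recs)
        associations.append(
            AssociationRecord(
                cnv_id=cnv_id,
                disease_id=disease_id,
                n_sentences=len(recs),
                n_articles=len(pmids),
                pmids=pmids,
                polarity_counts={
                    "gain": polarity_counts.get("gain", 0),
                    "loss": polarity_counts.get("loss", 0),
                    "unknown": polarity_counts.get("unknown", 0),
                },
            )
        )
    associations.sort(
        key=lambda a: (-a.n_articles, -a.n_sentences, a.cnv_id, a.disease_id)
    )
    stats = CorpusStats(
        n_relation_sentences=len({(r.pmid, r.field, r.sentence_index) for r in related}),
        n_distinct_cnvs=len({r.cnv_id for r in related}),
        n_distinct_diseases=len({r.disease_id for r in related}),
        n_articles=len({r.pmid for r in related}),
    )
    return associations, stats


def _rank_key(partner_attr: str):
    return lambda a: (-a.n_articles, -a.n_sentences, getattr(a, partner_attr))


def top_k(
    summaries: Sequence[AssociationRecord],
    *,
    cnv_id: Optional[str] = None,
    disease_id: Optional[str] = None,
    k: int = 20,
) -> list[AssociationRecord]:
    """Top-k partners for a fixed CNV or a fixed disease.

    Exactly one of ``cnv_id``/``disease_id`` fixes the query side; partners
    on the other side are ranked by article count desc, sentence count desc,
    then lexicographic partner id. An unknown id yields an empty list.
    ``top_k(k)`` is always a prefix of ``top_k(k+1)``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if (cnv_id is None) == (disease_id is None):
        raise ValueError("fix exactly one of cnv_id or disease_id")
    if cnv_id is not None:
        rows = [a for a in summaries if a.cnv_id == cnv_id]
        rows.sort(key=_rank_key("disease_id"))
    else:
        rows = [a for a in summaries if a.disease_id == disease_id]
        rows.sort(key=_rank_key("cnv_id"))
    return rows[:k]


def query_by_pmid(
    records: Iterable[RelationRecord], pmids: Sequence[str]
) -> "OrderedDict[str, list[RelationRecord]]":
    """Group evidence records by article for the queried PMIDs.

    Every queried PMID appears as a group (possibly empty); within a group,
    sentences keep reading order (title before abstract). Records carry
    mention offsets for highlighting.
    """
    wanted = list(dict.fromkeys(pmids))
    groups: "OrderedDict[str, list[RelationRecord]]" = OrderedDict(
        (pmid, []) for pmid in wanted
    )
    for rec in records:
        if rec.pmid in groups:
            groups[rec.pmid].append(rec)
    for pmid in groups:
        groups[pmid].sort(key=sort_key)
    return groups


def _coarser_cnv_id(id_a: str, id_b: str) -> str:
    """The coarser of two overlapping cytoband ids (fewer band digits)."""
    if id_a == id_b:
        return id_a
    digits_a = len(id_a.replace(".", ""))
    digits_b = len(id_b.replace(".", ""))
    if digits_a != digits_b:
        return id_a if digits_a < digits_b else id_b
    return min(id_a, id_b)


def common_partners(
    summaries: Sequence[AssociationRecord],
    disease_a: str,
    disease_b: str,
    k: int = 20,
) -> list[str]:
    """CNVs shared by the top-k lists of two diseases, overlap-merged.

    Cytobands that overlap (sub-band refinement or range intersection) are
    treated as one entity and the coarser band is reported. Output follows
    the rank order of ``disease_a``'s list; the merged set is symmetric in
    the two diseases.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    list_a = [a.cnv_id for a in top_k(summaries, disease_id=disease_a, k=k)]
    list_b = [a.cnv_id for a in top_k(summaries, disease_id=disease_b, k=k)]

    def locus_of(cnv_id: str):
        try:
            return parse_cytoband(cnv_id)
        except CytobandParseError:
            return None

    loci_b = [(cid, locus_of(cid)) for cid in list_b]
    merged: list[str] = []
    for cid_a in list_a:
        locus_a = locus_of(cid_a)
        for cid_b, locus_b in loci_b:
            if cid_a == cid_b:
                rep = cid_a
            elif locus_a is not None and locus_b is not None and cytoband_overlaps(locus_a, locus_b):
                rep = _coarser_cnv_id(cid_a, cid_b)
            else:
                continue
            if rep not in merged:
                merged.append(rep)
            break
    return merged
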