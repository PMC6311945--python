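"""Corpus input/output: MEDLINE-style XML reading, sentence segmentation,
and serialization of relation records.

Two XML dialects are accepted: the ``<PubmedArticle>`` subset used by the
MEDLINE baseline distribution (PMID, ArticleTitle, AbstractText) and the
minimal ``<article pmid="...">`` dialect emitted by
:mod:`cnvdigest.synthetic_corpus`.

All character offsets in this package are 0-based, half-open, and refer to
decoded (unicode) text, never to bytes.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from lxml import etree

from cnvdigest.errors import CorpusFormatError

__all__ = [
    "Document",
    "Sentence",
    "read_corpus",
    "split_sentences",
    "write_annotations",
    "read_annotations",
    "TSV_COLUMNS",
]


@dataclass(frozen=True)
class Document:
    """One abstract record: a PubMed identifier, a title, and an optional
    abstract body (empty string when the record has no abstract)."""

    pmid: str
    title: str
    abstract: str = ""


@dataclass(frozen=True)
class Sentence:
    """An offset-anchored sentence within one field of a document.

    ``start``/``end`` slice the source field so that
    ``source[start:end] == text``; ``index`` counts sentences within the
    field starting at 0.
    """

    pmid: str
    field: str  # "title" | "abstract"
    index: int
    start: int
    end: int
    text: str


# ---------------------------------------------------------------------------
# XML reading
# ---------------------------------------------------------------------------


def _byte_offset(path: Path, line: int, column: int) -> int:
    """Best-effort byte offset of (line, column) in *path*."""
    try:
        raw = Path(path).read_bytes()
    except OSError:
        return -1
    lines = raw.splitlines(keepends=True)
    return sum(len(l) for l in lines[: max(line - 1, 0)]) + max(column - 1, 0)


def _element_text(elem) -> str:
    return "".join(elem.itertext()).strip()


def _doc_from_pubmed(elem, path) -> Document:
    pmid = elem.findtext(".//PMID")
    title_elem = elem.find(".//ArticleTitle")
    if pmid is None or not pmid.strip():
        raise CorpusFormatError(f"{path}: PubmedArticle record without a PMID")
    title = _element_text(title_elem) if title_elem is not None else ""
    if not title:
        raise CorpusFormatError(f"{path}: record {pmid.strip()} has an empty ArticleTitle")
    # Structured abstracts carry several AbstractText paragraphs; they are
    # joined with a single space before sentence splitting.
    paragraphs = [_element_text(a) for a in elem.findall(".//AbstractText")]
    abstract = " ".join(p for p in paragraphs if p)
    return Document(pmid=pmid.strip(), title=title, abstract=abstract)


def _doc_from_minimal(elem, path) -> Document:
    pmid = (elem.get("pmid") or "").strip()
    if not pmid:
        raise CorpusFormatError(f"{path}: <article> element without a pmid attribute")
    title_elem = elem.find("title")
    title = _element_text(title_elem) if title_elem is not None else ""
    if not title:
        raise CorpusFormatError(f"{path}: record {pmid} has an empty <title>")
    paragraphs = [_element_text(a) for a in elem.findall("abstract")]
    abstract = " ".join(p for p in paragraphs if p)
    return Document(pmid=pmid, title=title, abstract=abstract)


def read_corpus(path, pmid_filter: Optional[set] = None) -> Iterator[Document]:
    """Read a corpus file into :class:`Document` records.

    Parameters
    ----------
    path:
        XML file containing zero or more ``<PubmedArticle>`` or
        ``<article pmid=...>`` records.
    pmid_filter:
        Optional allow-list of PMIDs; when given, only matching records are
        yielded. ``None`` keeps everything.

    Input order is preserved. A duplicated PMID raises a warning and only the
    first occurrence is kept. Malformed XML raises
    :class:`~cnvdigest.errors.CorpusFormatError` naming the byte offset of
    the defect.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        line, column = exc.position
        offset = _byte_offset(path, line, column)
        raise CorpusFormatError(
            f"malformed XML in {path} at line {line}, column {column}"
            f" (byte offset {offset}): {exc.msg}"
        ) from exc

    docs: list[Document] = []
    seen: set[str] = set()
    for elem in tree.iter("PubmedArticle", "article"):
        if elem.tag == "PubmedArticle":
            doc = _doc_from_pubmed(elem, path)
        else:
            doc = _doc_from_minimal(elem, path)
        if doc.pmid in seen:
            warnings.warn(
                f"duplicate PMID {doc.pmid} in {path}; keeping first occurrence",
                stacklevel=2,
            )
            continue
        seen.add(doc.pmid)
        if pmid_filter is not None and doc.pmid not in pmid_filter:
            continue
        docs.append(doc)
    return iter(docs)


# ---------------------------------------------------------------------------
# Sentence segmentation
# ---------------------------------------------------------------------------

# A boundary is a run of terminators followed by whitespace and an
# upper-case letter, digit, or opening quote/bracket. Common abbreviations
# and single-letter initials are exempted.
_TERMINATOR = re.compile(r"([.!?]+)(\s+)(?=[\"'(\[]?[A-Z0-9])")
_ABBREV_TOKEN = re.compile(r"([A-Za-z][A-Za-z.]*)$")
_ABBREVIATIONS = {
    "fig", "figs", "eg", "ie", "al", "etal", "dr", "mr", "mrs", "ms",
    "prof", "vs", "no", "ca", "cf", "approx", "st", "etc", "resp", "ref",
}


def _is_abbreviation(prefix: str) -> bool:
    m = _ABBREV_TOKEN.search(prefix)
    if m is None:
        return False
    token = m.group(1).replace(".", "").lower()
    return token in _ABBREVIATIONS or len(token) == 1


def _sentence_spans(text: str) -> list[tuple[int, int]]:
    spans: list[tuple[int, int]] = []
    pos = 0
    for m in _TERMINATOR.finditer(text):
        if _is_abbreviation(text[: m.start(1)]):
            continue
        spans.append((pos, m.end(1)))
        pos = m.end()
    if pos < len(text):
        spans.append((pos, len(text)))
    trimmed = []
    for start, end in spans:
        while start < end and text[start].isspace():
            start += 1
        while end > start and text[end - 1].isspace():
            end -= 1
        if end > start:
            trimmed.append((start, end))
    return trimmed


def split_sentences(doc: Document) -> list[Sentence]:
    """Segment title and abstract into offset-anchored sentences.

    The concatenation of the returned slices, in order, reconstructs each
    source field up to inter-sentence whitespace. An empty abstract yields
    title sentences only.
    """
    out: list[Sentence] = []
    for field_name, source in (("title", doc.title), ("abstract", doc.abstract)):
        for i, (start, end) in enumerate(_sentence_spans(source)):
            out.append(
                Sentence(
                    pmid=doc.pmid,
                    field=field_name,
                    index=i,
                    start=start,
                    end=end,
                    text=source[start:end],
                )
            )
    return out


# ---------------------------------------------------------------------------
# Annotation serialization
# ---------------------------------------------------------------------------

TSV_COLUMNS: tuple[str, ...] = (
    "pmid",
    "field",
    "sentence_index",
    "sentence_text",
    "cnv_id",
    "cnv_start",
    "cnv_end",
    "cnv_surface",
    "disease_id",
    "disease_start",
    "disease_end",
    "disease_surface",
    "polarity",
    "trigger",
    "related",
)

_INT_COLUMNS = {"sentence_index", "cnv_start", "cnv_end", "disease_start", "disease_end"}


def _record_to_row(d: dict) -> list[str]:
    row = []
    for col in TSV_COLUMNS:
        v = d[col]
        if v is None:
            row.append("")
        elif isinstance(v, bool):
            row.append("true" if v else "false")
        else:
            row.append(str(v))
    return row


def write_annotations(records: Iterable, path, format: str = "jsonl") -> int:
    """Write relation records to *path*; returns the number written.

    ``jsonl`` emits one JSON object per line with sorted keys; ``tsv`` emits
    a header plus one row per record in :data:`TSV_COLUMNS` order. Both
    round-trip through :func:`read_annotations`.
    """
    if format not in ("jsonl", "tsv"):
        raise ValueError(f"unknown annotation format {format!r}")
    path = Path(path)
    count = 0
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        if format == "tsv":
            fh.write("\t".join(TSV_COLUMNS) + "\n")
        for rec in records:
            d = rec.to_dict()
            if format == "jsonl":
                fh.write(json.dumps(d, sort_keys=True, ensure_ascii=False) + "\n")
            else:
                fh.write("\t".join(_record_to_row(d)) + "\n")
            count += 1
    return count


def read_annotations(path, format: str = "jsonl") -> list:
    """Read relation records written by :func:`write_annotations`."""
    from cnvdigest.relation_extract import RelationRecord  # local: avoids cycle

    if format not in ("jsonl", "tsv"):
        raise ValueError(f"unknown annotation format {format!r}")
    path = Path(path)
    records = []
    with path.open("r", encoding="utf-8") as fh:
        if format == "jsonl":
            for line in fh:
                line = line.strip()
                if line:
                    records.append(RelationRecord.from_dict(json.loads(line)))
        else:
            header = fh.readline().rstrip("\n")
            if header and tuple(header.split("\t")) != TSV_COLUMNS:
                raise CorpusFormatError(f"{path}: unexpected TSV header")
            for line in fh:
                if not line.strip():
                    continue
                values = line.rstrip("\n").split("\t")
                d = dict(zip(TSV_COLUMNS, values))
                for col in _INT_COLUMNS:
                    d[col] = int(d[col])
                d["related"] = d["related"] == "true"
                if d["trigger"] == "":
                    d["trigger"] = None
                records.append(RelationRecord.from_dict(d))
    return records
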