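"""Recognition and normalization of copy-number-variant mentions.

Three mention families are covered, reflecting how CNVs are written in
abstracts:

* cytoband addresses — ``22q11.2``, ``1p36.1-p36.3``, ``Xq28``: a chromosome
  token (1-22, X, Y), an arm (p/q), a band of one or two digits with an
  optional dot-separated sub-band, and an optional range tail introduced by
  ``-`` or ``~``;
* autosomal trisomies — ``trisomy 21`` (chromosomes 1-22; ``trisomy X`` is
  normalized to the XXX karyotype);
* sex-chromosome aneuploidies — ``XXX`` and ``XXY`` at token boundaries.

Loci are symbolic cytogenetic entities: no genome assembly, coordinates, or
liftover are involved. Gain/loss polarity (duplication vs. deletion wording)
is detected from keywords in the same sentence; the keyword inventory ships
as an editable plain-text config (``data/polarity_keywords.tsv``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources
from typing import Optional

from cnvdigest.corpus_io import Sentence
from cnvdigest.errors import ContractViolation, CytobandParseError

__all__ = [
    "CnvLocus",
    "CnvMention",
    "find_cnv_mentions",
    "parse_cytoband",
    "detect_polarity",
    "canonical_cnv_id",
    "cytoband_overlaps",
]

# --- grammar constants (single source of truth) ----------------------------
# chromosome: 1-22 or a sex chromosome, either case; two-digit alternatives
# first so "22" is not read as "2" + junk.
_CHROM = r"(?:1[0-9]|2[0-2]|[1-9]|[XxYy])"
# band: 1-2 digits, optional "." + 1-2 digit sub-band.
_BAND = r"\d{1,2}(?:\.\d{1,2})?"

# Word-boundary anchoring on both sides rejects "p21" (no chromosome token)
# and "22q11.2a"; the trailing (?!\.?\d) rejects truncated reads such as
# "22q11" out of "22q11.222".
_CYTOBAND_CORE = (
    rf"({_CHROM})([pqPQ])({_BAND})"
    rf"(?:([\-~])([pqPQ])?({_BAND}))?"
)
_CYTOBAND_RE = re.compile(rf"(?<![0-9A-Za-z_.]){_CYTOBAND_CORE}(?!\w)(?!\.?\d)")
_CYTOBAND_FULL = re.compile(rf"{_CYTOBAND_CORE}\Z")
_CYTOBAND_PREFIX = re.compile(_CYTOBAND_CORE)

# "trisomy" + optional space + chromosome number; the number is validated by
# the alternation itself (23-99 cannot match).
_TRISOMY_RE = re.compile(r"(?<!\w)([Tt]risomy)\s?(1[0-9]|2[0-2]|[1-9]|[Xx])(?!\w)")

# XXX / XXY at token boundaries (whitespace, punctuation, or sentence edge).
_SEX_RE = re.compile(r"(?<!\w)([Xx][Xx][XxYy])(?!\w)")


@dataclass(frozen=True)
class CnvLocus:
    """A normalized CNV identity.

    ``kind`` is one of ``cytoband``, ``autosomal_trisomy``,
    ``sex_aneuploidy``. Cytobands carry chromosome/arm/band (plus an optional
    range end); trisomies carry the chromosome; aneuploidies carry the
    karyotype. ``canonical_id`` is filled automatically.
    """

    kind: str
    chromosome: Optional[str] = None
    arm: Optional[str] = None
    band: Optional[str] = None
    arm_end: Optional[str] = None
    band_end: Optional[str] = None
    karyotype: Optional[str] = None
    canonical_id: str = field(default="", compare=False)

    def __post_init__(self):
        if self.kind == "cytoband":
            if not (self.chromosome and self.arm and self.band):
                raise ContractViolation("cytoband locus requires chromosome, arm, and band")
        elif self.kind == "autosomal_trisomy":
            if self.chromosome not in {str(i) for i in range(1, 23)}:
                raise ContractViolation("autosomal trisomy requires a chromosome in 1..22")
            if self.arm is not None:
                raise ContractViolation("trisomy locus must not carry an arm")
        elif self.kind == "sex_aneuploidy":
            if self.karyotype not in ("XXX", "XXY"):
                raise ContractViolation("sex aneuploidy karyotype must be XXX or XXY")
        else:
            raise ContractViolation(f"unknown CNV kind {self.kind!r}")
        object.__setattr__(self, "canonical_id", canonical_cnv_id(self))


@dataclass(frozen=True)
class CnvMention:
    """One CNV mention anchored in a sentence.

    Offsets are sentence-relative; ``sentence.text[start:end] == surface``.
    """

    pmid: str
    field: str
    sentence_index: int
    start: int
    end: int
    surface: str
    locus: CnvLocus
    polarity: str = "unknown"


def canonical_cnv_id(locus: CnvLocus) -> str:
    """Deterministic canonical string for a locus.

    Cytoband: ``<chrom><arm><band>[-<arm_end><band_end>]`` with upper-case
    X/Y and lower-case p/q; trisomy: ``trisomy <chrom>``; aneuploidy: the
    upper-case karyotype. Idempotent under re-parsing.
    """
    if locus.kind == "cytoband":
        out = f"{locus.chromosome.upper()}{locus.arm.lower()}{locus.band}"
        if locus.band_end is not None:
            arm_end = (locus.arm_end or locus.arm).lower()
            out += f"-{arm_end}{locus.band_end}"
        return out
    if locus.kind == "autosomal_trisomy":
        return f"trisomy {locus.chromosome}"
    if locus.kind == "sex_aneuploidy":
        return locus.karyotype.upper()
    raise ContractViolation(f"unknown CNV kind {locus.kind!r}")


def _locus_from_cytoband_match(m: re.Match) -> CnvLocus:
    chrom, arm, band, _sep, arm_end, band_end = m.groups()
    return CnvLocus(
        kind="cytoband",
        chromosome=chrom.upper(),
        arm=arm.lower(),
        band=band,
        arm_end=(arm_end.lower() if arm_end else (arm.lower() if band_end else None)),
        band_end=band_end,
    )


def parse_cytoband(text: str) -> CnvLocus:
    """Parse a bare cytoband string into a :class:`CnvLocus`.

    Raises :class:`~cnvdigest.errors.CytobandParseError` naming the first
    offending character when *text* does not match the grammar.
    """
    m = _CYTOBAND_FULL.match(text)
    if m is None:
        partial = _CYTOBAND_PREFIX.match(text)
        pos = partial.end() if partial else 0
        char = text[pos] if pos < len(text) else "<end of string>"
        raise CytobandParseError(
            f"invalid cytoband {text!r}: unexpected character {char!r} at position {pos}"
        )
    return _locus_from_cytoband_match(m)


def find_cnv_mentions(sentence: Sentence) -> list[CnvMention]:
    """Find every maximal, non-overlapping CNV mention in a sentence.

    Matches are returned left-to-right; where candidate matches overlap, the
    longest one wins. Polarity is filled via :func:`detect_polarity`.
    """
    text = sentence.text
    candidates: list[tuple[int, int, CnvLocus]] = []
    for m in _CYTOBAND_RE.finditer(text):
        candidates.append((m.start(), m.end(), _locus_from_cytoband_match(m)))
    for m in _TRISOMY_RE.finditer(text):
        num = m.group(2).upper()
        if num == "X":
            locus = CnvLocus(kind="sex_aneuploidy", karyotype="XXX")
        else:
            locus = CnvLocus(kind="autosomal_trisomy", chromosome=num)
        candidates.append((m.start(), m.end(), locus))
    for m in _SEX_RE.finditer(text):
        karyotype = m.group(1).upper()
        candidates.append((m.start(), m.end(), CnvLocus(kind="sex_aneuploidy", karyotype=karyotype)))

    candidates.sort(key=lambda c: (c[0], -(c[1] - c[0])))
    mentions: list[CnvMention] = []
    last_end = -1
    for start, end, locus in candidates:
        if start < last_end:
            continue
        mention = CnvMention(
            pmid=sentence.pmid,
            field=sentence.field,
            sentence_index=sentence.index,
            start=start,
            end=end,
            surface=text[start:end],
            locus=locus,
        )
        mention = replace(mention, polarity=detect_polarity(sentence, mention))
        mentions.append(mention)
        last_end = end
    return mentions


# --- polarity --------------------------------------------------------------

_TOKEN_RE = re.compile(r"[A-Za-z0-9.]+")


@lru_cache(maxsize=1)
def _polarity_keywords() -> dict[str, str]:
    """Keyword -> direction map loaded from the shipped config."""
    text = resources.files("cnvdigest.data").joinpath("polarity_keywords.tsv").read_text()
    table: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        direction, word = line.split("\t")
        table[word.lower()] = direction
    return table


def detect_polarity(sentence: Sentence, mention: CnvMention) -> str:
    """Gain/loss/unknown polarity of a CNV mention.

    The nearest polarity keyword in the sentence, by token distance to the
    mention, decides; ties break toward the left (English pre-modifier
    convention). No keyword means ``unknown``.
    """
    if not (0 <= mention.start <= mention.end <= len(sentence.text)):
        raise ContractViolation("mention does not lie within the sentence")
    keywords = _polarity_keywords()
    tokens = [(m.group().strip(".").lower(), m.start(), m.end()) for m in _TOKEN_RE.finditer(sentence.text)]
    mention_idx = [
        i for i, (_, s, e) in enumerate(tokens) if s < mention.end and e > mention.start
    ]
    if not mention_idx:
        return "unknown"
    lo, hi = mention_idx[0], mention_idx[-1]
    best: Optional[tuple[int, int, str]] = None  # (distance, token index, direction)
    for i, (word, _, _) in enumerate(tokens):
        direction = keywords.get(word)
        if direction is None:
            continue
        dist = lo - i if i < lo else (i - hi if i > hi else 0)
        key = (dist, i, direction)
        if best is None or key[:2] < best[:2]:
            best = key
    return best[2] if best else "unknown"


# --- overlap ---------------------------------------------------------------


def _band_interval(band: str) -> tuple[int, int]:
    """Half-open interval for one band on a 100-units-per-major-band scale.

    ``13`` covers [1300, 1400); ``13.1`` covers [1310, 1320); ``13.11``
    covers [1311, 1312) — so sub-band refinement nests inside its parent,
    matching the convention that e.g. 16p13.11 lies within 16p13.1.
    """
    major, _, sub = band.partition(".")
    lo = int(major) * 100
    if sub:
        lo += int(sub) * (10 if len(sub) == 1 else 1)
        step = 10 if len(sub) == 1 else 1
    else:
        step = 100
    return lo, lo + step


def _locus_interval(locus: CnvLocus) -> tuple[int, int]:
    arm_offset = {"p": 0, "q": 100_000}
    start_lo, start_hi = _band_interval(locus.band)
    lo = arm_offset[locus.arm] + start_lo
    if locus.band_end is not None:
        end_arm = locus.arm_end or locus.arm
        end_lo, end_hi = _band_interval(locus.band_end)
        hi = arm_offset[end_arm] + end_hi
    else:
        hi = arm_offset[locus.arm] + start_hi
    return (min(lo, hi - 1), max(lo + 1, hi))


def cytoband_overlaps(a: CnvLocus, b: CnvLocus) -> bool:
    """True when two cytoband loci denote overlapping band intervals.

    A sub-band lies within its parent band (16p13.11 overlaps 16p13.1), and
    ranges intersect by symbolic band order. Reflexive and symmetric.
    Non-cytoband input is a contract violation.
    """
    if a.kind != "cytoband" or b.kind != "cytoband":
        raise ContractViolation("cytoband_overlaps requires two cytoband loci")
    if a.chromosome != b.chromosome:
        return False
    a_lo, a_hi = _locus_interval(a)
    b_lo, b_hi = _locus_interval(b)
    return a_lo < b_hi and b_lo < a_hi
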