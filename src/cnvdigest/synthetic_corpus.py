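"""Synthetic MEDLINE-style corpora with planted, machine-readable ground truth.

The generator assembles abstracts from sentence templates of five kinds:

* positive — one CNV and one disease joined by a trigger word (and, for
  cytobands, an optional gain/loss cue), e.g.
  "DiGeorge syndrome is associated with deletion of 22q11.2.";
* co-occurrence negative — both entities present, no trigger anywhere;
* CNV-only / disease-only — exactly one entity;
* distractor — plain laboratory prose verified to contain neither a CNV
  grammar match nor a lexicon disease name.

CNV surfaces are drawn from the same grammar the recognizer implements
(cytobands with sub-bands and ranges, trisomies, XXX/XXY); disease surfaces
come from the supplied lexicon. Every planted mention is recorded with its
sentence index and character offsets, every planted relation with its
trigger and polarity, and per-pair sentence tallies are included, so the
manifest can serve as an exact oracle for NER, relation extraction, and
aggregation. Identical configuration and seed produce byte-identical output.
"""

from __future__ import annotations

import json
import random
from collections import Counter
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional
from xml.sax.saxutils import escape

from cnvdigest.cnv_ner import canonical_cnv_id, find_cnv_mentions, parse_cytoband
from cnvdigest.corpus_io import Document, Sentence, split_sentences
from cnvdigest.disease_ner import DiseaseLexicon, default_lexicon, find_disease_mentions
from cnvdigest.errors import ConfigError, IntegrityError
from cnvdigest.relation_extract import TriggerLexicon, _trigger_matches, default_triggers

__all__ = [
    "GeneratorConfig",
    "PlantedMention",
    "PlantedRelation",
    "GroundTruth",
    "CnvExample",
    "enumerate_cnv_surfaces",
    "generate_corpus",
    "score_against_truth",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic corpus.

    Sentence-category probabilities must lie in [0, 1] and sum to at most 1;
    the remainder becomes distractor sentences. ``polarity_mix`` weights the
    gain/loss/unknown wording of cytoband mentions. The seed fixes all
    randomness.
    """

    n_docs: int = 200
    sentences_per_doc: tuple[int, int] = (3, 8)
    p_positive: float = 0.35
    p_cooccur_negative: float = 0.15
    p_cnv_only: float = 0.10
    p_disease_only: float = 0.10
    polarity_mix: tuple[tuple[str, float], ...] = (
        ("gain", 0.3),
        ("loss", 0.4),
        ("unknown", 0.3),
    )
    seed: int = 0
    allow_hard_negatives: bool = False
    pmid_start: int = 100001

    def validate(self) -> None:
        probs = (self.p_positive, self.p_cooccur_negative, self.p_cnv_only, self.p_disease_only)
        if any(p < 0 or p > 1 for p in probs):
            raise ConfigError("sentence-category probabilities must lie in [0, 1]")
        if sum(probs) > 1 + 1e-9:
            raise ConfigError("sentence-category probabilities sum to more than 1")
        if self.n_docs < 0:
            raise ConfigError("n_docs must be non-negative")
        lo, hi = self.sentences_per_doc
        if lo < 1 or hi < lo:
            raise ConfigError("sentences_per_doc must be a range 1 <= lo <= hi")
        mix = dict(self.polarity_mix)
        if set(mix) != {"gain", "loss", "unknown"} or any(v < 0 for v in mix.values()):
            raise ConfigError("polarity_mix must weight gain, loss, and unknown")
        if sum(mix.values()) <= 0:
            raise ConfigError("polarity_mix weights must not all be zero")


@dataclass(frozen=True)
class PlantedMention:
    pmid: str
    field: str
    index: int
    start: int
    end: int
    surface: str
    kind: str  # cytoband | autosomal_trisomy | sex_aneuploidy | disease
    canonical_id: str
    polarity: str = "unknown"  # CNV mentions only; diseases stay "unknown"


@dataclass(frozen=True)
class PlantedRelation:
    pmid: str
    field: str
    index: int
    cnv_id: str
    disease_id: str
    trigger: str
    polarity: str


@dataclass
class GroundTruth:
    """The generator's manifest: planted mentions, relations, and tallies."""

    pmids: list[str]
    mentions: list[PlantedMention] = dc_field(default_factory=list)
    relations: list[PlantedRelation] = dc_field(default_factory=list)
    pair_counts: dict = dc_field(default_factory=dict)

    def recount_pairs(self) -> dict:
        """Recompute per-pair sentence counts from the relation list."""
        return dict(Counter((r.cnv_id, r.disease_id) for r in self.relations))

    def cnv_mention_keys(self) -> set:
        return {
            (m.pmid, m.field, m.index, m.start, m.end, m.canonical_id)
            for m in self.mentions
            if m.kind != "disease"
        }

    def disease_mention_keys(self) -> set:
        return {
            (m.pmid, m.field, m.index, m.start, m.end, m.canonical_id)
            for m in self.mentions
            if m.kind == "disease"
        }

    def relation_keys(self) -> set:
        return {(r.pmid, r.field, r.index, r.cnv_id, r.disease_id) for r in self.relations}

    def to_jsonl(self, path) -> None:
        with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
            fh.write(json.dumps({"type": "corpus", "pmids": self.pmids}, sort_keys=True) + "\n")
            for m in self.mentions:
                fh.write(json.dumps({"type": "mention", **m.__dict__}, sort_keys=True) + "\n")
            for r in self.relations:
                fh.write(json.dumps({"type": "relation", **r.__dict__}, sort_keys=True) + "\n")
            for (cnv_id, disease_id), n in sorted(self.pair_counts.items()):
                fh.write(
                    json.dumps(
                        {"type": "pair_count", "cnv_id": cnv_id, "disease_id": disease_id, "n": n},
                        sort_keys=True,
                    )
                    + "\n"
                )

    @classmethod
    def from_jsonl(cls, path) -> "GroundTruth":
        truth = cls(pmids=[])
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if not line.strip():
                continue
            d = json.loads(line)
            kind = d.pop("type")
            if kind == "corpus":
                truth.pmids = list(d["pmids"])
            elif kind == "mention":
                truth.mentions.append(PlantedMention(**d))
            elif kind == "relation":
                truth.relations.append(PlantedRelation(**d))
            elif kind == "pair_count":
                truth.pair_counts[(d["cnv_id"], d["disease_id"])] = d["n"]
            else:
                raise IntegrityError(f"unknown manifest record type {kind!r}")
        return truth


# ---------------------------------------------------------------------------
# Grammar enumeration (shared oracle for evaluation)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CnvExample:
    """One grammar production with its expected canonical id."""

    surface: str
    canonical_id: str
    kind: str


def enumerate_cnv_surfaces() -> list[CnvExample]:
    """Deterministic enumeration of CNV grammar productions.

    The expected canonical ids are assembled directly from the production
    components (chromosome, arm, band), independently of the parser, so the
    list doubles as a round-trip oracle.
    """
    chroms = [str(i) for i in range(1, 23)] + ["X", "Y"]
    bands = ["3", "11.2", "13.11", "36"]
    out: list[CnvExample] = []
    for chrom in chroms:
        for arm in "pq":
            for band in bands:
                canonical = f"{chrom}{arm}{band}"
                out.append(CnvExample(f"{chrom}{arm}{band}", canonical, "cytoband"))
                out.append(CnvExample(f"{chrom}{arm.upper()}{band}", canonical, "cytoband"))
    for chrom in ("x", "y"):
        for arm in "pq":
            for band in bands:
                out.append(
                    CnvExample(f"{chrom}{arm}{band}", f"{chrom.upper()}{arm}{band}", "cytoband")
                )
    for chrom in chroms:
        out.append(CnvExample(f"{chrom}p36.1-p36.3", f"{chrom}p36.1-p36.3", "cytoband"))
        out.append(CnvExample(f"{chrom}q11.2-q13", f"{chrom}q11.2-q13", "cytoband"))
        out.append(CnvExample(f"{chrom}q11-13", f"{chrom}q11-q13", "cytoband"))
        out.append(CnvExample(f"{chrom}p21~p22", f"{chrom}p21-p22", "cytoband"))
    for n in range(1, 23):
        out.append(CnvExample(f"trisomy {n}", f"trisomy {n}", "autosomal_trisomy"))
        out.append(CnvExample(f"Trisomy {n}", f"trisomy {n}", "autosomal_trisomy"))
    out.append(CnvExample("trisomy X", "XXX", "sex_aneuploidy"))
    out.append(CnvExample("XXX", "XXX", "sex_aneuploidy"))
    out.append(CnvExample("XXY", "XXY", "sex_aneuploidy"))
    out.append(CnvExample("xxy", "XXY", "sex_aneuploidy"))
    return out


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

_LOSS_WORDS = ("deletion", "loss", "microdeletion")
_GAIN_WORDS = ("duplication", "amplification", "triplication")

_DISTRACTORS = (
    "The protein p21 was measured in control samples.",
    "Genomic DNA was extracted from peripheral blood.",
    "All participants provided written informed consent.",
    "Microarray hybridization was performed according to standard protocols.",
    "Samples were processed by two independent observers.",
    "The study protocol was approved by the institutional review board.",
    "Follow-up visits occurred every six months thereafter.",
    "Quantitative PCR was used to validate the array findings.",
)

# Emitted only when hard negatives are enabled; these deliberately contain
# CNV-grammar matches in non-CNV context, so purity checking skips them.
_HARD_NEGATIVES = (
    "The identifier XXX masked patient names in the registry.",
    "Patients were stratified as group 3p or group 3q by protocol.",
)


def _sample_band(rng: random.Random) -> str:
    band = str(rng.randint(1, 39))
    if rng.random() < 0.55:
        band += "." + (str(rng.randint(1, 9)) if rng.random() < 0.6 else str(rng.randint(10, 39)))
    return band


def _sample_cnv(rng: random.Random) -> tuple[str, str, str]:
    """Sample (surface, canonical_id, kind) from the CNV grammar."""
    r = rng.random()
    if r < 0.60:
        chrom = rng.choice([str(i) for i in range(1, 23)] + ["X", "Y"])
        arm = rng.choice("pq")
        surface = f"{chrom}{arm if rng.random() < 0.9 else arm.upper()}{_sample_band(rng)}"
        if rng.random() < 0.15:
            surface += rng.choice("-~") + (arm if rng.random() < 0.5 else "") + _sample_band(rng)
        return surface, canonical_cnv_id(parse_cytoband(surface)), "cytoband"
    if r < 0.85:
        n = rng.randint(1, 22)
        return f"trisomy {n}", f"trisomy {n}", "autosomal_trisomy"
    karyotype = rng.choice(("XXX", "XXY"))
    return karyotype, karyotype, "sex_aneuploidy"


def _sample_disease(rng: random.Random, lexicon: DiseaseLexicon) -> tuple[str, str]:
    """Sample (name, concept_id); the id is resolved through the lexicon so
    ground truth follows the matcher's collision policy."""
    entry = rng.choice(lexicon.entries)
    name = rng.choice((entry.preferred_name, *entry.synonyms))
    return name, lexicon.resolve(name)


def _sample_polarity(rng: random.Random, mix: tuple[tuple[str, float], ...]) -> str:
    total = sum(w for _, w in mix)
    r = rng.random() * total
    acc = 0.0
    for name, w in mix:
        acc += w
        if r < acc:
            return name
    return mix[-1][0]


# ---------------------------------------------------------------------------
# Sentence construction
# ---------------------------------------------------------------------------


@dataclass
class _BuiltSentence:
    text: str
    cnv: Optional[tuple[int, int, str, str, str]] = None  # start, end, canonical, kind, polarity
    disease: Optional[tuple[int, int, str]] = None  # start, end, concept_id
    trigger: Optional[str] = None


def _assemble(parts: list[tuple[str, Optional[str]]]) -> tuple[str, dict]:
    """Concatenate (text, tag) parts; return text and tag -> (start, end)."""
    text = ""
    spans: dict = {}
    for chunk, tag in parts:
        if tag is not None:
            spans[tag] = (len(text), len(text) + len(chunk))
        text += chunk
    if text and text[0].islower():
        text = text[0].upper() + text[1:]
    return text, spans


def _build_positive(rng, cnv, disease, polarity) -> _BuiltSentence:
    surface, canonical, kind = cnv
    name, concept_id = disease
    if kind == "cytoband" and polarity in ("gain", "loss"):
        pol_word = rng.choice(_LOSS_WORDS if polarity == "loss" else _GAIN_WORDS)
        variant = rng.choice("ab")
        if variant == "a":
            parts = [
                (name, "disease"),
                (" is associated with ", None),
                (f"{pol_word} of ", None),
                (surface, "cnv"),
                (".", None),
            ]
            trigger = "associated"
        else:
            parts = [
                (f"{pol_word.capitalize()} of ", None),
                (surface, "cnv"),
                (" is a cause of ", None),
                (name, "disease"),
                (".", None),
            ]
            trigger = "cause"
    else:
        polarity = "unknown"
        variant = rng.choice("cde")
        if variant == "c":
            parts = [(name, "disease"), (" is associated with ", None), (surface, "cnv"), (".", None)]
            trigger = "associated"
        elif variant == "d":
            parts = [(surface, "cnv"), (" is linked to ", None), (name, "disease"), (".", None)]
            trigger = "linked"
        else:
            parts = [(surface, "cnv"), (" is a cause of ", None), (name, "disease"), (".", None)]
            trigger = "cause"
    text, spans = _assemble(parts)
    return _BuiltSentence(
        text=text,
        cnv=(*spans["cnv"], canonical, kind, polarity),
        disease=(*spans["disease"], concept_id),
        trigger=trigger,
    )


def _build_cooccur_negative(rng, cnv, disease) -> _BuiltSentence:
    surface, canonical, kind = cnv
    name, concept_id = disease
    variant = rng.choice("abc")
    if variant == "a":
        parts = [
            (name, "disease"),
            (" patients were screened for ", None),
            (surface, "cnv"),
            (" copy number.", None),
        ]
    elif variant == "b":
        parts = [
            ("We measured ", None),
            (surface, "cnv"),
            (" dosage in patients with ", None),
            (name, "disease"),
            (".", None),
        ]
    else:
        parts = [
            (surface, "cnv"),
            (" and ", None),
            (name, "disease"),
            (" were studied in this cohort.", None),
        ]
    text, spans = _assemble(parts)
    return _BuiltSentence(
        text=text,
        cnv=(*spans["cnv"], canonical, kind, "unknown"),
        disease=(*spans["disease"], concept_id),
    )


def _build_cnv_only(rng, cnv, polarity) -> _BuiltSentence:
    surface, canonical, kind = cnv
    if kind == "cytoband" and polarity in ("gain", "loss"):
        pol_word = rng.choice(_LOSS_WORDS if polarity == "loss" else _GAIN_WORDS)
        parts = [
            (f"{pol_word.capitalize()} of ", None),
            (surface, "cnv"),
            (" was detected in three patients.", None),
        ]
    else:
        polarity = "unknown"
        if rng.random() < 0.5:
            parts = [("The region ", None), (surface, "cnv"), (" was examined by microarray.", None)]
        else:
            parts = [("Karyotype analysis confirmed ", None), (surface, "cnv"), (" in the proband.", None)]
    text, spans = _assemble(parts)
    return _BuiltSentence(text=text, cnv=(*spans["cnv"], canonical, kind, polarity))


def _build_disease_only(rng, disease) -> _BuiltSentence:
    name, concept_id = disease
    if rng.random() < 0.5:
        parts = [("Clinical features of ", None), (name, "disease"), (" were reviewed.", None)]
    else:
        parts = [(name, "disease"), (" was diagnosed in the proband.", None)]
    text, spans = _assemble(parts)
    return _BuiltSentence(text=text, disease=(*spans["disease"], concept_id))


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _verify_sentence(
    sent: Sentence,
    built: Optional[_BuiltSentence],
    lexicon: DiseaseLexicon,
    triggers: TriggerLexicon,
    is_hard_negative: bool,
) -> None:
    """Generation-time fidelity check: the pipeline's matchers must see
    exactly what was planted (and nothing in distractors)."""
    if is_hard_negative:
        return
    cnv_found = [(m.start, m.end, m.locus.canonical_id) for m in find_cnv_mentions(sent)]
    dis_found = [(m.start, m.end, m.concept_id) for m in find_disease_mentions(sent, lexicon)]
    cnv_want = [built.cnv[:3]] if built and built.cnv else []
    dis_want = [built.disease[:3]] if built and built.disease else []
    if cnv_found != cnv_want or dis_found != dis_want:
        raise IntegrityError(
            f"template emitted unplanned mentions in {sent.text!r}: "
            f"cnv {cnv_found} vs {cnv_want}, disease {dis_found} vs {dis_want}"
        )
    has_trigger = bool(_trigger_matches(sent.text, triggers))
    wants_trigger = bool(built and built.trigger)
    if has_trigger != wants_trigger:
        raise IntegrityError(
            f"trigger inventory conflicts with template in {sent.text!r}"
        )


def generate_corpus(
    config: GeneratorConfig,
    lexicon: Optional[DiseaseLexicon] = None,
    triggers: Optional[TriggerLexicon] = None,
    xml_path=None,
    manifest_path=None,
) -> tuple[str, GroundTruth]:
    """Generate a corpus and its ground-truth manifest.

    Returns ``(xml_text, truth)``; when ``xml_path``/``manifest_path`` are
    given the artifacts are also written there. The same config and seed
    always produce byte-identical output.
    """
    config.validate()
    lexicon = lexicon if lexicon is not None else default_lexicon()
    triggers = triggers if triggers is not None else default_triggers()
    for needed in ("associated", "cause", "linked"):
        if needed not in triggers:
            raise ConfigError(f"generator templates require trigger term {needed!r}")

    rng = random.Random(config.seed)
    truth = GroundTruth(pmids=[])
    articles: list[str] = []
    cum = [
        ("positive", config.p_positive),
        ("cooccur", config.p_cooccur_negative),
        ("cnv_only", config.p_cnv_only),
        ("disease_only", config.p_disease_only),
    ]

    for doc_i in range(config.n_docs):
        pmid = str(config.pmid_start + doc_i)
        truth.pmids.append(pmid)
        title = f"Clinical and molecular findings in study cohort {doc_i + 1}."
        n_sent = rng.randint(*config.sentences_per_doc)
        sentences: list[str] = []
        offset = 0
        for sent_i in range(n_sent):
            r = rng.random()
            category = "distractor"
            acc = 0.0
            for name, p in cum:
                acc += p
                if r < acc:
                    category = name
                    break

            built: Optional[_BuiltSentence] = None
            is_hard = False
            if category == "positive":
                built = _build_positive(
                    rng, _sample_cnv(rng), _sample_disease(rng, lexicon),
                    _sample_polarity(rng, config.polarity_mix),
                )
            elif category == "cooccur":
                built = _build_cooccur_negative(rng, _sample_cnv(rng), _sample_disease(rng, lexicon))
            elif category == "cnv_only":
                built = _build_cnv_only(rng, _sample_cnv(rng), _sample_polarity(rng, config.polarity_mix))
            elif category == "disease_only":
                built = _build_disease_only(rng, _sample_disease(rng, lexicon))
            else:
                pool = _DISTRACTORS + (_HARD_NEGATIVES if config.allow_hard_negatives else ())
                text = rng.choice(pool)
                is_hard = text in _HARD_NEGATIVES
                built = _BuiltSentence(text=text) if not is_hard else None
                if is_hard:
                    sentences.append(text)
                    offset += len(text) + 1
                    continue

            text = built.text
            sent = Sentence(pmid=pmid, field="abstract", index=sent_i, start=offset,
                            end=offset + len(text), text=text)
            _verify_sentence(sent, built, lexicon, triggers, is_hard)

            if built.cnv is not None:
                start, end, canonical, kind, polarity = built.cnv
                truth.mentions.append(
                    PlantedMention(pmid, "abstract", sent_i, start, end,
                                   text[start:end], kind, canonical, polarity)
                )
            if built.disease is not None:
                start, end, concept_id = built.disease
                truth.mentions.append(
                    PlantedMention(pmid, "abstract", sent_i, start, end,
                                   text[start:end], "disease", concept_id)
                )
            if built.trigger is not None and built.cnv is not None and built.disease is not None:
                truth.relations.append(
                    PlantedRelation(pmid, "abstract", sent_i, built.cnv[2],
                                    built.disease[2], built.trigger, built.cnv[4])
                )
            sentences.append(text)
            offset += len(text) + 1  # single joining space

        abstract = " ".join(sentences)
        doc = Document(pmid=pmid, title=title, abstract=abstract)
        # The splitter must reproduce exactly the sentence boundaries the
        # offsets were computed against.
        split = [s for s in split_sentences(doc) if s.field == "abstract"]
        if [s.text for s in split] != sentences:
            raise IntegrityError(f"sentence splitter disagrees with generator for PMID {pmid}")
        articles.append(
            f'  <article pmid="{pmid}">\n'
            f"    <title>{escape(title)}</title>\n"
            f"    <abstract>{escape(abstract)}</abstract>\n"
            f"  </article>\n"
        )

    truth.pair_counts = truth.recount_pairs()
    xml_text = (
        '<?xml version="1.0" encoding="UTF-8"?>\n<corpus>\n' + "".join(articles) + "</corpus>\n"
    )
    if xml_path is not None:
        Path(xml_path).write_text(xml_text, encoding="utf-8", newline="\n")
    if manifest_path is not None:
        truth.to_jsonl(manifest_path)
    return xml_text, truth


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


def _prf(predicted: set, expected: set) -> dict:
    tp = len(predicted & expected)
    out = {
        "tp": tp,
        "n_predicted": len(predicted),
        "n_truth": len(expected),
        "precision": tp / len(predicted) if predicted else 0.0,
        "recall": tp / len(expected) if expected else 1.0,
        "undefined_precision": not predicted,
    }
    return out


def score_against_truth(predicted, truth: GroundTruth) -> dict:
    """Per-stage precision/recall of pipeline output against the manifest.

    *predicted* must expose ``cnv_mentions``, ``disease_mentions``, and
    ``relations`` (see :class:`cnvdigest.pipeline.Predictions`). NER is
    scored on exact (sentence, span, id) matches; relations on
    (sentence, cnv_id, disease_id) over ``related=True`` records. An empty
    prediction set reports precision 0 with ``undefined_precision`` set.
    """
    known = set(truth.pmids)
    seen = (
        {m.pmid for m in predicted.cnv_mentions}
        | {m.pmid for m in predicted.disease_mentions}
        | {r.pmid for r in predicted.relations}
    )
    stray = seen - known
    if stray:
        raise IntegrityError(f"predictions mention PMIDs absent from manifest: {sorted(stray)[:5]}")

    cnv_pred = {
        (m.pmid, m.field, m.sentence_index, m.start, m.end, m.locus.canonical_id)
        for m in predicted.cnv_mentions
    }
    dis_pred = {
        (m.pmid, m.field, m.sentence_index, m.start, m.end, m.concept_id)
        for m in predicted.disease_mentions
    }
    rel_pred = {
        (r.pmid, r.field, r.sentence_index, r.cnv_id, r.disease_id)
        for r in predicted.relations
        if r.related
    }
    return {
        "cnv_ner": _prf(cnv_pred, truth.cnv_mention_keys()),
        "disease_ner": _prf(dis_pred, truth.disease_mention_keys()),
        "relation": _prf(rel_pred, truth.relation_keys()),
    }
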