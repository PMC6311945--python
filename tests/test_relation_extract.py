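"""Instance generation, trigger search, and relation classification."""

import itertools

import pytest

from cnvdigest.cnv_ner import find_cnv_mentions
from cnvdigest.corpus_io import read_corpus
from cnvdigest.disease_ner import find_disease_mentions
from cnvdigest.errors import LexiconFormatError
from cnvdigest.pipeline import annotate_documents
from cnvdigest.relation_extract import (
    TriggerLexicon,
    classify_relation,
    find_trigger,
    fold_token,
    generate_instances,
    load_triggers,
)
from cnvdigest.synthetic_corpus import GeneratorConfig, generate_corpus
from tests.conftest import make_sentence


def _mentions(text, lexicon):
    s = make_sentence(text)
    return s, find_cnv_mentions(s), find_disease_mentions(s, lexicon)


# --- folding / lexicon -----------------------------------------------------


def test_fold_token_inflection_families():
    family = {"associate", "associated", "associates", "association"}
    assert len({fold_token(w) for w in family}) == 1
    assert len({fold_token(w) for w in ("cause", "caused", "causes")}) == 1
    # short function words are not mangled
    assert fold_token("is") == "is"
    assert fold_token("as") == "as"
    # derivationally distinct words stay distinct
    assert fold_token("causal") != fold_token("cause")
    assert fold_token("unrelated") != fold_token("related")


def test_trigger_lexicon_folds_duplicates_and_validates(tmp_path, triggers):
    assert "associated" in triggers and "Association" in triggers
    stems = [t.stem for t in triggers.terms]
    assert len(stems) == len(set(stems))  # unique after folding
    p = tmp_path / "t.txt"
    p.write_text("linked\tadverb\n")
    with pytest.raises(LexiconFormatError, match="category"):
        load_triggers(p)


# --- instances -------------------------------------------------------------


@pytest.mark.parametrize(
    "text, n_cnv, n_dis",
    [
        ("The 22q11.2 region met schizophrenia and autism in text.", 1, 2),
        ("The 22q11.2 region was mapped with no phenotype.", 1, 0),
        ("Both 22q11.2 and 1q21.1 met schizophrenia and autism here.", 2, 2),
    ],
)
def test_generate_instances_is_ordered_cross_product(lexicon, text, n_cnv, n_dis):
    s, cnvs, diseases = _mentions(text, lexicon)
    instances = generate_instances(s, cnvs, diseases)
    expected = sorted(
        itertools.product(cnvs, diseases), key=lambda p: (p[0].start, p[1].start)
    )
    assert [(i.cnv, i.disease) for i in instances] == expected
    assert len(instances) == n_cnv * n_dis


# --- trigger search --------------------------------------------------------


def _single_instance(text, lexicon):
    s, cnvs, diseases = _mentions(text, lexicon)
    (inst,) = generate_instances(s, cnvs, diseases)
    return inst


def test_trigger_between_entities(lexicon, triggers):
    inst = _single_instance(
        "DiGeorge syndrome is closely associated with deletions at 22q11 loci.",
        lexicon,
    )
    surface, pos = find_trigger(inst, triggers)
    assert surface == "associated"
    assert inst.sentence.text[pos : pos + len(surface)] == surface


def test_no_trigger_returns_none(lexicon, triggers):
    inst = _single_instance("Both 22q11.2 and schizophrenia were studied.", lexicon)
    assert find_trigger(inst, triggers) is None


def test_whole_sentence_fallback_when_gap_is_empty(lexicon, triggers):
    inst = _single_instance(
        "Association studies compared 22q11.2 against schizophrenia cohorts.",
        lexicon,
    )
    surface, _ = find_trigger(inst, triggers)
    assert surface == "Association"


def _oracle_trigger(text, span_a, span_b, surfaces):
    """Independent re-derivation: literal scan + midpoint rule."""
    matches = []
    lower = text.lower()
    for surf in surfaces:
        start = 0
        while True:
            i = lower.find(surf, start)
            if i < 0:
                break
            matches.append((i, i + len(surf), text[i : i + len(surf)]))
            start = i + 1
    matches = [
        m for m in matches
        if (m[1] <= span_a[0] or m[0] >= span_a[1])
        and (m[1] <= span_b[0] or m[0] >= span_b[1])
    ]
    if not matches:
        return None
    gap_lo = min(span_a[1], span_b[1])
    gap_hi = max(span_a[0], span_b[0])
    between = [m for m in matches if m[0] >= gap_lo and m[1] <= gap_hi]
    pool = between or matches
    target = (sum(span_a) / 2 + sum(span_b) / 2) / 2
    return min(pool, key=lambda m: (abs((m[0] + m[1]) / 2 - target), m[0]))[2]


def test_midpoint_rule_with_equidistant_tie_breaks_left(lexicon, triggers):
    """Scan paddings until two between-window triggers sit exactly
    equidistant from the entity midpoint; the leftmost must win. All other
    paddings must agree with an independently computed nearest trigger."""
    tie_seen = False
    for pad1 in range(1, 6):
        for pad2 in range(1, 4):
            for pad3 in range(1, 8):
                text = (
                    f"obesity {'f' * pad1} linked {'g' * pad2} caused {'h' * pad3} 22q11 here."
                )
                inst = _single_instance(text, lexicon)
                spans = ((inst.disease.start, inst.disease.end), (inst.cnv.start, inst.cnv.end))
                expected = _oracle_trigger(text, *spans, surfaces=("linked", "caused"))
                got = find_trigger(inst, triggers)
                assert got is not None and got[0] == expected
                t_linked = text.index("linked")
                t_caused = text.index("caused")
                target = (sum(spans[0]) / 2 + sum(spans[1]) / 2) / 2
                if abs(t_linked + 3 - target) == abs(t_caused + 3 - target):
                    tie_seen = True
                    assert got[0] == "linked"
    assert tie_seen


# --- classification --------------------------------------------------------


def test_classify_relation_motif(lexicon, triggers):
    inst = _single_instance(
        "DiGeorge syndrome is associated with deletion of 22q11 anomalies.",
        lexicon,
    )
    rec = classify_relation(inst, find_trigger(inst, triggers))
    assert rec.related is True
    assert rec.trigger == "associated"
    assert rec.cnv_id == "22q11"
    assert rec.disease_id == "MESH:D000001"
    assert rec.polarity == "loss"
    assert rec.sentence_text[rec.cnv_start : rec.cnv_end] == rec.cnv_surface
    assert rec.sentence_text[rec.disease_start : rec.disease_end] == rec.disease_surface


def test_classify_without_trigger_is_unrelated(lexicon, triggers):
    inst = _single_instance("Both 22q11.2 and schizophrenia were studied.", lexicon)
    rec = classify_relation(inst, find_trigger(inst, triggers))
    assert rec.related is False and rec.trigger is None


def test_planted_corpus_classification_matches_ground_truth(tmp_path, lexicon, triggers):
    xml_path = tmp_path / "c.xml"
    _, truth = generate_corpus(GeneratorConfig(n_docs=60, seed=11), xml_path=xml_path)
    pred = annotate_documents(list(read_corpus(xml_path)), lexicon, triggers)
    predicted = {
        (r.pmid, r.field, r.sentence_index, r.cnv_id, r.disease_id)
        for r in pred.relations
        if r.related
    }
    assert predicted == truth.relation_keys()


def test_removing_trigger_terms_is_monotone(tmp_path, lexicon, triggers):
    """Shrinking the trigger lexicon never creates new related records."""
    xml_path = tmp_path / "c.xml"
    generate_corpus(GeneratorConfig(n_docs=40, seed=5), xml_path=xml_path)
    docs = list(read_corpus(xml_path))

    def related_count(trig):
        return sum(r.related for r in annotate_documents(docs, lexicon, trig).relations)

    full = related_count(triggers)
    reduced = triggers
    for term in ("associated", "cause", "linked"):
        reduced = reduced.without(term)
        current = related_count(reduced)
        assert current <= full
        full = current
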