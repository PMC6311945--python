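# Methods

## Problem setting

The package extracts sentence-level evidence for CNV-disease associations
from titles and abstracts of biomedical articles. The unit of evidence is a
single sentence containing one CNV mention and one disease mention;
cross-sentence and cross-document inference is deliberately out of scope.
All downstream statistics are counts over such records — no significance
test is attached, because the extraction itself provides no error model
that would justify one.

## Corpus model

Input is MEDLINE-baseline-style XML (`PMID`, `ArticleTitle`,
`AbstractText`); a minimal `<article pmid=...>` dialect is accepted for
fixtures. Multi-paragraph abstracts are joined with a single space before
segmentation. All offsets are 0-based half-open indices into decoded text:
this makes `source[start:end] == text` an invariant that every stage
asserts or round-trips, and avoids the ambiguity of byte offsets under
non-ASCII input.

Sentence segmentation is rule-based: a boundary is a run of `.!?` followed
by whitespace and an upper-case letter or digit, with an exception list for
common abbreviations (`Fig.`, `et al.`, `e.g.`, ...) and single-letter
initials. A digit may open a sentence because cytoband subjects
("22q11.2 was affected.") are common in this domain. The splitter is
deterministic and offset-faithful, which matters more here than linguistic
perfection: every mention is anchored to a sentence slice, and the
synthetic generator verifies at build time that the splitter reproduces its
intended boundaries.

## CNV recognition

Three surface families are captured by one grammar (all constants in
`cnv_ner.py`):

* **cytoband** — chromosome token (`1`–`22`, `X`, `Y`, either case), arm
  (`p`/`q`, either case), band of 1–2 digits with optional `.` + 1–2 digit
  sub-band, optional range tail `-`/`~` with optional arm repetition
  (`1p36.1-p36.3`, `5q11-13`). Word-boundary anchoring on both sides
  rejects protein names (`p21` has no chromosome token) and trailing junk
  (`22q11.2a`); a trailing `(?!\.?\d)` guard prevents truncated reads.
* **autosomal trisomy** — `trisomy` + optional space + number; the number
  is constrained to 1–22 by the alternation itself. `trisomy X` denotes a
  triple-X complement and normalizes to the `XXX` karyotype rather than to
  an (invalid) autosomal locus.
* **sex aneuploidy** — `XXX`/`XXY` at token boundaries, any case.
  `XYY` and monosomies are not captured: they are outside the pattern set
  this package commits to.

Overlapping candidates resolve longest-first, left to right, so emitted
spans are sorted and disjoint. Canonical ids are `22q11.2`-style strings
with upper-case chromosomes and lower-case arms (`trisomy N`, `XXX`, `XXY`
for the other kinds); canonicalization is idempotent under re-parsing,
which the tests check over the full grammar enumeration.

Loci are symbolic: no genome assembly, base-pair coordinates, or ISCN
karyotype strings (`46,XX,del(22)(q11.2)`), and no gene-level CNV mentions
("EGFR amplification").

**Polarity.** Gain/loss is decided by the nearest polarity keyword (token
distance) in the mention's sentence, ties toward the left — the
pre-modifier position ("22q11.2 deletion" / "deletion of 22q11.2") makes
the nearest keyword the natural attachment in English. The keyword list
(`data/polarity_keywords.tsv`) is an editable config, not code.

**Band overlap.** For merging ranked lists, each band maps to a half-open
interval on a 100-units-per-major-band scale, so `13.11 ⊂ 13.1 ⊂ 13` nests
the way cytogenetic sub-band refinement does, and ranges intersect by
symbolic band order (p before q). This is a notational model, not a
physical map: it reproduces the convention that `16p13.11` overlaps
`16p13.1` without claiming base-pair accuracy.

## Disease recognition

A deterministic dictionary matcher over a MEDIC-style lexicon
(MeSH/OMIM concept ids, preferred names, pipe-separated synonyms). Keys are
case-folded token sequences; matching is greedy longest-match left to
right, anchored at alphanumeric-run boundaries, so "flu" never fires inside
"fluid" and "autism spectrum disorder" shadows "autism". Name collisions
across concepts resolve to the first-listed concept with a warning at load
time. Abbreviations match only if present as synonyms — no expansion
heuristics, since silent expansion would manufacture precision the lexicon
cannot support. The interface (lexicon in, offset-anchored normalized
mentions out) would equally accommodate a learned normalizer.

A ~20-concept fixture lexicon ships with the package
(`data/disease_lexicon_synthetic.tsv`); its concept ids are synthetic
stand-ins, clearly labelled as such, used for tests and the synthetic
corpus.

## Relation extraction

Candidate instances are the full cross product of CNV × disease mentions
within one sentence, ordered by mention position. Classification is
trigger-based: terms from an editable lexicon
(`data/triggers_default.txt` — associate*, cause*, linked, correlated,
related, results in, responsible for, risk) are matched case-insensitively
with light inflection folding (one suffix stripped, stems shorter than 3
characters left alone), so "associated" and "association" are one family.
The gap between the two entity spans is searched first; only if it is
trigger-free is the whole sentence searched. Among candidates the one
nearest the midpoint of the two entities wins, ties to the left. A pair
with a trigger is `related`; trigger-free co-occurrences are retained with
`related = false` rather than discarded, so a consumer preferring plain
co-occurrence recall can still get it.

Design choices a maintainer should know:

* The trigger-window search replaces dependency-path rules. The observable
  contract — a lexical cue between two entities signals a relation — is
  kept, the syntax machinery is not; `find_trigger` is isolated so a
  parser-based strategy could be swapped in without touching the rest.
* Only "associated" among the default triggers is grounded in the domain's
  canonical worked example; the rest of the list is configuration, and
  shrinking it is monotone (never creates new related records — tested).
* Negation is not modelled: "not associated" counts as associated. This is
  a known limitation, visible in the records via the stored sentence text.

## Aggregation and queries

Records are de-duplicated on (PMID, field, sentence index, CNV id, disease
id), first occurrence kept, output sorted by that key — which makes
de-duplication idempotent, permutation-invariant, and the anchor for
parallel/serial byte-equivalence. A declarative exclusion list
((pmid, cnv_id, disease_id) patterns, `*` wildcards) replaces manual
cleanup of known-bad extractions; it is auditable and replayable, which a
hand-edit is not.

Associations aggregate related records per (CNV, disease) pair with
sentence counts, article counts, PMID lists, and per-polarity tallies;
conservation (Σ pair sentence counts = related record count) is asserted in
tests. Rankings order partners by article count first — the count a reader
of a results list sees — then sentence count, then id; `top_k(k)` is a
prefix of `top_k(k+1)` by construction, and k defaults to 20. When two
diseases' top lists are intersected (`common_partners`), cytobands that
overlap merge into one entry and the coarser band is reported.

The three query perspectives (by CNV, by disease, by PMID list with grouped
evidence sentences and highlight offsets) are exposed both as library
functions and as `cnvdigest query`.

## Parallel execution

Documents are partitioned by summed character length (title + abstract)
using longest-processing-time greedy assignment: sort by length descending
(ties by PMID), assign each to the least-loaded worker (ties to the lowest
id). The classic bound — max load ≤ (4/3 − 1/(3m)) × optimum — is verified
in tests against a branch-and-bound exact solver on instances of up to 12
documents. Characters are the load unit because processing cost here is
essentially linear in text length; token or sentence counts would change
nothing structurally.

Workers are separate processes with no shared state; each writes its own
relation file. The merge step concatenates, checks PMID disjointness, and
re-sorts into the canonical order, so output bytes are identical for any
worker count — equivalence is a tested invariant, not an aspiration.

## Synthetic corpus

The generator emulates exactly the statistical structure the pipeline's
features observe: per-sentence categories (trigger-bearing positive pairs,
trigger-free co-occurrence negatives, single-entity sentences, distractors)
drawn with configured probabilities, CNV surfaces sampled from the
recognition grammar (band numbers are sampled over the grammar's numeric
range, not restricted to bands that exist on real chromosome maps), disease
surfaces from the lexicon, and a gain/loss/unknown wording mix for
cytobands. Positive templates realize both entity orders so trigger search
is exercised in both directions.

Defaults: 200 documents, 3–8 abstract sentences each, 35% positive, 15%
co-occurrence negative, 10% CNV-only, 10% disease-only, 30% distractor,
polarity mix 0.3/0.4/0.3 gain/loss/unknown. These sizes keep a full
end-to-end evaluation in the low seconds while producing several hundred
relations — enough for every per-stage metric to be meaningfully exercised.

Everything is verified at generation time: distractors must match neither
the CNV grammar nor the lexicon; planted sentences must yield exactly the
planted mentions; negative templates must be trigger-free under the
supplied trigger lexicon; and the splitter must reproduce the intended
sentence boundaries. The same seed therefore yields byte-identical XML and
manifest, and scoring against the manifest is exact, not approximate.

What passing on synthetic corpora does **not** show: robustness to real
abstract prose — paraphrase, anaphora, negation, enumerated findings,
diseases missing from the lexicon, or CNV notations outside the grammar.
The generator's positives are, by construction, sentences the extractor
can read; real-world recall is bounded by lexicon coverage and template
diversity of actual writing. An opt-in hard-negative mode plants
grammar-colliding distractors (e.g. `XXX` as a masking string) to measure
precision degradation; it is off by default and excluded from purity
checks.

Scoring uses exact-match precision/recall: (sentence, span, id) for NER,
(sentence, cnv_id, disease_id) for relations. Empty prediction sets report
precision 0 with an `undefined_precision` flag rather than NaN.

## Numerical and degenerate-input choices

* Ties are broken deterministically everywhere (leftmost trigger, leftmost
  polarity keyword, lowest worker id, lexicographic ids) so all artifacts
  are reproducible byte-for-byte.
* Empty corpora, empty abstracts, empty prediction sets, and k exceeding
  the partner count all degrade to empty-but-well-formed outputs, never
  errors.
* Duplicate PMIDs and lexicon name collisions keep the first occurrence
  and warn, rather than failing a whole run for a data wrinkle.
* The acceptance script derives all randomness from a single `--seed` and
  generates every input at run time.

## Known limitations

Sentence-bounded evidence only; no negation or speculation handling; no
ISCN karyotypes, genomic coordinates, or gene-level CNVs; dictionary-bound
disease recall; band-overlap model is notational, not physical; trigger
list curation is the user's lever for precision/recall trade-offs on real
text.
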