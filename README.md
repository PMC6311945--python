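# cnvdigest

Text mining of copy-number-variant (CNV) / disease associations from
MEDLINE-style abstracts.

Clinical geneticists who interpret CNV findings routinely fall back on
PubMed when a variant is absent from curated resources (ClinGen, DGV,
DECIPHER) — a slow, manual search. `cnvdigest` automates the literature
side of that workflow: it reads abstracts, recognizes CNV mentions
(cytobands such as `22q11.2` or `1p36.1-p36.3`, autosomal trisomies,
XXX/XXY aneuploidies) and disease mentions (dictionary lookup against a
MEDIC-style MeSH/OMIM lexicon), pairs the entities that co-occur in one
sentence, classifies each pair by trigger-word evidence ("associated",
"caused", "linked", ...), detects gain/loss polarity from
duplication/deletion wording, and aggregates everything into ranked,
queryable association summaries with the original evidence sentences
attached.

## Method in brief

For each abstract *d* and sentence *s* ∈ *d*:

1. **CNV NER** — regular-expression grammar over cytoband notation
   (`<chrom 1-22|X|Y><p|q><band>[.<sub-band>][-<arm><band>]`), `trisomy N`,
   and karyotypes `XXX`/`XXY`; each match is normalized to a canonical
   locus id.
2. **Disease NER** — greedy longest-match, token-anchored, case-insensitive
   lookup against the lexicon; mentions are normalized to `MESH:`/`OMIM:`
   concept ids.
3. **Relation extraction** — for every (CNV, disease) pair in *s*, search
   the span between the entities (then the whole sentence) for a trigger
   term; the trigger nearest the pair's midpoint decides `related = true`.
   Polarity comes from the nearest duplication/deletion keyword.
4. **Aggregation** — records are de-duplicated by
   (PMID, field, sentence, CNV, disease), optionally filtered by a
   declarative exclusion list, and summarized per (CNV, disease) pair with
   sentence and article counts. Rankings order partners by article count,
   then sentence count. Overlapping cytobands (e.g. `16p13.1` vs
   `16p13.11`) merge to the coarser band when two ranked lists are
   intersected.

Corpora can be processed in parallel: documents are distributed to worker
processes by summed text length (longest-processing-time greedy, max load ≤
(4/3 − 1/(3m)) × optimum), and the merged output is byte-identical to a
serial run.

A synthetic-corpus generator (`cnvdigest simulate`) emits MEDLINE-style XML
with planted mentions, triggers, polarity cues, and distractors, plus a
ground-truth manifest, so the whole pipeline is testable without any
downloads.

## Worked example

```sh
$ cnvdigest simulate --n-docs 100 --seed 42 --out-xml corpus.xml --out-manifest truth.jsonl
wrote 100 documents, 655 mentions, 195 relations

$ cnvdigest mine --input corpus.xml --workers 2 --out store
{
  "associations": 188,
  "cnv_mentions": 325,
  "disease_mentions": 330,
  "documents": 100,
  "documents_with_relations": 86,
  "instances": 273,
  "records_after_dedup": 273,
  "records_before_dedup": 273,
  "records_excluded": 0,
  "related_records": 195,
  "sentences": 644,
  "workers": 2
}
```

The report is the mining funnel: 100 documents split into 644 sentences
yielded 325 CNV and 330 disease mentions; 273 of their sentence-level
pairings (instances) were formed, 195 carried a trigger word
(`related_records`), and these collapse into 188 distinct (CNV, disease)
associations. The 195 related records here equal the 195 planted relations
in `truth.jsonl` — on synthetic corpora the pipeline recovers the ground
truth exactly.

Querying works from any of the three perspectives:

```sh
$ cnvdigest query --pmid 100004 --store store
# PMID 100004: 1 evidence sentence(s)
XXX	MESH:D000011	unknown	linked	XXX is linked to developmental delay.

$ cnvdigest query --disease MESH:D000002 --k 5 --store store
rank	partner	n_articles	n_sentences	gain	loss	unknown
1	15q38.5	1	1	0	1	0
...
```

Each evidence line carries the canonical CNV id, the disease concept id,
the detected polarity, the trigger word, and the sentence itself, with
character offsets available in `store/relations.jsonl` for highlighting.

The same operations are available as a library
(`cnvdigest.pipeline.run`, `cnvdigest.aggregate.top_k`,
`cnvdigest.aggregate.query_by_pmid`, ...).

## Scope

Abstracts only (no full text); no dependency parsing, negation handling, or
statistical significance testing — the system reports counts with evidence.
The web front end, database server, and deployment stack that a production
service would add are out of scope here; this package is the mining engine
and its evaluation harness.
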