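"""End-to-end orchestration: read -> split -> NER -> RE -> dedup -> summarize.

The pipeline runs serially or over N worker processes. Documents are
assigned to workers by :func:`cnvdigest.parallel_partition.partition_documents`;
each worker materializes its own relation file (mirroring a file-per-node
parallel design, and making partial runs inspectable), and the merge step
restores the canonical order, so the final artifacts are byte-identical for
any worker count. Workers share nothing and communicate only through their
output files.
"""

from __future__ import annotations

import json
import logging
import sys
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from cnvdigest import aggregate, corpus_io
from cnvdigest.aggregate import AssociationRecord, CorpusStats
from cnvdigest.cnv_ner import CnvMention, find_cnv_mentions
from cnvdigest.corpus_io import Document, read_corpus, split_sentences, write_annotations
from cnvdigest.disease_ner import (
    DiseaseLexicon,
    DiseaseMention,
    default_lexicon,
    find_disease_mentions,
    load_lexicon,
)
from cnvdigest.errors import CnvDigestError
from cnvdigest.parallel_partition import merge_worker_outputs, partition_documents
from cnvdigest.relation_extract import (
    RelationRecord,
    TriggerLexicon,
    classify_relation,
    default_triggers,
    find_trigger,
    generate_instances,
    load_triggers,
)

logger = logging.getLogger("cnvdigest")

__all__ = ["PipelineConfig", "Predictions", "RunResult", "annotate_documents", "run"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one mining run needs.

    ``lexicon_path``/``trigger_path`` default to the bundled fixtures when
    None. ``formats`` selects relation-file serializations.
    """

    input_path: str
    out_dir: str
    lexicon_path: Optional[str] = None
    trigger_path: Optional[str] = None
    exclusion_path: Optional[str] = None
    pmid_list_path: Optional[str] = None
    workers: int = 1
    formats: tuple[str, ...] = ("jsonl", "tsv")


@dataclass
class Predictions:
    """Raw per-stage pipeline output for a set of documents."""

    cnv_mentions: list[CnvMention] = field(default_factory=list)
    disease_mentions: list[DiseaseMention] = field(default_factory=list)
    relations: list[RelationRecord] = field(default_factory=list)
    n_documents: int = 0
    n_sentences: int = 0
    n_instances: int = 0


@dataclass
class RunResult:
    out_dir: Path
    relations_path: Path
    associations_path: Path
    stats_path: Path
    report_path: Path
    records: list[RelationRecord]
    associations: list[AssociationRecord]
    stats: CorpusStats
    report: dict


def annotate_documents(
    docs: Sequence[Document],
    lexicon: DiseaseLexicon,
    triggers: TriggerLexicon,
) -> Predictions:
    """Run NER and relation extraction over documents; no aggregation."""
    pred = Predictions()
    for doc in docs:
        pred.n_documents += 1
        try:
            for sentence in split_sentences(doc):
                pred.n_sentences += 1
                cnvs = find_cnv_mentions(sentence)
                diseases = find_disease_mentions(sentence, lexicon)
                pred.cnv_mentions.extend(cnvs)
                pred.disease_mentions.extend(diseases)
                for instance in generate_instances(sentence, cnvs, diseases):
                    pred.n_instances += 1
                    trigger = find_trigger(instance, triggers)
                    pred.relations.append(classify_relation(instance, trigger))
        except CnvDigestError as exc:
            raise type(exc)(f"[annotate, PMID {doc.pmid}] {exc}") from exc
    return pred


def _process_partition(docs: list[Document], lexicon, triggers) -> Predictions:
    # Top-level so it pickles for process workers.
    return annotate_documents(docs, lexicon, triggers)


def run(config: PipelineConfig) -> RunResult:
    """Execute the full pipeline and materialize all artifacts.

    Writes (into ``out_dir``): per-worker relation files, the merged and
    de-duplicated ``relations.jsonl``/``relations.tsv``, association
    summaries (``associations.tsv``/``associations.json``), corpus
    ``stats.json``, and a machine-readable ``report.json`` with per-stage
    counts. Output bytes are independent of the worker count.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lexicon = load_lexicon(config.lexicon_path) if config.lexicon_path else default_lexicon()
    triggers = load_triggers(config.trigger_path) if config.trigger_path else default_triggers()
    exclusions = (
        aggregate.load_exclusions(config.exclusion_path) if config.exclusion_path else []
    )
    pmid_filter = None
    if config.pmid_list_path:
        pmid_filter = {
            line.strip()
            for line in Path(config.pmid_list_path).read_text(encoding="utf-8").splitlines()
            if line.strip()
        }

    docs = list(read_corpus(config.input_path, pmid_filter=pmid_filter))
    by_pmid = {d.pmid: d for d in docs}
    partitions = partition_documents(docs, config.workers)
    worker_docs = [[by_pmid[p] for p in part.doc_pmids] for part in partitions]

    logger.info("processing %d documents on %d worker(s)", len(docs), config.workers)
    if config.workers == 1:
        results = [_process_partition(worker_docs[0], lexicon, triggers)]
    else:
        with ProcessPoolExecutor(max_workers=config.workers) as pool:
            futures = [
                pool.submit(_process_partition, wdocs, lexicon, triggers)
                for wdocs in worker_docs
            ]
            results = [f.result() for f in futures]

    for part, pred in zip(partitions, results):
        path = out_dir / f"relations.worker{part.worker_id:02d}.jsonl"
        write_annotations(pred.relations, path, format="jsonl")

    merged = merge_worker_outputs([pred.relations for pred in results])
    deduped = aggregate.deduplicate(merged)
    kept, n_excluded = aggregate.apply_exclusions(deduped, exclusions)
    associations, stats = aggregate.summarize(kept)

    relations_path = out_dir / "relations.jsonl"
    write_annotations(kept, relations_path, format="jsonl")
    if "tsv" in config.formats:
        write_annotations(kept, out_dir / "relations.tsv", format="tsv")

    associations_path = out_dir / "associations.tsv"
    with associations_path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(
            "cnv_id\tdisease_id\tn_articles\tn_sentences\tn_gain\tn_loss\tn_unknown\tpmids\n"
        )
        for a in associations:
            fh.write(
                f"{a.cnv_id}\t{a.disease_id}\t{a.n_articles}\t{a.n_sentences}\t"
                f"{a.polarity_counts['gain']}\t{a.polarity_counts['loss']}\t"
                f"{a.polarity_counts['unknown']}\t{','.join(a.pmids)}\n"
            )
    (out_dir / "associations.json").write_text(
        json.dumps([a.to_dict() for a in associations], indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    stats_path = out_dir / "stats.json"
    stats_path.write_text(json.dumps(stats.to_dict(), indent=2, sort_keys=True) + "\n", encoding="utf-8")

    related = [r for r in kept if r.related]
    report = {
        "workers": config.workers,
        "documents": sum(p.n_documents for p in results),
        "sentences": sum(p.n_sentences for p in results),
        "cnv_mentions": sum(len(p.cnv_mentions) for p in results),
        "disease_mentions": sum(len(p.disease_mentions) for p in results),
        "instances": sum(p.n_instances for p in results),
        "records_before_dedup": len(merged),
        "records_after_dedup": len(deduped),
        "records_excluded": n_excluded,
        "related_records": len(related),
        "associations": len(associations),
        "documents_with_relations": len({r.pmid for r in related}),
    }
    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    for stage in ("documents", "sentences", "cnv_mentions", "disease_mentions",
                  "instances", "related_records", "associations"):
        logger.info("%s: %d", stage, report[stage])

    return RunResult(
        out_dir=out_dir,
        relations_path=relations_path,
        associations_path=associations_path,
        stats_path=stats_path,
        report_path=report_path,
        records=kept,
        associations=associations,
        stats=stats,
        report=report,
    )
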