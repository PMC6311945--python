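"""Load-balanced corpus partitioning and worker-output merging.

Work is balanced by the summed character length (title + abstract) of the
documents assigned to each worker, using the classic longest-processing-time
greedy rule: documents are taken in decreasing length order (ties by PMID)
and each goes to the currently least-loaded worker (ties to the lowest
worker id). This is deterministic and carries the textbook guarantee that
the maximum load is within a factor 4/3 - 1/(3m) of the optimal makespan
for m workers.

Workers share no mutable state; their outputs are merged by concatenation
followed by the canonical record sort, which makes any parallel run
byte-identical to the serial one.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from itertools import chain
from typing import Iterable, Sequence

from cnvdigest.aggregate import sort_key
from cnvdigest.corpus_io import Document
from cnvdigest.errors import IntegrityError
from cnvdigest.relation_extract import RelationRecord

__all__ = ["Partition", "document_length", "partition_documents", "merge_worker_outputs"]


def document_length(doc: Document) -> int:
    """Work-load estimate for one document: characters of title + abstract."""
    return len(doc.title) + len(doc.abstract)


@dataclass
class Partition:
    """One worker's share of the corpus."""

    worker_id: int
    doc_pmids: list[str] = field(default_factory=list)
    load: int = 0


def partition_documents(docs: Sequence[Document], n_workers: int) -> list[Partition]:
    """Greedy longest-first assignment of documents to workers.

    Always returns exactly ``n_workers`` partitions (some possibly empty);
    together they cover every document exactly once.
    """
    if n_workers < 1:
        raise ValueError(f"n_workers must be >= 1, got {n_workers}")
    partitions = [Partition(worker_id=i) for i in range(n_workers)]
    heap: list[tuple[int, int]] = [(0, i) for i in range(n_workers)]
    heapq.heapify(heap)
    for doc in sorted(docs, key=lambda d: (-document_length(d), d.pmid)):
        load, worker_id = heapq.heappop(heap)
        part = partitions[worker_id]
        part.doc_pmids.append(doc.pmid)
        part.load = load + document_length(doc)
        heapq.heappush(heap, (part.load, worker_id))
    return partitions


def merge_worker_outputs(
    outputs: Sequence[Iterable[RelationRecord]],
) -> list[RelationRecord]:
    """Combine per-worker record streams into the canonical serial order.

    Streams must come from disjoint partitions: a PMID appearing in two
    streams raises :class:`~cnvdigest.errors.IntegrityError`.
    """
    streams = [list(s) for s in outputs]
    seen_pmids: dict[str, int] = {}
    for i, stream in enumerate(streams):
        for pmid in {r.pmid for r in stream}:
            if pmid in seen_pmids and seen_pmids[pmid] != i:
                raise IntegrityError(
                    f"PMID {pmid} appears in worker streams {seen_pmids[pmid]} and {i}"
                )
            seen_pmids[pmid] = i
    return sorted(chain.from_iterable(streams), key=sort_key)
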