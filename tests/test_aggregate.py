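"""De-duplication, summaries, rankings, and query operations."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from cnvdigest.aggregate import (
    ExclusionPattern,
    apply_exclusions,
    common_partners,
    deduplicate,
    load_exclusions,
    query_by_pmid,
    record_key,
    summarize,
    top_k,
)
from cnvdigest.errors import ConfigError
from cnvdigest.relation_extract import RelationRecord


def make_record(pmid="1", field="abstract", index=0, cnv="22q11.2",
                disease="MESH:D000001", polarity="loss", related=True):
    return RelationRecord(
        pmid=pmid, field=field, sentence_index=index,
        sentence_text=f"sentence {pmid}/{index} about {cnv} and {disease}.",
        cnv_id=cnv, cnv_start=0, cnv_end=1, cnv_surface=cnv,
        disease_id=disease, disease_start=2, disease_end=3, disease_surface=disease,
        polarity=polarity, trigger="associated" if related else None, related=related,
    )


record_strategy = st.builds(
    make_record,
    pmid=st.sampled_from(["1", "2", "3"]),
    index=st.integers(0, 3),
    cnv=st.sampled_from(["22q11.2", "1q21.1", "trisomy 21"]),
    disease=st.sampled_from(["MESH:D000001", "MESH:D000002"]),
    polarity=st.sampled_from(["gain", "loss", "unknown"]),
)


# --- deduplicate -----------------------------------------------------------


def test_deduplicate_examples():
    a, b = make_record(index=0), make_record(index=0)
    assert deduplicate([a, b]) == [a]  # identical key collapses
    c = make_record(index=1)
    assert deduplicate([a, c]) == [a, c]  # distinct sentences both kept


@settings(derandomize=True, max_examples=60)
@given(st.lists(record_strategy, max_size=25), st.randoms(use_true_random=False))
def test_deduplicate_idempotent_and_permutation_invariant(records, rnd):
    once = deduplicate(records)
    assert deduplicate(once) == once
    doubled = records + records
    rnd.shuffle(doubled)
    assert {record_key(r) for r in deduplicate(doubled)} == {record_key(r) for r in once}
    assert [record_key(r) for r in once] == sorted(record_key(r) for r in set(once))


# --- exclusions ------------------------------------------------------------


def test_exclusions_empty_list_is_identity():
    records = [make_record(index=i) for i in range(3)]
    kept, removed = apply_exclusions(records, [])
    assert kept == records and removed == 0


def test_exclusion_by_disease_and_oracle_count():
    records = [
        make_record(pmid=p, index=i, disease=d)
        for p in ("1", "2")
        for i in range(2)
        for d in ("MESH:D000001", "MESH:D000002")
    ]
    pattern = ExclusionPattern("*", "*", "MESH:D000001")
    kept, removed = apply_exclusions(records, [pattern])
    brute = [r for r in records if r.disease_id != "MESH:D000001"]
    assert kept == brute
    assert removed == len(records) - len(brute)


def test_load_exclusions(tmp_path):
    p = tmp_path / "ex.tsv"
    p.write_text("# comment\n*\t22q11.2\t*\n123\t*\tMESH:D000002\n")
    patterns = load_exclusions(p)
    assert patterns == [
        ExclusionPattern("*", "22q11.2", "*"),
        ExclusionPattern("123", "*", "MESH:D000002"),
    ]
    p.write_text("only two\tcolumns\n")
    with pytest.raises(ConfigError):
        load_exclusions(p)


# --- summarize -------------------------------------------------------------


def test_summarize_counts_and_conservation():
    records = [
        make_record(pmid="1", index=0),
        make_record(pmid="2", index=0),
        make_record(pmid="2", index=1, cnv="1q21.1", polarity="gain"),
    ]
    associations, stats = summarize(records)
    assert len(associations) == 2
    first = associations[0]
    assert (first.cnv_id, first.n_sentences, first.n_articles) == ("22q11.2", 2, 2)
    assert first.pmids == ("1", "2")
    assert sum(a.n_sentences for a in associations) == len(records)
    for a in associations:
        assert a.n_articles == len(a.pmids)
        assert a.n_sentences >= a.n_articles >= 1
        assert sum(a.polarity_counts.values()) == a.n_sentences
    assert stats.n_relation_sentences == 3
    assert stats.n_distinct_cnvs == 2
    assert stats.n_distinct_diseases == 1
    assert stats.n_articles == 2


def test_summarize_empty_and_unrelated_filtered():
    associations, stats = summarize([make_record(related=False)])
    assert associations == []
    assert stats.n_relation_sentences == stats.n_articles == 0


@settings(derandomize=True, max_examples=40)
@given(st.lists(record_strategy, max_size=30))
def test_summarize_conservation_property(records):
    unique = deduplicate(records)
    associations, _ = summarize(unique)
    assert sum(a.n_sentences for a in associations) == sum(r.related for r in unique)


# --- top_k -----------------------------------------------------------------


def _summaries_for_ranking(seed):
    rng = random.Random(seed)
    records = []
    for i in range(rng.randint(10, 40)):
        records.append(
            make_record(
                pmid=str(rng.randint(1, 9)),
                index=rng.randint(0, 5),
                cnv=rng.choice(["22q11.2", "1q21.1", "15q11.2", "16p11.2", "3q29"]),
                disease="MESH:D000001",
            )
        )
    associations, _ = summarize(deduplicate(records))
    return associations


def test_top_k_all_partners_when_k_exceeds():
    associations, _ = summarize(
        deduplicate(
            [make_record(cnv=c, pmid=p, index=0)
             for c, p in (("22q11.2", "1"), ("22q11.2", "2"), ("1q21.1", "1"), ("3q29", "1"))]
        )
    )
    ranked = top_k(associations, disease_id="MESH:D000001", k=20)
    assert [a.cnv_id for a in ranked] == ["22q11.2", "1q21.1", "3q29"]  # ties lexicographic
    assert top_k(associations, disease_id="MESH:D999999", k=5) == []


@pytest.mark.parametrize("seed", range(5))
def test_top_k_equals_sorted_prefix(seed):
    associations = _summaries_for_ranking(seed)
    full = sorted(
        [a for a in associations if a.disease_id == "MESH:D000001"],
        key=lambda a: (-a.n_articles, -a.n_sentences, a.cnv_id),
    )
    for k in (1, 2, 3, 20):
        assert top_k(associations, disease_id="MESH:D000001", k=k) == full[:k]
    # prefix property
    assert top_k(associations, disease_id="MESH:D000001", k=2) == top_k(
        associations, disease_id="MESH:D000001", k=3
    )[:2]


# --- query_by_pmid ---------------------------------------------------------


def test_query_by_pmid_groups_partition_records():
    records = [
        make_record(pmid="1", index=0),
        make_record(pmid="1", index=2),
        make_record(pmid="2", index=0),
    ]
    groups = query_by_pmid(records, ["2", "1", "404"])
    assert list(groups) == ["2", "1", "404"]
    assert groups["404"] == []
    assert [r.sentence_index for r in groups["1"]] == [0, 2]
    flattened = [r for recs in groups.values() for r in recs]
    assert sorted(map(record_key, flattened)) == sorted(map(record_key, records))


# --- common_partners -------------------------------------------------------


def _two_disease_summaries(pairs):
    records = []
    for disease, cnvs in pairs.items():
        for rank, cnv in enumerate(cnvs):
            # earlier ranks get more articles
            for p in range(len(cnvs) - rank):
                records.append(
                    make_record(pmid=f"{disease[-1]}{cnv}{p}", index=0, cnv=cnv, disease=disease)
                )
    associations, _ = summarize(deduplicate(records))
    return associations


def test_common_partners_exact_shared_entry():
    summaries = _two_disease_summaries(
        {"MESH:D000002": ["22q11.2", "1q21.1"], "MESH:D000003": ["22q11.2", "3q29"]}
    )
    assert common_partners(summaries, "MESH:D000002", "MESH:D000003", k=10) == ["22q11.2"]


def test_common_partners_merges_overlapping_subbands():
    summaries = _two_disease_summaries(
        {"MESH:D000002": ["16p13.1", "22q11.2"], "MESH:D000003": ["16p13.11", "22q11.2"]}
    )
    merged = common_partners(summaries, "MESH:D000002", "MESH:D000003", k=10)
    assert "16p13.1" in merged and "16p13.11" not in merged
    assert set(merged) == {"16p13.1", "22q11.2"}
    # symmetric as a set
    swapped = common_partners(summaries, "MESH:D000003", "MESH:D000002", k=10)
    assert set(swapped) == set(merged)


def test_common_partners_disjoint_lists():
    summaries = _two_disease_summaries(
        {"MESH:D000002": ["22q11.2"], "MESH:D000003": ["3q29"]}
    )
    assert common_partners(summaries, "MESH:D000002", "MESH:D000003", k=10) == []
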