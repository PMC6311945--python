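import pytest

from cnvdigest.corpus_io import Sentence
from cnvdigest.disease_ner import default_lexicon
from cnvdigest.relation_extract import default_triggers


def make_sentence(text: str, pmid: str = "1", field: str = "abstract", index: int = 0) -> Sentence:
    """A standalone sentence whose offsets cover the whole text."""
    return Sentence(pmid=pmid, field=field, index=index, start=0, end=len(text), text=text)


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def triggers():
    return default_triggers()
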