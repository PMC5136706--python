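import numpy as np
import pytest
from hypothesis import settings

from treecheck.io_formats import Alignment, SequenceRecord, TaxonomyTable
from treecheck.io_formats import read_tree

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20160921)


@pytest.fixture
def two_family_tree():
    """Rooted ((f1a,f1b)85,(f2a,f2b)90); both families monophyletic."""
    return read_tree("((f1a:1,f1b:1)85:1,(f2a:1,f2b:1)90:1);")


@pytest.fixture
def two_family_taxonomy():
    return {"f1a": "Fam1", "f1b": "Fam1", "f2a": "Fam2", "f2b": "Fam2"}


@pytest.fixture
def grade_tree():
    """f1 paraphyletic: f2 nested whole inside the f1 grade."""
    return read_tree("(f1a:1,(f1b:1,(f1c:1,(f2a:1,f2b:1)95:1)80:1)99:1);")


@pytest.fixture
def grade_taxonomy():
    return {
        "f1a": "Fam1",
        "f1b": "Fam1",
        "f1c": "Fam1",
        "f2a": "Fam2",
        "f2b": "Fam2",
    }


def make_alignment(seqs: dict[str, str]) -> Alignment:
    return Alignment([SequenceRecord(k, v) for k, v in seqs.items()])


@pytest.fixture
def conflict_free_alignment():
    """Two identical pairs, maximally separated: a single unambiguous split."""
    return make_alignment(
        {
            "A": "A" * 100,
            "B": "A" * 100,
            "C": "A" * 80 + "C" * 20,
            "D": "A" * 80 + "C" * 20,
        }
    )
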