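import numpy as np
import pytest

from orfstack.features import CODONS
from orfstack.sequence_io import Fragment
from orfstack.orf_finder import OrfCandidate
from orfstack.synthetic_data import SyntheticGenomeSpec, make_labeled_dataset
from orfstack.evaluation import sample_balanced


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_orf(rng, n_codons=40, L=None):
    """A syntactically valid ORF with random codons for feature tests."""
    codons = [CODONS[i] for i in rng.integers(0, 64, size=n_codons)]
    l = 3 * n_codons
    L = L or l
    return OrfCandidate(
        fragment_id="t",
        strand="+",
        frame=0,
        start=0,
        end=l,
        codons=codons,
        has_start=False,
        has_stop=False,
        L=L,
    )


def random_fragment(rng, length=200, id="frag"):
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
    return Fragment(id=id, sequence=seq)


@pytest.fixture(scope="session")
def biased_dataset():
    """Balanced labeled features from the default codon-biased world."""
    ds = make_labeled_dataset(SyntheticGenomeSpec(seed=1), frag_len=700, coverage=3.0, seed=2)
    idx = sample_balanced(ds.labels, min(ds.class_counts.values()), seed=3)
    return ds.X[idx], ds.labels[idx]
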