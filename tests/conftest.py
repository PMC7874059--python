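import numpy as np
import pytest

from mlstpop import ProfileMatrix, default_scheme, fixture_records, registry_from_records


@pytest.fixture(scope="session")
def records():
    return fixture_records()


@pytest.fixture(scope="session")
def pm(records):
    return ProfileMatrix.from_records(records)


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture()
def registry(records):
    return registry_from_records(records)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)


def random_dna(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))


def random_alignment(rng, n, length, n_variable):
    """Alignment built by sprinkling substitutions on a random backbone."""
    base = random_dna(rng, length)
    seqs = [list(base) for _ in range(n)]
    positions = rng.choice(length, size=n_variable, replace=False)
    for pos in positions:
        carriers = rng.choice(n, size=int(rng.integers(1, n)), replace=False)
        alt = rng.choice([b for b in "ACGT" if b != base[pos]])
        for c in carriers:
            seqs[c][pos] = alt
    return ["".join(s) for s in seqs]
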