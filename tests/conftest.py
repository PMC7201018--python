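import numpy as np
import pytest

from gofuse import simulate
from gofuse.io import AnnotationRecord, DomainHit, ScoredLink


@pytest.fixture(scope="session")
def trigram_table():
    """Deterministic stand-in embedding table over the 20-letter alphabet."""
    return simulate.make_protvec_stub(seed=0)


@pytest.fixture(scope="session")
def small_dataset():
    """An 80-protein planted-signal dataset shared by fast tests."""
    cfg = simulate.SimConfig(
        n_proteins=80, n_terms=6, n_domains=12, n_clusters=3,
        seq_len_range=(40, 80), label_noise=0.0, seed=123,
    )
    return simulate.generate_dataset(cfg)


@pytest.fixture
def toy_hits():
    return [
        DomainHit("P1", "A", 10, 50),
        DomainHit("P1", "B", 60, 200),
        DomainHit("P1", "C", 100, 140),
    ]


@pytest.fixture
def toy_links():
    return [
        ScoredLink("P1", "P2", 700),
        ScoredLink("P2", "P3", 400),
        ScoredLink("P1", "P3", 150),
    ]


@pytest.fixture
def toy_annotations():
    rows = [
        ("P1", "GO:0000001", "MF"), ("P2", "GO:0000001", "MF"),
        ("P3", "GO:0000001", "MF"), ("P4", "GO:0000001", "MF"),
        ("P5", "GO:0000001", "MF"),
        ("P1", "GO:0000002", "MF"), ("P2", "GO:0000002", "MF"),
        ("P1", "GO:0000003", "MF"),
        ("P1", "GO:0000009", "BP"),
    ]
    return [AnnotationRecord(*r) for r in rows]


@pytest.fixture
def rng():
    return np.random.default_rng(0)
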