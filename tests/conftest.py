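import numpy as np
import pytest

from deepsub import fixtures


@pytest.fixture
def six_entry_descriptors():
    """1 no-comment, 1 similarity-evidence, 1 qualifier, 1 ambiguous, 2 clean."""
    return [
        fixtures.EntryDescriptor("P00001", "MKVA"),
        fixtures.EntryDescriptor(
            "P00002", "MKVC", subunit_text="Monomer.", evidence_codes=["ECO:0000250"]
        ),
        fixtures.EntryDescriptor(
            "P00003", "MKVD", subunit_text="Homodimer (By similarity).",
            evidence_codes=["ECO:0000269"],
        ),
        fixtures.EntryDescriptor(
            "P00004", "MKVE", subunit_text="Homodimer; can also form homotetramers.",
            evidence_codes=["ECO:0000269"],
        ),
        fixtures.EntryDescriptor(
            "P00005", "MKVF",
            subunit_text="Homooctamer of 4 homodimers; disulfide-linked.",
            evidence_codes=["ECO:0000269"], ec_numbers=["1.1.1.1"],
            organism="Homo sapiens",
        ),
        fixtures.EntryDescriptor(
            "P00006", "MKVG", subunit_text="Monomer.",
            evidence_codes=["ECO:0000269"], ec_numbers=["1.1.1.1"],
            organism="Escherichia coli",
        ),
    ]


@pytest.fixture
def small_cluster_data():
    """Separable class-conditional embeddings at reduced width."""
    spec = fixtures.FixtureSpec(n_per_class=12, width=16, noise_sd=0.05, seed=7)
    dataset, centers = fixtures.make_synthetic_embeddings(spec)
    X, y = fixtures.embeddings_as_arrays(dataset)
    return X, y, centers, spec


def nearest_centroid_labels(X: np.ndarray, centers: np.ndarray, labels) -> np.ndarray:
    """Independent oracle: assign each point to the closest class center."""
    d = np.linalg.norm(X[:, None, :] - centers[None, :, :], axis=-1)
    return np.asarray(labels)[np.argmin(d, axis=1)]
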