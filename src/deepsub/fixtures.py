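"""Synthetic-data generators: every pipeline stage runs with no download.

Two families of fixtures:

* toy UniProt-dialect XML documents with subunit comments, evidence
  declarations, EC numbers and organism fields, for exercising the
  curation pipeline end to end;
* class-conditional embeddings and sequences: pooled vectors drawn as
  ``center_c + N(0, noise_sd^2)`` around ten per-class centers, and
  random amino-acid sequences whose synthetic-backend embeddings carry
  the same class structure (the backend adds ``center_c`` keyed by a
  deterministic label function of the sequence). With noise far below
  the inter-center separation the classes are separable by construction
  — a nearest-centroid oracle attains 100% — which is what makes
  parameter-recovery tests meaningful.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from lxml import etree

from deepsub.curation import SEQUENCE_ALPHABET, _ECO_PATTERN
from deepsub.embedding import PooledEmbedding, SyntheticBackend
from deepsub.model import NS_LABELS

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_NS = "http://uniprot.org/uniprot"


@dataclass
class FixtureSpec:
    """Study conditions for the synthetic class-conditional fixtures."""

    n_per_class: int = 20
    width: int = 64  # reduced width for speed; use 1280 for the full contract
    noise_sd: float = 0.05
    seed: int = 0
    sequence_length: tuple[int, int] = (50, 100)
    labels: tuple[int, ...] = NS_LABELS
    #: scale of the class centers; inter-center distance ~ center_scale * sqrt(2 * width)
    center_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n_per_class < 1 or self.width < 1:
            raise ValueError("n_per_class and width must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        lo, hi = self.sequence_length
        if not (1 <= lo <= hi):
            raise ValueError("sequence_length must be an increasing positive range")


def make_class_centers(spec: FixtureSpec) -> np.ndarray:
    """Seeded per-class center vectors, pairwise distinct.

    Standard-normal coordinates scaled by ``center_scale``: the expected
    inter-center distance is ``center_scale * sqrt(2 * width)``, so the
    default noise_sd of 0.05 sits far below the separation.
    """
    rng = np.random.Generator(np.random.PCG64(_stable_int(spec.seed, "centers")))
    centers = spec.center_scale * rng.standard_normal((len(spec.labels), spec.width))
    dists = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
    if np.any(dists[~np.eye(len(spec.labels), dtype=bool)] == 0):
        raise ValueError("degenerate centers; change the seed")
    return centers


def _stable_int(*parts) -> int:
    h = hashlib.blake2b("|".join(map(str, parts)).encode(), digest_size=8)
    return int.from_bytes(h.digest(), "little") % 2**63


# ---------------------------------------------------------------------------
# toy UniProt-dialect XML
# ---------------------------------------------------------------------------

@dataclass
class EntryDescriptor:
    """Blueprint for one toy XML entry."""

    accession: str
    sequence: str
    subunit_text: str = ""
    evidence_codes: list[str] = field(default_factory=list)
    ec_numbers: list[str] = field(default_factory=list)
    organism: str = ""
    protein_name: str = ""
    is_fragment: bool = False

    def validate(self) -> None:
        if not self.accession:
            raise ValueError("descriptor accession must be non-empty")
        bad = set(self.sequence) - SEQUENCE_ALPHABET
        if not self.sequence or bad:
            raise ValueError(f"descriptor sequence invalid for {self.accession}: {sorted(bad)}")
        for code in self.evidence_codes:
            if not _ECO_PATTERN.match(code):
                raise ValueError(f"descriptor evidence code {code!r} malformed")


def make_toy_xml(descriptors: Sequence[EntryDescriptor], namespaced: bool = True) -> str:
    """Well-formed UniProt-dialect XML that round-trips losslessly
    through the curation parser. Descriptors are validated before any
    output is produced."""
    for d in descriptors:
        d.validate()

    def q(tag: str) -> str:
        return f"{{{_NS}}}{tag}" if namespaced else tag

    nsmap = {None: _NS} if namespaced else None
    root = etree.Element(q("uniprot"), nsmap=nsmap)
    for d in descriptors:
        entry = etree.SubElement(root, q("entry"), dataset="Swiss-Prot")
        etree.SubElement(entry, q("accession")).text = d.accession
        protein = etree.SubElement(entry, q("protein"))
        rec = etree.SubElement(protein, q("recommendedName"))
        etree.SubElement(rec, q("fullName")).text = d.protein_name or d.accession
        for ec in d.ec_numbers:
            etree.SubElement(rec, q("ecNumber")).text = ec
        organism = etree.SubElement(entry, q("organism"))
        etree.SubElement(organism, q("name"), type="scientific").text = d.organism or "synthetic organism"
        if d.subunit_text:
            comment = etree.SubElement(entry, q("comment"), type="subunit")
            text = etree.SubElement(comment, q("text"))
            text.text = d.subunit_text
            if d.evidence_codes:
                keys = [str(i + 1) for i in range(len(d.evidence_codes))]
                text.set("evidence", " ".join(keys))
        for i, code in enumerate(d.evidence_codes):
            etree.SubElement(entry, q("evidence"), key=str(i + 1), type=code)
        seq_attrs = {"length": str(len(d.sequence))}
        if d.is_fragment:
            seq_attrs["fragment"] = "single"
        etree.SubElement(entry, q("sequence"), **seq_attrs).text = d.sequence
    return etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8").decode()


def random_descriptors(n: int, seed: int = 0) -> list[EntryDescriptor]:
    """Random but valid entry descriptors, e.g. for round-trip tests."""
    rng = np.random.Generator(np.random.PCG64(_stable_int(seed, "descriptors")))
    texts = [
        "", "Monomer.", "Homodimer.", "Homotetramer.",
        "Homodimer (By similarity).", "Homooctamer of 4 homodimers; disulfide-linked.",
        "Homodimer; can also form homotetramers.",
    ]
    out = []
    for i in range(n):
        length = int(rng.integers(20, 60))
        seq = "".join(rng.choice(list(_AMINO_ACIDS), size=length))
        evidence = ["ECO:0000250"] if rng.random() < 0.3 else (
            ["ECO:0000269"] if rng.random() < 0.5 else []
        )
        out.append(
            EntryDescriptor(
                accession=f"T{i:05d}",
                sequence=seq,
                subunit_text=str(rng.choice(texts)),
                evidence_codes=evidence,
                ec_numbers=[f"{int(rng.integers(1, 7))}.1.1.{int(rng.integers(1, 99))}"]
                if rng.random() < 0.7 else [],
                organism=str(rng.choice(["Escherichia coli", "Homo sapiens", "Mus musculus"])),
                is_fragment=bool(rng.random() < 0.1),
            )
        )
    return out


# ---------------------------------------------------------------------------
# class-conditional embeddings and sequences
# ---------------------------------------------------------------------------

def make_synthetic_embeddings(
    spec: FixtureSpec,
) -> tuple[list[tuple[PooledEmbedding, int]], np.ndarray]:
    """Pooled embeddings drawn class-conditionally around known centers.

    For each class c, ``n_per_class`` points ``center_c + N(0, noise_sd^2 I)``.
    Returns the labeled dataset plus the centers (the ground truth for
    nearest-centroid oracles). ``noise_sd = 0`` puts every point exactly
    on its class center.
    """
    centers = make_class_centers(spec)
    rng = np.random.Generator(np.random.PCG64(_stable_int(spec.seed, "embeddings")))
    dataset: list[tuple[PooledEmbedding, int]] = []
    for ci, label in enumerate(spec.labels):
        noise = spec.noise_sd * rng.standard_normal((spec.n_per_class, spec.width))
        for row in centers[ci] + noise:
            dataset.append((PooledEmbedding(row), label))
    return dataset, centers


def embeddings_as_arrays(
    dataset: Sequence[tuple[PooledEmbedding, int]]
) -> tuple[np.ndarray, np.ndarray]:
    X = np.vstack([emb.x for emb, _ in dataset])
    y = np.asarray([label for _, label in dataset], dtype=int)
    return X, y


def sequence_class_index(sequence: str, n_classes: int) -> int:
    """Deterministic hidden class of a synthetic sequence (stable hash)."""
    digest = hashlib.md5(sequence.encode()).digest()
    return int.from_bytes(digest[:8], "little") % n_classes


def make_synthetic_sequences(
    spec: FixtureSpec,
) -> tuple[list[tuple[str, str]], dict[str, int], SyntheticBackend]:
    """Random sequences with hidden class assignments plus the matching
    class-conditional backend.

    Returns ``(records, hidden_labels, backend)`` where records are
    ``(accession, sequence)`` pairs, hidden_labels maps accession -> NS
    label (balanced: exactly ``n_per_class`` per class), and the backend
    embeds each sequence near its class center so the end-to-end
    FASTA -> embed -> train -> predict pipeline can recover the labels.
    """
    centers = make_class_centers(spec)
    n_classes = len(spec.labels)
    backend = SyntheticBackend(
        width=spec.width,
        seed=spec.seed,
        noise_sd=spec.noise_sd,
        class_centers=centers,
        label_fn=lambda seq: sequence_class_index(seq, n_classes),
    )
    rng = np.random.Generator(np.random.PCG64(_stable_int(spec.seed, "sequences")))
    lo, hi = spec.sequence_length
    counts = [0] * n_classes
    records: list[tuple[str, str]] = []
    hidden: dict[str, int] = {}
    i = 0
    while min(counts) < spec.n_per_class:
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(list(_AMINO_ACIDS), size=length))
        ci = sequence_class_index(seq, n_classes)
        if counts[ci] >= spec.n_per_class:
            continue
        counts[ci] += 1
        accession = f"SYN{i:05d}"
        records.append((accession, seq))
        hidden[accession] = spec.labels[ci]
        i += 1
    return records, hidden, backend


def write_fasta_records(records: Sequence[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for accession, seq in records:
            fh.write(f">{accession}\n")
            for j in range(0, len(seq), 60):
                fh.write(seq[j : j + 60] + "\n")
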