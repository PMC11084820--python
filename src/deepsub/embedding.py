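"""Sequence -> embedding plumbing.

A protein language model maps an amino-acid sequence of length ``l`` to a
per-residue embedding matrix of shape ``l x n`` (``n`` = 1280 for the
ESM2 650M-parameter encoder). The classifier consumes a single pooled
vector per protein, obtained by collapsing the residue axis. Encoders
are pluggable behind :class:`EncoderBackend`; the deterministic
:class:`SyntheticBackend` makes the full pipeline runnable and testable
with no model download.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Protocol, runtime_checkable

import h5py
import numpy as np

from deepsub.curation import SEQUENCE_ALPHABET

ESM2_WIDTH = 1280
#: ESM2 positional context limit (tokens); longer sequences are truncated.
ESM2_MAX_LENGTH = 1022


@dataclass
class EmbeddingMatrix:
    """Per-residue embedding, one row per residue."""

    values: np.ndarray  # (l, n)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] < 1:
            raise ValueError(f"expected an l x n matrix with l >= 1, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("embedding matrix contains non-finite values")

    @property
    def l(self) -> int:  # noqa: E743 - domain name
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]


@dataclass
class PooledEmbedding:
    """The per-sequence vector x (1 x n) fed to the classifier."""

    x: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64).reshape(1, -1)
        if not np.all(np.isfinite(self.x)):
            raise ValueError("pooled embedding contains non-finite values")

    @property
    def width(self) -> int:
        return self.x.shape[1]


@runtime_checkable
class EncoderBackend(Protocol):
    """Contract for encoders: a deterministic map sequence -> matrix."""

    name: str
    width: int
    max_length: int

    def encode(self, sequence: str) -> np.ndarray:
        """Return the (l, width) per-residue embedding."""
        ...


def _mix(*ints: int) -> int:
    """Stable 64-bit hash of a tuple of integers (independent of PYTHONHASHSEED)."""
    h = hashlib.blake2b(digest_size=8)
    for v in ints:
        h.update(int(v).to_bytes(8, "little", signed=True))
    return int.from_bytes(h.digest(), "little")


class SyntheticBackend:
    """Deterministic stand-in encoder for tests and fixtures.

    Each residue vector is a seeded pseudo-random function of
    ``(residue, position)`` scaled by ``noise_sd``. When driven by the
    fixtures module the backend also adds a class-conditional center
    vector chosen by ``label_fn(sequence)``, so pooled embeddings form
    Gaussian-like clusters with known ground truth: as ``noise_sd -> 0``
    the pooled vector converges to its class center.
    """

    def __init__(
        self,
        width: int = ESM2_WIDTH,
        seed: int = 0,
        noise_sd: float = 1.0,
        class_centers: np.ndarray | None = None,
        label_fn: Callable[[str], int] | None = None,
        max_length: int = ESM2_MAX_LENGTH,
    ) -> None:
        self.name = f"synthetic-w{width}-s{seed}"
        self.width = int(width)
        self.seed = int(seed)
        self.noise_sd = float(noise_sd)
        self.max_length = int(max_length)
        if (class_centers is None) != (label_fn is None):
            raise ValueError("class_centers and label_fn must be given together")
        self.class_centers = None if class_centers is None else np.asarray(class_centers, float)
        if self.class_centers is not None and self.class_centers.shape[1] != self.width:
            raise ValueError("class_centers width does not match backend width")
        self.label_fn = label_fn

    def _residue_vector(self, residue: str, position: int) -> np.ndarray:
        rng = np.random.Generator(np.random.PCG64(_mix(self.seed, ord(residue), position) % 2**63))
        return rng.standard_normal(self.width)

    def encode(self, sequence: str) -> np.ndarray:
        rows = np.stack(
            [self._residue_vector(res, pos) for pos, res in enumerate(sequence)]
        )
        matrix = self.noise_sd * rows
        if self.class_centers is not None:
            cls = self.label_fn(sequence)  # type: ignore[misc]
            matrix = matrix + self.class_centers[cls]
        return matrix


class ESM2Backend:
    """ESM2 650M encoder (width 1280), available when the ``fair-esm``
    package and its weights are installed. Optional at install time."""

    name = "esm2_t33_650M_UR50D"
    width = ESM2_WIDTH
    max_length = ESM2_MAX_LENGTH

    def __init__(self) -> None:
        try:
            import esm  # type: ignore
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "the ESM2 backend requires the optional 'fair-esm' package; "
                "install it or use the synthetic backend"
            ) from exc
        self._model, self._alphabet = esm.pretrained.esm2_t33_650M_UR50D()  # pragma: no cover
        self._model.eval()  # pragma: no cover

    def encode(self, sequence: str) -> np.ndarray:  # pragma: no cover - needs weights
        import torch  # type: ignore

        converter = self._alphabet.get_batch_converter()
        _, _, tokens = converter([("query", sequence)])
        with torch.no_grad():
            out = self._model(tokens, repr_layers=[33])
        # strip begin/end tokens; rows correspond to residues
        return out["representations"][33][0, 1 : len(sequence) + 1].numpy()


def embed_sequence(sequence: str, backend: EncoderBackend) -> EmbeddingMatrix:
    """Embed one sequence through a backend, validating the alphabet and
    truncating (with a warning) beyond the backend's context limit."""
    if not sequence:
        raise ValueError("sequence must be non-empty")
    for pos, res in enumerate(sequence):
        if res.upper() not in SEQUENCE_ALPHABET:
            raise ValueError(f"illegal character {res!r} at position {pos}")
    seq = sequence.upper()
    if len(seq) > backend.max_length:
        warnings.warn(
            f"sequence length {len(seq)} exceeds backend limit "
            f"{backend.max_length}; truncating",
            stacklevel=2,
        )
        seq = seq[: backend.max_length]
    matrix = backend.encode(seq)
    if matrix.shape != (len(seq), backend.width):
        raise ValueError(
            f"backend returned shape {matrix.shape}, expected {(len(seq), backend.width)}"
        )
    return EmbeddingMatrix(matrix)


def pool(matrix: EmbeddingMatrix, method: str = "mean") -> PooledEmbedding:
    """Collapse the residue axis: l x n -> 1 x n.

    Mean pooling is the default (standard for protein-LM classifier
    heads); max pooling is available as a config option.
    """
    if method == "mean":
        return PooledEmbedding(matrix.values.mean(axis=0, keepdims=True))
    if method == "max":
        return PooledEmbedding(matrix.values.max(axis=0, keepdims=True))
    raise ValueError(f"unknown pooling method {method!r}")


@dataclass
class EmbeddingStore:
    """HDF5 store: one dataset per accession, pooled (1 x n) or raw (l x n),
    with backend name, width and pooling recorded as attributes."""

    path: Path
    backend_name: str = ""
    width: int = 0
    pooling: str = "mean"
    raw: bool = False
    _written: set = field(default_factory=set)

    def write(
        self,
        records: dict[str, str],
        backend: EncoderBackend,
        pooling: str = "mean",
        raw: bool = False,
        overwrite: bool = False,
    ) -> int:
        """Embed ``{accession: sequence}`` and store results.

        Existing datasets are kept unless ``overwrite``: the store is an
        embedding cache keyed by accession, so repeated runs are
        idempotent. Returns the number of newly written datasets.
        """
        n_new = 0
        with h5py.File(self.path, "a") as fh:
            fh.attrs["backend"] = backend.name
            fh.attrs["width"] = backend.width
            fh.attrs["pooling"] = "none" if raw else pooling
            for accession, sequence in records.items():
                if accession in fh:
                    if not overwrite:
                        continue
                    del fh[accession]
                matrix = embed_sequence(sequence, backend)
                data = matrix.values if raw else pool(matrix, pooling).x
                ds = fh.create_dataset(accession, data=data)
                ds.attrs["sequence_sha1"] = hashlib.sha1(sequence.encode()).hexdigest()
                n_new += 1
        return n_new

    def load(self) -> dict[str, np.ndarray]:
        with h5py.File(self.path, "r") as fh:
            return {key: np.asarray(fh[key]) for key in fh.keys()}

    def load_pooled(self) -> tuple[list[str], np.ndarray]:
        """Accessions plus an (N, width) matrix of pooled embeddings."""
        data = self.load()
        accessions = sorted(data)
        return accessions, np.vstack([data[a].reshape(1, -1) for a in accessions])
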