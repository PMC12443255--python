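"""Per-residue embedding backends.

A backend maps a validated peptide sequence to an L x d matrix with one row
per residue (special begin/end marker rows, if a backend emits them, are
stripped). The core package ships a deterministic mock backend so the whole
pipeline builds and tests offline; an adapter for a pretrained protein
language model (ESMC family, e.g. the 600M model with embedding width 1152)
is an optional extra that raises a capability error when the model stack is
not installed — never a silent fallback.

Sequence-level features are obtained by arithmetic mean pooling over the
residue rows. Mean pooling is linear, which makes the residue-level
attribution decomposition exact: the per-residue projection scores sum to
L times the pooled feature's contribution.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Protocol, Sequence

import numpy as np

__all__ = [
    "ResidueEmbedding",
    "EmbeddingBackend",
    "BackendUnavailableError",
    "MockBackend",
    "EsmcBackend",
    "mock_backend",
    "embed_residues",
    "pool_sequence",
    "write_embedding_cache",
    "read_embedding_cache",
    "write_embeddings_text",
]


class BackendUnavailableError(RuntimeError):
    """An optional embedding backend's dependencies are not installed."""


@dataclass
class ResidueEmbedding:
    """The L x d residue embedding matrix of one peptide."""

    sequence: str
    matrix: np.ndarray
    backend: str

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.sequence):
            raise ValueError(
                f"matrix must have one row per residue: "
                f"{self.matrix.shape[0]} rows for length {len(self.sequence)}"
            )

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]


class EmbeddingBackend(Protocol):
    name: str
    dim: int

    def embed(self, sequence: str) -> np.ndarray:  # L x d, no special tokens
        ...


class MockBackend:
    """Deterministic offline embedding backend.

    Row i for residue letter ``a`` is a pseudo-random d-vector keyed by
    ``(a, i mod period)``, derived via BLAKE2 from the backend seed, so the
    same letter at nearby positions receives related (here: identical) rows
    and the whole mapping is a pure function of ``(dim, seed, period)``.
    Default dim mirrors the 1152-wide embedding of the 600M-parameter
    language model the toolkit targets.
    """

    def __init__(self, dim: int = 1152, seed: int = 0, period: int = 8) -> None:
        if dim < 1:
            raise ValueError("dim must be >= 1")
        if period < 1:
            raise ValueError("period must be >= 1")
        self.dim = dim
        self.seed = seed
        self.period = period
        self.name = f"mock(dim={dim},seed={seed},period={period})"
        self._cache: dict[tuple[str, int], np.ndarray] = {}

    def _row(self, letter: str, phase: int) -> np.ndarray:
        key = (letter, phase)
        if key not in self._cache:
            digest = hashlib.blake2b(
                f"{self.seed}:{letter}:{phase}".encode(), digest_size=4
            ).digest()
            sub_seed = int.from_bytes(digest, "big") % (2**31)
            rng = np.random.default_rng(sub_seed)
            self._cache[key] = rng.standard_normal(self.dim)
        return self._cache[key]

    def embed(self, sequence: str) -> np.ndarray:
        return np.vstack([self._row(c, i % self.period) for i, c in enumerate(sequence)])


def mock_backend(dim: int = 1152, seed: int = 0, period: int = 8) -> MockBackend:
    """Construct the deterministic mock backend (pure function of its args)."""
    return MockBackend(dim=dim, seed=seed, period=period)


class EsmcBackend:
    """Adapter for the pretrained ESMC protein language model.

    Requires the external ``esm`` model stack (and its weights); the core
    package never depends on it. The model name ("esmc_600m", ...) is a
    plain configuration string passed through to the loader. Marker rows
    added around the sequence are stripped so the contract (one row per
    residue) holds for every backend.
    """

    def __init__(self, model_name: str = "esmc_600m", device: str = "cpu") -> None:
        try:
            from esm.models.esmc import ESMC  # type: ignore
            from esm.sdk.api import ESMProtein, LogitsConfig  # type: ignore
        except ImportError as exc:  # pragma: no cover - optional extra
            raise BackendUnavailableError(
                "the optional 'esm' model stack is not installed; "
                "use MockBackend for offline work"
            ) from exc
        self._ESMProtein = ESMProtein
        self._LogitsConfig = LogitsConfig
        self._model = ESMC.from_pretrained(model_name).to(device).eval()
        self.name = f"esmc({model_name})"
        self.dim = -1  # set on first embed

    def embed(self, sequence: str) -> np.ndarray:  # pragma: no cover - optional extra
        protein = self._ESMProtein(sequence=sequence)
        tensor = self._model.encode(protein)
        out = self._model.logits(
            tensor, self._LogitsConfig(sequence=True, return_embeddings=True)
        )
        emb = np.asarray(out.embeddings.squeeze(0).detach().cpu().numpy(), dtype=float)
        # strip begin/end marker rows
        if emb.shape[0] == len(sequence) + 2:
            emb = emb[1:-1]
        self.dim = emb.shape[1]
        return emb


def embed_residues(backend: EmbeddingBackend, sequence: str) -> ResidueEmbedding:
    """Embed one validated sequence; the result has one row per residue."""
    if not sequence:
        raise ValueError("cannot embed an empty sequence")
    matrix = np.asarray(backend.embed(sequence), dtype=float)
    if matrix.shape[0] != len(sequence):
        raise ValueError(
            f"backend {backend.name!r} returned {matrix.shape[0]} rows "
            f"for a length-{len(sequence)} sequence"
        )
    return ResidueEmbedding(sequence=sequence, matrix=matrix, backend=backend.name)


def pool_sequence(embedding: ResidueEmbedding) -> np.ndarray:
    """Arithmetic mean over residue rows -> one d-vector per peptide."""
    return embedding.matrix.mean(axis=0)


# ---------------------------------------------------------------------------
# Batch cache
# ---------------------------------------------------------------------------

def write_embedding_cache(
    path: str | Path,
    ids: Sequence[str],
    embeddings: Sequence[ResidueEmbedding],
) -> None:
    """Write a batch of residue embeddings to one ``.npz`` cache file."""
    if len(ids) != len(embeddings):
        raise ValueError("ids and embeddings length mismatch")
    meta = {
        "ids": list(ids),
        "sequences": [e.sequence for e in embeddings],
        "backends": [e.backend for e in embeddings],
    }
    arrays = {f"m{i}": e.matrix for i, e in enumerate(embeddings)}
    np.savez(path, meta=json.dumps(meta), **arrays)


def read_embedding_cache(path: str | Path) -> tuple[list[str], list[ResidueEmbedding]]:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        embeddings = [
            ResidueEmbedding(sequence=seq, matrix=data[f"m{i}"], backend=bk)
            for i, (seq, bk) in enumerate(zip(meta["sequences"], meta["backends"]))
        ]
    return meta["ids"], embeddings


def write_embeddings_text(
    path: str | Path,
    ids: Sequence[str],
    embeddings: Iterable[ResidueEmbedding],
) -> None:
    """Plain-text interchange fallback: one tab-separated row per residue
    (id, position, residue letter, then the d embedding values)."""
    with open(path, "w") as fh:
        for ident, emb in zip(ids, embeddings):
            for pos, letter in enumerate(emb.sequence):
                vals = "\t".join(f"{v:.8g}" for v in emb.matrix[pos])
                fh.write(f"{ident}\t{pos}\t{letter}\t{vals}\n")
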