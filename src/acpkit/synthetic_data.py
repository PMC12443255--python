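"""Synthetic fixtures emulating the statistical structure the pipeline assumes.

Two generators cover the toolkit's needs offline:

* :func:`make_blobs` — a two-class Gaussian feature matrix with tunable
  imbalance and overlap. Defaults mirror the reference training imbalance
  of 487 minority (ACP) versus 1,479 majority (non-ACP) rows, so the
  headline resampling behaviour runs at realistic sizes.
* :func:`make_sequences` — random peptides over the 20-letter alphabet
  with lengths in the functional band [5, 50]; positives are enriched in a
  designated residue set (default K, L, F, G — the residues repeatedly
  implicated in membrane binding and cytotoxicity of anticancer peptides)
  so attribution recovery is testable without real data.

Both are pure functions of their spec (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet

import numpy as np

from .sampling import LabeledMatrix
from .sequence_io import AMINO_ACIDS, PeptideRecord

__all__ = ["BlobSpec", "SequenceSpec", "make_blobs", "make_sequences"]


@dataclass(frozen=True)
class BlobSpec:
    """Two-class Gaussian blob specification.

    ``class_separation`` is the Euclidean distance between the class means
    (along the first feature axis); ``within_class_spread`` the isotropic
    per-coordinate standard deviation.
    """

    n_minority: int = 487
    n_majority: int = 1479
    dim: int = 16
    class_separation: float = 2.0
    within_class_spread: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_minority < 2 or self.n_majority < 2:
            raise ValueError("both class counts must be >= 2")
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.within_class_spread <= 0:
            raise ValueError("within_class_spread must be > 0")


@dataclass(frozen=True)
class SequenceSpec:
    """Planted-signal peptide generator specification.

    Negatives are i.i.d. uniform over the alphabet; positives upweight the
    ``enriched_residues`` by ``enrichment_factor`` before renormalizing.
    """

    n_pos: int = 500
    n_neg: int = 500
    length_range: tuple[int, int] = (5, 50)
    enriched_residues: FrozenSet[str] = frozenset("KLFG")
    enrichment_factor: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (5 <= lo <= hi <= 50):
            raise ValueError("length_range must lie within [5, 50]")
        if self.enrichment_factor <= 1 and self.enrichment_factor != 1:
            raise ValueError("enrichment_factor must be >= 1")
        bad = set(self.enriched_residues) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"non-canonical enriched residues: {sorted(bad)}")


def make_blobs(spec: BlobSpec = BlobSpec()) -> LabeledMatrix:
    """Two seeded Gaussian clusters: minority (label 1) centred at
    ``class_separation`` along axis 0, majority (label 0) at the origin."""
    rng = np.random.default_rng(spec.seed)
    offset = np.zeros(spec.dim)
    offset[0] = spec.class_separation
    X_min = rng.normal(0.0, spec.within_class_spread, (spec.n_minority, spec.dim)) + offset
    X_maj = rng.normal(0.0, spec.within_class_spread, (spec.n_majority, spec.dim))
    X = np.vstack([X_maj, X_min])
    y = np.concatenate([np.zeros(spec.n_majority, dtype=int), np.ones(spec.n_minority, dtype=int)])
    return LabeledMatrix(X, y)


def make_sequences(spec: SequenceSpec = SequenceSpec()) -> list[PeptideRecord]:
    """Generate labelled peptides with composition-planted positive signal.

    Every output passes alphabet validation and the [5, 50] length filter
    unchanged; records are ordered positives first, then negatives.
    """
    rng = np.random.default_rng(spec.seed)
    letters = np.array(list(AMINO_ACIDS))
    uniform = np.full(20, 1 / 20)
    enriched = np.array(
        [spec.enrichment_factor if a in spec.enriched_residues else 1.0 for a in AMINO_ACIDS]
    )
    enriched = enriched / enriched.sum()

    lo, hi = spec.length_range
    records: list[PeptideRecord] = []
    for label, n, probs, prefix in (
        (1, spec.n_pos, enriched, "pos"),
        (0, spec.n_neg, uniform, "neg"),
    ):
        for i in range(n):
            length = int(rng.integers(lo, hi + 1))
            seq = "".join(rng.choice(letters, size=length, p=probs))
            records.append(PeptideRecord(id=f"{prefix}_{i:04d}", sequence=seq, label=label))
    return records
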