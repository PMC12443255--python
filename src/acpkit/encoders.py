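"""Classical hand-crafted peptide feature encoders.

These are the frequency / physicochemical baselines against which learned
embeddings are compared: amino-acid composition (AAC, 20-d), dipeptide
composition (DC, 400-d), Chou's pseudo amino-acid composition (PAAC,
(20+lambda)-d), and the composition/transition/distribution descriptors
(CTD) over three-class physicochemical groupings.

Feature ordering is fixed and alphabetical over ``ACDEFGHIKLMNPQRSTVWY`` so
encoded matrices are bit-reproducible across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .sequence_io import AMINO_ACIDS, PeptideRecord

__all__ = [
    "FeatureMatrix",
    "encode_aac",
    "encode_dc",
    "encode_paac",
    "encode_ctd",
    "CtdResult",
    "CTD_PROPERTIES",
    "PAAC_PROPERTY_SCALES",
    "aac_feature_names",
    "dc_feature_names",
    "encode_dataset",
]

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


# ---------------------------------------------------------------------------
# Feature matrix container
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """An n x d feature matrix with names, row ids and provenance."""

    values: np.ndarray
    feature_names: list[str]
    row_ids: list[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        n, d = self.values.shape
        if len(self.row_ids) != n or len(self.feature_names) != d:
            raise ValueError("names/ids do not match matrix shape")
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains missing values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.feature_names)

    def write_csv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "id"
        df.to_csv(path)

    @classmethod
    def read_csv(cls, path: str | Path, provenance: str = "") -> "FeatureMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(
            values=df.to_numpy(dtype=float),
            feature_names=[str(c) for c in df.columns],
            row_ids=[str(i) for i in df.index],
            provenance=provenance,
        )


def aac_feature_names() -> list[str]:
    return [f"AAC_{a}" for a in AMINO_ACIDS]


def dc_feature_names() -> list[str]:
    return [f"DC_{a}{b}" for a in AMINO_ACIDS for b in AMINO_ACIDS]


# ---------------------------------------------------------------------------
# AAC / DC
# ---------------------------------------------------------------------------

def encode_aac(sequence: str) -> np.ndarray:
    """Amino-acid composition: relative frequency of each of the 20 letters."""
    if not sequence:
        raise ValueError("cannot encode an empty sequence")
    vec = np.zeros(20)
    for c in sequence:
        vec[_AA_INDEX[c]] += 1.0
    return vec / len(sequence)


def encode_dc(sequence: str) -> np.ndarray:
    """Dipeptide composition: frequency of each adjacent residue pair,
    row-major (first letter, second letter) over the alphabetical alphabet."""
    if len(sequence) < 2:
        raise ValueError("dipeptide composition needs length >= 2")
    vec = np.zeros(400)
    for a, b in zip(sequence, sequence[1:]):
        vec[_AA_INDEX[a] * 20 + _AA_INDEX[b]] += 1.0
    return vec / (len(sequence) - 1)


# ---------------------------------------------------------------------------
# PAAC
# ---------------------------------------------------------------------------

# Standard Chou-style property scales: hydrophobicity, hydrophilicity
# (Hopp-Woods) and side-chain mass, keyed by residue letter.
PAAC_PROPERTY_SCALES: dict[str, dict[str, float]] = {
    "hydrophobicity": {
        "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19,
        "G": 0.48, "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06,
        "M": 0.64, "N": -0.78, "P": 0.12, "Q": -0.85, "R": -2.53,
        "S": -0.18, "T": -0.05, "V": 1.08, "W": 0.81, "Y": 0.26,
    },
    "hydrophilicity": {
        "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5,
        "G": 0.0, "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8,
        "M": -1.3, "N": 0.2, "P": 0.0, "Q": 0.2, "R": 3.0,
        "S": 0.3, "T": -0.4, "V": -1.5, "W": -3.4, "Y": -2.3,
    },
    "side_chain_mass": {
        "A": 15.0, "C": 47.0, "D": 59.0, "E": 73.0, "F": 91.0,
        "G": 1.0, "H": 82.0, "I": 57.0, "K": 73.0, "L": 57.0,
        "M": 75.0, "N": 58.0, "P": 42.0, "Q": 72.0, "R": 101.0,
        "S": 31.0, "T": 45.0, "V": 43.0, "W": 130.0, "Y": 107.0,
    },
}


def _standardized_scales() -> np.ndarray:
    """Each scale standardized to zero mean / unit (population) std over the
    20 letters; shape (n_scales, 20) in alphabetical letter order."""
    rows = []
    for scale in PAAC_PROPERTY_SCALES.values():
        vals = np.array([scale[a] for a in AMINO_ACIDS])
        rows.append((vals - vals.mean()) / np.sqrt(((vals - vals.mean()) ** 2).mean()))
    return np.vstack(rows)


def encode_paac(sequence: str, lam: int = 4, w: float = 0.05) -> np.ndarray:
    """Pseudo amino-acid composition (Chou 2001 style).

    The first 20 components carry composition, the next *lam* components
    carry tier-correlation factors over the standardized hydrophobicity /
    hydrophilicity / side-chain-mass scales; the full vector sums to 1.

    Parameters
    ----------
    lam:
        Number of sequence-order correlation tiers; must be < len(sequence).
        Default 4, the largest value every length-5 peptide supports.
    w:
        Weight of the sequence-order part relative to composition (> 0).
    """
    L = len(sequence)
    if lam < 1:
        raise ValueError("lam must be >= 1")
    if lam >= L:
        raise ValueError(f"lam={lam} must be smaller than sequence length {L}")
    if w <= 0:
        raise ValueError("w must be positive")

    scales = _standardized_scales()  # (3, 20)
    idx = np.array([_AA_INDEX[c] for c in sequence])
    props = scales[:, idx]  # (3, L)

    theta = np.empty(lam)
    for t in range(1, lam + 1):
        diffs = props[:, : L - t] - props[:, t:]
        # Theta(i, i+t) averaged over scales, then over positions
        theta[t - 1] = np.mean(np.mean(diffs**2, axis=0))

    freqs = np.bincount(idx, minlength=20) / L
    denom = freqs.sum() + w * theta.sum()
    return np.concatenate([freqs, w * theta]) / denom


# ---------------------------------------------------------------------------
# CTD
# ---------------------------------------------------------------------------

# Three-class physicochemical groupings (Dubchak-style); each property
# partitions the 20-letter alphabet into exactly three classes.
CTD_PROPERTIES: dict[str, tuple[str, str, str]] = {
    "hydrophobicity": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "vdw_volume": ("GASTPDC", "NVEQIL", "MHKFRYW"),
    "polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    "charge": ("KR", "ANCQGHILMFPSTWYV", "DE"),
    "secondary_structure": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    "solvent_accessibility": ("ALFCGIVW", "RKQEND", "MSPTHY"),
}


@dataclass
class CtdResult:
    """Composition / transition / distribution blocks per property.

    composition: (P, 3) class fractions; transition: (P, 3) adjacent
    cross-class transition rates for class pairs (1,2), (1,3), (2,3);
    distribution: (P, 15) first/25%/50%/75%/last occurrence positions of
    each class as fractions of sequence length (0 where a class is absent).
    """

    properties: list[str]
    composition: np.ndarray
    transition: np.ndarray
    distribution: np.ndarray

    def as_vector(self) -> np.ndarray:
        return np.concatenate(
            [self.composition.ravel(), self.transition.ravel(), self.distribution.ravel()]
        )

    def feature_names(self) -> list[str]:
        names: list[str] = []
        for p in self.properties:
            names += [f"CTDC_{p}_g{g}" for g in (1, 2, 3)]
        for p in self.properties:
            names += [f"CTDT_{p}_{a}{b}" for a, b in ((1, 2), (1, 3), (2, 3))]
        for p in self.properties:
            for g in (1, 2, 3):
                names += [f"CTDD_{p}_g{g}_p{q}" for q in (0, 25, 50, 75, 100)]
        return names


def _class_map(groups: tuple[str, str, str]) -> dict[str, int]:
    joined = "".join(groups)
    if sorted(joined) != sorted(AMINO_ACIDS):
        raise ValueError("grouping must partition the 20-letter alphabet into 3 classes")
    return {c: g for g, letters in enumerate(groups) for c in letters}


def encode_ctd(
    sequence: str,
    groups: Mapping[str, tuple[str, str, str]] | None = None,
) -> CtdResult:
    """Composition/transition/distribution descriptors.

    Default property set: the seven standard physicochemical properties in
    :data:`CTD_PROPERTIES` (21 + 21 + 105 = 147 dimensions). The property
    table is configurable; each entry must partition the alphabet into
    three classes.
    """
    L = len(sequence)
    if L < 2:
        raise ValueError("CTD needs length >= 2")
    groups = dict(groups) if groups is not None else dict(CTD_PROPERTIES)
    names = list(groups)
    P = len(names)
    comp = np.zeros((P, 3))
    trans = np.zeros((P, 3))
    dist = np.zeros((P, 15))
    for pi, prop in enumerate(names):
        cmap = _class_map(groups[prop])
        classes = np.array([cmap[c] for c in sequence])
        for g in range(3):
            comp[pi, g] = np.mean(classes == g)
        pairs = {(0, 1): 0, (0, 2): 1, (1, 2): 2}
        for a, b in zip(classes, classes[1:]):
            if a != b:
                trans[pi, pairs[(min(a, b), max(a, b))]] += 1.0
        trans[pi] /= L - 1
        for g in range(3):
            pos = np.flatnonzero(classes == g) + 1  # 1-based
            n = len(pos)
            if n == 0:
                continue  # absent class: positions stay 0
            ranks = [1, max(1, ceil(0.25 * n)), max(1, ceil(0.5 * n)),
                     max(1, ceil(0.75 * n)), n]
            dist[pi, g * 5: g * 5 + 5] = pos[np.array(ranks) - 1] / L
    return CtdResult(names, comp, trans, dist)


# ---------------------------------------------------------------------------
# Dataset-level encoding
# ---------------------------------------------------------------------------

_ENCODERS: dict[str, Callable[[str], np.ndarray]] = {
    "aac": encode_aac,
    "dc": encode_dc,
    "paac": lambda s: encode_paac(s),
    "ctd": lambda s: encode_ctd(s).as_vector(),
}


def encode_dataset(records: Sequence[PeptideRecord], encoder: str = "aac") -> FeatureMatrix:
    """Encode a batch of validated records into a :class:`FeatureMatrix`."""
    if encoder not in _ENCODERS:
        raise ValueError(f"unknown encoder {encoder!r}; choose from {sorted(_ENCODERS)}")
    fn = _ENCODERS[encoder]
    rows = [fn(r.sequence) for r in records]
    if encoder == "aac":
        names = aac_feature_names()
    elif encoder == "dc":
        names = dc_feature_names()
    elif encoder == "paac":
        names = [f"PAAC_{a}" for a in AMINO_ACIDS] + [f"PAAC_theta{t}" for t in range(1, 5)]
    else:
        names = encode_ctd(records[0].sequence).feature_names()
    return FeatureMatrix(
        values=np.vstack(rows),
        feature_names=names,
        row_ids=[r.id for r in records],
        provenance=encoder,
    )
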