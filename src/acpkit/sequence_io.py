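"""Reading, validation and filtering of peptide sequence data.

Peptides are short chains over the 20 canonical amino-acid letters; the
toolkit's working range is 5-50 residues, the length band characteristic of
most functional anticancer peptides. Binary activity labels (1 = ACP,
0 = non-ACP) travel either in a ``|label=0/1`` suffix on the FASTA header
token or in a separate two-column delimited file of ``id<TAB>label`` pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AMINO_ACIDS",
    "PeptideRecord",
    "FastaParseError",
    "AlphabetError",
    "read_fasta",
    "write_fasta",
    "read_label_table",
    "write_label_table",
    "validate_alphabet",
    "filter_by_length",
]

logger = logging.getLogger(__name__)

#: The 20 canonical amino-acid one-letter codes, alphabetically ordered.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

_LABEL_TAG = "|label="


class FastaParseError(ValueError):
    """Raised for structurally malformed FASTA input."""


class AlphabetError(ValueError):
    """Raised when a sequence contains a non-canonical residue letter."""


@dataclass(frozen=True)
class PeptideRecord:
    """One identified peptide with an optional binary activity label."""

    id: str
    sequence: str
    label: Optional[int] = None

    def __len__(self) -> int:
        return len(self.sequence)


def _scan_fasta_structure(path: Path) -> None:
    """Pre-scan raising :class:`FastaParseError` with a line number.

    Two malformations are rejected: non-blank text before the first header,
    and a header immediately followed by another header or end-of-file
    (an entry with an empty sequence).
    """
    header_line: int | None = None
    saw_seq = False
    seen_any_header = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if seen_any_header and not saw_seq:
                    raise FastaParseError(
                        f"{path}: record starting at line {header_line} has an "
                        f"empty sequence"
                    )
                header_line = lineno
                seen_any_header = True
                saw_seq = False
            else:
                if not seen_any_header:
                    raise FastaParseError(
                        f"{path}: line {lineno}: sequence data before the "
                        f"first '>' header"
                    )
                saw_seq = True
    if seen_any_header and not saw_seq:
        raise FastaParseError(
            f"{path}: record starting at line {header_line} has an empty sequence"
        )


def _split_label_suffix(token: str) -> tuple[str, Optional[int]]:
    if _LABEL_TAG in token:
        ident, _, raw = token.rpartition(_LABEL_TAG)
        if raw in {"0", "1"}:
            return ident, int(raw)
    return token, None


def read_fasta(path: str | Path, labels: Optional[str | Path] = None) -> list[PeptideRecord]:
    """Read peptide records from a FASTA file, order preserved.

    The header token before the first whitespace becomes the record id. A
    ``|label=0`` / ``|label=1`` suffix on that token is parsed into the
    record's label; alternatively *labels* may point at a two-column
    delimited file mapping ids to labels (which overrides the suffix).
    Sequences are uppercased; alphabet validation is a separate step
    (:func:`validate_alphabet`).
    """
    path = Path(path)
    _scan_fasta_structure(path)
    label_map = read_label_table(labels) if labels is not None else {}
    records: list[PeptideRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ident, suffix_label = _split_label_suffix(rec.id)
        label = label_map.get(ident, suffix_label)
        records.append(PeptideRecord(id=ident, sequence=str(rec.seq).upper(), label=label))
    return records


def write_fasta(
    records: Iterable[PeptideRecord],
    path: str | Path,
    label_style: Literal["suffix", "none"] = "suffix",
) -> None:
    """Write records as FASTA; labels go into a ``|label=`` header suffix
    unless ``label_style="none"``."""
    seq_records = []
    for rec in records:
        ident = rec.id
        if label_style == "suffix" and rec.label is not None:
            ident = f"{rec.id}{_LABEL_TAG}{rec.label}"
        seq_records.append(SeqRecord(Seq(rec.sequence), id=ident, description=""))
    SeqIO.write(seq_records, str(path), "fasta")


def read_label_table(path: str | Path) -> dict[str, int]:
    """Read a two-column (id, label) delimited file; tab or comma separated."""
    mapping: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 'id<sep>label'")
            ident, label = parts[0].strip(), parts[1].strip()
            if label not in {"0", "1"}:
                raise ValueError(f"{path}: line {lineno}: label must be 0 or 1, got {label!r}")
            mapping[ident] = int(label)
    return mapping


def write_label_table(records: Iterable[PeptideRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if rec.label is not None:
                fh.write(f"{rec.id}\t{rec.label}\n")


def validate_alphabet(
    records: Sequence[PeptideRecord],
    policy: Literal["reject", "drop"] = "reject",
) -> list[PeptideRecord]:
    """Enforce the 20-letter canonical alphabet.

    ``policy="reject"`` raises :class:`AlphabetError` on the first
    non-canonical letter (X, B, Z, U, O, ``*``, gap characters, ...);
    ``policy="drop"`` removes offending records, logging how many were
    dropped. Sequences are uppercased before checking. An empty sequence is
    always invalid.
    """
    if policy not in {"reject", "drop"}:
        raise ValueError(f"unknown policy {policy!r}")
    kept: list[PeptideRecord] = []
    dropped = 0
    for rec in records:
        seq = rec.sequence.upper()
        bad = next((c for c in seq if c not in _AA_SET), None)
        if not seq:
            bad = "<empty>"
        if bad is not None:
            if policy == "reject":
                raise AlphabetError(
                    f"record {rec.id!r}: non-canonical residue {bad!r}"
                )
            dropped += 1
            continue
        kept.append(rec if seq == rec.sequence else PeptideRecord(rec.id, seq, rec.label))
    if dropped:
        logger.info("validate_alphabet: dropped %d record(s)", dropped)
    return kept


def filter_by_length(
    records: Sequence[PeptideRecord],
    min_len: int = 5,
    max_len: int = 50,
) -> list[PeptideRecord]:
    """Retain records with ``min_len <= length <= max_len`` (inclusive),
    order preserved. Defaults bracket the functional-peptide range."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if max_len < min_len:
        raise ValueError("max_len must be >= min_len")
    return [r for r in records if min_len <= len(r) <= max_len]
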