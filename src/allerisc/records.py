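"""Core record types shared across the package.

The analysis works on protein sequences over the standard 20-letter amino
acid alphabet.  ``X`` (unknown residue) is tolerated but flagged, because
substitution-matrix lookups must stay total; other ambiguity codes (B, Z, U,
J, O) are rejected outright.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

AA20 = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AA20 + "X"
_ALPHABET_SET = frozenset(ALPHABET)

CLUSTER_LABELS = ("I", "II", "III", "IV")


class SequenceAlphabetError(ValueError):
    """Raised when a sequence contains a character outside the allowed alphabet."""

    def __init__(self, record_id: str, position: int, char: str):
        self.record_id = record_id
        self.position = position  # 1-based, as users read FASTA
        self.char = char
        super().__init__(
            f"illegal residue {char!r} in record {record_id!r} at position {position}"
        )


def validate_sequence(sequence: str, record_id: str = "<anonymous>") -> None:
    """Check that *sequence* is non-empty, uppercase, and drawn from the
    20-letter amino acid alphabet plus X.  Raises :class:`SequenceAlphabetError`
    naming the first offending position (1-based)."""
    if not sequence:
        raise ValueError(f"record {record_id!r} has an empty sequence")
    for i, ch in enumerate(sequence):
        if ch not in _ALPHABET_SET:
            raise SequenceAlphabetError(record_id, i + 1, ch)


@dataclass
class ProteinRecord:
    """One allergen (or synthetic) protein sequence.

    ``id`` is the accession, ``label`` a short display name such as
    ``kiwi_D8``, ``cluster`` an optional phylogroup label.  Catalog entries
    are metadata-only and carry ``sequence == ""``; any record that enters
    alignment or motif search must have a validated non-empty sequence.
    """

    id: str
    sequence: str = ""
    label: Optional[str] = None
    species: Optional[str] = None
    cluster: Optional[str] = None

    @property
    def has_ambiguous(self) -> bool:
        """True if the sequence contains the wildcard residue X."""
        return "X" in self.sequence

    @property
    def display_id(self) -> str:
        return f"{self.id}_{self.label}" if self.label else self.id

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Table1Row:
    """One row of the packaged transmembrane / signal-peptide summary table.

    Values are stored exactly as printed in the source table; no
    normalisation or cross-column consistency repair is applied.
    """

    cluster: str
    protein_id: str
    length: int
    n_predicted_tmh: int
    exp_aa_in_tmh: float
    exp_aa_first60: float
    prob_n_in: float
    signal_length: int
    signal_peptide: bool
    sp_probability: float
    anchor_probability: float

    @property
    def accession(self) -> str:
        """Accession parsed from the printed protein id (``sp|`` prefix stripped)."""
        from .fasta import split_header

        acc, _ = split_header(self.protein_id)
        return acc
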