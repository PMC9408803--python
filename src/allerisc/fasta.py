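"""FASTA input/output.

Parsing is delegated to :mod:`Bio.SeqIO`; this module adds strict alphabet
validation and the ``accession_label`` header convention used by the packaged
allergen catalog (e.g. ``CAM31909.1_kiwi_D8`` -> accession ``CAM31909.1``,
label ``kiwi_D8``).  Headers that do not look like an accession followed by a
label are kept whole as the record id.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, List, Optional, Tuple, Union

from Bio import SeqIO

from .records import ProteinRecord, validate_sequence

# Accession shapes seen in the catalog: RefSeq (XP_004296886.1), GenBank
# (CAM31909.1, AAB82772.2), versioned UniProt (P85524.1), bare UniProt
# (M5X16, G1UH28).  A leading "sp|" database tag is stripped.
_ACCESSION = (
    r"[A-Z]{2,3}_\d+\.\d+"  # RefSeq
    r"|[A-Z]{2,4}\d+\.\d+"  # GenBank protein
    r"|[A-Z]\d[A-Z0-9]{3,8}\.\d+"  # versioned UniProt
    r"|[A-Z]\d[A-Z0-9]{3,8}"  # bare UniProt
)
_HEADER_RE = re.compile(rf"^(?:sp\|)?({_ACCESSION})_(.+)$")


def split_header(header: str) -> Tuple[str, Optional[str]]:
    """Split a FASTA header into ``(accession, label)``.

    Returns ``(header, None)`` when the header does not match the
    ``accession_label`` pattern.  A leading ``sp|`` tag is dropped from the
    accession but does not affect the label.
    """
    m = _HEADER_RE.match(header)
    if m:
        return m.group(1), m.group(2)
    return header.removeprefix("sp|"), None


def read_fasta(path: Union[str, Path]) -> List[ProteinRecord]:
    """Read protein records from a FASTA file.

    Sequences are uppercased and validated against the 20-letter alphabet
    plus X; the first illegal character raises an error naming the record and
    1-based position.  An empty file (no entries) is an error.
    """
    path = Path(path)
    records: List[ProteinRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        validate_sequence(seq, entry.id)
        accession, label = split_header(entry.id)
        records.append(ProteinRecord(id=accession, label=label, sequence=seq))
    if not records:
        raise ValueError(f"no FASTA entries found in {path}")
    return records


def write_fasta(
    records: Iterable[ProteinRecord], path: Union[str, Path], width: int = 60
) -> None:
    """Write records as FASTA, wrapping sequence lines at *width* columns.

    Headers are emitted as ``accession_label`` when a label is present, so
    that :func:`read_fasta` round-trips id, label, and sequence.
    """
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            validate_sequence(rec.sequence, rec.id)
            fh.write(f">{rec.display_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")
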