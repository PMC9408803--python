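"""Pairwise global protein alignment with affine gap penalties.

Supplies the percent identity (I) and percent similarity (S) that feed the
A-RISC cross-reactivity index.  The underlying optimal-alignment engine is
Biopython's :class:`Bio.Align.PairwiseAligner`; this module fixes the scoring
dialect and the column bookkeeping.

Scoring dialect
---------------
* substitution matrix: BLOSUM62 by default (any matrix loadable by
  :mod:`Bio.Align.substitution_matrices`, or an NCBI-format matrix file);
* affine gaps: a gap of length k costs ``gap_open + (k - 1) * gap_extend``
  (defaults 10 and 0.5);
* end gaps are penalised (true global alignment); ``end_gaps=False`` gives a
  semi-global variant with free terminal gaps, useful when one homolog is
  substantially shorter.

Column classification
---------------------
Each alignment column is *identical* (same residue), *similar-only*
(different residues with a positive substitution score — or sharing a
conservation group when ``similar_rule="groups"``), *dissimilar*, or a *gap*
column.  By default percentages use all alignment columns as denominator
(gap columns count against both I and S); ``denominator`` can instead be
``"aligned"`` (gapless columns only) or ``"shorter"`` (length of the shorter
input).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

from Bio import Align
from Bio.Align import substitution_matrices

#: ClustalW "strong" conservation groups; used when similar_rule="groups".
SIMILARITY_GROUPS = (
    "STA",
    "NEQK",
    "NHQK",
    "NDEQ",
    "QHRK",
    "MILV",
    "MILF",
    "HY",
    "FYW",
)

_DENOMINATORS = ("columns", "aligned", "shorter")
_SIMILAR_RULES = ("matrix_positive", "groups")


@dataclass
class AlignParams:
    """Alignment configuration; defaults follow the most common dialect for
    published percent identity/similarity figures."""

    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    end_gaps: bool = True
    denominator: str = "columns"
    similar_rule: str = "matrix_positive"

    def __post_init__(self):
        if not (self.gap_open >= self.gap_extend > 0):
            raise ValueError("require gap_open >= gap_extend > 0")
        if self.denominator not in _DENOMINATORS:
            raise ValueError(f"denominator must be one of {_DENOMINATORS}")
        if self.similar_rule not in _SIMILAR_RULES:
            raise ValueError(f"similar_rule must be one of {_SIMILAR_RULES}")

    def load_matrix(self):
        """Resolve ``matrix_name`` to a substitution matrix.  Names are looked
        up among Biopython's packaged matrices; a path to an NCBI-format
        matrix file is also accepted."""
        if Path(self.matrix_name).is_file():
            return substitution_matrices.read(self.matrix_name)
        try:
            return substitution_matrices.load(self.matrix_name)
        except FileNotFoundError as exc:
            raise ValueError(f"unknown substitution matrix {self.matrix_name!r}") from exc


@dataclass
class PairwiseAlignmentResult:
    """One optimal global alignment with its column tally."""

    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float
    similarity_pct: float
    n_columns: int
    n_identical: int
    n_similar_only: int
    n_dissimilar: int
    n_gap_columns: int

    def category_counts(self) -> Tuple[int, int, int, int]:
        """(identical, similar-only, dissimilar, gap) column counts —
        sufficient statistics for column-resampling bootstraps."""
        return (self.n_identical, self.n_similar_only, self.n_dissimilar, self.n_gap_columns)


def _make_aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = params.load_matrix()
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    if not params.end_gaps:
        aligner.end_gap_score = 0.0
    return aligner


def _is_similar(a: str, b: str, matrix, rule: str) -> bool:
    if rule == "matrix_positive":
        return matrix[a, b] > 0
    return any(a in g and b in g for g in SIMILARITY_GROUPS)


def percent_counts(
    n_identical: int,
    n_similar_only: int,
    n_columns: int,
    n_gap_columns: int,
    len_a: int,
    len_b: int,
    denominator: str = "columns",
) -> Tuple[float, float]:
    """Turn column counts into (identity_pct, similarity_pct) under the
    chosen denominator convention."""
    if denominator == "columns":
        denom = n_columns
    elif denominator == "aligned":
        denom = n_columns - n_gap_columns
    else:  # shorter
        denom = min(len_a, len_b)
    if denom <= 0:
        raise ValueError("degenerate alignment: empty denominator")
    identity = 100.0 * n_identical / denom
    similarity = 100.0 * (n_identical + n_similar_only) / denom
    return identity, similarity


def global_align(
    a: str, b: str, params: Optional[AlignParams] = None
) -> PairwiseAlignmentResult:
    """Optimal affine-gap global alignment of two protein sequences.

    Returns the alignment together with percent identity I and percent
    similarity S.  Ties between equally optimal alignments are broken by
    Biopython's deterministic traceback enumeration (first alignment taken),
    so results are reproducible for fixed inputs and parameters.
    """
    params = params or AlignParams()
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    from .records import validate_sequence

    validate_sequence(a, "query_a")
    validate_sequence(b, "query_b")
    aligner = _make_aligner(params)
    matrix = aligner.substitution_matrix
    alignment = aligner.align(a, b)[0]
    aligned_a, aligned_b = str(alignment[0]), str(alignment[1])

    n_identical = n_similar_only = n_dissimilar = n_gap = 0
    for ca, cb in zip(aligned_a, aligned_b):
        if ca == "-" or cb == "-":
            n_gap += 1
        elif ca == cb:
            n_identical += 1
        elif _is_similar(ca, cb, matrix, params.similar_rule):
            n_similar_only += 1
        else:
            n_dissimilar += 1
    n_columns = len(aligned_a)
    identity, similarity = percent_counts(
        n_identical, n_similar_only, n_columns, n_gap, len(a), len(b), params.denominator
    )
    return PairwiseAlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(alignment.score),
        identity_pct=identity,
        similarity_pct=similarity,
        n_columns=n_columns,
        n_identical=n_identical,
        n_similar_only=n_similar_only,
        n_dissimilar=n_dissimilar,
        n_gap_columns=n_gap,
    )
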