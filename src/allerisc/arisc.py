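"""The A-RISC cross-reactivity index.

For a pair of allergens with percent identity I and percent similarity S
(similar = identical + similar-but-not-identical), the A-RISC index is the
average (I + S) / 2.  It estimates the fraction of aligned residues able to
engage cross-reactive IgE antibodies: identical residues contribute fully,
similar-but-not-identical residues half.  High values between two allergens
flag a high risk that antibodies raised against one will bind the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .align import AlignParams, PairwiseAlignmentResult, global_align
from .records import ProteinRecord


def arisc_index(identity: float, similarity: float) -> float:
    """A-RISC index (I + S) / 2 for one pair, on whichever scale (percent or
    fraction) I and S are given.  Requires 0 <= I <= S."""
    if identity < 0 or similarity < 0:
        raise ValueError("I and S must be non-negative")
    if identity > similarity:
        raise ValueError(
            f"identity ({identity}) exceeds similarity ({similarity}); "
            "'similar' includes identical residues"
        )
    return (identity + similarity) / 2.0


@dataclass
class RiskBands:
    """Risk classification bands on the A-RISC percent scale.

    A single cut at 60 separates high from low risk by default; an optional
    intermediate band can be enabled by setting ``intermediate_threshold``.
    Values exactly at a threshold fall in the higher band.
    """

    high_threshold: float = 60.0
    intermediate_threshold: Optional[float] = None

    def __post_init__(self):
        if not (0 < self.high_threshold < 100):
            raise ValueError("high_threshold must lie in (0, 100)")
        if self.intermediate_threshold is not None and not (
            0 < self.intermediate_threshold < self.high_threshold
        ):
            raise ValueError("intermediate_threshold must lie below high_threshold")

    def label(self, value: float) -> str:
        if value >= self.high_threshold:
            return "high"
        if self.intermediate_threshold is not None and value >= self.intermediate_threshold:
            return "intermediate"
        return "low"


@dataclass
class ARiscMatrix:
    """Symmetric all-vs-all A-RISC matrix.

    Stored on the 0-100 percent scale by default (``scale="percent"``);
    ``as_fraction()`` returns the equivalent 0-1 matrix.  The diagonal is 100
    by definition.  ``identity`` and ``similarity`` hold the matching I and S
    matrices so that I <= A-RISC <= S can always be checked.
    """

    ids: List[str]
    values: np.ndarray
    identity: np.ndarray
    similarity: np.ndarray
    scale: str = "percent"

    def __post_init__(self):
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match id list")

    def as_fraction(self) -> np.ndarray:
        return self.values / 100.0 if self.scale == "percent" else self.values

    def pair(self, id_a: str, id_b: str) -> float:
        i, j = self.ids.index(id_a), self.ids.index(id_b)
        return float(self.values[i, j])

    def to_square_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_long_frame(self) -> pd.DataFrame:
        """Long format: one row per unordered pair (id_a, id_b, I, S, arisc)."""
        rows = []
        for i in range(len(self.ids)):
            for j in range(i + 1, len(self.ids)):
                rows.append(
                    {
                        "id_a": self.ids[i],
                        "id_b": self.ids[j],
                        "identity": self.identity[i, j],
                        "similarity": self.similarity[i, j],
                        "arisc": self.values[i, j],
                    }
                )
        return pd.DataFrame(rows)

    def write_square_tsv(self, path: Union[str, Path]) -> None:
        self.to_square_frame().to_csv(path, sep="\t", float_format="%.4f")

    def write_long_tsv(
        self, path: Union[str, Path], bands: Optional[RiskBands] = None
    ) -> None:
        df = self.to_long_frame()
        if bands is not None:
            df["risk"] = [bands.label(v) for v in df["arisc"]]
        df.to_csv(path, sep="\t", index=False, float_format="%.4f")


def arisc_matrix(
    records: Sequence[ProteinRecord],
    params: Optional[AlignParams] = None,
    progress: bool = False,
) -> ARiscMatrix:
    """All-vs-all A-RISC matrix over *records* (n(n-1)/2 alignments).

    Deterministic for fixed records and parameters.  Record ids must be
    unique; the diagonal is set to 100 without aligning.
    """
    params = params or AlignParams()
    ids = [r.id for r in records]
    if len(ids) < 2:
        raise ValueError("need at least 2 records")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids")
    n = len(records)
    values = np.full((n, n), 100.0)
    ident = np.full((n, n), 100.0)
    simil = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            res = global_align(records[i].sequence, records[j].sequence, params)
            a = arisc_index(res.identity_pct, res.similarity_pct)
            values[i, j] = values[j, i] = a
            ident[i, j] = ident[j, i] = res.identity_pct
            simil[i, j] = simil[j, i] = res.similarity_pct
    return ARiscMatrix(ids=ids, values=values, identity=ident, similarity=simil)


def classify_pairs(
    matrix: ARiscMatrix, bands: Optional[RiskBands] = None
) -> List[Tuple[str, str, float, str]]:
    """Label every unordered pair with its A-RISC value and risk band."""
    bands = bands or RiskBands()
    out = []
    for i in range(len(matrix.ids)):
        for j in range(i + 1, len(matrix.ids)):
            v = float(matrix.values[i, j])
            out.append((matrix.ids[i], matrix.ids[j], v, bands.label(v)))
    return out
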