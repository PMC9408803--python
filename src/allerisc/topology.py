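"""Transmembrane-helix and signal-peptide screening.

Two fully specified heuristics stand behind this module:

* **TM helices** — Kyte-Doolittle hydropathy averaged over a sliding window
  (default 19 residues, the canonical helix-spanning width); maximal runs of
  window centres above the threshold (default 1.6, the classic cut-off for
  membrane-spanning segments) are expanded to the residues they cover,
  merged, and reported as 0-based half-open spans.
* **Signal peptides** — the classic tripartite architecture: a positively
  charged n-region (net K/R vs D/E charge in residues 1-5), a hydrophobic
  h-region (a >= 7-residue window of mean hydropathy >= 1.6 within residues
  3-25), and a c-region with small residues (A/G/S/C) at the -3 and -1
  positions of a putative cleavage site within the first ``search_len``
  residues.  A protein is called SP-positive iff all three sub-rules pass;
  ``sp_score`` is the mean of the three smoothed sub-scores.

Reproduction of the published per-protein numbers goes through the packaged
summary table (:func:`allerisc.catalog.load_table1`), because those values
are the output of external HMM/neural-network predictors and are treated as
data.  :func:`summarize_table1` computes the per-cluster counts from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .records import ProteinRecord, Table1Row

#: Kyte & Doolittle (1982) hydropathy scale.  X is treated as neutral (0).
KYTE_DOOLITTLE: Dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}

SMALL_RESIDUES = frozenset("AGSC")
POSITIVE_RESIDUES = frozenset("KR")
NEGATIVE_RESIDUES = frozenset("DE")


@dataclass
class TopologyAnnotation:
    """Per-protein topology call: TM helix spans (0-based half-open) and the
    signal-peptide decision.  ``source`` records whether the values were
    predicted by the heuristics or read from the packaged table."""

    record_id: str
    n_tmh: int
    tmh_spans: List[Tuple[int, int]]
    signal_peptide: bool
    sp_score: float
    source: str = "predicted"
    too_short: bool = False


def hydropathy_profile(seq: str, window: int = 19) -> np.ndarray:
    """Mean Kyte-Doolittle hydropathy for every length-*window* stretch;
    entry i covers residues [i, i + window)."""
    values = np.array([KYTE_DOOLITTLE[ch] for ch in seq])
    if len(values) < window:
        return np.empty(0)
    kernel = np.ones(window) / window
    return np.convolve(values, kernel, mode="valid")


def predict_tmh(
    seq: str, record_id: str = "<anonymous>", window: int = 19, threshold: float = 1.6
) -> TopologyAnnotation:
    """Sliding-window hydropathy scan for transmembrane helices.

    Runs of consecutive windows whose mean hydropathy is >= *threshold* are
    expanded to the residues they cover and merged; spans shorter than the
    window are discarded.  Sequences shorter than the window get a zero-TMH
    annotation flagged ``too_short``.
    """
    means = hydropathy_profile(seq, window)
    if len(means) == 0:
        return TopologyAnnotation(
            record_id=record_id,
            n_tmh=0,
            tmh_spans=[],
            signal_peptide=False,
            sp_score=0.0,
            too_short=True,
        )
    above = means >= threshold
    spans: List[Tuple[int, int]] = []
    start = None
    for i, flag in enumerate(np.append(above, False)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            spans.append((start, (i - 1) + window))  # residues covered by the run
            start = None
    merged: List[Tuple[int, int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    merged = [(s, e) for s, e in merged if e - s >= window]
    sp, sp_score = predict_signal_peptide(seq)
    return TopologyAnnotation(
        record_id=record_id,
        n_tmh=len(merged),
        tmh_spans=merged,
        signal_peptide=sp,
        sp_score=sp_score,
    )


def _n_region_score(seq: str) -> Tuple[bool, float]:
    head = seq[:5]
    net = sum(ch in POSITIVE_RESIDUES for ch in head) - sum(
        ch in NEGATIVE_RESIDUES for ch in head
    )
    return net >= 1, float(np.clip(net / 2.0, 0.0, 1.0))


def _h_region_score(seq: str, h_window: int = 7, threshold: float = 1.6) -> Tuple[bool, float, int]:
    """Best mean-hydropathy h_window within residues 3-25 (1-based); returns
    (passes, smoothed score, 0-based start of the best window)."""
    region = seq[2:25]
    if len(region) < h_window:
        return False, 0.0, 0
    means = hydropathy_profile(region, h_window)
    best = int(np.argmax(means))
    best_mean = float(means[best])
    return best_mean >= threshold, float(np.clip(best_mean / threshold, 0.0, 1.0)), best + 2


def _c_region_score(seq: str, h_start: int, search_len: int) -> Tuple[bool, float]:
    """Small residues at the -3 and -1 positions of a putative cleavage
    point.  The c-region of a signal peptide is short (a handful of
    residues), so candidate cleavage sites are restricted to the stretch
    just downstream of the hydrophobic core, still bounded by *search_len*."""
    h_end = h_start + 7
    lo = max(h_end, 10)
    hi = min(h_end + 11, search_len, len(seq))
    for c in range(lo, hi):
        if seq[c - 3] in SMALL_RESIDUES and seq[c - 1] in SMALL_RESIDUES:
            return True, 1.0
    return False, 0.0


def predict_signal_peptide(seq: str, search_len: int = 70) -> Tuple[bool, float]:
    """Tripartite signal-peptide heuristic; see the module docstring.

    Returns ``(signal_peptide, sp_score)`` with ``sp_score`` in [0, 1], the
    mean of the three sub-scores.  The call is positive iff all three
    sub-rules pass.
    """
    if not seq:
        raise ValueError("empty sequence")
    n_ok, n_score = _n_region_score(seq)
    h_ok, h_score, h_start = _h_region_score(seq)
    c_ok, c_score = _c_region_score(seq, h_start, search_len)
    return (n_ok and h_ok and c_ok), float((n_score + h_score + c_score) / 3.0)


def annotate_records(
    records: Sequence[ProteinRecord],
    mode: str = "heuristic",
    table_by_accession: Optional[Dict[str, Table1Row]] = None,
) -> List[TopologyAnnotation]:
    """Annotate records either with the heuristics (``mode="heuristic"``) or
    from the packaged summary table (``mode="table1"``; spans unavailable)."""
    if mode == "heuristic":
        return [predict_tmh(r.sequence, r.id) for r in records]
    if mode != "table1":
        raise ValueError("mode must be 'heuristic' or 'table1'")
    if table_by_accession is None:
        from .catalog import join_catalog_table1

        table_by_accession = join_catalog_table1()
    out = []
    for r in records:
        row = table_by_accession.get(r.id)
        if row is None:
            raise KeyError(f"record {r.id} not found in the packaged table")
        out.append(
            TopologyAnnotation(
                record_id=r.id,
                n_tmh=row.n_predicted_tmh,
                tmh_spans=[],
                signal_peptide=row.signal_peptide,
                sp_score=row.sp_probability,
                source="table1",
            )
        )
    return out


def summarize_table1(rows: Sequence[Table1Row], cluster: str) -> Dict[str, object]:
    """Per-cluster summary of the packaged table: member count, members with
    >= 1 predicted TM helix, members with a signal-peptide call, lengths."""
    members = [r for r in rows if r.cluster == cluster]
    if not members:
        raise ValueError(f"unknown cluster label {cluster!r}")
    return {
        "n_members": len(members),
        "n_with_tmh": sum(r.n_predicted_tmh >= 1 for r in members),
        "n_with_sp": sum(r.signal_peptide for r in members),
        "lengths": [r.length for r in members],
    }


def annotations_to_frame(annotations: Sequence[TopologyAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [a.record_id for a in annotations],
            "n_tmh": [a.n_tmh for a in annotations],
            "tmh_spans": [
                ";".join(f"{s}-{e}" for s, e in a.tmh_spans) for a in annotations
            ],
            "signal_peptide": [a.signal_peptide for a in annotations],
            "sp_score": [round(a.sp_score, 4) for a in annotations],
            "source": [a.source for a in annotations],
        }
    )
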