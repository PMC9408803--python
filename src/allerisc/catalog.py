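"""Packaged study fixtures: the 60-allergen accession catalog and the
transmembrane / signal-peptide summary table.

Both resources are shipped as plain TSV transcribed verbatim from the source
study, including its printed irregularities (inconsistent accession spellings
and misspelled labels); the loaders deliberately do not normalise them.  The
catalog carries metadata only — sequences are identified by accession and are
not bundled, and nothing here touches the network.
"""

from __future__ import annotations

from importlib.resources import files
from typing import Dict, List, Optional

import pandas as pd

from .records import CLUSTER_LABELS, ProteinRecord, Table1Row


def _resource(name: str):
    res = files("allerisc.data").joinpath(name)
    if not res.is_file():
        raise FileNotFoundError(f"packaged resource {name!r} is missing")
    return res


def load_table1() -> List[Table1Row]:
    """Load the packaged per-protein topology summary (60 rows).

    Columns mirror the printed table: protein length, number of predicted
    transmembrane helices (TMHs), expected residues in TMHs (total and within
    the first 60 residues), probability that the N-terminus is cytoplasmic,
    signal-peptide search length, call, and probabilities.
    """
    with _resource("table1.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    expected_cols = [
        "cluster",
        "protein",
        "length",
        "n_predicted_tmh",
        "exp_aa_in_tmh",
        "exp_aa_first60",
        "prob_n_in",
        "signal_length",
        "signal_peptide",
        "sp_probability",
        "anchor_probability",
    ]
    if list(df.columns) != expected_cols:
        raise ValueError("packaged table1.tsv is corrupt: unexpected columns")
    rows: List[Table1Row] = []
    for rec in df.itertuples(index=False):
        rows.append(
            Table1Row(
                cluster=rec.cluster,
                protein_id=rec.protein,
                length=int(rec.length),
                n_predicted_tmh=int(rec.n_predicted_tmh),
                exp_aa_in_tmh=float(rec.exp_aa_in_tmh),
                exp_aa_first60=float(rec.exp_aa_first60),
                prob_n_in=float(rec.prob_n_in),
                signal_length=int(rec.signal_length),
                signal_peptide=rec.signal_peptide == "yes",
                sp_probability=float(rec.sp_probability),
                anchor_probability=float(rec.anchor_probability),
            )
        )
    if len(rows) != 60:
        raise ValueError(f"packaged table1.tsv is corrupt: {len(rows)} rows, expected 60")
    return rows


def load_catalog() -> List[ProteinRecord]:
    """Load the 60-entry allergen catalog (accession, label, species,
    phylogroup).  Records are metadata-only: ``sequence`` is empty."""
    with _resource("catalog.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    records = [
        ProteinRecord(
            id=rec.accession,
            label=rec.label,
            species=rec.species,
            cluster=rec.cluster,
            sequence="",
        )
        for rec in df.itertuples(index=False)
    ]
    if len(records) != 60:
        raise ValueError("packaged catalog.tsv is corrupt")
    return records


def cluster_sizes(records: Optional[List[ProteinRecord]] = None) -> Dict[str, int]:
    """Number of catalog entries per phylogroup, keyed I..IV."""
    if records is None:
        records = load_catalog()
    sizes = {c: 0 for c in CLUSTER_LABELS}
    for rec in records:
        if rec.cluster in sizes:
            sizes[rec.cluster] += 1
    return sizes


def join_catalog_table1() -> Dict[str, Table1Row]:
    """Join catalog entries to table rows by accession.

    The table prints each protein as ``accession_label`` (sometimes with a
    ``sp|`` tag or a trailing suffix); the join matches a catalog accession to
    the row whose printed id starts with it.  Every one of the 60 entries must
    match exactly one row.
    """
    rows = load_table1()
    out: Dict[str, Table1Row] = {}
    for rec in load_catalog():
        matches = [
            r
            for r in rows
            if r.protein_id.removeprefix("sp|") == rec.id
            or r.protein_id.removeprefix("sp|").startswith(rec.id + "_")
        ]
        if len(matches) != 1:
            raise ValueError(
                f"catalog accession {rec.id} matched {len(matches)} table rows"
            )
        out[rec.id] = matches[0]
    return out
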