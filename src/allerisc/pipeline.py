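"""End-to-end analysis pipeline: align -> A-RISC -> cluster -> motifs ->
topology -> report.

The pipeline is a pure function of (input, configuration, seed): all outputs
are deterministic text files (TSV, Newick, MEME-minimal, plain-text report)
with no timestamps, so two runs with the same configuration are
byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .align import AlignParams
from .arisc import ARiscMatrix, RiskBands, arisc_matrix, classify_pairs
from .catalog import cluster_sizes, load_catalog, load_table1
from .cluster import (
    ClusterTree,
    DistanceMatrix,
    bootstrap_support,
    build_tree,
    cut_clusters,
    to_newick,
    write_assignment_tsv,
)
from .fasta import read_fasta, write_fasta
from .motifs import MotifSearchConfig, discover_motifs, motif_presence, write_meme_minimal
from .records import ProteinRecord
from .simulate import generate_study
from .topology import annotate_records, annotations_to_frame, summarize_table1

logger = logging.getLogger("allerisc")


@dataclass
class PipelineConfig:
    """Configuration for :func:`run_pipeline`.

    ``input`` is either a FASTA path or the literal ``"paper_like"`` to run
    on the packaged synthetic four-family study preset.
    """

    input: Union[str, Path] = "paper_like"
    outdir: Union[str, Path] = "allerisc_out"
    align: AlignParams = field(default_factory=AlignParams)
    risk: RiskBands = field(default_factory=RiskBands)
    k_clusters: int = 4
    linkage: str = "upgma"
    bootstrap_reps: int = 0
    motif: MotifSearchConfig = field(default_factory=MotifSearchConfig)
    topology_mode: str = "heuristic"
    seed: int = 0


@dataclass
class ReportBundle:
    """Handles to everything the pipeline produced."""

    records: List[ProteinRecord]
    matrix: ARiscMatrix
    tree: ClusterTree
    assignment: Dict[str, int]
    motifs: list
    annotations: list
    report_path: Path
    outdir: Path


def _stage_seed(seed: int, stage: int) -> int:
    """Deterministically derive a per-stage seed below 2**31."""
    return int(np.random.default_rng([seed, stage]).integers(2**31))


def _load_input(cfg: PipelineConfig) -> List[ProteinRecord]:
    if str(cfg.input) == "paper_like":
        records, _truth = generate_study(preset="paper_like", seed=_stage_seed(cfg.seed, 0))
        return records
    return read_fasta(cfg.input)


def run_pipeline(cfg: PipelineConfig) -> ReportBundle:
    """Run the full analysis; writes all outputs under ``cfg.outdir``.

    Raises with the failing stage named in the message.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "input"
    try:
        records = _load_input(cfg)
        if len(records) < 2:
            raise ValueError("need >= 2 sequences")
        logger.info("input: %d sequences", len(records))
        if str(cfg.input) == "paper_like":
            write_fasta(records, outdir / "input.fasta")

        stage = "arisc"
        matrix = arisc_matrix(records, cfg.align)
        matrix.write_square_tsv(outdir / "arisc_square.tsv")
        matrix.write_long_tsv(outdir / "arisc_long.tsv", bands=cfg.risk)
        logger.info("arisc: %d pairwise alignments", len(records) * (len(records) - 1) // 2)

        stage = "cluster"
        if cfg.bootstrap_reps > 0:
            tree = bootstrap_support(
                records,
                cfg.align,
                n_reps=cfg.bootstrap_reps,
                seed=_stage_seed(cfg.seed, 2),
                linkage=cfg.linkage,
            )
        else:
            tree = build_tree(DistanceMatrix.from_arisc(matrix), cfg.linkage)
        (outdir / "tree.nwk").write_text(to_newick(tree) + "\n")
        k = min(cfg.k_clusters, tree.n_leaves)
        assignment = cut_clusters(tree, k)
        write_assignment_tsv(assignment, outdir / "clusters.tsv")
        logger.info("cluster: cut at k=%d (%s linkage)", k, cfg.linkage)

        stage = "motifs"
        motif_cfg = MotifSearchConfig(
            **{**cfg.motif.__dict__, "seed": _stage_seed(cfg.seed, 3)}
        )
        motifs = discover_motifs(records, motif_cfg)
        write_meme_minimal(motifs, outdir / "motifs.meme")
        presence = motif_presence(records, motifs)
        presence.to_csv(outdir / "motif_presence.tsv", sep="\t")
        logger.info("motifs: %d discovered", len(motifs))

        stage = "topology"
        annotations = annotate_records(records, mode=cfg.topology_mode)
        annotations_to_frame(annotations).to_csv(
            outdir / "topology.tsv", sep="\t", index=False
        )

        stage = "report"
        report_path = outdir / "report.txt"
        report_path.write_text(
            _render_report(records, matrix, assignment, motifs, annotations, presence, cfg)
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return ReportBundle(
        records=records,
        matrix=matrix,
        tree=tree,
        assignment=assignment,
        motifs=motifs,
        annotations=annotations,
        report_path=report_path,
        outdir=outdir,
    )


def _render_report(records, matrix, assignment, motifs, annotations, presence, cfg) -> str:
    lines = []
    lines.append("allerisc run report")
    lines.append("===================")
    lines.append(f"sequences: {len(records)}")
    lines.append(f"clusters (k={len(set(assignment.values()))}):")
    ann_by_id = {a.record_id: a for a in annotations}
    ids = matrix.ids
    idx = {r: i for i, r in enumerate(ids)}
    for label in sorted(set(assignment.values())):
        members = [r for r in ids if assignment[r] == label]
        vals = [
            matrix.values[idx[a], idx[b]]
            for ai, a in enumerate(members)
            for b in members[ai + 1 :]
        ]
        mean_arisc = float(np.mean(vals)) if vals else float("nan")
        n_high = sum(v >= cfg.risk.high_threshold for v in vals)
        n_tm = sum(ann_by_id[m].n_tmh > 0 for m in members)
        n_sp = sum(ann_by_id[m].signal_peptide for m in members)
        risk = (
            "high cross-reactivity risk"
            if vals and mean_arisc >= cfg.risk.high_threshold
            else "low cross-reactivity risk"
        )
        lines.append(
            f"  cluster {label}: n={len(members)} mean_arisc={mean_arisc:.1f} "
            f"high_risk_pairs={n_high}/{len(vals)} tm={n_tm} sp={n_sp} -> {risk}"
        )
    lines.append(f"motifs discovered: {len(motifs)}")
    for i, m in enumerate(motifs, start=1):
        lines.append(
            f"  motif_{i}: width={m.width} sites={len(m.occurrences)} "
            f"llr={m.log_likelihood_ratio:.1f} consensus={m.consensus}"
        )
    high_pairs = [
        (a, b, v) for a, b, v, lab in classify_pairs(matrix, cfg.risk) if lab == "high"
    ]
    lines.append(f"high-risk pairs (A-RISC >= {cfg.risk.high_threshold:g}): {len(high_pairs)}")
    return "\n".join(lines) + "\n"


def reproduce_table1_counts(verbose: bool = True) -> List[Tuple[str, int, int, bool]]:
    """Recompute the per-cluster member/TMH/SP counts from the packaged
    summary table and check them against the study's headline numbers.

    Returns (check name, expected, observed, passed) tuples and optionally
    prints a summary.  All counts are exact integers read from the table.
    """
    rows = load_table1()
    catalog = load_catalog()
    sizes = cluster_sizes(catalog)
    s = {c: summarize_table1(rows, c) for c in ("I", "II", "III", "IV")}
    modal_ii = max(set(s["II"]["lengths"]), key=s["II"]["lengths"].count)
    kiwi_d9 = next(r for r in rows if "kiwi_D9" in r.protein_id)
    checks = [
        ("total allergens", 60, len(rows)),
        ("catalog entries", 60, len(catalog)),
        ("cluster I members", 9, s["I"]["n_members"]),
        ("cluster II members", 10, s["II"]["n_members"]),
        ("cluster III members (12 tabulated)", 12, s["III"]["n_members"]),
        ("cluster IV members", 29, s["IV"]["n_members"]),
        ("cluster I TM helices", 0, s["I"]["n_with_tmh"]),
        ("cluster I signal peptides", 0, s["I"]["n_with_sp"]),
        ("cluster II TM helices", 0, s["II"]["n_with_tmh"]),
        ("cluster II signal peptides", 0, s["II"]["n_with_sp"]),
        ("cluster III members with TM helix", 7, s["III"]["n_with_tmh"]),
        ("cluster III signal peptides", 12, s["III"]["n_with_sp"]),
        ("cluster IV members with TM helix", 12, s["IV"]["n_with_tmh"]),
        ("cluster IV signal peptides", 26, s["IV"]["n_with_sp"]),
        ("kiwi D9 shorter than modal cluster II length", 22, modal_ii - kiwi_d9.length),
        ("catalog/table cluster sizes agree", 1, int(all(
            sizes[c] == s[c]["n_members"] for c in ("I", "II", "III", "IV")
        ))),
    ]
    results = [(name, exp, obs, exp == obs) for name, exp, obs in checks]
    if verbose:
        for name, exp, obs, ok in results:
            print(f"[{'PASS' if ok else 'FAIL'}] {name}: expected {exp}, observed {obs}")
    return results
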