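"""Synthetic allergen families with known ground truth.

Families emulate the statistical structure of real allergen phylogroups:
high within-family sequence homology, near-background between-family
homology, optionally decorated with planted motifs, hydrophobic
transmembrane (TM) segments, and N-terminal signal peptides (SP).

Mutation model
--------------
An ancestor of length L is drawn iid from the background residue
distribution (uniform over the 20 amino acids by default).  Each family
member is derived from the ancestor by substituting every site independently
with probability ``1 - p`` (``p = target_identity``); a substituted residue
is drawn from the BLOSUM62-positive partners of the original with
probability ``q`` (``similar_sub_fraction``), otherwise uniformly from the
other 19 residues.  Because members mutate independently, the *pairwise*
identity between two members is approximately ``p**2`` plus a small
coincidence term; :func:`expected_pairwise_stats` computes the exact
expectation of pairwise identity, similarity, and A-RISC for gapless columns
under this model, which is what alignment-based estimates are compared to.

Planted blocks (motifs, TM segments, SP) are written over the mutated
sequences at non-overlapping positions, so truth-table occurrences contain
the planted consensus exactly.  An optional indel process (off by default)
adds geometric-length insertions/deletions before blocks are planted, to
exercise gapped alignment paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio.Align import substitution_matrices

from .records import AA20, ProteinRecord

#: Default background: uniform over the 20 standard residues.
UNIFORM_BACKGROUND = np.full(20, 1.0 / 20.0)

#: N-terminal signal peptide planted on SP-positive members: positively
#: charged n-region (MKK), an Ala/Leu-rich h-region, and a small-residue
#: c-region with the A-X-A motif before the cleavage point.  The h-region is
#: the minimal 7-residue hydrophobic window (mean hydropathy ~2.7, as in
#: typical Ala/Leu-rich signal sequences) rather than a long poly-Leu run,
#: so a signal peptide does not masquerade as a 19-residue membrane span.
SIGNAL_PEPTIDE_BLOCK = "MKKLALALAADASAQA"

#: Residues used for planted transmembrane segments (strongly hydrophobic).
TM_RESIDUES = "LIVF"
TM_SEGMENT_LENGTH = 21

_AA_INDEX = {aa: i for i, aa in enumerate(AA20)}


def _positive_partner_sets(matrix_name: str = "BLOSUM62") -> List[np.ndarray]:
    """For each residue index, the indices of *different* residues with a
    positive substitution score.  Residues with no positive partner (C in
    BLOSUM62) get an empty array; the generator falls back to a uniform
    different residue there."""
    m = substitution_matrices.load(matrix_name)
    out = []
    for a in AA20:
        partners = [_AA_INDEX[b] for b in AA20 if b != a and m[a, b] > 0]
        out.append(np.array(partners, dtype=np.int64))
    return out

_POSITIVE_PARTNERS = _positive_partner_sets()


@dataclass
class FamilySpec:
    """Parameters for one synthetic family."""

    n_members: int = 10
    length: int = 300
    target_identity: float = 0.9  # per-member retention probability p
    similar_sub_fraction: float = 0.5  # q: substitutions drawn from positive partners
    planted_motifs: Sequence[Tuple[str, float]] = ()  # (consensus, inclusion prob)
    tm_segments: int = 0
    signal_peptide: bool = False
    indel_rate: float = 0.0  # expected indel events per site
    label: str = "F1"
    seed: int = 0

    def __post_init__(self):
        if self.n_members < 2:
            raise ValueError("a family needs at least 2 members")
        if not (0 < self.target_identity <= 1):
            raise ValueError("target_identity must lie in (0, 1]")
        if not (0 <= self.similar_sub_fraction <= 1):
            raise ValueError("similar_sub_fraction must lie in [0, 1]")
        for consensus, prob in self.planted_motifs:
            if not (6 <= len(consensus) <= 60):
                raise ValueError("planted motif widths must lie in [6, 60]")
            if not (0 <= prob <= 1):
                raise ValueError("motif inclusion probability must lie in [0, 1]")


@dataclass
class TruthTable:
    """Ground truth for generated records.

    ``expected`` holds, per family, the exact model expectations of pairwise
    percent identity, similarity, and A-RISC (mutation model only — planted
    blocks shift the realised values slightly upward)."""

    family_of: Dict[str, str] = field(default_factory=dict)
    motif_sites: Dict[str, List[Tuple[str, int]]] = field(default_factory=dict)
    tm_spans: Dict[str, List[Tuple[int, int]]] = field(default_factory=dict)
    sp_flags: Dict[str, bool] = field(default_factory=dict)
    expected: Dict[str, Dict[str, float]] = field(default_factory=dict)

    def merge(self, other: "TruthTable") -> None:
        if set(self.family_of) & set(other.family_of):
            raise ValueError("record id collision while merging truth tables")
        self.family_of.update(other.family_of)
        self.motif_sites.update(other.motif_sites)
        self.tm_spans.update(other.tm_spans)
        self.sp_flags.update(other.sp_flags)
        self.expected.update(other.expected)

    def labels_for(self, ids: Sequence[str]) -> List[str]:
        return [self.family_of[i] for i in ids]


def expected_pairwise_stats(
    p: float,
    q: float,
    background: Optional[np.ndarray] = None,
    matrix_name: str = "BLOSUM62",
) -> Dict[str, float]:
    """Exact expected pairwise identity/similarity/A-RISC (percent) between
    two members independently mutated from a common ancestor.

    Per ancestor residue a, a member residue is distributed
    ``r_a = p * delta_a + (1 - p) * m_a`` where ``m_a`` mixes the
    BLOSUM62-positive partners of a (weight q) with a uniform different
    residue (weight 1 - q).  Identity is ``E_a[ sum_b r_a(b)^2 ]``;
    similarity additionally counts residue pairs with a positive
    substitution score.
    """
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background)
    m = substitution_matrices.load(matrix_name)
    sim = np.zeros((20, 20))
    for i, a in enumerate(AA20):
        for j, b in enumerate(AA20):
            sim[i, j] = 1.0 if (i == j or m[a, b] > 0) else 0.0
    e_ident = 0.0
    e_simil = 0.0
    for a in range(20):
        m_a = np.zeros(20)
        others = np.array([b for b in range(20) if b != a])
        pos = _POSITIVE_PARTNERS[a]
        if len(pos) > 0:
            m_a[pos] += q / len(pos)
            m_a[others] += (1 - q) / len(others)
        else:
            m_a[others] += 1.0 / len(others)
        r_a = (1 - p) * m_a
        r_a[a] += p
        e_ident += bg[a] * float(r_a @ r_a)
        e_simil += bg[a] * float(r_a @ sim @ r_a)
    return {
        "identity": 100.0 * e_ident,
        "similarity": 100.0 * e_simil,
        "arisc": 100.0 * (e_ident + e_simil) / 2.0,
    }


def hamming_identity(a: str, b: str) -> float:
    """Position-wise percent identity of two equal-length sequences (the
    gapless oracle the mutation-model expectations refer to)."""
    if len(a) != len(b):
        raise ValueError("hamming_identity requires equal-length sequences")
    return 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)


def _mutate(ancestor: np.ndarray, p: float, q: float, rng: np.random.Generator) -> np.ndarray:
    member = ancestor.copy()
    mask = rng.random(len(ancestor)) < (1.0 - p)
    for site in np.flatnonzero(mask):
        a = int(ancestor[site])
        pos = _POSITIVE_PARTNERS[a]
        if len(pos) > 0 and rng.random() < q:
            member[site] = pos[rng.integers(len(pos))]
        else:
            choice = int(rng.integers(19))
            member[site] = choice if choice < a else choice + 1
    return member


def _apply_indels(seq: List[int], rate: float, rng: np.random.Generator, bg: np.ndarray) -> List[int]:
    n_events = rng.poisson(rate * len(seq))
    for _ in range(n_events):
        if len(seq) < 10:
            break
        pos = int(rng.integers(len(seq)))
        length = int(rng.geometric(1 / 3.0))
        if rng.random() < 0.5:
            del seq[pos : pos + length]
        else:
            insert = list(rng.choice(20, size=length, p=bg))
            seq[pos:pos] = insert
    return seq


#: Minimum spacing between planted blocks, so that e.g. two TM segments stay
#: resolvable by a 19-residue sliding-window scan (distinct membrane passes
#: have intervening loops).
BLOCK_MARGIN = 25


def _place_blocks(
    widths: List[int], length: int, reserved: int, rng: np.random.Generator
) -> List[int]:
    """Choose non-overlapping start positions (with a BLOCK_MARGIN buffer)
    for blocks of the given widths, avoiding the first *reserved* residues.
    Raises if they cannot fit."""
    occupied: List[Tuple[int, int]] = [(0, reserved)] if reserved else []
    starts: List[int] = []
    for w in sorted(widths, reverse=True):
        placed = False
        for _ in range(500):
            lo, hi = reserved, length - w
            if hi < lo:
                break
            s = int(rng.integers(lo, hi + 1))
            if all(s + w + BLOCK_MARGIN <= a or s >= b + BLOCK_MARGIN for a, b in occupied):
                occupied.append((s, s + w))
                starts.append(s)
                placed = True
                break
        if not placed:
            raise ValueError("planted blocks do not fit in the sequence length")
    # restore caller's width order
    order = np.argsort(np.argsort([-w for w in widths], kind="stable"), kind="stable")
    return [starts[i] for i in order]


def _check_blocks_fit(length: int, reserved: int, block_widths: List[int], sp: bool) -> None:
    sp_len = len(SIGNAL_PEPTIDE_BLOCK) if sp else 0
    if sp_len + sum(block_widths) > length or reserved + sum(block_widths) > length:
        raise ValueError("planted blocks do not fit in the sequence length")


def _plant(
    chars: List[str],
    rng: np.random.Generator,
    tm_segments: int,
    planted_motifs: Sequence[Tuple[str, float]],
    signal_peptide: bool,
) -> Tuple[List[str], List[Tuple[int, int]], List[Tuple[str, int]]]:
    """Overwrite TM / motif / SP blocks at non-overlapping positions; returns
    the decorated sequence plus the planted TM spans and motif sites."""
    reserved = 30 if (signal_peptide or tm_segments) else 0
    block_widths = [TM_SEGMENT_LENGTH] * tm_segments + [len(c) for c, _ in planted_motifs]
    starts = _place_blocks(block_widths, len(chars), reserved, rng)
    tm_spans: List[Tuple[int, int]] = []
    for s in starts[:tm_segments]:
        block = "".join(
            TM_RESIDUES[int(rng.integers(len(TM_RESIDUES)))]
            for _ in range(TM_SEGMENT_LENGTH)
        )
        chars[s : s + TM_SEGMENT_LENGTH] = block
        tm_spans.append((s, s + TM_SEGMENT_LENGTH))
    motif_sites: List[Tuple[str, int]] = []
    for (consensus, prob), s in zip(planted_motifs, starts[tm_segments:]):
        if rng.random() < prob:
            chars[s : s + len(consensus)] = consensus
            motif_sites.append((consensus, s))
    if signal_peptide:
        chars[: len(SIGNAL_PEPTIDE_BLOCK)] = SIGNAL_PEPTIDE_BLOCK
    return chars, tm_spans, motif_sites


def generate_family(spec: FamilySpec) -> Tuple[List[ProteinRecord], TruthTable]:
    """Generate one family of homologous sequences plus its truth table.

    Reproducible: identical spec (including seed) gives byte-identical
    sequences.
    """
    rng = np.random.default_rng(spec.seed)
    bg = UNIFORM_BACKGROUND
    ancestor = rng.choice(20, size=spec.length, p=bg)

    truth = TruthTable()
    truth.expected[spec.label] = expected_pairwise_stats(
        spec.target_identity, spec.similar_sub_fraction
    )
    reserved = 30 if (spec.signal_peptide or spec.tm_segments) else 0
    block_widths = [TM_SEGMENT_LENGTH] * spec.tm_segments + [
        len(c) for c, _ in spec.planted_motifs
    ]
    _check_blocks_fit(spec.length, reserved, block_widths, spec.signal_peptide)

    records: List[ProteinRecord] = []
    for i in range(spec.n_members):
        rid = f"{spec.label}_m{i + 1:02d}"
        member = _mutate(ancestor, spec.target_identity, spec.similar_sub_fraction, rng)
        seq_list = list(int(x) for x in member)
        if spec.indel_rate > 0:
            seq_list = _apply_indels(seq_list, spec.indel_rate, rng, bg)
        chars = [AA20[x] for x in seq_list]
        chars, tm_spans, motif_sites = _plant(
            chars, rng, spec.tm_segments, spec.planted_motifs, spec.signal_peptide
        )
        truth.tm_spans[rid] = tm_spans
        truth.motif_sites[rid] = motif_sites
        truth.sp_flags[rid] = spec.signal_peptide
        truth.family_of[rid] = spec.label
        records.append(
            ProteinRecord(id=rid, sequence="".join(chars), label=rid, cluster=spec.label)
        )
    return records, truth


def generate_proteins(
    n: int,
    length: int,
    tm_segments: int = 0,
    signal_peptide: bool = False,
    planted_motifs: Sequence[Tuple[str, float]] = (),
    seed: int = 0,
    label: str = "P",
) -> Tuple[List[ProteinRecord], TruthTable]:
    """Generate *n* mutually unrelated proteins (independent iid backbones,
    no family structure) with optional planted TM / SP / motif blocks.

    This is the right input for evaluating per-protein classifiers such as
    the topology heuristics: members of one simulated family share an
    ancestor, and hydropathy-preserving substitutions make their profiles
    correlated, so family members are not independent trials.
    """
    rng = np.random.default_rng(seed)
    reserved = 30 if (signal_peptide or tm_segments) else 0
    widths = [TM_SEGMENT_LENGTH] * tm_segments + [len(c) for c, _ in planted_motifs]
    _check_blocks_fit(length, reserved, widths, signal_peptide)
    truth = TruthTable()
    records: List[ProteinRecord] = []
    for i in range(n):
        rid = f"{label}{i + 1:03d}"
        chars = [AA20[x] for x in rng.choice(20, size=length, p=UNIFORM_BACKGROUND)]
        chars, tm_spans, motif_sites = _plant(
            chars, rng, tm_segments, planted_motifs, signal_peptide
        )
        truth.tm_spans[rid] = tm_spans
        truth.motif_sites[rid] = motif_sites
        truth.sp_flags[rid] = signal_peptide
        truth.family_of[rid] = rid
        records.append(ProteinRecord(id=rid, sequence="".join(chars), label=rid))
    return records, truth


#: Study preset mirroring the shape of the real four-phylogroup panel:
#: family sizes 9/10/12/29; the two small families tightly homologous (the
#: high cross-reactivity phylogroups), the two large ones diverse, membrane-
#: and SP-bearing.  Lengths follow the modal lengths of the four clusters.
PAPER_LIKE_SPECS: Tuple[FamilySpec, ...] = (
    FamilySpec(n_members=9, length=160, target_identity=0.97, label="I"),
    FamilySpec(n_members=10, length=131, target_identity=0.95, label="II"),
    FamilySpec(
        n_members=12,
        length=117,
        target_identity=0.75,
        tm_segments=1,
        signal_peptide=True,
        label="III",
    ),
    FamilySpec(
        n_members=29,
        length=250,
        target_identity=0.75,
        tm_segments=1,
        signal_peptide=True,
        label="IV",
    ),
)


def generate_study(
    n_families: int = 4,
    specs: Optional[Sequence[FamilySpec]] = None,
    seed: int = 0,
    preset: Optional[str] = None,
) -> Tuple[List[ProteinRecord], TruthTable]:
    """Generate a multi-family study with disjoint record id spaces.

    ``preset="paper_like"`` uses :data:`PAPER_LIKE_SPECS` (4 families of
    sizes 9/10/12/29).  Otherwise *specs* (or default-parameter families
    labelled F1..Fn) are used.  The top-level seed deterministically derives
    one seed per family.
    """
    if preset == "paper_like":
        specs = PAPER_LIKE_SPECS
    elif preset is not None:
        raise ValueError(f"unknown preset {preset!r}")
    if specs is None:
        specs = [
            FamilySpec(label=f"F{i + 1}") for i in range(n_families)
        ]
    if len(specs) < 2:
        raise ValueError("need at least 2 families")
    master = np.random.default_rng(seed)
    records: List[ProteinRecord] = []
    truth = TruthTable()
    for spec0 in specs:
        spec = FamilySpec(**{**spec0.__dict__, "seed": int(master.integers(2**31))})
        fam_records, fam_truth = generate_family(spec)
        truth.merge(fam_truth)
        records.extend(fam_records)
    return records, truth
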