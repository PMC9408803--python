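# Methods

This note documents the models, defaults, and design choices behind
`allerisc`, in the order the pipeline runs them.

## Pairwise alignment and the A-RISC index

Cross-reactivity risk for a pair of allergens is summarised by the A-RISC
index, `(I + S) / 2`, where *I* and *S* are percent identity and percent
similarity of a pairwise alignment. The index has a direct physical
reading: identical aligned residues are fully available to a cross-reactive
antibody, similar-but-not-identical residues partially, dissimilar ones not
at all. Averaging I and S counts the first group with weight 1 and the
second with weight 1/2.

Published identity/similarity figures rarely state their alignment dialect,
so this package fixes one and makes every piece configurable:

- **Algorithm**: optimal global (Needleman–Wunsch) alignment with affine
  gaps, via Biopython's `PairwiseAligner`. Local alignment is deliberately
  excluded: allergen family members are near-full-length homologs, and a
  semi-global mode (`end_gaps=False`, terminal gaps free) covers the case
  of a moderately truncated member.
- **Substitution matrix**: BLOSUM62 (any Biopython-packaged matrix or an
  NCBI-format file may be substituted).
- **Gap penalties**: open 10, extend 0.5 — the most common convention for
  published percent-identity figures. A gap of length *k* costs
  `open + (k-1)·extend`; this is Biopython's convention and is asserted
  against an exhaustive-enumeration oracle in the tests.
- **Percent denominator**: all alignment columns, gap columns included
  (`denominator="columns"`). Alternatives — gapless columns only, or the
  shorter sequence length — are selectable, because no single convention
  can be inferred from typical published values.
- **"Similar"**: a column whose residues have a strictly positive
  substitution score. A fixed conservation-group table (ClustalW strong
  groups) is available via `similar_rule="groups"`.
- **Tie-breaking**: when several alignments are optimal, the first
  alignment in Biopython's deterministic enumeration is used. Ties can
  change which columns are gaps but not the score; results are reproducible
  for fixed inputs.

`arisc_matrix` computes all n(n−1)/2 alignments; the matrix is stored on
the 0–100 percent scale (the fraction scale is a view, `as_fraction()`),
with I ≤ A-RISC ≤ S guaranteed pairwise. Risk classification uses a single
threshold, default 60, with values exactly at the threshold classed high;
an optional intermediate band can be enabled but no extra band boundaries
are invented by default.

## Phylogrouping

Allergens are grouped from the distance matrix `d = 1 − A-RISC/100` by
agglomerative clustering, UPGMA by default. This is an explicit stand-in
for maximum-likelihood phylogenetics: the claims the pipeline supports
(number of phylogroups, within-group homogeneity, which members are
outliers) are distance-level claims, and UPGMA's ultrametric merge tree
makes the k-cut unambiguous. Complete linkage and neighbour joining
(scikit-bio, midpoint-rooted) are available; NJ trees are cut by node
height, which is well-defined but not ultrametric — UPGMA is the
recommended default.

Determinism: tied merges are broken on the lexicographically smallest pair
of cluster representatives (minimum leaf id), so the partition is invariant
to input order. Node heights are kept on a 10⁻⁹ decimal grid, which makes
Newick serialisation byte-stable under write → read → write.

Branch support is a column-resampling bootstrap: each pairwise alignment is
reduced to its (identical, similar-only, dissimilar, gap) column counts;
a replicate resamples those counts multinomially at fixed alignment length,
rebuilds distances and the tree, and each reference clade's support is the
fraction of replicates containing it. This perturbs exactly the sampling
noise that the A-RISC estimate carries. It is *not* an alignment-site
bootstrap in the phylogenetic sense and should be read as stability of the
distance clustering, not as phylogenetic support.

## Motif discovery

Conserved motifs are found by expectation-maximisation under the ZOOPS
model (zero or one occurrence per sequence): a motif is a position weight
matrix (PWM) of width *w*; each sequence carries an occurrence with
probability γ, uniformly placed; everything else is a fixed 0-order
background estimated from the input. Up to `max_motifs` (default 8) motifs
are extracted greedily, masking each motif's occurrences (with a neutral
symbol excluded from all counts) before the next round; motifs are ranked
by log-likelihood ratio (LLR) of their decoded sites versus background.

Key choices:

- **Widths** are scanned over the grid {6, 8, 10, 15, 20, 30, 45, 60}
  (clipped to the configured [6, 60] bounds). The grid quantises motif
  widths; a planted motif of an off-grid width is recovered at the nearest
  grid width.
- **Width selection** uses a chance-corrected LLR: the winning width
  maximises `LLR − w · c`, where `c = (A−1)/2 + 3·√((A−1)/2)` (A = 20) is
  the null mean plus three standard deviations of the LLR a single fitted
  column contributes by overfitting (Wilks: 2·LLR per column is
  asymptotically χ²₍A₋₁₎). Raw LLR always prefers the widest window and
  LLR-per-column is flat across sub-blocks of a true motif; the penalised
  form recovers exact planted widths in the 8–20 range.
- **Seeding**: every subsequence of the trial width from the first two
  input sequences is converted to a peaked PWM (seed residue weight 0.55)
  and quick-scored with a single E-step; the best three run to convergence
  (≤100 iterations, relative tolerance 10⁻⁶). This is the subsequence-seed
  strategy with an explicit budget; it is fully deterministic.
- **Numerics**: PWM columns carry a pseudocount of 0.1, making the EM a MAP
  estimate under a Dirichlet prior. The corresponding penalised objective
  (log-likelihood + 0.1·Σ log pwm) is checked to be non-decreasing at
  *every* iteration and any decrease raises an error — a bug guard, since
  MAP-EM guarantees monotonicity.
- **Decoding and presence**: a sequence carries an occurrence iff its
  posterior presence exceeds 1/2; site = posterior-max window. Presence of
  a motif in an arbitrary record is a thresholded best-site log-odds score
  (default threshold 0: any site scoring above background).

Deliberately not implemented: MEME's E-value calibration, OOPS/ANR modes,
and HMM logos. Motif numbering is rank-by-LLR and is not comparable to any
external tool's numbering; concordance with a clustering is therefore
evaluated structurally (which clusters share motifs), never by index.

## Transmembrane and signal-peptide screening

Published per-protein topology values for the packaged 60-allergen panel
come from external HMM/neural-network predictors; they are shipped as a
verbatim table and never recomputed — every published count the package
reproduces is an exact filter on that table (members per phylogroup,
members with ≥1 predicted TM helix, members with a signal-peptide call).
The table is stored as printed, including its internal oddities
(inconsistent accession spellings, two label misspellings, and a
member-count discrepancy for the third phylogroup, where the source text
says thirteen but lists and tabulates twelve). The catalog resolves
conflicts in favour of the table.

For sequences outside the packaged panel the package provides two fully
specified heuristics (simplified rules designed here, with honest, tested
error rates — not re-implementations of the external predictors):

- **TM helices**: Kyte–Doolittle hydropathy averaged over a 19-residue
  sliding window (the canonical span of a membrane helix); maximal runs of
  windows with mean ≥ 1.6 are expanded to the residues they cover, merged,
  and reported as 0-based half-open spans. On 150-residue random-composition
  proteins the false-positive rate (≥1 span) is ≈5%; sensitivity on planted
  21-residue hydrophobic segments is ≈100%.
- **Signal peptides**: the classic tripartite architecture, all three rules
  required — (n) net positive K/R−D/E charge ≥ 1 in residues 1–5;
  (h) a 7-residue window with mean hydropathy ≥ 1.6 within residues 3–25;
  (c) small residues (A/G/S/C) at the −3 and −1 positions of a putative
  cleavage site in the short stretch just downstream of the hydrophobic
  core (within the first 70 residues, the same search length the packaged
  table reports). Restricting the cleavage search to just after the
  h-region matters: the −3/−1 pattern alone matches 91% of random proteins
  somewhere in a 70-residue window. The score is the mean of the three
  smoothed sub-scores. False-positive rate ≈2% on random proteins;
  sensitivity ≈100% on planted signal peptides.

Coordinates are 0-based half-open throughout. The signal-anchor probability
column of the packaged table is stored but never predicted.

## Synthetic data

The generator produces allergen-like families with known truth so every
stage is testable without downloads. An ancestor of length L is drawn iid
from a uniform residue background; each member keeps each site with
probability p (`target_identity`) and otherwise substitutes it — with
probability q (`similar_sub_fraction`, default 0.5) to a uniformly chosen
BLOSUM62-positive partner of the ancestral residue (cysteine, which has no
positive partner, falls back to a uniform different residue), else to a
uniform different residue. Members mutate independently, so the *pairwise*
identity between members is ≈ p² plus a coincidence term;
`expected_pairwise_stats` computes the exact expected pairwise identity,
similarity, and A-RISC for this model numerically, and these closed forms
are what alignment-based estimates are tested against (±5 points at
L = 600 over 50 seeds). Indels are off by default (keeping the closed
forms exact); an optional indel rate adds geometric-length insertions and
deletions to exercise gapped alignment paths.

Planted features are written over the mutated sequence at non-overlapping
positions with a 25-residue buffer (so two TM segments remain resolvable by
a 19-residue window scan, as real membrane passes are separated by loops):
motif consensus strings (width 6–60, per-member inclusion probability),
21-residue hydrophobic TM segments (L/I/V/F), and a 16-residue N-terminal
signal peptide `MKKLALALAADASAQA` — charged n-region, minimal 7-residue
Ala/Leu h-region (mean hydropathy ≈2.7, hydrophobic enough for the SP rule
but too short to light up a 19-residue TM window), and an A-X-A c-region.
Interior blocks avoid the first 30 residues whenever an SP or TM block is
planted, keeping the N-terminal region interpretable.

Two generator entry points serve different purposes. `generate_family` /
`generate_study` produce homologous families (the `paper_like` preset: four
families of 9/10/12/29 members, lengths 160/131/117/250 matching the modal
lengths of the real phylogroups, the two small families at p = 0.97/0.95
and the two large ones at p = 0.75 with TM + SP blocks). Family members
share an ancestor, and because q-weighted substitutions are
hydropathy-preserving, their hydropathy profiles are correlated — which is
realistic for homologs but means family members are *not* independent
trials for a per-protein classifier. Per-protein classifier evaluation
therefore uses `generate_proteins`, which draws mutually unrelated
backbones; the TM/SP accuracy figures above are measured on 100 such
proteins (25 per TM×SP condition).

What the generator does not emulate: tree-structured evolution (all members
are star-shaped around one ancestor), rate heterogeneity across sites,
realistic residue composition (background is uniform), domain architecture,
and correlated indels. Passing recovery tests therefore demonstrates that
the pipeline's inference is correct under its own model assumptions, not
that it matches external predictors on natural sequences.

## Determinism and problem sizes

Every stochastic component takes an explicit seed; the pipeline derives
per-stage seeds from one top-level seed, and identical configuration +
seed yields byte-identical output files (no timestamps are written). The
bundled verification script (`scripts/acceptance.py`) sizes its
simulations to run in a few minutes on a single CPU: 100 oracle alignment
pairs, 50 generator seeds at L = 600 for parameter recovery, 12 study
seeds for phylogroup recovery, 12 seeds for motif recovery, a 100-replicate
bootstrap, and 100 proteins for the topology screen. These sizes were
chosen so that sampling error is small relative to the tolerances being
checked (e.g. the ±5-point recovery band corresponds to >10 standard
errors at those sizes).

## Reproduction scope for the published panel

The packaged fixtures reproduce every count-level claim about the real
60-allergen panel exactly. Published *pairwise* values on the real
sequences (a 61% similarity for one kiwi–apricot pair; fraction-scale
A-RISC values between 0.67 and 0.97 for named pairs in the largest
phylogroup) are **not** reproduction targets: they require downloading the
accessions' sequences and depend on an unstated alignment dialect. Given a
user-supplied FASTA of those accessions, `allerisc arisc` computes the
corresponding matrix directly, and the configurable alignment conventions
above are the knobs such a best-effort comparison would explore.
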