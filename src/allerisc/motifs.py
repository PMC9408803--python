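"""Conserved-motif discovery by expectation-maximisation (ZOOPS model).

Finds ungapped motifs of width 6-60 shared across protein sequences, in the
style of classic EM motif discovery: each sequence contains zero or one
occurrence (ZOOPS), modelled by a position weight matrix (PWM) against a
fixed 0-order background estimated from the input.  Up to ``max_motifs``
motifs are extracted greedily, masking each motif's occurrences before
searching for the next, and ranked by log-likelihood ratio (LLR).

Seeding follows the subsequence strategy: every subsequence of the trial
width taken from the first ``n_seed_sequences`` input sequences is converted
to a peaked PWM and quick-scored with a single E-step; the best few seeds
are run to convergence.  Widths are scanned over a small grid and the best
LLR-per-column model is kept.  Everything is deterministic for a fixed
configuration, and the (MAP) EM objective is checked to be non-decreasing
at every iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .records import AA20, ProteinRecord

_AA_INDEX = {aa: i for i, aa in enumerate(AA20)}
MASK_INDEX = 20  # neutral symbol for masked / unknown residues
_NEG = -1e30

DEFAULT_WIDTH_GRID = (6, 8, 10, 15, 20, 30, 45, 60)


class EMConvergenceError(RuntimeError):
    """Raised if the EM objective ever decreases — a bug guard, not a user error."""


@dataclass
class MotifSearchConfig:
    max_motifs: int = 8
    width_min: int = 6
    width_max: int = 60
    width_grid: Sequence[int] = DEFAULT_WIDTH_GRID
    mode: str = "zoops"
    pseudocount: float = 0.1
    max_iter: int = 100
    tol: float = 1e-6
    seed: int = 0
    n_seed_sequences: int = 2
    n_refine: int = 3

    def __post_init__(self):
        if self.max_motifs < 1:
            raise ValueError("max_motifs must be >= 1")
        if not (1 <= self.width_min <= self.width_max):
            raise ValueError("require 1 <= width_min <= width_max")
        if self.mode != "zoops":
            raise ValueError("only the ZOOPS occurrence model is supported")

    def widths(self) -> List[int]:
        return [w for w in self.width_grid if self.width_min <= w <= self.width_max]


@dataclass
class MotifModel:
    """A discovered motif: PWM (20 x width), background, occurrences, LLR."""

    width: int
    pwm: np.ndarray
    background: np.ndarray
    occurrences: List[Tuple[str, int, str]]  # (record id, 0-based start, site)
    log_likelihood_ratio: float
    gamma: float = 0.0

    @property
    def consensus(self) -> str:
        return "".join(AA20[i] for i in np.argmax(self.pwm, axis=0))

    def log_odds(self) -> np.ndarray:
        """log2 odds matrix (20 x width) against the motif's background."""
        return np.log2(self.pwm / self.background[:, None])


def encode(sequence: str) -> np.ndarray:
    """Encode a sequence as residue indices; X (and the mask symbol) -> 20."""
    return np.array([_AA_INDEX.get(ch, MASK_INDEX) for ch in sequence], dtype=np.int64)


def estimate_background(encoded: Sequence[np.ndarray], pseudocount: float = 1.0) -> np.ndarray:
    """0-order background frequencies from the input, masked residues excluded."""
    counts = np.full(20, pseudocount)
    for seq in encoded:
        valid = seq[seq < 20]
        counts += np.bincount(valid, minlength=20)
    return counts / counts.sum()


class _WindowIndex:
    """Flattened view of all width-W windows of a dataset, with per-sequence
    segment bookkeeping for vectorised E-steps."""

    def __init__(self, encoded: Sequence[np.ndarray], width: int, log_bg: np.ndarray):
        wins = []
        seq_slices: List[Tuple[int, int]] = []
        n_valid = []
        total = 0
        for seq in encoded:
            if len(seq) < width:
                seq_slices.append((total, total))
                n_valid.append(0)
                continue
            w = np.lib.stride_tricks.sliding_window_view(seq, width)
            wins.append(w)
            seq_slices.append((total, total + len(w)))
            total += len(w)
            n_valid.append(0)  # fill below
        self.width = width
        self.windows = (
            np.concatenate(wins, axis=0) if wins else np.zeros((0, width), dtype=np.int64)
        )
        self.seq_slices = seq_slices
        self.valid = ~(self.windows >= 20).any(axis=1)
        for s, (lo, hi) in enumerate(seq_slices):
            n_valid[s] = int(self.valid[lo:hi].sum())
        self.n_valid = np.array(n_valid)
        safe = np.where(self.windows < 20, self.windows, 0)
        self.safe_windows = safe
        lb = np.concatenate([log_bg, [0.0]])
        self.bg_ll = np.where(self.windows < 20, lb[self.windows], 0.0).sum(axis=1)

    def site_log_lik(self, log_pwm: np.ndarray) -> np.ndarray:
        """Per-window log P(window | motif); invalid windows get -inf-like."""
        cols = np.arange(self.width)
        ll = log_pwm[self.safe_windows, cols].sum(axis=1)
        return np.where(self.valid, ll, _NEG)

    def lambdas(self, log_pwm: np.ndarray) -> np.ndarray:
        return np.where(
            self.valid, self.site_log_lik(log_pwm) - self.bg_ll, _NEG
        )


def _e_step(
    index: _WindowIndex, log_pwm: np.ndarray, gamma: float
) -> Tuple[float, np.ndarray, np.ndarray]:
    """Returns (sum of per-sequence log-likelihoods up to the constant
    background term, per-window posteriors z, per-sequence presence q)."""
    lam = index.lambdas(log_pwm)
    z = np.zeros(len(lam))
    q = np.zeros(len(index.seq_slices))
    ll_total = 0.0
    log_1mg = np.log1p(-gamma)
    for s, (lo, hi) in enumerate(index.seq_slices):
        m = index.n_valid[s]
        if m == 0:
            ll_total += log_1mg
            continue
        a = lam[lo:hi] + np.log(gamma) - np.log(m)
        amax = max(a.max(), log_1mg)
        denom = np.exp(log_1mg - amax) + np.exp(a - amax).sum()
        ll_s = amax + np.log(denom)
        ll_total += ll_s
        z[lo:hi] = np.exp(a - ll_s)
        q[s] = z[lo:hi].sum()
    return ll_total, z, q


def _m_step(
    index: _WindowIndex, z: np.ndarray, q: np.ndarray, pseudocount: float
) -> Tuple[np.ndarray, float]:
    counts = np.full((20, index.width), pseudocount)
    for w in range(index.width):
        col = index.safe_windows[:, w]
        keep = index.valid
        np.add.at(counts[:, w], col[keep], z[keep])
    pwm = counts / counts.sum(axis=0, keepdims=True)
    gamma = float(np.clip(q.mean(), 1e-4, 1 - 1e-4))
    return pwm, gamma


def _map_objective(ll: float, pwm: np.ndarray, pseudocount: float) -> float:
    return ll + pseudocount * float(np.log(pwm).sum())


def _run_em(
    index: _WindowIndex,
    pwm0: np.ndarray,
    gamma0: float,
    cfg: MotifSearchConfig,
) -> Tuple[np.ndarray, float, float]:
    """EM to convergence; asserts the MAP objective is non-decreasing at
    every iteration.  Returns (pwm, gamma, final objective)."""
    pwm, gamma = pwm0, gamma0
    prev = None
    for _ in range(cfg.max_iter):
        ll, z, q = _e_step(index, np.log(pwm), gamma)
        obj = _map_objective(ll, pwm, cfg.pseudocount)
        if prev is not None:
            if obj < prev - 1e-6 * (1.0 + abs(prev)):
                raise EMConvergenceError(
                    f"EM objective decreased: {prev} -> {obj}"
                )
            if obj - prev < cfg.tol * (1.0 + abs(prev)):
                prev = obj
                break
        prev = obj
        pwm, gamma = _m_step(index, z, q, cfg.pseudocount)
    return pwm, gamma, prev if prev is not None else _NEG


def _seed_pwm(window: np.ndarray, background: np.ndarray, weight: float = 0.55) -> np.ndarray:
    width = len(window)
    pwm = np.tile(((1.0 - weight) * background)[:, None], (1, width))
    pwm[window, np.arange(width)] += weight
    return pwm / pwm.sum(axis=0, keepdims=True)


def _hard_occurrences(
    index: _WindowIndex,
    log_pwm: np.ndarray,
    gamma: float,
    record_ids: Sequence[str],
    sequences: Sequence[str],
) -> Tuple[List[Tuple[str, int, str]], float]:
    """ZOOPS decoding: a sequence has an occurrence iff its posterior
    presence exceeds 1/2; the site is the posterior-max window.  Also
    returns the LLR summed over decoded sites."""
    _, z, q = _e_step(index, log_pwm, gamma)
    lam = index.lambdas(log_pwm)
    occ: List[Tuple[str, int, str]] = []
    llr = 0.0
    for s, (lo, hi) in enumerate(index.seq_slices):
        if q[s] <= 0.5 or hi == lo:
            continue
        best = int(np.argmax(z[lo:hi]))
        occ.append(
            (record_ids[s], best, sequences[s][best : best + index.width])
        )
        llr += float(lam[lo + best])
    return occ, llr


def discover_motifs(
    records: Sequence[ProteinRecord], cfg: Optional[MotifSearchConfig] = None
) -> List[MotifModel]:
    """Greedy multi-motif ZOOPS EM discovery.

    Returns up to ``cfg.max_motifs`` motifs sorted by decreasing LLR.
    Occurrences of each motif are masked before the next search round.
    Deterministic for a fixed configuration.
    """
    cfg = cfg or MotifSearchConfig()
    if len(records) < 2:
        raise ValueError("need at least 2 sequences")
    widths = cfg.widths()
    if not widths:
        raise ValueError("width grid is empty within [width_min, width_max]")
    if all(len(r.sequence) < min(widths) for r in records):
        raise ValueError("all sequences are shorter than the minimum motif width")

    record_ids = [r.id for r in records]
    sequences = [r.sequence for r in records]
    encoded = [encode(s) for s in sequences]
    background = estimate_background(encoded)
    log_bg = np.log(background)

    # Width selection: penalise each column by the chance-level LLR a fitted
    # 20-letter column contributes under the null (chi-square mean (A-1)/2
    # plus three standard deviations), so sub-blocks and overhanging columns
    # of a true motif both lose to its actual width.
    a = 19 / 2.0
    column_penalty = a + 3.0 * np.sqrt(a)

    found: List[MotifModel] = []
    for _ in range(cfg.max_motifs):
        best_model: Optional[MotifModel] = None
        best_metric = 0.0
        for width in widths:
            index = _WindowIndex(encoded, width, log_bg)
            if index.valid.sum() == 0:
                continue
            # subsequence seeds from the first n_seed_sequences sequences
            seeds: List[np.ndarray] = []
            seen = set()
            for s in range(min(cfg.n_seed_sequences, len(encoded))):
                lo, hi = index.seq_slices[s]
                for w_i in range(lo, hi):
                    if not index.valid[w_i]:
                        continue
                    key = index.windows[w_i].tobytes()
                    if key not in seen:
                        seen.add(key)
                        seeds.append(index.windows[w_i])
            if not seeds:
                continue
            scored = []
            for seed in seeds:
                pwm0 = _seed_pwm(seed, background)
                ll, _, _ = _e_step(index, np.log(pwm0), 0.5)
                scored.append((ll, seed))
            scored.sort(key=lambda t: -t[0])
            for _, seed in scored[: cfg.n_refine]:
                pwm0 = _seed_pwm(seed, background)
                pwm, gamma, _ = _run_em(index, pwm0, 0.5, cfg)
                occ, llr = _hard_occurrences(
                    index, np.log(pwm), gamma, record_ids, sequences
                )
                if len(occ) < 2:
                    continue
                metric = llr - column_penalty * width
                if metric > best_metric:
                    best_metric = metric
                    best_model = MotifModel(
                        width=width,
                        pwm=pwm,
                        background=background,
                        occurrences=occ,
                        log_likelihood_ratio=llr,
                        gamma=gamma,
                    )
        if best_model is None or best_model.log_likelihood_ratio <= 0:
            break
        found.append(best_model)
        # mask occurrences before hunting the next motif
        for rid, start, _site in best_model.occurrences:
            s = record_ids.index(rid)
            encoded[s] = encoded[s].copy()
            encoded[s][start : start + best_model.width] = MASK_INDEX
    found.sort(key=lambda m: -m.log_likelihood_ratio)
    return found


def motif_presence(
    records: Sequence[ProteinRecord],
    motifs: Sequence[MotifModel],
    score_threshold: float = 0.0,
) -> pd.DataFrame:
    """Presence/absence matrix: a motif is present in a record iff the best
    site log-odds score (natural log, against the motif background) reaches
    *score_threshold*.  Rows are record ids, columns motif_1..motif_k in the
    given order."""
    data = {}
    encoded = [encode(r.sequence) for r in records]
    for k, motif in enumerate(motifs, start=1):
        log_pwm = np.log(motif.pwm)
        log_bg = np.log(motif.background)
        col = []
        for seq in encoded:
            if len(seq) < motif.width:
                col.append(False)
                continue
            index = _WindowIndex([seq], motif.width, log_bg)
            lam = index.lambdas(log_pwm)
            col.append(bool(len(lam) and lam.max() >= score_threshold))
        data[f"motif_{k}"] = col
    return pd.DataFrame(data, index=[r.id for r in records])


def best_site_scores(record: ProteinRecord, motif: MotifModel) -> float:
    """Best log-odds site score of *motif* in *record* (-inf if too short)."""
    seq = encode(record.sequence)
    if len(seq) < motif.width:
        return float("-inf")
    index = _WindowIndex([seq], motif.width, np.log(motif.background))
    return float(index.lambdas(np.log(motif.pwm)).max())


def write_meme_minimal(
    motifs: Sequence[MotifModel], path, alphabet: str = AA20
) -> None:
    """Write motifs in MEME minimal motif text format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\n")
        fh.write(f"ALPHABET= {alphabet}\n\n")
        if motifs:
            fh.write("Background letter frequencies\n")
            bg = motifs[0].background
            fh.write(
                " ".join(f"{aa} {bg[i]:.5f}" for i, aa in enumerate(alphabet)) + "\n\n"
            )
        for k, motif in enumerate(motifs, start=1):
            fh.write(f"MOTIF motif_{k} {motif.consensus}\n")
            fh.write(
                f"letter-probability matrix: alength= {len(alphabet)} "
                f"w= {motif.width} nsites= {len(motif.occurrences)} E= 0\n"
            )
            for col in range(motif.width):
                fh.write(
                    " ".join(f"{motif.pwm[i, col]:.6f}" for i in range(len(alphabet)))
                    + "\n"
                )
            fh.write("\n")
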