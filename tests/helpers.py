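"""Shared test utilities, including the exhaustive alignment oracle."""

from __future__ import annotations

import numpy as np

from allerisc.records import AA20


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AA20[i] for i in rng.integers(0, 20, size=length))


def brute_force_global_score(
    a: str, b: str, matrix, gap_open: float, gap_extend: float
) -> float:
    """Optimal affine-gap global alignment score by exhaustive enumeration of
    every gapped alignment (no gap-gap columns).  A gap run of length k costs
    gap_open + (k - 1) * gap_extend, end gaps included.  Independent of the
    dynamic-programming implementation under test; practical for len <= ~7.
    """
    best = [-np.inf]

    def rec(i: int, j: int, score: float, last: str) -> None:
        if i == len(a) and j == len(b):
            if score > best[0]:
                best[0] = score
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + matrix[a[i], b[j]], "M")
        if i < len(a):
            rec(i + 1, j, score - (gap_extend if last == "A" else gap_open), "A")
        if j < len(b):
            rec(i, j + 1, score - (gap_extend if last == "B" else gap_open), "B")

    rec(0, 0, 0.0, "-")
    return float(best[0])


def mutate_positions(seq: str, k: int, rng: np.random.Generator) -> str:
    """Substitute exactly k distinct positions with a different residue."""
    positions = rng.choice(len(seq), size=k, replace=False)
    chars = list(seq)
    for pos in positions:
        current = chars[pos]
        choices = [aa for aa in AA20 if aa != current]
        chars[pos] = choices[rng.integers(len(choices))]
    return "".join(chars)
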