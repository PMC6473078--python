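"""Independent oracles and small utilities shared by the test modules.

Everything here deliberately re-derives results from first principles
(enumeration, direct formulas) without calling the code paths under test.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def random_genome(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def naive_relative_score(weights: np.ndarray, smin: float, smax: float, word: str) -> float:
    """Left-to-right summed log-odds, min-max scaled to percent."""
    score = 0.0
    for i, b in enumerate(word):
        score += weights[i, BASES.index(b)]
    return 100.0 * ((score - smin) / (smax - smin))


def naive_scan(seq: str, weights: np.ndarray, min_percent: float,
               circular: bool = True) -> set[tuple[int, str]]:
    """Enumerate every window on both strands; return {(position, strand)}.

    Positions wrap on circular sequences; windows containing N are skipped.
    """
    W = weights.shape[0]
    L = len(seq)
    smin = sum(min(weights[i]) for i in range(W))
    smax = sum(max(weights[i]) for i in range(W))
    hits = set()
    n_starts = L if circular else L - W + 1
    for p in range(n_starts):
        word = seq[p : p + W] if p + W <= L else seq[p:] + seq[: p + W - L]
        if "N" in word:
            continue
        for strand, w in (("+", word), ("-", rc(word))):
            if naive_relative_score(weights, smin, smax, w) >= min_percent:
                hits.add((p, strand))
    return hits


def naive_bh(pvalues: list[float]) -> list[float]:
    """Direct step-up enumeration: q_i = min over ranks j >= rank(i) of p_(j)*m/j."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    for rank_pos, idx in enumerate(order):
        q = min(
            pvalues[order[j]] * m / (j + 1)
            for j in range(rank_pos, m)
        )
        adjusted[idx] = min(q, 1.0)
    return adjusted
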