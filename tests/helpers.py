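"""Arithmetic-space brute-force oracles, independent of the log-space kernel.

Everything here works in plain probability space on tiny instances
(short reads, small windows), by direct enumeration — no log-sum-exp, no
closed forms — so it can serve as an independent check of the package's
log-space implementations.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

BASES = "ACGT"


def bf_base_prob(g: str, r: str, e: float) -> float:
    if g == "N" or r == "N":
        return 0.25
    return (1.0 - e) if g == r else e / 3.0


def bf_read_segment_prob(seq: str, e: np.ndarray, segment: str) -> float:
    p = 1.0
    for ri, ei, gi in zip(seq, e, segment):
        p *= bf_base_prob(gi, ri, ei)
    return p


def bf_window_sum(seq: str, e: np.ndarray, window: str, starts=None) -> float:
    ell = len(seq)
    if starts is None:
        starts = range(len(window) - ell + 1)
    return sum(bf_read_segment_prob(seq, e, window[s : s + ell]) for s in starts)


def bf_hamming_sum(seq: str, e: np.ndarray) -> float:
    """Enumerate all 3*l+1 sequences within Hamming distance 1 of seq."""
    total = bf_read_segment_prob(seq, e, seq)
    for i in range(len(seq)):
        for b in BASES:
            if b != seq[i]:
                total += bf_read_segment_prob(seq, e, seq[:i] + b + seq[i + 1 :])
    return total


def bf_read_given_hypothesis(
    seq: str,
    e: np.ndarray,
    windows: list[str],
    paralog_windows: list[str] = (),
    h: float = 0.0,
    m_r: int = 1,
) -> float:
    """Mean over chromosome-copy windows + paralog windows + outside term."""
    p = sum(bf_window_sum(seq, e, w) for w in windows) / len(windows)
    for w in paralog_windows:
        p += bf_window_sum(seq, e, w)
    if h > 0:
        p += m_r * h * bf_hamming_sum(seq, e)
    return p


def bf_marginal_odds(
    reads: list[tuple[str, np.ndarray]],
    hypotheses: list[tuple[bool, float, list[str]]],
    h: float = 0.0,
) -> float:
    """Arithmetic marginal odds.

    ``hypotheses``: (contains_v, prior, windows) triples. Returns
    sum over contains-v of prior * prod_r P[r|G], divided by the same
    over the rest.
    """
    num = den = 0.0
    for contains_v, prior, windows in hypotheses:
        like = prior
        for seq, e in reads:
            like *= bf_read_given_hypothesis(seq, e, windows, h=h)
        if contains_v:
            num += like
        else:
            den += like
    return num / den


def random_read(rng: np.random.Generator, ell: int) -> tuple[str, np.ndarray]:
    seq = "".join(BASES[i] for i in rng.integers(0, 4, size=ell))
    e = rng.uniform(0.001, 0.4, size=ell)
    return seq, e


def random_window(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def rel_err(a: float, b: float) -> float:
    return abs(a - b) / max(abs(a), abs(b), 1e-300)


def enumerate_hypothesis_count(k: int) -> int:
    """Explicit enumeration oracle for 1 + 2*(2^k - 1)."""
    n = 1
    for size in range(1, k + 1):
        n += 2 * math.comb(k, size)
    return n


def all_subsets(k: int) -> list[tuple[int, ...]]:
    out = []
    for size in range(k + 1):
        out.extend(itertools.combinations(range(k), size))
    return out
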