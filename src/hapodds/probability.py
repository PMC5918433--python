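"""Log-space probability kernel for the generative read model.

Everything here is pure: no I/O, no genome coordinates, just reads,
segments and log-probabilities.

The model: a read ``r`` with called sequence ``r*`` and per-base error
probabilities ``e_i`` was sequenced from some read-length substring
(*segment*) ``g`` of the sample genome.  Per base,

    P[g_i | r_i] = 1 - e_i   if r_i == g_i
                 = e_i / 3   otherwise

and ``P[r|g]`` is the product over positions (no indel sequencing errors
are modelled).  ``P[r|G]`` for a genome hypothesis ``G`` is the sum of
``P[r|g]`` over the segments of ``G`` overlapping the read's mapped
location(s) — summing over segment placements absorbs ambiguous gap
placement, and summing over mapped locations absorbs multi-mapping.

Reads that derive from sample sequence absent from the reference
("reference-external" reads, e.g. extra repeat copies) are covered by an
outside-paralog term: ``m_r * h * sum_{f: HD(f, r*) <= 1} prod_i P[f_i|r_i]``
where ``m_r`` is the read's mapping multiplicity and ``h`` a small
constant (default 1e-4).  The Hamming-distance-<=1 sum has the closed form
``prod_i(1-e_i) * (1 + sum_i e_i/(1-e_i))``.

All arithmetic is in natural-log space with log-sum-exp; arithmetic-space
products over 100-base reads would underflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "MappedLocation",
    "ReadObservation",
    "SegmentSet",
    "ParalogParams",
    "base_match_log_prob",
    "read_segment_log_prob",
    "read_given_segments_log_sum",
    "hamming_neighborhood_log_sum",
    "outside_paralog_log_term",
    "read_given_hypothesis_log_prob",
]

# e_i clamped to this range after Phred conversion: e in {0, 1} breaks
# both branches; 0.75 is the uniform-base limit.
ERROR_PROB_FLOOR = 1e-6
ERROR_PROB_CEIL = 0.75

LOG_QUARTER = math.log(0.25)

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class MappedLocation:
    """One place a read maps to: contig, 0-based leftmost position, strand."""

    contig: str
    pos: int
    is_reverse: bool = False


@dataclass
class ReadObservation:
    """One read: called sequence, per-base error probabilities, locations.

    ``called_seq`` is the sequence in reference orientation, as stored in
    standard alignments. ``multiplicity`` is m_r, the number of places the
    read maps to in the reference genome (>= 1).
    """

    read_id: str
    called_seq: str
    error_probs: np.ndarray
    locations: list[MappedLocation] = field(default_factory=list)
    multiplicity: int = 1

    def __post_init__(self) -> None:
        self.error_probs = np.asarray(self.error_probs, dtype=float)
        if len(self.called_seq) == 0:
            raise ValueError("empty read")
        if self.error_probs.shape != (len(self.called_seq),):
            raise ValueError(
                f"read {self.read_id}: {len(self.called_seq)} bases but "
                f"{self.error_probs.shape} error probabilities"
            )
        if not np.all(np.isfinite(self.error_probs)):
            raise ValueError(f"read {self.read_id}: non-finite error probability")
        if np.any(self.error_probs <= 0) or np.any(self.error_probs >= 1):
            raise ValueError(f"read {self.read_id}: error probabilities must be in (0,1)")
        bad = set(self.called_seq) - _VALID_BASES
        if bad:
            raise ValueError(f"read {self.read_id}: invalid bases {sorted(bad)}")
        if self.multiplicity < 1:
            raise ValueError(f"read {self.read_id}: multiplicity must be >= 1")

    def __len__(self) -> int:
        return len(self.called_seq)


@dataclass
class SegmentSet:
    """The read-length substrings of one haplotype window.

    ``segment_starts`` are 0-based offsets into ``window_seq``; the
    segments are exactly the length-``segment_length`` substrings there.
    """

    window_seq: str
    segment_length: int
    segment_starts: list[int]

    def __post_init__(self) -> None:
        lo, hi = 0, len(self.window_seq) - self.segment_length
        for s in self.segment_starts:
            if not lo <= s <= hi:
                raise ValueError(
                    f"segment start {s} outside [0, {hi}] for window of "
                    f"length {len(self.window_seq)}, segment length {self.segment_length}"
                )

    @classmethod
    def all_segments(cls, window_seq: str, segment_length: int) -> "SegmentSet":
        n = len(window_seq) - segment_length
        if n < 0:
            raise ValueError("window shorter than segment length")
        return cls(window_seq, segment_length, list(range(n + 1)))

    def segments(self) -> list[str]:
        ell = self.segment_length
        return [self.window_seq[s : s + ell] for s in self.segment_starts]


@dataclass(frozen=True)
class ParalogParams:
    """Outside-paralog model parameters. ``h=0`` disables the outside source."""

    h: float = 1e-4
    include_outside: bool = True

    def __post_init__(self) -> None:
        if self.h < 0:
            raise ValueError("h must be >= 0")


def _check_error_prob(e: float) -> None:
    if not (math.isfinite(e) and 0.0 < e < 1.0):
        raise ValueError(f"error probability {e!r} not in (0, 1)")


def base_match_log_prob(g: str, r: str, e: float) -> float:
    """log P[g | r, e] for one base: log(1-e) on match, log(e/3) on mismatch.

    ``N`` in either read or segment scores log(1/4) regardless of ``e``
    (maximum-entropy policy for no-call bases).
    """
    _check_error_prob(e)
    if g not in _VALID_BASES or r not in _VALID_BASES:
        raise ValueError(f"invalid base in ({g!r}, {r!r})")
    if g == "N" or r == "N":
        return LOG_QUARTER
    if g == r:
        return math.log1p(-e)
    return math.log(e / 3.0)


def read_segment_log_prob(read: ReadObservation, segment: str) -> float:
    """log P[r|g] = sum_i log P[g_i|r_i] for an equal-length ungapped segment."""
    if len(segment) != len(read):
        raise ValueError(
            f"segment length {len(segment)} != read length {len(read)} "
            "(ungapped comparison requires equal lengths)"
        )
    e = read.error_probs
    r = np.frombuffer(read.called_seq.encode(), dtype=np.uint8)
    g = np.frombuffer(segment.encode(), dtype=np.uint8)
    n_mask = (r == ord("N")) | (g == ord("N"))
    match = r == g
    out = np.where(match, np.log1p(-e), np.log(e / 3.0))
    out = np.where(n_mask, LOG_QUARTER, out)
    return float(out.sum())


def read_given_segments_log_sum(read: ReadObservation, segments: SegmentSet) -> float:
    """Unnormalized log P[r|G] for one window: logsumexp over its segments.

    The uniform segment prior P[g|G] is dropped (proportionality), so this
    is a log-sum, not a log-probability.
    """
    if not segments.segment_starts:
        raise ValueError("empty segment set")
    vals = [read_segment_log_prob(read, g) for g in segments.segments()]
    return float(logsumexp(vals))


def hamming_neighborhood_log_sum(read: ReadObservation) -> float:
    """log sum over all f with HD(f, r*) <= 1 of prod_i P[f_i|r_i].

    Closed form: the exact-match product plus the 3*ell single-substitution
    terms,  prod_i p_match_i * (1 + sum_i 3*p_mis_i / p_match_i),
    where (p_match, p_mis) = (1-e_i, e_i/3), or (1/4, 1/4) at N positions.
    Always <= 0 (a sub-probability), with equality iff ell == 1.
    """
    e = read.error_probs
    r = np.frombuffer(read.called_seq.encode(), dtype=np.uint8)
    n_mask = r == ord("N")
    p_match = np.where(n_mask, 0.25, 1.0 - e)
    p_mis3 = np.where(n_mask, 0.75, e)  # 3 * per-substitution probability
    if np.any(p_match <= 0):
        raise ValueError("error probability of 1 makes the product degenerate")
    if len(read) == 1:
        return 0.0  # HD<=1 covers all four length-1 sequences: total mass exactly 1
    log_exact = float(np.log(p_match).sum())
    return log_exact + math.log1p(float((p_mis3 / p_match).sum()))


def outside_paralog_log_term(read: ReadObservation, params: ParalogParams) -> float:
    """log of m_r * h * (Hamming-neighborhood sum); -inf when disabled."""
    if not params.include_outside or params.h == 0.0:
        return -math.inf
    return (
        math.log(read.multiplicity)
        + math.log(params.h)
        + hamming_neighborhood_log_sum(read)
    )


def read_given_hypothesis_log_prob(
    read: ReadObservation,
    hypothesis_segments: list[SegmentSet],
    inside_paralog_segments: list[SegmentSet] | None = None,
    params: ParalogParams | None = None,
) -> float:
    """Per-read log-likelihood under one genome hypothesis.

    ``hypothesis_segments`` holds one SegmentSet per chromosome copy of the
    hypothesis window (one for reference/homozygous, two for heterozygous);
    the copies are averaged (each copy is an equally likely source), which
    reduces to the plain segment log-sum when there is one copy.
    ``inside_paralog_segments`` are reference windows around the read's
    other mapped locations; they and the outside-paralog term are added to
    the total sum, identically under every hypothesis.
    """
    if not hypothesis_segments:
        raise ValueError("at least one hypothesis segment set required")
    copy_sums = [read_given_segments_log_sum(read, s) for s in hypothesis_segments]
    terms = [float(logsumexp(copy_sums)) - math.log(len(copy_sums))]
    for seg in inside_paralog_segments or []:
        terms.append(read_given_segments_log_sum(read, seg))
    if params is not None:
        out = outside_paralog_log_term(read, params)
        if out > -math.inf:
            terms.append(out)
    return float(logsumexp(terms))


def phred_to_error_prob(quals: np.ndarray) -> np.ndarray:
    """Phred Q -> e = 10^(-Q/10), clamped to [1e-6, 0.75]."""
    e = np.power(10.0, -np.asarray(quals, dtype=float) / 10.0)
    return np.clip(e, ERROR_PROB_FLOOR, ERROR_PROB_CEIL)
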