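"""Scoring orchestration: reads -> per-hypothesis likelihoods -> marginal odds.

For each cluster of candidate variants the evaluator gathers the reads
overlapping its span (reads elsewhere cannot change the hypothesis
ratio), computes log P[R|G] for every genome hypothesis as a sum of
independent per-read terms, and marginalizes: a variant's odds are the
prior-weighted likelihood mass of the hypotheses containing it over the
mass of those not containing it.

The per-read term for a hypothesis sums P[r|g] over every read-length
segment of the hypothesis haplotype window(s) — averaging the two
chromosome copies when heterozygous — plus the read's inside-paralog
segments (reference windows at its other mapped locations) and the
outside-paralog term.  The paralog terms are identical under every
hypothesis, so they act purely as damping on the per-read ratio.

The inner loop is vectorized: for a batch of equal-length reads and one
window, log P[r|g] over all segments factorizes into a constant per read
plus a match-indicator inner product, computed as four matmuls (one per
base) against the window's one-hot sliding segments.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pysam
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import logsumexp

from .hypotheses import (
    DEFAULT_MAX_COMBOS,
    DEFAULT_MAX_DIST,
    DEFAULT_PAD,
    GenomeHypothesis,
    VariantRecord,
    build_hypotheses,
    cluster_variants,
)
from .probability import (
    LOG_QUARTER,
    MappedLocation,
    ParalogParams,
    ReadObservation,
    phred_to_error_prob,
    read_given_segments_log_sum,
    SegmentSet,
)

logger = logging.getLogger(__name__)

DEFAULT_MAX_READS = 10_000
DEFAULT_QUALITY_LESS_Q = 20.0

_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i


@dataclass
class HypothesisLikelihoodTable:
    """Per-hypothesis log P[R|G] for one cluster's reads."""

    cluster_id: int
    hypotheses: list[GenomeHypothesis]
    log_likelihoods: np.ndarray  # shape (n_hypotheses,)
    n_reads: int


@dataclass
class ScoredVariant:
    """A candidate variant with its marginal posterior odds."""

    variant: VariantRecord
    log_odds: float
    posterior: float
    n_reads: int
    n_hypotheses: int
    cluster_id: int
    best_hypothesis: str = ""
    flags: list[str] = field(default_factory=list)


def collect_reads(
    alignments: pysam.AlignmentFile | str,
    contig: str,
    span: tuple[int, int],
    max_reads: int = DEFAULT_MAX_READS,
    min_mapq: int = 0,
    include_duplicates: bool = False,
) -> tuple[list[ReadObservation], list[str]]:
    """Reads whose alignment overlaps ``span`` (0-based half-open).

    Base qualities are converted with e = 10^(-Q/10) and clamped;
    soft-clipped bases are trimmed (the model compares the full read to
    equal-length segments, and clipped bases have no reference
    counterpart).  Secondary/supplementary records contribute the read's
    other mapped locations; the multiplicity m_r comes from an NH tag
    when present, else from the number of alignment records observed for
    the read.  Returns (reads, flags); flags may contain "high_depth".
    """
    close = False
    if isinstance(alignments, (str, bytes)):
        alignments = pysam.AlignmentFile(str(alignments))
        close = True
    flags: list[str] = []
    primaries: dict[tuple[str, bool], dict] = {}
    extra_locs: dict[tuple[str, bool], list[MappedLocation]] = {}
    extra_counts: dict[tuple[str, bool], int] = {}
    try:
        for aln in alignments.fetch(contig, span[0], span[1]):
            if aln.is_unmapped or aln.is_qcfail:
                continue
            if aln.is_duplicate and not include_duplicates:
                continue
            key = (aln.query_name, aln.is_read2)
            if aln.is_secondary or aln.is_supplementary:
                extra_locs.setdefault(key, []).append(
                    MappedLocation(aln.reference_name, aln.reference_start, aln.is_reverse)
                )
                extra_counts[key] = extra_counts.get(key, 0) + 1
                continue
            if aln.mapping_quality < min_mapq:
                continue
            seq = aln.query_alignment_sequence
            if not seq:
                continue
            quals = aln.query_alignment_qualities
            if quals is None:
                warnings.warn(
                    f"read {aln.query_name} has no base qualities; "
                    f"assuming Q{DEFAULT_QUALITY_LESS_Q:g}",
                    stacklevel=2,
                )
                quals = np.full(len(seq), DEFAULT_QUALITY_LESS_Q)
            e = phred_to_error_prob(np.asarray(quals))
            primaries[key] = {
                "seq": seq.upper(),
                "e": e,
                "loc": MappedLocation(aln.reference_name, aln.reference_start, aln.is_reverse),
                "nh": aln.get_tag("NH") if aln.has_tag("NH") else None,
            }
    finally:
        if close:
            alignments.close()

    reads: list[ReadObservation] = []
    for key in sorted(primaries, key=lambda k: (k[0], k[1])):
        info = primaries[key]
        others = extra_locs.get(key, [])
        m_r = info["nh"] if info["nh"] is not None else 1 + extra_counts.get(key, 0)
        read_id = f"{key[0]}/{2 if key[1] else 1}"
        try:
            reads.append(
                ReadObservation(
                    read_id=read_id,
                    called_seq=info["seq"],
                    error_probs=info["e"],
                    locations=[info["loc"], *others],
                    multiplicity=max(1, m_r),
                )
            )
        except ValueError as exc:
            logger.warning("skipping read %s: %s", read_id, exc)
    if len(reads) > max_reads:
        flags.append("high_depth")
        reads = reads[:max_reads]
    return reads, flags


def _encode_reads(reads: list[ReadObservation]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Encode equal-length reads as (codes, per-base log-weights, constants).

    log P[r|g] over a segment = const_r + sum_i w[r,i] * [g_i == r_i] for
    non-N segment bases; N read positions carry weight 0 and contribute
    log(1/4) to the constant.
    """
    ell = len(reads[0])
    codes = np.empty((len(reads), ell), dtype=np.uint8)
    e = np.empty((len(reads), ell))
    for i, r in enumerate(reads):
        codes[i] = _BASE_CODE[np.frombuffer(r.called_seq.encode(), dtype=np.uint8)]
        e[i] = r.error_probs
    n_mask = codes == 4
    log_mis = np.log(e / 3.0)
    w = np.where(n_mask, 0.0, np.log1p(-e) - log_mis)
    const = np.where(n_mask, LOG_QUARTER, log_mis).sum(axis=1)
    return codes, w, const


def _window_logsums(window: str, codes: np.ndarray, w: np.ndarray, const: np.ndarray,
                    reads: list[ReadObservation]) -> np.ndarray:
    """Per-read logsumexp of log P[r|g] over all segments of one window."""
    ell = codes.shape[1]
    if len(window) < ell:
        raise ValueError(f"window ({len(window)} bp) shorter than read length {ell}")
    if "N" in window:  # rare: fall back to the scalar kernel
        seg = SegmentSet.all_segments(window, ell)
        return np.array([read_given_segments_log_sum(r, seg) for r in reads])
    wcodes = _BASE_CODE[np.frombuffer(window.encode(), dtype=np.uint8)]
    segs = sliding_window_view(wcodes, ell)  # (n_seg, ell)
    scores = np.zeros((codes.shape[0], segs.shape[0]))
    for b in range(4):
        wb = np.where(codes == b, w, 0.0)
        scores += wb @ (segs == b).T.astype(float)
    return const + logsumexp(scores, axis=1)


def score_cluster(
    reads: list[ReadObservation],
    hypotheses: list[GenomeHypothesis],
    params: ParalogParams,
    cluster_id: int = 0,
    reference: "object | None" = None,
    pad: int = DEFAULT_PAD,
) -> HypothesisLikelihoodTable:
    """log P[R|G] per hypothesis: per-read independence, fixed read order.

    ``reference`` (any contig-name -> sequence mapping) is needed only
    when some read maps to additional locations, to build the
    inside-paralog reference windows there.
    """
    n_h = len(hypotheses)
    logL = np.zeros(n_h)
    by_len: dict[int, list[ReadObservation]] = {}
    for r in reads:
        by_len.setdefault(len(r), []).append(r)

    for ell, batch in sorted(by_len.items()):
        codes, w, const = _encode_reads(batch)
        # Paralog terms: identical across hypotheses, computed once.
        paralog = np.full(len(batch), -np.inf)
        if params.include_outside and params.h > 0:
            from .probability import outside_paralog_log_term
            paralog = np.array([outside_paralog_log_term(r, params) for r in batch])
        if reference is not None:
            for i, r in enumerate(batch):
                terms = [paralog[i]]
                for loc in r.locations[1:]:
                    if loc.contig not in reference:
                        continue
                    contig_seq = reference[loc.contig]
                    lo = max(0, loc.pos - pad)
                    hi = min(len(contig_seq), loc.pos + ell + pad)
                    win = contig_seq[lo:hi]
                    if len(win) >= ell:
                        terms.append(
                            _window_logsums(win, codes[i : i + 1], w[i : i + 1],
                                            const[i : i + 1], [r])[0]
                        )
                if len(terms) > 1:
                    paralog[i] = logsumexp(terms)

        window_cache: dict[str, np.ndarray] = {}
        for j, h in enumerate(hypotheses):
            copies = []
            usable = True
            for win in h.haplotype_windows:
                if len(win) < ell:
                    usable = False
                    break
                if win not in window_cache:
                    window_cache[win] = _window_logsums(win, codes, w, const, batch)
                copies.append(window_cache[win])
            if not usable:
                logger.warning(
                    "cluster %d: window shorter than read length %d; reads skipped",
                    cluster_id, ell,
                )
                continue
            hyp_term = logsumexp(np.stack(copies), axis=0) - math.log(len(copies))
            per_read = np.logaddexp(hyp_term, paralog)
            logL[j] += float(per_read.sum())
    return HypothesisLikelihoodTable(cluster_id, hypotheses, logL, len(reads))


def marginalize_variant(table: HypothesisLikelihoodTable, v: VariantRecord) -> ScoredVariant:
    """Marginal posterior odds of ``v``: hypotheses with v vs. without.

    log-odds = logsumexp_{G contains v}(log P[G] + log P[R|G])
             - logsumexp_{G without v}(log P[G] + log P[R|G]);
    posterior = odds / (1 + odds) = sigmoid(log-odds).
    """
    weighted = np.array(
        [math.log(h.prior) + ll for h, ll in zip(table.hypotheses, table.log_likelihoods)]
    )
    in_v = np.array([h.contains(v) for h in table.hypotheses])
    flags: list[str] = []
    if not in_v.any():
        return ScoredVariant(v, math.nan, math.nan, table.n_reads,
                             len(table.hypotheses), table.cluster_id,
                             flags=["not_evaluated"])
    log_odds = float(logsumexp(weighted[in_v]) - logsumexp(weighted[~in_v]))
    posterior = float(1.0 / (1.0 + math.exp(-log_odds))) if log_odds < 700 else 1.0
    # Best hypothesis: max posterior weight; float ties broken toward
    # fewer variants (parsimony).
    best = max(
        range(len(table.hypotheses)),
        key=lambda i: (weighted[i], -len(table.hypotheses[i].included_variants)),
    )
    return ScoredVariant(
        v, log_odds, posterior, table.n_reads, len(table.hypotheses),
        table.cluster_id, best_hypothesis=table.hypotheses[best].describe(),
        flags=flags,
    )


def evaluate_variants(
    reference,
    variants: list[VariantRecord],
    alignment_path: str,
    params: ParalogParams | None = None,
    max_dist: int = DEFAULT_MAX_DIST,
    max_combos: int = DEFAULT_MAX_COMBOS,
    pad: int = DEFAULT_PAD,
    max_reads: int = DEFAULT_MAX_READS,
    min_mapq: int = 0,
    include_duplicates: bool = False,
    dump_hypotheses: "list | None" = None,
) -> list[ScoredVariant]:
    """Score every candidate variant: cluster, hypothesize, marginalize.

    Clusters with no overlapping reads are reported with log-odds 0 and a
    ``no_data`` flag rather than omitted.  ``dump_hypotheses``, if a
    list, receives every HypothesisLikelihoodTable for raw inspection.
    """
    if params is None:
        params = ParalogParams()
    scored: list[ScoredVariant] = []
    with pysam.AlignmentFile(alignment_path) as bam:
        for cluster in cluster_variants(variants, max_dist):
            reads, cflags = collect_reads(
                bam, cluster.contig, cluster.span, max_reads=max_reads,
                min_mapq=min_mapq, include_duplicates=include_duplicates,
            )
            if not reads:
                for v in cluster.variants:
                    scored.append(
                        ScoredVariant(v, 0.0, 0.5, 0, 0, cluster.cluster_id,
                                      flags=["no_data"])
                    )
                continue
            read_length = max(len(r) for r in reads)
            hyps = build_hypotheses(
                reference[cluster.contig], cluster, read_length,
                pad=pad, max_combos=max_combos,
            )
            table = score_cluster(reads, hyps, params, cluster_id=cluster.cluster_id,
                                  reference=reference, pad=pad)
            if dump_hypotheses is not None:
                dump_hypotheses.append(table)
            for v in cluster.variants:
                sv = marginalize_variant(table, v)
                sv.flags.extend(cflags)
                scored.append(sv)
    return scored
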