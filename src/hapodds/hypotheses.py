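"""Explicit genome hypotheses from candidate variants.

Candidate variants close enough that one read can span several are
chained into clusters ("mini-haplotypes") and evaluated jointly: every
subset of a cluster's variants, homozygous or heterozygous (never mixed
zygosity), is realized as an explicit haplotype window against which
reads are scored.  The reference hypothesis always gets prior 0.5; the
remaining 0.5 is split evenly among the alternatives, so large clusters
are implicitly penalized for multiple testing.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum

logger = logging.getLogger(__name__)

DEFAULT_MAX_DIST = 10
DEFAULT_MAX_COMBOS = 1024
DEFAULT_PAD = 2


@dataclass(frozen=True)
class VariantRecord:
    """A normalized candidate variant (VCF anchored-allele convention)."""

    contig: str
    pos: int  # 1-based, as in VCF
    ref_allele: str
    alt_allele: str
    source_id: int = -1

    def __post_init__(self) -> None:
        if not self.ref_allele or not self.alt_allele:
            raise ValueError(f"{self.contig}:{self.pos}: empty allele")
        for allele in (self.ref_allele, self.alt_allele):
            if set(allele) - set("ACGTN"):
                raise ValueError(f"{self.contig}:{self.pos}: non-ACGTN allele {allele}")

    @property
    def start(self) -> int:
        """0-based start of the reference bases this variant affects."""
        return self.pos - 1

    @property
    def end(self) -> int:
        """0-based exclusive end of the affected reference interval."""
        return self.pos - 1 + len(self.ref_allele)

    @property
    def is_snp(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1

    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref_allele, self.alt_allele)

    def __str__(self) -> str:
        return f"{self.contig}:{self.pos}:{self.ref_allele}>{self.alt_allele}"


@dataclass
class VariantCluster:
    """A transitively chained group of nearby variants on one contig."""

    variants: list[VariantRecord]
    cluster_id: int = 0

    @property
    def contig(self) -> str:
        return self.variants[0].contig

    @property
    def span(self) -> tuple[int, int]:
        """0-based half-open interval covering all affected reference bases."""
        return (min(v.start for v in self.variants), max(v.end for v in self.variants))


class Zygosity(str, Enum):
    REFERENCE = "reference"
    HETEROZYGOUS = "heterozygous"
    HOMOZYGOUS = "homozygous"


@dataclass
class GenomeHypothesis:
    """One explicit sample-genome hypothesis for a cluster.

    ``haplotype_windows`` holds one window sequence per distinct chromosome
    copy: the reference window alone (reference hypothesis), the variant
    window alone (homozygous), or reference + variant (heterozygous).
    ``variant_mark_starts`` are the variant-window segment starts whose
    length-l segment overlaps at least one applied variant.
    """

    included_variants: tuple[VariantRecord, ...]
    zygosity: Zygosity
    haplotype_windows: list[str] = field(default_factory=list)
    prior: float = 0.0
    window_start: int = 0
    variant_mark_starts: frozenset[int] = frozenset()

    @property
    def is_reference(self) -> bool:
        return self.zygosity is Zygosity.REFERENCE

    def contains(self, v: VariantRecord) -> bool:
        return any(u.key() == v.key() for u in self.included_variants)

    def describe(self) -> str:
        if self.is_reference:
            return "reference"
        names = ",".join(str(v) for v in self.included_variants)
        return f"{self.zygosity.value}[{names}]"


def cluster_variants(
    variants: list[VariantRecord], max_dist: int = DEFAULT_MAX_DIST
) -> list[VariantCluster]:
    """Chain variants whose reference-affected intervals are within ``max_dist``.

    Single-linkage and transitive: the clusters partition the (sorted)
    input.  The gap is measured from the end of one affected interval to
    the start of the next, so multi-base indel REF alleles chain by their
    full footprint rather than their POS field.
    """
    for a, b in itertools.pairwise(variants):
        if (a.contig, a.pos) > (b.contig, b.pos):
            raise ValueError(
                f"variants not sorted by (contig, pos): {a} before {b}"
            )
    clusters: list[VariantCluster] = []
    current: list[VariantRecord] = []
    current_end = 0
    for v in variants:
        if current and v.contig == current[0].contig and v.start - current_end <= max_dist:
            current.append(v)
            current_end = max(current_end, v.end)
        else:
            if current:
                clusters.append(VariantCluster(current, cluster_id=len(clusters)))
            current = [v]
            current_end = v.end
    if current:
        clusters.append(VariantCluster(current, cluster_id=len(clusters)))
    return clusters


def _subset_overlaps(subset: tuple[VariantRecord, ...]) -> bool:
    for a, b in itertools.pairwise(subset):
        if b.start < a.end:
            return True
    return False


def enumerate_subsets(k: int, max_combos: int = DEFAULT_MAX_COMBOS) -> list[tuple[int, ...]]:
    """Variant-inclusion combinations (index tuples), empty set first.

    All 2^k subsets when 2^k <= max_combos.  Beyond the cap: the empty
    set, every singleton, the full set, then subsets by increasing size
    until ``max_combos`` combinations are selected.
    """
    if 2**k <= max_combos:
        out: list[tuple[int, ...]] = []
        for size in range(k + 1):
            out.extend(itertools.combinations(range(k), size))
        return out
    selected: list[tuple[int, ...]] = [()]
    selected.extend((i,) for i in range(k))
    selected.append(tuple(range(k)))
    seen = set(selected)
    for size in range(2, k):
        for combo in itertools.combinations(range(k), size):
            if len(selected) >= max_combos:
                return selected
            if combo not in seen:
                selected.append(combo)
                seen.add(combo)
    return selected[:max_combos]


def enumerate_hypotheses(
    cluster: VariantCluster, max_combos: int = DEFAULT_MAX_COMBOS
) -> list[GenomeHypothesis]:
    """Reference hypothesis + (het, hom) for each non-empty variant subset.

    Mixed-zygosity combinations are not considered.  Subsets whose
    variants overlap on the reference (mutually exclusive alleles) are
    skipped with a warning; singletons are always kept.  For k variants
    under the cap this yields 1 + 2*(2^k - 1) hypotheses.
    """
    if not cluster.variants:
        raise ValueError("empty cluster")
    hyps: list[GenomeHypothesis] = []
    for idx in enumerate_subsets(len(cluster.variants), max_combos):
        subset = tuple(cluster.variants[i] for i in idx)
        if not subset:
            hyps.append(GenomeHypothesis((), Zygosity.REFERENCE))
            continue
        if _subset_overlaps(subset):
            logger.debug(
                "cluster %d: skipping overlapping subset %s",
                cluster.cluster_id,
                [str(v) for v in subset],
            )
            continue
        hyps.append(GenomeHypothesis(subset, Zygosity.HETEROZYGOUS))
        hyps.append(GenomeHypothesis(subset, Zygosity.HOMOZYGOUS))
    return hyps


def assign_priors(hypotheses: list[GenomeHypothesis]) -> list[GenomeHypothesis]:
    """Reference prior 0.5; each alternative 0.5/(total - 1). Sums to 1."""
    n_ref = sum(1 for h in hypotheses if h.is_reference)
    if n_ref != 1:
        raise ValueError(f"expected exactly one reference hypothesis, got {n_ref}")
    n_alt = len(hypotheses) - 1
    if n_alt == 0:
        raise ValueError("degenerate cluster: no alternative hypotheses")
    for h in hypotheses:
        h.prior = 0.5 if h.is_reference else 0.5 / n_alt
    return hypotheses


def apply_variants(window: str, window_start: int, subset: tuple[VariantRecord, ...]) -> str:
    """Apply anchored substitutions/insertions/deletions right-to-left."""
    out = window
    for v in sorted(subset, key=lambda v: v.start, reverse=True):
        off = v.start - window_start
        if off < 0 or off + len(v.ref_allele) > len(window):
            raise ValueError(f"variant {v} does not fit in window")
        observed = window[off : off + len(v.ref_allele)]
        if observed != v.ref_allele:
            raise ValueError(
                f"variant {v}: REF allele {v.ref_allele!r} does not match "
                f"window sequence {observed!r}"
            )
        out = out[:off] + v.alt_allele + out[off + len(v.ref_allele) :]
    return out


@dataclass
class HaplotypeWindowPair:
    window_start: int  # 0-based reference coordinate of the window's left edge
    ref_window: str
    var_window: str
    variant_mark_starts: frozenset[int]


def build_haplotype_window(
    reference: str,
    cluster: VariantCluster,
    subset: tuple[VariantRecord, ...],
    read_length: int,
    pad: int = DEFAULT_PAD,
) -> HaplotypeWindowPair:
    """Reference and variant windows around a cluster, plus segment marks.

    The window is the reference slice ``[span.start - read_length - pad,
    span.end + read_length + pad)`` clipped to the contig, wide enough
    that every read overlapping the cluster finds all its shifted
    segments.  Marks record which length-``read_length`` segment starts of
    the variant window overlap at least one applied variant.
    """
    lo, hi = cluster.span
    start = max(0, lo - read_length - pad)
    end = min(len(reference), hi + read_length + pad)
    ref_window = reference[start:end]
    var_window = apply_variants(ref_window, start, subset)

    # Each applied variant's alt allele occupies, in variant-window
    # coordinates, its window offset shifted by the net length change of
    # the subset variants to its left.
    marks: set[int] = set()
    max_start = len(var_window) - read_length
    for v in subset:
        shift = sum(
            len(u.alt_allele) - len(u.ref_allele) for u in subset if u.start < v.start
        )
        a = v.start - start + shift
        b = a + len(v.alt_allele)
        for s in range(max(0, a - read_length + 1), min(max_start, b - 1) + 1):
            marks.add(s)
    return HaplotypeWindowPair(start, ref_window, var_window, frozenset(marks))


def build_hypotheses(
    reference: str,
    cluster: VariantCluster,
    read_length: int,
    pad: int = DEFAULT_PAD,
    max_combos: int = DEFAULT_MAX_COMBOS,
) -> list[GenomeHypothesis]:
    """Enumerate, realize as haplotype windows, and assign priors."""
    hyps = enumerate_hypotheses(cluster, max_combos)
    realized: list[GenomeHypothesis] = []
    pair_cache: dict[tuple, HaplotypeWindowPair] = {}
    for h in hyps:
        key = tuple(v.key() for v in h.included_variants)
        if key not in pair_cache:
            try:
                pair_cache[key] = build_haplotype_window(
                    reference, cluster, h.included_variants, read_length, pad
                )
            except ValueError as exc:
                if len(h.included_variants) == 1:
                    raise
                warnings.warn(f"skipping subset: {exc}", stacklevel=2)
                pair_cache[key] = None  # type: ignore[assignment]
        pair = pair_cache[key]
        if pair is None:
            continue
        h.window_start = pair.window_start
        h.variant_mark_starts = pair.variant_mark_starts
        if h.is_reference:
            h.haplotype_windows = [pair.ref_window]
        elif h.zygosity is Zygosity.HOMOZYGOUS:
            h.haplotype_windows = [pair.var_window]
        else:
            h.haplotype_windows = [pair.ref_window, pair.var_window]
        realized.append(h)
    return assign_priors(realized)
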