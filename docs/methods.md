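# Methods

## The model

`hapodds` re-scores candidate variants by asking, for each one, how much
more likely the observed reads are under a sample genome that carries
the variant than under one that does not. Rather than counting alleles
in a pileup, it builds *explicit* candidate genome sequences and
computes a generative likelihood for the read data under each.

### Per-read likelihood

A genome hypothesis `G` is represented, locally, as the multiset of its
read-length substrings ("segments"). A read `r` with called sequence
`r*` of length `ℓ` and per-base error probabilities `e_i` (from the
Phred qualities, `e = 10^(-Q/10)`) is scored against a segment `g` as

    P[r|g] = ∏_i P[g_i | r_i],   P[g_i|r_i] = 1 - e_i   if r_i = g_i
                                             = e_i / 3   otherwise,

assuming no indel sequencing errors, and against the hypothesis as the
sum of `P[r|g]` over the segments overlapping the read's mapped
location(s). Two properties follow directly:

* **Gap-placement ambiguity is absorbed.** Every shifted placement of
  the read against the local haplotype contributes, so the aligner's
  particular gap placement never matters; CIGAR indels in the input are
  deliberately ignored (only the called sequence, qualities and
  leftmost position are used).
* **Multi-mapping is absorbed.** Segments from every location a read
  maps to contribute. Since these "inside-paralog" contributions are
  identical under every hypothesis, they act purely to damp per-read
  likelihood ratios toward 1.

Two standard approximations keep this tractable: reads not overlapping
a candidate's neighborhood are ignored (they cancel in the ratio), and
for the remaining reads only segments overlapping the read's mapped
locations are summed. Concretely we sum all segments of the hypothesis
window built around the cluster (see below), which is the superset of
placements reachable by any overlapping read.

### Diploidy and the heterozygous hypothesis

A heterozygous hypothesis has one chromosome copy equal to the
reference window and one carrying the variant(s). Its per-read term is
the *mean* of the two copies' segment sums (each copy is an equally
likely source); for homozygous and reference hypotheses the single
distinct copy's sum is used as-is. Within one copy the segment sum is
left unnormalized, as the uniform-coverage segment prior is dropped
proportionally. When reference and variant windows differ in length
(indels) their segment counts differ by the net indel length; we do not
re-normalize for this — the discrepancy is at most a few parts in a
hundred for windows of ~200 bp and short indels, and applies equally to
every read.

### Variant clusters and hypothesis enumeration

Variants whose reference footprints lie within 10 bp of each other
(measured between affected intervals, so long deletion alleles chain by
their full extent) are chained transitively into clusters. For a
cluster of `k` variants, every inclusion subset is realized both
heterozygously and homozygously — never mixed zygosity — giving
`1 + 2·(2^k − 1)` hypotheses, with the subset count (including the
empty set) capped at 1024, i.e. all combinations up to `k = 10`. Above
the cap we keep, in order: the empty set, all singletons, the full set,
then subsets by increasing size. Subsets containing mutually
overlapping alleles (two alternatives claiming the same reference base)
are skipped; singletons always survive.

Priors implement a multiple-testing-style correction: the reference
hypothesis always gets 0.5 and the remaining 0.5 is split evenly among
the alternatives. This prior is a belief about the *candidate list*,
not about population polymorphism rates.

### Marginal posterior odds

For a variant `v` in a cluster with hypothesis set `G`:

    odds(v) = Σ_{G ∋ v} P[G] P[R|G]  /  Σ_{G ∌ v} P[G] P[R|G]

where the denominator set includes hypotheses carrying *other* cluster
variants but not `v`, and `P[R|G]` is the product of per-read terms.
Reported per variant: the natural-log odds, the posterior
`odds/(1+odds)`, and the maximum-a-posteriori hypothesis descriptor
(ties broken toward fewer variants). Ranking by log-odds and by
posterior are the same ordering.

### Outside source of reads

Reads may derive from sample sequence with no counterpart in the
reference (extra repeat copies — "reference-external" reads). Forcing
such reads to be explained inside the reference framework lets them
masquerade as variant evidence. Each read therefore also carries an
outside-paralog term

    m_r · h · Σ_{f: HD(f, r*) ≤ 1} ∏_i P[f_i|r_i]

added to every hypothesis's per-read sum, where `m_r` is the read's
mapping multiplicity, HD is Hamming distance, and `h` (default `1e-4`)
scales the term. The neighborhood sum has the closed form
`∏(1−e_i) · (1 + Σ e_i/(1−e_i))` — the exact-match product plus all
`3ℓ` single-substitution products — and is a sub-probability, exactly 1
only at `ℓ = 1`. A read that matches no hypothesis window well (more
mismatches than its qualities explain) is dominated by this floor under
*every* hypothesis, so its misleading ratio collapses toward 1; a read
that matches some window well is unaffected, because the floor is ~4
orders of magnitude below a clean match. `h = 0` disables the term
(`score --h-param 0`).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `max_dist` | 10 bp | chaining distance between variants' reference footprints |
| `max_combos` | 1024 | cap on inclusion subsets per cluster (all subsets for k ≤ 10) |
| `h` | 1e-4 | outside-paralog scale; 0 disables |
| `pad` | 2 bp | window margin beyond one read length on each side |
| `min_mapq` | 0 | no mapping-quality filter by default — the outside term is the mechanism for dubious reads |
| `max_reads` | 10 000 | per-cluster cap; deeper clusters are truncated and flagged `high_depth` |

Error probabilities are clamped to `[1e-6, 0.75]` after Phred
conversion (`e ∈ {0,1}` breaks both branches of the base model; 0.75 is
the uniform-base limit). `N` bases, in read or segment, score
probability 1/4 regardless of quality. Reads without quality strings
are assigned Q20 with a warning. Soft-clipped bases are trimmed before
scoring, since clipped bases have no counterpart under the
equal-length-segment comparison.

## Numerical choices

All probability arithmetic is in natural-log space with log-sum-exp;
products over 100-base reads underflow double precision by hundreds of
orders of magnitude. The inner loop is vectorized: for a batch of
equal-length reads against one window, `log P[r|g]` decomposes into a
per-read constant plus an inner product of per-base log-weights with
the segment's match indicators, evaluated as four matrix products (one
per base) against the window's one-hot sliding segments; windows
containing `N` fall back to the scalar kernel. Summation order is fixed
(reads by identifier, then hypothesis index), so identical inputs give
bit-identical outputs. Arithmetic-space brute-force enumeration exists
only in the test suite and acceptance script, as an independent oracle;
on instances with `ℓ ≤ 10` and windows ≤ 50 bp the two routes agree to
better than 1e-12 relative.

Degenerate cases: a cluster with no overlapping reads is reported with
log-odds 0, posterior 0.5 and a `no_data` flag rather than dropped; a
variant excluded from every enumerated subset by the combination cap is
flagged `not_evaluated`.

## The simulator

The bundled generator emulates a small-scale version of a
diploid-resequencing benchmark: a random contig (default 100 kb), 50
planted variants (30 SNPs, 10 insertions, 10 deletions; indel lengths
geometric with p = 0.5, capped at 10 bp; half heterozygous with random
phase), paired-end 100 bp reads with insert 500 ± 30 bp at 30×
coverage, and per-base errors drawn to match their Phred qualities
(uniform Q20 by default, or a per-cycle profile). Decoy candidates —
planted in the VCF but absent from the sample genome — are placed at
least two read lengths from any truth variant, and truth labels are
written to a sidecar TSV; correctness in evaluation is exact sequence +
position match, zygosity ignored. A separate fixture copies a 1-kb
region, mutates it at 3% divergence, and emits reads from the copy at
the original coordinates while only the original exists in the
reference, exercising the outside-paralog term.

Reads are emitted at their *true* source positions, projected from
haplotype to reference coordinates through the variant map, with a
plain `<ℓ>M` CIGAR. This isolates the scorer from mapper behavior: what
passing tests show is that the probabilistic machinery ranks true
variation above noise when alignment positions are correct. They do not
show robustness to mapper artifacts (misplaced alignments, clipped
alignments at structural breakpoints), to quality miscalibration, or to
real-genome repeat structure and variant-density heterogeneity — random
sequence contains far less low-complexity repetition than a real
chromosome, which is precisely where re-scoring is hardest. The
external-copy fixture reintroduces one such artifact class
(reference-external reads) deliberately.

Problem sizes in the test suite and the acceptance script (100-kb
contigs, a handful of seeds, 1000+ randomized oracle instances) were
chosen so a full run completes in well under a minute each on one core
while keeping binomial noise on measured fractions small against the
asserted margins.

## Known limitations

* Indel *sequencing* errors are not modelled inside `P[r|g]`; indel
  variation is handled at the hypothesis level only.
* Mates of a pair are scored as independent reads; insert-size
  information is unused.
* No phasing across clusters; zygosity is reported descriptively
  (best hypothesis), not called.
* The candidate VCF is assumed normalized; a shared REF/ALT suffix
  triggers a left-alignment warning but no automatic normalization.
* `m_r` relies on an `NH` tag or on alignment records visible near the
  cluster; hits recorded only in distant parts of the file are not
  counted.
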