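"""Synthetic diploid genomes and error-bearing reads, at toy scale.

The generator plants SNPs and short indels (mixed zygosity) in a random
reference contig, builds the two haplotype sequences, and draws reads —
paired-end 100 bp with insert 500±30 at 30x coverage by default — with
per-base errors matching their Phred qualities.  Reads are emitted at
their TRUE source positions (projected from haplotype to reference
coordinates), isolating the scorer from mapper behavior.  Decoy
candidates (planted in the VCF but absent from the sample genome) allow
precision/recall evaluation against a known truth set; a separate
fixture simulates reads from a diverged off-reference copy of a region
to exercise the outside-paralog damping term.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .hypotheses import VariantRecord

BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}

# Minimum spacing between planted sites keeps planted alleles mutually
# non-overlapping even for capped-length indels.
MIN_SITE_SPACING = 25


@dataclass
class SimulationConfig:
    contig_name: str = "sim1"
    contig_length: int = 100_000
    seed: int = 0
    n_snps: int = 30
    n_insertions: int = 10
    n_deletions: int = 10
    het_fraction: float = 0.5
    coverage: float = 30.0
    read_length: int = 100
    base_quality: float = 20.0
    quality_profile: tuple[float, ...] | None = None  # per-cycle Phred Q
    paired: bool = True
    insert_mean: float = 500.0
    insert_sd: float = 30.0
    n_decoys: int = 50
    indel_geom_p: float = 0.5
    indel_max_len: int = 10

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.read_length < 20:
            raise ValueError("read length must be >= 20")
        if self.quality_profile is not None and len(self.quality_profile) != self.read_length:
            raise ValueError("quality profile length must equal read length")

    def error_probs(self) -> np.ndarray:
        q = (
            np.asarray(self.quality_profile, dtype=float)
            if self.quality_profile is not None
            else np.full(self.read_length, self.base_quality)
        )
        return np.power(10.0, -q / 10.0)

    def qualities(self) -> np.ndarray:
        q = (
            np.asarray(self.quality_profile, dtype=float)
            if self.quality_profile is not None
            else np.full(self.read_length, self.base_quality)
        )
        return np.rint(q).astype(np.uint8)


@dataclass
class PlantedVariant:
    variant: VariantRecord
    zygosity: str  # "het" | "hom"
    haplotype: int | None  # 0/1 for het, None for hom


@dataclass
class SimulatedGenome:
    config: SimulationConfig
    reference: str
    haplotypes: tuple[str, str]
    hap_to_ref: tuple[np.ndarray, np.ndarray]  # per-haplotype base -> ref position
    truth: list[PlantedVariant]


@dataclass
class SimulatedRead:
    name: str
    pos: int  # 0-based reference leftmost
    seq: str
    quals: np.ndarray
    flag: int = 0
    mate_pos: int = -1
    tlen: int = 0


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def _other_base(rng: np.random.Generator, base: str) -> str:
    return BASES[(_BASE_IDX[base] + int(rng.integers(1, 4))) % 4]


def _sample_sites(
    rng: np.random.Generator,
    n: int,
    lo: int,
    hi: int,
    existing: list[int],
    spacing: int = MIN_SITE_SPACING,
) -> list[int]:
    sites = list(existing)
    chosen: list[int] = []
    attempts = 0
    while len(chosen) < n:
        attempts += 1
        if attempts > 1000 * max(n, 1):
            raise ValueError(
                f"cannot place {n} sites with spacing {spacing} in [{lo}, {hi})"
            )
        p = int(rng.integers(lo, hi))
        if all(abs(p - q) >= spacing for q in sites):
            sites.append(p)
            chosen.append(p)
    return sorted(chosen)


def _geometric_len(rng: np.random.Generator, p: float, cap: int) -> int:
    return min(int(rng.geometric(p)), cap)


def build_diploid_genome(config: SimulationConfig) -> SimulatedGenome:
    """Random reference + planted variants realized on two haplotypes."""
    rng = np.random.default_rng([config.seed, 11])
    L = config.contig_length
    ref = random_sequence(rng, L)
    n_total = config.n_snps + config.n_insertions + config.n_deletions
    margin = config.read_length + config.indel_max_len + 2
    if n_total * MIN_SITE_SPACING > L - 2 * margin:
        raise ValueError("more variants requested than positions available")
    positions = _sample_sites(rng, n_total, margin, L - margin, [])
    kinds = ["snp"] * config.n_snps + ["ins"] * config.n_insertions + ["del"] * config.n_deletions
    rng.shuffle(kinds)  # type: ignore[arg-type]

    truth: list[PlantedVariant] = []
    for pos0, kind in zip(positions, kinds):
        if kind == "snp":
            ref_allele = ref[pos0]
            alt_allele = _other_base(rng, ref_allele)
        elif kind == "ins":
            ln = _geometric_len(rng, config.indel_geom_p, config.indel_max_len)
            ref_allele = ref[pos0]
            alt_allele = ref_allele + random_sequence(rng, ln)
        else:
            ln = _geometric_len(rng, config.indel_geom_p, config.indel_max_len)
            ref_allele = ref[pos0 : pos0 + 1 + ln]
            alt_allele = ref[pos0]
        v = VariantRecord(config.contig_name, pos0 + 1, ref_allele, alt_allele)
        if rng.random() < config.het_fraction:
            truth.append(PlantedVariant(v, "het", int(rng.integers(2))))
        else:
            truth.append(PlantedVariant(v, "hom", None))

    haplotypes: list[str] = []
    maps: list[np.ndarray] = []
    for hap in (0, 1):
        pieces: list[str] = []
        idx: list[np.ndarray] = []
        cur = 0
        for pv in truth:
            if pv.zygosity == "het" and pv.haplotype != hap:
                continue
            v = pv.variant
            pieces.append(ref[cur : v.start])
            idx.append(np.arange(cur, v.start))
            alt_map = np.minimum(v.start + np.arange(len(v.alt_allele)), v.end - 1)
            pieces.append(v.alt_allele)
            idx.append(alt_map)
            cur = v.end
        pieces.append(ref[cur:])
        idx.append(np.arange(cur, L))
        haplotypes.append("".join(pieces))
        maps.append(np.concatenate(idx))
    return SimulatedGenome(config, ref, (haplotypes[0], haplotypes[1]),
                           (maps[0], maps[1]), truth)


def _apply_errors(rng: np.random.Generator, seq: str, e: np.ndarray) -> str:
    codes = np.array([_BASE_IDX[b] for b in seq], dtype=np.int64)
    err = rng.random(len(seq)) < e
    if err.any():
        codes[err] = (codes[err] + rng.integers(1, 4, size=int(err.sum()))) % 4
    return "".join(BASES[c] for c in codes)


def simulate_reads(genome: SimulatedGenome, config: SimulationConfig | None = None) -> list[SimulatedRead]:
    """Draw reads uniformly from either haplotype with per-base errors.

    Paired fragments have normally distributed insert sizes; both mates
    are emitted in reference orientation with true projected positions
    and a plain ``<l>M`` CIGAR (gap placement is the scorer's job, not
    the simulator's).
    """
    if config is None:
        config = genome.config
    rng = np.random.default_rng([config.seed, 23])
    ell = config.read_length
    e = config.error_probs()
    quals = config.qualities()
    L = config.contig_length
    n_ends = max(1, int(round(config.coverage * L / ell)))
    n_frag = max(1, n_ends // 2) if config.paired else n_ends
    reads: list[SimulatedRead] = []
    for f in range(n_frag):
        name = f"sim{f:07d}"
        for _attempt in range(100):
            hap = int(rng.integers(2))
            hseq, hmap = genome.haplotypes[hap], genome.hap_to_ref[hap]
            if config.paired:
                insert = int(round(rng.normal(config.insert_mean, config.insert_sd)))
                insert = max(2 * ell, min(insert, len(hseq)))
                start = int(rng.integers(0, len(hseq) - insert + 1))
                spans = [(start, start + ell), (start + insert - ell, start + insert)]
            else:
                start = int(rng.integers(0, len(hseq) - ell + 1))
                spans = [(start, start + ell)]
            poss = [int(hmap[s]) for s, _ in spans]
            if any(p + ell > L for p in poss):
                continue  # deletion near the contig end pushes the M-span off
            break
        else:
            continue
        mates = []
        for (s, t), pos in zip(spans, poss):
            mates.append(SimulatedRead(name, pos, _apply_errors(rng, hseq[s:t], e),
                                       quals.copy()))
        if config.paired:
            r1, r2 = mates
            tlen = r2.pos + ell - r1.pos
            r1.flag = 0x1 | 0x2 | 0x20 | 0x40
            r2.flag = 0x1 | 0x2 | 0x10 | 0x80
            r1.mate_pos, r2.mate_pos = r2.pos, r1.pos
            r1.tlen, r2.tlen = tlen, -tlen
        reads.extend(mates)
    return reads


def make_decoy_candidates(
    genome: SimulatedGenome,
    n_decoys: int | None = None,
    snp_fraction: float = 0.6,
) -> tuple[list[VariantRecord], dict[tuple, str]]:
    """Candidate VCF records = truth + decoys; labels keyed by variant.

    Decoys are placed at least 2*read_length from every truth variant so
    each false candidate's evidence window is truth-free.  A candidate is
    labeled "truth" only on exact (contig, pos, ref, alt) match.
    """
    config = genome.config
    if n_decoys is None:
        n_decoys = config.n_decoys
    rng = np.random.default_rng([config.seed, 37])
    ref = genome.reference
    margin = config.read_length + config.indel_max_len + 2
    truth_sites = [pv.variant.start for pv in genome.truth]
    decoys: list[VariantRecord] = []
    positions = _sample_sites(
        rng, n_decoys, margin, config.contig_length - margin,
        truth_sites, spacing=2 * config.read_length,
    )
    for pos0 in positions:
        u = rng.random()
        if u < snp_fraction:
            ref_allele = ref[pos0]
            alt_allele = _other_base(rng, ref_allele)
        elif u < snp_fraction + (1 - snp_fraction) / 2:
            ln = _geometric_len(rng, config.indel_geom_p, config.indel_max_len)
            ref_allele = ref[pos0]
            alt_allele = ref_allele + random_sequence(rng, ln)
        else:
            ln = _geometric_len(rng, config.indel_geom_p, config.indel_max_len)
            ref_allele = ref[pos0 : pos0 + 1 + ln]
            alt_allele = ref[pos0]
        decoys.append(VariantRecord(config.contig_name, pos0 + 1, ref_allele, alt_allele))

    truth_keys = {pv.variant.key() for pv in genome.truth}
    candidates = sorted(
        [pv.variant for pv in genome.truth] + decoys,
        key=lambda v: (v.contig, v.pos, v.ref_allele, v.alt_allele),
    )
    labels = {v.key(): ("truth" if v.key() in truth_keys else "decoy") for v in candidates}
    return candidates, labels


def simulate_external_copy(
    genome: SimulatedGenome,
    region_start: int,
    region_length: int = 1000,
    divergence: float = 0.03,
    coverage: float = 30.0,
    seed_stream: int = 53,
) -> tuple[list[SimulatedRead], list[VariantRecord]]:
    """Reads from a diverged off-reference copy, aligned to the original.

    Emulates an extra repeat copy present in the sample but absent from
    the reference: the region is copied, mutated at the given divergence,
    and single-end reads from the copy are emitted at the coordinates of
    the ORIGINAL region.  The divergent sites, read as SNP candidates
    against the reference, are returned as decoy variants — apparent
    variation that no reference-framework hypothesis explains.
    """
    config = genome.config
    rng = np.random.default_rng([config.seed, seed_stream])
    ell = config.read_length
    region = genome.reference[region_start : region_start + region_length]
    codes = np.array([_BASE_IDX[b] for b in region], dtype=np.int64)
    div = rng.random(region_length) < divergence
    codes[div] = (codes[div] + rng.integers(1, 4, size=int(div.sum()))) % 4
    copy_seq = "".join(BASES[c] for c in codes)
    decoys = [
        VariantRecord(config.contig_name, region_start + i + 1, region[i], copy_seq[i])
        for i in np.flatnonzero(div)
    ]
    e = config.error_probs()
    quals = config.qualities()
    n_reads = max(1, int(round(coverage * region_length / ell)))
    reads = []
    for f in range(n_reads):
        start = int(rng.integers(0, region_length - ell + 1))
        reads.append(
            SimulatedRead(
                f"ext{f:05d}", region_start + start,
                _apply_errors(rng, copy_seq[start : start + ell], e), quals.copy(),
            )
        )
    return reads, decoys


# ---------------------------------------------------------------------------
# Writers


def write_fasta(path: Path, name: str, seq: str, width: int = 70) -> None:
    with open(path, "w") as out:
        out.write(f">{name}\n")
        for i in range(0, len(seq), width):
            out.write(seq[i : i + width] + "\n")
    pysam.faidx(str(path))


def write_vcf(path: Path, contig: str, contig_length: int,
              records: list[VariantRecord], info: dict[tuple, str] | None = None) -> None:
    with open(path, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        out.write(f"##contig=<ID={contig},length={contig_length}>\n")
        out.write('##INFO=<ID=ZYG,Number=1,Type=String,Description="Planted zygosity">\n')
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(records, key=lambda v: (v.pos, v.ref_allele, v.alt_allele)):
            tag = info.get(v.key(), ".") if info else "."
            field8 = f"ZYG={tag}" if tag != "." else "."
            out.write(f"{v.contig}\t{v.pos}\t.\t{v.ref_allele}\t{v.alt_allele}\t.\t.\t{field8}\n")


def write_alignments(path: Path, contig: str, contig_length: int,
                     reads: list[SimulatedRead], read_group: str = "sim") -> None:
    """Coordinate-sorted, indexed BAM of simulated reads (CIGAR <l>M)."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": contig, "LN": contig_length}],
        "RG": [{"ID": read_group}],
    }
    ordered = sorted(reads, key=lambda r: (r.pos, r.name, r.flag))
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for r in ordered:
            a = pysam.AlignedSegment(bam.header)
            a.query_name = r.name
            a.query_sequence = r.seq
            a.query_qualities = r.quals.tolist()
            a.flag = r.flag
            a.reference_id = 0
            a.reference_start = r.pos
            a.mapping_quality = 60
            a.cigarstring = f"{len(r.seq)}M"
            if r.mate_pos >= 0:
                a.next_reference_id = 0
                a.next_reference_start = r.mate_pos
                a.template_length = r.tlen
            bam.write(a)
    pysam.index(str(path))


def write_labels(path: Path, labels: dict[tuple, str]) -> None:
    with open(path, "w") as out:
        out.write("contig\tpos\tref\talt\tlabel\n")
        for (contig, pos, ref, alt), label in sorted(labels.items()):
            out.write(f"{contig}\t{pos}\t{ref}\t{alt}\t{label}\n")


def read_labels(path: Path) -> dict[tuple, str]:
    labels: dict[tuple, str] = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            contig, pos, ref, alt, label = line.rstrip("\n").split("\t")
            labels[(contig, int(pos), ref, alt)] = label
    return labels


def simulate_to_dir(
    config: SimulationConfig,
    outdir: str | Path,
    external_copy: bool = False,
    external_region_start: int | None = None,
) -> dict[str, Path]:
    """Run the full generator and write FASTA/VCF/BAM/labels to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = build_diploid_genome(config)
    reads = simulate_reads(genome)
    candidates, labels = make_decoy_candidates(genome)
    if external_copy:
        start = (
            external_region_start
            if external_region_start is not None
            else config.contig_length // 3
        )
        ext_reads, ext_decoys = simulate_external_copy(genome, start)
        reads = reads + ext_reads
        fresh = [d for d in ext_decoys if d.key() not in labels]
        candidates = sorted(candidates + fresh,
                            key=lambda v: (v.contig, v.pos, v.ref_allele, v.alt_allele))
        labels.update({d.key(): "decoy" for d in fresh})

    paths = {
        "reference": outdir / "ref.fa",
        "truth_vcf": outdir / "truth.vcf",
        "candidates_vcf": outdir / "candidates.vcf",
        "labels": outdir / "labels.tsv",
        "alignments": outdir / "reads.bam",
        "config": outdir / "sim_config.txt",
    }
    write_fasta(paths["reference"], config.contig_name, genome.reference)
    zyg = {pv.variant.key(): pv.zygosity for pv in genome.truth}
    write_vcf(paths["truth_vcf"], config.contig_name, config.contig_length,
              [pv.variant for pv in genome.truth], info=zyg)
    write_vcf(paths["candidates_vcf"], config.contig_name, config.contig_length, candidates)
    write_labels(paths["labels"], labels)
    write_alignments(paths["alignments"], config.contig_name, config.contig_length, reads)
    with open(paths["config"], "w") as out:
        for f in dataclasses.fields(config):
            out.write(f"{f.name}={getattr(config, f.name)}\n")
    return paths
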