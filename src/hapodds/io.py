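"""Readers and writers for the formats at the tool boundary.

FASTA reference and VCF candidates come in through pysam; scored
variants go out as a TSV (and optionally as an annotated copy of the
input VCF).  Alignment reading lives in :mod:`hapodds.evaluator` next to
the read-collection policy.
"""

from __future__ import annotations

import logging
import re
import warnings
from pathlib import Path

import pysam

from .hypotheses import VariantRecord

logger = logging.getLogger(__name__)

_NON_ACGTN = re.compile(r"[^ACGTN]")

TSV_COLUMNS = [
    "contig",
    "pos",
    "ref",
    "alt",
    "log_odds",
    "posterior",
    "n_reads",
    "n_hypotheses",
    "cluster_id",
    "flags",
]


class ReferenceGenome:
    """Uppercase in-memory reference; non-ACGTN characters folded to N."""

    def __init__(self, sequences: dict[str, str]):
        self.sequences = sequences

    def __getitem__(self, contig: str) -> str:
        return self.sequences[contig]

    def __contains__(self, contig: str) -> bool:
        return contig in self.sequences

    @property
    def contigs(self) -> list[str]:
        return list(self.sequences)

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}


def load_reference(fasta_path: str | Path) -> ReferenceGenome:
    """Load a FASTA reference, folding case and IUPAC ambiguity codes."""
    fasta_path = Path(fasta_path)
    if not fasta_path.exists():
        raise FileNotFoundError(fasta_path)
    sequences: dict[str, str] = {}
    with pysam.FastxFile(str(fasta_path)) as fh:
        for entry in fh:
            if entry.name in sequences:
                raise ValueError(f"duplicate contig name {entry.name!r} in {fasta_path}")
            sequences[entry.name] = _NON_ACGTN.sub("N", entry.sequence.upper())
    if not sequences:
        raise ValueError(f"no sequences in {fasta_path}")
    return ReferenceGenome(sequences)


def load_candidates(vcf_path: str | Path, reference: ReferenceGenome) -> list[VariantRecord]:
    """Load candidate variants, split multi-allelics, validate REF alleles.

    Symbolic alleles (``<DEL>``, breakends, ``*``) are skipped with a
    warning.  A REF allele that does not match the reference genome is an
    error listing every offender.  Unnormalized indels whose REF/ALT share
    a common suffix trigger a left-alignment warning but are accepted.
    """
    records: list[VariantRecord] = []
    mismatches: list[str] = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for line_idx, rec in enumerate(vcf):
            if rec.contig not in reference:
                mismatches.append(f"line {line_idx}: unknown contig {rec.contig}")
                continue
            ref = rec.ref.upper()
            for alt in rec.alts or ():
                if alt is None or alt == "*" or any(c in alt for c in "<>[]."):
                    warnings.warn(
                        f"{rec.contig}:{rec.pos}: skipping symbolic allele {alt!r}",
                        stacklevel=2,
                    )
                    continue
                alt = alt.upper()
                contig_seq = reference[rec.contig]
                observed = contig_seq[rec.pos - 1 : rec.pos - 1 + len(ref)]
                if observed != ref:
                    mismatches.append(
                        f"line {line_idx} {rec.contig}:{rec.pos}: REF {ref!r} "
                        f"but reference has {observed!r}"
                    )
                    continue
                if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1] and ref != alt:
                    warnings.warn(
                        f"{rec.contig}:{rec.pos}: REF/ALT share a common suffix; "
                        "input may not be left-aligned",
                        stacklevel=2,
                    )
                records.append(
                    VariantRecord(rec.contig, rec.pos, ref, alt, source_id=line_idx)
                )
    if mismatches:
        raise ValueError(
            "candidate VCF does not match the reference genome:\n  "
            + "\n  ".join(mismatches)
        )
    records.sort(key=lambda v: (v.contig, v.pos, v.ref_allele, v.alt_allele))
    return records


def write_scores(scored, tsv_path: str | Path) -> None:
    """Write scored variants as a TSV, ordered by (contig, pos)."""
    rows = sorted(scored, key=lambda s: (s.variant.contig, s.variant.pos,
                                         s.variant.ref_allele, s.variant.alt_allele))
    with open(tsv_path, "w") as out:
        out.write("\t".join(TSV_COLUMNS) + "\n")
        for s in rows:
            out.write(
                "\t".join(
                    [
                        s.variant.contig,
                        str(s.variant.pos),
                        s.variant.ref_allele,
                        s.variant.alt_allele,
                        f"{s.log_odds:.12g}",
                        f"{s.posterior:.12g}",
                        str(s.n_reads),
                        str(s.n_hypotheses),
                        str(s.cluster_id),
                        ",".join(s.flags) if s.flags else ".",
                    ]
                )
                + "\n"
            )


def read_scores(tsv_path: str | Path) -> list[dict]:
    """Read a score TSV back into a list of row dicts (typed columns)."""
    rows: list[dict] = []
    with open(tsv_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != TSV_COLUMNS:
            raise ValueError(f"unexpected score TSV header: {header}")
        for line in fh:
            fields = dict(zip(header, line.rstrip("\n").split("\t")))
            fields["pos"] = int(fields["pos"])
            fields["log_odds"] = float(fields["log_odds"])
            fields["posterior"] = float(fields["posterior"])
            for k in ("n_reads", "n_hypotheses", "cluster_id"):
                fields[k] = int(fields[k])
            rows.append(fields)
    return rows


def write_annotated_vcf(scored, vcf_in: str | Path, vcf_out: str | Path) -> None:
    """Copy the input VCF, adding log-odds and posterior INFO fields."""
    by_key = {s.variant.key(): s for s in scored}
    with pysam.VariantFile(str(vcf_in)) as vcf:
        header = vcf.header.copy()
        header.info.add("LOGODDS", "A", "Float",
                        "Marginal natural-log posterior odds for each ALT allele")
        header.info.add("POSTERIOR", "A", "Float",
                        "Marginal posterior probability for each ALT allele")
        with pysam.VariantFile(str(vcf_out), "w", header=header) as out:
            for rec in vcf:
                new = rec.copy()
                new.translate(header)
                odds, post = [], []
                found = False
                for alt in rec.alts or ():
                    s = by_key.get((rec.contig, rec.pos, rec.ref.upper(), str(alt).upper()))
                    if s is None:
                        odds.append(None)
                        post.append(None)
                    else:
                        odds.append(s.log_odds)
                        post.append(s.posterior)
                        found = True
                if found:
                    new.info["LOGODDS"] = tuple(odds)
                    new.info["POSTERIOR"] = tuple(post)
                out.write(new)


def read_config(path: str | Path) -> dict[str, str]:
    """key=value config file; ``#`` comments and blank lines ignored."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for n, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{n}: expected key=value, got {line!r}")
            key, value = line.split("=", 1)
            out[key.strip().replace("-", "_")] = value.strip()
    return out
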