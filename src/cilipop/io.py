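"""Readers and writers for the standard formats the pipeline touches.

FASTA goes through Biopython, VCF through pysam, GFF3 through gffutils.
External coordinates are 1-based inclusive (VCF/GFF3 convention); conversion
to the internal 0-based half-open convention happens via :mod:`cilipop.coords`.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .coords import to_internal

MISSING = -1  # missing allele index in genotype tuples

VALID_BASES = set("ACGTN")
FAMILY_STATUSES = ("expanding", "contracting", "stable", "unknown")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class SequenceRecord:
    """A named nucleotide sequence, uppercase-normalized."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ParseError("sequence record with empty id")
        self.seq = self.seq.upper()


@dataclass
class VariantRecord:
    """One biallelic SNP with per-sample diploid genotype calls.

    ``pos`` is 1-based (VCF convention).  Genotypes are pairs of allele
    indices (0 = ref, 1 = alt) with ``MISSING`` for uncalled alleles.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotypes: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ParseError(f"variant position must be >= 1, got {self.pos}")
        if len(self.ref) != 1 or len(self.alt) != 1 or self.ref == self.alt:
            raise ParseError(
                f"not a biallelic SNP: ref={self.ref!r} alt={self.alt!r}"
            )


@dataclass
class GeneModel:
    """CDS structure of one gene/transcript.

    ``cds_intervals`` are 1-based inclusive (start, end) pairs ordered 5'->3'
    in *transcript* order (reversed genomic order on the minus strand).
    """

    gene_id: str
    chrom: str
    strand: str
    cds_intervals: list[tuple[int, int]]
    phase: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ParseError(f"strand must be + or -, got {self.strand!r}")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_intervals) - self.phase

    def genomic_cds_positions(self) -> list[int]:
        """0-based genomic positions of CDS bases in transcript order.

        The first ``phase`` bases are trimmed so index 0 is the first base of
        a codon.
        """
        out: list[int] = []
        for s1, e1 in self.cds_intervals:
            s0, e0 = to_internal(s1, e1)
            block = range(s0, e0)
            if self.strand == "-":
                block = reversed(block)
            out.extend(block)
        return out[self.phase:]

    def extract_cds(self, reference: dict[str, str]) -> str:
        """Spliced CDS sequence (reverse-complemented on the minus strand)."""
        chrom_seq = reference[self.chrom]
        bases = [chrom_seq[i] for i in self.genomic_cds_positions()]
        if self.strand == "-":
            bases = [str(Seq(b).complement()) for b in bases]
        return "".join(bases).upper()


@dataclass
class VcfReadResult:
    """Biallelic SNPs plus bookkeeping on what was skipped."""

    variants: list[VariantRecord]
    samples: list[str]
    n_multiallelic: int = 0
    n_indel: int = 0
    n_invalid: int = 0

    @property
    def n_skipped(self) -> int:
        return self.n_multiallelic + self.n_indel + self.n_invalid


@dataclass
class GffReadResult:
    models: list[GeneModel]
    rejects: list[tuple[str, str]] = field(default_factory=list)  # (gene_id, reason)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into uppercase SequenceRecords, in file order."""
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise ParseError(f"{path}: empty sequence for record {rec.id!r}")
        records.append(SequenceRecord(rec.id, seq))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    bio = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def fasta_dict(records: Iterable[SequenceRecord]) -> dict[str, str]:
    return {r.id: r.seq for r in records}


# ---------------------------------------------------------------------------
# VCF

def read_vcf_biallelic(
    path: str | Path, samples: Sequence[str] | None = None
) -> VcfReadResult:
    """Read biallelic SNPs from a VCF 4.x file.

    Multiallelic sites, indels/non-SNPs and sites with ref == alt are skipped
    and counted, never silently dropped.  ``samples`` restricts and reorders
    the genotype columns.
    """
    vf = pysam.VariantFile(str(path))
    if "GT" not in vf.header.formats:
        raise ParseError(f"{path}: VCF has no GT FORMAT field")
    all_samples = list(vf.header.samples)
    if samples is not None:
        unknown = [s for s in samples if s not in all_samples]
        if unknown:
            raise ParseError(f"{path}: unknown sample name(s) {unknown}")
        use = list(samples)
    else:
        use = all_samples

    result = VcfReadResult(variants=[], samples=use)
    for rec in vf:
        alts = rec.alts or ()
        if len(alts) != 1:
            result.n_multiallelic += 1
            continue
        ref, alt = rec.ref, alts[0]
        if len(ref) != 1 or len(alt) != 1 or ref == alt or alt == "*":
            if ref == alt:
                result.n_invalid += 1
            else:
                result.n_indel += 1
            continue
        gts: list[tuple[int, int]] = []
        for name in use:
            call = rec.samples[name].get("GT")
            if call is None:
                call = (None, None)
            a = MISSING if call[0] is None else int(call[0])
            b = a if len(call) < 2 else (MISSING if call[1] is None else int(call[1]))
            gts.append((a, b))
        result.variants.append(
            VariantRecord(rec.chrom, rec.pos, ref.upper(), alt.upper(), gts)
        )
    return result


def write_vcf(
    variants: Sequence[VariantRecord],
    samples: Sequence[str],
    path: str | Path,
    contigs: Sequence[tuple[str, int]] | None = None,
) -> None:
    """Write biallelic SNPs as a minimal plain-text VCF 4.2 file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if contigs:
            for name, length in contigs:
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for v in variants:
            gt_strs = [
                "/".join("." if a == MISSING else str(a) for a in gt)
                for gt in v.genotypes
            ]
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gt_strs)
                + "\n"
            )


# ---------------------------------------------------------------------------
# GFF3

def read_gff3_cds(path: str | Path) -> GffReadResult:
    """Group GFF3 CDS features into per-transcript GeneModels.

    Models whose CDS length (after trimming the first segment's phase) is not
    a multiple of 3 land in ``rejects`` and are excluded from codon analyses.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    by_parent: dict[str, list] = {}
    for feat in db.features_of_type("CDS"):
        parents = feat.attributes.get("Parent") or feat.attributes.get("ID")
        if not parents:
            raise ParseError(f"{path}: CDS feature without Parent/ID at line {feat.start}")
        by_parent.setdefault(parents[0], []).append(feat)

    result = GffReadResult(models=[])
    for gene_id in sorted(by_parent):
        feats = sorted(by_parent[gene_id], key=lambda f: f.start)
        strand = feats[0].strand
        if strand not in "+-":
            result.rejects.append((gene_id, "unknown strand"))
            continue
        intervals = [(f.start, f.end) for f in feats]
        if strand == "-":
            intervals = intervals[::-1]
            first = feats[-1]
        else:
            first = feats[0]
        phase = int(first.frame) if first.frame not in (None, ".") else 0
        model = GeneModel(gene_id, feats[0].seqid, strand, intervals, phase)
        if model.cds_length % 3 != 0:
            result.rejects.append((gene_id, f"CDS length {model.cds_length} not multiple of 3"))
            continue
        result.models.append(model)
    return result


# ---------------------------------------------------------------------------
# Tabular inputs

def read_gene_sets(path: str | Path) -> pd.DataFrame:
    """Gene-set membership table: gene_id, class (life-stage DEG class or
    'background'), family_status (expanding/contracting/stable/unknown)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "class", "family_status"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ParseError(f"{path}: duplicate gene ids {dups[:5]}")
    bad = set(df["family_status"]) - set(FAMILY_STATUSES)
    if bad:
        raise ParseError(f"{path}: unknown family_status values {sorted(bad)}")
    return df


def read_paralog_pairs(path: str | Path) -> pd.DataFrame:
    """Paralog pair list: gene_a, gene_b (ids into an aligned FASTA)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_a", "gene_b"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if (df["gene_a"] == df["gene_b"]).any():
        raise ParseError(f"{path}: self-paired gene id")
    return df


def write_tsv(df: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> None:
    """Write a TSV with an optional '#'-prefixed provenance comment line."""
    buf = _stdio.StringIO()
    df.to_csv(buf, sep="\t", index=False)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write(buf.getvalue())


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
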