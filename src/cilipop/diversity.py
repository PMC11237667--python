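"""Nucleotide diversity and neutrality statistics.

Segregating sites S, mean pairwise differences (k-hat) and per-site pi,
Watterson's theta, silent-site diversity pi_s restricted to synonymous coding
positions (NG86 fractional site counting), and Tajima's D with the full
variance constants — genome-wide and per gene.

Missing genotype calls are handled pairwise-complete: a haplotype pair skips
a site where either call is missing, and per-site sample sizes are recomputed
from the non-missing calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .codons import BASES, GeneticCode, pathway_diffs, potential_sites
from .io import MISSING, GeneModel, VariantRecord

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

GENOME_ROW_ID = "GENOME"


@dataclass
class HaplotypeMatrix:
    """n haplotypes x L segregating sites of 0/1 alleles.

    ``alleles`` uses -1 for missing calls.  ``positions`` are (chrom, 1-based
    pos) per column.  ``callable_length`` is the total number of surveyed
    sites (monomorphic included) and is the denominator of pi.
    """

    alleles: np.ndarray
    positions: list[tuple[str, int]]
    callable_length: int

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D matrix")
        if self.alleles.shape[1] != len(self.positions):
            raise ValueError("positions must match the number of columns")
        if self.callable_length <= 0:
            raise ValueError("callable_length must be positive")

    @property
    def n(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]


def haplotypes_from_variants(
    variants: Sequence[VariantRecord], callable_length: int
) -> HaplotypeMatrix:
    """Split diploid genotype calls into 2*n_samples haplotype rows.

    Phase is irrelevant for the site-wise statistics computed here; the two
    alleles of each sample become adjacent rows.
    """
    if not variants:
        return HaplotypeMatrix(
            np.zeros((0, 0), dtype=np.int8), [], callable_length
        )
    n_hap = 2 * len(variants[0].genotypes)
    mat = np.full((n_hap, len(variants)), MISSING, dtype=np.int8)
    positions = []
    for j, v in enumerate(variants):
        positions.append((v.chrom, v.pos))
        for i, (a, b) in enumerate(v.genotypes):
            mat[2 * i, j] = a
            mat[2 * i + 1, j] = b
    return HaplotypeMatrix(mat, positions, callable_length)


# ---------------------------------------------------------------------------
# Core statistics

def seg_sites(matrix: HaplotypeMatrix) -> int:
    """Number of columns with >= 2 distinct non-missing alleles."""
    a = matrix.alleles
    if a.size == 0:
        return 0
    obs = a != MISSING
    any0 = ((a == 0) & obs).any(axis=0)
    any1 = ((a == 1) & obs).any(axis=0)
    return int((any0 & any1).sum())


def pairwise_pi(matrix: HaplotypeMatrix) -> tuple[float, float]:
    """Mean pairwise difference count k-hat and per-site pi.

    k-hat averages per-pair difference counts over all n(n-1)/2 haplotype
    pairs, skipping sites where either member of a pair is missing.  On
    complete data this equals the frequency form
    sum_j 2 p_j (1 - p_j) n_j / (n_j - 1).
    """
    n = matrix.n
    if n < 2:
        raise ValueError("pairwise pi needs >= 2 haplotypes")
    a = matrix.alleles
    if a.shape[1] == 0:
        return 0.0, 0.0
    obs = (a != MISSING)
    total = 0.0
    n_pairs = n * (n - 1) // 2
    for i in range(n - 1):
        both = obs[i] & obs[i + 1:]
        diff = (a[i] != a[i + 1:]) & both
        total += diff.sum()
    k_hat = total / n_pairs
    return k_hat, k_hat / matrix.callable_length


def pi_frequency_form(matrix: HaplotypeMatrix) -> float:
    """Frequency form of k-hat: sum_j 2 p_j q_j n_j/(n_j - 1).

    Serves as the cross-check counterpart of :func:`pairwise_pi` on complete
    data; with missing data it is the site-wise unbiased estimator.
    """
    a = matrix.alleles
    if a.shape[1] == 0:
        return 0.0
    obs = a != MISSING
    n_j = obs.sum(axis=0).astype(float)
    ones = ((a == 1) & obs).sum(axis=0)
    valid = n_j >= 2
    p = np.zeros_like(n_j)
    p[valid] = ones[valid] / n_j[valid]
    terms = np.zeros_like(n_j)
    terms[valid] = 2.0 * p[valid] * (1 - p[valid]) * n_j[valid] / (n_j[valid] - 1)
    return float(terms.sum())


@dataclass(frozen=True)
class TajimaConstants:
    """The a1..e2 constants of Tajima's D variance for sample size n."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n: int) -> TajimaConstants:
    if n < 2:
        raise ValueError("constants need n >= 2")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(n, a1, a2, b1, b2, c1, c2, e1, e2)


def watterson_theta(s: int, n: int) -> float:
    """Watterson's per-locus theta, S / a1(n)."""
    if n < 2:
        raise ValueError("Watterson's theta needs n >= 2")
    if s < 0:
        raise ValueError("S must be >= 0")
    if s == 0:
        return 0.0
    return s / tajima_constants(n).a1


@dataclass
class DiversityResult:
    """Genome- or gene-level diversity summary."""

    S: int
    k_hat: float
    pi: float
    theta_w: float            # per locus
    theta_w_per_site: float
    tajima_d: float | None    # None when undefined (S == 0 or n < 4)
    n: int
    n_eff: float              # median per-site non-missing haplotype count


def tajimas_d(matrix: HaplotypeMatrix) -> DiversityResult:
    """Tajima's D: (k-hat - S/a1) / sqrt(e1 S + e2 S (S-1)).

    Undefined (None) when S == 0 or when n < 4, where the variance constants
    are not usable.
    """
    n = matrix.n
    s = seg_sites(matrix)
    k_hat, pi = pairwise_pi(matrix) if n >= 2 else (0.0, 0.0)
    theta_w = watterson_theta(s, n) if n >= 2 else 0.0
    obs = (matrix.alleles != MISSING).sum(axis=0) if matrix.n_sites else np.array([n])
    n_eff = float(np.median(obs)) if len(obs) else float(n)
    d: float | None = None
    if s > 0 and n >= 4:
        c = tajima_constants(n)
        var = c.e1 * s + c.e2 * s * (s - 1)
        d = (k_hat - s / c.a1) / math.sqrt(var)
    return DiversityResult(
        S=s, k_hat=k_hat, pi=pi,
        theta_w=theta_w,
        theta_w_per_site=theta_w / matrix.callable_length,
        tajima_d=d, n=n, n_eff=n_eff,
    )


# ---------------------------------------------------------------------------
# Silent-site (synonymous) diversity

def haplotype_cds_sequences(
    variants: Sequence[VariantRecord],
    model: GeneModel,
    reference: dict[str, str],
) -> tuple[list[str], list[VariantRecord]]:
    """Per-haplotype CDS sequences with variant alleles substituted in.

    Variants are mapped into the codon frame via the gene model
    (strand-aware: alleles are complemented on minus-strand genes).  Missing
    calls become 'N'.  Variants whose reference allele disagrees with the
    FASTA base are returned in the second element and excluded.
    """
    ref_cds = model.extract_cds(reference)
    pos_map = {g: i for i, g in enumerate(model.genomic_cds_positions())}
    n_hap = 2 * len(variants[0].genotypes) if variants else 0
    haps = [list(ref_cds) for _ in range(n_hap)]
    mismatched: list[VariantRecord] = []
    for v in variants:
        if v.chrom != model.chrom:
            continue
        idx = pos_map.get(v.pos - 1)
        if idx is None:
            continue
        ref_b, alt_b = v.ref, v.alt
        if model.strand == "-":
            ref_b = ref_b.translate(_COMPLEMENT)
            alt_b = alt_b.translate(_COMPLEMENT)
        if ref_cds[idx] != ref_b:
            mismatched.append(v)
            continue
        for i, (a, b) in enumerate(v.genotypes):
            for k, allele in ((2 * i, a), (2 * i + 1, b)):
                haps[k][idx] = (
                    "N" if allele == MISSING else (ref_b if allele == 0 else alt_b)
                )
    return ["".join(h) for h in haps], mismatched


def synonymous_site_total(ref_cds: str, code: GeneticCode) -> float:
    """Sum of NG86 fractional synonymous sites over reference codons.

    Stop and ambiguous codons contribute nothing (terminal stops are the
    usual case).
    """
    total = 0.0
    for i in range(0, len(ref_cds) - len(ref_cds) % 3, 3):
        codon = ref_cds[i:i + 3]
        if any(b not in BASES for b in codon) or code.is_stop(codon):
            continue
        total += potential_sites(codon, code).s_sites
    return total


def silent_pi(
    variants: Sequence[VariantRecord],
    model: GeneModel,
    reference: dict[str, str],
    code: GeneticCode,
) -> float | None:
    """Synonymous-site nucleotide diversity pi_s for one gene.

    Numerator: mean pairwise count of synonymous differences between
    haplotype CDS sequences (multi-hit codons resolved by NG86 pathway
    averaging, pairwise-complete over N codons).  Denominator: total
    fractional synonymous sites of the reference CDS.  ``None`` when the
    gene is not codon-clean or there are < 2 haplotypes.
    """
    ref_cds = model.extract_cds(reference)
    if len(ref_cds) % 3 != 0:
        return None
    s_total = synonymous_site_total(ref_cds, code)
    if s_total <= 0:
        return None
    haps, _ = haplotype_cds_sequences(variants, model, reference)
    n = len(haps)
    if n < 2:
        return None
    # only codons touched by a variant can differ between haplotypes
    var_codons = sorted({
        i // 3 for i, base in enumerate(ref_cds)
        if any(h[i] != base for h in haps)
    })
    total = 0.0
    n_pairs = n * (n - 1) // 2
    for i in range(n):
        for j in range(i + 1, n):
            for ci in var_codons:
                ca = haps[i][3 * ci:3 * ci + 3]
                cb = haps[j][3 * ci:3 * ci + 3]
                if ca == cb:
                    continue
                if any(b not in BASES for b in ca + cb):
                    continue
                if code.is_stop(ca) or code.is_stop(cb):
                    continue
                d = pathway_diffs(ca, cb, code)
                if d is not None:
                    total += d[0]
    return (total / n_pairs) / s_total


# ---------------------------------------------------------------------------
# Per-gene table

def _gene_span(model: GeneModel) -> tuple[int, int]:
    starts = [s for s, _ in model.cds_intervals]
    ends = [e for _, e in model.cds_intervals]
    return min(starts), max(ends)


def per_gene_stats(
    variants: Sequence[VariantRecord],
    models: Sequence[GeneModel],
    reference: dict[str, str],
    code: GeneticCode,
    genome_length: int | None = None,
    gene_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Diversity statistics per gene plus a genome-wide aggregate row.

    Per-gene callable length defaults to the annotated gene span;
    ``gene_lengths`` (e.g. derived from a callability mask) overrides.
    Genes with no variants get S = 0 rows with undefined D.  Output is
    ordered by gene_id with the genome row first.
    """
    if genome_length is None:
        genome_length = sum(len(s) for s in reference.values())
    rows = []
    genome_matrix = haplotypes_from_variants(list(variants), genome_length)
    g = tajimas_d(genome_matrix)
    rows.append(_row(GENOME_ROW_ID, g, None, genome_length))
    by_chrom: dict[str, list[VariantRecord]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v)
    n_genotypes = len(variants[0].genotypes) if variants else 0
    for model in sorted(models, key=lambda m: m.gene_id):
        lo, hi = _gene_span(model)
        length = (gene_lengths or {}).get(model.gene_id, hi - lo + 1)
        in_gene = [
            v for v in by_chrom.get(model.chrom, []) if lo <= v.pos <= hi
        ]
        if in_gene:
            m = haplotypes_from_variants(in_gene, length)
            res = tajimas_d(m)
        else:
            res = DiversityResult(
                S=0, k_hat=0.0, pi=0.0, theta_w=0.0, theta_w_per_site=0.0,
                tajima_d=None, n=2 * n_genotypes, n_eff=float(2 * n_genotypes),
            )
        ps = silent_pi(in_gene, model, reference, code)
        rows.append(_row(model.gene_id, res, ps, length))
    return pd.DataFrame(rows)


def _row(gene_id: str, r: DiversityResult, pi_s: float | None, length: int) -> dict:
    return {
        "gene_id": gene_id,
        "n_hap": r.n,
        "callable_length": length,
        "S": r.S,
        "k_hat": r.k_hat,
        "pi": r.pi,
        "pi_s": np.nan if pi_s is None else pi_s,
        "theta_w": r.theta_w,
        "theta_w_per_site": r.theta_w_per_site,
        "tajima_d": np.nan if r.tajima_d is None else r.tajima_d,
        "n_eff": r.n_eff,
    }
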