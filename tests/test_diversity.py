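"""Diversity statistics against hand counts and an independent oracle."""

from __future__ import annotations

import math

import numpy as np
import pytest

from cilipop.codons import get_code, jukes_cantor
from cilipop.diversity import (
    GENOME_ROW_ID,
    HaplotypeMatrix,
    haplotypes_from_variants,
    pairwise_pi,
    per_gene_stats,
    pi_frequency_form,
    seg_sites,
    silent_pi,
    tajima_constants,
    tajimas_d,
    watterson_theta,
)
from cilipop.io import MISSING, GeneModel, VariantRecord


def oracle_tajima_d(matrix: np.ndarray) -> float:
    """From-scratch Tajima's D: explicit pair loop for k-hat, constants
    recomputed from their definitions."""
    n, L = matrix.shape
    s = sum(1 for j in range(L) if len(set(matrix[:, j])) > 1)
    diffs = [
        int((matrix[i] != matrix[j]).sum())
        for i in range(n) for j in range(i + 1, n)
    ]
    k_hat = sum(diffs) / len(diffs)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (k_hat - s / a1) / math.sqrt(e1 * s + e2 * s * (s - 1))


# ---------------------------------------------------------------------------

def test_seg_sites_worked_matrix(worked_matrix):
    assert seg_sites(worked_matrix) == 3


def test_seg_sites_monomorphic_and_missing():
    m = HaplotypeMatrix(
        np.array([[0, 0], [0, MISSING], [0, 0]], dtype=np.int8),
        [("c", 1), ("c", 2)], 10,
    )
    assert seg_sites(m) == 0  # missing call does not make a site segregating


def test_pairwise_pi_worked_matrix(worked_matrix):
    k_hat, pi = pairwise_pi(worked_matrix)
    assert k_hat == pytest.approx(10 / 6)
    assert pi == pytest.approx(10 / 18)


def test_pairwise_pi_two_haplotypes():
    m = HaplotypeMatrix(
        np.array([[0, 0], [1, 1]], dtype=np.int8), [("c", 1), ("c", 2)], 100
    )
    k_hat, pi = pairwise_pi(m)
    assert k_hat == 2.0 and pi == pytest.approx(0.02)


def test_pairwise_equals_frequency_form_on_random_complete_matrices():
    rng = np.random.default_rng(0)
    for _ in range(200):
        n = int(rng.integers(2, 12))
        L = int(rng.integers(1, 30))
        mat = rng.integers(0, 2, size=(n, L)).astype(np.int8)
        m = HaplotypeMatrix(mat, [("c", j + 1) for j in range(L)], L)
        assert pairwise_pi(m)[0] == pytest.approx(pi_frequency_form(m), abs=1e-12)


@pytest.mark.parametrize("s,n,expected", [
    (3, 2, 3.0),
    (3, 4, 3 / (1 + 0.5 + 1 / 3)),
    (0, 10, 0.0),
])
def test_watterson_theta(s, n, expected):
    assert watterson_theta(s, n) == pytest.approx(expected)


def test_tajima_constants_finite_positive():
    for n in range(4, 60):
        c = tajima_constants(n)
        assert c.a1 > 0 and c.e1 > 0 and c.e2 > 0


def test_tajimas_d_worked_matrix(worked_matrix):
    r = tajimas_d(worked_matrix)
    assert r.tajima_d == pytest.approx(0.1677, abs=5e-4)
    assert r.tajima_d == pytest.approx(
        oracle_tajima_d(worked_matrix.alleles), abs=1e-12
    )


def test_tajimas_d_matches_oracle_random_matrices():
    """D agrees with an independently coded oracle to 1e-10 on random
    complete polymorphic matrices."""
    rng = np.random.default_rng(123)
    checked = 0
    while checked < 200:
        n = int(rng.integers(4, 31))
        L = int(rng.integers(1, 101))
        mat = rng.integers(0, 2, size=(n, L)).astype(np.int8)
        m = HaplotypeMatrix(mat, [("c", j + 1) for j in range(L)], L)
        if seg_sites(m) == 0:
            continue
        assert tajimas_d(m).tajima_d == pytest.approx(
            oracle_tajima_d(mat), abs=1e-10
        )
        checked += 1


def test_tajimas_d_undefined_cases():
    mono = HaplotypeMatrix(
        np.zeros((5, 2), dtype=np.int8), [("c", 1), ("c", 2)], 10
    )
    assert tajimas_d(mono).tajima_d is None  # S == 0 -> undefined, not 0
    small = HaplotypeMatrix(
        np.array([[0, 1], [1, 0], [1, 1]], dtype=np.int8),
        [("c", 1), ("c", 2)], 10,
    )
    assert tajimas_d(small).tajima_d is None  # n == 3 -> variance unusable


# ---------------------------------------------------------------------------
# silent pi

def _single_gene_setup(n_codons: int = 100):
    """Plus-strand single-exon gene of GGG codons on a small chromosome."""
    cds = "GGG" * n_codons
    chrom_seq = "A" * 10 + cds + "T" * 10
    model = GeneModel("g1", "chr", "+", [(11, 10 + len(cds))])
    return {"chr": chrom_seq}, model


def test_silent_pi_single_synonymous_snp(code1):
    """One synonymous SNP at frequency 1/2 among 4 haplotypes in 100 GGG
    codons: pi_s = (2*(1/2)(1/2)*(4/3)) / 100."""
    reference, model = _single_gene_setup(100)
    # third position of the first codon: genome pos 13, G->A is synonymous
    v = VariantRecord("chr", 13, "G", "A", [(0, 0), (1, 1)])
    got = silent_pi([v], model, reference, code1)
    expected = (2 * 0.5 * 0.5 * (4 / 3)) / 100.0
    assert got == pytest.approx(expected, abs=1e-12)


def test_silent_pi_nonsynonymous_only_is_zero(code1):
    reference, model = _single_gene_setup(50)
    v = VariantRecord("chr", 11, "G", "A", [(0, 0), (1, 1)])  # GGG->AGG, Gly->Arg
    assert silent_pi([v], model, reference, code1) == 0.0


def test_silent_pi_strand_symmetry(code1):
    """A minus-strand gene gives the same pi_s as its plus-strand mirror."""
    n_codons = 30
    cds = "GGGGCTACT" * 10  # 30 codons
    plus_chrom = "A" * 5 + cds + "T" * 5
    rc = cds.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    minus_chrom = "A" * 5 + rc + "T" * 5
    plus_model = GeneModel("g+", "p", "+", [(6, 5 + len(cds))])
    minus_model = GeneModel("g-", "m", "-", [(6, 5 + len(cds))])
    # synonymous SNP at third position of plus codon 2 (GCT->GCC), pos 5+6=11
    v_plus = VariantRecord("p", 11, "T", "C", [(0, 0), (0, 1)])
    # mirrored position on the minus chromosome: L - pos + 1, complemented
    L = len(plus_chrom)
    v_minus = VariantRecord("m", L - 11 + 1, "A", "G", [(0, 0), (0, 1)])
    pi_plus = silent_pi([v_plus], plus_model, {"p": plus_chrom}, code1)
    pi_minus = silent_pi([v_minus], minus_model, {"m": minus_chrom}, code1)
    assert pi_plus is not None and pi_plus > 0
    assert pi_plus == pytest.approx(pi_minus, abs=1e-12)


def test_silent_pi_reference_mismatch_excluded(code1):
    reference, model = _single_gene_setup(10)
    bad = VariantRecord("chr", 13, "C", "A", [(0, 0), (1, 1)])  # FASTA has G
    assert silent_pi([bad], model, reference, code1) == 0.0


# ---------------------------------------------------------------------------
# per-gene table

def test_per_gene_stats_partition_conserves_S(code1):
    reference = {"chr": "A" * 10 + "GGG" * 40 + "C" * 10 + "GGG" * 40 + "T" * 10}
    m1 = GeneModel("geneA", "chr", "+", [(11, 130)])
    m2 = GeneModel("geneB", "chr", "+", [(141, 260)])
    variants = [
        VariantRecord("chr", 13, "G", "A", [(0, 0), (0, 1)]),
        VariantRecord("chr", 40, "G", "T", [(0, 1), (1, 1)]),
        VariantRecord("chr", 150, "G", "A", [(0, 0), (1, 1)]),
    ]
    df = per_gene_stats(variants, [m1, m2], reference, code1)
    genome = df[df.gene_id == GENOME_ROW_ID].iloc[0]
    per_gene = df[df.gene_id != GENOME_ROW_ID]
    assert per_gene["S"].sum() == genome["S"] == 3
    assert list(per_gene["gene_id"]) == ["geneA", "geneB"]  # deterministic order


def test_per_gene_stats_gene_without_variants_gets_zero_row(code1):
    reference = {"chr": "A" * 10 + "GGG" * 40 + "C" * 10 + "GGG" * 40 + "T" * 10}
    m1 = GeneModel("geneA", "chr", "+", [(11, 130)])
    m2 = GeneModel("geneB", "chr", "+", [(141, 260)])
    variants = [VariantRecord("chr", 13, "G", "A", [(0, 0), (0, 1)])]
    df = per_gene_stats(variants, [m1, m2], reference, code1)
    row_b = df[df.gene_id == "geneB"].iloc[0]
    assert row_b["S"] == 0
    assert np.isnan(row_b["tajima_d"])


def test_haplotypes_from_variants_splits_diploid_calls():
    v = VariantRecord("c", 5, "A", "G", [(0, 1), (MISSING, 1)])
    m = haplotypes_from_variants([v], 100)
    assert m.n == 4
    assert list(m.alleles[:, 0]) == [0, 1, MISSING, 1]
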