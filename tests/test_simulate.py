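"""Ground-truth properties of the synthetic-data generators."""

from __future__ import annotations

import math

import numpy as np
import pytest

from cilipop.codons import get_code
from cilipop.diversity import pairwise_pi, seg_sites, tajimas_d
from cilipop.kswgd import ks_for_pairs
from cilipop.linkage import moments_f, r2_haplotypes
from cilipop.simulate import (
    CoalescentConfig,
    Demography,
    InbreedingSimConfig,
    KsMixtureSpec,
    MKSimConfig,
    ScaffoldSimConfig,
    derive_seed,
    simulate_coalescent,
    simulate_genotypes_inbreeding,
    simulate_ks_pairs,
    simulate_ld_haplotypes,
    simulate_mk_genes,
    simulate_scaffolds,
)


# ---------------------------------------------------------------------------
# coalescent

def test_coalescent_deterministic_given_seed():
    cfg = CoalescentConfig(n=8, theta=5.0, seed=99)
    m1, t1 = simulate_coalescent(cfg)
    m2, t2 = simulate_coalescent(cfg)
    assert np.array_equal(m1.alleles, m2.alleles)
    assert m1.positions == m2.positions
    assert t1.total_branch_length == t2.total_branch_length


def test_coalescent_pair_expected_differences_is_theta():
    """n = 2: E[pairwise differences] = theta (E[T2] = 1 coalescent unit)."""
    theta = 4.0
    diffs = [
        pairwise_pi(simulate_coalescent(
            CoalescentConfig(n=2, theta=theta, seed=s)
        )[0])[0]
        for s in range(2000)
    ]
    assert np.mean(diffs) == pytest.approx(theta, rel=0.08)


def test_coalescent_expected_segregating_sites():
    """E[S] = theta * a1(n); n=10, theta=5 gives ~14.14."""
    a1 = sum(1.0 / i for i in range(1, 10))
    s_vals = [
        seg_sites(simulate_coalescent(
            CoalescentConfig(n=10, theta=5.0, seed=s)
        )[0])
        for s in range(1500)
    ]
    assert np.mean(s_vals) == pytest.approx(5.0 * a1, rel=0.05)


def test_coalescent_demography_shifts_tajimas_d_sign():
    """Expansion drives mean D negative; a past bottleneck drives it
    positive (sign checks on replicate means)."""
    def mean_d(demog, base_seed):
        vals = []
        for s in range(300):
            m, _ = simulate_coalescent(CoalescentConfig(
                n=20, theta=10.0, seed=base_seed + s, demography=demog,
            ))
            r = tajimas_d(m)
            if r.tajima_d is not None:
                vals.append(r.tajima_d)
        return float(np.mean(vals))

    d_exp = mean_d(Demography("expansion", factor=50.0, time=0.05), 10_000)
    # moderate bottleneck: a few lineages survive it and split deep in the
    # past, leaving intermediate-frequency variants (a too-severe bottleneck
    # would instead produce a star genealogy and negative D)
    d_bot = mean_d(
        Demography("bottleneck", factor=0.1, start=0.02, duration=0.05), 50_000
    )
    assert d_exp < -0.3
    assert d_bot > 0.1


def test_coalescent_sites_distinct_and_sorted():
    """A tight locus forces collisions; sites stay distinct and sorted."""
    m, truth = simulate_coalescent(CoalescentConfig(n=10, theta=20.0,
                                                    locus_length=500, seed=3))
    pos = [p for _, p in m.positions]
    assert pos == sorted(pos)
    assert len(pos) == len(set(pos))
    assert truth.n_mutations == len(pos)


def test_coalescent_overfull_locus_raises():
    with pytest.raises(ValueError, match="locus_length"):
        simulate_coalescent(CoalescentConfig(n=10, theta=50.0,
                                             locus_length=20, seed=1))


# ---------------------------------------------------------------------------
# LD copying chain

def test_ld_infinite_d0_perfect_correlation():
    m, _ = simulate_ld_haplotypes(40, 10, 100.0, math.inf, seed=1)
    cols = [m.alleles[:, j] for j in range(m.n_sites)]
    r = r2_haplotypes(cols[0], cols[-1])
    assert r.defined and r.r2 == pytest.approx(1.0)


def test_ld_tiny_d0_independence_floor():
    """d0 -> 0: mean adjacent r^2 approaches the 1/(n-1) sampling floor."""
    vals = []
    for s in range(60):
        m, _ = simulate_ld_haplotypes(60, 40, 100.0, 1e-6, seed=s)
        for j in range(m.n_sites - 1):
            r = r2_haplotypes(m.alleles[:, j], m.alleles[:, j + 1])
            if r.defined:
                vals.append(r.r2)
    assert np.mean(vals) == pytest.approx(1.0 / 59, rel=0.25)


def test_ld_adjacent_correlation_matches_construction():
    """Mean adjacent-site r^2 ~ exp(-2 d / d0) at d = spacing."""
    d0, spacing = 500.0, 100.0
    vals = []
    for s in range(80):
        m, _ = simulate_ld_haplotypes(100, 30, spacing, d0, seed=200 + s)
        for j in range(m.n_sites - 1):
            r = r2_haplotypes(m.alleles[:, j], m.alleles[:, j + 1])
            if r.defined:
                vals.append(r.r2)
    expected = math.exp(-2 * spacing / d0)
    assert np.mean(vals) == pytest.approx(expected + 1 / 99, abs=0.05)


# ---------------------------------------------------------------------------
# MK tables

def test_mk_sim_equal_omegas_centre_ni_at_one():
    df, truth = simulate_mk_genes(MKSimConfig(
        n_genes=3000, omega_poly=0.3, omega_div=0.3, seed=8,
    ))
    ni = (df.Pn / df.Ps) / (df.Dn / df.Ds)
    ni = ni[np.isfinite(ni)]
    assert truth["expected_ni"] == 1.0
    assert ni.mean() == pytest.approx(1.0, abs=0.1)


def test_mk_sim_reproducible_counts():
    cfg = MKSimConfig(n_genes=50, seed=5)
    df1, _ = simulate_mk_genes(cfg)
    df2, _ = simulate_mk_genes(cfg)
    assert df1.equals(df2)


# ---------------------------------------------------------------------------
# Ks pairs

def test_ks_sequence_emission_recovers_target(code1):
    spec = KsMixtureSpec(
        components=[(1.0, math.log(0.5), 0.05)],
        n_pairs=60, emit_sequences=True, codons_per_pair=400, seed=21,
    )
    truth, pairs = simulate_ks_pairs(spec, code1)
    dist, _ = ks_for_pairs(pairs, code1, ks_min=0.0, ks_max=10.0)
    err = np.median(np.abs(np.sort(dist.values) - np.sort(truth.truth_ks)))
    assert np.median(dist.values) == pytest.approx(0.5, abs=0.06)
    assert err < 0.12


def test_ks_estimator_consistency_with_length():
    """Median |ks_hat - ks_target| shrinks as codons_per_pair grows."""
    code = get_code(1)
    errs = []
    for n_codons in (100, 800):
        spec = KsMixtureSpec(
            components=[(1.0, math.log(0.4), 0.01)],
            n_pairs=40, emit_sequences=True, codons_per_pair=n_codons, seed=4,
        )
        truth, pairs = simulate_ks_pairs(spec, code)
        dist, _ = ks_for_pairs(pairs, code, ks_min=0.0, ks_max=10.0)
        errs.append(float(np.median(np.abs(dist.values - truth.truth_ks.median()))))
    assert errs[1] < errs[0]


def test_ks_zero_weight_background_never_drawn():
    spec = KsMixtureSpec(
        components=[(1.0, math.log(0.5), 0.1)],
        background=(0.0, 1.0), n_pairs=500, seed=2,
    )
    truth, _ = simulate_ks_pairs(spec)
    assert (truth.truth_component == 0).all()


# ---------------------------------------------------------------------------
# inbreeding genotypes

def test_inbreeding_f_zero_matches_hardy_weinberg():
    cfg = InbreedingSimConfig(
        n_individuals=30, n_sites=20_000,
        f_values=[0.0] * 30, freq_range=(0.5, 0.5), seed=6,
    )
    geno, _ = simulate_genotypes_inbreeding(cfg)
    het = (geno == 1).mean()
    assert het == pytest.approx(0.5, abs=0.01)   # 2pq at p = 0.5


def test_inbreeding_f_one_has_no_heterozygotes():
    cfg = InbreedingSimConfig(
        n_individuals=5, n_sites=5000, f_values=[1.0] * 5, seed=7,
    )
    geno, _ = simulate_genotypes_inbreeding(cfg)
    assert not (geno == 1).any()


def test_inbreeding_moments_f_recovery():
    f_true = [0.0, 0.3, 0.6, 0.9] * 5
    cfg = InbreedingSimConfig(
        n_individuals=20, n_sites=10_000, f_values=f_true, seed=11,
    )
    geno, _ = simulate_genotypes_inbreeding(cfg)
    est = np.array([r.f for r in moments_f(geno)])
    assert np.abs(est - np.array(f_true)).max() < 0.05


# ---------------------------------------------------------------------------
# scaffolds

def test_scaffold_background_gc_converges():
    cfg = ScaffoldSimConfig(
        n_scaffolds=1, length_range=(100_000, 100_000),
        gc_target=0.335, class_proportions=(1.0, 0.0, 0.0), seed=9,
    )
    recs, _ = simulate_scaffolds(cfg)
    seq = recs[0].seq
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    assert gc == pytest.approx(0.335, abs=0.01)


def test_scaffold_truth_proportions_and_tracts():
    cfg = ScaffoldSimConfig(
        n_scaffolds=200, class_proportions=(0.3, 0.3, 0.4),
        repeats_per_tract=4, seed=12,
    )
    recs, truth = simulate_scaffolds(cfg)
    assert len(recs) == 200
    frac2 = (truth.truth_class == 2).mean()
    assert frac2 == pytest.approx(0.4, abs=0.1)
    # a class-2 scaffold starts with motif copies and ends with their revcomp
    row = truth[truth.truth_class == 2].iloc[0]
    seq = next(r.seq for r in recs if r.id == row.scaffold_id)
    assert seq[:6] in ("TTTGGG", "TTGGGG")
    assert seq[-6:] in ("CCCAAA", "CCCCAA")


def test_generators_pure_functions_of_seed():
    a, _ = simulate_scaffolds(ScaffoldSimConfig(n_scaffolds=5, seed=3))
    b, _ = simulate_scaffolds(ScaffoldSimConfig(n_scaffolds=5, seed=3))
    assert [r.seq for r in a] == [r.seq for r in b]
    assert derive_seed(1, "x") == derive_seed(1, "x")
    assert derive_seed(1, "x") != derive_seed(1, "y")
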