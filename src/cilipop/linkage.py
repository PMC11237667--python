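"""Linkage disequilibrium and inbreeding coefficients.

r^2 is the squared correlation between allelic states at two loci, computed
either from haplotype frequencies (phased/haploid data) or as the squared
Pearson correlation of genotype dosages (Rogers-Huff style, phase-free).
Decay curves bin pairwise r^2 by physical distance.

The inbreeding coefficient F is the method-of-moments excess of observed
over expected homozygosity: F = (O_hom - E_hom)/(N - E_hom), with the
expected homozygous site count E_hom = sum_j [1 - 2 p_j q_j n_j/(n_j - 1)]
from sample allele frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import HaplotypeMatrix
from .io import MISSING


@dataclass
class LDPair:
    pos_a: int
    pos_b: int
    distance: int
    d_coef: float | None
    r2: float | None
    method: str
    defined: bool = True


@dataclass
class LDDecay:
    """Distance-binned mean r^2 curve."""

    bin_edges: list[float]
    mean_r2: list[float]
    n_pairs: list[int]
    max_pairs_per_bin: int | None
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_lo": self.bin_edges[:-1],
            "bin_hi": self.bin_edges[1:],
            "mean_r2": self.mean_r2,
            "n_pairs": self.n_pairs,
        })


@dataclass
class HetResult:
    individual: str
    o_hom: int
    e_hom: float
    n_sites: int
    f: float | None
    defined: bool = True


DEFAULT_BIN_EDGES = [0.0, 100.0, 500.0, 1000.0, 5000.0, 10000.0]


# ---------------------------------------------------------------------------
# Pairwise r^2

def r2_haplotypes(
    col_a: np.ndarray, col_b: np.ndarray, pos_a: int = 0, pos_b: int = 0
) -> LDPair:
    """Haplotype-frequency r^2 between two 0/1 allele columns.

    Frequencies come from pairwise-complete haplotypes; r^2 =
    D^2 / (p_A q_A p_B q_B) with D = p(AB) - p(A) p(B).  Undefined (flagged)
    when either locus is monomorphic after pairwise completion.
    """
    a = np.asarray(col_a)
    b = np.asarray(col_b)
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok].astype(float), b[ok].astype(float)
    dist = abs(pos_b - pos_a)
    if len(a) < 2:
        return LDPair(pos_a, pos_b, dist, None, None, "haplotype", defined=False)
    p_a, p_b = a.mean(), b.mean()
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return LDPair(pos_a, pos_b, dist, None, None, "haplotype", defined=False)
    p_ab = float((a * b).mean())
    d = p_ab - p_a * p_b
    r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    return LDPair(pos_a, pos_b, dist, float(d), min(float(r2), 1.0), "haplotype")


def r2_genotypes(
    col_a: np.ndarray, col_b: np.ndarray, pos_a: int = 0, pos_b: int = 0
) -> LDPair:
    """Squared Pearson correlation of 0/1/2 genotype dosages over
    pairwise-complete individuals (phase-free composite LD)."""
    a = np.asarray(col_a)
    b = np.asarray(col_b)
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok].astype(float), b[ok].astype(float)
    dist = abs(pos_b - pos_a)
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        return LDPair(pos_a, pos_b, dist, None, None, "genotype-dosage", defined=False)
    cov = float(np.cov(a, b, ddof=0)[0, 1])
    r2 = cov * cov / (a.var() * b.var())
    return LDPair(pos_a, pos_b, dist, cov, min(float(r2), 1.0), "genotype-dosage")


# ---------------------------------------------------------------------------
# Decay curve

def ld_decay(
    matrix: HaplotypeMatrix,
    max_dist: float = 10_000.0,
    bin_edges: list[float] | None = None,
    max_pairs_per_bin: int | None = 10_000,
    seed: int = 0,
    method: str = "haplotype",
) -> LDDecay:
    """Mean r^2 per distance bin over all same-chromosome variant pairs.

    Pairs farther apart than ``max_dist`` are skipped; bins holding more
    than ``max_pairs_per_bin`` candidates are thinned by a seeded uniform
    subsample.  Pairs with undefined r^2 do not contribute.
    """
    edges = list(bin_edges) if bin_edges is not None else list(DEFAULT_BIN_EDGES)
    if sorted(edges) != edges or len(edges) < 2:
        raise ValueError("bin_edges must be ascending with >= 2 values")
    pair_fn = r2_haplotypes if method == "haplotype" else r2_genotypes
    # enumerate eligible pairs per bin
    by_bin: dict[int, list[tuple[int, int]]] = {i: [] for i in range(len(edges) - 1)}
    positions = matrix.positions
    for i in range(len(positions)):
        chrom_i, pos_i = positions[i]
        for j in range(i + 1, len(positions)):
            chrom_j, pos_j = positions[j]
            if chrom_j != chrom_i:
                continue
            dist = pos_j - pos_i
            if dist > max_dist:
                break  # positions sorted within chrom
            if dist <= 0:
                continue
            k = int(np.searchsorted(edges, dist, side="right")) - 1
            if 0 <= k < len(edges) - 1:
                by_bin[k].append((i, j))
    rng = np.random.default_rng(seed)
    mean_r2: list[float] = []
    n_pairs: list[int] = []
    for k in range(len(edges) - 1):
        pairs = by_bin[k]
        if max_pairs_per_bin is not None and len(pairs) > max_pairs_per_bin:
            idx = rng.choice(len(pairs), size=max_pairs_per_bin, replace=False)
            pairs = [pairs[int(x)] for x in sorted(idx)]
        vals = []
        for i, j in pairs:
            res = pair_fn(
                matrix.alleles[:, i], matrix.alleles[:, j],
                positions[i][1], positions[j][1],
            )
            if res.defined:
                vals.append(res.r2)
        mean_r2.append(float(np.mean(vals)) if vals else float("nan"))
        n_pairs.append(len(vals))
    return LDDecay(edges, mean_r2, n_pairs, max_pairs_per_bin, seed)


# ---------------------------------------------------------------------------
# Inbreeding F

def moments_f(
    genotypes: np.ndarray,
    individual_ids: list[str] | None = None,
    exclude_self: bool = False,
) -> list[HetResult]:
    """Per-individual method-of-moments inbreeding coefficient F.

    ``genotypes`` is individuals x sites with dosages 0/1/2 and -1 for
    missing.  Allele frequencies use all non-missing alleles (including the
    focal individual unless ``exclude_self``); sites monomorphic overall are
    skipped; per individual, sites with a missing call are skipped.

    F = (O_hom - E_hom) / (N - E_hom) with
    E_hom = sum_j [1 - 2 p_j q_j n_j/(n_j - 1)] over that individual's
    usable sites.
    """
    g = np.asarray(genotypes)
    if g.ndim != 2 or g.shape[0] < 2:
        raise ValueError("need a 2-D genotype matrix with >= 2 individuals")
    n_ind, n_sites = g.shape
    ids = individual_ids or [f"ind{i:03d}" for i in range(n_ind)]
    obs = g != MISSING
    alt_counts = np.where(obs, g, 0).sum(axis=0).astype(float)
    allele_n = 2.0 * obs.sum(axis=0)
    results: list[HetResult] = []
    for i in range(n_ind):
        usable = obs[i].copy()
        if not usable.any():
            results.append(HetResult(ids[i], 0, 0.0, 0, None, defined=False))
            continue
        if exclude_self:
            ac = alt_counts - np.where(obs[i], g[i], 0)
            an = allele_n - 2.0 * obs[i]
        else:
            ac, an = alt_counts, allele_n
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(an > 0, ac / an, np.nan)
        poly = usable & (an >= 2) & (p > 0) & (p < 1)
        n_used = int(poly.sum())
        if n_used == 0:
            results.append(HetResult(ids[i], 0, 0.0, 0, None, defined=False))
            continue
        q = 1.0 - p[poly]
        nj = an[poly]
        e_hom = float(np.sum(1.0 - 2.0 * p[poly] * q * nj / (nj - 1.0)))
        o_hom = int(np.sum((g[i, poly] == 0) | (g[i, poly] == 2)))
        denom = n_used - e_hom
        f = (o_hom - e_hom) / denom if denom != 0 else None
        results.append(HetResult(
            ids[i], o_hom, e_hom, n_used,
            None if f is None else float(f), defined=f is not None,
        ))
    return results


def het_frame(results: list[HetResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "individual": r.individual,
        "o_hom": r.o_hom,
        "e_hom": r.e_hom,
        "n_sites": r.n_sites,
        "f": np.nan if r.f is None else r.f,
        "defined": r.defined,
    } for r in results])
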