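"""Genetic-code-aware codon primitives.

Implements the Nei-Gojobori (1986) counting scheme: fractional synonymous /
nonsynonymous *site* counts per codon, pathway-averaged synonymous /
nonsynonymous *difference* counts between codon pairs, and Jukes-Cantor
corrected Ks/Ka for a gap-free codon alignment.

Conventions (the standard NG86 variant):

* site counting — a single-base change that creates a stop codon counts as
  nonsynonymous;
* difference counting — mutational pathways that pass through a stop codon
  are excluded and the average is renormalized over the remaining pathways.

The genetic code is configurable by NCBI translation-table id.  Table 1
(standard) is the default; table 6 (ciliate nuclear, where TAA/TAG encode
glutamine and only TGA is a stop) matters for ciliate macronuclear genes and
is fully supported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations, product

from Bio.Data import CodonTable

BASES = "ACGT"
STOP = "*"
ALL_CODONS = ["".join(c) for c in product(BASES, repeat=3)]


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino-acid map built from an NCBI translation table."""

    table_id: int
    forward: dict = field(hash=False, repr=False, default=None)
    stops: frozenset = field(hash=False, repr=False, default=None)

    @classmethod
    def from_ncbi_id(cls, table_id: int = 1) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[table_id]
        forward = dict(table.forward_table)
        stops = frozenset(table.stop_codons)
        for codon in stops:
            forward[codon] = STOP
        if len(forward) != 64:
            raise ValueError(f"translation table {table_id} does not map 64 codons")
        return cls(table_id=table_id, forward=forward, stops=stops)

    def is_stop(self, codon: str) -> bool:
        return codon in self.stops


@lru_cache(maxsize=8)
def get_code(table_id: int = 1) -> GeneticCode:
    return GeneticCode.from_ncbi_id(table_id)


def translate(codon: str, code: GeneticCode) -> str | None:
    """Amino acid for ``codon`` (one-letter), ``'*'`` for stops, ``None`` if
    the codon contains a base outside {A,C,G,T}."""
    codon = codon.upper()
    if len(codon) != 3 or any(b not in BASES for b in codon):
        return None
    return code.forward[codon]


@dataclass(frozen=True)
class CodonSiteCounts:
    """Fractional synonymous/nonsynonymous site counts for one codon."""

    s_sites: float
    n_sites: float

    def __post_init__(self) -> None:
        assert self.s_sites >= 0 and self.n_sites >= 0
        assert abs(self.s_sites + self.n_sites - 3.0) < 1e-12


@lru_cache(maxsize=512)
def _potential_sites_cached(codon: str, table_id: int) -> CodonSiteCounts:
    code = get_code(table_id)
    aa = code.forward[codon]
    syn = 0.0
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1:]
            # change to a stop counts as nonsynonymous
            if not code.is_stop(mutant) and code.forward[mutant] == aa:
                syn += 1.0
    s = syn / 3.0
    return CodonSiteCounts(s_sites=s, n_sites=3.0 - s)


def potential_sites(codon: str, code: GeneticCode) -> CodonSiteCounts:
    """NG86 fractional synonymous/nonsynonymous sites of a sense codon.

    Per position, the fraction of the three possible single-base changes that
    are synonymous, summed over the three positions; s + n == 3 exactly.
    """
    codon = codon.upper()
    if any(b not in BASES for b in codon) or len(codon) != 3:
        raise ValueError(f"not an unambiguous codon: {codon!r}")
    if code.is_stop(codon):
        raise ValueError(f"potential_sites undefined for stop codon {codon}")
    return _potential_sites_cached(codon, code.table_id)


def pathway_diffs(
    codon_a: str, codon_b: str, code: GeneticCode
) -> tuple[float, float] | None:
    """Pathway-averaged (synonymous, nonsynonymous) differences between two
    sense codons.

    With k differing positions, all k! single-step orderings are enumerated;
    orderings passing through a stop codon are dropped and the average is
    renormalized over the remainder.  Returns ``None`` when every pathway
    passes through a stop (the codon pair should then be excluded from
    totals).
    """
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    if code.is_stop(codon_a) or code.is_stop(codon_b):
        raise ValueError("pathway_diffs requires sense codons")
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return (0.0, 0.0)
    total_s = total_n = 0.0
    n_valid = 0
    for order in permutations(diff_pos):
        cur = codon_a
        s = n = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if code.is_stop(nxt):
                ok = False
                break
            if code.forward[cur] == code.forward[nxt]:
                s += 1
            else:
                n += 1
            cur = nxt
        if ok:
            total_s += s
            total_n += n
            n_valid += 1
    if n_valid == 0:
        return None
    return total_s / n_valid, total_n / n_valid


@dataclass
class PairwiseDivergence:
    """Ks/Ka summary for one codon-aligned sequence pair."""

    sd: float
    nd: float
    s_total: float
    n_total: float
    p_s: float
    p_n: float
    ks: float | None
    ka: float | None
    n_codons_used: int
    n_codons_dropped: int
    saturated_s: bool = False
    saturated_n: bool = False


def jukes_cantor(p: float) -> float | None:
    """JC69 multiple-hit correction; ``None`` at/beyond saturation (p >= 3/4)."""
    if p < 0:
        raise ValueError("proportion of differences must be >= 0")
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


def _clean_codon(codon: str) -> bool:
    return len(codon) == 3 and all(b in BASES for b in codon)


def ks_ka_pair(cds_a: str, cds_b: str, code: GeneticCode) -> PairwiseDivergence:
    """NG86 Ks/Ka for a gap-free, equal-length codon alignment.

    Codon columns containing gaps, ambiguity codes, or a stop codon in either
    sequence are dropped pairwise; site totals are averaged over the two
    sequences; the Jukes-Cantor correction is applied to p_s and p_n
    independently.  Symmetric in its arguments.
    """
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    if len(cds_a) != len(cds_b):
        raise ValueError("sequences must be aligned to equal length")
    if len(cds_a) % 3 != 0:
        raise ValueError("alignment length must be a multiple of 3")
    sd = nd = 0.0
    s_a = n_a = s_b = n_b = 0.0
    used = dropped = 0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i:i + 3], cds_b[i:i + 3]
        if not (_clean_codon(ca) and _clean_codon(cb)):
            dropped += 1
            continue
        if code.is_stop(ca) or code.is_stop(cb):
            dropped += 1
            continue
        diffs = pathway_diffs(ca, cb, code)
        if diffs is None:
            dropped += 1
            continue
        sa = potential_sites(ca, code)
        sb = potential_sites(cb, code)
        sd += diffs[0]
        nd += diffs[1]
        s_a += sa.s_sites
        n_a += sa.n_sites
        s_b += sb.s_sites
        n_b += sb.n_sites
        used += 1
    s_total = (s_a + s_b) / 2.0
    n_total = (n_a + n_b) / 2.0
    p_s = sd / s_total if s_total > 0 else 0.0
    p_n = nd / n_total if n_total > 0 else 0.0
    ks = jukes_cantor(p_s)
    ka = jukes_cantor(p_n)
    return PairwiseDivergence(
        sd=sd, nd=nd, s_total=s_total, n_total=n_total,
        p_s=p_s, p_n=p_n, ks=ks, ka=ka,
        n_codons_used=used, n_codons_dropped=dropped,
        saturated_s=ks is None, saturated_n=ka is None,
    )
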