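"""Simulators that generate every pipeline input with known ground truth.

Each generator is a pure function of its config (including the seed):
reruns are byte-identical.  Truth records are always returned alongside the
data so downstream recovery tests read truth from here instead of
re-deriving it.

Generators and what they emulate:

* :func:`simulate_coalescent` — neutral Kingman coalescent with infinite-sites
  mutation at per-locus theta; optional stepwise demography (expansion /
  bottleneck) for Tajima's D sign checks.  Time is in coalescent units
  (2N generations = 1), which makes E[S] = theta * a1 and E[pi * L] = theta
  exact test anchors.
* :func:`simulate_ld_haplotypes` — a latent copying chain with closed-form
  expected LD decay r^2 ~ exp(-2 d / d0); a deliberately simplified stand-in
  for a coalescent with recombination.
* :func:`simulate_mk_genes` — Poisson McDonald-Kreitman tables with
  controllable polymorphism/divergence omega.
* :func:`simulate_ks_pairs` — paralog Ks values from a log-normal mixture
  (plus optional exponential background), optionally materialized as codon
  alignments whose measured Ks recovers the target.
* :func:`simulate_genotypes_inbreeding` — diploid genotypes with
  per-individual inbreeding coefficient F.
* :func:`simulate_scaffolds` — scaffold FASTA with 0/1/2 terminal telomere
  tracts of the ciliate macronuclear motif TT(T/G)GGG.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .codons import BASES, GeneticCode, get_code, potential_sites
from .diversity import HaplotypeMatrix
from .io import SequenceRecord

TELOMERE_MOTIF_CHOICES = ("TTTGGG", "TTGGGG")


def derive_seed(seed: int, label: str) -> int:
    """Named substream seed below 2^31, stable across runs."""
    return (zlib.crc32(f"{seed}:{label}".encode()) ^ seed) % (2**31 - 1)


# ---------------------------------------------------------------------------
# Coalescent

@dataclass
class Demography:
    """Stepwise relative population size looking backwards in time.

    ``kind='constant'``: size 1 throughout.
    ``kind='expansion'``: the population grew by ``factor`` at ``time`` ago —
    ancestral relative size is 1/factor beyond ``time``.
    ``kind='bottleneck'``: relative size ``factor`` during
    [start, start + duration), 1 elsewhere.
    """

    kind: Literal["constant", "expansion", "bottleneck"] = "constant"
    factor: float = 1.0
    time: float = 0.0
    start: float = 0.0
    duration: float = 0.0

    def epochs(self) -> list[tuple[float, float]]:
        """(epoch start time, relative size) pairs, ascending in time."""
        if self.kind == "constant":
            return [(0.0, 1.0)]
        if self.kind == "expansion":
            if self.factor <= 0 or self.time < 0:
                raise ValueError("expansion needs factor > 0 and time >= 0")
            return [(0.0, 1.0), (self.time, 1.0 / self.factor)]
        if self.kind == "bottleneck":
            if not (0 < self.factor) or self.start < 0 or self.duration <= 0:
                raise ValueError("bottleneck needs factor > 0, start >= 0, duration > 0")
            return [
                (0.0, 1.0),
                (self.start, self.factor),
                (self.start + self.duration, 1.0),
            ]
        raise ValueError(f"unknown demography kind {self.kind!r}")


@dataclass
class CoalescentConfig:
    n: int
    theta: float
    locus_length: int = 100_000
    seed: int = 0
    demography: Demography = field(default_factory=Demography)

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need n >= 2 haplotypes")
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if self.locus_length < 1:
            raise ValueError("locus_length must be >= 1")


@dataclass
class CoalescentTruth:
    total_branch_length: float
    tmrca: float
    n_mutations: int
    n_site_collisions: int
    theta: float
    n: int


def _coalescent_waiting_time(
    k: int, t0: float, epochs: list[tuple[float, float]], u: float
) -> float:
    """Time of the next coalescence among k lineages starting at t0.

    Inverts the cumulative hazard of the piecewise-constant rate
    k(k-1)/2 / size(t) against the exponential quantile -log(u).
    """
    target = -math.log(u)
    rate_base = k * (k - 1) / 2.0
    t = t0
    acc = 0.0
    for i, (e_start, size) in enumerate(epochs):
        e_end = epochs[i + 1][0] if i + 1 < len(epochs) else math.inf
        if e_end <= t:
            continue
        seg_start = max(t, e_start)
        rate = rate_base / size
        seg_hazard = (e_end - seg_start) * rate
        if acc + seg_hazard >= target:
            return seg_start + (target - acc) / rate
        acc += seg_hazard
    raise RuntimeError("ran out of epochs (last epoch must be unbounded)")


def simulate_coalescent(config: CoalescentConfig) -> tuple[HaplotypeMatrix, CoalescentTruth]:
    """Neutral coalescent haplotypes under the infinite-sites model.

    While k lineages remain, the next coalescence time is drawn from the
    piecewise-exponential with rate k(k-1)/2 / size(t); a uniform random pair
    merges.  Mutations: Poisson(theta/2 * total branch length), each placed
    uniformly on branches and assigned a distinct site (collisions are
    resampled and counted).
    """
    rng = np.random.default_rng(config.seed)
    epochs = config.demography.epochs()
    n = config.n
    # lineages: (leaf index set, birth time)
    lineages: list[tuple[frozenset[int], float]] = [
        (frozenset([i]), 0.0) for i in range(n)
    ]
    branches: list[tuple[frozenset[int], float]] = []
    t = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        t = _coalescent_waiting_time(k, t, epochs, rng.random())
        i, j = rng.choice(k, size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        (set_j, birth_j) = lineages.pop(j)
        (set_i, birth_i) = lineages.pop(i)
        branches.append((set_i, t - birth_i))
        branches.append((set_j, t - birth_j))
        lineages.append((set_i | set_j, t))
    tmrca = t
    lengths = np.array([b[1] for b in branches])
    total_len = float(lengths.sum())
    n_mut = int(rng.poisson(config.theta / 2.0 * total_len))
    cols = np.zeros((n, n_mut), dtype=np.int8)
    if n_mut > 0:
        which = rng.choice(len(branches), size=n_mut, p=lengths / total_len)
        for m, b in enumerate(which):
            for leaf in branches[int(b)][0]:
                cols[leaf, m] = 1
    # distinct site placement (infinite sites on a finite grid)
    if n_mut > config.locus_length:
        raise ValueError(
            f"locus_length={config.locus_length} cannot hold {n_mut} distinct "
            "mutations; increase locus_length relative to theta"
        )
    taken: set[int] = set()
    collisions = 0
    sites: list[int] = []
    for _ in range(n_mut):
        pos = int(rng.integers(1, config.locus_length + 1))
        while pos in taken:
            collisions += 1
            pos = int(rng.integers(1, config.locus_length + 1))
        taken.add(pos)
        sites.append(pos)
    order = np.argsort(sites) if n_mut else np.array([], dtype=int)
    matrix = HaplotypeMatrix(
        cols[:, order],
        [("sim", sites[int(o)]) for o in order],
        config.locus_length,
    )
    truth = CoalescentTruth(
        total_branch_length=total_len, tmrca=tmrca, n_mutations=n_mut,
        n_site_collisions=collisions, theta=config.theta, n=n,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# LD copying chain

def simulate_ld_haplotypes(
    n_hap: int,
    n_sites: int,
    spacing: float,
    d0: float,
    freq_range: tuple[float, float] = (0.3, 0.7),
    seed: int = 0,
) -> tuple[HaplotypeMatrix, dict]:
    """Haplotypes whose LD decays as r^2 ~ exp(-2 d / d0).

    Construction: each haplotype carries a latent uniform that is redrawn
    with probability 1 - exp(-spacing/d0) between adjacent sites; the allele
    at every site is latent < p with a single dataset-wide frequency p drawn
    from ``freq_range``.  Sharing p across sites makes the copying
    rank-preserving and marginal-preserving, so the allelic correlation at
    distance d is exactly exp(-d/d0) and expected r^2 is approximately
    exp(-2 d / d0) plus the 1/(n_hap - 1) small-sample floor.
    """
    if d0 <= 0:
        raise ValueError("d0 must be > 0 (use math.inf for no decay)")
    if n_hap < 2 or n_sites < 1:
        raise ValueError("need n_hap >= 2 and n_sites >= 1")
    rng = np.random.default_rng(seed)
    p = float(rng.uniform(*freq_range))
    copy_prob = math.exp(-spacing / d0) if math.isfinite(d0) else 1.0
    latents = rng.random(n_hap)
    mat = np.empty((n_hap, n_sites), dtype=np.int8)
    mat[:, 0] = latents < p
    for j in range(1, n_sites):
        redraw = rng.random(n_hap) >= copy_prob
        latents = np.where(redraw, rng.random(n_hap), latents)
        mat[:, j] = latents < p
    positions = [("sim", int(1 + round(j * spacing))) for j in range(n_sites)]
    matrix = HaplotypeMatrix(mat, positions, int(max(1, round(n_sites * spacing))))
    truth = {"p": p, "d0": d0, "spacing": spacing, "copy_prob": copy_prob}
    return matrix, truth


# ---------------------------------------------------------------------------
# McDonald-Kreitman tables

@dataclass
class MKSimConfig:
    n_genes: int
    lambda_ps: float = 50.0
    lambda_ds: float = 50.0
    site_ratio: float = 2.5     # nonsynonymous/synonymous potential-site ratio
    omega_poly: float = 0.2
    omega_div: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("lambda_ps", "lambda_ds", "site_ratio", "omega_poly", "omega_div"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def expected_ni(self) -> float:
        return self.omega_poly / self.omega_div


def simulate_mk_genes(config: MKSimConfig) -> tuple[pd.DataFrame, dict]:
    """Per-gene (Pn, Ps, Dn, Ds) counts from independent Poissons.

    Ps ~ Poisson(lambda_ps); Pn ~ Poisson(lambda_ps * site_ratio * omega_poly);
    Ds ~ Poisson(lambda_ds); Dn ~ Poisson(lambda_ds * site_ratio * omega_div).
    The expected neutrality index is omega_poly / omega_div.
    """
    rng = np.random.default_rng(config.seed)
    g = config.n_genes
    df = pd.DataFrame({
        "gene_id": [f"g{i:05d}" for i in range(g)],
        "Ps": rng.poisson(config.lambda_ps, g),
        "Pn": rng.poisson(config.lambda_ps * config.site_ratio * config.omega_poly, g),
        "Ds": rng.poisson(config.lambda_ds, g),
        "Dn": rng.poisson(config.lambda_ds * config.site_ratio * config.omega_div, g),
    })
    truth = {
        "expected_ni": config.expected_ni,
        "omega_poly": config.omega_poly,
        "omega_div": config.omega_div,
    }
    return df, truth


# ---------------------------------------------------------------------------
# Ks mixture / paralog pairs

@dataclass
class KsMixtureSpec:
    components: list[tuple[float, float, float]]  # (weight, log-mean, log-sd)
    background: tuple[float, float] | None = None  # (weight, exponential rate)
    n_pairs: int = 1000
    emit_sequences: bool = False
    codons_per_pair: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        w = sum(c[0] for c in self.components) + (self.background[0] if self.background else 0.0)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"mixture weights must sum to 1, got {w}")
        if any(c[0] < 0 or c[2] <= 0 for c in self.components):
            raise ValueError("component weights must be >= 0 and log-sds > 0")


def _fourfold_codons(code: GeneticCode) -> list[str]:
    """Sense codons with a fully degenerate third position and exactly one
    NG86 synonymous site (so synonymous sites == codon count exactly)."""
    out = []
    for c1 in BASES:
        for c2 in BASES:
            family = [c1 + c2 + b for b in BASES]
            if any(code.is_stop(c) for c in family):
                continue
            if len({code.forward[c] for c in family}) != 1:
                continue
            if all(abs(potential_sites(c, code).s_sites - 1.0) < 1e-9 for c in family):
                out.extend(family)
    return out


def simulate_ks_pairs(
    spec: KsMixtureSpec, code: GeneticCode | None = None
) -> tuple[pd.DataFrame, list[tuple[SequenceRecord, SequenceRecord]] | None]:
    """Paralog-pair Ks targets from a log-normal mixture.

    With ``emit_sequences``, each pair is materialized as a codon alignment
    built from four-fold-degenerate codons: a copy of a random sequence
    receives third-position substitutions per site with probability
    p = (3/4)(1 - exp(-(4/3) Ks_target)), so NG86 + Jukes-Cantor Ks
    estimation recovers the target in expectation.
    """
    code = code or get_code(1)
    rng = np.random.default_rng(spec.seed)
    weights = [c[0] for c in spec.components]
    labels = list(range(len(spec.components)))
    if spec.background:
        weights = weights + [spec.background[0]]
        labels = labels + [-1]
    choice = rng.choice(len(weights), size=spec.n_pairs, p=np.array(weights))
    ks_target = np.empty(spec.n_pairs)
    comp_label = np.empty(spec.n_pairs, dtype=int)
    for i, c in enumerate(choice):
        lab = labels[int(c)]
        comp_label[i] = lab
        if lab == -1:
            ks_target[i] = rng.exponential(1.0 / spec.background[1])
        else:
            _, mu, sd = spec.components[lab]
            ks_target[i] = math.exp(rng.normal(mu, sd))
    df = pd.DataFrame({
        "pair_id": [f"pair{i:05d}" for i in range(spec.n_pairs)],
        "truth_component": comp_label,
        "truth_ks": ks_target,
    })
    if not spec.emit_sequences:
        return df, None
    pool = _fourfold_codons(code)
    pairs: list[tuple[SequenceRecord, SequenceRecord]] = []
    for i in range(spec.n_pairs):
        codons = rng.choice(pool, size=spec.codons_per_pair)
        seq_a = "".join(codons)
        p_sub = 0.75 * (1.0 - math.exp(-(4.0 / 3.0) * ks_target[i]))
        b = list(seq_a)
        hit = rng.random(spec.codons_per_pair) < p_sub
        for j in np.nonzero(hit)[0]:
            third = 3 * int(j) + 2
            alternatives = [x for x in BASES if x != b[third]]
            b[third] = alternatives[int(rng.integers(3))]
        pairs.append((
            SequenceRecord(f"pair{i:05d}_a", seq_a),
            SequenceRecord(f"pair{i:05d}_b", "".join(b)),
        ))
    return df, pairs


# ---------------------------------------------------------------------------
# Inbreeding genotypes

@dataclass
class InbreedingSimConfig:
    n_individuals: int
    n_sites: int
    f_values: list[float]
    freq_range: tuple[float, float] = (0.05, 0.95)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.f_values) != self.n_individuals:
            raise ValueError("need one F per individual")
        if any(not (0.0 <= f <= 1.0) for f in self.f_values):
            raise ValueError("F must lie in [0, 1]")
        lo, hi = self.freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("freq_range must satisfy 0 < p_min <= p_max < 1")


def simulate_genotypes_inbreeding(
    config: InbreedingSimConfig,
) -> tuple[np.ndarray, dict]:
    """Diploid genotype dosages (alt-allele counts 0/1/2) with known F.

    Per site j a ref-allele frequency p_j is drawn uniformly from
    ``freq_range``; individual i's genotype follows
    hom-ref p^2 + F p q, het 2 p q (1 - F), hom-alt q^2 + F p q.
    """
    rng = np.random.default_rng(config.seed)
    p = rng.uniform(*config.freq_range, size=config.n_sites)
    q = 1.0 - p
    geno = np.empty((config.n_individuals, config.n_sites), dtype=np.int8)
    for i, f in enumerate(config.f_values):
        probs = np.stack([
            p * p + f * p * q,       # dosage 0 (hom ref)
            2 * p * q * (1 - f),     # dosage 1 (het)
            q * q + f * p * q,       # dosage 2 (hom alt)
        ])
        u = rng.random(config.n_sites)
        geno[i] = (u >= probs[0]).astype(np.int8) + (u >= probs[0] + probs[1])
    truth = {"f_values": list(config.f_values), "p": p}
    return geno, truth


# ---------------------------------------------------------------------------
# Scaffolds with telomere tracts

@dataclass
class ScaffoldSimConfig:
    n_scaffolds: int
    length_range: tuple[int, int] = (5_000, 60_000)
    gc_target: float = 0.335
    class_proportions: tuple[float, float, float] = (0.2, 0.45, 0.35)  # 0/1/2 ends
    repeats_per_tract: int = 5
    jitter: int = 0             # max random offset of a tract from the scaffold end
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if self.repeats_per_tract < 1:
            raise ValueError("repeats_per_tract must be >= 1")
        if not (0.0 < self.gc_target < 1.0):
            raise ValueError("gc_target must be in (0, 1)")


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _telomere_tract(rng: np.random.Generator, repeats: int) -> str:
    units = rng.integers(0, 2, size=repeats)
    return "".join(TELOMERE_MOTIF_CHOICES[int(u)] for u in units)


def simulate_scaffolds(
    config: ScaffoldSimConfig,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Random scaffolds carrying 0, 1 or 2 terminal telomere tracts.

    The tract is ``repeats_per_tract`` tandem copies of TT(T/G)GGG with the
    degenerate position drawn independently per copy; 5' tracts run in the
    forward orientation, 3' tracts are reverse-complemented (the motif reads
    CCC(A/C)AA on the forward strand at the 3' end).  ``jitter`` shifts the
    tract up to that many bases away from the scaffold end.
    """
    rng = np.random.default_rng(config.seed)
    gc = config.gc_target
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    records: list[SequenceRecord] = []
    rows = []
    classes = rng.choice(3, size=config.n_scaffolds, p=np.array(config.class_proportions))
    for i in range(config.n_scaffolds):
        length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        seq = "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=base_p)])
        cls = int(classes[i])
        has5 = cls == 2 or (cls == 1 and rng.random() < 0.5)
        has3 = cls == 2 or (cls == 1 and not has5)
        off5 = off3 = 0
        if has5:
            tract = _telomere_tract(rng, config.repeats_per_tract)
            off5 = int(rng.integers(0, config.jitter + 1)) if config.jitter else 0
            seq = seq[:off5] + tract + seq[off5 + len(tract):]
        if has3:
            tract = _revcomp(_telomere_tract(rng, config.repeats_per_tract))
            off3 = int(rng.integers(0, config.jitter + 1)) if config.jitter else 0
            end = length - off3
            seq = seq[:end - len(tract)] + tract + seq[end:]
        sid = f"scaffold{i:04d}"
        records.append(SequenceRecord(sid, seq))
        rows.append({
            "scaffold_id": sid,
            "truth_length": length,
            "truth_class": cls,
            "truth_telomere_5p": has5,
            "truth_telomere_3p": has3,
            "truth_offset_5p": off5,
            "truth_offset_3p": off3,
        })
    return records, pd.DataFrame(rows)
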