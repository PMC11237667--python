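"""McDonald-Kreitman tests, neutrality indices and gene-class summaries.

The MK test contrasts nonsynonymous/synonymous ratios of within-species
polymorphism (Pn/Ps) against between-species fixed divergence (Dn/Ds).
The neutrality index NI = (Pn/Ps)/(Dn/Ds) exceeds 1 when nonsynonymous
variants segregate in excess of their fixation rate — the signature of
purifying selection against mildly deleterious amino-acid variants.

Class summaries join per-gene diversity and MK statistics to life-stage
DEG-class labels and gene-family expansion status, producing the per-class
tables (mean Tajima's D, NI distribution, expanding/contracting overlap
fractions) that this kind of study reports.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .codons import BASES, GeneticCode, pathway_diffs


@dataclass
class MKTable:
    """The 2x2 MK counts for one gene.

    Polymorphism counts are integers (one per segregating coding site);
    divergence counts may be pathway-averaged fractions when a codon carries
    several fixed differences (``fractional`` is then set).
    """

    gene_id: str
    Pn: float
    Ps: float
    Dn: float
    Ds: float
    n_codons_excluded: int = 0
    fractional: bool = False

    def __post_init__(self) -> None:
        if min(self.Pn, self.Ps, self.Dn, self.Ds) < 0:
            raise ValueError("MK counts must be >= 0")


@dataclass
class MKResult:
    gene_id: str
    ni: float | None
    fisher_p: float
    defined: bool
    correction_used: Literal["none", "haldane"] = "none"


# ---------------------------------------------------------------------------
# Counting

def _major_allele(counts: dict[str, int], tie_break: str) -> str:
    """Most common base; ties resolved toward ``tie_break`` if tied, else
    alphabetically for determinism."""
    top = max(counts.values())
    tied = sorted(b for b, c in counts.items() if c == top)
    if tie_break in tied:
        return tie_break
    return tied[0]


def count_mk(
    ingroup_cds: Sequence[str],
    outgroup_cds: str,
    code: GeneticCode,
    gene_id: str = "",
    ref_cds: str | None = None,
) -> MKTable:
    """Build the MK 2x2 table from aligned CDS sequences.

    * Polymorphism: a site segregating within the ingroup, classified
      synonymous/nonsynonymous by substituting the minor allele into the
      ingroup major-allele codon context.  Counted once per segregating
      site, so Pn + Ps equals the number of segregating coding sites.
    * Fixed difference: a site monomorphic in the ingroup and different from
      the outgroup, classified via NG86 pathway averaging on the
      (ingroup codon, outgroup codon) pair with ingroup-polymorphic
      positions neutralized — sites both polymorphic and divergent count as
      polymorphism only.
    * Codons containing a stop in the ingroup consensus or the outgroup, or
      whose divergence pathways all pass through stops, are excluded and
      counted in ``n_codons_excluded``.

    ``ref_cds`` breaks major-allele ties toward the reference base
    (defaults to the first ingroup sequence).
    """
    if len(ingroup_cds) < 2:
        raise ValueError("count_mk needs >= 2 ingroup haplotypes")
    length = len(outgroup_cds)
    if any(len(s) != length for s in ingroup_cds):
        raise ValueError("ingroup and outgroup CDS must be aligned to equal length")
    if length % 3 != 0:
        raise ValueError("alignment length must be a multiple of 3")
    ref_cds = ref_cds or ingroup_cds[0]

    pn = ps = 0
    dn = ds = 0.0
    excluded = 0
    fractional = False
    for c0 in range(0, length, 3):
        out_codon = outgroup_cds[c0:c0 + 3].upper()
        # per-position allele counts among non-ambiguous ingroup calls
        pos_counts: list[dict[str, int]] = []
        for off in range(3):
            counts: dict[str, int] = {}
            for seq in ingroup_cds:
                b = seq[c0 + off].upper()
                if b in BASES:
                    counts[b] = counts.get(b, 0) + 1
            pos_counts.append(counts)
        if any(not c for c in pos_counts):
            excluded += 1
            continue
        major = "".join(
            _major_allele(pos_counts[off], ref_cds[c0 + off].upper())
            for off in range(3)
        )
        if code.is_stop(major):
            excluded += 1
            continue
        out_ok = all(b in BASES for b in out_codon) and not code.is_stop(out_codon)

        poly_positions = [off for off in range(3) if len(pos_counts[off]) > 1]
        codon_pn = codon_ps = 0
        for off in poly_positions:
            minors = sorted(
                (b for b in pos_counts[off] if b != major[off]),
                key=lambda b: (-pos_counts[off][b], b),
            )
            minor = minors[0]
            mutant = major[:off] + minor + major[off + 1:]
            if code.is_stop(mutant) or code.forward[mutant] != code.forward[major]:
                codon_pn += 1
            else:
                codon_ps += 1
        pn += codon_pn
        ps += codon_ps

        if not out_ok:
            excluded += 1
            continue
        # neutralize polymorphic positions so only fixed differences remain
        fixed_target = list(out_codon)
        for off in poly_positions:
            fixed_target[off] = major[off]
        fixed_target = "".join(fixed_target)
        if fixed_target != major:
            diffs = pathway_diffs(major, fixed_target, code)
            if diffs is None:
                excluded += 1
                continue
            if diffs[0] % 1 or diffs[1] % 1:
                fractional = True
            ds += diffs[0]
            dn += diffs[1]
    return MKTable(
        gene_id=gene_id, Pn=pn, Ps=ps, Dn=dn, Ds=ds,
        n_codons_excluded=excluded, fractional=fractional,
    )


# ---------------------------------------------------------------------------
# NI and Fisher test

def mk_fisher(table: MKTable) -> float:
    """Two-sided Fisher exact p for [[Dn, Ds], [Pn, Ps]].

    Counts are rounded to the nearest integer (pathway-averaged fractions
    occur only for multi-hit codons).  An all-zero table returns p = 1.
    """
    cells = np.round([[table.Dn, table.Ds], [table.Pn, table.Ps]]).astype(int)
    if cells.sum() == 0:
        return 1.0
    return float(stats.fisher_exact(cells, alternative="two-sided")[1])


def neutrality_index(
    table: MKTable, correction: Literal["none", "haldane"] = "none"
) -> MKResult:
    """NI = (Pn/Ps)/(Dn/Ds) plus the Fisher exact p for the same table.

    With ``correction='none'`` any zero denominator (Ps, Dn or Ds = 0, or
    Pn = 0 making the ratio 0) leaves NI undefined; ``'haldane'`` adds 0.5
    to all four cells first.
    """
    pn, ps, dn, ds = table.Pn, table.Ps, table.Dn, table.Ds
    if correction == "haldane":
        pn, ps, dn, ds = pn + 0.5, ps + 0.5, dn + 0.5, ds + 0.5
    if ps > 0 and ds > 0 and dn > 0 and pn > 0:
        ni = (pn / ps) / (dn / ds)
        defined = True
    else:
        ni, defined = None, False
    return MKResult(
        gene_id=table.gene_id, ni=ni, fisher_p=mk_fisher(table),
        defined=defined, correction_used=correction,
    )


def ni_tg(tables: Sequence[MKTable]) -> float | None:
    """Stoletzki & Eyre-Walker cross-gene ratio-of-sums neutrality index:

    NI_TG = sum_i(Ds_i Pn_i / (Ps_i + Ds_i)) / sum_i(Ps_i Dn_i / (Ps_i + Ds_i))

    Less biased than averaging per-gene NI when counts are small.
    """
    num = den = 0.0
    for t in tables:
        tot = t.Ps + t.Ds
        if tot <= 0:
            continue
        num += t.Ds * t.Pn / tot
        den += t.Ps * t.Dn / tot
    if den == 0:
        return None
    return num / den


def mk_results_frame(
    tables: Sequence[MKTable], correction: Literal["none", "haldane"] = "none"
) -> pd.DataFrame:
    columns = ["gene_id", "Pn", "Ps", "Dn", "Ds", "ni", "fisher_p",
               "ni_defined", "correction"]
    rows = []
    for t in tables:
        r = neutrality_index(t, correction)
        rows.append({
            "gene_id": t.gene_id, "Pn": t.Pn, "Ps": t.Ps, "Dn": t.Dn, "Ds": t.Ds,
            "ni": np.nan if r.ni is None else r.ni,
            "fisher_p": r.fisher_p, "ni_defined": r.defined,
            "correction": r.correction_used,
        })
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# Class comparison layer

def family_overlap(
    gene_sets: pd.DataFrame, include_unknown: bool = True
) -> pd.DataFrame:
    """Per-class fractions of genes in expanding/contracting/stable families.

    With ``include_unknown`` (default) the denominator is all class genes and
    the four fractions sum to 1; otherwise genes with unknown family status
    leave the denominator.
    """
    rows = []
    for label, sub in gene_sets.groupby("class", sort=True):
        if not include_unknown:
            sub = sub[sub["family_status"] != "unknown"]
        n = len(sub)
        row = {"class": label, "n_genes": n}
        for status in ("expanding", "contracting", "stable", "unknown"):
            row[f"frac_{status}"] = (
                float((sub["family_status"] == status).sum()) / n if n else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _bootstrap_ci(
    values: np.ndarray, b: int, seed: int, level: float = 0.95
) -> tuple[float, float]:
    """Percentile bootstrap CI for the mean, resampling genes."""
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(b, len(values)))
    means = values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def class_summary(
    gene_stats: pd.DataFrame,
    mk_results: pd.DataFrame,
    gene_sets: pd.DataFrame,
    b_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-DEG-class diversity/selection summary.

    Joins per-gene diversity statistics and MK results onto class labels and
    reports, per class: gene count, mean pi, mean Tajima's D (over defined
    values), mean/median NI, the fraction of defined NI values above 1 with
    a seeded percentile-bootstrap CI for the mean NI, and the
    expanding/contracting family-overlap fractions.  A 'background' row is
    always emitted for contrast (empty if no genes carry that label).
    """
    stats_df = gene_stats.merge(gene_sets, on="gene_id", how="inner")
    mk_df = mk_results.merge(gene_sets, on="gene_id", how="inner")
    fam = family_overlap(gene_sets).set_index("class")
    labels = sorted(set(gene_sets["class"]))
    if "background" not in labels:
        labels.append("background")
    rows = []
    for label in labels:
        s = stats_df[stats_df["class"] == label]
        m = mk_df[mk_df["class"] == label]
        d_vals = s["tajima_d"].dropna().to_numpy(dtype=float)
        ni_vals = m.loc[m["ni_defined"].astype(bool), "ni"].to_numpy(dtype=float) \
            if len(m) else np.array([])
        row = {
            "class": label,
            "n_genes": int(len(s)) if len(s) else int(len(m)),
            "mean_pi": float(s["pi"].mean()) if len(s) else np.nan,
            "mean_pi_s": float(s["pi_s"].dropna().mean())
            if len(s) and s["pi_s"].notna().any() else np.nan,
            "mean_tajima_d": float(d_vals.mean()) if len(d_vals) else np.nan,
            "mean_ni": float(ni_vals.mean()) if len(ni_vals) else np.nan,
            "median_ni": float(np.median(ni_vals)) if len(ni_vals) else np.nan,
            "frac_ni_gt1": float((ni_vals > 1).mean()) if len(ni_vals) else np.nan,
            "n_ni_defined": int(len(ni_vals)),
        }
        if len(ni_vals) >= 2:
            lo, hi = _bootstrap_ci(
                ni_vals, b_boot, seed ^ (zlib.crc32(label.encode()) & 0x7FFFFFFF)
            )
            row["ni_ci_lo"], row["ni_ci_hi"] = lo, hi
        else:
            row["ni_ci_lo"] = row["ni_ci_hi"] = np.nan
        if label in fam.index:
            row["frac_expanding"] = fam.loc[label, "frac_expanding"]
            row["frac_contracting"] = fam.loc[label, "frac_contracting"]
        else:
            row["frac_expanding"] = row["frac_contracting"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
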