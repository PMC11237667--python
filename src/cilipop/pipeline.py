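"""End-to-end pipeline orchestration.

A declarative config names the inputs (VCF, reference FASTA, GFF3, gene-set
labels, paralog-pair alignments, outgroup CDS, scaffold FASTA) and the
per-stage parameters; stages write TSV/JSON outputs plus a manifest with
checksums so deterministic stages can be audited byte-for-byte.

The ``simulate`` stage materializes a fully synthetic demo cohort — every
input the other stages consume, generated with known ground truth — so the
whole pipeline runs offline end to end.
"""

from __future__ import annotations

import hashlib
import json
import math
import os
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__, assembly, diversity, io, kswgd, linkage, selection
from .codons import BASES, get_code, potential_sites
from .simulate import (
    CoalescentConfig,
    Demography,
    InbreedingSimConfig,
    KsMixtureSpec,
    ScaffoldSimConfig,
    derive_seed,
    simulate_coalescent,
    simulate_genotypes_inbreeding,
    simulate_ks_pairs,
    simulate_ld_haplotypes,
    simulate_scaffolds,
)

STAGES = ("simulate", "diversity", "mktest", "classes", "ld", "het", "ks", "telomere")


class StageError(RuntimeError):
    """A stage failed or a prerequisite stage has not been run."""


@dataclass
class PipelineConfig:
    outdir: Path
    seed: int = 1
    genetic_code: int = 1
    inputs: dict[str, Any] = field(default_factory=dict)
    params: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "outdir" not in raw:
            raise ValueError(f"{path}: config must set 'outdir'")
        return cls(
            outdir=Path(raw["outdir"]),
            seed=int(raw.get("seed", 1)),
            genetic_code=int(raw.get("genetic_code", 1)),
            inputs=raw.get("inputs", {}) or {},
            params=raw.get("params", {}) or {},
        )

    def to_dict(self) -> dict:
        return {
            "outdir": str(self.outdir),
            "seed": self.seed,
            "genetic_code": self.genetic_code,
            "inputs": {k: str(v) for k, v in self.inputs.items()},
            "params": self.params,
        }

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def provenance(self) -> str:
        return f"cilipop v{__version__} config={self.config_hash} seed={self.seed}"

    def input_path(self, key: str) -> Path:
        if key not in self.inputs:
            raise StageError(
                f"input '{key}' not configured; run the 'simulate' stage or "
                f"point inputs.{key} at a file"
            )
        p = Path(self.inputs[key])
        if not p.exists():
            raise StageError(f"input '{key}' missing on disk: {p}")
        return p

    def param(self, stage: str, key: str, default: Any) -> Any:
        return (self.params.get(stage) or {}).get(key, default)


# ---------------------------------------------------------------------------
# Manifest and atomic output helpers

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _manifest_path(config: PipelineConfig) -> Path:
    return config.outdir / "manifest.json"


def _record_stage(config: PipelineConfig, stage: str, outputs: list[Path],
                  warnings: list[str]) -> None:
    path = _manifest_path(config)
    manifest = {"tool": f"cilipop v{__version__}", "config_hash": config.config_hash,
                "stages": {}}
    if path.exists():
        manifest = json.loads(path.read_text())
    manifest["stages"][stage] = {
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "outputs": {p.name: _sha256(p) for p in outputs},
        "warnings": warnings,
    }
    _atomic_write_text(path, json.dumps(manifest, indent=2) + "\n")


def _atomic_write_text(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def _write_tsv(config: PipelineConfig, df: pd.DataFrame, name: str) -> Path:
    path = config.outdir / name
    tmp = path.with_suffix(".tmp")
    io.write_tsv(df, tmp, header_comment=config.provenance())
    os.replace(tmp, path)
    return path


def _write_json(config: PipelineConfig, obj: dict, name: str) -> Path:
    path = config.outdir / name
    obj = {"provenance": config.provenance(), **obj}
    _atomic_write_text(path, json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path


# ---------------------------------------------------------------------------
# Demo-cohort generation (the 'simulate' stage)

_SENSE_CODON_CACHE: dict[int, list[str]] = {}


def _sense_codons(code_id: int) -> list[str]:
    if code_id not in _SENSE_CODON_CACHE:
        code = get_code(code_id)
        _SENSE_CODON_CACHE[code_id] = [
            c for c in sorted(code.forward) if not code.is_stop(c)
        ]
    return _SENSE_CODON_CACHE[code_id]


def _random_cds(rng: np.random.Generator, n_codons: int, code_id: int) -> str:
    pool = _sense_codons(code_id)
    return "".join(pool[int(i)] for i in rng.integers(0, len(pool), size=n_codons))


def _mutate_outgroup(
    rng: np.random.Generator, cds: str, code_id: int, sub_rate: float,
) -> str:
    """Outgroup CDS: unconstrained single-base substitutions at ``sub_rate``
    per site (at most one per codon, never creating stops), so divergence is
    as selectively neutral as the simulated polymorphism."""
    code = get_code(code_id)
    out = []
    for i in range(0, len(cds), 3):
        codon = cds[i:i + 3]
        if rng.random() < 3 * sub_rate:
            neigh = [c for c in _codon_neighbours(codon) if not code.is_stop(c)]
            if neigh:
                codon = neigh[int(rng.integers(len(neigh)))]
        out.append(codon)
    return "".join(out)


def _codon_neighbours(codon: str) -> list[str]:
    return [
        codon[:p] + b + codon[p + 1:]
        for p in range(3) for b in BASES if b != codon[p]
    ]


def simulate_cohort(config: PipelineConfig) -> dict[str, Path]:
    """Generate every pipeline input with known ground truth.

    Writes, under ``outdir/cohort``: a reference FASTA of gene-bearing
    chromosomes, a GFF3 of single-exon CDS genes, a coalescent-derived VCF
    for nine diploid strains, gene-set labels with class-dependent family
    status, an outgroup CDS FASTA, LD and inbreeding VCFs on dedicated
    chromosomes, paralog-pair alignments for a two-WGD and a one-WGD
    "species", and a scaffold FASTA with telomere tracts.  Truth tables are
    emitted alongside with ``truth_`` columns.
    """
    cohort = config.outdir / "cohort"
    cohort.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    code_id = config.genetic_code
    sim = config.params.get("simulate") or {}
    n_strains = int(sim.get("n_strains", 9))
    n_genes = int(sim.get("n_genes", 24))
    codons_per_gene = int(sim.get("codons_per_gene", 200))
    theta = float(sim.get("theta_per_gene", 8.0))
    samples = [f"strain{i+1:02d}" for i in range(n_strains)]
    rng = np.random.default_rng(derive_seed(seed, "cohort"))

    # --- gene-bearing chromosomes, gene models, coalescent variants -------
    gene_len = codons_per_gene * 3
    spacer = 400
    genes_per_chrom = max(1, n_genes // 2)
    chroms: dict[str, str] = {}
    models: list[io.GeneModel] = []
    variants: list[io.VariantRecord] = []
    gene_rows = []
    gidx = 0
    for c in range(math.ceil(n_genes / genes_per_chrom)):
        chrom = f"chr{c+1}"
        seq_parts: list[str] = []
        cursor = 0
        for _ in range(min(genes_per_chrom, n_genes - gidx)):
            gene_id = f"gene{gidx:03d}"
            pad = "".join(
                "ACGT"[int(x)] for x in rng.integers(0, 4, size=spacer)
            )
            cds = _random_cds(rng, codons_per_gene, code_id)
            start = cursor + len(pad) + 1          # 1-based
            end = start + gene_len - 1
            seq_parts.extend([pad, cds])
            cursor = end
            models.append(io.GeneModel(gene_id, chrom, "+", [(start, end)]))
            # neutral coalescent polymorphism mapped onto the gene span
            hap, truth = simulate_coalescent(CoalescentConfig(
                n=2 * n_strains, theta=theta, locus_length=gene_len,
                seed=derive_seed(seed, f"coal:{gene_id}"),
            ))
            for (_, rel_pos), col in zip(hap.positions, hap.alleles.T):
                pos = start + rel_pos - 1
                ref_base = cds[rel_pos - 1]
                alt_base = "ACGT"[(("ACGT".index(ref_base)) +
                                   1 + int(rng.integers(3))) % 4]
                gts = [
                    (int(col[2 * s]), int(col[2 * s + 1]))
                    for s in range(n_strains)
                ]
                variants.append(io.VariantRecord(chrom, pos, ref_base, alt_base, gts))
            gene_rows.append({
                "gene_id": gene_id, "truth_theta": theta,
                "truth_S": truth.n_mutations,
            })
            gidx += 1
        tail = "".join("ACGT"[int(x)] for x in rng.integers(0, 4, size=spacer))
        seq_parts.append(tail)
        chroms[chrom] = "".join(seq_parts)
    variants.sort(key=lambda v: (v.chrom, v.pos))

    ref_path = cohort / "reference.fasta"
    io.write_fasta(
        [io.SequenceRecord(k, v) for k, v in sorted(chroms.items())], ref_path
    )
    gff_path = cohort / "genes.gff3"
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            s, e = m.cds_intervals[0]
            fh.write(
                f"{m.chrom}\tcilipop\tgene\t{s}\t{e}\t.\t{m.strand}\t.\tID={m.gene_id}\n"
                f"{m.chrom}\tcilipop\tCDS\t{s}\t{e}\t.\t{m.strand}\t0\t"
                f"ID=cds.{m.gene_id};Parent={m.gene_id}\n"
            )
    vcf_path = cohort / "variants.vcf"
    io.write_vcf(variants, samples, vcf_path,
                 contigs=[(k, len(v)) for k, v in sorted(chroms.items())])
    io.write_tsv(pd.DataFrame(gene_rows), cohort / "truth_genes.tsv")

    # --- outgroup CDS ------------------------------------------------------
    reference = {k: v for k, v in chroms.items()}
    out_rng = np.random.default_rng(derive_seed(seed, "outgroup"))
    out_records = []
    for m in models:
        cds = m.extract_cds(reference)
        out_records.append(io.SequenceRecord(
            m.gene_id,
            _mutate_outgroup(
                out_rng, cds, code_id,
                sub_rate=float(sim.get("outgroup_sub_rate", 0.02)),
            ),
        ))
    outgroup_path = cohort / "outgroup_cds.fasta"
    io.write_fasta(out_records, outgroup_path)

    # --- gene-set labels ---------------------------------------------------
    label_rng = np.random.default_rng(derive_seed(seed, "labels"))
    classes = ["DEG_reproductive", "DEG_resting", "DEG_revived", "background"]
    class_probs = [0.15, 0.15, 0.15, 0.55]
    fam_probs = {
        # DEG classes enriched for expanding families, background not
        "DEG_reproductive": [0.29, 0.06, 0.45, 0.20],
        "DEG_resting": [0.29, 0.06, 0.45, 0.20],
        "DEG_revived": [0.29, 0.03, 0.48, 0.20],
        "background": [0.10, 0.10, 0.60, 0.20],
    }
    fam_labels = ["expanding", "contracting", "stable", "unknown"]
    rows = []
    for m in models:
        cls = classes[int(label_rng.choice(4, p=class_probs))]
        fam = fam_labels[int(label_rng.choice(4, p=fam_probs[cls]))]
        rows.append({"gene_id": m.gene_id, "class": cls, "family_status": fam})
    gene_sets_path = cohort / "gene_sets.tsv"
    io.write_tsv(pd.DataFrame(rows), gene_sets_path)

    # --- LD chromosome -----------------------------------------------------
    ld_d0 = float(sim.get("ld_d0", 500.0))
    ld_hap, ld_truth = simulate_ld_haplotypes(
        n_hap=2 * n_strains,
        n_sites=int(sim.get("ld_sites", 200)),
        spacing=float(sim.get("ld_spacing", 100.0)),
        d0=ld_d0,
        seed=derive_seed(seed, "ld"),
    )
    ld_variants = []
    for (_, pos), col in zip(ld_hap.positions, ld_hap.alleles.T):
        gts = [(int(col[2 * s]), int(col[2 * s + 1])) for s in range(n_strains)]
        ld_variants.append(io.VariantRecord("ld_chrom", pos, "A", "G", gts))
    ld_path = cohort / "ld.vcf"
    io.write_vcf(ld_variants, samples, ld_path)
    io.write_tsv(
        pd.DataFrame([{"truth_d0": ld_d0, "truth_p": ld_truth["p"]}]),
        cohort / "truth_ld.tsv",
    )

    # --- inbreeding genotypes ---------------------------------------------
    f_lo = float(sim.get("f_min", 0.5))
    f_hi = float(sim.get("f_max", 0.9))
    f_values = list(np.round(np.linspace(f_lo, f_hi, n_strains), 3))
    geno, _ = simulate_genotypes_inbreeding(InbreedingSimConfig(
        n_individuals=n_strains,
        n_sites=int(sim.get("f_sites", 4000)),
        f_values=f_values,
        seed=derive_seed(seed, "inbreeding"),
    ))
    het_variants = []
    for j in range(geno.shape[1]):
        gts = []
        for i in range(n_strains):
            d = int(geno[i, j])
            gts.append((0, 0) if d == 0 else ((0, 1) if d == 1 else (1, 1)))
        het_variants.append(io.VariantRecord("het_chrom", j + 1, "A", "G", gts))
    het_path = cohort / "inbreeding.vcf"
    io.write_vcf(het_variants, samples, het_path)
    io.write_tsv(
        pd.DataFrame({"individual": samples, "truth_f": f_values}),
        cohort / "truth_f.tsv",
    )

    # --- paralog pairs: two-WGD vs one-WGD species -------------------------
    ks_codons = int(sim.get("ks_codons_per_pair", 300))
    species_specs = {
        "speciesA": KsMixtureSpec(
            components=[(0.55, math.log(0.5), 0.15), (0.45, math.log(1.5), 0.15)],
            n_pairs=int(sim.get("ks_pairs_two_peak", 700)),
            emit_sequences=True, codons_per_pair=ks_codons,
            seed=derive_seed(seed, "ks:A"),
        ),
        "speciesB": KsMixtureSpec(
            components=[(1.0, math.log(0.9), 0.20)],
            n_pairs=int(sim.get("ks_pairs_one_peak", 500)),
            emit_sequences=True, codons_per_pair=ks_codons,
            seed=derive_seed(seed, "ks:B"),
        ),
    }
    code = get_code(code_id)
    for name, spec in species_specs.items():
        truth_df, pairs = simulate_ks_pairs(spec, code)
        recs = []
        pair_rows = []
        for a, b in pairs:
            recs.extend([a, b])
            pair_rows.append({"gene_a": a.id, "gene_b": b.id})
        io.write_fasta(recs, cohort / f"paralogs_{name}.fasta")
        io.write_tsv(pd.DataFrame(pair_rows), cohort / f"paralogs_{name}.tsv")
        io.write_tsv(truth_df, cohort / f"truth_ks_{name}.tsv")

    # --- scaffolds with telomeres -----------------------------------------
    scaff_cfg = ScaffoldSimConfig(
        n_scaffolds=int(sim.get("n_scaffolds", 120)),
        gc_target=float(sim.get("gc_target", 0.335)),
        class_proportions=tuple(sim.get("telomere_proportions", (0.2, 0.45, 0.35))),
        repeats_per_tract=int(sim.get("telomere_repeats", 5)),
        jitter=int(sim.get("telomere_jitter", 20)),
        length_range=tuple(sim.get("scaffold_length_range", (3_000, 30_000))),
        seed=derive_seed(seed, "scaffolds"),
    )
    scaff_records, scaff_truth = simulate_scaffolds(scaff_cfg)
    scaff_path = cohort / "scaffolds.fasta"
    io.write_fasta(scaff_records, scaff_path)
    io.write_tsv(scaff_truth, cohort / "truth_scaffolds.tsv")

    paths = {
        "reference": ref_path, "gff3": gff_path, "vcf": vcf_path,
        "gene_sets": gene_sets_path, "outgroup_cds": outgroup_path,
        "ld_vcf": ld_path, "het_vcf": het_path,
        "paralogs_speciesA": cohort / "paralogs_speciesA.fasta",
        "paralogs_speciesA_pairs": cohort / "paralogs_speciesA.tsv",
        "paralogs_speciesB": cohort / "paralogs_speciesB.fasta",
        "paralogs_speciesB_pairs": cohort / "paralogs_speciesB.tsv",
        "scaffolds": scaff_path,
    }
    config.inputs.update({k: str(v) for k, v in paths.items()})
    _record_stage(config, "simulate", sorted(cohort.glob("*")), [])
    return paths


# ---------------------------------------------------------------------------
# Analysis stages

def _load_core_inputs(config: PipelineConfig):
    reference = io.fasta_dict(io.read_fasta(config.input_path("reference")))
    gff = io.read_gff3_cds(config.input_path("gff3"))
    vcf = io.read_vcf_biallelic(config.input_path("vcf"))
    return reference, gff, vcf


def stage_diversity(config: PipelineConfig) -> dict:
    """Per-gene and genome-wide pi, pi_s, S, Watterson's theta, Tajima's D."""
    reference, gff, vcf = _load_core_inputs(config)
    code = get_code(config.genetic_code)
    table = diversity.per_gene_stats(
        vcf.variants, gff.models, reference, code,
    )
    out = _write_tsv(config, table, "diversity_per_gene.tsv")
    warnings = []
    if vcf.n_skipped:
        warnings.append(f"skipped {vcf.n_skipped} non-biallelic/indel VCF records")
    if gff.rejects:
        warnings.append(f"{len(gff.rejects)} gene models rejected (frame)")
    _record_stage(config, "diversity", [out], warnings)
    genome = table[table["gene_id"] == diversity.GENOME_ROW_ID].iloc[0]
    return {
        "n_genes": int(len(table)) - 1,
        "genome_S": int(genome["S"]),
        "genome_pi": float(genome["pi"]),
        "genome_tajima_d": None if pd.isna(genome["tajima_d"])
        else float(genome["tajima_d"]),
        "mean_gene_tajima_d": float(
            table.loc[table["gene_id"] != diversity.GENOME_ROW_ID, "tajima_d"]
            .dropna().mean()
        ),
    }


def stage_mktest(config: PipelineConfig) -> dict:
    """Per-gene McDonald-Kreitman tables, NI and Fisher exact p."""
    reference, gff, vcf = _load_core_inputs(config)
    outgroup = io.fasta_dict(io.read_fasta(config.input_path("outgroup_cds")))
    code = get_code(config.genetic_code)
    correction = config.param("mk", "correction", "none")
    by_chrom: dict[str, list[io.VariantRecord]] = {}
    for v in vcf.variants:
        by_chrom.setdefault(v.chrom, []).append(v)
    tables = []
    for model in gff.models:
        if model.gene_id not in outgroup:
            continue
        lo = min(s for s, _ in model.cds_intervals)
        hi = max(e for _, e in model.cds_intervals)
        in_gene = [v for v in by_chrom.get(model.chrom, []) if lo <= v.pos <= hi]
        haps, _ = diversity.haplotype_cds_sequences(in_gene, model, reference)
        if len(haps) < 2:
            continue
        tables.append(selection.count_mk(
            haps, outgroup[model.gene_id], code, gene_id=model.gene_id,
            ref_cds=model.extract_cds(reference),
        ))
    df = selection.mk_results_frame(tables, correction=correction)
    out = _write_tsv(config, df, "mk_per_gene.tsv")
    _record_stage(config, "mktest", [out], [])
    defined = df[df["ni_defined"].astype(bool)]
    cross = selection.ni_tg(tables)
    return {
        "n_genes": int(len(df)),
        "n_ni_defined": int(len(defined)),
        "mean_ni": float(defined["ni"].mean()) if len(defined) else None,
        "ni_tg": None if cross is None else float(cross),
        "outgroup": str(config.inputs.get("outgroup_cds")),
    }


def stage_classes(config: PipelineConfig) -> dict:
    """Join diversity and MK results to DEG-class and family labels."""
    div_path = config.outdir / "diversity_per_gene.tsv"
    mk_path = config.outdir / "mk_per_gene.tsv"
    for p, stage in ((div_path, "diversity"), (mk_path, "mktest")):
        if not p.exists():
            raise StageError(f"'classes' needs the '{stage}' stage output {p.name}")
    gene_stats = io.read_tsv(div_path)
    gene_stats = gene_stats[gene_stats["gene_id"] != diversity.GENOME_ROW_ID]
    mk = io.read_tsv(mk_path)
    gene_sets = io.read_gene_sets(config.input_path("gene_sets"))
    summary = selection.class_summary(
        gene_stats, mk, gene_sets,
        b_boot=int(config.param("classes", "bootstrap_b", 1000)),
        seed=derive_seed(config.seed, "classes"),
    )
    overlap = selection.family_overlap(gene_sets)
    out1 = _write_tsv(config, summary, "class_summary.tsv")
    out2 = _write_tsv(config, overlap, "family_overlap.tsv")
    _record_stage(config, "classes", [out1, out2], [])
    return {
        "classes": summary["class"].tolist(),
        "mean_tajima_d_by_class": {
            r["class"]: (None if pd.isna(r["mean_tajima_d"]) else float(r["mean_tajima_d"]))
            for _, r in summary.iterrows()
        },
        "frac_ni_gt1_by_class": {
            r["class"]: (None if pd.isna(r["frac_ni_gt1"]) else float(r["frac_ni_gt1"]))
            for _, r in summary.iterrows()
        },
    }


def stage_ld(config: PipelineConfig) -> dict:
    """Distance-binned LD decay curve."""
    key = "ld_vcf" if "ld_vcf" in config.inputs else "vcf"
    vcf = io.read_vcf_biallelic(config.input_path(key))
    matrix = diversity.haplotypes_from_variants(
        vcf.variants, max(v.pos for v in vcf.variants) if vcf.variants else 1
    )
    curve = linkage.ld_decay(
        matrix,
        max_dist=float(config.param("ld", "max_dist", 10_000)),
        bin_edges=config.param("ld", "bin_edges", None),
        max_pairs_per_bin=config.param("ld", "max_pairs_per_bin", 10_000),
        seed=derive_seed(config.seed, "ld"),
        method=config.param("ld", "method", "haplotype"),
    )
    out = _write_tsv(config, curve.to_frame(), "ld_decay.tsv")
    _record_stage(config, "ld", [out], [])
    return {
        "bins": curve.bin_edges,
        "mean_r2": [None if math.isnan(x) else float(x) for x in curve.mean_r2],
        "method": config.param("ld", "method", "haplotype"),
    }


def stage_het(config: PipelineConfig) -> dict:
    """Per-strain observed/expected homozygosity and inbreeding F."""
    key = "het_vcf" if "het_vcf" in config.inputs else "vcf"
    vcf = io.read_vcf_biallelic(config.input_path(key))
    n = len(vcf.samples)
    geno = np.full((n, len(vcf.variants)), io.MISSING, dtype=np.int8)
    for j, v in enumerate(vcf.variants):
        for i, (a, b) in enumerate(v.genotypes):
            if a != io.MISSING and b != io.MISSING:
                geno[i, j] = a + b
    results = linkage.moments_f(geno, individual_ids=vcf.samples)
    df = linkage.het_frame(results)
    out = _write_tsv(config, df, "inbreeding_f.tsv")
    _record_stage(config, "het", [out], [])
    defined = df[df["defined"].astype(bool)]
    return {
        "f_by_individual": dict(zip(defined["individual"], defined["f"].round(4))),
        "f_min": float(defined["f"].min()),
        "f_max": float(defined["f"].max()),
    }


def stage_ks(config: PipelineConfig) -> dict:
    """Ks distributions, mixture fits and WGD peak calls per species."""
    code = get_code(config.genetic_code)
    species = sorted(
        k.removeprefix("paralogs_")
        for k in config.inputs
        if k.startswith("paralogs_") and not k.endswith("_pairs")
    )
    if not species:
        raise StageError("no paralogs_<species> inputs configured")
    outputs = []
    summary = {}
    for name in species:
        seqs = io.fasta_dict(io.read_fasta(config.input_path(f"paralogs_{name}")))
        pairs_df = io.read_paralog_pairs(config.input_path(f"paralogs_{name}_pairs"))
        pairs = [
            (io.SequenceRecord(a, seqs[a]), io.SequenceRecord(b, seqs[b]))
            for a, b in zip(pairs_df["gene_a"], pairs_df["gene_b"])
        ]
        dist, per_pair = kswgd.ks_for_pairs(
            pairs, code,
            ks_min=float(config.param("ks", "ks_min", 0.01)),
            ks_max=float(config.param("ks", "ks_max", 5.0)),
        )
        fit = kswgd.fit_ks_mixture(
            dist,
            k_range=range(1, int(config.param("ks", "k_max", 4)) + 1),
            n_restarts=int(config.param("ks", "n_restarts", 10)),
            seed=derive_seed(config.seed, f"ks:{name}"),
        )
        peaks = kswgd.call_wgd_peaks(
            fit, min_weight=float(config.param("ks", "min_weight", 0.1))
        )
        outputs.append(_write_tsv(config, per_pair, f"ks_values_{name}.tsv"))
        outputs.append(_write_tsv(
            config, kswgd.fit_summary_frame(fit), f"ks_fit_{name}.tsv"
        ))
        summary[name] = {
            "n_retained": dist.n_retained,
            "selected_k": fit.k,
            "n_peaks": peaks.n_peaks,
            "peak_modes": [round(m, 4) for m in peaks.modes],
            "peak_weights": [round(w, 4) for w in peaks.weights],
        }
    _record_stage(config, "ks", outputs, [])
    return summary


def stage_telomere(config: PipelineConfig) -> dict:
    """Assembly report with telomere scaffold classes."""
    records = io.read_fasta(config.input_path("scaffolds"))
    tcfg = assembly.TelomereConfig(
        min_repeats=int(config.param("telomere", "min_repeats", 3)),
        window=int(config.param("telomere", "window", 200)),
        max_offset=int(config.param("telomere", "max_offset", 50)),
        search_revcomp=bool(config.param("telomere", "search_revcomp", True)),
    )
    report, table = assembly.assembly_report(records, tcfg)
    out1 = _write_tsv(config, table, "scaffold_report.tsv")
    out2 = _write_json(config, {"assembly": report.to_dict()}, "assembly_report.json")
    _record_stage(config, "telomere", [out1, out2], [])
    return report.to_dict()


_STAGE_FNS = {
    "diversity": stage_diversity,
    "mktest": stage_mktest,
    "classes": stage_classes,
    "ld": stage_ld,
    "het": stage_het,
    "ks": stage_ks,
    "telomere": stage_telomere,
}


def run_stage(name: str, config: PipelineConfig) -> dict:
    """Run one named stage; outputs land under ``config.outdir``."""
    config.outdir.mkdir(parents=True, exist_ok=True)
    if name == "simulate":
        paths = simulate_cohort(config)
        return {k: str(v) for k, v in paths.items()}
    if name not in _STAGE_FNS:
        raise StageError(f"unknown stage {name!r}; choose from {STAGES}")
    return _STAGE_FNS[name](config)


def run_all(config: PipelineConfig, simulate_first: bool = False) -> dict:
    """Run every stage in dependency order and write a combined report.

    Stage failures are recorded as explicit gaps instead of aborting the
    remaining stages.
    """
    config.outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"seed": config.seed, "sections": {}, "gaps": {}}
    order = (("simulate",) if simulate_first else ()) + tuple(
        s for s in STAGES if s != "simulate"
    )
    for name in order:
        try:
            report["sections"][name] = run_stage(name, config)
        except StageError as exc:
            report["gaps"][name] = str(exc)
    _write_json(config, report, "report.json")
    _atomic_write_text(config.outdir / "report.txt", render_report(report))
    return report


def render_report(report: dict) -> str:
    lines = [f"cilipop combined report (seed {report['seed']})", "=" * 46]
    for name, section in report["sections"].items():
        lines.append(f"\n[{name}]")
        lines.append(json.dumps(section, indent=2, sort_keys=True, default=str))
    for name, gap in report.get("gaps", {}).items():
        lines.append(f"\n[{name}] FAILED: {gap}")
    return "\n".join(lines) + "\n"
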