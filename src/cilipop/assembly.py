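"""Macronuclear assembly profiling.

Ciliate macronuclear chromosomes are short and telomere-capped, so a useful
assembly-quality signal is the fraction of scaffolds that end in telomeric
repeats.  This module scans scaffold ends for tandem copies of the
degenerate ciliate telomere unit TT(T/G)GGG, classifies scaffolds by how
many ends carry a tract (0/1/2), and aggregates the standard assembly
features: N50, GC content, size-class counts, largest scaffold.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .io import SequenceRecord

TELOMERE_UNIT_FWD = r"TT[TG]GGG"
TELOMERE_UNIT_REV = r"CCC[AC]AA"   # reverse complement of the unit


@dataclass
class TelomereConfig:
    """Parameters of the terminal telomere-tract scan.

    ``min_repeats`` tandem unit copies must begin (5') or end (3') within
    ``max_offset`` bases of the scaffold end, searched inside a terminal
    ``window``.  With ``search_revcomp`` (default) the forward-strand motif
    is also accepted at the 3' end and vice versa, since assembly
    orientation is arbitrary.
    """

    min_repeats: int = 3
    window: int = 200
    max_offset: int = 50
    search_revcomp: bool = True

    def __post_init__(self) -> None:
        if self.min_repeats < 1:
            raise ValueError("min_repeats must be >= 1")
        if self.window < 6 * self.min_repeats:
            raise ValueError("window must cover min_repeats motif copies")

    @property
    def fwd_pattern(self) -> re.Pattern:
        return re.compile(f"(?:{TELOMERE_UNIT_FWD}){{{self.min_repeats},}}")

    @property
    def rev_pattern(self) -> re.Pattern:
        return re.compile(f"(?:{TELOMERE_UNIT_REV}){{{self.min_repeats},}}")


@dataclass
class ScaffoldReport:
    id: str
    length: int
    gc: float | None
    telomere_5p: bool
    telomere_3p: bool
    short_flag: bool = False

    @property
    def telomere_class(self) -> int:
        return int(self.telomere_5p) + int(self.telomere_3p)


@dataclass
class AssemblyReport:
    """Aggregate macronuclear assembly features (Table-1-style surface)."""

    n_scaffolds: int
    n_ge_1kb: int
    n_ge_10kb: int
    n_ge_50kb: int
    total_length: int
    largest_scaffold: int
    n50: int
    gc_percent: float
    n_telomere_2: int
    n_telomere_1: int
    n_telomere_0: int
    config: TelomereConfig = field(repr=False, default_factory=TelomereConfig)

    @property
    def pct_with_telomere(self) -> float:
        return 100.0 * (self.n_telomere_1 + self.n_telomere_2) / self.n_scaffolds

    def to_dict(self) -> dict:
        return {
            "Number of scaffolds": self.n_scaffolds,
            "Number of scaffolds (>=1,000 bp)": self.n_ge_1kb,
            "Number of scaffolds (>=10,000 bp)": self.n_ge_10kb,
            "Number of scaffolds (>=50,000 bp)": self.n_ge_50kb,
            "Genome size (bp)": self.total_length,
            "Largest scaffolds": self.largest_scaffold,
            "N50 (bp)": self.n50,
            "GC content (%)": round(self.gc_percent, 2),
            "Scaffolds with telomere (%)": round(self.pct_with_telomere, 2),
            "2-Telomeres scaffolds": self.n_telomere_2,
            "1-Telomere scaffolds": self.n_telomere_1,
        }


# ---------------------------------------------------------------------------

def scan_telomere(
    seq: str, config: TelomereConfig | None = None
) -> tuple[bool, bool, bool]:
    """Detect terminal telomere tracts; returns (5' hit, 3' hit, short flag).

    5' end: a run of >= min_repeats tandem motif copies starting within
    ``max_offset`` of position 1 inside the leading window.  3' end: the
    reverse-complement tract ending within ``max_offset`` of the final
    base.  Sequences shorter than the window are scanned whole and flagged.
    """
    config = config or TelomereConfig()
    seq = seq.upper()
    short = len(seq) < config.window
    window = min(config.window, len(seq))

    head = seq[:window]
    tail = seq[-window:]
    patterns_5p = [config.fwd_pattern]
    patterns_3p = [config.rev_pattern]
    if config.search_revcomp:
        patterns_5p.append(config.rev_pattern)
        patterns_3p.append(config.fwd_pattern)

    hit5 = any(
        m.start() <= config.max_offset
        for pat in patterns_5p for m in pat.finditer(head)
    )
    tail_offset = len(seq) - window
    hit3 = any(
        tail_offset + m.end() >= len(seq) - config.max_offset
        for pat in patterns_3p for m in pat.finditer(tail)
    )
    return hit5, hit3, short


def gc_content(seq: str) -> float | None:
    """(G+C) / (A+C+G+T); N and other ambiguity codes excluded from the
    denominator.  ``None`` for an effectively all-N sequence."""
    if not seq:
        raise ValueError("gc_content of empty sequence")
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    atgc = gc + seq.count("A") + seq.count("T")
    if atgc == 0:
        return None
    return gc / atgc


def n50(lengths: Sequence[int]) -> int:
    """Largest L such that scaffolds of length >= L total at least half the
    assembly."""
    if not lengths:
        raise ValueError("n50 of empty length list")
    if any(x <= 0 for x in lengths):
        raise ValueError("lengths must be positive")
    total = sum(lengths)
    acc = 0
    for x in sorted(lengths, reverse=True):
        acc += x
        if 2 * acc >= total:
            return x
    raise AssertionError("unreachable")


def scaffold_report(rec: SequenceRecord, config: TelomereConfig) -> ScaffoldReport:
    t5, t3, short = scan_telomere(rec.seq, config)
    return ScaffoldReport(
        id=rec.id, length=len(rec.seq), gc=gc_content(rec.seq),
        telomere_5p=t5, telomere_3p=t3, short_flag=short,
    )


def assembly_report(
    records: Iterable[SequenceRecord], config: TelomereConfig | None = None
) -> tuple[AssemblyReport, pd.DataFrame]:
    """Aggregate report plus a per-scaffold table for a scaffold FASTA."""
    config = config or TelomereConfig()
    reports = [scaffold_report(r, config) for r in records]
    if not reports:
        raise ValueError("no scaffolds in input")
    lengths = [r.length for r in reports]
    gc_num = sum(
        r.gc * r.length for r in reports if r.gc is not None
    )
    gc_den = sum(r.length for r in reports if r.gc is not None)
    classes = [r.telomere_class for r in reports]
    agg = AssemblyReport(
        n_scaffolds=len(reports),
        n_ge_1kb=sum(1 for x in lengths if x >= 1_000),
        n_ge_10kb=sum(1 for x in lengths if x >= 10_000),
        n_ge_50kb=sum(1 for x in lengths if x >= 50_000),
        total_length=sum(lengths),
        largest_scaffold=max(lengths),
        n50=n50(lengths),
        gc_percent=100.0 * gc_num / gc_den if gc_den else float("nan"),
        n_telomere_2=classes.count(2),
        n_telomere_1=classes.count(1),
        n_telomere_0=classes.count(0),
        config=config,
    )
    table = pd.DataFrame([{
        "scaffold_id": r.id,
        "length": r.length,
        "gc": r.gc,
        "telomere_5p": r.telomere_5p,
        "telomere_3p": r.telomere_3p,
        "telomere_class": r.telomere_class,
        "short_flag": r.short_flag,
    } for r in reports])
    return agg, table
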