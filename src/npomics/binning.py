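"""Contig binning and genome quality control.

Contigs are binned into the target (cyanobacterial) genome when they carry
at least one gene assigned to the target taxon AND their GC content is at
or below the GC ceiling (default 58%, inclusive). Assembled genomes pass
quality control when completeness is strictly above the floor (default
90%) and the scaffold count is strictly below the cap (default 500).
Summary statistics (per-genome BGC totals, scaffold ranges, genus tallies)
reproduce the dataset-level reporting of the study design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .config import PipelineConfig


@dataclass
class Contig:
    """One assembled contig with its upstream taxon annotation."""

    id: str
    sequence: str = ""
    gc_fraction: float | None = None
    has_target_taxon_gene: bool = False

    def __post_init__(self):
        if self.gc_fraction is None:
            if not self.sequence:
                raise ValueError(
                    f"contig {self.id}: no sequence and no GC value")
            self.gc_fraction = gc_content(self.sequence)
        elif self.sequence:
            expected = gc_content(self.sequence)
            if abs(expected - self.gc_fraction) > 1e-12:
                raise ValueError(
                    f"contig {self.id}: stated GC {self.gc_fraction} "
                    f"disagrees with sequence GC {expected}")


@dataclass
class GenomeRecord:
    """Genome-level metadata consumed from upstream assembly and QC."""

    id: str
    taxon_label: str
    n_scaffolds: int
    completeness: float | None  # externally supplied (e.g. CheckM)
    bgc_fragmented: int = 0
    bgc_complete: int = 0

    def __post_init__(self):
        if self.n_scaffolds < 0 or self.bgc_fragmented < 0 or self.bgc_complete < 0:
            raise ValueError(f"genome {self.id}: counts must be >= 0")
        if self.completeness is not None and not 0.0 <= self.completeness <= 1.0:
            raise ValueError(f"genome {self.id}: completeness must be in [0,1]")

    @property
    def total_bgcs(self) -> int:
        return self.bgc_fragmented + self.bgc_complete


def gc_content(sequence: str) -> float:
    """GC fraction over unambiguous bases only: (G+C)/(A+C+G+T)."""
    s = sequence.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return gc / (gc + at)


def bin_contigs(contigs: list[Contig], cfg: PipelineConfig,
                ) -> tuple[list[Contig], list[tuple[Contig, str]]]:
    """Split contigs into (kept, discarded-with-reason).

    Kept iff the contig has a target-taxon gene AND GC <= cfg.gc_max
    (inclusive boundary). Discard reasons: ``gc_too_high``,
    ``no_taxon_gene``, or ``both``.
    """
    kept: list[Contig] = []
    discarded: list[tuple[Contig, str]] = []
    for c in contigs:
        gc_ok = c.gc_fraction <= cfg.gc_max
        taxon_ok = c.has_target_taxon_gene
        if gc_ok and taxon_ok:
            kept.append(c)
        elif not gc_ok and not taxon_ok:
            discarded.append((c, "both"))
        elif not gc_ok:
            discarded.append((c, "gc_too_high"))
        else:
            discarded.append((c, "no_taxon_gene"))
    return kept, discarded


def quality_filter(genomes: list[GenomeRecord], cfg: PipelineConfig,
                   ) -> tuple[list[GenomeRecord], list[GenomeRecord]]:
    """Return (passing, unevaluable) genomes.

    Pass iff completeness > cfg.completeness_min AND n_scaffolds <
    cfg.max_contigs — both boundaries strict. Genomes missing a
    completeness value are listed as unevaluable, not failed.
    """
    passing: list[GenomeRecord] = []
    unevaluable: list[GenomeRecord] = []
    for g in genomes:
        if g.completeness is None:
            unevaluable.append(g)
        elif (g.completeness > cfg.completeness_min
              and g.n_scaffolds < cfg.max_contigs):
            passing.append(g)
    return passing, unevaluable


def _round_half_up(x: float, decimals: int = 1) -> float:
    factor = 10 ** decimals
    return math.floor(x * factor + 0.5) / factor


def genome_summary(genomes: list[GenomeRecord]) -> dict:
    """Dataset summary: BGC totals, scaffold range, genus tallies.

    The mean total BGC count is reported to one decimal (round half up).
    """
    if not genomes:
        raise ValueError("genome_summary requires at least one genome")
    totals = [g.total_bgcs for g in genomes]
    scaffolds = [g.n_scaffolds for g in genomes]
    tallies: dict[str, int] = {}
    for g in genomes:
        tallies[g.taxon_label] = tallies.get(g.taxon_label, 0) + 1
    return {
        "n_genomes": len(genomes),
        "bgc_total_sum": sum(totals),
        "bgc_total_mean": _round_half_up(sum(totals) / len(totals), 1),
        "bgc_total_min": min(totals),
        "bgc_total_max": max(totals),
        "scaffold_min": min(scaffolds),
        "scaffold_max": max(scaffolds),
        "scaffold_mean": _round_half_up(sum(scaffolds) / len(scaffolds), 1),
        "genus_tallies": dict(sorted(tallies.items(),
                                     key=lambda kv: (-kv[1], kv[0]))),
    }


def summary_frame(genomes: list[GenomeRecord]) -> pd.DataFrame:
    """Per-genome table mirroring the dataset summary statistics."""
    return pd.DataFrame({
        "genome_id": [g.id for g in genomes],
        "taxon": [g.taxon_label for g in genomes],
        "n_scaffolds": [g.n_scaffolds for g in genomes],
        "bgc_fragmented": [g.bgc_fragmented for g in genomes],
        "bgc_complete": [g.bgc_complete for g in genomes],
        "bgc_total": [g.total_bgcs for g in genomes],
        "completeness": [g.completeness for g in genomes],
    })
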