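"""Per-genome feature summaries (genome size, GC, gene counts, density...).

Conventions, chosen to be self-consistent and fully reproducible:

* "unique" counts collapse inverted-repeat-resident duplicates only — two
  loci collapse when both lie within the IR intervals of a supplied
  quadripartite partition and share normalized name and feature type;
* rRNA/tRNA *bases* sum over all copies, unlike the unique counts;
* coverage-derived fields (intergenic, overlapping) count every copy;
* rounding happens at the reporting layer: GC 2 decimals, density 3
  decimals, coding percentage 1 decimal (half-up); average gene length is
  floor-rounded.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .genome_model import AnnotatedGenome, GeneFeature, GenomeModelError

__all__ = ["SummaryRow", "gc_percentage", "summarize", "SUMMARY_COLUMNS"]


@dataclass
class SummaryRow:
    genome_id: str
    genome_size: int
    gc_percentage: float
    gene_unique_loci: int
    rrna_unique_count: int
    rrna_total_bases: int
    trna_unique_count: int
    trna_total_bases: int
    cds_conserved: int
    cds_all: int
    nonspliced_count: int
    nonspliced_bases: int
    spliced_count: int
    spliced_bases: int
    intron_count: int
    intron_bases: int
    density: float
    avg_len_excl_introns: int
    coding_pct_excl_introns: float
    intergenic_bases_excl_rna: int
    overlapping_bases: int

    def as_dict(self) -> dict:
        return asdict(self)


SUMMARY_COLUMNS = list(SummaryRow.__dataclass_fields__)


def _round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def gc_percentage(genome: AnnotatedGenome | str) -> float:
    """100 * (G + C) / length, 2 decimals; ambiguity codes only dilute."""
    seq = genome.sequence if isinstance(genome, AnnotatedGenome) else genome
    if not seq:
        raise GenomeModelError("cannot compute GC of an empty sequence")
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    return _round_half_up(100.0 * gc / len(s), 2)


def _in_ir(feature: GeneFeature, ir_intervals, genome_length: int) -> bool:
    span = feature.span(genome_length)
    for iv in ir_intervals:
        if span.wraps != iv.wraps:
            continue
        if not span.wraps:
            if iv.wraps:
                continue
            if iv.start <= span.start and span.end <= iv.end:
                return True
        else:
            if iv.start <= span.start and span.end <= iv.end:
                return True
    # non-wrapping feature inside a wrapping IR interval
    for iv in ir_intervals:
        if iv.wraps and not span.wraps:
            if span.start >= iv.start or span.end <= iv.end:
                return True
    return False


def collapse_ir_duplicates(
    features: list[GeneFeature], ir, genome_length: int
) -> list[GeneFeature]:
    """Drop all but one of each (name, ftype) group fully inside the IRs.

    ``ir`` is anything with ``ira``/``irb`` Interval attributes (a
    QuadripartitePartition) or an iterable of two intervals; ``None`` keeps
    every feature.
    """
    if ir is None:
        return list(features)
    if hasattr(ir, "ira"):
        ir_intervals = [ir.ira, ir.irb]
    else:
        ir_intervals = list(ir)
    for iv in ir_intervals:
        for s, e in iv.unwrap(genome_length):
            if e > genome_length:
                raise GenomeModelError(f"IR interval {iv} outside genome")
    kept: list[GeneFeature] = []
    seen: set[tuple[str, str]] = set()
    for f in sorted(features, key=lambda f: f.start):
        if _in_ir(f, ir_intervals, genome_length):
            key = (f.name, f.ftype)
            if key in seen:
                continue
            seen.add(key)
        kept.append(f)
    return kept


def _coverage(genome: AnnotatedGenome) -> np.ndarray:
    L = len(genome)
    cov = np.zeros(L, dtype=np.int32)
    for f in genome.features:
        for s, e in f.span(L).unwrap(L):
            cov[s:e] += 1
    return cov


def summarize(genome: AnnotatedGenome, ir=None) -> SummaryRow:
    """Compute one summary row; ``ir`` enables IR-duplicate collapsing."""
    L = len(genome)
    feats = genome.features_of_type()
    unique = collapse_ir_duplicates(feats, ir, L)

    u_cds = [f for f in unique if f.ftype == "CDS"]
    u_trna = [f for f in unique if f.ftype == "tRNA"]
    u_rrna = [f for f in unique if f.ftype == "rRNA"]

    rrna_species = {(f.name, f.ftype) for f in u_rrna}
    trna_species = {(f.name, f.ftype) for f in u_trna}
    rrna_total = sum(f.exon_bases(L) for f in feats if f.ftype == "rRNA")
    trna_total = sum(f.exon_bases(L) for f in feats if f.ftype == "tRNA")

    spliced = [f for f in u_cds if len(f.segments) > 1]
    nonspliced = [f for f in u_cds if len(f.segments) == 1]
    cds_exon_bases = sum(f.exon_bases(L) for f in u_cds)
    intron_count = sum(f.n_introns for f in u_cds)
    intron_bases = sum(f.intron_bases(L) for f in u_cds)

    cov = _coverage(genome)
    intergenic = int(np.count_nonzero(cov == 0))
    overlapping = int(np.count_nonzero(cov >= 2))

    n_cds = len(u_cds)
    density = _round_half_up(n_cds / (L / 1000.0), 3) if n_cds else 0.0
    avg_len = cds_exon_bases // n_cds if n_cds else 0
    coding_pct = _round_half_up(100.0 * cds_exon_bases / L, 1)

    return SummaryRow(
        genome_id=genome.id,
        genome_size=L,
        gc_percentage=gc_percentage(genome),
        gene_unique_loci=len(unique),
        rrna_unique_count=len(rrna_species),
        rrna_total_bases=rrna_total,
        trna_unique_count=len(trna_species),
        trna_total_bases=trna_total,
        cds_conserved=sum(1 for f in u_cds if f.conserved),
        cds_all=n_cds,
        nonspliced_count=len(nonspliced),
        nonspliced_bases=sum(f.exon_bases(L) for f in nonspliced),
        spliced_count=len(spliced),
        spliced_bases=sum(f.exon_bases(L) for f in spliced),
        intron_count=intron_count,
        intron_bases=intron_bases,
        density=density,
        avg_len_excl_introns=avg_len,
        coding_pct_excl_introns=coding_pct,
        intergenic_bases_excl_rna=intergenic,
        overlapping_bases=overlapping,
    )
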