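"""Gene-content set algebra and the gene-fate classifier.

``content_partition`` produces the Venn-style partition of gene sets over
2-4 genomes. ``classify_fates`` assigns each reference gene a fate relative
to a family of descendant plastid gene sets, using an evidence table of
nuclear-transcript observations per lineage:

* present in every plastid set            -> retained_plastid
* present in a proper nonempty subset     -> lost_post_split
* absent everywhere, transcript in all    -> transferred_ancestral_both
* absent everywhere, transcript in some   -> transferred_ancestral_lost_in_one
* absent everywhere, transcript in none   -> lost_completely
* in a plastid set but not the reference  -> lineage_specific_gain
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .genome_model import AnnotatedGenome, is_conserved_name

logger = logging.getLogger(__name__)

__all__ = [
    "ContentPartition",
    "EvidenceTable",
    "FateReport",
    "TRANSFERRED_FATES",
    "content_partition",
    "content_partition_sets",
    "classify_fates",
    "read_evidence_tsv",
    "evidence_from_hits",
]

TRANSFERRED_FATES = ("transferred_ancestral_both", "transferred_ancestral_lost_in_one")

FATES = TRANSFERRED_FATES + (
    "retained_plastid",
    "lost_post_split",
    "lost_completely",
    "lineage_specific_gain",
)


@dataclass
class ContentPartition:
    """Disjoint regions keyed by the sorted tuple of member genome ids."""

    regions: dict[tuple[str, ...], set[str]]

    def only(self, genome_id: str) -> set[str]:
        return set(self.regions.get((genome_id,), set()))

    def shared_by_all(self) -> set[str]:
        key = max(self.regions, key=len, default=None)
        all_ids = sorted({g for k in self.regions for g in k})
        return set(self.regions.get(tuple(all_ids), set()))


@dataclass
class EvidenceTable:
    """(gene, source) -> transcript present flag; rows unique per key."""

    rows: dict[tuple[str, str], bool] = field(default_factory=dict)

    @property
    def sources(self) -> list[str]:
        return sorted({src for _, src in self.rows})

    def positive_sources(self, gene: str) -> set[str]:
        return {src for (g, src), present in self.rows.items()
                if g == gene and present}

    def add(self, gene: str, source: str, present: bool) -> None:
        self.rows[(gene, source)] = present


@dataclass
class FateReport:
    fates: dict[str, str]
    evidence: dict[str, list[str]]
    caveat: str = (
        "genes called lost may have transcripts missed by sampling; "
        "loss calls are therefore 'probably lost'"
    )

    def genes_with_fate(self, *fates: str) -> set[str]:
        return {g for g, f in self.fates.items() if f in fates}

    def count(self, *fates: str) -> int:
        return len(self.genes_with_fate(*fates))


def _gene_set(genome: AnnotatedGenome, protein_only: bool) -> set[str]:
    types = ("CDS",) if protein_only else ("CDS", "tRNA", "rRNA")
    names = [f.name for f in genome.features_of_type(*types)]
    out: set[str] = set()
    for n in names:
        if n in out:
            logger.info("duplicate gene name %r collapsed", n)
        out.add(n)
    return out


def content_partition_sets(named_sets: dict[str, set[str]]) -> ContentPartition:
    """Exact set partition of 2-4 named gene sets into Venn regions."""
    if not 2 <= len(named_sets) <= 4:
        raise ValueError("content partition takes 2-4 gene sets")
    ids = sorted(named_sets)
    regions: dict[tuple[str, ...], set[str]] = {}
    universe = set().union(*named_sets.values())
    for gene in universe:
        members = tuple(i for i in ids if gene in named_sets[i])
        regions.setdefault(members, set()).add(gene)
    return ContentPartition(regions=regions)


def content_partition(
    genomes: list[AnnotatedGenome], protein_only: bool = True
) -> ContentPartition:
    return content_partition_sets(
        {g.id: _gene_set(g, protein_only) for g in genomes}
    )


def classify_fates(
    reference: set[str],
    plastid_sets: dict[str, set[str]],
    evidence: EvidenceTable,
) -> FateReport:
    """Classify every reference gene (plus lineage-specific extras)."""
    if len(plastid_sets) < 2:
        raise ValueError("need >= 2 plastid gene sets")
    lineages = sorted(plastid_sets)
    known = set(reference) | set().union(*plastid_sets.values())
    for (gene, _src) in list(evidence.rows):
        if gene not in known:
            logger.warning("evidence row for unknown gene %r ignored", gene)

    # sources correspond one-to-one to lineages; "positive everywhere"
    # therefore means positive in as many sources as there are lineages
    n_sources = len(lineages)

    fates: dict[str, str] = {}
    ev: dict[str, list[str]] = {}
    union_plastid = set().union(*plastid_sets.values())

    for gene in sorted(reference):
        present_in = {lin for lin in lineages if gene in plastid_sets[lin]}
        if present_in == set(lineages):
            fates[gene] = "retained_plastid"
        elif present_in:
            fates[gene] = "lost_post_split"
        else:
            pos = sorted(evidence.positive_sources(gene))
            ev[gene] = pos
            if pos and len(pos) >= n_sources:
                fates[gene] = "transferred_ancestral_both"
            elif pos:
                fates[gene] = "transferred_ancestral_lost_in_one"
            else:
                fates[gene] = "lost_completely"

    for gene in sorted(union_plastid - reference):
        fates[gene] = "lineage_specific_gain"

    return FateReport(fates=fates, evidence=ev)


# ---------------------------------------------------------------------------
# Evidence I/O
# ---------------------------------------------------------------------------


def read_evidence_tsv(path: str | Path) -> EvidenceTable:
    """Read a 3-column TSV: gene, source, present (0/1)."""
    table = EvidenceTable()
    with open(path, encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#") or row[0] == "gene":
                continue
            gene, source, present = row[0], row[1], row[2]
            table.add(gene.strip(), source.strip(), present.strip() in ("1", "true", "True"))
    return table


def evidence_from_hits(
    path: str | Path, source: str, max_evalue: float = 1e-10
) -> EvidenceTable:
    """Threshold a tabular search-hit file (query, subject, e-value) into
    an evidence table for one source."""
    table = EvidenceTable()
    with open(path, encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            gene, _subject, evalue = row[0], row[1], float(row[2])
            key = (gene.strip(), source)
            hit = evalue <= max_evalue
            table.rows[key] = table.rows.get(key, False) or hit
    return table
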