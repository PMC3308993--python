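"""Gene-order conservation: shared neighboring gene pairs between genomes.

The statistic is the size of the (multiset) intersection of the two
genomes' adjacency-pair sets. Default policy: CDS + tRNA + rRNA included,
unnamed ORFs excluded, inverted-repeat duplicates collapsed to one copy,
unordered pairs, strand-insensitive, and for circular genomes the
wrap-around pair counts, so n retained genes yield n pairs (n - 1 linear).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .genome_model import AnnotatedGenome
from .summary_stats import collapse_ir_duplicates

__all__ = ["SyntenyPolicy", "AdjacencyPair", "SyntenyResult",
           "adjacency_pairs", "shared_adjacency"]


@dataclass(frozen=True)
class SyntenyPolicy:
    include_types: tuple[str, ...] = ("CDS", "tRNA", "rRNA")
    include_orfs: bool = False
    collapse_ir: bool = True
    ordered: bool = False


@dataclass(frozen=True, order=True)
class AdjacencyPair:
    """Unordered neighbor pair stored in canonical lexicographic order."""

    gene_a: str
    gene_b: str

    @classmethod
    def of(cls, a: str, b: str, ordered: bool = False) -> "AdjacencyPair":
        if ordered:
            return cls(a, b)
        return cls(min(a, b), max(a, b))


@dataclass
class SyntenyResult:
    shared_count: int
    shared_pairs: list[AdjacencyPair]
    n_a: int
    n_b: int


def _retained_genes(
    genome: AnnotatedGenome, policy: SyntenyPolicy, partition=None
) -> list[str]:
    feats = genome.features_of_type(*policy.include_types)
    if policy.collapse_ir and partition is not None:
        feats = collapse_ir_duplicates(feats, partition, len(genome))
    if not policy.include_orfs:
        feats = [f for f in feats if f.conserved]
    feats.sort(key=lambda f: f.start)
    return [f.name for f in feats]


def adjacency_pairs(
    genome: AnnotatedGenome,
    policy: SyntenyPolicy = SyntenyPolicy(),
    partition=None,
) -> Counter:
    """Multiset of neighbor pairs in circular (or linear) gene order."""
    names = _retained_genes(genome, policy, partition)
    n = len(names)
    pairs: Counter = Counter()
    if n < 2:
        return pairs
    last = n if genome.is_circular else n - 1
    for i in range(last):
        a, b = names[i], names[(i + 1) % n]
        pairs[AdjacencyPair.of(a, b, policy.ordered)] += 1
    return pairs


def shared_adjacency(
    a: AnnotatedGenome,
    b: AnnotatedGenome,
    policy: SyntenyPolicy = SyntenyPolicy(),
    partition_a=None,
    partition_b=None,
) -> SyntenyResult:
    """Count neighbor pairs common to both genomes (multiset intersection).

    With ``policy.ordered`` the orientation-reflected reading of the second
    genome is also tried and the better one kept, so the statistic stays
    symmetric.
    """
    pa = adjacency_pairs(a, policy, partition_a)
    pb = adjacency_pairs(b, policy, partition_b)
    inter = pa & pb
    if policy.ordered:
        flipped = Counter(
            {AdjacencyPair(p.gene_b, p.gene_a): c for p, c in pb.items()}
        )
        alt = pa & flipped
        if sum(alt.values()) > sum(inter.values()):
            inter = alt
    shared = sorted(inter.elements())
    return SyntenyResult(
        shared_count=sum(inter.values()),
        shared_pairs=list(shared),
        n_a=sum(pa.values()),
        n_b=sum(pb.values()),
    )
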