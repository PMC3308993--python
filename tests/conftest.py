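import numpy as np
import pytest

from plastidcomp.genome_model import (
    AnnotatedGenome,
    GeneFeature,
    Interval,
    is_conserved_name,
)
from plastidcomp.synthetic_data import SimConfig, simulate_genome

GENE_LEN = 30
GAP = 10


def make_genome(
    order,
    topology: "str" = "circular",
    seed: int = 0,
    genome_id: str = "toy",
) -> AnnotatedGenome:
    """Fabricate a tiny genome from an ordered gene spec.

    ``order`` is a list of names or (name, strand) or
    (name, strand, ftype) tuples; genes are placed left to right with
    fixed gaps.
    """
    rng = np.random.default_rng(seed)
    features = []
    pos = GAP
    for item in order:
        if isinstance(item, str):
            name, strand, ftype = item, "+", "CDS"
        elif len(item) == 2:
            (name, strand), ftype = item, "CDS"
        else:
            name, strand, ftype = item
        features.append(
            GeneFeature(
                raw_name=name,
                name=name,
                ftype=ftype,
                strand=strand,
                segments=[Interval(pos, pos + GENE_LEN)],
                conserved=is_conserved_name(name),
            )
        )
        pos += GENE_LEN + GAP
    seq = "".join(rng.choice(list("ACGT"), size=pos + GAP))
    return AnnotatedGenome(
        id=genome_id, sequence=seq, topology=topology, features=features
    )


@pytest.fixture(scope="session")
def default_sim():
    """One default simulated genome shared by read-only tests."""
    return simulate_genome(SimConfig(), seed=1)


@pytest.fixture(scope="session")
def mismatch_sim():
    return simulate_genome(SimConfig(ir_mismatches=3), seed=2)
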