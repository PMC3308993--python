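"""Coverage-based selection of organellar contigs from an assembly table.

Seed contigs (identified by homology elsewhere) define a fold-coverage
window; non-seed contigs whose coverage falls inside the window and whose
length clears a floor are co-selected.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = ["ContigRecord", "select_by_coverage", "read_contig_table"]


@dataclass(frozen=True)
class ContigRecord:
    id: str
    length: int
    coverage: float
    seed: bool = False

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"contig {self.id!r} has non-positive length")
        if self.coverage < 0:
            raise ValueError(f"contig {self.id!r} has negative coverage")


def select_by_coverage(
    contigs: list[ContigRecord],
    tolerance: float = 0.25,
    min_len: int = 500,
) -> list[str]:
    """Seeds plus all non-seed contigs with coverage inside the window
    ``[min(seed cov) * (1 - tol), max(seed cov) * (1 + tol)]`` (inclusive)
    and length >= ``min_len``; sorted by length descending."""
    seeds = [c for c in contigs if c.seed]
    if not seeds:
        raise ValueError("coverage binning requires at least one seed contig")
    lo = min(c.coverage for c in seeds) * (1.0 - tolerance)
    hi = max(c.coverage for c in seeds) * (1.0 + tolerance)
    selected = list(seeds)
    for c in contigs:
        if c.seed:
            continue
        if c.length >= min_len and lo <= c.coverage <= hi:
            selected.append(c)
    selected.sort(key=lambda c: (-c.length, c.id))
    return [c.id for c in selected]


def read_contig_table(path: str | Path, seed_ids: set[str]) -> list[ContigRecord]:
    """TSV with columns id, length, coverage."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    missing = {"id", "length", "coverage"} - set(df.columns)
    if missing:
        raise ValueError(f"contig table lacks columns {sorted(missing)}")
    return [
        ContigRecord(
            id=row.id,
            length=int(row.length),
            coverage=float(row.coverage),
            seed=row.id in seed_ids,
        )
        for row in df.itertuples(index=False)
    ]
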