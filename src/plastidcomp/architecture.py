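"""Genome architecture: inverted repeats, quadripartite partition,
coding-strand switch points and tandem repeats.

Inverted-repeat detection is seed-and-extend over exact k-mer matches
between the sequence and its reverse complement. Extension allows
substitutions but no indels, so a repeat pair lives on one anti-diagonal
(``x + y = const`` for paired positions ``x`` in copy A and ``y`` in copy
B). Detection runs on the linear representation: a repeat copy crossing
the circular origin is not found (rotate the sequence first if needed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_model import (
    AnnotatedGenome,
    GeneFeature,
    GenomeModelError,
    Interval,
    reverse_complement,
)

__all__ = [
    "RepeatHit",
    "QuadripartitePartition",
    "TandemRepeat",
    "StrandLayout",
    "detect_inverted_repeats",
    "partition_quadripartite",
    "detect_strand_switch",
    "find_tandem_repeats",
]

_STOP_RUN = 4  # consecutive mismatches that stop an extension probe


@dataclass(frozen=True)
class RepeatHit:
    interval_a: Interval
    interval_b: Interval
    length: int
    mismatches: int

    def __post_init__(self) -> None:
        if self.interval_a.length() != self.interval_b.length():
            raise GenomeModelError("repeat copies differ in length")
        if self.interval_a.end > self.interval_b.start:
            raise GenomeModelError("repeat copies overlap")


@dataclass
class QuadripartitePartition:
    """IRA/IRB spans, the two single-copy arcs, and single-copy insertions.

    ``ira``/``irb`` are the full spans of each repeat copy; when a copy is
    interrupted by a single-copy insertion the insertion interval lies
    inside the span and is listed in ``insertions``. ``ssc`` is ``None``
    when the two repeat copies are adjacent (degenerate, zero-length arc).
    """

    ira: Interval
    irb: Interval
    lsc: Interval | None
    ssc: Interval | None
    insertions: list[Interval] = field(default_factory=list)
    degenerate: bool = False
    genome_length: int = 0

    def lsc_length(self) -> int:
        return self.lsc.length(self.genome_length) if self.lsc else 0

    def ssc_length(self) -> int:
        return self.ssc.length(self.genome_length) if self.ssc else 0

    def covered_bases(self) -> int:
        L = self.genome_length
        total = self.ira.length(L) + self.irb.length(L)
        total += self.lsc_length() + self.ssc_length()
        return total


@dataclass(frozen=True)
class TandemRepeat:
    start: int
    period: int
    copies: float
    unit: str

    @property
    def span(self) -> int:
        return int(round(self.period * self.copies))


@dataclass
class StrandLayout:
    switch_points: list[int]
    consistency: float
    boundary_indices: tuple[int, int] | None = None


# ---------------------------------------------------------------------------
# Inverted repeats
# ---------------------------------------------------------------------------


def _complement_base(a: str, b: str) -> bool:
    return a == {"A": "T", "T": "A", "C": "G", "G": "C"}.get(b, "?")


def _diagonal_seeds(seq: str, k: int) -> dict[int, list[int]]:
    """Map anti-diagonal c -> seed x-positions (copy-A k-mer starts)."""
    L = len(seq)
    index: dict[str, list[int]] = {}
    for i in range(L - k + 1):
        index.setdefault(seq[i:i + k], []).append(i)
    seeds: dict[int, list[int]] = {}
    for j in range(L - k + 1):
        rc = reverse_complement(seq[j:j + k])
        for i in index.get(rc, ()):
            if i + k <= j:  # copy A strictly left of copy B
                seeds.setdefault(i + j + k - 1, []).append(i)
    return seeds


def _best_subrun(
    lo: int, hi: int, mismatch_xs: list[int], seed_lo: int, seed_hi: int,
    max_rate: float, min_len: int,
) -> tuple[int, int, int] | None:
    """Longest [a, b] within [lo, hi] containing the seed, with mismatch
    fraction <= max_rate and both ends matching. Returns (a, b, n_mm)."""
    mm = sorted(mismatch_xs)
    lefts = [lo] + [x + 1 for x in mm]
    rights = [hi] + [x - 1 for x in mm]
    best: tuple[int, int, int] | None = None
    import bisect

    for a in lefts:
        if a > seed_lo:
            continue
        for b in rights:
            if b < seed_hi or b < a:
                continue
            n = b - a + 1
            if n < min_len:
                continue
            n_mm = bisect.bisect_right(mm, b) - bisect.bisect_left(mm, a)
            if n_mm / n > max_rate:
                continue
            if best is None or n > best[1] - best[0] + 1:
                best = (a, b, n_mm)
    return best


def detect_inverted_repeats(
    genome: AnnotatedGenome | str,
    min_len: int = 1000,
    max_mismatch_rate: float = 0.01,
    k: int = 21,
) -> list[RepeatHit]:
    """Find inverted-repeat pairs of length >= ``min_len``.

    Substitutions are allowed up to ``max_mismatch_rate`` of the repeat
    length; indels are not. Hits are sorted by length descending, ties by
    smaller start of the first copy.
    """
    seq = (genome.sequence if isinstance(genome, AnnotatedGenome) else genome).upper()
    L = len(seq)
    if min_len > L or L < k:
        return []
    if not 0 <= max_mismatch_rate <= 0.05:
        raise ValueError("max_mismatch_rate must be in [0, 0.05]")

    seeds = _diagonal_seeds(seq, k)
    hits: dict[tuple[int, int, int, int], int] = {}

    for c, xs in seeds.items():
        covered: list[tuple[int, int]] = []
        for x0 in sorted(xs):
            if any(a <= x0 and x0 + k - 1 <= b for a, b in covered):
                continue
            # extension probe along the anti-diagonal, both directions
            x_max_valid = (c - 1) // 2  # keep x < y = c - x
            mism: list[int] = []
            lo = x0
            run = 0
            x = x0 - 1
            while x >= 0 and c - x < L and run < _STOP_RUN:
                if _complement_base(seq[x], seq[c - x]):
                    run = 0
                    lo = x
                else:
                    run += 1
                    mism.append(x)
                x -= 1
            hi = x0 + k - 1
            run = 0
            x = x0 + k
            while x <= x_max_valid and c - x >= 0 and run < _STOP_RUN:
                if _complement_base(seq[x], seq[c - x]):
                    run = 0
                    hi = x
                else:
                    run += 1
                    mism.append(x)
                x += 1
            mism = [m for m in mism if lo <= m <= hi]
            best = _best_subrun(lo, hi, mism, x0, x0 + k - 1,
                                max_mismatch_rate, min_len)
            covered.append((lo, hi))
            if best is None:
                continue
            a, b, n_mm = best
            key = (a, b + 1, c - b, c - a + 1)
            hits[key] = n_mm

    results = [
        RepeatHit(Interval(a0, a1), Interval(b0, b1), a1 - a0, n_mm)
        for (a0, a1, b0, b1), n_mm in hits.items()
    ]
    # drop hits nested inside a larger hit on both sides
    results.sort(key=lambda h: (-h.length, h.interval_a.start))
    kept: list[RepeatHit] = []
    for h in results:
        nested = any(
            g.interval_a.start <= h.interval_a.start
            and h.interval_a.end <= g.interval_a.end
            and g.interval_b.start <= h.interval_b.start
            and h.interval_b.end <= g.interval_b.end
            for g in kept
        )
        if not nested:
            kept.append(h)
    return kept


# ---------------------------------------------------------------------------
# Quadripartite partition
# ---------------------------------------------------------------------------


def _chain_hits(hits: list[RepeatHit], max_insertion: int) -> list[RepeatHit]:
    """Anti-collinear chain of hits around the longest one.

    Successive members move right in copy A and left in copy B with gaps
    bounded by ``max_insertion`` — the gaps are single-copy insertions
    interrupting one repeat copy.
    """
    slack = 100  # tolerated overlap from boundary drift through chance matches
    anchor = max(hits, key=lambda h: (h.length, -h.interval_a.start))
    ordered = sorted(hits, key=lambda h: h.interval_a.start)
    chain = [anchor]
    # extend right of the anchor
    cur = anchor
    for h in ordered:
        if h is anchor:
            continue
        gap_a = h.interval_a.start - cur.interval_a.end
        gap_b = cur.interval_b.start - h.interval_b.end
        if -slack <= gap_a <= max_insertion and -slack <= gap_b <= max_insertion:
            chain.append(h)
            cur = h
    # extend left of the anchor
    cur = anchor
    for h in reversed(ordered):
        if h is anchor or h in chain:
            continue
        gap_a = cur.interval_a.start - h.interval_a.end
        gap_b = h.interval_b.start - cur.interval_b.end
        if -slack <= gap_a <= max_insertion and -slack <= gap_b <= max_insertion:
            chain.insert(0, h)
            cur = h
    chain.sort(key=lambda h: h.interval_a.start)
    return chain


def partition_quadripartite(
    genome: AnnotatedGenome,
    hit: RepeatHit | list[RepeatHit],
    max_insertion: int = 10000,
) -> QuadripartitePartition:
    """Partition a circular genome into IRA/IRB and the two single-copy arcs.

    Accepts the top RepeatHit or the full detector output; in the latter
    case hits that continue the top repeat across a single-copy insertion
    (anti-collinear chain) are merged and the interrupting gaps reported as
    ``insertions``.
    """
    if not genome.is_circular:
        raise GenomeModelError("quadripartite partition requires a circular genome")
    hits = [hit] if isinstance(hit, RepeatHit) else list(hit)
    if not hits:
        raise GenomeModelError("no repeat hit supplied")
    chain = _chain_hits(hits, max_insertion)

    L = len(genome)
    ira = Interval(chain[0].interval_a.start, chain[-1].interval_a.end)
    irb = Interval(chain[-1].interval_b.start, chain[0].interval_b.end)

    insertions: list[Interval] = []
    for prev, nxt in zip(chain, chain[1:]):
        if nxt.interval_a.start > prev.interval_a.end:
            insertions.append(Interval(prev.interval_a.end, nxt.interval_a.start))
        if prev.interval_b.start > nxt.interval_b.end:
            insertions.append(Interval(nxt.interval_b.end, prev.interval_b.start))

    def make_arc(start: int, end: int) -> Interval | None:
        if start == end:
            return None
        if start < end:
            return Interval(start, end)
        return Interval(start, end, wraps=True)

    arc1 = make_arc(ira.end, irb.start)
    arc2 = make_arc(irb.end % L, ira.start)

    def arc_len(a: Interval | None) -> int:
        return a.length(L) if a else 0

    if arc_len(arc1) >= arc_len(arc2):
        lsc, ssc = arc1, arc2
    else:
        lsc, ssc = arc2, arc1
    return QuadripartitePartition(
        ira=ira,
        irb=irb,
        lsc=lsc,
        ssc=ssc,
        insertions=insertions,
        degenerate=ssc is None,
        genome_length=L,
    )


# ---------------------------------------------------------------------------
# Coding-strand switch
# ---------------------------------------------------------------------------


def detect_strand_switch(genome: AnnotatedGenome) -> StrandLayout:
    """Two-arc partition of the circular gene order maximizing strand
    consistency (each arc scored by its majority strand)."""
    feats = sorted(genome.features_of_type(), key=lambda f: f.start)
    n = len(feats)
    if n < 2:
        raise GenomeModelError("strand-switch detection needs >= 2 features")
    plus = np.array([1 if f.strand == "+" else 0 for f in feats])
    total_plus = int(plus.sum())
    if total_plus in (0, n):
        return StrandLayout(switch_points=[], consistency=1.0)

    prefix = np.concatenate([[0], np.cumsum(plus)])
    best = (-1, 0, 0)
    for i in range(n):
        for j in range(i + 1, n + 1):
            l1 = j - i
            p1 = int(prefix[j] - prefix[i])
            p2 = total_plus - p1
            l2 = n - l1
            score = max(p1, l1 - p1) + (max(p2, l2 - p2) if l2 else 0)
            if score > best[0]:
                best = (score, i, j)
    score, i, j = best
    consistency = score / n
    L = len(genome)

    def boundary_pos(idx: int) -> int:
        a = feats[(idx - 1) % n]
        b = feats[idx % n]
        a_end = a.span(L).end % L
        b_start = b.start
        if idx % n == 0:  # wrap boundary
            gap = (b_start - a_end) % L
            return (a_end + gap // 2) % L
        if b_start >= a_end:
            return (a_end + b_start) // 2
        return b_start

    return StrandLayout(
        switch_points=sorted([boundary_pos(i), boundary_pos(j % n)]),
        consistency=consistency,
        boundary_indices=(i, j % n),
    )


# ---------------------------------------------------------------------------
# Tandem repeats
# ---------------------------------------------------------------------------


def find_tandem_repeats(
    seq: str,
    min_period: int = 5,
    max_period: int = 100,
    min_copies: float = 2.5,
) -> list[TandemRepeat]:
    """Fixed-period tandem repeats via self-match runs.

    For each period ``p`` maximal runs of ``seq[i] == seq[i+p]`` are
    located; a run of length r spans r+p bases = (r+p)/p copies. Reports
    whose period is a multiple of a shorter period repeating at the same
    locus are suppressed (so a homopolymer is not re-reported at every
    period).
    """
    s = seq.upper()
    n = len(s)
    candidates: list[tuple[int, int, int]] = []  # (period, start, span)
    arr = np.frombuffer(s.encode(), dtype=np.uint8)
    for p in range(1, min(max_period, n - 1) + 1):
        m = arr[:-p] == arr[p:]
        if not m.any():
            continue
        # maximal runs of True
        padded = np.concatenate([[False], m, [False]])
        d = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        for u, v in zip(starts, ends):
            r = int(v - u)
            if (r + p) / p >= min_copies:
                candidates.append((p, int(u), r + p))

    reports: list[TandemRepeat] = []
    accepted_spans: list[tuple[int, int, int]] = []  # (period, start, end)
    for p, start, span in sorted(candidates):
        end = start + span
        suppressed = False
        for q, qs, qe in candidates_index(candidates, p):
            if p % q == 0:
                ov = min(end, qs + qe) - max(start, qs)
                if ov >= 0.8 * span:
                    suppressed = True
                    break
        if suppressed or p < min_period:
            continue
        copies = span / p
        unit = _consensus_unit(s, start, p, span)
        reports.append(TandemRepeat(start=start, period=p, copies=copies, unit=unit))
        accepted_spans.append((p, start, end))
    reports.sort(key=lambda t: (t.start, t.period))
    return reports


def candidates_index(candidates: list[tuple[int, int, int]], p: int):
    """Candidates with strictly smaller period, as (period, start, span)."""
    for q, qs, qspan in candidates:
        if q < p:
            yield q, qs, qspan


def _consensus_unit(s: str, start: int, period: int, span: int) -> str:
    unit = []
    for t in range(period):
        col = [s[start + t + j * period]
               for j in range((span - t + period - 1) // period)
               if start + t + j * period < start + span]
        unit.append(max(set(col), key=col.count))
    return "".join(unit)
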