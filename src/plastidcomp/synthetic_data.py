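"""Synthetic annotated plastid genomes with fully known ground truth.

Every generator is deterministic per (config, seed) and emits a
:class:`SimulationTruth` holding all planted parameters, so each analysis
stage can be tested round-trip without external data:

* ``simulate_genome`` — circular quadripartite genome (LSC / SSC / two IR
  copies, near-identical up to a planted number of substitutions, with an
  optional single-copy gene block inserted into one IR copy), named
  CDS/tRNA/rRNA features on two strands with one planted strand-switch
  point, a minority of intron-containing CDS, and tandem repeats embedded
  in the IR spacer;
* ``apply_inversions`` — known number of segmental gene-order inversions;
* ``simulate_contigs`` — bimodal contig coverage table with class labels;
* ``simulate_fate_scenario`` — planted transfer/loss fates with a
  consistent evidence table;
* ``paper_fixture`` — the packaged in-text gene-content comparison
  (reference algal set, two euglenid plastid sets, transcript evidence).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .coverage_binning import ContigRecord
from .gene_content import EvidenceTable
from .genome_model import (
    AnnotatedGenome,
    GeneFeature,
    GenomeModelError,
    Interval,
    is_conserved_name,
    reverse_complement,
)

__all__ = [
    "SimConfig",
    "TandemSpec",
    "SimulationTruth",
    "simulate_genome",
    "apply_inversions",
    "simulate_contigs",
    "simulate_fate_scenario",
    "paper_fixture",
    "PaperFixture",
]

_BASES = np.array(list("ACGT"))

# conserved plastid-style gene names for planted CDS loci
_CDS_NAME_POOL = [
    "psbA", "psbB", "psbC", "psbD", "psbE", "psbF", "psbH", "psbI", "psbJ",
    "psbK", "psbL", "psbN", "psbT", "psbM", "psbZ", "psaA", "psaB", "psaC",
    "psaJ", "psaM", "atpA", "atpB", "atpE", "atpF", "atpH", "atpI", "petB",
    "petD", "rbcL", "rpoA", "rpoB", "rpoC1", "rpoC2", "tufA", "rps2", "rps3",
    "rps4", "rps7", "rps8", "rps9", "rps11", "rps12", "rps14", "rps18",
    "rps19", "rpl2", "rpl5", "rpl12", "rpl14", "rpl16", "rpl20", "rpl22",
    "rpl23", "rpl32", "rpl36", "mat1", "ycf1", "ycf4", "ycf12", "ycf65",
]

_AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"
_ANTICODONS = [
    "UGC", "GCA", "GUC", "UUC", "GAA", "GCC", "GUG", "GAU", "UUU", "UAA",
    "CAU", "GUU", "UGG", "UUG", "ACG", "UGA", "UGU", "UAC", "CCA", "GUA",
]


@dataclass(frozen=True)
class TandemSpec:
    period: int
    copies: float

    @property
    def span(self) -> int:
        return int(round(self.period * self.copies))


@dataclass
class SimConfig:
    size: int = 60000
    gc: float = 0.34
    n_cds: int = 26            # conserved CDS planted in the LSC
    n_trna: int = 10
    n_spliced: int = 2         # of the LSC CDS, how many carry one intron
    intron_length: int = 300
    ir_length: int = 4000      # repeated sequence per copy
    ir_mismatches: int = 0
    rrn16_length: int = 1200
    rrn23_length: int = 2000
    ssc_length: int = 1200
    insertion_genes: int = 0   # single-copy CDS inserted into IR copy A
    strand_switch_frac: float = 2.0 / 3.0
    tandem_repeats: tuple[TandemSpec, ...] = (
        TandemSpec(11, 3.0),
        TandemSpec(33, 3.4),
    )

    def as_dict(self) -> dict:
        d = asdict(self)
        d["tandem_repeats"] = [asdict(t) for t in self.tandem_repeats]
        return d


@dataclass
class SimulationTruth:
    seed: int
    genome_size: int | None = None
    config: dict | None = None
    ir: dict | None = None
    insertions: list = field(default_factory=list)
    genes: list = field(default_factory=list)
    strand_boundary_indices: tuple | None = None
    strand_consistency: float | None = None
    tandem_repeats: list = field(default_factory=list)
    spacer_interval: tuple | None = None
    summary: dict | None = None
    inversions: list = field(default_factory=list)
    fates: dict | None = None
    contig_labels: dict | None = None

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=1, sort_keys=True, default=list)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text


def _round_half_up(x: float, nd: int) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(1).scaleb(-nd),
                                           rounding=ROUND_HALF_UP))


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.arange(4), size=n, p=p)


def _to_str(codes: np.ndarray) -> str:
    return "".join(_BASES[codes])


def _random_cds(rng: np.random.Generator, length: int, gc: float) -> str:
    body = _to_str(_random_seq(rng, length - 6, gc))
    return "ATG" + body + "TAA"


def _tandem_unit(rng: np.random.Generator, period: int, gc: float) -> str:
    """Random unit with no sub-period (no proper divisor q with unit
    periodic at lag q), so the planted repeat is the fundamental one."""
    while True:
        unit = _to_str(_random_seq(rng, period, gc))
        ok = True
        for q in range(1, period):
            if period % q == 0 and all(
                unit[i] == unit[i % q] for i in range(period)
            ):
                ok = False
                break
        if ok and len(set(unit)) > 1:
            return unit


def _build_spacer(
    rng: np.random.Generator, length: int, gc: float,
    specs: tuple[TandemSpec, ...],
) -> tuple[str, list[dict]]:
    """Spacer sequence with tandem repeats planted at known offsets; the
    flanking bases are sealed so each run has exactly its planted span."""
    total_spans = sum(t.span for t in specs)
    gap = 30
    need = total_spans + gap * (len(specs) + 1)
    if need > length:
        raise GenomeModelError("tandem repeats do not fit in the IR spacer")
    seq = list(_to_str(_random_seq(rng, length, gc)))
    placed = []
    pos = gap
    for spec in specs:
        unit = _tandem_unit(rng, spec.period, gc)
        span = spec.span
        for t in range(span):
            seq[pos + t] = unit[t % spec.period]
        # seal: break the self-match just outside the run on both sides
        p = spec.period
        left = pos - 1
        if seq[left] == seq[left + p]:
            seq[left] = _other_base(rng, seq[left + p])
        right = pos + span
        if right < length and seq[right] == seq[right - p]:
            seq[right] = _other_base(rng, seq[right - p])
        placed.append(
            {"offset": pos, "period": p, "span": span,
             "copies": span / p, "unit": unit}
        )
        pos += span + gap
    return "".join(seq), placed


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(0, 3)]


def simulate_genome(
    config: SimConfig | None = None, seed: int = 0
) -> tuple[AnnotatedGenome, SimulationTruth]:
    """Generate a circular quadripartite genome plus its ground truth."""
    cfg = config or SimConfig()
    rng = np.random.default_rng(seed)
    L = cfg.size
    gap = 50

    # --- IR copy content -------------------------------------------------
    r16, r23 = cfg.rrn16_length, cfg.rrn23_length
    spacer_len = cfg.ir_length - (3 * gap + r16 + r23)
    if spacer_len < 120:
        raise GenomeModelError("ir_length too small for rRNA content")
    spacer, placed_trs = _build_spacer(rng, spacer_len, cfg.gc,
                                       cfg.tandem_repeats)
    rrn16_seq = _to_str(_random_seq(rng, r16, cfg.gc))
    rrn23_seq = _to_str(_random_seq(rng, r23, cfg.gc))
    rep = (
        _to_str(_random_seq(rng, gap, cfg.gc)) + rrn16_seq
        + _to_str(_random_seq(rng, gap, cfg.gc)) + rrn23_seq
        + _to_str(_random_seq(rng, gap, cfg.gc)) + spacer
    )
    assert len(rep) == cfg.ir_length
    rrn16_off = gap
    rrn23_off = 2 * gap + r16
    spacer_off = 3 * gap + r16 + r23
    split_off = spacer_off  # insertion goes between rRNA block and spacer

    # --- insertion block -------------------------------------------------
    ins_genes: list[tuple[str, int, int]] = []  # (name, offset, length)
    ins_seq = ""
    if cfg.insertion_genes:
        pos = gap
        parts = [_to_str(_random_seq(rng, gap, cfg.gc))]
        for t in range(cfg.insertion_genes):
            length = 3 * int(rng.integers(100, 200))
            ins_genes.append((f"ins{t + 1:02d}", pos, length))
            parts.append(_random_cds(rng, length, cfg.gc))
            parts.append(_to_str(_random_seq(rng, gap, cfg.gc)))
            pos += length + gap
        ins_seq = "".join(parts)
    ins_len = len(ins_seq)

    # --- region coordinates ---------------------------------------------
    ssc_len = cfg.ssc_length
    lsc_len = L - (2 * cfg.ir_length + ins_len + ssc_len)
    if lsc_len < 1000:
        raise GenomeModelError("genes exceed genome size (LSC too small)")
    ira_start = lsc_len
    ira_end = ira_start + cfg.ir_length + ins_len  # span incl. insertion
    ssc_start = ira_end
    irb_start = L - cfg.ir_length
    irb_end = L
    if ssc_start + ssc_len != irb_start:
        raise GenomeModelError("inconsistent layout arithmetic")
    if ssc_len >= lsc_len:
        raise GenomeModelError("ssc_length must be smaller than the LSC")

    # --- LSC genes -------------------------------------------------------
    if cfg.n_cds > len(_CDS_NAME_POOL):
        raise GenomeModelError("n_cds exceeds the conserved name pool")
    if cfg.n_trna > len(_AA_LETTERS):
        raise GenomeModelError("n_trna exceeds the tRNA name pool")
    cds_names = list(_CDS_NAME_POOL[: cfg.n_cds])
    trna_names = [
        f"trn{_AA_LETTERS[t]}-{_ANTICODONS[t]}" for t in range(cfg.n_trna)
    ]

    cds_lens = [3 * int(rng.integers(100, 300)) for _ in range(cfg.n_cds)]
    trna_lens = [int(rng.integers(72, 91)) for _ in range(cfg.n_trna)]
    spliced_idx = sorted(
        rng.choice(cfg.n_cds, size=cfg.n_spliced, replace=False).tolist()
    ) if cfg.n_spliced else []

    slots: list[tuple[str, str, int, bool]] = []  # (name, ftype, exon len, spliced)
    for i, name in enumerate(cds_names):
        slots.append((name, "CDS", cds_lens[i], i in spliced_idx))
    for name, ln in zip(trna_names, trna_lens):
        slots.append((name, "tRNA", ln, False))
    order = rng.permutation(len(slots))
    slots = [slots[i] for i in order]

    span_total = sum(
        ln + (cfg.intron_length if spl else 0) for _, _, ln, spl in slots
    )
    min_gap = 20
    free = lsc_len - span_total - min_gap * (len(slots) + 1)
    if free < 0:
        raise GenomeModelError("genes exceed genome size (LSC packing)")
    extra = rng.multinomial(min(free, 4 * len(slots)),
                            np.ones(len(slots) + 1) / (len(slots) + 1))

    lsc_parts: list[str] = []
    features: list[GeneFeature] = []
    gene_plan: list[dict] = []  # ordered plan incl. IR/SSC genes, filled later
    pos = 0

    def emit_gap(n: int):
        nonlocal pos
        lsc_parts.append(_to_str(_random_seq(rng, n, cfg.gc)))
        pos += n

    ordered_lsc: list[dict] = []
    emit_gap(min_gap + int(extra[0]))
    for t, (name, ftype, exon_len, spliced) in enumerate(slots):
        if ftype == "CDS":
            if spliced:
                half = 3 * int(rng.integers(20, exon_len // 6))
                exon1 = _random_cds(rng, exon_len, cfg.gc)[:half]
                rest = _random_cds(rng, exon_len, cfg.gc)[half:]
                intron = _to_str(_random_seq(rng, cfg.intron_length, cfg.gc))
                gene_seq = exon1 + intron + rest
                segments = [
                    Interval(pos, pos + half),
                    Interval(pos + half + cfg.intron_length,
                             pos + cfg.intron_length + exon_len),
                ]
            else:
                gene_seq = _random_cds(rng, exon_len, cfg.gc)
                segments = [Interval(pos, pos + exon_len)]
        else:
            gene_seq = _to_str(_random_seq(rng, exon_len, cfg.gc))
            segments = [Interval(pos, pos + exon_len)]
        lsc_parts.append(gene_seq)
        ordered_lsc.append(
            {"name": name, "ftype": ftype, "segments": segments,
             "exon": exon_len, "spliced": spliced}
        )
        pos += len(gene_seq)
        emit_gap(min_gap + int(extra[t + 1]))
    lsc_seq = "".join(lsc_parts)
    # pad the LSC to its exact budget with background sequence
    if len(lsc_seq) < lsc_len:
        lsc_seq += _to_str(_random_seq(rng, lsc_len - len(lsc_seq), cfg.gc))
    assert len(lsc_seq) == lsc_len

    # --- strand plan -----------------------------------------------------
    n_lsc = len(ordered_lsc)
    n_total = n_lsc + 2 + len(ins_genes) + 1 + 2  # + IRA rRNAs, ins, SSC, IRB
    m = int(round(cfg.strand_switch_frac * n_total))
    m = max(1, min(m, n_lsc))  # the switch must fall inside the LSC

    # --- SSC -------------------------------------------------------------
    ssc_gene_len = 3 * int(rng.integers(80, min(200, (ssc_len - 2 * gap) // 3)))
    ssc_gene_off = (ssc_len - ssc_gene_len) // 2
    ssc_seq = (
        _to_str(_random_seq(rng, ssc_gene_off, cfg.gc))
        + _random_cds(rng, ssc_gene_len, cfg.gc)
    )
    ssc_seq += _to_str(_random_seq(rng, ssc_len - len(ssc_seq), cfg.gc))

    # --- copy B with planted mismatches ---------------------------------
    rep_b = list(reverse_complement(rep))
    mm_positions: list[int] = []
    if cfg.ir_mismatches:
        margin = 25
        while len(mm_positions) < cfg.ir_mismatches:
            cand = int(rng.integers(margin, cfg.ir_length - margin))
            if all(abs(cand - p) >= 10 for p in mm_positions):
                mm_positions.append(cand)
        for p in sorted(mm_positions):
            rep_b[p] = _other_base(rng, rep_b[p])
    rep_b = "".join(rep_b)

    sequence = lsc_seq + rep[:split_off] + ins_seq + rep[split_off:] + ssc_seq + rep_b
    assert len(sequence) == L

    # seal the repeat boundaries so seed-and-extend recovers exactly the
    # planted repeat length: force non-complementary bases just outside
    # each repeat segment (the outer boundary is the circular origin and
    # cannot be crossed by the linear detector). Sealed positions are
    # always intergenic gap bases.
    seq = list(sequence)

    def seal(x: int, y: int) -> None:
        if 0 <= x < L and 0 <= y < L and seq[x] == reverse_complement(seq[y]):
            seq[x] = _other_base(rng, seq[x])

    for t in range(4):
        # inner boundary: IRA span end vs IRB start (both flanks in the SSC)
        seal(ira_end + t, irb_start - 1 - t)
    if ins_len:
        a2_start = ira_start + split_off + ins_len
        c1 = ira_start + L - 1                  # anti-diagonal of segment 1
        c2 = a2_start + (L - split_off) - 1     # anti-diagonal of segment 2
        for t in range(4):
            x = ira_start + split_off + t       # leading insertion gap
            seal(x, c1 - x)
            x = a2_start - 1 - t                # trailing insertion gap
            seal(x, c2 - x)
    sequence = "".join(seq)

    # --- features --------------------------------------------------------
    def strand_for(idx: int) -> str:
        if idx >= n_total - 2:   # IR copy B rRNAs
            return "+"
        return "+" if idx < m else "-"

    idx = 0
    for g in ordered_lsc:
        features.append(_make_feature(g["name"], "CDS" if g["ftype"] == "CDS"
                                      else g["ftype"], strand_for(idx),
                                      g["segments"]))
        idx += 1
    a16 = Interval(ira_start + rrn16_off, ira_start + rrn16_off + r16)
    a23 = Interval(ira_start + rrn23_off, ira_start + rrn23_off + r23)
    features.append(_make_feature("rrn16", "rRNA", strand_for(idx), [a16])); idx += 1
    features.append(_make_feature("rrn23", "rRNA", strand_for(idx), [a23])); idx += 1
    ins_start_genome = ira_start + split_off
    for name, off, length in ins_genes:
        iv = Interval(ins_start_genome + off, ins_start_genome + off + length)
        features.append(_make_feature(name, "CDS", strand_for(idx), [iv]))
        idx += 1
    ssc_name = "orf901"
    ssc_iv = Interval(ssc_start + ssc_gene_off,
                      ssc_start + ssc_gene_off + ssc_gene_len)
    features.append(_make_feature(ssc_name, "CDS", strand_for(idx), [ssc_iv]))
    idx += 1
    # copy B rRNA coordinates mirror copy A inside the pure repeat
    b16 = Interval(irb_start + cfg.ir_length - rrn16_off - r16,
                   irb_start + cfg.ir_length - rrn16_off)
    b23 = Interval(irb_start + cfg.ir_length - rrn23_off - r23,
                   irb_start + cfg.ir_length - rrn23_off)
    features.append(_make_feature("rrn23", "rRNA", strand_for(idx), [b23])); idx += 1
    features.append(_make_feature("rrn16", "rRNA", strand_for(idx), [b16])); idx += 1
    assert idx == n_total

    genome = AnnotatedGenome(id=f"sim{seed}", sequence=sequence,
                             topology="circular", features=features)

    # --- truth bookkeeping ----------------------------------------------
    exon_cds = sum(g["exon"] for g in ordered_lsc if g["ftype"] == "CDS")
    exon_cds += sum(length for _, _, length in ins_genes) + ssc_gene_len
    cds_all = cfg.n_cds + len(ins_genes) + 1
    spliced_bases = sum(g["exon"] for g in ordered_lsc if g["spliced"])
    rna_bases_all = sum(g["exon"] for g in ordered_lsc if g["ftype"] == "tRNA")
    span_sum = sum(
        f.span(L).length(L) for f in features
    )
    s = sequence
    gc_pct = _round_half_up(100.0 * (s.count("G") + s.count("C")) / L, 2)

    summary = {
        "genome_id": genome.id,
        "genome_size": L,
        "gc_percentage": gc_pct,
        "gene_unique_loci": cds_all + cfg.n_trna + 2,
        "rrna_unique_count": 2,
        "rrna_total_bases": 2 * (r16 + r23),
        "trna_unique_count": cfg.n_trna,
        "trna_total_bases": rna_bases_all,
        "cds_conserved": cfg.n_cds + len(ins_genes),
        "cds_all": cds_all,
        "nonspliced_count": cds_all - cfg.n_spliced,
        "nonspliced_bases": exon_cds - spliced_bases,
        "spliced_count": cfg.n_spliced,
        "spliced_bases": spliced_bases,
        "intron_count": cfg.n_spliced,
        "intron_bases": cfg.n_spliced * cfg.intron_length,
        "density": _round_half_up(cds_all / (L / 1000.0), 3),
        "avg_len_excl_introns": exon_cds // cds_all,
        "coding_pct_excl_introns": _round_half_up(100.0 * exon_cds / L, 1),
        "intergenic_bases_excl_rna": L - span_sum,
        "overlapping_bases": 0,
    }

    truth = SimulationTruth(
        seed=seed,
        genome_size=L,
        config=cfg.as_dict(),
        ir={
            "length": cfg.ir_length,
            "mismatches": cfg.ir_mismatches,
            "ira_span": (ira_start, ira_end),
            "irb_span": (irb_start, irb_end),
            "segment_a1": (ira_start, ira_start + split_off),
            "segment_a2": (ira_start + split_off + ins_len, ira_end),
        },
        insertions=[(ins_start_genome, ins_start_genome + ins_len)]
        if ins_len else [],
        genes=[
            {"name": f.name, "ftype": f.ftype, "strand": f.strand,
             "segments": [(sg.start, sg.end) for sg in f.segments]}
            for f in features
        ],
        strand_boundary_indices=(m, n_total - 2),
        strand_consistency=1.0,
        tandem_repeats=[
            {"start": ira_start + split_off + ins_len
             + (spacer_off - split_off) + tr["offset"],
             "period": tr["period"], "copies": tr["copies"],
             "span": tr["span"], "unit": tr["unit"]}
            for tr in placed_trs
        ],
        spacer_interval=(ira_start + split_off + ins_len
                         + (spacer_off - split_off),
                         ira_end),
        summary=summary,
    )
    return genome, truth


def _make_feature(name: str, ftype: str, strand: str,
                  segments: list[Interval]) -> GeneFeature:
    segs = sorted(segments, key=lambda s: s.start)
    if strand == "-":
        segs = list(reversed(segs))
    return GeneFeature(
        raw_name=name,
        name=name,
        ftype=ftype,
        strand=strand,
        segments=segs,
        conserved=is_conserved_name(name),
    )


# ---------------------------------------------------------------------------
# Inversions
# ---------------------------------------------------------------------------


def apply_inversions(
    genome: AnnotatedGenome, k: int, seed: int = 0
) -> tuple[AnnotatedGenome, SimulationTruth]:
    """Apply ``k`` random segmental inversions of whole-gene blocks.

    The inverted block is reverse-complemented in the sequence; features
    inside are remapped and strand-flipped. Blocks never include the first
    or last feature so they stay clear of the circular origin.
    """
    rng = np.random.default_rng(seed)
    out = AnnotatedGenome(
        id=genome.id,
        sequence=genome.sequence,
        topology=genome.topology,
        features=[GeneFeature(f.raw_name, f.name, f.ftype, f.strand,
                              list(f.segments), f.conserved)
                  for f in genome.features],
    )
    truth = SimulationTruth(seed=seed, genome_size=len(genome))
    L = len(genome)
    for _ in range(max(0, k)):
        feats = sorted(out.features, key=lambda f: f.start)
        n = len(feats)
        if n < 4:
            break
        i = int(rng.integers(1, n - 2))
        j = int(rng.integers(i, n - 2))
        prev_end = feats[i - 1].span(L).end
        next_start = feats[j + 1].start
        s = (prev_end + feats[i].start) // 2
        e = (feats[j].span(L).end + next_start) // 2
        if s >= e:
            continue
        out.sequence = (
            out.sequence[:s]
            + reverse_complement(out.sequence[s:e])
            + out.sequence[e:]
        )
        for f in out.features:
            if s <= f.start and f.span(L).end <= e:
                new_segs = [
                    Interval(s + (e - sg.end), s + (e - sg.start))
                    for sg in f.segments
                ]
                f.segments = sorted(new_segs, key=lambda x: x.start)
                f.strand = "+" if f.strand == "-" else "-"
                if f.strand == "-":
                    f.segments = list(reversed(f.segments))
        truth.inversions.append(
            {"gene_indices": (i, j), "block": (s, e)}
        )
    return out, truth


# ---------------------------------------------------------------------------
# Contig coverage scenario
# ---------------------------------------------------------------------------


def simulate_contigs(
    seed: int = 0,
    n: int = 200,
    plastid_frac: float = 0.15,
    plastid_cov: tuple[float, float] = (32.0, 2.0),
    nuclear_cov: tuple[float, float] = (5.0, 1.0),
    n_seeds: int = 2,
) -> tuple[list[ContigRecord], SimulationTruth]:
    """Bimodal contig table: plastid contigs at high fold-coverage,
    nuclear background at low; the two largest plastid contigs are seeds."""
    rng = np.random.default_rng(seed)
    n_plastid = max(n_seeds, int(round(n * plastid_frac)))
    labels: dict[str, str] = {}
    records: list[ContigRecord] = []
    plastid_lengths = sorted(
        (int(x) for x in rng.integers(600, 30000, size=n_plastid)),
        reverse=True,
    )
    for t in range(n_plastid):
        cov = max(0.1, float(rng.normal(*plastid_cov)))
        cid = f"contig{t + 1:05d}"
        records.append(ContigRecord(cid, plastid_lengths[t], cov,
                                    seed=t < n_seeds))
        labels[cid] = "plastid"
    for t in range(n - n_plastid):
        cov = max(0.1, float(rng.normal(*nuclear_cov)))
        cid = f"contig{n_plastid + t + 1:05d}"
        records.append(ContigRecord(cid, int(rng.integers(500, 3000)), cov))
        labels[cid] = "nuclear"
    truth = SimulationTruth(seed=seed, contig_labels=labels)
    return records, truth


# ---------------------------------------------------------------------------
# Planted gene-fate scenarios
# ---------------------------------------------------------------------------


def simulate_fate_scenario(
    seed: int = 0,
    n_core: int = 30,
    n_missing: int = 12,
    n_gains: int = 3,
    lineages: tuple[str, ...] = ("lineageA", "lineageB"),
) -> tuple[set, dict, EvidenceTable, SimulationTruth]:
    """Random reference/plastid sets plus an evidence table that encode a
    known fate for every gene (noise-free)."""
    rng = np.random.default_rng(seed)
    genes = [f"g{t:03d}" for t in range(n_core + n_missing)]
    core = set(genes[:n_core])
    missing = genes[n_core:]
    plastid = {lin: set(core) for lin in lineages}
    evidence = EvidenceTable()
    fates: dict[str, str] = {g: "retained_plastid" for g in core}

    # some core genes are dropped from a proper subset of lineages
    n_post = min(3, n_core // 5)
    for g in rng.choice(sorted(core), size=n_post, replace=False):
        drop = rng.choice(len(lineages))
        plastid[lineages[drop]].discard(str(g))
        fates[str(g)] = "lost_post_split"

    choices = ["transferred_ancestral_both",
               "transferred_ancestral_lost_in_one",
               "lost_completely"]
    for g in missing:
        fate = choices[int(rng.integers(0, 3))]
        fates[g] = fate
        if fate == "transferred_ancestral_both":
            for lin in lineages:
                evidence.add(g, f"{lin}_transcriptome", True)
        elif fate == "transferred_ancestral_lost_in_one":
            keep = int(rng.integers(0, len(lineages)))
            for t, lin in enumerate(lineages):
                evidence.add(g, f"{lin}_transcriptome", t == keep)
        else:
            for lin in lineages:
                evidence.add(g, f"{lin}_transcriptome", False)

    for t in range(n_gains):
        g = f"x{t:03d}"
        lin = lineages[int(rng.integers(0, len(lineages)))]
        plastid[lin].add(g)
        fates[g] = "lineage_specific_gain"

    reference = core | set(missing)
    truth = SimulationTruth(seed=seed, fates=fates)
    return reference, plastid, evidence, truth


# ---------------------------------------------------------------------------
# In-paper gene-content fixture
# ---------------------------------------------------------------------------

_PHOTO = [
    "psbA", "psbB", "psbC", "psbD", "psbE", "psbF", "psbH", "psbI", "psbJ",
    "psbK", "psbL", "psbM", "psbN", "psbT", "psbZ", "psaA", "psaB", "psaC",
    "psaJ", "psaM", "atpA", "atpB", "atpE", "atpF", "atpH", "atpI", "petB",
    "petD", "rbcL", "ycf4", "ycf12",
]  # 31 photosynthesis-related proteins
_TXN = ["rpoA", "rpoB", "rpoC1", "rpoC2", "tufA"]  # 5 transcription/translation
_RIBO = [
    "rps2", "rps3", "rps4", "rps7", "rps8", "rps9", "rps11", "rps12",
    "rps14", "rps18", "rps19", "rpl2", "rpl5", "rpl12", "rpl14", "rpl16",
    "rpl20", "rpl22", "rpl23", "rpl32", "rpl36",
]  # 21 ribosomal proteins

_CORE = _PHOTO + _TXN + _RIBO + ["mat1"]  # 58 genes shared by both euglenids

_NDH = ["ndhA", "ndhB", "ndhC", "ndhD", "ndhE", "ndhF", "ndhG", "ndhH",
        "ndhI", "ndhJ"]
MISSING_GENES = _NDH + [
    "petA", "petN", "chlL", "chlN", "chlB", "ccsA", "psaI", "infA",
    "clpP", "ftsH", "ycf3",
    # three unknown-function placeholders completing the 24-gene list
    "ycfX1", "ycfX2", "ycfX3",
]

EUTREPTIELLA_SPECIFIC = {"orf291", "orf386", "orf248", "orf372", "ycf65"}
EUGLENA_SPECIFIC = {"mat2", "roaA", "orf506", "orf42", "orf43", "orf44",
                    "orf45", "orf46"}

TRANSFERRED_BOTH = ["petA", "petN", "ycf3", "clpP", "ftsH"]
TRANSFERRED_ONE = ["ccsA"]  # transcript only in the Euglena source


@dataclass
class PaperFixture:
    reference: set
    plastid_sets: dict
    evidence: EvidenceTable


def paper_fixture() -> PaperFixture:
    """The packaged in-text content comparison: reference algal gene set,
    the two euglenid plastid sets, and the transcript-evidence table."""
    core = set(_CORE)
    eutreptiella = core | EUTREPTIELLA_SPECIFIC
    euglena = core | EUGLENA_SPECIFIC
    # the reference relative lacks the euglenid-specific maturase but
    # carries the 24 genes the euglenids went on to lose, plus ycf65
    reference = (core - {"mat1"}) | set(MISSING_GENES) | {"ycf65"}

    evidence = EvidenceTable()
    for g in MISSING_GENES:
        evidence.add(g, "Euglena_transcriptome", g in TRANSFERRED_BOTH
                     or g in TRANSFERRED_ONE)
        evidence.add(g, "Eutreptiella_transcriptome", g in TRANSFERRED_BOTH)
    return PaperFixture(
        reference=reference,
        plastid_sets={
            "Euglena_gracilis": euglena,
            "Eutreptiella_gymnastica": eutreptiella,
        },
        evidence=evidence,
    )
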