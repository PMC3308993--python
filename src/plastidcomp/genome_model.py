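"""Core data model for annotated (usually circular) plastid genomes.

Internal coordinates are 0-based half-open everywhere; all file I/O converts
at the boundary (GenBank/EMBL and GFF3 are 1-based inclusive on disk).
Intervals that cross the circular origin are first class: they carry a
``wraps`` flag and their length arithmetic is modular.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

FEATURE_TYPES = ("CDS", "tRNA", "rRNA")

_ORF_RE = re.compile(r"^orf\d+$")

_IUPAC = set("ACGTUNRYSWKMBDHV")

_COMPLEMENT = str.maketrans(
    "ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
    "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb",
)

# one- and three-letter amino-acid codes used to canonicalize tRNA labels
_AA3_TO_1 = {
    "ala": "A", "arg": "R", "asn": "N", "asp": "D", "cys": "C",
    "gln": "Q", "glu": "E", "gly": "G", "his": "H", "ile": "I",
    "leu": "L", "lys": "K", "met": "M", "phe": "F", "pro": "P",
    "ser": "S", "thr": "T", "trp": "W", "tyr": "Y", "val": "V",
    "fmet": "M", "sec": "U",
}


class GenomeModelError(ValueError):
    """Raised on malformed genomes, features or coordinates."""


# ---------------------------------------------------------------------------
# Intervals on a (possibly circular) sequence
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class Interval:
    """Half-open interval ``[start, end)``; ``wraps`` marks origin crossing.

    For a wrapping interval on a circle of length ``L`` the convention is
    ``start < L`` and ``end <= start``; the covered positions are
    ``start..L-1`` followed by ``0..end-1``.
    """

    start: int
    end: int
    wraps: bool = False

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < 0:
            raise GenomeModelError(f"negative coordinate in {self!r}")
        if not self.wraps and self.start >= self.end:
            raise GenomeModelError(f"empty or inverted interval {self!r}")

    def length(self, genome_length: int | None = None) -> int:
        if not self.wraps:
            return self.end - self.start
        if genome_length is None:
            raise GenomeModelError("wrapping interval needs genome_length")
        n = (self.end - self.start) % genome_length
        return n if n else genome_length

    def positions(self, genome_length: int) -> Iterator[int]:
        """Yield every covered position (use only for small intervals)."""
        if not self.wraps:
            yield from range(self.start, self.end)
        else:
            yield from range(self.start, genome_length)
            yield from range(0, self.end)

    def unwrap(self, genome_length: int) -> list[tuple[int, int]]:
        """Linear (start, end) pieces covering the interval."""
        if not self.wraps:
            return [(self.start, self.end)]
        pieces = [(self.start, genome_length)]
        if self.end > 0:
            pieces.append((0, self.end))
        return pieces

    def contains(self, pos: int, genome_length: int) -> bool:
        if not self.wraps:
            return self.start <= pos < self.end
        return pos >= self.start or pos < self.end


def interval_from_genbank(start_1based: int, end_inclusive: int) -> Interval:
    """Convert 1-based inclusive (GenBank/GFF) coordinates to internal form."""
    return Interval(start_1based - 1, end_inclusive)


def interval_to_genbank(iv: Interval) -> tuple[int, int]:
    """Back to 1-based inclusive; wrapping intervals are not representable."""
    if iv.wraps:
        raise GenomeModelError("cannot express wrapping interval as one span")
    return iv.start + 1, iv.end


# ---------------------------------------------------------------------------
# Features and genomes
# ---------------------------------------------------------------------------


@dataclass
class GeneFeature:
    """A CDS/tRNA/rRNA locus; >1 segment encodes introns."""

    raw_name: str
    name: str
    ftype: str
    strand: str
    segments: list[Interval]
    conserved: bool = True

    def __post_init__(self) -> None:
        if self.ftype not in FEATURE_TYPES:
            raise GenomeModelError(f"unsupported feature type {self.ftype!r}")
        if self.strand not in ("+", "-"):
            raise GenomeModelError(f"bad strand {self.strand!r}")
        if not self.segments:
            raise GenomeModelError(f"feature {self.name!r} has no segments")

    @property
    def start(self) -> int:
        """Smallest genomic start over segments (wrapping: wrapped start)."""
        return min(s.start for s in self.segments)

    def exon_bases(self, genome_length: int | None = None) -> int:
        return sum(s.length(genome_length) for s in self.segments)

    def span(self, genome_length: int | None = None) -> Interval:
        """Single interval from first to last transcribed base."""
        if len(self.segments) == 1:
            return self.segments[0]
        if any(s.wraps for s in self.segments):
            raise GenomeModelError(
                f"multi-segment wrapping feature {self.name!r} unsupported"
            )
        return Interval(min(s.start for s in self.segments),
                        max(s.end for s in self.segments))

    def intron_bases(self, genome_length: int | None = None) -> int:
        n = self.span(genome_length).length(genome_length) - self.exon_bases(genome_length)
        if n < 0:
            raise GenomeModelError(f"overlapping segments in {self.name!r}")
        return n

    @property
    def n_introns(self) -> int:
        return len(self.segments) - 1


@dataclass
class AnnotatedGenome:
    id: str
    sequence: str
    topology: str = "circular"
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise GenomeModelError(f"genome {self.id!r} has no sequence")
        if self.topology not in ("circular", "linear"):
            raise GenomeModelError(f"bad topology {self.topology!r}")
        L = len(self.sequence)
        for f in self.features:
            for seg in f.segments:
                if seg.start >= L or (not seg.wraps and seg.end > L):
                    raise GenomeModelError(
                        f"feature {f.raw_name!r} ({f.ftype}) outside sequence "
                        f"of length {L}: {seg}"
                    )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def features_of_type(self, *ftypes: str) -> list[GeneFeature]:
        wanted = ftypes or FEATURE_TYPES
        return [f for f in self.features if f.ftype in wanted]

    def segment_sequence(self, iv: Interval) -> str:
        if not iv.wraps:
            return self.sequence[iv.start:iv.end]
        return self.sequence[iv.start:] + self.sequence[:iv.end]


# ---------------------------------------------------------------------------
# Sequence utilities
# ---------------------------------------------------------------------------


def reverse_complement(seq: str) -> str:
    """Reverse complement over the IUPAC alphabet; N maps to N."""
    bad = set(seq.upper()) - _IUPAC
    if bad:
        raise GenomeModelError(f"non-IUPAC characters {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Gene-name normalization
# ---------------------------------------------------------------------------


def _load_packaged_synonyms() -> dict[str, str]:
    table: dict[str, str] = {}
    ref = resources.files("plastidcomp").joinpath("data/synonyms.tsv")
    with ref.open("r", encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or len(row) < 2:
                continue
            table[row[0].strip().lower()] = row[1].strip()
    return table


_SYNONYMS: dict[str, str] | None = None


def _synonyms() -> dict[str, str]:
    global _SYNONYMS
    if _SYNONYMS is None:
        _SYNONYMS = _load_packaged_synonyms()
    return _SYNONYMS


def load_synonyms(path: str | Path) -> dict[str, str]:
    """Read a user synonym table (2-column TSV: alias, canonical)."""
    table: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or len(row) < 2:
                continue
            table[row[0].strip().lower()] = row[1].strip()
    return table


_TRNA_FULL_RE = re.compile(
    r"^t?rna[-_ ]?([a-z]{3,4})(?:[-_ (]+([acgut]{3})\)?)?$", re.IGNORECASE
)
_TRNA_SHORT_RE = re.compile(r"^trn([a-z])(?:[-_]([acgut]{3}))?$", re.IGNORECASE)
_GENE_CASE_RE = re.compile(r"^([A-Za-z]{3})([A-Za-z]?)(\d*)$")


def normalize_gene_name(raw: str, synonyms: dict[str, str] | None = None) -> str:
    """Map an annotated label to a canonical gene name.

    tRNAs become ``trn<AA>[-<ANTICODON>]``; other labels get conventional
    plastid-gene casing (lower-case stem, final capital, e.g. ``psbA``);
    a synonym table maps aliases to one canonical label. Unnamed ORFs
    (``orf123``) pass through unchanged.
    """
    name = raw.strip()
    if not name:
        return name

    m = _TRNA_SHORT_RE.match(name)
    if m:
        aa, anticodon = m.group(1).upper(), m.group(2)
        out = f"trn{aa}"
        if anticodon:
            out += f"-{anticodon.upper().replace('T', 'U')}"
        return _apply_synonyms(out, synonyms)
    m = _TRNA_FULL_RE.match(name)
    if m and m.group(1).lower() in _AA3_TO_1:
        aa = _AA3_TO_1[m.group(1).lower()]
        out = f"trn{aa}"
        if m.group(2):
            out += f"-{m.group(2).upper().replace('T', 'U')}"
        return _apply_synonyms(out, synonyms)

    low = name.lower()
    if _ORF_RE.match(low):
        return low

    m = _GENE_CASE_RE.match(name)
    if m:
        stem, letter, digits = m.groups()
        cased = stem.lower() + letter.upper() + digits
    else:
        cased = low
    return _apply_synonyms(cased, synonyms)


def _apply_synonyms(name: str, synonyms: dict[str, str] | None) -> str:
    table = dict(_synonyms())
    if synonyms:
        table.update({k.lower(): v for k, v in synonyms.items()})
    return table.get(name.lower(), name)


def is_conserved_name(name: str) -> bool:
    """Conserved = not an unnamed-ORF label."""
    return not _ORF_RE.match(name.lower())


# ---------------------------------------------------------------------------
# GenBank / EMBL I/O
# ---------------------------------------------------------------------------


def _feature_name(feat: SeqFeature) -> str:
    for key in ("gene", "standard_name", "product", "locus_tag"):
        if key in feat.qualifiers and feat.qualifiers[key]:
            return str(feat.qualifiers[key][0])
    return f"{feat.type}_{int(feat.location.start)}"


def _segments_from_location(feat: SeqFeature, genome_length: int) -> list[Interval]:
    parts = feat.location.parts
    raw = [(int(p.start), int(p.end)) for p in parts]
    # a join (x, L) + (0, y) on a circular record is an origin-crossing exon
    merged: list[Interval] = []
    i = 0
    while i < len(raw):
        s, e = raw[i]
        if (
            i + 1 < len(raw)
            and e == genome_length
            and raw[i + 1][0] == 0
        ):
            merged.append(Interval(s, raw[i + 1][1], wraps=True))
            i += 2
        else:
            merged.append(Interval(s, e))
            i += 1
    strand = "-" if feat.location.strand == -1 else "+"
    merged.sort(key=lambda iv: iv.start)
    if strand == "-":
        merged.reverse()  # transcription order for the minus strand
    return merged


def _genome_from_record(record: SeqRecord) -> AnnotatedGenome:
    if record.seq is None or len(record.seq) == 0:
        raise GenomeModelError(f"record {record.id!r} has no sequence")
    topology = str(record.annotations.get("topology", "circular")).lower()
    if topology not in ("circular", "linear"):
        topology = "circular"
    L = len(record.seq)
    features: list[GeneFeature] = []
    for feat in record.features:
        if feat.type not in FEATURE_TYPES:
            continue
        for part in feat.location.parts:
            if int(part.start) < 0 or int(part.end) > L:
                raise GenomeModelError(
                    f"feature {_feature_name(feat)!r} ({feat.type}) outside "
                    f"sequence of length {L}"
                )
        raw_name = _feature_name(feat)
        name = normalize_gene_name(raw_name)
        features.append(
            GeneFeature(
                raw_name=raw_name,
                name=name,
                ftype=feat.type,
                strand="-" if feat.location.strand == -1 else "+",
                segments=_segments_from_location(feat, L),
                conserved=is_conserved_name(name),
            )
        )
    return AnnotatedGenome(
        id=record.id or record.name or "genome",
        sequence=str(record.seq).upper(),
        topology=topology,
        features=features,
    )


def read_genbank(path: str | Path) -> AnnotatedGenome:
    """Read a GenBank or EMBL flat file into an :class:`AnnotatedGenome`."""
    path = Path(path)
    fmt = "embl" if path.suffix.lower() in (".embl", ".dat") else "genbank"
    try:
        record = SeqIO.read(str(path), fmt)
    except ValueError:
        # wrong guess for the flavour: try the other one
        other = "genbank" if fmt == "embl" else "embl"
        record = SeqIO.read(str(path), other)
    return _genome_from_record(record)


def write_genbank(genome: AnnotatedGenome, path: str | Path) -> None:
    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.id,
        name=genome.id[:16].replace(" ", "_"),
        description="synthetic plastid genome",
        annotations={
            "molecule_type": "DNA",
            "topology": genome.topology,
            "date": "01-JAN-2000",  # fixed: byte-identical output per seed
        },
    )
    L = len(genome.sequence)
    for f in genome.features:
        strand = -1 if f.strand == "-" else 1
        locs = []
        for seg in sorted(f.segments, key=lambda s: s.start):
            for s, e in seg.unwrap(L):
                locs.append(SimpleLocation(s, e, strand=strand))
        loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        record.features.append(
            SeqFeature(loc, type=f.ftype, qualifiers={"gene": [f.raw_name]})
        )
    SeqIO.write(record, str(path), "genbank")


# ---------------------------------------------------------------------------
# GFF3 + FASTA I/O
# ---------------------------------------------------------------------------


def read_gff_fasta(gff: str | Path, fasta: str | Path) -> AnnotatedGenome:
    """Read a GFF3 annotation plus its FASTA sequence.

    GFF 1-based inclusive coordinates are converted to internal 0-based
    half-open form; rows sharing an ``ID`` become one multi-segment feature.
    """
    records = list(SeqIO.parse(str(fasta), "fasta"))
    if not records:
        raise GenomeModelError(f"no sequence in {fasta}")
    record = records[0]
    seq_id = record.id
    topology = "linear" if "topology=linear" in record.description.lower() else "circular"

    groups: dict[str, dict] = {}
    order: list[str] = []
    with open(gff, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                if line.startswith("##sequence-region"):
                    continue
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                continue
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = cols
            if ftype not in FEATURE_TYPES:
                if ftype not in ("gene", "exon", "region"):
                    logger.warning("ignoring unknown feature type %r", ftype)
                continue
            if seqid != seq_id:
                raise GenomeModelError(
                    f"GFF sequence id {seqid!r} does not match FASTA {seq_id!r}"
                )
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            key = attr.get("ID", f"{ftype}:{start}-{end}")
            iv = interval_from_genbank(int(start), int(end))
            if key not in groups:
                groups[key] = {
                    "name": attr.get("Name", attr.get("gene", key)),
                    "ftype": ftype,
                    "strand": strand if strand in "+-" else "+",
                    "segments": [],
                }
                order.append(key)
            groups[key]["segments"].append(iv)

    L = len(record.seq)
    features = []
    for key in order:
        g = groups[key]
        segs = sorted(g["segments"], key=lambda s: s.start)
        # rejoin an origin-crossing exon that was written as two rows
        if (
            len(segs) >= 2
            and segs[0].start == 0
            and segs[-1].end == L
            and topology == "circular"
        ):
            head, tail = segs[0], segs[-1]
            segs = segs[1:-1]
            segs.append(Interval(tail.start, head.end, wraps=True))
        if g["strand"] == "-":
            segs.reverse()
        name = normalize_gene_name(g["name"])
        features.append(
            GeneFeature(
                raw_name=g["name"],
                name=name,
                ftype=g["ftype"],
                strand=g["strand"],
                segments=segs,
                conserved=is_conserved_name(name),
            )
        )
    return AnnotatedGenome(
        id=seq_id,
        sequence=str(record.seq).upper(),
        topology=topology,
        features=features,
    )


def write_gff_fasta(genome: AnnotatedGenome, gff: str | Path, fasta: str | Path) -> None:
    with open(fasta, "w", encoding="utf-8") as fh:
        fh.write(f">{genome.id} topology={genome.topology}\n")
        seq = genome.sequence
        for i in range(0, len(seq), 70):
            fh.write(seq[i:i + 70] + "\n")
    L = len(genome.sequence)
    with open(gff, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {L}\n")
        for idx, f in enumerate(genome.features):
            fid = f"feat{idx:04d}"
            for seg in sorted(f.segments, key=lambda s: s.start):
                for s, e in seg.unwrap(L):
                    attrs = f"ID={fid};Name={f.raw_name}"
                    fh.write(
                        f"{genome.id}\tplastidcomp\t{f.ftype}\t{s + 1}\t{e}\t.\t"
                        f"{f.strand}\t.\t{attrs}\n"
                    )
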