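# plastidcomp

Comparative analysis of annotated plastid (chloroplast) genomes:

* **genome_model** — GenBank/EMBL and GFF3+FASTA I/O, circular-coordinate
  arithmetic (0-based half-open internally, origin-crossing intervals are
  first class), gene-name normalization with an extensible synonym table;
* **summary_stats** — per-genome feature summaries (size, GC, unique loci
  with inverted-repeat duplicate collapsing, spliced/non-spliced CDS,
  intron bases, gene density, coding percentage, intergenic and
  overlapping bases);
* **architecture** — inverted-repeat detection (seed-and-extend,
  substitutions but no indels), LSC/SSC/IR quadripartite partitioning with
  single-copy insertion blocks, coding-strand switch-point search, and
  fixed-period tandem-repeat (VNTR) finding;
* **synteny** — the shared neighboring-gene-pair statistic between two
  genomes under a configurable counting policy;
* **gene_content** — gene-content Venn partitions and the endosymbiotic
  gene-fate classifier (retained / transferred to nucleus / lost), driven
  by a transcript-evidence table;
* **coverage_binning** — coverage-window selection of organellar contigs
  from an assembly table;
* **chronology** — relative node-age ratios on ultrametric Newick trees
  (BEAST-style height intervals or sidecar TSV);
* **synthetic_data** — a deterministic simulator that plants a full
  quadripartite genome (IR copies with known mismatches, optional
  insertion blocks, introns, strand switch, tandem repeats), segmental
  inversions, contig-coverage scenarios and gene-fate scenarios, each with
  machine-readable ground truth, plus the packaged in-paper gene-content
  fixture.

## CLI

One entry point, `plastidcomp`, with a subcommand per stage:

```sh
plastidcomp simulate --seed 1 --out sim/          # genome.gb + truth.json
plastidcomp summarize sim/genome.gb --with-ir
plastidcomp ir sim/genome.gb --min-len 1000
plastidcomp vntr sim/genome.gb --region 54150:54800
plastidcomp synteny a.gb b.gb
plastidcomp content a.gb b.gb
plastidcomp fate                                   # packaged fixture
plastidcomp fate --reference ref.gb --plastids a.gb --plastids b.gb \
    --evidence evidence.tsv
plastidcomp bin-contigs contigs.tsv --seeds contig1,contig2 --tolerance 0.25
plastidcomp chrono tree.nwk --old A,B,C --young A,B
```

All commands emit TSV by default or JSON with `--json`; `--out` writes to
a file. Exit codes: 0 success, 1 data error, 2 usage error.

## Library use

```python
from plastidcomp import simulate_genome, summarize
from plastidcomp.architecture import detect_inverted_repeats, partition_quadripartite

genome, truth = simulate_genome(seed=1)
hits = detect_inverted_repeats(genome)
part = partition_quadripartite(genome, hits)
row = summarize(genome, part)
assert row.as_dict() == truth.summary
```

## Conventions worth knowing

* Internal coordinates are 0-based half-open everywhere; GenBank/GFF
  1-based inclusive coordinates are converted at the I/O boundary.
* "Unique" locus counts collapse only duplicates that lie inside the two
  IR intervals and share normalized name and feature type; rRNA/tRNA
  *base* totals sum over all copies.
* Rounding happens at the reporting layer only: GC 2 decimals, density 3
  decimals, coding percentage 1 decimal (half-up); average CDS length is
  floor-rounded.
* The synteny policy defaults to CDS+tRNA+rRNA, unnamed ORFs excluded, IR
  duplicates collapsed, unordered strand-insensitive pairs, circular
  wrap-around pair included; every switch is exposed on
  `SyntenyPolicy` / the CLI so counts can be compared across conventions.
* Inverted-repeat detection runs on the linear sequence: a repeat copy
  crossing the circular origin must be rotated into view first.
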