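# Methods

## Scope and model

contigscout treats contig classification as a per-contig voting problem
over homology evidence, combined with composition metrics that need no
database at all. The core assumptions are:

- Each ORF's single best database hit (ranked by bitscore, then e-value,
  then input order for determinism) is a usable proxy for its taxonomic
  origin, and a strict majority of such top hits identifies the contig's
  source organism. Only ORFs with at least one hit enter the denominator:
  a contig of poorly represented organisms should read as "unclassified",
  not as "not taxon X".
- Mean amino-acid identity (AAI) to those top hits measures database
  representation: a taxonomically mixed contig with low AAI is more likely
  a novel genome than a chimera.
- Coding density (genes/kbp) separates prokaryotic from eukaryotic
  contigs: prokaryotes sit near 1/kbp, while eukaryotes land far lower —
  an effect amplified by prokaryote-style gene calling, and therefore
  diagnostic rather than a nuisance.
- Tetranucleotide frequency (TNF) and codon usage bias are genome-specific
  signatures, so hierarchical clustering over them yields putative bins,
  with the cluster count anchored by single-copy marker gene counts.

## Pipeline stages and key rules

1. **FASTA ingest** — sequences uppercased; non-ACGTN characters coerced
   to N (count logged). Duplicate ids and empty records are format errors.
2. **Fragmentation utility** — contigs strictly longer than 1 Mb
   (default) are split into consecutive 100 kb pieces plus the remainder;
   the remainder is kept, so concatenating fragments always reproduces the
   input. Used to emulate metagenome-grade fragmentation of finished
   genomes.
3. **Gene calls** — a deterministic six-frame maximal-span caller: in each
   frame an ORF runs from the first permitted start codon (ATG/GTG/TTG)
   after the previous stop to the next stop, translation table 11. Spans
   reaching the contig edge without a stop are emitted as partial.
   External calls (GFF3 CDS + protein FASTA) can be imported instead.
4. **Hit table** — eight tab-separated columns (qseqid, sseqid, pident,
   length, evalue, bitscore, stitle, staxlineage); lineages are consumed
   pre-resolved, semicolon-joined, domain first, padded to seven ranks
   with `unclassified`. Query ids `<contig>_<serial>` attribute hits to
   contigs, which decouples the hit table from the local gene caller: a
   table produced against any gene set remains usable.
5. **Classification** — `fraction(taxon, rank) · 100 > perc` (strict).
   With `--phage`, a hit matches when its domain is Viruses and the taxon
   token appears in the subject title or lineage, since phage subjects
   usually carry their host genus only in free text.
6. **Binning** — features are 136 canonical TNF classes + 59 RSCU values,
   each column standardized (constant columns dropped); contigs under
   2000 bp or without a complete ORF are excluded (short-contig TNF is
   noise) but stay in the report with an empty cluster field. k = mean
   marker hit count, rounded half-up, floor 1; Ward linkage on Euclidean
   distance (complete/average available), tree cut to exactly k.
7. **HGT screen** — contigs with a strict Eukaryota top-hit majority are
   scanned; an ORF is flagged when strictly more than `perc`% of its top-n
   hits are Bacteria or Archaea (pooled — the biological claim is
   "prokaryotic origin", and separating the two at this evidence level is
   not meaningful). Viral hits count in the denominator only. A coding
   density ceiling (~0.5 genes/kbp) is available as an additional AND
   condition on the eukaryote test.
8. **Extraction** — a contig matches iff ALL active criteria hold;
   numeric bounds are inclusive (a "maximum GC of 50%" reads naturally as
   ≤ 50). Missing values (no depth table, no hits, all-N sequence) fail
   the criteria that need them; matched ∪ unmatched is always an exact
   partition of the input.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `perc` | 50 | % | strict majority for taxon assignment and HGT flagging |
| `hits_n` | 100 | hits | top hits kept per ORF (tophits file, HGT fractions) |
| `orf_min_length` | 300 | nt incl. stop | see below |
| fragmentation | 1 Mb / 100 kb | bp | long-contig split threshold / piece size |
| cluster `min_length` | 2000 | bp | TNF of shorter contigs is too noisy to bin |
| marker set | 16 ribosomal proteins | — | universal single-copy set for k estimation |

**ORF length floor (300 nt).** A maximal-span caller has no coding
statistics, so on random or shadow-frame sequence it emits every open span
with a start codon. At a 90 nt floor that is several spurious calls per
kbp — enough to erase the prokaryote/eukaryote density contrast the
pipeline relies on. At 300 nt (100 codons) the expected spurious rate on
random sequence drops to well under one call per 10 kbp at moderate GC,
while genuine prokaryotic genes (median ~900 nt) are essentially
unaffected. The floor is exposed (`-orf_min_length`) for users who import
real gene calls and want shorter genes.

**Codon bias as RSCU.** "Codon usage bias" is quantified as relative
synonymous codon usage because it is scale-free across contigs with very
different gene counts; stop codons and the single-codon families (ATG,
TGG) carry no synonymous information and are excluded, giving 59 features.
For every family with at least one observation the k family values average
exactly 1.

**Strand-folded TNF.** Raw 256-mer counts would make a contig and its
reverse complement look different; folding each 4-mer onto the
lexicographically smaller of itself and its reverse complement (136
classes) makes binning strand-agnostic, like standard composition binners.

**k rounding.** The marker-count mean is rounded half-up with a floor of
1: half-up keeps the estimator unbiased for means near x.5 and the floor
guarantees a valid clustering even for marker-free (e.g. purely
eukaryotic or viral) assemblies.

## The synthetic-data generator

`contigscout.fixtures` plants: per-genome GC (intergenic base composition
is solved analytically so the whole contig lands within ~2 points of
target), gene density (gene count = `round(density · L / 1000)`), a
genome-specific codon preference (one preferred codon per family, weight
10:1, wobble base matched to the GC target), random gene strands, lineage-
labelled hit tables (identities ~ Normal(mean, sd) clipped to [20, 100],
strictly decreasing bitscores, optional decoy-lineage contamination and
per-ORF overrides for planting HGT cases), per-contig coverages and a
marker table with one count per prokaryotic genome. Everything is
deterministic under the spec seeds.

Two deliberate idealizations make the planted structure *exactly*
recoverable by the maximal-span caller: each gene interleaves a fixed
9-codon sense block that places a stop codon in all five shadow frames
every ~40 codons, and intergenic sequence carries a 15-mer cassette with
stops in all six frames every ~45 bases. Consequently no spurious open
span can reach the 300 nt floor anywhere in a synthetic genome. Real DNA
is not like this: real shadow frames contain long open spans, real
intergenic DNA is not stop-saturated, real hit tables contain paralogs and
chimeric lineages, and real coverage varies along a genome. Passing tests
on these fixtures therefore demonstrates the correctness of the decision
rules, thresholds, bookkeeping and I/O — not classifier performance on
real assemblies, which is bounded by the reference database and the gene
caller used.

## Numerical and degenerate-input choices

- GC of an all-N sequence is reported as missing (NA), never 0; N bases
  are excluded from numerator and denominator.
- TNF windows containing N are skipped; sequences with no valid window get
  the all-zero vector and are excluded from clustering.
- Codons containing N translate as X and are skipped in RSCU counts;
  partial ORFs are excluded from RSCU pooling.
- Hit-table ties: bitscore desc, e-value asc, input order — all outputs
  are byte-deterministic for identical inputs (reports use fixed column
  orders and fixed float formats; the run manifest contains no
  timestamps).
- Binning with fewer than two eligible contigs is skipped with a warning
  (labels empty), and k is clamped to the number of eligible contigs when
  the marker table implies more genomes than there are clusterable
  contigs.
- Empty extraction criteria are a usage error rather than "match
  everything": silently writing the whole assembly to `matched.fa` is a
  likelier bug than an intent.

## Problem sizes used in tests and the acceptance script

Unit tests run on 20–120 kb genomes. The acceptance machinery uses
1.05 Mb genomes (so the default 1 Mb/100 kb fragmentation is exercised,
44 fragments), five replicate 3 × 200 kb communities fragmented to 50 kb
for clustering purity, and a 70 kb eukaryotic contig (21 genes) for the
HGT screen — sizes chosen so the full suite completes in well under a
minute per component while every rule operates at its default thresholds.

## Known limitations

- Cluster labels are putative: clustering is coverage-blind by design
  (only TNF + RSCU, per the anchoring on marker-derived k), and genomes
  contributing no markers (eukaryotes, viruses) are absorbed into the
  nearest composition bin rather than given their own.
- The ORF caller is a stand-in: it has no coding-statistics model, no
  RBS/start refinement and no intron awareness, so absolute gene counts on
  real eukaryotic DNA are unreliable (usefully so, for density-based
  domain separation, but not for annotation).
- HGT candidates are a screen only; genomic-context and phylogenetic
  validation are explicitly out of scope.
- Lineages are consumed as pre-resolved strings; no taxonomy-database
  resolution or LCA reconciliation is performed.
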