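# Methods

## Model and procedure

`syntenic` treats synteny detection as a four-stage pipeline over annotated
replicons (one `GenomeRecord` per GenBank LOCUS; coordinates 0-based
half-open; translation table 11 throughout, since the domain is bacteria and
archaea).

**Alignment primitive.** All protein comparisons use Smith-Waterman-Gotoh
local alignment under affine gaps: a gap of length *k* costs
`gap_open + k·gap_extend` (defaults 11 and 1), substitution scores from
BLOSUM62 with the `X` and `*` rows forced to zero so unknown residues and
annotation artifacts can neither create nor destroy similarity. Local, not
global, alignment is used everywhere: the pipeline routinely compares
unrelated window proteins, for which global alignment yields uninterpretable
negative scores. A global (Needleman-Wunsch-Gotoh) mode is kept behind
`AlignmentParams(mode="global")` purely for auditing. The kernel is a
numba-compiled linear-memory DP; alignment spans are recovered by re-aligning
the reversed prefixes that end at the optimum, so no traceback matrix is
stored.

**Score normalization.** Raw scores are matrix-scale dependent, so every
decision threshold operates on the normalized score
`100·S(a,b)/S(ref,ref)`, clipped to [0, 100]. For query-vs-genome hits the
reference is the query itself; for pairwise window comparisons it is the
*longer* sequence of the pair. The longer-sequence rule is deliberate: a
fusion protein then scores only moderately against each parent (roughly the
fraction of the fusion the parent covers) instead of 100, which keeps
fusions colored after their better half while their anomalous length remains
visible on the scale-exact map. Bit-score conversion is not implemented;
self-normalization already makes the ratio threshold approximately
matrix-invariant.

**Translated search.** Each genome is translated in six frames; stops split
frames into blocks, blocks shorter than 10 residues are skipped as noise
floor, and each block is aligned to the query exactly. The hit coordinate is
the midpoint of the genomic interval covered by the aligned codons
(frame- and strand-aware). This is the TBLASTN operation class executed
exactly rather than heuristically — at desk scale (≤100 replicons per job)
the full DP is affordable and removes any seeding nondeterminism. Queries
are accepted only over the strict 20+X alphabet and must be ≥10 residues
after cleaning (FASTA headers, digits and whitespace removed).

**Hit policy.** The orthology threshold accepts exactly [10, 100] %,
default 30 % — the customary discriminant for bona fide orthology from
normalized genomic search scores. In `best_hit` mode one window per genome
is kept; in `all_hits` mode, hits whose windows would overlap by more than
half are merged, keeping the higher-scoring center, since two near-identical
windows carry no extra information.

**Windows.** Windows default to 15 000 bp centered on the hit. Linear
replicons clip at their ends (a centered mid-replicon hit yields exactly
15 kb); circular replicons always yield exactly `min(15 kb, L)` with
wrap-around re-linearized for display. Genes overlapping a window edge are
kept with full coordinates and clipped only visually — dropping them would
hide boundary synteny. Origin-spanning CDS are removed at parse time by
rotating the whole replicon (offset recorded), so all downstream arithmetic
is linear.

**Star coloring.** The top-ranked genome's best window is the single
reference even in `all_hits` mode. Its proteins are compared all-vs-all;
edges at/above threshold define connected components; components are colored
1, 2, … in left-to-right order of their first gene. Other windows are
compared only to the reference (pure star topology — no transitive color
cascade between non-reference windows), each gene inheriting its best
reference match's color, ties to the leftmost reference gene for
determinism. A window with no gene reaching the threshold is flagged
non-syntenic. Because coloring depends only on the reference, permuting the
other genomes can only reorder rows, never change colors.

**Cluster scan.** For multi-query scans, all above-threshold hits of all
queries are pooled per replicon, sorted by center, and chained greedily
while consecutive centers differ by strictly less than `max_gap`
(default 8000 bp; the strict inequality is part of the contract and is
tested at the 7999/8001 boundary). Chains are maximal by construction;
completeness means every query id occurs at least once, and paralogous hits
of one query may appear repeatedly in a chain.

**Taxonomy.** Lineages are normalized to a constant depth of 7. A lineage
with a known superkingdom but incomplete internal ranks is filed under
`<Superkingdom>/unclassified`, keeping its phylum one level below when
known; lineages without a superkingdom go under `Prokaryote/unclassified`.
Padding (rather than truncating) incomplete lineages was a genuine design
choice: it preserves the invariant that every leaf sits at depth 7, which
keeps node selection and tree merging trivially regular. Genus/species fall
back to the first two tokens of the organism name with a leading
"Candidatus" stripped, matching NCBI naming practice. Selection of any node
recursively selects all species beneath it; jobs are capped at 100 genomes,
enforced before any computation. Input is a flat TSV lineage table
(`accession  organism  rank=value;…`) so the package runs fully offline; a
live taxonomy fetcher can produce the same table but is intentionally out of
scope. Each replicon is scored independently; multi-replicon organisms are
simply several rows.

## Rendering

All rows share one `px_per_kb` scale (default 40) and are aligned on the
anchor hit center; arrow width is exactly `(end−start)·px_per_kb/1000`, so
rendered width ratios equal bp ratios to the stated 1 px rounding, which is
what makes fusion detection by eye sound. The anchor (query) gene is stroked
bold. The palette holds 24 maximally distinct colors and cycles with a
progressive whitening (22 % per cycle) beyond 24 components; neutral grey is
reserved for uncolored genes. Minus-strand genes are left-pointing arrows on
the same baseline. SVG is written directly (SVG 1.1 is plain XML and the
geometry is trivial); per-gene metadata is embedded both as `<title>`
tooltips and `data-` attributes. The PDF report is drawn with matplotlib's
vector backend with compression disabled and creation/modification dates
omitted, giving byte-identical output for identical input; the first page
header carries the run parameters and the full query sequence (also stored
in the document's Subject field). CSV export is one row per gene
(rank, accession, organism, locus_tag, start, end, strand, color,
norm_score, product) with not-found genomes appended as gene-less rows, and
round-trips through `read_report_csv`.

## Synthetic study genomes

`make_fixture_genome` is first-class, tested code, not a throwaway fixture.
It plants genes (given protein, position, strand; fusions are simply
concatenated proteins) into random background DNA of chosen GC content, and
is deterministic: same spec + seed gives byte-identical GenBank text. Two
properties make planted expectations *exact* rather than approximate:

* each CDS is flanked by in-frame stop codons, so a local alignment against
  the planted protein cannot extend past the gene body and the
  translated-search hit center is exactly `start + (3·len(protein))//2`
  (plus 3 on the minus strand);
* the background is verified to contain no 30-mer of any planted protein in
  any reading frame (regenerated from a derived seed in the vanishingly rare
  case of a collision), so decoy regions cannot reach the 30 % threshold.

What the generator emulates: gene density and spacing of a prokaryotic
neighborhood, paralog pairs at tunable identity (`mutate_protein`), gene
fusions, circular replicons, strand mixtures, decoy genomes. What it does
not emulate: real codon usage and GC skew, overlapping genes, pseudogenes,
mobile elements, sequencing/annotation errors, and realistic protein family
divergence (mutations are i.i.d. substitutions without indels). Passing
tests therefore demonstrate the correctness of the machinery — coordinate
arithmetic, normalization, chaining, coloring, rendering — not the
biological sensitivity of a 30 % threshold on real diverged families.

Study problem sizes were chosen to represent the method honestly at desk
scale: 30 kb replicons with a five-gene cluster (one paralog pair, one
fusion) across three genomes plus one decoy for the end-to-end suite, a
ten-genome library with exactly two complete four-gene clusters for the
scan, twenty 5 kb decoys for the false-positive check, and 200 random pairs
of ≤15-mers against an exhaustive cubic reference DP for the kernel.

## Numerical and degenerate-input choices

* Integer scoring end to end; no floating-point in the DP.
* Empty sequences and all-negative landscapes score 0 with empty spans;
  global-mode scores may be negative by design.
* Ambiguous DNA other than N is rejected at parse time; N translates to X,
  which scores 0.
* CDS whose length is not a multiple of 3 translate floor(len/3) codons with
  a warning; a trailing stop is trimmed, internal stops are preserved
  (the annotation is authoritative).
* Tie-breaks are all deterministic: first-encountered optimum in the DP,
  leftmost reference gene in propagation, ascending accession in ranking
  ties, position-then-query-id in chain pooling.
* The whole pipeline is deterministic given its inputs; the only randomness
  anywhere is the seeded fixture generator.

## Known limitations

* The exact translated search is quadratic per block; genomes of several Mb
  with long queries take minutes, not seconds. An adapter for an external
  TBLASTN-compatible tool behind the same `GenomicHit` contract is the
  intended escape hatch for library-scale scans and is deliberately not part
  of the tested surface.
* Star coloring cannot link two non-reference genes that are orthologous to
  each other but both absent from the reference window.
* Normalized-score thresholds are not e-values: no significance statistics
  are attached, and ranking is by normalized score only.
* EMBL/GFF3 input, pseudogene handling and strain-level taxonomy sub-ranks
  are out of scope.
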