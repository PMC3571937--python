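# syntenic

A taxonomy-aware synteny viewer for prokaryotic genomes.

Conservation of gene order (shared synteny) is strong evidence that genomic
regions in different organisms are orthologous and that neighboring genes are
functionally related. `syntenic` answers the question a geneticist actually
asks: *given one protein, where does its gene sit in each of these genomes,
and is its neighborhood conserved?* It works entirely offline from annotated
GenBank flat files and a flat lineage table, so results are exactly
reproducible.

## What it computes

1. **Translated search.** The query protein `q` is first aligned to itself
   to obtain the self-score `S(q,q)`. Each genome's DNA is translated in all
   six reading frames; stop codons split frames into blocks, and each block
   is aligned to the query with the Smith-Waterman-Gotoh (SWG) local
   algorithm under affine gaps (BLOSUM62, gap of length *k* costing
   `11 + k·1`). Every hit is scored by the *normalized score*

   `norm(q, t) = 100 · S(q, t) / S(q, q)  ∈ [0, 100]`,

   and hits below the user threshold (range 10–100 %, default 30 % — the
   customary discriminant for bona fide orthology) are discarded.
2. **Ranking and windows.** Genomes are ranked by their best normalized hit;
   hitless genomes form the explicit *not found* list. Around each retained
   hit a 15 kb window (circular replicons wrap exactly) is extracted with
   all overlapping CDS and their annotated translations.
3. **Star-topology coloring.** The proteins of the top-ranked window are
   compared all-against-all; pairs at or above the threshold (normalized by
   the longer sequence's self-score) form edges and each connected component
   receives one color, so reference paralogs share a color. Every other
   window is compared *only* to the reference and inherits colors from its
   best reference match.
4. **Scale-exact maps.** All rows are drawn with one shared px/kb scale, so
   gene length is comparable across rows and a gene *fusion* is immediately
   visible: its arrow is as wide as its parents' arrows combined.
5. **Cluster scan.** Several queries (e.g. the subunits of a multiprotein
   complex) can be scanned jointly: their pooled hits are chained while
   consecutive hit centers lie strictly less than 8000 bp apart, and chains
   covering every query are flagged as complete clusters.

Organisms are selected through a constant-depth 7-rank taxonomy
(superkingdom…species): selecting any tree node recursively selects all
genomes beneath it, up to 100 per job.

## Worked example

```python
import numpy as np
from syntenic import (FixtureSpec, PlantedGene, make_fixture_genome,
                      random_protein, run_synteny, render_svg, export_csv)

rng = np.random.default_rng(7)
query = random_protein(rng, 80)
neighbor = random_protein(rng, 60)

def genome(acc, organism, seed, with_cluster=True):
    genes = (PlantedGene("qry", query, 12000),
             PlantedGene("nbr", neighbor, 12600)) if with_cluster else ()
    spec = FixtureSpec(acc, organism, 30000, genes)
    return make_fixture_genome(spec, seed)[0]

genomes = [genome("DEMO01", "Synthetica prima", 1),
           genome("DEMO02", "Synthetica secunda", 2),
           genome("DEMO03", "Vacua tertia", 3, with_cluster=False)]

report = run_synteny(query, genomes)
for rank, seg in enumerate(report.rows, 1):
    genes = [(g.feature.locus_tag, g.color, round(g.norm_score or 0, 1))
             for g in seg.genes]
    print(rank, seg.accession, f"{seg.anchor.norm_score:.1f}%", genes)
print("not found:", report.not_found)
```

prints

```
1 DEMO01 100.0% [('qry', 1, 100.0), ('nbr', 2, 100.0)]
2 DEMO02 100.0% [('qry', 1, 100.0), ('nbr', 2, 100.0)]
not found: [('DEMO03', 'Vacua tertia')]
```

Both genomes carrying the planted pair rank at 100 % (an exact translated
match of the query), the query gene and its neighbor receive colors 1 and 2
consistently across rows, and the genome without the cluster is reported in
the not-found list. `render_svg(report)` / `export_csv(report)` produce the
scale-exact map and the spreadsheet export.

The same pipeline is available from the shell:

```bash
syntenic run  --query q.faa --genomes genomes/ --taxa Bacteria/Firmicutes \
              --lineages lineages.tsv --min-score 30 --out report/ --format svg,csv,pdf
syntenic scan --queries subunits.faa --genomes genomes/ --max-gap 8000 --out clusters.csv
syntenic tax  search bacillus --lineages lineages.tsv
```

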