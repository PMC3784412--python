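# chromnest

Gene-neighborhood co-expression scoring and chromatin domain-state analysis
for two-tissue comparisons.

Adjacent genes in mammalian genomes are often co-expressed, and broad histone
modifications (H3K4me2 and H3K36me3 over active chromatin, H3K27me3 over
silenced chromatin) can cover whole groups of neighboring genes at once.
`chromnest` is for researchers who want to ask, on microarray-style expression
data plus ChIP-seq broad-peak calls: which runs of adjacent genes behave as
conserved co-expressed neighborhoods, and does their chromatin state differ
between a tissue of interest and a control tissue?

## The scores

**Total Neighborhood Score (TNS).** Every run of 2–10 adjacent probed genes is
a candidate neighborhood. With ANC the *average neighborhood correlation*
(mean of all pairwise expression correlations among the window's genes,
Spearman by default), SS the *synteny score* (fraction of comparison genomes
in which all window genes lie in a single syntenic block), and *p* a
permutation p-value for the ANC obtained from randomized transcriptomes
(expression profiles shuffled across genome positions, null pooled over
windows of the same size):

    TNS = SS · ANC   if p ≤ 0.05 and ANC > 0,   else 0

TNS lies in [0, 1]: 0 means "not a neighborhood", 1 a perfectly co-expressed,
perfectly conserved one.

**Chromatin domain ratios and the Domain Score (DS).** For any genomic region,
island mass is Σ height × width over the SICER-style broad peaks intersecting
it (clipped at the region's edges). With tissue-1-to-tissue-2 ratios

    CADR = mass(active marks, tissue 1) / mass(active marks, tissue 2)
    CSDR = mass(H3K27me3,   tissue 1) / mass(H3K27me3,   tissue 2)
    DS   = log2(CADR + 1) − log2(CSDR + 1)

a positive DS means more active and/or less silenced chromatin in tissue 1;
near zero means the chromatin state is shared. Per-gene scores use the span
from transcription start to end; NCADR/NCSDR use a whole neighborhood's span.
A pseudomass of 1 score·bp keeps ratios finite where a tissue has no islands.

The package also provides a simplified broad-island caller (fixed 200-bp
windows, Poisson background, gap-merging) with the gap-size scan that picks,
per mark, the gap maximizing the aggregate island score; distance-binned
co-expression profiles with a cross-chromosome baseline; run-based
neighborhood sharing between tissues; and the group statistics (Wilcoxon
rank-sum with continuity correction, two-sample KS, hub chi-square,
permutation tests for neighborhood membership).

A synthetic-data generator with planted ground truth (co-expressed
neighborhoods with known ANC and synteny, tissue-specific active/silenced
chromatin domains, distance-decaying co-expression) makes every stage testable
without any external data.

## Worked example

```python
import chromnest as cn

# synthetic bundle: 400 genes on 2 chromosomes, 4 planted neighborhoods
ann, truth, expr, smap, marks = cn.simulate.simulate_bundle(
    seed=1, n_genes=400, n_chroms=2, n_plants=4)

scored = cn.score_windows(ann, expr, smap, n_perm=500, seed=1)
print(scored.sort_values("TNS", ascending=False).head(4)
      [["chrom", "start", "end", "n_genes", "ANC", "SS", "p", "TNS"]])
```

```
chrom    start      end  n_genes      ANC  SS        p      TNS
 chr2 12740521 12857670        2 0.863039 1.0 0.000015 0.863039
 chr2 12633884 12749671        2 0.862289 1.0 0.000020 0.862289
 chr2 12633884 12857670        3 0.850219 1.0 0.000005 0.850219
 chr2  2440325  2534643        2 0.781238 1.0 0.000126 0.781238
```

The top-scoring windows are a planted 3-gene neighborhood and its 2-gene
sub-windows: their genes share a latent expression profile (ANC ≈ 0.85, far
above the permutation null, so p ≈ 10⁻⁵) and sit in one syntenic block in
every comparison genome (SS = 1), giving TNS ≈ 0.85.

```python
tbl = cn.gene_chromatin_table(ann, marks)
print(cn.ds_summary(tbl["DS"]))
# {'min': -18.27, 'max': 18.11, 'frac_within_2': 0.915}
```

Domain Scores span roughly ±18 — the planted tissue-specific domains — while
91.5% of genes have |DS| ≤ 2, i.e. chromatin state shared between the two
tissues, as the generator's shared-background model plants it.

A CLI mirrors the library: `chromnest simulate`, `distance-profile`,
`score-neighborhoods`, `chromatin-scores`, `call-islands`, `gap-scan`,
`classify`, `compare-groups`, and `run-all` (full pipeline from a YAML
config). See `chromnest --help`.

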