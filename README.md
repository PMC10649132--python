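# lncpipe

Discovery of long non-coding RNAs (lncRNAs) from assembled transcripts,
negative-binomial differential expression for small two-group designs, and
co-expression-based cis/trans target inference — as one tested, reproducible
Python pipeline.

The package is aimed at transcriptomics analysts who have assembled
transcript models (GTF + FASTA), a reference annotation with biotypes, and a
raw count table for a treatment-vs-control comparison, and who want the
standard lncRNA cascade without cluster-scale infrastructure. Because the
real inputs to such a study are large, `lncpipe` ships a first-class
synthetic-data generator that emulates the whole study — genome, annotation,
coding/noncoding sequence composition, assembled transcripts engineered for
each structural class code, and counts for a 4-control vs 3-treated design
with planted effects — so every stage is testable against known ground
truth.

## What the pipeline computes

1. **Class codes & retention cascade.** Each assembled transcript gets a
   structural code against the reference (`=` identical intron chain, `j`
   shared junction, `o` same-strand exonic overlap, `x` antisense overlap,
   `i` intronic, `u` intergenic; precedence `=`>`j`>`o`>`x`>`i`>`u`).
   Codes {x, o, i, u, j} are retained as novel candidates; `=` matches
   resolve to annotated lncRNAs or known mRNAs by reference biotype; then
   mature length ≥ 200 nt, ≥ 2 exons, and sequence deduplication.
2. **Coding potential.** Longest-ORF filter (remove ≥ 300 nt), a 10-fold
   cross-validated random forest over six sequence features (ORF length and
   coverage, Fickett TESTCODE, hexamer usage log-ratio, GC, log length),
   and homology triage of survivors at E ≤ 1e-5 into coding-match
   (removed) / lncRNA-match / no-match groups.
3. **Differential expression.** Median-of-ratios size factors s_j,
   per-feature NB dispersion α with shrinkage, Wald test on
   log2FC = log2((μ̂_t+c)/(μ̂_c+c)) with SE from Var(K) = μ + αμ², BH
   adjustment per family; calls at padj ≤ 0.05 and |log2FC| ≥ 1. Sample QC
   (PCA + distance matrix) flags aberrant replicates for explicit exclusion.
4. **Targets.** Pearson r with t-test p over log2-normalized expression for
   every DEL × DEG pair; edges at |r| ≥ 0.90, p ≤ 0.05; *cis* when gene
   bodies lie within 20 kb, else *trans*. Plus lncRNA-vs-mRNA structure
   statistics and a database-agnostic hypergeometric over-representation
   test.

See `docs/methods.md` for the model details, parameter defaults and
limitations.

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic data
(seed 1) and write their tables under `results/`:

```sh
python analysis/01_simulate_study.py
python analysis/02_identify_lncrnas.py
python analysis/03_differential_expression.py
python analysis/04_target_network.py
```

`02_identify_lncrnas.py` prints:

```
class codes: {'=': 20, 'i': 10, 'j': 20, 'o': 11, 'u': 12, 'x': 10}
classifier: {'n_estimators': 100, 'max_depth': None}, CV F1 1.000, held-out F1 1.000
novel lncRNAs: 50, annotated lncRNAs: 10
removals by stage: {'cascade': 13, 'orf_filter': 10}
vs truth: sensitivity 1.000, contamination 0.000
```

All 50 planted novel lncRNAs are recovered (the 13 cascade removals are the
10 copies of known mRNAs plus 3 duplicate sequences; the 10 ORF-filter
removals are the planted coding-locus extensions), with no coding
contamination. `03_differential_expression.py` then reports

```
DEGs: 23 (11 up, 12 down)
DELs: 16 (7 up, 9 down)
planted effects recovered: 39/42; false discoveries: 0
```

and `04_target_network.py` builds the co-expression network:

```
edges: 113 (12 cis, 101 trans; 56 positive, 57 negative)
planted cis pairs recovered as cis edges: 10/10
```

Every planted cis lncRNA–target pair is recovered with mode `cis`; the
trans edges connect treatment-responsive genes whose profiles co-vary, as
expected at n = 7. The structure summary shows the planted ordering
(lncRNAs shorter with fewer exons than mRNAs, Mann–Whitney p < 1e-40).

The same stages are available as a CLI:

```sh
lncpipe run-all --seed 1 --inputs results/study --simulate --out results/run
lncpipe de --counts counts.tsv --groups groups.tsv --out de.tsv
```

Rerunning `run-all` with the same seed reproduces every output byte for
byte; the manifest records config, seed and SHA-256 checksums.

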