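# Methods

`lncpipe` reimplements, at desk scale, a multistep analysis for discovering
long non-coding RNAs (lncRNAs) in assembled RNA-seq transcripts, calling
differential expression in a small unbalanced two-group design, and
inferring cis/trans lncRNA target genes by co-expression. This note records
the models, the tunable parameters, the synthetic-data assumptions and the
numerical choices, so results can be interpreted without reading the code.

## 1. Structural class codes and the retention cascade

Each assembled transcript is compared with every reference transcript on
its chromosome and assigned one code, with per-pair evaluation order and
global precedence `=` > `j` > `o` > `x` > `i` > `u`:

| code | meaning |
|------|---------|
| `=` | identical ordered intron chain (mono-exonic: same-strand exonic overlap with both termini within 100 bp) |
| `j` | shares ≥ 1 exact intron (donor+acceptor) with a same-strand reference |
| `o` | any other same-strand exonic base overlap |
| `x` | exonic base overlap on the opposite strand |
| `i` | entirely inside a single reference intron (any strand) |
| `u` | no base overlap with any reference exon or intron |

Only these six codes are implemented; the finer distinctions made by
assembly-comparison tools (contained, polymerase run-on, repeats, …)
collapse into the nearest of {`o`, `x`, `i`, `u`} because they do not change
retention. One genuinely ambiguous case had to be decided: a transcript
that touches a reference intron without exonic overlap but is not fully
contained in a single intron satisfies no rule above; we collapse it to
`i`. The 100 bp terminus tolerance for mono-exonic `=` is required because
intron-chain equality is undefined for single exons; it is explicit and
tested. Ties between references yielding the same code break to the
lexicographically smallest reference id, making the assignment fully
deterministic.

The retention cascade then runs in a fixed order: (1) class filter —
codes {x, o, i, u, j} become novel candidates; `=` matches are resolved by
the matched reference's biotype (lncRNA → annotated lncRNA; protein-coding →
removed as a known mRNA); (2) structural filter — keep mature (spliced)
length ≥ 200 nt and ≥ 2 exons; "length" is always spliced length, since the
200 nt lncRNA definition applies to the mature RNA; (3) deduplication —
among byte-identical sequences the lexicographically smallest id is kept
and the rest logged as `duplicate_of:<kept>`. Every input transcript ends
in exactly one of {novel candidate, annotated lncRNA, removal log}; this
partition is asserted on every run.

## 2. Coding potential

Candidates then pass three coding-potential gates.

**Long-ORF exclusion.** The longest sense-strand ORF (ATG to stop, stop
included; all three frames; open-ended ORFs counted to the last complete
codon; codons containing N never match) is computed by a linear scan that
is tested against an exhaustive start/stop enumeration. Transcripts with
longest ORF ≥ 300 nt (100 aa) are removed as putatively coding. The
boundary is ≥: an ORF of exactly 300 nt is removed, 297 nt is kept.

**Random-forest classifier.** Six features per sequence: longest ORF
length (nt), ORF coverage (ORF/transcript length), Fickett TESTCODE score
(published position/composition lookup tables, shipped as packaged JSON; N
bases ignored in counts), hexamer usage score (mean over sliding 6-mers of
log((c_cod+1)/Σ) − log((c_non+1)/Σ) from coding/noncoding training counts;
N-windows skipped), GC fraction, and log length. Secondary-structure
features are deliberately excluded: they need an external folding engine
and the remaining features already carry the discriminative signal at this
scale. Training uses the reference transcripts labelled by biotype,
deduplicated; a stratified 20% held-out test set is reserved first, then
10-fold cross-validation over a small grid (trees ∈ {100, 300}, depth ∈
{none, 10}, class-balanced weights) selects hyperparameters by mean CV F1;
the winner is refit on the training portion. All seeds are explicit;
training twice with one seed gives identical metadata. Candidates with
P(coding) ≥ 0.5 are removed as predicted mRNA (boundary inclusive).

**Homology triage.** From a BLASTn-style tabular hit table, hits with
E ≤ 1e-5 are significant. Group 1 (any significant hit to a coding/other
subject) is removed; group 2 (significant lncRNA hit) and group 3 (no
significant hit) together form the novel lncRNAs. The pipeline consumes a
hit table rather than running a search; a small exact-11-mer seed,
ungapped-extension aligner (match +1/mismatch −2, ungapped Karlin–Altschul
constants λ=1.33, K=0.621) is included so tests are self-contained — it is
a test utility, not a BLASTn replacement.

## 3. Differential expression

Counts K_fs are modelled NB with variance μ + αμ². Size factors are
median-of-ratios (features containing zeros excluded from the reference
geometric means), rescaled to geometric mean 1. Per-feature dispersion is
pooled within-group method of moments,
α_f = Σ_g (n_g−1)(s_g² − μ_g) / Σ_g (n_g−1) μ_g², floored at 1e-8, then
shrunk (weight 0.7) toward a global center computed as the ratio of summed
moments with a bias-corrected denominator (μ̂² overestimates μ² by
var(μ̂) ≈ s²/n, which is subtracted). The heavy shrinkage is deliberate:
with 4 + 3 samples the per-feature moments carry ~5 residual degrees of
freedom and are right-skewed and biased low, while the ratio-of-sums center
is nearly unbiased; null simulations (m = 2000) put the empirical type-I
error at nominal p < 0.05 in the 0.05–0.065 range across seeds, versus
~0.078 for per-feature-dominated variants.

The Wald test uses log2fc = log2((μ_t + c)/(μ_c + c)) with moderating
constant c = 0.5 on normalized counts, a delta-method standard error from
the NB variance, and a two-sided normal reference. Calls: padj ≤ 0.05
(Benjamini–Hochberg) and |log2fc| ≥ 1, boundaries inclusive. BH is applied
separately to the gene family and the lncRNA family, mirroring separate
DEG/DEL reporting. A known nuance: the unmoderated group-mean ratio is
exactly invariant to rescaling one sample's counts, but the c = 0.5
moderator perturbs log2fc at order c/μ (~1e-4 at depth 200), because a
single-column rescale shifts all normalized counts by a common factor
k^(1/m).

**Sample QC.** PCA (first two components) and Euclidean distances on
feature-centered log2(normalized + 1) profiles. A sample is flagged when
its median distance to same-group samples exceeds the group median of those
medians by 3 MADs; the MAD over 3–4 values can collapse to ~0, so it is
floored at 2.5% of the group median distance. Flags are advisory —
exclusion is always an explicit user action, mirroring how an aberrant
replicate would be dropped manually after inspection.

## 4. Target inference

All DEL × DEG pairs are Pearson-correlated on log2(normalized + 1)
expression over the DE samples (Pearson on raw counts would be dominated by
magnitude; the log scale is our choice and is stated in the output
metadata). Edges require |r| ≥ 0.90 and p ≤ 0.05 (two-sided t, n−2 df); at
n = 7, r = 0.90 gives p ≈ 0.0058, so the joint threshold is internally
consistent. A pair is *cis* when the gene bodies (union of transcript
spans) are on one chromosome with a gap < 20 000 bp (overlap → 0; boundary
strict; strand ignored) — gene-body distance is the most conservative
explicit reading of "distance". Cis status only annotates the edge; both
modes share the thresholds. No multiple-testing correction is applied
across the correlation family (raw p, as thresholded); this caveat is
written into the edge metadata. Over-representation analysis is a
database-agnostic hypergeometric upper tail P(X ≥ k) with BH across terms;
term databases themselves are out of scope. The structure summary reports
mean ± sd of transcript length, exon length and exon count per class with
two-sided Mann–Whitney U p-values (the comparison test is our choice) and
fixed histogram bins (lengths 0–500–1000–…, exon counts 1, 2, 3, …).

## 5. Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the pipeline assumes,
with ground truth for every object. Defaults (one place, `SimulationConfig`):

| parameter | default | why |
|---|---|---|
| design | 4 control vs 3 treated | the emulated study design |
| genome | 4 × 2.5 Mb | fits ~420 non-overlapping gene loci |
| genes | 300 coding, 120 lncRNA | desk-scale, resolvable class statistics |
| exons per gene | coding 3–12, lncRNA 2–4 (150–400 bp; introns 0.2–1.5 kb) | coding transcripts longer with more exons, as in real annotation |
| `frac_de` | 0.10 | planted DE fraction |
| `planted_lfc` | ±2 (log2) | detectable at n = 4 vs 3 |
| `nb_dispersion` | 0.1 | typical bulk RNA-seq biological CV ≈ 0.32 |
| baseline means | log-uniform 20–2000 | spans the informative count range |
| cis pairs | 10, gap uniform in [0, 20 kb) | planted cis regulation |
| `cis_planted_lfc` | ±4, same sign in a pair | see below |
| `cis_latent_sdlog` | 0.7 | shared lognormal factor per pair |
| `coding_bias_strength` | 0.75 | codon usage bias (GC-weighted) |

Coding transcript sequences are UTR + ATG + codons drawn from a GC-biased
codon model + stop + UTR, guaranteeing a ≥ 306 nt ORF; noncoding sequences
are drawn from an AT-rich background and rejection-sampled until the
longest ORF is < 300 nt. Assembled transcripts are engineered per class
code: exact copies (`=`, split between coding and lncRNA references),
junction-sharing subsets and coding-locus extensions (`j`), shifted-splice
overlaps (`o`), antisense overlaps (`x`), intron-interior transcripts
(`i`), and intergenic transcripts (`u`), plus byte-identical duplicate
pairs for the dedup stage. Novel-candidate codes anchor on noncoding loci
so their planted coding label is unambiguous; the `j` extensions of coding
loci retain the full ORF and are planted as coding (the contamination
challenge for the classifier cascade).

Planted cis pairs correlate through two mechanisms, both biologically
motivated: a strong same-sign treatment response (|log2FC| = 4 in both
members — cis regulation implies co-response) and a shared per-sample
lognormal latent factor (sdlog 0.7). With n = 7 samples, a true |r| ≥ 0.9
requires the shared signal to dominate the NB noise; the combination yields
true r ≈ 0.94–0.96 while keeping both members reliably callable as DE.
Their baselines are floored at the upper quartile of the mean range so
count noise does not mask the correlation.

What the generator does **not** emulate: read-level sampling and mapping
ambiguity (counts are drawn at gene level), isoform mixtures (one
transcript per gene), batch effects beyond the single planted outlier
sample, length-dependent library biases, and correlated null features.
Consequently, passing tests demonstrate the pipeline's correctness and
calibration under its stated model, not robustness to real-data artefacts
such as misassembly or mapping multi-hits.

## 6. Numerical and degenerate-case conventions

Coordinates are 0-based half-open internally; conversion to 1-based GTF
happens only in `formats`. N bases are retained in sequences; each feature
computation states its N-handling (ORF codons with N never match; Fickett
ignores N in counts; hexamer windows containing N are skipped). Constant
expression vectors make Pearson undefined — such pairs are skipped with a
warning rather than given r = 0. Empty candidate sets propagate as empty
outputs. BH adjusted values are clamped to ≥ raw p to absorb 1-ulp float
dips of m·p/k at the element's own rank. All pipeline outputs carry no
timestamps, so a rerun with one seed is byte-identical; the provenance
manifest records config, seed and SHA-256 checksums.

## 7. Known limitations

- The NB Wald test has no trend-fitted dispersion, no LFC shrinkage and no
  independent filtering; it is validated by simulation, not by parity with
  any external DE tool, and its calibration is only established for designs
  near 4 vs 3 at m ≈ 2000 features.
- The classifier's near-perfect accuracy on synthetic data reflects the
  generator's strong, clean coding signal; real coding/noncoding boundaries
  (short ORFs, pseudogenes, bicistronic transcripts) are much harder.
- Homology triage is only as good as the supplied hit table; the built-in
  naive aligner has no gapped extension and misreports E-values for highly
  repetitive sequences.
- The 20 kb cis window uses gene-body distance; a TSS-anchored definition
  would classify some near-boundary pairs differently.
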