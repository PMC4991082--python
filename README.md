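# dielnet

Detection of 24 h (diel) rhythms in temporal expression data, combined
with gene co-expression network analysis to predict *additional* rhythmic
genes from network topology and to transfer functional (GO) annotations by
guilt-by-association.

The package is aimed at chronobiology and systems-biology analyses of
time-course transcriptomes — the motivating setting is a zooplankton
sampled every 4 h over 44 h under a light:dark cycle with 4 technical
replicates per timepoint — and ships a synthetic-data generator with full
ground truth so the entire pipeline is testable without any download.

## The method

**Rhythm scan.** Each gene's series is ranked against cyclical reference
orderings derived from cosine curves over a (period, phase) grid. For a
reference ordering with tie groups (replicates share ties), the
Jonckheere–Terpstra/Kendall statistic

&nbsp;&nbsp;&nbsp;&nbsp;*S* = #(concordant pairs) − #(discordant pairs)

is compared against its **exact** permutation null, obtained from the
Gaussian q-multinomial coefficient [*n*; *n*₁…*n*_g]_q by exact integer
convolution. The minimum two-sided *p* over the grid (Bonferroni-corrected
within gene over the orderings distinct up to reversal) is converted to a
Benjamini–Hochberg *q* across genes; genes with *q* < 0.1 and best period
in 22–26 h are called rhythmic. A single-harmonic cosinor fit
(*y* = *m* + *a* cos ω*t* + *b* sin ω*t*, F-test vs. flat) provides
amplitude/acrophase estimates.

**Networks.** All gene pairs are scored by signed Pearson correlation,
absolute correlation, and mutual information of binned profiles; the top
*K* = multiplier × *N* pairs become edges. Five standard networks are
analyzed: SIGN_N, ABS_N, MI_N (*K* = *N*) and the intersections
ABS_MI_10N / ABS_MI_25N.

**Topology-based prediction.** Where detected rhythmic genes occupy
distinctive network positions (Mann–Whitney *p* < 0.01 for any of 7
centralities — betweenness, closeness, clustering coefficient, degree,
eccentricity, graphlet degree over the 15 orbits of 2–4-node graphlets,
k-coreness — on 5 networks), the F-score-optimal top-*K*% band is kept if
its rhythmic enrichment survives Bonferroni over the 35 combinations.
Independently, Markov clusters (inflation 2) enriched in rhythmic genes
contribute predictions when their F-score beats a null of 100 random
same-size clusterings. Genes the scan did not call are the novel
predictions; the intersection of both routes is the high-confidence set.

**Function prediction.** Enriched terms of a gene's clusters (with a
majority-coverage rule) and centrality bands are transferred to
unannotated members; the intersection of the two sources is validated by
leave-one-out cross-validation (LOOCV).

## Worked example

Run the numbered analysis scripts (or equivalently `dielnet all --outdir
results/run --seed 0`):

```bash
python analysis/01_simulate.py            --outdir results/run --seed 0
python analysis/02_detect_rhythms.py      --outdir results/run --seed 0
python analysis/03_build_networks.py      --outdir results/run --seed 0
python analysis/04_predict_rhythmic_genes.py --outdir results/run --seed 0
python analysis/05_predict_function.py    --outdir results/run --seed 0
python analysis/06_validate.py            --outdir results/run --seed 0
```

which prints (abridged):

```
wrote results/run/expression.tsv: 2000 genes, 200 rhythmic (40 sub-threshold), ...
background filter: kept 1879 / 2000 genes (cutoff 136.5)
rhythmic genes (q<0.1, 22-26 h): 157
median peak-to-trough fold change: 2.13
peak-phase histogram: ZT0-4: 14, ZT4-8: 30, ZT8-12: 40, ZT12-16: 5, ZT16-20: 39, ZT20-24: 29
centrality: 25 combinations passed both gates; 695 genes predicted, 539 novel
clustering: 5 networks beat their randomized null; 217 genes predicted, 65 novel
LOOCV: 98/101 predicted associations correct -> precision 97.0% over 101 genes
cluster_pred_vs_jtk: overlap 152 (|a|=217, |b|=157), p = 5.99e-163
high-confidence predictions: 211 (59 novel)
novel predictions vs planted-but-undetected rhythmic truth: 47/50 recovered, p = 1.35e-22
```

Reading the numbers: of 2 000 simulated genes, 1 879 exceed the
background fluorescence floor; the scan calls 157 rhythmic (the design
plants 160 detectable ones plus 40 sub-threshold ones), with the expected
bimodal mid-day/mid-night peak-phase histogram and a detected median
peak-to-trough fold change of 2.13. The network analysis then recovers 47
of the 50 planted-but-undetected rhythmic genes among its novel
predictions (hypergeometric p ≈ 1e-22) — the sub-threshold genes are
invisible to the cosine scan but co-express with their modules — and
annotation transfer is 97 % correct under leave-one-out validation.

The same pipeline runs on user data: a tab-separated genes × samples
matrix with `ZT<hh>_r<k>` sample columns, an optional two-column
(gene, term) annotation file, and an optional reference rhythmic-gene
list (`PipelineConfig(simulate=False, expression_path=..., ...)`). For a
public expression archive, export the gene-level intensity table with
such column labels and point `expression_path` at it.

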