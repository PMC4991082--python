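# Methods

`dielnet` detects 24 h (diel) rhythms in a temporal expression matrix and
then uses gene co-expression networks to (i) predict additional rhythmic
genes from network topology and (ii) transfer functional (GO-style)
annotations by guilt-by-association. This note records the models, the
parameters that matter, the numerical choices, and what the bundled
synthetic data does and does not establish.

## Rhythm detection

### The rank scan

For each gene the series `y(t)` over samples (timepoints x technical
replicates) is compared against *reference orderings*: the tied ranks of
`cos(2*pi*(t - phi)/T)` evaluated at the sample times, over a grid of
candidate periods `T` and phases `phi`. Replicate samples at one timepoint
share a tie group, as do timepoints whose cosine values coincide by
symmetry. For each ordering the statistic is

    S = (# concordant pairs) - (# discordant pairs)

over sample pairs *untied in the reference*; pairs tied in the data
contribute zero. Because the statistic depends on ranks only, the scan is
invariant to monotone transformations of intensity; positive scaling and
shifts leave p and phase unchanged, and negation shifts the phase by half
a period.

### Exact null distribution

Under exchangeability of the data the null distribution of `S` depends
only on the multiset of reference tie-group sizes `n_1..n_g`. The number
of arrangements with `w` discordant pairs is the coefficient of `q^w` in
the Gaussian (q-)multinomial coefficient `[n; n_1..n_g]_q`, which the
package builds by exact integer polynomial arithmetic (multiplying and
dividing factors `1 - q^m`), giving `S = M - 2w` with `M` the number of
untied pairs. Tail probabilities are therefore exact to floating-point
rounding; the test-suite checks them against exhaustive permutation for
every ordering with up to 7 tie-free timepoints. Convolution is feasible
to roughly 60 samples; the default design (48 samples) takes milliseconds
because the six scanned phases share one tie structure.

Two-sided p-values are `P(|S| >= |s_obs|)`. A reference ordering and its
antiphase mirror define the same two-sided test (they negate `S`), so the
scan (a) counts only orderings distinct up to reversal when applying its
within-gene Bonferroni correction, and (b) breaks p-ties between mirrored
orderings toward the ordering with the most positive `S`, which is the
phase at which the series actually peaks. Without the tie-break, half of
the night-phased genes would be reported 12 h off; without the Bonferroni
factor (here 3: six phases in mirrored pairs) the minimum-p over the grid
is anticonservative and the realized FDR roughly triples. A
`grid_bonferroni=False` switch restores the uncorrected minimum.

Heavily tied data can fall back to a Monte-Carlo permutation p
(`permutation_null=True`); the exact null otherwise assumes the response
is continuous.

### Classification and estimates

Genes are called rhythmic when the Benjamini–Hochberg q-value is below 0.1
and the best period lies in 22–26 h. With 4 h sampling, candidate periods
are the multiples of the sampling interval inside the window (i.e. 24 h;
a relaxed window such as 20–28 h admits 20 and 28 h), and the phase grid
steps by the sampling interval. Reported per gene: p, q, best period,
phase (ZT), the Kendall-style correlation at the optimum, and two fold
changes: `fold_change` (max/min of timepoint means on the raw scale, with
`amplitude` its half log2) and `fold_change_cosinor` (`2^(2A)` from the
single-harmonic least-squares fit on log2 values). The max/min estimate is
biased upward by sampling noise at the extremes (~20–40 % under the
default noise model), so summary medians use the cosinor estimate.

The cosinor fit itself is `y = m + a cos(2*pi*t/T) + b sin(2*pi*t/T)` by
least squares, amplitude `sqrt(a^2+b^2)`, acrophase from `atan2(b, a)`,
and an F-test of `(a, b) = 0` against the intercept-only model.

## Preprocessing

Quantile normalization maps every sample column onto the per-rank means of
the column-sorted matrix; ties receive the mean of their occupied rank
targets (deterministic; exactly idempotent for tie-free columns). The
background filter then removes genes whose maximum raw fluorescence never
exceeds the floor (default 136.5). *Known artifact:* when a sizeable
fraction of genes is strongly rhythmic, quantile normalization makes flat
genes weakly antiphase (rank competition within columns), which raises the
realized FDR of the scan from ~0.09 to ~0.14 on the default synthetic
data. The pipeline keeps the normalization as standard practice for
multi-array fluorescence data; analyses of detector accuracy in the tests
run on filtered raw intensities, which the generator already draws on a
common scale.

## Co-expression networks

Pairwise scores over gene profiles: signed Pearson `r`, absolute `|r|`,
and plug-in mutual information (bits) after per-gene equal-width binning
(default B = 3; the coarsest informative choice for short profiles).
Profiles default to log2 replicate-level values (48 points). With only 12
timepoint means, the null correlation between unrelated genes has sd
~0.30, so tens of thousands of pure-noise pairs outscore genuinely
co-expressed pairs and the top-K networks are mostly sampling noise;
48-point profiles halve the null sd. Timepoint means remain available
(`network_profile: means`).

A network keeps the top K = multiplier x N pairs (N = scored genes),
breaking score ties at the K-th edge by lexicographic pair id so the edge
count is exactly K. The standard set is SIGN_N, ABS_N, MI_N (K = N) plus
ABS_MI_10N and ABS_MI_25N, the edge-set intersections of the absolute
Pearson and MI rankings at K = 10N and 25N. Zero-variance genes are
excluded from Pearson scoring with a logged warning. Networks at smaller K
are subgraphs of the same method's networks at larger K.

## Graph algorithms

Seven node centralities on each network's largest connected component
(the distance-based measures require connectivity): betweenness
(unnormalized shortest-path pair counts, via igraph), closeness
`(n-1)/sum(d)`, clustering coefficient, degree, eccentricity, k-coreness,
and graphlet degree. Graphlet degree summarizes the 15 automorphism
orbits of the connected 2–4-node graphlets:

    GDC(v) = sum_i w_i log(d_i(v) + 1),  w_i = 1 - log(o_i)/log(15),

where `d_i(v)` counts orbit `i` at `v` and `o_i` is the number of orbits
that orbit `i` depends on — the distinct orbits a node at orbit `i`
necessarily touches within its own graphlet (derived by enumerating each
graphlet's induced subgraphs; the table is `[1,2,2,2,3,4,3,3,4,3,4,4,4,4,3]`).
Restricting to 4-node graphlets (rather than the 73 orbits of 5-node
graphlets) keeps exact counting tractable at desk scale; downstream
analysis consumes only the ranking. Orbit counts are computed exactly by
combinatorial identities (triangle-anchored sweeps over common-neighbour
bitsets plus inclusion–exclusion on vertex-distinct walk counts) and are
validated against exhaustive subgraph enumeration on every connected
graph with <= 7 nodes.

Markov clustering (MCL) runs on the binary self-loop-augmented
column-stochastic adjacency matrix of the *full* network — MCL factorizes
over connected components, and restricting it to the largest component
would silently discard whole co-expression modules. Iterations alternate
expansion (matrix squaring) and inflation (elementwise power 2, column
renormalization), prune entries below 1e-8, and stop when the largest
entry change is below 1e-6 (cap 200 iterations, warning on
non-convergence). Clusters are the connected components of the attractor
structure; the output is a deterministic, relabel-invariant partition.

## Predicting rhythmic genes

**Centrality route.** For each of the 35 (network x measure) combinations:
a two-sided Mann–Whitney test asks whether detected rhythmic genes occupy
different network positions than the rest (alpha 0.01; direction = group
with the higher median). Passing combinations sweep the top-K% band
(most- or least-central, K = 1..100, deterministic gene-id tie-breaks),
score precision/recall/F against the detected set, and take the smallest
argmax-F K. The band must finally pass an upper-tail hypergeometric
enrichment gate, Bonferroni-corrected over all 35 combinations (alpha
0.05), over the component's node universe. Band genes not detected by the
scan are novel predictions; support counts the passing combinations per
gene.

**Clustering route.** Meaningful clusters (size >= 2 with >= 2 detected
rhythmic members) enter a sweep over K = 1..100 %: clusters whose rhythmic
fraction is at least K % *and* whose enrichment passes Bonferroni (over
the meaningful clusters) pool their genes; precision/recall/F are scored
per K. One hundred random partitions preserving the exact cluster-size
multiset provide a null F-curve; a network contributes its argmax-F
predictions only when the real F exceeds the null's 95th percentile at
that K (the operationalization of "significantly better than random").
Predictions pool over all significant clusters at the chosen K; support
counts contributing networks.

## Function prediction and LOOCV

Groups: every meaningful MCL cluster of every network (clustering source)
and the optimal top-K% band of every gate-passing combination (centrality
source). A term transfers from a group when it is enriched
(Bonferroni-corrected hypergeometric over the terms tested in that group,
alpha 0.05) and — for clusters only — carried by a majority (> 0.5) of the
group's annotated members, the neighbour-majority rule of
guilt-by-association annotation. Within a source, a gene's terms are the
consensus (intersection) over the informative groups containing it;
groups left with no transferable term abstain. High-confidence pairs are
the intersection of the two sources. Without the consensus and coverage
rules, the dense intersection networks' merged superclusters transfer
every module's term to every member and precision collapses to the module
base rate (~0.25).

Leave-one-out validation hides one annotated gene's terms at a time,
recomputes enrichment for the groups containing it, and scores the
intersection-of-sources predictions for that gene against the hidden
truth; precision is pooled over all predicted associations. Terms are
used flat (no ontology propagation).

## Validation utilities

Exact upper-tail hypergeometric overlap tests (cross-checked against
big-integer binomial arithmetic), overlap of prediction sets with an
external reference rhythmic list restricted to network genes, pairwise
overlap of enriched-term sets between positive controls / novel
predictions / negative controls (negative = network genes predicted by no
route), and condition-overlap counts (percentage of an external
differentially-expressed list that is also rhythmic). Universes default to
the union of network genes for network-level tests and the expressed-gene
set for condition comparisons, and are recorded in each report.

## Synthetic data

The generator emulates a diel microarray design: 12 timepoints every 4 h
over 44 h, 4 technical replicates, 2 000 genes, 8 % rhythmic. On the log2
scale a rhythmic gene is

    b_g + (log2 f_g)/2 * cos(2*pi*(t - phi_g)/24) + lambda_g w_m(t) + eps,

exponentiated to fluorescence units. Defaults, with rationale:

| parameter | default | why |
| --- | --- | --- |
| `fold_change_median` | 2.06 | emulated design's detected median |
| `fold_change_spread` | 0.5 (log2 sd) | realistic spread; few genes near the detection boundary |
| `baseline_log2_mean/sd` | 10 / 1.5 | typical fluorescence well above background |
| `noise_sd_log2` | 0.15 | free choice: moderate technical noise for arrays |
| `background_floor` | 136.5 | raw-scale filter cutoff |
| `frac_below_background` | 0.05 | exercises the filter |
| `phase_modes_zt` | 6, 18 | bimodal mid-day/mid-night peak distribution |
| `module_phase_spacing_h` | 3.5 | distinct temporal programs per module (i.i.d. centres regularly coincide, making two modules statistically identical) |
| `module_phase_window_h` | 4 | members within +/-2 h of the centre |
| `module_wiggle_rel` | 0.5 | module-shared fluctuation, see below |
| `frac_near_rhythmic` | 0 (scenario knob: 0.02) | planted sub-threshold rhythmic genes |
| `near_fold_change` | 1.10 | below the scan's detection boundary |
| `near_wiggle_sd` | 0.25 (log2) | couples sub-threshold genes to their module |

Modules exist only among rhythmic genes; each carries a *wiggle* `w_m(t)`
— a temporal fluctuation shared by members and consistent across technical
replicates, projected orthogonal to the first diel harmonic and
unit-normalized. Strong members load it in proportion to their own
amplitude (`lambda_g = 0.5 a_g`); planted sub-threshold members load it at
a fixed sd of 0.25. The wiggle plays two roles: it distinguishes modules
that happen to share a peak phase, and it is precisely the kind of shared
temporal structure that co-expression sees but a cosine-ordering test does
not — which is what makes the sub-threshold genes recoverable by the
network analysis while remaining invisible to the scan.

Annotations: each module gets a dedicated term annotating a fraction
`signal` (default 0.9) of its members; a fraction `noise_rate` (default
0.02) of all genes carries one uniformly chosen background term; the rest
stay unannotated. The reference rhythmic list draws `(1 - contamination) n`
genes from the true rhythmic set and the rest from flat genes.

**What the synthetic data does not emulate:** probe-level effects, dye or
array batch structure, intensity-dependent noise, correlated technical
replicates (replicate noise is independent here, which favours the exact
null), non-sinusoidal waveform families beyond the wiggle, and a realistic
GO DAG. Passing tests therefore demonstrate correctness of the algorithms
and recoverability under the stated statistical structure, not performance
on any particular real dataset.

## Determinism, sizes, and edge cases

Every stage is deterministic given the global seed (sub-seeds are derived
for annotations, the reference list, and each network's randomized null);
identical seeds give byte-identical run directories. Default problem
sizes — 2 000 genes, 48 samples, five networks of up to ~15 000 edges —
run end-to-end in well under a minute on one CPU; the acceptance script
and test-suite use these sizes directly. Degenerate inputs are defined
rather than fatal where sensible: constant series get p = 1 and fold 1;
zero-variance genes are dropped from Pearson scoring; K exceeding the
number of scored pairs yields the complete graph with a warning; empty
groups, empty rhythmic sets, disconnected inputs to distance-based
centralities, and inconsistent universes raise errors that name the
offending object.
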