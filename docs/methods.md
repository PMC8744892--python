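# Methods

This note records the models implemented in `ernascope`, the defaults
and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical decisions a maintainer would want
written down.

## Coordinate and overlap conventions

All internal coordinates are 0-based half-open (`[start, end)`, the BED
convention); GTF is converted on read/write (1-based closed). Intervals
that merely touch share zero bases: a peak ending at position *x* and a
peak starting at *x* do **not** overlap. Strand is ignored in every
overlap and counting operation — nascent-transcription counting here is
unstranded.

Two binding-site peaks from different replicates make a *reproducible*
site when they overlap by at least 1 bp. The anchor convention keeps the
first replicate's coordinates for downstream windows; the choice of
anchor only shifts window centers by at most the replicate jitter and is
configurable by swapping the argument order.

A site is *intergenic* when it overlaps no gene feature (promoter, exon,
UTR, intron) of any gene — expressed or not — and its center lies more
than 1 kb from every annotated TSS. Promoters are TSS ± 1 000 bp
(configurable; annotations rarely agree on a promoter width, so it is a
parameter rather than a constant). Nearest-gene annotation is measured
peak-center to TSS among *expressed* genes only, signed by gene strand,
with ties broken to the lexicographically smaller gene id so results are
deterministic.

Fixed windows are centered on `floor((start+end)/2)`: 588 bp (four
nucleosomes) for site-centric eRNA detection, 1 000 bp for differential
counting, 100 bp trims for motif-style analyses. Windows clipped at a
chromosome edge record their shortened length, but TPM uses the nominal
width by default so the length constant stays interpretable.

## Quantification

A fragment is counted when its mapping quality is ≥ 20 and its length is
within [50, 1000] bp; it is credited to **every** window it overlaps by
≥ 1 bp. Windows around distinct sites can overlap, and a
multi-assignment rule is the one that is exactly testable against a
per-fragment oracle; the generator lays sites out far enough apart that
the rule never actually double-counts in simulated runs. The library
size is the number of filter-passing fragments genome-wide, not only
in-window fragments. Malformed records are skipped and tallied; more
than 10% malformed in one sample aborts the run.

The windowed TPM is `counts × 1000 / (library_size × length)` applied
verbatim. This variant omits the conventional scaling to one million and
the per-sample renormalisation; every downstream use is a
within-experiment percentile or ratio, which monotone rescaling cannot
change, so the formula is kept literal rather than "corrected".

The expression gate removes zero-mean features, takes the 5th percentile
(linear-interpolation quantile, the numpy default — pinned so tests can
assert exact thresholds) of the non-zero per-feature mean TPM pooled
over all samples of both conditions, and keeps features strictly above
it. When strictness would empty the set (single feature, all means
equal) the gate falls back to ≥ with a logged warning.

For site-centric eRNA calling, sites with a zero count in **any**
nascent sample are removed before the gate (`zero_policy="any"`). A site
transcribed in only a subset of libraries is not reproducibly expressed;
the weaker alternative (drop only all-zero sites) is available as
`zero_policy="all"` but lets sporadic background counts through the
percentile gate and roughly halves precision on synthetic data.

## The negative-binomial differential engine

Counts are modelled as `K[f,j] ~ NB(μ[f,c(j)] · s_j, α_f)` with
`var = μ + αμ²`. The engine's defining feature is that the size factors
`s_j` are a first-class argument: the default is the median-of-ratios
estimator, but factors estimated from a different dataset — the
assembled-transcript counts of the same libraries, or the reads-in-peaks
statistic of a chromatin assay — can be substituted and are honoured
verbatim. On a two-sample toy, substituting factors shifts the log2
fold-change by exactly the log-ratio of the factor ratios, which the
tests pin as a closed form.

Per feature: condition means are estimated on normalised counts
(`q = K/s`). Dispersion uses a bias-corrected method of moments pooled
within condition — `α̂ = (v − m·mean(1/s)) / (m² − v/n)`, df-weighted
across conditions; the denominator correction removes the
`E[m²] = μ² + Var(m)` bias that otherwise inflates the Wald statistic at
small n. A mean–dispersion trend `ᾱ(μ) = a0/μ + a1` is fitted by least
squares over features with mean ≥ 1 (clipping estimates to
[−1, 50] so outliers cannot steer it), and the working dispersion is the
weighted average `0.25·α̂ + 0.75·ᾱ(μ)`. The weights are a calibration
choice: with three replicates per condition the raw moment estimate has
roughly two degrees of freedom per condition, and giving it more weight
makes the test anticonservative (empirical type-I ≈ 0.06–0.08 at
nominal 0.05 under a 50/50 weighting, versus 0.04–0.06 at 25/75 across
seeds in the null simulations the test suite runs). The trend still
lets genuinely high-dispersion features raise their own variance.

The Wald statistic is `log2FC / SE` with the delta-method standard error
`SE² = [w_A/(n_A m_A) + α/n_A + w_B/(n_B m_B) + α/n_B] / ln²2`
(`w = mean(1/s)` within condition), referred to the standard normal,
two-sided; BH adjustment runs across all tested features. All-zero
features are excluded and reported NaN; when one condition's mean is
zero, a pseudocount of `0.5/n` enters both means so the fold-change is
finite and its SE reflects the uncertainty. Conditions with a single
sample yield fold-changes but NaN p-values. There is no independent
filtering or outlier replacement — calibration, not replication of any
particular package's estimates, is the design goal.

Regulation classes: induced ⇔ padj < 0.05 ∧ log2FC > log2 1.5; repressed
⇔ padj < 0.05 ∧ log2FC < −log2 1.5; thresholds apply to the unshrunk
estimate.

## Reads-in-peaks normalisation

For each chromatin assay, the peak union is the merged (bookended
intervals joined) union of peaks across all replicates and conditions.
A sample's RiP ratio is the fraction of its fragments overlapping the
union by ≥ 1 bp — a joint readout of depth and immunoprecipitation
efficiency. Ratios are scaled by the smallest one (which maps to 1) and
size factors are the reciprocals of the scaled ratios, so all factors
are ≤ 1 and the weakest-signal sample anchors the scale. Anchoring at
the minimum rather than at the smallest library changes nothing in the
relative factors; it is a presentation choice.

One algebraic caveat recorded deliberately: because the RiP ratio is a
*proportion*, adding in-union fragments worth the same fraction of each
library moves every ratio by the common affine map `(r+p)/(1+p)` —
order and anchor are preserved, but ratios of ratios are not exactly
invariant. Exact invariance holds under proportional whole-library
growth, and both properties are what the tests assert.

## Stratified testing and correlation

At regulated enhancers, per-assay log2 fold-changes are correlated with
eRNA fold-changes by Spearman (average ranks on ties; constant columns
give NaN), pooled over induced and repressed sites. Distributional
shifts per regulation group are tested in two stages against the
unchanged group: a two-sample Kolmogorov–Smirnov gate at p < 0.05, and —
only when the gate opens — a two-sided Wilcoxon–Mann–Whitney test (exact
null for small tie-free groups, otherwise the normal approximation with
tie and continuity correction). Significance tiers are reported at
p < 0.1 / 10⁻³ / 10⁻⁵.

## The synthetic-data generator

The generator emulates the *statistical structure* the analysis relies
on, not sequence-level realism. Its defaults define the reference study
condition used throughout the tests and the acceptance script:

| parameter | default | meaning |
|---|---|---|
| `n_chromosomes × chrom_length` | 3 × 2 Mb | genome size |
| `n_genes` | 60 (80% expressed) | gene models with UTRs/exons/introns |
| `n_peaks_per_tissue` | 625 | underlying binding sites per tissue |
| `frac_reproducible` | 0.8 | sites emitted in both replicates (≤ 50 bp jitter) |
| `frac_intergenic` | 0.8 | sites placed in gene-free slots |
| `frac_shared_tissue` | 0.1 | sites emitted in both tissues |
| `frac_ernaproducing` | 0.5 | reproducible intergenic sites with true eRNA |
| `n_induced / n_repressed` | 60 / 60 | truly differential enhancers |
| `lfc_induced / lfc_repressed` | 2.0 | true |log2FC| of the condition effect |
| `nb_mean_erna` | 50 | expected fragments per eRNA site window |
| `background_ratio` | 50 | signal-to-background ratio (μ_bg = 1) |
| `nb_mean_gene` | 100 | expected fragments per expressed gene |
| `nb_dispersion` | 0.1 | NB α, `var = μ + αμ²` |
| `feature_corr` | 0.75 ATAC/H3K27ac/BRD4, 0.2 H3K4me1/2/3, 0.5–0.6 others | eRNA–feature LFC coupling |
| `frac_active / frac_poised` | 0.658 / 0.287 | chromatin classes of true eRNA sites |
| `frac_polyA` | 0.576 | expressed genic transcripts flagged polyadenylated |

These sample sizes keep a full end-to-end run below ten seconds on one
CPU while leaving every recovery statistic well-measured (≥ 200 truth
positives per contrast); larger instances are a config change, not a
code change.

Placement is slot-based: genes are laid down with ≥ 3 kb intergenic
gaps, and binding sites occupy disjoint 1.4 kb intergenic (0.7 kb genic)
slots with margins, so intergenic sites are guaranteed > 1 kb from every
TSS, site windows never overlap each other, and truth bookkeeping is
exact (e.g. the reproducible fraction is a count, not an expectation).
Counts are NB draws as in the engine's model, with per-sample scale
factors lognormal(0, 0.15²) for nascent libraries. Background
transcription at non-eRNA intergenic sites is nonzero (μ_erna/50) so the
expression gate is genuinely exercised. Chromatin-feature fold-changes
are mixed at the latent level, `LFC_feat = ρ·LFC_eRNA + √(1−ρ²)·ε` with
ε Gaussian at the spread of the differential eRNA LFCs; with a
three-level eRNA LFC (±2, 0) the realised Spearman against the latent
truth tracks ρ closely in the ranges used (sampling SD ≈ 0.07 at 200
differential sites, which is why the targeting test uses ~900). For
chromatin assays the generator draws each sample's RiP ratio and sets
the sample's true count scale to the scaled reciprocal-RiP factor, so
the normalisation model is exact by construction and recovery failures
indicate implementation bugs, not model mismatch.

Fragments are *realised from counts*: each counted fragment passes the
filters and lies inside its source window/transcript, and on top each
sample receives ~5% filter-violating fragments (low MAPQ or
out-of-bounds length) and ~20% passing background fragments far from
every window — so counting filters and library-size accounting are
exercised, and counting the emitted fragments reproduces the count
matrix exactly on isolated windows. Transcripts give the transcript
route something real to do: expressed genes contribute genic
transcripts, true eRNA sites one or two intergenic transcripts each
(polyadenylated at rate 0.002, versus 0.576 for genic ones), plus
expressed intergenic decoys at no binding site.

What the generator does **not** emulate, and what passing tests
therefore do not show: sequence content and mappability (no motifs, no
repeats), fragment-level GC or length biases, spatial autocorrelation of
coverage, peak-caller artefacts (the "peaks" are truth emissions with
jitter), exon-structure assembly of transcripts, or dispersion trends
that vary with mean beyond the fitted `a0/μ + a1` family. Results on
real data additionally depend on alignment and peak-calling quality,
which are upstream of this package's scope.

## Reproducibility

Every stochastic stage draws from `numpy.random.default_rng([seed,
stage_id])`, so outputs are byte-identical for identical configs and
independent of stage execution order. Pipeline tables carry JSON
sidecars (stage, version, config hash). The acceptance script seeds
everything from `--seed` and recomputes all reported quantities at run
time.

## Known limitations

- The NB engine has no covariates, likelihood-ratio tests, or shrunken
  fold-change estimates; it is a two-group Wald test by design.
- Multi-replicate (> 2) reproducibility schemes (e.g. IDR) are out of
  scope; reproducibility is the two-replicate 1 bp rule.
- The transcript route uses provided transcript spans; it does not
  assemble transcripts or predict exon structure.
- With only two replicates per chromatin condition, per-site feature
  fold-changes are noisy; the correlation analysis is reliable at the
  cohort level (≥ ~100 differential sites), not per site.
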