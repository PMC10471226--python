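# Methods

`homeovar` analyses how gene dosage changes alter homoeolog expression in
resynthesized allopolyploids such as CCAA *Brassica napus* (BnC subgenome
from *B. oleracea*, BnA from *B. rapa*). It implements three connected
pieces: a read-depth dosage caller for homoeologous exchanges (HEs), the
per-GO-term expression-response variance statistics (HERV and PRV), and
the rank-based comparisons between dosage-sensitive and
dosage-insensitive gene classes predicted to differ under the gene
balance hypothesis. A synthetic-data generator with known truth backs
every stage.

## Dosage calling from read-depth ratios

For each syntenic homoeolog pair the BnC depth fraction is

    r = depth_C / (depth_C + depth_A),

undefined (missing) when the total depth is zero. Along each
homoeologous chromosome pair, ordered by syntenic gene rank
(`order_index`), the fraction is smoothed with a sliding gene window
(default 170 genes, step 1): each pair's smoothed value is the mean of
the means of all full windows containing it, which makes the effective
kernel triangular with half-width one window. Missing values are ignored
within windows; pairs near chromosome ends use the truncated window set;
a window longer than the chromosome degrades to a single
whole-chromosome window with a warning.

Smoothed fractions map to dosage classes by equal quintiles, read in
BnC:BnA order: [0, 0.2) → 0:4, [0.2, 0.4) → 1:3, [0.4, 0.6) → 2:2,
[0.6, 0.8) → 3:1, [0.8, 1.0] → 4:0. The bins are half-open with the top
bin closed so the map is a total partition of [0, 1]; boundary values
belong to the upper class (0.2 → 1:3). Classification is monotone in the
BnC fraction by construction.

An HE segment is a maximal run of at least `min_run` (default 10)
consecutive pairs in the same non-2:2 class. Shorter non-2:2 runs are
relabeled 2:2 rather than dropped, so every observed pair carries a
final class and the balanced dataset is defined by exclusion of HEs.
Missing states break runs. Runs of different HE classes are separate
candidate segments, keeping segments dosage-homogeneous for the
per-dosage analyses. Segment output is BED6 in pair-order coordinates
(0-based half-open `order_index` units), since the whole procedure works
in gene windows, not base pairs.

Chromosome-scale skew — aneuploidy or near-whole-chromosome events
rather than segmental HE — is flagged per (chromosome pair, sample) when
more than `gene_majority` (default 0.5) of non-missing pairs are
non-2:2. Chromosomes flagged in more than `sample_majority` (default
0.5) of samples are excluded for every sample; otherwise only the
flagged samples are excluded. Exclusions are applied before both the HE
and the 2:2 expression datasets are assembled, so downstream comparisons
share one gene universe.

Two window sizes are plausible for this class of caller (a shorter one
for ratio computation, a longer one for class assignment); this
implementation applies a single window once and exposes it as
configuration, since the composition of the two is not well defined and
a single 170-gene window reproduces the intended behaviour (see the
recovery study below).

## Expression responses and HERV/PRV

Lowly expressed pairs are removed per (sample, pair) when summed
homoeolog TPM falls below `min_sum_tpm` (default 10); the rule is on the
pair sum only, so a truly silenced single copy is retained. The parental
baseline per pair is the mean over parental replicate libraries, fixed
once.

The expression response of a pair in a sample is a fold change against
its progenitor baseline:

* HE response: (Exp_BnC + Exp_BnA) / (Exp_oleracea + Exp_rapa), computed
  for (pair, sample) observations whose called dosage class is 0:4, 1:3,
  3:1 or 4:0. The summed parental expression represents the balanced
  2:2 state, so a dosage-neutral pair has fold change 1.
* Polyploid (WGD) response: the same numerator over the midparent,
  (Exp_oleracea + Exp_rapa) / 2, computed for 2:2 observations. A pair
  need not be 2:2 in every sample; it contributes from the samples where
  it is. Exact dosage doubling gives fold change 2.

The two definitions satisfy `fold_change_wgd = 2 * fold_change_he`
exactly; observations with a zero baseline are excluded and counted.

Homoeolog expression bias is classified from the progenitor orthologs:
log2((oleracea + ε)/(rapa + ε)) strictly above 3.5 is BnC-biased,
strictly below −3.5 is BnA-biased, otherwise unbiased. The pseudocount
ε = 0.01 TPM tolerates a single zero parent; both-zero pairs are
unclassifiable and excluded from bias strata. Boundary values are
unbiased (strict inequalities).

GO annotations reach the *Brassica* pairs through an annotation
transfer: GO gene ids may be pair ids, subgenome gene ids, or
*A. thaliana* gene ids chained through an ortholog map
(thaliana → oleracea → pair). One-to-many ortholog hits annotate all
targets (union), which is logged. Each GO term carries a dosage class:
I = dosage-insensitive, II = dosage-sensitive (reciprocally retained
terms, the proxy for stoichiometric constraint).

Within a stratum (bias class × generation × dosage group), the response
variance of a GO term is the coefficient of variation — sample SD
(n−1) over mean — of the fold changes of its member observations. Each
(pair, sample) fold change is one observation by default (the pooled
design; `collapse_pairs="mean"` averages per pair first). GO terms with
fewer than `min_go_genes` = 20 distinct pairs in the stratum are
dropped: the size filter counts genes, not observations, and "at least
20" is used as the inclusive reading. CV over HE observations is the HE
response variance (HERV); over 2:2 observations it is the polyploid
response variance (PRV).

## Statistical comparisons

All comparisons treat one GO term as one observation:

* Class I vs class II CVs: Kruskal–Wallis H with midrank tie correction,
  p from the chi-square approximation (k−1 df). Degenerate input (all
  values identical) reports H = 0, p = 1.
* Each HE dosage group vs the 2:2 group: two-sided Wilcoxon rank-sum
  per group, exact when the combined sample is ≤ 20 and tie-free,
  otherwise the normal approximation with tie correction and no
  continuity correction (so the two-group Kruskal–Wallis and the
  asymptotic rank-sum give identical p-values). No multiple-testing
  adjustment by default — the four comparisons are starred individually
  (\* p ≤ 0.05, \*\* ≤ 0.01, \*\*\* ≤ 0.001, \*\*\*\* ≤ 0.0001);
  Benjamini–Hochberg is available behind `adjust="bh"`.
* Class-proportion check between the HE and 2:2 gene sets: Pearson
  chi-square on the 2×2 table of distinct pairs per class, without Yates
  correction (expected counts are large); correction available by flag.
* Expression confound check: per-GO mean summed TPM compared between
  classes with Kruskal–Wallis, per-GO-term units (each term is one
  observation, matching the CV analysis; the per-gene alternative is
  noted but not used).

The test suite verifies the exact Wilcoxon p against full enumeration of
rank assignments for combined n ≤ 12 and the H statistic against the
explicit rank formula.

## Synthetic data generator

The generator emulates the statistical structure of a resynthesized
allopolyploid study. Defaults define the emulated design:

| parameter | default | meaning |
|---|---|---|
| `n_chromosome_pairs`, `pairs_per_chromosome` | 10 × 2,600 | ~26,000 syntenic pairs on ordered chromosome pairs |
| `n_lines`, `generations` | 6, (1, 5, 10) | isogenic lines sampled over ten generations |
| `he_rate_per_generation` | 3.0 | expected new HE segments per line per generation |
| `segment_min_length`, `segment_mean_length` | 20, 150 genes | shifted-geometric segment lengths |
| `segment_min_gap` | 200 genes | planted segments are disjoint with a buffer, keeping truth identifiable after window smoothing |
| `dosage_class_weights` | 0.15/0.35/0.35/0.15 | extreme exchanges (0:4/4:0) rarer than single-copy shifts |
| `depth_mean`, `depth_dispersion` | 50, 0.1 | negative-binomial (gamma–Poisson) total depth; Poisson at dispersion 0 |
| `cross_mapping_rate` | 0.02 | fraction of reads leaking between subgenomes; a modelling choice, not an estimate |
| `expression_log_mean`, `expression_log_sd` | 3.0, 1.2 | lognormal parental TPM (median ≈ 20) |
| `biased_fraction`, `bias_c_share`, `bias_magnitude` | 0.15, 0.6, 5.0 | biased pairs exceed the ±3.5 log2 cutoff, weighted toward the dominant BnC subgenome |
| `response_noise_sd` | 0.2 | multiplicative lognormal noise on each homoeolog's response |
| `constraint_factor` κ | 0.7 | multiplies the noise SD for dosage-sensitive (class II) genes; κ = 1 makes classes exchangeable |
| `n_go_per_class`, `genes_per_go` | 150, 40 | disjoint GO terms per dosage class |

HE segments accumulate: a generation-g sample carries its line's earlier
segments plus newly planted ones. Depths allocate a negative-binomial
total between homoeologs binomially with expected BnC share
(c_C + ε·c_A) / ((1 + ε)(c_C + c_A)). Polyploid expression is
dosage-dependent — each homoeolog expresses its parental level times
copies/2 — under per-homoeolog multiplicative noise exp(N(0, sd)).
Because HE preserves the total copy number (c_C + c_A = 4), unbiased
pairs respond with fold change 1 regardless of HE class; only biased
pairs shift total expression, which is what generates the increasing CV
with dosage distance (0:4/4:0 > 1:3/3:1 > 2:2) seen in the imbalance
comparison. The `constraint_bias_scope` option restricts κ to chosen
bias classes; applying it only to BnC-biased and unbiased genes
reproduces the stratified pattern in which the class difference is
absent for BnA-biased pairs.

One global seed drives named substreams (genome, bias, per-line
segments, per-sample depths, per-sample expression), so adding samples
or stages never perturbs earlier draws and all outputs are reproducible
byte for byte.

A segment-free mixture mode assigns each (pair, sample) a dosage class
i.i.d. from given probabilities. It is used for statistical studies
(power, type-I error, CV ordering) where segment geometry is irrelevant
and per-dosage GO coverage must be controlled.

What the generator does not emulate: trans-acting effects of
hybridization, epigenetic remodelling, aneuploidy beyond whole-segment
copy change, mapping-bias structure along the genome, expression
correlation between neighbouring genes, or overlap between GO terms.
Passing tests therefore demonstrate that the pipeline recovers the
truth of this model, not that the model captures every property of real
resequencing data.

## Validation studies and problem sizes

`homeovar.studies` packages the standard verification experiments, sized
to run in a few minutes on one core:

* **Segment recovery** — 6 chromosome pairs × 2,000 genes, 16 samples
  (8 lines × 2 generations), default noise. Planted segments long enough
  to survive smoothing (≥ min_run + window genes) must be recovered with
  the correct class and both boundaries within window/2; on the
  noiseless variant, no called segment may lie further than one window
  from any planted segment. Window smoothing blurs true boundaries by
  roughly 0.1–0.2 windows (the triangular kernel crosses the quintile
  threshold inside the segment), which is why boundary tolerance is
  stated in window units. One known bias: for a segment lying within one
  window of a chromosome end, the truncated window set on the outer side
  is dominated by the segment itself, so the called boundary smears to
  the chromosome end (an error up to the truth-to-end distance). Such
  segments can exceed the half-window tolerance, putting measured
  recovery at roughly 90–98% depending on where segments land.
* **HERV class power/type-I** — 150 + 150 GO terms of 25 genes, uniform
  HE dosage mixture pooled over 16 samples. With κ = 0.5 the class
  comparison should reject essentially always; with κ = 1 the rejection
  rate at α = 0.05 stays within binomial bounds.
* **Imbalance ordering** — dosage mixture with 60% balanced
  observations pooled over 16 samples; mean per-GO CV must increase with
  dosage distance and every HE group must test significantly above the
  2:2 group in both GO classes, while class proportions between the HE
  and 2:2 gene sets do not differ.

`scripts/acceptance.py` reruns these studies plus the full pipeline at
the default design from a single seed and writes the resulting numbers
as JSON.

## Numerical and design notes

* Ratio orientation is the BnC fraction, so quintile labels read
  literally in BnC:BnA order.
* Quintile boundaries: half-open, closed at the top; dosage class
  assignment uses binary search on the edges rather than division to
  avoid floating-point misclassification at 0.2/0.4/0.6/0.8.
* CV requires ≥ 2 observations and a positive mean (guaranteed for fold
  changes, which are positive).
* The per-gene depth may be read counts or mean coverage; the caller
  only uses the ratio, so either works as "depth".
* Whether parental replicate variation should propagate into the fold
  changes is an open design point; it is not propagated here (the
  parental mean is treated as a fixed baseline).
* The 2:2 CV reference in the imbalance comparison is the PRV table
  itself, not a recomputation per dosage-group universe.

## Limitations

Breakpoints are reported at gene resolution, not base pairs. The caller
does not separate HE from aneuploidy beyond the chromosome-scale
exclusion rule. Expression values are relative (no spike-in
normalisation), so responses are interpretable as relative fold changes
only, and dosage-compensation categories are deliberately not called.
GO terms are broad functional bins; class II membership is a proxy for
dosage sensitivity, not a per-gene measurement.
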