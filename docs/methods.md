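# Methods

## Data model

The unit of raw data is a spot-level table: one row per microarray spot per
hybridized sample, keyed by `(gene_id, spot_id, region, phenotype,
replica)`, carrying foreground and background fluorescence and a corrupted
flag. One `(region, phenotype, replica)` triple is one array
(hybridization); the replica index identifies the same animal across
regions, making the design paired between regions.

Quality control removes corrupted spots and spots with foreground below
twice the background. The boundary is strict on the removal side: a spot at
exactly twice the background is retained. A spot that is both corrupted and
dim is counted under the corrupted rule. Background-subtracted signals that
are not strictly positive are dropped (all later statistics require
positive values), and each array is scaled to median 1 over its remaining
valid signals. Because the median is computed per array *before* any gene
selection, normalization commutes with later subsetting, and every
expression value is a multiple of its array's median gene expression.

Datasets are assembled per `(region, phenotype)`: a spot enters only with a
value in every replica (inconsistent spot sets are intersected down); a
gene survives a dataset with at least one complete spot; and genes are
finally restricted to the common universe present in every dataset, so all
datasets share one gene count N. The choice of a common universe is this
package's convention for reporting a single N across datasets; partially
quantified genes are dropped and itemized in the filter report.

## Per-gene statistics

**AVE** is the mean over a gene's spots of the per-spot replicate means —
equivalently the grand mean of its normalized values.

**REV** is a pooled coefficient of variation across replicas, corrected by
the mid-point of the chi-square confidence interval of a standard deviation
with `r = n·R − 1` degrees of freedom (n replicas, R spots):

    REV = ½ [ √(r/χ²_{r;1−α/2}) + √(r/χ²_{r;α/2}) ] · √( (1/R) Σ_k cv_k² ) · 100

with `cv_k = s_k/μ_k` the per-spot replicate CV using the sample (n−1)
standard deviation. The correction exceeds 1 and shrinks to 1 as degrees of
freedom grow; at R = 1, n = 4 it is 2.1475, which counteracts the severe
downward bias of a 4-point CV. Worked value: one spot with replicas
(8, 10, 10, 12) has CV 0.16330, r = 3 and REV = 35.07%. A caveat that
matters when interpreting simulated REVs: biological noise is shared by all
spots of a gene, so pooling over spots tightens only the technical
component — the effective degrees of freedom of the biological part stay at
n − 1.

**COR** correlates two genes' per-replica profiles `v_iξ` (the spot-mean
per replica) across the n biological replicas — correlating per-spot
replicate means against their own means would be degenerate, and the
replicate profile is the formulation consistent with coordination "among
biological replicas" and with the paired cross-region analysis (the Welch
test operates on the same profiles, so the biological replica is the
inference unit everywhere). Significance uses the
t-transform `t = r√((n−2)/(1−r²))` two-tailed; at n = 4 and α = 0.05 the
critical value is |r| = 0.950. Zero-variance profiles yield undefined
correlations, which are flagged and excluded from all downstream sums.

Pairwise correlation over all C(N, 2) pairs is streamed through an
accumulator in chunks; the per-gene sum Σ_{j≠i} COR²_ij needed by GCH is
computed exactly in O(N·n²) via the n×n Gram matrix of standardized
profiles (Σ_j (z_i·z_j)² = z_iᵀ(ZᵀZ)z_i), avoiding the N×N matrix.

**GCH** combines expression control and coordination:

    GCH_i = (REV_med/REV_i) · exp( (n/N) Σ_{j≠i} COR²_ij − 1 )

with REV_med the dataset median REV. Two open choices are resolved as
follows and kept switchable: the dataset-level REV norm is the *median*
(robust to the long right tail of REV), and the exponent is the
"offset" form above (default), with `exp(n(⟨COR²⟩ − 1))` available as
`gch_variant="scaled"`. The offset form gives a typical gene
(E[r²] = 1/(n−1) at independence) a GCH near `exp(n/(n−1) − 1) ≈ 1.4` and a
strongly coordinated, tightly controlled hub values in the hundreds, which
matches the observed dynamic range of such hierarchies; the scaled form
compresses everything toward `e^{−n}`. A REV of exactly 0 (possible only in
degenerate synthetic data) is replaced by the smallest positive REV with a
warning. Ranking is by descending GCH with ties broken by gene id; rank 1
is the dataset's Gene Master Regulator.

## Regulation

For a comparison "test vs reference" (two phenotypes, same region): the
signed ratio `x = AVE_test/AVE_ref` (or its negative reciprocal when the
gene is down in test, so |x| ≥ 1 always), the per-gene cutoff
`CUT = 1 + √(2(REV²_t + REV²_r))/100`, and a two-tailed Welch t-test on the
replicate profiles with Welch–Satterthwaite degrees of freedom. The
composite call requires both `|x| > CUT` (strict) and `p < α` (strict).
Degenerate Welch inputs follow a documented convention: both groups
zero-variance gives p = 1 for equal means, else p = 0.

`WIR = AVE_ref · sign(x) · (|x|−1) · (1−p)` is computed for *all* genes;
the reference level is the second-named phenotype of the comparison.
`WPR` aggregates a pathway as the mean of |WIR| over its quantified genes
(`wpr_variant="rms"` gives the root-mean-square alternative; both produce
the same pathway orderings in simulation, and the mean of √(WIR²) = |WIR|
is the default). p-values are
deliberately not multiplicity-adjusted — the composite criterion is a raw
per-gene rule, and the CUT clause already removes most borderline calls (on
null simulations at 20% CV the composite call rate is ~0.2%, far below the
5% of the p-clause alone).

## Coordination and synchrony

Within a dataset, pairs with significant positive/negative COR are
synergistic/antagonistic edges; the network over a gene selection is
emitted as an edge list and can be scored against declared expectations
(group, member gene, target gene, expected sign read from a TSV — a local
stand-in for curated pathway relations, so no live database access is
needed). Relations whose pair is absent from the network are reported as
`not_detected` rather than failing.

Across regions, the same gene's per-animal profiles (paired by replica
index) are correlated per phenotype; significantly positive/negative genes
are in-phase/anti-phase, and percentages are reported over the analyzed
gene set. Unpaired replica labels are an error, not a silent re-ordering.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes:

- **Abundances** lognormal across genes (`baseline_log_mean` 5.0,
  `baseline_log_sd` 1.5), spanning ~4 orders of magnitude as observed on
  high-density arrays.
- **Biological replicate noise** multiplicative lognormal with gene-level
  CV drawn from `cv_range` (default U(0.10, 0.40)), shared by all spots of
  a gene within an array; **spot-level technical noise** a smaller
  multiplicative term (`spot_cv` 2%).
- **Signals**: foreground = background + gain·expression with background
  U(1, 3) and gain 20, so background subtraction recovers the expression
  exactly and the filter boundary is essentially never hit by clean spots;
  a `frac_corrupted_spots` fraction (1%) is flagged corrupted, and a
  `frac_low_signal_spots` fraction (1%) has its foreground forced below
  twice the background.
- **Co-regulation**: a block with loading l gives each member the
  biological log-noise `σ_i(l·f + (1−l)ε)/√(l²+(1−l)²)` with one factor
  draw f per array — two members correlate `l²/(l²+(1−l)²)` on the log
  scale (0.997 at l = 0.95) while keeping the marginal CV at σ_i. This
  coefficient map (rather than the classic λ, √(1−λ²) loading) is chosen so
  that a "strong" loading of 0.95 actually produces correlations detectable
  at n = 4, where the significance threshold is r = 0.95; under the classic
  map the induced correlation (0.9025) would sit below the threshold and no
  loading short of ~0.999 would be recoverable.
- **Cross-region synchrony**: listed genes draw their factor per *animal*
  (phenotype × replica), shared across regions, same mixing scheme.
- **Regulation**: per-gene true fold-changes multiply the test phenotype's
  mean in all regions.

All draws flow from one `numpy` Generator seeded by the config, in a fixed
order, so identical configs are byte-identical. The ground truth (true
folds, CVs, block memberships, animal latents, per-spot validity) is
emitted alongside as JSON.

What the generator does *not* emulate: dye/channel effects beyond a
per-array signal, spatial array artifacts, probe-sequence biases,
heavy-tailed technical outliers, batch/day effects, and correlated
backgrounds. Passing recovery tests therefore demonstrates that the
statistics behave as designed under the assumed noise model, not that they
are robust to every artifact of real arrays.

### Simulation-scale effects that shaped the test scenarios

Two small-sample artifacts of simulating *whole arrays* at desk scale were
identified analytically and by simulation, and the recovery scenarios are
designed around them:

1. **Normalization common mode.** The per-array median over N simulated
   genes is itself a noisy statistic (variance ≈ Σp(1−p)/(n²f(m)²) across
   replicas); at N = 200 it adds a ~3% CV common to all genes of the array
   and independent across arrays. Worse, a co-regulation block that is a
   sizable fraction of the array shifts the median with its own factor,
   leaking an anti-correlated common mode into every other gene. Real
   44k-spot arrays make this negligible. Recovery scenarios therefore
   simulate realistic array content (2,000–4,000 genes) and, where a small
   analysis set is wanted, subset the tensor to a gene panel *after*
   normalization — exactly how a real study quantifies a pathway subset.
2. **Minimum-REV tails.** With 4 replicas the realized biological CV has
   ~3 effective degrees of freedom, so across hundreds of genes some null
   gene always draws a very small REV. A hub can therefore not be
   distinguished by REV alone; the hierarchy scenario gives the hub both a
   low CV (3%) and a large block (80 of a 200-gene panel, loading 0.95) so
   the coordination term of GCH is decisive. The pathway-ranking scenario
   likewise controls abundance spread (log-sd 0.5) because with disjoint
   20-gene sets the heavy lognormal abundance tail, not regulation, would
   otherwise dominate the WPR comparison.
3. **Clustered phase rates.** The cross-region in-phase rate clusters on
   the per-phenotype animal-latent draw (4 values); a degenerate draw
   suppresses all shared genes of that phenotype at once. Rates are
   therefore measured across many independent latent draws (all phenotypes
   of each seed).

## Numerical conventions

- Strict inequalities at every threshold: filtering removes
  `foreground < 2·background`; significance requires `p < α` and
  `|x| > CUT`.
- Correlations are clipped to [−1, 1] before the t-transform; |r| = 1 maps
  to p = 0.
- GCH ties break by gene id; hierarchy output is deterministic.
- All tolerances in tests compare against independently computed values
  (closed forms, brute-force loops, or chi-square/t quantiles), at 1e-9
  relative where the quantity is deterministic.

## Known limitations

- With n = 4 replicas, profile space has 3 degrees of freedom: random
  gene pairs align (cos² ~ U-shaped) far more often than high-dimensional
  intuition suggests, which bounds how cleanly coordination structure can
  be recovered and makes single-dataset GMR calls sensitive to one factor
  realization.
- The O(N²) correlation p-values are intentionally unadjusted; at
  N ≈ 17,000 a 5% edge rule admits ~7M false edges by construction. Edge
  lists are exploratory screens, not inference.
- The common-universe rule discards genes quantified in only some
  datasets; with 1% + 1% spot corruption and 2 spots per gene this loses
  ~3% of genes, itemized in the filter report.
- Counts reported at the full study scale (e.g. between-region
  correlations = N × phenotypes for two regions) follow from the design
  arithmetic; the amplification ratio is likewise reported as computed
  from those counts.
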