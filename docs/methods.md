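# Methods

This note documents the models behind `hemodyn`, the synthetic study
conditions, and the numerical choices that matter.  Coordinates are
BED-style 0-based half-open throughout; GTF is converted on read.  The six
stages ESC < MES < HB < HE < HP < MAC are totally ordered and transition
Tk joins stage k−1 to stage k.

## Synthetic study conditions

`hemodyn.simulate.generate_fixture` emulates the *shape* of a six-stage
multi-omics differentiation series; all planted structure is recorded in a
JSON-serializable truth manifest whose summaries are recomputable by
counting (`manifest_census`).

Default conditions (one `FixtureConfig`, one global seed; every component
draws from a named substream — seed plus CRC32 of the component name — so
adding a component never shifts the others):

- **Genome**: 2 chromosomes × 5 Mb of i.i.d. uniform ACGT sequence.
- **Genes**: 200, TSS placed with a ≥ 5 kb minimum gap and otherwise
  uniform positions (this makes regulatory-domain lengths genuinely
  unequal, which the length-weighted overlap null needs), alternating
  strand, 4 kb spans.  Five genes are the TF panel (Tal1, Lmo2, Gata2,
  Fli1, Cebpb) with hand-set FPKM trajectories; 39 genes are flat
  housekeeping controls (constant 10 FPKM); the remaining 156 are split
  evenly over four expression clusters.
- **Expression**: FPKM = 10^(cluster mean + N(0, 0.10)) per stage, in
  log₁₀ units.  The four cluster mean profiles are chosen to mimic the
  major pattern families of a blood time course — pluripotency-silenced,
  HE-transient, HP-peaked (declining in MAC), and MAC-only — and to be
  mutually well separated after per-gene standardization.  The noise sd
  of 0.10 keeps clusters ≥ 2 sd apart and keeps constant genes below the
  2-fold differential threshold.
- **DHS**: 2,000 distal DHS of 400 bp with planted six-digit codes
  (populations 100–440 per code), placed ≥ 1.5 kb from every TSS and
  outside the TF genes' regulatory domains (so stray TF binding cannot
  create unplanned network edges).  Each gene additionally carries a
  promoter DHS whose code follows its promoter-state timeline.
- **Promoter chromatin**: each gene has a six-letter plan over
  {A, R, P, U}; the marks deposited per state are A → DHS+K4me3+K9ac+K27ac,
  P → DHS+K4me3+K27me3, R → K27me3, U → none, over TSS ± 1 kb.
- **Count tracks**: 200 bp bins; Poisson with background mean 1/bin and
  enriched mean 12/bin (deterministic variant: exact means).  The
  enriched mean is set so that Poisson binarization at p < 10⁻⁴ separates
  signal from background even on the DHS track, whose genome-wide mean is
  inflated to ~1.4 by the open regions themselves; with an enriched mean
  of 8 the tail probability of an enriched count lands marginally *above*
  the threshold (sf(7, 1.43) ≈ 1.2 × 10⁻⁴) and the DHS track binarizes to
  all zeros, so 12 was chosen to keep separation clean yet (under Poisson
  noise) imperfect.
- **TF ChIP**: peaks of 200 bp nested in DHS, with per-(TF, stage, code)
  binding fractions (binding to codes closed at that stage models
  enhancer priming), plus planted network-edge peaks at target TF loci
  and blood-regulator-locus peaks for the reprogramming analysis.  Two
  replicates per assay; replicates are the planted peaks, jittered ±j bp
  and dropped independently with the configured dropout probability.
- **Motifs**: 12-bp consensus motifs (E-box, GATA, ETS, TEAD, RUNX,
  C/EBP) as PWMs with 0.7 on the consensus base; instances embedded with
  per-position mutation probability 0.05, both strands, never
  overlapping another instance.  TEAD is additionally planted in 50% of
  HB-only DHS versus 5% elsewhere, and in 40% of Tal1/Lmo2 HB peaks.
- **Gene-set ChIP assay**: a separate peak set per (TF, stage) in which
  one expression cluster is bound at 90% of its genes and the background
  rate (5%) is applied *stratified within every cluster*.  Stratification
  makes the unplanted cells of the integration matrix sit at their null
  expectation instead of fluctuating, which is what a planted-null
  calibration requires.

What the generator does **not** emulate: read-level noise, GC and
mappability bias, fragment-size effects, peak-width variation, correlated
replicate structure, copy number, chromosome-scale heterogeneity in
background rate, overlapping genes, and realistic motif information
content (12-bp motifs with near-uniform background are cleaner than real
PWM libraries).  Passing tests therefore demonstrate correctness of the
algorithms and their statistical calibration under idealized conditions,
not performance on real sequencing data.

## Chromatin-state model

`binarize` calls a bin present when the upper-tail Poisson probability of
its count under the track-wide mean rate is < 10⁻⁴ (global background, no
local correction — simple and testable; a signal-rich track inflates the
global mean, which is the main source of imperfection).

`fit_hmm` is Baum–Welch EM for a K-state HMM whose emission for state k
is a product of M independent Bernoullis (one per mark).  Scaled
forward–backward recursions; the log-likelihood is asserted non-decreasing
per iteration, and forward and backward total likelihoods agree to 1e-8
relative (both tested).  Initialization anchors each state's emissions on
observation vectors sampled uniformly over the *distinct* vectors (60%
anchor + 30% empirical frequency + U(0, 0.2) jitter, clipped to
[0.05, 0.95]); sampling distinct vectors rather than random bins makes
rare states (poised) reachable even when > 95% of bins are background.
Three restarts by default, best final log-likelihood wins; states are
returned in emission-sorted canonical order so results are stable under
relabeling.  Emissions are clipped to [1e-6, 1−1e-6]; empty transition
rows (unvisited states) reset to uniform.  K defaults to 8 on fixtures:
the coarse-graining, not K, is what makes segmentations comparable.

Coarse-graining applies the four-state rule to emissions thresholded at
0.5 (HMM path) or to direct mark calls (rule path).  The rule order is
POISED before ACTIVE (accessibility + K27me3 + any active mark wins),
then REPRESSED, else UNMARKED; it is total over all 2⁵ mark combinations
(exhaustively tested).  Promoter timelines take the majority coarse label
over the bins covering TSS ± 1 kb; ties break POISED > ACTIVE >
REPRESSED > UNMARKED, preserving the rarer informative state.  Promoters
covering no bins get a `.` sentinel and a logged warning.

For the fixture-level HMM property test, training bins are the promoter
neighborhoods (TSS ± 2 kb) of all stages plus every 20th background bin.
Training genome-wide is possible but wasteful at desk scale: poised bins
are ~0.5% of the genome and EM can absorb them into background; the
promoter-enriched training set raises their frequency tenfold while
keeping the fit under a minute.

## Expression dynamics

Differential calling uses a transparent threshold rule: gene up at Tk iff
expr(k) ≥ floor and expr(k)/max(expr(k−1), floor) ≥ min_fc (defaults
min_fc = 2, floor = 1 FPKM); down symmetric.  The rule is invariant to
rescaling the matrix and the floor together.  Standardization is
z = (log₁₀(x + 0.01) − mean)/sd per gene (population sd); genes whose
log-profile is constant to within 1e-12 are excluded with a logged count
(the tolerance absorbs float residue of log-transforming a constant row).

Pattern discovery is k-means over z-profiles with k-means++ restarts
(default 20) and the lowest inertia kept; deterministic given the seed.
Greedy farthest-point (maximin) seeding was evaluated and rejected: after
the random first center the remaining centers are deterministic and
outlier-seeking, so every restart seeds the same noisy-gene singleton and
the fit sticks in a poor optimum; k-means++ restores restart diversity.
k is a free parameter (a real time course uses ~31 patterns; the fixture
plants 4 for testability).

Stage correlation computes Pearson r between a profile and each stage
column on the log₁₀(x + 0.01) scale and compares correlations with the
two-sided Fisher z-transform test, z = atanh(r), SE = √(2/(n−3)); equal
correlations return p = 1 exactly (this also covers r = 1 vs itself,
where atanh diverges).

## Overlap statistics

Regulatory domains tile each chromosome with boundaries at midpoints
between consecutive TSS; first/last domains extend to the chromosome
ends; lengths sum exactly to the chromosome length (tested).  A gene is a
peak target iff ≥ 1 peak midpoint falls in its domain.

`overlap_significance` draws null gene sets of equal size without
replacement with probability proportional to domain length, via the
exponential-key trick (the m smallest Exp(1)/wᵢ keys form a successive
weighted sample).  The add-one estimator p = (1 + #{null ≥ obs})/(R + 1)
never returns 0 and keeps strict thresholds meaningful; R defaults to
100,000 so the p < 10⁻⁴ regime is resolvable.  Because the statistic is
an integer count, the test is conservatively calibrated: ties at the
observed value push p upward, so the realized type-I error at α sits at
or below α by an amount that depends on the null lattice.  The
calibration test therefore averages over gene-set sizes (40–100) to mix
lattices; with equal-length domains the null reduces exactly to the
hypergeometric distribution (tested against the closed form).

The DHS-pattern × TF test uses a uniform-over-rows null on the union-DHS
universe — fixture DHS widths are near constant, so length weighting
would change nothing; the null overlap count is then exactly
hypergeometric and is drawn as such.  Patterns with population ≤ 100 are
skipped.  The integration matrix composes the gene-set test with the
H3K27ac bootstrap Z (equal-size site resamples with replacement;
degenerate null sd reports Z = 0 with a warning) and flags cells at
p < 10⁻⁴, strictly.

## Motif analysis

Scanning scores each window as Σ log₂(p_base/bg_base), both strands, N
scoring log₂(0.25/mean(bg)); a hit is a window at or above the motif
threshold, default 80% of the maximum attainable score (for the fixture's
12-bp, 0.7-consensus PWMs this tolerates one mutated position, giving
~88% recovery of embedded instances at a ~2% per-400-bp-window false
positive rate).  Regions are standardized to midpoint-centered 400 bp
windows before scanning so both sides of a comparison are length-matched,
and hits are counted per-region (presence/absence), making RE robust to
region length.

RE = (f_A + ε)/(f_B + ε) with ε = 1/(2·min(n_A, n_B)); RE(A,B)·RE(B,A) = 1
for equal set sizes by construction.  Significance and the 95% CI come
from resampling regions with replacement within each set; since hit
indicators are 0/1, the bootstrap of the mean is drawn as the equivalent
binomial.  p is the fraction of resamples with RE ≤ 1 (one-sided,
enrichment claims).  The stage-pair matrix holds log₂ RE of
distal-unique DHS for all 30 ordered pairs, optionally restricted to
motifs of TFs expressed in the focal stage (floor 1 FPKM); rows are
clustered by average linkage on Euclidean distance with missing cells
treated as 0 for distances only, and the scipy leaf order is
deterministic for a fixed input.  Cell-type-unique sets are the pairwise
differences (one row per ordered stage pair); callers wanting
one-vs-all-others can intersect the five pairwise sets.

## Gene regulatory networks

Edge rule: source TF has ChIP data at the stage and ≥ 1 reproducible peak
midpoint inside the target's locus window — gene span ± 50 kb, clipped at
the target's regulatory-domain boundary so a peak supports at most one
target.  The flank is the single most consequential free parameter and is
exposed; an optional strict mode additionally requires the peak to
overlap a stage-open DHS.  TFs without ChIP data at a stage contribute no
out-edges but remain as annotated nodes (expression, promoter DHS
presence, promoter coarse state).  Per-stage ChIP availability is an
explicit table, so a factor can be excluded at a stage where no data
exist.  Rewiring is reported as gained/lost/retained edge sets per
transition.  Reprogramming candidates are ranked by (earliest stage with
expression ≥ 1 FPKM, then more target-set loci bound at or before HE,
then TF name); factors never reaching the floor are excluded.

## Reproducibility filtering

`filter_reproducible` merges all replicate peaks into candidate regions
and keeps those in which ≥ 2 distinct replicates cover at least one
common base pair; the retained interval is the full merged extent.  With
two replicates this is an AND-rule: under independent per-replicate
dropout q the survival of a stage presence bit is (1−q)², which falls
quickly — at q = 0.1 only ~81% of single-stage calls survive, and the
expected fraction of union DHS with an exactly recovered six-digit code
is Σ_c w_c·0.81^ones(c) ≈ 0.65 at the default code mix.  This is a
structural property of 2-of-2 filtering, not an implementation artifact;
robust pattern recovery under dropout requires ≥ 3 replicates (2-of-3
survival 0.972 per bit) or a union-based presence rule.

## Problem sizes

The shipped tests and the acceptance script run the default fixture
(2 chromosomes × 5 Mb, 200 genes, 2,200 union DHS, two replicates), a
10,000-bin planted HMM, 500 calibration simulations at 1,000 resamples,
100,000 resamples for the planted-enrichment matrix, and 10,000-replicate
bootstraps for Z-scores and RE; a reduced fixture (2 × 1.2 Mb, 60 genes,
~460 DHS) backs the per-module unit tests.  The full suite completes in
about a minute on one CPU.
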