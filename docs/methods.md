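# Methods

## Generative model

`cspower` simulates a two-group bulk RNA-seq experiment whose samples are
mixtures of K cell types.

**Purified profiles.** For gene g, cell type k and group d, the log2-scale
purified signal is Gamma distributed, L ~ Gamma(shape, rate), and the
expression read-out is X = 2^L − 1. The log transform keeps the
heavy-tailed expression distribution in a two-parameter family whose shape
controls dispersion independently of the mean (mean = shape/rate on the
log2 scale). Fitting and simulation use the shape/rate parametrization on
log2(x + 1) throughout; this convention is fixed here and used consistently
by the simulator and the estimators.

**csDE truth.** A fraction of genes (default 5%) is flagged as
differentially expressed; each flagged gene is perturbed in exactly one
target cell type, drawn uniformly, with a signed log2-fold-change equal to
the scenario's effect size. The effect shifts the case-group log2-scale
mean by δ by rescaling the rate (rate′ = rate · m/(m + δ), m = shape/rate),
leaving the shape — and so the shape-controlled dispersion — untouched.
Down-regulating effects that would push the log2 mean to ≤ 0.1 are
re-assigned as up-regulation, so means stay positive. With effect size 0
the flagged genes carry no effect (a pure-null scenario usable for
false-positive calibration).

**Compositions and sequencing.** Per-sample proportions are Dirichlet
draws with per-group concentration vectors; the concentration sum controls
across-sample composition variability (scaling all alphas up provably
shrinks every component's variance). Bulk signal is mixed on the
*expression* scale — bulk = Σ_k p_k X_k — matching the physical
interpretation of bulk RNA as a weighted average of per-cell-type RNA.
Counts are Poisson draws of depth · bulk, with per-sample depth factors
LogNormal(log depth_mean, 0.15), a mild library-size spread.

The latent location retained for stratification, `cts_mean`, is
2^(shape/rate) − 1, the expression at the mean log2 signal. The exact
Gamma mean of 2^L diverges whenever rate ≤ ln 2, which estimated parameter
sets can produce; the plug-in location is noise-free, always finite and
monotone in the log2 mean, which is all stratification needs.

## Detection

Per gene, ordinary least squares of y = log2(CPM + 1) on the 2K-column
design [p_1..p_K, p_1 z..p_K z] without intercept; the t statistic of the
k-th interaction coefficient (df = N − 2K) tests csDE in cell type k, and
Benjamini–Hochberg runs within each cell type (metrics are reported per
cell type, so each cell type is its own testing family). CPM
normalization makes results exactly invariant to per-sample library
scaling. All genes share one design matrix, so the fits are computed in a
single batched pass. Genes with zero residual variance report p = 1; a
numerically singular design falls back to the pseudo-inverse with
rank-adjusted df and a logged warning. Detection conditions on the true
simulated proportions: composition-estimation error is a separate problem
and out of scope here.

## Metrics

- **Power**: among genes truly csDE in cell type k, the fraction with
  q < threshold (default 0.05) in k. Reported overall and per
  baseline-expression stratum; strata holding no true csDE gene report a
  missing value, never 0.
- **Strata**: nine left-closed right-open bins of the latent control-group
  bulk mean ([0,10), [10,20), [20,40), … [1280, ∞)). The latent mean
  (mean control composition × cts_mean × mean depth) is used rather than
  an observed average because it is noise-free in simulation.
- **TDR(j)**: fraction of the top-j genes (ascending p within cell type)
  truly csDE there; TDR = 1 − FDR at the same cutoff, exactly.
- **FDC**: false positives per true positive. At a q-threshold this equals
  FDR/(1−FDR) and — whenever the FDR is controlled — stays pinned near
  q/(1−q) regardless of effect size; at a fixed top-j cutoff it equals
  (1−TDR_j)/TDR_j and falls steeply as effects grow. Both are computed;
  the top-j variant is the one that expresses "cost per true discovery"
  for a biomarker hunter following up a fixed number of hits, and it is
  the variant whose effect-size trend the acceptance checks assert.
  Replicate-level FDC keeps +inf (TP = 0 < FP) and missing (nothing
  declared) sentinels; scenario summaries average the finite replicate
  values only, since weak-signal replicates with TP ∈ {0, 1} make the raw
  ratio unstable.

## Estimation from pilot data

Dirichlet parameters are fitted per group by the digamma fixed-point MLE
(method-of-moments start, tolerance 1e-8 on the alpha max-change, ≤1000
iterations), after clipping proportions to [1e-6, 1−1e-6] and
renormalizing. Gamma fitting for arbitrary positive samples uses Newton
iteration on log-shape of the profile likelihood (closed-form rate,
method-of-moments start, tolerance 1e-10, ≤200 iterations); by
construction its log-likelihood is never below the method-of-moments
start.

Recovering per-cell-type expression from bulk pilot data is
under-determined per sample, so estimation back-solves at the group level:
counts are normalized against the median library (depth_mean is then mean
library / median library, ≈ the mean depth factor), and per gene and group
a nonnegative least squares of normalized bulk on the group's proportion
rows yields purified means. Each cell type of that gene/group receives
the same log2-scale variance, equal to the NNLS residual variance on the
log2 scale (floored at 1e-3): the bulk residual cannot be attributed to
individual cell types, so it is assigned equally. Log2 means are floored
at 0.05 so Gamma parameters stay positive. Genes with zero count variance
are dropped with a logged count — they carry no information and break the
MLE. Median-library normalization (rather than per-million) keeps the
estimated parameters on the original count scale, so simulate → estimate →
simulate round-trips preserve per-gene means.

## Packaged parameter sets

The shipped sets (`threecell_default` G=10000/K=3, `fivecell_default`
G=10000/K=5, `null_only` G=2000/K=3) are synthetic, rebuilt
deterministically from fixed seeds at load time. They emulate a sequencing
experiment on pure cell lines — the setting in which csDE power analysis
is typically calibrated — with these choices:

- gene-level log2 baselines uniform on [0.4, 11.5], spreading latent bulk
  means from fractions of a count to several thousand so all nine
  expression strata are populated;
- per-cell-type means jittered around the gene baseline (log2 sd 0.25,
  i.e. cell types differing by up to ~40% for most genes);
- log2-scale Gamma variances uniform on [0.0005, 0.006] — an
  expression-scale replicate CV of roughly 2–6%, the reproducibility of
  isogenic cell lines sequenced in one batch. Counting noise then
  dominates at low expression, which is what produces the low-stratum
  power deficit;
- Dirichlet concentrations of 30 with mean compositions 0.15/0.30/0.55
  (three-cell) — moderately variable mixtures. This sits deliberately
  between two failure modes: much higher concentration removes the
  composition spread the interaction design needs for power, while much
  lower concentration makes the per-sample mixture variance (∝ Σ_k p_k²)
  vary so strongly across samples that the homoscedastic OLS t test
  becomes structurally anticonservative;
- depth_mean 1.0 (counts are on the latent expression scale); case
  parameters equal control parameters — effects are injected from the DE
  truth at simulation time.

Under these defaults the reference scenario (n = 50/group, log2FC 0.5)
has moderate overall power (~0.25) with a strong abundance gradient, the
10→20 sample-size gain exceeds the 40→50 gain, pooled null p-values are
KS-uniform, and the BH q < 0.05 rule controls the per-cell-type FDR —
the qualitative regime a usable design tool must expose.

What the generator does **not** emulate: UMI/zero-inflation, batch
effects, more than two phenotype groups, gene–gene correlation beyond the
shared composition/depth draws, composition-estimation error (true
proportions are handed to the detector), and the larger biological
dispersion of patient-derived tissue. Passing checks on these synthetic
conditions therefore demonstrate the machinery and its statistical
behaviour in a favourable, cell-line-like regime; absolute power numbers
for tissue studies require re-estimated parameters from pilot data.

## Workbench

A grid run crosses sample sizes (default 10/20/50 per group) with effect
sizes (default 0/0.25/0.5/0.75/1.0; the null point is always included so
every run carries its own calibration scenario), simulating n_sims
replicates per cell (default 30) at n_genes (default 10000). Replicate
seeds derive as seed + 1000·scenario_index + replicate, giving
reproducible independent streams without global state; every stochastic
operation takes an explicit seed. A failing scenario is logged, recorded
in the run manifest and skipped, never destroying completed scenarios.
The manifest (config echo, per-replicate seeds, version, wall times)
suffices to reproduce any row of the metrics table.

`quick_power` serves packaged pre-evaluated tables: `threecell_default`
(the full default grid on the packaged three-cell set, averaged over
replicates at package-build time) and `demo_small` (a tiny
replicate-level grid whose exact equality with a fresh run is asserted in
the test suite).

## Numerical and testing notes

- Digamma inversion (Dirichlet fixed point) uses Minka-style
  initialization plus eight Newton steps; the returned alpha satisfies the
  per-observation score equations to < 1e-6 in max-norm.
- BH adjustment is the standard step-up with cumulative-minimum
  monotonicity; the test suite cross-checks it against an independent
  implementation and a hand-worked example.
- The batched OLS is cross-checked gene-by-gene against statsmodels.
- Statistical acceptance checks run at desk scale (G = 2000–5000, 30
  replicates per scenario), chosen so the whole suite completes in a few
  minutes on one CPU while leaving Monte-Carlo margins wide relative to
  the asserted orderings. Dataset-internal quantities are never tested
  with independence assumptions they do not satisfy: genes within one
  dataset share composition and depth draws, so symmetry and calibration
  claims are asserted across replicates or with replicate-level units.
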