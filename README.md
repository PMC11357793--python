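# cspower

**Experimental design and statistical power assessment for cell-type-specific
differential expression (csDE) analysis of bulk RNA-seq.**

Clinical bulk RNA-seq samples are mixtures of cell types: the observed
expression of each gene is a composition-weighted average of unobserved
purified cell-type-specific (CTS) profiles. Deconvolution-aware methods can
test, per cell type, whether a gene is differentially expressed between two
phenotype groups — but the sensitivity of such csDE testing depends jointly
on sample size, effect size, cell-type abundance, expression level,
sequencing depth and biological dispersion, so classical sample-size
formulas do not apply. `cspower` answers the design question by simulation:
it generates realistic cell-type-mixed two-group count data with known csDE
truth, runs a csDE detector on it, and reports power and error metrics over
grids of sample size and effect size.

## Model

For gene *g*, cell type *k* and group *d* ∈ {control, case}, the purified
log-scale signal and the observed counts follow a Gamma–Dirichlet–Poisson
hierarchy:

- **CTS profiles** — L<sub>gki</sub> ~ Gamma(α<sub>gkd</sub>, β<sub>gkd</sub>)
  on the log2(expression + 1) scale; expression X<sub>gki</sub> = 2^L − 1.
  The Gamma law captures biological variation across replicates.
- **csDE truth** — a configurable fraction of genes is differentially
  expressed, each in **exactly one** target cell type, with a signed
  log2-fold-change effect δ applied to the case-group log2-scale mean
  (rate rescaled, shape — hence dispersion — unchanged).
- **Compositions** — sample proportions p<sub>i·</sub> ~ Dirichlet(a<sub>d</sub>);
  the concentration Σ<sub>k</sub> a<sub>kd</sub> controls across-sample
  composition variability.
- **Sequencing** — counts Y<sub>gi</sub> ~ Poisson(s<sub>i</sub> ·
  Σ<sub>k</sub> p<sub>ik</sub> X<sub>gki</sub>) with a log-normal per-sample
  depth factor s<sub>i</sub>.

Detection fits, per gene, the interaction linear model

  y<sub>i</sub> = Σ<sub>k</sub> p<sub>ik</sub> β<sub>k</sub> +
  Σ<sub>k</sub> p<sub>ik</sub> z<sub>i</sub> γ<sub>k</sub> + ε<sub>i</sub>,

with y = log2(CPM + 1) and z the phenotype indicator; the t-statistic of
γ<sub>k</sub> tests csDE in cell type k, with Benjamini–Hochberg adjustment
within each cell type. Evaluation reports, per cell type (and per
baseline-expression stratum):

- **power** — fraction of true csDE genes declared (q < 0.05) in their
  target cell type;
- **TDR(j)** — true discovery rate among the top-j ranked genes
  (TDR = 1 − FDR);
- **FDC** — false discovery cost, false positives per true positive
  (FDR/(1−FDR) at a q-threshold; (1−TDR)/TDR at a top-j cutoff).

## Worked example

```python
import cspower as cp

params = cp.load_packaged_params("threecell_default")   # G=10000, K=3
scenario = cp.ScenarioConfig(n_per_group=50, effect_size=0.5,
                             n_genes=2000, seed=1)
ds = cp.simulate_dataset(params, scenario)              # counts + truth
res = cp.detect_csde(ds.counts, ds.proportions, ds.group)

print(cp.compute_power(res, ds.truth).query("stratum == 'all'"))
print(cp.compute_tdr(res, ds.truth, top_j=[100]))
print(cp.compute_fdc_topj(res, ds.truth, top_j=[100]))
```

Output (mean control compositions of the three cell types are
0.15 / 0.30 / 0.55):

```
   celltype stratum     power
0         0     all  0.000000
1         1     all  0.285714
2         2     all  0.424242

   celltype  top_j   tdr
0         0    100  0.09
1         1    100  0.17
2         2    100  0.18

   celltype  top_j        fdc
0         0    100  10.111111
1         1    100   4.882353
2         2    100   4.555556
```

At n = 50/group and a log2-fold-change of 0.5, 42% of the genes truly
perturbed in the most abundant cell type are recovered, against 0% in the
rarest — power tracks abundance. Following up the top 100 ranked genes in
the abundant cell type costs ~4.6 false positives per true positive at this
effect size; larger effects drive that cost down sharply.

Grid-level orchestration, with one YAML config and TSV/plot outputs:

```sh
cspower power-grid --config grid.yaml --seed 1 --out results/ --plots
cspower quick-power threecell_default        # packaged pre-evaluated table
cspower simulate --params packaged:threecell_default \
    --n-per-group 50 --effect-size 0.5 --out sim/
cspower estimate --counts counts.tsv --proportions props.tsv \
    --groups groups.tsv --out paramset.json   # pilot-data estimation
```

With pilot data, `estimate` fits the Gamma/Dirichlet parameters from your
own counts and proportions (`simulate`/`power-grid` then accept
`--params paramset:<file>`); without pilot data, the packaged synthetic
parameter sets (`threecell_default`, `fivecell_default`, `null_only`) or the
pre-evaluated `quick-power` tables stand in.

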