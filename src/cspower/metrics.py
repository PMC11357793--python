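"""Evaluation metrics for csDE power analysis: power, TDR and FDC.

Per cell type k, over the genes truly csDE in k:

* power = fraction declared significant (q < threshold) in k;
* TDR(j) = fraction of the top-j genes (ascending p in k) truly csDE in k,
  the complement of the FDR at the same cutoff (TDR = 1 - FDR);
* FDC = false positives per true positive among declared genes,
  algebraically FDR / (1 - FDR).

Power can additionally be decomposed over nine baseline-expression strata
([0,10), [10,20), [20,40), ..., [1280, inf)); the baseline is the latent
control-group bulk mean, which is noise-free in simulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .csde import DEFAULT_Q_THRESHOLD, CsDEResult
from .errors import InvalidInputError
from .params import DirichletParams
from .simulator import DETruth, SimulatedDataset

DEFAULT_CUTPOINTS = (0.0, 10.0, 20.0, 40.0, 80.0, 160.0, 320.0, 640.0, 1280.0)
DEFAULT_TOP_J = tuple(range(100, 1001, 100))


@dataclass(frozen=True)
class StrataSpec:
    """Ascending cutpoints defining left-closed right-open expression bins;
    the last bin is unbounded above."""

    cutpoints: tuple = DEFAULT_CUTPOINTS

    def __post_init__(self):
        cp = tuple(float(c) for c in self.cutpoints)
        if len(cp) < 2 or cp[0] != 0.0 or any(b <= a for a, b in zip(cp, cp[1:])):
            raise InvalidInputError(
                "cutpoints must be strictly ascending and start at 0"
            )
        object.__setattr__(self, "cutpoints", cp)

    @property
    def n_strata(self) -> int:
        return len(self.cutpoints)


def stratify_genes(baseline_mean, spec: StrataSpec = StrataSpec()) -> np.ndarray:
    """Map each gene's baseline expression to a 1-based stratum index."""
    x = np.asarray(baseline_mean, dtype=float)
    if np.any(~np.isfinite(x)) or np.any(x < 0):
        raise InvalidInputError("baseline means must be finite and >= 0")
    return np.digitize(x, spec.cutpoints[1:], right=False) + 1


def baseline_bulk_mean(dataset: SimulatedDataset) -> np.ndarray:
    """Latent control-group bulk mean per gene.

    Mean control composition (empirical, converging to the Dirichlet mean)
    weighted over the latent purified locations, scaled by the mean depth.
    """
    ctrl = dataset.group == 0
    pbar = dataset.proportions[ctrl].mean(axis=0)
    return dataset.cts_mean[:, :, 0] @ pbar * float(dataset.depth[ctrl].mean())


def _check_pair(result: CsDEResult, truth: DETruth):
    if result.n_genes != truth.n_genes:
        raise InvalidInputError(
            f"result has {result.n_genes} genes, truth {truth.n_genes}"
        )


def _true_in_k(truth: DETruth, k: int) -> np.ndarray:
    return truth.is_de & (truth.lfc != 0) & (truth.target_celltype == k)


def compute_power(result: CsDEResult, truth: DETruth,
                  q_threshold: float = DEFAULT_Q_THRESHOLD,
                  strata: np.ndarray | None = None) -> pd.DataFrame:
    """Per-cell-type (optionally per-stratum) statistical power.

    Returns a DataFrame with columns celltype, stratum ("all" or 1..S) and
    power; strata holding no true csDE gene report NaN (missing), not 0.
    """
    if not 0.0 < q_threshold < 1.0:
        raise InvalidInputError("q_threshold must lie in (0, 1)")
    _check_pair(result, truth)
    declared = result.qvalue < q_threshold
    rows = []
    for k in range(result.n_celltypes):
        true_k = _true_in_k(truth, k)
        groups = {"all": np.ones(result.n_genes, dtype=bool)}
        if strata is not None:
            for s in np.unique(strata):
                groups[int(s)] = strata == s
        for label, mask in groups.items():
            denom = int((true_k & mask).sum())
            value = (
                float((true_k & mask & declared[:, k]).sum() / denom)
                if denom else np.nan
            )
            rows.append({"celltype": k, "stratum": label, "power": value})
    return pd.DataFrame(rows)


def compute_tdr(result: CsDEResult, truth: DETruth,
                top_j=DEFAULT_TOP_J) -> pd.DataFrame:
    """True discovery rate at top-j cutoffs of the per-cell-type p ranking."""
    _check_pair(result, truth)
    top_j = [int(j) for j in np.atleast_1d(top_j)]
    if any(j < 1 or j > result.n_genes for j in top_j):
        raise InvalidInputError(
            f"top-j cutoffs must lie in [1, G={result.n_genes}]"
        )
    rows = []
    for k in range(result.n_celltypes):
        hits = np.cumsum(_true_in_k(truth, k)[result.rank[:, k]])
        for j in top_j:
            rows.append({"celltype": k, "top_j": j, "tdr": float(hits[j - 1] / j)})
    return pd.DataFrame(rows)


def confusion_by_celltype(result: CsDEResult, truth: DETruth,
                          q_threshold: float = DEFAULT_Q_THRESHOLD) -> pd.DataFrame:
    """TP/FP counts of the q < threshold rule per cell type."""
    if not 0.0 < q_threshold < 1.0:
        raise InvalidInputError("q_threshold must lie in (0, 1)")
    _check_pair(result, truth)
    declared = result.qvalue < q_threshold
    rows = []
    for k in range(result.n_celltypes):
        true_k = _true_in_k(truth, k)
        rows.append({
            "celltype": k,
            "tp": int((declared[:, k] & true_k).sum()),
            "fp": int((declared[:, k] & ~true_k).sum()),
        })
    return pd.DataFrame(rows)


def _ratio_fdc(tp: int, fp: int) -> float:
    if tp == 0 and fp == 0:
        return np.nan  # nothing declared: FDC undefined (missing, not 0)
    if tp == 0:
        return np.inf
    return fp / tp


def compute_fdc(result: CsDEResult, truth: DETruth,
                q_threshold: float = DEFAULT_Q_THRESHOLD) -> pd.DataFrame:
    """False discovery cost FP/TP per cell type (inf if TP=0<FP; NaN if
    nothing is declared)."""
    tab = confusion_by_celltype(result, truth, q_threshold)
    tab["fdc"] = [_ratio_fdc(tp, fp) for tp, fp in zip(tab.tp, tab.fp)]
    return tab[["celltype", "fdc"]]


def compute_fdc_topj(result: CsDEResult, truth: DETruth,
                     top_j=DEFAULT_TOP_J) -> pd.DataFrame:
    """False discovery cost of following up the top-j ranked genes.

    At a fixed ranking cutoff j the declared set is the top j genes by
    ascending p-value in cell type k, so FDC = (j - TP_j) / TP_j =
    (1 - TDR_j) / TDR_j.  Unlike the adaptive q-threshold rule — whose FDC
    stays near q/(1-q) whenever the FDR is controlled — this cost drops
    steeply as the effect size grows, reflecting what a biomarker hunter
    following up a fixed number of hits actually pays per true discovery.
    """
    tdr = compute_tdr(result, truth, top_j)
    fdc = np.where(tdr.tdr > 0, (1.0 - tdr.tdr) / tdr.tdr.replace(0, 1), np.inf)
    out = tdr[["celltype", "top_j"]].copy()
    out["fdc"] = fdc
    return out


def compute_fdr(result: CsDEResult, truth: DETruth,
                q_threshold: float = DEFAULT_Q_THRESHOLD) -> pd.DataFrame:
    """Empirical FDR FP/(TP+FP) per cell type (NaN if nothing declared)."""
    tab = confusion_by_celltype(result, truth, q_threshold)
    denom = tab.tp + tab.fp
    tab["fdr"] = np.where(denom > 0, tab.fp / denom.replace(0, 1), np.nan)
    return tab[["celltype", "fdr"]]


def abundance_power_association(power_by_celltype, dirichlet: DirichletParams,
                                group: int = 0) -> float:
    """Spearman correlation between Dirichlet mean abundance and power.

    Requires K >= 3 (the correlation is degenerate below that); returns NaN
    when either vector has zero variance.
    """
    power = np.asarray(power_by_celltype, dtype=float)
    if dirichlet.n_celltypes < 3 or power.shape[0] != dirichlet.n_celltypes:
        raise InvalidInputError("need power values for K >= 3 cell types")
    means = dirichlet.mean[:, group]
    if np.allclose(power, power[0]) or np.allclose(means, means[0]):
        return float("nan")
    rho = spearmanr(means, power).statistic
    return float(rho)


# ---------------------------------------------------------------------------
# dataset-level evaluation (used by the workbench grid)
# ---------------------------------------------------------------------------

def evaluate_dataset(dataset: SimulatedDataset, result: CsDEResult, *,
                     q_threshold: float = DEFAULT_Q_THRESHOLD,
                     top_j=DEFAULT_TOP_J,
                     strata_spec: StrataSpec = StrataSpec()) -> pd.DataFrame:
    """All metrics for one simulated dataset, in tidy long format.

    Columns: celltype, stratum, metric, cutoff, value.  Top-j cutoffs
    larger than G are dropped.
    """
    strata = stratify_genes(baseline_bulk_mean(dataset), strata_spec)
    rows = []
    power = compute_power(result, dataset.truth, q_threshold, strata=strata)
    for rec in power.itertuples(index=False):
        rows.append((rec.celltype, str(rec.stratum), "power",
                     f"q<{q_threshold:g}", rec.power))
    fdr = compute_fdr(result, dataset.truth, q_threshold)
    for rec in fdr.itertuples(index=False):
        rows.append((rec.celltype, "all", "fdr", f"q<{q_threshold:g}", rec.fdr))
    fdc = compute_fdc(result, dataset.truth, q_threshold)
    for rec in fdc.itertuples(index=False):
        rows.append((rec.celltype, "all", "fdc", f"q<{q_threshold:g}", rec.fdc))
    top_j = [j for j in np.atleast_1d(top_j) if j <= dataset.n_genes]
    if top_j:
        tdr = compute_tdr(result, dataset.truth, top_j)
        for rec in tdr.itertuples(index=False):
            rows.append((rec.celltype, "all", "tdr", f"top{rec.top_j}", rec.tdr))
        fdc_j = compute_fdc_topj(result, dataset.truth, top_j)
        for rec in fdc_j.itertuples(index=False):
            rows.append((rec.celltype, "all", "fdc", f"top{rec.top_j}", rec.fdc))
    return pd.DataFrame(rows, columns=["celltype", "stratum", "metric",
                                       "cutoff", "value"])


# ---------------------------------------------------------------------------
# plotting conveniences (numeric tables are the contract; plots mirror the
# standard power-analysis panels)
# ---------------------------------------------------------------------------

def _agg(table: pd.DataFrame) -> pd.DataFrame:
    clean = table.replace([np.inf, -np.inf], np.nan)
    keys = [c for c in ("scenario", "n_per_group", "effect_size", "celltype",
                        "stratum", "metric", "cutoff") if c in clean.columns]
    return clean.groupby(keys, dropna=False)["value"].mean().reset_index()


def plot_power_vs_effect(table: pd.DataFrame, path) -> None:
    """Mean power (over cell types/reps) against effect size, per n."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    agg = _agg(table.query("metric == 'power' and stratum == 'all'"))
    fig, ax = plt.subplots(figsize=(5, 4))
    for n, sub in agg.groupby("n_per_group"):
        curve = sub.groupby("effect_size")["value"].mean()
        ax.plot(curve.index, curve.values, marker="o", label=f"n={n}/group")
    ax.set_xlabel("effect size (log2 fold change)")
    ax.set_ylabel("power")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_fdc_vs_effect(table: pd.DataFrame, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fdc = table.query("metric == 'fdc'")
    topj = fdc[fdc.cutoff.str.startswith("top")]
    agg = _agg(topj if len(topj) else fdc)
    fig, ax = plt.subplots(figsize=(5, 4))
    for n, sub in agg.groupby("n_per_group"):
        curve = sub[sub.effect_size > 0].groupby("effect_size")["value"].mean()
        ax.plot(curve.index, curve.values, marker="o", label=f"n={n}/group")
    ax.set_xlabel("effect size (log2 fold change)")
    ax.set_ylabel("false discovery cost (FP per TP)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_tdr_curve(table: pd.DataFrame, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    agg = _agg(table.query("metric == 'tdr'"))
    agg["top_j"] = agg["cutoff"].str.removeprefix("top").astype(int)
    fig, ax = plt.subplots(figsize=(5, 4))
    for (n, es), sub in agg.groupby(["n_per_group", "effect_size"]):
        if es <= 0:
            continue
        curve = sub.groupby("top_j")["value"].mean()
        ax.plot(curve.index, curve.values, marker=".", label=f"n={n}, lfc={es}")
    ax.set_xlabel("top-ranked genes")
    ax.set_ylabel("true discovery rate")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_power_by_stratum(table: pd.DataFrame, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    agg = _agg(table.query("metric == 'power' and stratum != 'all'"))
    agg["stratum"] = agg["stratum"].astype(int)
    fig, ax = plt.subplots(figsize=(5, 4))
    curve = agg.groupby("stratum")["value"].mean()
    ax.bar(curve.index, curve.values)
    ax.set_xlabel("expression stratum (low to high)")
    ax.set_ylabel("power")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
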