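"""Two-group cell-type-mixed bulk RNA-seq count simulator.

Pipeline, per dataset: assign a cell-type-specific differential expression
(csDE) truth (each DE gene affects exactly one cell type), draw per-sample
cell-type compositions from the per-group Dirichlet law, draw purified
log2-scale cell-type-specific (CTS) profiles from the per-(gene, cell type,
group) Gamma law — shifting the case-group log2 mean by the signed
log2-fold-change for DE genes in their target cell type — mix profiles on
the expression scale with the composition weights and a per-sample depth
factor, and read counts out through a Poisson layer for technical noise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numpy.random import SeedSequence, default_rng

from .errors import InvalidInputError
from .params import DirichletParams, GammaProfileParams, ParamSet

#: genes whose control log2 mean would be pushed to <= this floor by a
#: down-regulating effect are re-assigned an up effect instead.
LOG_MEAN_FLOOR = 0.1

_GROUP_INDEX = {"control": 0, "case": 1, 0: 0, 1: 1}


def _group_index(group) -> int:
    try:
        return _GROUP_INDEX[group]
    except (KeyError, TypeError):
        raise InvalidInputError(
            f"group must be 'control'/'case' or 0/1, got {group!r}"
        ) from None


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DETruth:
    """Ground-truth csDE assignment.

    ``is_de[g]`` flags DE genes; each DE gene has exactly one
    ``target_celltype`` (index, -1 for non-DE) and a signed log2-fold-change
    ``lfc`` (0 for non-DE genes, and for all genes in a null scenario with
    effect size 0).
    """

    is_de: np.ndarray
    target_celltype: np.ndarray
    lfc: np.ndarray

    def __post_init__(self):
        is_de = np.asarray(self.is_de, dtype=bool)
        target = np.asarray(self.target_celltype, dtype=int)
        lfc = np.asarray(self.lfc, dtype=float)
        if not (is_de.shape == target.shape == lfc.shape) or is_de.ndim != 1:
            raise InvalidInputError("truth arrays must be 1-D and congruent")
        if np.any(target[~is_de] != -1) or np.any(lfc[~is_de] != 0):
            raise InvalidInputError(
                "non-DE genes must have target -1 and lfc 0"
            )
        if np.any(target[is_de] < 0):
            raise InvalidInputError("every DE gene needs a target cell type")
        object.__setattr__(self, "is_de", is_de)
        object.__setattr__(self, "target_celltype", target)
        object.__setattr__(self, "lfc", lfc)

    @property
    def n_genes(self) -> int:
        return self.is_de.shape[0]


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation scenario (a cell of the design grid)."""

    n_per_group: int
    effect_size: float
    n_genes: int
    de_fraction: float = 0.05
    seed: int = 0
    depth_mean: float = 1.0

    def __post_init__(self):
        if self.n_per_group < 1 or self.n_genes < 1:
            raise InvalidInputError("n_per_group and n_genes must be >= 1")
        if not 0.0 < self.de_fraction < 1.0:
            raise InvalidInputError("de_fraction must lie strictly in (0, 1)")
        if self.effect_size < 0:
            raise InvalidInputError("effect_size must be >= 0")
        if self.depth_mean <= 0:
            raise InvalidInputError("depth_mean must be > 0")


@dataclass(frozen=True)
class SimulatedDataset:
    """A simulated two-group bulk dataset with embedded truth.

    ``counts`` is genes x samples; ``proportions`` samples x cell types;
    ``group`` 0 (control) / 1 (case); ``depth`` per-sample scaling factors;
    ``cts_mean[g, k, d]`` the latent purified expression location
    ``2**(shape/rate) - 1`` (case column includes the injected effect),
    retained for noise-free expression stratification.
    """

    counts: np.ndarray
    proportions: np.ndarray
    group: np.ndarray
    depth: np.ndarray
    truth: DETruth
    cts_mean: np.ndarray
    gene_ids: tuple = ()
    celltype_ids: tuple = ()

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def n_celltypes(self) -> int:
        return self.proportions.shape[1]


# ---------------------------------------------------------------------------
# sampling operations
# ---------------------------------------------------------------------------

def assign_de_truth(n_genes: int, n_celltypes: int, de_fraction: float,
                    effect_size: float, seed: int) -> DETruth:
    """Flag round(G * de_fraction) genes as csDE.

    Target cell types are uniform over 1..K; the log2-fold-change equals
    ``effect_size`` with an equiprobable sign.  Deterministic given seed.
    """
    if n_genes < 1 or n_celltypes < 2:
        raise InvalidInputError("need n_genes >= 1 and n_celltypes >= 2")
    if not 0.0 < de_fraction < 1.0:
        raise InvalidInputError("de_fraction must lie strictly in (0, 1)")
    if effect_size < 0:
        raise InvalidInputError("effect_size must be >= 0")
    rng = default_rng(seed)
    n_de = int(round(n_genes * de_fraction))
    idx = rng.choice(n_genes, size=n_de, replace=False)
    is_de = np.zeros(n_genes, dtype=bool)
    is_de[idx] = True
    target = np.full(n_genes, -1, dtype=int)
    target[idx] = rng.integers(0, n_celltypes, size=n_de)
    lfc = np.zeros(n_genes)
    lfc[idx] = effect_size * rng.choice([-1.0, 1.0], size=n_de)
    return DETruth(is_de=is_de, target_celltype=target, lfc=lfc)


def enforce_sign_floor(truth: DETruth, gamma: GammaProfileParams,
                       floor: float = LOG_MEAN_FLOOR) -> DETruth:
    """Re-assign down effects that would push the log2 mean to <= floor."""
    lfc = truth.lfc.copy()
    de = np.flatnonzero(truth.is_de & (lfc < 0))
    if de.size:
        k = truth.target_celltype[de]
        m = gamma.log_mean[de, k, 0]
        flip = m + lfc[de] <= floor
        lfc[de[flip]] = -lfc[de[flip]]
    return replace(truth, lfc=lfc)


def sample_proportions(dirichlet: DirichletParams, n: int, group,
                       seed: int) -> np.ndarray:
    """Draw n composition rows from the given group's Dirichlet law."""
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    d = _group_index(group)
    rng = default_rng(seed)
    return rng.dirichlet(dirichlet.alpha[:, d], size=n)


def shifted_gamma_params(gamma: GammaProfileParams, truth: DETruth, group):
    """Gamma (shape, rate) for one group with the DE effect injected.

    For a case-group DE gene g targeting cell type k*, the log2-scale mean
    m = shape/rate moves to m + lfc by rescaling the rate (shape, hence the
    shape-controlled dispersion, is unchanged): rate' = rate * m/(m + lfc).
    """
    d = _group_index(group)
    shape = gamma.shape[:, :, d].copy()
    rate = gamma.rate[:, :, d].copy()
    if d == 1:
        de = np.flatnonzero(truth.is_de & (truth.lfc != 0))
        if de.size:
            k = truth.target_celltype[de]
            m = shape[de, k] / rate[de, k]
            m_new = np.maximum(m + truth.lfc[de], LOG_MEAN_FLOOR / 2.0)
            rate[de, k] = rate[de, k] * m / m_new
    return shape, rate


def sample_cts_profiles(gamma: GammaProfileParams, truth: DETruth, group,
                        n: int, seed: int) -> np.ndarray:
    """Draw purified CTS expression, shape (G, K, n).

    Log2-scale signals L are Gamma draws (case group includes the DE
    shift); the returned expression is 2**L - 1 (nonnegative since L >= 0).
    """
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    if truth.n_genes != gamma.n_genes:
        raise InvalidInputError("truth and gamma disagree on G")
    shape, rate = shifted_gamma_params(gamma, truth, group)
    rng = default_rng(seed)
    log_expr = rng.gamma(shape[:, :, None], 1.0 / rate[:, :, None],
                         size=(gamma.n_genes, gamma.n_celltypes, n))
    return np.exp2(log_expr) - 1.0


def convolve_and_count(cts: np.ndarray, proportions: np.ndarray,
                       depth: np.ndarray, seed: int) -> np.ndarray:
    """Mix CTS expression and read out Poisson counts.

    lambda[g, i] = depth[i] * sum_k proportions[i, k] * cts[g, k, i];
    counts[g, i] ~ Poisson(lambda[g, i]).
    """
    cts = np.asarray(cts, dtype=float)
    proportions = np.asarray(proportions, dtype=float)
    depth = np.asarray(depth, dtype=float)
    if cts.ndim != 3:
        raise InvalidInputError("cts must be (G, K, n)")
    G, K, n = cts.shape
    if proportions.shape != (n, K) or depth.shape != (n,):
        raise InvalidInputError(
            f"dimension mismatch: cts {cts.shape}, proportions "
            f"{proportions.shape}, depth {depth.shape}"
        )
    if np.any(cts < 0):
        raise InvalidInputError("cts expression must be nonnegative (floor upstream)")
    if np.any(depth <= 0):
        raise InvalidInputError("depth factors must be > 0")
    lam = depth[None, :] * np.einsum("gki,ik->gi", cts, proportions)
    rng = default_rng(seed)
    return rng.poisson(lam)


def cts_mean_array(gamma: GammaProfileParams, truth: DETruth) -> np.ndarray:
    """Latent purified expression locations 2**(shape/rate) - 1, (G, K, 2)."""
    out = np.empty((gamma.n_genes, gamma.n_celltypes, 2))
    for d in (0, 1):
        shape, rate = shifted_gamma_params(gamma, truth, d)
        out[:, :, d] = np.exp2(shape / rate) - 1.0
    return out


def _child_seeds(seed: int, n: int) -> list:
    state = SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s) & 0x7FFFFFFF for s in state]


def simulate_dataset(params: ParamSet, scenario: ScenarioConfig) -> SimulatedDataset:
    """Run the full generative pipeline for one scenario.

    Composes :func:`assign_de_truth` (with the down-regulation sign floor)
    -> :func:`sample_proportions` per group -> :func:`sample_cts_profiles`
    per group -> depth sampling -> :func:`convolve_and_count`.  Fully
    reproducible from ``(params, scenario.seed)``.
    """
    if params.n_genes < scenario.n_genes:
        raise InvalidInputError(
            f"parameter set has {params.n_genes} genes, scenario wants "
            f"{scenario.n_genes}"
        )
    if params.n_genes > scenario.n_genes:
        # deterministic head subset keeps gene identity stable across scenarios
        gamma = GammaProfileParams(
            shape=params.gamma.shape[: scenario.n_genes],
            rate=params.gamma.rate[: scenario.n_genes],
        )
        gene_ids = params.gene_ids[: scenario.n_genes]
    else:
        gamma = params.gamma
        gene_ids = params.gene_ids

    (s_truth, s_prop0, s_prop1, s_cts0, s_cts1, s_depth,
     s_pois) = _child_seeds(scenario.seed, 7)
    n = scenario.n_per_group
    truth = assign_de_truth(scenario.n_genes, params.n_celltypes,
                            scenario.de_fraction, scenario.effect_size, s_truth)
    truth = enforce_sign_floor(truth, gamma)

    prop = np.vstack([
        sample_proportions(params.dirichlet, n, "control", s_prop0),
        sample_proportions(params.dirichlet, n, "case", s_prop1),
    ])
    group = np.repeat([0, 1], n)
    depth = default_rng(s_depth).lognormal(np.log(scenario.depth_mean), 0.15,
                                           size=2 * n)
    cts = np.concatenate([
        sample_cts_profiles(gamma, truth, "control", n, s_cts0),
        sample_cts_profiles(gamma, truth, "case", n, s_cts1),
    ], axis=2)
    counts = convolve_and_count(cts, prop, depth, s_pois)
    return SimulatedDataset(
        counts=counts, proportions=prop, group=group, depth=depth,
        truth=truth, cts_mean=cts_mean_array(gamma, truth),
        gene_ids=gene_ids, celltype_ids=params.celltype_ids,
    )
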