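"""Distributional parameters of the cell-type-mixed bulk RNA-seq model.

The generative model behind this package factorises a two-group bulk
RNA-seq experiment into three layers:

* purified cell-type-specific (CTS) expression — for gene ``g``, cell type
  ``k`` and phenotype group ``d`` the log2-scale signal ``L ~ Gamma(shape,
  rate)`` and the expression read-out is ``2**L - 1``;
* cell-type composition — each sample's proportion vector is drawn from a
  per-group Dirichlet law whose concentration (sum of alphas) controls
  across-sample composition variability;
* sequencing — the proportion-weighted mixture of CTS expression, scaled by
  a per-sample depth factor, is read out through a Poisson layer
  (:mod:`cspower.simulator`).

This module holds the parameter containers (:class:`GammaProfileParams`,
:class:`DirichletParams`, :class:`ParamSet`), maximum-likelihood estimators
for both laws, pilot-data estimation (:func:`estimate_from_pilot`) and the
packaged synthetic parameter sets (:func:`load_packaged_params`).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from numpy.random import default_rng
from scipy.optimize import nnls
from scipy.special import gammaln, polygamma, psi

from .errors import InvalidInputError, UnknownResourceError

logger = logging.getLogger(__name__)

GROUP_LABELS = ("control", "case")
PARAMSET_VERSION = 1

#: proportions are clipped into [EPS, 1-EPS] and renormalized before the
#: Dirichlet fit; exact 0/1 entries have -inf log-density.
PROPORTION_EPS = 1e-6


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GammaProfileParams:
    """Per-(gene, cell type, group) Gamma law of log2(expression + 1).

    Arrays have shape ``(G, K, 2)``; group axis order is
    ``("control", "case")``.
    """

    shape: np.ndarray
    rate: np.ndarray

    def __post_init__(self):
        shape = np.asarray(self.shape, dtype=float)
        rate = np.asarray(self.rate, dtype=float)
        if shape.ndim != 3 or shape.shape[2] != 2:
            raise InvalidInputError(
                f"gamma arrays must have shape (G, K, 2), got {shape.shape}"
            )
        if shape.shape != rate.shape:
            raise InvalidInputError(
                f"shape {shape.shape} and rate {rate.shape} dimensions disagree"
            )
        if not (np.all(np.isfinite(shape)) and np.all(shape > 0)):
            raise InvalidInputError("all Gamma shape parameters must be finite and > 0")
        if not (np.all(np.isfinite(rate)) and np.all(rate > 0)):
            raise InvalidInputError("all Gamma rate parameters must be finite and > 0")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "rate", rate)

    @property
    def n_genes(self) -> int:
        return self.shape.shape[0]

    @property
    def n_celltypes(self) -> int:
        return self.shape.shape[1]

    @property
    def log_mean(self) -> np.ndarray:
        """Mean of the log2-scale signal, shape/rate, shape ``(G, K, 2)``."""
        return self.shape / self.rate

    def is_null(self, atol: float = 0.0) -> bool:
        """True when case parameters equal control parameters everywhere."""
        return bool(
            np.allclose(self.shape[..., 0], self.shape[..., 1], atol=atol, rtol=0)
            and np.allclose(self.rate[..., 0], self.rate[..., 1], atol=atol, rtol=0)
        )


@dataclass(frozen=True)
class DirichletParams:
    """Per-group Dirichlet concentration vectors, shape ``(K, 2)``.

    ``mean[:, d] = alpha[:, d] / alpha[:, d].sum()`` is the expected
    composition; ``concentration[d] = alpha[:, d].sum()`` controls
    across-sample variability (larger = less variable).
    """

    alpha: np.ndarray

    def __post_init__(self):
        alpha = np.asarray(self.alpha, dtype=float)
        if alpha.ndim != 2 or alpha.shape[1] != 2:
            raise InvalidInputError(
                f"alpha must have shape (K, 2), got {alpha.shape}"
            )
        if not (np.all(np.isfinite(alpha)) and np.all(alpha > 0)):
            raise InvalidInputError("all Dirichlet alphas must be finite and > 0")
        object.__setattr__(self, "alpha", alpha)

    @property
    def n_celltypes(self) -> int:
        return self.alpha.shape[0]

    @property
    def mean(self) -> np.ndarray:
        return self.alpha / self.alpha.sum(axis=0, keepdims=True)

    @property
    def concentration(self) -> np.ndarray:
        return self.alpha.sum(axis=0)


@dataclass(frozen=True)
class ParamSet:
    """Everything the simulator needs: Gamma profiles, Dirichlet
    compositions, an expected depth scaling factor and identifiers."""

    gamma: GammaProfileParams
    dirichlet: DirichletParams
    depth_mean: float
    gene_ids: tuple
    celltype_ids: tuple

    def __post_init__(self):
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "celltype_ids", tuple(self.celltype_ids))
        if len(self.gene_ids) != self.gamma.n_genes:
            raise InvalidInputError(
                f"{len(self.gene_ids)} gene_ids for {self.gamma.n_genes} genes"
            )
        if len(self.celltype_ids) != self.gamma.n_celltypes:
            raise InvalidInputError(
                f"{len(self.celltype_ids)} celltype_ids for "
                f"{self.gamma.n_celltypes} cell types"
            )
        if self.dirichlet.n_celltypes != self.gamma.n_celltypes:
            raise InvalidInputError("gamma and dirichlet disagree on K")
        if not (np.isfinite(self.depth_mean) and self.depth_mean > 0):
            raise InvalidInputError("depth_mean must be finite and > 0")

    @property
    def n_genes(self) -> int:
        return self.gamma.n_genes

    @property
    def n_celltypes(self) -> int:
        return self.gamma.n_celltypes

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "paramset_version": PARAMSET_VERSION,
            "group_labels": list(GROUP_LABELS),
            "gene_ids": list(self.gene_ids),
            "celltype_ids": list(self.celltype_ids),
            "depth_mean": float(self.depth_mean),
            "gamma": {
                "shape": self.gamma.shape.tolist(),
                "rate": self.gamma.rate.tolist(),
            },
            "dirichlet": {"alpha": self.dirichlet.alpha.tolist()},
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "ParamSet":
        version = doc.get("paramset_version")
        if version != PARAMSET_VERSION:
            raise InvalidInputError(
                f"unsupported paramset_version {version!r} "
                f"(this build reads version {PARAMSET_VERSION})"
            )
        return cls(
            gamma=GammaProfileParams(
                shape=np.asarray(doc["gamma"]["shape"], dtype=float),
                rate=np.asarray(doc["gamma"]["rate"], dtype=float),
            ),
            dirichlet=DirichletParams(
                alpha=np.asarray(doc["dirichlet"]["alpha"], dtype=float)
            ),
            depth_mean=float(doc["depth_mean"]),
            gene_ids=tuple(doc["gene_ids"]),
            celltype_ids=tuple(doc["celltype_ids"]),
        )

    def save(self, path) -> None:
        """Write as JSON (``.json``) or YAML (``.yaml``/``.yml``)."""
        path = Path(path)
        doc = self.to_dict()
        if path.suffix == ".json":
            path.write_text(json.dumps(doc))
        elif path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(doc, sort_keys=False))
        else:
            raise InvalidInputError(f"unsupported paramset extension {path.suffix!r}")

    @classmethod
    def load(cls, path) -> "ParamSet":
        path = Path(path)
        text = path.read_text()
        doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(doc)


# ---------------------------------------------------------------------------
# Gamma MLE
# ---------------------------------------------------------------------------

def gamma_loglik(x: np.ndarray, shape: float, rate: float) -> float:
    """Gamma log-likelihood in the shape/rate parametrization."""
    x = np.asarray(x, dtype=float)
    n = x.size
    return float(
        n * (shape * np.log(rate) - gammaln(shape))
        + (shape - 1.0) * np.log(x).sum()
        - rate * x.sum()
    )


def fit_gamma_mle(values, tol: float = 1e-10, max_iter: int = 200):
    """Maximum-likelihood Gamma(shape, rate) fit.

    Newton iteration on log(shape) of the profile likelihood (rate is
    shape/mean in closed form), initialized at the method-of-moments
    estimate.  Requires at least 3 finite, strictly positive, non-constant
    values.

    Returns
    -------
    (shape, rate) : tuple of float
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 3:
        raise InvalidInputError(f"need at least 3 values, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("values must all be finite")
    if np.any(x <= 0):
        raise InvalidInputError("values must all be strictly positive")
    mean = x.mean()
    var = x.var(ddof=1)
    if var <= 0:
        raise InvalidInputError("values have zero variance; Gamma fit undefined")

    # profile-likelihood score for shape a: log(a) - psi(a) = s
    s = np.log(mean) - np.log(x).mean()
    a = mean * mean / var  # method of moments
    if s <= 0:  # numerically degenerate; MoM is the best we can say
        return float(a), float(a / mean)
    for _ in range(max_iter):
        f = np.log(a) - psi(a) - s
        # d/d(log a) of f = 1 - a * trigamma(a)  (always negative)
        step = f / (1.0 - a * polygamma(1, a))
        a_new = a * np.exp(-step)
        if abs(a_new - a) <= tol * max(1.0, a):
            a = a_new
            break
        a = a_new
    return float(a), float(a / mean)


# ---------------------------------------------------------------------------
# Dirichlet MLE
# ---------------------------------------------------------------------------

def _inv_psi(y: np.ndarray) -> np.ndarray:
    # Newton inversion of the digamma function (Minka's initialization)
    x = np.where(y >= -2.22, np.exp(y) + 0.5, -1.0 / (y - psi(1.0)))
    for _ in range(8):
        x = x - (psi(x) - y) / polygamma(1, x)
    return x


def dirichlet_score(alpha: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Per-observation gradient of the Dirichlet log-likelihood at alpha."""
    alpha = np.asarray(alpha, dtype=float)
    return psi(alpha.sum()) - psi(alpha) + np.log(P).mean(axis=0)


def fit_dirichlet_mle(P, tol: float = 1e-8, max_iter: int = 1000) -> np.ndarray:
    """Maximum-likelihood Dirichlet concentration fit.

    Fixed-point iteration on the digamma score equations with
    method-of-moments initialization.  Rows must lie strictly inside the
    simplex (sum to 1 within 1e-8, entries in the open interval (0, 1));
    clip noisy inputs upstream by an explicit epsilon (see
    :data:`PROPORTION_EPS`) before calling.

    Returns the alpha vector (length K).
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2:
        raise InvalidInputError("P must be a 2-D samples x K matrix")
    n, k = P.shape
    if n < k + 1:
        raise InvalidInputError(f"need at least K+1={k + 1} rows, got {n}")
    if np.any(~np.isfinite(P)):
        raise InvalidInputError("proportions must be finite")
    if np.any(P <= 0.0) or np.any(P >= 1.0):
        raise InvalidInputError(
            "proportions must lie strictly inside (0, 1); clip inputs "
            "upstream by an explicit epsilon (e.g. 1e-6) and renormalize"
        )
    if np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-8):
        raise InvalidInputError("every proportions row must sum to 1 within 1e-8")

    mean_logp = np.log(P).mean(axis=0)
    m = P.mean(axis=0)
    v = P.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = m * (1.0 - m) / v - 1.0
    s = s[np.isfinite(s) & (s > 0)]
    conc0 = float(np.exp(np.log(s).mean())) if s.size else 1.0
    alpha = np.maximum(m * conc0, 1e-8)

    for _ in range(max_iter):
        alpha_new = _inv_psi(psi(alpha.sum()) + mean_logp)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    if np.any(~np.isfinite(alpha)) or np.any(alpha <= 0):
        raise InvalidInputError("Dirichlet fit failed to produce positive alphas")
    return alpha


# ---------------------------------------------------------------------------
# pilot-data estimation
# ---------------------------------------------------------------------------

def _log_floor(mu: np.ndarray, floor: float = 0.05) -> np.ndarray:
    return np.maximum(np.log2(mu + 1.0), floor)


def estimate_from_pilot(counts, proportions, groups, *, gene_ids=None,
                        celltype_ids=None) -> ParamSet:
    """Estimate a complete :class:`ParamSet` from pilot bulk data.

    Parameters
    ----------
    counts : (G, N) nonnegative integers (array or DataFrame, genes x samples)
    proportions : (N, K) simplex rows (array or DataFrame)
    groups : length-N two-level label vector; ``np.unique(groups)[0]`` maps
        to the "control" slot.

    Procedure: genes with zero count variance are dropped (with a logged
    count); counts are library-size normalized against the median library;
    per group, cell-type compositions are fitted by Dirichlet MLE and a
    nonnegative least-squares back-solve of normalized bulk expression on the
    proportion matrix recovers per-(gene, cell type) purified means, whose
    log2 values together with the NNLS residual log2-variance parametrize the
    Gamma profiles.
    """
    import pandas as pd

    if isinstance(counts, pd.DataFrame):
        if gene_ids is None:
            gene_ids = list(counts.index.astype(str))
        counts = counts.to_numpy()
    if isinstance(proportions, pd.DataFrame):
        if celltype_ids is None:
            celltype_ids = list(proportions.columns.astype(str))
        proportions = proportions.to_numpy()
    counts = np.asarray(counts, dtype=float)
    P = np.asarray(proportions, dtype=float)
    groups = np.asarray(groups)
    if counts.ndim != 2 or P.ndim != 2:
        raise InvalidInputError("counts and proportions must be 2-D")
    G, N = counts.shape
    if P.shape[0] != N or groups.shape[0] != N:
        raise InvalidInputError(
            f"dimension mismatch: counts has {N} samples, proportions "
            f"{P.shape[0]} rows, groups {groups.shape[0]} labels"
        )
    K = P.shape[1]
    labels = np.unique(groups)
    if labels.size != 2:
        raise InvalidInputError(
            f"groups must contain exactly 2 labels, got {labels.size}"
        )
    for lab in labels:
        if int((groups == lab).sum()) < K + 1:
            raise InvalidInputError(
                f"group {lab!r} has fewer than K+1={K + 1} samples"
            )
    if np.any(counts < 0):
        raise InvalidInputError("counts must be nonnegative")

    if gene_ids is None:
        gene_ids = [f"gene{i + 1}" for i in range(G)]
    if celltype_ids is None:
        celltype_ids = [f"ct{i + 1}" for i in range(K)]

    keep = counts.var(axis=1) > 0
    n_dropped = int(G - keep.sum())
    if n_dropped:
        logger.info("dropping %d zero-variance gene(s) before estimation", n_dropped)
    counts = counts[keep]
    gene_ids = [g for g, k_ in zip(gene_ids, keep) if k_]
    G = counts.shape[0]
    if G == 0:
        raise InvalidInputError("no genes left after dropping zero-variance rows")

    lib = counts.sum(axis=0)
    if np.any(lib <= 0):
        raise InvalidInputError("every sample must have a positive library size")
    size_factor = lib / np.median(lib)
    norm = counts / size_factor  # median-library scale
    depth_mean = float(lib.mean() / np.median(lib))

    alpha = np.empty((K, 2))
    shape = np.empty((G, K, 2))
    rate = np.empty((G, K, 2))
    for d, lab in enumerate(labels):
        idx = np.flatnonzero(groups == lab)
        Pd = np.clip(P[idx], PROPORTION_EPS, 1.0 - PROPORTION_EPS)
        Pd = Pd / Pd.sum(axis=1, keepdims=True)
        alpha[:, d] = fit_dirichlet_mle(Pd)
        Yd = norm[:, idx]
        logYd = np.log2(Yd + 1.0)
        for g in range(G):
            mu, _ = nnls(Pd, Yd[g])
            resid = logYd[g] - np.log2(Pd @ mu + 1.0)
            v = max(float(resid.var(ddof=1)), 1e-3)
            m = _log_floor(mu)
            shape[g, :, d] = m * m / v
            rate[g, :, d] = m / v

    return ParamSet(
        gamma=GammaProfileParams(shape=shape, rate=rate),
        dirichlet=DirichletParams(alpha=alpha),
        depth_mean=depth_mean,
        gene_ids=tuple(gene_ids),
        celltype_ids=tuple(celltype_ids),
    )


# ---------------------------------------------------------------------------
# packaged synthetic parameter sets
# ---------------------------------------------------------------------------

def build_synthetic_paramset(n_genes: int, n_celltypes: int, alpha,
                             seed: int, *, depth_mean: float = 1.0,
                             log_mean_range=(0.4, 11.5),
                             log_var_range=(0.0005, 0.006)) -> ParamSet:
    """Deterministically construct a realistic synthetic :class:`ParamSet`.

    Gene-level log2 baselines are spread uniformly over ``log_mean_range``
    so latent bulk means populate the full expression range (fractions of a
    count up to several thousand); per-cell-type means jitter around the
    gene baseline; log2-scale variances (biological dispersion) are uniform
    on ``log_var_range``, i.e. an expression-scale replicate CV of roughly
    2–6%, the low replicate-to-replicate variability of isogenic cell lines
    sequenced in one batch (counting noise then dominates at low
    expression, which is what produces the low-stratum power deficit).
    Case parameters
    equal control parameters: differential effects are injected at
    simulation time from the DE truth.
    """
    rng = default_rng(seed)
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape != (n_celltypes,):
        raise InvalidInputError("alpha must have length n_celltypes")
    m0 = rng.uniform(*log_mean_range, size=n_genes)
    m = np.clip(m0[:, None] + rng.normal(0.0, 0.25, size=(n_genes, n_celltypes)),
                0.2, None)
    v = rng.uniform(*log_var_range, size=(n_genes, n_celltypes))
    shape2 = np.repeat((m * m / v)[:, :, None], 2, axis=2)
    rate2 = np.repeat((m / v)[:, :, None], 2, axis=2)
    ndig = len(str(n_genes))
    return ParamSet(
        gamma=GammaProfileParams(shape=shape2, rate=rate2),
        dirichlet=DirichletParams(alpha=np.repeat(alpha[:, None], 2, axis=1)),
        depth_mean=depth_mean,
        gene_ids=tuple(f"g{i + 1:0{ndig}d}" for i in range(n_genes)),
        celltype_ids=tuple(f"ct{i + 1}" for i in range(n_celltypes)),
    )


_PACKAGED_PARAMS = {
    "threecell_default": dict(n_genes=10_000, n_celltypes=3,
                              alpha=(4.5, 9.0, 16.5), seed=727001),
    "fivecell_default": dict(n_genes=10_000, n_celltypes=5,
                             alpha=(3.0, 4.5, 6.0, 7.5, 9.0), seed=727002),
    "null_only": dict(n_genes=2_000, n_celltypes=3,
                      alpha=(4.5, 9.0, 16.5), seed=727003),
}


def load_packaged_params(name: str) -> ParamSet:
    """Load one of the packaged synthetic parameter sets.

    Available: ``threecell_default`` (G=10000, K=3), ``fivecell_default``
    (G=10000, K=5), ``null_only`` (G=2000, K=3, case == control).  Sets are
    rebuilt deterministically from fixed seeds, so repeated calls are
    bit-identical.
    """
    try:
        spec = _PACKAGED_PARAMS[name]
    except KeyError:
        raise UnknownResourceError(
            f"unknown parameter set {name!r}; available: "
            + ", ".join(sorted(_PACKAGED_PARAMS))
        ) from None
    return build_synthetic_paramset(**spec)
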