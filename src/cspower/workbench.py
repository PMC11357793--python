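"""Scenario-grid orchestration: run power-analysis grids, serve packaged
pre-evaluated tables, and generate pilot-data fixtures.

A grid crosses per-group sample sizes with effect sizes; every cell is
simulated ``n_sims`` times, each replicate is pushed through detection and
metric evaluation, and all replicate-level metric rows are collected into
one tidy MetricsTable (long-format DataFrame) together with a JSON-able run
manifest that suffices to reproduce any row.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .csde import DEFAULT_Q_THRESHOLD, detect_csde
from .errors import InvalidInputError, UnknownResourceError
from .metrics import DEFAULT_TOP_J, StrataSpec, evaluate_dataset
from .params import ParamSet, build_synthetic_paramset, load_packaged_params
from .simulator import ScenarioConfig, simulate_dataset

logger = logging.getLogger(__name__)

METRICS_COLUMNS = ("scenario", "n_per_group", "effect_size", "sim",
                   "celltype", "stratum", "metric", "cutoff", "value")


@dataclass(frozen=True)
class GridConfig:
    """A power-analysis design grid.

    The null effect size 0 is always included (appended when absent) so
    every run carries its own false-positive calibration scenarios.
    Replicate seeds derive as ``seed + 1000 * scenario_index + replicate``.
    """

    n_per_group: tuple = (10, 20, 50)
    effect_size: tuple = (0.0, 0.25, 0.5, 0.75, 1.0)
    n_sims: int = 30
    n_genes: int = 10_000
    de_fraction: float = 0.05
    seed: int = 1
    q_threshold: float = DEFAULT_Q_THRESHOLD
    top_j: tuple = DEFAULT_TOP_J
    strata: StrataSpec = field(default_factory=StrataSpec)
    param_source: str = "packaged:threecell_default"

    def __post_init__(self):
        ns = tuple(int(n) for n in self.n_per_group)
        ess = tuple(float(e) for e in self.effect_size)
        if not ns or not ess:
            raise InvalidInputError("n_per_group and effect_size must be non-empty")
        if any(n < 1 for n in ns):
            raise InvalidInputError("sample sizes must be >= 1")
        if any(e < 0 for e in ess):
            raise InvalidInputError("effect sizes must be >= 0")
        if 0.0 not in ess:
            ess = ess + (0.0,)
        if self.n_sims < 1 or self.n_genes < 1:
            raise InvalidInputError("n_sims and n_genes must be >= 1")
        if not 0.0 < self.q_threshold < 1.0:
            raise InvalidInputError("q_threshold must lie in (0, 1)")
        object.__setattr__(self, "n_per_group", ns)
        object.__setattr__(self, "effect_size", ess)
        object.__setattr__(self, "top_j", tuple(int(j) for j in self.top_j))

    @property
    def scenarios(self) -> list:
        return [(n, es) for n in self.n_per_group for es in self.effect_size]

    def to_dict(self) -> dict:
        return {
            "n_per_group": list(self.n_per_group),
            "effect_size": list(self.effect_size),
            "n_sims": self.n_sims, "n_genes": self.n_genes,
            "de_fraction": self.de_fraction, "seed": self.seed,
            "q_threshold": self.q_threshold, "top_j": list(self.top_j),
            "strata_cutpoints": list(self.strata.cutpoints),
            "param_source": self.param_source,
        }


def resolve_params(source: str) -> ParamSet:
    """Resolve ``packaged:<name>`` or ``paramset:<path>`` sources."""
    kind, _, rest = source.partition(":")
    if kind == "packaged":
        return load_packaged_params(rest)
    if kind == "paramset":
        return ParamSet.load(rest)
    raise InvalidInputError(
        f"unresolvable parameter source {source!r}; use "
        "'packaged:<name>' or 'paramset:<path>'"
    )


def run_grid(config: GridConfig, params: ParamSet | None = None):
    """Run the full scenario grid.

    Returns ``(table, manifest)``: the replicate-level MetricsTable and a
    manifest (config echo, per-replicate seeds, version, wall times, any
    scenario failures).  A failing scenario is logged and skipped; completed
    scenarios are kept (fail-soft).
    """
    if params is None:
        params = resolve_params(config.param_source)
    if params.n_genes < config.n_genes:
        raise InvalidInputError(
            f"parameter source provides {params.n_genes} genes; the grid "
            f"wants {config.n_genes}"
        )
    frames = []
    manifest = {
        "config": config.to_dict(),
        "cspower_version": __version__,
        "scenarios": [],
        "failures": [],
    }
    for s_idx, (n, es) in enumerate(config.scenarios):
        sid = f"n{n}_es{es:g}"
        seeds = [config.seed + 1000 * s_idx + rep for rep in range(config.n_sims)]
        t0 = time.perf_counter()
        try:
            for rep, rep_seed in enumerate(seeds):
                scenario = ScenarioConfig(
                    n_per_group=n, effect_size=es, n_genes=config.n_genes,
                    de_fraction=config.de_fraction, seed=rep_seed,
                    depth_mean=params.depth_mean,
                )
                ds = simulate_dataset(params, scenario)
                res = detect_csde(ds.counts, ds.proportions, ds.group)
                tab = evaluate_dataset(ds, res, q_threshold=config.q_threshold,
                                       top_j=config.top_j,
                                       strata_spec=config.strata)
                tab.insert(0, "scenario", sid)
                tab.insert(1, "n_per_group", n)
                tab.insert(2, "effect_size", es)
                tab.insert(3, "sim", rep)
                frames.append(tab)
        except Exception as exc:  # fail-soft: keep completed scenarios
            logger.error("scenario %s failed: %s", sid, exc)
            manifest["failures"].append({"scenario": sid, "error": str(exc)})
            continue
        manifest["scenarios"].append({
            "scenario": sid, "n_per_group": n, "effect_size": es,
            "seeds": seeds, "wall_seconds": round(time.perf_counter() - t0, 3),
        })
        logger.info("scenario %s done (%d reps, %.1fs)", sid, config.n_sims,
                    time.perf_counter() - t0)
    table = (pd.concat(frames, ignore_index=True) if frames
             else pd.DataFrame(columns=list(METRICS_COLUMNS)))
    return table, manifest


def aggregate_metrics(table: pd.DataFrame) -> pd.DataFrame:
    """Average metric values across replicates.

    Infinite replicate values (FDC with TP=0) and missing values are
    excluded from the mean, matching the convention that scenario summaries
    average the finite replicate-level outcomes.
    """
    clean = table.replace([np.inf, -np.inf], np.nan)
    keys = ["scenario", "n_per_group", "effect_size", "celltype", "stratum",
            "metric", "cutoff"]
    return (clean.groupby(keys, dropna=False)["value"].mean()
            .reset_index())


# ---------------------------------------------------------------------------
# packaged pre-evaluated tables (the no-pilot-data quick path)
# ---------------------------------------------------------------------------

#: the tiny replicate-level packaged grid; rebuilt verbatim by tests.
DEMO_SMALL_CONFIG = GridConfig(
    n_per_group=(10,), effect_size=(0.0, 0.5), n_sims=2, n_genes=400,
    seed=2024, top_j=(50, 100), param_source="packaged:null_only",
)

_PACKAGED_RESULTS = {
    "threecell_default": "threecell_default.tsv",
    "demo_small": "demo_small.tsv",
}


def quick_power(name: str) -> pd.DataFrame:
    """Return a packaged pre-evaluated MetricsTable without simulating.

    ``threecell_default`` holds the default grid on the packaged three-cell
    parameters, averaged over replicates at build time; ``demo_small`` a
    tiny replicate-level grid kept exactly reproducible by the test suite.
    """
    try:
        fname = _PACKAGED_RESULTS[name]
    except KeyError:
        raise UnknownResourceError(
            f"unknown result set {name!r}; available: "
            + ", ".join(sorted(_PACKAGED_RESULTS))
        ) from None
    with resources.as_file(resources.files("cspower.data") / fname) as p:
        return pd.read_csv(p, sep="\t")


# ---------------------------------------------------------------------------
# fixture generation
# ---------------------------------------------------------------------------

_FIXTURES = {
    "pilot_small": dict(n_genes=500, n_celltypes=3, alpha=(4.5, 9.0, 16.5),
                        n_per_group=20, effect_size=0.5),
    "pilot_null": dict(n_genes=500, n_celltypes=3, alpha=(4.5, 9.0, 16.5),
                       n_per_group=20, effect_size=0.0),
    "cellline_like": dict(n_genes=2000, n_celltypes=5,
                          alpha=(3.0, 4.5, 6.0, 7.5, 9.0),
                          n_per_group=25, effect_size=1.0),
}


def generate_fixture(kind: str, seed: int, outdir) -> dict:
    """Write a complete pilot triple (counts, proportions, groups) plus the
    generating ParamSet, for round-trip estimation tests."""
    from .io import write_dataset

    try:
        spec = _FIXTURES[kind]
    except KeyError:
        raise UnknownResourceError(
            f"unknown fixture kind {kind!r}; available: "
            + ", ".join(sorted(_FIXTURES))
        ) from None
    params = build_synthetic_paramset(
        n_genes=spec["n_genes"], n_celltypes=spec["n_celltypes"],
        alpha=spec["alpha"], seed=int(seed) & 0x7FFFFFFF,
    )
    scenario = ScenarioConfig(
        n_per_group=spec["n_per_group"], effect_size=spec["effect_size"],
        n_genes=spec["n_genes"], seed=(int(seed) + 1) & 0x7FFFFFFF,
    )
    ds = simulate_dataset(params, scenario)
    outdir = Path(outdir)
    paths = write_dataset(ds, outdir, scenario=scenario)
    pset_path = outdir / "paramset.json"
    params.save(pset_path)
    paths["paramset"] = pset_path
    return paths
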