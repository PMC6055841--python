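"""Experiment-grid orchestration and the post-analyses built on it.

A grid is a set of labelled analyses ("SA-IR-3P", "SB-IR-3P", ...) sharing a
dataset but differing in calibration strategy, clock model, birth-death
parameters or partition scheme.  Each analysis runs a posterior chain plus a
prior-only twin (for specified-vs-effective prior comparison).  On top of the
per-analysis summaries sit:

* composite credibility intervals — the per-node envelope from the smallest
  lower limit to the largest upper limit across analyses (conventionally
  excluding the maximum-inheriting strategy SB);
* branch-rate differences — per node, the absolute and proportional
  difference between a branch's posterior mean rate and its parent branch's,
  reported as positive magnitudes;
* cross-analysis scatters — paired posterior means and intervals between two
  analyses, with the maximum mean discrepancy and Lin's concordance
  correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from divtime.calibrations import CalibrationRecord, StrategySpec, apply_strategy
from divtime.mcmc_engine import MCMCConfig, MCMCResult, PosteriorSummary, run_chain
from divtime.rate_models import ClockModelSpec
from divtime.time_prior import BDParams, TimeTree

__all__ = [
    "AnalysisSpec",
    "GridDataset",
    "GridRun",
    "CompositeInterval",
    "run_grid",
    "composite_intervals",
    "branch_rate_differences",
    "cross_analysis_scatter",
    "filter_long_branch_sequences",
]

logger = logging.getLogger("divtime")


@dataclass(frozen=True)
class AnalysisSpec:
    """One labelled cell of the experiment grid."""

    label: str
    strategy: StrategySpec
    clock: ClockModelSpec
    bd: BDParams
    partition_scheme: str = "3P"
    taxa_filter: tuple[str, ...] | None = None


@dataclass
class GridDataset:
    """A dataset a grid can run on: tree, calibration records, and one
    likelihood-source list per partition scheme."""

    tree: TimeTree
    records: list[CalibrationRecord]
    likelihood_sources: dict[str, list]


@dataclass
class GridRun:
    """Outcome of one grid cell (posterior chain + prior-only twin)."""

    spec: AnalysisSpec
    posterior: MCMCResult | None = None
    prior: MCMCResult | None = None
    error: str | None = None

    @property
    def failed(self) -> bool:
        return self.error is not None

    def summary(self) -> PosteriorSummary:
        if self.posterior is None:
            raise RuntimeError(f"analysis {self.spec.label} failed: {self.error}")
        return self.posterior.summary()


def run_grid(
    dataset: GridDataset,
    specs: list[AnalysisSpec],
    config: MCMCConfig,
    prior_config: MCMCConfig | None = None,
) -> dict[str, GridRun]:
    """Run every analysis in the grid; failures are recorded, not raised.

    Each spec gets a seeded posterior chain and a prior-only twin run with
    the same calibration densities.  Labels must be unique.
    """
    labels = [s.label for s in specs]
    if len(set(labels)) != len(labels):
        raise ValueError("grid labels must be unique")
    if prior_config is None:
        prior_config = MCMCConfig(
            iterations=config.iterations, burnin=config.burnin,
            sample_every=config.sample_every, seed=config.seed + 101,
            mode="prior_only",
        )
    out: dict[str, GridRun] = {}
    for spec in specs:
        run = GridRun(spec)
        try:
            densities = apply_strategy(dataset.records, dataset.tree,
                                       spec.strategy)
            sources = dataset.likelihood_sources[spec.partition_scheme]
            run.posterior = run_chain(
                dataset.tree, densities, spec.bd, spec.clock, sources, config
            )
            run.prior = run_chain(
                dataset.tree, densities, spec.bd, spec.clock, None,
                prior_config,
            )
        except Exception as exc:  # noqa: BLE001 - grid must keep going
            run.error = f"{type(exc).__name__}: {exc}"
            logger.warning("analysis %s failed: %s", spec.label, run.error)
        out[spec.label] = run
    return out


@dataclass
class CompositeInterval:
    """Per-node envelope across analyses: smallest lower limit to largest
    upper limit.  ``table`` is indexed by node name with columns ``lower``,
    ``upper``; ``excluded`` names the analyses left out."""

    table: pd.DataFrame
    excluded: frozenset[str]
    interval: str = "hpd"


def composite_intervals(
    summaries: dict[str, PosteriorSummary],
    exclude: set[str] = frozenset(),
    interval: str = "hpd",
    nodes: list[str] | None = None,
) -> CompositeInterval:
    """Envelope of per-analysis 95% intervals, excluding named analyses.

    ``interval`` selects HPD (default, as in the composite timescale) or
    equal-tail limits.  All included summaries must cover the same nodes.
    """
    lo_col, hi_col = ("hpd_lo", "hpd_hi") if interval == "hpd" \
        else ("eq_lo", "eq_hi")
    included = {k: v for k, v in summaries.items() if k not in exclude}
    if not included:
        raise ValueError("no analyses left after exclusion")
    tables = list(included.values())
    if nodes is None:
        nodes = list(tables[0].table.index)
    for label, summ in included.items():
        missing = set(nodes) - set(summ.table.index)
        if missing:
            raise ValueError(
                f"analysis {label} lacks nodes {sorted(missing)}"
            )
    lower = pd.concat(
        [s.table.loc[nodes, lo_col] for s in tables], axis=1
    ).min(axis=1)
    upper = pd.concat(
        [s.table.loc[nodes, hi_col] for s in tables], axis=1
    ).max(axis=1)
    return CompositeInterval(
        pd.DataFrame({"lower": lower, "upper": upper}),
        frozenset(exclude), interval,
    )


def branch_rate_differences(
    mean_rates: np.ndarray,
    tree: TimeTree,
) -> pd.DataFrame:
    """Parent-child branch rate contrasts, reported as positive magnitudes.

    ``mean_rates`` are posterior mean branch rates indexed like
    ``tree.branch_nodes()``.  For each branch whose parent node also subtends
    a branch, the absolute difference ``|r_child - r_parent|`` and the
    proportional difference ``|r_child - r_parent| / r_parent`` are emitted;
    branches hanging off the root have no parent branch and get NaN.
    """
    branches = tree.branch_nodes()
    pos = {int(b): i for i, b in enumerate(branches)}
    rows = []
    for i, b in enumerate(branches):
        b = int(b)
        p = int(tree.parent[b])
        if p == tree.root or tree.parent[p] < 0:
            rows.append({"node": tree.label_of(b), "absolute": np.nan,
                         "proportional": np.nan})
            continue
        r_child = mean_rates[i]
        r_parent = mean_rates[pos[p]]
        d = abs(r_child - r_parent)
        rows.append({"node": tree.label_of(b), "absolute": d,
                     "proportional": d / r_parent})
    return pd.DataFrame(rows).set_index("node")


@dataclass
class ScatterComparison:
    table: pd.DataFrame
    max_abs_mean_diff: float
    concordance: float


def cross_analysis_scatter(
    summary_a: PosteriorSummary,
    summary_b: PosteriorSummary,
    nodes: list[str] | None = None,
) -> ScatterComparison:
    """Paired per-node means and intervals for two analyses.

    Returns the table driving a mean-vs-mean scatter plus the maximum
    absolute mean difference and Lin's concordance correlation coefficient.
    The two summaries must cover the same nodes.
    """
    if nodes is None:
        nodes = [n for n in summary_a.table.index
                 if not (n.startswith("mu_") or n.startswith("sigma2_"))]
    missing = (set(nodes) - set(summary_a.table.index)) \
        | (set(nodes) - set(summary_b.table.index))
    if missing:
        raise ValueError(f"node sets differ: missing {sorted(missing)}")
    a = summary_a.table.loc[nodes]
    b = summary_b.table.loc[nodes]
    table = pd.DataFrame({
        "mean_a": a["mean"], "lo_a": a["eq_lo"], "hi_a": a["eq_hi"],
        "mean_b": b["mean"], "lo_b": b["eq_lo"], "hi_b": b["eq_hi"],
    })
    xa, xb = a["mean"].to_numpy(), b["mean"].to_numpy()
    max_diff = float(np.max(np.abs(xa - xb)))
    if len(xa) < 2 or (np.var(xa) + np.var(xb)) == 0:
        ccc = 1.0 if max_diff == 0 else 0.0
    else:
        ccc = float(
            2 * np.cov(xa, xb, bias=True)[0, 1]
            / (np.var(xa) + np.var(xb) + (xa.mean() - xb.mean()) ** 2)
        )
    return ScatterComparison(table, max_diff, ccc)


def filter_long_branch_sequences(
    gene_tree: "dendropy.Tree | str",
    threshold: float = 0.3,
) -> list[str]:
    """Taxa whose terminal branch exceeds ``threshold`` of total tree length.

    Preprocessing utility for per-gene quality control: sequences producing
    unusually long external branches on their gene tree are candidates for
    removal before concatenation.
    """
    if isinstance(gene_tree, str):
        gene_tree = dendropy.Tree.get(data=gene_tree, schema="newick",
                                      preserve_underscores=True)
    total = sum(
        e.length or 0.0 for e in gene_tree.preorder_edge_iter()
    )
    if total <= 0:
        return []
    flagged = []
    for leaf in gene_tree.leaf_node_iter():
        if (leaf.edge.length or 0.0) > threshold * total:
            flagged.append(leaf.taxon.label if leaf.taxon else leaf.label)
    return sorted(flagged)
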