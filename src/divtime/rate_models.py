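"""Branch-rate priors: strict clock, independent lognormal, autocorrelated.

Three flavours of rate variation across branches of a time tree:

strict
    All branches share a single rate ``mu``; only the hyperprior on ``mu``
    contributes.

independent (IR)
    Each branch rate is an iid draw from a lognormal with mean-rate ``mu`` and
    log-rate variance ``sigma2``: ``log r ~ N(log mu - sigma2/2, sigma2)``,
    so that ``E[r] = mu`` (``mu`` is the mean of the rate, not the log-scale
    median).

autocorrelated (AR)
    Rates drift along the tree as geometric Brownian motion.  The rate of a
    branch lives at the branch midpoint; a branch's log-rate is normal around
    its parent branch's log-rate with variance ``sigma2 * dt`` (dt = elapsed
    time between midpoints) and drift ``-sigma2 * dt / 2``, which keeps the
    rate process a martingale (``E[r_child | r_parent] = r_parent``).

Hyperpriors on ``mu`` and ``sigma2`` are gamma distributions; the study's
defaults are G(2, 50) on mu (mean 0.04 substitutions/site/100 Myr) and
G(2, 4) on sigma2 (mean 0.5), with G(2, 60) (mean 0.03) for analyses that
drop the distant outgroups and G(2, 10) (mean 0.2) in model-selection runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from divtime.time_prior import TimeTree

__all__ = [
    "GammaPrior",
    "ClockModelSpec",
    "log_prior_rates",
    "sample_rates",
]


@dataclass(frozen=True)
class GammaPrior:
    """Gamma(shape, rate) hyperprior; mean = shape / rate."""

    shape: float
    rate: float

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.rate <= 0:
            raise ValueError("gamma shape and rate must be positive")

    @property
    def mean(self) -> float:
        return self.shape / self.rate

    def logpdf(self, x: float) -> float:
        if x <= 0:
            return -np.inf
        a, b = self.shape, self.rate
        return a * np.log(b) - gammaln(a) + (a - 1.0) * np.log(x) - b * x

    def sample(self, rng: np.random.Generator) -> float:
        return float(rng.gamma(self.shape, 1.0 / self.rate))


@dataclass(frozen=True)
class ClockModelSpec:
    """Clock flavour plus hyperpriors on the mean rate and log-rate variance."""

    flavor: str = "independent"
    mu_prior: GammaPrior = GammaPrior(2.0, 50.0)
    sigma2_prior: GammaPrior = GammaPrior(2.0, 4.0)

    def __post_init__(self) -> None:
        if self.flavor not in ("strict", "independent", "autocorrelated"):
            raise ValueError(f"unknown clock flavor {self.flavor!r}")


def _midpoint_structure(tree: TimeTree):
    """Per-branch (midpoint age, parent-branch index or -1, dt to parent).

    For branches hanging off the root the 'parent rate' is the root rate and
    dt is the distance from the root age to the branch midpoint.
    """
    branches = tree.branch_nodes()
    mid = 0.5 * (tree.ages[branches] + tree.ages[tree.parent[branches]])
    pos = {int(b): k for k, b in enumerate(branches)}
    parent_idx = np.full(len(branches), -1, dtype=int)
    dt = np.empty(len(branches))
    root_age = tree.ages[tree.root]
    for k, b in enumerate(branches):
        p = int(tree.parent[b])
        if p == tree.root:
            dt[k] = root_age - mid[k]
        else:
            parent_idx[k] = pos[p]
            dt[k] = mid[pos[p]] - mid[k]
    return branches, mid, parent_idx, np.maximum(dt, 1e-12)


def log_prior_rates(
    rates: np.ndarray,
    tree: TimeTree,
    spec: ClockModelSpec,
    mu: float,
    sigma2: float,
) -> float:
    """Log prior density of per-branch rates given (mu, sigma2).

    ``rates`` is indexed like ``tree.branch_nodes()``.  The hyperprior terms
    on mu and sigma2 are *not* included; add them separately.
    """
    rates = np.asarray(rates, dtype=float)
    if np.any(rates <= 0):
        return -np.inf
    if spec.flavor == "strict":
        return 0.0 if np.allclose(rates, mu) else -np.inf
    if sigma2 < 0:
        return -np.inf
    if sigma2 == 0:
        return np.inf if np.allclose(rates, mu) else -np.inf
    log_r = np.log(rates)
    if spec.flavor == "independent":
        m = np.log(mu) - sigma2 / 2.0
        z = (log_r - m) ** 2 / sigma2
        return float(
            -0.5 * np.sum(z + np.log(2 * np.pi * sigma2)) - np.sum(log_r)
        )
    # autocorrelated: geometric BM over branch midpoints
    _, _, parent_idx, dt = _midpoint_structure(tree)
    parent_log = np.where(parent_idx >= 0, log_r[np.maximum(parent_idx, 0)],
                          np.log(mu))
    var = sigma2 * dt
    m = parent_log - var / 2.0
    z = (log_r - m) ** 2 / var
    return float(-0.5 * np.sum(z + np.log(2 * np.pi * var)) - np.sum(log_r))


def sample_rates(
    tree: TimeTree,
    spec: ClockModelSpec,
    mu: float,
    sigma2: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Draw per-branch rates from the prior of :func:`log_prior_rates`.

    Deterministic per seed; returns rates indexed like ``tree.branch_nodes()``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    branches = tree.branch_nodes()
    n = len(branches)
    if spec.flavor == "strict" or sigma2 == 0:
        return np.full(n, mu)
    if spec.flavor == "independent":
        m = np.log(mu) - sigma2 / 2.0
        return np.exp(rng.normal(m, np.sqrt(sigma2), size=n))
    _, mid, parent_idx, dt = _midpoint_structure(tree)
    # parents have larger midpoints; fill in age-descending order
    order = np.argsort(-mid)
    log_r = np.empty(n)
    eps = rng.standard_normal(n)
    for k in order:
        parent_log = np.log(mu) if parent_idx[k] < 0 else log_r[parent_idx[k]]
        var = sigma2 * dt[k]
        log_r[k] = parent_log - var / 2.0 + np.sqrt(var) * eps[k]
    return np.exp(log_r)
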