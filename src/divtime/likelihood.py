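"""Sequence likelihoods: exact HKY85+Gamma5 pruning and the quadratic approximation.

Two likelihood paths are provided:

* :func:`exact_loglik` — Felsenstein pruning under HKY85 with discrete-gamma
  among-site rate variation (5 equal-probability categories by default),
  pattern-compressed, with gaps and ambiguity codes treated as missing data.
  HKY transition probabilities use the closed-form spectral solution.

* :func:`fit_branch_approx` / :func:`approx_loglik` — the approximate method
  used for large dating analyses: the log-likelihood is expanded to second
  order around the maximum-likelihood branch lengths, on square-root
  transformed lengths (z = sqrt(b)), so that MCMC iterations cost a quadratic
  form instead of a pruning pass.  The expansion is
  ``g . dz + dz' H dz / 2`` with dz = z - z_hat, g the gradient and H the
  Hessian at the optimum (both on the transformed scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammainc

__all__ = [
    "Alignment",
    "SubstModel",
    "BranchLengthApprox",
    "gamma_category_rates",
    "hky_transition_matrices",
    "exact_loglik",
    "fit_branch_approx",
    "approx_loglik",
]

# nucleotide coding: A C G T = 0..3, anything else (gap/ambiguity) = 4
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
MISSING = 4


@dataclass
class Alignment:
    """A gap-tolerant nucleotide alignment.

    ``codes`` is an (n_taxa, n_sites) int8 matrix with A,C,G,T as 0..3 and
    4 for anything else (gaps and ambiguity codes are likelihood-missing).
    """

    taxa: list[str]
    codes: np.ndarray

    @classmethod
    def from_sequences(cls, seqs: dict[str, str]) -> "Alignment":
        taxa = list(seqs)
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) != 1:
            raise ValueError("sequences are not aligned (unequal lengths)")
        codes = np.full((len(taxa), lengths.pop()), MISSING, dtype=np.int8)
        for i, name in enumerate(taxa):
            for j, ch in enumerate(seqs[name].upper()):
                codes[i, j] = _CODE.get(ch, MISSING)
        return cls(taxa, codes)

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    def to_sequences(self) -> dict[str, str]:
        letters = np.array(list("ACGT-"))
        return {
            name: "".join(letters[row])
            for name, row in zip(self.taxa, self.codes)
        }


@dataclass(frozen=True)
class SubstModel:
    """HKY85 + discrete-gamma substitution model.

    ``kappa`` is the transition/transversion rate ratio, ``base_freqs`` the
    stationary frequencies in A,C,G,T order, ``gamma_alpha`` the shape of the
    gamma distribution of site rates (mean fixed at 1), discretised into
    ``n_categories`` equal-probability categories represented by their means.
    """

    kappa: float = 2.0
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    gamma_alpha: float = 1.0
    n_categories: int = 5

    def __post_init__(self) -> None:
        if self.kappa <= 0 or self.gamma_alpha <= 0:
            raise ValueError("kappa and gamma_alpha must be positive")
        f = np.asarray(self.base_freqs, dtype=float)
        if f.shape != (4,) or np.any(f <= 0) or abs(f.sum() - 1.0) > 1e-8:
            raise ValueError("base_freqs must be 4 positive values summing to 1")

    @property
    def freqs(self) -> np.ndarray:
        return np.asarray(self.base_freqs, dtype=float)


from functools import lru_cache


@lru_cache(maxsize=64)
def _gamma_category_rates_cached(alpha: float, k: int) -> tuple[float, ...]:
    return tuple(_gamma_category_rates(alpha, k))


def gamma_category_rates(alpha: float, k: int) -> np.ndarray:
    """Cached front end of :func:`_gamma_category_rates`."""
    return np.array(_gamma_category_rates_cached(float(alpha), int(k)))


def _gamma_category_rates(alpha: float, k: int) -> np.ndarray:
    """Mean rates of k equal-probability categories of Gamma(alpha, alpha).

    The category over quantile interval (i/k, (i+1)/k) is represented by its
    conditional mean, computed from the incomplete gamma function; the rates
    average exactly 1.
    """
    from scipy.stats import gamma as gamma_dist

    edges = gamma_dist.ppf(np.arange(1, k) / k, alpha, scale=1.0 / alpha)
    edges = np.concatenate([[0.0], edges, [np.inf]])
    # E[X; a<X<b] for Gamma(alpha, rate alpha) via the shape alpha+1 CDF
    upper = gammainc(alpha + 1.0, alpha * edges[1:])
    lower = gammainc(alpha + 1.0, alpha * edges[:-1])
    upper[np.isinf(edges[1:])] = 1.0
    return k * (upper - lower)


def hky_transition_matrices(t: np.ndarray, model: SubstModel) -> np.ndarray:
    """Closed-form HKY85 transition matrices for an array of branch lengths.

    Returns shape ``t.shape + (4, 4)``; rows index the parent state, columns
    the child state (A,C,G,T).  The rate matrix is scaled so a length of 1
    is one expected substitution per site.
    """
    t = np.asarray(t, dtype=float)
    pi = model.freqs
    kappa = model.kappa
    piA, piC, piG, piT = pi
    piR, piY = piA + piG, piC + piT
    beta = 0.5 / (piR * piY + kappa * (piA * piG + piC * piT))
    d = beta * t[..., None, None]

    e2 = np.exp(-d)
    # class-dependent second eigenvalue: purines vs pyrimidines
    big_pi = np.array([piR, piY, piR, piY])
    rate3 = big_pi * kappa + (1.0 - big_pi)
    e3 = np.exp(-beta * t[..., None, None] * rate3[None, :])  # (..., 1, 4)

    pi_j = pi[None, :]
    same = np.eye(4, dtype=bool)
    transition = np.zeros((4, 4), dtype=bool)
    transition[0, 2] = transition[2, 0] = True  # A <-> G
    transition[1, 3] = transition[3, 1] = True  # C <-> T
    transversion = ~same & ~transition

    diag = pi_j + pi_j * (1.0 / big_pi - 1.0) * e2 + ((big_pi - pi_j) / big_pi) * e3
    trans = pi_j + pi_j * (1.0 / big_pi - 1.0) * e2 - (pi_j / big_pi) * e3
    tv = pi_j * (1.0 - e2)
    # each entry depends only on the column and the (same/ts/tv) class of the
    # (row, column) pair, so the matrix assembles from three masked columns
    P = (np.eye(4) * diag
         + transition * trans
         + transversion * tv)
    return P


def compress_patterns(alignment: Alignment) -> tuple[np.ndarray, np.ndarray]:
    """Unique site patterns and their counts (columns of the code matrix)."""
    patterns, counts = np.unique(alignment.codes, axis=1, return_counts=True)
    return patterns, counts.astype(float)


def _tip_partials(patterns: np.ndarray) -> np.ndarray:
    """(n_taxa, n_patterns, 4) indicator partials; missing = all ones."""
    n_taxa, n_pat = patterns.shape
    L = np.zeros((n_taxa, n_pat, 4))
    for s in range(4):
        L[..., s] = (patterns == s) | (patterns == MISSING)
    return L


def exact_loglik(
    alignment: Alignment,
    tree,
    branch_lengths: np.ndarray,
    model: SubstModel,
) -> float:
    """Exact log-likelihood by Felsenstein pruning under HKY85+Gamma.

    ``branch_lengths`` (substitutions/site) are indexed like
    ``tree.branch_nodes()``.  Taxa are matched to tips by name; an alignment
    whose taxon set differs from the tree's raises ``ValueError``.
    """
    if set(alignment.taxa) != set(tree.taxon_names):
        raise ValueError("alignment taxa do not match tree tips")
    branch_lengths = np.asarray(branch_lengths, dtype=float)
    if np.any(branch_lengths < 0):
        return -np.inf
    patterns, counts = compress_patterns(alignment)
    order = [alignment.taxa.index(name) for name in tree.taxon_names]
    patterns = patterns[order]
    return _pruning_loglik(patterns, counts, tree, branch_lengths, model)


def _pruning_loglik(patterns, counts, tree, branch_lengths, model,
                    tipL: np.ndarray | None = None) -> float:
    k = model.n_categories
    rates = gamma_category_rates(model.gamma_alpha, k)
    branches = tree.branch_nodes()
    # (n_branches, k) effective lengths -> (n_branches, k, 4, 4) matrices
    eff = branch_lengths[:, None] * rates[None, :]
    P = hky_transition_matrices(eff, model)
    pos = {int(b): i for i, b in enumerate(branches)}

    n_pat = patterns.shape[1]
    if tipL is None:
        tipL = _tip_partials(patterns)
    partials: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        node = int(node)
        if node < tree.n_tips:
            partials[node] = np.broadcast_to(tipL[node], (k, n_pat, 4))
            continue
        acc = None
        for child in tree.children[node]:
            # batched (k,p,4) x (k,4,4)^T contraction over child states
            contrib = partials[child] @ P[pos[child]].transpose(0, 2, 1)
            acc = contrib if acc is None else acc * contrib
            del partials[child]
        partials[node] = acc
    root = partials[tree.root]  # (k, n_pat, 4)
    site_lik = np.mean(root @ model.freqs, axis=0)  # average over categories
    if np.any(site_lik <= 0):
        return -np.inf
    return float(np.sum(counts * np.log(site_lik)))


@dataclass
class BranchLengthApprox:
    """Quadratic summary of a partition's log-likelihood surface.

    Holds the MLE branch lengths ``b_hat`` (substitutions/site, indexed like
    ``tree.branch_nodes()``), the gradient and Hessian of the log-likelihood
    at the optimum on the transformed scale, the transform used, and the
    log-likelihood value at the MLE.
    """

    b_hat: np.ndarray
    gradient: np.ndarray
    hessian: np.ndarray
    transform: str = "sqrt"
    loglik_at_mle: float = 0.0

    def __post_init__(self) -> None:
        self.b_hat = np.asarray(self.b_hat, dtype=float)
        self.gradient = np.asarray(self.gradient, dtype=float)
        self.hessian = np.asarray(self.hessian, dtype=float)
        n = len(self.b_hat)
        if self.hessian.shape != (n, n) or len(self.gradient) != n:
            raise ValueError("gradient/Hessian dimensions must equal branch count")
        if not np.allclose(self.hessian, self.hessian.T, atol=1e-8):
            raise ValueError("Hessian must be symmetric")
        if self.transform not in ("sqrt", "none"):
            raise ValueError("transform must be 'sqrt' or 'none'")

    def _z(self, b: np.ndarray) -> np.ndarray:
        b = np.asarray(b, dtype=float)
        return np.sqrt(b) if self.transform == "sqrt" else b

    @property
    def z_hat(self) -> np.ndarray:
        return self._z(self.b_hat)


def fit_branch_approx(
    alignment: Alignment,
    tree,
    model: SubstModel,
    transform: str = "sqrt",
    fd_step: float = 1e-4,
    zero_gradient: bool = False,
    x0: np.ndarray | None = None,
) -> BranchLengthApprox:
    """Maximise branch lengths and build the quadratic likelihood summary.

    The optimisation runs on the transformed scale; the Hessian is obtained
    by central finite differences with step ``fd_step`` (transformed scale).
    With ``zero_gradient=True`` the gradient is forced to zero (the MLE is
    then taken as exactly stationary); otherwise the measured central-
    difference gradient is stored.  Branch lengths estimated at the zero
    boundary get a zeroed gradient component and a regularised Hessian
    row/column.
    """
    if tree.n_tips < 3:
        raise ValueError("need at least 3 taxa to fit branch lengths")
    patterns, counts = compress_patterns(alignment)
    order = [alignment.taxa.index(name) for name in tree.taxon_names]
    patterns = patterns[order]
    n_branches = len(tree.branch_nodes())

    def neg_loglik_z(z: np.ndarray) -> float:
        b = z**2 if transform == "sqrt" else np.maximum(z, 0.0)
        return -_pruning_loglik(patterns, counts, tree, b, model)

    if x0 is None:
        x0 = np.full(n_branches, 0.1)
    z0 = np.sqrt(x0) if transform == "sqrt" else x0
    res = minimize(
        neg_loglik_z, z0, method="L-BFGS-B",
        bounds=[(0.0, None)] * n_branches,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    if not res.success and res.fun > neg_loglik_z(z0):
        raise RuntimeError(f"branch-length optimisation failed: {res.message}")
    z_hat = res.x
    f0 = -res.fun

    h = fd_step

    def fd_gradient(z: np.ndarray) -> np.ndarray:
        g = np.empty(n_branches)
        for i in range(n_branches):
            zp, zm = z.copy(), z.copy()
            zp[i] += h
            zm[i] = max(zm[i] - h, 0.0)
            g[i] = -(neg_loglik_z(zp) - neg_loglik_z(zm)) / (zp[i] - zm[i])
        return g

    # Newton polish: L-BFGS-B stops on ftol; push the stationarity further
    grad = fd_gradient(z_hat)
    for _ in range(8):
        interior = z_hat > 10 * h
        if np.max(np.abs(grad[interior]), initial=0.0) < 1e-6:
            break
        hpol = _fd_hessian(neg_loglik_z, z_hat, h)
        try:
            step = np.linalg.solve(hpol, -grad)
        except np.linalg.LinAlgError:
            break
        z_new = np.maximum(z_hat + step, 0.0)
        f_new = -neg_loglik_z(z_new)
        if not np.isfinite(f_new) or f_new < f0 - 1e-9:
            break
        z_hat, f0 = z_new, f_new
        grad = fd_gradient(z_hat)
    if zero_gradient:
        grad = np.zeros(n_branches)
    hess = _fd_hessian(neg_loglik_z, z_hat, h)

    b_hat = z_hat**2 if transform == "sqrt" else z_hat
    boundary = b_hat < 1e-10
    if np.any(boundary):
        idx = np.flatnonzero(boundary)
        grad[idx] = 0.0
        hess[idx, :] = 0.0
        hess[:, idx] = 0.0
        hess[idx, idx] = -1.0 / h  # weak curvature keeps the form proper
    hess = 0.5 * (hess + hess.T)
    return BranchLengthApprox(b_hat, grad, hess, transform, f0)


def _fd_hessian(neg_f, z_hat: np.ndarray, h: float) -> np.ndarray:
    """Central-difference Hessian of -neg_f at z_hat (step h, clipped at 0)."""
    n = len(z_hat)
    evals: dict[tuple, float] = {}

    def f_at(delta: dict[int, float]) -> float:
        key = tuple(sorted(delta.items()))
        if key not in evals:
            z = z_hat.copy()
            for i, d in delta.items():
                z[i] = max(z[i] + d, 0.0)
            evals[key] = -neg_f(z)
        return evals[key]

    fc = f_at({})
    hess = np.zeros((n, n))
    for i in range(n):
        hess[i, i] = (f_at({i: h}) - 2 * fc + f_at({i: -h})) / h**2
        for j in range(i + 1, n):
            hess[i, j] = hess[j, i] = (
                f_at({i: h, j: h}) - f_at({i: h, j: -h})
                - f_at({i: -h, j: h}) + f_at({i: -h, j: -h})
            ) / (4 * h**2)
    return hess


def approx_loglik(branch_lengths: np.ndarray, approx: BranchLengthApprox) -> float:
    """Quadratic approximate log-likelihood, relative to its value at the MLE.

    ``g . dz + dz' H dz / 2`` with dz the displacement from the MLE on the
    transformed scale.  Finite for zero-length branches (sqrt removes the
    boundary singularity of the derivative).
    """
    b = np.asarray(branch_lengths, dtype=float)
    if np.any(b < 0):
        return -np.inf
    dz = approx._z(b) - approx.z_hat
    return float(approx.gradient @ dz + 0.5 * dz @ approx.hessian @ dz)
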