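"""Fossil calibration densities and the five calibration strategies.

A fossil calibration turns palaeontological evidence about a clade into a
prior density on the age of its crown node.  Two soft-bound families are used:

``soft_uniform`` — B(t_L, t_U, p_L, p_U)
    Uniform between a minimum ``t_L`` and a maximum ``t_U`` holding mass
    ``1 - p_L - p_U``, with a power-decay tail below the minimum (mass
    ``p_L``) and an exponential-decay tail above the maximum (mass ``p_U``).
    Both tail branches are matched for continuity with the uniform plateau.

``truncated_cauchy`` — L(t_L, p, c, p_L)
    A heavy-tailed density above a minimum bound: a Cauchy with location
    ``t_L (1 + p)`` and scale ``c t_L`` truncated to ``t > t_L`` (mass
    ``1 - p_L``), plus a continuity-matched power-decay tail below ``t_L``
    (mass ``p_L``).  ``p`` sets how far past the bound the mode sits, ``c``
    how slowly the density decays towards older ages.

Five strategies (SA-SE) map a table of minimum / minimum+maximum records to
per-node densities; they differ in how strongly the fossil minima are taken
as approximations of the true clade ages.

All ages are in units of 100 Myr.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from divtime.time_prior import TimeTree

__all__ = [
    "CalibrationRecord",
    "CalibrationDensity",
    "SoftUniform",
    "TruncatedCauchy",
    "StrategySpec",
    "make_soft_uniform",
    "make_truncated_cauchy",
    "make_point_band",
    "strategy",
    "apply_strategy",
]

#: default tail probabilities for soft-bound uniform calibrations
DEFAULT_P_L = 0.01
DEFAULT_P_U = 0.05

#: default truncated-Cauchy shape: mode offset p and tail decay c
DEFAULT_CAUCHY_P = 0.1
DEFAULT_CAUCHY_C = 0.1

#: clade labels that SC/SD/SE treat specially
SPECIAL_NODES = ("crown_angiosperms", "crown_mesangiosperms")

#: optimistic soft maximum used by strategy SE (139.4 Ma, in 100 Myr units)
SE_MAXIMUM = 1.394


@dataclass(frozen=True)
class CalibrationRecord:
    """One row of a calibration table: a clade and its fossil bounds.

    ``t_min`` / ``t_max`` are in units of 100 Myr; ``t_max`` is ``None`` for
    minimum-only calibrations.
    """

    node_label: str
    t_min: float
    t_max: float | None = None

    def __post_init__(self) -> None:
        if self.t_min <= 0:
            raise ValueError(f"{self.node_label}: t_min must be positive")
        if self.t_max is not None and self.t_max < self.t_min:
            raise ValueError(
                f"{self.node_label}: t_max ({self.t_max}) must not be below "
                f"t_min ({self.t_min})"
            )

    @property
    def kind(self) -> str:
        if self.t_max is None:
            return "min_only"
        return "point" if self.t_max == self.t_min else "min_max"


class CalibrationDensity:
    """A univariate prior on one node age: piecewise, normalised, evaluable.

    Subclasses implement ``pdf``/``cdf``/``ppf`` branches; ``logpdf`` and
    seeded sampling come for free.  Support is the positive reals.
    """

    form: str

    def pdf(self, t):
        raise NotImplementedError

    def cdf(self, t):
        raise NotImplementedError

    def ppf(self, q):
        raise NotImplementedError

    def logpdf(self, t):
        with np.errstate(divide="ignore"):
            return np.log(self.pdf(t))

    def logpdf_scalar(self, t: float) -> float:
        """Fast scalar log-density (hot path of the MCMC sampler)."""
        return float(self.logpdf(t))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.ppf(rng.uniform(size=n))

    def mean(self) -> float:
        from scipy.integrate import quad

        hi = float(self.ppf(1.0 - 1e-9))
        return quad(lambda t: t * self.pdf(t), 0.0, hi, limit=200)[0]


class SoftUniform(CalibrationDensity):
    """Soft-bound uniform B(t_L, t_U, p_L, p_U).

    Piecewise density (h = (1 - p_L - p_U) / (t_U - t_L) is the plateau):

    * ``0 < t < t_L``:  p_L * a * t**(a-1) / t_L**a  with  a = h t_L / p_L,
      so the branch holds mass p_L and meets the plateau continuously;
    * ``t_L <= t <= t_U``:  h;
    * ``t > t_U``:  p_U * b * exp(-b (t - t_U))  with  b = h / p_U,
      mass p_U, continuous at t_U.
    """

    form = "soft_uniform"

    def __init__(self, t_L: float, t_U: float, p_L: float = DEFAULT_P_L,
                 p_U: float = DEFAULT_P_U) -> None:
        if not 0 < t_L < t_U:
            raise ValueError("bounds must satisfy 0 < t_L < t_U")
        if not (0 < p_L < 0.5 and 0 < p_U < 0.5 and p_L + p_U < 1):
            raise ValueError("tail probabilities must be in (0, 0.5) and sum < 1")
        self.t_L, self.t_U, self.p_L, self.p_U = t_L, t_U, p_L, p_U
        self.height = (1.0 - p_L - p_U) / (t_U - t_L)
        self.power = self.height * t_L / p_L        # lower power-decay exponent
        self.rate = self.height / p_U               # upper exponential rate

    def pdf(self, t):
        t = np.asarray(t, dtype=float)
        out = np.zeros(t.shape if t.ndim else (1,))
        tt = np.atleast_1d(t)
        lo = (tt > 0) & (tt < self.t_L)
        mid = (tt >= self.t_L) & (tt <= self.t_U)
        hi = tt > self.t_U
        out[lo] = self.height * (tt[lo] / self.t_L) ** (self.power - 1.0)
        out[mid] = self.height
        out[hi] = self.height * np.exp(-self.rate * (tt[hi] - self.t_U))
        return float(out[0]) if t.ndim == 0 else out

    def cdf(self, t):
        t = np.asarray(t, dtype=float)
        tt = np.atleast_1d(t)
        out = np.zeros(tt.shape)
        lo = (tt > 0) & (tt < self.t_L)
        mid = (tt >= self.t_L) & (tt <= self.t_U)
        hi = tt > self.t_U
        out[lo] = self.p_L * (tt[lo] / self.t_L) ** self.power
        out[mid] = self.p_L + self.height * (tt[mid] - self.t_L)
        out[hi] = 1.0 - self.p_U * np.exp(-self.rate * (tt[hi] - self.t_U))
        return float(out[0]) if t.ndim == 0 else out

    def ppf(self, q):
        q = np.asarray(q, dtype=float)
        qq = np.atleast_1d(q)
        out = np.empty(qq.shape)
        lo = qq < self.p_L
        hi = qq > 1.0 - self.p_U
        mid = ~lo & ~hi
        out[lo] = self.t_L * (qq[lo] / self.p_L) ** (1.0 / self.power)
        out[mid] = self.t_L + (qq[mid] - self.p_L) / self.height
        with np.errstate(divide="ignore"):
            out[hi] = self.t_U - np.log((1.0 - qq[hi]) / self.p_U) / self.rate
        return float(out[0]) if q.ndim == 0 else out

    def logpdf(self, t):
        # log-space evaluation: the power branch underflows pdf for narrow
        # bands (large exponents) long before the log-density is -inf
        t = np.asarray(t, dtype=float)
        tt = np.atleast_1d(t)
        out = np.full(tt.shape, -np.inf)
        log_h = np.log(self.height)
        lo = (tt > 0) & (tt < self.t_L)
        mid = (tt >= self.t_L) & (tt <= self.t_U)
        hi = tt > self.t_U
        out[lo] = log_h + (self.power - 1.0) * np.log(tt[lo] / self.t_L)
        out[mid] = log_h
        out[hi] = log_h - self.rate * (tt[hi] - self.t_U)
        return float(out[0]) if t.ndim == 0 else out

    def logpdf_scalar(self, t: float) -> float:
        if t <= 0:
            return -math.inf
        log_h = math.log(self.height)
        if t < self.t_L:
            return log_h + (self.power - 1.0) * math.log(t / self.t_L)
        if t <= self.t_U:
            return log_h
        return log_h - self.rate * (t - self.t_U)

    def breakpoints(self) -> list[float]:
        return [self.t_L, self.t_U]

    def __repr__(self) -> str:
        return (f"SoftUniform(t_L={self.t_L:g}, t_U={self.t_U:g}, "
                f"p_L={self.p_L:g}, p_U={self.p_U:g})")


class TruncatedCauchy(CalibrationDensity):
    """Truncated Cauchy minimum-bound calibration L(t_L, p, c, p_L).

    Above ``t_L`` the density is Cauchy(location t_L(1+p), scale c t_L)
    truncated to ``t > t_L`` and carrying mass ``1 - p_L``; its truncation
    constant is ``A = 1/2 + arctan(p/c)/pi``.  Below ``t_L`` a power-decay
    branch holds mass ``p_L`` with exponent chosen so the two branches meet
    continuously at ``t_L``.
    """

    form = "truncated_cauchy"

    def __init__(self, t_L: float, p: float = DEFAULT_CAUCHY_P,
                 c: float = DEFAULT_CAUCHY_C, p_L: float = DEFAULT_P_L) -> None:
        if t_L <= 0 or c <= 0:
            raise ValueError("t_L and c must be positive")
        if p < 0:
            raise ValueError("p must be non-negative")
        if not 0 < p_L < 0.5:
            raise ValueError("p_L must be in (0, 0.5)")
        self.t_L, self.p, self.c, self.p_L = t_L, p, c, p_L
        self.loc = t_L * (1.0 + p)
        self.scale = c * t_L
        self.A = 0.5 + math.atan(p / c) / math.pi
        # density just above the bound; the power branch must match it
        f0 = (1.0 - p_L) / (math.pi * self.A * self.scale * (1.0 + (p / c) ** 2))
        self.power = f0 * t_L / p_L

    def pdf(self, t):
        t = np.asarray(t, dtype=float)
        tt = np.atleast_1d(t)
        out = np.zeros(tt.shape)
        lo = (tt > 0) & (tt < self.t_L)
        hi = tt >= self.t_L
        f_bound = self.power * self.p_L / self.t_L
        out[lo] = f_bound * (tt[lo] / self.t_L) ** (self.power - 1.0)
        z = (tt[hi] - self.loc) / self.scale
        out[hi] = (1.0 - self.p_L) / (math.pi * self.A * self.scale * (1.0 + z**2))
        return float(out[0]) if t.ndim == 0 else out

    def cdf(self, t):
        t = np.asarray(t, dtype=float)
        tt = np.atleast_1d(t)
        out = np.zeros(tt.shape)
        lo = (tt > 0) & (tt < self.t_L)
        hi = tt >= self.t_L
        out[lo] = self.p_L * (tt[lo] / self.t_L) ** self.power
        z = (tt[hi] - self.loc) / self.scale
        z0 = -self.p / self.c
        out[hi] = self.p_L + (1.0 - self.p_L) * (
            (np.arctan(z) - math.atan(z0)) / (math.pi * self.A)
        )
        return float(out[0]) if t.ndim == 0 else out

    def ppf(self, q):
        q = np.asarray(q, dtype=float)
        qq = np.atleast_1d(q)
        out = np.empty(qq.shape)
        lo = qq < self.p_L
        hi = ~lo
        out[lo] = self.t_L * (qq[lo] / self.p_L) ** (1.0 / self.power)
        z0 = math.atan(-self.p / self.c)
        ang = z0 + (qq[hi] - self.p_L) / (1.0 - self.p_L) * math.pi * self.A
        out[hi] = self.loc + self.scale * np.tan(np.clip(ang, None, math.pi / 2 - 1e-12))
        return float(out[0]) if q.ndim == 0 else out

    def logpdf(self, t):
        t = np.asarray(t, dtype=float)
        tt = np.atleast_1d(t)
        out = np.full(tt.shape, -np.inf)
        lo = (tt > 0) & (tt < self.t_L)
        hi = tt >= self.t_L
        f_bound = self.power * self.p_L / self.t_L
        out[lo] = np.log(f_bound) \
            + (self.power - 1.0) * np.log(tt[lo] / self.t_L)
        z = (tt[hi] - self.loc) / self.scale
        out[hi] = np.log(
            (1.0 - self.p_L) / (math.pi * self.A * self.scale)
        ) - np.log1p(z * z)
        return float(out[0]) if t.ndim == 0 else out

    def logpdf_scalar(self, t: float) -> float:
        if t <= 0:
            return -math.inf
        if t < self.t_L:
            f_bound = self.power * self.p_L / self.t_L
            return math.log(f_bound) + (self.power - 1.0) * math.log(t / self.t_L)
        z = (t - self.loc) / self.scale
        return math.log(
            (1.0 - self.p_L) / (math.pi * self.A * self.scale)
        ) - math.log1p(z * z)

    def breakpoints(self) -> list[float]:
        return [self.t_L, self.loc]

    def __repr__(self) -> str:
        return (f"TruncatedCauchy(t_L={self.t_L:g}, p={self.p:g}, "
                f"c={self.c:g}, p_L={self.p_L:g})")


def make_soft_uniform(t_L: float, t_U: float, p_L: float = DEFAULT_P_L,
                      p_U: float = DEFAULT_P_U) -> SoftUniform:
    """Soft-bound uniform calibration B(t_L, t_U, p_L, p_U)."""
    return SoftUniform(t_L, t_U, p_L, p_U)


def make_truncated_cauchy(t_L: float, p: float = DEFAULT_CAUCHY_P,
                          c: float = DEFAULT_CAUCHY_C,
                          p_L: float = DEFAULT_P_L) -> TruncatedCauchy:
    """Truncated Cauchy minimum-bound calibration L(t_L, p, c, p_L)."""
    return TruncatedCauchy(t_L, p, c, p_L)


def make_point_band(t_0: float, rel_half_width: float = 0.01) -> SoftUniform:
    """Point calibration as a narrow soft-uniform band t_0 * (1 -+ w).

    This is how a root age is effectively fixed, e.g. B(0.99, 1.01) for a
    root scaled to age 1.
    """
    if t_0 <= 0:
        raise ValueError("t_0 must be positive")
    return SoftUniform(t_0 * (1.0 - rel_half_width), t_0 * (1.0 + rel_half_width))


# ---------------------------------------------------------------------------
# Calibration strategies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StrategySpec:
    """One of the five calibration strategies SA-SE.

    SA: minima as truncated Cauchy (p=0.1, c=0.1), min+max pairs as soft
    uniforms — fossil minima treated as close approximations of clade age.
    SB: every minimum inherits the maximum of its youngest maximum-bearing
    ancestor; all calibrations become soft uniforms (agnostic between bounds).
    SC / SD: as SA but the crown-angiosperm and crown-mesangiosperm nodes use
    a shorter Cauchy tail (c=0.01 / c=0.005).
    SE: as SA but those two nodes receive an optimistic soft maximum (139.4 Ma).
    """

    name: str
    cauchy_p: float = DEFAULT_CAUCHY_P
    cauchy_c: float = DEFAULT_CAUCHY_C
    tail_pL: float = DEFAULT_P_L
    tail_pU: float = DEFAULT_P_U
    special_nodes: tuple[str, ...] = SPECIAL_NODES
    special_c: float | None = None      # SC/SD: Cauchy c override on special nodes
    special_max: float | None = None    # SE: soft maximum on special nodes

    def __post_init__(self) -> None:
        if not (0 < self.tail_pL < 0.5 and 0 < self.tail_pU < 0.5):
            raise ValueError("tail probabilities must be in (0, 0.5)")


_STRATEGIES = {
    "SA": StrategySpec("SA"),
    "SB": StrategySpec("SB"),
    "SC": StrategySpec("SC", special_c=0.01),
    "SD": StrategySpec("SD", special_c=0.005),
    "SE": StrategySpec("SE", special_max=SE_MAXIMUM),
}


def strategy(name: str, special_nodes: tuple[str, ...] = SPECIAL_NODES) -> StrategySpec:
    """Preset StrategySpec for one of SA, SB, SC, SD, SE."""
    try:
        base = _STRATEGIES[name.upper()]
    except KeyError:
        raise ValueError(f"unknown strategy {name!r}; expected SA..SE") from None
    if special_nodes != base.special_nodes:
        return StrategySpec(**{**base.__dict__, "special_nodes": special_nodes})
    return base


def apply_strategy(
    records: list[CalibrationRecord],
    tree: TimeTree,
    spec: StrategySpec,
) -> dict[int, CalibrationDensity]:
    """Map calibration records to per-node densities under a strategy.

    Returns a map from internal-node index to density, covering exactly the
    input record set.  For SB, a minimum-only node with no maximum-bearing
    calibrated ancestor raises a ``ValueError`` naming the node.
    """
    by_node: dict[int, CalibrationRecord] = {}
    for rec in records:
        node = tree.node_by_label(rec.node_label)
        if node < tree.n_tips:
            raise ValueError(f"calibration {rec.node_label!r} is on a tip")
        if node in by_node:
            raise ValueError(f"duplicate calibration on {rec.node_label!r}")
        by_node[node] = rec

    out: dict[int, CalibrationDensity] = {}
    for node, rec in by_node.items():
        special = rec.node_label in spec.special_nodes
        if rec.kind == "point":
            out[node] = make_point_band(rec.t_min)
        elif spec.name == "SB":
            if rec.t_max is not None:
                t_max = rec.t_max
            else:
                t_max = _inherited_maximum(tree, node, by_node)
                if t_max is None:
                    raise ValueError(
                        f"SB inheritance failed for {rec.node_label!r}: no "
                        "ancestor carries a maximum bound"
                    )
            out[node] = SoftUniform(rec.t_min, t_max, spec.tail_pL, spec.tail_pU)
        elif rec.t_max is not None:
            out[node] = SoftUniform(rec.t_min, rec.t_max, spec.tail_pL, spec.tail_pU)
        elif special and spec.special_max is not None:
            out[node] = SoftUniform(rec.t_min, spec.special_max,
                                    spec.tail_pL, spec.tail_pU)
        else:
            c = spec.special_c if (special and spec.special_c is not None) \
                else spec.cauchy_c
            out[node] = TruncatedCauchy(rec.t_min, spec.cauchy_p, c, spec.tail_pL)
    return out


def _inherited_maximum(
    tree: TimeTree, node: int, by_node: dict[int, CalibrationRecord]
) -> float | None:
    """Maximum bound of the youngest (nearest) maximum-bearing ancestor."""
    for anc in tree.ancestors(node):
        rec = by_node.get(anc)
        if rec is not None and rec.t_max is not None:
            return rec.t_max
    return None
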