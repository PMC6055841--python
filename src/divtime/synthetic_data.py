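"""Simulators for every input the dating pipeline consumes.

Ground-truth time trees come from the birth-death-sampling process
conditioned on a root age; branch rates from one of the three clock models;
alignments from HKY85 with discrete-gamma site rates; and fossil calibration
tables from the true node ages (minima drawn below the truth, maxima above),
so that posterior estimates can be checked against a known answer.

Everything is driven by explicit seeds: the same seed reproduces the same
tree, sequences and calibrations bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from divtime.calibrations import CalibrationRecord, make_point_band
from divtime.likelihood import Alignment, SubstModel, gamma_category_rates, \
    hky_transition_matrices
from divtime.rate_models import ClockModelSpec, GammaPrior, sample_rates
from divtime.time_prior import BDParams, TimeTree, sample_bd_ages

__all__ = [
    "CalibrationPlan",
    "SimulationRecipe",
    "simulate_time_tree",
    "simulate_alignment",
    "generate_calibrations",
    "simulate_dataset",
    "calibration_fixture_52",
    "ten_taxon_fixture",
]


@dataclass(frozen=True)
class CalibrationPlan:
    """How many nodes get calibrations and how tight the bounds are.

    Minima are ``true age * U(min_lo, min_hi)`` (factors in (0, 1]), maxima
    ``true age * U(max_lo, max_hi)`` (factors >= 1).  The defaults emulate
    informative fossil minima sitting close below the true clade ages.  The
    root is always calibrated and always receives a maximum.
    """

    n_min_only: int
    n_min_max: int
    min_factor: tuple[float, float] = (0.6, 0.95)
    max_factor: tuple[float, float] = (1.05, 1.6)

    def __post_init__(self) -> None:
        if not (0 < self.min_factor[0] <= self.min_factor[1] <= 1.0):
            raise ValueError("min factors must lie in (0, 1]")
        if not (1.0 <= self.max_factor[0] <= self.max_factor[1]):
            raise ValueError("max factors must be >= 1")
        if self.n_min_max < 1:
            raise ValueError("the root needs a min+max calibration")


@dataclass(frozen=True)
class SimulationRecipe:
    """Full specification of one synthetic dataset."""

    n_tips: int = 8
    root_age: float = 1.0
    bd: BDParams = BDParams(1.0, 1.0, 0.0)
    clock: ClockModelSpec = ClockModelSpec()
    mu: float = 0.2
    sigma2: float = 0.5
    subst: SubstModel = SubstModel()
    seq_lengths: tuple[int, ...] = (1000,)
    plan: CalibrationPlan = CalibrationPlan(2, 1)
    seed: int = 0


def simulate_time_tree(
    n_tips: int,
    root_age: float = 1.0,
    bd: BDParams = BDParams(1.0, 1.0, 0.0),
    seed: int | np.random.Generator = 0,
    taxon_names: list[str] | None = None,
) -> TimeTree:
    """Ultrametric tree from the conditioned birth-death-sampling process.

    Internal-node ages (other than the root, fixed at ``root_age``) are iid
    draws from the BD kernel; the labelled history is built by splitting a
    uniformly chosen extant lineage at each successive age, which matches
    the exchangeability of the conditioned process.
    """
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if taxon_names is None:
        taxon_names = [f"t{i+1}" for i in range(n_tips)]
    inner_ages = np.sort(sample_bd_ages(n_tips - 2, root_age, bd, rng))[::-1]
    n_nodes = 2 * n_tips - 1
    parent = np.full(n_nodes, -1, dtype=int)
    ages = np.zeros(n_nodes)
    root = n_tips
    ages[root] = root_age
    next_id = n_tips + 1
    slots = [root, root]  # open child slots, one entry per active lineage
    for a in inner_ages:
        k = rng.integers(len(slots))
        p = slots.pop(k)
        parent[next_id] = p
        ages[next_id] = a
        slots.extend([next_id, next_id])
        next_id += 1
    tips = rng.permutation(n_tips)
    for tip, p in zip(tips, slots):
        parent[tip] = p
    return TimeTree(parent, ages, taxon_names)


def simulate_alignment(
    tree: TimeTree,
    rates: np.ndarray,
    model: SubstModel,
    length: int,
    seed: int | np.random.Generator = 0,
) -> Alignment:
    """Evolve sequences down the tree under HKY85 + discrete gamma.

    ``rates`` are per-branch (indexed like ``tree.branch_nodes()``); branch
    lengths are rate x duration.  Each site draws one of the equal-probability
    gamma categories (represented by its mean rate); sites are independent
    given the category.  No gaps are produced.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    branches = tree.branch_nodes()
    dur = tree.branch_durations()[branches]
    b = np.asarray(rates, dtype=float) * dur
    if not np.all(np.isfinite(b)) or np.any(b < 0):
        raise ValueError("branch lengths must be finite and non-negative")
    k = model.n_categories
    cat_rates = gamma_category_rates(model.gamma_alpha, k)
    site_cat = rng.integers(k, size=length)
    P = hky_transition_matrices(b[:, None] * cat_rates[None, :], model)
    pos = {int(n): i for i, n in enumerate(branches)}

    states = np.empty((tree.n_nodes, length), dtype=np.int8)
    pi = model.freqs
    states[tree.root] = rng.choice(4, size=length, p=pi)
    order = tree.postorder()[::-1]  # preorder: parents first
    for node in order:
        node = int(node)
        if node == tree.root:
            continue
        ps = states[tree.parent[node]]
        Pn = P[pos[node]]  # (k, 4, 4)
        # cumulative transition probabilities per (category, parent state)
        cum = np.cumsum(Pn, axis=-1)
        u = rng.uniform(size=length)
        thresholds = cum[site_cat, ps]  # (length, 4)
        states[node] = np.argmax(u[:, None] < thresholds, axis=-1)
    seqs = {name: states[i] for i, name in enumerate(tree.taxon_names)}
    return Alignment(list(tree.taxon_names),
                     np.vstack([seqs[n] for n in tree.taxon_names]))


def generate_calibrations(
    tree: TimeTree,
    plan: CalibrationPlan,
    seed: int | np.random.Generator = 0,
) -> list[CalibrationRecord]:
    """Fossil-style calibrations derived from the true node ages.

    Nodes are sampled without replacement; the root is always calibrated and
    always carries a maximum.  Minima never exceed the true age; maxima
    never fall below it.  Chosen nodes are labelled in ``tree.node_labels``
    (``n<index>``) so records resolve against the tree.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    internal = [int(i) for i in tree.internal_nodes]
    n_cal = plan.n_min_only + plan.n_min_max
    if n_cal > len(internal):
        raise ValueError("more calibrations requested than internal nodes")
    others = [i for i in internal if i != tree.root]
    chosen = [tree.root] + list(rng.choice(others, size=n_cal - 1, replace=False))
    with_max = set(chosen[:plan.n_min_max])   # root first -> root has a maximum
    records = []
    for node in chosen:
        label = tree.label_of(node)
        if label not in tree.node_labels:
            tree.node_labels[label] = node
        truth = tree.ages[node]
        t_min = truth * rng.uniform(*plan.min_factor)
        t_max = truth * rng.uniform(*plan.max_factor) if node in with_max else None
        records.append(CalibrationRecord(label, t_min, t_max))
    return records


@dataclass
class SyntheticDataset:
    """A simulated problem with its ground truth."""

    tree: TimeTree
    rates: np.ndarray                    # truth, per branch
    alignments: list[Alignment]
    records: list[CalibrationRecord]
    recipe: SimulationRecipe

    @property
    def true_ages(self) -> np.ndarray:
        return self.tree.ages[self.tree.internal_nodes]


def simulate_dataset(recipe: SimulationRecipe) -> SyntheticDataset:
    """Simulate tree, rates, per-partition alignments and calibrations."""
    rng = np.random.default_rng(recipe.seed)
    tree = simulate_time_tree(recipe.n_tips, recipe.root_age, recipe.bd, rng)
    rates = sample_rates(tree, recipe.clock, recipe.mu, recipe.sigma2, rng)
    alns = [
        simulate_alignment(tree, rates, recipe.subst, L, rng)
        for L in recipe.seq_lengths
    ]
    records = generate_calibrations(tree, recipe.plan, rng)
    return SyntheticDataset(tree, rates, alns, records, recipe)


def calibration_fixture_52(seed: int = 52) -> tuple[TimeTree, list[CalibrationRecord]]:
    """Synthetic 52-calibration table on a 54-tip tree (41 min-only, 11 min+max).

    A stand-in emulating the structure of the real calibration set: 52
    calibrated nodes of which 11 carry soft maxima, a calibrated root with a
    maximum, and labelled crown-angiosperm / crown-mesangiosperm nodes whose
    minimum is the published 125.9 Ma fossil bound (1.259 in 100 Myr units).
    Deterministic for a given seed; the numbers are synthetic, not the real
    fossil table.
    """
    rng = np.random.default_rng(seed)
    tree = simulate_time_tree(54, root_age=4.4, seed=rng)
    plan = CalibrationPlan(41, 11)
    records = generate_calibrations(tree, plan, rng)
    # relabel two deep min-only nodes as the strategy-sensitive crown nodes
    min_only = [r for r in records if r.t_max is None]
    min_only.sort(key=lambda r: -tree.ages[tree.node_by_label(r.node_label)])
    relabel = {
        min_only[0].node_label: "crown_angiosperms",
        min_only[1].node_label: "crown_mesangiosperms",
    }
    out = []
    for rec in records:
        if rec.node_label in relabel:
            new_label = relabel[rec.node_label]
            node = tree.node_labels.pop(rec.node_label)
            tree.node_labels[new_label] = node
            # published minima: 125.9 Ma (angiosperms), 125.6 Ma (mesangiosperms)
            t_min = 1.259 if new_label == "crown_angiosperms" else 1.256
            out.append(CalibrationRecord(new_label, t_min, rec.t_max))
        else:
            out.append(rec)
    return tree, out


#: tip labels of the small tracheophyte dataset used for model selection
TEN_TAXA = ("Huperzia", "Psilotum", "Ginkgo", "Amborella", "Nymphaea",
            "Acorus", "Calycanthus", "Platanus", "Oxalis", "Cornus")


@dataclass
class TenTaxonBundle:
    """Synthetic ten-taxon model-selection bundle.

    Tree rooted on the lycophyte/fern outgroups with the root age scaled to
    1 (fixed via a narrow B(0.99, 1.01)-style band), three nucleotide
    partitions plus their concatenation, and the model-selection prior
    configuration: rate prior G(2, 10), sigma2 prior G(2, 4).
    """

    tree: TimeTree
    rates: np.ndarray
    alignments: list[Alignment]          # 3 partitions
    concatenation: Alignment
    densities: dict
    clock_priors: dict[str, GammaPrior]
    subst: SubstModel
    seed: int


def ten_taxon_fixture(seed: int = 1234,
                      seq_lengths: tuple[int, ...] = (600, 500, 400),
                      sigma2: float = 0.5) -> TenTaxonBundle:
    """Synthetic stand-in for the ten-species tracheophyte dataset.

    The topology places the outgroups (Huperzia, Psilotum, Ginkgo) basally
    and ladders the angiosperms; sequences are simulated under the
    independent-rates clock (mean rate 0.2 per root-unit, log-variance
    ``sigma2``) so the rate process genuinely violates a strict clock.
    """
    newick = ("(Huperzia,(Psilotum,(Ginkgo,(Amborella,(Nymphaea,(Acorus,"
              "(Calycanthus,(Platanus,(Oxalis,Cornus)))))))));")
    rel_ages = [1.0, 0.93, 0.85, 0.55, 0.50, 0.45, 0.40, 0.33, 0.25]
    tree = _ladder_tree(newick, rel_ages)
    rng = np.random.default_rng(seed)
    clock = ClockModelSpec("independent",
                           mu_prior=GammaPrior(2.0, 10.0),
                           sigma2_prior=GammaPrior(2.0, 4.0))
    rates = sample_rates(tree, clock, 0.2, sigma2, rng)
    subst = SubstModel(kappa=3.0, base_freqs=(0.30, 0.19, 0.21, 0.30),
                       gamma_alpha=0.5)
    alns = [simulate_alignment(tree, rates, subst, L, rng)
            for L in seq_lengths]
    concat = Alignment(list(tree.taxon_names),
                       np.hstack([a.codes for a in alns]))
    densities = {tree.root: make_point_band(1.0, 0.01)}
    return TenTaxonBundle(tree, rates, alns, concat, densities,
                          {"mu": GammaPrior(2.0, 10.0),
                           "sigma2": GammaPrior(2.0, 4.0)},
                          subst, seed)


def _ladder_tree(newick: str, internal_ages_preorder: list[float]) -> TimeTree:
    """Parse a topology-only newick and assign internal ages (preorder)."""
    import dendropy

    dtree = dendropy.Tree.get(data=newick, schema="newick",
                              preserve_underscores=True)
    internals = [nd for nd in dtree.preorder_node_iter() if not nd.is_leaf()]
    if len(internals) != len(internal_ages_preorder):
        raise ValueError("age list does not match internal node count")
    age = {id(nd): a for nd, a in zip(internals, internal_ages_preorder)}
    for nd in dtree.preorder_node_iter():
        a = age.get(id(nd), 0.0)
        if nd.parent_node is not None:
            nd.edge.length = age[id(nd.parent_node)] - a
    return TimeTree.from_dendropy(dtree)
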