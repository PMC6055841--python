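"""Exact pruning likelihood and its quadratic approximation."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

import divtime as dt
from divtime.likelihood import (
    Alignment,
    compress_patterns,
    gamma_category_rates,
    hky_transition_matrices,
)


def hky_rate_matrix(model):
    """Independent construction of the scaled HKY generator (test oracle)."""
    pi = model.freqs
    Q = np.zeros((4, 4))
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}
    for i in range(4):
        for j in range(4):
            if i != j:
                Q[i, j] = pi[j] * (model.kappa if (i, j) in transitions else 1)
        Q[i, i] = -Q[i].sum()
    return Q / -np.sum(pi * np.diag(Q))


def brute_force_loglik(aln, tree, b, model):
    """Exhaustive summation over internal-state assignments (oracle)."""
    k = model.n_categories
    cr = gamma_category_rates(model.gamma_alpha, k)
    branches = tree.branch_nodes()
    pos = {int(n): i for i, n in enumerate(branches)}
    P = {int(n): hky_transition_matrices(b[pos[int(n)]] * cr, model)
         for n in branches}
    pi = model.freqs
    order = [aln.taxa.index(n) for n in tree.taxon_names]
    codes = aln.codes[order]
    internals = [int(i) for i in tree.internal_nodes]
    total = 0.0
    for s in range(aln.n_sites):
        site = 0.0
        for c in range(k):
            for assign in itertools.product(range(4), repeat=len(internals)):
                st = dict(zip(internals, assign))
                p = pi[st[tree.root]]
                for n in branches:
                    n = int(n)
                    child = st[n] if n in st else codes[n, s]
                    p *= P[n][c, st[int(tree.parent[n])], child]

                site += p / k
        total += np.log(site)
    return total


class TestTransitionMatrices:
    def test_closed_form_matches_matrix_exponential(self, quartet_model):
        Q = hky_rate_matrix(quartet_model)
        for t in (0.01, 0.1, 0.5, 2.0):
            P = hky_transition_matrices(np.array(t), quartet_model)
            np.testing.assert_allclose(P, expm(Q * t), atol=1e-12)

    def test_rows_sum_to_one_and_stationarity(self, quartet_model):
        P = hky_transition_matrices(np.array([0.3]), quartet_model)[0]
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(quartet_model.freqs @ P,
                                   quartet_model.freqs, atol=1e-12)


def test_gamma_categories_average_to_one():
    for alpha in (0.2, 0.8, 5.0):
        r = gamma_category_rates(alpha, 5)
        assert len(r) == 5
        assert r.mean() == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(r) > 0)


class TestExactLoglik:
    def test_identical_sequences_zero_branches(self):
        tree = dt.TimeTree.from_newick("((A:0.5,B:0.5):0.5,C:1.0);")
        seq = "ACGTACGT"
        aln = Alignment.from_sequences({n: seq for n in "ABC"})
        model = dt.SubstModel(base_freqs=(0.1, 0.2, 0.3, 0.4))
        b = np.zeros(len(tree.branch_nodes()))
        expected = sum(np.log(model.freqs["ACGT".index(ch)]) for ch in seq)
        assert dt.exact_loglik(aln, tree, b, model) \
            == pytest.approx(expected, rel=1e-12)

    def test_two_sequence_jukes_cantor_closed_form(self):
        """kappa=1, equal frequencies, alpha -> inf reduces to JC69, whose
        two-sequence likelihood has the classic closed form."""
        tree = dt.TimeTree.from_newick("((A:0.5,B:0.5):0.5,C:1.0);")
        model = dt.SubstModel(kappa=1.0, gamma_alpha=1e8)
        rng = np.random.default_rng(3)
        n = 600
        seq_a = rng.integers(0, 4, n)
        # place C identical to A and put all divergence on branch B
        codes = np.vstack([seq_a, seq_a, seq_a])
        aln = Alignment(["A", "B", "C"], codes.astype(np.int8))
        branches = list(tree.branch_nodes())
        b = np.zeros(len(branches))
        tB = 0.3
        iB = branches.index(tree.taxon_names.index("B"))
        b[iB] = tB
        # mutate B's sequence according to the analytic JC transition prob
        p_diff = 0.75 * (1 - np.exp(-4 * tB / 3))
        seq_b = seq_a.copy()
        flip = rng.uniform(size=n) < p_diff
        seq_b[flip] = (seq_b[flip] + rng.integers(1, 4, flip.sum())) % 4
        aln.codes[1] = seq_b
        x = int(np.sum(seq_a != seq_b))
        expected = (
            n * np.log(0.25)
            + x * np.log(p_diff / 3)
            + (n - x) * np.log(1 - p_diff)
        )
        assert dt.exact_loglik(aln, tree, b, model) \
            == pytest.approx(expected, rel=1e-9)

    def test_matches_exhaustive_enumeration(self, quartet_model):
        tree = dt.simulate_time_tree(4, 1.0, seed=1)
        rates = np.full(len(tree.branch_nodes()), 0.3)
        aln = dt.simulate_alignment(tree, rates, quartet_model, 60, seed=2)
        b = rates * tree.branch_durations()[tree.branch_nodes()]
        assert dt.exact_loglik(aln, tree, b, quartet_model) == pytest.approx(
            brute_force_loglik(aln, tree, b, quartet_model), abs=1e-8)

    def test_invariant_to_taxon_order(self, quartet_data, quartet_model):
        tree, aln = quartet_data["tree"], quartet_data["aln"]
        b = quartet_data["b_true"]
        ref = dt.exact_loglik(aln, tree, b, quartet_model)
        perm = [2, 0, 3, 1]
        shuffled = Alignment([aln.taxa[i] for i in perm], aln.codes[perm])
        assert dt.exact_loglik(shuffled, tree, b, quartet_model) \
            == pytest.approx(ref, rel=1e-12)

    def test_pattern_compression_preserves_site_count(self, quartet_data):
        aln = quartet_data["aln"]
        _, counts = compress_patterns(aln)
        assert counts.sum() == aln.n_sites

    def test_taxon_mismatch_rejected(self, quartet_data, quartet_model):
        tree = quartet_data["tree"]
        bad = Alignment(["x1", "x2", "x3", "x4"],
                        quartet_data["aln"].codes)
        with pytest.raises(ValueError):
            dt.exact_loglik(bad, tree, quartet_data["b_true"], quartet_model)


class TestBranchApprox:
    def test_recovers_true_lengths_at_large_n(self, quartet_model):
        """MLE consistency: identifiable lengths within 5% at 50 kb.

        Under a reversible model the two root-adjacent branch lengths are
        only identifiable through their sum (pulley principle), so they are
        compared summed.
        """
        tree = dt.simulate_time_tree(4, 1.0, seed=21)
        rates = np.full(len(tree.branch_nodes()), 0.25)
        branches = list(tree.branch_nodes())
        b_true = rates * tree.branch_durations()[branches]
        aln = dt.simulate_alignment(tree, rates, quartet_model, 50000, seed=22)
        ap = dt.fit_branch_approx(aln, tree, quartet_model)
        root_kids = [branches.index(c) for c in tree.children[tree.root]]
        rest = [i for i in range(len(branches)) if i not in root_kids]
        np.testing.assert_allclose(ap.b_hat[rest], b_true[rest], rtol=0.05)
        assert ap.b_hat[root_kids].sum() == pytest.approx(
            b_true[root_kids].sum(), rel=0.05)

    def test_gradient_vanishes_at_optimum(self, quartet_data):
        assert np.max(np.abs(quartet_data["approx"].gradient)) < 1e-4

    def test_hessian_negative_semidefinite(self, quartet_data):
        eig = np.linalg.eigvalsh(quartet_data["approx"].hessian)
        assert np.all(eig <= 1e-3)

    def test_expansion_vanishes_at_its_centre(self, quartet_data):
        ap = quartet_data["approx"]
        assert dt.approx_loglik(ap.b_hat, ap) == pytest.approx(0.0, abs=1e-9)

    def test_tracks_exact_for_small_perturbations(self, quartet_data,
                                                  quartet_model):
        tree, aln, ap = (quartet_data["tree"], quartet_data["aln"],
                        quartet_data["approx"])
        rng = np.random.default_rng(5)
        for _ in range(15):
            b = ap.b_hat * rng.uniform(0.9, 1.1, size=len(ap.b_hat))
            exact = dt.exact_loglik(aln, tree, b, quartet_model) \
                - ap.loglik_at_mle
            assert abs(dt.approx_loglik(b, ap) - exact) < 0.5

    def test_discrepancy_grows_smoothly(self, quartet_data, quartet_model):
        """The approximation error is continuous in the perturbation size."""
        tree, aln, ap = (quartet_data["tree"], quartet_data["aln"],
                        quartet_data["approx"])
        scales = np.linspace(1.0, 1.5, 11)
        errs = []
        for s in scales:
            b = ap.b_hat * s
            exact = dt.exact_loglik(aln, tree, b, quartet_model) \
                - ap.loglik_at_mle
            errs.append(abs(dt.approx_loglik(b, ap) - exact))
        errs = np.array(errs)
        assert errs[0] < 1e-9
        assert np.all(np.diff(errs) > 0)            # monotone growth
        assert np.all(np.abs(np.diff(errs)) < 10.0)  # no discontinuities

    def test_zero_length_branch_is_finite(self, quartet_data):
        ap = quartet_data["approx"]
        b = ap.b_hat.copy()
        b[0] = 0.0
        assert np.isfinite(dt.approx_loglik(b, ap))

    def test_likelihood_decreases_away_from_mle(self, quartet_data,
                                                quartet_model):
        tree, aln, ap = (quartet_data["tree"], quartet_data["aln"],
                        quartet_data["approx"])
        f0 = ap.loglik_at_mle
        for i in range(len(ap.b_hat)):
            for fac in (0.8, 1.25):
                b = ap.b_hat.copy()
                b[i] = max(b[i] * fac, 1e-6)
                assert dt.exact_loglik(aln, tree, b, quartet_model) <= f0 + 1e-6
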