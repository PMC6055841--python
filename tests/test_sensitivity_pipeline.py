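"""Grid orchestration, composite intervals, rate contrasts, scatters."""

import numpy as np
import pandas as pd
import pytest

import divtime as dt
from divtime.mcmc_engine import MCMCConfig, PosteriorSummary
from divtime.sensitivity_pipeline import (
    AnalysisSpec,
    GridDataset,
    branch_rate_differences,
    composite_intervals,
    cross_analysis_scatter,
    filter_long_branch_sequences,
    run_grid,
)


def mock_summary(intervals: dict[str, tuple[float, float]]) -> PosteriorSummary:
    rows = {
        node: {"mean": (lo + hi) / 2, "eq_lo": lo, "eq_hi": hi,
               "hpd_lo": lo, "hpd_hi": hi, "ess": 1000.0}
        for node, (lo, hi) in intervals.items()
    }
    return PosteriorSummary(pd.DataFrame(rows).T)


class TestCompositeIntervals:
    def test_envelope_arithmetic(self):
        """Two crown-age intervals, (206,255) and (149,162), compose to
        (149,255) — the published strategy-A / strategy-E pattern."""
        summaries = {
            "SA": mock_summary({"crown": (206.0, 255.0)}),
            "SE": mock_summary({"crown": (149.0, 162.0)}),
        }
        comp = composite_intervals(summaries)
        assert comp.table.loc["crown", "lower"] == 149.0
        assert comp.table.loc["crown", "upper"] == 255.0

    def test_single_analysis_identity(self):
        summaries = {"SA": mock_summary({"n1": (10.0, 20.0)})}
        comp = composite_intervals(summaries)
        assert comp.table.loc["n1", "lower"] == 10.0
        assert comp.table.loc["n1", "upper"] == 20.0

    def test_exclusion_is_honoured(self):
        summaries = {
            "SA": mock_summary({"n1": (10.0, 20.0)}),
            "SB": mock_summary({"n1": (5.0, 40.0)}),
        }
        comp = composite_intervals(summaries, exclude={"SB"})
        assert comp.table.loc["n1", "upper"] == 20.0
        assert "SB" in comp.excluded

    def test_monotone_under_added_analyses(self):
        base = {"SA": mock_summary({"n1": (10.0, 20.0), "n2": (3.0, 4.0)})}
        extra = dict(base)
        extra["SC"] = mock_summary({"n1": (12.0, 25.0), "n2": (2.0, 3.5)})
        c1 = composite_intervals(base).table
        c2 = composite_intervals(extra).table
        assert (c2["lower"] <= c1["lower"]).all()
        assert (c2["upper"] >= c1["upper"]).all()

    def test_node_mismatch_rejected(self):
        summaries = {
            "SA": mock_summary({"n1": (10.0, 20.0)}),
            "SC": mock_summary({"other": (1.0, 2.0)}),
        }
        with pytest.raises(ValueError, match="lacks"):
            composite_intervals(summaries)


class TestBranchRateDifferences:
    @pytest.fixture()
    def tree(self):
        return dt.simulate_time_tree(6, 1.0, seed=33)

    def test_equal_rates_give_zero_differences(self, tree):
        rates = np.full(len(tree.branch_nodes()), 0.2)
        table = branch_rate_differences(rates, tree)
        assert np.nanmax(table["absolute"].to_numpy()) == 0.0

    def test_contrast_arithmetic(self, tree):
        branches = list(tree.branch_nodes())
        rates = np.full(len(branches), 1.0)
        # pick a branch whose parent also subtends a branch
        child = next(
            i for i, b in enumerate(branches)
            if tree.parent[b] != tree.root and b >= tree.n_tips
        )
        rates[child] = 1.5
        parent_rate = 1.0
        table = branch_rate_differences(rates, tree)
        label = tree.label_of(int(branches[child]))
        assert table.loc[label, "absolute"] == pytest.approx(0.5)
        assert table.loc[label, "proportional"] == pytest.approx(0.5)

    def test_forced_outlier_is_maximal(self, tree):
        branches = list(tree.branch_nodes())
        rng = np.random.default_rng(34)
        rates = rng.uniform(0.18, 0.22, len(branches))
        child = next(
            i for i, b in enumerate(branches)
            if tree.parent[b] != tree.root
        )
        parent_idx = branches.index(int(tree.parent[branches[child]]))
        rates[child] = 3.0 * rates[parent_idx]
        table = branch_rate_differences(rates, tree).dropna()
        label = tree.label_of(int(branches[child]))
        assert table["absolute"].idxmax() == label
        assert table["proportional"].idxmax() == label

    def test_root_adjacent_branches_absent(self, tree):
        rates = np.full(len(tree.branch_nodes()), 0.2)
        table = branch_rate_differences(rates, tree)
        for child in tree.children[tree.root]:
            assert np.isnan(table.loc[tree.label_of(int(child)), "absolute"])


class TestCrossAnalysisScatter:
    def test_identical_summaries_on_identity_line(self):
        s = mock_summary({"n1": (1.0, 2.0), "n2": (3.0, 5.0),
                          "n3": (0.5, 0.9)})
        cmp_ = cross_analysis_scatter(s, s)
        assert cmp_.max_abs_mean_diff == 0.0
        assert cmp_.concordance == pytest.approx(1.0)

    def test_node_mismatch_rejected(self):
        a = mock_summary({"n1": (1.0, 2.0)})
        b = mock_summary({"n2": (1.0, 2.0)})
        with pytest.raises(ValueError):
            cross_analysis_scatter(a, b)


class TestRunGrid:
    def test_cardinality_and_failure_isolation(self):
        rec = dt.SimulationRecipe(n_tips=6, seq_lengths=(400,), mu=0.2,
                                  sigma2=0.3, plan=dt.CalibrationPlan(2, 1),
                                  seed=35)
        ds = dt.simulate_dataset(rec)
        ap = dt.fit_branch_approx(ds.alignments[0], ds.tree, rec.subst)
        dataset = GridDataset(ds.tree, ds.records,
                              {"1P": [dt.ApproxLikelihood(ap)]})
        specs = [
            AnalysisSpec("SA-IR-1P", dt.strategy("SA"), dt.ClockModelSpec(),
                         dt.BDParams(), "1P"),
            AnalysisSpec("SB-IR-1P", dt.strategy("SB"), dt.ClockModelSpec(),
                         dt.BDParams(), "1P"),
            AnalysisSpec("broken", dt.strategy("SA"), dt.ClockModelSpec(),
                         dt.BDParams(), "no-such-scheme"),
        ]
        cfg = MCMCConfig(iterations=1600, burnin=400, seed=3)
        runs = run_grid(dataset, specs, cfg)
        assert set(runs) == {"SA-IR-1P", "SB-IR-1P", "broken"}
        assert runs["broken"].failed
        for label in ("SA-IR-1P", "SB-IR-1P"):
            assert not runs[label].failed
            assert runs[label].posterior.n_draws > 0
            assert runs[label].prior.n_draws > 0

    def test_duplicate_labels_rejected(self):
        spec = AnalysisSpec("x", dt.strategy("SA"), dt.ClockModelSpec(),
                            dt.BDParams())
        with pytest.raises(ValueError):
            run_grid(GridDataset(None, [], {}), [spec, spec],
                     MCMCConfig(iterations=200, burnin=100))


def test_long_branch_filter():
    nwk = "((A:0.05,B:0.05):0.05,(C:0.05,LONG:2.0):0.05);"
    assert filter_long_branch_sequences(nwk, threshold=0.3) == ["LONG"]
    assert filter_long_branch_sequences(nwk, threshold=0.95) == []
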