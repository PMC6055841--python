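"""Calibration densities: normalisation, tail masses, continuity, strategies."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst
from scipy.integrate import quad

import divtime as dt
from divtime.calibrations import CalibrationRecord, SoftUniform, TruncatedCauchy


def integrate(dens, a, b):
    """Piecewise adaptive quadrature honouring the density's breakpoints.

    Heavy (Cauchy) tails need the infinite-interval transform, so an upper
    bound of inf is passed through to quad directly.
    """
    cuts = [a] + [x for x in dens.breakpoints() if a < x < b] + [b]
    total = 0.0
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        total += quad(dens.pdf, lo, hi, limit=400)[0]
    return total


DENSITY_GRID = [
    dt.make_soft_uniform(1.259, 2.474, 0.01, 0.05),
    dt.make_soft_uniform(0.5, 0.6, 0.025, 0.025),
    dt.make_soft_uniform(3.0, 10.0, 0.1, 0.2),
    dt.make_truncated_cauchy(1.259, 0.1, 0.1, 0.01),
    dt.make_truncated_cauchy(1.0, 0.1, 0.01, 0.01),
    dt.make_truncated_cauchy(1.0, 0.1, 0.005, 0.01),
    dt.make_truncated_cauchy(2.0, 0.0, 0.5, 0.05),
    dt.make_point_band(1.0, 0.01),
    dt.make_point_band(4.38, 0.01),
]


@pytest.mark.parametrize("dens", DENSITY_GRID, ids=repr)
class TestDensityContracts:
    def test_normalised(self, dens):
        assert integrate(dens, 0.0, np.inf) == pytest.approx(1.0, abs=1e-6)

    def test_tail_masses(self, dens):
        below = integrate(dens, 0, dens.t_L)
        assert below == pytest.approx(dens.p_L, abs=1e-6)
        if isinstance(dens, SoftUniform):
            above = integrate(dens, dens.t_U, dens.ppf(1 - 1e-13))
            assert above == pytest.approx(dens.p_U, abs=1e-6)

    def test_continuity_at_breakpoints(self, dens):
        eps = 1e-9
        points = [dens.t_L] if isinstance(dens, TruncatedCauchy) \
            else [dens.t_L, dens.t_U]
        for x in points:
            assert dens.pdf(x - eps) == pytest.approx(dens.pdf(x + eps),
                                                      rel=1e-5)

    def test_cdf_matches_quadrature(self, dens):
        for x in [dens.t_L * 0.7, dens.t_L, dens.t_L * 1.3, dens.t_L * 3.0]:
            assert dens.cdf(x) == pytest.approx(integrate(dens, 0, x),
                                                abs=1e-8)

    def test_ppf_inverts_cdf(self, dens):
        q = np.array([1e-4, 0.005, 0.01, 0.3, 0.5, 0.9, 0.95, 0.999])
        np.testing.assert_allclose(dens.cdf(dens.ppf(q)), q, atol=1e-10)

    def test_logpdf_scalar_matches_vector(self, dens):
        for x in [dens.t_L * 0.5, dens.t_L * 1.1, dens.t_L * 4.0]:
            assert dens.logpdf_scalar(x) == pytest.approx(
                float(dens.logpdf(x)), rel=1e-12)


class TestSoftUniform:
    def test_default_tail_split(self):
        """94% between bounds, 1% below, 5% above with the default tails."""
        d = dt.make_soft_uniform(1.259, 2.474, 0.01, 0.05)
        mid, _ = quad(d.pdf, 1.259, 2.474)
        below, _ = quad(d.pdf, 0, 1.259)
        assert mid == pytest.approx(0.94, abs=1e-9)
        assert below == pytest.approx(0.01, abs=1e-9)

    def test_monte_carlo_mean_matches_quadrature(self):
        d = dt.make_soft_uniform(1.0, 2.0, 0.01, 0.05)
        rng = np.random.default_rng(7)
        x = d.sample(10**6, rng)
        se = x.std() / np.sqrt(len(x))
        assert abs(x.mean() - d.mean()) < 3 * se

    @pytest.mark.parametrize("args", [(2.0, 1.0, 0.01, 0.05),
                                      (1.0, 2.0, 0.5, 0.5),
                                      (-1.0, 2.0, 0.01, 0.05)])
    def test_rejects_bad_inputs(self, args):
        with pytest.raises(ValueError):
            dt.make_soft_uniform(*args)


class TestTruncatedCauchy:
    def test_mode_at_offset_location(self):
        d = dt.make_truncated_cauchy(1.0, 0.1, 0.1, 0.01)
        ts = np.linspace(0.5, 3.0, 20001)
        assert ts[np.argmax(d.pdf(ts))] == pytest.approx(1.1, abs=1e-3)

    def test_shorter_tail_concentrates_mass(self):
        masses = [dt.make_truncated_cauchy(1.0, 0.1, c, 0.01).cdf(1.5)
                  for c in (0.1, 0.01, 0.005)]
        assert masses[0] < masses[1] < masses[2]

    def test_small_c_limit_concentrates_above_bound(self):
        """As c -> 0 all non-tail mass piles up just above the minimum."""
        delta = 0.15  # just past the mode offset p = 0.1
        for c, target in [(1e-3, 0.97), (1e-5, 0.9899)]:
            d = dt.make_truncated_cauchy(1.0, 0.1, c, 0.01)
            assert d.cdf(1.0 * (1 + delta)) > target

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            dt.make_truncated_cauchy(-1.0, 0.1, 0.1, 0.01)
        with pytest.raises(ValueError):
            dt.make_truncated_cauchy(1.0, 0.1, 0.0, 0.01)


class TestPointBand:
    def test_band_bounds(self):
        d = dt.make_point_band(1.0, 0.01)
        assert (d.t_L, d.t_U) == (0.99, 1.01)
        d2 = dt.make_point_band(4.38, 0.01)
        assert d2.t_L == pytest.approx(4.3362)
        assert d2.t_U == pytest.approx(4.4238)

    def test_band_mass(self):
        d = dt.make_point_band(1.0, 0.01)
        mid, _ = quad(d.pdf, 0.99, 1.01)
        assert mid == pytest.approx(0.94, abs=1e-9)


@settings(max_examples=50, deadline=None)
@given(
    t_L=hst.floats(0.05, 10.0),
    width=hst.floats(0.01, 5.0),
    p_L=hst.floats(0.001, 0.4),
    p_U=hst.floats(0.001, 0.4),
)
def test_soft_uniform_mass_split_property(t_L, width, p_L, p_U):
    """Closed-form CDF realises exactly the nominal p_L / 1-p_L-p_U / p_U split."""
    d = dt.make_soft_uniform(t_L, t_L + width, p_L, p_U)
    assert d.cdf(d.t_L) == pytest.approx(p_L, rel=1e-9)
    assert d.cdf(d.t_U) == pytest.approx(1 - p_U, rel=1e-9)


class TestApplyStrategy:
    def test_sa_splits_forms_by_record_kind(self, fixture_52):
        tree, records = fixture_52
        dens = dt.apply_strategy(records, tree, dt.strategy("SA"))
        forms = [d.form for d in dens.values()]
        assert len(dens) == 52
        assert forms.count("truncated_cauchy") == 41
        assert forms.count("soft_uniform") == 11

    def test_sb_gives_every_node_a_maximum(self, fixture_52):
        tree, records = fixture_52
        dens = dt.apply_strategy(records, tree, dt.strategy("SB"))
        assert len(dens) == 52
        assert all(d.form == "soft_uniform" for d in dens.values())

    def test_sb_inherits_youngest_ancestral_maximum(self):
        tree = dt.TimeTree.from_newick(
            "(((A:1,B:1)C1:1,X:2)C2:1,(Y:2.5,Z:2.5):0.5)R:0;")
        tree.node_labels.update({"R": tree.root})
        c1 = tree.mrca(["A", "B"])
        c2 = tree.mrca(["A", "X"])
        tree.node_labels.update({"C1": c1, "C2": c2})
        records = [
            CalibrationRecord("R", 2.8, 4.0),
            CalibrationRecord("C2", 1.8),
            CalibrationRecord("C1", 0.9),
        ]
        dens = dt.apply_strategy(records, tree, dt.strategy("SB"))
        assert dens[c2].t_U == 4.0
        assert dens[c1].t_U == 4.0

    def test_sb_without_ancestral_maximum_names_the_node(self):
        tree = dt.TimeTree.from_newick("((A:1,B:1)C1:1,X:2)R:0;")
        tree.node_labels.update({"R": tree.root, "C1": tree.mrca(["A", "B"])})
        records = [CalibrationRecord("R", 1.5), CalibrationRecord("C1", 0.9)]
        with pytest.raises(ValueError, match="R"):
            dt.apply_strategy(records, tree, dt.strategy("SB"))

    def test_se_caps_crown_angiosperms(self, fixture_52):
        tree, records = fixture_52
        dens = dt.apply_strategy(records, tree, dt.strategy("SE"))
        node = tree.node_by_label("crown_angiosperms")
        assert dens[node].form == "soft_uniform"
        assert dens[node].t_U == pytest.approx(1.394)
        meso = tree.node_by_label("crown_mesangiosperms")
        assert dens[meso].t_U == pytest.approx(1.394)

    @pytest.mark.parametrize("name,c", [("SC", 0.01), ("SD", 0.005)])
    def test_sc_sd_shorten_special_tails(self, fixture_52, name, c):
        tree, records = fixture_52
        dens = dt.apply_strategy(records, tree, dt.strategy(name))
        node = tree.node_by_label("crown_angiosperms")
        assert dens[node].c == c
        # everything else keeps the default tail
        other = next(
            tree.node_by_label(r.node_label) for r in records
            if r.t_max is None and r.node_label not in
            ("crown_angiosperms", "crown_mesangiosperms")
        )
        assert dens[other].c == 0.1

    def test_deterministic_and_total(self, fixture_52):
        tree, records = fixture_52
        spec = dt.strategy("SA")
        a = dt.apply_strategy(records, tree, spec)
        b = dt.apply_strategy(records, tree, spec)
        assert set(a) == set(b) == {
            tree.node_by_label(r.node_label) for r in records
        }
        assert all(repr(a[n]) == repr(b[n]) for n in a)
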