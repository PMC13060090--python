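import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, optimize, stats

from metamod.network import MetabolicNetwork, NodeType
from metamod.scores import (
    ScoreTable,
    da_probability,
    fdr_threshold,
    fdr_threshold_params,
    fit_bum,
    project_scores,
    read_score_table,
    sample_pvalues,
    _fdr_curve,
)

from conftest import make_fit


def _mixture_draws(a, lam, n, seed):
    rng = np.random.default_rng(seed)
    noise = rng.random(n)
    signal = rng.random(n) ** (1 / a)
    return np.where(rng.random(n) < lam, noise, signal)


class TestScoreTables:
    def test_zero_pvalues_clamped(self):
        t = ScoreTable.from_pairs({"E1": 0.0, "E2": 0.5}, NodeType.EC)
        assert t.n_clamped == 1
        assert t.entries["E1"][1] == pytest.approx(1e-10)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ScoreTable({"E1": (NodeType.EC, 1.5)})

    def test_read_rejects_duplicates(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("node_id\tnode_type\tp_value\nE1\tEC\t0.1\nE1\tEC\t0.2\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_score_table(str(p))

    def test_read_roundtrip(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("node_id\tnode_type\tp_value\nE1\tEC\t0.1\nM1\tMETABOLITE\t0.9\n")
        t = read_score_table(str(p))
        assert t.entries["M1"] == (NodeType.METABOLITE, 0.9)


class TestProjection:
    def test_partial_ec_coverage(self, toy_net):
        an = project_scores(
            toy_net,
            ScoreTable.from_pairs({"E1": 0.1}, NodeType.EC),
            ScoreTable.from_pairs({}, NodeType.METABOLITE),
        )
        assert an.coverage[NodeType.EC] == pytest.approx(1 / 3)
        assert an.observed == {"E1"}

    def test_empty_tables(self, toy_net):
        an = project_scores(
            toy_net,
            ScoreTable.from_pairs({}, NodeType.EC),
            ScoreTable.from_pairs({}, NodeType.METABOLITE),
        )
        assert an.observed == set()
        assert an.coverage[NodeType.EC] == 0.0

    def test_unknown_ids_dropped_and_counted(self, toy_net):
        an = project_scores(
            toy_net,
            ScoreTable.from_pairs({"E99": 0.1}, NodeType.EC),
            ScoreTable.from_pairs({}, NodeType.METABOLITE),
        )
        assert an.n_dropped == 1
        assert an.observed == set()

    def test_type_conflict_with_network_rejected(self):
        net = MetabolicNetwork.from_edges([("X1", "M1")])
        with pytest.raises(ValueError):
            project_scores(
                net,
                ScoreTable.from_pairs({"M1": 0.1}, NodeType.EC),
                ScoreTable.from_pairs({}, NodeType.METABOLITE),
            )


class TestFitBum:
    def test_parameter_recovery(self):
        p = _mixture_draws(0.3, 0.6, 5000, seed=5)
        fit = fit_bum(p)
        assert fit.a == pytest.approx(0.3, abs=0.05)
        assert fit.lam == pytest.approx(0.6, abs=0.05)

    def test_uniform_data_fits_mostly_noise(self):
        p = np.random.default_rng(6).random(10000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_bum(p)
        assert fit.lam >= 0.9 or fit.a >= 0.9  # a -> 1 makes the signal uniform too

    def test_density_normalizes(self):
        fit = fit_bum(_mixture_draws(0.4, 0.5, 2000, seed=7))
        total, _err = integrate.quad(fit.density, 0, 1)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            fit_bum([0.1] * 10)

    def test_identical_values_degenerate(self):
        with pytest.warns(UserWarning, match="identical"):
            fit = fit_bum([0.5] * 30)
        assert fit.lam > 0.99
        assert fit.boundary

    def test_optimum_not_worse_than_coarse_grid(self):
        p = _mixture_draws(0.2, 0.7, 2000, seed=8)
        fit = fit_bum(p)
        logp = np.log(p)
        grid = np.linspace(1e-6, 1 - 1e-6, 60)
        best = -np.inf
        for a in grid:
            x = a * np.exp((a - 1) * logp)
            ll = np.log(grid[:, None] + (1 - grid[:, None]) * x[None, :]).sum(axis=1)
            best = max(best, float(ll.max()))
        assert fit.loglik >= best - 1e-9


class TestFdrThreshold:
    def test_matches_bisection_root(self):
        fit = make_fit(0.3, 0.6)
        tau = fdr_threshold(fit, 0.1)
        root = optimize.brentq(lambda t: _fdr_curve(t, 0.3, 0.6) - 0.1, 1e-12, 1 - 1e-12)
        assert tau == pytest.approx(root, abs=1e-9)

    def test_monotone_in_fdr(self):
        fit = make_fit(0.3, 0.6)
        assert fdr_threshold(fit, 0.2) > fdr_threshold(fit, 0.1)

    def test_pure_noise_returns_sentinel(self):
        with pytest.warns(UserWarning):
            tau = fdr_threshold_params(0.5, 1 - 1e-6, 0.1)
        assert tau == 0.0

    @pytest.mark.parametrize("seed", range(25))
    def test_closed_form_agrees_with_numeric_root(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0.05, 0.9)
        lam = rng.uniform(0.1, 0.95)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tau = fdr_threshold_params(a, lam, 0.1)
        if tau == 0.0:
            return
        root = optimize.brentq(
            lambda t: _fdr_curve(t, a, lam) - 0.1, 1e-13, 1 - 1e-13, xtol=1e-15
        )
        assert abs(tau - root) <= 1e-9


class TestSamplePvalues:
    def test_zero_draws(self, rng):
        assert sample_pvalues(make_fit(0.5, 0.5), 0, rng).size == 0

    def test_empirical_cdf_matches_mixture(self, rng):
        fit = make_fit(0.5, 0.5)
        draws = sample_pvalues(fit, 50_000, rng)
        expect = 0.5 * 0.25 + 0.5 * 0.25**0.5  # F(0.25) = 0.375
        emp = float(np.mean(draws <= 0.25))
        se = np.sqrt(expect * (1 - expect) / draws.size)
        assert abs(emp - expect) <= 3 * se

    def test_noise_boundary_is_uniform(self, rng):
        fit = make_fit(0.5, 1 - 1e-6, fdr_level=0.5)
        draws = sample_pvalues(fit, 10_000, rng)
        assert stats.kstest(draws, "uniform").pvalue > 0.01


class TestDaProbability:
    def test_one_minus_p_at_one(self):
        assert da_probability(1.0, mode="one_minus_p") == 0.0

    def test_posterior_limit_at_zero(self):
        fit = make_fit(0.3, 0.6)
        assert da_probability(1e-12, fit, mode="bum_posterior") > 0.999

    def test_posterior_worked_value(self):
        fit = make_fit(0.5, 0.5)
        # a * p**(a-1) = 0.70711 at p = 0.5 -> posterior 0.41421
        assert da_probability(0.5, fit, "bum_posterior") == pytest.approx(0.41421, abs=1e-4)

    @settings(max_examples=40, derandomize=True)
    @given(
        a=st.floats(0.05, 0.95),
        lam=st.floats(0.05, 0.95),
        mode=st.sampled_from(["bum_posterior", "one_minus_p"]),
    )
    def test_non_increasing_in_p(self, a, lam, mode):
        fit = make_fit(a, lam, fdr_level=0.5)
        p = np.linspace(1e-6, 1.0, 200)
        vals = da_probability(p, fit, mode)
        assert np.all(np.diff(vals) <= 1e-12)
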