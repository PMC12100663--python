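import numpy as np
import pytest

from mmrst import (
    ModelSpec,
    fit_bmstvi,
    model_structures,
    prepare_log_panel,
    simulate_panel,
    spatial_risk_maps,
    temporal_trend,
)
from mmrst.bmstvi import (
    EFFECTS,
    load_draws,
    rw_structure,
    save_draws,
    split_rhat,
)
from mmrst.core import SpaceTimePanel

from conftest import PAPER_LIKE_SHARES

ALL_STRUCTURED = frozenset(EFFECTS)


@pytest.fixture(scope="module")
def recovery_fit(medium_world):
    """Shared medium-scale fit against a known generator truth."""
    hierarchy, _, weights = medium_world
    panel, truth = simulate_panel(
        hierarchy, weights, 20, PAPER_LIKE_SHARES, seed=21
    )
    spec = ModelSpec(iterations=5000, burnin=2000, thin=3, chains=2, seed=33)
    draws = fit_bmstvi(
        np.log(panel.values), hierarchy, weights, spec, years=panel.years
    )
    return draws, truth, panel, hierarchy, weights


class TestPrepareLogPanel:
    def make(self, vals):
        vals = np.asarray(vals, dtype=float)
        return SpaceTimePanel(
            tuple(f"u{i}" for i in range(vals.shape[0])),
            tuple(range(vals.shape[1])),
            vals,
        )

    def test_natural_log(self):
        out = prepare_log_panel(self.make([[100.0]]))
        assert out[0, 0] == pytest.approx(4.60517, abs=1e-5)

    def test_half_min_rule(self):
        out = prepare_log_panel(self.make([[4.0, 0.0, 9.0]]))
        assert out[0, 1] == pytest.approx(np.log(2.0))

    def test_noop_when_positive(self):
        vals = [[1.0, 2.0], [3.0, 4.0]]
        np.testing.assert_allclose(
            prepare_log_panel(self.make(vals)), np.log(vals)
        )

    def test_offset_rule(self):
        out = prepare_log_panel(self.make([[0.0, 1.0]]), rule="offset", offset=1.0)
        np.testing.assert_allclose(out, [[0.0, np.log(2.0)]])

    def test_drop_rule_marks_nan(self):
        out = prepare_log_panel(self.make([[0.0, 1.0]]), rule="drop")
        assert np.isnan(out[0, 0]) and out[0, 1] == 0.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            prepare_log_panel(self.make([[0.0, 0.0]]))


class TestModelSpec:
    def test_validation(self):
        with pytest.raises(ValueError):
            ModelSpec(iterations=10, burnin=10)
        with pytest.raises(ValueError):
            ModelSpec(a=-1.0)
        with pytest.raises(ValueError):
            ModelSpec(disable=frozenset({"bogus"}))


class TestConjugacy:
    def test_matches_normal_inverse_gamma(self, small_world):
        """With every structured block off the sampler must reproduce the
        flat-mean Normal-Inverse-Gamma posterior."""
        hierarchy, _, weights = small_world
        rng = np.random.default_rng(42)
        Y = rng.normal(3.0, 0.7, size=(hierarchy.n_counties, 2))
        n = Y.size
        spec = ModelSpec(
            iterations=6000, burnin=1000, thin=1, chains=1, seed=7,
            disable=ALL_STRUCTURED,
        )
        d = fit_bmstvi(Y, hierarchy, weights, spec)
        ybar = Y.mean()
        ss = float(((Y - ybar) ** 2).sum())
        a, b = spec.a, spec.b
        # closed forms: alpha | y has mean ybar; sigma2 marginal mean from
        # tau ~ Gamma(a + (n-1)/2, b + ss/2)
        exp_sigma2 = (b + ss / 2) / (a + (n - 1) / 2 - 1)
        mc_se_alpha = d.alpha.std() / np.sqrt(d.n_draws / 10)
        mc_se_s2 = d.sigma2.std() / np.sqrt(d.n_draws / 10)
        assert abs(d.alpha.mean() - ybar) < 3 * mc_se_alpha
        assert abs(d.sigma2.mean() - exp_sigma2) < 3 * mc_se_s2
        # disabled blocks stay at zero
        assert np.all(d.xi == 0.0)
        assert np.all(d.psi == 0.0)


class TestFit:
    def test_sum_to_zero_every_draw(self, recovery_fit):
        draws, *_ = recovery_fit
        for name in ("psi", "omega", "delta", "phi", "gamma", "xi"):
            sums = draws.effect(name).sum(axis=1)
            assert np.abs(sums).max() < 1e-8 * draws.effect(name).shape[1]

    def test_precisions_positive(self, recovery_fit):
        draws, *_ = recovery_fit
        for name in EFFECTS:
            assert np.all(draws.tau[name] > 0)
        assert np.all(draws.sigma2 > 0)

    def test_trend_recovery(self, recovery_fit):
        draws, truth, *_ = recovery_fit
        r = np.corrcoef(draws.psi.mean(axis=0), truth.psi_true)[0, 1]
        assert r > 0.9

    def test_county_effect_recovery(self, recovery_fit):
        draws, truth, *_ = recovery_fit
        r = np.corrcoef(draws.xi.mean(axis=0), truth.xi_true)[0, 1]
        assert r > 0.8

    def test_residual_mean_identity(self, recovery_fit):
        draws, truth, panel, hierarchy, _ = recovery_fit
        Y = np.log(panel.values)
        idx = draws.level_index
        j = draws.n_draws // 2  # arbitrary retained draw
        fitted = (
            draws.alpha[j]
            + draws.psi[j][None, :]
            + (
                draws.omega[j][idx["omega"]]
                + draws.delta[j][idx["delta"]]
                + draws.phi[j][idx["phi"]]
                + draws.gamma[j][idx["gamma"]]
                + draws.xi[j]
            )[:, None]
        )
        assert abs((Y - fitted).mean()) < 0.01

    def test_chain_convergence(self, recovery_fit):
        draws, *_ = recovery_fit
        assert split_rhat(draws.alpha, draws.n_chains) <= 1.05
        assert split_rhat(draws.sigma2, draws.n_chains) <= 1.05
        for name in EFFECTS:
            assert split_rhat(draws.tau[name], draws.n_chains) <= 1.05

    def test_nonfinite_rejected(self, small_world):
        hierarchy, _, weights = small_world
        Y = np.zeros((hierarchy.n_counties, 3))
        Y[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_bmstvi(Y, hierarchy, weights, ModelSpec(iterations=10, burnin=0))


class TestSummaries:
    def test_trend_bands_nested(self, recovery_fit):
        draws, *_ = recovery_fit
        t = temporal_trend(draws)
        assert (t["lo95"] <= t["lo50"]).all()
        assert (t["lo50"] <= t["hi50"]).all()
        assert (t["hi50"] <= t["hi95"]).all()

    def test_monotone_trend_recovered(self, medium_world):
        hierarchy, _, weights = medium_world
        # monotone psi_true: overwrite generator trend by sorting
        panel, truth = simulate_panel(
            hierarchy, weights, 14, PAPER_LIKE_SHARES, seed=77
        )
        psi_sorted = np.sort(truth.psi_true)[::-1]
        idxs = {
            lvl: hierarchy.group_indices(lvl)[0]
            for lvl in ("rural-urban", "region", "province", "city")
        }
        logv = np.log(panel.values) - truth.psi_true[None, :] + psi_sorted[None, :]
        spec = ModelSpec(iterations=1500, burnin=500, thin=2, chains=1, seed=3)
        draws = fit_bmstvi(logv, hierarchy, weights, spec)
        est = temporal_trend(draws)["mean"].to_numpy()
        steps = np.diff(est)
        assert (steps < 0).sum() >= 11  # >= 11 of 13 declining steps

    def test_zero_width_intervals_for_constant_draws(self, recovery_fit):
        import copy

        draws, *_ = recovery_fit
        frozen = copy.copy(draws)
        frozen.psi = np.tile(draws.psi[:1], (draws.n_draws, 1))
        t = temporal_trend(frozen)
        np.testing.assert_allclose(t["lo95"], t["hi95"])

    def test_risk_positive_all_levels(self, recovery_fit):
        draws, *_ = recovery_fit
        for level in ("rural-urban", "region", "province", "city", "county"):
            df = spatial_risk_maps(draws, level)
            assert (df["mean"] > 0).all()
            assert (df["lo95"] > 0).all()

    def test_zero_variance_level_risk_is_one(self, small_world):
        hierarchy, _, weights = small_world
        rng = np.random.default_rng(5)
        Y = rng.normal(0, 0.1, (hierarchy.n_counties, 4))
        spec = ModelSpec(
            iterations=300, burnin=100, thin=1, chains=1, seed=1,
            disable=frozenset({"delta"}),
        )
        draws = fit_bmstvi(Y, hierarchy, weights, spec)
        df = spatial_risk_maps(draws, "region")
        np.testing.assert_allclose(df["mean"], 1.0)

    def test_elevated_region_ranks_highest(self, medium_world):
        hierarchy, _, weights = medium_world
        rng = np.random.default_rng(11)
        s_idx, regions = hierarchy.group_indices("region")
        Y = rng.normal(0.0, 0.3, (hierarchy.n_counties, 8))
        Y += np.where(s_idx == 1, 0.5, 0.0)[:, None]
        spec = ModelSpec(iterations=1200, burnin=400, thin=2, chains=1, seed=2)
        draws = fit_bmstvi(Y, hierarchy, weights, spec)
        df = spatial_risk_maps(draws, "region").set_index("unit")
        assert df["mean"].idxmax() == regions[1]

    def test_invalid_level(self, recovery_fit):
        draws, *_ = recovery_fit
        with pytest.raises(ValueError):
            spatial_risk_maps(draws, "continent")


class TestPersistence:
    def test_roundtrip(self, tmp_path, recovery_fit):
        draws, *_ = recovery_fit
        save_draws(draws, tmp_path / "d.csv", tmp_path / "m.json")
        back = load_draws(tmp_path / "d.csv", tmp_path / "m.json")
        np.testing.assert_allclose(back.alpha, draws.alpha)
        np.testing.assert_allclose(back.xi, draws.xi)
        np.testing.assert_allclose(back.tau["psi"], draws.tau["psi"])
        assert back.n_chains == draws.n_chains
        assert back.years == draws.years
        assert back.level_labels["region"] == draws.level_labels["region"]


def test_rw_structure_rank():
    r1 = rw_structure(6, 1)
    r2 = rw_structure(6, 2)
    assert np.linalg.matrix_rank(r1) == 5
    assert np.linalg.matrix_rank(r2) == 4
    np.testing.assert_allclose(r1.sum(axis=1), 0.0, atol=1e-12)
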