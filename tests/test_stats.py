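import numpy as np
import pandas as pd
import pytest

from eagkit.stats import (
    ModelError,
    PosteriorDraws,
    ecotype_contrast,
    fit_strength_model,
    fit_timing_model,
    group_mean_summary,
    inverse_transform_strength,
    simulate_posterior,
    stars_for_certainty,
    summarize_comparison,
    summarize_strength_contrasts,
    transform_strength,
)

DURATIONS = (15.0, 30.0, 150.0, 300.0)


def metrics_table(
    n_per_ecotype=4,
    log2_ratio=0.0,
    antenna_sd=0.0,
    noise_sd=0.0,
    onset_ratio_log2=0.0,
    seed=0,
):
    """Strength data generated directly on the modelling scale.

    Transformed strength = base + duration effect + ecotype effect +
    antenna intercept + residual, then back-transformed, so the true model
    coefficients are known exactly.
    """
    rng = np.random.default_rng(seed)
    dur_effect = {15.0: 0.0, 30.0: 1.0, 150.0: 2.5, 300.0: 3.2}
    rows = []
    for eco, eco_eff in (("full-winged", 0.0), ("wing-reduced", log2_ratio)):
        for a in range(n_per_ecotype):
            intercept = rng.normal(0.0, antenna_sd)
            onset = 0.1 * 2.0 ** (onset_ratio_log2 if eco == "wing-reduced" else 0.0)
            for d in DURATIONS:
                y = -2.0 + dur_effect[d] + eco_eff + intercept + rng.normal(0, noise_sd)
                rows.append(
                    {
                        "antenna_id": f"{eco[:2]}{a}",
                        "ecotype": eco,
                        "population": "p",
                        "odorant": "2-heptanone",
                        "pulse_duration_ms": d,
                        "strength_mV": float(inverse_transform_strength(y)),
                        "onset_s": onset,
                        "offset_s": 1.0,
                    }
                )
    return pd.DataFrame(rows)


class TestTransform:
    def test_offset_examples(self):
        assert transform_strength(0.99) == pytest.approx(0.0, abs=1e-12)
        assert transform_strength(1.99) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("x", [0.001, 0.5, 7.3])
    def test_round_trip(self, x):
        assert inverse_transform_strength(transform_strength(x)) == pytest.approx(
            x, abs=1e-12
        )

    def test_domain_error(self):
        with pytest.raises(ValueError, match="rows"):
            transform_strength(np.array([0.5, -0.02]))


class TestFitStrengthModel:
    def test_noiseless_recovery_exact(self):
        table = metrics_table(log2_ratio=-1.0)
        fit = fit_strength_model(table)
        assert fit.params["ecotype[wing-reduced]"] == pytest.approx(-1.0, abs=1e-8)
        for d in (30, 150, 300):
            assert fit.params[f"ecotype[wing-reduced]:dur[{d}]"] == pytest.approx(
                0.0, abs=1e-8
            )
        assert fit.re_var == pytest.approx(0.0, abs=1e-6)

    def test_row_order_invariance(self):
        table = metrics_table(log2_ratio=-0.5, antenna_sd=0.3, noise_sd=0.2, seed=3)
        fit1 = fit_strength_model(table)
        shuffled = table.sample(frac=1.0, random_state=7).reset_index(drop=True)
        fit2 = fit_strength_model(shuffled)
        assert np.allclose(fit1.params.to_numpy(), fit2.params.to_numpy(), atol=1e-8)

    def test_constant_shift_moves_only_intercept(self):
        table = metrics_table(log2_ratio=-0.5, antenna_sd=0.3, noise_sd=0.2, seed=5)
        fit1 = fit_strength_model(table)
        shifted = table.copy()
        shifted["strength_mV"] = inverse_transform_strength(
            transform_strength(shifted["strength_mV"].to_numpy()) + 2.0
        )
        fit2 = fit_strength_model(shifted)
        assert fit2.params["intercept"] == pytest.approx(
            fit1.params["intercept"] + 2.0, abs=1e-6
        )
        assert np.allclose(
            fit1.params.drop("intercept").to_numpy(),
            fit2.params.drop("intercept").to_numpy(),
            atol=1e-6,
        )

    def test_single_ecotype_rejected(self):
        table = metrics_table()
        with pytest.raises(ModelError, match="ecotype"):
            fit_strength_model(table[table["ecotype"] == "full-winged"])

    def test_random_intercept_absorbs_antenna_variance(self):
        table = metrics_table(antenna_sd=1.0, noise_sd=0.1, n_per_ecotype=10, seed=2)
        fit = fit_strength_model(table)
        assert fit.re_var > 5 * fit.scale


class TestFitTimingModel:
    def test_two_group_geometric_means_closed_form(self):
        # fw onsets {0.05, 0.2} (gm 0.1) vs wr {0.1, 0.4} (gm 0.2) -> coef 1.0
        rows = []
        for eco, onsets in (
            ("full-winged", [0.05, 0.2]),
            ("wing-reduced", [0.1, 0.4]),
        ):
            for i, onset in enumerate(onsets):
                rows.append(
                    {
                        "antenna_id": f"{eco[:2]}{i}",
                        "ecotype": eco,
                        "population": "p",
                        "odorant": "x",
                        "pulse_duration_ms": 300.0,
                        "strength_mV": 1.0,
                        "onset_s": onset,
                        "offset_s": 1.0,
                    }
                )
        fit = fit_timing_model(pd.DataFrame(rows), which="onset")
        assert fit.params["ecotype[wing-reduced]"] == pytest.approx(1.0, abs=1e-12)

    def test_equal_groups_zero_coefficient(self):
        table = metrics_table(onset_ratio_log2=0.0)
        fit = fit_timing_model(table, which="onset")
        assert fit.params["ecotype[wing-reduced]"] == pytest.approx(0.0, abs=1e-12)

    def test_invalid_rows_excluded_and_counted(self):
        table = metrics_table(n_per_ecotype=4)
        table.loc[table.index[3], "onset_s"] = np.nan
        table.loc[table.index[7], "onset_s"] = -0.1
        sub = table[table["pulse_duration_ms"] == 300.0]
        bad = int(sub["onset_s"].isna().sum() + (sub["onset_s"] <= 0).sum())
        fit = fit_timing_model(table, which="onset")
        assert fit.n_dropped == bad
        assert fit.n_obs == len(sub) - bad

    def test_uses_only_300ms_rows(self):
        table = metrics_table(onset_ratio_log2=1.0)
        fit = fit_timing_model(table, which="onset")
        assert fit.n_obs == 8  # 4 antennae x 2 ecotypes

    def test_too_few_antennae_rejected(self):
        table = metrics_table(n_per_ecotype=1)
        with pytest.raises(ModelError):
            fit_timing_model(table, which="onset")

    def test_which_validated(self):
        with pytest.raises(ValueError, match="which"):
            fit_timing_model(metrics_table(), which="peak")


@pytest.fixture(scope="module")
def linear_fit():
    return fit_timing_model(
        metrics_table(n_per_ecotype=8, onset_ratio_log2=0.5, noise_sd=0.0, seed=1)
        .assign(onset_s=lambda df: df["onset_s"] * np.random.default_rng(0).lognormal(0, 0.2, len(df)))
    )


@pytest.fixture(scope="module")
def mixed_fit():
    return fit_strength_model(
        metrics_table(n_per_ecotype=8, log2_ratio=-0.5, antenna_sd=0.4,
                      noise_sd=0.2, seed=4)
    )


class TestSimulatePosterior:
    def test_same_seed_identical(self, mixed_fit):
        d1 = simulate_posterior(mixed_fit, n_sim=500, seed=7)
        d2 = simulate_posterior(mixed_fit, n_sim=500, seed=7)
        assert d1.coef.equals(d2.coef)
        assert np.array_equal(d1.sigma2, d2.sigma2)

    def test_exactly_n_sim_rows(self, mixed_fit):
        assert simulate_posterior(mixed_fit, n_sim=123, seed=0).n_sim == 123

    @pytest.mark.parametrize("which", ["linear", "mixed"])
    def test_draw_mean_near_estimates(self, which, linear_fit, mixed_fit):
        fit = linear_fit if which == "linear" else mixed_fit
        draws = simulate_posterior(fit, n_sim=10_000, seed=3)
        se = np.sqrt(np.diag(fit.cov.to_numpy()))
        err = np.abs(draws.coef.mean().to_numpy() - fit.params.to_numpy())
        assert np.all(err < 5 * se / np.sqrt(10_000) + 5e-3)

    def test_empirical_covariance_matches_fit(self, mixed_fit):
        draws = simulate_posterior(mixed_fit, n_sim=10_000, seed=9)
        emp = np.cov(draws.coef.to_numpy().T)
        ref = mixed_fit.cov.to_numpy()
        rel = np.linalg.norm(emp - ref) / np.linalg.norm(ref)
        assert rel < 0.10

    def test_linear_sigma2_follows_inverse_chi2(self, linear_fit):
        draws = simulate_posterior(linear_fit, n_sim=10_000, seed=5)
        df = linear_fit.df_resid
        # posterior mean of sigma2 = scale * df / (df - 2)
        expected = linear_fit.scale * df / (df - 2.0)
        assert np.mean(draws.sigma2) == pytest.approx(expected, rel=0.1)

    def test_invalid_n_sim_rejected(self, mixed_fit):
        with pytest.raises(ValueError):
            simulate_posterior(mixed_fit, n_sim=0)


def draws_from_values(values):
    return PosteriorDraws(
        coef=pd.DataFrame({"intercept": np.zeros(len(values)),
                           "ecotype[wing-reduced]": -np.asarray(values)}),
        sigma2=np.ones(len(values)),
        kind="linear",
        seed=None,
    )


class TestSummarizeComparison:
    def contrast(self):
        c = pd.Series(0.0, index=["intercept", "ecotype[wing-reduced]"])
        c["ecotype[wing-reduced]"] = -1.0
        return c

    def test_all_positive_draws_two_stars(self):
        s = summarize_comparison(draws_from_values(np.linspace(0.1, 1, 1000)), self.contrast())
        assert s.certainty == 1.0
        assert s.stars == "**"
        assert s.direction == "full-winged > wing-reduced"

    def test_symmetric_draws_no_stars(self):
        vals = np.concatenate([np.linspace(-1, -0.001, 500), np.linspace(0.001, 1, 500)])
        s = summarize_comparison(draws_from_values(vals), self.contrast())
        assert s.certainty == pytest.approx(0.5, abs=0.01)
        assert s.stars == ""

    def test_certainty_097_gets_one_star(self):
        vals = np.concatenate([np.full(970, 1.0), np.full(30, -1.0)])
        s = summarize_comparison(draws_from_values(vals), self.contrast())
        assert s.certainty == pytest.approx(0.97)
        assert s.stars == "*"

    def test_interval_is_quantile_range(self):
        vals = np.arange(10_000, dtype=float)
        s = summarize_comparison(draws_from_values(vals), self.contrast())
        assert s.lo95 == pytest.approx(np.quantile(vals, 0.025))
        assert s.hi95 == pytest.approx(np.quantile(vals, 0.975))
        assert s.lo95 <= s.mean <= s.hi95

    def test_star_boundaries_strict(self):
        assert stars_for_certainty(0.95) == ""
        assert stars_for_certainty(0.951) == "*"
        assert stars_for_certainty(0.99) == "*"
        assert stars_for_certainty(0.991) == "**"


class TestContrastsAndGroupMeans:
    def test_per_duration_contrasts_recover_truth(self):
        table = metrics_table(n_per_ecotype=10, log2_ratio=-0.8, antenna_sd=0.2,
                              noise_sd=0.05, seed=6)
        fit = fit_strength_model(table)
        draws = simulate_posterior(fit, n_sim=4000, seed=1)
        summary = summarize_strength_contrasts(fit, draws)
        assert len(summary) == 4
        # fw - wr = +0.8 at every duration
        assert np.allclose(summary["mean_log2"], 0.8, atol=0.25)
        assert (summary["stars"] == "**").all()

    def test_group_means_backtransform(self):
        table = metrics_table(n_per_ecotype=10, log2_ratio=-1.0, noise_sd=0.01, seed=8)
        fit = fit_strength_model(table)
        draws = simulate_posterior(fit, n_sim=4000, seed=2)
        gm = group_mean_summary(fit, draws, duration_ms=300.0, backtransform_offset=0.01)
        fw = gm.loc[gm["ecotype"] == "full-winged", "mean"].iloc[0]
        wr = gm.loc[gm["ecotype"] == "wing-reduced", "mean"].iloc[0]
        # true values: 2^(1.2) - 0.01 and 2^(0.2) - 0.01
        assert fw == pytest.approx(2**1.2 - 0.01, rel=0.05)
        assert wr == pytest.approx(2**0.2 - 0.01, rel=0.05)
        assert (gm["lo95"] <= gm["mean"]).all() and (gm["mean"] <= gm["hi95"]).all()

    def test_unknown_duration_rejected(self):
        fit = fit_strength_model(metrics_table(noise_sd=0.1, seed=9))
        with pytest.raises(ValueError, match="duration"):
            ecotype_contrast(fit, duration_ms=77.0)


class TestCalibrationProperties:
    """Direct simulation of the modelling-scale generative process (fast)."""

    def _one_replicate(self, seed, log2_ratio, n=8):
        table = metrics_table(
            n_per_ecotype=n, log2_ratio=log2_ratio, antenna_sd=0.4,
            noise_sd=0.25, seed=seed,
        )
        fit = fit_strength_model(table)
        draws = simulate_posterior(fit, n_sim=1000, seed=seed)
        return summarize_comparison(draws, ecotype_contrast(fit, 300.0))

    def test_power_monotone_in_effect_size(self):
        n_rep = 30
        rates = []
        for effect in (0.0, -0.6, -1.5):
            hits = sum(
                self._one_replicate(1000 + i, effect).stars != ""
                for i in range(n_rep)
            )
            rates.append(hits / n_rep)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] > 0.9

    def test_interval_width_shrinks_with_n(self):
        widths = []
        for n in (5, 10, 20):
            w = [
                (lambda s: s.hi95 - s.lo95)(self._one_replicate(2000 + i, 0.0, n=n))
                for i in range(12)
            ]
            widths.append(np.mean(w))
        assert widths[0] > widths[1] > widths[2]
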