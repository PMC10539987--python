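"""Effect sizes, regression contrasts, correlations, and mediation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import painattrib as pa


class TestHedgesG:
    def test_identical_samples_zero(self):
        res = pa.hedges_g([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.g == pytest.approx(0.0)
        assert res.ci_low <= 0 <= res.ci_high

    def test_hand_computed_example(self):
        """x={0,2}, y={-1,1}: s_pooled=sqrt(2), d=1/sqrt(2), J=4/7."""
        res = pa.hedges_g([0.0, 2.0], [-1.0, 1.0])
        assert res.g == pytest.approx(4.0 / (7.0 * np.sqrt(2.0)))
        df = 2
        var_g = (2 + 2) / (2 * 2) + res.g**2 / (2 * df)
        assert res.ci_high - res.g == pytest.approx(1.96 * np.sqrt(var_g))

    def test_antisymmetry(self, rng):
        x, y = rng.normal(1, 1, 20), rng.normal(0, 1, 25)
        a, b = pa.hedges_g(x, y), pa.hedges_g(y, x)
        assert a.g == pytest.approx(-b.g)
        assert a.ci_low == pytest.approx(-b.ci_high)
        assert a.ci_high == pytest.approx(-b.ci_low)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        st.floats(-50, 50),
        st.floats(0.1, 20),
        st.integers(0, 2**31 - 1),
    )
    def test_affine_invariance(self, shift, scale, seed):
        r = np.random.default_rng(seed)
        x, y = r.normal(0.5, 1, 15), r.normal(0, 1, 18)
        base = pa.hedges_g(x, y)
        moved = pa.hedges_g(x * scale + shift, y * scale + shift)
        assert moved.g == pytest.approx(base.g, rel=1e-9, abs=1e-9)

    def test_degenerate_zero_variance(self):
        res = pa.hedges_g([1.0, 1.0], [1.0, 1.0])
        assert res.g == 0.0
        res = pa.hedges_g([2.0, 2.0], [1.0, 1.0])
        assert np.isinf(res.g) and res.g > 0


def _standardize(v):
    return (v - v.mean()) / v.std(ddof=1)


class TestAncova:
    def test_null_when_outcome_equals_baseline(self, rng):
        n = 60
        base = rng.normal(0, 1, n)
        data = pd.DataFrame(
            {
                "arm": np.repeat(["prt", "placebo"], n // 2),
                "baseline": base,
                "outcome": base,
            }
        )
        res = pa.ancova_effect(
            data, "outcome", contrasts=[("prt", "placebo")], covariates=["baseline"]
        )["prt_vs_placebo"]
        assert abs(res.beta_standardized) < 1e-8

    def test_beta_matches_normal_equations_oracle(self):
        """Six hand-rows: compare against an explicit normal-equations solve."""
        data = pd.DataFrame(
            {
                "arm": ["prt", "prt", "prt", "placebo", "placebo", "placebo"],
                "baseline": [1.0, 2.0, 3.0, 1.5, 2.5, 0.5],
                "outcome": [3.0, 4.0, 6.0, 1.0, 2.0, 0.5],
            }
        )
        res = pa.ancova_effect(
            data, "outcome", contrasts=[("prt", "placebo")], covariates=["baseline"]
        )["prt_vs_placebo"]
        y = _standardize(data["outcome"].to_numpy())
        X = np.column_stack(
            [
                np.ones(6),
                (data["arm"] == "prt").astype(float).to_numpy(),
                _standardize(data["baseline"].to_numpy()),
            ]
        )
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        sigma2 = resid @ resid / (6 - 3)
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        assert res.beta_standardized == pytest.approx(beta[1], abs=1e-10)
        assert res.t == pytest.approx(beta[1] / se, abs=1e-8)
        assert res.df == 3

    def test_collinear_design_fails(self):
        data = pd.DataFrame(
            {
                "arm": ["prt", "prt", "placebo", "placebo", "prt", "placebo"],
                "c1": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                "c2": [2.0, 4.0, 6.0, 8.0, 10.0, 12.0],
                "outcome": [1.0, 0.0, 2.0, 1.0, 3.0, 2.0],
            }
        )
        with pytest.raises(ValueError, match="collinear"):
            pa.ancova_effect(
                data, "outcome", contrasts=[("prt", "placebo")], covariates=["c1", "c2"]
            )

    def test_treatment_effect_detected_with_power(self):
        """A positive generative a-path yields a positive, significant PRT
        contrast on the score change in nearly every replicate."""
        hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            cfg = pa.SimulationConfig(n_per_arm=200, seed=seed)
            _, truth = pa.generate_trial(cfg)
            d = truth.delta_score.copy()
            d["arm"] = np.repeat(["prt", "placebo", "usual_care"], 200)
            res = pa.ancova_effect(
                d, "delta_score_true", contrasts=[("prt", "placebo")]
            )["prt_vs_placebo"]
            hits += (res.beta_standardized > 0) and (res.p < 0.05)
        assert hits >= int(0.95 * n_seeds)


class TestAssociation:
    def test_perfect_negative_relation(self):
        data = pd.DataFrame(
            {"delta": [0.0, 1.0, 2.0, 3.0], "pain": [6.0, 5.0, 4.0, 3.0]}
        )
        model, r = pa.association_change_vs_outcome(
            data, "delta", "pain", baseline=None, condition=None
        )
        assert r.r == pytest.approx(-1.0)
        assert r.df == 2

    def test_pearson_matches_covariance_formula(self):
        x = np.array([1.0, 2.0, 4.0, 4.5, 7.0])
        y = np.array([2.0, 1.0, 5.0, 3.0, 6.0])
        r = pa.pearson_r(x, y)
        num = ((x - x.mean()) * (y - y.mean())).sum()
        den = np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert r.r == pytest.approx(num / den, abs=1e-12)
        assert r.df == 3

    def test_negative_mediator_outcome_path_sign_recovered(self):
        """b_true < 0 shows up as a negative fitted coefficient in nearly
        every replicate at trial scale."""
        hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            cfg = pa.SimulationConfig(n_per_arm=150, seed=100 + seed)
            ds, truth = pa.generate_trial(cfg)
            d = ds.participants.merge(truth.delta_score, on="participant_id")
            model, r = pa.association_change_vs_outcome(
                d, "delta_score_true", "pain_post", baseline="pain_pre"
            )
            hits += model.beta_standardized < 0
        assert hits >= int(0.95 * n_seeds)

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError, match="zero variance"):
            pa.pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


@pytest.fixture(scope="module")
def trial_frame():
    cfg = pa.SimulationConfig(n_per_arm=100, seed=21)
    ds, truth = pa.generate_trial(cfg)
    d = ds.participants.merge(truth.delta_score, on="participant_id")
    d["prt"] = (d["arm"] == "prt").astype(float)
    return d


class TestMediation:
    def test_indirect_equals_total_minus_direct(self, trial_frame):
        med = pa.mediate(
            trial_frame, "prt", "delta_score_true", "pain_1yr",
            covariates=["pain_pre"], n_boot=50, seed=3,
        )
        assert abs(med.indirect - (med.c - med.c_prime)) < 1e-10

    def test_bootstrap_reproducible(self, trial_frame):
        kw = dict(x="prt", m="delta_score_true", y="pain_1yr",
                  covariates=["pain_pre"], n_boot=200, seed=9)
        m1 = pa.mediate(trial_frame, **kw)
        m2 = pa.mediate(trial_frame, **kw)
        assert m1.boot_ci_low == m2.boot_ci_low
        assert m1.boot_ci_high == m2.boot_ci_high
        assert (m1.boot_indirect == m2.boot_indirect).all()

    def test_negative_indirect_detected(self, trial_frame):
        med = pa.mediate(
            trial_frame, "prt", "delta_score_true", "pain_1yr",
            covariates=["pain_pre"], n_boot=1000, seed=4,
        )
        assert med.indirect < 0
        assert med.boot_ci_high < 0  # clearly resolved at this effect size

    def test_mean_estimate_matches_generative_standardized_paths(self):
        """Across seeds the mean standardized indirect estimate agrees with
        the population value computed by brute force from the generative
        equations (one huge structural-equation draw, no text layer)."""
        b_true, direct, noise = -0.3, -0.5, 1.0
        cfg0 = pa.SimulationConfig(
            n_per_arm=500, seed=0, a_true=1.3, mindbrain_shift_prt=None,
            b_true=b_true, direct_true=direct, noise_sd=noise, dropout_rate=0.0,
        )
        shift, pmb = cfg0.mindbrain_shift_prt, cfg0.prob_mindbrain_pre

        # population oracle: draw the structural model directly at n=600k
        r = np.random.default_rng(999)
        n = 600_000
        x = (np.arange(n) % 3 == 0).astype(float)  # one third treated
        pre = r.binomial(3, pmb, n)
        p_post = np.where(x == 1, shift + (1 - shift) * pmb, pmb)
        post = r.binomial(3, p_post)
        m = (post - pre).astype(float)
        pain_pre = np.clip(r.normal(4.10, 1.26, n), 0, 10)
        y = np.clip(pain_pre + direct * x + b_true * m + r.normal(0, noise, n), 0, 10)
        def z(v):
            return (v - v.mean()) / v.std(ddof=1)

        ones = np.ones(n)
        xs, ms, ys, cs = z(x), z(m), z(y), z(pain_pre)
        a_pop = np.linalg.lstsq(
            np.column_stack([ones, xs, cs]), ms, rcond=None
        )[0][1]
        b_pop = np.linalg.lstsq(
            np.column_stack([ones, xs, ms, cs]), ys, rcond=None
        )[0][2]
        oracle = a_pop * b_pop

        estimates = []
        for seed in range(40):
            cfg = pa.SimulationConfig(
                n_per_arm=500, seed=seed, a_true=1.3, mindbrain_shift_prt=None,
                b_true=b_true, direct_true=direct, noise_sd=noise, dropout_rate=0.0,
            )
            ds, truth = pa.generate_trial(cfg)
            d = ds.participants.merge(truth.delta_score, on="participant_id")
            d["prt"] = (d["arm"] == "prt").astype(float)
            estimates.append(
                pa.mediate(d, "prt", "delta_score_true", "pain_1yr",
                           covariates=["pain_pre"], n_boot=1, seed=seed).indirect
            )
        assert np.mean(estimates) == pytest.approx(oracle, rel=0.10)

    def test_too_few_cases_rejected(self):
        d = pd.DataFrame({"x": [0.0, 1.0], "m": [0.1, 0.2], "y": [1.0, 2.0]})
        with pytest.raises(ValueError, match="too few"):
            pa.mediate(d, "x", "m", "y", n_boot=10, seed=0)
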