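"""SEM: implied moments, ML fitting, indices, effects, model selection."""

import math

import numpy as np
import pandas as pd
import pytest

from flavopath import published
from flavopath.semfit import (
    FitIndices,
    SemSpec,
    effects_decomposition,
    effects_from_edges,
    fit_indices,
    fit_sem,
    implied_covariance,
    parse_spec,
    select_models,
)
from flavopath.synth import default_config, generate

CHAIN = SemSpec(variables=("X", "M", "Y"),
                regressions=(("X", "M"), ("M", "Y")))

A_MODEL = SemSpec(
    variables=("X_AMAT", "X_MAW", "Y_CGC", "a"),
    regressions=(("X_AMAT", "Y_CGC"), ("X_MAW", "Y_CGC"),
                 ("Y_CGC", "a"), ("X_AMAT", "a"), ("X_MAW", "a")),
    exogenous_covariances=(("X_AMAT", "X_MAW"),))


def _chain_data(n=400, seed=0, b1=0.45, b2=0.75):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    m = b1 * x + rng.normal(size=n) * math.sqrt(1 - b1**2)
    y = b2 * m + rng.normal(size=n) * math.sqrt(1 - b2**2)
    return pd.DataFrame({"X": x, "M": m, "Y": y})


class TestSpec:
    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            SemSpec(variables=("A", "B"),
                    regressions=(("A", "B"), ("B", "A")))

    def test_undeclared_variable_rejected(self):
        with pytest.raises(ValueError, match="undeclared"):
            SemSpec(variables=("A",), regressions=(("A", "B"),))

    def test_degrees_of_freedom_formula(self):
        # chain: 6 moments, 5 free (2 betas + 1 exog var + 2 resid) -> df 1
        assert CHAIN.degrees_of_freedom() == 1
        assert A_MODEL.degrees_of_freedom() == 0

    def test_text_grammar_round_trip(self):
        text = """
        # lightness model
        X_MAW -> Y_PG
        Y_PG -> L
        X_MAW -> L
        X_AMAT ~~ X_MAW
        """
        spec = parse_spec(text, variables=("X_MAW", "X_AMAT", "Y_PG", "L"))
        assert ("X_MAW", "Y_PG") in spec.regressions
        assert ("X_AMAT", "X_MAW") in spec.exogenous_covariances

    def test_unparseable_line_raises(self):
        with pytest.raises(ValueError, match="line"):
            parse_spec("X_MAW with L")


class TestImpliedCovariance:
    def test_all_edges_zero_gives_diagonal(self):
        spec = SemSpec(variables=("X", "Y"), regressions=(("X", "Y"),))
        sigma = implied_covariance(spec, [0.0, 2.0, 3.0])
        assert np.allclose(sigma, np.diag([2.0, 3.0]))

    def test_single_edge_closed_form(self):
        spec = SemSpec(variables=("X", "Y"), regressions=(("X", "Y"),))
        sigma = implied_covariance(spec, [0.7, 1.0, 1.0])
        assert sigma[0, 1] == pytest.approx(0.7)
        assert sigma[1, 1] == pytest.approx(1.49)  # 0.7^2 + residual 1.0

    def test_matches_monte_carlo_oracle(self):
        """Implied covariance of a small spec agrees with a brute-force
        simulation of its generative equations at n = 1e6."""
        theta = [0.45, 0.75, 1.0, 1.0 - 0.45**2, 1.0 - 0.75**2]
        sigma = implied_covariance(CHAIN, theta)
        rng = np.random.default_rng(0)
        n = 1_000_000
        x = rng.normal(size=n)
        m = 0.45 * x + rng.normal(size=n) * math.sqrt(theta[3])
        y = 0.75 * m + rng.normal(size=n) * math.sqrt(theta[4])
        mc = np.cov(np.vstack([x, m, y]))
        assert np.abs(sigma - mc).max() < 0.01

    def test_wrong_theta_length_raises(self):
        with pytest.raises(ValueError, match="length"):
            implied_covariance(CHAIN, [0.1, 0.2])


class TestFit:
    def test_saturated_model_reproduces_sample_cov(self):
        rng = np.random.default_rng(5)
        frame = pd.DataFrame(rng.normal(size=(60, 3)), columns=["A", "B", "C"])
        spec = SemSpec(variables=("A", "B", "C"), regressions=(),
                       exogenous_covariances=(("A", "B"), ("A", "C"), ("B", "C")))
        fit = fit_sem(frame, spec)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-6)
        assert np.abs(fit.implied_cov.to_numpy()
                      - fit.sample_cov.to_numpy()).max() < 1e-6
        assert fit.df == 0

    def test_just_identified_chain_chi2_zero(self):
        frame = _chain_data(seed=2)
        spec = SemSpec(variables=("X", "M", "Y"),
                       regressions=(("X", "M"), ("M", "Y"), ("X", "Y")))
        fit = fit_sem(frame, spec)
        assert fit.df == 0
        assert fit.chi2 == pytest.approx(0.0, abs=1e-6)

    def test_chain_standardized_recovery_single_draw(self):
        frame = _chain_data(n=2000, seed=3)
        fit = fit_sem(frame, CHAIN)
        assert fit.converged
        assert fit.standardized["X->M"] == pytest.approx(0.45, abs=0.06)
        assert fit.standardized["M->Y"] == pytest.approx(0.75, abs=0.06)

    def test_covariance_input_equivalent_to_raw_data(self):
        frame = _chain_data(seed=4)
        fit_raw = fit_sem(frame, CHAIN)
        fit_cov = fit_sem((frame.cov(), len(frame)), CHAIN)
        for name in fit_raw.estimates:
            assert fit_cov.estimates[name] == pytest.approx(
                fit_raw.estimates[name], abs=1e-5)

    def test_scale_invariance_of_standardized_output_and_chi2(self):
        frame = _chain_data(seed=6)
        scaled = frame.copy()
        scaled["M"] = scaled["M"] * 37.0
        a = fit_sem(frame, CHAIN)
        b = fit_sem(scaled, CHAIN)
        assert b.chi2 == pytest.approx(a.chi2, abs=1e-4)
        for name in a.standardized:
            assert b.standardized[name] == pytest.approx(
                a.standardized[name], abs=1e-5)

    def test_pre_standardized_data_estimates_equal_standardized(self):
        frame = _chain_data(seed=7)
        z = (frame - frame.mean()) / frame.std(ddof=1)
        fit = fit_sem(z, CHAIN)
        for s, t in CHAIN.regressions:
            name = f"{s}->{t}"
            assert fit.standardized[name] == pytest.approx(
                fit.estimates[name], abs=0.02)

    def test_nested_models_chi2_monotone(self):
        """Freeing an extra edge can only lower the ML discrepancy."""
        frame = _chain_data(seed=8)
        restricted = fit_sem(frame, CHAIN)
        full = fit_sem(frame, SemSpec(
            variables=("X", "M", "Y"),
            regressions=(("X", "M"), ("M", "Y"), ("X", "Y"))))
        assert full.chi2 <= restricted.chi2 + 1e-6

    def test_non_positive_definite_cov_rejected(self):
        S = pd.DataFrame(np.ones((3, 3)), index=list("XMY"),
                         columns=list("XMY"))
        with pytest.raises(ValueError, match="positive definite"):
            fit_sem((S, 100), CHAIN)

    def test_small_sample_warns(self):
        frame = _chain_data(n=12, seed=9)
        with pytest.warns(UserWarning, match="small sample"):
            fit_sem(frame, CHAIN)

    def test_r2_matches_one_minus_standardized_residual(self):
        frame = _chain_data(seed=10)
        fit = fit_sem(frame, CHAIN)
        for var, r2 in fit.r2.items():
            assert 0.0 <= r2 <= 1.0
            assert r2 == pytest.approx(
                1.0 - fit.standardized[f"{var}~~{var}"], abs=1e-10)

    def test_wald_tests_flag_strong_edges(self):
        frame = _chain_data(n=500, seed=11)
        fit = fit_sem(frame, CHAIN)
        wald = fit.wald_tests()
        assert wald.loc["X->M", "p"] < 0.01
        assert wald.loc["X->M", "stars"] == "**"


class TestIndices:
    def test_rmsea_closed_form(self):
        idx = fit_indices(4.0, 2, 101, np.eye(2), np.eye(2), 1)
        assert idx.rmsea == pytest.approx(0.1)
        assert idx.cmin_df == pytest.approx(2.0)

    def test_rmsea_clamped_at_zero(self):
        idx = fit_indices(1.5, 2, 101, np.eye(2), np.eye(2), 1)
        assert idx.rmsea == 0.0

    def test_perfect_fit_gfi_agfi_one(self):
        S = np.array([[2.0, 0.5], [0.5, 1.0]])
        idx = fit_indices(0.0, 1, 50, S, S, 2)
        assert idx.gfi == pytest.approx(1.0)
        assert idx.agfi == pytest.approx(1.0)

    def test_df_zero_indices_undefined(self):
        idx = fit_indices(0.0, 0, 50, np.eye(2), np.eye(2), 3)
        assert math.isnan(idx.cmin_df) and math.isnan(idx.rmsea)


class TestSelection:
    @staticmethod
    def _fake_fit(cmin_df, rmsea, agfi):
        class F:
            converged = True
        f = F()
        f.cmin_df, f.rmsea, f.agfi = cmin_df, rmsea, agfi
        return f

    def test_thresholds(self):
        good = self._fake_fit(0.8, 0.05, 0.95)
        bad_chi = self._fake_fit(1.5, 0.05, 0.95)
        boundary = self._fake_fit(1.0, 0.08, 0.9)
        undefined = self._fake_fit(float("nan"), float("nan"), float("nan"))
        accepted = select_models([good, bad_chi, boundary, undefined])
        assert accepted == [good]


class TestEffects:
    def test_published_a_model_products(self):
        """The a* model's printed indirect coefficients are reproduced as
        standardized path products at 2 d.p."""
        table = effects_from_edges(published.SEM_EDGES["a"])
        assert round(table.mediator_contribution("X_AMAT", "a", "Y_CGC"), 2) == -0.44
        assert round(table.mediator_contribution("X_MAW", "a", "Y_CGC"), 2) == 0.36
        d, i, t = table.effect("X_AMAT", "a")
        assert d == pytest.approx(-0.46)
        assert t == pytest.approx(d + i)

    def test_published_lightness_model_products(self):
        table = effects_from_edges(published.SEM_EDGES["L"])
        assert round(table.mediator_contribution("X_MAW", "L", "Y_PG"), 2) == 0.34
        d, i, t = table.effect("X_MAW", "L")
        assert i == pytest.approx(0.45 * 0.75, abs=1e-12)
        assert t == pytest.approx(0.21 + 0.3375, abs=1e-12)

    def test_no_path_gives_zero(self):
        table = effects_from_edges({("A", "B"): 0.5})
        assert table.effect("B", "A") == (0.0, 0.0, 0.0)

    def test_mediator_products_sum_to_indirect_exhaustive(self):
        """On random acyclic graphs of <= 6 nodes the per-mediator
        contributions sum to the indirect effect, cross-checked by
        exhaustive path enumeration."""
        rng = np.random.default_rng(17)
        for _ in range(50):
            k = int(rng.integers(3, 7))
            nodes = [f"v{i}" for i in range(k)]
            edges = {}
            for i in range(k):
                for j in range(i + 1, k):
                    if rng.random() < 0.5:
                        edges[(nodes[i], nodes[j])] = float(
                            rng.uniform(-0.8, 0.8))
            if not edges:
                continue
            table = effects_from_edges(edges)
            # independent oracle: recursive path enumeration
            def products(src, dst):
                out = []
                def walk(node, prod, length):
                    if node == dst and length > 0:
                        out.append((prod, length))
                    for (s, t), v in edges.items():
                        if s == node:
                            walk(t, prod * v, length + 1)
                walk(src, 1.0, 0)
                return out
            for s in nodes:
                for t in nodes:
                    if s == t:
                        continue
                    terms = products(s, t)
                    direct = sum(p for p, ln in terms if ln == 1)
                    indirect = sum(p for p, ln in terms if ln > 1)
                    got = table.effect(s, t)
                    assert got[0] == pytest.approx(direct, abs=1e-12)
                    assert got[1] == pytest.approx(indirect, abs=1e-10)
                    assert got[2] == pytest.approx(direct + indirect, abs=1e-10)

    def test_cyclic_edge_set_rejected(self):
        with pytest.raises(ValueError, match="acyclic"):
            effects_from_edges({("A", "B"): 0.5, ("B", "A"): 0.5})

    def test_fitted_decomposition_consistent_with_matrix_form(self):
        frame = _chain_data(seed=12)
        fit = fit_sem(frame, CHAIN)
        table = effects_decomposition(fit)
        d, i, t = table.effect("X", "Y")
        assert d == 0.0
        assert i == pytest.approx(
            fit.standardized["X->M"] * fit.standardized["M->Y"], abs=1e-12)
        assert t == pytest.approx(i)


class TestParameterRecovery:
    def test_chain_recovery_bias(self):
        """Mean standardized estimates over 200 replicates at n = 500 are
        within +/-0.03 of the generating paths (0.45, 0.75)."""
        sums = np.zeros(2)
        n_rep = 200
        for rep in range(n_rep):
            frame = _chain_data(n=500, seed=30_000 + rep)
            fit = fit_sem(frame, CHAIN)
            sums += [fit.standardized["X->M"], fit.standardized["M->Y"]]
        means = sums / n_rep
        assert abs(means[0] - 0.45) < 0.03
        assert abs(means[1] - 0.75) < 0.03

    def test_a_model_recovery_on_synthetic_cohorts(self):
        """Fitting the a*-model structure to synthetic cohorts (n = 500,
        200 replicates) recovers every standardized generating path with
        |bias| < 0.03 and RMSE < 0.08."""
        cfg = default_config()
        cfg.samples_per_group = (84, 84, 83, 83, 83, 83)
        _, truth = generate(cfg, seed=0)
        edges = list(A_MODEL.regressions)
        target = np.array([truth.standardized_paths[e] for e in edges])
        n_rep = 200
        estimates = np.zeros((n_rep, len(edges)))
        for rep in range(n_rep):
            table, _ = generate(cfg, seed=40_000 + rep)
            fit = fit_sem(table, A_MODEL)
            estimates[rep] = [fit.standardized[f"{s}->{t}"] for s, t in edges]
        bias = estimates.mean(axis=0) - target
        rmse = np.sqrt(((estimates - target) ** 2).mean(axis=0))
        assert np.abs(bias).max() < 0.03, dict(zip(edges, bias))
        assert rmse.max() < 0.08, dict(zip(edges, rmse))
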