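"""Poisson ML fitting, likelihood-ratio tests, and their oracles."""

import warnings

import numpy as np
import pytest
from scipy import optimize

import triolinear as tl
from triolinear.cell_table import build_design_matrix, cell_index
from triolinear.fitting import Design, _lrt_from_full, fit_design

from conftest import FALSE_P1, FALSE_P2, TRUE_P, coef_vector


def _random_counts(rng, mean=8.0, n=45):
    return rng.poisson(mean, size=n).astype(float)


class TestFitModel:
    def test_perfect_data_recovery_codominant(self, pop, codominant_full_spec):
        """Fitting expected counts returns the generating log risks exactly."""
        risk = tl.RiskModel(
            s=(1.5, 2.2), r=(1.2, 1.8), tau=(1.1, 0.7),
            theta=((1.3, 1.1), (1.6, 2.0)), phi=((0.8, 1.2), (1.4, 0.9)),
        )
        counts = 750.0 * tl.expected_cell_proportions(risk, pop)
        design = build_design_matrix(
            tl.ModelSpec.full("eq1", p=pop.p)
        )
        truth = coef_vector(design, risk, pop)
        fit = tl.fit_model(counts, design.spec)
        for lab, target in zip(design.labels, truth):
            if lab.startswith("mu_"):
                continue  # strata absorb the count scale
            assert fit.coefficients[lab] == pytest.approx(target, abs=1e-6)
        assert fit.converged

    @pytest.mark.parametrize("coding", [tl.GeneticCoding.DOMINANT,
                                        tl.GeneticCoding.MULTIPLICATIVE])
    def test_perfect_data_recovery_constrained(self, pop, coding):
        if coding == tl.GeneticCoding.DOMINANT:
            risk = tl.RiskModel(s=1.4, r=1.2, theta=1.8, phi=1.3)
            expect = {"ln_S_dom": np.log(1.4), "ln_theta_dom": np.log(1.8),
                      "ln_phi_dom": np.log(1.3)}
        else:
            risk = tl.RiskModel(
                s=(1.4, 1.4**2), r=(1.2, 1.2**2),
                theta=((1.5, 1.5**2), (1.5**2, 1.5**4)),
                phi=((1.2, 1.2**2), (1.2**2, 1.2**4)),
            )
            expect = {"ln_S_mult": np.log(1.4), "ln_theta_mult": np.log(1.5),
                      "ln_phi_mult": np.log(1.2)}
        counts = 1000.0 * tl.expected_cell_proportions(risk, tl.PopulationParams.hwe())
        fit = tl.fit_model(counts, tl.ModelSpec.full("eq1", coding, p=TRUE_P))
        for lab, target in expect.items():
            assert fit.coefficients[lab] == pytest.approx(target, abs=1e-6)

    def test_sufficient_statistics_preserved(self, rng, codominant_full_spec):
        y = _random_counts(rng)
        design = build_design_matrix(codominant_full_spec)
        fit = fit_design(design, y)
        keep = [design.labels.index(lab) for lab in fit.labels]
        resid = design.X[:, keep].T @ (y - fit.fitted)
        assert np.max(np.abs(resid)) < 1e-8 * max(1.0, y.sum())

    def test_statsmodels_oracle(self, rng, codominant_full_spec):
        """Independent GLM fit agrees on coefficients and fitted means."""
        sm = pytest.importorskip("statsmodels.api")
        y = _random_counts(rng)
        design = build_design_matrix(codominant_full_spec)
        fit = fit_design(design, y)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glm = sm.GLM(y, design.X, family=sm.families.Poisson(),
                         offset=design.offset).fit(tol=1e-12)
        np.testing.assert_allclose(
            [fit.coefficients[lab] for lab in design.labels], glm.params, atol=1e-6
        )
        np.testing.assert_allclose(fit.fitted, glm.mu, rtol=1e-6)

    def test_all_zero_counts_rejected(self, codominant_full_spec):
        with pytest.raises(tl.ConfigurationError):
            tl.fit_model(np.zeros(45), codominant_full_spec)

    def test_empty_stratum_drops_parameters_with_warning(self, rng, codominant_full_spec):
        y = _random_counts(rng)
        y[[cell_index(c, 2) for c in range(15)]] = 0.0  # no M2=2 families
        with pytest.warns(tl.AliasingWarning) as record:
            fit = tl.fit_model(y, codominant_full_spec)
        msg = str(record[0].message)
        for lab in ("delta_2", "ln_theta_12", "ln_theta_22", "ln_phi_12", "ln_phi_22"):
            assert lab in msg
            assert lab in fit.dropped
        # the k=1 interaction contrasts remain testable with reduced df
        res = tl.lrt(y, codominant_full_spec, tl.MXM, warn=False)
        assert res.estimable and res.df == 2

    def test_structural_rank_deficiency_raises(self, rng):
        y = _random_counts(rng, n=45)
        design = build_design_matrix(tl.ModelSpec.full("eq1", p=TRUE_P))
        X = np.column_stack([design.X, design.X[:, -1]])
        dup = Design(X=X, labels=design.labels + ["dup"],
                     columns=design.columns, offset=design.offset, spec=design.spec)
        with pytest.raises(tl.IdentifiabilityError) as err:
            fit_design(dup, y)
        assert err.value.aliased


class TestLRT:
    def test_null_counts_give_zero_statistic(self, pop, dominant_full_spec):
        counts = 500.0 * tl.expected_cell_proportions(tl.RiskModel(), pop)
        for effect in (tl.MXM, tl.MXO):
            res = tl.lrt(counts, dominant_full_spec, effect)
            assert res.statistic == pytest.approx(0.0, abs=1e-8)
            assert res.p_value == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize(
        "coding,df_theta,df_main",
        [(tl.GeneticCoding.DOMINANT, 1, 1), (tl.GeneticCoding.CODOMINANT, 4, 2)],
    )
    def test_degrees_of_freedom(self, rng, coding, df_theta, df_main):
        y = _random_counts(rng)
        spec = tl.ModelSpec.full("eq1", coding, p=TRUE_P)
        assert tl.lrt(y, spec, tl.MXM).df == df_theta
        assert tl.lrt(y, spec, tl.MATERNAL_MAIN).df == df_main

    def test_eq1_eq2_interaction_identity(self, rng):
        """Specifying any positive frequencies equals estimating them."""
        for _ in range(20):
            y = _random_counts(rng, mean=6.0)
            for effect in (tl.MXM, tl.MXO):
                stats = [
                    tl.lrt(y, tl.ModelSpec.full("eq1", p=p), effect, warn=False).statistic
                    for p in (TRUE_P, FALSE_P1, FALSE_P2)
                ]
                stats.append(tl.lrt(y, tl.ModelSpec.full("eq2"), effect, warn=False).statistic)
                assert np.ptp(stats) < 1e-6

    def test_mating_type_collapse_leaves_interaction_power_unchanged(self, dominant_full_spec):
        """One intercept instead of six mu strata: same interaction decisions.

        The interactions contrast locus-2 strata within configuration rows,
        which all share their mating-type multiplier, so the interaction
        tests carry over when the mating-type stratification is collapsed;
        the agreement is at the level of rejection decisions and power, not
        bitwise statistics (the row-margin model is not saturated).
        """
        from triolinear.simulator import scenario, simulate_cell_counts

        design = build_design_matrix(dominant_full_spec)
        mu_cols = design.columns["strata"]
        keep = [j for j in range(design.X.shape[1]) if j not in mu_cols]
        X = np.column_stack([np.ones(45)] + [design.X[:, j] for j in keep])
        labels = ["intercept"] + [design.labels[j] for j in keep]
        columns = {"strata": [0]}
        for eff, idx in design.columns.items():
            if eff == "strata":
                continue
            columns[eff] = [labels.index(design.labels[j]) for j in idx]
        collapsed = Design(X=X, labels=labels, columns=columns,
                           offset=design.offset, spec=design.spec)
        n_rep, agree, rej = 120, 0, np.zeros(2)
        for r in range(n_rep):
            y = simulate_cell_counts(scenario("model7", 300), 9000 + r)
            full_fit = fit_design(design, y, warn=False)
            coll_fit = fit_design(collapsed, y, warn=False)
            for e_i, effect in enumerate((tl.MXM, tl.MXO)):
                a = _lrt_from_full(design, y, full_fit, effect, warn=False)
                b = _lrt_from_full(collapsed, y, coll_fit, effect, warn=False)
                assert abs(a.statistic - b.statistic) < 2.5  # same order, small shift
                agree += (a.p_value < 0.05) == (b.p_value < 0.05)
                rej += [a.p_value < 0.05, b.p_value < 0.05]
        assert agree / (2 * n_rep) > 0.9
        assert abs(rej[0] - rej[1]) / (2 * n_rep) < 3 * np.sqrt(0.35 * 0.65 / n_rep)

    def test_effect_not_in_model_rejected(self, rng, dominant_full_spec):
        with pytest.raises(tl.ConfigurationError):
            tl.lrt(_random_counts(rng), dominant_full_spec.drop(tl.MXM), tl.MXM)


class TestLocus2MainTest:
    def test_warns_about_frequency_dependence(self, rng, dominant_full_spec):
        y = _random_counts(rng)
        with pytest.warns(tl.exceptions.FrequencyWarning):
            res = tl.test_locus2_main(y, dominant_full_spec)
        assert res.effect == tl.LOCUS2_MAIN
        assert res.df == 2

    def test_misspecified_frequencies_inflate_delta_not_interactions(self, pop):
        """delta absorbs a wrong specified distribution; interactions do not."""
        counts = 2000.0 * tl.expected_cell_proportions(tl.RiskModel(), pop)
        spec_true = tl.ModelSpec.full("eq1", tl.GeneticCoding.DOMINANT, p=TRUE_P)
        spec_false = tl.ModelSpec.full("eq1", tl.GeneticCoding.DOMINANT, p=FALSE_P1)
        stat_true = tl.lrt(counts, spec_true, tl.LOCUS2_MAIN).statistic
        stat_false = tl.lrt(counts, spec_false, tl.LOCUS2_MAIN).statistic
        assert stat_true == pytest.approx(0.0, abs=1e-8)
        assert stat_false > 100  # gross inflation on expected null counts
        for effect in (tl.MXM, tl.MXO):
            assert tl.lrt(counts, spec_false, effect).statistic == pytest.approx(0.0, abs=1e-6)


class TestSingleLocus:
    def test_rho_null_on_expected_counts(self, pop):
        counts = tl.CellTable(400.0 * tl.expected_cell_proportions(tl.RiskModel(rho=1.0), pop))
        spec = tl.ModelSpec.full("eq3", tl.GeneticCoding.DOMINANT)
        res = tl.lrt(counts.collapse_locus2(), spec, tl.RHO)
        assert res.statistic == pytest.approx(0.0, abs=1e-8)

    def test_multinomial_oracle(self, rng):
        """The Poisson rho LRT equals the conditional multinomial LRT."""
        spec = tl.ModelSpec(
            "eq3",
            (tl.MATERNAL_MAIN, tl.CHILD_MAIN, tl.RHO),
            {tl.MATERNAL_MAIN: tl.GeneticCoding.CODOMINANT,
             tl.CHILD_MAIN: tl.GeneticCoding.CODOMINANT,
             tl.RHO: tl.GeneticCoding.DOMINANT},
        )
        design = build_design_matrix(spec)
        rho_cols = design.columns[tl.RHO]

        def multinomial_lrt(y):
            n = y.sum()

            def neg_ll_and_grad(X):
                def fun(beta):
                    eta = X @ beta + design.offset
                    eta = eta - eta.max()
                    w = np.exp(eta)
                    pi = w / w.sum()
                    ll = float(y @ np.log(pi))
                    grad = X.T @ y - n * (X.T @ pi)
                    return -ll, -grad
                return fun

            def maximize(X):
                res = optimize.minimize(
                    neg_ll_and_grad(X), np.zeros(X.shape[1]), jac=True,
                    method="BFGS", options={"gtol": 1e-10, "maxiter": 500},
                )
                return -res.fun

            keep = [j for j in range(design.X.shape[1]) if j not in rho_cols]
            return 2.0 * (maximize(design.X) - maximize(design.X[:, keep]))

        for _ in range(10):
            y = rng.poisson(20.0, size=15).astype(float) + 1.0
            ours = tl.lrt(y, spec, tl.RHO, warn=False).statistic
            assert ours == pytest.approx(multinomial_lrt(y), abs=1e-6)

    def test_collapses_two_locus_counts(self, rng):
        y45 = tl.CellTable(rng.poisson(10, size=45).astype(float))
        spec = tl.ModelSpec.full("eq3", tl.GeneticCoding.DOMINANT)
        fit45 = tl.fit_single_locus(y45, spec, warn=False)
        fit15 = tl.fit_model(y45.collapse_locus2(), spec, warn=False)
        assert fit45.coefficients == fit15.coefficients


class TestSerialization:
    def test_effects_table_and_record(self, rng, dominant_full_spec):
        y = _random_counts(rng)
        fit = tl.fit_model(y, dominant_full_spec, warn=False)
        tests = {e: tl.lrt(y, dominant_full_spec, e, warn=False)
                 for e in (tl.MXM, tl.MXO)}
        table = tl.effects_table(fit, tests)
        assert {"effect", "parameter", "relative_risk", "lrt_p"} <= set(table.columns)
        assert (table.ci_low <= table.relative_risk).all()
        rec = tl.fit_record(fit, tests)
        import json

        json.dumps(rec)  # must be serializable
        assert rec["tests"][tl.MXM]["df"] == 1
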