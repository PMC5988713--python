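"""FIML likelihood, optimization, standard errors and standardization."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from copdsem.model import ModelSpec, VariableDef, Path, build_ram
from copdsem.estimation import (
    Dataset,
    fit,
    implied_moments,
    loglik_fiml,
    saturated_loglik,
    baseline_loglik,
    standardize,
    _starting_values,
)
from conftest import (
    CHAIN_A,
    CHAIN_B,
    make_chain_spec,
    make_factor_spec,
    simulate_chain,
    simulate_factor,
)


def _chain_theta(ram, a=CHAIN_A, b=CHAIN_B):
    """Parameter vector for the unit-variance chain at the generating values."""
    theta = np.zeros(ram.q)
    vals = {
        "path:x->m": a,
        "path:m->y": b,
        "var:x": 1.0,
        "var:m": 1 - a**2,
        "var:y": 1 - b**2,
        "mean:x": 0.0,
        "mean:m": 0.0,
        "mean:y": 0.0,
    }
    for k, fp in enumerate(ram.free_map):
        theta[k] = vals[fp.label]
    return theta


class TestImpliedMoments:
    def test_identity_case(self):
        """No paths, unit variances, zero means: Sigma = I, mu = 0."""
        spec = ModelSpec(variables=[VariableDef(v) for v in ("a", "b", "c")])
        ram = build_ram(spec)
        theta = np.zeros(ram.q)
        for k, fp in enumerate(ram.free_map):
            theta[k] = 1.0 if fp.kind == "variance" else 0.0
        mu, Sigma = implied_moments(ram, theta)
        assert np.allclose(Sigma, np.eye(3)) and np.allclose(mu, 0)

    def test_chain_hand_values(self):
        """x->m->y with a=0.5, b=0.4: cov(x,m)=0.5, cov(m,y)=0.4,
        cov(x,y)=0.20, all variances 1 (hand substitution)."""
        ram = build_ram(make_chain_spec())
        mu, Sigma = implied_moments(ram, _chain_theta(ram))
        i = {n: k for k, n in enumerate(ram.spec.observed_names())}
        assert Sigma[i["x"], i["m"]] == pytest.approx(0.5)
        assert Sigma[i["m"], i["y"]] == pytest.approx(0.4)
        assert Sigma[i["x"], i["y"]] == pytest.approx(0.20)
        assert np.allclose(np.diag(Sigma), 1.0)

    def test_saturated_reproduces_sample_moments(self, chain_data):
        """A saturated spec evaluated at the sample moments returns them."""
        names = chain_data.columns
        spec = ModelSpec(
            variables=[VariableDef(v) for v in names],
            covariances=[(a, b) for i, a in enumerate(names) for b in names[i + 1 :]],
        )
        ram = build_ram(spec)
        X = chain_data.values_for(names)
        mu_s = X.mean(axis=0)
        Sig_s = np.cov(X.T, bias=True)
        theta = np.zeros(ram.q)
        col = {n: k for k, n in enumerate(names)}
        for k, fp in enumerate(ram.free_map):
            if fp.kind == "variance":
                theta[k] = Sig_s[fp.i, fp.i]
            elif fp.kind == "covariance":
                theta[k] = Sig_s[fp.i, fp.j]
            else:
                theta[k] = mu_s[fp.i]
        mu, Sigma = implied_moments(ram, theta)
        assert np.allclose(mu, mu_s) and np.allclose(Sigma, Sig_s)


class TestFimlLoglik:
    def test_equals_complete_data_mvn(self, chain_data):
        """With no missing cells FIML is the ordinary multivariate-normal
        log-likelihood, to 1e-10."""
        ram = build_ram(make_chain_spec())
        theta = _chain_theta(ram)
        ll = loglik_fiml(chain_data, ram, theta)
        mu, Sigma = implied_moments(ram, theta)
        X = chain_data.values_for(ram.spec.observed_names())
        ref = stats.multivariate_normal(mu, Sigma).logpdf(X).sum()
        assert ll == pytest.approx(ref, abs=1e-10 * abs(ref))

    def test_matches_naive_per_row_with_missingness(self):
        """Pattern-grouped FIML equals the row-by-row marginal-density sum."""
        rng = np.random.default_rng(3)
        ds = simulate_chain(60, seed=3)
        df = ds.df.copy()
        holes = rng.random(df.shape) < 0.25
        holes[holes.all(axis=1)] = False  # keep every variable partially observed
        df = df.mask(holes)
        data = Dataset(df)
        ram = build_ram(make_chain_spec())
        theta = _chain_theta(ram)
        mu, Sigma = implied_moments(ram, theta)
        X = data.values_for(ram.spec.observed_names())
        naive = 0.0
        for row in X:
            o = ~np.isnan(row)
            if not o.any():
                continue
            naive += stats.multivariate_normal(
                mu[o], Sigma[np.ix_(o, o)]
            ).logpdf(row[o])
        assert loglik_fiml(data, ram, theta) == pytest.approx(naive, abs=1e-8)

    def test_single_observed_cell_is_univariate_density(self):
        """A row observed on one variable contributes the univariate normal
        log-density at that variable's implied moments."""
        ram = build_ram(make_chain_spec())
        theta = _chain_theta(ram)
        mu, Sigma = implied_moments(ram, theta)
        df = pd.DataFrame({"x": [np.nan, 1.0], "m": [0.7, np.nan], "y": [np.nan, 0.1]})
        ll = loglik_fiml(Dataset(df), ram, theta)
        names = ram.spec.observed_names()
        j = names.index("m")
        expected = stats.norm(mu[j], np.sqrt(Sigma[j, j])).logpdf(0.7)
        # second row observed on (x, y): bivariate marginal
        sel = [names.index("x"), names.index("y")]
        expected += stats.multivariate_normal(
            mu[sel], Sigma[np.ix_(sel, sel)]
        ).logpdf([1.0, 0.1])
        assert ll == pytest.approx(expected, abs=1e-12)

    def test_fully_missing_row_contributes_zero(self):
        ram = build_ram(make_chain_spec())
        theta = _chain_theta(ram)
        base = pd.DataFrame({"x": [1.0], "m": [0.5], "y": [0.2]})
        extended = pd.concat(
            [base, pd.DataFrame({"x": [np.nan], "m": [np.nan], "y": [np.nan]})],
            ignore_index=True,
        )
        assert loglik_fiml(Dataset(extended), ram, theta) == pytest.approx(
            loglik_fiml(Dataset(base), ram, theta), abs=1e-12
        )

    def test_row_order_invariance(self):
        ds = simulate_chain(100, seed=5)
        df = ds.df.copy()
        df.iloc[::7, 1] = np.nan
        ram = build_ram(make_chain_spec())
        theta = _chain_theta(ram)
        ll1 = loglik_fiml(Dataset(df), ram, theta)
        ll2 = loglik_fiml(Dataset(df.sample(frac=1, random_state=0)), ram, theta)
        assert ll1 == pytest.approx(ll2, abs=1e-9)

    def test_non_pd_returns_penalty_not_crash(self):
        ram = build_ram(make_chain_spec())
        theta = _chain_theta(ram)
        theta[ram.param_index("var:x")] = -1.0
        ds = simulate_chain(20, seed=1)
        assert loglik_fiml(ds, ram, theta) < -1e11


class TestFit:
    def test_saturated_fit_reproduces_sample_moments(self, chain_data):
        names = chain_data.columns
        spec = ModelSpec(
            variables=[VariableDef(v) for v in names],
            covariances=[(a, b) for i, a in enumerate(names) for b in names[i + 1 :]],
        )
        res = fit(chain_data, spec, compute_se=False)
        assert res.converged
        X = chain_data.values_for(names)
        mu_s = X.mean(axis=0)
        Sig_s = np.cov(X.T, bias=True)
        ram = res.ram
        for k, fp in enumerate(ram.free_map):
            if fp.kind == "mean":
                assert res.theta[k] == pytest.approx(mu_s[fp.i], abs=1e-4)
            else:
                assert res.theta[k] == pytest.approx(Sig_s[fp.i, fp.j], abs=1e-3)
        assert res.loglik == pytest.approx(saturated_loglik(chain_data), abs=1e-5)

    def test_factor_loading_recovery(self):
        """Loadings 0.8 on a 4-indicator factor recovered within 0.03 at
        n = 5000."""
        data = simulate_factor(5000, seed=11, loading=0.8)
        res = fit(data, make_factor_spec(k=4), compute_se=False)
        assert res.converged
        std = standardize(res).set_index("label")["standardized"]
        for j in range(4):
            assert std[f"loading:f->y{j + 1}"] == pytest.approx(0.8, abs=0.03)

    def test_fiml_uses_partial_rows(self):
        """Masking one variable MCAR barely moves the estimates (FIML keeps
        the partially observed rows)."""
        data = simulate_chain(3000, seed=13)
        df = data.df.copy()
        rng = np.random.default_rng(13)
        df.loc[rng.choice(len(df), 900, replace=False), "m"] = np.nan
        res = fit(Dataset(df), make_chain_spec(), compute_se=False)
        assert res.converged
        std = standardize(res).set_index("label")["standardized"]
        assert std["path:x->m"] == pytest.approx(CHAIN_A, abs=0.06)
        assert std["path:m->y"] == pytest.approx(CHAIN_B, abs=0.06)

    def test_heywood_flagged(self):
        """Nearly collinear indicators push a residual variance negative;
        the fit reports a warning instead of failing."""
        rng = np.random.default_rng(2)
        n = 200
        f = rng.standard_normal(n)
        df = pd.DataFrame(
            {
                "y1": f + 0.05 * rng.standard_normal(n),
                "y2": 0.7 * f + 0.7 * rng.standard_normal(n),
                "y3": 0.7 * f + 0.7 * rng.standard_normal(n),
            }
        )
        res = fit(Dataset(df), make_factor_spec(k=3), compute_se=False)
        # not asserting a Heywood occurs (data-dependent); just that the fit
        # copes and any negative variance is reported, not hidden
        for k, fp in enumerate(res.ram.free_map):
            if fp.kind == "variance" and res.theta[k] < 0:
                assert any("Heywood" in w for w in res.warnings)


class TestStandardErrors:
    def test_mean_se_matches_closed_form(self):
        """Saturated one-variable model: SE(mean) = ML-SD / sqrt(n)."""
        rng = np.random.default_rng(21)
        x = rng.normal(10.0, 3.0, 500)
        data = Dataset(pd.DataFrame({"x": x}))
        res = fit(data, ModelSpec(variables=[VariableDef("x")]))
        k = res.ram.param_index("mean:x")
        expected = x.std() / np.sqrt(len(x))  # ML sd (ddof=0)
        assert res.se[k] == pytest.approx(expected, rel=0.02)

    def test_fixed_parameters_have_no_se(self):
        data = simulate_factor(300, seed=4)
        res = fit(data, make_factor_spec(k=4))
        tab = res.estimates.set_index("label")
        assert np.isnan(tab.loc["loading:f->y1", "se"])
        assert tab.loc["loading:f->y1", "estimate"] == 1.0


class TestStandardize:
    def test_already_standardized_model_unchanged(self):
        """At generating values with unit variances the standardized and
        unstandardized path coefficients coincide."""
        ram = build_ram(make_chain_spec())
        theta = _chain_theta(ram)
        from copdsem.estimation import _standardized_vector

        std = _standardized_vector(ram, theta)
        for k, fp in enumerate(ram.free_map):
            if fp.kind == "path":
                assert std[k] == pytest.approx(theta[k], abs=1e-6)

    def test_boundary_full_determination(self):
        """y = 2x with zero residual variance: standardized path = 1."""
        spec = ModelSpec(
            variables=[VariableDef("x"), VariableDef("y")],
            structural_paths=[Path("x", "y")],
        )
        ram = build_ram(spec)
        vals = {"path:x->y": 2.0, "var:x": 1.0, "var:y": 1e-12, "mean:x": 0.0, "mean:y": 0.0}
        theta = np.array([vals[fp.label] for fp in ram.free_map])
        from copdsem.estimation import _standardized_vector

        std = _standardized_vector(ram, theta)
        k = ram.param_index("path:x->y")
        assert std[k] == pytest.approx(1.0, abs=1e-6)

    def test_invariant_to_identification_convention(self):
        """Unit-loading and unit-variance identification give the same
        standardized solution (within 1e-4)."""
        data = simulate_factor(1500, seed=9)
        res_l = fit(data, make_factor_spec(k=4, identification="loading"), compute_se=False)
        res_v = fit(data, make_factor_spec(k=4, identification="variance"), compute_se=False)
        std_l = standardize(res_l).set_index("label")["standardized"]
        std_v = standardize(res_v).set_index("label")["standardized"]
        for j in range(4):
            lbl = f"loading:f->y{j + 1}"
            assert std_l[lbl] == pytest.approx(std_v[lbl], abs=1e-4)


class TestSaturatedAndBaseline:
    def test_em_saturated_dominates_structured_model(self):
        """Under missingness the EM-fitted saturated log-likelihood is at
        least the structured model's (it nests every model)."""
        ds = simulate_chain(400, seed=17)
        df = ds.df.copy()
        rng = np.random.default_rng(17)
        for c in df.columns:
            df.loc[rng.choice(len(df), 60, replace=False), c] = np.nan
        data = Dataset(df)
        res = fit(data, make_chain_spec(), compute_se=False)
        ll_sat = saturated_loglik(data)
        assert ll_sat >= res.loglik - 1e-6

    def test_baseline_separates_by_variable(self, chain_data):
        ll, q = baseline_loglik(chain_data)
        X = chain_data.values_for(chain_data.columns)
        ref = sum(
            stats.norm(x.mean(), x.std()).logpdf(x).sum() for x in X.T
        )
        assert ll == pytest.approx(ref, rel=1e-10)
        assert q == 6


def test_starting_values_are_finite(chain_data):
    ram = build_ram(make_chain_spec())
    theta0 = _starting_values(ram, chain_data)
    assert np.all(np.isfinite(theta0))
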