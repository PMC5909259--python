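"""Closed-form and oracle checks of the regression core."""
import numpy as np
import pandas as pd
import pytest

from conftest import make_single_row_table
from mutrate import glm
from mutrate.glm import (FitError, ModelSpec, Term, add_pseudo_counts,
                         count_observations, count_parameters, deviance_loss,
                         fit_binomial, fit_multinomial,
                         fit_multinomial_via_binary, fit_null_single_rate,
                         fit_poisson, mcfadden_r2, mcfadden_r2_from_loglik,
                         null_loglik)
from mutrate.tabulate import COUNT_COLS, CountTable, build_count_table, expand_table

INTERCEPT_ONLY = ModelSpec(intercept_scope="global", context=False)


class TestParameterAccounting:
    def test_published_counts(self):
        m4 = ModelSpec(context=False)
        assert count_parameters(m4, 505, 14) == 3030
        m5 = ModelSpec(context=True)
        assert count_parameters(m5, 505, 14) == 4374
        assert count_parameters(m5, 505, 14) - count_parameters(m4, 505, 14) \
            == 14 * 96
        m6 = m5.with_terms(Term("conservation"))
        assert count_parameters(m6, 505, 14) == 4458
        m7 = m6.with_terms(Term("replication_timing"))
        assert count_parameters(m7, 505, 14) == 4542
        final = m7.with_terms(Term("expression"),
                              Term("expressed", kind="dummy"))
        assert count_parameters(final, 505, 14) == 4710

    def test_observation_count(self):
        assert count_observations(505, 2.56e9) == pytest.approx(1.3e12, rel=0.01)

    def test_binomial_and_poisson_single_outcome(self):
        spec = ModelSpec(outcome="binomial", context=False)
        assert count_parameters(spec, 10, 2) == 10


class TestPseudoCounts:
    def _two_sample_table(self):
        rows = [
            # sample A has a zero C>A cell; counts (C>A, C>C, C>G, C>T)
            {"strand_class": "C", "sample": "A", "cancer_type": "can",
             "n_A": 0.0, "n_C": 100.0, "n_G": 2.0, "n_T": 3.0},
            # sample B completes the cancer aggregate (10, 1000, 20, 30)
            {"strand_class": "C", "sample": "B", "cancer_type": "can",
             "n_A": 10.0, "n_C": 900.0, "n_G": 18.0, "n_T": 27.0},
        ]
        df = pd.DataFrame(rows)[["strand_class", "sample", "cancer_type",
                                 "n_A", "n_C", "n_G", "n_T"]]
        return CountTable(df, ["strand_class"])

    def test_printed_formula(self):
        """n=(0,2,100,3), cancer aggregate (10,20,1000,30) ->
        (0.495283, 1.990566, 99.528302, 2.985849), sum preserved at 105."""
        out = add_pseudo_counts(self._two_sample_table())
        a = out.data[out.data["sample"] == "A"].iloc[0]
        assert a["n_A"] == pytest.approx(0.495283, abs=1e-6)
        assert a["n_G"] == pytest.approx(1.990566, abs=1e-6)
        assert a["n_C"] == pytest.approx(99.528302, abs=1e-6)
        assert a["n_T"] == pytest.approx(2.985849, abs=1e-6)
        assert a[list(COUNT_COLS)].sum() == pytest.approx(105.0, abs=1e-12)

    def test_all_positive_rows_untouched(self):
        out = add_pseudo_counts(self._two_sample_table())
        b = out.data[out.data["sample"] == "B"].iloc[0]
        assert (b["n_A"], b["n_C"], b["n_G"], b["n_T"]) == (10, 900, 18, 27)

    def test_single_sample_cancer_type_is_identity(self):
        table = make_single_row_table("C", (0, 2, 3, 95))
        out = add_pseudo_counts(table)
        # n_K,sam = n_K,can: 0.5 n + 0.5 n = n
        assert np.allclose(out.data[list(COUNT_COLS)].to_numpy(),
                           table.data[list(COUNT_COLS)].to_numpy())

    def test_randomized_sum_preservation(self):
        rng = np.random.default_rng(7)
        n = 2000
        counts = rng.integers(0, 5, size=(n, 3)).astype(float)
        ref = rng.integers(50, 5000, size=n).astype(float)
        df = pd.DataFrame({
            "strand_class": "C",
            "sample": rng.choice([f"s{i}" for i in range(20)], n),
            "cancer_type": rng.choice(["c1", "c2", "c3"], n),
            "n_A": counts[:, 0], "n_C": ref, "n_G": counts[:, 1],
            "n_T": counts[:, 2]})
        df["ctx"] = rng.choice(["k1", "k2", "k3", "k4"], n)
        table = CountTable(df, ["strand_class", "ctx"])
        out = add_pseudo_counts(table)
        np.testing.assert_allclose(out.row_totals(), table.row_totals(),
                                   rtol=1e-12)
        untouched = (counts > 0).all(axis=1)
        assert np.allclose(
            out.data.loc[untouched, list(COUNT_COLS)].to_numpy(),
            table.data.loc[untouched, list(COUNT_COLS)].to_numpy())


class TestMultinomialFit:
    @pytest.mark.parametrize("method", ["exact", "binary"])
    def test_saturated_closed_form(self, method):
        """Intercept-only on counts (C>A,C>G,C>T,ref)=(1,2,3,94): fitted
        probabilities exactly (0.01,0.02,0.03,0.94); C>A intercept ln(1/94)."""
        table = make_single_row_table("C", (1, 2, 3, 94))
        fit = fit_multinomial(table, INTERCEPT_ONLY, method=method)
        probs = fit.predict_type_probs(table.data)[0]
        # columns (n_A, n_C, n_G, n_T): ref prob sits at n_C
        assert probs == pytest.approx([0.01, 0.94, 0.02, 0.03], abs=1e-8)
        ca = fit.coefficients[(fit.coefficients["outcome"] == "C>A")
                              & (fit.coefficients["term"] == "mu")]
        assert ca["estimate"].iloc[0] == pytest.approx(np.log(1 / 94), abs=1e-8)

    def test_zero_type_counts_flagged(self):
        table = make_single_row_table("C", (0, 2, 3, 95))
        with pytest.raises(FitError, match="pseudo"):
            fit_multinomial(table, INTERCEPT_ONLY)

    def test_binary_route_matches_exact_in_rare_event_regime(self, tiny_ds,
                                                             tiny_table):
        """All type probabilities ~1e-3: the three separate binary logits agree
        with the joint multinomial MLE to < 0.02 per coefficient."""
        spec = ModelSpec(terms=(Term("conservation"),))
        table = add_pseudo_counts(tiny_table)
        exact = fit_multinomial(table, spec, method="exact")
        binary = fit_multinomial_via_binary(table, spec, compute_vcov=False)
        merged = exact.coefficients.merge(binary.coefficients,
                                          on=["outcome", "term"],
                                          suffixes=("_e", "_b"))
        merged = merged.dropna(subset=["estimate_e", "estimate_b"])
        # restrict to identified coefficients: cells whose cancer-aggregate
        # count is zero stay unidentified even after pseudo counts (the
        # adjustment is proportional to the aggregate) and both routes
        # legitimately diverge there
        merged = merged[merged["se_e"] < 5.0]
        assert len(merged) > 100
        assert (merged["estimate_e"] - merged["estimate_b"]).abs().max() < 0.02

    def test_determinism(self, tiny_table):
        spec = ModelSpec(terms=(Term("conservation"),))
        f1 = fit_multinomial_via_binary(tiny_table, spec, compute_vcov=False)
        f2 = fit_multinomial_via_binary(tiny_table, spec, compute_vcov=False)
        pd.testing.assert_frame_equal(f1.coefficients, f2.coefficients)

    def test_nesting_monotonicity(self, tiny_ds, tiny_annotated):
        """Adding a term never decreases the training log-likelihood."""
        table = build_count_table(tiny_ds.sites, tiny_annotated, tiny_ds.samples,
                                  covariates=["conservation",
                                              "replication_timing"])
        base = ModelSpec(context=True)
        lls = []
        for spec in (base, base.with_terms(Term("conservation")),
                     base.with_terms(Term("conservation"),
                                     Term("replication_timing"))):
            lls.append(fit_multinomial(table, spec, method="exact",
                                       compute_vcov=False).loglik)
        assert lls[0] <= lls[1] + 1e-6 and lls[1] <= lls[2] + 1e-6

    def test_score_equations_per_sample(self, tiny_table):
        """Canonical link + per-sample intercepts: fitted per-sample expected
        type totals equal the observed totals."""
        spec = ModelSpec(terms=(Term("conservation"),))
        fit = fit_multinomial(tiny_table, spec, method="exact",
                              compute_vcov=False)
        totals = glm.expected_type_totals(fit, tiny_table)
        np.testing.assert_allclose(totals["expected"], totals["observed"],
                                   rtol=1e-6, atol=1e-6)

    def test_collapsed_equals_expanded_fit(self):
        """Fitting the collapsed table equals fitting one row per observation."""
        from mutrate import synthetic
        cfg = synthetic.SyntheticConfig(genome_length=220, n_cancer_types=2,
                                        samples_per_cancer_type=2, seed=9,
                                        base_rate=0.05)
        ds = synthetic.synthesize(cfg)
        table = build_count_table(ds.sites, ds.annotated_mutations(),
                                  ds.samples, covariates=["conservation"])
        spec = ModelSpec(intercept_scope="per_cancer", context=True,
                         terms=(Term("conservation", per_cancer=False),))
        fit_c = fit_multinomial(table, spec, method="exact", compute_vcov=False)
        obs = expand_table(table)
        from mutrate.tabulate import table_from_observations
        per_obs = table_from_observations(obs, table.key_cols)
        # shuffle and re-collapse at one-row-per-observation granularity
        fit_o = fit_multinomial(per_obs, spec, method="exact",
                                compute_vcov=False)
        merged = fit_c.coefficients.merge(fit_o.coefficients,
                                          on=["outcome", "term"],
                                          suffixes=("_c", "_o"))
        merged = merged.dropna(subset=["estimate_c", "estimate_o"])
        assert (merged["estimate_c"] - merged["estimate_o"]).abs().max() < 1e-6


class TestBinomialFit:
    def test_closed_form_rate(self):
        table = make_single_row_table("C", (5, 0, 0, 995))
        spec = ModelSpec(outcome="binomial", intercept_scope="global",
                         context=False)
        fit = fit_binomial(table, spec)
        p = fit.predict_mut_prob(table.data)[0]
        assert p == pytest.approx(0.005, abs=1e-10)

    def test_nested_in_multinomial(self):
        """On an intercept-only table the multinomial total mutation
        probability equals the binomial estimate."""
        table = make_single_row_table("C", (1, 2, 3, 94))
        multi = fit_multinomial(table, INTERCEPT_ONLY, method="exact")
        spec_b = ModelSpec(outcome="binomial", intercept_scope="global",
                           context=False)
        bino = fit_binomial(table, spec_b)
        assert multi.predict_mut_prob(table.data)[0] == pytest.approx(
            bino.predict_mut_prob(table.data)[0], abs=1e-8)

    def test_separation_flagged(self):
        df = pd.DataFrame({
            "strand_class": ["C", "C"], "sample": ["s", "s"],
            "cancer_type": ["c", "c"], "x": [0.0, 1.0],
            "n_A": [0.0, 50.0], "n_C": [100.0, 0.0],
            "n_G": [0.0, 0.0], "n_T": [0.0, 0.0]})
        table = CountTable(df, ["strand_class", "x"])
        spec = ModelSpec(outcome="binomial", intercept_scope="global",
                         context=False, terms=(Term("x", per_cancer=False),))
        with pytest.warns(UserWarning, match="separation|converge"):
            fit = fit_binomial(table, spec)
        assert not fit.converged


class TestPoissonFit:
    def _regions(self, counts, lengths, covariate=None):
        rows = []
        for i, (c, L) in enumerate(zip(counts, lengths)):
            rows.append({"region": i, "length": float(L), "count": float(c),
                         "sample": "s1", "cancer_type": "c1",
                         **({"x": covariate[i]} if covariate is not None else {})})
        return pd.DataFrame(rows)

    def test_intercept_only_mle_is_mean(self):
        regions = self._regions([3, 4, 5], [1000, 1000, 1000])
        spec = ModelSpec(outcome="poisson", intercept_scope="global",
                         context=False)
        fit = fit_poisson(regions, spec)
        np.testing.assert_allclose(fit.predict_rate(regions), [4.0] * 3,
                                   rtol=1e-8)

    def test_offset_identity(self):
        regions = self._regions([3, 4, 5], [1000, 1000, 1000])
        doubled = regions.assign(length=regions["length"] * 2)
        spec = ModelSpec(outcome="poisson", intercept_scope="global",
                         context=False)
        f1 = fit_poisson(regions, spec)
        f2 = fit_poisson(doubled, spec)
        # doubling exposure halves the fitted rate density ...
        assert f2.coefficients["estimate"].iloc[0] == pytest.approx(
            f1.coefficients["estimate"].iloc[0] - np.log(2), abs=1e-8)
        # ... while predictions at the original exposures are unchanged
        np.testing.assert_allclose(f2.predict_rate(doubled),
                                   f1.predict_rate(regions), rtol=1e-8)

    def test_against_newton_oracle(self):
        """One-covariate Poisson fit equals an independent Newton solver."""
        rng = np.random.default_rng(11)
        x = rng.normal(size=40)
        L = np.full(40, 500.0)
        lam = L * np.exp(-6.0 + 0.8 * x)
        y = rng.poisson(lam)
        regions = self._regions(y, L, covariate=x)
        spec = ModelSpec(outcome="poisson", intercept_scope="global",
                         context=False, terms=(Term("x", per_cancer=False),))
        fit = fit_poisson(regions, spec)
        # independent oracle: Newton-Raphson on the Poisson log-likelihood
        beta = np.zeros(2)
        X = np.column_stack([np.ones(40), x])
        for _ in range(50):
            mu = np.exp(X @ beta + np.log(L))
            grad = X.T @ (y - mu)
            hess = X.T @ (mu[:, None] * X)
            beta += np.linalg.solve(hess, grad)
        est = fit.coefficients.set_index("term")["estimate"]
        assert est["mu"] == pytest.approx(beta[0], abs=1e-8)
        assert est["b[x]"] == pytest.approx(beta[1], abs=1e-8)

    def test_zero_length_rejected(self):
        regions = self._regions([1], [0])
        spec = ModelSpec(outcome="poisson", intercept_scope="global",
                         context=False)
        with pytest.raises(FitError):
            fit_poisson(regions, spec)

    def test_poisson_matches_binomial_at_low_rates(self, tiny_ds,
                                                   tiny_annotated):
        """Region-level expected counts from the binomial site model and the
        Poisson region model agree within 1% when p ~ 1e-3."""
        regions = [("chr1", 0, 10_000), ("chr1", 10_000, 20_000)]
        from mutrate.tabulate import summarize_regions
        summ = summarize_regions(tiny_ds.sites, tiny_annotated, regions,
                                 tiny_ds.samples, covariates=["conservation"])
        spec_p = ModelSpec(outcome="poisson", context=False,
                           terms=(Term("conservation"),))
        pois = fit_poisson(summ, spec_p)
        table = build_count_table(tiny_ds.sites, tiny_annotated, tiny_ds.samples,
                                  covariates=["conservation"], context=False)
        spec_b = ModelSpec(outcome="binomial", context=False,
                           terms=(Term("conservation"),))
        bino = fit_binomial(table, spec_b)
        # compare total expected counts per sample
        lam = pois.predict_rate(summ)
        pois_tot = pd.Series(lam).groupby(summ["sample"].to_numpy()).sum()
        p = bino.predict_mut_prob(table.data)
        bino_tot = pd.Series(p * table.row_totals()).groupby(
            table.data["sample"].to_numpy()).sum()
        for sam in pois_tot.index:
            assert pois_tot[sam] == pytest.approx(bino_tot[sam], rel=0.01)


class _StubFit:
    """Minimal predictor with fixed type probabilities, for deviance checks."""

    def __init__(self, probs):
        self._p = np.asarray(probs, dtype=float)

    def predict_type_probs(self, df):
        return np.tile(self._p, (len(df), 1))


class TestDeviance:
    def test_perfect_prediction_zero(self):
        table = make_single_row_table("C", (0, 0, 0, 10))
        stub = _StubFit([0.0, 1.0, 0.0, 0.0])  # all mass on the observed ref
        d, _ = deviance_loss(stub, table, floor=1e-300)
        assert d == 0.0

    def test_half_probability(self):
        """One observation with p-hat(observed) = 0.5 -> D = 2 ln 2."""
        table = make_single_row_table("C", (1, 0, 0, 0))
        stub = _StubFit([0.5, 0.5, 0.0, 0.0])
        d, _ = deviance_loss(stub, table)
        assert d == pytest.approx(2 * np.log(2), abs=1e-9)

    def test_two_observation_closed_form(self):
        """p-hat=0.01 for a mutated and 0.98 for an unmutated observation:
        D = 9.21034 + 0.040405 = 9.250746."""
        t1 = make_single_row_table("C", (1, 0, 0, 0))
        d1, _ = deviance_loss(_StubFit([0.01, 0.99, 0.0, 0.0]), t1)
        t2 = make_single_row_table("C", (0, 0, 0, 1))
        d2, _ = deviance_loss(_StubFit([0.02, 0.98, 0.0, 0.0]), t2)
        assert d1 + d2 == pytest.approx(9.250746, abs=1e-5)

    def test_probability_floor_guard(self, caplog):
        table = make_single_row_table("C", (1, 0, 0, 9))
        stub = _StubFit([0.0, 1.0, 0.0, 0.0])
        with caplog.at_level("WARNING"):
            d, _ = deviance_loss(stub, table)
        assert np.isfinite(d)
        assert "floor" in caplog.text


class TestMcFadden:
    def test_single_rate_null_is_exactly_zero(self, tiny_table):
        fit = fit_null_single_rate(tiny_table)
        assert mcfadden_r2(fit, tiny_table) == 0.0

    def test_substitution(self):
        assert mcfadden_r2_from_loglik(-50.0, -100.0) == pytest.approx(0.5)

    def test_saturated_model_approaches_one(self):
        assert mcfadden_r2_from_loglik(0.0, -100.0) == 1.0

    def test_model_improves_over_null(self, tiny_table):
        spec = ModelSpec(terms=(Term("conservation"),))
        fit = fit_multinomial(tiny_table, spec, method="exact",
                              compute_vcov=False)
        r2 = mcfadden_r2(fit, tiny_table)
        assert 0.0 < r2 < 1.0

    def test_per_type_null_variant(self, tiny_table):
        """The pooled per-type model scores R^2 = 0 against the per-type null."""
        spec = ModelSpec(intercept_scope="global", context=False)
        fit = fit_multinomial(tiny_table, spec, method="exact",
                              compute_vcov=False)
        r2 = mcfadden_r2(fit, tiny_table, null="per-type")
        assert r2 == pytest.approx(0.0, abs=1e-9)


class TestVcov:
    def test_saturated_closed_form_variances(self):
        """Intercept-only multinomial on (1,2,3,94): Var(beta_k) = 1/n_k + 1/n_ref."""
        table = make_single_row_table("C", (1, 2, 3, 94))
        fit = fit_multinomial(table, INTERCEPT_ONLY, method="exact")
        for outc, n_k in zip(("C>A", "C>G", "C>T"), (1, 2, 3)):
            row = fit.coefficients[(fit.coefficients["outcome"] == outc)]
            expected_se = np.sqrt(1 / n_k + 1 / 94)
            assert row["se"].iloc[0] == pytest.approx(expected_se, rel=1e-6)

    def test_symmetry(self, tiny_table):
        spec = ModelSpec(terms=(Term("conservation"),))
        fit = fit_multinomial(tiny_table, spec, method="exact")
        for bf in fit.blocks.values():
            assert np.allclose(bf.vcov, bf.vcov.T, atol=1e-10)


class TestPredictProbs:
    def test_uniform_when_counts_equal(self):
        """Equal saturated counts (1,1,1,1) -> probabilities (1/4,...)."""
        table = make_single_row_table("C", (1, 1, 1, 1))
        fit = fit_multinomial(table, INTERCEPT_ONLY, method="exact")
        probs = fit.predict_type_probs(table.data)[0]
        assert probs == pytest.approx([0.25] * 4, abs=1e-9)

    def test_softmax_arithmetic(self):
        """Counts (1,2,3,1): saturated probabilities are (1,2,3,1)/7, i.e. the
        softmax of logits (ln1, ln2, ln3) against the reference."""
        table = make_single_row_table("C", (1, 2, 3, 1))
        fit = fit_multinomial(table, INTERCEPT_ONLY, method="exact")
        probs = fit.predict_type_probs(table.data)[0]
        # columns (A, C=ref, G, T)
        assert probs == pytest.approx(np.array([1, 1, 2, 3]) / 7, abs=1e-9)

    def test_rows_sum_to_one(self, tiny_table):
        spec = ModelSpec(terms=(Term("conservation"),))
        fit = fit_multinomial(tiny_table, spec, method="exact",
                              compute_vcov=False)
        probs = fit.predict_type_probs(tiny_table.data)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_monotone_in_covariate(self, tiny_table):
        """Raising a covariate with positive coefficient raises that type's
        probability."""
        spec = ModelSpec(terms=(Term("conservation"),))
        fit = fit_multinomial(tiny_table, spec, method="exact",
                              compute_vcov=False)
        coef = fit.coefficients.dropna(subset=["estimate"])
        row = coef[coef["term"].str.startswith("b[conservation")].iloc[0]
        sam = [s for s, c in fit.sample_map.items()
               if f"|{c}]" in row["term"]][0]
        base = tiny_table.data[(tiny_table.data["sample"] == sam)
                               & (tiny_table.data["strand_class"]
                                  == row["outcome"][0])].head(1).copy()
        lo, hi = base.copy(), base.copy()
        lo["conservation"], hi["conservation"] = 0.0, 1.0
        col = {"A": 0, "C": 1, "G": 2, "T": 3}[row["outcome"][-1]]
        p_lo = fit.predict_type_probs(lo)[0, col]
        p_hi = fit.predict_type_probs(hi)[0, col]
        if row["estimate"] > 0:
            assert p_hi > p_lo
        else:
            assert p_hi < p_lo

    def test_unknown_sample_rejected(self, tiny_table):
        spec = ModelSpec(terms=(Term("conservation"),))
        fit = fit_multinomial(tiny_table, spec, method="exact",
                              compute_vcov=False)
        with pytest.raises(glm.UnknownLevelError):
            glm.predict_probs(fit, tiny_table.data.head(2), "nonexistent")
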