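"""EM estimator checks: E-step arithmetic, ascent, constraints, oracles."""

import numpy as np
import pytest
from scipy import optimize, special

from taxanorm.em import (
    CONSTRAINTS,
    FitConfig,
    e_step,
    fit_matrix,
    fit_taxon,
    initialize,
    m_step,
)
from taxanorm.io import filter_taxa
from taxanorm.simulate import SimConfig, simulate_counts
from taxanorm.zinb import CountMatrix, TaxonParams, taxon_loglik


def direct_mle_loglik(y, x, constraint="full", n_starts=8, seed=0):
    """Independent oracle: multi-start direct (no-EM) maximization of the
    observed ZINB log-likelihood over the model's admissible box (the same
    coefficient bounds the fitter declares), on the centered covariate."""
    fixed = CONSTRAINTS[constraint]
    names = [k for k in ("beta0", "beta1", "kappa0", "kappa1") if k not in fixed]
    bounds = {"beta0": (-40, 40), "beta1": (-15, 15),
              "kappa0": (-10, 15), "kappa1": (-3, 3)}
    rng = np.random.default_rng(seed)
    xc = np.asarray(x) - np.mean(x)

    def negll(v):
        vals = dict(fixed)
        vals.update(zip(names, v[:-1]))
        params = TaxonParams(vals["beta0"], vals["beta1"], vals["kappa0"],
                             vals["kappa1"], float(np.clip(v[-1], -30, 30)))
        return -taxon_loglik(params, y, xc)

    best = np.inf
    zf = max(min(np.mean(y == 0), 0.99), 0.01)
    base = np.concatenate([np.zeros(len(names)), [special.logit(zf)]])
    box = [bounds[k] for k in names] + [(-30, 30)]
    for s in range(n_starts):
        v0 = base + (rng.normal(scale=1.0, size=base.size) if s else 0.0)
        res = optimize.minimize(negll, v0, method="Nelder-Mead", bounds=box,
                                options={"maxiter": 6000, "fatol": 1e-10, "xatol": 1e-8})
        best = min(best, res.fun)
    return -best


@pytest.fixture
def zinb_taxon(rng):
    n = 200
    x = np.log(rng.uniform(1e4, 1e5, size=n))
    params = TaxonParams(-6.0, 0.9, 0.5, 0.0, -1.0)
    mu = np.exp(params.beta0 + params.beta1 * x)
    theta = np.exp(params.kappa0)
    lam = rng.gamma(theta, mu / theta)
    y = np.where(rng.uniform(size=n) < special.expit(params.gamma),
                 0, rng.poisson(lam)).astype(float)
    return y, x, params


class TestInitialize:
    def test_gamma_is_logit_zero_fraction(self, zinb_taxon):
        y, x, _ = zinb_taxon
        init = initialize(y, x)
        zf = np.mean(y == 0)
        assert init.gamma == pytest.approx(special.logit(zf))
        assert init.kappa1 == 0.0

    def test_boundary_correction_no_zeros(self, rng):
        n = 50
        x = np.log(rng.uniform(1e4, 1e5, size=n))
        y = rng.poisson(20.0, size=n).astype(float) + 1.0
        init = initialize(y, x)
        assert init.gamma == pytest.approx(special.logit(0.5 / (n + 1)))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            initialize(np.zeros(10), np.linspace(9, 11, 10))


class TestESten:
    def test_positive_count_has_zero_weight(self):
        w = e_step(np.array([5.0, 0.0]), np.array([2.0, 2.0]),
                   np.array([1.0, 1.0]), pi=0.3)
        assert w[0] == 0.0

    def test_boundaries(self):
        y = np.zeros(3)
        mu = np.full(3, 2.0)
        th = np.full(3, 1.0)
        assert np.all(e_step(y, mu, th, pi=0.0) == 0.0)
        assert np.all(e_step(y, mu, th, pi=1 - 1e-12) > 1 - 1e-9)

    def test_hand_arithmetic(self):
        # mu=2, theta=1: nb(0) = 1/3; w = 0.3 / (0.3 + 0.7/3)
        w = e_step(np.array([0.0]), np.array([2.0]), np.array([1.0]), pi=0.3)
        assert w[0] == pytest.approx(0.3 / (0.3 + 0.7 / 3.0), rel=1e-10)


class TestMStep:
    def test_gamma_closed_form(self, zinb_taxon):
        y, x, params = zinb_taxon
        w = (y == 0).astype(float)
        new = m_step(y, x, w, params)
        assert special.expit(new.gamma) == pytest.approx(np.mean(w), rel=1e-8)

    def test_q_ascent(self, zinb_taxon):
        y, x, params = zinb_taxon
        y, x = y[:50], x[:50]
        mu = np.exp(params.beta0 + params.beta1 * x)
        w = e_step(y, mu, np.exp(params.kappa0) * np.ones_like(y),
                   special.expit(params.gamma))
        start = TaxonParams(-5.0, 0.7, 0.0, 0.0, params.gamma)

        def q(p):
            c = 1.0 - w
            from taxanorm.zinb import link_arrays, nb_logpmf

            mu_, th_, pi_ = link_arrays(p, x)
            pi_ = min(max(pi_, 1e-10), 1 - 1e-10)
            return (np.sum(w) * np.log(pi_) + np.sum(c) * np.log1p(-pi_)
                    + np.sum(c * nb_logpmf(y, mu_, th_)))

        new = m_step(y, x, w, start)
        assert q(new) >= q(start) - 1e-6


class TestFitTaxon:
    def test_nb_reduction_when_no_zero_inflation(self, rng):
        # pi=0, kappa1=0 data: EM matches a direct NB maximum-likelihood fit
        n = 300
        x = np.log(rng.uniform(1e4, 1e5, size=n))
        mu = np.exp(-5.0 + 0.8 * x)
        y = rng.poisson(rng.gamma(2.0, mu / 2.0)).astype(float)
        y[y == 0] = 1.0  # keep the taxon in the NB class deterministically
        fit = fit_taxon(y, x, FitConfig(), constraint="fixed-dispersion")
        assert fit.model_class == "NB"
        oracle = direct_mle_loglik(y, x, constraint="fixed-dispersion")
        assert fit.loglik == pytest.approx(oracle, abs=1e-2)

    def test_em_matches_direct_mle_small(self, sim_small):
        kept, _, _ = filter_taxa(sim_small.counts, 10)
        x = np.log(sim_small.depths)
        mismatches = 0
        for i in range(min(6, kept.n_taxa)):
            y = kept.counts[i].astype(float)
            fit = fit_taxon(y, x, FitConfig())
            if fit.model_class != "ZINB" or not fit.converged:
                continue
            oracle = direct_mle_loglik(y, x)
            # EM must reach (or exceed, if multi-start missed) the direct MLE
            if fit.loglik < oracle - 1e-3:
                mismatches += 1
        assert mismatches == 0

    def test_nested_models_loglik_ordering(self, sim_small):
        kept, _, _ = filter_taxa(sim_small.counts, 10)
        x = np.log(sim_small.depths)
        for i in range(4):
            y = kept.counts[i].astype(float)
            full = fit_taxon(y, x, FitConfig())
            prev = fit_taxon(y, x, FitConfig(), constraint="prevalence-null")
            equiv = fit_taxon(y, x, FitConfig(), constraint="equivalence-null")
            assert full.loglik >= prev.loglik - 1e-6
            assert full.loglik >= equiv.loglik - 1e-6

    def test_observed_loglik_ascends(self, sim_small):
        # EM guarantees monotone observed-data log-likelihood (the Q sequence
        # across iterations is not monotone in general, since the weights move)
        kept, _, _ = filter_taxa(sim_small.counts, 10)
        x = np.log(sim_small.depths)
        for i in range(kept.n_taxa):
            fit = fit_taxon(kept.counts[i].astype(float), x, FitConfig())
            if fit.ll_trace.size > 1:
                assert np.all(np.diff(fit.ll_trace) >= -1e-8 * np.abs(fit.ll_trace[:-1]))

    def test_weights_zero_on_positive_counts(self, sim_small):
        kept, _, _ = filter_taxa(sim_small.counts, 10)
        x = np.log(sim_small.depths)
        fit = fit_taxon(kept.counts[0].astype(float), x, FitConfig())
        y = kept.counts[0]
        assert np.all(fit.weights[y > 0] == 0.0)
        assert np.all((fit.weights >= 0) & (fit.weights <= 1))


class TestFitMatrix:
    def test_model_class_split(self, rng):
        x = np.exp(np.linspace(9, 11, 40))
        no_zeros = rng.poisson(50, size=40) + 1
        many_zeros = np.where(rng.uniform(size=40) < 0.4, 0, rng.poisson(30, size=40))
        m = CountMatrix(np.vstack([no_zeros, many_zeros]).astype(np.int64),
                        ["dense", "sparse"], [f"s{j}" for j in range(40)])
        fits = fit_matrix(m)
        assert fits[0].model_class == "NB"
        assert fits[1].model_class == "ZINB"

    def test_matrix_equals_per_taxon_fits(self, sim_small):
        kept, _, _ = filter_taxa(sim_small.counts, 10)
        x = np.log(sim_small.depths)
        fits = fit_matrix(kept, depth=sim_small.depths)
        for i in [0, 3, 7]:
            solo = fit_taxon(kept.counts[i].astype(float), x, FitConfig())
            assert fits[i].loglik == pytest.approx(solo.loglik, abs=1e-9)

    def test_observed_loglik_consistency(self, sim_small):
        kept, _, _ = filter_taxa(sim_small.counts, 10)
        fits = fit_matrix(kept, depth=sim_small.depths)
        x = np.log(sim_small.depths)
        for f in fits:
            if f.model_class == "ZINB":
                i = kept.taxon_ids.index(f.taxon_id)
                assert f.loglik == pytest.approx(
                    taxon_loglik(f.params, kept.counts[i].astype(float), x), abs=1e-8)


class TestParameterRecovery:
    def test_beta1_recovery_large_n(self, rng):
        # the depth coefficient on the mean is estimated with small bias
        n, reps = 1000, 30
        errs = []
        for _ in range(reps):
            x = np.log(rng.uniform(1e4, 1e5, size=n))
            true = TaxonParams(rng.uniform(-4, -1), rng.uniform(0.5, 1.4),
                               rng.uniform(0.0, 1.0), 0.2, rng.uniform(-2, 0))
            mu = np.exp(true.beta0 + true.beta1 * x)
            th = np.exp(true.kappa0 + true.kappa1 * x)
            lam = rng.gamma(th, mu / th)
            y = np.where(rng.uniform(size=n) < special.expit(true.gamma),
                         0, rng.poisson(lam)).astype(float)
            if not np.any(y > 0):
                continue
            fit = fit_taxon(y, x, FitConfig())
            errs.append(fit.params.beta1 - true.beta1)
        assert abs(np.mean(errs)) < 0.05
        # dispersion/zero-mass estimates need only stay bounded
        assert np.all(np.isfinite(errs))
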