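"""Occupancy likelihoods against brute-force oracles, MLE behaviour, and the
false-positive diagnostic model."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import pastocc as po
from pastocc.occupancy import fitted_psi_p, fp_nll, occ_nll, occ_nll_grad

from conftest import make_matrix, null_covariates


def oracle_occ_nll(params, m, cov, spec):
    """Explicit latent-state marginalization: sum over z in {0,1} per site."""
    from pastocc.occupancy import _design, _split

    X, W, y, mask = _design(m, cov, spec)
    beta, alpha = _split(params, spec)
    psi = expit(X @ beta)
    p = expit(W @ alpha)
    total = 0.0
    for i in range(len(psi)):
        L = 0.0
        for z in (0, 1):
            pr = psi[i] if z else 1 - psi[i]
            for j in range(y.shape[1]):
                if not mask[i, j]:
                    continue
                pij = p[i, j] if z else 0.0
                pr *= pij if y[i, j] == 1 else 1 - pij
            L += pr
        total -= np.log(L)
    return total


def oracle_fp_nll(params, m, cov, spec):
    """Two-state marginalization oracle for the three-state model."""
    from pastocc.occupancy import _fp_design

    X, W, s, mask = _fp_design(m, cov, spec)
    kpsi = 1 + len(spec.psi_covariates)
    kp = 1 + len(spec.p_covariates)
    psi = expit(X @ params[:kpsi])
    p11 = expit(W @ params[kpsi:kpsi + kp])
    p10 = expit(params[-2])
    b = expit(params[-1])
    total = 0.0
    for i in range(len(psi)):
        L = 0.0
        for z in (0, 1):
            pr = psi[i] if z else 1 - psi[i]
            for j in range(s.shape[1]):
                if not mask[i, j]:
                    continue
                st = s[i, j]
                if z:
                    pr *= {0: 1 - p11[i, j], 1: p11[i, j] * (1 - b), 2: p11[i, j] * b}[st]
                else:
                    pr *= {0: 1 - p10, 1: p10, 2: 0.0}[st]
            L += pr
        total -= np.log(max(L, 1e-300))
    return total


def random_instance(rng, three_state=False, max_sites=5, max_reps=4):
    n = rng.integers(1, max_sites + 1)
    J = rng.integers(1, max_reps + 1)
    vals = [0.0, 1.0, 2.0, np.nan] if three_state else [0.0, 1.0, np.nan]
    probs = [0.4, 0.2, 0.2, 0.2] if three_state else [0.5, 0.3, 0.2]
    states = rng.choice(vals, size=(n, J), p=probs)
    # every site needs at least one usable replicate
    for i in range(n):
        if np.isnan(states[i]).all():
            states[i, rng.integers(J)] = 0.0
    if not three_state:
        states = np.where(states == 1.0, 2.0, states)  # binary layer as certain
    return make_matrix(states)


class TestLikelihoodValues:
    def test_closed_form_single_site(self):
        cov = null_covariates(make_matrix([[2, 0]]))
        spec = po.ModelSpec()
        # psi = p = 0.5, history [1, 0]: L = 0.5 * 0.5 * 0.5
        m = make_matrix([[2, 0]])
        assert occ_nll(np.zeros(2), m, cov, spec) == pytest.approx(-np.log(0.125), abs=1e-10)
        # all-zero history: L = 0.5 * 0.25 + 0.5
        m0 = make_matrix([[0, 0]])
        assert occ_nll(np.zeros(2), m0, null_covariates(m0), spec) == pytest.approx(
            -np.log(0.625), abs=1e-10
        )

    def test_matches_marginalization_oracle(self):
        """Vector likelihood equals the explicit sum over occupancy states
        on random ragged instances, to 1e-10."""
        rng = np.random.default_rng(10)
        for _ in range(200):
            m = random_instance(rng)
            with_cov = rng.random() < 0.5
            if with_cov:
                cov = null_covariates(m, one=rng.normal(size=m.n_sites))
                spec = po.ModelSpec(psi_covariates=("one",))
            else:
                cov = null_covariates(m)
                spec = po.ModelSpec()
            params = rng.normal(scale=1.5, size=spec.n_params)
            assert occ_nll(params, m, cov, spec) == pytest.approx(
                oracle_occ_nll(params, m, cov, spec), abs=1e-10
            )

    def test_analytic_gradient_matches_finite_difference(self):
        rng = np.random.default_rng(11)
        m = random_instance(rng, max_sites=8, max_reps=5)
        cov = null_covariates(m, one=rng.normal(size=m.n_sites))
        spec = po.ModelSpec(psi_covariates=("one",), p_covariates=("one",))
        params = rng.normal(size=spec.n_params)
        g = occ_nll_grad(params, m, cov, spec)
        eps = 1e-6
        for k in range(len(params)):
            e = np.zeros_like(params); e[k] = eps
            fd = (occ_nll(params + e, m, cov, spec) - occ_nll(params - e, m, cov, spec)) / (2 * eps)
            assert g[k] == pytest.approx(fd, rel=1e-5, abs=1e-6)

    def test_permutation_and_site_order_invariance(self):
        rng = np.random.default_rng(12)
        states = rng.choice([0.0, 2.0, np.nan], size=(15, 4), p=[0.5, 0.3, 0.2])
        states[:, 0] = 0.0
        m = make_matrix(states)
        cov = null_covariates(m)
        spec = po.ModelSpec()
        params = np.array([0.3, -0.7])
        base = occ_nll(params, m, cov, spec)
        perm = np.array([rng.permutation(4) for _ in range(15)])
        m2 = make_matrix(np.take_along_axis(states, perm, axis=1))
        assert occ_nll(params, m2, null_covariates(m2), spec) == pytest.approx(base, abs=1e-10)
        order = rng.permutation(15)
        m3 = make_matrix(states[order])
        assert occ_nll(params, m3, null_covariates(m3), spec) == pytest.approx(base, abs=1e-10)


class TestFitting:
    def test_null_mle_matches_grid_search(self):
        """The 2-parameter null MLE agrees with a 200x200 grid search over
        (psi, p) to within the grid resolution."""
        rng = np.random.default_rng(13)
        z = rng.random(60) < 0.6
        y = ((rng.random((60, 4)) < 0.55) & z[:, None]).astype(float)
        m = make_matrix(y * 2)
        cov = null_covariates(m)
        fit = po.fit_occupancy(m, cov, po.ModelSpec(), n_starts=4, seed=0)
        assert fit.converged

        grid = np.linspace(0.0025, 0.9975, 200)
        det = y.sum(axis=1)
        J = np.full(60, 4)
        best = (np.inf, None, None)
        for psi in grid:
            # vectorize over p for speed
            for p in grid:
                Ls = psi * p**det * (1 - p) ** (J - det) + (1 - psi) * (det == 0)
                nll = -np.log(Ls).sum()
                if nll < best[0]:
                    best = (nll, psi, p)
        res = np.ptp(grid) / 199
        assert expit(fit.beta_psi["(Intercept)"]) == pytest.approx(best[1], abs=res)
        assert expit(fit.beta_p["(Intercept)"]) == pytest.approx(best[2], abs=res)

    def test_parameter_recovery_small(self):
        """Intercept-only estimates land near the generating (psi, p) on one
        large simulated dataset."""
        rng = np.random.default_rng(14)
        psi, p = 0.6, 0.7
        z = rng.random(500) < psi
        y = ((rng.random((500, 5)) < p) & z[:, None]).astype(float)
        m = make_matrix(y * 2)
        fit = po.fit_occupancy(m, null_covariates(m), po.ModelSpec(), n_starts=4, seed=1)
        assert fit.converged
        assert expit(fit.beta_psi["(Intercept)"]) == pytest.approx(psi, abs=0.08)
        assert expit(fit.beta_p["(Intercept)"]) == pytest.approx(p, abs=0.06)

    def test_all_detected_boundary(self):
        m = make_matrix(np.full((20, 3), 2.0))
        fit = po.fit_occupancy(m, null_covariates(m), po.ModelSpec(), n_starts=2, seed=0)
        assert expit(fit.beta_psi["(Intercept)"]) > 0.99
        assert expit(fit.beta_p["(Intercept)"]) > 0.99

    def test_null_psi_hat_at_least_naive(self, default_survey):
        m, cov = default_survey["matrix"], default_survey["cov"]
        fit = po.fit_occupancy(m, cov, po.ModelSpec(), n_starts=4, seed=2)
        psi_hat = expit(fit.beta_psi["(Intercept)"])
        assert psi_hat >= po.naive_occupancy(m) - 1e-9

    def test_nonconvergence_is_flagged_not_raised(self):
        # quasi-separated data drive the slope to infinity: the fit must
        # come back flagged, never raise
        one = np.array([-3.0] * 10 + [3.0] * 10)
        y = np.array([0.0] * 10 + [1.0] * 10)[:, None] * np.ones((1, 3))
        m = make_matrix(y * 2)
        cov = null_covariates(m, one=one)
        fit = po.fit_occupancy(m, cov, po.ModelSpec(psi_covariates=("one",)),
                               n_starts=3, seed=0)
        assert not fit.converged


class TestPrediction:
    def _fit(self, seed=15, n=300):
        rng = np.random.default_rng(seed)
        one = rng.normal(size=n)
        psi = expit(0.2 + 0.9 * one)
        z = rng.random(n) < psi
        y = ((rng.random((n, 4)) < 0.45) & z[:, None]).astype(float)
        m = make_matrix(y * 2)
        cov = null_covariates(m, one=one)
        fit = po.fit_occupancy(m, cov, po.ModelSpec(psi_covariates=("one",)),
                               n_starts=4, seed=0)
        return fit, m, cov

    def test_intercept_only_predicts_half_at_zero(self):
        m = make_matrix([[2, 0], [0, 0]])
        fit = po.OccupancyFit(
            spec=po.ModelSpec(), params=np.array([0.0, 0.0]),
            se=np.array([0.1, 0.1]), vcov=np.eye(2) * 0.01,
            log_likelihood=0.0, n_sites=2, converged=True, hessian_pd=True,
            max_gradient_norm=0.0,
        )
        pred = po.predict_psi(fit, pd.DataFrame(index=m.site_ids))
        np.testing.assert_allclose(pred["psi"], 0.5)

    def test_monotone_in_positive_covariate(self):
        fit, m, cov = self._fit()
        assert fit.converged and fit.beta_psi["one"] > 0
        rows = pd.DataFrame({"one": np.linspace(-2, 2, 9)})
        pred = po.predict_psi(fit, rows)
        assert (np.diff(pred["psi"]) > 0).all()

    def test_extrapolation_warns(self):
        fit, m, cov = self._fit()
        rows = pd.DataFrame({"one": [99.0]})
        with pytest.warns(UserWarning, match="training range"):
            po.predict_psi(fit, rows)

    def test_delta_method_se_matches_bootstrap(self):
        """Delta-method SE of predicted psi agrees with a parametric
        bootstrap within 10%."""
        fit, m, cov = self._fit()
        rows = pd.DataFrame({"one": [0.5]})
        se_delta = po.predict_psi(fit, rows)["se"].iloc[0]

        rng = np.random.default_rng(99)
        psi, p, mask = fitted_psi_p(fit, m, cov)
        boots = []
        for _ in range(150):
            yb = po.occupancy.simulate_binary_from(psi, p, mask, rng)
            mb = make_matrix(yb * 2, site_ids=m.site_ids)
            fb = po.fit_occupancy(mb, cov, fit.spec, n_starts=1, seed=0, start=fit.params)
            if fb.converged:
                boots.append(po.predict_psi(fb, rows)["psi"].iloc[0])
        se_boot = np.std(boots, ddof=1)
        assert se_delta == pytest.approx(se_boot, rel=0.10)


class TestFalsePositive:
    def test_single_replicate_closed_form(self):
        # one site, one replicate, state 0, psi=p11=p10=0.5, b~1:
        # L = 0.5*0.5 + 0.5*0.5 = 0.5
        m = make_matrix([[0.0]])
        cov = null_covariates(m)
        params = np.array([0.0, 0.0, 0.0, 40.0])  # logits; b -> 1
        assert fp_nll(params, m, cov, po.ModelSpec()) == pytest.approx(np.log(2), abs=1e-9)

    def test_matches_marginalization_oracle(self):
        rng = np.random.default_rng(16)
        for _ in range(150):
            m = random_instance(rng, three_state=True)
            cov = null_covariates(m)
            spec = po.ModelSpec()
            params = rng.normal(scale=1.5, size=spec.n_params + 2)
            assert fp_nll(params, m, cov, spec) == pytest.approx(
                oracle_fp_nll(params, m, cov, spec), abs=1e-10
            )

    def test_reduces_to_binary_model_when_b_one_p10_zero(self):
        """With b = 1 and p10 = 0, every detection is certain and the
        three-state likelihood coincides with the binary likelihood at
        p = p11 * b on the certain-only collapse."""
        rng = np.random.default_rng(17)
        for _ in range(30):
            states = rng.choice([0.0, 2.0, np.nan], size=(6, 3), p=[0.5, 0.3, 0.2])
            for i in range(6):
                if np.isnan(states[i]).all():
                    states[i, 0] = 0.0
            m = make_matrix(states)
            cov = null_covariates(m)
            b_logit, p10_logit = 40.0, -40.0
            base = rng.normal(size=2)
            v_fp = fp_nll(np.r_[base, p10_logit, b_logit], m, cov, po.ModelSpec())
            v_occ = occ_nll(base, m, cov, po.ModelSpec())
            assert v_fp == pytest.approx(v_occ, abs=1e-7)

    def test_certain_at_unoccupied_impossible(self):
        # psi -> 0 with a certain detection forces the occupied branch; at
        # psi exactly 0 the likelihood hits the -inf guard, not an exception
        m = make_matrix([[2.0]])
        cov = null_covariates(m)
        v = fp_nll(np.array([-60.0, 0.0, 0.0, 0.0]), m, cov, po.ModelSpec())
        assert np.isfinite(v) and v > 20  # huge penalty, no crash

    def test_structural_nonidentifiability_flagged(self):
        """b at one with no uncertain records leaves p10 inestimable."""
        rng = np.random.default_rng(18)
        z = rng.random(80) < 0.5
        det = (rng.random((80, 3)) < 0.5) & z[:, None]
        m = make_matrix(det.astype(float) * 2)
        fit = po.fit_false_positive(m, null_covariates(m), n_starts=3, seed=0)
        assert fit.boundary_flags["p10"]
        assert fit.profile_flat

    def test_recovery_with_informative_contrast(self):
        """With abundant certain/uncertain contrast the three-state MLE
        recovers the generating parameters."""
        rng = np.random.default_rng(19)
        n, J = 1000, 4
        psi, p11, p10, b = 0.55, 0.5, 0.10, 0.7
        z = rng.random(n) < psi
        states = np.zeros((n, J))
        det = (rng.random((n, J)) < p11) & z[:, None]
        certain = rng.random((n, J)) < b
        states[det] = np.where(certain[det], 2.0, 1.0)
        fp = (rng.random((n, J)) < p10) & ~z[:, None]
        states[fp] = 1.0
        m = make_matrix(states)
        fit = po.fit_false_positive(m, null_covariates(m), n_starts=4, seed=1)
        assert fit.psi_hat == pytest.approx(psi, abs=0.08)
        assert fit.p11_hat == pytest.approx(p11, abs=0.06)
        assert fit.p10_hat == pytest.approx(p10, abs=0.04)
        assert fit.b_hat == pytest.approx(b, abs=0.06)
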