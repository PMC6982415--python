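from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import medperm.permutation as perm
from medperm import (
    MediationData,
    PermutationConfig,
    iefm_test,
    ierm_test,
    nearest_quantile,
    psrm_test,
    two_sided_perm_pvalue,
)


def brute_force_reduced_pvalues(data: MediationData):
    """Independent nested-loop enumeration of the reduced-model permutation test.

    Every OLS fit is a direct ``np.linalg.lstsq`` call on the explicit design;
    no code is shared with the vectorized engine.  Returns the exact p-values
    for the indirect effect, alpha1 and gamma3 over the full Cartesian product
    of residual permutations.
    """
    n = data.n

    def ols(y, cols):
        design = np.column_stack([np.ones(n)] + cols)
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        return coef, design @ coef

    xc = [data.x] + [data.c[:, j] for j in range(data.n_covariates)]
    c_only = [data.c[:, j] for j in range(data.n_covariates)]

    coef_y, _ = ols(data.y, xc + [data.m])
    coef_m, _ = ols(data.m, xc)
    a1_obs, g3_obs = coef_m[1], coef_y[-1]
    ie_obs = a1_obs * g3_obs

    _, yhat_r = ols(data.y, xc)
    ey = data.y - yhat_r
    _, mhat_r = ols(data.m, c_only)
    em = data.m - mhat_r

    tol = 1 - perm.TIE_RTOL
    counts = [0, 0, 0]
    total = 0
    for py in permutations(range(n)):
        ystar = yhat_r + ey[list(py)]
        coef_ys, _ = ols(ystar, xc + [data.m])
        g3 = coef_ys[-1]
        for pm in permutations(range(n)):
            mstar = mhat_r + em[list(pm)]
            coef_ms, _ = ols(mstar, xc)
            a1 = coef_ms[1]
            total += 1
            if abs(a1 * g3) >= abs(ie_obs) * tol:
                counts[0] += 1
            if abs(a1) >= abs(a1_obs) * tol:
                counts[1] += 1
            if abs(g3) >= abs(g3_obs) * tol:
                counts[2] += 1
    return tuple(c / total for c in counts)


class TestTwoSidedPvalue:
    @pytest.mark.parametrize(
        "observed, draws, expected",
        [
            (0.0, [1.0, -5.0, 0.2], 1.0),
            (10.0, [1.0, -2.0, 3.0], 0.0),
            (2.0, [1.0, -2.0, 3.0, 0.5], 0.5),  # draws -2 and 3 qualify
        ],
    )
    def test_examples(self, observed, draws, expected):
        assert two_sided_perm_pvalue(observed, draws) == expected

    def test_smoothed_variant(self):
        assert two_sided_perm_pvalue(10.0, [1.0, -2.0, 3.0], smoothed=True) == 0.25

    def test_empty_draws_rejected(self):
        with pytest.raises(ValueError):
            two_sided_perm_pvalue(1.0, [])

    @given(
        draws=st.lists(
            st.floats(-1e6, 1e6, allow_nan=False), min_size=1, max_size=50
        ),
        observed=st.floats(-1e6, 1e6, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_is_valid_proportion_on_grid(self, draws, observed):
        p = two_sided_perm_pvalue(observed, draws)
        assert 0.0 <= p <= 1.0
        assert (p * len(draws)) == pytest.approx(round(p * len(draws)))

    @given(
        draws=st.lists(st.floats(-100, 100, allow_nan=False), min_size=1, max_size=30)
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_observed_magnitude(self, draws):
        ps = [two_sided_perm_pvalue(o, draws) for o in (0.0, 1.0, 10.0, 1e6)]
        assert ps == sorted(ps, reverse=True)


class TestEngine:
    def test_vectorized_refits_equal_literal_refits(self, random_data, monkeypatch):
        """The QR/Frisch-Waugh engine must equal per-permutation fit_linear refits."""
        from medperm.models import fit_linear, fit_mediation

        rng = np.random.default_rng(5)
        n = random_data.n
        perms_y = np.array([rng.permutation(n) for _ in range(20)])
        perms_m = np.array([rng.permutation(n) for _ in range(20)])

        def fixed_matrices(ey, em, cfg, n):
            return ey[perms_y].T, em[perms_m].T

        monkeypatch.setattr(perm, "_permutation_matrices", fixed_matrices)
        cfg = PermutationConfig(n_perm=20, seed=0)
        fits, alpha1, gamma3 = perm._permuted_coefficients(random_data, cfg, "reduced")

        full = fit_mediation(random_data, with_reduced=True)
        xc = np.column_stack([random_data.x, random_data.c])
        for k in range(20):
            ystar = full.outcome_reduced.fitted + full.outcome_reduced.residuals[perms_y[k]]
            mstar = full.mediator_reduced.fitted + full.mediator_reduced.residuals[perms_m[k]]
            a1 = fit_linear(mstar, xc).coefficients[1]
            g3 = fit_linear(ystar, np.column_stack([xc, random_data.m])).coefficients[-1]
            assert alpha1[k] == pytest.approx(a1, abs=1e-10)
            assert gamma3[k] == pytest.approx(g3, abs=1e-10)

    def test_identity_permutations_give_pvalue_one(self, random_data, monkeypatch):
        def identity_matrices(ey, em, cfg, n):
            return np.tile(ey, (cfg.n_perm, 1)).T, np.tile(em, (cfg.n_perm, 1)).T

        monkeypatch.setattr(perm, "_permutation_matrices", identity_matrices)
        cfg = PermutationConfig(n_perm=50, seed=0)
        res_ierm = ierm_test(random_data, cfg)
        res_psrm = psrm_test(random_data, cfg)
        assert res_ierm.p_value == 1.0
        assert res_psrm.p_value == 1.0
        assert res_psrm.component_p_alpha == 1.0
        assert res_psrm.component_p_gamma == 1.0


class TestExactEnumeration:
    @pytest.fixture
    def tiny_data(self):
        rng = np.random.default_rng(99)
        return MediationData(
            x=rng.standard_normal(5), m=rng.standard_normal(5), y=rng.standard_normal(5)
        )

    def test_matches_brute_force_oracle(self, tiny_data):
        """Exhaustive IERM/PSRM p-values equal an independent nested-loop enumeration."""
        p_ie, p_a, p_g = brute_force_reduced_pvalues(tiny_data)
        cfg = PermutationConfig(exact=True, seed=0)
        res_ierm = ierm_test(tiny_data, cfg)
        res_psrm = psrm_test(tiny_data, cfg)
        assert res_ierm.n_resamples == 120 * 120
        assert res_ierm.p_value == p_ie
        assert res_psrm.component_p_alpha == p_a
        assert res_psrm.component_p_gamma == p_g
        assert res_psrm.p_value == max(p_ie, p_a, p_g)

    def test_enumeration_cap_enforced(self, rng):
        data = MediationData(
            x=rng.standard_normal(10), m=rng.standard_normal(10),
            y=rng.standard_normal(10),
        )
        with pytest.raises(ValueError, match="enumeration"):
            ierm_test(data, PermutationConfig(exact=True))


class TestProcedures:
    def test_seed_determinism(self, random_data):
        cfg = PermutationConfig(n_perm=300, seed=42)
        for test in (ierm_test, psrm_test, iefm_test):
            assert test(random_data, cfg) == test(random_data, cfg)

    def test_different_seeds_give_different_draws_but_close_pvalues(self, random_data):
        a1_a, _ = perm._permuted_coefficients(
            random_data, PermutationConfig(n_perm=500, seed=1), "reduced"
        )[1:]
        a1_b, _ = perm._permuted_coefficients(
            random_data, PermutationConfig(n_perm=500, seed=2), "reduced"
        )[1:]
        assert not np.array_equal(a1_a, a1_b)
        pa = ierm_test(random_data, PermutationConfig(n_perm=500, seed=1)).p_value
        pb = ierm_test(random_data, PermutationConfig(n_perm=500, seed=2)).p_value
        assert abs(pa - pb) < 0.2

    def test_supremum_dominance(self, rng):
        """PSRM's p-value can never fall below IERM's on the same draws."""
        for k in range(5):
            n = 25
            data = MediationData(
                x=rng.standard_normal(n),
                m=rng.standard_normal(n),
                y=rng.standard_normal(n),
                c=rng.standard_normal((n, 1)),
            )
            cfg = PermutationConfig(n_perm=400, seed=k)
            res_i = ierm_test(data, cfg)
            res_p = psrm_test(data, cfg)
            assert res_p.p_value >= res_i.p_value
            if not res_i.reject:
                assert not res_p.reject

    def test_overwhelming_signal_rejects(self, chain_data):
        cfg = PermutationConfig(n_perm=500, seed=3)
        assert ierm_test(chain_data, cfg).p_value == 0.0
        assert ierm_test(chain_data, cfg).reject
        assert psrm_test(chain_data, cfg).reject
        res = iefm_test(chain_data, cfg)
        assert res.reject and res.ci_lower > 0

    def test_iefm_interval_is_ordered_and_monotone_in_alpha(self, random_data):
        rejected_at = []
        for alpha in (0.2, 0.05, 0.01):
            res = iefm_test(random_data, PermutationConfig(n_perm=500, seed=7, alpha=alpha))
            assert res.ci_lower <= res.ci_upper
            assert res.p_value is None
            rejected_at.append(res.reject)
        # widening alpha never turns a rejection into a non-rejection
        for tighter, wider in zip(rejected_at[1:], rejected_at[:-1]):
            assert wider or not tighter

    def test_joint_scheme_runs_and_is_deterministic(self, random_data):
        cfg = PermutationConfig(n_perm=200, seed=11, scheme="joint")
        assert psrm_test(random_data, cfg) == psrm_test(random_data, cfg)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PermutationConfig(n_perm=0)
        with pytest.raises(ValueError):
            PermutationConfig(alpha=1.5)
        with pytest.raises(ValueError):
            PermutationConfig(scheme="sideways")


class TestNearestQuantile:
    def test_order_statistics(self):
        draws = np.arange(1.0, 101.0)
        assert nearest_quantile(draws, 0.05) == 5.0
        assert nearest_quantile(draws, 0.95) == 95.0
        assert nearest_quantile(draws, 0.0) == 1.0
        assert nearest_quantile(draws, 1.0) == 100.0
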