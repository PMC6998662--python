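"""Negative-binomial Wald differential expression engine."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.stats import kstest, spearmanr

from serumrna.cohort import CountMatrix
from serumrna.de import (
    adjust_bh,
    build_design,
    estimate_dispersions,
    size_factors,
    wald_test,
)

from conftest import make_case, make_control


def _nb_counts(rng, n_rnas, n_samples, mu, alpha, lfc=None, group=None):
    """Two-group NB counts with optional per-RNA log2 fold changes."""
    mu = np.broadcast_to(np.atleast_1d(mu), (n_rnas,)).astype(float)
    mean = np.tile(mu[:, None], (1, n_samples))
    if lfc is not None:
        mean = mean * 2.0 ** (np.atleast_1d(lfc)[:, None] * group[None, :])
    r = 1.0 / alpha if np.isscalar(alpha) else 1.0 / np.asarray(alpha)[:, None]
    r = np.broadcast_to(r, mean.shape)
    return rng.negative_binomial(r, r / (r + mean))


def _matrix(counts):
    n_r, n_s = counts.shape
    return CountMatrix(
        [f"r{i:03d}" for i in range(n_r)], ["miRNA"] * n_r,
        [f"s{j:03d}" for j in range(n_s)], counts,
    )


class TestSizeFactors:
    def test_doubled_column_closed_form(self):
        c = np.array([[10, 20], [4, 8], [100, 200]])
        sf = size_factors(c)
        assert sf == pytest.approx([2 ** -0.5, 2 ** 0.5], rel=1e-12)

    def test_identical_columns_give_unit_factors(self):
        c = np.tile(np.array([[3], [9], [27]]), (1, 4))
        assert size_factors(c) == pytest.approx([1, 1, 1, 1])

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        c = rng.poisson(30, size=(50, 6))
        sf = size_factors(c)
        perm = [3, 1, 5, 0, 2, 4]
        assert size_factors(c[:, perm]) == pytest.approx(sf[perm])

    def test_no_reference_rna_errors(self):
        c = np.array([[0, 5], [3, 0]])
        with pytest.raises(ValueError, match="all-positive"):
            size_factors(c)


class TestDispersions:
    def test_poisson_data_near_zero(self):
        rng = np.random.default_rng(1)
        c = rng.poisson(50, size=(200, 100))
        X = np.column_stack([np.ones(100), np.repeat([0.0, 1.0], 50)])
        d = estimate_dispersions(c, np.ones(100), X)
        assert np.median(d) <= 0.01

    def test_nb_dispersion_recovery(self):
        rng = np.random.default_rng(2)
        c = _nb_counts(rng, 200, 100, mu=50.0, alpha=0.5)
        X = np.column_stack([np.ones(100), np.repeat([0.0, 1.0], 50)])
        d = estimate_dispersions(c, np.ones(100), X)
        assert 0.3 <= np.median(d) <= 0.8

    def test_constant_counts_hit_floor(self):
        c = np.full((5, 20), 7)
        X = np.column_stack([np.ones(20), np.repeat([0.0, 1.0], 10)])
        d = estimate_dispersions(c, np.ones(20), X)
        assert np.all(d == pytest.approx(1e-8))

    def test_requires_residual_dof(self):
        c = np.full((3, 3), 5)
        X = np.column_stack([np.ones(3), [0, 1, 0]])
        with pytest.raises(ValueError, match="degrees of freedom"):
            estimate_dispersions(c, np.ones(3), X)


class TestAdjustBH:
    def test_step_up_hand_example(self):
        padj = adjust_bh([0.01, 0.02, 0.03, 0.04, 0.05])
        assert padj == pytest.approx([0.05] * 5)

    def test_single_and_degenerate(self):
        assert adjust_bh([0.031]) == pytest.approx([0.031])
        assert adjust_bh([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_nan_reduces_m_with_warning(self):
        with pytest.warns(UserWarning, match="excluding 1"):
            padj = adjust_bh([0.01, np.nan, 0.04])
        assert np.isnan(padj[1])
        # m = 2: padj = (2*0.01/1 capped by step-up, 2*0.04/2)
        assert padj[0] == pytest.approx(0.02)
        assert padj[2] == pytest.approx(0.04)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.5])

    def test_monotone_in_pvalue(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=40)
        padj = adjust_bh(p)
        order = np.argsort(p)
        assert np.all(np.diff(padj[order]) >= -1e-12)
        assert np.all(padj >= p - 1e-12)


class TestDesign:
    @staticmethod
    def _samples():
        rng = np.random.default_rng(4)
        out = []
        for i in range(20):
            age = float(rng.uniform(40, 65))
            sex = ["male", "female"][i % 2]
            bdg = ["BDg_A", "BDg_B"][(i // 2) % 2]
            smoking = ["current", "former"][(i // 4) % 2]
            if i < 10:
                out.append(make_case(i, age=age, sex=sex, bdg=bdg, smoking=smoking))
            else:
                out.append(make_control(i, age=age, sex=sex, bdg=bdg, smoking=smoking))
        return out

    def test_reference_levels_and_scaling(self):
        X, names = build_design(self._samples())
        assert names[0] == "intercept"
        assert "group_case" in names
        assert "sex_male" in names and "sex_female" not in names
        assert "smoking_current" in names and "smoking_former" not in names
        assert "bdg_BDg_B" in names and "bdg_BDg_A" not in names
        age = X[:, names.index("age_z")]
        assert age.mean() == pytest.approx(0.0, abs=1e-12)
        assert age.std() == pytest.approx(1.0)

    def test_constant_covariate_dropped(self):
        rng = np.random.default_rng(12)
        samples = [
            make_case(i, age=float(rng.uniform(40, 60)), smoking="current")
            if i < 5
            else make_control(i, age=float(rng.uniform(40, 60)), smoking="current")
            for i in range(10)
        ]
        X, names = build_design(samples)
        assert not any(n.startswith("smoking") for n in names)


class TestWaldTest:
    def test_agrees_with_independent_glm_fit(self):
        """Coefficients and SEs match a statsmodels NB GLM per RNA."""
        rng = np.random.default_rng(5)
        group = np.repeat([0.0, 1.0], 20)
        counts = _nb_counts(rng, 12, 40, mu=80.0, alpha=0.2,
                            lfc=rng.normal(0, 1, 12), group=group)
        m = _matrix(counts)
        X = np.column_stack([np.ones(40), group, rng.normal(size=40)])
        sf = size_factors(counts)
        disp = estimate_dispersions(counts, sf, X)
        res = wald_test(m, X, sf, disp, group_col=1)
        for i, r in enumerate(res):
            fit = sm.GLM(
                counts[i].astype(float), X,
                family=sm.families.NegativeBinomial(alpha=float(disp[i])),
                offset=np.log(sf),
            ).fit()
            assert r.log2fc == pytest.approx(fit.params[1] / np.log(2), abs=1e-4)
            assert r.se == pytest.approx(fit.bse[1] / np.log(2), abs=1e-4)

    def test_effect_size_consistency(self):
        """True log2fc = 1 recovered within +/-0.1 on average at large n."""
        rng = np.random.default_rng(6)
        group = np.repeat([0.0, 1.0], 200)
        counts = _nb_counts(rng, 100, 400, mu=60.0, alpha=0.2,
                            lfc=np.ones(100), group=group)
        m = _matrix(counts)
        X = np.column_stack([np.ones(400), group])
        sf = np.ones(400)
        disp = estimate_dispersions(counts, sf, X)
        res = wald_test(m, X, sf, disp, group_col=1)
        assert np.mean([r.log2fc for r in res]) == pytest.approx(1.0, abs=0.1)

    def test_permutation_null_pvalues_uniform(self):
        """Shuffled group labels give uniform p-values (KS)."""
        rng = np.random.default_rng(7)
        counts = _nb_counts(rng, 400, 60, mu=50.0, alpha=0.3)
        m = _matrix(counts)
        group = rng.permutation(np.repeat([0.0, 1.0], 30))
        X = np.column_stack([np.ones(60), group])
        sf = size_factors(counts)
        disp = estimate_dispersions(counts, sf, X)
        res = wald_test(m, X, sf, disp, group_col=1)
        p = np.array([r.pvalue for r in res if np.isfinite(r.pvalue)])
        assert kstest(p, "uniform").pvalue > 0.01

    def test_scale_invariance_under_library_rescaling(self):
        """Sequencing-depth changes are absorbed by the size-factor offsets.

        A common rescaling of all size factors shifts only the intercept
        (log2fc invariant to numerical tolerance); scaling one sample's
        counts and re-estimating its size factor leaves log2fc nearly
        unchanged (the NB likelihood is not exactly scale-equivariant for
        a single sample, so this part is approximate).
        """
        rng = np.random.default_rng(8)
        counts = _nb_counts(rng, 50, 20, mu=40.0, alpha=0.2)
        group = np.repeat([0.0, 1.0], 10)
        X = np.column_stack([np.ones(20), group])
        disp = np.full(50, 0.2)

        sf = size_factors(counts)
        res_a = wald_test(_matrix(counts), X, sf, disp, group_col=1)
        res_common = wald_test(_matrix(counts), X, 7.0 * sf, disp, group_col=1)
        for a, b in zip(res_a, res_common):
            assert b.log2fc == pytest.approx(a.log2fc, abs=1e-6)

        scaled = counts.copy()
        scaled[:, 3] *= 3
        res_b = wald_test(_matrix(scaled), X, size_factors(scaled), disp, group_col=1)
        assert size_factors(scaled)[3] / sf[3] == pytest.approx(3.0 * 3 ** (-1 / 20))
        for a, b in zip(res_a, res_b):
            assert b.log2fc == pytest.approx(a.log2fc, abs=0.02)

    def test_all_zero_rna_flagged_not_crashed(self):
        rng = np.random.default_rng(9)
        counts = _nb_counts(rng, 10, 20, mu=30.0, alpha=0.2)
        counts[4] = 0
        group = np.repeat([0.0, 1.0], 10)
        X = np.column_stack([np.ones(20), group])
        res = wald_test(_matrix(counts), X, size_factors(counts), np.full(10, 0.2), group_col=1)
        assert not res[4].converged
        assert np.isnan(res[4].pvalue)
        assert all(r.converged for i, r in enumerate(res) if i != 4)

    def test_ranking_agrees_with_likelihood_ratio_oracle(self):
        """Wald ranking ~ profile LRT ranking (Spearman rho > 0.95)."""
        rng = np.random.default_rng(10)
        group = np.repeat([0.0, 1.0], 20)
        counts = _nb_counts(rng, 50, 40, mu=60.0, alpha=0.15,
                            lfc=rng.normal(0, 0.8, 50), group=group)
        m = _matrix(counts)
        X = np.column_stack([np.ones(40), group])
        sf = size_factors(counts)
        disp = estimate_dispersions(counts, sf, X)
        res = wald_test(m, X, sf, disp, group_col=1)
        lrt = []
        for i in range(50):
            fam = sm.families.NegativeBinomial(alpha=float(disp[i]))
            y = counts[i].astype(float)
            full = sm.GLM(y, X, family=fam, offset=np.log(sf)).fit()
            red = sm.GLM(y, X[:, :1], family=fam, offset=np.log(sf)).fit()
            lrt.append(2 * (full.llf - red.llf))
        rho = spearmanr([abs(r.wald) for r in res], lrt).statistic
        assert rho > 0.95

    def test_padj_invariants(self):
        rng = np.random.default_rng(11)
        counts = _nb_counts(rng, 100, 30, mu=40.0, alpha=0.3)
        group = np.repeat([0.0, 1.0], 15)
        X = np.column_stack([np.ones(30), group])
        sf = size_factors(counts)
        res = wald_test(_matrix(counts), X, sf, np.full(100, 0.3), group_col=1)
        p = np.array([r.pvalue for r in res])
        padj = np.array([r.padj for r in res])
        assert np.all(padj >= p - 1e-12)
        assert np.all((padj >= 0) & (padj <= 1))
        order = np.argsort(p)
        assert np.all(np.diff(padj[order]) >= -1e-12)
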