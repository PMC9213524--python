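import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from saltwise import CountMatrix, ExperimentDesign, filter_genes, fit_glm
from saltwise.glm import test_contrast as single_contrast_test
from saltwise.glm import (
    estimate_dispersions,
    normalization_factors,
    offsets_from_library_sizes,
    tmm_factors,
)

LN2 = np.log(2.0)


def make_design(n_strains=1, n_salinities=2, n_reps=3, salinities=None):
    salinities = salinities or list(range(8, 8 + 8 * n_salinities, 8))
    strains = [chr(ord("A") + i) for i in range(n_strains)]
    rows, ids = [], []
    for st_ in strains:
        for sal in salinities:
            for r in range(1, n_reps + 1):
                ids.append(f"{st_}_{sal}_r{r}")
                rows.append({"strain": st_, "salinity": sal, "replicate": r})
    return ExperimentDesign(
        pd.DataFrame(rows, index=ids), salinity_order=salinities
    )


def make_counts(values, design):
    values = np.atleast_2d(values)
    return CountMatrix(
        pd.DataFrame(
            values,
            index=[f"g{i}" for i in range(values.shape[0])],
            columns=design.sample_ids,
        )
    )


class TestFilter:
    def test_all_zero_gene_removed(self):
        design = make_design()
        counts = make_counts([[0] * 6, [100] * 6], design)
        kept = filter_genes(counts, design, min_cpm=1, min_samples=1)
        assert kept.gene_ids == ["g1"]

    def test_zero_threshold_is_identity(self):
        design = make_design()
        counts = make_counts([[0] * 6, [5] * 6], design)
        kept = filter_genes(counts, design, min_cpm=0, min_samples=1)
        assert kept.gene_ids == counts.gene_ids

    def test_hand_computed_cpm_rule(self):
        design = make_design(n_reps=2)  # 4 samples
        values = np.array(
            [
                [10, 10, 10, 10],   # cpm 1e4 everywhere -> kept
                [1, 0, 0, 0],       # cpm 1000,0,0,0 -> 1 sample >= 2000? no
                [5, 5, 0, 0],       # above threshold in 2 samples
                [0, 0, 0, 1],
            ]
        )
        counts = make_counts(values, design)
        totals = values.sum(axis=0)
        cpm = values / totals * 1e6
        expected = [
            f"g{i}" for i in range(4) if (cpm[i] >= 2000).sum() >= 2
        ]
        kept = filter_genes(counts, design, min_cpm=2000, min_samples=2)
        assert kept.gene_ids == expected


def brute_force_tmm(values, trim_m=0.3, trim_a=0.05):
    """Direct re-derivation of the weighted trimmed mean of M-values,
    written independently as explicit loops."""
    totals = values.sum(axis=0)
    props = values / totals
    uqs = []
    for j in range(values.shape[1]):
        expressed = props[:, j][values[:, j] > 0]
        uqs.append(np.quantile(expressed, 0.75))
    ref = int(np.argmin([abs(u - np.mean(uqs)) for u in uqs]))
    logf = []
    for j in range(values.shape[1]):
        if j == ref:
            logf.append(0.0)
            continue
        Ms, As, ws = [], [], []
        for g in range(values.shape[0]):
            if values[g, j] > 0 and values[g, ref] > 0:
                Ms.append(np.log2(props[g, j] / props[g, ref]))
                As.append(0.5 * np.log2(props[g, j] * props[g, ref]))
                ws.append(
                    1.0
                    / (
                        (totals[j] - values[g, j]) / (totals[j] * values[g, j])
                        + (totals[ref] - values[g, ref]) / (totals[ref] * values[g, ref])
                    )
                )
        Ms, As, ws = map(np.array, (Ms, As, ws))
        if len(Ms) > 10:
            m_lo, m_hi = np.quantile(Ms, [trim_m, 1 - trim_m])
            a_lo, a_hi = np.quantile(As, [trim_a, 1 - trim_a])
            keep = (Ms >= m_lo) & (Ms <= m_hi) & (As >= a_lo) & (As <= a_hi)
        else:
            keep = np.ones(len(Ms), bool)
        logf.append(float(np.sum(ws[keep] * Ms[keep]) / np.sum(ws[keep])))
    f = 2.0 ** np.array(logf)
    return f / np.exp(np.mean(np.log(f)))


class TestTMM:
    def test_identical_samples_factor_one(self):
        design = make_design(n_reps=1)
        counts = make_counts(np.tile([[10], [50], [200]], (1, 2)), design)
        f = tmm_factors(counts)
        np.testing.assert_allclose(f, 1.0)

    def test_pure_depth_change_factor_one(self):
        design = make_design(n_reps=1)
        rng = np.random.default_rng(0)
        a = rng.integers(10, 500, size=50)
        counts = make_counts(np.column_stack([a, 2 * a]), design)
        f = tmm_factors(counts)
        np.testing.assert_allclose(f.iloc[0] / f.iloc[1], 1.0, atol=1e-9)
        eff = normalization_factors(counts)
        np.testing.assert_allclose(eff.iloc[1] / eff.iloc[0], 2.0, rtol=1e-9)

    def test_matches_independent_brute_force(self):
        design = make_design(n_salinities=2, n_reps=2)  # 4 samples
        rng = np.random.default_rng(5)
        values = rng.integers(1, 1000, size=(80, 4))
        values[:20, 3] *= 5  # composition shift in one sample
        counts = make_counts(values, design)
        np.testing.assert_allclose(
            tmm_factors(counts).to_numpy(), brute_force_tmm(values.astype(float)),
            rtol=1e-10,
        )

    def test_all_zero_sample_errors(self):
        design = make_design(n_reps=1)
        counts = make_counts(np.array([[5, 0], [3, 0]]), design)
        with pytest.raises(ValueError, match="zero total"):
            tmm_factors(counts)


class TestDispersions:
    def _estimate(self, values, design):
        counts = make_counts(values, design)
        offsets = offsets_from_library_sizes(
            pd.Series(values.sum(axis=0).astype(float), index=design.sample_ids)
        )
        return estimate_dispersions(counts, design, offsets)

    def test_poisson_counts_near_zero(self):
        design = make_design(n_salinities=2, n_reps=6)  # 12 samples, 2 cells
        rng = np.random.default_rng(1)
        mu = rng.lognormal(4.5, 1.0, size=2000)
        values = rng.poisson(mu[:, None], size=(2000, 12))
        est = self._estimate(values, design)
        assert est.median() <= 0.05

    def test_nb_dispersion_recovered_within_band(self):
        design = make_design(n_salinities=2, n_reps=6)
        rng = np.random.default_rng(2)
        mu = rng.lognormal(5.0, 1.0, size=2000)
        lam = rng.gamma(1 / 0.4, 0.4 * mu[:, None], size=(2000, 12))
        values = rng.poisson(lam)
        est = self._estimate(values, design)
        assert 0.25 <= est.median() <= 0.6

    def test_no_residual_variance_gives_zero(self):
        design = make_design(n_salinities=2, n_reps=3)
        values = np.array([[5, 5, 5, 8, 8, 8]])
        est = self._estimate(values, design)
        assert est.iloc[0] == 0.0

    def test_monotone_in_replicate_spread(self):
        design = make_design(n_salinities=2, n_reps=3)
        tight = self._estimate(np.array([[5, 5, 5, 8, 8, 8]]), design)
        wide = self._estimate(np.array([[1, 9, 5, 2, 14, 8]]), design)
        assert wide.iloc[0] >= tight.iloc[0]

    def test_zero_residual_df_errors(self):
        design = make_design(n_salinities=2, n_reps=1)
        with pytest.raises(ValueError, match="common dispersion"):
            self._estimate(np.array([[5, 9]]), design)


def independent_nb_ml(y, cells, offsets, phi):
    """Numeric ML of the NB cell-means model via scipy.stats.nbinom."""

    def negll(beta):
        mu = np.exp(beta[cells] + offsets)
        n = 1.0 / phi
        p = n / (n + mu)
        return -stats.nbinom.logpmf(y, n, p).sum()

    res = optimize.minimize(
        negll,
        x0=np.zeros(cells.max() + 1),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000},
    )
    return res.x


class TestFit:
    def test_saturated_cell_means_identity(self):
        design = make_design(n_strains=2, n_salinities=2, n_reps=3)
        rng = np.random.default_rng(3)
        values = rng.integers(50, 500, size=(4, 12))
        counts = make_counts(values, design)
        lib = pd.Series(np.full(12, 1e4), index=design.sample_ids)
        offsets = offsets_from_library_sizes(lib)
        disp = pd.Series(0.0, index=counts.gene_ids)
        fit = fit_glm(counts, design, offsets, disp)
        cells = design.sample_cells()
        for cell in design.cell_labels:
            cols = cells.index[cells == cell]
            o = offsets[cols].to_numpy()
            expected = np.log2(
                counts.counts[cols].sum(axis=1) / np.exp(o).sum()
            )
            np.testing.assert_allclose(
                fit.coefficients[cell], expected, atol=1e-6
            )

    def test_matches_independent_likelihood_maximisation(self):
        design = make_design(n_strains=1, n_salinities=2, n_reps=3)
        y = np.array([3, 7, 5, 20, 31, 25])
        counts = make_counts(y, design)
        offsets = pd.Series(
            [0.0, 0.1, -0.1, 0.05, 0.0, -0.05], index=design.sample_ids
        )
        phi = 0.3
        fit = fit_glm(
            counts, design, offsets, pd.Series([phi], index=["g0"])
        )
        cells = np.array([0, 0, 0, 1, 1, 1])
        oracle = independent_nb_ml(y, cells, offsets.to_numpy(), phi)
        np.testing.assert_allclose(
            fit.coefficients.iloc[0].to_numpy() * LN2, oracle, atol=1e-4
        )

    def test_offset_doubling_shifts_coefficients(self):
        design = make_design(n_strains=1, n_salinities=2, n_reps=3)
        y = np.array([[12, 15, 9, 30, 25, 27]])
        counts = make_counts(y, design)
        disp = pd.Series(0.1, index=counts.gene_ids)
        o1 = pd.Series(0.0, index=design.sample_ids)
        o2 = o1 + np.log(2.0)
        f1 = fit_glm(counts, design, o1, disp)
        f2 = fit_glm(counts, design, o2, disp)
        np.testing.assert_allclose(
            f2.coefficients.to_numpy(), f1.coefficients.to_numpy() - 1.0,
            atol=1e-6,
        )


class TestContrastTest:
    def test_zero_weight_vector_rejected(self, small_fit):
        w = pd.Series(0.0, index=small_fit.cell_labels)
        with pytest.raises(ValueError, match="zero"):
            single_contrast_test(small_fit, w)

    def test_nonzero_sum_rejected(self, small_fit):
        w = pd.Series(0.0, index=small_fit.cell_labels)
        w.iloc[0] = 1.0
        with pytest.raises(ValueError, match="sum to zero"):
            single_contrast_test(small_fit, w)

    def test_logfc_is_definitional(self, small_fit):
        w = pd.Series(0.0, index=small_fit.cell_labels)
        w.iloc[0], w.iloc[1] = 1.0, -1.0
        res = single_contrast_test(small_fit, w)
        expected = (
            small_fit.coefficients.iloc[:, 0] - small_fit.coefficients.iloc[:, 1]
        )
        np.testing.assert_allclose(res.logfc.iloc[:, 0], expected, atol=1e-12)

    def test_permutation_equivariance(self):
        design = make_design(n_strains=2, n_salinities=2, n_reps=3)
        rng = np.random.default_rng(8)
        values = rng.integers(5, 300, size=(20, 12))
        counts = make_counts(values, design)
        offsets = pd.Series(0.0, index=design.sample_ids)
        disp = pd.Series(0.1, index=counts.gene_ids)
        fit1 = fit_glm(counts, design, offsets, disp)

        perm = rng.permutation(12)
        ids = [design.sample_ids[i] for i in perm]
        counts2 = CountMatrix(counts.counts[ids])
        design2 = design.reorder(ids)
        fit2 = fit_glm(counts2, design2, offsets[ids], disp)
        np.testing.assert_allclose(
            fit1.coefficients.to_numpy(),
            fit2.coefficients[fit1.cell_labels].to_numpy(),
            atol=1e-6,
        )
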