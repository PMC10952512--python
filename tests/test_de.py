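"""Normalization and NB-GLM testing engine: closed forms, limits, calibration."""

import numpy as np
import pandas as pd
import pytest

from transplant_decomp import de
from transplant_decomp.data_io import CountMatrix, SampleDesign

from conftest import make_design, nb_counts


def unit_norm(cm):
    return de.NormFactors.unit(cm.design.samples)


class TestCpm:
    def test_linear_scaling(self, pair1_design, rng):
        cm, _ = nb_counts(rng, 4, pair1_design, mu=10, phi=0)
        cm.library_size[:] = 1e6
        cm.counts.iloc[0, 0] = 10
        cm.counts.iloc[1, 0] = 0
        vals = de.cpm(cm)
        assert vals.iloc[0, 0] == 10.0
        assert vals.iloc[1, 0] == 0.0
        cm.library_size[:] = 2.5e5
        cm.counts.iloc[0, 0] = 5
        assert de.cpm(cm).iloc[0, 0] == 20.0

    def test_effective_library_used_with_norm(self, pair1_design, rng):
        cm, _ = nb_counts(rng, 5, pair1_design, mu=20)
        f = pd.Series(2.0, index=cm.design.samples)
        f /= np.exp(np.mean(np.log(f)))  # geometric mean 1
        norm = de.NormFactors(f)
        pd.testing.assert_frame_equal(de.cpm(cm, norm), de.cpm(cm))


class TestFilter:
    def test_mean_rule_strictly_greater(self, pair1_design):
        # 4 samples, library 1e6: CPM == counts
        design = SampleDesign(pair1_design.table.iloc[:4])
        counts = pd.DataFrame(
            {
                s: c
                for s, c in zip(
                    design.samples,
                    np.array([[0.5e0, 0.5, 2.1, 1.0], [1, 1, 1, 1], [0, 0, 0, 0]]).T
                    * 1,
                )
            },
            index=["g_mean_1.025", "g_mean_1.0", "g_zero"],
        ).astype(int)
        # integer counts: use scaled libraries so CPM hits the intended values
        counts = pd.DataFrame(
            [[5, 5, 21, 10], [10, 10, 10, 10], [0, 0, 0, 0]],
            index=["g_mean_1.025", "g_mean_1.0", "g_zero"],
            columns=design.samples,
        )
        cm = CountMatrix(counts, design, pd.Series(1e7, index=design.samples))
        kept = de.filter_low_expression(cm, threshold=1.0)
        assert kept.gene_ids.tolist() == ["g_mean_1.025"]  # mean 1.025 > 1; 1.0 is not

    def test_retained_count_matches_brute_force_recount(self, pair1_design, rng):
        cm, _ = nb_counts(rng, 3000, pair1_design, mu=rng.uniform(0.1, 60, 3000))
        kept = de.filter_low_expression(cm, 1.0)
        # independent recount: per-gene mean of count/lib*1e6 over samples
        lib = cm.library_size.values
        brute = 0
        for g in range(cm.n_genes):
            if np.mean(cm.counts.values[g] / lib * 1e6) > 1.0:
                brute += 1
        assert kept.n_genes == brute


class TestTmm:
    def test_identical_samples_unit_factors(self, rng):
        design = make_design(reps=2)
        y = rng.poisson(50, size=100)
        counts = pd.DataFrame(
            np.tile(y[:, None], (1, len(design.samples))),
            index=[f"g{i}" for i in range(100)],
            columns=design.samples,
        )
        cm = CountMatrix(counts, design)
        f = de.tmm_factors(cm).tmm_factor
        assert np.allclose(f, 1.0)

    def test_scaled_sample_absorbed_by_m_centering(self, rng):
        """B = 2 x A with equal library-size fields: constant M is absorbed."""
        design = SampleDesign(
            pd.DataFrame(
                {
                    "sample": ["a", "b"],
                    "pair": ["1", "1"],
                    "ecotype": ["montane", "alpine"],
                    "environment": ["montane", "montane"],
                }
            )
        )
        a = np.array([10, 20, 30, 40, 50, 60, 70, 80, 90, 100])
        counts = pd.DataFrame(
            {"a": a, "b": 2 * a}, index=[f"g{i}" for i in range(10)]
        )
        cm = CountMatrix(counts, design, pd.Series(1e6, index=["a", "b"]))
        f = de.tmm_factors(cm).tmm_factor
        # M_g = -1 for every gene: after geometric-mean rescale both factors
        # equal sqrt-balanced values, i.e. the pair is symmetric
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-9)
        assert f["b"] / f["a"] == pytest.approx(2.0, rel=1e-9)

    def test_gene_permutation_invariance(self, pair1_design, rng):
        cm, _ = nb_counts(rng, 400, pair1_design, mu=rng.uniform(5, 100, 400))
        f1 = de.tmm_factors(cm).tmm_factor
        perm = rng.permutation(400)
        cm2 = CountMatrix(
            cm.counts.iloc[perm], cm.design, cm.library_size
        )
        f2 = de.tmm_factors(cm2).tmm_factor
        assert np.allclose(f1.values, f2.values)

    def test_geometric_mean_is_one(self, pair1_design, rng):
        for seed in range(3):
            r = np.random.default_rng(seed)
            cm, _ = nb_counts(r, 300, pair1_design, mu=r.uniform(1, 80, 300), phi=0.3)
            f = de.tmm_factors(cm).tmm_factor
            assert np.exp(np.mean(np.log(f.values))) == pytest.approx(1.0, abs=1e-9)


class TestDispersion:
    def test_recovers_true_common_dispersion(self, pair1_design, rng):
        cm, _ = nb_counts(rng, 2000, pair1_design, mu=50, phi=0.1)
        disp = de.estimate_dispersion(cm, unit_norm(cm))
        assert 0.08 <= disp.common <= 0.12

    def test_poisson_boundary(self, pair1_design, rng):
        cm, _ = nb_counts(rng, 500, pair1_design, mu=50, phi=0)
        disp = de.estimate_dispersion(cm, unit_norm(cm))
        assert disp.common <= 0.01

    def test_infinite_prior_df_collapses_to_common(self, pair1_design, rng):
        cm, _ = nb_counts(rng, 200, pair1_design, mu=30, phi=0.2)
        disp = de.estimate_dispersion(cm, unit_norm(cm), prior_df=1e9)
        assert np.allclose(disp.shrunken.values, disp.common, rtol=1e-4)

    def test_shrunken_between_genewise_and_common(self, pair1_design, rng):
        cm, _ = nb_counts(rng, 300, pair1_design, mu=40, phi=0.15)
        disp = de.estimate_dispersion(cm, unit_norm(cm))
        lo = np.minimum(disp.genewise.values, disp.common)
        hi = np.maximum(disp.genewise.values, disp.common)
        assert ((disp.shrunken.values >= lo - 1e-12) & (disp.shrunken.values <= hi + 1e-12)).all()


class TestNbGlm:
    def test_saturated_mle_equals_group_mean(self):
        design = make_design(reps=5)
        counts = pd.DataFrame(
            np.full((3, 20), 10), index=["g0", "g1", "g2"], columns=design.samples
        )
        cm = CountMatrix(counts, design, pd.Series(1e6, index=design.samples))
        disp = de.DispersionModel(
            0.1, pd.Series(0.1, index=cm.gene_ids), pd.Series(0.1, index=cm.gene_ids), 10
        )
        fit = de.fit_nb_glm(cm, unit_norm(cm), disp, "1")
        assert np.allclose(np.exp(fit.beta), 10 / 1e6, rtol=1e-6)

    def test_offset_contract_under_library_doubling(self, pair1_design, rng):
        cm, _ = nb_counts(rng, 50, pair1_design, mu=30, phi=0.1)
        disp = de.DispersionModel(
            0.1, pd.Series(0.1, index=cm.gene_ids), pd.Series(0.1, index=cm.gene_ids), 10
        )
        fit1 = de.fit_nb_glm(cm, unit_norm(cm), disp, "1")
        cm2 = CountMatrix(cm.counts, cm.design, cm.library_size * 2)
        fit2 = de.fit_nb_glm(cm2, unit_norm(cm2), disp, "1")
        assert np.allclose(fit2.beta, fit1.beta - np.log(2), atol=1e-6)
        assert np.allclose(fit2.fitted_mu(), fit1.fitted_mu(), rtol=1e-6)

    def test_poisson_limit_matches_closed_form_poisson_glm(self, pair1_design, rng):
        """At phi ~ 0 the NB deviance equals an independently coded Poisson GLM's.

        For a saturated one-way layout with offsets, the Poisson MLE has the
        closed form rate = sum(y) / sum(exp(offset)) per group, so the oracle
        needs no iterative fitting at all.
        """
        cm, _ = nb_counts(rng, 40, pair1_design, mu=20, phi=0)
        lib = cm.library_size.values
        tiny = pd.Series(1e-8, index=cm.gene_ids)
        disp = de.DispersionModel(1e-8, tiny, tiny, 10)
        fit = de.fit_nb_glm(cm, unit_norm(cm), disp, "1")

        y = cm.counts.values.astype(float)
        labels = (cm.design.table["ecotype"] + ":" + cm.design.table["environment"]).values
        dev_oracle = np.zeros(cm.n_genes)
        for lab in np.unique(labels):
            cols = labels == lab
            rate = y[:, cols].sum(axis=1) / lib[cols].sum()
            mu = rate[:, None] * lib[None, cols]
            yy = y[:, cols]
            with np.errstate(divide="ignore", invalid="ignore"):
                term = np.where(yy > 0, yy * np.log(yy / mu), 0.0)
            dev_oracle += 2 * (term - (yy - mu)).sum(axis=1)
        assert np.allclose(fit.deviance, dev_oracle, atol=1e-4)


class TestLrt:
    @pytest.fixture()
    def fitted(self, pair1_design, rng):
        cm, _ = nb_counts(rng, 300, pair1_design, mu=40, phi=0.1)
        disp = de.estimate_dispersion(cm, unit_norm(cm))
        return de.fit_nb_glm(cm, unit_norm(cm), disp, "1")

    def test_identical_group_data_gives_zero_stat(self, pair1_design):
        design = pair1_design
        y = np.tile(np.arange(10, 15), (8, 4))[:, : len(design.samples)]
        # force the two montane-environment cells identical per replicate slot
        counts = pd.DataFrame(
            np.tile([[10, 11, 12, 13, 14]], (8, 4)).reshape(8, 20),
            index=[f"g{i}" for i in range(8)],
            columns=design.samples,
        )
        cm = CountMatrix(counts, design, pd.Series(1e6, index=design.samples))
        disp = de.DispersionModel(
            0.1, pd.Series(0.1, index=cm.gene_ids), pd.Series(0.1, index=cm.gene_ids), 10
        )
        fit = de.fit_nb_glm(cm, unit_norm(cm), disp, "1")
        res = de.lrt_contrast(fit, de.ContrastSpec("1", "ecotype_in_env", "montane"))
        assert np.allclose(res["lrt_stat"], 0.0, atol=1e-8)
        assert np.allclose(res["log2fc"], 0.0, atol=1e-8)
        assert np.allclose(res["p"], 1.0)

    def test_null_calibration_chi2(self, pair1_design):
        """Null LRT stats track chi-square(1): P(stat > 3.841) near 0.05."""
        r = np.random.default_rng(7)
        cm, _ = nb_counts(r, 2000, pair1_design, mu=50, phi=0.1)
        disp = de.estimate_dispersion(cm, unit_norm(cm))
        fit = de.fit_nb_glm(cm, unit_norm(cm), disp, "1")
        res = de.lrt_contrast(fit, de.ContrastSpec("1", "ecotype_in_env", "montane"))
        frac = float((res["lrt_stat"] > 3.841).mean())
        assert 0.03 <= frac <= 0.08

    def test_planted_log2fc_recovery(self, pair1_design):
        r = np.random.default_rng(17)
        cm, planted = nb_counts(
            r, 500, pair1_design, mu=50, phi=0.1, log2fc=2.0, n_affected=500
        )
        disp = de.estimate_dispersion(cm, unit_norm(cm))
        fit = de.fit_nb_glm(cm, unit_norm(cm), disp, "1")
        res = de.lrt_contrast(fit, de.ContrastSpec("1", "ecotype_in_env", "montane"))
        assert np.median(np.abs(res["log2fc"] - 2.0)) < 0.3

    def test_stat_invariant_to_gene_and_sample_reordering(self, fitted, pair1_design, rng):
        cm, _ = nb_counts(np.random.default_rng(3), 100, pair1_design, mu=40, phi=0.1)
        disp = de.estimate_dispersion(cm, unit_norm(cm))
        contrast = de.ContrastSpec("1", "ecotype_in_env", "montane")
        res1 = de.lrt_contrast(de.fit_nb_glm(cm, unit_norm(cm), disp, "1"), contrast)

        perm_g = rng.permutation(100)
        cm_g = CountMatrix(cm.counts.iloc[perm_g], cm.design, cm.library_size)
        disp_g = de.DispersionModel(
            disp.common, disp.genewise.iloc[perm_g], disp.shrunken.iloc[perm_g], 10
        )
        res2 = de.lrt_contrast(de.fit_nb_glm(cm_g, unit_norm(cm_g), disp_g, "1"), contrast)
        assert np.allclose(
            res1["lrt_stat"].sort_index(), res2["lrt_stat"].sort_index(), atol=1e-8
        )

        # permute samples within each (ecotype, environment) cell
        t = cm.design.table
        order = np.concatenate(
            [rng.permutation(np.flatnonzero((t["ecotype"] == e) & (t["environment"] == v)))
             for e in ("montane", "alpine") for v in ("montane", "alpine")]
        )
        cm_s = cm.subset_samples([t["sample"].iloc[i] for i in order])
        res3 = de.lrt_contrast(de.fit_nb_glm(cm_s, unit_norm(cm_s), disp, "1"), contrast)
        assert np.allclose(res1["lrt_stat"], res3["lrt_stat"], atol=1e-8)


class TestBh:
    def test_hand_step_up(self):
        assert np.allclose(
            de.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_degenerate_vectors(self):
        assert de.bh_adjust([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]
        assert de.bh_adjust([0.73]).tolist() == [0.73]

    def test_matches_statsmodels_on_random_vectors(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 200))
            _, oracle, _, _ = multipletests(p, method="fdr_bh")
            assert np.allclose(de.bh_adjust(p), oracle, atol=1e-12)

    def test_monotone_and_dominating(self, rng):
        p = rng.uniform(size=500)
        adj = de.bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_out_of_range_fatal(self):
        with pytest.raises(ValueError):
            de.bh_adjust([0.5, 1.5])
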