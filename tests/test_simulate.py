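"""Generator contracts: determinism, conservation, truth passthrough, moments."""

import numpy as np
import pandas as pd
import pytest

from immunokit.simulate import (
    CohortSimConfig,
    TissueSimConfig,
    default_programs,
    gen_adt,
    gen_age_response_cohort,
    gen_aging_series,
    gen_assay,
    gen_expression,
    gen_repertoire,
    gen_spatial_tissue,
)


def tissue_cfg(**kw):
    base = dict(
        n_cells_per_type={"A": 100, "B": 50},
        attraction={("A", "B"): 0.5},
        seed=3,
    )
    base.update(kw)
    return TissueSimConfig(**base)


class TestTissue:
    def test_count_conservation(self):
        m = gen_spatial_tissue(tissue_cfg())
        assert len(m) == 150
        assert (m["cell_type"] == "A").sum() == 100
        assert m["cell_id"].is_unique

    def test_determinism(self):
        a = gen_spatial_tissue(tissue_cfg())
        b = gen_spatial_tissue(tissue_cfg())
        pd.testing.assert_frame_equal(a, b)

    def test_coordinates_inside_domain(self):
        cfg = tissue_cfg(domain_width=500.0, domain_height=400.0, cluster_sd=200.0)
        m = gen_spatial_tissue(cfg)
        assert m["x"].between(0, 500).all()
        assert m["y"].between(0, 400).all()

    @pytest.mark.parametrize(
        "kw",
        [
            dict(domain_width=0.0),
            dict(attraction={("A", "Z"): 0.5}),
            dict(attraction={("A", "B"): 1.5}),
            dict(cluster_sd=0.0),
            dict(n_cells_per_type={"A": 0}),
        ],
    )
    def test_invalid_configs(self, kw):
        with pytest.raises(ValueError):
            gen_spatial_tissue(tissue_cfg(**kw))


class TestAgingSeries:
    def test_single_age(self):
        maps = gen_aging_series(tissue_cfg(), [20.0], {20.0: 0.3})
        assert len(maps) == 1
        assert (maps[0]["age"] == 20.0).all()

    def test_missing_age_raises(self):
        with pytest.raises(ValueError, match="missing"):
            gen_aging_series(tissue_cfg(), [10.0, 20.0], {10.0: 0.3})

    def test_adding_age_preserves_existing(self):
        short = gen_aging_series(tissue_cfg(), [10.0, 20.0], {10.0: 0.5, 20.0: 0.2})
        full = gen_aging_series(
            tissue_cfg(), [10.0, 15.0, 20.0], {10.0: 0.5, 15.0: 0.3, 20.0: 0.2}
        )
        pd.testing.assert_frame_equal(short[0], full[0])
        pd.testing.assert_frame_equal(short[1], full[2])


class TestExpression:
    def test_poisson_limit_variance_equals_mean(self):
        prog = default_programs(2, 20, effect=1.0)  # homogeneous
        adata, _ = gen_expression(
            "types", prog, nb_mean=3.0, n_cells=10_000, seed=0, poisson=True
        )
        X = np.asarray(adata.X)
        ratio = X.var(axis=0) / X.mean(axis=0)
        assert np.all(np.abs(ratio - 1.0) < 0.08)

    def test_negative_binomial_is_overdispersed(self):
        prog = default_programs(2, 20, effect=1.0)
        adata, _ = gen_expression(
            "types", prog, nb_mean=3.0, nb_dispersion=1.0, n_cells=10_000, seed=0
        )
        X = np.asarray(adata.X)
        # var = mu + mu^2/theta = 3 + 9 = 12, ratio 4
        ratio = X.var(axis=0) / X.mean(axis=0)
        assert np.all(ratio > 2.5)

    def test_shape_and_truth_separation(self):
        prog = default_programs(4, 19)
        adata, truth = gen_expression("types", prog, n_cells=200, seed=1)
        assert adata.shape == (200, 19)
        assert len(truth) == 200
        assert "truth_group" not in adata.obs.columns

    def test_regions_mode_has_contiguous_blocks(self):
        prog = default_programs(3, 12)
        adata, truth = gen_expression("regions", prog, n_cells=300, seed=2)
        # region label is a function of x alone: x-sorted labels are sorted
        order = np.argsort(adata.obs["x"].to_numpy())
        codes = pd.Categorical(
            truth.to_numpy()[order], categories=prog.names
        ).codes
        assert np.all(np.diff(codes) >= 0)

    @pytest.mark.parametrize("kw", [dict(nb_mean=0.0), dict(nb_dispersion=-1.0)])
    def test_invalid_params(self, kw):
        with pytest.raises(ValueError):
            gen_expression("types", default_programs(2, 10), **kw)

    def test_unknown_mode(self):
        with pytest.raises(ValueError, match="mode"):
            gen_expression("voxels", default_programs(2, 10))


class TestCohort:
    def test_noise_free_on_curve(self):
        cfg = CohortSimConfig(noise_sd=0.0, seed=0)
        tab = gen_age_response_cohort(cfg)
        a, b, c = cfg.coeffs
        expect = a + b * tab["age"] + c * tab["age"] ** 2
        assert np.allclose(tab["response"], expect)
        assert not tab["clipped"].any()

    def test_row_count_8_ages_4_animals(self):
        tab = gen_age_response_cohort(CohortSimConfig())
        assert len(tab) == 32

    def test_clipping_flagged(self):
        cfg = CohortSimConfig(coeffs=(0.1, 0.0, 0.0), noise_sd=5.0, seed=4)
        tab = gen_age_response_cohort(cfg)
        assert (tab["response"] >= 0).all()
        assert tab["clipped"].any()
        assert (tab.loc[tab["clipped"], "response"] == 0).all()

    def test_needs_three_distinct_ages(self):
        with pytest.raises(ValueError):
            gen_age_response_cohort(CohortSimConfig(ages=[10.0, 20.0]))


class TestRepertoire:
    def test_uniform_equal_sizes(self):
        table, truth = gen_repertoire(80, "uniform", {"n_clones": 8}, seed=0)
        sizes = truth.value_counts()
        assert (sizes == 10).all()

    def test_determinism(self):
        a, _ = gen_repertoire(100, "powerlaw", {"exponent": 1.5}, seed=5)
        b, _ = gen_repertoire(100, "powerlaw", {"exponent": 1.5}, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_distribution(self):
        with pytest.raises(ValueError, match="distribution"):
            gen_repertoire(10, "zipfish", {})

    def test_powerlaw_exponent_decreases_entropy(self):
        def mean_h(s_exp):
            hs = []
            for seed in range(30):
                _, truth = gen_repertoire(
                    300, "powerlaw", {"exponent": s_exp, "n_clones": 20, "exact": 1},
                    seed=seed,
                )
                p = truth.value_counts(normalize=True).to_numpy()
                hs.append(-(p * np.log(p)).sum())
            return np.mean(hs)

        hs = [mean_h(s) for s in (0.5, 1.5, 2.5)]
        assert hs[0] > hs[1] > hs[2]


class TestADT:
    def test_all_negative_when_pos_fraction_zero(self):
        _, truth = gen_adt(200, pos_fraction=0.0, seed=0)
        assert not truth.any()

    def test_reproducible(self):
        a, ta = gen_adt(100, seed=9)
        b, tb = gen_adt(100, seed=9)
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_series_equal(ta, tb)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            gen_adt(10, pos_fraction=1.2)
        with pytest.raises(ValueError):
            gen_adt(10, pos_logmean=0.0, neg_logmean=1.0)


class TestAssay:
    def test_pk_noise_free_auc_near_closed_form(self):
        times = np.linspace(0, 48, 400)
        tab = gen_assay("pk", {"times": times, "c0": 100.0, "k": 0.1})
        from immunokit.assays import TimeSeries, auc_trapezoid

        auc = auc_trapezoid(TimeSeries.from_dataframe(tab), 48.0)
        exact = 100.0 / 0.1 * (1 - np.exp(-0.1 * 48))
        # trapezoid error bound: (b-a) h^2 max|f''| / 12
        h = times[1] - times[0]
        bound = 48 * h**2 * (100.0 * 0.1**2) / 12
        assert abs(auc - exact) <= bound

    def test_qpcr_noise_free_neg_delta_ct(self):
        tab = gen_assay("qpcr", {"n_samples": 2, "delta_ct": 5.0, "noise_sd": 0.0})
        from immunokit.assays import QpcrRecord, trec_neg_delta_ct

        for sid, g in tab.groupby("sample_id"):
            rec = QpcrRecord(
                sample_id=str(sid),
                ct_trec=g.loc[g["target"] == "TREC", "ct"].tolist(),
                ct_tcra=g.loc[g["target"] == "TCRA", "ct"].tolist(),
            )
            assert trec_neg_delta_ct(rec) == pytest.approx(-5.0)

    def test_pk_never_negative(self):
        tab = gen_assay("pk", {"times": [0, 10, 20], "noise_cv": 2.0}, seed=3)
        assert (tab["value"] >= 0).all()

    def test_empty_time_grid(self):
        with pytest.raises(ValueError):
            gen_assay("pk", {"times": []})
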