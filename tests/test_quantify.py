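"""Bacterial load summaries, prognosis table, co-localization."""

import numpy as np
import pandas as pd
import pytest

import microspot as ms


class TestPerSpotLoad:
    def test_cpm_definition(self):
        # 5 reads of one species over 1e6 total reads -> 5.0 CPM
        counts = pd.DataFrame({"s": [5, 0]},
                              index=pd.Index(["b1", "b2"], name="barcode"))
        totals = pd.Series([1_000_000, 1_000_000], index=counts.index)
        cpm = ms.counts_to_cpm(counts, totals)
        assert cpm.loc["b1", "s"] == 5.0
        assert cpm.loc["b2", "s"] == 0.0

    def test_equals_brute_force_row_sum(self, worked):
        fixture, _ = worked
        retained, _ = ms.decontaminate(fixture)
        loads = ms.per_spot_load(fixture, retained)
        cpm = retained.cpm(fixture.total_reads)
        for barcode in fixture.barcodes[:10]:
            assert loads[barcode] == pytest.approx(
                sum(cpm.loc[barcode]), rel=1e-12
            )

    def test_zero_reads_zero_load(self, worked):
        fixture, _ = worked
        loads = ms.per_spot_load(fixture)
        zero_rows = fixture.species_single.counts.sum(axis=1) == 0
        assert (loads[zero_rows] == 0).all()


class TestGroupCompare:
    def test_exchangeable_groups_maximal_p(self):
        loads = pd.Series(
            [1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
            index=[f"b{i}" for i in range(6)],
        )
        groups = pd.Series(["g1"] * 3 + ["g2"] * 3, index=loads.index)
        summary, pairwise = ms.group_compare(loads, groups)
        assert summary.loc["g1", "mean_cpm"] == summary.loc["g2", "mean_cpm"]
        assert pairwise.loc[0, "p"] == 1.0

    def test_complete_separation_exact_p(self):
        loads = pd.Series([0.0, 0, 0, 10, 10, 10],
                          index=[f"b{i}" for i in range(6)])
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=loads.index)
        summary, pairwise = ms.group_compare(loads, groups)
        assert summary.loc["a", "mean_cpm"] == 0
        assert summary.loc["b", "mean_cpm"] == 10
        assert pairwise.loc[0, "p"] == pytest.approx(0.1)

    def test_sem_missing_below_two_spots(self):
        loads = pd.Series([1.0, 2.0, 5.0], index=["b1", "b2", "b3"])
        groups = pd.Series(["g1", "g1", "g2"], index=loads.index)
        summary, _ = ms.group_compare(loads, groups)
        assert summary.loc["g1", "sem_cpm"] == pytest.approx(
            np.std([1.0, 2.0], ddof=1) / np.sqrt(2)
        )
        assert np.isnan(summary.loc["g2", "sem_cpm"])

    def test_permutation_symmetry(self):
        rng = np.random.default_rng(3)
        loads = pd.Series(rng.gamma(2, 5, size=60),
                          index=[f"b{i}" for i in range(60)])
        groups = pd.Series(["x"] * 20 + ["y"] * 20 + ["z"] * 20,
                           index=loads.index)
        swapped = groups.map({"x": "y", "y": "x", "z": "z"})
        s1, p1 = ms.group_compare(loads, groups)
        s2, p2 = ms.group_compare(loads, swapped)
        assert s1.loc["x", "mean_cpm"] == s2.loc["y", "mean_cpm"]
        pair1 = {frozenset((r.group1, r.group2)): r.p
                 for r in p1.itertuples()}
        pair2 = {frozenset((r.group1, r.group2)): r.p
                 for r in p2.itertuples()}
        for key in pair1:
            mapped = frozenset({"x": "y", "y": "x", "z": "z"}[g]
                               for g in key)
            assert pair1[key] == pytest.approx(pair2[mapped])

    def test_planted_group_ordering_recovered(self, planted_analysis):
        dataset, retained, _, _ = planted_analysis
        loads = ms.per_spot_load(dataset, retained)
        summary, _ = ms.group_compare(loads, dataset.obs["group"])
        assert (summary.loc["CD_inflamed", "mean_cpm"]
                > summary.loc["CD_noninflamed", "mean_cpm"]
                > summary.loc["control", "mean_cpm"])

    def test_planted_area_effect(self, planted_analysis):
        dataset, retained, _, _ = planted_analysis
        loads = ms.per_spot_load(dataset, retained)
        summary, _ = ms.area_compare(loads, dataset.obs["area_label"])
        assert summary["mean_cpm"].idxmax() == "M cell-rich"

    def test_single_group_rejected(self):
        loads = pd.Series([1.0, 2.0], index=["b1", "b2"])
        groups = pd.Series(["only", "only"], index=loads.index)
        with pytest.raises(ms.ParameterError):
            ms.group_compare(loads, groups)


class TestPrognosis:
    def test_single_patient_not_computable(self):
        obs = pd.DataFrame(
            {
                "patient_id": ["p1", "p1"],
                "group": ["CD_inflamed"] * 2,
                "time_to_relapse_months": [12.0, 12.0],
                "rutgeerts_score": [3, 3],
            },
            index=["b1", "b2"],
        )
        loads = pd.Series([1.0, 3.0], index=obs.index)
        table, corr = ms.patient_prognosis_table(loads, obs)
        assert len(table) == 1
        assert corr["spearman_rho"].isna().all()
        assert (corr["n"] == 1).all()

    def test_antimonotone_relapse_rho_minus_one(self):
        obs = pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(5)],
                "group": ["CD_inflamed"] * 5,
                "time_to_relapse_months": [50.0, 40, 30, 20, 10],
                "rutgeerts_score": [0, 1, 2, 3, 4],
            },
            index=[f"b{i}" for i in range(5)],
        )
        loads = pd.Series([1.0, 2, 3, 4, 5], index=obs.index)
        table, corr = ms.patient_prognosis_table(loads, obs)
        corr = corr.set_index("against")
        assert corr.loc["time_to_relapse_months",
                        "spearman_rho"] == pytest.approx(-1.0)
        assert corr.loc["rutgeerts_score",
                        "spearman_rho"] == pytest.approx(1.0)

    def test_means_equal_brute_force(self, planted_analysis):
        dataset, retained, _, _ = planted_analysis
        loads = ms.per_spot_load(dataset, retained)
        table, _ = ms.patient_prognosis_table(loads, dataset.obs)
        for patient in table.index:
            spots = dataset.obs.index[dataset.obs["patient_id"] == patient]
            assert table.loc[patient, "mean_cpm"] == pytest.approx(
                loads[spots].mean()
            )


class TestColocalization:
    def test_two_by_two_identity(self):
        idx = pd.Index(["b1", "b2"], name="barcode")
        counts = pd.DataFrame({"s1": [1, 0], "s2": [0, 1]}, index=idx)
        frac = pd.DataFrame({"ct1": [1.0, 0.0], "ct2": [0.0, 1.0]},
                            index=idx)
        host = _tiny_host(idx)
        ds = ms.SpatialDataset(host, ms.SpeciesCounts(counts, "single"),
                               None, frac,
                               pd.Series({"s1": 100, "s2": 100}))
        coloc = ms.colocalization(ds)
        np.testing.assert_allclose(coloc.weights.to_numpy(), np.eye(2))
        np.testing.assert_allclose(coloc.probabilities.to_numpy(),
                                   np.eye(2))

    def test_concentrated_fractions(self):
        idx = pd.Index(["b1", "b2"], name="barcode")
        counts = pd.DataFrame({"s1": [3, 4]}, index=idx)
        frac = pd.DataFrame({"ct1": [1.0, 1.0], "ct2": [0.0, 0.0]},
                            index=idx)
        ds = ms.SpatialDataset(_tiny_host(idx),
                               ms.SpeciesCounts(counts, "single"),
                               None, frac, pd.Series({"s1": 100}))
        coloc = ms.colocalization(ds)
        assert coloc.probabilities.loc["s1", "ct1"] == 1.0

    def test_conservation_exact(self, worked):
        fixture, _ = worked
        coloc = ms.colocalization(fixture)
        np.testing.assert_allclose(
            coloc.weights.sum(axis=1).to_numpy(),
            fixture.species_single.total_per_species().to_numpy(
                dtype=float),
            rtol=1e-12,
        )

    def test_zero_read_species_row_missing(self):
        idx = pd.Index(["b1", "b2", "b3"], name="barcode")
        counts = pd.DataFrame({"s1": [1, 2, 0], "s_empty": [0, 0, 0]},
                              index=idx)
        frac = pd.DataFrame({"ct1": [0.5] * 3, "ct2": [0.5] * 3}, index=idx)
        ds = ms.SpatialDataset(_tiny_host(idx),
                               ms.SpeciesCounts(counts, "single"),
                               None, frac,
                               pd.Series({"s1": 9, "s_empty": 9}))
        coloc = ms.colocalization(ds)
        assert coloc.probabilities.loc["s_empty"].isna().all()
        assert coloc.probabilities.loc["s1"].sum() == pytest.approx(1.0)

    def test_m_cell_enrichment_for_exposed_species(self, planted_analysis):
        dataset, retained, _, truth = planted_analysis
        coloc = ms.colocalization(dataset, retained)
        # bacterial exposure is boosted in the planted M-cell stratum, so
        # the M-cell column outweighs its Dirichlet share (1/8) on average
        assert coloc.probabilities["M_cell"].mean() > 1 / 8


def _tiny_host(index):
    import anndata as ad
    from scipy import sparse

    n = len(index)
    obs = pd.DataFrame(
        {
            "sample_id": "S01",
            "patient_id": "P01",
            "group": pd.Categorical(["CD_inflamed"] * n,
                                    categories=list(ms.GROUPS)),
            "x": range(n),
            "y": 0,
            "total_sequencing_reads": 1000,
            "mito_fraction": 0.05,
        },
        index=index,
    )
    var = pd.DataFrame({"mito": [False]}, index=pd.Index(["G1"], name="gene"))
    return ad.AnnData(X=sparse.csr_matrix(np.ones((n, 1))), obs=obs, var=var)
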