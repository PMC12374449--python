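"""Presence-expression correlations and the correlation-matrix PCA."""

import numpy as np
import pandas as pd
import pytest

import microspot as ms


def _frames(expr_arr, presence_arr, genes=None, species=None):
    n = expr_arr.shape[0]
    idx = pd.Index([f"b{i}" for i in range(n)], name="barcode")
    expr = pd.DataFrame(
        expr_arr, index=idx,
        columns=genes or [f"g{j}" for j in range(expr_arr.shape[1])],
    )
    counts = pd.DataFrame(
        presence_arr, index=idx,
        columns=species or [f"s{j}" for j in range(presence_arr.shape[1])],
    )
    return expr, counts


class TestCorrelation:
    def test_hand_example_perfect_correlation(self):
        expr, counts = _frames(
            np.array([[2.0], [2.0], [0.0], [0.0]]),
            np.array([[1], [1], [0], [0]]),
        )
        corr = ms.presence_expression_correlation(expr, counts)
        assert corr.r.iloc[0, 0] == pytest.approx(1.0)

    def test_sign_check_expressed_only_in_exposed(self):
        rng = np.random.default_rng(0)
        presence = (rng.uniform(size=(50, 1)) < 0.5).astype(int)
        expr_col = presence[:, 0] * rng.uniform(1, 2, size=50)
        expr, counts = _frames(expr_col[:, None], presence)
        corr = ms.presence_expression_correlation(expr, counts)
        assert corr.r.iloc[0, 0] > 0

    def test_constant_gene_masked(self):
        expr, counts = _frames(
            np.column_stack([np.ones(6), np.arange(6, dtype=float)]),
            np.array([[1], [0], [1], [0], [1], [0]]),
        )
        corr = ms.presence_expression_correlation(expr, counts)
        assert corr.mask.iloc[0, 0]
        assert np.isnan(corr.r.iloc[0, 0])
        assert not corr.mask.iloc[0, 1]

    def test_constant_presence_masked(self):
        expr, counts = _frames(
            np.arange(8, dtype=float)[:, None], np.ones((8, 1), dtype=int)
        )
        corr = ms.presence_expression_correlation(expr, counts)
        assert corr.mask.iloc[0, 0]

    def test_too_few_spots_rejected(self):
        expr, counts = _frames(np.ones((2, 1)), np.ones((2, 1), dtype=int))
        with pytest.raises(ms.ParameterError):
            ms.presence_expression_correlation(expr, counts)

    def test_matches_numpy_oracle(self):
        rng = np.random.default_rng(1)
        expr_arr = rng.normal(size=(10, 4))
        presence_arr = (rng.uniform(size=(10, 3)) < 0.5).astype(int)
        presence_arr[:, 2] = [1, 0] * 5  # guarantee variation
        expr, counts = _frames(expr_arr, presence_arr)
        corr = ms.presence_expression_correlation(expr, counts)
        for si in range(3):
            for gi in range(4):
                ref = np.corrcoef(presence_arr[:, si] >= 1,
                                  expr_arr[:, gi])[0, 1]
                assert corr.r.iloc[si, gi] == pytest.approx(ref, abs=1e-12)


def _toy_corr(r_arr):
    r = pd.DataFrame(
        r_arr,
        index=pd.Index([f"s{i}" for i in range(r_arr.shape[0])],
                       name="species"),
        columns=[f"g{j}" for j in range(r_arr.shape[1])],
    )
    mask = pd.DataFrame(False, index=r.index, columns=r.columns)
    return ms.CorrelationMatrix(r=r, mask=mask)


class TestPCA:
    def test_duplicate_species_rows_identical_scores(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(4, 6)) * 0.3
        arr = np.vstack([base, base[1]])
        pca = ms.pca_on_correlations(_toy_corr(arr), n_components=3)
        np.testing.assert_allclose(
            pca.scores.iloc[1].to_numpy(), pca.scores.iloc[4].to_numpy(),
            atol=1e-10,
        )

    def test_rank_one_matrix_single_component(self):
        u = np.array([1.0, -1.0, 2.0, 0.5])
        v = np.array([0.3, -0.2, 0.4, 0.1, 0.0])
        pca = ms.pca_on_correlations(_toy_corr(np.outer(u, v)),
                                     n_components=3)
        assert pca.explained_variance_ratio.iloc[0] == pytest.approx(
            1.0, abs=1e-12
        )

    def test_reconstruction_at_full_rank(self):
        rng = np.random.default_rng(3)
        arr = np.clip(rng.normal(scale=0.3, size=(5, 7)), -1, 1)
        pca = ms.pca_on_correlations(_toy_corr(arr), n_components=4)
        centered = arr - arr.mean(axis=0, keepdims=True)
        approx = pca.scores.to_numpy() @ pca.loadings.to_numpy().T
        np.testing.assert_allclose(approx, centered, atol=1e-8)

    def test_deterministic_sign_and_repeatability(self):
        rng = np.random.default_rng(4)
        arr = np.clip(rng.normal(scale=0.3, size=(6, 8)), -1, 1)
        p1 = ms.pca_on_correlations(_toy_corr(arr))
        p2 = ms.pca_on_correlations(_toy_corr(arr))
        pd.testing.assert_frame_equal(p1.scores, p2.scores)
        for comp in p1.loadings.columns:
            lead = p1.loadings[comp].abs().idxmax()
            assert p1.loadings.loc[lead, comp] > 0

    def test_component_clipping_warns_not_raises(self):
        arr = np.clip(np.random.default_rng(5).normal(size=(3, 4)), -1, 1)
        pca = ms.pca_on_correlations(_toy_corr(arr), n_components=10)
        assert pca.scores.shape[1] == 2  # min(n_species - 1, n_genes)

    def test_masked_entries_imputed_as_zero(self):
        arr = np.array([[0.5, 0.1], [-0.5, -0.1], [0.2, 0.0]])
        corr = _toy_corr(arr)
        corr.mask.iloc[0, 0] = True
        corr.r.iloc[0, 0] = np.nan
        pca = ms.pca_on_correlations(corr, n_components=1)
        assert np.isfinite(pca.scores.to_numpy()).all()

    def test_top_genes_table_shape(self):
        rng = np.random.default_rng(6)
        arr = np.clip(rng.normal(scale=0.3, size=(6, 30)), -1, 1)
        pca = ms.pca_on_correlations(_toy_corr(arr), n_components=2,
                                     top_k=20)
        assert (pca.top_genes.groupby("component").size() == 20).all()
        pc1 = pca.top_genes[pca.top_genes["component"] == "PC1"]
        mags = pc1["loading"].abs().to_numpy()
        assert (np.diff(mags) <= 1e-12).all()  # sorted by |contribution|


class TestSeparation:
    @staticmethod
    def _planted_pca(n_ben=5, n_pat=4):
        rng = np.random.default_rng(7)
        genes = [f"g{j}" for j in range(12)]
        rows, labels = [], {}
        for i in range(n_ben):
            row = rng.normal(scale=0.05, size=12)
            row[:4] += 0.6  # beneficial program on genes 0-3
            rows.append(row)
            labels[f"b{i}"] = "beneficial"
        for i in range(n_pat):
            row = rng.normal(scale=0.05, size=12)
            row[4:8] += 0.6  # pathogenic program on genes 4-7
            rows.append(row)
            labels[f"p{i}"] = "pathogenic"
        r = pd.DataFrame(
            np.clip(np.array(rows), -1, 1),
            index=pd.Index(list(labels), name="species"), columns=genes,
        )
        mask = pd.DataFrame(False, index=r.index, columns=r.columns)
        pca = ms.pca_on_correlations(ms.CorrelationMatrix(r, mask),
                                     n_components=3)
        return pca, pd.Series(labels)

    def test_perfect_separation_exact_minimal_p(self):
        from math import comb

        pca, labels = self._planted_pca()
        report = ms.component_separation_report(pca, labels)
        assert report["p"].min() == pytest.approx(2 / comb(9, 4))
        assert report.loc[report["p"].idxmin(), "best"]

    def test_separating_component_among_first_two(self):
        pca, labels = self._planted_pca()
        report = ms.component_separation_report(pca, labels)
        assert report["p"].idxmin() in ("PC1", "PC2")

    def test_single_label_not_computable(self):
        pca, labels = self._planted_pca()
        report = ms.component_separation_report(
            pca, pd.Series("beneficial", index=labels.index)
        )
        assert report.empty

    def test_null_labels_rarely_flagged(self):
        rng = np.random.default_rng(8)
        flagged = 0
        reps = 40
        for _ in range(reps):
            arr = np.clip(rng.normal(scale=0.2, size=(10, 8)), -1, 1)
            r = pd.DataFrame(
                arr, index=pd.Index([f"s{i}" for i in range(10)],
                                    name="species"),
                columns=[f"g{j}" for j in range(8)],
            )
            mask = pd.DataFrame(False, index=r.index, columns=r.columns)
            pca = ms.pca_on_correlations(ms.CorrelationMatrix(r, mask),
                                         n_components=2)
            labels = pd.Series(
                rng.permutation(["beneficial"] * 5 + ["pathogenic"] * 5),
                index=r.index,
            )
            report = ms.component_separation_report(pca, labels)
            flagged += int((report["p"] < 0.05).any())
        assert flagged / reps <= 0.25  # ~2 tests per rep at alpha 0.05


def test_end_to_end_planted_programs_separate(planted_analysis):
    """Presence-correlation PCA separates species with planted expression
    programs from the rest of the screen's machinery."""
    dataset, retained, _, _ = planted_analysis
    cd = dataset.subset(dataset.cd_mask())
    adata = ms.normalize_expression(cd)
    expr = ms.expression_frame(adata)
    corr = ms.presence_expression_correlation(
        expr, retained.counts.loc[expr.index]
    )
    pca = ms.pca_on_correlations(corr, n_components=3)
    # the two species with planted programs sit far from the null species
    scores = pca.scores[["PC1", "PC2"]]
    planted = scores.loc[["sp_001", "sp_002"]].abs().max(axis=1)
    others = scores.drop(index=["sp_001", "sp_002"]).abs().max(axis=1)
    assert planted.min() > others.max()
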