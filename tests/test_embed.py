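"""Normalization, TF-IDF/LSI, PCA, gene activity, the joint SNN graph and
Leiden clustering."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from fmm import embed, io as fio
from tests.conftest import make_count_matrix, make_gene_model


class TestNormalizeRna:
    def test_log_cp10k_closed_form(self):
        cm = make_count_matrix([[1], [99]])
        out = embed.normalize_rna(cm)
        assert np.isclose(out.values[0, 0], np.log1p(1e4 * 1 / 100))
        assert np.isclose(out.values[0, 0], 4.61512, atol=1e-4)

    def test_zero_count_stays_zero(self):
        cm = make_count_matrix([[0], [10]])
        assert embed.normalize_rna(cm).values[0, 0] == 0.0

    def test_depth_invariance(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(2.0, size=(20, 6))
        X[:, 0] += 1  # avoid zero-total cells
        cm = make_count_matrix(X)
        doubled = X.copy()
        doubled[:, 2] *= 2
        out1 = embed.normalize_rna(cm).values[:, 2]
        out2 = embed.normalize_rna(make_count_matrix(doubled)).values[:, 2]
        assert np.allclose(out1, out2)

    def test_zero_total_cell_errors(self):
        with pytest.raises(ValueError):
            embed.normalize_rna(make_count_matrix([[0, 1], [0, 1]]))


class TestTfidf:
    def test_closed_form_single_peak(self):
        cm = make_count_matrix([[1, 1]], modality=fio.ATAC_PEAKS)
        out = embed.run_tfidf(cm)
        assert np.allclose(out.values, np.log1p(1e4))
        assert np.isclose(out.values[0, 0], 9.2104, atol=1e-4)

    def test_undetected_peak_row_is_zero(self):
        cm = make_count_matrix([[0, 0], [2, 3]], modality=fio.ATAC_PEAKS)
        assert np.all(embed.run_tfidf(cm).values[0] == 0)

    def test_matches_dense_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.poisson(1.0, size=(20, 10))
        X[0, :] += 1  # no zero-total cell
        cm = make_count_matrix(X, modality=fio.ATAC_PEAKS)
        ours = embed.run_tfidf(cm).values
        tf = X / X.sum(axis=0, keepdims=True)
        det = (X > 0).sum(axis=1)
        idf = np.where(det > 0, X.shape[1] / np.maximum(det, 1), 0.0)
        expected = np.log1p(1e4 * tf * idf[:, None])
        assert np.max(np.abs(ours - expected)) < 1e-12

    def test_depth_invariance(self):
        rng = np.random.default_rng(2)
        X = rng.poisson(1.5, size=(15, 5)) + (np.arange(15) == 0)[:, None]
        cm = make_count_matrix(X, modality=fio.ATAC_PEAKS)
        scaled = X.copy()
        scaled[:, 3] *= 5
        v1 = embed.run_tfidf(cm).values[:, 3]
        v2 = embed.run_tfidf(make_count_matrix(scaled, modality=fio.ATAC_PEAKS)).values[:, 3]
        assert np.allclose(v1, v2)


class TestDecompositions:
    def test_lsi_rank_one_matrix(self):
        u = np.arange(1, 9, dtype=float)
        v = np.arange(1, 7, dtype=float)
        X = np.outer(u, v)
        nm = embed.NormalizedMatrix(X, [f"p{i}" for i in range(8)], [f"c{i}" for i in range(6)], embed.TFIDF)
        emb = embed.run_lsi(nm, n_components=4)
        assert np.all(emb.singular_values[1:] < 1e-8)

    def test_lsi_deterministic_and_drops_first(self):
        rng = np.random.default_rng(3)
        X = rng.random((30, 12))
        nm = embed.NormalizedMatrix(X, [f"p{i}" for i in range(30)], [f"c{i}" for i in range(12)], embed.TFIDF)
        e1 = embed.run_lsi(nm, 5)
        e2 = embed.run_lsi(nm, 5)
        assert np.array_equal(e1.coords, e2.coords)
        assert e1.dims_used == (2, 3, 4, 5)
        assert e1.coords.shape[1] == 4

    def test_lsi_component_one_tracks_depth(self, scenario):
        """On simulated ATAC data the dropped first LSI component is a depth
        proxy: |r| > 0.9 with the per-cell detected-peak count, the sequencing
        depth measure a near-binary assay exposes."""
        _, ds, _ = scenario
        tfidf = embed.run_tfidf(ds.atac)
        emb = embed.run_lsi(tfidf, 25)
        depth = np.log1p(np.asarray((ds.atac.values > 0).sum(axis=0)).ravel())
        r = np.corrcoef(emb.dropped_first, depth)[0, 1]
        assert abs(r) > 0.9

    def test_pca_planar_data(self):
        rng = np.random.default_rng(4)
        basis = rng.random((30, 2))
        scores = rng.random((2, 40))
        X = basis @ scores  # rank 2
        nm = embed.NormalizedMatrix(X, [f"g{i}" for i in range(30)], [f"c{i}" for i in range(40)], embed.LOG_CP10K)
        emb = embed.run_pca(nm, 10, scale=False)
        assert np.all(emb.coords[:, 2:].var(axis=0) < 1e-10)

    def test_pca_separates_simulated_types(self, scenario):
        """PC1 separates two simulated cell types with Cohen's d > 2."""
        _, ds, truth = scenario
        mask = truth.labels["cell_type"].isin(["ILC2", "Tcell"]).to_numpy()
        sub = ds.subset_cells(mask)
        norm = embed.normalize_rna(sub.rna)
        emb = embed.run_pca(norm, 10)
        lab = truth.labels.loc[mask, "cell_type"].to_numpy()
        a = emb.coords[lab == "ILC2", 0]
        b = emb.coords[lab == "Tcell", 0]
        pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
        assert abs(a.mean() - b.mean()) / pooled > 2

    def test_too_many_components_errors(self):
        nm = embed.NormalizedMatrix(np.ones((3, 4)), list("abc"), list("wxyz"), embed.LOG_CP10K)
        with pytest.raises(ValueError):
            embed.run_lsi(nm, 5)
        with pytest.raises(ValueError):
            embed.run_pca(nm, 5)


class TestGeneActivity:
    def _frags(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "barcode", "count"])

    def test_upstream_window_arithmetic(self):
        genes = make_gene_model([("g", "chr1", 10_000, 12_000, "+")])
        frags = self._frags([("chr1", 8_500, 8_600, "c0", 1)])
        ga = embed.gene_activity(frags, genes, ["c0"])
        assert ga.values[0, 0] == 1

    def test_upstream_boundary_exclusive(self):
        genes = make_gene_model([("g", "chr1", 10_000, 12_000, "+")])
        frags = self._frags([("chr1", 7_900, 7_950, "c0", 1)])
        ga = embed.gene_activity(frags, genes, ["c0"])
        assert ga.values[0, 0] == 0

    def test_matches_brute_force_interval_oracle(self):
        rng = np.random.default_rng(5)
        genes = make_gene_model(
            [(f"g{i}", "chr1", int(s), int(s) + 3_000, "+" if i % 2 else "-")
             for i, s in enumerate(rng.integers(0, 50_000, 8))]
        )
        rows = []
        for i in range(200):
            s = int(rng.integers(0, 55_000))
            rows.append(("chr1", s, s + int(rng.integers(50, 300)), f"c{rng.integers(3)}", int(rng.integers(1, 4))))
        frags = self._frags(rows)
        barcodes = ["c0", "c1", "c2"]
        ga = embed.gene_activity(frags, genes, barcodes)
        gv = fio.validate_gene_model(genes)
        expected = np.zeros((len(genes), 3), dtype=int)
        for gidx, g in gv.iterrows():
            ws = g.start - 2000 if g.strand == "+" else g.start
            we = g.end if g.strand == "+" else g.end + 2000
            ws = max(ws, 0)
            for r in frags.itertuples():
                if r.start < we and r.end > ws:
                    expected[gidx, barcodes.index(r.barcode)] += r.count
        assert np.array_equal(np.asarray(ga.values.todense()), expected)


class TestGraphAndClustering:
    def _emb(self, coords, modality="RNA"):
        return embed.Embedding(np.asarray(coords, float), tuple(range(1, np.asarray(coords).shape[1] + 1)), modality)

    def test_identical_modalities_equal_single_modality_graph(self):
        rng = np.random.default_rng(6)
        coords = rng.random((40, 5))
        e = self._emb(coords)
        joint = embed.joint_neighbor_graph(e, self._emb(coords, "ATAC"), [f"c{i}" for i in range(40)], k=5)
        single = embed._snn(coords, 5)
        assert np.allclose(joint.adjacency.toarray(), ((single + single.T) / 2).toarray())

    def test_constant_modality_keeps_edges_defined(self):
        rng = np.random.default_rng(7)
        coords = rng.random((30, 4))
        const = np.ones((30, 4))
        joint = embed.joint_neighbor_graph(
            self._emb(coords), self._emb(const, "ATAC"), [f"c{i}" for i in range(30)], k=5
        )
        A = joint.adjacency.toarray()
        assert np.isfinite(A).all()
        # the degenerate modality contributes a complete graph at weight 0.5
        off_diag = A[~np.eye(30, dtype=bool)]
        assert (off_diag >= 0.5 - 1e-12).all()

    def test_knn_sets_match_brute_force(self):
        rng = np.random.default_rng(8)
        coords = rng.random((50, 3))
        from sklearn.neighbors import NearestNeighbors

        idx = NearestNeighbors(n_neighbors=6).fit(coords).kneighbors(coords)[1]
        D = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
        brute = np.argsort(D, axis=1, kind="stable")[:, :6]
        for i in range(50):
            assert set(idx[i]) == set(brute[i])

    def test_two_cliques_yield_two_clusters(self):
        n = 20
        A = np.zeros((2 * n, 2 * n))
        A[:n, :n] = 1
        A[n:, n:] = 1
        np.fill_diagonal(A, 0)
        g = embed.NeighborGraph(sp.csr_matrix(A), np.array([f"c{i}" for i in range(2 * n)], dtype=object))
        cl = embed.cluster_graph(g, resolution=0.1, seed=0)
        assert len(np.unique(cl.labels)) == 2
        assert len(set(cl.labels[:n])) == 1 and len(set(cl.labels[n:])) == 1

    def test_clustering_deterministic_under_seed(self):
        rng = np.random.default_rng(9)
        coords = rng.random((60, 4))
        e = self._emb(coords)
        g = embed.joint_neighbor_graph(e, self._emb(coords + 0.01, "ATAC"), [f"c{i}" for i in range(60)], k=6)
        l1 = embed.cluster_graph(g, 0.5, seed=42).labels
        l2 = embed.cluster_graph(g, 0.5, seed=42).labels
        assert np.array_equal(l1, l2)

    def test_k_too_large_errors(self):
        with pytest.raises(ValueError):
            embed._snn(np.random.default_rng(0).random((5, 2)), 5)
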