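"""Gene-peak link calling with the matched-background null, per-condition
regulomes, peak dedup, exclusive intersections, and induced-peak logic."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from fmm import links as lk
from fmm.dataset import DISEASE_SS, FATE_NAIVE
from fmm.scenarios import two_state_link_config
from fmm.simulate import simulate_multiome


@pytest.fixture(scope="module")
def planted_run():
    cfg = two_state_link_config(beta=1.0, cells_per_state=500, seed=6)
    ds, truth = simulate_multiome(cfg)
    active = ((ds.obs.fate_map == FATE_NAIVE) & (ds.obs.disease == DISEASE_SS)).to_numpy()
    return cfg, ds, truth, active


class TestComputeLinks:
    def test_planted_pair_retained_with_strong_score(self, planted_run):
        cfg, ds, truth, active = planted_run
        data = lk.LinkData.from_dataset(ds.subset_cells(active))
        out = lk.compute_links(data, seed=0)
        rec = out[(out.gene == "glink") & (out.peak == truth.links.peak[0])]
        assert len(rec) == 1
        assert rec.score.iloc[0] > 0.3 and rec.z.iloc[0] > 3

    def test_min_cells_gate(self, planted_run):
        """A peak detected in exactly one cell is never tested."""
        cfg, ds, truth, active = planted_run
        sub = ds.subset_cells(active)
        data = lk.LinkData.from_dataset(sub)
        # force the planted peak to a single detected cell
        pidx = list(sub.atac.feature_ids).index(truth.links.peak[0])
        dense = np.asarray(sub.atac.values.todense())
        dense[pidx] = 0
        dense[pidx, 0] = 5
        import scipy.sparse as sp
        from fmm import io as fio

        atac = fio.CountMatrix(sp.csr_matrix(dense), sub.atac.feature_ids, sub.atac.barcodes,
                               fio.ATAC_PEAKS)
        data2 = lk.LinkData(rna=sub.rna, atac=atac, norm_rna=data.norm_rna,
                            norm_atac=data.norm_atac, genes=data.genes, peaks=data.peaks,
                            peak_gc=data.peak_gc)
        out = lk.compute_links(data2, min_cells=2, seed=0)
        assert not ((out.gene == "glink") & (out.peak == truth.links.peak[0])).any()

    def test_zero_variance_vector_skipped(self, planted_run):
        cfg, ds, truth, active = planted_run
        data = lk.LinkData.from_dataset(ds.subset_cells(active))
        data.norm_rna = data.norm_rna.copy()
        data.norm_rna[0] = 1.0  # constant gene vector
        out = lk.compute_links(data, seed=0)
        assert not (out.gene == data.genes.gene.iloc[0]).any()

    def test_permutation_null_retention_calibrated(self):
        """Permuting expression breaks all couplings: retained fraction among
        candidates stays at the nominal level (<= 0.07 at p < 0.05)."""
        from fmm.scenarios import null_calibration_config

        cfg = null_calibration_config(n_cells=300, n_genes=60, peaks_per_gene=8, seed=5)
        ds, _ = simulate_multiome(cfg)
        data = lk.LinkData.from_dataset(ds)
        fr = lk.permutation_null_retention(data, n_perm=200, seed=0)
        assert fr.mean() <= 0.07


class TestLinksByCondition:
    def test_single_condition_equals_global_run(self, planted_run):
        cfg, ds, truth, active = planted_run
        sub = ds.subset_cells(active)
        data = lk.LinkData.from_dataset(sub)
        labels = np.array(["only"] * sub.n_cells)
        per = lk.links_by_condition(data, labels, seed=0)["only"]
        glob = lk.compute_links(
            data, seed=0,
            bg_indices=lk.background_peak_indices(data, 200, 0), condition="only",
        )
        pd.testing.assert_frame_equal(per, glob)

    def test_duplicated_condition_symmetry(self, planted_run):
        cfg, ds, truth, active = planted_run
        sub = ds.subset_cells(active)
        import scipy.sparse as sp
        from fmm import io as fio
        from fmm.dataset import PairedMultiomeDataset

        rna2 = fio.CountMatrix(sp.hstack([sub.rna.values, sub.rna.values]).tocsr(),
                               sub.rna.feature_ids,
                               [f"{b}_{i}" for i in (0, 1) for b in sub.rna.barcodes], fio.RNA)
        atac2 = fio.CountMatrix(sp.hstack([sub.atac.values, sub.atac.values]).tocsr(),
                                sub.atac.feature_ids, rna2.barcodes, fio.ATAC_PEAKS)
        obs2 = pd.concat([sub.obs, sub.obs], ignore_index=True)
        obs2["barcode"] = rna2.barcodes
        ds2 = PairedMultiomeDataset(rna=rna2, atac=atac2, fragments=sub.fragments.iloc[:0],
                                    peaks=sub.peaks, genes=sub.genes, obs=obs2,
                                    peak_sequences=sub.peak_sequences)
        data2 = lk.LinkData.from_dataset(ds2)
        labels = np.array(["A"] * sub.n_cells + ["B"] * sub.n_cells)
        runs = lk.links_by_condition(data2, labels, seed=0)
        a = runs["A"].drop(columns="condition")
        b = runs["B"].drop(columns="condition")
        pd.testing.assert_frame_equal(a, b)

    def test_condition_below_floor_errors(self, planted_run):
        cfg, ds, truth, active = planted_run
        data = lk.LinkData.from_dataset(ds)
        labels = np.array(["big"] * (ds.n_cells - 5) + ["tiny"] * 5)
        with pytest.raises(ValueError, match="tiny"):
            lk.links_by_condition(data, labels, min_condition_cells=30, seed=0)


def link_frame(pairs, condition=None):
    return pd.DataFrame(
        {"gene": [g for g, _ in pairs], "peak": [p for _, p in pairs],
         "score": 0.5, "z": 4.0, "p_value": 1e-4, "condition": condition}
    )


class TestRegulomeCounts:
    def test_basic_delta(self):
        naive = link_frame([("g1", "p1"), ("g1", "p2")])
        exp = link_frame([("g1", "p1")])
        out = lk.regulome_counts(naive, exp)
        assert out.iloc[0].delta == 1

    def test_identical_lists_zero_delta(self):
        links = link_frame([("g1", "p1"), ("g2", "p2")])
        out = lk.regulome_counts(links, links.copy())
        assert (out.delta == 0).all()

    def test_matches_group_by_tally_oracle(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(10)]
        peaks = [f"p{i}" for i in range(40)]
        naive = link_frame([(rng.choice(genes), rng.choice(peaks)) for _ in range(200)])
        exp = link_frame([(rng.choice(genes), rng.choice(peaks)) for _ in range(150)])
        out = lk.regulome_counts(naive, exp).set_index("gene")
        for g in set(naive.gene) | set(exp.gene):
            assert out.loc[g, "n_links_naive"] == (naive.gene == g).sum()
            assert out.loc[g, "n_links_exp"] == (exp.gene == g).sum()
        # sorted by delta descending
        assert list(out.delta) == sorted(out.delta, reverse=True)


class TestSetOperations:
    def test_dedup_examples(self):
        links = link_frame([("g1", "p1"), ("g2", "p1"), ("g1", "p2")])
        assert lk.dedup_peaks(links) == ["p1", "p2"]
        assert lk.dedup_peaks(link_frame([])) == []

    def test_dedup_random_set_oracle(self):
        rng = np.random.default_rng(1)
        peaks = [f"p{i}" for i in range(100)]
        pairs = [(f"g{rng.integers(50)}", rng.choice(peaks)) for _ in range(1000)]
        out = lk.dedup_peaks(link_frame(pairs))
        assert len(out) <= 100
        assert set(out) == {p for _, p in pairs}

    def test_identical_sets_only_fourway(self):
        s = {c: set(f"p{i}" for i in range(7)) for c in "ABCD"}
        out = lk.exclusive_intersections(s)
        nonzero = out[out["size"] > 0]
        assert len(nonzero) == 1
        assert nonzero.iloc[0].combination == "A&B&C&D" and nonzero.iloc[0]["size"] == 7

    def test_disjoint_sets_only_singletons(self):
        s = {c: {f"{c}{i}" for i in range(3)} for c in "ABCD"}
        out = lk.exclusive_intersections(s)
        nonzero = out[out["size"] > 0]
        assert set(nonzero.combination) == set("ABCD")

    def test_random_systems_match_membership_tally(self):
        """Exclusive intersection sizes equal the brute-force 2^4 tally and
        always sum to the union size."""
        rng = np.random.default_rng(2)
        universe = [f"p{i}" for i in range(200)]
        for _ in range(50):
            sets = {c: set(rng.choice(universe, size=rng.integers(10, 120), replace=False))
                    for c in "ABCD"}
            out = lk.exclusive_intersections(sets)
            assert len(out) == 15
            union = set().union(*sets.values())
            assert out["size"].sum() == len(union)
            tally = {}
            for el in union:
                key = "&".join(c for c in "ABCD" if el in sets[c])
                tally[key] = tally.get(key, 0) + 1
            for rec in out.itertuples():
                assert rec.size == tally.get(rec.combination, 0)


class TestInducedPeaks:
    def _system(self, naive_ss, naive_ad, exp_ss, exp_ad):
        return {
            "naive:SS": set(naive_ss), "naive:AD": set(naive_ad),
            "exp:SS": set(exp_ss), "exp:AD": set(exp_ad),
        }

    def test_peak_in_all_four_sets_not_induced(self):
        sys4 = self._system({"p"}, {"p"}, {"p"}, {"p"})
        assert lk.induced_peaks(sys4) == set()

    def test_distinct_peak_counting(self):
        sys4 = self._system({"p1"}, {"p1"}, set(), {"p1"})
        cond_links = {
            "naive:SS": link_frame([("g1", "p1"), ("g1", "p1"), ("g2", "p1")]),
        }
        out = lk.induced_peak_genes(sys4, cond_links)
        assert dict(zip(out.gene, out.n_induced_peaks)) == {"g1": 1, "g2": 1}

    def test_empty_induced_set_is_valid(self):
        sys4 = self._system(set(), set(), set(), set())
        assert len(lk.induced_peak_genes(sys4, {})) == 0

    def test_missing_condition_errors(self):
        with pytest.raises(ValueError):
            lk.induced_peaks({"naive:SS": set()})


class TestTh2Report:
    def test_missing_locus_gene_errors(self, planted_run):
        cfg, ds, truth, active = planted_run
        data = lk.LinkData.from_dataset(ds)
        with pytest.raises(ValueError, match="Il4"):
            lk.th2_locus_report(
                data, ds.obs.fate_map.to_numpy(),
                (ds.obs.fate_map + ":" + ds.obs.disease).to_numpy(),
            )

    def test_no_links_gives_zero_counts(self, planted_run):
        cfg, ds, truth, active = planted_run
        data = lk.LinkData.from_dataset(ds)
        report = lk.th2_locus_report(
            data, ds.obs.fate_map.to_numpy(),
            (ds.obs.fate_map + ":" + ds.obs.disease).to_numpy(),
            locus=["gd00", "gd01"],
        )
        assert (report.regulome[["n_links_naive", "n_links_exp"]].to_numpy() == 0).all()
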