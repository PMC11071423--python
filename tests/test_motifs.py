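"""Motif scanning, chromVAR-style deviations, hypergeometric enrichment and
TF-expression cross-referencing."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import stats as sps
from scipy.special import comb

from fmm import io as fio, motifs as mo
from fmm.scenarios import _consensus_pfm
from tests.conftest import make_count_matrix

BASES = "ACGT"
COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq):
    return seq.translate(COMP)[::-1]


def deterministic_pfm(consensus):
    pfm = _consensus_pfm("M0", consensus, consensus, strength=100)
    pfm.counts[pfm.counts == 5] = 0
    return pfm


def brute_force_hit(seq, pfm, frac=0.8, pc=0.8):
    lo = mo.pfm_to_log_odds(pfm, pc)
    w = lo.shape[1]
    thresh = frac * lo.max(axis=0).sum()
    idx = {b: i for i, b in enumerate(BASES)}
    best = -np.inf
    for s in (seq, revcomp(seq)):
        for off in range(len(s) - w + 1):
            score = sum(
                lo[idx[b], j] if b in idx else 0.0 for j, b in enumerate(s[off : off + w])
            )
            best = max(best, score)
    return best >= thresh


class TestScan:
    def test_consensus_hit(self):
        hits = mo.scan_motifs(["CCTATACC"], [deterministic_pfm("TATA")])
        assert hits.values[0, 0]

    def test_reverse_strand_hit(self):
        seq = "CCTATACC"
        hits = mo.scan_motifs([revcomp(seq)], [deterministic_pfm("TATA")])
        assert hits.values[0, 0]

    def test_short_sequence_no_hit_no_error(self):
        hits = mo.scan_motifs(["AC"], [deterministic_pfm("TATAAA")])
        assert not hits.values[0, 0]

    def test_matches_exhaustive_scan_oracle(self):
        """Hit calls equal a brute-force full scan on 100 random peaks."""
        rng = np.random.default_rng(0)
        pfm = fio.PFM("M1", "R8", rng.integers(1, 40, size=(4, 8)).astype(float))
        seqs = ["".join(rng.choice(list("ACGTN"), p=[0.24, 0.24, 0.24, 0.24, 0.04], size=60))
                for _ in range(100)]
        hits = mo.scan_motifs(seqs, [pfm], threshold_fraction=0.8)
        expected = [brute_force_hit(s, pfm) for s in seqs]
        assert list(hits.values[0]) == expected

    def test_strand_symmetry_of_hit_matrix(self):
        rng = np.random.default_rng(1)
        pfm = fio.PFM("M1", "R8", rng.integers(1, 30, size=(4, 7)).astype(float))
        seqs = ["".join(rng.choice(list(BASES), size=50)) for _ in range(40)]
        fwd = mo.scan_motifs(seqs, [pfm])
        rev = mo.scan_motifs([revcomp(s) for s in seqs], [pfm])
        assert np.array_equal(fwd.values, rev.values)


class TestDeviations:
    def test_motif_in_all_peaks_has_zero_raw_deviation(self):
        rng = np.random.default_rng(2)
        cm = make_count_matrix(rng.poisson(2.0, size=(12, 25)), modality=fio.ATAC_PEAKS)
        hits = pd.DataFrame(np.ones((1, 12), dtype=bool), index=["all"])
        dev = mo.motif_deviations(cm, hits, rng.random(12), n_bg=8, seed=0)
        assert np.nanmax(np.abs(dev.raw)) == 0.0

    def test_invariant_to_peak_order(self):
        rng = np.random.default_rng(3)
        X = rng.poisson(1.5, size=(15, 20))
        gc = rng.random(15)
        H = rng.random((2, 15)) < 0.4
        cm = make_count_matrix(X, modality=fio.ATAC_PEAKS)
        hits = pd.DataFrame(H, index=["a", "b"])
        d1 = mo.motif_deviations(cm, hits, gc, n_bg=5, seed=1)
        perm = rng.permutation(15)
        cm2 = make_count_matrix(X[perm], genes=[f"g{i}" for i in perm], modality=fio.ATAC_PEAKS)
        d2 = mo.motif_deviations(cm2, pd.DataFrame(H[:, perm], index=["a", "b"]), gc[perm],
                                 n_bg=5, seed=1)
        assert np.allclose(np.nan_to_num(d1.raw), np.nan_to_num(d2.raw))

    def test_empty_motif_warns(self):
        rng = np.random.default_rng(4)
        cm = make_count_matrix(rng.poisson(2.0, size=(6, 10)), modality=fio.ATAC_PEAKS)
        hits = pd.DataFrame(np.zeros((1, 6), dtype=bool), index=["none"])
        with pytest.warns(UserWarning, match="zero peaks"):
            dev = mo.motif_deviations(cm, hits, rng.random(6), n_bg=4, seed=0)
        assert np.isnan(dev.raw).all()

    def test_planted_type_specific_motif_scores_high_in_type(self, scenario):
        """A motif planted only in ILC2-open peaks: mean deviation z in ILC2
        cells exceeds other cells by >= 1."""
        from fmm.scenarios import default_motif_set

        _, ds, truth = scenario
        hits = mo.scan_motifs(ds.peak_sequences, default_motif_set())
        from fmm import links as lk

        gc = lk.gc_content(ds.peak_sequences)
        dev = mo.motif_deviations(ds.atac, hits, gc, n_bg=30, seed=0)
        z = dev.z[dev.motif_names.index("GATA3")]
        is_ilc2 = (truth.labels["cell_type"] == "ILC2").to_numpy()
        assert np.nanmean(z[is_ilc2]) - np.nanmean(z[~is_ilc2]) >= 1.0


class TestEnrichment:
    def test_closed_form_hypergeometric(self):
        hits = pd.DataFrame(np.r_[np.ones(5), np.zeros(20)].reshape(1, 25).astype(bool),
                            index=["m"])
        names = [f"p{i}" for i in range(25)]
        out = mo.enrich_motifs(names[:5], names, hits, np.full(25, 0.5))
        assert np.isclose(out.p_value[0], 1 / comb(25, 5))

    def test_equal_frequency_is_null(self):
        rng = np.random.default_rng(5)
        H = (rng.random(200) < 0.3).reshape(1, 200)
        hits = pd.DataFrame(H, index=["m"])
        names = [f"p{i}" for i in range(200)]
        fg = list(rng.choice(names, size=60, replace=False))
        out = mo.enrich_motifs(fg, names, hits, np.full(200, 0.5), seed=0)
        assert 0.5 < out.fold_enrichment[0] < 2.0
        assert out.p_value[0] > 0.05

    def test_fg_equals_all_peaks_fold_one(self):
        hits = pd.DataFrame((np.arange(10) < 4).reshape(1, 10), index=["m"])
        names = [f"p{i}" for i in range(10)]
        out = mo.enrich_motifs(names, names, hits, np.full(10, 0.5))
        assert np.isclose(out.fold_enrichment[0], 1.0)

    def test_empty_foreground_errors(self):
        hits = pd.DataFrame(np.zeros((1, 4), dtype=bool), index=["m"])
        with pytest.raises(ValueError):
            mo.enrich_motifs([], [f"p{i}" for i in range(4)], hits, np.full(4, 0.5))

    def test_matches_fisher_exact_oracle(self):
        """Hypergeometric upper-tail p equals the one-sided Fisher test on 20
        random contingency configurations."""
        rng = np.random.default_rng(6)
        for _ in range(20):
            n_fg, n_bg = rng.integers(5, 30), rng.integers(10, 60)
            H = rng.random(n_fg + n_bg) < rng.uniform(0.2, 0.7)
            hits = pd.DataFrame(H.reshape(1, -1), index=["m"])
            names = [f"p{i}" for i in range(n_fg + n_bg)]
            out = mo.enrich_motifs(names[:n_fg], names, hits, np.full(len(names), 0.5))
            fg_with = H[:n_fg].sum()
            bg_with = H[n_fg:].sum()
            table = [[fg_with, n_fg - fg_with], [bg_with, n_bg - bg_with]]
            ref = sps.fisher_exact(table, alternative="greater")[1]
            assert abs(out.p_value[0] - ref) < 1e-10


class TestCrossref:
    def _enrich_row(self, motif, p_adj=0.001):
        return pd.DataFrame([{"motif": motif, "p_adj": p_adj, "fold_enrichment": 5.0}])

    def _norm(self, values, genes):
        from fmm import embed

        values = np.asarray(values, float)
        return embed.NormalizedMatrix(values, np.array(genes, dtype=object),
                                      np.array([f"c{i}" for i in range(values.shape[1])],
                                               dtype=object), embed.LOG_CP10K)

    def test_unexpressed_tf_is_discordant(self):
        norm = self._norm([[0, 0, 0]], ["Rorc"])
        out = mo.crossref_expression(self._enrich_row("RORC"), norm, {"RORC": "Rorc"})
        assert not out.concordant[0]

    def test_two_motifs_sharing_tf_carry_identical_expression(self):
        norm = self._norm([[1, 2, 0]], ["Gata3"])
        enr = pd.concat([self._enrich_row("GATA3a"), self._enrich_row("GATA3b")],
                        ignore_index=True)
        out = mo.crossref_expression(enr, norm, {"GATA3a": "Gata3", "GATA3b": "Gata3"})
        assert out.pct_detected[0] == out.pct_detected[1]
        assert out.mean_expression[0] == out.mean_expression[1]

    def test_expressed_enriched_tf_is_concordant(self):
        norm = self._norm([[1, 2, 3]], ["Gata3"])
        out = mo.crossref_expression(self._enrich_row("GATA3"), norm, {"GATA3": "Gata3"})
        assert bool(out.concordant[0])
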