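import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from spatialtme import GenePositionTable, cluster_subclones, cnv_profile
from spatialtme.cnv import _smooth_within_chromosomes
from spatialtme.scoring import ScoreTable

from conftest import make_dataset


def positions_for(genes, n_chrom=2):
    per = int(np.ceil(len(genes) / n_chrom))
    rows = [
        (g, f"chr{i // per + 1}", (i % per) * 100 + 1, (i % per) * 100 + 50)
        for i, g in enumerate(genes)
    ]
    return GenePositionTable(
        pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"]).set_index("gene")
    )


class TestSmoothing:
    def test_window_one_is_identity(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(3, 30))
        chroms = np.array(["chr1"] * 15 + ["chr2"] * 15)
        assert np.array_equal(_smooth_within_chromosomes(vals, chroms, 1), vals)

    def test_never_averages_across_chromosomes(self):
        # chr1 all zeros, chr2 all tens: smoothing must keep them flat
        vals = np.concatenate([np.zeros((1, 10)), np.full((1, 10), 10.0)], axis=1)
        chroms = np.array(["chr1"] * 10 + ["chr2"] * 10)
        out = _smooth_within_chromosomes(vals, chroms, 7)
        assert np.allclose(out[0, :10], 0.0)
        assert np.allclose(out[0, 10:], 10.0)

    def test_truncated_edges_match_naive_average(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(1, 12))
        chroms = np.array(["chr1"] * 12)
        out = _smooth_within_chromosomes(vals, chroms, 5)
        for i in range(12):
            lo, hi = max(0, i - 2), min(12, i + 3)
            assert out[0, i] == pytest.approx(vals[0, lo:hi].mean())


class TestCnvProfile:
    def _dataset(self, n_spots=40, n_genes=60, gain=None, seed=0):
        """Poisson dataset; optionally multiply a gene block x2 in the last
        half of the spots (the "query" side)."""
        rng = np.random.default_rng(seed)
        rate = np.full((n_spots, n_genes), 50.0)
        if gain is not None:
            rate[n_spots // 2 :, gain] *= 2.0
        ds = make_dataset(
            rng.poisson(rate), coords=[(i % 8, i // 8) for i in range(n_spots)]
        )
        return ds

    def test_identically_distributed_query_is_flat(self):
        ds = self._dataset()
        pos = positions_for(ds.genes)
        ref = ds.barcodes[:20]
        prof = cnv_profile(ds, pos, ref, window=11)
        assert np.abs(prof.to_numpy()).mean() < 0.05

    def test_planted_gain_block_elevated(self):
        ds = self._dataset(n_genes=60, gain=slice(0, 30))
        pos = positions_for(ds.genes, n_chrom=2)  # gain = all of chr1
        prof = cnv_profile(ds, pos, ds.barcodes[:20], window=11)
        query = prof.loc[ds.barcodes[20:]]
        inside = query.iloc[:, :30].to_numpy().mean()
        outside = query.iloc[:, 30:].to_numpy().mean()
        assert inside - outside > 0.3

    def test_empty_reference_fatal(self):
        ds = self._dataset()
        with pytest.raises(ValueError, match="reference"):
            cnv_profile(ds, positions_for(ds.genes), [])

    def test_too_few_genes_per_chromosome_fatal(self):
        ds = self._dataset(n_genes=20)
        pos = positions_for(ds.genes, n_chrom=10)  # 2 genes per chromosome
        with pytest.raises(ValueError, match="window/4"):
            cnv_profile(ds, pos, ds.barcodes[:10], window=101)

    def test_clip_bound_respected(self):
        ds = self._dataset(gain=slice(0, 30))
        prof = cnv_profile(ds, positions_for(ds.genes), ds.barcodes[:20], window=5, clip=0.4)
        assert np.abs(prof.to_numpy()).max() <= 0.4 + 1e-12

    def test_invariant_to_gene_input_order(self):
        ds = self._dataset(seed=3)
        pos = positions_for(ds.genes)
        ref = ds.barcodes[:20]
        a = cnv_profile(ds, pos, ref, window=7)
        rng = np.random.default_rng(4)
        perm = rng.permutation(ds.n_genes)
        ds2 = make_dataset(
            ds.counts[:, perm],
            coords=[tuple(c) for c in ds.coords],
            genes=[ds.genes[j] for j in perm],
        )
        b = cnv_profile(ds2, pos, ref, window=7)
        assert list(a.columns) == list(b.columns)
        assert np.allclose(a.to_numpy(), b.to_numpy())


class TestClusterSubclones:
    def _cnv_with_clones(self, n_per=50, n_genes=40, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.normal(0, 0.05, size=(2 * n_per, n_genes))
        base[:n_per, :10] += 0.8    # clone 1: gain in first block
        base[n_per:, 20:30] -= 0.8  # clone 2: loss in a disjoint block
        names = [f"s{i}" for i in range(2 * n_per)]
        cnv = pd.DataFrame(base, index=names, columns=[f"g{j}" for j in range(n_genes)])
        # graded scores: every spot except the minimum is "tumor rich" at q=0
        scores = ScoreTable(
            pd.DataFrame({"tumor": 1.0 + np.arange(2 * n_per)}, index=names)
        )
        truth = pd.Series(np.repeat([1, 2], n_per), index=names)
        return cnv, scores, truth

    def test_two_planted_clones_recovered(self):
        cnv, scores, truth = self._cnv_with_clones()
        sm = cluster_subclones(cnv, scores, tumor_quantile=0.0)
        ari = adjusted_rand_score(truth[sm.tumor_spots], sm.labels[sm.tumor_spots])
        assert ari >= 0.8
        assert sm.k == 2

    def test_identical_profiles_fall_back_to_k_min(self, caplog):
        names = [f"s{i}" for i in range(20)]
        cnv = pd.DataFrame(np.zeros((20, 10)), index=names)
        scores = ScoreTable(
            pd.DataFrame({"tumor": 1.0 + np.arange(20)}, index=names)
        )
        with caplog.at_level("WARNING"):
            sm = cluster_subclones(cnv, scores, tumor_quantile=0.0)
        assert sm.k == 2
        assert "silhouette undefined" in caplog.text

    def test_too_few_tumor_spots_fatal(self):
        names = [f"s{i}" for i in range(8)]
        cnv = pd.DataFrame(np.random.default_rng(0).normal(size=(8, 5)), index=names)
        scores = ScoreTable(
            pd.DataFrame({"tumor": np.arange(8.0)}, index=names)
        )
        with pytest.raises(ValueError, match="tumor-rich"):
            cluster_subclones(cnv, scores, tumor_quantile=0.75)

    def test_labels_invariant_to_spot_order(self):
        cnv, scores, truth = self._cnv_with_clones(seed=5)
        sm1 = cluster_subclones(cnv, scores, tumor_quantile=0.0)
        rng = np.random.default_rng(6)
        perm = rng.permutation(len(cnv))
        cnv2 = cnv.iloc[perm]
        scores2 = ScoreTable(scores.values.iloc[perm])
        sm2 = cluster_subclones(cnv2, scores2, tumor_quantile=0.0)
        shared = sorted(set(sm1.tumor_spots) & set(sm2.tumor_spots))
        assert adjusted_rand_score(
            sm1.labels[shared], sm2.labels[shared]
        ) == pytest.approx(1.0)

    def test_reference_side_spots_labelled_zero(self):
        cnv, _, _ = self._cnv_with_clones()
        score_vals = np.ones(len(cnv))
        score_vals[:10] = 0.0
        scores = ScoreTable(pd.DataFrame({"tumor": score_vals}, index=cnv.index))
        sm = cluster_subclones(cnv, scores, tumor_quantile=0.05)
        assert (sm.labels.iloc[:10] == 0).all()
        assert (sm.labels.iloc[10:] > 0).all()
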