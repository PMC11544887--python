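"""Expression-stage tests: filtering, clustering, voom DE, BH, ORA.

The differential-expression route is cross-checked against the reference
R/Bioconductor implementation (limma with voom precision weights) run
through Rscript on the same counts — a fully independent code path.
"""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from tumortract import phantom, transcriptome as tx


def make_counts(arr, groups):
    arr = np.asarray(arr)
    genes = [f"g{i}" for i in range(arr.shape[0])]
    samples = [f"s{j}" for j in range(arr.shape[1])]
    return phantom.CountsMatrix(
        counts=pd.DataFrame(arr.astype(np.int64), index=genes, columns=samples),
        sample_groups=pd.Series(groups, index=samples),
    )


class TestCpmFilter:
    def test_rule_application(self):
        # libraries of 1e6 -> counts are CPM directly
        base = np.full((3, 3), 0)
        arr = np.vstack([[4, 4, 4], [6, 6, 0], np.full((1, 3), 10 ** 6 - 10)])
        cm = make_counts(arr + base, ["tract", "tumor", "tumor"])
        # normalize library to ~1e6 by the large third gene
        kept = tx.cpm_filter(cm, min_cpm=5.0, min_samples=2)
        assert "g0" not in kept.counts.index     # CPM < 5 everywhere
        assert "g1" in kept.counts.index         # CPM >= 5 in 2 samples

    def test_idempotent(self):
        cm = phantom.simulate_counts(n_genes=400, de_fraction=0.0, seed=1)
        once = tx.cpm_filter(cm)
        twice = tx.cpm_filter(once)
        assert list(once.counts.index) == list(twice.counts.index)

    def test_matches_bruteforce_oracle(self):
        cm = phantom.simulate_counts(n_genes=500, de_fraction=0.0, seed=2)
        kept = tx.cpm_filter(cm, min_cpm=5.0, min_samples=2)
        lib = cm.counts.sum(0).to_numpy(float)
        expected = []
        for g, row in cm.counts.iterrows():
            cpm = row.to_numpy(float) * 1e6 / lib
            if (cpm >= 5.0).sum() >= 2:
                expected.append(g)
        assert list(kept.counts.index) == expected

    def test_empty_result_raises(self):
        cm = make_counts(np.array([[1, 1, 1], [10 ** 6, 10 ** 6, 10 ** 6]]),
                         ["tract", "tumor", "tumor"])
        with pytest.raises(ValueError):
            tx.cpm_filter(cm, min_cpm=2e6, min_samples=1)


class TestHierCluster:
    def test_separated_groups_recovered(self):
        """Large between-group shifts: cutting at k = 3 recovers the groups
        exactly (adjusted Rand index 1)."""
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(0)
        shifts = {"tract": 0.0, "tumor": 8.0, "normal": -8.0}
        cols, labels = [], []
        for g, n in [("tract", 5), ("tumor", 4), ("normal", 4)]:
            for _ in range(n):
                cols.append(rng.normal(shifts[g], 0.5, 200))
                labels.append(g)
        logcpm = pd.DataFrame(np.column_stack(cols),
                              columns=[f"s{i}" for i in range(len(cols))])
        res = tx.hier_cluster(logcpm, k=3)
        assert adjusted_rand_score(labels, res["labels"]) == 1.0

    def test_duplicate_sample_merges_first(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=50)
        logcpm = pd.DataFrame({"s0": a, "s1": a, "s2": a + 5.0, "s3": a - 5.0})
        res = tx.hier_cluster(logcpm)
        Z = res["linkage"]
        assert Z[0, 2] == 0.0
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_order_invariance_up_to_relabeling(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(2)
        cols = [rng.normal(0, 1, 100) for _ in range(4)] + \
               [rng.normal(9, 1, 100) for _ in range(4)]
        logcpm = pd.DataFrame(np.column_stack(cols),
                              columns=[f"s{i}" for i in range(8)])
        perm = [3, 1, 7, 5, 0, 6, 2, 4]
        shuffled = logcpm.iloc[:, perm]
        l1 = tx.hier_cluster(logcpm, k=2)["labels"]
        l2 = tx.hier_cluster(shuffled, k=2)["labels"]
        l2_back = np.empty_like(l2)
        l2_back[perm] = l2
        assert adjusted_rand_score(l1, l2_back) == 1.0


class TestVoomDe:
    def test_null_p_uniform(self):
        cm = phantom.simulate_counts(n_genes=5000, de_fraction=0.0, seed=3)
        table = tx.voom_de(tx.cpm_filter(cm))
        assert stats.kstest(table["p"], "uniform").pvalue > 0.01

    def test_true_positive_sign(self):
        """Detected true-DE genes carry a positive tract-vs-rest log2FC."""
        cm = phantom.simulate_counts(n_genes=3000, de_fraction=0.1,
                                     fold_change=2.0, seed=4)
        filtered = tx.cpm_filter(cm)
        table = tx.voom_de(filtered)
        truth = filtered.true_fold_change
        detected = table.index[(table["q"] < 0.05)]
        true_pos = [g for g in detected if truth.loc[g] > 1.0]
        assert len(true_pos) > 20
        signs = table.loc[true_pos, "log2fc"] > 0
        assert signs.mean() >= 0.95

    def test_constant_gene_zero_logfc(self):
        rng = np.random.default_rng(5)
        arr = rng.poisson(100.0, (40, 8))
        arr[0] = 77     # identical counts in all samples
        cm = make_counts(arr, ["tract"] * 4 + ["tumor"] * 4)
        lib = cm.counts.sum(0).to_numpy(float)
        table = tx.voom_de(cm, lib=np.full_like(lib, lib.mean()))
        assert table.loc["g0", "log2fc"] == pytest.approx(0.0, abs=1e-12)

    def test_weights_positive_finite(self):
        cm = phantom.simulate_counts(n_genes=800, de_fraction=0.0, seed=6)
        filtered = tx.cpm_filter(cm)
        table = tx.voom_de(filtered)
        assert np.isfinite(table["t"]).all()
        assert np.isfinite(table["p"]).all()
        assert ((table["p"] >= 0) & (table["p"] <= 1)).all()

    def test_matches_limma_voom_reference(self, tmp_path):
        """Dual-route check: log2FC and moderated t agree with R limma-voom
        on the same matrix (same design, same contrast)."""
        cm = phantom.simulate_counts(n_genes=400, de_fraction=0.1,
                                     fold_change=2.0, seed=11)
        filtered = tx.cpm_filter(cm)
        table = tx.voom_de(filtered)
        counts_csv = tmp_path / "counts.csv"
        groups_csv = tmp_path / "groups.csv"
        out_csv = tmp_path / "limma.csv"
        filtered.counts.to_csv(counts_csv)
        filtered.sample_groups.to_csv(groups_csv)
        script = tmp_path / "run.R"
        script.write_text(f"""
suppressMessages(library(limma))
counts <- as.matrix(read.csv("{counts_csv}", row.names=1, check.names=FALSE))
groups <- read.csv("{groups_csv}", row.names=1)[,1]
design <- cbind(Intercept=1, tract=as.numeric(groups == "tract"))
v <- voom(counts, design)
fit <- eBayes(lmFit(v, design))
tt <- topTable(fit, coef="tract", number=Inf, sort.by="none")
write.csv(tt, "{out_csv}")
""")
        subprocess.run(["Rscript", str(script)], check=True,
                       capture_output=True)
        ref = pd.read_csv(out_csv, index_col=0)
        assert np.abs(table["log2fc"] - ref["logFC"]).max() < 0.01
        t_corr = np.corrcoef(table["t"], ref["t"])[0, 1]
        assert t_corr > 0.999

    def test_small_contrast_side_rejected(self):
        cm = phantom.simulate_counts(
            n_genes=50, samples_per_group={"tract": 1, "tumor": 5}, seed=7)
        with pytest.raises(ValueError):
            tx.voom_de(cm)


class TestBhAdjust:
    def test_step_up_example(self):
        q = tx.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_single_p(self):
        assert tx.bh_adjust([0.3])[0] == pytest.approx(0.3)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    def test_matches_bruteforce_step_up(self, ps):
        """Oracle: direct evaluation q(i) = min_{j >= i} p(j) * m / j on the
        sorted vector, mapped back."""
        ps = np.asarray(ps)
        q = tx.bh_adjust(ps)
        m = len(ps)
        order = np.argsort(ps, kind="mergesort")
        expected = np.empty(m)
        running = np.inf
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, ps[i] * m / rank)
            expected[i] = min(running, 1.0)
        assert np.allclose(q, expected, atol=1e-12)
        assert np.all(q >= ps - 1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            tx.bh_adjust([0.5, 1.5])


class TestDeCall:
    def test_fold_threshold_excludes_sub_twofold(self):
        table = pd.DataFrame({
            "log2fc": [0.9, 1.5, -1.2, 2.0],
            "t": [5.0, 5.0, -5.0, 6.0],
            "p": [0.001, 0.001, 0.002, 0.0001],
            "q": [0.001, 0.01, 0.01, 0.001],
            "ave_logcpm": [5.0] * 4,
        }, index=["a", "b", "c", "d"])
        calls = tx.de_call(table, fc_threshold=2.0, q_threshold=0.05)
        assert "a" not in calls.index            # 0.9 < log2(2)
        assert set(calls.index) == {"b", "c", "d"}
        assert calls.loc["c", "direction"] == "down"

    def test_matches_row_scan(self):
        rng = np.random.default_rng(8)
        table = pd.DataFrame({
            "log2fc": rng.normal(0, 2, 300),
            "t": rng.normal(0, 3, 300),
            "p": rng.random(300),
            "q": rng.random(300),
            "ave_logcpm": rng.normal(5, 1, 300),
        }, index=[f"g{i}" for i in range(300)])
        calls = tx.de_call(table, fc_threshold=2.0, q_threshold=0.05)
        expected = {g for g, row in table.iterrows()
                    if abs(row["log2fc"]) >= 1.0 and row["q"] < 0.05}
        assert set(calls.index) == expected


class TestOraFisher:
    def test_exact_tail_sum_oracle(self):
        universe = [f"g{i}" for i in range(100)]
        ann = set(universe[:20])
        de = set(universe[:8]) | set(universe[30:32])   # overlap 8 of 10
        res = tx.ora_fisher(de, ann, universe)
        oracle = sum(stats.hypergeom.pmf(k, 100, 20, 10) for k in range(8, 11))
        assert res["p"] == pytest.approx(oracle, rel=1e-10)
        assert res["overlap"] == 8

    def test_independence_overlap_not_significant(self):
        universe = [f"g{i}" for i in range(100)]
        ann = set(universe[:20])
        de = set(universe[18:28])   # overlap 2 = expected 20*10/100
        res = tx.ora_fisher(de, ann, universe)
        assert res["p"] > 0.3

    def test_full_overlap_boundary(self):
        universe = [f"g{i}" for i in range(50)]
        s = set(universe[:10])
        res = tx.ora_fisher(s, s, universe)
        assert res["overlap"] == 10
        oracle = stats.hypergeom.pmf(10, 50, 10, 10)
        assert res["p"] == pytest.approx(oracle, rel=1e-10)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            tx.ora_fisher(set(), set(), [])
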