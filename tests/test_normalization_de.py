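import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from tests.conftest import make_matrix
from xlps.data_io import SampleSheet
from xlps.de import (
    DEConfig,
    bh_fdr,
    estimate_consensus_correlation,
    fit_blocked_moderated_test,
    moderated_group_test,
    pca_overview,
    quantile_normalize,
)


class TestBhFdr:
    def test_hand_computed_step_up(self):
        # step-up: min over j>=r of n*p_j/j = 0.03 for all three
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_degenerate_inputs(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_dominates_p_and_permutation_invariant(self):
        rng = np.random.default_rng(0)
        p = rng.random(200)
        q = bh_fdr(p)
        assert (q >= p - 1e-15).all()
        perm = rng.permutation(200)
        np.testing.assert_allclose(q[perm], bh_fdr(p[perm]))


class TestQuantileNormalize:
    def test_two_column_example(self):
        mat = make_matrix(np.array([[1, 4], [2, 5], [3, 6]], float), ["a", "b"])
        out = quantile_normalize(mat)
        np.testing.assert_allclose(out.values, [[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])

    def test_identical_columns_unchanged(self):
        col = np.array([3.0, 1.0, 2.0])
        mat = make_matrix(np.column_stack([col, col]), ["a", "b"])
        np.testing.assert_allclose(quantile_normalize(mat).values, mat.values)

    def test_defining_property_and_idempotence_random(self):
        rng = np.random.default_rng(1)
        mat = make_matrix(rng.normal(5, 2, size=(200, 10)), [f"s{j}" for j in range(10)])
        out = quantile_normalize(mat)
        ref = np.sort(out.values[:, 0])
        for j in range(10):
            np.testing.assert_allclose(np.sort(out.values[:, j]), ref, atol=1e-9)
        np.testing.assert_allclose(quantile_normalize(out).values, out.values, atol=1e-9)

    def test_missing_cells_excluded_from_rank_pool(self):
        vals = np.array([[1.0, 10.0], [2.0, 11.0], [3.0, 0.0]])
        missing = np.array([[False, False], [False, False], [False, True]])
        out = quantile_normalize(make_matrix(vals, ["a", "b"], missing=missing))
        assert out.missing_mask[2, 1]
        # column b's two observed values span the same quantile range as a's extremes
        assert out.values[0, 1] < out.values[1, 1]

    def test_column_with_single_value_rejected(self):
        vals = np.array([[1.0, 1.0], [2.0, 2.0]])
        missing = np.array([[False, True], [False, False]])
        with pytest.raises(ValueError, match="fewer than 2"):
            quantile_normalize(make_matrix(vals, ["a", "b"], missing=missing))


def two_group_design(n_res=4, n_sens=6, nper=5):
    blocks = [f"res{i}" for i in range(n_res) for _ in range(nper)] + \
             [f"sen{i}" for i in range(n_sens) for _ in range(nper)]
    groups = ["resilient"] * (n_res * nper) + ["sensitive"] * (n_sens * nper)
    return np.array(groups), np.array(blocks)


def simulate_blocked(rng, n_genes, groups, blocks, sd_block=0.3, sd_noise=0.5, effect=None):
    uniq = sorted(set(blocks))
    u = {b: rng.normal(0, sd_block, n_genes) for b in uniq}
    y = np.column_stack([u[b] for b in blocks]) + rng.normal(0, sd_noise, (n_genes, len(blocks)))
    if effect is not None:
        y[:, groups == "sensitive"] += effect[:, None]
    return y


class TestModeratedBlockedTest:
    def test_constant_gene_is_null(self):
        groups, blocks = two_group_design()
        rng = np.random.default_rng(0)
        y = simulate_blocked(rng, 50, groups, blocks)
        y[0] = 3.14  # identical in every sample
        res = moderated_group_test(y, np.zeros_like(y, bool), [f"g{i}" for i in range(50)],
                                   groups, blocks, DEConfig())
        assert res[0].log2fc == pytest.approx(0.0, abs=1e-12) and not res[0].significant
        assert res[0].p_value == pytest.approx(1.0)

    def test_label_swap_antisymmetry(self):
        groups, blocks = two_group_design()
        rng = np.random.default_rng(1)
        y = simulate_blocked(rng, 80, groups, blocks, effect=rng.normal(0, 1, 80))
        mask = np.zeros_like(y, bool)
        ids = [f"g{i}" for i in range(80)]
        res = moderated_group_test(y, mask, ids, groups, blocks, DEConfig())
        swapped = np.where(groups == "sensitive", "resilient", "sensitive")
        res_sw = moderated_group_test(y, mask, ids, swapped, blocks, DEConfig())
        for a, b in zip(res, res_sw):
            assert a.log2fc == pytest.approx(-b.log2fc, abs=1e-9)
            assert a.moderated_t == pytest.approx(-b.moderated_t, abs=1e-9)
            assert a.p_value == pytest.approx(b.p_value, abs=1e-9)

    def test_unmoderated_matches_matrix_algebra_gls(self):
        """d0 -> 0 limit: per-gene statistic equals explicit GLS by linear algebra."""
        groups, blocks = two_group_design(n_res=3, n_sens=3, nper=4)
        rng = np.random.default_rng(2)
        y = simulate_blocked(rng, 30, groups, blocks)
        mask = np.zeros_like(y, bool)
        ids = [f"g{i}" for i in range(30)]
        res = moderated_group_test(y, mask, ids, groups, blocks, DEConfig(), moderate=False)
        rho = estimate_consensus_correlation(y, mask, groups, blocks)
        n = len(blocks)
        X = np.column_stack([(groups == "sensitive").astype(float),
                             (groups == "resilient").astype(float)])
        V = np.where(np.equal.outer(blocks, blocks), rho, 0.0) + np.eye(n) * (1 - rho)
        Vi = np.linalg.inv(V)
        A = np.linalg.inv(X.T @ Vi @ X)
        c = np.array([1.0, -1.0])
        for i, r in enumerate(res):
            beta = A @ X.T @ Vi @ y[i]
            resid = y[i] - X @ beta
            s2 = (resid @ Vi @ resid) / (n - 2)
            t = (c @ beta) / np.sqrt(s2 * (c @ A @ c))
            assert r.log2fc == pytest.approx(c @ beta, abs=1e-9)
            assert r.moderated_t == pytest.approx(t, abs=1e-9)

    def test_single_block_group_refused(self):
        groups, blocks = two_group_design(n_res=1, n_sens=3, nper=4)
        rng = np.random.default_rng(3)
        y = simulate_blocked(rng, 10, groups, blocks)
        with pytest.raises(ValueError, match="fewer than 2 blocks"):
            moderated_group_test(y, np.zeros_like(y, bool), [f"g{i}" for i in range(10)],
                                 groups, blocks, DEConfig())

    def test_gene_missing_in_group_excluded_with_reason(self):
        groups, blocks = two_group_design(n_res=2, n_sens=2, nper=3)
        rng = np.random.default_rng(4)
        y = simulate_blocked(rng, 20, groups, blocks)
        mask = np.zeros_like(y, bool)
        mask[0, groups == "resilient"] = True
        res = moderated_group_test(y, mask, [f"g{i}" for i in range(20)], groups, blocks, DEConfig())
        assert res[0].exclusion_reason == "missing_in_group"
        assert not res[0].significant and np.isnan(res[0].log2fc)

    def test_sheet_interface_blocks_on_species(self):
        import pandas as pd

        from xlps.data_io import SampleSheet

        rows = [{"sample_id": f"{sp}_i{i}_d0_t2", "species": sp, "group": grp,
                 "individual": f"{sp}_i{i}", "dose": 0.0, "time": 2.0}
                for sp, grp in (("mouse", "resilient"), ("rat", "resilient"),
                                ("pig", "sensitive"), ("cow", "sensitive"))
                for i in (1, 2, 3)]
        sheet = SampleSheet(pd.DataFrame(rows))
        rng = np.random.default_rng(5)
        y = rng.normal(5, 1, (15, 12))
        mat = make_matrix(y, sheet.sample_ids)
        res = fit_blocked_moderated_test(mat, sheet, DEConfig())
        assert len(res) == 15 and all(r.exclusion_reason is None for r in res)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
class TestLimmaCrossCheck:
    def test_moderated_t_matches_limma_without_blocking(self, tmp_path):
        """Independent oracle: limma lmFit+eBayes on a design with no block structure.

        Singleton blocks force rho = 0, so the GLS reduces to OLS and the
        empirical-Bayes machinery is directly comparable.
        """
        rng = np.random.default_rng(7)
        n_genes, nper = 60, 5
        groups = np.array(["resilient"] * nper + ["sensitive"] * nper)
        blocks = np.array([f"b{i}" for i in range(2 * nper)])  # singletons
        y = rng.normal(0, 1, (n_genes, 2 * nper)) * rng.uniform(0.5, 2, (n_genes, 1))
        y[:10, groups == "sensitive"] += 1.0
        ids = [f"g{i}" for i in range(n_genes)]
        res = moderated_group_test(y, np.zeros_like(y, bool), ids, groups, blocks, DEConfig())

        mat_path = tmp_path / "y.tsv"
        pd.DataFrame(y, index=ids).to_csv(mat_path, sep="\t", header=False)
        script = tmp_path / "limma.R"
        script.write_text(f"""
suppressMessages(library(limma))
y <- as.matrix(read.delim("{mat_path}", header=FALSE, row.names=1))
design <- cbind(resilient=rep(c(1,0), each={nper}), sensitive=rep(c(0,1), each={nper}))
fit <- eBayes(contrasts.fit(lmFit(y, design), c(-1, 1)))
write.table(data.frame(t=fit$t, p=fit$p.value), "{tmp_path}/out.tsv", sep="\\t")
""")
        subprocess.run(["Rscript", "--vanilla", str(script)], check=True,
                       capture_output=True, timeout=300)
        limma = pd.read_csv(tmp_path / "out.tsv", sep="\t")
        np.testing.assert_allclose([r.moderated_t for r in res], limma["t"], rtol=1e-6)
        np.testing.assert_allclose([r.p_value for r in res], limma["p"], rtol=1e-6)


class TestPcaOverview:
    def make_sheet(self, sample_ids):
        rows = [{"sample_id": s, "species": "mouse", "group": "resilient",
                 "individual": f"m{i}", "dose": 0.0, "time": 2.0}
                for i, s in enumerate(sample_ids)]
        return SampleSheet(pd.DataFrame(rows))

    def test_identical_samples_coincide(self):
        col = np.arange(5.0)
        mat = make_matrix(np.column_stack([col, col, col + 1]), ["a", "b", "c"])
        coords, _ = pca_overview(mat, self.make_sheet(["a", "b", "c"]))
        np.testing.assert_allclose(coords.loc["a", ["PC1", "PC2"]].astype(float),
                                   coords.loc["b", ["PC1", "PC2"]].astype(float), atol=1e-9)

    def test_variance_fractions_sorted_and_bounded(self):
        rng = np.random.default_rng(8)
        mat = make_matrix(rng.normal(0, 1, (40, 8)), [f"s{j}" for j in range(8)])
        _, frac = pca_overview(mat)
        assert frac.sum() <= 1 + 1e-9
        assert all(frac[i] >= frac[i + 1] for i in range(len(frac) - 1))

    def test_rank_one_matrix_loads_on_first_component(self):
        u = np.linspace(-1, 1, 30)
        v = np.array([1.0, 2.0, 3.0, 4.0])
        mat = make_matrix(np.outer(u, v), [f"s{j}" for j in range(4)])
        _, frac = pca_overview(mat)
        assert frac[0] == pytest.approx(1.0, abs=1e-9)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(9)
        y = rng.normal(0, 1, (40, 6))
        mat = make_matrix(y, [f"s{j}" for j in range(6)])
        a, _ = pca_overview(mat)
        b, _ = pca_overview(make_matrix(y.copy(), [f"s{j}" for j in range(6)]))
        pd.testing.assert_frame_equal(a, b)
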