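"""Normalization, moderated/Welch testing, multiple-testing correction."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from kmerdiff import KmerCountMatrix
from kmerdiff import diffexpr as dx

from tests.conftest import conditions_of, make_sheet


def _matrix(data, n_tumor, n_normal, index=None):
    sheet = make_sheet(n_tumor, n_normal)
    df = pd.DataFrame(np.asarray(data, dtype=float), columns=sheet["sample_id"])
    if index is not None:
        df.index = index
    return KmerCountMatrix(df, 31, conditions_of(sheet))


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        M = _matrix([[3, 3, 3, 3], [7, 7, 7, 7]], 2, 2)
        assert np.allclose(dx.size_factors(M), 1.0)

    def test_worked_two_by_two_example(self):
        # rows (2,4) and (4,8): geometric means 2*sqrt(2), 4*sqrt(2);
        # per-sample ratio medians 1/sqrt(2) and sqrt(2)
        M = _matrix([[2, 4], [4, 8]], 1, 1)
        s = dx.size_factors(M).to_numpy()
        assert np.allclose(s, [1 / np.sqrt(2), np.sqrt(2)])

    def test_single_sample_is_one(self):
        M = _matrix([[4], [9]], 1, 0)
        assert np.allclose(dx.size_factors(M), 1.0)

    def test_scale_equivariance(self):
        # scaling one sample's library by lambda moves its factor by lambda
        # relative to every other sample (factors are defined up to a common
        # constant: the geometric-mean pseudo-reference itself shifts by
        # lambda^(1/n), so the absolute factor moves by lambda^(1-1/n))
        rng = np.random.default_rng(0)
        lam, n = 3.0, 6
        base = rng.poisson(50, size=(200, n)) + 1
        s0 = dx.size_factors(_matrix(base, 3, 3))
        scaled = base.astype(float).copy()
        scaled[:, 0] *= lam
        s1 = dx.size_factors(_matrix(scaled, 3, 3))
        rel0 = (s1.iloc[0] / s1.iloc[1:]).to_numpy()
        assert np.allclose(rel0, lam * (s0.iloc[0] / s0.iloc[1:]).to_numpy(), rtol=1e-12)
        assert np.isclose(s1.iloc[0] / s0.iloc[0], lam ** (1 - 1 / n), rtol=1e-12)

    def test_fallback_without_all_positive_rows_warns(self):
        M = _matrix([[0, 4], [4, 0]], 1, 1)
        with pytest.warns(UserWarning):
            s = dx.size_factors(M)
        assert (s > 0).all()


class TestNormalize:
    def test_unit_factors_identity(self):
        M = _matrix([[2, 4], [4, 8]], 1, 1)
        out = dx.normalize(M, pd.Series(1.0, index=M.samples))
        pd.testing.assert_frame_equal(out.counts, M.counts)

    def test_columns_scaled_by_inverse_factor(self):
        M = _matrix([[2, 4], [4, 8]], 1, 1)
        s = pd.Series([2.0, 0.5], index=M.samples)
        out = dx.normalize(M, s)
        assert np.allclose(out.counts.iloc[:, 0], M.counts.iloc[:, 0] / 2.0)
        assert np.allclose(out.counts.iloc[:, 1], M.counts.iloc[:, 1] * 2.0)

    def test_doubled_library_renormalizes(self):
        # after doubling one sample's raw library and renormalizing, its
        # expression relative to the other samples is restored exactly (the
        # common pseudo-reference scale is arbitrary, so compare ratios)
        rng = np.random.default_rng(1)
        base = rng.poisson(100, size=(500, 6)) + 1
        M = dx.normalize(_matrix(base, 3, 3), dx.size_factors(_matrix(base, 3, 3)))
        doubled = base.astype(float).copy()
        doubled[:, 2] *= 2.0
        M2 = dx.normalize(
            _matrix(doubled, 3, 3), dx.size_factors(_matrix(doubled, 3, 3))
        )
        before = M.counts.iloc[:, 2] / M.counts.iloc[:, 0]
        after = M2.counts.iloc[:, 2] / M2.counts.iloc[:, 0]
        assert np.allclose(after, before, rtol=1e-10)

    def test_length_mismatch_errors(self):
        M = _matrix([[2, 4]], 1, 1)
        with pytest.raises(ValueError):
            dx.normalize(M, pd.Series([1.0]))


class TestTestFeature:
    def test_identical_groups_p_one(self):
        lfc, p = dx.test_feature([5, 5, 5], [5, 5, 5])
        assert lfc == 0.0 and p == 1.0

    def test_closed_form_log2fc(self):
        lfc, _ = dx.test_feature([10, 10], [40, 40])
        assert np.isclose(lfc, np.log2(10.5 / 40.5))
        lfc2, _ = dx.test_feature([40, 40], [10, 10])
        assert np.isclose(lfc2, np.log2(40.5 / 10.5))
        assert np.isclose(lfc2, 1.9475, atol=5e-5)

    def test_single_sample_group_flagged_undefined(self):
        lfc, p = dx.test_feature([10], [40, 42])
        assert np.isfinite(lfc) and np.isnan(p)

    def test_p_decreases_with_separation(self):
        rng = np.random.default_rng(2)
        noise = rng.normal(0, 1, size=8)
        ps = []
        for shift in (1.0, 2.0, 4.0, 8.0):
            a = 50 + noise[:4]
            b = 50 + shift * 10 + noise[4:]
            ps.append(dx.test_feature(b, a)[1])
        assert all(p2 < p1 for p1, p2 in zip(ps, ps[1:]))


class TestDifferentialTest:
    def test_swap_symmetry(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(60, size=(100, 8)).astype(float)
        M = _matrix(counts, 4, 4)
        fwd = dx.differential_test(M, method="moderated")
        swapped = conditions_of(make_sheet(4, 4)).map(
            {"tumor": "normal", "normal": "tumor"}
        )
        rev = dx.differential_test(M.counts, conditions=swapped, method="moderated")
        assert np.allclose(fwd["log2FC"], -rev["log2FC"])
        assert np.allclose(fwd["pvalue"], rev["pvalue"])

    @pytest.mark.parametrize("method", ["moderated", "welch"])
    def test_planted_shift_detected(self, method):
        rng = np.random.default_rng(4)
        counts = rng.poisson(50, size=(300, 16)).astype(float)
        counts[:10, :8] *= 4  # first 10 features up in tumor
        M = _matrix(counts, 8, 8)
        de = dx.differential_test(M, method=method)
        de["padj"] = dx.adjust_pvalues(de["pvalue"].to_numpy())
        sig = dx.select_significant(de)
        assert set(sig.index) == set(M.counts.index[:10])
        assert (sig["direction"] == "up").all()

    def test_matches_limma_ebayes_oracle(self, tmp_path):
        """Moderated t against the Bioconductor limma implementation."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable; limma cross-check cannot run")
        rng = np.random.default_rng(5)
        x = rng.normal(8, 1, size=(150, 10))
        x[:5, :5] += 2
        # heteroscedastic rows so the prior degrees of freedom come out finite
        x *= np.sqrt(rng.chisquare(4, size=150) / 4)[:, None]
        np.savetxt(tmp_path / "x.tsv", x, delimiter="\t")
        script = tmp_path / "limma.R"
        script.write_text(
            """
            suppressMessages(library(limma))
            x <- as.matrix(read.table(commandArgs(TRUE)[1], sep="\\t"))
            design <- cbind(1, c(rep(1,5), rep(0,5)))
            fit <- eBayes(lmFit(x, design))
            write.table(fit$p.value[,2], commandArgs(TRUE)[2], col.names=FALSE,
                        row.names=FALSE)
            """
        )
        out = tmp_path / "p.txt"
        subprocess.run(
            ["Rscript", str(script), str(tmp_path / "x.tsv"), str(out)], check=True
        )
        p_limma = np.loadtxt(out)
        is_a = np.array([True] * 5 + [False] * 5)
        _, _, p_ours, _, _ = dx.moderated_ttest(x, is_a)
        assert np.allclose(p_ours, p_limma, rtol=1e-4, atol=1e-12)


def bh_oracle(p):
    """Independent hand-coded Benjamini-Hochberg step-up with monotone completion."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


class TestAdjustPvalues:
    def test_single_p_unchanged(self):
        assert np.allclose(dx.adjust_pvalues([0.03]), [0.03])

    def test_hand_step_up_example(self):
        assert np.allclose(
            dx.adjust_pvalues([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_equal_stay_equal(self):
        out = dx.adjust_pvalues([0.2, 0.2, 0.2])
        assert np.allclose(out, 0.2)

    def test_empty(self):
        assert dx.adjust_pvalues(np.array([])).size == 0

    def test_matches_step_up_oracle_on_random_vectors(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            p = rng.random(int(rng.integers(1, 51)))
            assert np.allclose(dx.adjust_pvalues(p), bh_oracle(p))

    def test_padj_at_least_pvalue(self):
        rng = np.random.default_rng(7)
        p = rng.random(200)
        assert (dx.adjust_pvalues(p) >= p - 1e-12).all()


class TestSelectSignificant:
    @pytest.mark.parametrize(
        "padj,lfc,kept",
        [(0.01, 2.0, True), (0.01, 0.5, False), (0.06, 3.0, False), (0.01, -2.0, True)],
    )
    def test_threshold_logic(self, padj, lfc, kept):
        df = pd.DataFrame({"log2FC": [lfc], "pvalue": [padj], "padj": [padj]})
        out = dx.select_significant(df)
        assert (len(out) == 1) == kept
        if kept:
            assert out["direction"].iloc[0] == ("up" if lfc > 0 else "down")


class TestTypeIControl:
    def test_null_matrix_calibration(self):
        rng = np.random.default_rng(8)
        counts = rng.poisson(100, size=(1000, 16)).astype(float)
        M = _matrix(counts, 8, 8)
        welch = dx.differential_test(M, method="welch")
        frac_raw = (welch["pvalue"] < 0.05).mean()
        sigma = np.sqrt(0.05 * 0.95 / 1000)
        assert abs(frac_raw - 0.05) < 3 * sigma
        for method in ("welch", "moderated"):
            de = dx.differential_test(M, method=method)
            padj = dx.adjust_pvalues(de["pvalue"].to_numpy())
            assert (padj < 0.05).mean() <= 0.05
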