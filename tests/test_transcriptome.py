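"""Expression normalization, percentile transform and technical QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from scmtseq.transcriptome import (
    ercc_concordance,
    filter_and_normalize,
    library_qc,
    merge_split_concordance,
    pca_scores,
    percentile_transform,
    quantile_normalize,
    rpkm,
)


def _mat(data, cells=None):
    df = pd.DataFrame(data)
    df.index = [f"g{i}" for i in range(len(df))]
    if cells is not None:
        df.columns = cells
    elif not isinstance(data, dict):
        df.columns = [f"c{j}" for j in range(df.shape[1])]
    return df


class TestRpkm:
    def test_closed_form(self):
        counts = _mat({"a": [10, 0, 7]}, ["a"])
        lengths = pd.Series([1000, 500, 3500], index=counts.index)
        libs = pd.Series([1e6], index=["a"])
        out = rpkm(counts, lengths, libs)
        assert out.iloc[0, 0] == pytest.approx(10.0)
        assert out.iloc[1, 0] == 0.0
        counts2 = _mat({"a": [7]}, ["a"])
        out2 = rpkm(counts2, pd.Series([3500], index=["g0"]),
                    pd.Series([2e6], index=["a"]))
        assert out2.iloc[0, 0] == pytest.approx(1.0)

    def test_linear_in_counts_inverse_in_length_and_libsize(self, rng):
        counts = _mat(rng.integers(0, 100, size=(20, 3)))
        lengths = pd.Series(rng.integers(200, 5000, 20), index=counts.index)
        libs = pd.Series(rng.integers(10**5, 10**7, 3), index=counts.columns)
        base = rpkm(counts, lengths, libs)
        assert np.allclose(rpkm(counts * 3, lengths, libs), base * 3)
        assert np.allclose(rpkm(counts, lengths * 2, libs), base / 2)
        assert np.allclose(rpkm(counts, lengths, libs * 4), base / 4)

    def test_rejects_bad_denominators(self):
        counts = _mat({"a": [1]}, ["a"])
        with pytest.raises(ValueError):
            rpkm(counts, pd.Series([0], index=["g0"]), pd.Series([1e6], index=["a"]))
        with pytest.raises(ValueError):
            rpkm(counts, pd.Series([100], index=["g0"]), pd.Series([0], index=["a"]))


class TestFilterAndNormalize:
    def test_filter_threshold(self):
        mat = _mat({"a": [0.04, 0.15], "b": [0.06, 0.25]})
        out = filter_and_normalize(mat, min_mean_rpkm=0.1)
        assert list(out.index) == ["g1"]

    def test_identical_columns_unchanged(self):
        col = [5.0, 1.0, 3.0, 2.0]
        mat = _mat({"a": col, "b": col})
        out = filter_and_normalize(mat, min_mean_rpkm=0.0)
        assert np.allclose(out, mat)

    def test_columns_share_sorted_values(self, rng):
        mat = _mat(rng.gamma(2, 5, size=(200, 6)))
        out = filter_and_normalize(mat)
        ref = np.sort(out.iloc[:, 0].to_numpy())
        for j in range(1, out.shape[1]):
            assert np.allclose(np.sort(out.iloc[:, j].to_numpy()), ref)

    def test_ties_get_mean_of_spanned_ranks(self):
        # column a has a tie; its two tied entries must share one value
        mat = _mat({"a": [1.0, 1.0, 9.0], "b": [2.0, 4.0, 6.0]})
        out = quantile_normalize(mat)
        assert out.loc["g0", "a"] == out.loc["g1", "a"]
        # tied pair takes the mean of rank-1 and rank-2 means: (1.5 + 2.5)/2
        assert out.loc["g0", "a"] == pytest.approx(2.0)

    def test_all_filtered_is_error(self):
        with pytest.raises(ValueError, match="all genes"):
            filter_and_normalize(_mat({"a": [0.01], "b": [0.02]}), 0.1)


class TestPercentile:
    def test_examples(self):
        assert np.allclose(percentile_transform([5, 1, 3]),
                           [100, 100 / 3, 200 / 3], atol=0.01)
        assert np.allclose(percentile_transform([2, 2]), [75, 75])

    @pytest.mark.parametrize("n", [1, 4, 9])
    def test_constant_vector_closed_form(self, n):
        out = percentile_transform(np.full(n, 3.3))
        assert np.allclose(out, 100 * (n + 1) / (2 * n))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            percentile_transform([])

    @given(st.lists(st.integers(-5000, 5000), min_size=2, max_size=30,
                    unique=True))
    def test_invariant_under_monotone_transform(self, values):
        v = np.asarray(values, dtype=float) / 100.0
        base = percentile_transform(v)
        assert np.allclose(percentile_transform(3 * v + 7), base)
        assert np.allclose(percentile_transform(np.exp(v / 25)), base)


class TestLibraryQC:
    def test_failure_reasons(self, rng):
        mat = _mat(rng.gamma(2, 5, size=(5000, 3)))
        mat.iloc[3000:, 2] = 0.0  # cell c2 has <3000 genes above gate
        aligned = pd.Series([0.15, 0.5, 0.5], index=mat.columns)
        qc = library_qc(aligned, mat)
        assert not qc.loc["c0", "pass"] and "alignment" in qc.loc["c0", "failure_reasons"]
        assert qc.loc["c1", "pass"] and qc.loc["c1", "failure_reasons"] == ""
        assert not qc.loc["c2", "pass"]
        assert "gene coverage" in qc.loc["c2", "failure_reasons"]
        # pass <=> no failure reasons
        assert (qc["pass"] == (qc["failure_reasons"] == "")).all()


class TestErcc:
    def test_identical_and_anticorrelated(self):
        col = [1.0, 5.0, 3.0, 8.0]
        mat = _mat({"a": col, "b": col})
        corr, min_r = ercc_concordance(mat)
        assert min_r == pytest.approx(1.0)
        anti = [-x + 2 * np.mean(col) for x in col]
        corr2, min_r2 = ercc_concordance(_mat({"a": col, "b": anti}))
        assert min_r2 == pytest.approx(-1.0)

    def test_zero_variance_column_reported_missing(self):
        mat = _mat({"a": [1.0, 2.0, 3.0], "b": [4.0, 4.0, 4.0]})
        corr, _ = ercc_concordance(mat)
        assert np.isnan(corr.loc["a", "b"])

    def test_planted_common_signal_recovered(self, rng):
        signal = rng.lognormal(2, 1.5, size=60)
        cols = {f"c{i}": signal * rng.lognormal(0, 0.1, size=60) for i in range(3)}
        corr, min_r = ercc_concordance(_mat(cols))
        # log-normal multiplicative noise sigma=0.1 keeps Pearson high
        assert min_r > 0.85


class TestPca:
    def test_collinear_data(self):
        t = np.linspace(0, 1, 6)
        mat = _mat({f"c{i}": [2 * t[i], -t[i], 3 * t[i]] for i in range(6)})
        scores, evr = pca_scores(mat, 2)
        assert evr[0] == pytest.approx(1.0)
        assert list(evr) == sorted(evr, reverse=True)

    def test_duplicated_cell_gets_identical_scores(self, rng):
        mat = _mat(rng.normal(size=(30, 4)))
        mat["dup"] = mat["c0"]
        scores, _ = pca_scores(mat, 2)
        assert np.allclose(scores.loc["c0"], scores.loc["dup"])

    def test_isotropic_two_d(self, rng):
        mat = _mat(rng.normal(size=(2, 4000)))
        _, evr = pca_scores(mat, 2)
        assert np.allclose(evr, [0.5, 0.5], atol=0.05)

    def test_bad_component_count(self, rng):
        with pytest.raises(ValueError):
            pca_scores(_mat(rng.normal(size=(5, 3))), 0)


class TestMergeSplit:
    def test_identical_pairs(self, rng):
        base = rng.gamma(2, 5, size=(100, 2))
        mat = _mat(np.hstack([base, base]), ["p1a", "p2a", "p1b", "p2b"])
        labels = pd.Series({"p1a": 1, "p1b": 1, "p2a": 2, "p2b": 2})
        out = merge_split_concordance(labels, mat)
        assert np.allclose(out["within_r"], 1.0)

    def test_within_exceeds_between_for_shared_pair_signal(self, rng):
        hits = 0
        for _ in range(20):
            pairs = {}
            for p in range(3):
                sig = rng.lognormal(1, 1, size=200)
                for rep in "ab":
                    pairs[f"p{p}{rep}"] = sig * rng.lognormal(0, 0.3, size=200)
            mat = _mat(pairs)
            labels = pd.Series({c: c[:2] for c in mat.columns})
            out = merge_split_concordance(labels, mat)
            hits += int(out["within_gt_between"].all())
        assert hits >= 19

    def test_degenerate_identical_columns(self, rng):
        col = rng.gamma(2, 5, size=50)
        mat = _mat({c: col for c in ["x1", "x2", "y1", "y2"]})
        labels = pd.Series({"x1": "x", "x2": "x", "y1": "y", "y2": "y"})
        out = merge_split_concordance(labels, mat)
        assert np.allclose(out["within_r"], out["between_r"])

    def test_unpaired_label_rejected(self, rng):
        mat = _mat(rng.normal(size=(10, 3)))
        labels = pd.Series({"c0": 1, "c1": 1, "c2": 2})
        with pytest.raises(ValueError, match="exactly twice"):
            merge_split_concordance(labels, mat)
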