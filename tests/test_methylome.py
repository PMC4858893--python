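"""CpG call parsing, conversion QC, feature aggregation and the
variable-site screen."""

import numpy as np
import pandas as pd
import pytest

from scmtseq.annotation import GENE_COLUMNS, GenomeAnnotation
from scmtseq.methylome import (
    CallParseError,
    annotate_sites,
    conversion_rate,
    enrichment,
    feature_methylation,
    levels_matrix,
    load_cpg_calls,
    site_filter,
    variance_screen,
    variable_sites,
    write_cpg_calls,
)


# ----------------------------------------------------------------------
# I/O

class TestCallIO:
    def test_round_trip_both_dialects(self, toy_calls, tmp_path):
        for dialect in ("bedgraph", "cgmap"):
            p = tmp_path / f"x.{dialect}"
            write_cpg_calls(toy_calls, p, dialect)
            back = load_cpg_calls(p)  # auto-sniffed
            assert np.array_equal(back["pos"], toy_calls["pos"])
            assert np.array_equal(back["meth"], toy_calls["meth"])
            assert np.array_equal(back["total"], toy_calls["total"])

    def test_dialects_encode_identical_data(self, toy_calls, tmp_path):
        write_cpg_calls(toy_calls, tmp_path / "a.bg", "bedgraph")
        write_cpg_calls(toy_calls, tmp_path / "a.cgmap", "cgmap")
        a = load_cpg_calls(tmp_path / "a.bg", "bedgraph")
        b = load_cpg_calls(tmp_path / "a.cgmap", "cgmap")
        pd.testing.assert_frame_equal(a, b)

    def test_meth_exceeding_total_rejected_with_line_number(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("chr1\t5\t6\t1.0\t2\t4\nchr1\t9\t10\t1.0\t5\t3\n")
        with pytest.raises(CallParseError, match="lines 2"):
            load_cpg_calls(p)

    def test_well_formed_file(self, tmp_path):
        p = tmp_path / "ok.tsv"
        p.write_text("chr1\t5\t6\t0.5\t2\t4\nchr1\t9\t10\t1.0\t3\t3\n"
                     "chr2\t1\t2\t0.0\t0\t7\n")
        assert len(load_cpg_calls(p)) == 3

    def test_unknown_dialect(self, toy_calls, tmp_path):
        p = tmp_path / "x.tsv"
        write_cpg_calls(toy_calls, p)
        with pytest.raises(CallParseError, match="dialect"):
            load_cpg_calls(p, dialect="wig")


# ----------------------------------------------------------------------
# QC

def test_conversion_rate_examples():
    def tab(m, t, n=1):
        return pd.DataFrame({"chrom": "L", "pos": range(n),
                             "meth": [m] * n, "total": [t] * n})
    assert conversion_rate(tab(6, 1000)) == pytest.approx(0.994)
    assert conversion_rate(tab(0, 50)) == 1.0
    assert conversion_rate(tab(7, 7)) == 0.0
    with pytest.raises(ValueError):
        conversion_rate(pd.DataFrame({"chrom": [], "pos": [], "meth": [],
                                      "total": []}))


def test_site_filter(toy_calls):
    depths = pd.DataFrame({"chrom": "c", "pos": range(4), "meth": 0,
                           "total": [1, 4, 5, 9]})
    assert len(site_filter(depths, 5)) == 2
    pd.testing.assert_frame_equal(site_filter(depths, 1), depths)
    empty = depths.iloc[:0]
    assert len(site_filter(empty, 3)) == 0
    with pytest.raises(ValueError):
        site_filter(depths, 0)


# ----------------------------------------------------------------------
# feature aggregation on a hand-built annotation

@pytest.fixture
def tiny_annotation():
    genes = pd.DataFrame([
        # plus-strand gene: TSS 1000, promoter [500, 1000)
        ("gplus", "chr1", 1000, 3000, "+", "1000,2600", "1400,3000", "non-CGI"),
        # minus-strand gene: TSS 9999 (end-1), promoter [10000, 10500)
        ("gminus", "chr1", 8000, 10000, "-", "8000,9600", "8400,10000", "CGI"),
    ], columns=GENE_COLUMNS)
    cgi = pd.DataFrame({"chrom": ["chr1"], "start": [10000], "end": [10500]})
    return GenomeAnnotation({"chr1": 20000}, genes, cgi)


def _cells(rows):
    df = pd.DataFrame(rows, columns=["chrom", "pos", "meth", "total"])
    df["level"] = df["meth"] / df["total"]
    return {"cellA": df}


class TestFeatureMethylation:
    def test_promoter_mean_of_site_levels(self, tiny_annotation):
        rows = [("chr1", 600 + 10 * i, m, 5)
                for i, m in enumerate([0, 0, 5, 5, 5])]
        mat = feature_methylation(_cells(rows), tiny_annotation, "promoter",
                                  min_depth=1)
        assert mat.values.loc["gplus", "cellA"] == pytest.approx(0.6)

    def test_promoter_needs_min_sites(self, tiny_annotation):
        rows = [("chr1", 600 + 10 * i, 5, 5) for i in range(4)]
        mat = feature_methylation(_cells(rows), tiny_annotation, "promoter",
                                  min_depth=1)
        assert np.isnan(mat.values.loc["gplus", "cellA"])
        assert mat.n_sites.loc["gplus", "cellA"] == 4

    def test_minus_strand_promoter_window(self, tiny_annotation):
        # gminus TSS at 9999 -> promoter [10000, 10500)
        inside = [("chr1", 10100 + 3 * i, 5, 5) for i in range(5)]
        outside = [("chr1", 9900, 0, 5)]
        mat = feature_methylation(_cells(inside + outside), tiny_annotation,
                                  "promoter", min_depth=1)
        assert mat.values.loc["gminus", "cellA"] == pytest.approx(1.0)
        assert mat.n_sites.loc["gminus", "cellA"] == 5

    def test_genebody_span_rule(self, tiny_annotation):
        narrow = [("chr1", 1100 + i * 40, 5, 5) for i in range(8)]  # span 280
        mat = feature_methylation(_cells(narrow), tiny_annotation, "genebody",
                                  min_depth=1)
        assert np.isnan(mat.values.loc["gplus", "cellA"])
        wide = [("chr1", 1100 + i * 200, 5, 5) for i in range(8)]   # span 1400
        mat2 = feature_methylation(_cells(wide), tiny_annotation, "genebody",
                                   min_depth=1)
        assert mat2.values.loc["gplus", "cellA"] == pytest.approx(1.0)

    def test_depth_gate_applies_before_counting(self, tiny_annotation):
        rows = [("chr1", 600 + 10 * i, 2, 2) for i in range(5)]
        mat = feature_methylation(_cells(rows), tiny_annotation, "promoter",
                                  min_depth=5)
        assert np.isnan(mat.values.loc["gplus", "cellA"])

    def test_site_fraction_mode(self, tiny_annotation):
        rows = [("chr1", 600 + 10 * i, m, 10)
                for i, m in enumerate([0, 2, 5, 9, 10])]  # levels >= .5: 3 of 5
        mat = feature_methylation(_cells(rows), tiny_annotation, "promoter",
                                  min_depth=1, site_fraction=True)
        assert mat.values.loc["gplus", "cellA"] == pytest.approx(0.6)

    def test_invariant_to_site_order_and_file_split(self, tiny_annotation, rng):
        rows = [("chr1", int(p), int(m), 5) for p, m in
                zip(rng.choice(np.arange(500, 1000), 12, replace=False),
                    rng.integers(0, 6, 12))]
        shuffled = list(rows)
        rng.shuffle(shuffled)
        a = feature_methylation(_cells(rows), tiny_annotation, "promoter",
                                min_depth=1)
        b = feature_methylation(_cells(shuffled), tiny_annotation, "promoter",
                                min_depth=1)
        assert a.values.loc["gplus", "cellA"] == b.values.loc["gplus", "cellA"]


# ----------------------------------------------------------------------
# variance screen

class TestVarianceScreen:
    def test_constant_site_never_significant(self, rng):
        levels = pd.DataFrame(rng.uniform(0.3, 0.7, size=(40, 10)))
        levels.iloc[0] = 0.5
        out = variance_screen(levels, min_cells=2, fdr=0.01)
        assert out.iloc[0]["variance"] == 0
        assert out.iloc[0]["p"] == pytest.approx(1.0)
        assert not out.iloc[0]["significant"]

    def test_refuses_unstable_null(self):
        levels = pd.DataFrame(np.random.default_rng(0).uniform(size=(5, 6)))
        with pytest.raises(ValueError, match="unstable"):
            variance_screen(levels)

    def test_min_cells_coverage_gate(self, rng):
        levels = pd.DataFrame(rng.uniform(size=(30, 10)))
        levels.iloc[:15, 4:] = np.nan  # first 15 rows covered in only 4 cells
        out = variance_screen(levels, min_cells=5)
        assert len(out) == 15

    def test_null_pvalues_approximately_uniform(self, rng):
        from scipy.stats import kstest
        levels = pd.DataFrame(rng.normal(0.5, 0.1, size=(2000, 15)))
        out = variance_screen(levels, min_cells=8)
        stat = kstest(out["p"], "uniform").statistic
        assert stat < 0.05

    def test_default_min_cells_majority(self, small_dataset):
        res = variable_sites(small_dataset.calls_by_cell)
        # 8 cells -> default gate floor(8/2)+1 = 5
        assert int(res["n_cells"].min()) >= 5
        assert ((res["q"] >= 0) & (res["q"] <= 1)).all()


# ----------------------------------------------------------------------
# site annotation and enrichment

class TestAnnotateSites:
    def test_precedence(self, tiny_annotation):
        sites = pd.DataFrame({
            "chrom": ["chr1"] * 5,
            "pos": [10100,   # CGI overlapping promoter -> CGI promoter
                    700,     # non-CGI promoter
                    1100,    # exon of gplus
                    1500,    # intron of gplus
                    19000],  # intergenic
        })
        cls = annotate_sites(sites, tiny_annotation)
        assert cls.tolist() == ["CGI promoter", "non-CGI promoter",
                                "exon", "intron", "intergenic"]

    def test_classes_partition_all_sites(self, small_dataset):
        calls = small_dataset.calls_by_cell["cell01"]
        cls = annotate_sites(calls, small_dataset.reference.annotation)
        assert cls.notna().all()


class TestEnrichment:
    def test_hand_computed_two_class_case(self):
        obs = pd.Series({"A": 360, "B": 640})
        bg = pd.Series({"A": 100, "B": 900})
        out = enrichment(obs, bg)
        assert out.loc["A", "fold"] == pytest.approx(3.6)
        assert out.loc["A", "p"] < 1e-8
        assert out["observed"].sum() == 1000

    def test_matching_proportions_fold_one(self):
        obs = pd.Series({"A": 10, "B": 90})
        bg = pd.Series({"A": 100, "B": 900})
        out = enrichment(obs, bg)
        assert out.loc["A", "fold"] == pytest.approx(1.0)
        assert out.loc["A", "p"] > 0.5

    def test_zero_observed_depletion(self):
        obs = pd.Series({"A": 0, "B": 100})
        bg = pd.Series({"A": 500, "B": 500})
        out = enrichment(obs, bg)
        assert out.loc["A", "fold"] == 0.0
        assert out.loc["A", "p"] < 1e-8

    def test_class_missing_from_background_skipped(self, caplog):
        obs = pd.Series({"A": 5, "Z": 5})
        bg = pd.Series({"A": 50})
        with caplog.at_level("WARNING"):
            out = enrichment(obs, bg)
        assert "Z" not in out.index
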