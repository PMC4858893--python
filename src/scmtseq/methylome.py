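"""Per-cell CpG methylation calls: I/O, QC, aggregation and the
variable-site screen.

A call table holds one row per CpG site with methylated and total read
counts; the site methylation level is beta = m/t.  Feature aggregation
follows the promoter (500 bp 5' of the TSS, >=5 sites detected) and gene
body (TSS-TES, detected CpG span >=0.5 kb) rules.  Cross-cell variability
is screened with a variance test against the pooled null variance of all
tested sites (the variance-ratio statistic referred to a chi-square upper
tail), with Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import GenomeAnnotation, intervals_by_chrom, points_in_intervals

logger = logging.getLogger(__name__)

CALL_COLUMNS = ["chrom", "pos", "meth", "total"]

# precedence order for genomic annotation of CpG sites
SITE_CLASSES = [
    "CGI promoter", "non-CGI promoter", "CGI", "exon", "intron", "intergenic",
]


class CallParseError(ValueError):
    """Raised when a methylation-call file contains invalid rows."""


# ----------------------------------------------------------------------
# I/O: bedGraph-with-counts and CGmap-like dialects

def load_cpg_calls(path, dialect: str = "auto") -> pd.DataFrame:
    """Read a per-cell CpG call table.

    Two TSV dialects are supported and yield identical tables:

    - ``bedgraph``: ``chrom  pos0  pos1  level  meth_reads  total_reads``
      (0-based half-open coordinates);
    - ``cgmap``: ``chrom  pos1  context  level  meth_reads  total_reads``
      (1-based position, context string such as ``CG``).

    ``dialect="auto"`` sniffs the third column (integer -> bedgraph).
    Rows with meth_reads > total_reads are rejected with an error naming
    their line numbers.
    """
    raw = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if raw.shape[1] != 6:
        raise CallParseError(f"{path}: expected 6 columns, got {raw.shape[1]}")
    if dialect == "auto":
        dialect = "bedgraph" if raw.iloc[0, 2].lstrip("-").isdigit() else "cgmap"
    try:
        if dialect == "bedgraph":
            df = pd.DataFrame({
                "chrom": raw[0],
                "pos": raw[1].astype(int),
                "meth": raw[4].astype(int),
                "total": raw[5].astype(int),
            })
        elif dialect == "cgmap":
            df = pd.DataFrame({
                "chrom": raw[0],
                "pos": raw[1].astype(int) - 1,
                "meth": raw[4].astype(int),
                "total": raw[5].astype(int),
            })
        else:
            raise CallParseError(f"unknown dialect {dialect!r}")
    except ValueError as exc:  # non-integer field
        raise CallParseError(f"{path}: malformed row ({exc})") from exc
    bad = df.index[(df["meth"] > df["total"]) | (df["total"] < 1) | (df["meth"] < 0)]
    if len(bad):
        lines = ", ".join(str(i + 1) for i in bad[:10])
        raise CallParseError(
            f"{path}: {len(bad)} rows with meth > total or total < 1 (lines {lines})"
        )
    df["level"] = df["meth"] / df["total"]
    return df


def write_cpg_calls(calls: pd.DataFrame, path, dialect: str = "bedgraph") -> None:
    level = calls["meth"] / calls["total"]
    if dialect == "bedgraph":
        out = pd.DataFrame({
            0: calls["chrom"], 1: calls["pos"], 2: calls["pos"] + 1,
            3: level.round(6), 4: calls["meth"], 5: calls["total"],
        })
    elif dialect == "cgmap":
        out = pd.DataFrame({
            0: calls["chrom"], 1: calls["pos"] + 1, 2: "CG",
            3: level.round(6), 4: calls["meth"], 5: calls["total"],
        })
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    out.to_csv(path, sep="\t", index=False, header=False)


# ----------------------------------------------------------------------
# QC and filtering

def conversion_rate(lambda_calls: pd.DataFrame) -> float:
    """Bisulfite conversion rate from the unmethylated lambda spike-in.

    Lambda DNA carries no CpG methylation, so every methylated call is a
    conversion failure: rate = 1 - sum(m) / sum(t).
    """
    total = int(lambda_calls["total"].sum())
    if total == 0:
        raise ValueError("no lambda cytosine observations")
    return 1.0 - float(lambda_calls["meth"].sum()) / total


def site_filter(calls: pd.DataFrame, min_depth: int = 1) -> pd.DataFrame:
    """Keep sites covered by at least ``min_depth`` reads."""
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    return calls[calls["total"] >= min_depth].reset_index(drop=True)


# ----------------------------------------------------------------------
# feature-level aggregation

@dataclass
class MethFeatureMatrix:
    """Features x cells mean methylation with coverage companions.

    ``values`` is NaN where the feature's coverage rule failed in that
    cell; ``n_sites`` and ``span_bp`` record the qualifying evidence.
    """

    values: pd.DataFrame
    n_sites: pd.DataFrame
    span_bp: pd.DataFrame
    kind: str = "promoter"

    def feature_ids(self) -> list[str]:
        return [f"{self.kind}:{g}" for g in self.values.index]


def _aggregate_cell(calls: pd.DataFrame, windows: pd.DataFrame,
                    site_fraction: bool) -> pd.DataFrame:
    """Per-gene mean level, site count and detected-CpG span for one cell."""
    rows = []
    by_chrom = {
        str(c): sub.sort_values("pos")[["pos", "level"]].to_numpy()
        for c, sub in calls.groupby("chrom")
    }
    for gene_id, chrom, start, end in windows.itertuples(index=False):
        arr = by_chrom.get(str(chrom))
        if arr is None:
            continue
        lo = np.searchsorted(arr[:, 0], start, side="left")
        hi = np.searchsorted(arr[:, 0], end, side="left")
        if hi <= lo:
            continue
        levels = arr[lo:hi, 1]
        if site_fraction:
            value = float(np.mean(levels >= 0.5))
        else:
            value = float(levels.mean())
        rows.append((gene_id, value, hi - lo, int(arr[hi - 1, 0] - arr[lo, 0])))
    return pd.DataFrame(rows, columns=["gene_id", "value", "n_sites", "span"])


def feature_methylation(
    calls_by_cell: dict[str, pd.DataFrame],
    annotation: GenomeAnnotation,
    kind: str = "promoter",
    min_sites: int = 5,
    min_span_bp: int = 500,
    min_depth: int = 5,
    site_fraction: bool = False,
    strict_site_count: bool = False,
) -> MethFeatureMatrix:
    """Mean methylation per promoter or gene body, per cell.

    Promoter entries require at least ``min_sites`` detected CpGs
    (strictly more with ``strict_site_count``); gene-body entries require
    the detected CpGs to span at least ``min_span_bp``.  Values are the
    unweighted mean of site levels, or with ``site_fraction`` the fraction
    of sites with level >= 0.5.
    """
    if kind == "promoter":
        windows = annotation.promoter_windows()
    elif kind == "genebody":
        windows = annotation.gene_bodies()
    else:
        raise ValueError(f"unknown feature kind {kind!r}")
    genes = list(windows["gene_id"])
    cells = list(calls_by_cell)
    values = pd.DataFrame(np.nan, index=genes, columns=cells)
    n_sites = pd.DataFrame(0, index=genes, columns=cells)
    span = pd.DataFrame(0, index=genes, columns=cells)
    for cell, calls in calls_by_cell.items():
        usable = site_filter(calls, min_depth) if min_depth > 1 else calls
        agg = _aggregate_cell(usable, windows, site_fraction)
        if agg.empty:
            continue
        agg = agg.set_index("gene_id")
        n_sites.loc[agg.index, cell] = agg["n_sites"]
        span.loc[agg.index, cell] = agg["span"]
        if kind == "promoter":
            gate = agg["n_sites"] > min_sites if strict_site_count \
                else agg["n_sites"] >= min_sites
        else:
            gate = agg["span"] >= min_span_bp
        ok = agg.index[gate]
        values.loc[ok, cell] = agg.loc[ok, "value"]
    return MethFeatureMatrix(values, n_sites, span, kind=kind)


# ----------------------------------------------------------------------
# cross-cell variable-site screen

def levels_matrix(calls_by_cell: dict[str, pd.DataFrame],
                  min_depth: int = 1) -> pd.DataFrame:
    """Sites x cells matrix of beta levels (NaN where uncovered)."""
    cols = {}
    for cell, calls in calls_by_cell.items():
        usable = site_filter(calls, min_depth) if min_depth > 1 else calls
        cols[cell] = usable.set_index(["chrom", "pos"])["level"]
    return pd.DataFrame(cols)


def variance_screen(levels: pd.DataFrame, min_cells: int = 2,
                    fdr: float = 0.05) -> pd.DataFrame:
    """Variance test of each row against the pooled variance of all rows.

    The null variance sigma0^2 is the mean of per-row sample variances
    over all tested rows; the statistic (n_i - 1) s_i^2 / sigma0^2 is
    referred to the upper tail of chi-square with n_i - 1 degrees of
    freedom (the pooled variance is treated as known), followed by
    Benjamini-Hochberg correction across all tested rows.
    """
    if min_cells < 2:
        raise ValueError("min_cells must be >= 2")
    n = levels.notna().sum(axis=1)
    tested = levels[n >= min_cells]
    if len(tested) < 10:
        raise ValueError(
            f"only {len(tested)} rows covered in >= {min_cells} cells; "
            "the pooled null variance is unstable below 10"
        )
    ni = tested.notna().sum(axis=1).to_numpy()
    s2 = tested.var(axis=1, ddof=1).to_numpy()
    sigma0 = float(np.mean(s2))
    if sigma0 <= 0:
        pvals = np.ones(len(tested))
        statistic = np.zeros(len(tested))
    else:
        statistic = (ni - 1) * s2 / sigma0
        pvals = stats.chi2.sf(statistic, df=ni - 1)
    qvals = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame({
        "n_cells": ni, "variance": s2, "statistic": statistic,
        "p": pvals, "q": qvals, "significant": qvals < fdr,
    }, index=tested.index)


def variable_sites(calls_by_cell: dict[str, pd.DataFrame],
                   min_cells: int | None = None, fdr: float = 0.01,
                   min_depth: int = 1) -> pd.DataFrame:
    """Significantly variable CpG sites across cells (FDR-controlled).

    Default ``min_cells`` is floor(N/2) + 1, i.e. coverage in more than
    half of the cells.
    """
    levels = levels_matrix(calls_by_cell, min_depth=min_depth)
    if min_cells is None:
        min_cells = len(calls_by_cell) // 2 + 1
    return variance_screen(levels, min_cells=min_cells, fdr=fdr)


# ----------------------------------------------------------------------
# genomic annotation of sites and class enrichment

def annotate_sites(sites: pd.DataFrame, annotation: GenomeAnnotation
                   ) -> pd.Series:
    """Assign each (chrom, pos) site a genomic class.

    Precedence: CGI promoter > non-CGI promoter > CGI > exon > intron >
    intergenic.  A promoter window is CGI-class when it overlaps a CpG
    island.
    """
    chroms = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()
    prom = annotation.promoter_windows()
    classes = annotation.promoter_classes()
    prom_cls = prom.merge(
        classes.rename("cls"), left_on="gene_id", right_index=True
    )
    masks = {
        "CGI promoter": points_in_intervals(
            chroms, pos, intervals_by_chrom(prom_cls[prom_cls["cls"] == "CGI"])),
        "non-CGI promoter": points_in_intervals(
            chroms, pos, intervals_by_chrom(prom_cls[prom_cls["cls"] == "non-CGI"])),
        "CGI": points_in_intervals(chroms, pos, intervals_by_chrom(annotation.cgi)),
        "exon": points_in_intervals(
            chroms, pos, intervals_by_chrom(annotation.exon_blocks())),
        "intron": points_in_intervals(
            chroms, pos, intervals_by_chrom(annotation.gene_bodies())),
    }
    out = np.full(len(sites), "intergenic", dtype=object)
    assigned = np.zeros(len(sites), dtype=bool)
    for cls in SITE_CLASSES[:-1]:
        hit = masks[cls] & ~assigned
        out[hit] = cls
        assigned |= hit
    return pd.Series(out, index=sites.index, name="site_class")


def enrichment(observed: pd.Series, background: pd.Series) -> pd.DataFrame:
    """Class enrichment of observed sites against a background census.

    For each class the fold is (obs_k / N_obs) / (bg_k / N_bg) and the
    p-value comes from a two-sided exact binomial test of obs_k successes
    in N_obs trials at success probability bg_k / N_bg.
    """
    n_obs = int(observed.sum())
    n_bg = int(background.sum())
    if n_obs == 0 or n_bg == 0:
        raise ValueError("observed and background totals must be positive")
    rows = []
    for cls, obs_k in observed.items():
        bg_k = background.get(cls, 0)
        if bg_k == 0:
            logger.warning("class %r absent from background, skipped", cls)
            continue
        p_bg = bg_k / n_bg
        fold = (obs_k / n_obs) / p_bg
        pval = stats.binomtest(int(obs_k), n_obs, p_bg, alternative="two-sided").pvalue
        rows.append({
            "class": cls, "observed": int(obs_k), "background": int(bg_k),
            "fold": fold, "p": pval,
        })
    return pd.DataFrame(rows).set_index("class")
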