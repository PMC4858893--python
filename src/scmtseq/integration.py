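"""Methylation-expression integration.

Correlates feature-level methylation with expression percentile rank:
per-cell genome-wide Pearson correlations stratified by CGI vs non-CGI
promoter class, per-gene cross-cell correlations with Fisher-transform
significance, variably methylated feature detection, and the promoter
state / expression-pattern classification of genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .methylome import MethFeatureMatrix, variance_screen

# clamp before atanh so perfectly collinear vectors get a finite z
FISHER_R_CLAMP = 0.999999


def fisher_p(r: float, n: int) -> float:
    """Two-sided p-value for Pearson r via the Fisher z transformation.

    z = atanh(r) * sqrt(n - 3); requires n >= 4 (returns NaN below).
    """
    if n < 4 or not np.isfinite(r):
        return float("nan")
    z = np.arctanh(np.clip(r, -FISHER_R_CLAMP, FISHER_R_CLAMP)) * np.sqrt(n - 3)
    return float(2.0 * stats.norm.sf(abs(z)))


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def per_cell_correlation(
    meth: MethFeatureMatrix | pd.DataFrame,
    expr_percentile: pd.DataFrame,
    strata: pd.Series,
    min_pairs: int = 10,
) -> pd.DataFrame:
    """Per-cell Pearson r between feature methylation and expression
    percentile, within each promoter-class stratum.

    ``strata`` maps gene -> class (e.g. "CGI"/"non-CGI"); the special
    stratum "all" is always reported.  For each cell and stratum the
    correlation runs over genes carrying both a methylation entry and an
    expression value; cells with fewer than ``min_pairs`` such genes, or a
    constant vector, are omitted.
    """
    values = meth.values if isinstance(meth, MethFeatureMatrix) else meth
    shared_genes = values.index.intersection(expr_percentile.index)
    shared_cells = values.columns.intersection(expr_percentile.columns)
    if len(shared_genes) == 0 or len(shared_cells) == 0:
        raise ValueError("no shared gene x cell entries between layers")
    rows = []
    strata = strata.reindex(shared_genes)
    groups = {"all": shared_genes}
    for cls in strata.dropna().unique():
        groups[str(cls)] = shared_genes[(strata == cls).to_numpy()]
    for cell in shared_cells:
        m_col = values.loc[shared_genes, cell]
        e_col = expr_percentile.loc[shared_genes, cell]
        ok = m_col.notna() & e_col.notna()
        for stratum, genes in groups.items():
            sel = ok.reindex(genes, fill_value=False)
            n = int(sel.sum())
            if n < min_pairs:
                continue
            r = _pearson(m_col[genes][sel].to_numpy(dtype=float),
                         e_col[genes][sel].to_numpy(dtype=float))
            if np.isnan(r):
                continue
            rows.append({"cell": cell, "stratum": stratum, "r": r, "n": n})
    return pd.DataFrame(rows, columns=["cell", "stratum", "r", "n"])


def per_gene_correlation(
    meth: MethFeatureMatrix | pd.DataFrame,
    expr: pd.DataFrame,
    min_cells: int = 5,
) -> pd.DataFrame:
    """Cross-cell Pearson r per gene with Fisher-transform p.

    Only genes detected (both layers present) in at least ``min_cells``
    cells are tested; p is reported only when n >= 4 (the Fisher z needs
    n - 3 > 0) and r only when both vectors vary.
    """
    values = meth.values if isinstance(meth, MethFeatureMatrix) else meth
    shared_cells = values.columns.intersection(expr.columns)
    rows = []
    for gene in values.index.intersection(expr.index):
        m = values.loc[gene, shared_cells]
        e = expr.loc[gene, shared_cells]
        ok = m.notna() & e.notna()
        n = int(ok.sum())
        if n < min_cells:
            continue
        r = _pearson(m[ok].to_numpy(dtype=float), e[ok].to_numpy(dtype=float))
        rows.append({"gene": gene, "r": r, "n": n, "p": fisher_p(r, n)})
    return pd.DataFrame(rows, columns=["gene", "r", "n", "p"]).set_index("gene")


def variably_methylated_features(
    meth: MethFeatureMatrix | pd.DataFrame,
    min_cells: int = 5,
    fdr: float = 0.05,
    min_range: float = 0.3,
) -> pd.DataFrame:
    """Features whose cross-cell methylation varies beyond the pooled null.

    A feature is flagged when its cross-cell range reaches ``min_range``
    AND its pooled-variance chi-square test q-value is below ``fdr`` (the
    same machinery as the site-level screen, with the null variance pooled
    over all eligible features).
    """
    values = meth.values if isinstance(meth, MethFeatureMatrix) else meth
    screen = variance_screen(values, min_cells=min_cells, fdr=fdr)
    rng = (values.max(axis=1) - values.min(axis=1)).reindex(screen.index)
    screen = screen.copy()
    screen["range"] = rng
    screen["flagged"] = screen["significant"] & (rng >= min_range)
    return screen


def classify_gene_patterns(
    meth: MethFeatureMatrix | pd.DataFrame,
    expr_percentile: pd.DataFrame,
    min_cells: int = 5,
    hypo_max: float = 0.1,
    hyper_min: float = 0.9,
    dynamic_iqr: float = 25.0,
    fdr: float = 0.05,
    min_range: float = 0.3,
    corr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Joint promoter-state / expression-pattern call per gene.

    Promoter state: "variable" when flagged by the variably-methylated
    screen; otherwise "hypomethylated" (cross-cell mean <= ``hypo_max``),
    "hypermethylated" (mean >= ``hyper_min``) or "intermediate".
    Expression pattern: "dynamic" when the cross-cell IQR of the
    expression percentile exceeds ``dynamic_iqr``, else "stable-high" or
    "stable-low" by median percentile.  The correlation call comes from
    the per-gene Fisher test at ``corr_alpha``.
    """
    values = meth.values if isinstance(meth, MethFeatureMatrix) else meth
    try:
        vm = variably_methylated_features(values, min_cells=min_cells,
                                          fdr=fdr, min_range=min_range)
        variable = set(vm.index[vm["flagged"]])
    except ValueError:
        variable = set()
    corr = per_gene_correlation(values, expr_percentile, min_cells=min_cells)
    rows = []
    shared_cells = values.columns.intersection(expr_percentile.columns)
    for gene in values.index.intersection(expr_percentile.index):
        m = values.loc[gene, shared_cells]
        e = expr_percentile.loc[gene, shared_cells]
        ok = m.notna() & e.notna()
        if int(ok.sum()) < min_cells:
            continue
        mean_m = float(m[ok].mean())
        if gene in variable:
            state = "variable"
        elif mean_m <= hypo_max:
            state = "hypomethylated"
        elif mean_m >= hyper_min:
            state = "hypermethylated"
        else:
            state = "intermediate"
        ev = e[ok].to_numpy(dtype=float)
        iqr = float(np.percentile(ev, 75) - np.percentile(ev, 25))
        if iqr > dynamic_iqr:
            pattern = "dynamic"
        else:
            pattern = "stable-high" if float(np.median(ev)) > 50 else "stable-low"
        call = "none"
        if gene in corr.index:
            r, p = corr.loc[gene, "r"], corr.loc[gene, "p"]
            if np.isfinite(p) and p < corr_alpha and np.isfinite(r):
                call = "negative" if r < 0 else "positive"
        rows.append({
            "gene": gene, "promoter_state": state, "mean_methylation": mean_m,
            "expression_pattern": pattern, "percentile_iqr": iqr,
            "correlation_call": call,
        })
    return pd.DataFrame(rows).set_index("gene")
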