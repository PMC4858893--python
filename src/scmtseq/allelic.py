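"""Allele-specific methylation and expression analysis.

In a diploid single cell a CpG site can only take methylation level 0,
0.5 or 1 when both alleles are observed; allele dropout during library
preparation collapses observation to one allele and pushes levels to
{0, 1}.  This module quantifies that digitization, classifies RRBS
fragments as mono- or bi-allelic using strain-informative SNPs (bisulfite-
confounded C/T and G/A SNPs removed), compares methylation distributions
between the two fragment classes, and correlates strain-specific
methylation with strain-specific (allelic) expression.

Allele-count tables are long-format with one row per
cell x SNP x fraction: ``cell, snp_id, fraction (DNA|RNA), ref_reads,
alt_reads``; allelic balance is alt / (ref + alt).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .integration import fisher_p

logger = logging.getLogger(__name__)

ALLELIC_COLUMNS = ["cell", "snp_id", "fraction", "ref_reads", "alt_reads"]

# {ref, alt} pairs indistinguishable from bisulfite conversion on one strand
BISULFITE_CONFOUNDED = [frozenset({"C", "T"}), frozenset({"G", "A"})]


def load_snps(vcf_path) -> pd.DataFrame:
    """Read a strain SNP list from a VCF into a table.

    Keeps bi-allelic SNVs only; returns columns ``snp_id, chrom, pos
    (0-based), ref, alt, strain, valid`` with ``valid=True`` (filters are
    applied separately by :func:`filter_snps`).
    """
    import pysam

    rows = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1:
                continue
            strain = ""
            if "STRAIN" in rec.info:
                val = rec.info["STRAIN"]
                strain = val if isinstance(val, str) else val[0]
            rows.append({
                "snp_id": rec.id or f"{rec.chrom}:{rec.pos}",
                "chrom": rec.chrom, "pos": rec.pos - 1,
                "ref": ref, "alt": alt, "strain": strain, "valid": True,
            })
    return pd.DataFrame(rows)


def filter_snps(snps: pd.DataFrame, dna_depth: pd.Series | None = None,
                min_depth: int = 5, strict_ct_only: bool = False) -> pd.DataFrame:
    """Apply bisulfite-compatibility and coverage filters.

    C/T SNPs are indistinguishable from bisulfite conversion on the
    forward strand and are marked invalid; G/A SNPs are the reverse-strand
    image of the same confound and are removed as well unless
    ``strict_ct_only``.  When a per-SNP DNA-fraction depth is supplied,
    SNPs below ``min_depth`` reads are dropped.
    """
    out = snps.copy()
    pairs = [frozenset({r, a}) for r, a in zip(out["ref"], out["alt"])]
    confounded = BISULFITE_CONFOUNDED[:1] if strict_ct_only else BISULFITE_CONFOUNDED
    out["valid"] = [p not in confounded for p in pairs]
    if dna_depth is not None:
        depth = dna_depth.reindex(out["snp_id"]).fillna(0).to_numpy()
        out = out[depth >= min_depth]
    return out.reset_index(drop=True)


def digitization_histogram(calls: pd.DataFrame, tolerance: float = 0.05
                           ) -> pd.Series:
    """Fraction of site levels at the three diploid values {0, 0.5, 1}.

    A site is assigned to the nearest of 0, 0.5, 1 when its level is
    within ``tolerance`` of it, otherwise to "other"; the four fractions
    sum to 1.
    """
    if not 0 <= tolerance < 0.25:
        raise ValueError("tolerance must lie in [0, 0.25)")
    if len(calls) == 0:
        raise ValueError("empty call table")
    beta = (calls["meth"] / calls["total"]).to_numpy(dtype=float)
    out = {}
    assigned = np.zeros(len(beta), dtype=bool)
    for v, label in [(0.0, "0"), (0.5, "0.5"), (1.0, "1")]:
        hit = (np.abs(beta - v) <= tolerance) & ~assigned
        out[label] = float(hit.mean())
        assigned |= hit
    out["other"] = float((~assigned).mean())
    return pd.Series(out, name="fraction")


def classify_fragment_allelicity(snp_counts: pd.DataFrame,
                                 min_site_depth: int = 5) -> str:
    """Mono/bi-allelic call for one fragment in one cell.

    ``snp_counts`` holds the fragment's informative SNPs with ``ref_reads``
    and ``alt_reads``.  The call is "indeterminate" when no SNP reaches
    ``min_site_depth`` total reads; otherwise allele evidence is pooled
    over the qualifying SNPs (they are phased to the two strains, so
    ref-only at one SNP plus alt-only at another still means both alleles
    were sampled): "bi-allelic" when both alleles are observed with >= 1
    read, else "mono-allelic".
    """
    if len(snp_counts) == 0:
        raise ValueError("fragment has no informative SNPs")
    ref = snp_counts["ref_reads"].to_numpy()
    alt = snp_counts["alt_reads"].to_numpy()
    qualifying = (ref + alt) >= min_site_depth
    if not qualifying.any():
        return "indeterminate"
    if ref[qualifying].sum() >= 1 and alt[qualifying].sum() >= 1:
        return "bi-allelic"
    return "mono-allelic"


def classify_fragments(allelic_counts: pd.DataFrame, snp_fragment: pd.Series,
                       min_site_depth: int = 5) -> pd.DataFrame:
    """Fragment allelicity call for every cell x fragment with DNA evidence.

    ``snp_fragment`` maps snp_id -> fragment id; SNPs outside any retained
    fragment should be absent from the map and are skipped.
    """
    dna = allelic_counts[allelic_counts["fraction"] == "DNA"].copy()
    dna["fragment"] = dna["snp_id"].map(snp_fragment)
    dna = dna.dropna(subset=["fragment"])
    rows = []
    for (cell, frag), sub in dna.groupby(["cell", "fragment"]):
        rows.append({
            "cell": cell, "fragment": frag,
            "call": classify_fragment_allelicity(sub, min_site_depth),
        })
    return pd.DataFrame(rows, columns=["cell", "fragment", "call"])


def biallelic_methylation_distribution(
    calls_by_cell: dict[str, pd.DataFrame],
    fragment_calls: pd.DataFrame,
    site_fragment: dict[str, pd.Series] | pd.Series,
    which: str = "bi-allelic",
    tolerance: float = 0.05,
) -> pd.Series:
    """Digitization histogram restricted to sites on fragments of one class.

    ``site_fragment`` maps (chrom, pos) -> fragment id (one shared map or
    one per cell).  ``which`` selects the fragment class, so the bi- and
    mono-allelic distributions of the same dataset can be contrasted.
    """
    wanted = fragment_calls[fragment_calls["call"] == which]
    by_cell = wanted.groupby("cell")["fragment"].apply(set).to_dict()
    parts = []
    for cell, calls in calls_by_cell.items():
        frags = by_cell.get(cell)
        if not frags:
            continue
        fmap = site_fragment[cell] if isinstance(site_fragment, dict) else site_fragment
        frag_of = pd.MultiIndex.from_frame(calls[["chrom", "pos"]]).map(fmap)
        parts.append(calls[pd.Index(frag_of).isin(frags)])
    if not parts:
        raise ValueError(f"no sites on {which} fragments")
    return digitization_histogram(pd.concat(parts, ignore_index=True), tolerance)


def allelic_expression(balances: pd.Series | np.ndarray, rpkm: float) -> float:
    """Strain-specific expression of one gene in one cell.

    The mean allelic balance over the gene's covered SNPs multiplied by
    the gene's overall RPKM; missing (NaN) when no SNP has coverage.
    """
    b = pd.Series(balances).dropna()
    if b.empty:
        return float("nan")
    return float(b.mean() * rpkm)


def allelic_expression_matrix(allelic_counts: pd.DataFrame,
                              snp_gene: pd.Series, rpkm: pd.DataFrame,
                              min_rpkm: float = 5.0) -> pd.DataFrame:
    """Genes x cells strain-specific expression from RNA allele counts.

    Only genes whose overall RPKM reaches ``min_rpkm`` in a given cell are
    evaluated there (allelic balance is unstable for lowly expressed
    genes); RNA SNP observations need >= 1 informative read.
    """
    rna = allelic_counts[allelic_counts["fraction"] == "RNA"].copy()
    rna["gene"] = rna["snp_id"].map(snp_gene)
    rna = rna.dropna(subset=["gene"])
    depth = rna["ref_reads"] + rna["alt_reads"]
    rna = rna[depth >= 1]
    rna["balance"] = rna["alt_reads"] / (rna["ref_reads"] + rna["alt_reads"])
    mean_bal = rna.groupby(["gene", "cell"])["balance"].mean().unstack()
    out = pd.DataFrame(np.nan, index=mean_bal.index, columns=rpkm.columns)
    for gene in mean_bal.index:
        if gene not in rpkm.index:
            continue
        for cell in mean_bal.columns:
            bal = mean_bal.loc[gene, cell]
            r = rpkm.loc[gene, cell]
            if np.isfinite(bal) and r >= min_rpkm:
                out.loc[gene, cell] = bal * r
    return out


def allele_specific_methylation(
    calls_by_cell: dict[str, pd.DataFrame],
    fragment_calls: pd.DataFrame,
    fragment_allele: pd.DataFrame,
    site_fragment: pd.Series,
    fragment_gene: pd.Series,
    allele: str = "alt",
) -> pd.DataFrame:
    """Genes x cells mean beta over sites on fragments assigned to one allele.

    ``fragment_allele`` gives per cell x fragment the observed allele
    ("ref"/"alt", from the dominant SNP allele); only mono-allelic
    fragments carry an unambiguous assignment.
    """
    assign = fragment_calls.merge(fragment_allele, on=["cell", "fragment"])
    assign = assign[(assign["call"] == "mono-allelic") & (assign["allele"] == allele)]
    chosen = assign.groupby("cell")["fragment"].apply(set).to_dict()
    acc: dict[str, dict[str, list[float]]] = {}
    for cell, calls in calls_by_cell.items():
        frags = chosen.get(cell)
        if not frags:
            continue
        frag_of = pd.Series(
            pd.MultiIndex.from_frame(calls[["chrom", "pos"]]).map(site_fragment),
            index=calls.index,
        )
        sub = calls[frag_of.isin(frags)]
        genes = frag_of[sub.index].map(fragment_gene)
        for gene, grp in sub.groupby(genes.to_numpy()):
            acc.setdefault(str(gene), {}).setdefault(cell, []).extend(
                (grp["meth"] / grp["total"]).tolist())
    cells = list(calls_by_cell)
    out = pd.DataFrame(np.nan, index=sorted(acc), columns=cells)
    for gene, per_cell in acc.items():
        for cell, vals in per_cell.items():
            out.loc[gene, cell] = float(np.mean(vals))
    return out


def allelic_correlation(meth_per_cell: pd.Series, expr_per_cell: pd.Series,
                        min_cells: int = 5) -> dict:
    """Pearson r + Fisher p between allele-specific methylation and
    allelic expression across cells; missing when fewer than ``min_cells``
    paired cells or a constant vector."""
    m = pd.Series(meth_per_cell).astype(float)
    e = pd.Series(expr_per_cell).astype(float)
    ok = m.notna() & e.notna()
    n = int(ok.sum())
    if n < min_cells:
        return {"r": float("nan"), "n": n, "p": float("nan")}
    x, y = m[ok].to_numpy(), e[ok].to_numpy()
    if x.std() == 0 or y.std() == 0:
        return {"r": float("nan"), "n": n, "p": float("nan")}
    r = float(np.corrcoef(x, y)[0, 1])
    return {"r": r, "n": n, "p": fisher_p(r, n)}
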