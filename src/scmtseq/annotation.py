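"""Genome annotation container and coordinate helpers.

All coordinates are 0-based, half-open throughout the package; any 1-based
input dialect is converted at the parser boundary. The promoter window is
the 500 bp immediately 5' of the transcription start site (TSS),
strand-aware: for a plus-strand gene with TSS t it is [t-500, t); for a
minus-strand gene with TSS t it is [t+1, t+501).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

PROMOTER_SIZE = 500

GENE_COLUMNS = [
    "gene_id", "chrom", "start", "end", "strand",
    "exon_starts", "exon_ends", "promoter_class",
]


@dataclass
class GenomeAnnotation:
    """Coordinate frame for all feature aggregation.

    Attributes
    ----------
    chrom_sizes
        Mapping chromosome name -> length in bp.
    genes
        One row per gene: ``gene_id, chrom, start, end, strand,
        exon_starts, exon_ends, promoter_class``.  ``start``/``end`` span
        the gene body (TSS to TES in genomic order); ``exon_starts`` /
        ``exon_ends`` are comma-joined 0-based half-open blocks;
        ``promoter_class`` is ``"CGI"`` / ``"non-CGI"`` or empty.
    cgi
        CpG-island intervals: ``chrom, start, end``.
    fasta_path
        Optional path of the genome FASTA the annotation refers to.
    """

    chrom_sizes: dict[str, int]
    genes: pd.DataFrame
    cgi: pd.DataFrame
    fasta_path: Path | None = None

    def __post_init__(self) -> None:
        missing = [c for c in GENE_COLUMNS if c not in self.genes.columns]
        if missing:
            raise ValueError(f"gene table missing columns: {missing}")
        bad = ~self.genes["strand"].isin(["+", "-"])
        if bad.any():
            raise ValueError("gene strands must be '+' or '-'")

    # ------------------------------------------------------------------
    @property
    def tss(self) -> pd.Series:
        """TSS coordinate per gene (position of the first transcribed base)."""
        g = self.genes
        return pd.Series(
            np.where(g["strand"].values == "+", g["start"].values, g["end"].values - 1),
            index=g.index, name="tss",
        )

    def promoter_windows(self, size: int = PROMOTER_SIZE) -> pd.DataFrame:
        """Strand-aware promoter intervals, ``size`` bp 5' of the TSS."""
        g = self.genes
        t = self.tss.values
        plus = g["strand"].values == "+"
        start = np.where(plus, t - size, t + 1)
        end = np.where(plus, t, t + 1 + size)
        return pd.DataFrame({
            "gene_id": g["gene_id"].values,
            "chrom": g["chrom"].values,
            "start": np.maximum(start, 0),
            "end": end,
        })

    def gene_bodies(self) -> pd.DataFrame:
        """TSS-to-TES intervals (the full gene span, introns included)."""
        g = self.genes
        return g[["gene_id", "chrom", "start", "end"]].copy()

    def exon_blocks(self) -> pd.DataFrame:
        """Exploded exon intervals: one row per exon block."""
        rows = []
        for gid, chrom, starts, ends in zip(
            self.genes["gene_id"], self.genes["chrom"],
            self.genes["exon_starts"], self.genes["exon_ends"],
        ):
            for s, e in zip(_split_ints(starts), _split_ints(ends)):
                rows.append((gid, chrom, s, e))
        return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])

    def exon_lengths(self) -> pd.Series:
        """Summed exon length per gene (bp), the RPKM length denominator."""
        out = {}
        for gid, starts, ends in zip(
            self.genes["gene_id"], self.genes["exon_starts"], self.genes["exon_ends"]
        ):
            out[gid] = sum(e - s for s, e in zip(_split_ints(starts), _split_ints(ends)))
        return pd.Series(out, name="exon_length")

    def promoter_classes(self) -> pd.Series:
        """CGI / non-CGI promoter class per gene.

        Uses the stored class when present, otherwise derives it from
        overlap of the promoter window with a CGI interval.
        """
        stored = self.genes.set_index("gene_id")["promoter_class"]
        if stored.isin(["CGI", "non-CGI"]).all():
            return stored
        prom = self.promoter_windows()
        cgi_by_chrom = intervals_by_chrom(self.cgi)
        hit = overlaps_any(prom, cgi_by_chrom)
        return pd.Series(
            np.where(hit, "CGI", "non-CGI"), index=prom["gene_id"].values,
            name="promoter_class",
        )

    # ------------------------------------------------------------------
    def write(self, gene_path: Path | str, cgi_path: Path | str) -> None:
        """Write the gene table (8-column TSV) and the CGI track (BED6)."""
        self.genes[GENE_COLUMNS].to_csv(gene_path, sep="\t", index=False)
        cgi = self.cgi.copy()
        cgi["name"] = [f"CGI_{i}" for i in range(len(cgi))]
        cgi["score"] = 0
        cgi["strand"] = "."
        cgi.to_csv(cgi_path, sep="\t", index=False, header=False)


def read_annotation(
    gene_path: Path | str, cgi_path: Path | str,
    chrom_sizes: dict[str, int] | None = None,
) -> GenomeAnnotation:
    genes = pd.read_csv(gene_path, sep="\t", dtype={"exon_starts": str, "exon_ends": str})
    genes["promoter_class"] = genes["promoter_class"].fillna("")
    cgi = pd.read_csv(
        cgi_path, sep="\t", header=None, usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
    )
    if chrom_sizes is None:
        chrom_sizes = {
            c: int(genes.loc[genes["chrom"] == c, "end"].max()) + PROMOTER_SIZE + 1
            for c in genes["chrom"].unique()
        }
    return GenomeAnnotation(chrom_sizes, genes, cgi)


# ----------------------------------------------------------------------
# interval utilities shared across modules

def _split_ints(s: str) -> list[int]:
    return [int(x) for x in str(s).rstrip(",").split(",") if x != ""]


def intervals_by_chrom(df: pd.DataFrame) -> dict[str, np.ndarray]:
    """Merge intervals per chromosome into sorted disjoint (n, 2) arrays."""
    out: dict[str, np.ndarray] = {}
    for chrom, sub in df.groupby("chrom"):
        iv = sub[["start", "end"]].to_numpy()
        iv = iv[np.argsort(iv[:, 0])]
        merged: list[list[int]] = []
        for s, e in iv:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[str(chrom)] = np.asarray(merged)
    return out


def points_in_intervals(
    chroms: np.ndarray, pos: np.ndarray, ivs: dict[str, np.ndarray]
) -> np.ndarray:
    """Boolean membership of each (chrom, pos) point in merged intervals."""
    hit = np.zeros(len(pos), dtype=bool)
    for chrom in np.unique(chroms):
        iv = ivs.get(str(chrom))
        if iv is None or len(iv) == 0:
            continue
        mask = chroms == chrom
        p = pos[mask]
        idx = np.searchsorted(iv[:, 0], p, side="right") - 1
        ok = idx >= 0
        ok[ok] &= p[ok] < iv[idx[ok], 1]
        hit[mask] = ok
    return hit


def overlaps_any(features: pd.DataFrame, ivs: dict[str, np.ndarray]) -> np.ndarray:
    """Per feature row, does [start, end) overlap any merged interval by >=1 bp."""
    hit = np.zeros(len(features), dtype=bool)
    chroms = features["chrom"].to_numpy()
    starts = features["start"].to_numpy()
    ends = features["end"].to_numpy()
    for chrom in np.unique(chroms):
        iv = ivs.get(str(chrom))
        if iv is None or len(iv) == 0:
            continue
        mask = chroms == chrom
        s, e = starts[mask], ends[mask]
        # disjoint sorted intervals: overlap iff the first interval ending
        # after feature start begins before feature end
        i = np.searchsorted(iv[:, 1], s, side="right")
        ok = i < len(iv)
        ok[ok] &= iv[i[ok], 0] < e[ok]
        hit[mask] = ok
    return hit
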