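"""In silico restriction digestion and RRBS fragment analysis.

RRBS enriches CpG-dense sequence by MspI digestion (recognition site CCGG,
cut C^CGG) followed by size selection of the genomic inserts.  This module
predicts the fragment set a digest produces, applies a size-selection
window, and asks which annotated features (typically CpG islands) can be
covered by at least one retained fragment.  It also provides the two
coverage diagnostics used for single-cell libraries: the distribution of
features shared between randomly drawn cell subsets, and a read-subsampling
saturation curve for CpG site counts.

MspI is modeled as a blunt cut at offset 1 on the forward strand;
end-repair/fill-in chemistry is not modeled.  The default genomic-insert
window is 40-220 bp (standard RRBS).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MSPI_SITE = "CCGG"
MSPI_CUT_OFFSET = 1
DEFAULT_MIN_INSERT = 40
DEFAULT_MAX_INSERT = 220


@dataclass
class FragmentSet:
    """Digestion fragments as sorted, disjoint half-open intervals.

    ``fragments`` has columns ``chrom, start, end``; before size selection
    the fragments of each chromosome tile it exactly.
    """

    fragments: pd.DataFrame
    enzyme: str = "MspI"
    site: str = MSPI_SITE
    cut_offset: int = MSPI_CUT_OFFSET

    def __len__(self) -> int:
        return len(self.fragments)

    def lengths(self) -> np.ndarray:
        return (self.fragments["end"] - self.fragments["start"]).to_numpy()

    def intervals(self, chrom: str) -> np.ndarray:
        sub = self.fragments[self.fragments["chrom"] == chrom]
        return sub[["start", "end"]].to_numpy()

    def to_bed(self, path) -> None:
        bed = self.fragments.copy()
        bed["name"] = [f"frag_{i}" for i in range(len(bed))]
        bed.to_csv(path, sep="\t", index=False, header=False)


@dataclass
class CoverageReport:
    """How many features overlap at least one retained fragment."""

    n_features_total: int
    n_features_covered: int

    @property
    def fraction_covered(self) -> float:
        if self.n_features_total == 0:
            return float("nan")
        return self.n_features_covered / self.n_features_total


def _find_cuts(seq: str, site: str, cut_offset: int) -> list[int]:
    cuts = []
    i = seq.find(site)
    while i != -1:
        cuts.append(i + cut_offset)
        i = seq.find(site, i + 1)
    return cuts


def digest(
    sequences: dict[str, str] | str,
    site: str = MSPI_SITE,
    cut_offset: int = MSPI_CUT_OFFSET,
    enzyme: str = "MspI",
) -> FragmentSet:
    """Cut each sequence at every occurrence of ``site``.

    Cut positions are ``{i + cut_offset}`` over all occurrences of the
    recognition motif (matched case-insensitively and literally, so
    ambiguity codes never match); fragments are the half-open intervals
    between consecutive cuts, including both sequence ends.

    Parameters
    ----------
    sequences
        Mapping chromosome name -> sequence, or a single bare sequence
        (reported under chromosome name ``"seq"``).
    """
    if isinstance(sequences, str):
        sequences = {"seq": sequences}
    if not 0 <= cut_offset <= len(site):
        raise ValueError(f"cut_offset {cut_offset} outside [0, {len(site)}]")
    rows = []
    for chrom, seq in sequences.items():
        if len(seq) == 0:
            raise ValueError(f"empty sequence for {chrom!r}")
        s = seq.upper()
        cuts = _find_cuts(s, site.upper(), cut_offset)
        bounds = [0] + [c for c in cuts if 0 < c < len(s)] + [len(s)]
        for a, b in zip(bounds[:-1], bounds[1:]):
            if a < b:
                rows.append((chrom, a, b))
    frags = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return FragmentSet(frags, enzyme=enzyme, site=site.upper(), cut_offset=cut_offset)


def size_select(frags: FragmentSet, min_len: int = DEFAULT_MIN_INSERT,
                max_len: int = DEFAULT_MAX_INSERT) -> FragmentSet:
    """Keep fragments with ``min_len <= length <= max_len``, order preserved."""
    if min_len < 0 or max_len < 0:
        raise ValueError("size-selection bounds must be non-negative")
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    lengths = frags.lengths()
    keep = (lengths >= min_len) & (lengths <= max_len)
    return FragmentSet(
        frags.fragments[keep].reset_index(drop=True),
        enzyme=frags.enzyme, site=frags.site, cut_offset=frags.cut_offset,
    )


def feature_coverage(frags: FragmentSet, features: pd.DataFrame) -> CoverageReport:
    """Count features overlapping >=1 fragment by >=1 bp.

    ``features`` needs columns ``chrom, start, end`` (half-open, same
    coordinate frame as the fragments).  Features on chromosomes absent
    from the fragment set count as uncovered (with a logged warning).
    """
    frag_chroms = set(frags.fragments["chrom"].unique())
    missing = set(features["chrom"].unique()) - frag_chroms
    if missing:
        logger.warning(
            "feature chromosomes absent from fragment set, counted uncovered: %s",
            sorted(missing),
        )
    n_cov = 0
    for chrom, sub in features.groupby("chrom"):
        iv = frags.intervals(str(chrom))
        if len(iv) == 0:
            continue
        starts, ends = iv[:, 0], iv[:, 1]
        # fragments are sorted & disjoint: feature [s, e) is covered iff the
        # first fragment ending after s starts before e
        i = np.searchsorted(ends, sub["start"].to_numpy(), side="right")
        ok = i < len(iv)
        ok[ok] &= starts[i[ok]] < sub["end"].to_numpy()[ok]
        n_cov += int(ok.sum())
    return CoverageReport(n_features_total=len(features), n_features_covered=n_cov)


def shared_feature_distribution(
    per_cell_covered: list[set],
    k: int,
    n_draws: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Sizes of the intersection of the covered-feature sets of ``k`` cells.

    Each draw samples ``k`` distinct cells uniformly without replacement
    and records the size of the intersection of their covered sets.  With
    ``k`` equal to the number of cells every draw is the same deterministic
    value.
    """
    n_cells = len(per_cell_covered)
    if not 1 <= k <= n_cells:
        raise ValueError(f"k={k} outside [1, {n_cells}]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if k == n_cells:
        common = set.intersection(*map(set, per_cell_covered)) if n_cells else set()
        return np.full(n_draws, len(common), dtype=int)
    out = np.empty(n_draws, dtype=int)
    for i in range(n_draws):
        idx = rng.choice(n_cells, size=k, replace=False)
        inter = set(per_cell_covered[idx[0]])
        for j in idx[1:]:
            inter &= per_cell_covered[j]
            if not inter:
                break
        out[i] = len(inter)
    return out


def saturation_curve(
    calls: pd.DataFrame,
    fractions: list[float],
    min_depths: list[int],
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """CpG site counts after binomial read subsampling.

    At read fraction ``f`` each site's subsampled depth is drawn as
    Binomial(total_reads, f); the site is counted when the subsampled
    depth reaches ``min_depth``.  Fraction 1.0 reproduces the observed
    counts exactly.  Returns a table ``(fraction, min_depth, n_sites)``.
    """
    if any(f <= 0 or f > 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    if list(fractions) != sorted(fractions):
        raise ValueError("fractions must be sorted ascending")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    totals = calls["total"].to_numpy()
    rows = []
    for f in fractions:
        sub = totals if f == 1.0 else rng.binomial(totals, f)
        for d in min_depths:
            rows.append((f, d, int((sub >= d).sum())))
    return pd.DataFrame(rows, columns=["fraction", "min_depth", "n_sites"])
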