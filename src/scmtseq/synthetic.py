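"""Synthetic paired single-cell methylome + transcriptome generator.

Builds a fully specified toy genome (CCGG sites and CG-dense islands
planted at known positions), a gene annotation, and a 15-cell paired
dataset with known ground truth, so that every downstream stage of the
pipeline can be exercised against planted effects:

- CGI promoters are constitutively hypomethylated; non-CGI promoters are
  variably methylated with a planted negative coupling to expression;
- gene-body methylation of CGI-promoter genes carries a planted positive
  coupling to expression;
- per-cell, per-allele binary methylation states are observed through
  fragment-level allele dropout (sites on one RRBS fragment share the
  sampled allele) and finite read depth, digitizing levels toward
  {0, 0.5, 1};
- a fraction of reads from unmethylated cytosines report methylated
  (bisulfite conversion failure), and an unmethylated lambda spike-in is
  emitted to measure it;
- strain SNPs inside RRBS fragments carry allele-of-origin information for
  DNA and RNA fractions, with a planted positive coupling between
  alternate-allele gene-body methylation and alternate-allele expression
  in a subset of genes.

The generator's defaults are the study conditions; the coupling slopes
below were calibrated once so the *observed* downstream correlations land
on the configured targets under the default measurement model (mean depth
8, 90 % allele dropout) and are not tuning knobs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GENE_COLUMNS, GenomeAnnotation
from .rrbs import DEFAULT_MAX_INSERT, DEFAULT_MIN_INSERT, FragmentSet, digest, size_select
from .transcriptome import ExpressionMatrix, rpkm as rpkm_layer_fn

# expression log2 standard deviations (gene-level biological / cell-level)
GENE_LOGEXPR_SD = 1.0
CELL_LOGEXPR_SD = 0.6
# calibrated latent slopes mapping the unit meth axis to log2 expression at
# the default coupling targets (-0.22 promoter / +0.13 gene body)
CAL_SLOPE_PROMOTER = 0.30
CAL_SLOPE_GENEBODY = 0.10
CAL_TARGET_PROMOTER = -0.22
CAL_TARGET_GENEBODY = 0.13

LAMBDA_CHROM = "lambda"
LAMBDA_LENGTH = 48_502
INFINITE_DEPTH_READS = 10_000


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic dataset.

    Couplings are Pearson targets for the downstream per-cell
    methylation-expression correlations; ``allele_dropout`` is the
    probability that a captured RRBS fragment samples only one allele;
    ``conversion_failure`` is the per-read rate at which an unmethylated
    cytosine is reported methylated.
    """

    n_cells: int = 15
    n_genes: int = 2000
    frac_cgi_promoter: float = 0.5
    promoter_expr_coupling_noncgi: float = -0.22
    genebody_expr_coupling_cgi: float = 0.13
    allele_dropout: float = 0.9
    conversion_failure: float = 0.005
    mean_depth: float = 8.0
    n_snps: int = 300
    seed: int = 0
    # genome layout
    n_chroms: int = 2
    chrom_length: int = 5_000_000
    # observation model
    fragment_capture: float = 0.55
    infinite_depth: bool = False
    # planted feature classes
    n_variable_promoters: int = 30
    n_variable_genebodies: int = 60
    n_hyper_high: int = 10
    n_allelic_genes: int = 20
    n_ercc: int = 40
    n_lambda_sites: int = 2000
    frac_silent: float = 0.08
    frac_narrow_body: float = 0.05
    # fraction of promoters left without MspI sites: their CGIs cannot be
    # covered by any retained fragment (in real genomes ~9 % of CGIs fall
    # outside the RRBS insert window)
    frac_promoter_no_msp: float = 0.09

    def __post_init__(self) -> None:
        for name in ("frac_cgi_promoter", "allele_dropout", "conversion_failure",
                     "fragment_capture", "frac_silent", "frac_narrow_body"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not -1.0 <= self.promoter_expr_coupling_noncgi <= 0.0:
            raise ValueError("promoter coupling target must lie in [-1, 0]")
        if not 0.0 <= self.genebody_expr_coupling_cgi <= 1.0:
            raise ValueError("gene-body coupling target must lie in [0, 1]")
        if self.n_cells < 2:
            raise ValueError("n_cells must be >= 2")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")


@dataclass
class GroundTruth:
    """Planted effects the pipeline is expected to recover."""

    promoter_class: pd.Series
    expression_mu: pd.Series
    variable_promoters: list[str]
    variable_genebodies: list[str]
    hyper_high_genes: list[str]
    allelic_genes: list[str]
    allelic_state: pd.DataFrame           # allelic genes x cells, planted 0/1
    variable_sites: pd.DataFrame          # chrom, pos of CpGs in variable promoters
    correlated_genes: dict[str, list[str]]


@dataclass
class SyntheticReference:
    """Toy genome + annotation with all planted CCGG and CpG positions."""

    config: SyntheticConfig
    annotation: GenomeAnnotation
    sequences: dict[str, str]

    def write(self, outdir: Path | str) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fasta = outdir / "genome.fa"
        with open(fasta, "w") as fh:
            for chrom, seq in self.sequences.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")
        genes = outdir / "genes.tsv"
        cgi = outdir / "cgi.bed"
        self.annotation.write(genes, cgi)
        self.annotation.fasta_path = fasta
        return {"fasta": fasta, "genes": genes, "cgi": cgi}


@dataclass
class SyntheticDataset:
    """The full paired dataset plus the maps tests and the allelic stage need."""

    config: SyntheticConfig
    reference: SyntheticReference
    calls_by_cell: dict[str, pd.DataFrame]
    expression: ExpressionMatrix
    allelic_counts: pd.DataFrame
    lambda_calls: pd.DataFrame
    truth: GroundTruth
    fragments: FragmentSet
    site_fragment: pd.Series              # (chrom, pos) -> fragment id
    snps: pd.DataFrame
    snp_fragment: pd.Series
    snp_gene: pd.Series
    fragment_gene: pd.Series

    @property
    def cells(self) -> list[str]:
        return list(self.calls_by_cell)


# ----------------------------------------------------------------------
# reference genome

def generate_reference(config: SyntheticConfig) -> SyntheticReference:
    """Build the toy genome and annotation.

    Genes are laid out in equal slots; each promoter is tiled with 8-20
    CpGs and flanked by CCGG sites spaced so that the MspI fragments
    covering it fall inside the default 40-220 bp insert window.  CGI
    intervals coincide exactly with the promoter windows of CGI-class
    genes.  The background sequence contains no CG dinucleotide, so every
    CpG and every MspI site in the genome is planted and known.
    """
    rng = np.random.default_rng([config.seed, 0])
    genome_bp = config.n_chroms * config.chrom_length
    slot = genome_bp // config.n_genes
    margin = 600
    body_max = slot - 500 - 2 * margin
    if body_max < 600:
        raise ValueError(
            f"cannot place {config.n_genes} genes on {genome_bp} bp "
            f"({slot} bp per gene; need >= {500 + 2 * margin + 600})"
        )
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    seqs = {}
    for chrom in chrom_names:
        arr = rng.choice(np.frombuffer(b"ACGT", dtype="S1"),
                         size=config.chrom_length)
        cg = (arr[:-1] == b"C") & (arr[1:] == b"G")
        arr[1:][cg] = b"A"          # background is CG-free; all CpGs are planted
        seqs[chrom] = arr

    n_cgi = int(round(config.frac_cgi_promoter * config.n_genes))
    classes = np.array(["CGI"] * n_cgi + ["non-CGI"] * (config.n_genes - n_cgi))
    rng.shuffle(classes)

    gene_rows, cgi_rows = [], []
    per_chrom = config.n_genes // config.n_chroms
    narrow = rng.random(config.n_genes) < config.frac_narrow_body
    no_msp = rng.random(config.n_genes) < config.frac_promoter_no_msp
    for g in range(config.n_genes):
        chrom = chrom_names[min(g // per_chrom, config.n_chroms - 1)]
        slot0 = (g % per_chrom) * slot if g // per_chrom < config.n_chroms - 1 \
            else (g - per_chrom * (config.n_chroms - 1)) * slot
        body_len = int(rng.integers(max(600, min(1500, body_max)), body_max + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        a = slot0 + margin
        if strand == "+":
            prom0 = a
            start, end = a + 500, a + 500 + body_len
        else:
            start, end = a, a + body_len
            prom0 = end
        seq = seqs[chrom]

        # MspI sites: promoter tiled every 128 bp, body every 150 bp
        ccgg = [] if no_msp[g] else [prom0 - 24 + 128 * k for k in range(5)]
        ccgg += list(range(start, end - 3, 150)) + [end - 4]
        # intergenic cluster in the slot margin with its own small fragment
        inter0 = slot0 + 60
        ccgg += [inter0, inter0 + 120]
        for q in ccgg:
            seq[q:q + 4] = np.frombuffer(b"CCGG", dtype="S1")
        forbidden = np.zeros(slot + margin, dtype=bool)
        for q in ccgg:
            lo = max(q - slot0 - 2, 0)
            forbidden[lo:q - slot0 + 6] = True

        def plant_cpgs(lo: int, hi: int, n: int, step: int) -> list[int]:
            cand = np.arange(lo, hi - 2, step)
            ok = cand[~forbidden[cand - slot0]]
            take = min(n, len(ok))
            pos = np.sort(rng.choice(ok, size=take, replace=False))
            for p in pos:
                seq[p:p + 2] = np.frombuffer(b"CG", dtype="S1")
                if seq[p - 1] == b"C":
                    seq[p - 1] = b"T"      # avoid creating an accidental CCGG
                if seq[p + 2] == b"G":
                    seq[p + 2] = b"A"
            return list(pos)

        # CGI promoters are CG-dense islands; non-CGI promoters carry 8-20 CpGs
        if classes[g] == "CGI":
            n_prom_cpg = int(rng.integers(20, 41))
            plant_cpgs(prom0 + 4, prom0 + 496, n_prom_cpg, 2)
        else:
            n_prom_cpg = int(rng.integers(8, 21))
            plant_cpgs(prom0 + 4, prom0 + 496, n_prom_cpg, 3)
        n_body_cpg = int(rng.integers(10, 25))
        body_hi = start + 290 if narrow[g] else end - 6
        plant_cpgs(start + 6, body_hi, n_body_cpg, 7)
        plant_cpgs(inter0 + 8, inter0 + 116, 3, 9)

        e_len = max(60, int(0.3 * body_len))
        gene_rows.append({
            "gene_id": f"gene{g:04d}", "chrom": chrom, "start": start,
            "end": end, "strand": strand,
            "exon_starts": f"{start},{end - e_len}",
            "exon_ends": f"{start + e_len},{end}",
            "promoter_class": classes[g],
        })
        if classes[g] == "CGI":
            cgi_rows.append({"chrom": chrom, "start": prom0, "end": prom0 + 500})

    genes = pd.DataFrame(gene_rows, columns=GENE_COLUMNS)
    cgi = pd.DataFrame(cgi_rows, columns=["chrom", "start", "end"])
    annotation = GenomeAnnotation(
        {c: config.chrom_length for c in chrom_names}, genes, cgi)
    sequences = {c: s.tobytes().decode("ascii") for c, s in seqs.items()}
    return SyntheticReference(config, annotation, sequences)


# ----------------------------------------------------------------------
# paired cells

def _scan_cpg_positions(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
    return np.flatnonzero((arr[:-1] == b"C") & (arr[1:] == b"G"))


def simulate_cells(config: SyntheticConfig,
                   reference: SyntheticReference) -> SyntheticDataset:
    """Simulate the paired 15-cell methylome/transcriptome/allelic dataset.

    Every CpG in the genome falling inside a retained MspI fragment is a
    candidate site.  Per cell, each site carries two allelic binary
    states drawn from its gene-region propensity; each captured fragment
    either samples a single allele (probability ``allele_dropout``) or
    both, and reads then report methylation subject to the conversion-
    failure rate.
    """
    rng = np.random.default_rng([config.seed, 1])
    ann = reference.annotation
    genes = ann.genes
    G, C = len(genes), config.n_cells
    cells = [f"cell{c + 1:02d}" for c in range(C)]
    cls = genes["promoter_class"].to_numpy()
    gene_ids = genes["gene_id"].to_numpy()

    # --- retained fragments and site -> fragment assignment
    frags_all = digest(reference.sequences)
    frags = size_select(frags_all, DEFAULT_MIN_INSERT, DEFAULT_MAX_INSERT)
    ftab = frags.fragments
    frag_ids = np.array([f"{c}:{s}-{e}" for c, s, e in
                         ftab.itertuples(index=False)])

    site_rows = []
    for chrom in reference.sequences:
        pos = _scan_cpg_positions(reference.sequences[chrom])
        sub = ftab[ftab["chrom"] == chrom]
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = idx >= 0
        ok[ok] &= pos[ok] < ends[idx[ok]]
        site_rows.append(pd.DataFrame({
            "chrom": chrom, "pos": pos[ok],
            "frag": sub.index.to_numpy()[idx[ok]],
        }))
    sites = pd.concat(site_rows, ignore_index=True)

    # --- region assignment (promoter > gene body > intergenic)
    prom = ann.promoter_windows()
    region = np.full(len(sites), 2, dtype=int)      # 0 prom, 1 body, 2 inter
    gene_of = np.full(len(sites), -1, dtype=int)
    for chrom, sub in sites.groupby("chrom"):
        p = sub["pos"].to_numpy()
        for which, tab in ((0, prom), (1, ann.gene_bodies())):
            t = tab[tab["chrom"] == chrom]
            s_, e_, gidx = (t["start"].to_numpy(), t["end"].to_numpy(),
                            t.index.to_numpy())
            order = np.argsort(s_)
            s_, e_, gidx = s_[order], e_[order], gidx[order]
            j = np.searchsorted(s_, p, side="right") - 1
            hit = (j >= 0)
            hit[hit] &= p[hit] < e_[j[hit]]
            hit &= region[sub.index] == 2
            region[sub.index[hit]] = which
            gene_of[sub.index[hit]] = gidx[j[hit]]
    S = len(sites)

    # --- planted gene classes
    noncgi_idx = np.flatnonzero(cls == "non-CGI")
    cgi_idx = np.flatnonzero(cls == "CGI")
    var_prom = rng.choice(noncgi_idx, size=min(config.n_variable_promoters,
                                               len(noncgi_idx)), replace=False)
    var_body = rng.choice(cgi_idx, size=min(config.n_variable_genebodies,
                                            len(cgi_idx)), replace=False)
    remaining = np.setdiff1d(noncgi_idx, var_prom)
    hyper_high = rng.choice(remaining, size=min(config.n_hyper_high,
                                                len(remaining)), replace=False)
    allelic_pool = np.setdiff1d(np.arange(G), np.concatenate([var_prom, hyper_high]))
    allelic_genes = rng.choice(allelic_pool, size=min(config.n_allelic_genes,
                                                      len(allelic_pool)),
                               replace=False)

    # --- gene-level latents and per-cell propensity matrices
    u = rng.normal(size=G)          # non-CGI promoter methylation axis
    v = rng.normal(size=G)          # CGI gene-body methylation axis
    e = rng.normal(size=G)          # independent expression noise

    p_prom = np.empty((G, C))
    p_prom[cgi_idx] = 0.03
    base_nc = np.clip(0.5 + 0.28 * u[noncgi_idx], 0.03, 0.97)
    p_prom[noncgi_idx] = np.clip(
        base_nc[:, None] + 0.08 * rng.normal(size=(len(noncgi_idx), C)),
        0.02, 0.98)
    p_prom[var_prom] = rng.choice([0.08, 0.92], size=(len(var_prom), C))
    p_prom[hyper_high] = 0.95

    # gene bodies are site-patterned: each body CpG is constitutively
    # methylated (propensity 0.97) or not (0.03), with the methylated-site
    # density b_g varying across genes; the cross-gene density spread, not
    # cell-to-cell fluctuation, carries the gene-body expression coupling.
    body_density = np.empty(G)
    body_density[cgi_idx] = np.clip(0.5 + 0.25 * v[cgi_idx], 0.05, 0.95)
    body_density[noncgi_idx] = np.clip(
        0.88 + 0.05 * rng.normal(size=len(noncgi_idx)), 0.05, 0.97)
    # planted variably methylated gene bodies fluctuate across cells instead
    p_body_var = rng.choice([0.15, 0.85], size=(len(var_body), C))

    w_allelic = rng.integers(0, 2, size=(len(allelic_genes), C))

    # per-site propensities for each allele
    is_prom = region == 0
    is_body = region == 1
    site_state = np.empty(S)
    site_state[is_body] = np.where(
        rng.random(is_body.sum()) < body_density[gene_of[is_body]], 0.97, 0.03)
    inter = region == 2
    site_state[inter] = np.where(rng.random(inter.sum()) < 0.90, 0.97, 0.03)
    p0 = np.where(is_prom[:, None], p_prom[gene_of.clip(0)],
                  site_state[:, None])
    var_body_set = np.isin(gene_of, var_body) & is_body
    vb_pos = {g: i for i, g in enumerate(var_body)}
    for s_i in np.flatnonzero(var_body_set):
        p0[s_i] = p_body_var[vb_pos[gene_of[s_i]]]
    site_dev = 0.03 * rng.normal(size=S)
    p0 = np.clip(p0 + site_dev[:, None], 0.01, 0.99)
    p1 = p0.copy()
    # planted allele-specific gene-body methylation for allelic genes
    allelic_set = set(allelic_genes.tolist())
    body_allelic = np.flatnonzero(
        (region == 1) & np.isin(gene_of, allelic_genes))
    gpos = {g: i for i, g in enumerate(allelic_genes)}
    for s_i in body_allelic:
        p1[s_i] = 0.15 + 0.70 * w_allelic[gpos[gene_of[s_i]]]

    a0 = rng.random((S, C)) < p0
    a1 = rng.random((S, C)) < p1

    # --- fragment capture and allele sampling (shared by DNA sites & SNPs)
    F = len(ftab)
    captured = rng.random((F, C)) < config.fragment_capture
    mono = rng.random((F, C)) < config.allele_dropout
    which_allele = rng.integers(0, 2, size=(F, C))

    frag_idx = sites["frag"].to_numpy()
    cap_s = captured[frag_idx]
    mono_s = mono[frag_idx]
    k_s = which_allele[frag_idx]

    cf = config.conversion_failure
    th0 = np.where(a0, 1.0, cf)
    th1 = np.where(a1, 1.0, cf)
    if config.infinite_depth:
        t = np.full((S, C), INFINITE_DEPTH_READS)
        th_mono = np.where(k_s == 0, th0, th1)
        level = np.where(mono_s, th_mono, 0.5 * (th0 + th1))
        m = np.rint(level * t).astype(int)
    else:
        t = rng.poisson(config.mean_depth, size=(S, C))
        th_mono = np.where(k_s == 0, th0, th1)
        m_mono = rng.binomial(t, th_mono)
        n0 = rng.binomial(t, 0.5)
        m_bi = rng.binomial(n0, th0) + rng.binomial(t - n0, th1)
        m = np.where(mono_s, m_mono, m_bi)
    emit = cap_s & (t > 0)

    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    calls_by_cell = {}
    for c, cell in enumerate(cells):
        sel = emit[:, c]
        df = pd.DataFrame({
            "chrom": chrom_arr[sel], "pos": pos_arr[sel],
            "meth": m[sel, c], "total": t[sel, c],
        })
        df["level"] = df["meth"] / df["total"]
        calls_by_cell[cell] = df

    # --- expression
    slope_p = CAL_SLOPE_PROMOTER * (
        config.promoter_expr_coupling_noncgi / CAL_TARGET_PROMOTER)
    slope_b = CAL_SLOPE_GENEBODY * (
        config.genebody_expr_coupling_cgi / CAL_TARGET_GENEBODY)
    mu = np.where(cls == "CGI", 3.2 + slope_b * v, 3.0 - slope_p * u)
    mu = mu + GENE_LOGEXPR_SD * e * 0.8
    silent = rng.random(G) < config.frac_silent
    silent[np.concatenate([var_prom, var_body, hyper_high, allelic_genes])] = False
    mu[silent] = -4.0
    mu[hyper_high] = 6.0
    mu[allelic_genes] = np.maximum(mu[allelic_genes], 5.0)

    x = mu[:, None] + CELL_LOGEXPR_SD * rng.normal(size=(G, C))
    # dynamic expression of planted variable features follows their
    # per-cell methylation (negative for promoters, positive for bodies)
    x[var_prom] = (mu[var_prom, None]
                   - 2.5 * (p_prom[var_prom] - 0.5)
                   + 0.4 * rng.normal(size=(len(var_prom), C)))
    x[var_body] = (mu[var_body, None]
                   + 2.0 * (p_body_var - 0.5)
                   + 0.4 * rng.normal(size=(len(var_body), C)))
    rpkm_true = np.power(2.0, x)

    exon_len = ann.exon_lengths()
    lib_sizes = pd.Series(rng.integers(1_500_000, 3_000_001, size=C),
                          index=cells, name="lib_size")
    lam = rpkm_true * exon_len.to_numpy()[:, None] * \
        lib_sizes.to_numpy()[None, :] / 1e9
    counts = rng.poisson(lam)

    ercc_ids = [f"ERCC-{i + 1:05d}" for i in range(config.n_ercc)]
    ercc_conc = np.power(2.0, rng.uniform(0, 10, size=config.n_ercc))
    ercc_counts = rng.poisson(
        ercc_conc[:, None] * lib_sizes.to_numpy()[None, :] / 2e6 *
        np.exp(0.1 * rng.normal(size=(config.n_ercc, C))))

    all_ids = list(gene_ids) + ercc_ids
    counts_df = pd.DataFrame(np.vstack([counts, ercc_counts]),
                             index=all_ids, columns=cells)
    lengths = pd.concat([exon_len, pd.Series(1000, index=ercc_ids)])
    rpkm_df = rpkm_layer_fn(counts_df, lengths, lib_sizes)
    cell_meta = pd.DataFrame({
        "aligned_fraction": rng.uniform(0.55, 0.80, size=C),
        "fraction": "cytosol",
        "lib_size": lib_sizes,
    }, index=cells)
    expression = ExpressionMatrix(counts=counts_df, rpkm=rpkm_df,
                                  cell_meta=cell_meta)

    # --- lambda spike-in (fully unmethylated before conversion failure)
    lpos = np.sort(rng.choice(LAMBDA_LENGTH - 2, size=config.n_lambda_sites,
                              replace=False))
    lt = rng.poisson(max(config.mean_depth, 4.0), size=config.n_lambda_sites)
    lt = np.maximum(lt, 1)
    lm = rng.binomial(lt, cf)
    lambda_calls = pd.DataFrame({
        "chrom": LAMBDA_CHROM, "pos": lpos, "meth": lm, "total": lt,
    })
    lambda_calls["level"] = lambda_calls["meth"] / lambda_calls["total"]

    # --- SNPs inside retained gene-body fragments
    body_frag_gene: dict[int, int] = {}
    for s_i in np.flatnonzero(region == 1):
        body_frag_gene.setdefault(int(frag_idx[s_i]), int(gene_of[s_i]))
    frag_gene = pd.Series({frag_ids[f]: gene_ids[g]
                           for f, g in body_frag_gene.items()})
    snp_rows = []
    used_frags: set[int] = set()
    alt_conf = {"C": "T", "T": "C", "G": "A", "A": "G"}
    alt_valid = {"A": ["C", "T"], "T": ["A", "G"], "C": ["A", "G"], "G": ["C", "T"]}

    def add_snp(f: int, force_confounded: bool) -> None:
        row = ftab.loc[f]
        p = int(rng.integers(row["start"] + 2, row["end"] - 2))
        base = reference.sequences[row["chrom"]][p]
        alt = alt_conf[base] if force_confounded else str(rng.choice(alt_valid[base]))
        snp_rows.append({
            "snp_id": f"snp{len(snp_rows):04d}", "chrom": row["chrom"], "pos": p,
            "ref": base, "alt": alt, "strain": "DBA/2J", "valid": True,
            "frag": f, "gene": gene_ids[body_frag_gene[f]],
        })

    gene_frags: dict[int, list[int]] = {}
    for f, g in body_frag_gene.items():
        gene_frags.setdefault(g, []).append(f)
    for g in allelic_genes:
        for f in sorted(gene_frags.get(int(g), []))[:3]:
            add_snp(f, force_confounded=False)
            used_frags.add(f)
    other = np.array(sorted(set(body_frag_gene) - used_frags))
    n_extra = max(config.n_snps - len(snp_rows), 0)
    chosen = rng.choice(other, size=min(n_extra, len(other)), replace=False)
    for i, f in enumerate(chosen):
        add_snp(int(f), force_confounded=(i % 10 < 3))
    snps = pd.DataFrame(snp_rows)
    snp_fragment = pd.Series(frag_ids[snps["frag"].to_numpy()].tolist(),
                             index=snps["snp_id"])
    snp_gene = pd.Series(snps["gene"].to_list(), index=snps["snp_id"])

    # --- allele counts (DNA fraction shares the fragment sampling events)
    allelic_rows = []
    balance = np.full((len(snps), C), 0.5)
    for i, g in enumerate(allelic_genes):
        sel = snps.index[snps["gene"] == gene_ids[g]]
        balance[sel] = 0.25 + 0.5 * w_allelic[i][None, :]
    for j, snp in enumerate(snps.itertuples(index=False)):
        f = snp.frag
        for c, cell in enumerate(cells):
            if captured[f, c]:
                td = int(rng.poisson(config.mean_depth))
                if td > 0:
                    if mono[f, c]:
                        alt_reads = td if which_allele[f, c] == 1 else 0
                    else:
                        alt_reads = int(rng.binomial(td, 0.5))
                    allelic_rows.append((cell, snp.snp_id, "DNA",
                                         td - alt_reads, alt_reads))
            gene_row = all_ids.index(snp.gene)
            depth_rna = rng.poisson(min(float(rpkm_df.iloc[gene_row, c]), 50.0) / 2.0)
            if depth_rna > 0:
                alt_r = int(rng.binomial(depth_rna, balance[j, c]))
                allelic_rows.append((cell, snp.snp_id, "RNA",
                                     depth_rna - alt_r, alt_r))
    allelic_counts = pd.DataFrame(
        allelic_rows, columns=["cell", "snp_id", "fraction",
                               "ref_reads", "alt_reads"])

    site_fragment = pd.Series(
        frag_ids[frag_idx].tolist(),
        index=pd.MultiIndex.from_arrays([chrom_arr, pos_arr]))

    var_site_mask = (region == 0) & np.isin(gene_of, var_prom)
    truth = GroundTruth(
        promoter_class=pd.Series(cls, index=gene_ids),
        expression_mu=pd.Series(mu, index=gene_ids),
        variable_promoters=[gene_ids[i] for i in var_prom],
        variable_genebodies=[gene_ids[i] for i in var_body],
        hyper_high_genes=[gene_ids[i] for i in hyper_high],
        allelic_genes=[gene_ids[i] for i in allelic_genes],
        allelic_state=pd.DataFrame(w_allelic,
                                   index=[gene_ids[i] for i in allelic_genes],
                                   columns=cells),
        variable_sites=pd.DataFrame({"chrom": chrom_arr[var_site_mask],
                                     "pos": pos_arr[var_site_mask]}),
        correlated_genes={
            "negative": [gene_ids[i] for i in var_prom],
            "positive": [gene_ids[i] for i in var_body],
        },
    )
    frags_named = FragmentSet(ftab.assign(fragment_id=frag_ids),
                              enzyme=frags.enzyme, site=frags.site,
                              cut_offset=frags.cut_offset)
    return SyntheticDataset(
        config=config, reference=reference, calls_by_cell=calls_by_cell,
        expression=expression, allelic_counts=allelic_counts,
        lambda_calls=lambda_calls, truth=truth, fragments=frags_named,
        site_fragment=site_fragment, snps=snps, snp_fragment=snp_fragment,
        snp_gene=snp_gene, fragment_gene=frag_gene,
    )


def generate_dataset(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Convenience: reference + cells in one call."""
    config = config or SyntheticConfig()
    return simulate_cells(config, generate_reference(config))


# ----------------------------------------------------------------------
# text serialization of the full dataset

def write_dataset(ds: SyntheticDataset, outdir: Path | str) -> dict[str, Path]:
    """Write the dataset in its external text dialects.

    FASTA + gene TSV + CGI BED for the reference; per-cell methylation
    calls in both bedGraph-with-counts and CGmap-like TSV; counts and RPKM
    matrices; a VCF 4.2 SNP list; long-format allele-count TSV; the
    lambda spike-in call table.
    """
    from .methylome import write_cpg_calls

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = ds.reference.write(outdir)
    meth_dir = outdir / "meth"
    meth_dir.mkdir(exist_ok=True)
    for cell, calls in ds.calls_by_cell.items():
        write_cpg_calls(calls, meth_dir / f"{cell}.bedGraph", "bedgraph")
        write_cpg_calls(calls, meth_dir / f"{cell}.cgmap.tsv", "cgmap")
    ds.expression.counts.to_csv(outdir / "counts.tsv", sep="\t")
    ds.expression.rpkm.to_csv(outdir / "rpkm.tsv", sep="\t")
    ds.expression.cell_meta.to_csv(outdir / "cell_meta.tsv", sep="\t")
    write_cpg_calls(ds.lambda_calls, outdir / "lambda.bedGraph", "bedgraph")
    ds.allelic_counts.to_csv(outdir / "allele_counts.tsv", sep="\t", index=False)
    vcf = outdir / "snps.vcf"
    with open(vcf, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, size in ds.reference.annotation.chrom_sizes.items():
            fh.write(f"##contig=<ID={chrom},length={size}>\n")
        fh.write('##INFO=<ID=STRAIN,Number=1,Type=String,'
                 'Description="Strain carrying the alternate allele">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in ds.snps.sort_values(["chrom", "pos"]).itertuples(index=False):
            fh.write(f"{s.chrom}\t{s.pos + 1}\t{s.snp_id}\t{s.ref}\t{s.alt}"
                     f"\t.\tPASS\tSTRAIN={s.strain}\n")
    paths.update({"counts": outdir / "counts.tsv", "vcf": vcf,
                  "lambda": outdir / "lambda.bedGraph"})
    return paths
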