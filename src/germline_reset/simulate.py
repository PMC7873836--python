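"""Synthetic data with planted ground truth.

The generator builds a toy genome (three autosomes, X and Y) plus single-cell
expression, allelic read counts at X-linked SNVs, and per-sample CpG
methylomes whose statistical structure matches what the downstream analyses
assume:

* sex-structured chrY expression — males express single-copy chrY genes at
  high level; females express them not at all but carry low-level ambient
  signal on multi-copy chrY genes (cross-mapping background), which gives the
  two-pass sex-inference rule something real to do.  Optional "contaminant"
  cells are true females with enough single-copy chrY signal to pass the
  provisional-male threshold while their overall chrY:chrX ratio stays below
  the female range;
* X-dosage structure — X-inactive (XCI) females match male per-gene X output;
  X-reactivated (XCR) females double it; XIST is high in XCI females and
  reduced ~10x upon reactivation; somatic escaper genes are biallelic (2x) in
  every female cell regardless of XCI state;
* allelic structure — XCI cells draw reads from one haplotype (plus a small
  per-read error rate), XCR cells and escaper genes draw binomially from
  both, male cells are monoallelic at every X SNV;
* methylome structure — PGC samples near-completely demethylated (~1%)
  except for planted 800-nt methylation-retaining ("escapee") tiles (~40%),
  which preferentially overlap one designated evolutionarily young repeat
  family at a stated fold over its genome-wide density; somatic samples are
  hypermethylated (~75%) with unmethylated CpG islands (~10%).

Everything is deterministic given a seed, and every generator returns the
planted truth alongside the data so downstream tests are parameter-recovery
tests.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .expression import tpm_from_counts

logger = logging.getLogger("germline_reset")

AUTOSOMES = ("auto1", "auto2", "auto3")
SCALE_SIZES = {"tiny": 1_000_000, "default": 10_000_000}

#: (family, repeat class, mean length bp, elements per bp)
REPEAT_FAMILIES = (
    ("Pre0_SS", "SINE", 250, 8e-5),   # designated "young" family
    ("L1_SS", "LINE", 2500, 4e-5),
    ("LTR1_SS", "LTR", 1200, 3e-5),
    ("MIR_SS", "SINE", 180, 1e-4),
)
YOUNG_FAMILY = "Pre0_SS"

N_GENES_AUTO = 200           # per autosome
N_GENES_X = 32               # besides XIST
N_GENES_Y = 12
N_SINGLE_COPY_Y = 6

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimGenome:
    chrom_sizes: dict[str, int]
    genes: pd.DataFrame          # index gene: chrom, start, end, strand, single_copy_y, tss
    exons: pd.DataFrame          # chrom, start, end, name (gene)
    promoters: pd.DataFrame      # chrom, start, end, name (gene), strand
    cgis: pd.DataFrame
    repeats: pd.DataFrame        # chrom, start, end, name, family
    imprinted: pd.DataFrame
    snvs: pd.DataFrame           # chrom, pos, gene, ref, alt, hap_a_is_ref, validated
    cpg_sites: dict[str, np.ndarray]
    promoter_seqs: dict[str, str]
    promoter_class_truth: pd.Series

    @property
    def x_genes(self) -> pd.Index:
        return self.genes.index[self.genes["chrom"] == "X"]

    def gene_lengths(self) -> pd.Series:
        return self.genes["end"] - self.genes["start"]


@dataclass
class SimTruth:
    """Planted per-cell truth for expression/allelic simulations."""

    cells: pd.DataFrame          # index cell: stage, true_sex, xc_state, contaminant, qc_fail
    escaper_genes: list[str]


@dataclass
class MethTruth:
    """Planted truth for methylome simulations."""

    escapee_tiles: pd.DataFrame  # chrom, start, end, overlaps_young
    young_family: str
    background_young_frac: float
    site_rates: dict[str, dict[str, np.ndarray]]  # sample -> chrom -> per-CpG rate

    def expected_global(self, sample: str) -> float:
        rates = np.concatenate(list(self.site_rates[sample].values()))
        return float(rates.mean())


# ---------------------------------------------------------------------------
# genome


def _place_genes(rng, chrom: str, size: int, n: int, prefix: str,
                 min_len: int = 1500, max_len: int = 3500) -> pd.DataFrame:
    lengths = rng.integers(min_len, max_len + 1, size=n)
    spare = size - int(lengths.sum())
    if spare <= n:
        raise ValueError(f"{chrom}: cannot place {n} non-overlapping genes in {size} bp")
    gaps = np.floor(rng.dirichlet(np.ones(n + 1)) * spare).astype(int)
    starts = np.cumsum(gaps[:-1] + np.concatenate([[0], lengths[:-1]]))
    strands = rng.choice(["+", "-"], size=n)
    names = [f"{prefix}{i + 1:04d}" for i in range(n)]
    df = pd.DataFrame(
        {
            "gene": names,
            "chrom": chrom,
            "start": starts,
            "end": starts + lengths,
            "strand": strands,
        }
    )
    return df


def _gene_exons(rng, gene: pd.Series) -> list[tuple[int, int]]:
    n_exon = int(rng.integers(1, 4))
    if n_exon == 1:
        return [(gene.start, gene.end)]
    length = gene.end - gene.start
    n_seg = 2 * n_exon - 1
    fracs = rng.dirichlet(np.ones(n_seg))
    widths = np.maximum((fracs * (length - 50 * n_seg)).astype(int), 0) + 50
    bounds = gene.start + np.concatenate([[0], np.cumsum(widths)])
    bounds[-1] = gene.end
    return [(int(bounds[i]), int(bounds[i + 1])) for i in range(0, n_seg, 2)]


def _markov_sequences(rng, n: int, length: int, gc: float, cpg_keep: float) -> list[str]:
    """CpG-depleted random sequences: iid bases at the given GC content, then
    each CpG dinucleotide retained with probability ``cpg_keep`` (the G of a
    suppressed CpG is replaced by an A/T)."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seqs = rng.choice(4, size=(n, length), p=p).astype(np.uint8)
    is_cpg = (seqs[:, :-1] == 1) & (seqs[:, 1:] == 2)
    suppress = is_cpg & (rng.random(is_cpg.shape) > cpg_keep)
    repl = rng.choice([0, 3], size=suppress.shape).astype(np.uint8)
    right = seqs[:, 1:]
    right[suppress] = repl[suppress]
    seqs[:, 1:] = right
    return [bytes(_BASES[row]).decode() for row in seqs]


def simulate_genome(seed: int, scale: str = "tiny") -> SimGenome:
    """Deterministically generate the toy genome and all annotations."""
    if scale not in SCALE_SIZES:
        raise ValueError(f"unknown scale {scale!r}; expected one of {sorted(SCALE_SIZES)}")
    size = SCALE_SIZES[scale]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 101]))
    chrom_sizes = {c: size for c in (*AUTOSOMES, "X", "Y")}

    gene_frames = []
    for i, chrom in enumerate(AUTOSOMES):
        gene_frames.append(_place_genes(rng, chrom, size, N_GENES_AUTO, f"A{i + 1}G"))
    gene_frames.append(_place_genes(rng, "X", size, N_GENES_X + 1, "XG"))
    gene_frames.append(_place_genes(rng, "Y", size, N_GENES_Y, "YG"))
    genes = pd.concat(gene_frames, ignore_index=True)

    # rename one X gene to XIST; flag single-copy Y genes
    x_rows = genes.index[genes["chrom"] == "X"]
    xist_row = x_rows[int(rng.integers(len(x_rows)))]
    genes.loc[xist_row, "gene"] = "XIST"
    genes["single_copy_y"] = False
    y_rows = genes.index[genes["chrom"] == "Y"]
    genes.loc[y_rows[:N_SINGLE_COPY_Y], "single_copy_y"] = True
    genes["tss"] = np.where(genes["strand"] == "+", genes["start"], genes["end"] - 1)
    genes = genes.set_index("gene")

    exon_rows = []
    for gene, row in genes.iterrows():
        for s, e in _gene_exons(rng, row):
            exon_rows.append((row.chrom, s, e, gene))
    exons = pd.DataFrame(exon_rows, columns=["chrom", "start", "end", "name"])

    # promoters: -1000/+500 around the TSS, strand-aware
    prom = genes.reset_index()[["gene", "chrom", "tss", "strand"]].copy()
    plus = prom["strand"] == "+"
    prom["start"] = np.where(plus, prom["tss"] - 1000, prom["tss"] - 499)
    prom["end"] = np.where(plus, prom["tss"] + 500, prom["tss"] + 1001)
    prom["start"] = prom["start"].clip(lower=0)
    prom["end"] = prom["end"].clip(upper=size)
    promoters = prom.rename(columns={"gene": "name"})[
        ["chrom", "start", "end", "name", "strand"]
    ]

    # CpG islands at ~15% of promoters (always at HCP-truth genes, below)
    gene_names = genes.index.to_numpy()
    n_cgi = int(round(0.15 * len(gene_names)))
    cgi_genes = rng.choice(gene_names, size=n_cgi, replace=False)
    cgi_rows = []
    for g in cgi_genes:
        t = int(genes.loc[g, "tss"])
        cgi_rows.append((genes.loc[g, "chrom"], max(0, t - 400), min(size, t + 400),
                         f"CGI_{g}"))
    cgis = pd.DataFrame(cgi_rows, columns=["chrom", "start", "end", "name"])

    # repeats: Poisson-placed elements per family per chromosome
    rep_rows = []
    for family, rclass, mean_len, rate in REPEAT_FAMILIES:
        for chrom, csize in chrom_sizes.items():
            count = rng.poisson(rate * csize)
            starts = rng.integers(0, csize, size=count)
            lens = np.maximum(50, rng.normal(mean_len, 0.2 * mean_len, size=count)).astype(int)
            for k, (s, ln) in enumerate(zip(starts, lens)):
                rep_rows.append((chrom, int(s), int(min(csize, s + ln)),
                                 f"{family}_{chrom}_{k}", rclass, family))
    repeats = pd.DataFrame(
        rep_rows, columns=["chrom", "start", "end", "name", "feature_class", "family"]
    )
    repeats = repeats[repeats["end"] > repeats["start"]].reset_index(drop=True)

    # imprinted intervals: five autosomal gene bodies
    auto_genes = genes.index[genes["chrom"].isin(AUTOSOMES)]
    imp_genes = rng.choice(auto_genes.to_numpy(), size=5, replace=False)
    imprinted = pd.DataFrame(
        {
            "chrom": genes.loc[imp_genes, "chrom"].to_numpy(),
            "start": genes.loc[imp_genes, "start"].to_numpy(),
            "end": genes.loc[imp_genes, "end"].to_numpy(),
            "name": [f"IMP{i + 1}" for i in range(5)],
        }
    )

    # X-linked SNVs inside exons of X genes (not XIST), phased, mostly validated
    snv_rows = []
    x_exons = exons[exons["chrom"] == "X"]
    for gene in genes.index[(genes["chrom"] == "X") & (genes.index != "XIST")]:
        gx = x_exons[x_exons["name"] == gene]
        n_snv = 1 + min(2, int(rng.poisson(0.7)))
        for _ in range(n_snv):
            ex = gx.iloc[int(rng.integers(len(gx)))]
            pos = int(rng.integers(ex.start, ex.end))
            ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
            snv_rows.append(("X", pos, gene, ref, alt,
                             bool(rng.random() < 0.5), bool(rng.random() < 0.9)))
    snvs = pd.DataFrame(
        snv_rows,
        columns=["chrom", "pos", "gene", "ref", "alt", "hap_a_is_ref", "validated"],
    ).drop_duplicates(subset=["chrom", "pos"]).reset_index(drop=True)

    # CpG sites: ~70 bp mean spacing genome-wide, dense (~10 bp) inside CGIs
    cpg_sites = {}
    for chrom, csize in chrom_sizes.items():
        n_draw = int(csize / 70 * 1.3) + 100
        gaps = 2 + rng.exponential(68, size=n_draw)
        pos = np.cumsum(gaps).astype(np.int64)
        pos = pos[pos < csize]
        island = cgis[cgis["chrom"] == chrom]
        dense = []
        for _, row in island.iterrows():
            n_sites = max(1, (row.end - row.start) // 25)
            dense.append(row.start + np.sort(rng.choice(
                row.end - row.start, size=n_sites, replace=False)))
        if dense:
            pos = np.concatenate([pos, *dense])
        cpg_sites[chrom] = np.unique(pos)

    # promoter sequences with planted HCP/ICP/LCP composition
    truth_class = pd.Series("ICP", index=genes.index, name="promoter_class")
    truth_class[pd.Index(cgi_genes)] = "HCP"
    non_cgi = genes.index.difference(pd.Index(cgi_genes))
    n_lcp = int(round(0.35 * len(non_cgi)))
    lcp_genes = rng.choice(non_cgi.to_numpy(), size=n_lcp, replace=False)
    truth_class[pd.Index(lcp_genes)] = "LCP"
    params = {"HCP": (0.60, 1.0), "ICP": (0.45, 0.60), "LCP": (0.38, 0.12)}
    promoter_seqs: dict[str, str] = {}
    for cls in ("HCP", "ICP", "LCP"):
        members = truth_class.index[truth_class == cls].to_list()
        gc, keep = params[cls]
        for g, seq in zip(members, _markov_sequences(rng, len(members), 1500, gc, keep)):
            promoter_seqs[g] = seq

    return SimGenome(
        chrom_sizes=chrom_sizes, genes=genes, exons=exons, promoters=promoters,
        cgis=cgis, repeats=repeats, imprinted=imprinted, snvs=snvs,
        cpg_sites=cpg_sites, promoter_seqs=promoter_seqs,
        promoter_class_truth=truth_class,
    )


# ---------------------------------------------------------------------------
# expression


def _nb_counts(rng, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with var = mu + dispersion * mu^2."""
    if dispersion <= 0:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def simulate_expression(
    genome: SimGenome,
    design: list[tuple[str, int, str, str]],
    seed: int,
    *,
    dispersion: float = 0.2,
    qc_fail_frac: float = 0.05,
    contaminant_frac: float = 0.0,
    n_escaper_genes: int = 3,
    xcr_fold: float = 2.0,
    xist_tpm: dict[str, float] | None = None,
):
    """Simulate a TPM matrix for a design of (stage, n_cells, sex, xc_state).

    Returns ``(ExpressionMatrix, cells, SimTruth)`` where ``cells`` carries
    the observable per-cell metadata (stage, mapped_read_count,
    mito_fraction) and the truth records planted sex, XC state, contaminant
    status, QC failures and the escaper gene set.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 202]))
    xist_w = xist_tpm or {"XCI": 200.0, "XCR": 20.0, "male": 20.0}

    for stage, n_cells, sex, xc_state in design:
        if n_cells < 1:
            raise ValueError(f"group {stage}/{sex}: need at least one cell")
        if sex == "M" and xc_state != "male":
            raise ValueError("male cells cannot carry an XCI/XCR state")
        if sex == "F" and xc_state not in ("XCI", "XCR"):
            raise ValueError(f"female cells need xc_state XCI or XCR, got {xc_state!r}")

    genes = genome.genes
    gene_ids = genes.index
    lengths = genome.gene_lengths().to_numpy().astype(float)
    is_y = (genes["chrom"] == "Y").to_numpy()
    is_y_sc = (is_y & genes["single_copy_y"]).to_numpy()
    is_y_mc = is_y & ~is_y_sc
    is_x = (genes["chrom"] == "X").to_numpy()
    is_xist = np.asarray(gene_ids == "XIST")

    # baseline weights shared by all cells (approximate TPM units)
    w = rng.lognormal(np.log(50.0), 1.0, size=len(gene_ids))
    w[is_y_sc] = rng.lognormal(np.log(100.0), 0.5, size=is_y_sc.sum())
    # equalise the mean per-gene X output with the autosomal mean so the
    # X:allA baseline of an inactive-X cell sits at 1 by construction
    # (with only ~30 X genes the lognormal sample mean would otherwise
    # drift by tens of percent from genome to genome)
    is_auto = np.asarray(genes["chrom"].isin(AUTOSOMES))
    x_baseline = is_x & ~is_xist
    w[x_baseline] *= w[is_auto].mean() / w[x_baseline].mean()

    # escaper genes: X-linked, with at least one validated SNV
    snv_genes = set(genome.snvs.loc[genome.snvs["validated"], "gene"])
    candidates = [g for g in gene_ids[is_x & ~is_xist] if g in snv_genes]
    escapers = sorted(
        str(g) for g in rng.choice(
            candidates, size=min(n_escaper_genes, len(candidates)), replace=False)
    )
    is_escaper = np.asarray(gene_ids.isin(escapers))

    cell_rows, mu_cols = [], []
    counter = 0
    for stage, n_cells, sex, xc_state in design:
        n_cont = int(round(contaminant_frac * n_cells)) if sex == "F" else 0
        for i in range(n_cells):
            cell = f"{stage}_{sex}{xc_state if sex == 'F' else ''}_{counter:04d}"
            counter += 1
            contaminant = i < n_cont
            mu = w.copy()
            if sex == "M":
                mu[is_xist] = xist_w["male"]
            else:
                mu[is_y_sc] = 0.0
                mu[is_y_mc] = rng.uniform(9.0, 15.0, size=is_y_mc.sum())
                if contaminant:
                    boost = np.zeros(is_y_sc.sum())
                    boost[:3] = 10.0  # ~30 TPM of single-copy chrY contamination
                    mu[is_y_sc] = boost
                    mu[is_y_mc] = rng.uniform(0.5, 1.5, size=is_y_mc.sum())
                x_fold = np.ones(len(gene_ids))
                x_fold[is_x & ~is_xist] = xcr_fold if xc_state == "XCR" else 1.0
                x_fold[is_escaper] = 2.0  # biallelic in every female cell
                mu = mu * x_fold
                mu[is_xist] = xist_w[xc_state]
            cell_rows.append((cell, stage, sex, xc_state, contaminant))
            mu_cols.append(mu)

    mu_mat = np.column_stack(mu_cols)
    # counts with mean proportional to expression level x gene length
    alpha = 300_000 / (mu_mat * lengths[:, None] / 1000.0).sum(axis=0)
    count_mean = mu_mat * lengths[:, None] / 1000.0 * alpha
    counts = _nb_counts(rng, count_mean, dispersion)
    tpm = tpm_from_counts(
        pd.DataFrame(counts, index=gene_ids, columns=[r[0] for r in cell_rows]),
        pd.Series(lengths, index=gene_ids),
    )

    cells = pd.DataFrame(
        cell_rows, columns=["cell", "stage", "true_sex", "xc_state", "contaminant"]
    ).set_index("cell")
    n = len(cells)
    mapped = rng.lognormal(np.log(3e6), 0.25, size=n)
    mito = rng.beta(2.0, 38.0, size=n)
    qc_fail = np.zeros(n, dtype=bool)
    n_fail = int(round(qc_fail_frac * n))
    if n_fail:
        idx = rng.choice(n, size=n_fail, replace=False)
        qc_fail[idx] = True
        kind = rng.random(n_fail) < 0.5
        mapped[idx[kind]] = rng.uniform(2e5, 9.5e5, size=kind.sum())
        mito[idx[~kind]] = rng.uniform(0.5, 0.9, size=(~kind).sum())
    cells["mapped_read_count"] = mapped.astype(np.int64)
    cells["mito_fraction"] = mito
    cells["qc_fail"] = qc_fail

    annotation = genes[["chrom", "start", "end", "strand", "single_copy_y", "tss"]]
    matrix = gio.ExpressionMatrix(tpm, annotation.copy())
    truth = SimTruth(
        cells=cells[["stage", "true_sex", "xc_state", "contaminant", "qc_fail"]].copy(),
        escaper_genes=list(escapers),
    )
    meta = cells[["stage", "mapped_read_count", "mito_fraction"]].copy()
    return matrix, meta, truth


# ---------------------------------------------------------------------------
# allelic counts


def simulate_allelic_counts(
    genome: SimGenome,
    truth: SimTruth,
    seed: int,
    *,
    depth: float = 20.0,
    error_rate: float = 0.001,
) -> pd.DataFrame:
    """Per-(cell, SNV) reference/alternative read counts at X-linked SNVs."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 303]))
    snvs = genome.snvs
    escaper = snvs["gene"].isin(truth.escaper_genes).to_numpy()
    hap_a_is_ref = snvs["hap_a_is_ref"].to_numpy()

    rows = []
    for cell, crow in truth.cells.iterrows():
        n = rng.poisson(depth, size=len(snvs))
        if crow.true_sex == "F" and crow.xc_state == "XCR":
            from_a = rng.binomial(n, 0.5)
        else:
            # monoallelic from one haplotype (the single male X, or the
            # active X of an XCI cell), escaper genes biallelic regardless
            active_a = True if crow.true_sex == "M" else bool(rng.random() < 0.5)
            hap_reads = n if active_a else np.zeros_like(n)
            errors_out = rng.binomial(n, error_rate)
            from_a = np.where(active_a, n - errors_out, errors_out)
            from_a[escaper] = rng.binomial(n[escaper], 0.5)
        ref = np.where(hap_a_is_ref, from_a, n - from_a)
        keep = n > 0
        df = pd.DataFrame(
            {
                "cell": cell,
                "chrom": snvs["chrom"].to_numpy()[keep],
                "pos": snvs["pos"].to_numpy()[keep],
                "ref": snvs["ref"].to_numpy()[keep],
                "alt": snvs["alt"].to_numpy()[keep],
                "ref_reads": ref[keep],
                "alt_reads": (n - ref)[keep],
                "validated": snvs["validated"].to_numpy()[keep],
                "gene": snvs["gene"].to_numpy()[keep],
                "stage": crow.stage,
            }
        )
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# methylome


def _tile_overlaps(positions_start: np.ndarray, positions_end: np.ndarray,
                   tile_start: int, tile_end: int) -> bool:
    return bool(np.any((positions_start < tile_end) & (positions_end > tile_start)))


def plant_escapee_tiles(
    genome: SimGenome,
    rng,
    *,
    n_tiles: int = 50,
    tile: int = 800,
    te_fold: float = 5.0,
    young_family: str = YOUNG_FAMILY,
    min_cpgs: int = 12,
) -> tuple[pd.DataFrame, float]:
    """Choose escapee tiles so the young-family overlap is ``te_fold`` times
    its background frequency among candidate tiles (rejection-style exact
    sampling).  Returns (tiles, background overlap fraction)."""
    young = genome.repeats[genome.repeats["family"] == young_family]
    candidates = []
    for chrom in (*AUTOSOMES, "X"):
        sites = genome.cpg_sites[chrom]
        csize = genome.chrom_sizes[chrom]
        n_full = csize // tile
        counts = np.bincount(sites // tile, minlength=n_full)[:n_full]
        ok = np.nonzero(counts >= min_cpgs)[0]
        ys = young[young["chrom"] == chrom]
        ys_start, ys_end = ys["start"].to_numpy(), ys["end"].to_numpy()
        reps = genome.repeats[genome.repeats["chrom"] == chrom]
        r_start, r_end = reps["start"].to_numpy(), reps["end"].to_numpy()
        for k in ok:
            s, e = k * tile, (k + 1) * tile
            candidates.append(
                (chrom, s, e, _tile_overlaps(ys_start, ys_end, s, e),
                 _tile_overlaps(r_start, r_end, s, e))
            )
    cand = pd.DataFrame(
        candidates,
        columns=["chrom", "start", "end", "overlaps_young", "overlaps_any_te"],
    )
    p0 = float(cand["overlaps_young"].mean())
    k_young = int(round(min(1.0, te_fold * p0) * n_tiles))
    pool_y = cand.index[cand["overlaps_young"]]
    # the remaining escapee tiles are planted in repeat-free ("TE-poor")
    # candidates so the young-family 2x2 table is exact and no other family
    # is incidentally enriched in the TE-rich escapee class
    pool_n = cand.index[~cand["overlaps_any_te"]]
    k_young = min(k_young, len(pool_y))
    pick = np.concatenate(
        [
            rng.choice(pool_y.to_numpy(), size=k_young, replace=False),
            rng.choice(pool_n.to_numpy(), size=n_tiles - k_young, replace=False),
        ]
    )
    tiles = cand.loc[np.sort(pick)].reset_index(drop=True)
    return tiles, p0


def simulate_methylome(
    genome: SimGenome,
    samples: list[tuple[str, str, str]],
    seed: int,
    *,
    pgc_rate: float = 0.01,
    soma_rate: float = 0.75,
    soma_cgi_rate: float = 0.10,
    escapee_rate: float = 0.40,
    n_escapee_tiles: int = 50,
    escapee_te_fold: float = 5.0,
    coverage_mean: float = 10.0,
    tile: int = 800,
    escapee_tiles: pd.DataFrame | None = None,
) -> tuple[dict[str, pd.DataFrame], MethTruth]:
    """Per-sample CpG methylomes for ``samples`` = [(name, class, sex)] with
    class in {PGC, soma}.  PGC samples sit at ``pgc_rate`` except in planted
    escapee tiles (``escapee_rate``); somatic samples sit at ``soma_rate``
    with unmethylated CpG islands (``soma_cgi_rate``)."""
    for name, cls, sex in samples:
        if cls not in ("PGC", "soma"):
            raise ValueError(f"sample {name}: class must be PGC or soma, got {cls!r}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 404]))

    if escapee_tiles is None:
        esc_tiles, p0 = plant_escapee_tiles(
            genome, rng, n_tiles=n_escapee_tiles, tile=tile,
            te_fold=escapee_te_fold,
        )
    else:
        esc_tiles, p0 = escapee_tiles.copy(), float("nan")
        for _, row in esc_tiles.iterrows():
            csize = genome.chrom_sizes.get(row.chrom)
            if csize is None or row.start < 0 or row.end > csize:
                raise ValueError(
                    f"escapee tile {row.chrom}:{row.start}-{row.end} outside the genome"
                )

    # per-chromosome boolean masks for escapee tiles and CGI membership
    esc_mask: dict[str, np.ndarray] = {}
    cgi_mask: dict[str, np.ndarray] = {}
    for chrom, sites in genome.cpg_sites.items():
        mask = np.zeros(len(sites), dtype=bool)
        for _, row in esc_tiles[esc_tiles["chrom"] == chrom].iterrows():
            lo, hi = np.searchsorted(sites, [row.start, row.end])
            mask[lo:hi] = True
        esc_mask[chrom] = mask
        cmask = np.zeros(len(sites), dtype=bool)
        for _, row in genome.cgis[genome.cgis["chrom"] == chrom].iterrows():
            lo, hi = np.searchsorted(sites, [row.start, row.end])
            cmask[lo:hi] = True
        cgi_mask[chrom] = cmask

    tables: dict[str, pd.DataFrame] = {}
    site_rates: dict[str, dict[str, np.ndarray]] = {}
    for name, cls, sex in samples:
        chroms = [c for c in genome.cpg_sites if not (c == "Y" and sex == "F")]
        rates_by_chrom: dict[str, np.ndarray] = {}
        frames = []
        for chrom in chroms:
            sites = genome.cpg_sites[chrom]
            if cls == "PGC":
                rates = np.full(len(sites), pgc_rate)
                rates[esc_mask[chrom]] = escapee_rate
            else:
                rates = np.full(len(sites), soma_rate)
                rates[cgi_mask[chrom]] = soma_cgi_rate
            cov = rng.poisson(coverage_mean, size=len(sites))
            meth = rng.binomial(cov, rates)
            keep = cov > 0
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": sites[keep],
                        "meth": meth[keep],
                        "total": cov[keep],
                    }
                )
            )
            rates_by_chrom[chrom] = rates
        df = pd.concat(frames, ignore_index=True)
        df["level"] = df["meth"] / df["total"]
        tables[name] = df
        site_rates[name] = rates_by_chrom

    truth = MethTruth(
        escapee_tiles=esc_tiles, young_family=YOUNG_FAMILY,
        background_young_frac=p0, site_rates=site_rates,
    )
    return tables, truth


# ---------------------------------------------------------------------------
# bundle writer (CLI `simulate`)

DEFAULT_DESIGN = [
    ("early_PGC", 20, "F", "XCI"),
    ("PGC", 20, "F", "XCR"),
    ("PGC", 20, "M", "male"),
    ("soma", 15, "F", "XCI"),
    ("soma", 15, "M", "male"),
]

DEFAULT_METH_SAMPLES = [
    ("PGC_F", "PGC", "F"),
    ("PGC_M", "PGC", "M"),
    ("soma_F", "soma", "F"),
    ("soma_M", "soma", "M"),
]


def write_bundle(outdir: str | Path, seed: int, scale: str = "tiny",
                 design=None, meth_samples=None, **expr_kwargs) -> Path:
    """Generate the full synthetic input bundle plus truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = simulate_genome(seed, scale=scale)
    matrix, meta, truth = simulate_expression(
        genome, design or DEFAULT_DESIGN, seed, **expr_kwargs)
    allelic = simulate_allelic_counts(genome, truth, seed)
    methylomes, meth_truth = simulate_methylome(
        genome, meth_samples or DEFAULT_METH_SAMPLES, seed)

    gio.write_expression_table(matrix.tpm, outdir / "matrix.tsv")
    ann = matrix.genes.copy()
    ann.index.name = "gene"
    gio.write_gene_annotation(ann, outdir / "genes.tsv")
    gio.write_genome_sizes(genome.chrom_sizes, outdir / "genome.sizes")
    gio.write_cell_table(meta, outdir / "cells.tsv")
    gio.write_allelic_table(allelic, outdir / "allelic.tsv")

    def as_bed(df, feature_class):
        out = df.copy()
        if "name" not in out.columns:
            out["name"] = "."
        out["score"] = 0
        if "strand" not in out.columns:
            out["strand"] = "."
        out["feature_class"] = feature_class
        if "family" not in out.columns:
            out["family"] = ""
        return out

    gio.write_bed(as_bed(genome.exons, "exon"), outdir / "exons.bed")
    gio.write_bed(as_bed(genome.promoters, "promoter"), outdir / "promoters.bed")
    gio.write_bed(as_bed(genome.cgis, "CGI"), outdir / "cgi.bed")
    gio.write_bed(as_bed(genome.imprinted, "imprinted"), outdir / "imprinted.bed")
    rep = genome.repeats.copy()
    rep["score"] = 0
    rep["strand"] = "."
    rep["feature_class"] = "repeat"
    gio.write_bed(rep, outdir / "repeats.bed")
    for name, table in methylomes.items():
        gio.write_cpg_table(table, outdir / f"meth_{name}.cov.tsv")

    truth_payload = {
        "cells": truth.cells.reset_index().to_dict(orient="list"),
        "escaper_genes": truth.escaper_genes,
        "escapee_tiles": meth_truth.escapee_tiles.to_dict(orient="list"),
        "young_family": meth_truth.young_family,
        "background_young_frac": meth_truth.background_young_frac,
        "promoter_class": genome.promoter_class_truth.to_dict(),
    }
    (outdir / "truth.json").write_text(
        json.dumps(truth_payload, indent=2, sort_keys=True, default=str) + "\n")
    return outdir
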