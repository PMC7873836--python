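"""Expression-dosage evidence for X-chromosome reactivation.

Per-chromosome geometric means of TPM+1, female:male expression ratios over
shared expressed genes (chromosome-wide and in 1-Mb windows along chrX), and
the per-cell bootstrapped X:allA ratio (median over replicates of the summed
TPM of randomly drawn expressed X genes over randomly drawn expressed
autosomal genes).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import Thresholds
from .stats import compare_groups as compare_dosage_groups  # noqa: F401  (module surface)

logger = logging.getLogger("germline_reset")


def _unpack(matrix, genes):
    if genes is None:
        return matrix.tpm, matrix.genes
    tpm = matrix.tpm if hasattr(matrix, "tpm") else matrix
    return tpm, genes.reindex(tpm.index)


def chrom_geometric_mean(
    matrix, chrom: str, thr: Thresholds, genes: pd.DataFrame | None = None,
    cells=None, expressed: pd.Index | None = None,
) -> pd.Series:
    """Per-cell geometric mean of TPM + pseudocount over a chromosome's
    (expressed) genes."""
    tpm, ann = _unpack(matrix, genes)
    pool = ann.index[ann["chrom"] == chrom]
    if expressed is not None:
        pool = pool.intersection(expressed)
    if len(pool) == 0:
        raise ValueError(f"no genes on chromosome {chrom!r}")
    sub = tpm.loc[pool]
    if cells is not None:
        sub = sub.loc[:, cells]
    return np.exp(np.log(sub + thr.geomean_pseudocount).mean(axis=0))


def shared_expressed_genes(tpm: pd.DataFrame, sex: pd.Series, thr: Thresholds) -> pd.Index:
    """Genes with TPM > min_tpm in at least one cell of each sex."""
    f_cells = sex.index[sex == "F"]
    m_cells = sex.index[sex == "M"]
    expr_f = (tpm.loc[:, f_cells] > thr.min_tpm).any(axis=1)
    expr_m = (tpm.loc[:, m_cells] > thr.min_tpm).any(axis=1)
    return tpm.index[expr_f & expr_m]


def fm_ratio(
    matrix, sex: pd.Series, thr: Thresholds,
    chroms=("X", "auto1", "auto2", "auto3"),
    genes: pd.DataFrame | None = None, method: str = "geomean",
) -> pd.Series:
    """Female:male expression ratio per chromosome over shared expressed genes.

    ``method='geomean'`` (default) takes the ratio of geometric means of
    TPM+1 over (genes x cells) of each sex; ``method='total'`` uses mean
    total TPM per cell.
    """
    tpm, ann = _unpack(matrix, genes)
    sex = sex.reindex(tpm.columns)
    f_cells = sex.index[sex == "F"]
    m_cells = sex.index[sex == "M"]
    if len(f_cells) == 0 or len(m_cells) == 0:
        raise ValueError("stage lacks both sexes: need >=1 female and >=1 male cell")
    shared = shared_expressed_genes(tpm, sex, thr)

    out = {}
    for chrom in chroms:
        pool = ann.index[ann["chrom"] == chrom].intersection(shared)
        if len(pool) == 0:
            raise ValueError(f"no shared expressed genes on chromosome {chrom!r}")
        if method == "geomean":
            lf = np.log(tpm.loc[pool, f_cells] + thr.geomean_pseudocount)
            lm = np.log(tpm.loc[pool, m_cells] + thr.geomean_pseudocount)
            out[chrom] = float(np.exp(lf.mean(axis=None) - lm.mean(axis=None)))
        elif method == "total":
            out[chrom] = float(
                tpm.loc[pool, f_cells].sum(axis=0).mean()
                / tpm.loc[pool, m_cells].sum(axis=0).mean()
            )
        else:
            raise ValueError(f"unknown method {method!r}")
    return pd.Series(out, name="fm_ratio")


def fm_ratio_windows(
    matrix, sex: pd.Series, thr: Thresholds, chrom: str = "X",
    genes: pd.DataFrame | None = None, chrom_size: int | None = None,
) -> pd.DataFrame:
    """Median per-gene F:M ratio in consecutive fixed-width windows of a
    chromosome.

    Genes are binned by TSS into right-open windows; the per-gene ratio is
    (mean TPM over females + 1) / (mean TPM over males + 1); windows holding
    fewer than ``fm_window_min_genes`` genes report a missing median.
    """
    tpm, ann = _unpack(matrix, genes)
    sex = sex.reindex(tpm.columns)
    f_cells = sex.index[sex == "F"]
    m_cells = sex.index[sex == "M"]
    if len(f_cells) == 0 or len(m_cells) == 0:
        raise ValueError("stage lacks both sexes: need >=1 female and >=1 male cell")
    shared = shared_expressed_genes(tpm, sex, thr)
    pool = ann.index[ann["chrom"] == chrom].intersection(shared)

    tss = ann.loc[pool, "tss"] if "tss" in ann.columns else ann.loc[pool, "start"]
    ratio = (tpm.loc[pool, f_cells].mean(axis=1) + 1.0) / (
        tpm.loc[pool, m_cells].mean(axis=1) + 1.0
    )
    win = (tss // thr.fm_window).astype(int)

    limit = chrom_size if chrom_size is not None else (int(tss.max()) + 1 if len(tss) else 0)
    n_windows = int(np.ceil(limit / thr.fm_window)) if limit else 0
    rows = []
    by_window = ratio.groupby(win)
    for w in range(n_windows):
        vals = by_window.get_group(w) if w in by_window.groups else pd.Series(dtype=float)
        median = float(vals.median()) if len(vals) >= thr.fm_window_min_genes else np.nan
        rows.append((chrom, w * thr.fm_window, min((w + 1) * thr.fm_window, limit),
                     len(vals), median))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_genes", "median_fm_ratio"]
    )


def x_to_alla_bootstrap(
    matrix, cell: str, thr: Thresholds, seed: int,
    genes: pd.DataFrame | None = None,
    expressed: pd.Index | None = None,
    n_genes: int | None = None, n_reps: int | None = None,
    autosomes=("auto1", "auto2", "auto3"),
) -> float:
    """Bootstrapped X:allA expression ratio for one cell.

    Each replicate draws ``n_genes`` expressed X-linked genes and ``n_genes``
    expressed autosomal genes without replacement and forms the ratio of
    summed TPMs; the cell's ratio is the median over ``n_reps`` replicates.
    """
    tpm, ann = _unpack(matrix, genes)
    n_genes = n_genes if n_genes is not None else thr.boot_genes
    n_reps = n_reps if n_reps is not None else thr.boot_reps
    pool = ann.index if expressed is None else ann.index.intersection(expressed)
    x_pool = pool[ann.loc[pool, "chrom"] == "X"]
    a_pool = pool[ann.loc[pool, "chrom"].isin(autosomes)]
    if len(x_pool) < n_genes or len(a_pool) < n_genes:
        raise ValueError(
            f"not enough expressed genes for n_genes={n_genes} "
            f"(X: {len(x_pool)}, autosomal: {len(a_pool)}); use a smaller n_genes"
        )
    col = tpm[cell]
    x_vals = col.loc[x_pool].to_numpy()
    a_vals = col.loc[a_pool].to_numpy()
    rng = np.random.default_rng(seed)
    # vectorised without-replacement draws: argsort of uniforms per replicate
    x_idx = np.argsort(rng.random((n_reps, len(x_vals))), axis=1)[:, :n_genes]
    a_idx = np.argsort(rng.random((n_reps, len(a_vals))), axis=1)[:, :n_genes]
    ratios = x_vals[x_idx].sum(axis=1) / a_vals[a_idx].sum(axis=1)
    return float(np.median(ratios))


def x_to_alla_per_cell(
    matrix, cells, thr: Thresholds, seed: int, **kwargs,
) -> pd.Series:
    """X:allA bootstrap ratio for many cells (child seed per cell)."""
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(len(cells))
    out = {
        cell: x_to_alla_bootstrap(matrix, cell, thr, int(s) % (2**31), **kwargs)
        for cell, s in zip(cells, seeds)
    }
    return pd.Series(out, name="x_to_alla")


def xist_tpm(matrix, gene: str = "XIST") -> pd.Series:
    """Convenience extractor: XIST TPM per cell."""
    tpm = matrix.tpm if hasattr(matrix, "tpm") else matrix
    if gene not in tpm.index:
        raise KeyError(f"gene {gene!r} not in matrix")
    return tpm.loc[gene]
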