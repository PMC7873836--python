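"""Single-cell QC filtering, expressed-gene detection and sex inference.

Cells are removed when fewer than one million reads map to gene transcripts
or when the mitochondrial read proportion reaches 0.5; genes count as
expressed when detected at TPM > 1 in at least three cells.  Embryonic sex is
inferred with a two-pass rule: a cell is provisionally male when its summed
TPM over single-copy chrY genes reaches 10; provisional males whose
chrY:chrX expression ratio falls below the maximum ratio seen among
provisional females are then reclassified as female (a guard against
cross-contamination of chrY transcripts).  Pass 2 is applied once, not
iterated after reclassified cells join the female pool.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import Thresholds

logger = logging.getLogger("germline_reset")


def tpm_from_counts(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million from raw counts and gene lengths (bp)."""
    lens = lengths.reindex(counts.index)
    if lens.isna().any():
        missing = lens.index[lens.isna()]
        raise ValueError(f"genes without length annotation: {list(missing[:5])}")
    rate = counts.div(lens.to_numpy() / 1000.0, axis=0)
    return rate.div(rate.sum(axis=0), axis=1) * 1e6


def filter_cells(
    matrix,
    meta: pd.DataFrame,
    thr: Thresholds,
    exclude: tuple[str, ...] = (),
):
    """Drop cells failing the read-count or mitochondrial-fraction cut-off.

    ``meta`` must supply ``mapped_read_count`` and ``mito_fraction`` for every
    cell of the matrix.  ``exclude`` is an explicit outlier list (flagged in
    the report); the gene set is untouched.  Returns the filtered matrix and
    a per-cell QC report.
    """
    tpm = matrix.tpm if hasattr(matrix, "tpm") else matrix
    missing = tpm.columns.difference(meta.index)
    if len(missing):
        raise ValueError(f"cells missing QC metadata: {list(missing[:5])}")
    meta = meta.loc[tpm.columns]

    pass_reads = meta["mapped_read_count"] >= thr.min_mapped_reads
    pass_mito = meta["mito_fraction"] < thr.max_mito_fraction
    outlier = tpm.columns.isin(exclude)
    kept = pass_reads & pass_mito & ~outlier

    reason = np.select(
        [~pass_reads, ~pass_mito, outlier],
        ["reads", "mito", "outlier"],
        default="",
    )
    report = pd.DataFrame(
        {
            "mapped_read_count": meta["mapped_read_count"],
            "mito_fraction": meta["mito_fraction"],
            "pass_reads": pass_reads,
            "pass_mito": pass_mito,
            "outlier_flag": outlier,
            "kept": kept,
            "reason": reason,
        },
        index=tpm.columns,
    )
    for cell, row in report[~report["kept"]].iterrows():
        logger.info("cell %s removed (%s)", cell, row.reason)
    filtered = tpm.loc[:, kept[kept].index]
    if hasattr(matrix, "tpm"):
        from .io import ExpressionMatrix

        filtered = ExpressionMatrix(filtered, matrix.genes)
    return filtered, report


def detect_expressed_genes(tpm: pd.DataFrame, thr: Thresholds) -> pd.Index:
    """Genes with TPM > ``min_tpm`` in at least ``min_cells_expressing`` cells."""
    if hasattr(tpm, "tpm"):
        tpm = tpm.tpm
    n_cells = (tpm > thr.min_tpm).sum(axis=1)
    return tpm.index[n_cells >= thr.min_cells_expressing]


def gene_detection_report(tpm: pd.DataFrame, thr: Thresholds) -> pd.DataFrame:
    if hasattr(tpm, "tpm"):
        tpm = tpm.tpm
    n_cells = (tpm > thr.min_tpm).sum(axis=1)
    return pd.DataFrame(
        {"n_cells_expressing": n_cells,
         "detected": n_cells >= thr.min_cells_expressing}
    )


def infer_sex(matrix, thr: Thresholds, genes: pd.DataFrame | None = None) -> pd.DataFrame:
    """Two-pass embryonic sex inference; returns one row per cell.

    Pass 1: provisional male iff summed TPM of single-copy chrY genes >=
    ``chry_male_tpm``.  Pass 2: the chrY:chrX total-TPM ratio is computed per
    cell and any provisional male below the maximum ratio of provisional
    females is reclassified as female.
    """
    if genes is None:
        tpm, genes = matrix.tpm, matrix.genes
    else:
        tpm = matrix.tpm if hasattr(matrix, "tpm") else matrix
        genes = genes.reindex(tpm.index)

    y_genes = genes.index[genes["chrom"] == "Y"]
    y_single = genes.index[(genes["chrom"] == "Y") & genes["single_copy_y"].fillna(False)]
    x_genes = genes.index[genes["chrom"] == "X"]
    if len(y_single) == 0:
        raise ValueError("annotation contains no single-copy chrY genes")
    if len(x_genes) == 0:
        raise ValueError("annotation contains no chrX genes")

    chry_single = tpm.loc[y_single].sum(axis=0)
    provisional = np.where(chry_single >= thr.chry_male_tpm, "M", "F")

    ratio_pool = y_genes if thr.yx_ratio_genes == "all" else y_single
    y_total = tpm.loc[ratio_pool].sum(axis=0)
    x_total = tpm.loc[x_genes].sum(axis=0)
    zero_x = x_total == 0
    if zero_x.any():
        raise ValueError(
            f"chrX expression is zero in cell {x_total.index[zero_x][0]!r}; "
            "the chrY:chrX ratio is undefined"
        )
    yx_ratio = y_total / x_total

    final = provisional.copy()
    female_mask = provisional == "F"
    if not female_mask.any():
        logger.warning("no provisional female cells; pass-2 reclassification skipped")
    else:
        max_female_ratio = yx_ratio[female_mask].max()
        reclass = (provisional == "M") & (yx_ratio < max_female_ratio).to_numpy()
        final[reclass] = "F"

    return pd.DataFrame(
        {
            "chry_total_tpm": chry_single,
            "yx_ratio": yx_ratio,
            "provisional_sex": provisional,
            "final_sex": final,
            "reclassified": (provisional == "M") & (final == "F"),
        },
        index=tpm.columns,
    )
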