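"""Allelic-resolution evidence for X-chromosome reactivation.

SNV filtering (validated sites, >=3 reads, recurrent in >=2 cells of a
stage), per-(cell, SNV) mono/biallelic calling, identification of somatic
XCI "escaper" genes (X-linked genes with biallelic SNVs in somatic female
cells), and per-cell counts of biallelically expressed non-escaper genes.

Filter order matters and is fixed: the recurrence filter counts cells per
stage *after* the coverage filter, so a site seen in two cells but covered
by >=3 reads in only one is dropped.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import Thresholds

logger = logging.getLogger("germline_reset")

FILTER_REASONS = ("not-validated", "low-coverage", "not-recurrent")


def assign_genes(table: pd.DataFrame, exons: pd.DataFrame) -> pd.DataFrame:
    """Assign each SNV to the first exon strictly containing it; rows in no
    exon are dropped (count logged)."""
    out = table.copy()
    gene = np.full(len(out), None, dtype=object)
    for chrom, sub in out.groupby("chrom"):
        ex = exons[exons["chrom"] == chrom].sort_values("start")
        if not len(ex):
            continue
        starts = ex["start"].to_numpy()
        ends = ex["end"].to_numpy()
        names = ex["name"].to_numpy()
        pos = sub["pos"].to_numpy()
        for i, p in zip(sub.index, pos):
            hit = np.nonzero((starts <= p) & (p < ends))[0]
            if hit.size:
                gene[out.index.get_loc(i)] = names[hit[0]]
    out["gene"] = gene
    dropped = out["gene"].isna().sum()
    if dropped:
        logger.info("%d SNV records fall in no exon and were dropped", dropped)
    return out[out["gene"].notna()].copy()


def filter_snvs(table: pd.DataFrame, thr: Thresholds,
                stages: pd.Series | None = None) -> pd.DataFrame:
    """Apply the SNV filters; every record is annotated, none silently lost.

    Adds ``total``, ``kept`` and ``filter_reason`` columns.  ``stages`` maps
    cell -> stage; if omitted the table must carry a ``stage`` column.
    """
    out = table.copy()
    if "stage" not in out.columns:
        if stages is None:
            raise ValueError("need per-cell stages (column or mapping)")
        out["stage"] = out["cell"].map(stages)
        if out["stage"].isna().any():
            missing = out.loc[out["stage"].isna(), "cell"].unique()
            raise ValueError(f"cells without stage assignment: {list(missing[:5])}")
    out["total"] = out["ref_reads"] + out["alt_reads"]

    reason = np.full(len(out), "", dtype=object)
    reason[~out["validated"].to_numpy()] = "not-validated"
    low_cov = (out["total"] < thr.snv_min_reads).to_numpy()
    reason[(reason == "") & low_cov] = "low-coverage"

    # recurrence within stage, computed on records surviving the first two filters
    surviving = reason == ""
    key = out.loc[surviving, ["stage", "chrom", "pos"]]
    n_cells = (
        out.loc[surviving]
        .groupby(["stage", "chrom", "pos"])["cell"]
        .nunique()
    )
    counts = n_cells.reindex(pd.MultiIndex.from_frame(key)).to_numpy()
    not_recurrent = counts < thr.snv_min_cells
    idx = np.nonzero(surviving)[0]
    reason[idx[not_recurrent]] = "not-recurrent"

    out["filter_reason"] = reason
    out["kept"] = reason == ""
    return out


def call_allelic_status(calls: pd.DataFrame, thr: Thresholds) -> pd.DataFrame:
    """Mono-/biallelic status for records that passed the filters.

    Biallelic iff the minor allele has >= ``allele_detect_min_reads`` reads
    AND >= ``allele_detect_min_frac`` of the site's reads; otherwise
    monoallelic toward the majority allele (ties broken toward reference).
    Filtered records keep status ``filtered``.
    """
    out = calls.copy()
    if "total" not in out.columns:
        out["total"] = out["ref_reads"] + out["alt_reads"]
    if "kept" not in out.columns:
        out["kept"] = True
    if (out.loc[out["kept"], "total"] == 0).any():
        raise ValueError("zero-coverage record reached allelic calling; filter first")

    ref = out["ref_reads"].to_numpy(dtype=float)
    alt = out["alt_reads"].to_numpy(dtype=float)
    total = out["total"].to_numpy(dtype=float)
    minor = np.minimum(ref, alt)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, minor / total, 0.0)
    biallelic = (minor >= thr.allele_detect_min_reads) & (
        frac >= thr.allele_detect_min_frac
    )
    status = np.where(
        biallelic, "biallelic",
        np.where(alt > ref, "monoallelic-alt", "monoallelic-ref"),
    )
    status = np.where(out["kept"].to_numpy(), status, "filtered")
    out["status"] = status
    return out


def identify_escapers(calls: pd.DataFrame, somatic_female_cells) -> pd.DataFrame:
    """X-linked genes with >=1 biallelic SNV call in >=1 somatic female cell.

    Returns a table indexed by gene with supporting SNV and cell counts.
    """
    somatic_female_cells = pd.Index(somatic_female_cells)
    if len(somatic_female_cells) == 0:
        raise ValueError("no somatic female cells supplied")
    soma = calls[calls["cell"].isin(somatic_female_cells) & (calls["status"] == "biallelic")]
    if not len(soma):
        return pd.DataFrame(columns=["n_snvs", "n_cells"]).rename_axis("gene")
    grouped = soma.groupby("gene")
    return pd.DataFrame(
        {
            "n_snvs": grouped.apply(
                lambda g: g[["chrom", "pos"]].drop_duplicates().shape[0],
                include_groups=False,
            ),
            "n_cells": grouped["cell"].nunique(),
        }
    ).rename_axis("gene")


def count_biallelic_genes(
    calls: pd.DataFrame, escapers, female_cells,
) -> pd.Series:
    """Per female cell: number of distinct X genes with >=1 biallelic SNV,
    excluding escaper genes."""
    escaper_set = set(
        escapers.index if isinstance(escapers, pd.DataFrame) else escapers
    )
    female_cells = pd.Index(female_cells)
    bi = calls[
        calls["cell"].isin(female_cells)
        & (calls["status"] == "biallelic")
        & ~calls["gene"].isin(escaper_set)
    ]
    counts = bi.groupby("cell")["gene"].nunique()
    out = counts.reindex(female_cells, fill_value=0).astype(int)
    out.name = "n_biallelic_non_escaper_genes"
    assert not set(bi["gene"]) & escaper_set
    return out
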