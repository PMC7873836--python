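"""Readers and writers for the on-disk formats used by the pipeline.

Formats are plain text throughout:

* expression matrix — TSV, first column gene IDs, header row cell IDs;
* gene annotation — TSV with columns
  ``gene, chrom, start, end, strand, single_copy_y`` (BED-like, 0-based
  half-open coordinates);
* interval sets — BED6 plus optional extra columns ``feature_class`` and
  ``family`` (``chrom, start, end, name, score, strand[, feature_class[,
  family]]``);
* CpG methylation calls — bismark-coverage-style TSV
  (``chrom, start, end, meth_pct, count_meth, count_unmeth``; 1-based
  inclusive positions on disk, 0-based C positions in memory);
* allelic counts — TSV with columns
  ``cell, chrom, pos, ref, alt, ref_reads, alt_reads, validated, gene``;
* genome sizes — two-column TSV.

Chromosome names are taken verbatim from inputs (no ``chr`` normalisation);
:func:`check_chrom_names` reports disjoint naming between two sources.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("germline_reset")

GENE_COLUMNS = ["gene", "chrom", "start", "end", "strand", "single_copy_y"]
BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand", "feature_class", "family"]
ALLELIC_COLUMNS = [
    "cell", "chrom", "pos", "ref", "alt", "ref_reads", "alt_reads", "validated", "gene",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class ExpressionMatrix:
    """A genes x cells TPM matrix with an aligned gene annotation table."""

    tpm: pd.DataFrame
    genes: pd.DataFrame  # indexed by gene id: chrom, start, end, strand, single_copy_y

    def __post_init__(self) -> None:
        missing = self.tpm.index.difference(self.genes.index)
        if len(missing):
            logger.warning(
                "%d matrix genes missing from the annotation (e.g. %s)",
                len(missing), list(missing[:5]),
            )
        self.genes = self.genes.reindex(self.tpm.index)

    @property
    def cells(self) -> pd.Index:
        return self.tpm.columns

    def subset_cells(self, cells) -> "ExpressionMatrix":
        return ExpressionMatrix(self.tpm.loc[:, cells], self.genes)


# ---------------------------------------------------------------------------
# expression matrix


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Read a genes x cells TSV into a float DataFrame (genes as index)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0:
        raise FormatError(f"{path}: no genes in expression matrix")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique()
        raise FormatError(f"{path}: duplicated gene IDs: {list(dups[:5])}")
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise FormatError(
                f"{path}: non-numeric value at gene {row!r}, cell {col!r}"
            )
        df[col] = converted
    if (df.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative expression values")
    return df


def read_expression_matrix(path: str | Path, annotation_path: str | Path) -> ExpressionMatrix:
    tpm = read_expression_table(path)
    genes = read_gene_annotation(annotation_path)
    return ExpressionMatrix(tpm, genes)


def write_expression_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene", float_format="%.10g", lineterminator="\n")


# ---------------------------------------------------------------------------
# gene annotation


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(GENE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing annotation columns {sorted(missing)}")
    if df["gene"].duplicated().any():
        raise FormatError(f"{path}: duplicated gene IDs in annotation")
    if (df["start"] >= df["end"]).any():
        raise FormatError(f"{path}: annotation intervals must satisfy start < end")
    df["single_copy_y"] = df["single_copy_y"].astype(bool)
    return df.set_index("gene")


def write_gene_annotation(genes: pd.DataFrame, path: str | Path) -> None:
    out = genes.reset_index() if genes.index.name == "gene" else genes.copy()
    cols = GENE_COLUMNS + [c for c in out.columns if c not in GENE_COLUMNS]
    out[cols].to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# interval sets (BED6 + feature_class + family)


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    ncol = df.shape[1]
    if ncol < 3:
        raise FormatError(f"{path}: BED needs at least 3 columns")
    df.columns = BED_COLUMNS[:ncol]
    for col, default in (
        ("name", "."), ("score", 0), ("strand", "."),
        ("feature_class", "."), ("family", ""),
    ):
        if col not in df.columns:
            df[col] = default
    df["family"] = df["family"].fillna("").astype(str)
    if (df["start"] >= df["end"]).any():
        raise FormatError(f"{path}: intervals must satisfy start < end (0-based half-open)")
    repeats = df["feature_class"] == "repeat"
    if (repeats & (df["family"] == "")).any():
        raise FormatError(f"{path}: repeat records must carry a non-empty family")
    return df[BED_COLUMNS]


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    out = intervals.copy()
    for col, default in (
        ("name", "."), ("score", 0), ("strand", "."),
        ("feature_class", "."), ("family", ""),
    ):
        if col not in out.columns:
            out[col] = default
    out[BED_COLUMNS].to_csv(path, sep="\t", index=False, header=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# CpG methylation (bismark coverage style)


def read_cpg_table(path: str | Path, tolerance_pp: float = 0.5) -> pd.DataFrame:
    """Read a bismark-coverage-style TSV into (chrom, pos, meth, total, level).

    Positions on disk are 1-based; in memory the 0-based position of the C on
    the plus strand is stored.  The methylation level is recomputed from the
    counts; a warning is emitted where it disagrees with the stated percentage
    by more than ``tolerance_pp`` percentage points.
    """
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "meth_pct", "meth", "unmeth"],
    )
    if ((df["meth"] < 0) | (df["unmeth"] < 0)).any():
        raise FormatError(f"{path}: negative methylation counts")
    total = df["meth"] + df["unmeth"]
    if (total <= 0).any():
        raise FormatError(f"{path}: sites with zero total coverage")
    level = df["meth"] / total
    mismatch = (level * 100 - df["meth_pct"]).abs() > tolerance_pp
    if mismatch.any():
        warnings.warn(
            f"{path}: {int(mismatch.sum())} sites where the stated methylation "
            f"percentage disagrees with the counts by > {tolerance_pp} pp",
            stacklevel=2,
        )
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["start"].astype(np.int64) - 1,
            "meth": df["meth"].astype(np.int64),
            "total": total.astype(np.int64),
        }
    )
    out["level"] = out["meth"] / out["total"]
    return out


def write_cpg_table(cpgs: pd.DataFrame, path: str | Path) -> None:
    """Write (chrom, pos, meth, total) in bismark coverage format."""
    total = cpgs["total"].to_numpy()
    meth = cpgs["meth"].to_numpy()
    out = pd.DataFrame(
        {
            "chrom": cpgs["chrom"],
            "start": cpgs["pos"].to_numpy() + 1,
            "end": cpgs["pos"].to_numpy() + 1,
            "meth_pct": np.round(100.0 * meth / total, 6),
            "meth": meth,
            "unmeth": total - meth,
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False,
               float_format="%.10g", lineterminator="\n")


# ---------------------------------------------------------------------------
# allelic counts


def read_allelic_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(ALLELIC_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing allelic columns {sorted(missing)}")
    if ((df["ref_reads"] < 0) | (df["alt_reads"] < 0)).any():
        raise FormatError(f"{path}: negative read counts")
    df["validated"] = df["validated"].astype(bool)
    return df


def write_allelic_table(table: pd.DataFrame, path: str | Path) -> None:
    cols = ALLELIC_COLUMNS + [c for c in table.columns if c not in ALLELIC_COLUMNS]
    table[cols].to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# genome sizes, cells, misc


def read_genome_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    if (df["size"] <= 0).any():
        raise FormatError(f"{path}: chromosome sizes must be positive")
    return dict(zip(df["chrom"], df["size"].astype(int)))


def write_genome_sizes(sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_cell_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="cell")
    return df


def write_cell_table(cells: pd.DataFrame, path: str | Path) -> None:
    cells.to_csv(path, sep="\t", index_label="cell", float_format="%.10g",
                 lineterminator="\n")


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False,
              index_label=None) -> None:
    """Deterministic TSV writer used by the CLI (fixed float format, LF)."""
    df.to_csv(path, sep="\t", index=index, index_label=index_label,
              float_format="%.10g", lineterminator="\n")


def check_chrom_names(a, b, what_a: str = "first", what_b: str = "second") -> set[str]:
    """Return the shared chromosome names; warn if the two sets are disjoint."""
    sa, sb = set(a), set(b)
    shared = sa & sb
    if not shared:
        logger.warning(
            "chromosome names of %s (%s) and %s (%s) are disjoint — "
            "check naming conventions",
            what_a, sorted(sa)[:5], what_b, sorted(sb)[:5],
        )
    return shared


def write_run_manifest(path: str | Path, *, command: str, seed: int | None,
                       thresholds, inputs: dict | None = None,
                       outputs: list[str] | None = None) -> None:
    """Write the run manifest: resolved thresholds, seed, inputs and outputs.

    Deliberately contains no timestamps so reruns are byte-identical.
    """
    manifest = {
        "command": command,
        "seed": seed,
        "thresholds": thresholds.to_dict() if hasattr(thresholds, "to_dict") else thresholds,
        "inputs": inputs or {},
        "outputs": outputs or [],
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def setup_logging(level: int = logging.INFO) -> None:
    """Send pipeline logs to stderr (idempotent)."""
    log = logging.getLogger("germline_reset")
    if not log.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        log.addHandler(handler)
    log.setLevel(level)
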