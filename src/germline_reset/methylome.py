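"""Whole-genome bisulfite methylome analyses.

Coverage-weighted methylation over arbitrary intervals and fixed-width
genomic tiles, promoter CpG-class assignment (HCP/ICP/LCP), scaled gene
metaprofiles, detection of demethylation-resistant 800-nt "escapee" tiles
with TE-poor/TE-rich classification, transposable-element family enrichment
scoring with Fisher's exact test, and per-million normalisation of repeat
expression counts.

Region methylation is weighted: summed methylated read counts divided by
summed total read counts over the CpGs of a region (a mean-of-sites variant
is available for sensitivity analysis).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .config import Thresholds

logger = logging.getLogger("germline_reset")


# ---------------------------------------------------------------------------
# indexed CpG table helpers


def _index_cpgs(cpgs: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per chromosome: (sorted positions, cumulative meth, cumulative total)."""
    out = {}
    for chrom, sub in cpgs.groupby("chrom", sort=False):
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy()
        cm = np.concatenate([[0], np.cumsum(sub["meth"].to_numpy())])
        ct = np.concatenate([[0], np.cumsum(sub["total"].to_numpy())])
        out[chrom] = (pos, cm, ct)
    return out


def global_weighted_methylation(cpgs: pd.DataFrame) -> float:
    """Genome-wide weighted methylation: sum(meth) / sum(total)."""
    return float(cpgs["meth"].sum() / cpgs["total"].sum())


def region_methylation(
    cpgs: pd.DataFrame, intervals: pd.DataFrame,
    chrom_sizes: dict[str, int] | None = None,
    method: str = "weighted",
) -> pd.DataFrame:
    """Methylation level per interval (coverage-weighted by default).

    Intervals with zero covered CpGs get a missing level, not 0.  An interval
    on a chromosome unknown to the genome (or, lacking a sizes table, to the
    CpG table) raises.
    """
    idx = _index_cpgs(cpgs)
    known = set(chrom_sizes) if chrom_sizes is not None else set(idx)
    levels, ncpg, meths, totals = [], [], [], []
    chrom_arr = intervals["chrom"].to_numpy()
    start_arr = intervals["start"].to_numpy()
    end_arr = intervals["end"].to_numpy()
    for chrom, start, end in zip(chrom_arr, start_arr, end_arr):
        if chrom not in known:
            raise ValueError(f"interval on unknown chromosome {chrom!r}")
        if chrom not in idx:
            ncpg.append(0); meths.append(0); totals.append(0); levels.append(np.nan)
            continue
        pos, cm, ct = idx[chrom]
        lo, hi = np.searchsorted(pos, [start, end])
        n = int(hi - lo)
        m = int(cm[hi] - cm[lo])
        t = int(ct[hi] - ct[lo])
        ncpg.append(n); meths.append(m); totals.append(t)
        if t == 0:
            levels.append(np.nan)
        elif method == "weighted":
            levels.append(m / t)
        elif method == "mean_of_sites":
            sub = cpgs  # rare path; recompute directly
            sel = (cpgs["chrom"] == chrom) & (cpgs["pos"] >= start) & (cpgs["pos"] < end)
            levels.append(float((cpgs.loc[sel, "meth"] / cpgs.loc[sel, "total"]).mean()))
        else:
            raise ValueError(f"unknown method {method!r}")
    out = intervals.copy().reset_index(drop=True)
    out["n_cpg"] = ncpg
    out["meth_reads"] = meths
    out["total_reads"] = totals
    out["level"] = levels
    return out


def tile_methylation(
    cpgs: pd.DataFrame, chrom_sizes: dict[str, int], tile: int,
) -> pd.DataFrame:
    """Weighted methylation in non-overlapping left-closed tiles covering each
    chromosome (the last partial tile is kept)."""
    if tile <= 0:
        raise ValueError("tile width must be positive")
    rows = []
    for chrom, size in chrom_sizes.items():
        starts = np.arange(0, size, tile)
        ends = np.minimum(starts + tile, size)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    tiles = pd.concat(rows, ignore_index=True)
    return region_methylation(cpgs, tiles, chrom_sizes=chrom_sizes)


# ---------------------------------------------------------------------------
# promoter CpG classes


def window_composition(seq: str, window: int, step: int) -> pd.DataFrame:
    """CpG observed/expected ratio and GC content of sliding windows.

    The CpG ratio follows the observed/expected convention:
    ``n_CpG * window_length / (n_C * n_G)`` (0 when the window has no C or
    no G).
    """
    b = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_c = (b == ord("C")).astype(np.int64)
    is_g = (b == ord("G")).astype(np.int64)
    is_cpg = np.zeros(len(b), dtype=np.int64)
    if len(b) > 1:
        is_cpg[:-1] = (b[:-1] == ord("C")) & (b[1:] == ord("G"))
    cum_c = np.concatenate([[0], np.cumsum(is_c)])
    cum_g = np.concatenate([[0], np.cumsum(is_g)])
    cum_cpg = np.concatenate([[0], np.cumsum(is_cpg)])
    starts = np.arange(0, len(b) - window + 1, step)
    ends = starts + window
    nc = cum_c[ends] - cum_c[starts]
    ng = cum_g[ends] - cum_g[starts]
    # a CpG counts for the window containing its C
    ncpg = cum_cpg[np.minimum(ends - 1, len(b) - 1)] - cum_cpg[starts]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where((nc > 0) & (ng > 0), ncpg * window / np.maximum(nc * ng, 1), 0.0)
    gc = (nc + ng) / window
    return pd.DataFrame({"start": starts, "cpg_ratio": ratio, "gc": gc})


def classify_promoter_windows(windows: pd.DataFrame, thr: Thresholds) -> str:
    """HCP/ICP/LCP call from per-window CpG-ratio and GC statistics."""
    hcp = ((windows["cpg_ratio"] > thr.hcp_cpg_ratio) & (windows["gc"] > thr.hcp_gc)).any()
    if hcp:
        return "HCP"
    if (windows["cpg_ratio"] <= thr.lcp_cpg_ratio).all():
        return "LCP"
    return "ICP"


def classify_promoters(seqs: dict[str, str], thr: Thresholds) -> pd.DataFrame:
    """Classify promoter sequences into HCP/ICP/LCP.

    HCP: some ``promoter_win`` window has CpG ratio > ``hcp_cpg_ratio`` AND
    GC > ``hcp_gc``; LCP: no window has CpG ratio > ``lcp_cpg_ratio``;
    ICP otherwise.  Sequences shorter than the window are uncallable.
    """
    rows = []
    for name, seq in seqs.items():
        if len(seq) < thr.promoter_win:
            warnings.warn(f"promoter {name}: sequence shorter than the "
                          f"{thr.promoter_win}-bp window; uncallable", stacklevel=2)
            rows.append((name, "uncallable", np.nan, np.nan))
            continue
        win = window_composition(seq, thr.promoter_win, thr.promoter_step)
        cls = classify_promoter_windows(win, thr)
        best = win["cpg_ratio"].idxmax()
        rows.append((name, cls, float(win.loc[best, "cpg_ratio"]),
                     float(win.loc[best, "gc"])))
    return pd.DataFrame(
        rows, columns=["name", "class", "best_window_cpg_ratio", "best_window_gc"]
    ).set_index("name")


# ---------------------------------------------------------------------------
# gene metaprofile


def gene_metaprofile(
    cpgs: pd.DataFrame, genes: pd.DataFrame,
    flank: int = 5000, bins: tuple[int, int, int] = (50, 100, 50),
) -> pd.DataFrame:
    """Coverage-weighted mean methylation from 5' flank through the scaled
    gene body to the 3' flank.

    Flanks use fixed-width bins; the body is scaled to ``bins[1]`` bins;
    minus-strand genes are reversed so bin 0 is always 5'.  Genes shorter
    than the body bin count are skipped (logged).
    """
    n_up, n_body, n_down = bins
    n_total = n_up + n_body + n_down
    idx = _index_cpgs(cpgs)
    meth_acc = np.zeros(n_total)
    total_acc = np.zeros(n_total)
    site_acc = np.zeros(n_total, dtype=int)
    skipped = 0
    for _, g in genes.iterrows():
        length = g.end - g.start
        if length < n_body:
            skipped += 1
            continue
        if g.chrom not in idx:
            continue
        pos, cm, ct = idx[g.chrom]
        lo, hi = np.searchsorted(pos, [g.start - flank, g.end + flank])
        p = pos[lo:hi]
        m = np.diff(cm[lo:hi + 1])
        t = np.diff(ct[lo:hi + 1])
        rel = np.empty(len(p), dtype=np.int64)
        up = p < g.start
        body = (p >= g.start) & (p < g.end)
        down = p >= g.end
        rel[up] = (p[up] - (g.start - flank)) * n_up // flank
        rel[body] = n_up + (p[body] - g.start) * n_body // length
        rel[down] = n_up + n_body + (p[down] - g.end) * n_down // flank
        rel = np.clip(rel, 0, n_total - 1)
        if g.strand == "-":
            rel = n_total - 1 - rel
        np.add.at(meth_acc, rel, m)
        np.add.at(total_acc, rel, t)
        np.add.at(site_acc, rel, 1)
    if skipped:
        logger.info("metaprofile: %d genes shorter than %d bp skipped", skipped, n_body)
    region = (["upstream"] * n_up) + (["body"] * n_body) + (["downstream"] * n_down)
    with np.errstate(invalid="ignore", divide="ignore"):
        level = np.where(total_acc > 0, meth_acc / np.maximum(total_acc, 1), np.nan)
    return pd.DataFrame(
        {"bin": np.arange(n_total), "region": region,
         "mean_level": level, "n_sites": site_acc}
    )


# ---------------------------------------------------------------------------
# escapee tiles


def detect_escapees(
    cpgs: pd.DataFrame, chrom_sizes: dict[str, int], thr: Thresholds,
) -> pd.DataFrame:
    """Classify 800-nt genomic tiles as meth+ / meth- / uncallable.

    Per tile, only CpGs covered by >= ``escapee_min_cov`` reads count; tiles
    with fewer than ``escapee_min_callable_cpgs`` such CpGs are uncallable;
    ``frac`` is the share of counted CpGs whose pooled methylation level is
    >= ``escapee_meth_level``; meth+ requires ``frac`` strictly greater than
    ``escapee_cpg_frac``.
    """
    tile = thr.tile_escapee
    frames = []
    covered = cpgs[cpgs["total"] >= thr.escapee_min_cov]
    level = covered["meth"] / covered["total"]
    qualifies = level >= thr.escapee_meth_level
    for chrom, size in chrom_sizes.items():
        n_tiles = int(np.ceil(size / tile))
        sub = covered[covered["chrom"] == chrom]
        t_idx = (sub["pos"] // tile).to_numpy()
        n5x = np.bincount(t_idx, minlength=n_tiles)
        nq = np.bincount(t_idx, weights=qualifies[sub.index].to_numpy(),
                         minlength=n_tiles).astype(int)
        starts = np.arange(n_tiles) * tile
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(n5x > 0, nq / np.maximum(n5x, 1), np.nan)
        callable_ = n5x >= thr.escapee_min_callable_cpgs
        cls = np.where(
            ~callable_, "uncallable",
            np.where(frac > thr.escapee_cpg_frac, "meth+", "meth-"),
        )
        frames.append(pd.DataFrame(
            {
                "chrom": chrom,
                "start": starts,
                "end": np.minimum(starts + tile, size),
                "n_cpg_5x": n5x,
                "n_cpg_meth": nq,
                "frac": frac,
                "class": cls,
            }
        ))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# repeat overlap and TE enrichment


def _merge_intervals(starts: np.ndarray, ends: np.ndarray):
    """Merge possibly overlapping intervals into disjoint sorted ones."""
    if len(starts) == 0:
        return np.array([], dtype=np.int64), np.array([], dtype=np.int64)
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    keep_s, keep_e = [s[0]], [e[0]]
    for i in range(1, len(s)):
        if s[i] <= keep_e[-1]:
            keep_e[-1] = max(keep_e[-1], e[i])
        else:
            keep_s.append(s[i]); keep_e.append(e[i])
    return np.asarray(keep_s), np.asarray(keep_e)


def _covered_before(ms: np.ndarray, me: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Bases covered by the merged intervals below coordinate(s) x."""
    cumlen = np.concatenate([[0], np.cumsum(me - ms)])
    k = np.searchsorted(ms, x, side="right")
    partial = np.where(
        k > 0, np.clip(x - ms[np.maximum(k - 1, 0)], 0, (me - ms)[np.maximum(k - 1, 0)]), 0
    )
    full = cumlen[np.maximum(k - 1, 0)]
    return np.where(k > 0, full + partial, 0)


def interval_overlap_fraction(tiles: pd.DataFrame, features: pd.DataFrame) -> np.ndarray:
    """Per tile: fraction of bases covered by the union of the features."""
    frac = np.zeros(len(tiles))
    for chrom, sub in tiles.groupby("chrom", sort=False):
        feats = features[features["chrom"] == chrom]
        ms, me = _merge_intervals(feats["start"].to_numpy(), feats["end"].to_numpy())
        if len(ms) == 0:
            continue
        qs = sub["start"].to_numpy()
        qe = sub["end"].to_numpy()
        ov = _covered_before(ms, me, qe) - _covered_before(ms, me, qs)
        frac[tiles.index.get_indexer(sub.index)] = ov / (qe - qs)
    return frac


def classify_te_content(
    tiles: pd.DataFrame, repeats: pd.DataFrame, thr: Thresholds,
) -> pd.DataFrame:
    """Attach repeat-overlap fraction (union semantics) and TE-poor/TE-rich
    class (rich iff overlap >= ``te_rich_frac``)."""
    out = tiles.copy()
    out["te_overlap_frac"] = interval_overlap_fraction(out, repeats)
    out["te_class"] = np.where(
        out["te_overlap_frac"] >= thr.te_rich_frac, "TE-rich", "TE-poor"
    )
    return out


def te_enrichment(
    escapee_tiles: pd.DataFrame, background_tiles: pd.DataFrame,
    repeats: pd.DataFrame, thr: Thresholds,
) -> pd.DataFrame:
    """Per repeat family: enrichment score and Fisher's exact p.

    The 2x2 table is (escapee vs background tiles) x (overlaps the family vs
    not); ES is the ratio of overlap fractions; a family is flagged enriched
    when ES > ``es_cutoff`` and p < ``es_p_cutoff``.
    """
    n_fg, n_bg = len(escapee_tiles), len(background_tiles)
    if n_fg == 0 or n_bg == 0:
        raise ValueError("need non-empty escapee and background tile sets")
    rows = []
    for family, fam_repeats in repeats.groupby("family", sort=True):
        if not len(fam_repeats):
            logger.info("family %s absent from the genome; skipped", family)
            continue
        fg_ov = interval_overlap_fraction(escapee_tiles, fam_repeats) > 0
        bg_ov = interval_overlap_fraction(background_tiles, fam_repeats) > 0
        a, c = int(fg_ov.sum()), int(bg_ov.sum())
        fg_frac, bg_frac = a / n_fg, c / n_bg
        if bg_frac > 0:
            es = fg_frac / bg_frac
        else:
            es = np.inf if fg_frac > 0 else np.nan
        _, p = fisher_exact([[a, n_fg - a], [c, n_bg - c]], alternative="two-sided")
        rows.append((family, a, n_fg, c, n_bg, es, p))
    out = pd.DataFrame(
        rows,
        columns=["family", "n_escapee_overlap", "n_escapee",
                 "n_background_overlap", "n_background", "es", "p"],
    ).set_index("family")
    out["enriched"] = (out["es"] > thr.es_cutoff) & (out["p"] < thr.es_p_cutoff)
    return out


# ---------------------------------------------------------------------------
# repeat expression normalisation


def repeat_expression_rpm(
    counts: pd.DataFrame | pd.Series, library_sizes, lengths: pd.Series | None = None,
    rpkm: bool = False,
) -> pd.DataFrame | pd.Series:
    """Reads-per-million normalisation of repeat-region counts.

    ``rpkm=True`` additionally divides by region length in kb (the ambiguity
    between the two units is documented in the methods note).  Counts are
    assumed to come from an upstream counter restricted to mapping quality
    >= ``repeat_min_mapq``.
    """
    lib = pd.Series(library_sizes) if not np.isscalar(library_sizes) else library_sizes
    if np.isscalar(lib):
        if lib <= 0:
            raise ValueError("library size must be positive")
        out = counts * 1e6 / lib
    else:
        if (lib <= 0).any():
            raise ValueError("library sizes must be positive")
        out = counts.mul(1e6).div(lib, axis=1 if isinstance(counts, pd.DataFrame) else 0)
    if rpkm:
        if lengths is None:
            raise ValueError("rpkm normalisation needs region lengths")
        out = out.div(lengths.reindex(out.index) / 1000.0, axis=0)
    return out


def family_sums(values: pd.DataFrame | pd.Series, families: pd.Series):
    """Sum normalised repeat expression per family."""
    fam = families.reindex(values.index)
    return values.groupby(fam).sum()
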