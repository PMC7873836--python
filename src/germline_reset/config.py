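"""Global thresholds and configuration loading.

Every tunable constant of the pipeline lives in a single :class:`Thresholds`
object so that a run is fully described by (config, seed).  Defaults follow
the published analysis conventions for the pig germline: QC cut-offs of one
million mapped reads and a mitochondrial read proportion of 0.5, expressed
genes detected in >=3 cells at TPM>1, a chrY single-copy TPM of 10 for sex
calling, TPM+1 pseudocounts for geometric means, 1-Mb F:M ratio windows,
SNV filters (>=3 reads, >=2 cells per stage), 1-kb global and 800-nt escapee
methylation tiles, the escapee rule (>20% of >=5x CpGs at a species-specific
methylation level: 15% pig/mouse, 30% human), the TE-rich cut-off (10%
repeat overlap) and the enrichment criterion (ES>2, Fisher p<0.001), and
the HCP/ICP/LCP promoter classification windows.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

logger = logging.getLogger("germline_reset")

#: escapee methylation-level threshold by species preset
SPECIES_ESCAPEE_METH_LEVEL = {"pig": 0.15, "mouse": 0.15, "human": 0.30}


class ConfigError(ValueError):
    """Raised when a configuration value is out of range or unknown."""


@dataclass(frozen=True)
class Thresholds:
    # single-cell QC
    min_mapped_reads: int = 1_000_000
    max_mito_fraction: float = 0.5
    min_cells_expressing: int = 3
    min_tpm: float = 1.0
    # sex inference
    chry_male_tpm: float = 10.0
    #: pass-2 chrY:chrX ratio uses all chrY genes ("all") or single-copy only
    yx_ratio_genes: str = "all"
    # dosage
    geomean_pseudocount: float = 1.0
    fm_window: int = 1_000_000
    fm_window_min_genes: int = 3
    boot_genes: int = 100
    boot_reps: int = 1_000
    # allelic
    snv_min_reads: int = 3
    snv_min_cells: int = 2
    allele_detect_min_reads: int = 3
    allele_detect_min_frac: float = 0.10
    # methylome
    tile_global: int = 1_000
    tile_escapee: int = 800
    escapee_min_cov: int = 5
    escapee_cpg_frac: float = 0.20
    escapee_meth_level: float = 0.15
    escapee_min_callable_cpgs: int = 10
    te_rich_frac: float = 0.10
    es_cutoff: float = 2.0
    es_p_cutoff: float = 0.001
    # promoters
    promoter_up: int = 1_000
    promoter_down: int = 500
    promoter_win: int = 500
    promoter_step: int = 5
    hcp_cpg_ratio: float = 0.75
    hcp_gc: float = 0.55
    lcp_cpg_ratio: float = 0.48
    # metaprofile
    metaprofile_flank: int = 5_000
    # repeat expression
    repeat_min_mapq: int = 20
    #: species preset; switches escapee_meth_level unless that key is set
    species: str = "pig"

    def __post_init__(self) -> None:
        for key in (
            "max_mito_fraction",
            "allele_detect_min_frac",
            "escapee_cpg_frac",
            "escapee_meth_level",
            "te_rich_frac",
            "es_p_cutoff",
            "hcp_gc",
        ):
            v = getattr(self, key)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{key} must be a proportion in [0, 1], got {v!r}")
        for key in (
            "min_mapped_reads",
            "min_cells_expressing",
            "fm_window",
            "fm_window_min_genes",
            "boot_genes",
            "boot_reps",
            "snv_min_reads",
            "snv_min_cells",
            "allele_detect_min_reads",
            "tile_global",
            "tile_escapee",
            "escapee_min_cov",
            "escapee_min_callable_cpgs",
            "promoter_up",
            "promoter_down",
            "promoter_win",
            "promoter_step",
            "metaprofile_flank",
        ):
            v = getattr(self, key)
            if not (isinstance(v, (int,)) and v > 0):
                raise ConfigError(f"{key} must be a positive integer, got {v!r}")
        for key in ("min_tpm", "chry_male_tpm", "geomean_pseudocount", "es_cutoff"):
            if getattr(self, key) < 0:
                raise ConfigError(f"{key} must be non-negative")
        if not self.lcp_cpg_ratio < self.hcp_cpg_ratio:
            raise ConfigError(
                "lcp_cpg_ratio must be smaller than hcp_cpg_ratio "
                f"({self.lcp_cpg_ratio} vs {self.hcp_cpg_ratio})"
            )
        if self.species not in SPECIES_ESCAPEE_METH_LEVEL:
            raise ConfigError(
                f"unknown species {self.species!r}; "
                f"expected one of {sorted(SPECIES_ESCAPEE_METH_LEVEL)}"
            )
        if self.yx_ratio_genes not in ("all", "single_copy"):
            raise ConfigError("yx_ratio_genes must be 'all' or 'single_copy'")

    def replace(self, **kwargs) -> "Thresholds":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_FIELD_NAMES = {f.name for f in dataclasses.fields(Thresholds)}


def load_config(path: str | Path | None = None, **overrides) -> Thresholds:
    """Load a YAML/JSON configuration file and return resolved Thresholds.

    Absent keys take their defaults; unknown keys are rejected.  A ``species``
    key of ``pig``/``mouse``/``human`` switches ``escapee_meth_level`` to the
    corresponding preset unless that key is given explicitly.  The fully
    resolved configuration is logged.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)  # YAML is a JSON superset
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        data.update(loaded)
    data.update(overrides)

    unknown = set(data) - _FIELD_NAMES
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")

    if "species" in data and "escapee_meth_level" not in data:
        species = data["species"]
        if species not in SPECIES_ESCAPEE_METH_LEVEL:
            raise ConfigError(
                f"unknown species {species!r}; "
                f"expected one of {sorted(SPECIES_ESCAPEE_METH_LEVEL)}"
            )
        data["escapee_meth_level"] = SPECIES_ESCAPEE_METH_LEVEL[species]

    thr = Thresholds(**data)
    logger.info("resolved configuration: %s", json.dumps(thr.to_dict(), sort_keys=True))
    return thr
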