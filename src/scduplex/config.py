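"""Run configuration, caller thresholds, and cohort presets.

The ``published`` cohort preset encodes the study conditions the synthetic
cohort emulates: control neurons accumulating ~16.5 sSNVs and ~2.5 sIndels
per year, a CTE condition effect of +114 sSNVs per cell (of which +64 are
attributed to the disease-associated SNV signature), and a +312 sIndels per
cell cohort-mean excess produced by a mixture of High-Indel (excess 500) and
Low-Indel (excess 30) individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import yaml


@dataclass
class ConditionPreset:
    """Condition-specific burden effects (per cell, added to the age trend)."""

    n_individuals: int
    age_range: tuple[float, float]
    snv_excess: float = 0.0
    snv_excess_sig_disease: float = 0.0  # portion of snv_excess on the disease signature
    indel_excess_low: float = 0.0
    indel_excess_high: float = 0.0
    high_indel_fraction: float = 0.0


@dataclass
class CallerThresholds:
    """Filter cascade thresholds for duplex calling and cell-level QC."""

    min_total_alt: int = 4           # a4s2: total ALT reads (ds)
    min_strand_alt: int = 2          # a4s2: ALT reads per strand (ds)
    ss_min_alt: int = 4              # ss: ALT reads on the variant strand
    ss_min_other_ref: int = 4        # ss: REF reads on the non-variant strand
    require_vaf_one: bool = True     # single-molecule VAF = 1 (ds)
    proximity_bp: int = 100          # candidates within this distance both removed
    read_end_bp: int = 20            # min distance to read end (inclusive window)
    population_af: float = 0.01      # population-variant exclusion cutoff
    germline_flank_min_bp: int = 5   # flank = max(5, 2 * germline indel length)
    insert_mean_min: float = 280.0
    insert_mean_max: float = 500.0
    insert_sd_max: float = 750.0
    contamination_overlap: float = 0.5  # pre-filter population-variant overlap
    proximity_within_class_only: bool = True


@dataclass
class CohortConfig:
    """Everything the synthetic-data generator needs for one cohort."""

    seed: int = 1
    # genome fixture
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000}
    )
    accessibility_bin_bp: int = 1000
    n_genes: int = 400
    gene_length_bp: tuple[int, int] = (2000, 20_000)
    n_population_variants: int = 3000
    n_het_snps: int = 1000
    mask_fraction: float = 0.01
    repeat_fraction: float = 0.02  # homopolymer / STR tracts planted in the sequence
    # burden model (per cell per year / per cell)
    snv_rate_per_year: float = 16.5
    snv_intercept: float = 50.0
    snv_rate_sig_aging: float = 15.0     # age slope attributed to the aging signature
    snv_intercept_sig_aging: float = 35.0
    indel_rate_per_year: float = 2.5
    indel_rate_per_year_upper: float = 3.0  # upper bound of the normal annual rate
    indel_intercept: float = 10.0
    individual_sd_snv: float = 25.0
    individual_sd_indel: float = 12.0
    residual_sd_snv: float = 50.0
    residual_sd_indel: float = 25.0
    cells_per_individual: int = 4
    conditions: dict[str, ConditionPreset] = field(default_factory=dict)
    # spectra
    ss_sig_disease_weight: float = 0.67  # disease-signature share of ssSNV catalogs
    ds_sig_disease_weight: float = 0.23  # disease-signature share of dsSNV catalogs
    pta_ds_weight: float = 0.85          # DS share of PTA spectra (strand conversion)
    indel_weights_control: dict[str, float] = field(
        default_factory=lambda: {"ID_aging": 0.55, "ID_repeat": 0.35, "ID_deletion": 0.10}
    )
    indel_weights_high: dict[str, float] = field(
        default_factory=lambda: {"ID_aging": 0.20, "ID_repeat": 0.15, "ID_deletion": 0.65}
    )
    # duplex fragment simulation
    n_tags: int = 16
    fragments_per_cell: int = 300
    reads_per_strand: int = 4
    fragment_length: tuple[int, int] = (300, 500)
    lesion_to_mutation_ratio: float = 0.5
    artifact_rate_read_end: float = 0.0
    artifact_rate_collision: float = 0.0
    artifact_rate_merge_window: float = 0.0
    contamination_fraction: float = 0.0     # fraction of cells contaminated
    contamination_sites: int = 200
    n_germline_per_cell: int = 20
    germline_indel_fraction: float = 0.5
    # expression / accessibility
    expression_logmean: float = 1.0
    expression_logsd: float = 1.0
    zero_expression_fraction: float = 0.3
    accessibility_expression_corr: float = 0.6
    expression_gradient: float = 0.0  # planted mutation-vs-expression enrichment slope

    def validate(self) -> None:
        for name, ln in self.chrom_lengths.items():
            if ln < 10_000:
                raise ValueError(f"chromosome {name} shorter than 10 kb")
        for attr in (
            "snv_rate_per_year", "indel_rate_per_year", "individual_sd_snv",
            "individual_sd_indel", "residual_sd_snv", "residual_sd_indel",
        ):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be non-negative")
        for cond in self.conditions.values():
            lo, hi = cond.age_range
            if lo < 0 or hi < lo:
                raise ValueError("invalid age range")
        for w in (self.indel_weights_control, self.indel_weights_high):
            if abs(sum(w.values()) - 1.0) > 1e-9:
                raise ValueError("indel mixture weights must sum to 1")


def published_preset(
    seed: int = 1,
    n_control: int = 24,
    n_cte: int = 24,
    n_rhi: int = 0,
    n_ad: int = 0,
    cells_per_individual: int = 4,
) -> CohortConfig:
    """Cohort configuration carrying the published effect sizes.

    CTE: +114 excess sSNVs per cell (64 on the disease signature), and a
    High-/Low-Indel mixture with cohort-mean excess 0.6*500 + 0.4*30 = 312
    sIndels per cell.
    """
    conditions = {
        "control": ConditionPreset(n_individuals=n_control, age_range=(20.0, 95.0)),
    }
    if n_cte:
        conditions["CTE"] = ConditionPreset(
            n_individuals=n_cte,
            age_range=(40.0, 90.0),
            snv_excess=114.0,
            snv_excess_sig_disease=64.0,
            indel_excess_low=30.0,
            indel_excess_high=500.0,
            high_indel_fraction=0.6,
        )
    if n_rhi:
        conditions["RHI"] = ConditionPreset(n_individuals=n_rhi, age_range=(25.0, 60.0))
    if n_ad:
        conditions["AD"] = ConditionPreset(
            n_individuals=n_ad,
            age_range=(60.0, 95.0),
            snv_excess=110.0,
            snv_excess_sig_disease=55.0,
            indel_excess_low=30.0,
            indel_excess_high=450.0,
            high_indel_fraction=0.4,
        )
    return CohortConfig(seed=seed, cells_per_individual=cells_per_individual,
                        conditions=conditions)


def config_to_yaml(cfg: CohortConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(asdict(cfg)), fh, sort_keys=False)


def config_from_yaml(path) -> CohortConfig:
    with open(path) as fh:
        raw: dict[str, Any] = yaml.safe_load(fh)
    conds = {
        name: ConditionPreset(**{**c, "age_range": tuple(c["age_range"])})
        for name, c in raw.pop("conditions", {}).items()
    }
    raw["gene_length_bp"] = tuple(raw.get("gene_length_bp", (2000, 20_000)))
    raw["fragment_length"] = tuple(raw.get("fragment_length", (300, 500)))
    cfg = CohortConfig(**raw, conditions=conds)
    cfg.validate()
    return cfg


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj
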