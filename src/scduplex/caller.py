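"""Strand-resolved duplex variant caller.

Implements the full filter cascade for calling double-stranded (ds) somatic
mutations and single-stranded (ss) lesions from strand-tagged fragment
groups, plus single-cell amplification QC (MAPD, CoV, dropout rates) and
cell-level exclusions (insert-size gates, contamination by population-variant
overlap).

Calling rules:

* ds: no bulk ALT read, >=4 total ALT reads with >=2 from each strand
  (a4s2), and single-molecule VAF = 1.
* ss: no bulk ALT read, >=4 ALT reads on the variant strand, no ALT read on
  the other strand, and >=4 REF reads on the other strand.
* Site filters (both classes): low-quality-region overlap; population
  variants at >=1% allele frequency; two candidates within 100 bp remove
  each other; more than one barcode pair covering the site; more than one
  Tn5 cut-site set for the covering barcode pair; site within 20 bp of a
  read end. Indels additionally: merge-window overlap, absence from the
  unmerged representation, and proximity to a germline indel start within
  max(5, 2 x germline indel length) bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CallerThresholds
from .contexts import left_align_indel


# ---------------------------------------------------------------------------
# amplification QC


@dataclass
class CellQC:
    cell_id: str
    mapd: float
    cov_adjacent: float
    mean_depth: float
    allelic_dropout: float
    locus_dropout: float
    strand_dropout: float
    insert_mean: float = float("nan")
    insert_sd: float = float("nan")
    popvar_overlap: float = float("nan")
    flags: list[str] = field(default_factory=list)
    passed: bool = True
    reasons: list[str] = field(default_factory=list)


def compute_amplification_qc(
    bin_copy_ratios: np.ndarray,
    het_snp_depths: pd.DataFrame,
    read_stats: dict,
    cell_id: str = "cell",
) -> CellQC:
    """Amplification-evenness and dropout metrics for one cell.

    MAPD is the median of absolute pairwise differences between
    log2-transformed copy-number ratios of adjacent bins; CoV is the
    sd/mean of those absolute differences. Allelic dropout is the fraction
    of germline het SNPs with REF or ALT depth < 2; locus dropout the
    fraction with total depth < 5; strand dropout the square root of
    allelic dropout. Depth = properly-paired reads x read length / genome
    length.
    """
    ratios = np.asarray(bin_copy_ratios, dtype=float)
    if len(ratios) < 2:
        raise ValueError("need at least two bins")
    if np.any(ratios <= 0):
        raise ValueError("non-positive copy ratio: log2 undefined")
    diffs = np.abs(np.diff(np.log2(ratios)))
    mapd = float(np.median(diffs))
    flags = []
    mean_diff = diffs.mean()
    if mean_diff == 0:
        cov = float("nan")
        flags.append("cov_undefined")
    else:
        cov = float(diffs.std(ddof=1) / mean_diff)
    if len(het_snp_depths) < 1:
        raise ValueError("need at least one het SNP")
    ref_d = het_snp_depths["ref_depth"].to_numpy()
    alt_d = het_snp_depths["alt_depth"].to_numpy()
    ado = float(np.mean((ref_d < 2) | (alt_d < 2)))
    ldo = float(np.mean((ref_d + alt_d) < 5))
    depth = (read_stats["properly_paired"] * read_stats["read_length"]
             / read_stats["genome_length"])
    return CellQC(
        cell_id=cell_id,
        mapd=mapd,
        cov_adjacent=cov,
        mean_depth=float(depth),
        allelic_dropout=ado,
        locus_dropout=ldo,
        strand_dropout=float(np.sqrt(ado)),
        insert_mean=float(read_stats.get("insert_mean", np.nan)),
        insert_sd=float(read_stats.get("insert_sd", np.nan)),
        flags=flags,
    )


def filter_cells(qc: CellQC, thresholds: CallerThresholds | None = None) -> CellQC:
    """Apply the cell-level exclusion gates; records pass/fail with reasons."""
    th = thresholds or CallerThresholds()
    reasons = []
    if not np.isnan(qc.insert_mean) and not (
        th.insert_mean_min <= qc.insert_mean <= th.insert_mean_max
    ):
        reasons.append("insert_size")
    if not np.isnan(qc.insert_sd) and qc.insert_sd > th.insert_sd_max:
        reasons.append("insert_size_sd")
    if not np.isnan(qc.popvar_overlap) and qc.popvar_overlap > th.contamination_overlap:
        reasons.append("contamination")
    qc.reasons = reasons
    qc.passed = not reasons
    return qc


# ---------------------------------------------------------------------------
# fragment grouping and candidate evidence


def group_fragments(observations: pd.DataFrame) -> pd.DataFrame:
    """Group per-site observations into fragment groups.

    One group per (cell, chromosome, barcode pair, Tn5 cut-site pair);
    observations missing either barcode are dropped (count recorded in
    ``DataFrame.attrs['n_dropped_barcode']``). The output carries a stable
    ``group_id`` and is sorted canonically so that input order is
    irrelevant.
    """
    obs = observations.copy()
    missing = obs["bc1"].isna() | obs["bc2"].isna()
    n_dropped = int(missing.sum())
    obs = obs[~missing]
    bad = obs["end"] <= obs["start"]
    if bad.any():
        raise ValueError("cut sites must define a positive-length interval")
    outside = (obs["pos"] < obs["start"]) | (obs["pos"] > obs["end"])
    if outside.any():
        raise ValueError("observed site outside its cut-site interval")
    key_cols = ["cell_id", "chrom", "bc1", "bc2", "start", "end"]
    obs = obs.sort_values(key_cols + ["strand", "pos", "alt"],
                          kind="stable").reset_index(drop=True)
    obs["group_id"] = obs.groupby(key_cols, sort=True).ngroup()
    obs.attrs["n_dropped_barcode"] = n_dropped
    return obs


def build_candidates(
    grouped: pd.DataFrame,
    bulk: pd.DataFrame,
    thresholds: CallerThresholds | None = None,
) -> pd.DataFrame:
    """Aggregate per-site strand evidence into variant candidates.

    For each (cell, chrom, pos, alt) with ALT support: per-strand ALT/REF
    read counts on the variant molecule, single-molecule VAF, bulk ALT
    depth, the number of distinct barcode pairs covering the site, the
    number of distinct cut-site sets for the covering barcode pair, the
    minimum ALT-read distance to a read end, and merge-window /
    unmerged-representation annotations for indels.
    """
    alt_rows = grouped[grouped["alt"] != "."]
    if alt_rows.empty:
        return pd.DataFrame(columns=_CAND_COLS)
    bulk_idx = {}
    if len(bulk):
        bulk_idx = {(r.chrom, r.pos): r.alt_depth for r in bulk.itertuples(index=False)}
    # site-level coverage statistics over all fragments
    cov = grouped.groupby(["cell_id", "chrom", "pos"])
    n_bc = cov.apply(lambda d: d[["bc1", "bc2"]].drop_duplicates().shape[0],
                     include_groups=False)
    rows = []
    for (cell, chrom, pos, alt), sub in alt_rows.groupby(
        ["cell_id", "chrom", "pos", "alt"], sort=True
    ):
        ref = sub["ref"].iloc[0]
        bc1, bc2 = sub["bc1"].iloc[0], sub["bc2"].iloc[0]
        site_rows = grouped[
            (grouped["cell_id"] == cell) & (grouped["chrom"] == chrom)
            & (grouped["pos"] == pos)
        ]
        mol = site_rows[(site_rows["bc1"] == bc1) & (site_rows["bc2"] == bc2)]
        n_cut = mol[["start", "end"]].drop_duplicates().shape[0]
        mol_main = mol[(mol["start"] == sub["start"].iloc[0])
                       & (mol["end"] == sub["end"].iloc[0])]
        plus = mol_main[mol_main["strand"] == "+"]
        minus = mol_main[mol_main["strand"] == "-"]

        def _count(d, is_alt):
            sel = d["alt"] == alt if is_alt else d["alt"] == "."
            return int(d.loc[sel, "reads"].sum())

        pa, pr = _count(plus, True), _count(plus, False)
        ma, mr = _count(minus, True), _count(minus, False)
        total_alt = pa + ma
        total = total_alt + pr + mr
        vaf = total_alt / total if total else float("nan")
        dist = np.minimum(sub["pos"] - sub["start"], sub["end"] - sub["pos"])
        in_mw = bool(((sub["mw_start"] > 0) & (sub["pos"] >= sub["mw_start"])
                      & (sub["pos"] <= sub["mw_end"])).any())
        rows.append({
            "cell_id": cell, "chrom": chrom, "pos": int(pos), "ref": ref,
            "alt": alt, "var_class": sub["var_class"].iloc[0],
            "bulk_alt": int(bulk_idx.get((chrom, pos), 0)),
            "plus_alt": pa, "plus_ref": pr, "minus_alt": ma, "minus_ref": mr,
            "vaf": vaf,
            "n_barcode_pairs": int(n_bc.loc[(cell, chrom, pos)]),
            "n_cutsite_sets": int(n_cut),
            "min_dist_end": int(dist.min()),
            "in_merge_window": in_mw,
            "in_unmerged": bool(sub["in_unmerged"].all()),
            "filters": "",
        })
    return pd.DataFrame(rows, columns=_CAND_COLS)


_CAND_COLS = [
    "cell_id", "chrom", "pos", "ref", "alt", "var_class", "bulk_alt",
    "plus_alt", "plus_ref", "minus_alt", "minus_ref", "vaf",
    "n_barcode_pairs", "n_cutsite_sets", "min_dist_end", "in_merge_window",
    "in_unmerged", "filters",
]


# ---------------------------------------------------------------------------
# candidate screening


def _add_flag(flags: pd.Series, sel, name: str) -> None:
    flags.loc[sel] = flags.loc[sel].apply(
        lambda f: f"{f};{name}" if f else name
    )


def screen_candidates(
    candidates: pd.DataFrame,
    fixture=None,
    mask_regions: pd.DataFrame | None = None,
    population_variants: pd.DataFrame | None = None,
    germline_indels: pd.DataFrame | None = None,
    thresholds: CallerThresholds | None = None,
) -> pd.DataFrame:
    """Apply the site-level filter cascade; failed rules append named flags.

    A candidate passes only with an empty flag list. The proximity rule
    removes BOTH members of any pair closer than the window. Window rules
    are inclusive (distance <= window).
    """
    th = thresholds or CallerThresholds()
    if fixture is not None:
        mask_regions = getattr(fixture, "mask_regions", mask_regions)
        population_variants = getattr(fixture, "population_variants",
                                      population_variants)
    cand = candidates.copy().reset_index(drop=True)
    if cand.empty:
        return cand
    flags = cand["filters"].fillna("").copy()

    if mask_regions is not None and len(mask_regions):
        for row in mask_regions.itertuples(index=False):
            sel = ((cand["chrom"] == row.chrom) & (cand["pos"] >= row.start)
                   & (cand["pos"] <= row.end))
            _add_flag(flags, sel, "low_quality_region")

    if population_variants is not None and len(population_variants):
        pv = population_variants
        common = pv[pv["af"] >= th.population_af]
        is_indel = cand["var_class"].isin(["INS", "DEL"])
        snp_sites = set(zip(common.loc[common["var_class"] == "SNV", "chrom"],
                            common.loc[common["var_class"] == "SNV", "pos"]))
        ind_sites = set(zip(common.loc[common["var_class"] != "SNV", "chrom"],
                            common.loc[common["var_class"] != "SNV", "pos"]))
        key = list(zip(cand["chrom"], cand["pos"]))
        sel_snv = pd.Series([k in snp_sites for k in key], index=cand.index) & ~is_indel
        sel_ind = pd.Series([k in ind_sites for k in key], index=cand.index) & is_indel
        _add_flag(flags, sel_snv | sel_ind, "population_variant")

    # proximity: both members of any within-window pair are flagged
    classes = cand["var_class"].where(~cand["var_class"].isin(["INS", "DEL"]),
                                      "INDEL")
    prox_groups = (["cell_id", "chrom", classes] if th.proximity_within_class_only
                   else ["cell_id", "chrom"])
    prox = pd.Series(False, index=cand.index)
    for _, sub in cand.groupby(prox_groups, sort=False):
        pos = sub["pos"].sort_values()
        close = pos.diff() <= th.proximity_bp
        hit = close | close.shift(-1, fill_value=False)
        prox.loc[pos.index[hit]] = True
    _add_flag(flags, prox, "proximity")

    _add_flag(flags, cand["n_barcode_pairs"] > 1, "multi_barcode")
    _add_flag(flags, cand["n_cutsite_sets"] > 1, "cutsite_collision")
    _add_flag(flags, cand["min_dist_end"] <= th.read_end_bp, "read_end")

    is_indel = cand["var_class"].isin(["INS", "DEL"])
    _add_flag(flags, is_indel & cand["in_merge_window"], "merge_window")
    _add_flag(flags, is_indel & ~cand["in_unmerged"], "unmerged_absent")

    if germline_indels is not None and len(germline_indels):
        gsel = pd.Series(False, index=cand.index)
        for g in germline_indels.itertuples(index=False):
            glen = int(getattr(g, "indel_len", max(len(g.ref), len(g.alt)) - 1))
            flank = max(th.germline_flank_min_bp, 2 * glen)
            sel = (is_indel & (cand["chrom"] == g.chrom)
                   & ((cand["pos"] - g.pos).abs() <= flank))
            gsel |= sel
        _add_flag(flags, gsel, "germline_flank")

    cand["filters"] = flags
    return cand


# ---------------------------------------------------------------------------
# per-candidate calling rules


def call_ds_snv(c, thresholds: CallerThresholds | None = None):
    """a4s2 + VAF=1 double-stranded call, or None."""
    th = thresholds or CallerThresholds()
    if c["filters"]:
        return None
    if c["bulk_alt"] > 0:
        return None
    total_alt = c["plus_alt"] + c["minus_alt"]
    if total_alt < th.min_total_alt:
        return None
    if c["plus_alt"] < th.min_strand_alt or c["minus_alt"] < th.min_strand_alt:
        return None
    if th.require_vaf_one and not np.isclose(c["vaf"], 1.0):
        return None
    return {**_site(c), "strandedness": "ds", "strand": "."}


def call_ss_snv(c, thresholds: CallerThresholds | None = None):
    """Single-stranded call with strand label, or None.

    Sites with duplex-compatible evidence (ALT on both strands meeting the
    per-strand minimum) are routed to the ds path, not called ss.
    """
    th = thresholds or CallerThresholds()
    if c["filters"]:
        return None
    if c["bulk_alt"] > 0:
        return None
    if (c["plus_alt"] >= th.min_strand_alt
            and c["minus_alt"] >= th.min_strand_alt):
        return None  # ds-compatible evidence
    for var, other_alt, other_ref, strand in (
        ("plus", "minus_alt", "minus_ref", "+"),
        ("minus", "plus_alt", "plus_ref", "-"),
    ):
        if (c[f"{var}_alt"] >= th.ss_min_alt and c[other_alt] == 0
                and c[other_ref] >= th.ss_min_other_ref):
            return {**_site(c), "strandedness": "ss", "strand": strand}
    return None


def call_ds_indel(c, thresholds: CallerThresholds | None = None):
    """ds indel call: ds-SNV evidence thresholds plus the indel filters.

    The merge-window, unmerged-representation and germline-flank rules are
    applied during screening; their flags block the call here.
    """
    return call_ds_snv(c, thresholds)


def call_ss_indel(c, thresholds: CallerThresholds | None = None):
    return call_ss_snv(c, thresholds)


def _site(c) -> dict:
    return {k: c[k] for k in ("cell_id", "chrom", "pos", "ref", "alt",
                              "var_class", "vaf")}


def call_variants(
    candidates: pd.DataFrame, thresholds: CallerThresholds | None = None
) -> pd.DataFrame:
    """Apply the ds and ss calling rules to screened candidates.

    Returns the pass-filter call table; the ds and ss call sets are
    disjoint by construction (ds-compatible evidence is never called ss).
    """
    th = thresholds or CallerThresholds()
    calls = []
    for _, c in candidates.iterrows():
        is_indel = c["var_class"] in ("INS", "DEL")
        rec = (call_ds_indel(c, th) if is_indel else call_ds_snv(c, th))
        if rec is None:
            rec = (call_ss_indel(c, th) if is_indel else call_ss_snv(c, th))
        if rec is not None:
            rec["filters"] = ""
            calls.append(rec)
    cols = ["cell_id", "chrom", "pos", "ref", "alt", "var_class", "vaf",
            "strandedness", "strand", "filters"]
    return pd.DataFrame(calls, columns=cols)


def popvar_overlap_fraction(candidates: pd.DataFrame,
                            population_variants: pd.DataFrame,
                            af_min: float = 0.01) -> float:
    """Fraction of pre-filter somatic candidates (no bulk ALT support) at
    common population-variant sites (contamination diagnostic)."""
    if "bulk_alt" in candidates:
        candidates = candidates[candidates["bulk_alt"] == 0]
    if candidates.empty:
        return 0.0
    common = population_variants[population_variants["af"] >= af_min]
    sites = set(zip(common["chrom"], common["pos"]))
    hits = sum((c, p) in sites for c, p in zip(candidates["chrom"],
                                               candidates["pos"]))
    return hits / len(candidates)


def normalize_indel(seq: str, pos: int, ref: str, alt: str):
    """Left-align an indel (1-based pos in, 1-based out)."""
    p0, r, a = left_align_indel(seq, pos - 1, ref, alt)
    return p0 + 1, r, a
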