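"""Context-preserving permutation and enrichment analysis.

Observed somatic calls are shuffled across each cell's callable regions
while preserving chromosome and (pyrimidine-normalized) trinucleotide
context — indels keep their allele and take the context at their start
position. Enrichment across expression deciles / accessibility quantiles is
the observed/expected density ratio per permutation round, summarized as
mean +- SD with a linear trend test, optionally split by fitted signature
contributions, and compared between transcribed and non-transcribed genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .burden import test_excess_wilcoxon
from .contexts import TRINUC32_INDEX, normalize_trinuc, stable_key, trinuc_codes
from .signatures import fit_signatures


# ---------------------------------------------------------------------------
# permutation


@dataclass
class PermutationSet:
    """Shuffled call positions, one row per (round, call).

    ``table`` columns: round, cell_id, chrom, pos, ref, alt, var_class,
    context_code. Per round, the call count, per-chromosome count, and
    per-context count equal the originals by construction.
    """

    table: pd.DataFrame
    n_rounds: int


def _call_context_codes(calls: pd.DataFrame, fixture) -> np.ndarray:
    codes = np.empty(len(calls), dtype=int)
    for i, row in enumerate(calls.itertuples(index=False)):
        seq = fixture.sequences[row.chrom]
        p = int(row.pos) - 1
        codes[i] = TRINUC32_INDEX[normalize_trinuc(seq[p - 1 : p + 2])]
    return codes


def build_context_positions(fixture, callable_df=None):
    """Per-chromosome arrays of callable 1-based positions per context code."""
    if callable_df is None:
        return fixture.context_index()
    index = {}
    for chrom in fixture.chrom_lengths:
        codes = trinuc_codes(fixture.encoded(chrom).astype(np.int64))
        mask = np.zeros(fixture.chrom_lengths[chrom], dtype=bool)
        for row in callable_df[callable_df["chrom"] == chrom].itertuples(index=False):
            mask[row.start - 1 : row.end] = True
        inner = mask[1:-1]
        index[chrom] = {
            code: np.flatnonzero((codes == code) & inner) + 2 for code in range(32)
        }
    return index


def permute_calls(
    calls: pd.DataFrame,
    fixture,
    n_rounds: int = 1000,
    seed: int = 0,
    callable_df: pd.DataFrame | None = None,
) -> PermutationSet:
    """Generate ``n_rounds`` context- and chromosome-preserving shuffles.

    Each call is reassigned, independently per round, to a uniform position
    among the callable positions on its own chromosome with its own
    trinucleotide context. A context with no available position raises an
    error naming it.
    """
    if calls.empty:
        return PermutationSet(pd.DataFrame(columns=[
            "round", "cell_id", "chrom", "pos", "ref", "alt", "var_class",
            "context_code"]), n_rounds)
    index = build_context_positions(fixture, callable_df)
    calls = calls.reset_index(drop=True)
    codes = _call_context_codes(calls, fixture)
    out_pos = np.empty((n_rounds, len(calls)), dtype=np.int64)
    cell_ids = calls["cell_id"].to_numpy() if "cell_id" in calls else \
        np.repeat("cell", len(calls))
    for cell in pd.unique(cell_ids):
        cell_sel = np.flatnonzero(cell_ids == cell)
        rng = np.random.default_rng([seed, stable_key(str(cell))])
        sub_chrom = calls["chrom"].to_numpy()[cell_sel]
        sub_codes = codes[cell_sel]
        for chrom in np.unique(sub_chrom):
            for code in np.unique(sub_codes[sub_chrom == chrom]):
                sel = cell_sel[(sub_chrom == chrom) & (sub_codes == code)]
                pool = index[chrom][int(code)]
                if len(pool) == 0:
                    from .contexts import TRINUC32
                    raise ValueError(
                        f"context {TRINUC32[int(code)]} has no callable "
                        f"position on {chrom}")
                draw = rng.integers(0, len(pool), size=(n_rounds, len(sel)))
                out_pos[:, sel] = pool[draw]
    frames = []
    cols = ["cell_id", "chrom", "ref", "alt", "var_class"]
    if "context" in calls:
        cols.append("context")
    base = calls[[c for c in cols if c in calls]].copy()
    is_snv = (calls["var_class"] == "SNV").to_numpy() if "var_class" in calls \
        else np.ones(len(calls), bool)
    from .contexts import COMPLEMENT

    for r in range(n_rounds):
        f = base.copy()
        f.insert(0, "round", r)
        f["pos"] = out_pos[r]
        f["context_code"] = codes
        # re-strand SNV alleles to the destination site (context preserved up
        # to reverse complement, so the new reference base is ref or its
        # complement)
        new_ref, new_alt = [], []
        for i, row in enumerate(f.itertuples(index=False)):
            if not is_snv[i]:
                new_ref.append(row.ref)
                new_alt.append(row.alt)
                continue
            site = fixture.sequences[row.chrom][row.pos - 1]
            if site == row.ref:
                new_ref.append(row.ref)
                new_alt.append(row.alt)
            else:
                new_ref.append(site)
                new_alt.append(COMPLEMENT[row.alt])
        f["ref"] = new_ref
        f["alt"] = new_alt
        frames.append(f)
    return PermutationSet(pd.concat(frames, ignore_index=True), n_rounds)


# ---------------------------------------------------------------------------
# ranking / binning


def rank_bin_features(values: pd.Series, n_groups: int) -> tuple[pd.Series, dict]:
    """Rank-order split into equal-size groups (0 = lowest values).

    Ties are broken by stable input order; when the total is not divisible,
    the extra members go to the lowest groups. An all-equal input is
    flagged degenerate.
    """
    n = len(values)
    if n_groups < 1 or n_groups > n:
        raise ValueError("invalid group count")
    order = np.argsort(values.to_numpy(), kind="stable")
    sizes = np.full(n_groups, n // n_groups)
    sizes[: n % n_groups] += 1
    assignment = np.empty(n, dtype=int)
    start = 0
    for g, s in enumerate(sizes):
        assignment[order[start : start + s]] = g
        start += s
    degenerate = bool(values.nunique() <= 1)
    return (pd.Series(assignment, index=values.index, name="group"),
            {"degenerate": degenerate, "sizes": sizes.tolist()})


# ---------------------------------------------------------------------------
# enrichment ratios


@dataclass
class EnrichmentResult:
    table: pd.DataFrame      # group, observed, expected_mean, ratio_mean, ratio_sd, flagged
    trend_r: float
    trend_p: float
    ratios_by_round: np.ndarray  # n_rounds x n_groups


def _assign_groups(positions_chrom, positions_pos, regions: pd.DataFrame,
                   spans=None):
    """Map positions to region groups; -1 = outside, -2 = multi-region span.

    ``regions`` must be non-overlapping with columns chrom, start, end,
    group (1-based inclusive).
    """
    out = np.full(len(positions_pos), -1, dtype=int)
    for chrom, sub in regions.groupby("chrom"):
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        grp = sub["group"].to_numpy()
        sel = np.flatnonzero(positions_chrom == chrom)
        if len(sel) == 0:
            continue
        pos = positions_pos[sel]
        gi = np.searchsorted(starts, pos, side="right") - 1
        inside = (gi >= 0) & (pos <= ends[np.clip(gi, 0, None)])
        res = np.where(inside, grp[np.clip(gi, 0, None)], -1)
        if spans is not None:
            endpos = pos + spans[sel]
            gj = np.searchsorted(starts, endpos, side="right") - 1
            inside2 = (gj >= 0) & (endpos <= ends[np.clip(gj, 0, None)])
            multi = (inside | inside2) & ((gi != gj) | (inside != inside2))
            res = np.where(multi, -2, res)
        out[sel] = res
    return out


def _region_spans(calls: pd.DataFrame) -> np.ndarray:
    return np.array([max(len(r) - 1, 0) for r in calls["ref"]], dtype=int)


def enrichment_ratios(
    observed: pd.DataFrame,
    permutations: PermutationSet,
    regions: pd.DataFrame,
    n_groups: int | None = None,
) -> EnrichmentResult:
    """Observed/expected call-count ratios per region group and round.

    ``regions``: non-overlapping intervals with a ``group`` column. Calls
    overlapping more than one region are removed from both the observed and
    the permuted sets. A group with zero expected count in a round is
    flagged (its ratio is undefined and excluded from the mean).
    """
    if n_groups is None:
        n_groups = int(regions["group"].max()) + 1
    obs_grp = _assign_groups(observed["chrom"].to_numpy(),
                             observed["pos"].to_numpy(int), regions,
                             spans=_region_spans(observed))
    obs_counts = np.bincount(obs_grp[obs_grp >= 0], minlength=n_groups)
    pt = permutations.table
    perm_grp = _assign_groups(pt["chrom"].to_numpy(), pt["pos"].to_numpy(int),
                              regions, spans=_region_spans(pt))
    n_rounds = permutations.n_rounds
    exp_counts = np.zeros((n_rounds, n_groups))
    rounds = pt["round"].to_numpy()
    valid = perm_grp >= 0
    np.add.at(exp_counts, (rounds[valid], perm_grp[valid]), 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = obs_counts[None, :] / exp_counts
    ratios[~np.isfinite(ratios)] = np.nan
    mean = np.nanmean(ratios, axis=0)
    sd = np.nanstd(ratios, axis=0, ddof=1)
    flagged = np.isnan(ratios).any(axis=0)
    ok = np.isfinite(mean)
    if ok.sum() >= 3:
        trend = stats.pearsonr(np.flatnonzero(ok), mean[ok])
        trend_r, trend_p = float(trend.statistic), float(trend.pvalue)
    else:
        trend_r = trend_p = float("nan")
    table = pd.DataFrame({
        "group": np.arange(n_groups),
        "observed": obs_counts,
        "expected_mean": exp_counts.mean(axis=0),
        "ratio_mean": mean,
        "ratio_sd": sd,
        "flagged": flagged,
    })
    return EnrichmentResult(table, trend_r, trend_p, ratios)


def gene_group_regions(genes: pd.DataFrame, n_groups: int) -> pd.DataFrame:
    """Gene-body regions grouped by expression rank."""
    assign, _ = rank_bin_features(genes["mean_expression"], n_groups)
    out = genes[["chrom", "start", "end"]].copy()
    out["group"] = assign.to_numpy()
    return out


def bin_group_regions(bins: pd.DataFrame, n_groups: int) -> pd.DataFrame:
    """Accessibility-bin regions grouped by coverage rank."""
    assign, _ = rank_bin_features(bins["coverage"], n_groups)
    out = bins[["chrom", "start", "end"]].copy()
    out["group"] = assign.to_numpy()
    return out


# ---------------------------------------------------------------------------
# signature-specific enrichment


def signature_specific_enrichment(
    observed: pd.DataFrame,
    permutations: PermutationSet,
    regions: pd.DataFrame,
    signatures: pd.DataFrame,
    fixture,
    spectrum_builder,
    min_calls: int = 10,
) -> dict[str, EnrichmentResult]:
    """Per-signature observed/expected ratios.

    Group-level spectra (observed, and per permutation round) are refitted
    to the signature set by NNLS; attributed counts (proportion x group
    count) feed the same ratio machinery. Groups with fewer than
    ``min_calls`` observed calls are flagged low-support.
    """
    n_groups = int(regions["group"].max()) + 1
    obs_grp = _assign_groups(observed["chrom"].to_numpy(),
                             observed["pos"].to_numpy(int), regions,
                             spans=_region_spans(observed))
    sig_names = list(signatures.columns)
    obs_attr = np.zeros((len(sig_names), n_groups))
    low_support = np.zeros(n_groups, dtype=bool)
    for g in range(n_groups):
        sub = observed[obs_grp == g]
        low_support[g] = len(sub) < min_calls
        if len(sub) == 0:
            continue
        fitres = fit_signatures(spectrum_builder(sub, fixture), signatures)
        obs_attr[:, g] = fitres.proportions * len(sub)
    pt = permutations.table
    perm_grp = _assign_groups(pt["chrom"].to_numpy(), pt["pos"].to_numpy(int),
                              regions, spans=_region_spans(pt))
    n_rounds = permutations.n_rounds
    exp_attr = np.zeros((n_rounds, len(sig_names), n_groups))
    for (r, g), sub in pt[perm_grp >= 0].groupby(
        [pt["round"][perm_grp >= 0], pd.Series(perm_grp[perm_grp >= 0],
                                               index=pt.index[perm_grp >= 0])]
    ):
        fitres = fit_signatures(spectrum_builder(sub, fixture), signatures)
        exp_attr[int(r), :, int(g)] = fitres.proportions * len(sub)
    results = {}
    for si, name in enumerate(sig_names):
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = obs_attr[si][None, :] / exp_attr[:, si, :]
        ratios[~np.isfinite(ratios)] = np.nan
        mean = np.nanmean(ratios, axis=0)
        sd = np.nanstd(ratios, axis=0, ddof=1)
        ok = np.isfinite(mean)
        if ok.sum() >= 3:
            trend = stats.pearsonr(np.flatnonzero(ok), mean[ok])
            tr, tp = float(trend.statistic), float(trend.pvalue)
        else:
            tr = tp = float("nan")
        table = pd.DataFrame({
            "group": np.arange(n_groups),
            "observed": obs_attr[si],
            "expected_mean": exp_attr[:, si, :].mean(axis=0),
            "ratio_mean": mean, "ratio_sd": sd,
            "flagged": low_support | np.isnan(mean),
        })
        results[name] = EnrichmentResult(table, tr, tp, ratios)
    return results


# ---------------------------------------------------------------------------
# transcribed vs non-transcribed


def transcribed_vs_nontranscribed(
    observed: pd.DataFrame,
    permutations: PermutationSet,
    genes: pd.DataFrame,
) -> dict:
    """Enrichment ratios in transcribed (mean expression > 0) vs
    non-transcribed genes, with a two-tailed Wilcoxon rank-sum test between
    the per-round ratio vectors."""
    transcribed = genes["mean_expression"] > 0
    if transcribed.all() or (~transcribed).all():
        raise ValueError("need both transcribed and non-transcribed genes")
    regions = genes[["chrom", "start", "end"]].copy()
    regions["group"] = transcribed.astype(int).to_numpy()  # 1 = transcribed
    res = enrichment_ratios(observed, permutations, regions, n_groups=2)
    r_non = res.ratios_by_round[:, 0]
    r_tr = res.ratios_by_round[:, 1]
    ok = np.isfinite(r_non) & np.isfinite(r_tr)
    wil = test_excess_wilcoxon(r_tr[ok], r_non[ok])
    return {
        "transcribed_ratio": float(np.nanmean(r_tr)),
        "nontranscribed_ratio": float(np.nanmean(r_non)),
        "p": wil["p"],
        "per_round": res.ratios_by_round,
    }
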