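"""End-to-end orchestration.

Runs the stages in dependency order (simulate -> qc/call -> spectra ->
strand -> burden -> enrich -> report) from a single configuration, writing
standard-format artifacts plus a machine-readable ``summary.json``. Every
stage is deterministic given identical inputs and seed.

:func:`compute_headline_metrics` recomputes the cohort-level headline
quantities (age-adjusted excess burdens, signature-attributed excess,
strand-conversion weights, single-strand signature proportions) from
scratch on the published-parameter preset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .burden import (
    classify_indel_groups,
    compute_excess_burden,
    fit_control_age_model,
    test_excess_wilcoxon,
)
from .caller import (
    build_candidates,
    call_variants,
    filter_cells,
    group_fragments,
    popvar_overlap_fraction,
    screen_candidates,
    CellQC,
)
from .config import CohortConfig, published_preset
from .contexts import stable_key
from .enrichment import (
    enrichment_ratios,
    gene_group_regions,
    permute_calls,
)
from .signatures import (
    build_snv_spectrum,
    convert_pta_spectrum,
    derive_strand_conversion,
    fit_signatures,
    load_packaged_signatures,
    signature_burden,
)
from .synthetic import (
    GenomeFixture,
    IndelPlacer,
    build_genome_fixture,
    make_planted_truth,
    simulate_cohort_burdens,
    simulate_duplex_fragments,
    simulate_expression_accessibility,
    simulate_mutation_catalog,
    simulate_snv_catalog,
)


@dataclass
class RunConfig:
    outdir: str
    seed: int = 1
    n_control: int = 6
    n_cte: int = 6
    cells_per_individual: int = 2
    n_duplex_cells: int = 2          # cells run through the duplex caller
    permutation_rounds: int = 100
    expression_groups: int = 10
    stages: dict[str, bool] = field(default_factory=lambda: {
        "simulate": True, "call": True, "spectra": True, "burden": True,
        "enrich": True, "report": True,
    })

    def cohort(self) -> CohortConfig:
        return published_preset(
            seed=self.seed, n_control=self.n_control, n_cte=self.n_cte,
            cells_per_individual=self.cells_per_individual)


def _require(path: Path, stage: str, needed_by: str):
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{needed_by}' needs {path.name}, produced by stage "
            f"'{stage}' — run it first or enable it")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages; returns the summary dictionary."""
    out = sio.ensure_dir(config.outdir)
    cohort = config.cohort()
    summary: dict = {"seed": config.seed}
    fixture: GenomeFixture | None = None
    cells = None

    if config.stages.get("simulate", True):
        fixture = build_genome_fixture(cohort)
        fixture.write(out / "fixture")
        simulate_expression_accessibility(fixture, cohort)
        sio.write_table(out / "fixture" / "expression.tsv",
                        fixture.genes[["gene_id", "mean_expression"]])
        cells = simulate_cohort_burdens(cohort, fixture)
        sio.write_table(out / "cells.tsv", cells)

    if config.stages.get("call", True):
        _require(out / "cells.tsv", "simulate", "call")
        if fixture is None:
            raise FileNotFoundError("stage 'call' needs the in-memory fixture; "
                                    "enable stage 'simulate'")
        cells = pd.read_csv(out / "cells.tsv", sep="\t")
        placer = IndelPlacer(fixture, cohort.seed)
        all_calls, qc_rows = [], []
        bulk = fixture.population_variants.iloc[:0][["chrom", "pos"]].assign(alt_depth=0)
        for _, cell in cells.head(config.n_duplex_cells).iterrows():
            rng = np.random.default_rng([cohort.seed, 11,
                                         stable_key(cell["cell_id"])])
            small = cell.copy()
            small["sig_aging_burden"] = min(small["sig_aging_burden"], 40)
            small["sig_disease_burden"] = min(small["sig_disease_burden"], 20)
            small["indel_burden"] = min(small["indel_burden"], 20)
            truth = make_planted_truth(small, fixture, cohort, placer=placer,
                                       rng=rng)
            frags = simulate_duplex_fragments(small, truth, cohort, fixture,
                                              rng=rng)
            grouped = group_fragments(frags)
            germ = truth.sites("germline")
            germ_bulk = germ[["chrom", "pos"]].assign(alt_depth=15)
            germ_ind = germ[germ["var_class"] != "SNV"].copy()
            germ_ind["indel_len"] = [max(len(r), len(a)) - 1 for r, a in
                                     zip(germ_ind["ref"], germ_ind["alt"])]
            cand = build_candidates(grouped, pd.concat([bulk, germ_bulk]))
            cand = screen_candidates(cand, fixture, germline_indels=germ_ind)
            calls = call_variants(cand)
            all_calls.append(calls)
            qc = CellQC(cell_id=cell["cell_id"], mapd=cell["mapd"],
                        cov_adjacent=cell["cov_adjacent"],
                        mean_depth=cell["mean_depth"],
                        allelic_dropout=cell["allelic_dropout"],
                        locus_dropout=cell["allelic_dropout"] / 2,
                        strand_dropout=float(np.sqrt(cell["allelic_dropout"])),
                        insert_mean=400.0, insert_sd=120.0,
                        popvar_overlap=popvar_overlap_fraction(
                            cand, fixture.population_variants))
            qc = filter_cells(qc)
            qc_rows.append({**{k: getattr(qc, k) for k in (
                "cell_id", "mapd", "cov_adjacent", "mean_depth",
                "allelic_dropout", "locus_dropout", "strand_dropout",
                "insert_mean", "insert_sd", "popvar_overlap", "passed")},
                "reasons": ";".join(qc.reasons)})
        calls = pd.concat(all_calls, ignore_index=True)
        sio.write_calls_vcf(out / "calls.vcf", calls, fixture.chrom_lengths)
        sio.write_table(out / "cellqc.tsv", pd.DataFrame(qc_rows))
        summary["n_duplex_calls"] = int(len(calls))
        summary["n_ds_calls"] = int((calls["strandedness"] == "ds").sum())
        summary["n_ss_calls"] = int((calls["strandedness"] == "ss").sum())

    if config.stages.get("burden", True):
        _require(out / "cells.tsv", "simulate", "burden")
        cells = pd.read_csv(out / "cells.tsv", sep="\t")
        metrics = compute_headline_metrics(config.seed, cells=cells,
                                           fixture=fixture, cohort=cohort)
        summary.update(metrics)
        sio.write_table(out / "burden_fits.tsv", pd.DataFrame([
            {"model": k, "value": v} for k, v in metrics.items()
        ]))

    if config.stages.get("enrich", True):
        _require(out / "cells.tsv", "simulate", "enrich")
        if fixture is None:
            raise FileNotFoundError("stage 'enrich' needs the in-memory "
                                    "fixture; enable stage 'simulate'")
        rng = np.random.default_rng([config.seed, 21])
        calls = simulate_snv_catalog(300, {"SignatureA": 0.8, "SignatureC": 0.2},
                                     fixture, rng, cell_id="aggregate")
        perms = permute_calls(calls, fixture, n_rounds=config.permutation_rounds,
                              seed=config.seed)
        regions = gene_group_regions(fixture.genes, config.expression_groups)
        enr = enrichment_ratios(calls, perms, regions)
        sio.write_table(out / "enrichment.tsv", enr.table)
        summary["enrichment_trend_r"] = enr.trend_r
        summary["enrichment_trend_p"] = enr.trend_p

    if config.stages.get("report", True):
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
    return summary


# ---------------------------------------------------------------------------
# headline metrics (the acceptance surface)


def compute_headline_metrics(
    seed: int,
    cells: pd.DataFrame | None = None,
    fixture: GenomeFixture | None = None,
    cohort: CohortConfig | None = None,
    n_control: int = 100,
    n_cte: int = 100,
    cells_per_individual: int = 4,
    n_strand_cells: int = 100,
    strand_catalog_n: int = 300,
    n_ss_catalogs: int = 50,
    ss_catalog_n: int = 200,
    with_catalogs: bool = True,
) -> dict:
    """Recompute the headline cohort quantities from scratch.

    Simulates the published-parameter cohort, fits the control-only age
    models, and reports: mean age-adjusted CTE excess sSNV and sIndel
    burdens; the excess-sIndel / annual-rate equivalent-years ratio; the
    sIndel:sSNV excess fold; the disease-signature-attributed excess
    (catalog simulation + spectrum NNLS); the strand-conversion mean k1 on
    DS/SS-mixture spectra; and the mean disease-signature proportion of
    single-stranded catalogs.
    """
    if cohort is None:
        cohort = published_preset(seed=seed, n_control=n_control, n_cte=n_cte,
                                  cells_per_individual=cells_per_individual)
    if cells is None:
        cells = simulate_cohort_burdens(cohort)
    out: dict = {}

    snv_fit = fit_control_age_model(cells, outcome="snv_burden")
    cells = cells.copy()
    cells["excess_snv"] = compute_excess_burden(cells, snv_fit, "snv_burden")
    ind_fit = fit_control_age_model(cells, outcome="indel_burden")
    cells["excess_indel"] = compute_excess_burden(cells, ind_fit, "indel_burden")
    cte = cells[cells["condition"] == "CTE"]
    ctrl = cells[cells["condition"] == "control"]
    out["mean_excess_snv_cte"] = float(cte["excess_snv"].mean())
    out["mean_excess_indel_cte"] = float(cte["excess_indel"].mean())
    out["excess_indel_equivalent_years"] = (
        out["mean_excess_indel_cte"] / cohort.indel_rate_per_year_upper)
    out["indel_snv_excess_fold"] = (
        out["mean_excess_indel_cte"] / out["mean_excess_snv_cte"])
    out["wilcoxon_excess_snv_p"] = test_excess_wilcoxon(
        cte["excess_snv"], ctrl["excess_snv"])["p"]
    per_ind = cte.groupby("individual")["excess_indel"].mean()
    out["n_high_indel"] = int((classify_indel_groups(per_ind) == "High").sum())

    if with_catalogs:
        if fixture is None:
            fixture = build_genome_fixture(cohort)
        sbs = load_packaged_signatures("sbs")[["SignatureA", "SignatureC"]]
        rng = np.random.default_rng([seed, 31])
        c_burden = np.empty(len(cells))
        for i, (_, cell) in enumerate(cells.iterrows()):
            catalog = simulate_mutation_catalog(cell, fixture, cohort,
                                                rng=rng, include_indels=False)
            spectrum = build_snv_spectrum(catalog, fixture)
            fit = fit_signatures(spectrum, sbs)
            c_burden[i] = signature_burden(fit.proportions,
                                           cell["snv_burden"])[1]
        cells["sig_c_burden"] = c_burden
        c_fit = fit_control_age_model(cells, outcome="sig_c_burden")
        cells["excess_c"] = compute_excess_burden(cells, c_fit, "sig_c_burden")
        out["sig_c_excess_cte"] = float(
            cells.loc[cells["condition"] == "CTE", "excess_c"].mean()
            - cells.loc[cells["condition"] == "control", "excess_c"].mean())

    # strand conversion round trip at the preset DS weight
    strand = load_packaged_signatures("strand_snv")
    model = derive_strand_conversion(strand["DS"], strand["SS"])
    w = cohort.pta_ds_weight
    mixture = w * model.ds + (1 - w) * model.ss
    rng = np.random.default_rng([seed, 41])
    k1s = []
    for _ in range(n_strand_cells):
        counts = rng.multinomial(strand_catalog_n, mixture)
        k1, _, _, _ = convert_pta_spectrum(counts, model)
        k1s.append(k1)
    out["mean_k1_pct"] = float(np.mean(k1s) * 100)

    # single-stranded catalogs at the preset disease-signature weight
    if fixture is None:
        fixture = build_genome_fixture(cohort)
    sbs = load_packaged_signatures("sbs")[["SignatureA", "SignatureC"]]
    rng = np.random.default_rng([seed, 51])
    props = []
    for i in range(n_ss_catalogs):
        cat = simulate_snv_catalog(
            ss_catalog_n,
            {"SignatureA": 1 - cohort.ss_sig_disease_weight,
             "SignatureC": cohort.ss_sig_disease_weight},
            fixture, rng, cell_id=f"ss{i}")
        fit = fit_signatures(build_snv_spectrum(cat, fixture), sbs)
        props.append(fit.proportions[1])
    out["ss_sig_c_pct"] = float(np.mean(props) * 100)
    return out
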