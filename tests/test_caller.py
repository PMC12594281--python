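"""Duplex caller: QC oracles, cell gates, grouping, filter cascade, calling
rules, and the simulator round trip."""

import numpy as np
import pandas as pd
import pytest

from scduplex.caller import (
    CellQC,
    build_candidates,
    call_ds_snv,
    call_ss_snv,
    call_variants,
    compute_amplification_qc,
    filter_cells,
    group_fragments,
    screen_candidates,
)
from scduplex.config import CallerThresholds
from scduplex.synthetic import make_planted_truth, simulate_duplex_fragments
from conftest import small_config


def _qc(ratios, ref_d=None, alt_d=None, **read_stats):
    het = pd.DataFrame({
        "ref_depth": ref_d if ref_d is not None else [10, 10],
        "alt_depth": alt_d if alt_d is not None else [10, 10],
    })
    stats = {"properly_paired": 1_000_000, "read_length": 150,
             "genome_length": 3_000_000, **read_stats}
    return compute_amplification_qc(np.asarray(ratios), het, stats)


class TestAmplificationQC:
    def test_equal_ratios_give_zero_mapd_and_flagged_cov(self):
        qc = _qc([1.0, 1.0, 1.0, 1.0])
        assert qc.mapd == 0.0
        assert np.isnan(qc.cov_adjacent) and "cov_undefined" in qc.flags

    def test_strand_dropout_is_sqrt_of_allelic(self):
        qc = _qc([1, 2, 1], ref_d=[1, 10, 10, 10], alt_d=[5, 1, 10, 10])
        assert qc.allelic_dropout == 0.5
        assert qc.strand_dropout == pytest.approx(np.sqrt(0.5))
        qc = _qc([1, 2, 1], ref_d=[1, 10, 10, 10], alt_d=[10, 10, 10, 10])
        assert qc.allelic_dropout == 0.25
        assert qc.strand_dropout == 0.5

    def test_locus_dropout_threshold(self):
        qc = _qc([1, 2], ref_d=[2, 3, 0], alt_d=[2, 3, 2])
        # totals 4, 6, 2 -> two below 5
        assert qc.locus_dropout == pytest.approx(2 / 3)

    def test_mapd_matches_bruteforce_oracle(self, rng):
        ratios = rng.uniform(0.2, 3.0, size=200)
        qc = _qc(ratios)
        logs = np.log2(ratios)
        diffs = sorted(abs(logs[i + 1] - logs[i]) for i in range(len(logs) - 1))
        n = len(diffs)
        med = (diffs[n // 2] if n % 2 else (diffs[n // 2 - 1] + diffs[n // 2]) / 2)
        assert qc.mapd == pytest.approx(med)
        assert qc.cov_adjacent == pytest.approx(
            np.std(np.abs(np.diff(logs)), ddof=1) / np.mean(np.abs(np.diff(logs))))

    def test_depth_formula(self):
        qc = _qc([1, 2])
        assert qc.mean_depth == pytest.approx(1_000_000 * 150 / 3_000_000)

    def test_nonpositive_ratio_errors(self):
        with pytest.raises(ValueError):
            _qc([1.0, 0.0])


class TestCellGates:
    @pytest.mark.parametrize("mean,sd,overlap,passed,reason", [
        (250, 100, 0.05, False, "insert_size"),   # mean < 280
        (550, 100, 0.05, False, "insert_size"),   # mean > 500
        (400, 800, 0.05, False, "insert_size_sd"),  # sd > 750
        (400, 300, 0.05, True, None),
        (400, 300, 0.93, False, "contamination"),
    ])
    def test_insert_and_contamination_gates(self, mean, sd, overlap, passed,
                                            reason):
        qc = CellQC(cell_id="c", mapd=0.2, cov_adjacent=0.8, mean_depth=30,
                    allelic_dropout=0.2, locus_dropout=0.1, strand_dropout=0.45,
                    insert_mean=mean, insert_sd=sd, popvar_overlap=overlap)
        qc = filter_cells(qc)
        assert qc.passed is passed
        if reason:
            assert reason in qc.reasons


def _frag_row(pos=1000, start=900, end=1300, bc1="T00", bc2="T01", strand="+",
              ref="A", alt="T", reads=4, **kw):
    base = {"cell_id": "c1", "chrom": "chr1", "start": start, "end": end,
            "bc1": bc1, "bc2": bc2, "strand": strand, "pos": pos, "ref": ref,
            "alt": alt, "reads": reads, "merged": False, "mw_start": 0,
            "mw_end": 0, "in_unmerged": True, "var_class": "SNV"}
    base.update(kw)
    return base


class TestGrouping:
    def test_cutsite_collision_counted(self):
        obs = pd.DataFrame([
            _frag_row(), _frag_row(strand="-"),
            _frag_row(start=880, end=1280, alt="."),
        ])
        cand = build_candidates(group_fragments(obs), pd.DataFrame())
        assert len(cand) == 1
        assert cand.iloc[0]["n_cutsite_sets"] == 2
        assert cand.iloc[0]["n_barcode_pairs"] == 1

    def test_single_fragment_counts_one(self):
        obs = pd.DataFrame([_frag_row(), _frag_row(strand="-")])
        cand = build_candidates(group_fragments(obs), pd.DataFrame())
        assert cand.iloc[0]["n_cutsite_sets"] == 1
        assert cand.iloc[0]["n_barcode_pairs"] == 1

    def test_order_invariance(self, rng):
        rows = [_frag_row(pos=1000 + 200 * i, start=900 + 200 * i,
                          end=1300 + 200 * i, bc1=f"T{i:02d}")
                for i in range(6)]
        rows += [dict(r, strand="-") for r in rows]
        df = pd.DataFrame(rows)
        g1 = group_fragments(df)
        g2 = group_fragments(df.sample(frac=1, random_state=1))
        pd.testing.assert_frame_equal(
            g1.reset_index(drop=True), g2.reset_index(drop=True))

    def test_missing_barcode_dropped_with_count(self):
        df = pd.DataFrame([_frag_row(), _frag_row(bc1=None)])
        g = group_fragments(df)
        assert len(g) == 1 and g.attrs["n_dropped_barcode"] == 1


def _candidate(**kw):
    base = {"cell_id": "c1", "chrom": "chr1", "pos": 5000, "ref": "A",
            "alt": "T", "var_class": "SNV", "bulk_alt": 0, "plus_alt": 2,
            "plus_ref": 0, "minus_alt": 2, "minus_ref": 0, "vaf": 1.0,
            "n_barcode_pairs": 1, "n_cutsite_sets": 1, "min_dist_end": 50,
            "in_merge_window": False, "in_unmerged": True, "filters": ""}
    base.update(kw)
    return base


class TestScreening:
    def test_proximity_flags_both_members(self):
        cand = pd.DataFrame([_candidate(pos=1000), _candidate(pos=1080),
                             _candidate(pos=5000)])
        out = screen_candidates(cand)
        assert list(out["filters"]) == ["proximity", "proximity", ""]

    def test_proximity_inclusive_at_window(self):
        cand = pd.DataFrame([_candidate(pos=1000), _candidate(pos=1100)])
        out = screen_candidates(cand)
        assert (out["filters"] == "proximity").all()
        cand = pd.DataFrame([_candidate(pos=1000), _candidate(pos=1101)])
        out = screen_candidates(cand)
        assert (out["filters"] == "").all()

    def test_population_af_cutoff(self):
        pv = pd.DataFrame([
            {"chrom": "chr1", "pos": 1000, "ref": "A", "alt": "T", "af": 0.005,
             "var_class": "SNV", "indel_len": 0},
            {"chrom": "chr1", "pos": 5000, "ref": "A", "alt": "T", "af": 0.02,
             "var_class": "SNV", "indel_len": 0},
        ])
        cand = pd.DataFrame([_candidate(pos=1000), _candidate(pos=5000)])
        out = screen_candidates(cand, population_variants=pv)
        by_pos = dict(zip(out["pos"], out["filters"]))
        assert by_pos[1000] == ""            # 0.5% < 1%: retained
        assert by_pos[5000] == "population_variant"

    def test_read_end_window_inclusive(self):
        out = screen_candidates(pd.DataFrame([_candidate(min_dist_end=10)]))
        assert out.iloc[0]["filters"] == "read_end"
        out = screen_candidates(pd.DataFrame([_candidate(min_dist_end=20)]))
        assert out.iloc[0]["filters"] == "read_end"
        out = screen_candidates(pd.DataFrame([_candidate(min_dist_end=21)]))
        assert out.iloc[0]["filters"] == ""

    def test_multi_barcode_and_collision_flags(self):
        out = screen_candidates(pd.DataFrame([
            _candidate(n_barcode_pairs=2),
            _candidate(pos=9000, n_cutsite_sets=2),
        ]))
        assert out.iloc[0]["filters"] == "multi_barcode"
        assert out.iloc[1]["filters"] == "cutsite_collision"

    @pytest.mark.parametrize("glen,distance,expect_flag", [
        (2, 4, True),    # flank = max(5, 4) = 5; 4 <= 5 -> rejected
        (2, 6, False),   # outside the 5 bp flank
        (10, 19, True),  # flank = max(5, 20) = 20
        (10, 25, False),  # 25 > 20 -> retained
    ])
    def test_germline_flank_rule(self, glen, distance, expect_flag):
        germ = pd.DataFrame([{"chrom": "chr1", "pos": 5000 - distance,
                              "ref": "A" * (glen + 1), "alt": "A",
                              "indel_len": glen}])
        cand = pd.DataFrame([_candidate(var_class="DEL", ref="AT", alt="A")])
        out = screen_candidates(cand, germline_indels=germ)
        assert (out.iloc[0]["filters"] == "germline_flank") is expect_flag

    def test_merge_window_and_unmerged_rules_apply_to_indels_only(self):
        cand = pd.DataFrame([
            _candidate(var_class="DEL", ref="AT", alt="A", in_merge_window=True),
            _candidate(pos=9000, var_class="INS", ref="A", alt="AT",
                       in_unmerged=False),
            _candidate(pos=13000, in_merge_window=True),  # SNV: rule not applied
        ])
        out = screen_candidates(cand)
        assert out.iloc[0]["filters"] == "merge_window"
        assert out.iloc[1]["filters"] == "unmerged_absent"
        assert out.iloc[2]["filters"] == ""

    def test_proximity_within_class_by_default(self):
        cand = pd.DataFrame([
            _candidate(pos=1000),
            _candidate(pos=1050, var_class="DEL", ref="AT", alt="A"),
        ])
        out = screen_candidates(cand)
        assert (out["filters"] == "").all()
        th = CallerThresholds(proximity_within_class_only=False)
        out = screen_candidates(cand, thresholds=th)
        assert (out["filters"] == "proximity").all()


class TestCallingRules:
    def test_a4s2_vaf1_call(self):
        assert call_ds_snv(_candidate())["strandedness"] == "ds"

    def test_per_strand_minimum(self):
        assert call_ds_snv(_candidate(plus_alt=3, minus_alt=1)) is None

    def test_vaf_below_one_rejected(self):
        c = _candidate(plus_alt=2, minus_alt=2, minus_ref=1, vaf=0.8)
        assert call_ds_snv(c) is None

    def test_bulk_alt_blocks_call(self):
        assert call_ds_snv(_candidate(bulk_alt=1)) is None

    def test_ss_call_with_strand_label(self):
        c = _candidate(plus_alt=4, minus_alt=0, minus_ref=4, vaf=0.5)
        rec = call_ss_snv(c)
        assert rec["strandedness"] == "ss" and rec["strand"] == "+"

    def test_ss_requires_other_strand_ref_support(self):
        c = _candidate(plus_alt=4, minus_alt=0, minus_ref=3, vaf=0.57)
        assert call_ss_snv(c) is None

    def test_ds_compatible_evidence_not_called_ss(self):
        c = _candidate(plus_alt=4, minus_alt=2, vaf=1.0)
        assert call_ss_snv(c) is None
        assert call_ds_snv(c) is not None

    def test_filtered_candidate_never_called(self):
        assert call_ds_snv(_candidate(filters="read_end")) is None

    def test_monotonicity_relaxing_thresholds(self, rng):
        """Relaxing any single threshold never shrinks the call set."""
        cands = pd.DataFrame([
            _candidate(pos=1000 + 500 * i,
                       plus_alt=int(rng.integers(0, 6)),
                       minus_alt=int(rng.integers(0, 6)),
                       minus_ref=int(rng.integers(0, 6)),
                       min_dist_end=int(rng.integers(0, 60)),
                       vaf=1.0)
            for i in range(40)
        ])
        base_th = CallerThresholds()
        base = call_variants(screen_candidates(cands, thresholds=base_th))
        for relaxed in (
            CallerThresholds(min_total_alt=3),
            CallerThresholds(min_strand_alt=1),
            CallerThresholds(ss_min_other_ref=3),
            CallerThresholds(read_end_bp=10),
            CallerThresholds(proximity_bp=50),
        ):
            more = call_variants(screen_candidates(cands, thresholds=relaxed))
            assert len(more) >= len(base)
            base_sites = set(zip(base["pos"], base["strandedness"]))
            more_sites = set(zip(more["pos"], more["strandedness"]))
            # every ds call kept; ss calls may upgrade when thresholds relax
            assert {p for p, s in base_sites if s == "ds"} <= \
                {p for p, s in more_sites}


@pytest.fixture(scope="module")
def called(fixture, cells, placer):
    cfg = small_config()
    cfg.artifact_rate_read_end = 0.03
    cfg.artifact_rate_collision = 0.03
    cfg.artifact_rate_merge_window = 0.02
    cell = cells.iloc[0].copy()
    cell["sig_aging_burden"], cell["sig_disease_burden"] = 40, 15
    cell["indel_burden"] = 12
    rng = np.random.default_rng(31)
    truth = make_planted_truth(cell, fixture, cfg, placer=placer, rng=rng)
    frags = simulate_duplex_fragments(cell, truth, cfg, fixture, rng=rng)
    grouped = group_fragments(frags)
    germ = truth.sites("germline")
    bulk = germ[["chrom", "pos"]].assign(alt_depth=15)
    germ_ind = germ[germ["var_class"] != "SNV"].copy()
    germ_ind["indel_len"] = [max(len(r), len(a)) - 1 for r, a in
                             zip(germ_ind["ref"], germ_ind["alt"])]
    cand = build_candidates(grouped, bulk)
    cand = screen_candidates(cand, fixture, germline_indels=germ_ind)
    calls = call_variants(cand)
    return truth, cand, calls



class TestRoundTrip:
    def test_planted_ds_recall_and_no_false_calls(self, called):
        truth, _, calls = called
        ds_truth = set(zip(truth.sites("ds_mutation")["chrom"],
                           truth.sites("ds_mutation")["pos"]))
        ds_called = set(zip(calls.loc[calls["strandedness"] == "ds", "chrom"],
                            calls.loc[calls["strandedness"] == "ds", "pos"]))
        assert ds_called == ds_truth

    def test_planted_ss_recall(self, called):
        truth, _, calls = called
        ss = calls[calls["strandedness"] == "ss"]
        ss_truth = truth.sites("ss_lesion")
        assert set(zip(ss["chrom"], ss["pos"])) == \
            set(zip(ss_truth["chrom"], ss_truth["pos"]))
        # strand labels match the planted lesion strands
        planted = {(c, p): s for c, p, s in zip(
            ss_truth["chrom"], ss_truth["pos"], ss_truth["strand"])}
        for row in ss.itertuples(index=False):
            assert planted[(row.chrom, row.pos)] == row.strand

    def test_artifacts_carry_matching_flags(self, called):
        truth, cand, calls = called
        called_sites = set(zip(calls["chrom"], calls["pos"]))
        flags = {(c, p): f for c, p, f in zip(cand["chrom"], cand["pos"],
                                              cand["filters"])}
        art = truth.table[truth.table["expected_flag"] != ""]
        assert len(art) > 0
        for row in art.itertuples(index=False):
            assert (row.chrom, row.pos) not in called_sites
            assert row.expected_flag in flags.get((row.chrom, row.pos), "")

    def test_ds_ss_call_sets_disjoint(self, called):
        _, _, calls = called
        keys = list(zip(calls["chrom"], calls["pos"], calls["cell_id"]))
        assert len(keys) == len(set(keys))

    def test_negative_control_no_lesions_no_ss_calls(self, fixture, cells,
                                                     placer):
        cfg = small_config()
        cfg.lesion_to_mutation_ratio = 0.0
        cell = cells.iloc[2].copy()
        cell["sig_aging_burden"], cell["sig_disease_burden"] = 20, 10
        cell["indel_burden"] = 5
        rng = np.random.default_rng(37)
        truth = make_planted_truth(cell, fixture, cfg, placer=placer, rng=rng)
        frags = simulate_duplex_fragments(cell, truth, cfg, fixture, rng=rng)
        germ = truth.sites("germline")
        cand = build_candidates(group_fragments(frags),
                                germ[["chrom", "pos"]].assign(alt_depth=15))
        calls = call_variants(screen_candidates(cand, fixture))
        assert (calls["strandedness"] == "ss").sum() == 0
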