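"""Synthetic-data generator.

Produces a desk-scale genome fixture (FASTA/BED/TSV-serializable), a cohort
of single neurons whose somatic burdens follow the age + condition mixed
model the analysis assumes, per-cell mutation catalogs drawn from signature
mixtures and placed at genome positions whose local sequence context matches
the drawn class, strand-tagged duplex fragment groups with planted
double-stranded mutations, single-stranded lesions, germline variants,
artifacts and contamination, and expression/accessibility profiles.

All randomness flows from one seeded generator per run; identical config +
seed give identical outputs at every stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as sio
from .config import CohortConfig, ConditionPreset
from .contexts import (
    BASES,
    COMPLEMENT,
    SBS96_CONTEXTS,
    TRINUC32,
    TRINUC32_INDEX,
    classify_indel,
    encode_seq,
    normalize_trinuc,
    stable_key,
    trinuc_codes,
)
from .signatures import load_packaged_signatures

# ---------------------------------------------------------------------------
# genome fixture


@dataclass
class GenomeFixture:
    chrom_lengths: dict[str, int]
    sequences: dict[str, str]
    genes: pd.DataFrame              # gene_id, chrom, start, end, strand, mean_expression
    accessibility_bins: pd.DataFrame  # chrom, start, end, coverage
    callable_regions: pd.DataFrame   # chrom, start, end (1-based inclusive)
    mask_regions: pd.DataFrame       # chrom, start, end
    population_variants: pd.DataFrame  # chrom, pos, ref, alt, af, var_class, indel_len
    het_snps: pd.DataFrame           # chrom, pos, ref, alt
    seed: int
    _encoded: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    _ctx_index: dict | None = field(default=None, repr=False)

    def encoded(self, chrom: str) -> np.ndarray:
        if chrom not in self._encoded:
            self._encoded[chrom] = encode_seq(self.sequences[chrom])
        return self._encoded[chrom]

    def trinucleotide_counts(self) -> pd.Series:
        """Pyrimidine-normalized trinucleotide composition of the fixture."""
        counts = np.zeros(32, dtype=np.int64)
        for chrom in self.chrom_lengths:
            codes = trinuc_codes(self.encoded(chrom).astype(np.int64))
            counts += np.bincount(codes[codes >= 0], minlength=32)
        return pd.Series(counts, index=TRINUC32)

    def callable_mask(self, chrom: str) -> np.ndarray:
        """Boolean mask (0-based) of callable positions on a chromosome."""
        mask = np.zeros(self.chrom_lengths[chrom], dtype=bool)
        sub = self.callable_regions[self.callable_regions["chrom"] == chrom]
        for row in sub.itertuples(index=False):
            mask[row.start - 1 : row.end] = True
        return mask

    def context_index(self) -> dict[str, dict[int, np.ndarray]]:
        """Per-chromosome map: trinucleotide code -> callable 1-based positions."""
        if self._ctx_index is None:
            index: dict[str, dict[int, np.ndarray]] = {}
            for chrom in self.chrom_lengths:
                codes = trinuc_codes(self.encoded(chrom).astype(np.int64))
                mask = self.callable_mask(chrom)[1:-1]
                per: dict[int, np.ndarray] = {}
                for code in range(32):
                    pos0 = np.flatnonzero((codes == code) & mask)
                    per[code] = pos0 + 2  # centre base, 1-based
                index[chrom] = per
            self._ctx_index = index
        return self._ctx_index

    def write(self, outdir) -> None:
        out = sio.ensure_dir(outdir)
        sio.write_fasta(out / "genome.fa", self.sequences)
        sio.write_bed(out / "callable.bed", self.callable_regions)
        sio.write_bed(out / "mask.bed", self.mask_regions)
        bins = self.accessibility_bins.rename(columns={"coverage": "value"})
        sio.write_bed(out / "accessibility.bed", bins)
        sio.write_table(out / "genes.tsv", self.genes)
        sio.write_table(out / "population_variants.tsv", self.population_variants)
        sio.write_table(out / "het_snps.tsv", self.het_snps)


def _plant_repeats(seq: np.ndarray, rng: np.random.Generator,
                   fraction: float) -> None:
    """Overwrite ~``fraction`` of the sequence with homopolymers and STRs."""
    n = len(seq)
    target = int(n * fraction)
    planted = 0
    while planted < target:
        if rng.random() < 0.5:  # homopolymer, length 5-12
            ln = int(rng.integers(5, 13))
            base = int(rng.integers(0, 4))
            start = int(rng.integers(0, n - ln))
            seq[start : start + ln] = base
        else:  # short tandem repeat, unit 2-4 bp x 3-8 copies
            unit_len = int(rng.integers(2, 5))
            copies = int(rng.integers(3, 9))
            unit = rng.integers(0, 4, size=unit_len)
            ln = unit_len * copies
            start = int(rng.integers(0, n - ln))
            seq[start : start + ln] = np.tile(unit, copies)
        planted += ln


def build_genome_fixture(config: CohortConfig) -> GenomeFixture:
    """Build the deterministic genome fixture for a cohort configuration."""
    config.validate()
    rng = np.random.default_rng([config.seed, 101])
    sequences: dict[str, str] = {}
    for chrom, ln in config.chrom_lengths.items():
        if ln <= 0:
            raise ValueError(f"zero-length chromosome {chrom}")
        arr = rng.integers(0, 4, size=ln).astype(np.int8)
        _plant_repeats(arr, rng, config.repeat_fraction)
        sequences[chrom] = "".join(BASES[i] for i in arr)

    # non-overlapping gene models
    genes = []
    chroms = list(config.chrom_lengths)
    per_chrom = max(1, config.n_genes // len(chroms))
    gid = 0
    for chrom in chroms:
        ln = config.chrom_lengths[chrom]
        cursor = 1
        for _ in range(per_chrom):
            gap = int(rng.integers(100, max(200, ln // per_chrom // 3)))
            glen = int(rng.integers(*config.gene_length_bp))
            start = cursor + gap
            end = start + glen - 1
            if end > ln - 100:
                break
            genes.append({"gene_id": f"G{gid:05d}", "chrom": chrom,
                          "start": start, "end": end,
                          "strand": "+" if rng.random() < 0.5 else "-",
                          "mean_expression": 0.0})
            cursor = end + 1
            gid += 1
    genes = pd.DataFrame(genes)

    # accessibility bins tile each chromosome
    bins = []
    bw = config.accessibility_bin_bp
    for chrom, ln in config.chrom_lengths.items():
        starts = np.arange(1, ln + 1, bw)
        ends = np.minimum(starts + bw - 1, ln)
        bins.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends,
                                  "coverage": 0.0}))
    bins = pd.DataFrame(pd.concat(bins, ignore_index=True))

    # low-quality mask; callable = complement of the mask
    mask_rows, callable_rows = [], []
    for chrom, ln in config.chrom_lengths.items():
        n_mask = max(1, int(ln * config.mask_fraction / 500))
        starts = np.sort(rng.integers(1, ln - 600, size=n_mask))
        prev_end = 0
        for s in starts:
            s = int(s)
            if s <= prev_end + 1:
                continue
            e = min(s + 499, ln)
            mask_rows.append({"chrom": chrom, "start": s, "end": e})
            callable_rows.append({"chrom": chrom, "start": prev_end + 1, "end": s - 1})
            prev_end = e
        if prev_end < ln:
            callable_rows.append({"chrom": chrom, "start": prev_end + 1, "end": ln})
    mask_df = pd.DataFrame(mask_rows)
    callable_df = pd.DataFrame(callable_rows)

    # population variants (SNVs + some indels) with allele frequencies
    pv_rows = []
    for _ in range(config.n_population_variants):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        pos = int(rng.integers(2, config.chrom_lengths[chrom] - 10))
        ref = sequences[chrom][pos - 1]
        af = float(np.clip(rng.beta(0.25, 1.5), 1e-4, 0.999))
        if rng.random() < 0.85:
            alt = BASES[(BASES.index(ref) + int(rng.integers(1, 4))) % 4]
            pv_rows.append({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                            "af": af, "var_class": "SNV", "indel_len": 0})
        else:
            ln_i = int(rng.integers(1, 5))
            if rng.random() < 0.5:
                seg = sequences[chrom][pos - 1 : pos - 1 + ln_i + 1]
                pv_rows.append({"chrom": chrom, "pos": pos, "ref": seg,
                                "alt": seg[0], "af": af, "var_class": "DEL",
                                "indel_len": ln_i})
            else:
                ins = "".join(BASES[i] for i in rng.integers(0, 4, ln_i))
                pv_rows.append({"chrom": chrom, "pos": pos, "ref": ref,
                                "alt": ref + ins, "af": af, "var_class": "INS",
                                "indel_len": ln_i})
    popvar = pd.DataFrame(pv_rows).drop_duplicates(["chrom", "pos"]).reset_index(drop=True)

    # germline het SNPs for dropout QC
    het_rows = []
    for _ in range(config.n_het_snps):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        pos = int(rng.integers(2, config.chrom_lengths[chrom] - 2))
        ref = sequences[chrom][pos - 1]
        alt = BASES[(BASES.index(ref) + int(rng.integers(1, 4))) % 4]
        het_rows.append({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt})
    het = pd.DataFrame(het_rows).drop_duplicates(["chrom", "pos"]).reset_index(drop=True)

    return GenomeFixture(
        chrom_lengths=dict(config.chrom_lengths),
        sequences=sequences,
        genes=genes,
        accessibility_bins=bins,
        callable_regions=callable_df,
        mask_regions=mask_df,
        population_variants=popvar,
        het_snps=het,
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# cohort burdens


def simulate_cohort_burdens(config: CohortConfig,
                            fixture: GenomeFixture | None = None) -> pd.DataFrame:
    """Simulate per-cell burden records for every condition preset.

    burden = intercept + annual_rate*age + condition_excess + individual
    intercept + residual, truncated at 0. The sSNV burden is generated as
    the sum of an aging-signature component and a disease-signature
    component so that signature-attributed burdens are recoverable.
    sIndel excess uses the High-/Low-Indel mixture: the first
    round(fraction*n) individuals of a condition receive the High excess.
    """
    rng = np.random.default_rng([config.seed, 202])
    apoe_choices = ["e2/e2", "e2/e3", "e2/e4", "e3/e3", "e3/e4", "e4/e4"]
    apoe_probs = [0.01, 0.1, 0.03, 0.55, 0.25, 0.06]
    rate_c = config.snv_rate_per_year - config.snv_rate_sig_aging
    int_c = config.snv_intercept - config.snv_intercept_sig_aging
    rows = []
    for cond_name, preset in config.conditions.items():
        lo, hi = preset.age_range
        if lo < 0:
            raise ValueError("negative ages are not allowed")
        n_high = int(round(preset.high_indel_fraction * preset.n_individuals))
        for i in range(preset.n_individuals):
            ind_id = f"{cond_name}_{i:03d}"
            age = float(rng.uniform(lo, hi))
            high = i < n_high
            b_snv_a = rng.normal(0, config.individual_sd_snv / np.sqrt(2))
            b_snv_c = rng.normal(0, config.individual_sd_snv / np.sqrt(2))
            b_ind = rng.normal(0, config.individual_sd_indel)
            excess_c = preset.snv_excess_sig_disease
            excess_a = preset.snv_excess - excess_c
            ind_excess = preset.indel_excess_high if high else preset.indel_excess_low
            football = float(rng.uniform(5, 25)) if cond_name in ("CTE", "RHI") else 0.0
            symptoms = float(rng.uniform(2, 20)) if cond_name == "CTE" else 0.0
            apoe = rng.choice(apoe_choices, p=apoe_probs)
            for c in range(config.cells_per_individual):
                e_a = rng.normal(0, config.residual_sd_snv / np.sqrt(2))
                e_c = rng.normal(0, config.residual_sd_snv / np.sqrt(2))
                e_i = rng.normal(0, config.residual_sd_indel)
                aging = max(0.0, config.snv_intercept_sig_aging
                            + config.snv_rate_sig_aging * age + excess_a
                            + b_snv_a + e_a)
                disease = max(0.0, int_c + rate_c * age + excess_c + b_snv_c + e_c)
                indel = max(0.0, config.indel_intercept
                            + config.indel_rate_per_year * age + ind_excess
                            + b_ind + e_i)
                rows.append({
                    "cell_id": f"{ind_id}_c{c}",
                    "individual": ind_id,
                    "condition": cond_name,
                    "age": age,
                    "snv_burden": aging + disease,
                    "indel_burden": indel,
                    "sig_aging_burden": aging,
                    "sig_disease_burden": disease,
                    "high_indel": high,
                    "years_football": football,
                    "symptom_duration": symptoms,
                    "apoe": apoe,
                    "mapd": float(rng.normal(0.25, 0.05)),
                    "cov_adjacent": float(rng.normal(0.8, 0.1)),
                    "mean_depth": float(rng.normal(30, 3)),
                    "allelic_dropout": float(np.clip(rng.normal(0.2, 0.05), 0, 1)),
                })
    df = pd.DataFrame(rows)
    df.attrs["seed"] = config.seed
    return df


# ---------------------------------------------------------------------------
# mutation catalogs


class IndelPlacer:
    """Find genome positions where an indel of a requested 83-context class
    can be constructed.

    Maintains per-class pools of verified (chrom, pos, ref, alt) candidates,
    filled by rejection sampling against the fixture sequence: random
    positions are proposed, the implied indel classified, and every
    classified proposal cached into its class pool. Homopolymer-dependent
    classes are additionally filled by direct run scanning. A class that
    cannot be found in the genome raises an error naming the class.
    """

    MAX_PROPOSALS = 120_000

    def __init__(self, fixture: GenomeFixture, seed: int):
        self.fixture = fixture
        self.rng = np.random.default_rng([seed, 303])
        self.pools: dict[str, list[tuple]] = {}
        self.exhausted: set[str] = set()
        self._run_scanned: set[str] = set()

    def _add(self, label: str, item: tuple) -> None:
        self.pools.setdefault(label, []).append(item)

    def _scan_runs(self, base_class: str) -> None:
        """Directly index homopolymer runs for 1 bp classes of one base."""
        if base_class in self._run_scanned:
            return
        self._run_scanned.add(base_class)
        import re

        bases = "AT" if base_class == "T" else "CG"
        for chrom, seq in self.fixture.sequences.items():
            mask = self.fixture.callable_mask(chrom)
            for b in bases:
                for m in re.finditer(f"{b}{{1,}}", seq):
                    s, e = m.start(), m.end()
                    run = e - s
                    if s < 2 or e > len(seq) - 2 or not mask[s]:
                        continue
                    # deletion of the first base of the run (left-aligned)
                    ref = seq[s - 1 : s + 1]
                    lbl = f"1:Del:{base_class}:{min(run, 6) - 1}"
                    if len(self.pools.get(lbl, [])) < 2000:
                        self._add(lbl, (chrom, s, ref, ref[0]))  # pos 1-based = s
                    # insertion of the same base at the run start
                    lbl = f"1:Ins:{base_class}:{min(run, 5)}"
                    if len(self.pools.get(lbl, [])) < 2000:
                        self._add(lbl, (chrom, s, seq[s - 1], seq[s - 1] + b))

    def _callable(self, chrom: str) -> np.ndarray:
        if not hasattr(self, "_masks"):
            self._masks = {}
        if chrom not in self._masks:
            self._masks[chrom] = self.fixture.callable_mask(chrom)
        return self._masks[chrom]

    def _propose_batch(self, ln: int, event: str, n: int = 4000) -> None:
        chroms = list(self.fixture.chrom_lengths)
        for _ in range(n):
            chrom = chroms[int(self.rng.integers(0, len(chroms)))]
            seq = self.fixture.sequences[chrom]
            pos = int(self.rng.integers(ln + 2, len(seq) - ln - 2))  # 1-based anchor
            if not self._callable(chrom)[pos - 1 : pos + ln].all():
                continue
            anchor = seq[pos - 1]
            if event == "Del":
                ref = seq[pos - 1 : pos + ln]
                alt = anchor
            else:
                if self.rng.random() < 0.5:
                    ins = seq[pos : pos + ln]  # duplicate the following unit
                else:
                    ins = "".join(BASES[i] for i in self.rng.integers(0, 4, ln))
                ref, alt = anchor, anchor + ins
            try:
                label = classify_indel(seq, pos - 1, ref, alt)
            except ValueError:
                continue
            if len(self.pools.get(label, [])) < 2000:
                self._add(label, (chrom, pos, ref, alt))

    def sample(self, label: str) -> tuple[str, int, str, str]:
        parts = label.split(":")
        ln = 5 if parts[0] == "5" else int(parts[0])
        event = parts[1]
        if parts[2] in "CT":
            self._scan_runs(parts[2])
        proposals = 0
        while not self.pools.get(label) and label not in self.exhausted:
            self._propose_batch(ln, event)
            proposals += 4000
            if proposals >= self.MAX_PROPOSALS:
                self.exhausted.add(label)
        pool = self.pools.get(label)
        if not pool:
            raise ValueError(
                f"indel context class {label} has zero genomic availability "
                f"in the fixture"
            )
        return pool[int(self.rng.integers(0, len(pool)))]


def _alt_from_context(label: str) -> tuple[str, str]:
    """(pyrimidine ref, alt) for a 96-context label like T[C>A]T."""
    ref, alt = label[2], label[4]
    return ref, alt


def simulate_snv_catalog(
    n: int,
    weights: dict[str, float],
    fixture: GenomeFixture,
    rng: np.random.Generator,
    signature_matrix: pd.DataFrame | None = None,
    cell_id: str = "cell",
    expression_gradient: float = 0.0,
) -> pd.DataFrame:
    """Draw ``n`` SNVs from a signature mixture and place them on the genome.

    Context classes are drawn from the mixture spectrum; each call is placed
    uniformly at a callable position whose pyrimidine-normalized
    trinucleotide matches its class (exact index sampling, equal in law to
    rejection sampling). With a positive ``expression_gradient`` a fraction
    of calls is instead placed inside genes sampled with expression-rank
    weights, still at context-matching positions.
    """
    if signature_matrix is None:
        signature_matrix = load_packaged_signatures("sbs")
    missing = [k for k in weights if k not in signature_matrix.columns]
    if missing:
        raise ValueError(f"unknown signatures {missing}")
    mix = np.zeros(96)
    for name, w in weights.items():
        mix += w * signature_matrix[name].to_numpy()
    mix = mix / mix.sum()
    if n == 0:
        return pd.DataFrame(columns=["cell_id", "chrom", "pos", "ref", "alt",
                                     "var_class", "context"])
    counts = rng.multinomial(n, mix)
    index = fixture.context_index()
    chroms = list(fixture.chrom_lengths)
    gene_sampler = _GeneSampler(fixture, rng, expression_gradient) \
        if expression_gradient else None
    rows = []
    for ci, cnt in enumerate(counts):
        if cnt == 0:
            continue
        label = SBS96_CONTEXTS[ci]
        trinuc = f"{label[0]}{label[2]}{label[6]}"
        code = TRINUC32_INDEX[normalize_trinuc(trinuc)]
        pools = [index[c][code] for c in chroms]
        pool_sizes = np.array([len(p) for p in pools])
        if pool_sizes.sum() == 0:
            raise ValueError(
                f"context class {label} has zero genomic availability")
        placements: list[tuple[str, int]] = []
        n_plain = int(cnt)
        if gene_sampler is not None:
            for _ in range(int(cnt)):
                if rng.random() < gene_sampler.in_gene_prob:
                    hit = gene_sampler.place(code)
                    if hit is not None:
                        placements.append(hit)
                        n_plain -= 1
        if n_plain > 0:
            # uniform over all context-matching callable positions
            offsets = np.concatenate([[0], np.cumsum(pool_sizes)])
            draw = rng.integers(0, pool_sizes.sum(), size=n_plain)
            which = np.searchsorted(offsets, draw, side="right") - 1
            for d, w in zip(draw, which):
                placements.append((chroms[w], int(pools[w][d - offsets[w]])))
        _, alt_pyr = _alt_from_context(label)
        for chrom, pos in placements:
            ref = fixture.sequences[chrom][pos - 1]
            alt = alt_pyr if ref in "CT" else COMPLEMENT[alt_pyr]
            rows.append({"cell_id": cell_id, "chrom": chrom, "pos": pos,
                         "ref": ref, "alt": alt, "var_class": "SNV",
                         "context": label})
    df = pd.DataFrame(rows).drop_duplicates(["chrom", "pos"]).reset_index(drop=True)
    return df


class _GeneSampler:
    """Sample context-matching positions inside genes with expression-rank
    weights (positive-control enrichment gradient)."""

    in_gene_prob = 0.7

    def __init__(self, fixture: GenomeFixture, rng, gradient: float):
        self.fixture = fixture
        self.rng = rng
        genes = fixture.genes
        ranks = genes["mean_expression"].rank(method="first").to_numpy()
        w = np.exp(gradient * ranks / len(ranks))
        self.weights = w / w.sum()
        self.genes = genes.reset_index(drop=True)
        self.index = fixture.context_index()

    def place(self, code: int):
        g = self.genes.iloc[int(self.rng.choice(len(self.genes), p=self.weights))]
        positions = self.index[g["chrom"]][code]
        lo = np.searchsorted(positions, g["start"])
        hi = np.searchsorted(positions, g["end"], side="right")
        if hi <= lo:
            return None
        return (g["chrom"], int(positions[int(self.rng.integers(lo, hi))]))


def simulate_indel_catalog(
    n: int,
    weights: dict[str, float],
    fixture: GenomeFixture,
    rng: np.random.Generator,
    placer: IndelPlacer,
    signature_matrix: pd.DataFrame | None = None,
    cell_id: str = "cell",
) -> pd.DataFrame:
    """Draw ``n`` indels from an 83-context signature mixture and place them."""
    if signature_matrix is None:
        signature_matrix = load_packaged_signatures("id")
    mix = np.zeros(83)
    for name, w in weights.items():
        mix += w * signature_matrix[name].to_numpy()
    mix = mix / mix.sum()
    if n == 0:
        return pd.DataFrame(columns=["cell_id", "chrom", "pos", "ref", "alt",
                                     "var_class", "context"])
    counts = rng.multinomial(n, mix)
    rows = []
    from .contexts import ID83_CONTEXTS

    for ci, cnt in enumerate(counts):
        for _ in range(int(cnt)):
            label = ID83_CONTEXTS[ci]
            chrom, pos, ref, alt = placer.sample(label)
            rows.append({"cell_id": cell_id, "chrom": chrom, "pos": pos,
                         "ref": ref, "alt": alt,
                         "var_class": "DEL" if len(ref) > 1 else "INS",
                         "context": label})
    return pd.DataFrame(rows).drop_duplicates(["chrom", "pos"]).reset_index(drop=True)


def simulate_mutation_catalog(
    cell: pd.Series,
    fixture: GenomeFixture,
    config: CohortConfig,
    placer: IndelPlacer | None = None,
    rng: np.random.Generator | None = None,
    include_indels: bool = True,
) -> pd.DataFrame:
    """Per-cell somatic mutation catalog matching the cell's burden record.

    SNV counts follow the cell's aging/disease signature split; indel counts
    follow the control or High-Indel mixture depending on the cell.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 404, stable_key(cell["cell_id"])])
    n_aging = int(rng.poisson(cell["sig_aging_burden"]))
    n_disease = int(rng.poisson(cell["sig_disease_burden"]))
    n = n_aging + n_disease
    if n == 0 and not include_indels:
        return simulate_snv_catalog(0, {"SignatureA": 1.0}, fixture, rng,
                                    cell_id=cell["cell_id"])
    w_dis = n_disease / n if n else 0.0
    snvs = simulate_snv_catalog(
        n, {"SignatureA": 1.0 - w_dis, "SignatureC": w_dis}, fixture, rng,
        cell_id=cell["cell_id"],
        expression_gradient=config.expression_gradient,
    )
    if not include_indels:
        return snvs
    if placer is None:
        placer = IndelPlacer(fixture, config.seed)
    n_ind = int(rng.poisson(cell["indel_burden"]))
    weights = (config.indel_weights_high if cell.get("high_indel", False)
               else config.indel_weights_control)
    indels = simulate_indel_catalog(n_ind, weights, fixture, rng, placer,
                                    cell_id=cell["cell_id"])
    return pd.concat([snvs, indels], ignore_index=True)


# ---------------------------------------------------------------------------
# duplex fragments


@dataclass
class PlantedTruth:
    """Ground truth for one cell's duplex simulation.

    ``table`` columns: chrom, pos, ref, alt, var_class, category, strand,
    expected_flag. Categories are disjoint per site.
    """

    cell_id: str
    table: pd.DataFrame

    def __post_init__(self):
        dup = self.table.duplicated(["chrom", "pos"])
        if dup.any():
            raise ValueError("truth categories overlap at a site")

    def sites(self, category: str) -> pd.DataFrame:
        return self.table[self.table["category"] == category]


def make_planted_truth(
    cell: pd.Series,
    fixture: GenomeFixture,
    config: CohortConfig,
    catalog: pd.DataFrame | None = None,
    placer: IndelPlacer | None = None,
    rng: np.random.Generator | None = None,
    contaminated: bool = False,
    min_spacing: int = 101,
) -> PlantedTruth:
    """Assemble the disjoint per-cell truth table for the duplex simulator."""
    if rng is None:
        rng = np.random.default_rng([config.seed, 505,
                                     stable_key(cell["cell_id"])])
    if catalog is None:
        catalog = simulate_mutation_catalog(cell, fixture, config, placer=placer,
                                            rng=rng)
    parts = []
    ds = catalog.copy()
    ds["category"] = "ds_mutation"
    ds["strand"] = "."
    ds["expected_flag"] = ""
    parts.append(ds)

    n_lesions = int(round(len(catalog) * config.lesion_to_mutation_ratio))
    if n_lesions:
        les = simulate_snv_catalog(
            n_lesions,
            {"SignatureA": 1.0 - config.ss_sig_disease_weight,
             "SignatureC": config.ss_sig_disease_weight},
            fixture, rng, cell_id=cell["cell_id"])
        les["category"] = "ss_lesion"
        les["strand"] = np.where(rng.random(len(les)) < 0.5, "+", "-")
        les["expected_flag"] = ""
        parts.append(les)

    pv = fixture.population_variants
    n_germ = min(config.n_germline_per_cell, len(pv))
    germ_idx = rng.choice(len(pv), size=n_germ, replace=False)
    germ = pv.iloc[germ_idx][["chrom", "pos", "ref", "alt", "var_class"]].copy()
    germ["cell_id"] = cell["cell_id"]
    germ["context"] = ""
    germ["category"] = "germline"
    germ["strand"] = "."
    germ["expected_flag"] = ""
    parts.append(germ)

    def _artifact_sites(n, category, flag):
        if n == 0:
            return None
        art = simulate_snv_catalog(n, {"SignatureA": 1.0}, fixture, rng,
                                   cell_id=cell["cell_id"])
        art["category"] = category
        art["strand"] = "."
        art["expected_flag"] = flag
        return art

    n_frag = config.fragments_per_cell
    parts.append(_artifact_sites(int(rng.poisson(config.artifact_rate_read_end * n_frag)),
                                 "artifact_read_end", "read_end"))
    n_coll = int(rng.poisson(config.artifact_rate_collision * n_frag))
    coll = _artifact_sites(n_coll, "artifact_collision", "cutsite_collision")
    if coll is not None:
        half = len(coll) // 2
        coll.iloc[half:, coll.columns.get_loc("category")] = "artifact_multi_bc"
        coll.iloc[half:, coll.columns.get_loc("expected_flag")] = "multi_barcode"
    parts.append(coll)
    n_mw = int(rng.poisson(config.artifact_rate_merge_window * n_frag))
    if n_mw and placer is not None:
        mw = simulate_indel_catalog(n_mw, config.indel_weights_control, fixture,
                                    rng, placer, cell_id=cell["cell_id"])
        mw["category"] = "artifact_merge_window"
        mw["expected_flag"] = "merge_window"
        mw["strand"] = "."
        parts.append(mw)

    if contaminated:
        n_cont = min(config.contamination_sites, len(pv))
        cont_idx = rng.choice(len(pv), size=n_cont, replace=False)
        cont = pv.iloc[cont_idx][["chrom", "pos", "ref", "alt", "var_class"]].copy()
        cont["cell_id"] = cell["cell_id"]
        cont["context"] = ""
        cont["category"] = "contamination"
        cont["strand"] = "."
        cont["expected_flag"] = ""
        parts.append(cont)

    table = pd.concat([p for p in parts if p is not None], ignore_index=True)
    table = table.drop_duplicates(["chrom", "pos"], keep="first").reset_index(drop=True)
    if min_spacing > 0:
        # enforce inter-event spacing (earlier categories take precedence):
        # at genome scale somatic events are far sparser than on a Mb-scale
        # fixture, so without this the proximity filter would remove
        # legitimately planted pairs
        kept: dict[str, list[int]] = {}
        keep_idx = []
        for i, t in enumerate(table.itertuples(index=False)):
            positions = kept.setdefault(t.chrom, [])
            j = np.searchsorted(positions, t.pos)
            if (j > 0 and t.pos - positions[j - 1] <= min_spacing) or (
                j < len(positions) and positions[j] - t.pos <= min_spacing
            ):
                continue
            positions.insert(j, t.pos)
            keep_idx.append(i)
        table = table.iloc[keep_idx].reset_index(drop=True)
    return PlantedTruth(cell_id=cell["cell_id"], table=table)


def simulate_duplex_fragments(
    cell: pd.Series,
    truth: PlantedTruth,
    config: CohortConfig,
    fixture: GenomeFixture,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Emit strand-tagged fragment-group observations for one cell.

    Each planted event gets its own molecule (barcode pair + Tn5 cut-site
    pair). Double-stranded mutations appear on both strands at VAF 1;
    single-stranded lesions on exactly one strand with reference support on
    the other; artifact classes reproduce the evidence pattern their filter
    targets (sites near read ends, cut-site collisions, extra barcode-pair
    coverage, merge-window / unmerged-representation inconsistencies).
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 606,
                                     stable_key(cell["cell_id"])])
    tags = [f"T{i:02d}" for i in range(config.n_tags)]
    reads = config.reads_per_strand
    flen_lo, flen_hi = config.fragment_length
    rows = []

    def new_molecule(chrom, pos, margin_min=None):
        """Fragment interval containing pos with the event away from ends."""
        flen = int(rng.integers(flen_lo, flen_hi + 1))
        if margin_min is None:
            margin_min = 25
        margin_min = min(margin_min, (flen - 1) // 2)
        off = int(rng.integers(margin_min, flen - margin_min)) \
            if flen > 2 * margin_min else flen // 2
        start = pos - off
        end = start + flen - 1
        clen = fixture.chrom_lengths[chrom]
        if start < 1:
            start, end = 1, flen
        if end > clen:
            end, start = clen, clen - flen + 1
        bc1, bc2 = tags[int(rng.integers(0, len(tags)))], tags[int(rng.integers(0, len(tags)))]
        return start, end, bc1, bc2

    def emit(chrom, pos, start, end, bc1, bc2, strand, ref, alt, nreads,
             merged=False, mw=(0, 0), in_unmerged=True, var_class="SNV"):
        rows.append({
            "cell_id": cell["cell_id"], "chrom": chrom, "start": start,
            "end": end, "bc1": bc1, "bc2": bc2, "strand": strand,
            "pos": pos, "ref": ref, "alt": alt, "reads": nreads,
            "merged": merged, "mw_start": mw[0], "mw_end": mw[1],
            "in_unmerged": in_unmerged, "var_class": var_class,
        })

    for t in truth.table.itertuples(index=False):
        chrom, pos, ref, alt = t.chrom, int(t.pos), t.ref, t.alt
        vc = t.var_class
        if t.category in ("ds_mutation", "germline", "contamination"):
            start, end, bc1, bc2 = new_molecule(chrom, pos)
            for strand in "+-":
                emit(chrom, pos, start, end, bc1, bc2, strand, ref, alt, reads,
                     var_class=vc)
        elif t.category == "ss_lesion":
            start, end, bc1, bc2 = new_molecule(chrom, pos)
            var_strand = t.strand
            other = "-" if var_strand == "+" else "+"
            emit(chrom, pos, start, end, bc1, bc2, var_strand, ref, alt, reads,
                 var_class=vc)
            emit(chrom, pos, start, end, bc1, bc2, other, ref, ".", reads,
                 var_class=vc)
        elif t.category == "artifact_read_end":
            start, end, bc1, bc2 = new_molecule(chrom, pos, margin_min=25)
            # force the site within 20 bp of the left read end
            from .config import CallerThresholds

            start = pos - int(rng.integers(0, CallerThresholds().read_end_bp + 1))
            end = start + int(rng.integers(flen_lo, flen_hi + 1)) - 1
            for strand in "+-":
                emit(chrom, pos, start, end, bc1, bc2, strand, ref, alt, reads,
                     var_class=vc)
        elif t.category == "artifact_collision":
            start, end, bc1, bc2 = new_molecule(chrom, pos)
            for strand in "+-":
                emit(chrom, pos, start, end, bc1, bc2, strand, ref, alt, reads,
                     var_class=vc)
            # second fragment, same barcode pair, shifted cut sites
            shift = int(rng.integers(10, 40))
            emit(chrom, pos, start - shift, end - shift, bc1, bc2, "+", ref, ".",
                 reads, var_class=vc)
        elif t.category == "artifact_multi_bc":
            start, end, bc1, bc2 = new_molecule(chrom, pos)
            for strand in "+-":
                emit(chrom, pos, start, end, bc1, bc2, strand, ref, alt, reads,
                     var_class=vc)
            ob1 = tags[(tags.index(bc1) + 1) % len(tags)]
            start2, end2, _, ob2 = new_molecule(chrom, pos)
            emit(chrom, pos, start2, end2, ob1, ob2, "+", ref, ".", reads,
                 var_class=vc)
        elif t.category == "artifact_merge_window":
            start, end, bc1, bc2 = new_molecule(chrom, pos)
            mw = (pos - int(rng.integers(0, 10)), pos + int(rng.integers(0, 10)))
            absent_unmerged = bool(rng.random() < 0.5)
            for strand in "+-":
                emit(chrom, pos, start, end, bc1, bc2, strand, ref, alt, reads,
                     merged=True, mw=mw, in_unmerged=not absent_unmerged,
                     var_class=vc)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# expression / accessibility


def simulate_expression_accessibility(
    fixture: GenomeFixture,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign gene mean expressions and correlated accessibility coverage.

    Expression is log-normal with a configurable zero-expressed fraction;
    bin coverage shares a latent Gaussian with the expression of the gene
    overlapping each bin, at correlation ``accessibility_expression_corr``
    (intergenic bins get independent noise). Updates ``fixture.genes`` in
    place and returns (expression table, accessibility table).
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 707])
    genes = fixture.genes
    z = rng.normal(size=len(genes))
    expr = np.exp(config.expression_logmean + config.expression_logsd * z)
    zero = rng.random(len(genes)) < config.zero_expression_fraction
    expr[zero] = 0.0
    genes["mean_expression"] = expr
    rho = config.accessibility_expression_corr
    bins = fixture.accessibility_bins.copy()
    cov = np.empty(len(bins))
    noise = rng.normal(size=len(bins))
    for chrom in fixture.chrom_lengths:
        gsub = genes[genes["chrom"] == chrom]
        bsel = bins["chrom"] == chrom
        starts = gsub["start"].to_numpy()
        ends = gsub["end"].to_numpy()
        mids = (bins.loc[bsel, "start"].to_numpy()
                + bins.loc[bsel, "end"].to_numpy()) // 2
        gi = np.searchsorted(starts, mids, side="right") - 1
        inside = (gi >= 0) & (mids <= ends[np.clip(gi, 0, None)])
        latent = np.where(
            inside,
            rho * z[gsub.index.to_numpy()[np.clip(gi, 0, None)]]
            + np.sqrt(max(0.0, 1 - rho**2)) * noise[bsel.to_numpy().nonzero()[0]],
            noise[bsel.to_numpy().nonzero()[0]],
        )
        cov[bsel.to_numpy().nonzero()[0]] = np.exp(0.5 * latent) * 50
    bins["coverage"] = cov
    fixture.accessibility_bins = bins
    expr_table = genes[["gene_id", "mean_expression"]].copy()
    return expr_table, bins
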