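# Methods

This note documents the models, defaults and numerical choices behind
`scduplex`, and what the synthetic-data tests do and do not establish about
real data.

## Burden model

Per-cell somatic burden is modelled as

    burden = intercept + annual_rate × age + condition_excess
             + individual_intercept + cell_residual,   truncated at 0.

Defaults (the "published" preset) encode the study conditions the package
emulates:

| parameter | sSNV | sIndel | note |
|---|---|---|---|
| annual rate (per cell per year) | 16.5 | 2.5 | midpoints of the reported 16–17 and 2–3 ranges; 3.0 is kept as the upper bound of the normal annual sIndel rate |
| intercept at age 0 | 50 | 10 | small positive perinatal burden |
| CTE condition excess (per cell) | 114 | 312 (cohort mean) | — |
| individual random-intercept SD | 25 | 12 | between-donor variability |
| cell residual SD | 50 | 25 | within-donor, between-cell variability |

The sSNV burden is generated as the sum of an aging-signature component
(intercept 35, slope 15/yr) and a disease-signature component (intercept
15, slope 1.5/yr); the CTE excess splits as +50 aging / +64 disease, so the
signature-attributed excess is itself a recoverable parameter. Noise is
split evenly (variance-wise) between the two components.

The sIndel excess uses a High-/Low-Indel mixture: a fixed fraction (0.6) of
CTE individuals — deterministically the first round(0.6·n) — receives a
+500 excess, the rest +30, giving the 0.6·500 + 0.4·30 = 312 cohort mean.
Per-individual excesses are fixed at the preset magnitudes; individual
heterogeneity beyond the High/Low split enters only through the random
intercepts. Ages are uniform per condition (controls 20–95, CTE 40–90, RHI
25–60, AD 60–95). Burden truncation at 0 makes the young-control tail
slightly non-linear; at the default noise levels the induced bias on the
fitted age model is ≪ 1 mutation.

The per-cell residual distribution is Gaussian by default (the residual
family is not constrained by the linear model; Gaussian is the conventional
choice and is configurable through the config dataclass).

## Genome fixture

Desk scale: 2 chromosomes × 1 Mb by default (tests use 2 × 200 kb). The
sequence is uniform random with ~2% of positions overwritten by planted
homopolymer runs (5–12 bp) and short tandem repeats (2–4 bp units × 3–8
copies), so that repeat- and homopolymer-mediated indel context classes
have non-zero genomic availability; an indel class that still cannot be
constructed anywhere raises an error naming the class. Masks (~1% of the
genome in 500 bp blocks) define the low-quality regions; callable regions
are their complement. All interval logic is identical to full-genome
operation; only the scale differs.

SNV placement draws a context class from the signature mixture and then a
uniform position among all callable positions with that
(pyrimidine-normalized) trinucleotide, via a precomputed context→position
index — identical in law to rejection sampling but O(1) per draw. Indel
placement is genuine rejection sampling with per-class pools of verified
positions (homopolymer classes are additionally filled by direct run
scanning). Planted events keep a minimum inter-event spacing of 101 bp by
default: at genome scale somatic events are orders of magnitude sparser
than on a Mb fixture, and without the spacing the 100 bp proximity filter
would remove legitimately planted pairs, which would make the clean
round-trip recall property meaningless.

## Duplex simulation and caller

Each planted event receives its own molecule (barcode pair from a 16×16
ordered tag space, Tn5 cut-site pair, 300–500 bp) with 4 reads per strand
by default. Double-stranded mutations appear on both strands with no
reference reads on the molecule (VAF 1); single-stranded lesions on exactly
one strand with ≥4 reference reads on the other. Artifact classes plant the
evidence pattern their filter targets: read-end sites ≤20 bp from a cut
site, same-barcode-pair fragments with shifted cut sites (cut-site-set
count 2), extra barcode-pair coverage, and merged-read indels inside a
merge window or absent from the unmerged representation. Contaminated cells
receive duplex-supported calls at population-variant sites; because the
contaminant is absent from bulk these survive candidate generation and
inflate the pre-filter population-variant overlap, which is the detection
signal (study data showed ~93% overlap in contaminated cells; the default
exclusion threshold is 0.5 and is configurable, since only the observed
overlap, not a cutoff, is reported).

Filter conventions: the 100 bp proximity and 20 bp read-end windows are
inclusive (distance ≤ window) and the proximity rule removes both members
of a close pair; proximity is evaluated within variant class (SNV vs
indel) by default, configurable. "More than one barcode pair" is evaluated
per locus over all fragments observed there. Indels are left-aligned and
parsimony-trimmed before any distance computation or classification, since
distances and repeat counts are representation-dependent. The germline
flank is measured from the (left-aligned) candidate start to the germline
indel start. Monotonicity holds by construction: relaxing any single
threshold can only grow the call set.

What the round-trip tests show: with artifact rates 0 and ≥4 reads/strand,
recall of planted ds mutations is 1 with 0 false calls, and every planted
artifact carries its matching flag. They do not exercise sequencing error,
base quality, alignment ambiguity, or coverage fluctuation — the simulator
works at the fragment-evidence level, downstream of alignment, so caller
performance on real reads is not established here.

## Spectra and signatures

SNV spectra use the standard 96 pyrimidine-strand trinucleotide classes;
indels the standard 83-class scheme (type × length × repeat-unit count,
with microhomology classes for non-repeat deletions of ≥2 bp; homopolymer
length for 1 bp events). The classifier is validated against an independent
brute-force flank-scanning oracle on 1,000 random indels.

The packaged signature matrices are **synthetic stand-ins** (the database
originals and the published single-neuron signatures are not
redistributable here): an aging/clock-like flat signature A, a C>A-heavy
disease signature C (cosine(A, C) ≈ 0.31), three further SBS-like vectors
for residual decomposition, and aging-like / repeat-region / deletion-rich
(2–4 bp, microhomology-flavoured) indel signatures. The strand signatures
are DS = 0.77·A + 0.23·C and SS = 0.33·A + 0.67·C, matching the reported
~23% / ~67% disease-signature shares of ds and ss SNVs. Conclusions about
real signature biology require the real matrices, which drop in as TSVs of
the same shape.

Refitting is non-negative least squares (`scipy.optimize.nnls`), verified
against an independent bounded least-squares optimizer to 1e-6. Signature
burden = fitted proportion × genome-wide burden, which conserves the total.
De novo extraction is multiplicative-update NMF under Kullback–Leibler
divergence (200 runs at full scale, 20 in the test profile; seeded run
streams); rank selection combines run-to-run component stability with the
divergence. NMF corners are only identifiable when exposures include
near-pure samples; the recovery test plants such exposures deliberately.

### Strand conversion

The DS/SS pair is factored by rank-2 KL-NMF into intermediates IM₁, IM₂;
DS and SS are refitted onto the IMs and the coefficients column-normalized
so a₁+b₁ = 1, a₂+b₂ = 1; a cell spectrum fitted as c₁IM₁+c₂IM₂ (c₁+c₂ = 1)
converts to k₁ = c₁a₁+c₂a₂, k₂ = c₁b₁+c₂b₂, hence k₁+k₂ = 1 exactly.

Two intertwined subtleties are design decisions here. First, a rank-2
factorization of exactly two spectra is non-unique: every non-negative
recombination with zero divergence is equally optimal, and which one a
random-initialized NMF reaches is arbitrary. Second, the k-formulas are a
projection, not the algebraic inverse of the DS/SS-on-IM system; they
reproduce a known DS weight exactly only when the intermediates stay close
to DS and SS themselves (in the exact-inverse reading one would instead
solve the 2×2 system — deliberately not done, as the formulas are
implemented exactly as stated). We therefore canonicalize the factorization
by anchoring the multiplicative-update initialization at the observed
signatures, selecting the minimal-mixing zero-divergence solution; this
makes the projection self-consistent, and the round trip (spectra built as
0.85 DS + 0.15 SS convert to mean k₁ ≈ 0.85) holds to Monte-Carlo error.
With a free random initialization the same code yields systematically
shrunken k₁ (≈0.6 for a 0.85 mixture) — a property of the projection, not
of the data. Near-identical DS/SS inputs are flagged collinear and the
reconstruction error is reported with the model.

### Residuals, ratios, summaries

Disease-minus-control residual spectra are computed on proportions;
negative bins are floored at zero and the mass renormalized, with the raw
signed residual also returned (the subtraction's negative-bin handling is
otherwise undefined). Age-contribution ratios divide each cell's signature
burden by its control-model age expectation; relative contribution is the
disease median ratio minus the control median ratio. The 2–4 bp deletion
fraction sums the R and M deletion classes of lengths 2–4. Individual-level
PCA normalizes 83-context counts to proportions, centres them (no
unit-variance scaling — rare classes would otherwise dominate), excludes
individuals with fewer than 15 sIndels, and returns the first two
components with variance fractions; an all-identical input is flagged
degenerate rather than decomposed.

## Mixed-effects machinery

Estimation uses `statsmodels` MixedLM (REML, random intercept per
individual; BFGS with Powell/Nelder–Mead fallbacks). Burdens are modelled
on the natural count scale. On top of the fit, the package computes
Satterthwaite degrees of freedom from the closed-form random-intercept
marginal likelihood: df = 2f²/(gᵀH⁻¹g), where f(θ) is the fixed-effect
sampling variance as a function of θ = (τ², σ²), g its central-difference
gradient, and H the numeric Hessian of the negative REML log-likelihood
(Woodbury per-group algebra, so cost is linear in cells). When the Hessian
is singular or df < 1 (boundary fits, zero-variance degeneracies) the fit
is flagged and falls back to the residual df with a maximum-likelihood
likelihood-ratio p-value reported alongside. The machinery is cross-checked
against R's `lmerTest` on a shared dataset (estimates to 0.1%, df and p to
5%) and calibrated by simulation: under the null the condition t-test
rejects at 4.9% (1,000 replicates, nominal 5%).

Condition effects are tested each-against-control in separate fits.
Excess burden subtracts the control intercept as well as the age term, so
the control group centres at zero by the least-squares property (the
age-coefficient-only reading would leave a constant offset; the intercept
subtraction matches a zero-excess control baseline). Group comparisons of
excess use the two-sample Wilcoxon rank-sum test, exact for combined n ≤ 50
without ties, tie-corrected normal approximation otherwise. QC correction
estimates the metric coefficient in control cells only (metric + age fixed,
individuals random) and subtracts coefficient × metric from every cell.
APOE ε4 coding: dominant = any ε4, additive = ε4 count, recessive = ε4/ε4.

## Permutation and enrichment

Permutation preserves, per call: chromosome, pyrimidine-normalized
trinucleotide context (taken at the start position for indels), and the
allele (indels carry their sequence; SNV alleles are re-stranded to the
destination site so the context class is unchanged). Positions are sampled
uniformly from a precomputed per-chromosome context→callable-position
index; counts per (chromosome, context) are preserved by construction and
asserted in tests. Defaults: 1000 rounds (100 in the test profile), one
seeded substream per cell with rounds vectorized inside it.

Genes (or accessibility bins) are rank-split into equal-size groups —
10 for sSNVs, 5 for sIndels — with stable-order tie-breaking and remainder
to the lowest groups; enrichment per group and round is observed count /
permuted count (groups are equal-size, so counts and densities give the
same ratio), summarized as mean ± SD with a Pearson trend over group index.
Calls overlapping more than one gene are removed from observed and
permuted sets alike; a group with zero expected count in any round is
flagged and excluded from the mean. Signature-specific enrichment refits
each group's spectrum (observed, and per round — permuted indel spectra use
the carried context labels, since a moved indel cannot be re-classified
against the destination reference) and feeds attributed counts
(proportion × group count) through the same ratio machinery; attributed
counts sum to the group totals by construction.

The transcribed vs non-transcribed contrast compares the two per-round
ratio vectors with the rank-sum test. Note the rounds share one observed
draw, so this p-value quantifies permutation spread given that draw — it
is not calibrated across observed replicates, and the tests therefore check
the null behaviour of the ratio difference (small, sign-varying) rather
than of the p-value. The planted positive control (expression-rank
placement gradient) yields monotone increasing ratios, a positive trend,
and a significant transcribed excess.

## Problem sizes

The acceptance run simulates 100 control + 100 CTE individuals × 4 cells —
4 cells per individual matching the cohort design, and the individual count
chosen so that Monte-Carlo error on the recovered cohort means (SE ≈ 4–5
sSNVs for the +114 excess) sits well inside the recovery tolerances; the
whole run completes in well under a minute. Unit tests run on 2 × 200 kb
fixtures with catalogs of 100–500 events. The demo pipeline (6+6
individuals × 2 cells) is sized for interactive use and correspondingly
noisy.

## Known limitations

- No read-level simulation: base qualities, sequencing error, alignment
  and coverage structure are out of scope; the caller consumes
  fragment-level evidence tables.
- Packaged signatures are synthetic; quantitative signature attributions
  on real data require the real matrices.
- The strand-conversion weights depend on the factorization
  canonicalization discussed above; alternative anchors give different
  (systematically smaller) k₁ for the same data.
- Satterthwaite df relies on numeric differentiation; extremely
  ill-conditioned designs fall back to the flagged LRT path.
- The fixture genome's repeat content is stylized; indel context
  availability, not realistic repeat biology, is its purpose.
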