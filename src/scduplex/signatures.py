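"""Mutational-signature engine.

Builds 96-context SNV and 83-context indel spectra, refits them to known
signatures by non-negative least squares, extracts de novo signatures with
Kullback-Leibler NMF, and implements the double-/single-strand conversion:
two intermediate signatures IM1/IM2 are factored out of the DS and SS strand
signatures, DS and SS are refitted onto them with per-IM normalized
coefficients (a1 + b1 = 1, a2 + b2 = 1), and a cell spectrum fitted to the
IMs with coefficients (c1, c2) is converted to double-/single-strand weights

    k1 = c1 * a1 + c2 * a2,    k2 = c1 * b1 + c2 * b2,

so that k1 + k2 = c1 + c2 = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.decomposition import NMF, PCA

from .contexts import (
    ID83_CONTEXTS,
    ID83_INDEX,
    SBS96_CONTEXTS,
    SBS96_INDEX,
    classify_indel,
    sbs_context,
)

# ---------------------------------------------------------------------------
# packaged signature matrices


def load_packaged_signatures(which: str) -> pd.DataFrame:
    """Load a packaged signature matrix (synthetic stand-ins).

    ``which`` is one of ``sbs``, ``id``, ``strand_snv``, ``strand_indel``.
    The packaged matrices are synthetic constructions with the qualitative
    structure of the published single-neuron signatures (an aging/clock-like
    SNV signature A, a disease-associated C>A-heavy signature C, deletion-
    rich / clock-like / repeat-region indel signatures, and DS/SS strand
    signatures); they are not the database originals.
    """
    fname = {
        "sbs": "sbs_signatures_synthetic.tsv",
        "id": "id_signatures_synthetic.tsv",
        "strand_snv": "strand_snv_signatures_synthetic.tsv",
        "strand_indel": "strand_indel_signatures_synthetic.tsv",
    }[which]
    with resources.files("scduplex.data").joinpath(fname).open() as fh:
        df = pd.read_csv(fh, sep="\t", index_col=0)
    expected = SBS96_CONTEXTS if df.shape[0] == 96 else ID83_CONTEXTS
    if list(df.index) != expected:
        raise ValueError(f"{fname}: unexpected context ordering")
    return df


# ---------------------------------------------------------------------------
# spectra


def _get_seq(fixture, chrom: str) -> str:
    seqs = getattr(fixture, "sequences", fixture)
    return seqs[chrom]


def build_snv_spectrum(calls: pd.DataFrame, fixture) -> pd.Series:
    """Count SNV calls over the 96 trinucleotide context classes.

    The reference trinucleotide is re-extracted from the fixture sequence at
    each (1-based) position and pyrimidine-normalized.
    """
    counts = np.zeros(96, dtype=int)
    for row in calls.itertuples(index=False):
        seq = _get_seq(fixture, row.chrom)
        p = int(row.pos) - 1
        trinuc = seq[p - 1 : p + 2]
        if seq[p] != row.ref:
            raise ValueError(
                f"reference mismatch at {row.chrom}:{row.pos}: "
                f"{seq[p]} != {row.ref}"
            )
        counts[SBS96_INDEX[sbs_context(trinuc, row.alt)]] += 1
    return pd.Series(counts, index=SBS96_CONTEXTS, name="count")


def build_indel_spectrum(calls: pd.DataFrame, fixture) -> pd.Series:
    """Count indel calls over the 83 indel context classes."""
    counts = np.zeros(83, dtype=int)
    for row in calls.itertuples(index=False):
        seq = _get_seq(fixture, row.chrom)
        label = classify_indel(seq, int(row.pos) - 1, row.ref, row.alt)
        counts[ID83_INDEX[label]] += 1
    return pd.Series(counts, index=ID83_CONTEXTS, name="count")


def spectrum_from_context_labels(calls: pd.DataFrame, fixture=None) -> pd.Series:
    """Spectrum from a carried ``context`` label column (96 or 83 classes).

    Used for permuted call sets, whose indel alleles are positional copies
    and cannot be re-classified against the destination reference.
    """
    labels = calls["context"]
    if labels.str.contains(":").any():
        idx, order = ID83_INDEX, ID83_CONTEXTS
    else:
        idx, order = SBS96_INDEX, SBS96_CONTEXTS
    counts = np.zeros(len(order), dtype=int)
    for lab in labels:
        counts[idx[lab]] += 1
    return pd.Series(counts, index=order, name="count")


def normalize_spectrum(spectrum) -> np.ndarray:
    v = np.asarray(spectrum, dtype=float)
    total = v.sum()
    if total <= 0:
        return np.zeros_like(v)
    return v / total


# ---------------------------------------------------------------------------
# signature refitting


@dataclass
class SignatureFit:
    names: list[str]
    raw: np.ndarray           # non-negative contributions on the count scale
    proportions: np.ndarray   # normalized to sum 1 (zeros if empty spectrum)
    cosine: float             # reconstruction cosine similarity

    def as_series(self) -> pd.Series:
        return pd.Series(self.proportions, index=self.names)


def fit_signatures(spectrum, signatures: pd.DataFrame) -> SignatureFit:
    """Non-negative least-squares refit of a spectrum to known signatures."""
    y = np.asarray(spectrum, dtype=float)
    A = signatures.to_numpy(dtype=float)
    if A.shape[0] != y.shape[0]:
        raise ValueError("context dimensionality mismatch")
    coef, _ = nnls(A, y)
    recon = A @ coef
    denom = np.linalg.norm(recon) * np.linalg.norm(y)
    cosine = float(recon @ y / denom) if denom > 0 else float("nan")
    total = coef.sum()
    props = coef / total if total > 0 else np.zeros_like(coef)
    return SignatureFit(list(signatures.columns), coef, props, cosine)


def signature_burden(proportions, genome_wide_burden: float) -> np.ndarray:
    """Split a genome-wide burden across signatures by fitted proportion."""
    p = np.asarray(proportions, dtype=float)
    if p.sum() > 0:
        p = p / p.sum()
    return p * float(genome_wide_burden)


# ---------------------------------------------------------------------------
# de novo extraction


@dataclass
class DenovoResult:
    signatures: pd.DataFrame          # contexts x rank, columns N1..Nk
    exposures: np.ndarray             # samples x rank
    rank: int
    diagnostics: pd.DataFrame         # per-rank stability / divergence


def _kl_nmf(X: np.ndarray, rank: int, seed: int, max_iter: int = 2000) -> tuple:
    m = NMF(
        n_components=rank,
        init="random",
        solver="mu",
        beta_loss="kullback-leibler",
        max_iter=max_iter,
        tol=1e-8,
        random_state=seed,
    )
    W = m.fit_transform(X)
    return W, m.components_, m.reconstruction_err_


def _match_cosine(A: np.ndarray, B: np.ndarray) -> float:
    """Mean best-match cosine between two signature sets (rows)."""
    An = A / np.maximum(np.linalg.norm(A, axis=1, keepdims=True), 1e-12)
    Bn = B / np.maximum(np.linalg.norm(B, axis=1, keepdims=True), 1e-12)
    sim = An @ Bn.T
    used, total = set(), 0.0
    for i in np.argsort(-sim.max(axis=1)):
        j = int(np.argmax([s if jj not in used else -2 for jj, s in enumerate(sim[i])]))
        used.add(j)
        total += sim[i, j]
    return total / A.shape[0]


def extract_denovo_signatures(
    spectra: pd.DataFrame,
    rank_range=(2, 3),
    n_runs: int = 20,
    seed: int = 0,
) -> DenovoResult:
    """De novo signature extraction by multiplicative-update KL NMF.

    ``spectra`` is samples x contexts (counts). For each candidate rank,
    ``n_runs`` seeded runs are performed; rank selection combines run-to-run
    stability (mean best-match cosine between component sets) with the KL
    reconstruction divergence. The returned signatures come from the
    best-divergence run at the selected rank.
    """
    X = spectra.to_numpy(dtype=float)
    ranks = list(range(rank_range[0], rank_range[1] + 1))
    if max(ranks) > X.shape[0]:
        raise ValueError("rank exceeds the number of spectra")
    rows, best = [], {}
    for rank in ranks:
        runs = [_kl_nmf(X, rank, seed * 1000 + rank * 100 + r) for r in range(n_runs)]
        errs = np.array([r[2] for r in runs])
        ref = runs[int(np.argmin(errs))]
        stab = (
            np.mean([_match_cosine(ref[1], r[1]) for r in runs]) if n_runs > 1 else 1.0
        )
        rows.append({"rank": rank, "stability": stab, "kl_divergence": errs.min()})
        best[rank] = ref
    diag = pd.DataFrame(rows)
    # prefer the most stable rank; break ties toward lower divergence
    sel = diag.sort_values(["stability", "kl_divergence"],
                           ascending=[False, True]).iloc[0]
    rank = int(sel["rank"])
    W, H, _ = best[rank]
    sigs = H / H.sum(axis=1, keepdims=True)
    names = [f"N{i + 1}" for i in range(rank)]
    sig_df = pd.DataFrame(sigs.T, index=list(spectra.columns), columns=names)
    scale = H.sum(axis=1)
    return DenovoResult(sig_df, W * scale, rank, diag)


# ---------------------------------------------------------------------------
# double-/single-strand conversion


@dataclass
class StrandConversionModel:
    im: np.ndarray            # 2 x n_contexts, normalized intermediate signatures
    a: np.ndarray             # DS coefficients (a1, a2), per-IM normalized
    b: np.ndarray             # SS coefficients (b1, b2)
    ds: np.ndarray
    ss: np.ndarray
    reconstruction_error: float
    collinear: bool
    raw_mixing: np.ndarray = field(default=None)  # unnormalized NNLS coefficients

    @property
    def a1(self): return float(self.a[0])
    @property
    def a2(self): return float(self.a[1])
    @property
    def b1(self): return float(self.b[0])
    @property
    def b2(self): return float(self.b[1])


def derive_strand_conversion(
    ds, ss, max_iter: int = 2000, collinearity_cosine: float = 0.999
) -> StrandConversionModel:
    """Derive intermediate signatures IM1/IM2 and the (a, b) coefficients.

    The stacked, normalized DS/SS pair is factored by rank-2 KL NMF. Because
    a rank-2 factorization of two spectra is non-unique (any non-negative
    recombination with zero divergence is equally optimal), the factorization
    is canonicalized by anchoring the multiplicative-update initialization at
    the observed signatures, selecting the minimal-mixing solution; this
    keeps the downstream projection formulas self-consistent. DS and SS are
    then refitted onto the IMs and the coefficients normalized per IM so
    that a1 + b1 = 1 and a2 + b2 = 1. Near-identical DS/SS inputs are
    flagged as collinear.
    """
    ds = normalize_spectrum(ds)
    ss = normalize_spectrum(ss)
    X = np.vstack([ds, ss])
    cos = float(ds @ ss / max(np.linalg.norm(ds) * np.linalg.norm(ss), 1e-300))
    collinear = cos >= collinearity_cosine
    H0 = np.maximum(X, 1e-9)
    W0 = np.eye(2) + 1e-6
    m = NMF(
        n_components=2,
        init="custom",
        solver="mu",
        beta_loss="kullback-leibler",
        max_iter=max_iter,
        tol=1e-10,
    )
    m.fit_transform(X, W=W0.copy(), H=H0.copy())
    im = m.components_ / m.components_.sum(axis=1, keepdims=True)
    a_raw, _ = nnls(im.T, ds)
    b_raw, _ = nnls(im.T, ss)
    M = np.vstack([a_raw, b_raw])
    # orient IM1 toward DS: DS should load dominantly on the first IM
    if a_raw[0] < b_raw[0]:
        im = im[::-1]
        M = M[:, ::-1]
    colsum = np.maximum(M.sum(axis=0), 1e-300)
    N = M / colsum
    return StrandConversionModel(
        im=im,
        a=N[0],
        b=N[1],
        ds=ds,
        ss=ss,
        reconstruction_error=float(m.reconstruction_err_),
        collinear=collinear,
        raw_mixing=M,
    )


def convert_pta_spectrum(spectrum, model: StrandConversionModel):
    """Convert a cell spectrum to double-/single-strand weights (k1, k2).

    The spectrum is fitted to the intermediate signatures by NNLS, the
    coefficients normalized to c1 + c2 = 1, and the stated projection
    formulas applied exactly: k1 = c1*a1 + c2*a2, k2 = c1*b1 + c2*b2.
    """
    y = normalize_spectrum(spectrum)
    c_raw, _ = nnls(model.im.T, y)
    total = c_raw.sum()
    if total <= 0:
        raise ValueError("spectrum cannot be fitted to the intermediates")
    c = c_raw / total
    k1 = float(c @ model.a)
    k2 = float(c @ model.b)
    return k1, k2, float(c[0]), float(c[1])


# ---------------------------------------------------------------------------
# residuals, ratios, summaries


def residual_spectrum(disease, control) -> pd.DataFrame:
    """Disease-minus-control residual after normalizing each to proportions.

    Returns both the raw signed residual and the non-negative residual
    (negatives floored at zero, mass renormalized).
    """
    d = normalize_spectrum(disease)
    c = normalize_spectrum(control)
    raw = d - c
    pos = np.clip(raw, 0, None)
    total = pos.sum()
    floored = pos / total if total > 0 else pos
    idx = disease.index if isinstance(disease, pd.Series) else range(len(d))
    return pd.DataFrame({"raw": raw, "residual": floored}, index=idx)


def age_contribution_ratio(
    cell_burdens: pd.DataFrame,
    control_age_models: dict[str, tuple[float, float]],
) -> pd.DataFrame:
    """Per-cell ratio of signature burden to its age-expected burden.

    ``cell_burdens`` needs columns ``age``, ``condition`` and one column per
    signature; ``control_age_models`` maps signature name -> (intercept,
    age slope) fitted on control cells. Returns the per-cell ratios plus,
    per condition, the median ratio and the relative contribution (median
    minus the control median).
    """
    out = cell_burdens.copy()
    for sig, (icept, slope) in control_age_models.items():
        expected = icept + slope * out["age"].to_numpy()
        out[f"ratio_{sig}"] = out[sig].to_numpy() / np.maximum(expected, 1e-12)
    return out


def relative_contribution(ratios: pd.DataFrame, signature: str) -> pd.Series:
    """Per-condition median ratio minus the control median ratio."""
    med = ratios.groupby("condition")[f"ratio_{signature}"].median()
    return med - med.get("control", np.nan)


def deletion_fraction(spectrum: pd.Series, size_range=(2, 4)) -> float:
    """Proportion of spectrum mass in deletions of the given length range."""
    lo, hi = size_range
    total = float(np.asarray(spectrum, dtype=float).sum())
    if total <= 0:
        return 0.0
    mass = 0.0
    for label, v in spectrum.items():
        ln, event = label.split(":")[:2]
        if event == "Del" and lo <= int(ln) <= hi:
            mass += float(v)
    return mass / total


@dataclass
class PcaResult:
    embedding: pd.DataFrame         # individuals x (PC1, PC2)
    variance_explained: np.ndarray
    excluded: list[str]
    degenerate: bool


def cluster_individuals_pca(
    counts: pd.DataFrame, min_mutations: int = 15
) -> PcaResult:
    """PCA of per-individual indel spectra (proportions, centered).

    Individuals with fewer than ``min_mutations`` total calls are excluded.
    Spectra are normalized to proportions and mean-centered (no unit-variance
    scaling); the first two principal components are returned with variance
    fractions. A zero-variance input (all spectra identical) is flagged.
    """
    totals = counts.sum(axis=1)
    excluded = list(counts.index[totals < min_mutations])
    kept = counts.loc[totals >= min_mutations]
    if kept.shape[0] < 2:
        raise ValueError("need at least two individuals after exclusion")
    props = kept.div(kept.sum(axis=1), axis=0).to_numpy()
    centered = props - props.mean(axis=0)
    if np.allclose(centered, 0):
        emb = pd.DataFrame(0.0, index=kept.index, columns=["PC1", "PC2"])
        return PcaResult(emb, np.zeros(2), excluded, degenerate=True)
    n_comp = min(2, kept.shape[0] - 1, props.shape[1])
    pca = PCA(n_components=n_comp)
    coords = pca.fit_transform(props)
    if n_comp < 2:
        coords = np.column_stack([coords, np.zeros(len(coords))])
    var = np.zeros(2)
    var[: n_comp] = pca.explained_variance_ratio_
    emb = pd.DataFrame(coords[:, :2], index=kept.index, columns=["PC1", "PC2"])
    return PcaResult(emb, var, excluded, degenerate=False)
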