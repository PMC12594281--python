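"""Signature engine: spectra, NNLS refitting, NMF extraction, the
double-/single-strand conversion, residuals, and individual-level PCA."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import lsq_linear

from scduplex.contexts import ID83_CONTEXTS, SBS96_CONTEXTS
from scduplex.signatures import (
    build_snv_spectrum,
    build_indel_spectrum,
    cluster_individuals_pca,
    convert_pta_spectrum,
    deletion_fraction,
    derive_strand_conversion,
    extract_denovo_signatures,
    fit_signatures,
    load_packaged_signatures,
    residual_spectrum,
    signature_burden,
)
from scduplex.synthetic import simulate_snv_catalog


@pytest.fixture(scope="module")
def sbs():
    return load_packaged_signatures("sbs")


def test_spectrum_strand_normalization():
    # G>T at 5'-AGA-3' must land in T[C>A]T after complementation
    seqs = {"chr1": "AAGAA"}
    calls = pd.DataFrame([{"cell_id": "c", "chrom": "chr1", "pos": 3,
                           "ref": "G", "alt": "T"}])
    spec = build_snv_spectrum(calls, seqs)
    assert spec["T[C>A]T"] == 1 and spec.sum() == 1


def test_empty_call_set_gives_zero_spectrum():
    spec = build_snv_spectrum(pd.DataFrame(columns=["cell_id", "chrom", "pos",
                                                    "ref", "alt"]), {})
    assert spec.sum() == 0 and len(spec) == 96


def test_reference_mismatch_raises():
    seqs = {"chr1": "AAGAA"}
    calls = pd.DataFrame([{"cell_id": "c", "chrom": "chr1", "pos": 3,
                           "ref": "C", "alt": "T"}])
    with pytest.raises(ValueError, match="mismatch"):
        build_snv_spectrum(calls, seqs)


def test_indel_spectrum_counts_contexts():
    seqs = {"chr1": "GGTTTTTTGGAACAA"}
    calls = pd.DataFrame([
        {"cell_id": "c", "chrom": "chr1", "pos": 3, "ref": "TT", "alt": "T"},
        {"cell_id": "c", "chrom": "chr1", "pos": 12, "ref": "AC", "alt": "A"},
    ])
    spec = build_indel_spectrum(calls, seqs)
    assert spec["1:Del:T:5"] == 1 and spec["1:Del:C:0"] == 1


class TestFitSignatures:
    def test_exact_mixture_recovered(self, sbs):
        sig = sbs[["SignatureA", "SignatureC"]]
        y = 0.7 * sig["SignatureA"] + 0.3 * sig["SignatureC"]
        res = fit_signatures(y, sig)
        assert np.allclose(res.proportions, [0.7, 0.3], atol=1e-9)
        assert res.cosine == pytest.approx(1.0)

    def test_single_basis_gets_weight_one(self, sbs):
        sig = sbs[["SignatureA", "SignatureC"]]
        res = fit_signatures(sbs["SignatureC"], sig)
        assert np.allclose(res.proportions, [0.0, 1.0], atol=1e-9)

    def test_matches_constrained_optimizer_oracle(self, sbs, rng):
        A = sbs.to_numpy()
        for _ in range(10):
            w = rng.dirichlet(np.ones(A.shape[1]))
            y = A @ w * 500 + rng.normal(0, 0.3, A.shape[0]).clip(-0.2)
            y = np.clip(y, 0, None)
            res = fit_signatures(y, sbs)
            oracle = lsq_linear(A, y, bounds=(0, np.inf), tol=1e-14)
            assert np.allclose(res.raw, oracle.x, atol=1e-6)

    def test_dimension_mismatch(self, sbs):
        with pytest.raises(ValueError):
            fit_signatures(np.ones(83), sbs)


def test_signature_burden_conserves_total(rng):
    props = rng.dirichlet(np.ones(4))
    b = signature_burden(props, 200.0)
    assert b.sum() == pytest.approx(200.0)
    assert np.allclose(signature_burden([0.5, 0.5], 200), [100, 100])
    assert np.allclose(signature_burden([1, 0], 137.0), [137, 0])


class TestDenovo:
    def test_recovers_planted_pair(self, sbs, rng):
        a = sbs["SignatureA"].to_numpy()
        c = sbs["SignatureC"].to_numpy()
        # near-pure exposures included: the separability condition NMF
        # identifiability requires
        W = rng.dirichlet([0.3, 0.3], size=30)
        X = pd.DataFrame((W @ np.vstack([a, c])) * 400,
                         columns=SBS96_CONTEXTS)
        res = extract_denovo_signatures(X, rank_range=(2, 2), n_runs=5, seed=0)
        sigs = res.signatures.to_numpy().T
        for truth in (a, c):
            best = max(s @ truth / np.linalg.norm(s) / np.linalg.norm(truth)
                       for s in sigs)
            assert best > 0.98

    def test_deterministic_given_seed(self, sbs, rng):
        a = sbs["SignatureA"].to_numpy()
        X = pd.DataFrame(np.outer(rng.uniform(100, 300, 6), a),
                         columns=SBS96_CONTEXTS)
        r1 = extract_denovo_signatures(X, (2, 2), n_runs=1, seed=3)
        r2 = extract_denovo_signatures(X, (2, 2), n_runs=1, seed=3)
        pd.testing.assert_frame_equal(r1.signatures, r2.signatures)

    def test_rank_exceeding_samples_errors(self, sbs):
        X = pd.DataFrame(np.ones((2, 96)), columns=SBS96_CONTEXTS)
        with pytest.raises(ValueError):
            extract_denovo_signatures(X, (3, 3), n_runs=1)

    def test_kl_objective_nonincreasing_in_iterations(self, sbs, rng):
        from sklearn.decomposition import NMF

        a = sbs["SignatureA"].to_numpy()
        c = sbs["SignatureC"].to_numpy()
        W = rng.dirichlet([1, 1], size=10)
        X = (W @ np.vstack([a, c])) * 300 + rng.uniform(0, 0.5, (10, 96))
        errs = []
        for it in (5, 20, 80, 320):
            m = NMF(2, init="random", solver="mu",
                    beta_loss="kullback-leibler", max_iter=it, tol=0,
                    random_state=0)
            m.fit(X)
            errs.append(m.reconstruction_err_)
        assert all(e2 <= e1 + 1e-9 for e1, e2 in zip(errs, errs[1:]))


class TestStrandConversion:
    def test_disjoint_support_recovers_identity(self):
        ds = np.zeros(96); ds[:48] = 1 / 48
        ss = np.zeros(96); ss[48:] = 1 / 48
        model = derive_strand_conversion(ds, ss)
        assert model.a[0] > 0.99 and model.b[1] > 0.99
        assert not model.collinear

    def test_identical_inputs_flagged_collinear(self, sbs):
        s = sbs["SignatureA"]
        model = derive_strand_conversion(s, s)
        assert model.collinear

    def test_per_im_normalization_property(self, rng):
        for _ in range(5):
            ds = rng.dirichlet(np.ones(96))
            ss = rng.dirichlet(np.ones(96))
            model = derive_strand_conversion(ds, ss)
            assert model.a1 + model.b1 == pytest.approx(1.0, abs=1e-9)
            assert model.a2 + model.b2 == pytest.approx(1.0, abs=1e-9)

    def test_stated_k_formulas_worked_example(self):
        # direct arithmetic: c=(0.6,0.4), a=(0.9,0.2), b=(0.1,0.8)
        c = np.array([0.6, 0.4])
        a = np.array([0.9, 0.2])
        b = np.array([0.1, 0.8])
        k1 = c @ a
        k2 = c @ b
        assert k1 == pytest.approx(0.62) and k2 == pytest.approx(0.38)

    def test_c_on_first_im_returns_a1_b1(self):
        strand = load_packaged_signatures("strand_snv")
        model = derive_strand_conversion(strand["DS"], strand["SS"])
        k1, k2, c1, c2 = convert_pta_spectrum(model.im[0], model)
        assert c1 == pytest.approx(1.0, abs=1e-6)
        assert k1 == pytest.approx(model.a1, abs=1e-6)
        assert k2 == pytest.approx(model.b1, abs=1e-6)

    def test_k_sum_equals_c_sum(self, rng):
        strand = load_packaged_signatures("strand_snv")
        model = derive_strand_conversion(strand["DS"], strand["SS"])
        for _ in range(10):
            y = rng.dirichlet(np.ones(96))
            k1, k2, c1, c2 = convert_pta_spectrum(y, model)
            assert k1 + k2 == pytest.approx(c1 + c2, abs=1e-12)
            assert k1 + k2 == pytest.approx(1.0, abs=1e-9)

    def test_mixture_round_trip(self, rng):
        strand = load_packaged_signatures("strand_snv")
        model = derive_strand_conversion(strand["DS"], strand["SS"])
        mix = 0.85 * model.ds + 0.15 * model.ss
        k1s = [convert_pta_spectrum(rng.multinomial(300, mix), model)[0]
               for _ in range(100)]
        assert np.mean(k1s) == pytest.approx(0.85, abs=0.03)


class TestResidual:
    def test_equal_inputs_zero_residual(self, sbs):
        res = residual_spectrum(sbs["SignatureA"], sbs["SignatureA"])
        assert np.allclose(res["raw"], 0)

    def test_planted_excess_recovered(self, sbs):
        control = sbs["SignatureA"]
        disease = 0.6 * control + 0.4 * sbs["SBS29like"]
        res = residual_spectrum(disease, control)
        r = res["residual"].to_numpy()
        t = sbs["SBS29like"].to_numpy()
        assert r @ t / np.linalg.norm(r) / np.linalg.norm(t) > 0.9
        fitres = fit_signatures(r, sbs)
        assert fitres.as_series()["SBS29like"] > 0.5


class TestDeletionFraction:
    def test_trivial_cases(self):
        s = pd.Series(0.0, index=ID83_CONTEXTS)
        s["3:Del:R:0"] = 10
        assert deletion_fraction(s) == 1.0
        s = pd.Series(0.0, index=ID83_CONTEXTS)
        s["1:Ins:T:0"] = 5
        assert deletion_fraction(s) == 0.0

    def test_mixed_spectrum_hand_sum(self):
        s = pd.Series(0.0, index=ID83_CONTEXTS)
        s["2:Del:R:0"] = 3
        s["4:Del:M:1"] = 2
        s["5:Del:R:0"] = 4
        s["1:Del:T:2"] = 1
        assert deletion_fraction(s, (2, 4)) == pytest.approx(5 / 10)


class TestIndividualPca:
    def _counts(self, rng, weights_a, weights_b, n_each=6, total=200):
        idm = load_packaged_signatures("id")
        mix_a = idm @ pd.Series(weights_a)
        mix_b = idm @ pd.Series(weights_b)
        rows = {}
        for i in range(n_each):
            rows[f"A{i}"] = rng.multinomial(total, mix_a / mix_a.sum())
            rows[f"B{i}"] = rng.multinomial(total, mix_b / mix_b.sum())
        return pd.DataFrame.from_dict(rows, orient="index",
                                      columns=ID83_CONTEXTS)

    def test_two_groups_separate_on_pc1(self, rng):
        counts = self._counts(
            rng,
            {"ID_aging": 0.8, "ID_repeat": 0.2, "ID_deletion": 0.0},
            {"ID_aging": 0.2, "ID_repeat": 0.2, "ID_deletion": 0.6})
        res = cluster_individuals_pca(counts)
        pc1 = res.embedding["PC1"]
        a = pc1[[i.startswith("A") for i in pc1.index]]
        b = pc1[[i.startswith("B") for i in pc1.index]]
        assert max(a.max(), b.max()) < min(b.min(), a.min()) or \
            (a.max() < b.min() or b.max() < a.min())
        assert res.variance_explained[0] > 0.3

    def test_low_count_individuals_excluded(self, rng):
        counts = self._counts(
            rng, {"ID_aging": 1.0, "ID_repeat": 0.0, "ID_deletion": 0.0},
            {"ID_aging": 0.0, "ID_repeat": 1.0, "ID_deletion": 0.0})
        counts.loc["A0"] = 0
        counts.loc["A0", "1:Del:T:1"] = 10  # 10 < 15 sIndels
        res = cluster_individuals_pca(counts, min_mutations=15)
        assert res.excluded == ["A0"]
        assert "A0" not in res.embedding.index

    def test_identical_spectra_flagged_degenerate(self):
        row = np.zeros(83)
        row[5] = 30
        counts = pd.DataFrame([row] * 4, index=list("abcd"),
                              columns=ID83_CONTEXTS)
        res = cluster_individuals_pca(counts)
        assert res.degenerate
        assert np.allclose(res.variance_explained, 0)


def test_spectrum_from_simulated_pure_catalog(fixture, rng, sbs):
    cat = simulate_snv_catalog(500, {"SignatureC": 1.0}, fixture, rng)
    spec = build_snv_spectrum(cat, fixture)
    c = sbs["SignatureC"].to_numpy()
    v = spec.to_numpy(float)
    assert v @ c / np.linalg.norm(v) / np.linalg.norm(c) > 0.95
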