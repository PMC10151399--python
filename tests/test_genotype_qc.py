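import numpy as np
import pytest

from gpfusion.genotype_qc import (
    CodedGenotypes,
    GenotypeCalls,
    QCError,
    apply_qc,
    build_genomic_features,
    cholesky_factor,
    genomic_inputs,
    read_genotype_calls,
    vanraden_grm,
    write_coded_genotypes,
)


def make_calls(matrix, line_ids=None, marker_ids=None):
    m = np.array(matrix, dtype=object)
    line_ids = line_ids or [f"l{i}" for i in range(m.shape[0])]
    marker_ids = marker_ids or [f"m{k}" for k in range(m.shape[1])]
    return GenotypeCalls(line_ids, marker_ids, m)


class TestApplyQC:
    def test_three_rule_hand_example(self):
        # marker1: 2/3 AB (het filter); marker2: 1/3 NA (missingness);
        # marker3: monomorphic (MAF 0); marker4: MAF 1/3 survives
        calls = make_calls(
            [
                ["AB", "AA", "AA", "AA"],
                ["AB", "NA", "AA", "AA"],
                ["BB", "BB", "AA", "BB"],
            ]
        )
        coded = apply_qc(calls)
        assert coded.marker_ids == ["m3"]
        np.testing.assert_array_equal(coded.X.ravel(), [0.0, 0.0, 1.0])
        np.testing.assert_allclose(coded.maf, [1 / 3])

    def test_mean_imputation_of_residual_missing(self):
        # one NA among five calls (20% missing passes); column mean 0.5
        calls = make_calls([["AA"], ["AA"], ["BB"], ["BB"], ["NA"]])
        coded = apply_qc(calls)
        np.testing.assert_allclose(coded.X.ravel(), [0, 0, 1, 1, 0.5])

    def test_noop_thresholds_reproduce_binary_coding(self):
        m = np.array([["AA", "BB"], ["BB", "AA"], ["AA", "AA"]], dtype=object)
        coded = apply_qc(make_calls(m), het_max=1.0, miss_max=1.0, maf_min=0.0)
        expected = (m == "BB").astype(float)
        np.testing.assert_array_equal(coded.X, expected)

    def test_heterozygote_recode_to_majority_allele(self):
        # 1/4 AB passes het_max=0.25; AA majority -> AB becomes AA
        calls = make_calls([["AA"], ["AA"], ["AB"], ["BB"]])
        coded = apply_qc(calls, het_max=0.25, maf_min=0.0)
        np.testing.assert_array_equal(coded.X.ravel(), [0, 0, 0, 1])

    def test_all_markers_removed_is_explicit_error(self):
        calls = make_calls([["AA", "AA"], ["AA", "AA"], ["AA", "AA"]])
        with pytest.raises(QCError, match="empty after QC"):
            apply_qc(calls)

    def test_all_missing_marker_removed_without_division(self):
        calls = make_calls([["NA", "AA"], ["NA", "BB"], ["NA", "BB"]])
        coded = apply_qc(calls)
        assert coded.marker_ids == ["m1"]

    def test_idempotent_on_complete_coded_output(self, rng):
        X = (rng.random((15, 30)) < rng.uniform(0.2, 0.8, 30)).astype(float)
        calls = GenotypeCalls.from_coded(
            [f"l{i}" for i in range(15)], [f"m{k}" for k in range(30)], X
        )
        once = apply_qc(calls)
        again = apply_qc(
            GenotypeCalls.from_coded(once.line_ids, once.marker_ids, once.X)
        )
        assert once.marker_ids == again.marker_ids
        np.testing.assert_array_equal(once.X, again.X)


def brute_force_survivors(raw, het_max=0.10, miss_max=0.20, maf_min=0.05):
    """Independent per-rule recount used as the QC oracle."""
    survivors = []
    n = raw.shape[0]
    for k in range(raw.shape[1]):
        col = list(raw[:, k])
        n_obs = sum(c != "NA" for c in col)
        if n_obs and sum(c == "AB" for c in col) / n_obs > het_max:
            continue
        aa = sum(c == "AA" for c in col)
        bb = sum(c == "BB" for c in col)
        col = [("AA" if aa >= bb else "BB") if c == "AB" else c for c in col]
        if sum(c == "NA" for c in col) / n > miss_max:
            continue
        obs = [1.0 if c == "BB" else 0.0 for c in col if c != "NA"]
        if not obs:
            continue
        p = sum(obs) / len(obs)
        if min(p, 1 - p) < maf_min:
            continue
        survivors.append(k)
    return survivors


def test_survivor_counts_match_bruteforce(rng):
    for _ in range(20):
        raw = rng.choice(["AA", "AB", "BB", "NA"], size=(20, 50), p=[0.42, 0.08, 0.42, 0.08])
        calls = GenotypeCalls(
            [f"l{i}" for i in range(20)], [f"m{k}" for k in range(50)], raw.astype(object)
        )
        expected = [f"m{k}" for k in brute_force_survivors(raw)]
        try:
            got = apply_qc(calls).marker_ids
        except QCError:
            got = []
        assert got == expected


class TestVanRadenGRM:
    def test_two_line_hand_example(self):
        coded = CodedGenotypes(["a", "b"], ["m1", "m2"],
                               np.array([[0.0, 1.0], [1.0, 0.0]]), np.array([0.5, 0.5]))
        G = vanraden_grm(coded).G
        np.testing.assert_allclose(G, [[1, -1], [-1, 1]], atol=1e-12)

    def test_identical_lines_share_rows(self, rng):
        X = (rng.random((4, 40)) < 0.4).astype(float)
        X[1] = X[0]
        G = vanraden_grm(CodedGenotypes(list("abcd"), [f"m{k}" for k in range(40)],
                                        X, np.zeros(40))).G
        np.testing.assert_allclose(G[0], G[1])
        np.testing.assert_allclose(G[0, 1], G[0, 0])

    def test_monomorphic_column_leaves_grm_unchanged(self, rng):
        X = (rng.random((6, 25)) < 0.5).astype(float)
        base = vanraden_grm(
            CodedGenotypes(list("abcdef"), [f"m{k}" for k in range(25)], X, np.zeros(25))
        ).G
        X2 = np.column_stack([X, np.ones(6)])
        aug = vanraden_grm(
            CodedGenotypes(list("abcdef"), [f"m{k}" for k in range(26)], X2, np.zeros(26))
        ).G
        np.testing.assert_allclose(base, aug, atol=1e-12)

    def test_all_monomorphic_is_error(self):
        X = np.ones((3, 4))
        with pytest.raises(QCError, match="zero denominator"):
            vanraden_grm(CodedGenotypes(list("abc"), list("wxyz"), X, np.zeros(4)))

    def test_symmetry_on_random_matrices(self, rng):
        for _ in range(5):
            X = (rng.random((12, 60)) < rng.uniform(0.1, 0.9, 60)).astype(float)
            G = vanraden_grm(
                CodedGenotypes([f"l{i}" for i in range(12)],
                               [f"m{k}" for k in range(60)], X, np.zeros(60))
            ).G
            assert np.abs(G - G.T).max() < 1e-10


class TestCholesky:
    def test_diagonal_cases(self):
        fac = cholesky_factor(2.0 * np.eye(2))
        np.testing.assert_allclose(fac.L, np.sqrt(2) * np.eye(2))
        assert fac.jitter == 0.0
        fac = cholesky_factor(np.eye(3))
        np.testing.assert_allclose(fac.L, np.eye(3))

    def test_singular_grm_gets_jitter(self):
        G = np.array([[1.0, -1.0], [-1.0, 1.0]])
        fac = cholesky_factor(G)
        assert fac.jitter > 0
        resid = np.abs(fac.L.T @ fac.L - G - fac.jitter * np.eye(2)).max()
        assert resid < 1e-8

    def test_upper_triangular_orientation(self, rng):
        A = rng.standard_normal((5, 8))
        G = A @ A.T
        fac = cholesky_factor(G)
        assert np.allclose(fac.L, np.triu(fac.L))
        assert np.abs(fac.L.T @ fac.L - G - fac.jitter * np.eye(5)).max() < 1e-8

    def test_unfactorizable_reports_smallest_eigenvalue(self):
        G = np.diag([1.0, -5.0])
        with pytest.raises(np.linalg.LinAlgError, match="smallest eigenvalue"):
            cholesky_factor(G, base_jitter=1e-8)


class TestGenomicInputs:
    def test_identity_grm_yields_identity_rows(self):
        fac = cholesky_factor(np.eye(3))
        Z = genomic_inputs(fac, [0, 1, 2])
        np.testing.assert_allclose(Z, np.eye(3))

    def test_replicated_records_share_rows(self):
        fac = cholesky_factor(np.eye(3))
        Z = genomic_inputs(fac, [1, 1])
        np.testing.assert_array_equal(Z[0], Z[1])

    def test_row_inner_products_reconstruct_grm(self, rng):
        X = (rng.random((8, 30)) < 0.5).astype(float)
        coded = CodedGenotypes([f"l{i}" for i in range(8)],
                               [f"m{k}" for k in range(30)], X, np.zeros(30))
        feats = build_genomic_features(coded)
        Z = genomic_inputs(feats, np.arange(8))
        np.testing.assert_allclose(
            Z @ Z.T, feats.G + feats.jitter * np.eye(8), atol=1e-6
        )

    def test_unknown_line_index_is_error(self):
        fac = cholesky_factor(np.eye(2))
        with pytest.raises(KeyError, match="unknown line"):
            genomic_inputs(fac, [0, 5])


def test_genotype_reader_roundtrip(tmp_path, rng):
    X = (rng.random((5, 10)) < 0.5).astype(float)
    coded = CodedGenotypes([f"l{i}" for i in range(5)],
                           [f"m{k}" for k in range(10)], X, np.zeros(10))
    path = tmp_path / "coded.csv"
    write_coded_genotypes(coded, path)
    back = read_genotype_calls(path)
    recoded = apply_qc(back, het_max=1.0, miss_max=1.0, maf_min=0.0)
    np.testing.assert_array_equal(recoded.X, X)
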