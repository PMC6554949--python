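import numpy as np
import pytest

from replikit.concat import concatenate_families
from replikit.dca import (
    CouplingModel,
    compute_couplings,
    compute_frequencies,
    compute_weights,
    direct_information,
    encode,
    mutual_information,
    score_all_pairs,
    _two_site_model,
)
from replikit.msa import ALPHABET
from conftest import freq_from_joint, make_family


Q = len(ALPHABET)


class TestWeights:
    def test_identical_sequences(self):
        aln = ["ACDE"] * 5
        wv = compute_weights(aln, theta=0.8)
        assert np.allclose(wv.w, 0.2)
        assert wv.meff == pytest.approx(1.0)

    def test_all_distinct(self):
        aln = ["AAAA", "CCCC", "DDDD"]
        wv = compute_weights(aln, theta=0.8)
        assert np.allclose(wv.w, 1.0)
        assert wv.meff == pytest.approx(3.0)

    def test_hand_counted_neighborhoods(self):
        # two identical + two mutually/far distinct -> weights (1/2,1/2,1,1)
        aln = ["AAAAA", "AAAAA", "CCCCC", "DDDDD"]
        wv = compute_weights(aln, theta=0.8)
        assert np.allclose(sorted(wv.w), [0.5, 0.5, 1.0, 1.0])
        assert wv.meff == pytest.approx(3.0)

    def test_gap_counts_as_symbol(self):
        # 4/5 positions agree incl. the shared gap -> identity 0.8 >= theta
        aln = ["AC-DE", "AC-DY"]
        wv = compute_weights(aln, theta=0.8)
        assert np.allclose(wv.w, 0.5)

    def test_theta_none_disables(self):
        wv = compute_weights(["AAAA"] * 7, theta=None)
        assert wv.meff == pytest.approx(7.0)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            compute_weights([], theta=0.8)


class TestFrequencies:
    def test_unregularized_point_mass(self):
        with pytest.warns(UserWarning, match="singular"):  # constant column at lam=0
            freq = compute_frequencies(["A", "A", "A"], lam=0.0)
        assert freq.fi[0, ALPHABET.index("A")] == pytest.approx(1.0)
        assert freq.fi[0].sum() == pytest.approx(1.0)

    def test_pseudocount_formula(self):
        # f = lam/q + (1-lam)*1 at lam=0.5, q=21
        freq = compute_frequencies(["A", "A"], lam=0.5)
        assert freq.fi[0, ALPHABET.index("A")] == pytest.approx(0.5 / 21 + 0.5)

    def test_correlated_columns_diagonal_joint(self):
        aln = ["AA", "CC", "DD"]
        freq = compute_frequencies(aln, lam=0.0)
        block = freq.pair_block(1, 2)
        off_diag = block - np.diag(np.diag(block))
        assert np.all(off_diag == 0)
        assert block.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("lam", [0.0, 0.3, 0.5])
    def test_normalization_and_marginalization(self, lam):
        rng = np.random.default_rng(0)
        aln = ["".join(rng.choice(list("ACDE-"), size=6)) for _ in range(40)]
        wv = compute_weights(aln, theta=0.8)
        freq = compute_frequencies(aln, wv, lam=lam)
        assert np.allclose(freq.fi.sum(axis=1), 1.0, atol=1e-12)
        L = freq.L
        for i in range(1, L + 1):
            for j in range(1, L + 1):
                if i == j:
                    continue
                block = freq.pair_block(i, j)
                assert abs(block.sum() - 1.0) < 1e-12
                assert np.abs(block.sum(axis=1) - freq.fi[i - 1]).max() < 1e-12
                assert np.abs(block.sum(axis=0) - freq.fi[j - 1]).max() < 1e-12

    def test_constant_column_lambda_zero_warns(self):
        with pytest.warns(UserWarning, match="singular"):
            compute_frequencies(["AC", "AD"], lam=0.0)

    def test_invalid_lambda(self):
        with pytest.raises(ValueError):
            compute_frequencies(["AC"], lam=1.0)


class TestCouplings:
    def test_toy_q2_matches_hand_inversion(self):
        # L=2, q=2 toy: C is 2x2 over the first state of each column
        joint = np.array([[0.3, 0.2], [0.1, 0.4]])
        freq = freq_from_joint(joint)
        coup = compute_couplings(freq)
        fi = freq.fi
        C = np.array(
            [
                [fi[0, 0] - fi[0, 0] ** 2, joint[0, 0] - fi[0, 0] * fi[1, 0]],
                [joint[0, 0] - fi[0, 0] * fi[1, 0], fi[1, 0] - fi[1, 0] ** 2],
            ]
        )
        expected = -np.linalg.inv(C)
        assert coup.block(1, 2)[0, 0] == pytest.approx(expected[0, 1], abs=1e-12)
        assert coup.block(2, 1)[0, 0] == pytest.approx(expected[1, 0], abs=1e-12)
        # gauge state carries zero coupling
        assert np.all(coup.block(1, 2)[1, :] == 0)
        assert np.all(coup.block(1, 2)[:, 1] == 0)

    def test_toy_q3_matches_hand_inversion(self):
        rng = np.random.default_rng(3)
        X = rng.integers(0, 3, size=(60, 3)).astype(np.int8)
        freq = compute_frequencies(X, lam=0.4, q=3)
        coup = compute_couplings(freq)
        # independent elementwise construction of C and its inverse
        L, qs = 3, 2
        C = np.zeros((L * qs, L * qs))
        for i in range(L):
            for a in range(qs):
                for j in range(L):
                    for b in range(qs):
                        C[i * qs + a, j * qs + b] = (
                            freq.fij[i, a, j, b] - freq.fi[i, a] * freq.fi[j, b]
                        )
        E = -np.linalg.inv(C)
        for i in range(L):
            for j in range(L):
                if i == j:
                    continue
                block = E[i * qs : (i + 1) * qs, j * qs : (j + 1) * qs]
                assert np.allclose(coup.e[i, :qs, j, :qs], block, atol=1e-10)

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        aln = ["".join(rng.choice(list("ACDE"), size=4)) for _ in range(50)]
        coup = compute_couplings(compute_frequencies(aln, lam=0.5))
        for i in range(1, 5):
            for j in range(1, 5):
                if i != j:
                    assert np.allclose(coup.block(i, j), coup.block(j, i).T)

    def test_independent_columns_give_weak_couplings(self):
        rng = np.random.default_rng(11)
        n = 3000
        X_ind = rng.integers(0, 4, size=(n, 2)).astype(np.int8)
        flat = rng.choice(16, size=n, p=(np.exp(3 * np.eye(4)) / np.exp(3 * np.eye(4)).sum()).ravel())
        X_cpl = np.stack([flat // 4, flat % 4], axis=1).astype(np.int8)
        norm = lambda X: np.linalg.norm(
            compute_couplings(compute_frequencies(X, lam=0.5, q=4)).block(1, 2)
        )
        assert norm(X_ind) < 0.2 * norm(X_cpl)


class TestDirectInformation:
    def _freq(self, seed=0, L=4, n=80):
        rng = np.random.default_rng(seed)
        aln = ["".join(rng.choice(list("ACDE-"), size=L)) for _ in range(n)]
        freq = compute_frequencies(aln, compute_weights(aln), lam=0.5)
        return freq

    def test_zero_coupling_gives_zero_di(self):
        freq = self._freq()
        coup = CouplingModel(e=np.zeros((freq.L, Q, freq.L, Q)), q=Q)
        assert direct_information(1, 2, coup, freq) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_and_nonnegative(self):
        for seed in range(5):
            freq = self._freq(seed)
            coup = compute_couplings(freq)
            for (i, j) in [(1, 2), (2, 4), (1, 3)]:
                dij = direct_information(i, j, coup, freq, tol=1e-10, max_iter=5000)
                dji = direct_information(j, i, coup, freq, tol=1e-10, max_iter=5000)
                assert dij >= 0.0
                assert dij == pytest.approx(dji, abs=1e-8)

    def test_two_site_marginals_match(self):
        freq = self._freq(7)
        coup = compute_couplings(freq)
        tol = 1e-6
        P = _two_site_model(2, 3, coup, freq, tol=tol, max_iter=2000)
        assert np.abs(P.sum(axis=1) - freq.fi[1]).max() <= tol
        assert np.abs(P.sum(axis=0) - freq.fi[2]).max() <= tol

    def test_same_column_rejected(self):
        freq = self._freq()
        coup = compute_couplings(freq)
        with pytest.raises(ValueError):
            direct_information(2, 2, coup, freq)


class TestMutualInformation:
    def test_factorized_joint_is_zero(self):
        p = np.array([0.5, 0.3, 0.2])
        r = np.array([0.6, 0.4, 0.0])
        freq = freq_from_joint(np.outer(p, r))
        assert mutual_information(1, 2, freq) == pytest.approx(0.0, abs=1e-12)

    def test_perfectly_correlated_binary_is_log2(self):
        aln = ["AA", "CC"] * 10
        freq = compute_frequencies(aln, lam=0.0)
        assert mutual_information(1, 2, freq) == pytest.approx(np.log(2), abs=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            joint = rng.random((3, 3))
            joint /= joint.sum()
            freq = freq_from_joint(joint)
            p, r = joint.sum(axis=1), joint.sum(axis=0)
            expected = sum(
                joint[a, b] * np.log(joint[a, b] / (p[a] * r[b]))
                for a in range(3)
                for b in range(3)
                if joint[a, b] > 0
            )
            assert mutual_information(1, 2, freq) == pytest.approx(expected, abs=1e-12)


class TestScoreAllPairs:
    def _paired(self, n=60, seed=0, dup=1):
        rng = np.random.default_rng(seed)
        species = [f"s{k}" for k in range(n)]
        rows_a, rows_b = [], []
        for k, sp in enumerate(species):
            seq_a = "".join(rng.choice(list("ACDE"), size=5))
            seq_b = "".join(rng.choice(list("ACDE"), size=5))
            rows_a.append((sp, f"{sp}|a", seq_a))
            rows_b.append((sp, f"{sp}|b", seq_b))
        fam_a = make_family("a", rows_a)
        fam_b = make_family("b", rows_b)
        return concatenate_families(fam_a, fam_b, linker_length=3)

    def test_ab_filter_row_count(self):
        scores = score_all_pairs(self._paired())
        assert len(scores) == 25
        assert set(scores.columns) == {"i", "j", "di", "mi"}

    def test_unfiltered_pair_count(self):
        aln = make_family(
            "f",
            [
                (f"s{k}", f"s{k}|x", "".join(np.random.default_rng(k).choice(list("ACDE"), size=10)))
                for k in range(30)
            ],
        )
        scores = score_all_pairs(aln)
        assert len(scores) == 45  # C(10, 2)

    def test_deterministic(self):
        pa = self._paired()
        t1 = score_all_pairs(pa)
        t2 = score_all_pairs(pa)
        assert t1.equals(t2)

    def test_permutation_equivariance(self):
        pa = self._paired()
        shuffled = type(pa)(
            rows=list(reversed(pa.rows)),
            L_A=pa.L_A,
            L_B=pa.L_B,
            linker_length=pa.linker_length,
        )
        t1 = score_all_pairs(pa)
        t2 = score_all_pairs(shuffled)
        assert np.allclose(t1[["di", "mi"]], t2[["di", "mi"]], atol=1e-10)

    def test_duplication_invariance_under_reweighting(self):
        pa = self._paired()
        tripled = type(pa)(
            rows=[(f"{sp}_{c}", seq) for c in range(3) for sp, seq in pa.rows],
            L_A=pa.L_A,
            L_B=pa.L_B,
            linker_length=pa.linker_length,
        )
        t1 = score_all_pairs(pa, theta=0.8)
        t2 = score_all_pairs(tripled, theta=0.8)
        assert np.abs(t1["di"].to_numpy() - t2["di"].to_numpy()).max() < 1e-10
        assert np.abs(t1["mi"].to_numpy() - t2["mi"].to_numpy()).max() < 1e-10


def test_encode_roundtrip_alphabet():
    X = encode(["AC-W", "YYYY"])
    assert X.shape == (2, 4)
    assert X[0, 2] == ALPHABET.index("-")
    with pytest.raises(ValueError):
        encode(["AJ"])  # J is not a model letter (sanitized only on file read)
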