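"""Mean-field Direct Coupling Analysis over a (paired) alignment.

The alignment is modelled as samples from a 21-state Potts model (20 amino
acids plus gap).  The pipeline is the classical mean-field chain:

1. *reweighting* — sequences with fractional identity >= theta to many
   neighbours are down-weighted (w_a = 1/m_a), correcting phylogenetic
   redundancy; the sum of weights is the effective sample size Meff;
2. *regularized frequencies* — single-column and column-pair frequencies
   mixed with a uniform pseudocount of weight lambda, which guarantees an
   invertible covariance matrix;
3. *couplings* — the connected correlation matrix C, built over the first
   q-1 states of every column, is inverted; the negated off-diagonal blocks
   are the pair couplings e_ij(A,B) in the gauge where the last state
   (the gap) carries zero coupling;
4. *scores* — for every column pair, the mutual information MI of the
   empirical pair distribution, and the direct information DI: the mutual
   information of the two-site model built from e_ij alone with fields
   chosen so its marginals reproduce the observed single-column frequencies.

MI mixes direct and transitive covariation; DI isolates the direct
component and is the statistic of interest for interface prediction.
All information quantities use natural logarithms (nats).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial.distance import pdist, squareform

from replikit.msa import ALPHABET, AlignedFamily
from replikit.concat import PairedAlignment, PAIR_AB, classify_pair

DEFAULT_THETA = 0.8
DEFAULT_LAMBDA = 0.5
DEFAULT_DI_TOL = 1e-4
DEFAULT_DI_MAX_ITER = 500

_CHAR_TO_STATE = {ch: k for k, ch in enumerate(ALPHABET)}


class ConvergenceError(RuntimeError):
    """The two-site fixed-point iteration did not reach tolerance."""


def _rows_of(aln) -> list[str]:
    if isinstance(aln, PairedAlignment):
        return [seq for _, seq in aln.rows]
    if isinstance(aln, AlignedFamily):
        return [r.residues for r in aln.rows]
    return list(aln)


def encode(aln) -> np.ndarray:
    """Encode an alignment as an (M, L) int8 state matrix.

    Accepts an :class:`AlignedFamily`, a :class:`PairedAlignment` or a
    sequence of equal-length residue strings over :data:`ALPHABET`.
    """
    rows = _rows_of(aln)
    if not rows:
        raise ValueError("empty alignment")
    M, L = len(rows), len(rows[0])
    X = np.empty((M, L), dtype=np.int8)
    for a, seq in enumerate(rows):
        try:
            X[a] = [_CHAR_TO_STATE[ch] for ch in seq]
        except KeyError as exc:
            raise ValueError(f"illegal residue letter {exc} in row {a}") from exc
    return X


@dataclass
class WeightVector:
    """Per-sequence weights w_a = 1/m_a and their sum Meff."""

    w: np.ndarray
    theta: float

    @property
    def meff(self) -> float:
        return float(self.w.sum())

    @property
    def n_sequences(self) -> int:
        return len(self.w)


def compute_weights(aln, theta: float = DEFAULT_THETA) -> WeightVector:
    """Down-weight near-duplicate sequences.

    ``m_a`` counts the sequences (including ``a`` itself) whose fractional
    identity to ``a`` is at least ``theta``; identity counts positions with
    equal symbols (the gap is an ordinary symbol) over the full alignment
    length.  ``theta=None`` disables reweighting (all weights 1).
    """
    X = aln if isinstance(aln, np.ndarray) else encode(aln)
    M = X.shape[0]
    if M == 0:
        raise ValueError("empty alignment")
    if theta is None:
        return WeightVector(w=np.ones(M), theta=1.0 + 1e-9)
    if not 0.0 < theta <= 1.0:
        raise ValueError(f"theta must be in (0, 1], got {theta}")
    if M == 1:
        return WeightVector(w=np.ones(1), theta=theta)
    identity = 1.0 - squareform(pdist(X.astype(np.float64), metric="hamming"))
    # the diagonal is identity 1, so each sequence counts itself in m_a
    m = (identity >= theta).sum(axis=1)
    return WeightVector(w=1.0 / m, theta=theta)


@dataclass
class FrequencyModel:
    """Pseudocount-regularized single and pair frequencies.

    ``fi[i, A] = lam/q + (1-lam) * femp_i(A)`` and
    ``fij[i, A, j, B] = lam/q^2 + (1-lam) * femp_ij(A, B)`` with the
    weighted empirical frequencies using ``w_a / Meff``.  Diagonal blocks
    are forced consistent: ``fij[i, A, i, B] = delta(A, B) * fi[i, A]``.
    """

    fi: np.ndarray  # (L, q)
    fij: np.ndarray  # (L, q, L, q)
    lam: float
    q: int
    meff: float

    @property
    def L(self) -> int:
        return self.fi.shape[0]

    def pair_block(self, i: int, j: int) -> np.ndarray:
        """(q, q) joint frequency table for 1-based columns ``i, j``."""
        return self.fij[i - 1, :, j - 1, :]


def compute_frequencies(
    aln,
    weights: WeightVector | None = None,
    lam: float = DEFAULT_LAMBDA,
    q: int | None = None,
) -> FrequencyModel:
    """Weighted, pseudocount-regularized frequency estimates.

    ``q`` defaults to the full 21-letter alphabet; a smaller ``q`` may be
    given for toy state matrices whose entries are already in ``0..q-1``.
    With ``lam=0`` and a constant column the downstream covariance is
    singular; a warning is emitted in that case.
    """
    if not 0.0 <= lam < 1.0:
        raise ValueError(f"lambda must be in [0, 1), got {lam}")
    X = aln if isinstance(aln, np.ndarray) else encode(aln)
    M, L = X.shape
    if q is None:
        q = len(ALPHABET)
    if X.max() >= q:
        raise ValueError(f"state {X.max()} out of range for q={q}")
    if weights is None:
        weights = WeightVector(w=np.ones(M), theta=1.0)
    w = weights.w / weights.meff

    # one-hot sparse encoding: row a has ones at (i*q + X[a, i])
    cols = (np.arange(L)[None, :] * q + X).ravel()
    indptr = np.arange(M + 1) * L
    onehot = sparse.csr_matrix(
        (np.ones(M * L), cols, indptr), shape=(M, L * q)
    )
    femp_i = np.asarray(onehot.T @ w).reshape(L, q)
    femp_ij = ((onehot.multiply(w[:, None])).T @ onehot).toarray().reshape(L, q, L, q)

    fi = lam / q + (1.0 - lam) * femp_i
    fij = lam / q**2 + (1.0 - lam) * femp_ij
    # force diagonal blocks consistent with fi
    idx = np.arange(L)
    fij[idx, :, idx, :] = 0.0
    fij[idx[:, None], np.arange(q)[None, :], idx[:, None], np.arange(q)[None, :]] = fi

    if lam == 0.0:
        const_cols = np.count_nonzero(femp_i >= 1.0 - 1e-12)
        if const_cols:
            import warnings

            warnings.warn(
                f"{const_cols} constant column(s) with lambda=0: "
                "the covariance matrix will be singular; raise lambda",
                stacklevel=2,
            )
    return FrequencyModel(fi=fi, fij=fij, lam=lam, q=q, meff=weights.meff)


@dataclass
class CouplingModel:
    """Mean-field pair couplings e = -C^{-1} in the last-state-zero gauge.

    ``e[i, A, j, B]`` holds the coupling between state A at column i and
    state B at column j; entries involving the last alphabet state are zero
    (gauge choice), and diagonal blocks are not couplings and are zeroed.
    """

    e: np.ndarray  # (L, q, L, q)
    q: int

    @property
    def L(self) -> int:
        return self.e.shape[0]

    def block(self, i: int, j: int) -> np.ndarray:
        """(q, q) coupling block for 1-based columns ``i, j``."""
        return self.e[i - 1, :, j - 1, :]


def compute_couplings(freq: FrequencyModel) -> CouplingModel:
    """Estimate couplings by inverting the connected-correlation matrix.

    C is built over the first ``q-1`` states of every column,
    ``C[i,A;j,B] = fij - fi*fj``; with ``lam > 0`` it is positive definite.
    A singular C (possible only at ``lam = 0``) raises a linear-algebra
    error advising a positive pseudocount.
    """
    L, q = freq.L, freq.q
    qs = q - 1
    fi_r = freq.fi[:, :qs]
    C = freq.fij[:, :qs, :, :qs] - fi_r[:, :, None, None] * fi_r[None, None, :, :]
    C = C.reshape(L * qs, L * qs)
    try:
        invC = np.linalg.inv(C)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "covariance matrix is singular; use a pseudocount lambda > 0"
        ) from exc
    e = np.zeros((L, q, L, q))
    e[:, :qs, :, :qs] = -invC.reshape(L, qs, L, qs)
    idx = np.arange(L)
    e[idx, :, idx, :] = 0.0
    return CouplingModel(e=e, q=q)


def _two_site_model(
    i: int,
    j: int,
    coup: CouplingModel,
    freq: FrequencyModel,
    tol: float,
    max_iter: int,
) -> np.ndarray:
    """Two-site distribution P_ij(A,B) ~ exp(e_ij) * h_i(A) * h_j(B).

    The auxiliary fields are found by multiplicative marginal matching:
    iterate until both marginals of P reproduce fi and fj within ``tol``.
    """
    W = np.exp(coup.block(i, j))
    fi = freq.fi[i - 1]
    fj = freq.fi[j - 1]
    q = freq.q
    mu1 = np.full(q, 1.0 / q)
    mu2 = np.full(q, 1.0 / q)
    for _ in range(max_iter):
        new1 = fi / (W @ mu2)
        new1 /= new1.sum()
        new2 = fj / (W.T @ new1)
        new2 /= new2.sum()
        mu1, mu2 = new1, new2
        P = W * np.outer(mu1, mu2)
        P /= P.sum()
        resid = max(
            np.abs(P.sum(axis=1) - fi).max(), np.abs(P.sum(axis=0) - fj).max()
        )
        if resid <= tol:
            return P
    raise ConvergenceError(
        f"two-site fixed point for columns ({i}, {j}) did not converge "
        f"in {max_iter} iterations (marginal residual {resid:.3e} > {tol:g})"
    )


def direct_information(
    i: int,
    j: int,
    coup: CouplingModel,
    freq: FrequencyModel,
    tol: float = DEFAULT_DI_TOL,
    max_iter: int = DEFAULT_DI_MAX_ITER,
) -> float:
    """Direct information between 1-based columns ``i`` and ``j`` (nats).

    DI is the mutual information of the two-site model built from the pair
    coupling alone; it vanishes when the coupling block is zero, is
    symmetric in (i, j), and is non-negative.
    """
    if i == j:
        raise ValueError("direct information requires two distinct columns")
    P = _two_site_model(i, j, coup, freq, tol, max_iter)
    ref = np.outer(freq.fi[i - 1], freq.fi[j - 1])
    mask = P > 0
    di = float(np.sum(P[mask] * np.log(P[mask] / ref[mask])))
    return max(di, 0.0)


def mutual_information(i: int, j: int, freq: FrequencyModel) -> float:
    """Mutual information of the (regularized) pair frequency table (nats)."""
    if i == j:
        raise ValueError("mutual information requires two distinct columns")
    fij = freq.pair_block(i, j)
    ref = np.outer(freq.fi[i - 1], freq.fi[j - 1])
    mask = fij > 0
    mi = float(np.sum(fij[mask] * np.log(fij[mask] / ref[mask])))
    return max(mi, 0.0)


def score_all_pairs(
    aln,
    theta: float | None = DEFAULT_THETA,
    lam: float = DEFAULT_LAMBDA,
    pair_filter: set[str] | None = None,
    tol: float = DEFAULT_DI_TOL,
    max_iter: int = DEFAULT_DI_MAX_ITER,
) -> pd.DataFrame:
    """Score column pairs of an alignment; returns the four-column table.

    The result has one row per retained unordered pair (i < j, 1-based
    concatenated columns) with columns ``i, j, di, mi``.  For a
    :class:`PairedAlignment` the default filter keeps only inter-protein
    (AB) pairs, excluding the linker; pass an explicit set of labels from
    ``{"AA", "AB", "BB"}`` to change it, or ``pair_filter=None`` on a
    plain family to score every pair.  Deterministic given its inputs.
    """
    paired = isinstance(aln, PairedAlignment)
    if pair_filter is None and paired:
        pair_filter = {PAIR_AB}

    X = encode(aln)
    weights = compute_weights(X, theta)
    freq = compute_frequencies(X, weights, lam)
    coup = compute_couplings(freq)

    L = X.shape[1]
    pairs: list[tuple[int, int]] = []
    if paired and pair_filter is not None:
        for i in range(1, L + 1):
            for j in range(i + 1, L + 1):
                if classify_pair(i, j, aln) in pair_filter:
                    pairs.append((i, j))
    else:
        pairs = [(i, j) for i in range(1, L + 1) for j in range(i + 1, L + 1)]

    records = [
        (
            i,
            j,
            direct_information(i, j, coup, freq, tol, max_iter),
            mutual_information(i, j, freq),
        )
        for i, j in pairs
    ]
    return pd.DataFrame(records, columns=["i", "j", "di", "mi"])


def write_pair_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a pair-score table as four-column TSV (i, j, DI, MI)."""
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_pair_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
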