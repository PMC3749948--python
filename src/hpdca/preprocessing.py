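"""Reweighting, regularized frequencies, covariance and Pearson spectrum.

The statistical core of the method starts from weighted, pseudocount-
regularized frequency counts

    f_i(A)    — frequency of state A at position i,
    f_ij(A,B) — joint frequency of (A, B) at positions (i, j),

builds the covariance matrix ``C_ij(a,b) = f_ij(a,b) − f_i(a) f_j(b)`` over
the first ``q − 1`` states (the last alphabet state is dropped; the gap,
state 1, is kept), and whitens it site-by-site into the Pearson correlation
matrix

    Γ_ij = D_i^{-1/2} C_ij D_j^{-1/2},   D_i = C_ii.

Each diagonal block of Γ is the identity, so its trace — and hence the mean
of its eigenvalues — equals 1 exactly.  The eigenpairs of Γ drive pattern
inference downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .msa_io import EncodedMSA

logger = logging.getLogger(__name__)

DEFAULT_THETA = 0.2
DEFAULT_PSEUDOCOUNT = 0.5


class SingularSiteError(ValueError):
    """A diagonal covariance block is numerically singular."""


@dataclass
class SequenceWeights:
    """Similarity-based sequence weights.

    ``w[b]`` is the inverse of the number of sequences (including ``b``
    itself) whose Hamming distance to ``b`` is below ``theta * L``; for
    ``theta = 0`` only exact duplicates count.  ``M_eff = sum(w)`` is the
    effective number of independent sequences.
    """

    w: np.ndarray
    theta: float

    @property
    def M_eff(self) -> float:
        return float(self.w.sum())


@dataclass
class FrequencyModel:
    """Pseudocount-regularized single- and pair-site frequencies.

    ``f1`` has shape (L, q); ``f2`` has shape (L, L, q, q) with the
    consistency convention ``f2[i, i, a, b] = f1[i, a] * delta(a, b)``.
    """

    f1: np.ndarray
    f2: np.ndarray
    pseudocount_fraction: float
    M_eff: float

    @property
    def L(self) -> int:
        return self.f1.shape[0]

    @property
    def q(self) -> int:
        return self.f1.shape[1]


@dataclass
class PearsonSpectrum:
    """Covariance matrix, site-block whiteners, Pearson matrix and spectrum.

    ``C`` and ``Gamma`` are ``(q−1)L`` square in site-major block layout
    (row index ``i*(q−1) + a`` for position i, reduced state a, both
    0-based).  ``eigvals`` are sorted in decreasing order; ``eigvecs[:, k]``
    is the orthonormal eigenvector of ``eigvals[k]``.
    """

    C: np.ndarray
    D_sqrt: np.ndarray       # (L, q-1, q-1)
    D_sqrt_inv: np.ndarray   # (L, q-1, q-1)
    Gamma: np.ndarray
    eigvals: np.ndarray
    eigvecs: np.ndarray
    L: int
    q: int


def _hamming_neighbor_counts(data: np.ndarray, theta: float, chunk: int = 512) -> np.ndarray:
    """Count, per sequence, sequences within Hamming distance theta*L."""
    M, L = data.shape
    cutoff = theta * L
    counts = np.zeros(M, dtype=np.int64)
    for start in range(0, M, chunk):
        block = data[start:start + chunk]  # (m, L)
        d = (block[:, None, :] != data[None, :, :]).sum(axis=2)
        counts[start:start + chunk] = ((d < cutoff) | (d == 0)).sum(axis=1)
    return counts


def compute_weights(msa: EncodedMSA, theta: float = DEFAULT_THETA) -> SequenceWeights:
    """Inverse-neighborhood-size sequence weights.

    A sequence's weight is ``1 / n_b`` where ``n_b`` counts alignment members
    within fractional Hamming distance ``theta`` (gaps compared as ordinary
    states; the sequence always counts itself).  ``theta = 0`` reduces to
    removing duplicate counts.
    """
    if not 0 <= theta < 1:
        raise ValueError(f"theta must lie in [0, 1), got {theta}")
    counts = _hamming_neighbor_counts(msa.data, theta)
    w = 1.0 / counts
    weights = SequenceWeights(w=w, theta=theta)
    logger.info("reweighting: theta=%.3g, M=%d, M_eff=%.2f", theta, msa.M, weights.M_eff)
    return weights


def compute_frequencies(
    msa: EncodedMSA,
    weights: SequenceWeights | None = None,
    pseudocount_fraction: float = DEFAULT_PSEUDOCOUNT,
) -> FrequencyModel:
    """Weighted frequency counts mixed with a uniform pseudocount.

    With total pseudocount mass ``Λ = pc/(1−pc) · M_eff``:

        f_i(A)    = (Λ/q  + Σ_b w_b δ(a_i^b, A))              / (Λ + M_eff)
        f_ij(A,B) = (Λ/q² + Σ_b w_b δ(a_i^b, A) δ(a_j^b, B))  / (Λ + M_eff)

    so ``pc = 0.5`` means half empirical counts, half uniform prior,
    independent of the effective sample size.
    """
    if not 0 <= pseudocount_fraction < 1:
        raise ValueError("pseudocount_fraction must lie in [0, 1)")
    M, L, q = msa.M, msa.L, msa.q
    w = np.ones(M) if weights is None else np.asarray(weights.w, dtype=float)
    M_eff = float(w.sum())
    lam = pseudocount_fraction / (1.0 - pseudocount_fraction) * M_eff
    denom = lam + M_eff

    # one-hot encoding, states shifted to 0-based columns
    onehot = np.zeros((M, L * q))
    flat_idx = np.arange(L) * q + (msa.data - 1)
    np.put_along_axis(onehot, flat_idx, 1.0, axis=1)

    counts1 = (w[:, None] * onehot).sum(axis=0).reshape(L, q)
    f1 = (lam / q + counts1) / denom

    counts2 = (w[:, None] * onehot).T @ onehot  # (Lq, Lq)
    f2 = (lam / q**2 + counts2.reshape(L, q, L, q).transpose(0, 2, 1, 3)) / denom
    # i = j blocks follow the consistency convention f_ii(A,B) = f_i(A) δ(A,B)
    for i in range(L):
        f2[i, i] = np.diag(f1[i])
    return FrequencyModel(f1=f1, f2=f2, pseudocount_fraction=pseudocount_fraction, M_eff=M_eff)


def compute_covariance(freqs: FrequencyModel) -> np.ndarray:
    """Covariance ``C_ij(a,b) = f_ij(a,b) − f_i(a) f_j(b)`` on the reduced alphabet.

    The last alphabet state is dropped (columns ``a, b ∈ 1..q−1``); the
    result is the symmetric ``(q−1)L`` matrix in site-major block layout.
    """
    L, q = freqs.L, freqs.q
    r = q - 1
    cov = freqs.f2[:, :, :r, :r] - np.einsum("ia,jb->ijab", freqs.f1[:, :r], freqs.f1[:, :r])
    C = cov.transpose(0, 2, 1, 3).reshape(L * r, L * r)
    return (C + C.T) / 2.0


def compute_pearson(C: np.ndarray, L: int | None = None, q: int | None = None) -> PearsonSpectrum:
    """Whiten the covariance into the Pearson matrix and diagonalize it.

    Each diagonal block ``C_ii`` is inverted through its symmetric square
    root; a block with an eigenvalue below 1e−12 raises
    :class:`SingularSiteError` naming the position (add a pseudocount).
    Eigenvalues are returned in decreasing order, ties kept in ascending
    original-index order (stable sort).
    """
    n = C.shape[0]
    if q is None:
        q = 21 if L is None else n // L + 1
    r = q - 1
    if L is None:
        L = n // r
    if L * r != n:
        raise ValueError("matrix size incompatible with L and q")

    D_sqrt = np.empty((L, r, r))
    D_sqrt_inv = np.empty((L, r, r))
    for i in range(L):
        block = C[i * r:(i + 1) * r, i * r:(i + 1) * r]
        vals, vecs = scipy.linalg.eigh(block)
        if vals.min() < 1e-12:
            raise SingularSiteError(
                f"covariance block of position {i + 1} is singular "
                f"(min eigenvalue {vals.min():.3g}); use a pseudocount_fraction > 0"
            )
        D_sqrt[i] = (vecs * np.sqrt(vals)) @ vecs.T
        D_sqrt_inv[i] = (vecs / np.sqrt(vals)) @ vecs.T

    Dinv = scipy.linalg.block_diag(*D_sqrt_inv)
    Gamma = Dinv @ C @ Dinv
    Gamma = (Gamma + Gamma.T) / 2.0

    vals, vecs = scipy.linalg.eigh(Gamma)
    order = np.argsort(-vals, kind="stable")
    return PearsonSpectrum(
        C=C, D_sqrt=D_sqrt, D_sqrt_inv=D_sqrt_inv, Gamma=Gamma,
        eigvals=vals[order], eigvecs=vecs[:, order], L=L, q=q,
    )


def pearson_spectrum(
    msa: EncodedMSA,
    theta: float = DEFAULT_THETA,
    pseudocount_fraction: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[PearsonSpectrum, FrequencyModel, SequenceWeights]:
    """Convenience pipeline: weights → frequencies → covariance → spectrum."""
    weights = compute_weights(msa, theta)
    freqs = compute_frequencies(msa, weights, pseudocount_fraction)
    C = compute_covariance(freqs)
    spectrum = compute_pearson(C, L=freqs.L, q=freqs.q)
    return spectrum, freqs, weights


def write_spectrum_csv(spectrum: PearsonSpectrum, path) -> None:
    """Write eigenvalues as CSV rows (k, lambda_k), 1-based rank."""
    with open(path, "w") as fh:
        fh.write("k,eigenvalue\n")
        for k, lam in enumerate(spectrum.eigvals, 1):
            fh.write(f"{k},{lam:.12g}\n")


def write_weights_csv(weights: SequenceWeights, labels, path) -> None:
    with open(path, "w") as fh:
        fh.write("label,weight\n")
        for label, wb in zip(labels, weights.w):
            fh.write(f"{label},{wb:.12g}\n")
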