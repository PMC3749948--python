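"""The generative Hopfield-Potts sequence model.

A sequence a = (a_1..a_L) scores against a pattern ξ through the squared
projection

    S(a | ξ) = (Σ_i ξ_i(a_i))²,

and the model probability combines attractive (favored, λ > 1) and
repulsive (penalized, λ < 1) patterns with position-specific fields:

    P(a) ∝ exp( ½ Σ_μ+ S(a|ξ⁺) − ½ Σ_μ− S(a|ξ⁻) + Σ_i h_i(a_i) ).

Expanding the squares shows this is a Potts model whose coupling matrix is
the signed sum of pattern outer products,

    e_ij(a,b) = Σ_μ+ ξ⁺_i(a) ξ⁺_j(b) − Σ_μ− ξ⁻_i(a) ξ⁻_j(b),

of rank at most p.  At full rank p = (q−1)L the couplings coincide with
the mean-field direct-coupling-analysis solution e = −(C⁻¹) off the
diagonal blocks, so standard DCA is the limiting case.

This module also provides exact enumeration for desk-scale models (the
test oracle) and a heat-bath Gibbs sampler for generating synthetic
alignments.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .msa_io import ALPHABET, EncodedMSA
from .preprocessing import FrequencyModel, PearsonSpectrum
from .spectral_patterns import Pattern, PatternSet, likelihood_contribution

logger = logging.getLogger(__name__)

ENUMERATION_GUARD = 10**6


@dataclass
class CouplingModel:
    """Low-rank Potts couplings and fields.

    ``e`` is (L, L, q, q) with ``e[i, j, a, b] == e[j, i, b, a]``, zero
    diagonal blocks, and the last row/column of every block zero (gauge).
    ``h`` is (L, q) with the last column zero.
    """

    e: np.ndarray
    h: np.ndarray
    rank: int

    def __post_init__(self) -> None:
        self.e = np.asarray(self.e, dtype=float)
        self.h = np.asarray(self.h, dtype=float)

    @property
    def L(self) -> int:
        return self.h.shape[0]

    @property
    def q(self) -> int:
        return self.h.shape[1]


def log_score(seq: np.ndarray, pattern: Pattern) -> float:
    """Squared projection S = (Σ_i ξ_i(a_i))² of a sequence onto a pattern.

    ``seq`` holds 1-based states.  Nonnegative and invariant under a global
    sign flip of the pattern — only the *direction* in sequence space
    matters.  A repulsive pattern with two opposite-sign components at
    (i, A) and (j, B) scores 0 when both or neither favored state is
    present and 1 (in squared-component units) when exactly one is: an
    exclusive-or constraint on the pair.
    """
    seq = np.asarray(seq)
    if seq.shape != (pattern.L,):
        raise ValueError(f"sequence length {seq.shape} != pattern length {pattern.L}")
    proj = pattern.xi[np.arange(pattern.L), seq - 1].sum()
    return float(proj**2)


def build_couplings(patterns: PatternSet | list[Pattern], L: int | None = None,
                    q: int | None = None) -> CouplingModel:
    """Couplings as the signed sum of pattern outer products (fields zero).

    Attractive patterns add +ξ_i(a)ξ_j(b), repulsive ones subtract it.
    The result depends only on the span of each eigen-subspace, not on the
    basis chosen within degenerate groups.
    """
    pats = patterns.patterns if isinstance(patterns, PatternSet) else list(patterns)
    if pats:
        L, q = pats[0].L, pats[0].q
        if any(p.L != L or p.q != q for p in pats):
            raise ValueError("all patterns must share L and q")
    elif L is None or q is None:
        raise ValueError("L and q required for an empty pattern set")

    e = np.zeros((L, L, q, q))
    for pat in pats:
        sgn = 1.0 if pat.sign == "attractive" else -1.0
        e += sgn * np.einsum("ia,jb->ijab", pat.xi, pat.xi)
    for i in range(L):
        e[i, i] = 0.0
    return CouplingModel(e=e, h=np.zeros((L, q)), rank=len(pats))


def fit_fields(freqs: FrequencyModel, couplings: CouplingModel) -> CouplingModel:
    """Fields from the mean-field single-site consistency condition.

    h_i(a) = ln(f_i(a)/f_i(q)) − Σ_{j≠i} Σ_b e_ij(a,b) f_j(b), with
    h_i(q) = 0.  With zero couplings this is the position-specific scoring
    matrix (PSSM) of the alignment.
    """
    L, q = couplings.L, couplings.q
    if freqs.L != L or freqs.q != q:
        raise ValueError("frequency model and couplings have inconsistent shapes")
    if np.any(freqs.f1 <= 0):
        raise ValueError("zero frequencies; use a pseudocount_fraction > 0")
    h = np.zeros((L, q))
    mean_field = np.einsum("ijab,jb->ia", couplings.e, freqs.f1)
    h[:, :q - 1] = (np.log(freqs.f1[:, :q - 1] / freqs.f1[:, -1:])
                    - mean_field[:, :q - 1])
    return CouplingModel(e=couplings.e, h=h, rank=couplings.rank)


def _energies(model: CouplingModel, configs: np.ndarray) -> np.ndarray:
    """Σ_{i<j} e_ij(a_i,a_j) + Σ_i h_i(a_i) for rows of 1-based states."""
    L = model.L
    s = configs - 1
    energy = model.h[np.arange(L), s].sum(axis=1)
    for i in range(L):
        for j in range(i + 1, L):
            energy += model.e[i, j][s[:, i], s[:, j]]
    return energy


def enumerate_distribution(model: CouplingModel):
    """Exact probabilities and marginals by enumerating all q^L sequences.

    Returns ``(P, Z, f1, f2)``: the probability of every configuration (in
    ``itertools.product`` order over 1-based states), the partition
    function, and the one- and two-site marginals.  Guarded to
    q^L ≤ 10^6; larger state spaces need the Gibbs sampler.
    """
    L, q = model.L, model.q
    if q**L > ENUMERATION_GUARD:
        raise ValueError(
            f"state space q^L = {q**L} exceeds the enumeration guard "
            f"({ENUMERATION_GUARD}); use gibbs_sample instead"
        )
    configs = np.array(list(itertools.product(range(1, q + 1), repeat=L)), dtype=np.int64)
    energy = _energies(model, configs)
    weights = np.exp(energy - energy.max())
    Z = weights.sum()
    P = weights / Z
    s = configs - 1
    f1 = np.zeros((L, q))
    f2 = np.zeros((L, L, q, q))
    for i in range(L):
        np.add.at(f1[i], s[:, i], P)
        for j in range(L):
            np.add.at(f2[i, j], (s[:, i], s[:, j]), P)
    true_Z = Z * np.exp(energy.max())
    return P, float(true_Z), f1, f2


def gibbs_sample(model: CouplingModel, n_sequences: int, seed: int,
                 burn_in: int = 1000, thin: int = 10) -> EncodedMSA:
    """Sample an alignment by single-site heat-bath updates in fixed site order.

    One chain: ``burn_in`` full sweeps are discarded, then every ``thin``-th
    sweep emits the current configuration, until ``n_sequences`` rows are
    collected.  Deterministic for a fixed seed.
    """
    if n_sequences < 1:
        raise ValueError("n_sequences must be >= 1")
    L, q = model.L, model.q
    rng = np.random.default_rng(seed)
    state = rng.integers(0, q, size=L)  # 0-based internally

    # per-site conditional ingredients: e[i] rows vs all other sites
    e = model.e
    h = model.h
    out = np.empty((n_sequences, L), dtype=np.int64)
    n_collected = 0
    sweep = 0
    while n_collected < n_sequences:
        for i in range(L):
            logits = h[i].copy()
            for j in range(L):
                if j != i:
                    logits += e[i, j, :, state[j]]
            logits -= logits.max()
            p = np.exp(logits)
            cdf = np.cumsum(p)
            state[i] = np.searchsorted(cdf, rng.random() * cdf[-1], side="right")
        sweep += 1
        if sweep > burn_in and (sweep - burn_in) % thin == 0:
            out[n_collected] = state + 1
            n_collected += 1
    logger.info("gibbs_sample: %d sequences after %d sweeps (L=%d, q=%d)",
                n_sequences, sweep, L, q)
    alphabet = ALPHABET[:q] if q <= len(ALPHABET) else ALPHABET
    return EncodedMSA(out, alphabet=alphabet)


def interaction_likelihood_ratio(spectrum: PearsonSpectrum, p: int) -> float:
    """Fraction of the attainable pattern log-likelihood captured by p modes.

    Σ over the p best s(λ) divided by Σ over all modes; 0 at p = 0, 1 at
    full rank, non-decreasing in p.
    """
    s = likelihood_contribution(spectrum.eigvals)
    n = len(s)
    if not 0 <= p <= n:
        raise ValueError(f"p must lie in [0, {n}]")
    total = float(s.sum())
    if total == 0.0:
        return 1.0 if p == n else float(p == n)
    best = np.sort(s)[::-1][:p]
    return float(best.sum() / total)


def save_model(model: CouplingModel, path: str | Path) -> None:
    """Serialize to a plain-text block format (1-based indices), round-trip exact."""
    with open(path, "w") as fh:
        fh.write(f"# hopfield-potts model\nL {model.L}\nq {model.q}\nrank {model.rank}\n")
        for i in range(model.L):
            for a in range(model.q):
                fh.write(f"h {i + 1} {a + 1} {model.h[i, a].hex()}\n")
        for i in range(model.L):
            for j in range(i + 1, model.L):
                block = model.e[i, j]
                if not np.any(block):
                    continue
                for a in range(model.q):
                    for b in range(model.q):
                        fh.write(f"e {i + 1} {j + 1} {a + 1} {b + 1} {block[a, b].hex()}\n")


def load_model(path: str | Path) -> CouplingModel:
    """Read a model written by :func:`save_model`."""
    L = q = rank = None
    h = e = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if parts[0] == "L":
                L = int(parts[1])
            elif parts[0] == "q":
                q = int(parts[1])
            elif parts[0] == "rank":
                rank = int(parts[1])
            elif parts[0] == "h":
                if h is None:
                    h = np.zeros((L, q))
                    e = np.zeros((L, L, q, q))
                i, a = int(parts[1]) - 1, int(parts[2]) - 1
                h[i, a] = float.fromhex(parts[3])
            elif parts[0] == "e":
                i, j = int(parts[1]) - 1, int(parts[2]) - 1
                a, b = int(parts[3]) - 1, int(parts[4]) - 1
                val = float.fromhex(parts[5])
                e[i, j, a, b] = val
                e[j, i, b, a] = val
    if L is None or q is None or h is None:
        raise ValueError(f"not a valid model file: {path}")
    return CouplingModel(e=e, h=h, rank=rank if rank is not None else 0)
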