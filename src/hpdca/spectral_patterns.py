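"""Hopfield-Potts patterns from the Pearson spectrum.

Every eigenpair (λ, v) of the Pearson matrix Γ defines a candidate pattern

    ξ_i(a) = ω(λ) · (D_i^{-1/2} v)_i(a),   ω(λ) = sqrt(|1 − 1/λ|),

with the component on the dropped alphabet state fixed to zero (gauge).
Patterns with λ > 1 are *attractive* (they reward sequences aligned with
ξ), patterns with λ < 1 are *repulsive* (they penalize such sequences —
the mechanism that encodes XOR-type covariation constraints).  ω vanishes
at λ = 1, stays below 1 for attractive patterns, and grows without bound
as λ → 0, which is why low-eigenvalue modes dominate the couplings.

Maximum-likelihood selection keeps the p modes with the largest per-mode
log-likelihood contribution

    s(λ) = (λ − 1 − ln λ) / 2     (per unit of M_eff),

a convex function that vanishes only at λ = 1, so the best patterns sit in
*both* tails of the spectrum.

Localization of a pattern is measured by the inverse participation ratio
IPR = Σ ξ⁴ / (Σ ξ²)²: 1 for a single-component pattern, 1/N for N uniform
components.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .preprocessing import PearsonSpectrum

logger = logging.getLogger(__name__)

DEGENERACY_TOL = 1e-9


def omega(lam: float) -> float:
    """Pattern prefactor ω(λ) = sqrt(|1 − 1/λ|); 0 at λ = 1, unbounded as λ → 0."""
    if lam <= 0:
        raise ValueError(f"eigenvalue must be positive, got {lam}")
    return float(np.sqrt(abs(1.0 - 1.0 / lam)))


def likelihood_contribution(lam: float) -> float:
    """Per-mode log-likelihood contribution s(λ) = (λ − 1 − ln λ)/2, per unit M_eff.

    Strictly decreasing on (0, 1), zero at 1, strictly increasing on (1, ∞):
    both spectrum tails carry likelihood.
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("eigenvalues must be positive")
    s = (lam - 1.0 - np.log(lam)) / 2.0
    return float(s) if s.ndim == 0 else s


def ipr(xi: np.ndarray) -> float:
    """Inverse participation ratio of a pattern's components.

    Scale-invariant; 1 for perfect localization, ``1/n`` for ``n`` equal-
    magnitude components.  Undefined (raises) for an all-zero pattern.
    """
    xi = np.asarray(xi, dtype=float)
    norm2 = float((xi**2).sum())
    if norm2 == 0.0:
        raise ValueError("IPR undefined for an all-zero pattern")
    return float((xi**4).sum() / norm2**2)


@dataclass
class Pattern:
    """A single Hopfield-Potts pattern.

    ``xi`` is (L, q) with the last column identically zero (gauge).  The
    sign classifies the mode: attractive for λ > 1, repulsive for λ < 1.
    """

    xi: np.ndarray
    sign: str  # "attractive" | "repulsive"
    eigenvalue: float
    omega: float = field(default=None)  # type: ignore[assignment]
    loglik_contribution: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.xi = np.asarray(self.xi, dtype=float)
        if self.omega is None:
            self.omega = omega(self.eigenvalue)
        if self.loglik_contribution is None:
            self.loglik_contribution = likelihood_contribution(self.eigenvalue)

    @property
    def L(self) -> int:
        return self.xi.shape[0]

    @property
    def q(self) -> int:
        return self.xi.shape[1]

    @property
    def ipr(self) -> float:
        return ipr(self.xi)

    @property
    def delta(self) -> float:
        return coupling_contribution(self)


def pattern_from_mode(spectrum: PearsonSpectrum, k: int) -> Pattern:
    """Build the pattern of the k-th mode (1-based rank, eigenvalues descending).

    ξ_i(a) = ω(λ_k) (D_i^{-1/2} v_k)_i(a) on the q−1 retained states,
    extended by a zero column for the dropped state.
    """
    n = len(spectrum.eigvals)
    if not 1 <= k <= n:
        raise ValueError(f"mode index must lie in [1, {n}], got {k}")
    lam = float(spectrum.eigvals[k - 1])
    v = spectrum.eigvecs[:, k - 1]
    L, q = spectrum.L, spectrum.q
    r = q - 1
    x = v.reshape(L, r)
    xi_red = omega(lam) * np.einsum("iab,ib->ia", spectrum.D_sqrt_inv, x)
    xi = np.zeros((L, q))
    xi[:, :r] = xi_red
    return Pattern(xi=xi, sign="attractive" if lam > 1 else "repulsive", eigenvalue=lam)


def coupling_contribution(pattern: Pattern) -> float:
    """Typical coupling magnitude Δ contributed by a pattern.

    The pattern adds ±ξ_i(a) ξ_j(b) to each coupling; Δ is the root-mean-
    square of these contributions over the pattern's effective support of
    N_eff(N_eff−1)/2 site pairs, with N_eff = 1/IPR.  Homogeneous of
    degree 2 in the pattern; exactly 0 for a vanished (λ = 1) pattern.
    """
    xi = pattern.xi
    if not np.any(xi):
        return 0.0
    site_norms = (xi**2).sum(axis=1)  # r_i = Σ_a ξ_i(a)²
    # ordered pair sum Σ_{i≠j} r_i r_j
    s2 = float(site_norms.sum() ** 2 - (site_norms**2).sum())
    n_eff = 1.0 / ipr(xi)
    n_pairs_eff = n_eff * (n_eff - 1.0) / 2.0
    if n_pairs_eff <= 0:
        return float(np.sqrt(s2)) if s2 > 0 else 0.0
    return float(np.sqrt(s2 / n_pairs_eff))


@dataclass
class PatternSet:
    """Maximum-likelihood-selected patterns with the eigenvalue thresholds.

    ``x_minus < 1 < x_plus`` are the two roots of ``s(λ) = s_threshold``:
    every selected repulsive mode has λ ≤ x_minus, every selected
    attractive mode λ ≥ x_plus.
    """

    patterns: list[Pattern]
    p_plus: int
    p_minus: int
    x_minus: float
    x_plus: float

    @property
    def p(self) -> int:
        return len(self.patterns)


def _threshold_roots(s_threshold: float) -> tuple[float, float]:
    """The two positive roots x− < 1 < x+ of s(λ) = s_threshold."""
    if s_threshold <= 0:
        return 1.0, 1.0
    lo = 1.0
    while likelihood_contribution(lo / 2) < s_threshold:
        lo /= 2
        if lo < 1e-300:
            return 0.0, np.inf
    x_minus = brentq(lambda x: likelihood_contribution(x) - s_threshold, lo / 2, 1.0)
    hi = 2.0
    while likelihood_contribution(hi) < s_threshold:
        hi *= 2
    x_plus = brentq(lambda x: likelihood_contribution(x) - s_threshold, 1.0, hi)
    return float(x_minus), float(x_plus)


def select_patterns(spectrum: PearsonSpectrum, p: int) -> PatternSet:
    """Keep the p modes with the largest likelihood contribution s(λ).

    Ties in s are broken toward the smaller eigenvalue, then the smaller
    mode index, so selection is deterministic.  Numerically degenerate
    eigenvalue groups are reported with a warning: within such a group the
    individual patterns (and their IPRs) depend on the eigenbasis choice,
    although the summed couplings do not.
    """
    lams = spectrum.eigvals
    n = len(lams)
    if not 0 <= p <= n:
        raise ValueError(f"p must lie in [0, {n}], got {p}")
    s = likelihood_contribution(lams)
    # sort by (-s, λ, index); lexsort keys are last-key-primary
    order = np.lexsort((np.arange(n), lams, -s))
    selected = np.sort(order[:p])

    _warn_degenerate(lams[order[:p]] if p else lams[:0])

    patterns = [pattern_from_mode(spectrum, int(k) + 1) for k in selected]
    p_plus = sum(1 for pat in patterns if pat.eigenvalue > 1)
    p_minus = len(patterns) - p_plus

    if p == 0:
        s_thr = float(s.max()) + 1.0 if n else 1.0
    elif p == n:
        s_thr = 0.0
    else:
        s_thr = (s[order[p - 1]] + s[order[p]]) / 2.0
    x_minus, x_plus = _threshold_roots(s_thr)
    logger.info(
        "selected p=%d patterns (p_plus=%d, p_minus=%d), thresholds x-=%.4g x+=%.4g",
        p, p_plus, p_minus, x_minus, x_plus,
    )
    return PatternSet(patterns=patterns, p_plus=p_plus, p_minus=p_minus,
                      x_minus=x_minus, x_plus=x_plus)


def select_by_likelihood_fraction(spectrum: PearsonSpectrum, fraction: float) -> PatternSet:
    """Smallest p whose selected modes capture ≥ ``fraction`` of Σ s(λ)."""
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    s = likelihood_contribution(spectrum.eigvals)
    total = s.sum()
    if total == 0:
        return select_patterns(spectrum, 0)
    s_sorted = np.sort(s)[::-1]
    cum = np.cumsum(s_sorted) / total
    p = int(np.searchsorted(cum, fraction - 1e-12) + 1) if fraction > 0 else 0
    return select_patterns(spectrum, min(p, len(s)))


def _warn_degenerate(selected_lams: np.ndarray) -> None:
    if len(selected_lams) < 2:
        return
    lams = np.sort(selected_lams)
    groups = []
    start = 0
    for i in range(1, len(lams)):
        if lams[i] - lams[i - 1] >= DEGENERACY_TOL:
            if i - start > 1:
                groups.append(lams[start:i])
            start = i
    if len(lams) - start > 1:
        groups.append(lams[start:])
    if groups:
        warnings.warn(
            "degenerate eigenvalue groups among selected patterns: "
            + "; ".join(f"[{g[0]:.6g}..{g[-1]:.6g}] x{len(g)}" for g in groups)
            + " — per-pattern outputs (IPR) are basis-dependent within each group",
            stacklevel=2,
        )


def write_pattern_tsv(pattern: Pattern, alphabet: str, path) -> None:
    """One row per (position, state): i, symbol, ξ_i(a); 1-based positions."""
    with open(path, "w") as fh:
        fh.write("position\tstate\txi\n")
        for i in range(pattern.L):
            for a in range(pattern.q):
                fh.write(f"{i + 1}\t{alphabet[a]}\t{pattern.xi[i, a]:.12g}\n")


def write_pattern_summary_csv(patterns: PatternSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("rank,eigenvalue,sign,loglik_contribution,omega,ipr,delta\n")
        for k, pat in enumerate(patterns.patterns, 1):
            ipr_val = pat.ipr if np.any(pat.xi) else float("nan")
            fh.write(
                f"{k},{pat.eigenvalue:.12g},{pat.sign},{pat.loglik_contribution:.12g},"
                f"{pat.omega:.12g},{ipr_val:.12g},{pat.delta:.12g}\n"
            )
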