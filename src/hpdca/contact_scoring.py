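"""Contact scores from coupling blocks: zero-sum gauge, Frobenius norm, APC.

Each q×q coupling block is first double-centered into the zero-sum gauge
(row and column means removed), which is the gauge minimizing the block's
Frobenius norm and makes the score invariant under adding any single-
position function to the couplings.  The pairwise score is then

    F_ij = || ẽ_ij ||_F ,

corrected by the average-product correction (APC)

    F^APC_ij = F_ij − F_i· F_·j / F_·· ,

where the dots are means over the other positions (diagonal excluded).
APC suppresses the background coming from phylogenetic bias and uneven
position conservation.  Ranked pairs at a minimum sequence separation are
the contact predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .hopfield_model import CouplingModel

DEFAULT_MIN_SEPARATION = 5


@dataclass
class ContactScores:
    """Symmetric L×L Frobenius-norm scores and their APC-corrected version."""

    F: np.ndarray
    F_apc: np.ndarray | None = None
    min_separation: int = DEFAULT_MIN_SEPARATION

    @property
    def L(self) -> int:
        return self.F.shape[0]


def zero_sum_gauge(block: np.ndarray) -> np.ndarray:
    """Double-center a q×q coupling block: all row and column means become 0.

    ẽ(a,b) = e(a,b) − ē(·,b) − ē(a,·) + ē(·,·), averages taken over all q
    states including the gap.  Idempotent; annihilates constants and any
    term depending on one argument only.
    """
    block = np.asarray(block, dtype=float)
    if block.ndim != 2 or block.shape[0] != block.shape[1]:
        raise ValueError("coupling block must be square")
    return (block
            - block.mean(axis=0, keepdims=True)
            - block.mean(axis=1, keepdims=True)
            + block.mean())


def frobenius_scores(model: CouplingModel) -> ContactScores:
    """F_ij = Frobenius norm of the zero-sum-gauge block ẽ_ij; F_ii = 0."""
    L = model.L
    F = np.zeros((L, L))
    for i in range(L):
        for j in range(i + 1, L):
            F[i, j] = F[j, i] = np.linalg.norm(zero_sum_gauge(model.e[i, j]))
    return ContactScores(F=F)


def apc(scores: ContactScores) -> ContactScores:
    """Average-product correction with diagonal-free means.

    F_i· is the mean of F over j ≠ i, F_·· the mean over all ordered pairs
    i ≠ j.  A rank-one constant score matrix is mapped exactly to zero.
    """
    F = scores.F
    L = scores.L
    if L < 3:
        raise ValueError("APC needs at least 3 positions")
    off = ~np.eye(L, dtype=bool)
    row_mean = (F * off).sum(axis=1) / (L - 1)
    total_mean = (F * off).sum() / (L * (L - 1))
    if total_mean == 0.0:
        warnings.warn("all contact scores are zero; APC returns zeros", stacklevel=2)
        return ContactScores(F=F, F_apc=np.zeros_like(F),
                             min_separation=scores.min_separation)
    # divide first so the constant-background case cancels exactly
    F_apc = F - np.outer(row_mean / total_mean, row_mean)
    np.fill_diagonal(F_apc, 0.0)
    return ContactScores(F=F, F_apc=F_apc, min_separation=scores.min_separation)


def rank_pairs(scores: ContactScores,
               min_separation: int = DEFAULT_MIN_SEPARATION) -> list[tuple[int, int, float]]:
    """Pairs (i, j, score), i < j, |i − j| ≥ min_separation, best first.

    Positions are 1-based in the output.  Ties are broken by (i, j)
    lexicographic order so the ranking is deterministic.
    """
    if min_separation < 0:
        raise ValueError("min_separation must be >= 0")
    S = scores.F_apc if scores.F_apc is not None else scores.F
    L = scores.L
    pairs = [(i + 1, j + 1, float(S[i, j]))
             for i in range(L) for j in range(i + 1, L)
             if j - i >= min_separation]
    pairs.sort(key=lambda t: (-t[2], t[0], t[1]))
    return pairs


def contact_scores(model: CouplingModel,
                   min_separation: int = DEFAULT_MIN_SEPARATION) -> ContactScores:
    """Frobenius norms plus APC in one call."""
    s = frobenius_scores(model)
    s.min_separation = min_separation
    return apc(s)


def write_pairs_tsv(pairs, path, scores: ContactScores | None = None,
                    top: int | None = None) -> None:
    """TSV: rank, i, j, F, F_apc (1-based positions)."""
    with open(path, "w") as fh:
        fh.write("rank\ti\tj\tF\tF_apc\n")
        for rank, (i, j, s) in enumerate(pairs[:top], 1):
            raw = scores.F[i - 1, j - 1] if scores is not None else float("nan")
            fh.write(f"{rank}\t{i}\t{j}\t{raw:.12g}\t{s:.12g}\n")
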