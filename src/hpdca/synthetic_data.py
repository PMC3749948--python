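"""Synthetic alignment generators for every pipeline stage.

Three families of test alignments, matching the statistical regimes the
inference distinguishes:

* :func:`conserved_msa` — one sequence repeated M times.  With a
  pseudocount the Pearson matrix of this alignment has exactly three
  eigenvalues: one large non-degenerate (extended mode), one small
  (L−1)-fold degenerate (modes localized on pairs of sites with opposite
  signs), and 1 with multiplicity (q−2)L (single-site modes).
* :func:`independent_msa` — i.i.d. columns from a given profile; at large
  M all eigenvalues approach 1 and all inferred patterns vanish.
* :func:`planted_pattern_family` — sequences Gibbs-sampled from a
  Hopfield-Potts model with known two-site patterns, the ground truth for
  recovery tests.  An opposite-sign repulsive planted pattern enforces an
  exclusive-or constraint: configurations carrying exactly one of the two
  favored states are suppressed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .msa_io import ALPHABET, EncodedMSA
from .hopfield_model import CouplingModel, build_couplings, gibbs_sample
from .spectral_patterns import Pattern


def _alphabet(q: int) -> str:
    if q > len(ALPHABET):
        raise ValueError(f"q must be <= {len(ALPHABET)}")
    return ALPHABET[:q]


def conserved_msa(L: int, q: int = 21, M: int = 50, seed: int = 0) -> EncodedMSA:
    """M identical copies of one random sequence (fully conserved alignment)."""
    if L < 2 or M < 1:
        raise ValueError("need L >= 2 and M >= 1")
    rng = np.random.default_rng(seed)
    seq = rng.integers(1, q + 1, size=L)
    data = np.tile(seq, (M, 1))
    return EncodedMSA(data, alphabet=_alphabet(q))


def independent_msa(profile: np.ndarray, M: int, seed: int = 0) -> EncodedMSA:
    """i.i.d. sampling per site from per-position state profiles.

    ``profile`` is (L, q), each row a distribution over states 1..q.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.ndim != 2 or np.any(profile < 0) or \
            not np.allclose(profile.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("profile rows must be distributions over q states")
    L, q = profile.shape
    rng = np.random.default_rng(seed)
    data = np.empty((M, L), dtype=np.int64)
    for i in range(L):
        data[:, i] = rng.choice(q, size=M, p=profile[i] / profile[i].sum()) + 1
    return EncodedMSA(data, alphabet=_alphabet(q))


@dataclass
class TwoSitePattern:
    """Specification of a planted two-site pattern.

    Components ``+magnitude`` at (site_i, state_a) and ``±magnitude`` at
    (site_j, state_b): ``opposite_signs=True`` gives the XOR-enforcing
    construction, ``False`` the equal-sign (co-presence) variant.
    """

    site_i: int   # 1-based
    site_j: int
    state_a: int  # 1-based
    state_b: int
    magnitude: float = 1.0
    opposite_signs: bool = True
    sign: str = "repulsive"

    def to_pattern(self, L: int, q: int) -> Pattern:
        xi = np.zeros((L, q))
        xi[self.site_i - 1, self.state_a - 1] = self.magnitude
        xi[self.site_j - 1, self.state_b - 1] = (
            -self.magnitude if self.opposite_signs else self.magnitude
        )
        # eigenvalue only classifies the sign; pick a representative value
        lam = 0.5 if self.sign == "repulsive" else 2.0
        return Pattern(xi=xi, sign=self.sign, eigenvalue=lam)


def planted_pattern_family(
    L: int,
    q: int,
    pattern_spec: list[TwoSitePattern],
    M: int,
    seed: int = 0,
    field_spec: np.ndarray | None = None,
    burn_in: int = 1000,
    thin: int = 10,
) -> tuple[EncodedMSA, CouplingModel]:
    """Sample an alignment from a model with planted two-site patterns.

    Returns the alignment and the ground-truth :class:`CouplingModel`
    (fields from ``field_spec``, zero by default).
    """
    patterns = [ts.to_pattern(L, q) for ts in pattern_spec]
    model = build_couplings(patterns, L=L, q=q)
    if field_spec is not None:
        field_spec = np.asarray(field_spec, dtype=float)
        if field_spec.shape != (L, q):
            raise ValueError("field_spec must have shape (L, q)")
        model = CouplingModel(e=model.e, h=field_spec, rank=model.rank)
    msa = gibbs_sample(model, M, seed=seed, burn_in=burn_in, thin=thin)
    return msa, model
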