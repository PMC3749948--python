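# Methods

## The model

`hpdca` infers a low-rank Potts model for a protein family from its
multiple sequence alignment (MSA). Sequences `a = (a_1..a_L)` over `q = 21`
states (20 amino acids + gap) are modelled as

    P(a) ∝ exp( ½ Σ_{μ=1..p+} S(a|ξ⁺_μ) − ½ Σ_{ν=1..p−} S(a|ξ⁻_ν) + Σ_i h_i(a_i) ),
    S(a|ξ) = ( Σ_i ξ_i(a_i) )²,

a Hopfield-Potts model: the pairwise couplings are a signed sum of pattern
outer products

    e_ij(a,b) = Σ_μ ξ⁺_μ,i(a) ξ⁺_μ,j(b) − Σ_ν ξ⁻_ν,i(a) ξ⁻_ν,j(b),

of rank at most `p = p+ + p−` instead of the `(q−1)²L(L−1)/2` free
parameters of a full Potts model. *Attractive* patterns ξ⁺ reward sequences
aligned with them; *repulsive* patterns ξ⁻ penalize them — a repulsive
pattern with two opposite-sign components enforces an exclusive-or
constraint on a site pair (either both favored residues or neither), which
is precisely the signature of strongly coupled contacts such as disulfide
bridges or salt bridges.

## Inference

In mean-field approximation the maximum-likelihood patterns are
eigenmodes of the Pearson correlation matrix

    Γ_ij = D_i^{−1/2} C_ij D_j^{−1/2},   C_ij(a,b) = f_ij(a,b) − f_i(a) f_j(b),

where `D_i = C_ii` and the frequencies are reweighted and
pseudocount-regularized (below). For eigenpair (λ_k, v_k),

    ξ_k,i(a) = ω(λ_k) (D_i^{−1/2} v_k)_i(a),   ω(λ) = sqrt(|1 − 1/λ|),

attractive for λ > 1, repulsive for λ < 1. Each mode contributes

    s(λ) = (λ − 1 − ln λ)/2   (per unit M_eff)

to the log-likelihood, a convex function vanishing only at λ = 1, so the
`p` most likely patterns come from **both tails** of the spectrum; the
selection thresholds `x− < 1 < x+` are the two roots of `s(λ) = s_thr`
with `s_thr` chosen so that exactly `p` modes exceed it. We implement
`s` per unit of the effective sequence number M_eff: the global M_eff
factor is common to all modes and cancels from both the ranking and the
likelihood-capture ratio, the two quantities the selection uses.

At full rank `p = (q−1)L` the couplings reduce exactly to the mean-field
direct coupling analysis (DCA) solution `e_ij = −(C⁻¹)_ij`; at `p = 0`
the model is a position-specific scoring matrix. Both limits are verified
in the test suite, the first against an independent matrix-inversion
oracle.

### Eigenvalue degeneracies

Within a numerically degenerate eigenvalue group (gap < 1e−9) the
individual patterns depend on the arbitrary orthonormal basis returned by
the eigensolver; the summed couplings do not (verified by a
basis-rotation test). Pattern-level diagnostics (IPR) for degenerate
modes are therefore reported with a warning rather than silently. No
rotation-fixing inside degenerate subspaces is attempted.

## Preprocessing parameters

| parameter | default | meaning |
|---|---|---|
| θ (`theta`) | 0.2 | sequences within fractional Hamming distance θ share weight; `w_b = 1/#neighbors`, `M_eff = Σ w_b`. Corrects phylogenetic oversampling. θ=0 collapses exact duplicates only. |
| pseudocount fraction | 0.5 | mixing weight of the uniform prior: counts and prior contribute equally. Internally `Λ = pc/(1−pc)·M_eff`, so the setting is scale-free in M_eff. These are the standard mean-field DCA values. |
| `min_separation` | 5 | contact predictions exclude pairs closer than 5 positions along the backbone. |
| contact cutoff | 8 Å | a pair is a native contact when the minimal distance over all non-hydrogen atom pairs is strictly below the cutoff. |

The neighbor rule is `d < θ·L` with `d = 0` always included, so θ = 0
reproduces duplicate counting while θ > 0 keeps the strict-inequality
definition.

Alphabet convention: state 1 is the gap, states 2..21 the amino acids
alphabetically. The covariance matrix is built over the first q−1 states —
the **last** amino acid is dropped, never the gap, because coevolutionary
signal (e.g. terminal gap stretches) lives on the gap symbol and must
survive the projection. Contact predictions are invariant under the choice
of dropped state. Ambiguous residues (X, B, Z, U, O) are mapped to the gap
state to keep q = 21; this is a convention, logged at read time.

## Contact scoring

Each coupling block is double-centered into the zero-sum gauge (the gauge
minimizing its Frobenius norm), scored by `F_ij = ||ẽ_ij||_F`, and
corrected by the average-product correction
`F^APC_ij = F_ij − F_i·F_·j / F_··` with diagonal-free means. The APC
means exclude the diagonal because `F_ii = 0` is a convention, not a
score. The correction is computed division-first
(`(F_i·/F_··)·F_·j`) so a constant background cancels exactly when its
value is exactly representable. Ranked pairs at `|i−j| ≥ 5` are the
predictions; no score cutoff is imposed — evaluation is parametric in the
number of predictions, as a true-positive-rate curve against minimal
heavy-atom distances (< 8 Å) in a reference structure with an explicit,
user-supplied column↔residue mapping.

## Localization diagnostics

IPR(ξ) = Σ ξ⁴/(Σ ξ²)² measures pattern localization (1 = one component,
1/N = N uniform components). The typical coupling contribution of a
pattern is the RMS of its pairwise terms over its effective support:

    Δ² = Σ_{i≠j} (Σ_a ξ_i(a)²)(Σ_b ξ_j(b)²) / (N_eff(N_eff−1)/2),
    N_eff = 1/IPR.

The denominator counts *unordered* effective site pairs while the sum runs
over ordered pairs; for a perfect two-site pattern with components ±c this
gives Δ = c²√2. Only the qualitative behaviour of Δ — modes near λ = 1
contribute least, both tails contribute most — is asserted in tests, since
Δ is a diagnostic, not part of the inference.

In the strong-conservation limit (an MSA repeating a single sequence) the
Pearson matrix has exactly three eigenvalues: a non-degenerate large one
(extended mode, IPR ≤ 2/L), a small (L−1)-fold degenerate one whose
eigenspace admits a basis localized on site pairs with opposite signs, and
1 with multiplicity (q−2)L. This analytic fixture anchors the spectral
tests.

## Generative side

Fields are set by the independent-site/mean-field consistency condition
`h_i(a) = ln(f_i(a)/f_i(q)) − Σ_{j≠i,b} e_ij(a,b) f_j(b)` (gauge
`h_i(q) = 0`, zero-sum rows/columns on couplings) rather than by exact
maximum likelihood: the contact pipeline never uses fields, and the
approximation is verified against exact enumeration to reproduce weak-
coupling marginals within 5%. Exact enumeration is available up to
`q^L ≤ 10^6`; beyond that a single-chain heat-bath Gibbs sampler
(fixed site order, default burn-in 1000 sweeps, thinning 10) generates
synthetic families, validated against enumeration within Monte-Carlo
error on tiny models.

## Synthetic data and what the tests show

The generators produce (a) fully conserved alignments (the analytic
spectrum fixture), (b) independent-profile alignments (the null: all
eigenvalues → 1, all couplings → 0), and (c) families sampled from planted
low-rank models (recovery ground truth). They emulate the *statistical*
structure the method assumes — exchangeable sequences with site-wise and
pairwise dependencies — but not phylogenetic correlation, alignment
artifacts, or real amino-acid composition. Passing tests therefore
demonstrate correctness of the inference machinery, not field performance
on real families.

Planted-pattern recovery runs with θ = 0: Gibbs samples carry no
phylogenetic oversampling for reweighting to correct, and at toy scale
(L = 8, q = 4) a θ = 0.2 neighborhood covers Hamming distance ≤ 1 in a
65536-point sequence space, so random coincidences — not relatedness —
would drive the weights and visibly distort pair statistics. Recovery uses
M = 10⁴ sampled sequences, the default pseudocount, and p = 1, and is
asserted at |cosine| ≥ 0.95 against the planted pattern.

A practical note observable in the tests: with the full 21-letter
alphabet and a strong pseudocount, states absent from the data acquire a
small uniform positive covariance (`Λ/q² > (Λ/q)²` scaled), which shows up
as one large attractive mode and a band of shallow repulsive modes. This
is a property of pseudocount regularization shared with standard
mean-field DCA, visible here because synthetic families use few symbols;
at full rank it cancels from the ranking.

## Problem sizes

Enumeration-backed tests run at L ∈ [2, 4], q ∈ [2, 3]; oracle-equivalence
tests at L = 6, q = 4, M = 200 over 20 seeds; the conserved-limit fixture
at L = 20, q = 5; recovery at L = 8, q = 4, M = 10⁴. These scales keep
every statistical check well-powered while the whole suite runs in about
a minute.

## Known limitations

* Mean-field inference only; no pseudo-likelihood or message-passing
  variants, no exact Hopfield-Potts gradient fitting.
* No phylogeny-aware weighting beyond the Hamming-neighborhood rule.
* No automatic alignment-to-structure mapping; the column↔residue table
  must be supplied.
* Degenerate-subspace pattern identities are basis-dependent (warned, not
  resolved).
* First PDB model only; altLoc resolved by highest occupancy.
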