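# Methods

This note records the model implemented by `specguide`, the numerical
choices it makes, and what the synthetic tests do and do not establish.

## Model

All operators live on an undirected weighted graph with `N` nodes, no
self-loops, nonnegative weights, and (for every analysis beyond loading)
strictly positive degrees. We work throughout with the symmetrically
normalized adjacency `A = D^{-1/2} Ã D^{-1/2}` and Laplacian `L = I − A`,
whose spectrum lies in `[0, 2]`; for connected graphs `λ₁ = 0` with
eigenvector proportional to `D^{1/2} 1`.

Two classical bandlimited designs are provided for a binary node selection
`S` and bandwidth `W` (the span of the first `W` Laplacian eigenvectors):
the energy-concentration design, the eigenproblem of the `W×W` block of
`Uᵀ S U`, and the modified-embedded-distance design, the eigenproblem of
the `W×W` block of `Uᵀ L^{1/2} S L^{1/2} U`. At full bandwidth both
degenerate in a way the package treats as a diagnostic rather than a bug:
the concentration spectrum is exactly the multiset of diagonal entries of
`S`, and on a connected graph the embedded-distance operator has exactly
`z_S` zero eigenvalues, `z_S` being the number of unselected nodes (its
rank is at most `N − z_S`, and any proper subset of columns of `L^{1/2}`
of a connected graph is linearly independent, giving equality).

The guided criterion replaces `S` by a diagonal cooperation matrix `M`
with arbitrary nonnegative weights and subtracts the two objectives:

    ζ(g) = (gᵀ M g − gᵀ L^{1/2} M L^{1/2} g) / gᵀ g .

Its criterion matrix `M − L^{1/2} M L^{1/2}` is symmetric, needs no
bandlimit, reduces to `A` for `M = I`, and its eigenvalues satisfy
`m_max ≥ ζ₁ ≥ … ≥ ζ_N ≥ −2 m_max`. For every eigenvector we also report
the equivalent concentration `μ_k = g_kᵀ M g_k` and equivalent localized
frequency `ξ_k = g_kᵀ L^{1/2} M L^{1/2} g_k`, always measured against the
*exact* `M` and `L^{1/2} M L^{1/2}`, including for approximated criterion
matrices, so that approximation orders are compared in one fixed frame.

A caution on the ζ ≈ 0 regime with binary `M`: eigenvectors in the middle
of the spectrum have *both* μ and ξ small but not exactly zero. The
μ-null space `{g : Sg = 0}` and the ξ-null space `{g : S L^{1/2} g = 0}`
each have dimension `z_S` but generically intersect only at the origin,
so the joint null is approximate (μ = ξ to high accuracy, both of order
10⁻⁵ on a 60-node fixture). Tests assert the mathematically correct form
— μ ≈ ξ and both small — rather than machine-zero values.

## Taylor machinery

`L^{1/2} = (I − A)^{1/2}` expands as `I − Σₖ cₖ Aᵏ` with
`cₖ = (2k)! / (2^{2k} (k!)² (2k−1))`, i.e. 1/2, 1/8, 1/16, 5/128, …
Coefficients are evaluated by the multiplicative recurrence
`c₁ = 1/2`, `c_{k+1} = cₖ (2k−1)/(2k+2)` (no factorial overflow); an exact
`fractions.Fraction` reference path exists for validation at small k.

The order-K criterion matrix is computed square-root-first, as
`M − Q_K M Q_K` with `Q_K` the order-K truncation of `L^{1/2}`, then
symmetrized. This differs from truncating the double-sum expansion of the
criterion only in cross terms of total order above K, and matches the
reading "approximation through the Taylor series of the square root". The
linear form `(MA + AM)/2` and the quadratic form adding
`(MA² + A²M)/8 − AMA/4` are provided explicitly because of their path
interpretation (edge reweighting by endpoint means; length-2-path
penalties by the intermediate node's weight).

Error reporting uses the empirical Frobenius distances `d_K` (square
root) and `d_{K,M}` (criterion). The Lagrange remainder bound
`d_K ≤ Σᵢ |R_K(λᵢ)|` is implemented with the conservative reading of the
evaluation point — the supremum of the (K+1)-th derivative of √x over the
interval between λᵢ and 1 — which diverges at λ = 0; the λ₁ = 0 term of a
connected graph therefore contributes an infinite (still valid) bound, and
the inequality is informative only through the remaining terms. The
companion criterion-level bound quoted in the source literature appears to
contain a typesetting defect, so only the qualitative behavior of
`d_{K,M}` (non-increasing in K; hierarchy linear ≥ quadratic ≥ order-20)
is asserted.

## Embedding, sweeps, alignment, clustering

- **Embedding.** Nodes are projected on the eigenvectors with the second-
  and third-largest ζ (1-based indices (2, 3)); the unguided `M = I` case
  is then the adjacency eigenvector embedding, and the Laplacian-embedding
  baseline uses ascending-λ indices (2, 3). A requested pair with equal
  eigenvalues triggers a warning: the plane is only defined up to rotation
  inside the eigenspace.
- **Eigenvector determinism.** Every eigenvector column is flipped so its
  largest-magnitude entry is positive (ties: lowest index). Degenerate
  clusters are compared as subspaces in tests, never entrywise.
- **Focus sweep.** Default 51 evenly spaced focus strengths t from 1 to 0
  inclusive (the number of steps is a free choice; the analyses that
  motivated the design show halves 1→0.5 and 0.5→0 without a step count).
  Focus nodes keep weight 1, all others get weight t. Step 0 (t = 1,
  `M = I`) is the reference frame.
- **Alignment.** Orthogonal Procrustes (SVD of `XᵀY`, reflections
  allowed), chained step-to-previous-step rather than all-to-first: both
  are consistent with the published figures, chained is this package's
  documented choice. No centering and no scaling — the origin of an
  eigenvector embedding is meaningful and norms carry concentration
  information.
- **Clustering.** k-means on the focus nodes' endpoint coordinates,
  50 restarts, fixed seed; k selected by maximal mean silhouette over
  2..10 by default. Silhouette is this package's choice of "optimal"
  criterion; the upstream analyses do not state one, so published cluster
  memberships are not expected to reproduce exactly.

## Synthetic data

`synth_fixture` generates a three-class planted-partition (stochastic
block model) graph — the stand-in for a three-class connectome. Defaults
(50/50/50 nodes, within-class edge probability 0.3, between-class 0.05)
give a connected, modular, unweighted graph of roughly connectome-like
density; edges are redrawn (bounded retries) until connected, and the
generator is bit-reproducible under a fixed seed. It emulates class-
modular topology only: no spatial embedding, no degree heterogeneity
beyond Bernoulli sampling, no weighted synapse counts, no bilateral
symmetry. A green trajectory or clustering test on this fixture therefore
establishes the mechanics (determinism, alignment, periphery migration of
the focused class) but says nothing about biological cluster content on a
real connectome. `ring_with_chords` provides a second deterministic
family (ring lattice plus random chords) used where a connected graph of
exact size is needed, e.g. the 279-node degeneracy checks with 128
unselected nodes (151 concentration eigenvalues at 1, 128 embedded-
distance zeros).

## Numerical choices

- Symmetry of inputs is required to 1e−12; normalized operators are
  re-symmetrized by averaging with their transpose.
- Eigenvalues below −1e−6 invalidate a basis; small negatives above that
  are clamped to 0 before square-rooting.
- ≈0 / ≈1 classification in degeneracy reports uses tol 1e−8
  (double-precision eigensolver accuracy at N ≤ 10³), overridable.
- The ζ bound is asserted with slack 1e−6 inside `guided_spectrum`;
  violation raises, since it can only come from an invalid criterion
  matrix.
- Edge lists are undirected with each edge stored once; duplicate
  (including mirrored) entries are an error. Zero-degree nodes are
  rejected unless explicitly dropped (`drop_isolated` / CLI
  `--drop-isolated`). Binarization of weighted inputs is explicit
  (`binarize` / `--binarize`); when several connection types are merged
  upstream, the loader's binarization amounts to a logical OR.

## Known limitations

- Dense eigensolvers only; intended for N up to a few thousand.
- Directed, signed, or self-looped graphs are out of scope.
- The bandlimited version of the guided criterion is deliberately absent:
  the design removes the bandlimit.
- Plots produced by the CLI are cosmetic; the TSVs next to them are the
  authoritative outputs.
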