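# specguide — guided graph spectral embedding

`specguide` implements a *guided* spectral embedding for undirected weighted
graphs: a decomposition whose eigenvectors jointly maximize energy
concentration on an importance-weighted set of nodes and minimize a
localized graph frequency on that same set. It is aimed at network
neuroscience and systems-biology users who want to "focus" a spectral
embedding on a subsystem — e.g. one class of neurons in a connectome —
while keeping the rest of the topology in play.

## The criterion

Let `Ã` be the weighted adjacency of an undirected graph without
self-loops, `D` its degree matrix, `A = D^{-1/2} Ã D^{-1/2}` the normalized
adjacency and `L = I − A` the normalized Laplacian with eigendecomposition
`L = U Λ Uᵀ` (eigenvalues in `[0, 2]`). Classical graph Slepians restrict a
signal to the band spanned by the first `W` Laplacian eigenvectors and
either

- maximize the **energy concentration** `μ = gᵀ S g / gᵀ g` on a binary node
  selection `S`, or
- minimize the **modified embedded distance** `ξ = gᵀ L^{1/2} S L^{1/2} g / gᵀ g`,
  a smoothness measure localized on the selection.

At full bandwidth both designs degenerate — the concentration spectrum
collapses onto the diagonal of `S`, and the embedded-distance operator gains
one zero eigenvalue per unselected node. The guided criterion combines them
and generalizes `S` to a diagonal **cooperation matrix** `M` with arbitrary
nonnegative node weights:

    ζ(g) = (gᵀ M g − gᵀ L^{1/2} M L^{1/2} g) / gᵀ g,

an ordinary symmetric eigenvalue problem of the criterion matrix
`M − L^{1/2} M L^{1/2}`, stable at full bandwidth because the two goals
oppose each other. For `M = I` the criterion matrix is exactly `A`, so the
unguided embedding is the adjacency eigenvector embedding. Taylor-expanding
`L^{1/2} = I − Σₖ cₖ Aᵏ` (with `c₁ = 1/2, c₂ = 1/8, c₃ = 1/16, …`) gives
interpretable approximations: the linear criterion `(MA + AM)/2` reweights
each edge by the mean cooperation weight of its endpoints; the quadratic one
adds length-2-path terms `(MA² + A²M)/8 − AMA/4` that penalize paths through
de-emphasized nodes. The spectrum obeys `m_max ≥ ζ₁ ≥ … ≥ ζ_N ≥ −2 m_max`.

A **focus sweep** holds a node subset at weight 1 while lowering all other
weights from 1 to 0, embedding each step on the eigenvectors with the
second- and third-largest ζ and chaining orthogonal Procrustes alignments
between consecutive steps; the resulting per-node trajectories show how the
focused subsystem reorganizes. Endpoint coordinates of the focus nodes are
clustered by k-means with silhouette-based model selection.

## Worked example

```python
import numpy as np
import specguide as sg

# three-class planted-partition graph, 60 nodes, connected, seeded
g = sg.synth_fixture((20, 20, 20), p_within=0.35, p_between=0.06, seed=7)
ops = sg.normalize(g)
basis = sg.eigendecompose(ops)
sqrtL = sg.sqrt_laplacian_exact(basis)

# unguided: the criterion matrix collapses onto the normalized adjacency
coop = sg.CooperationProfile.identity(g.n_nodes)
C = sg.criterion_matrix_exact(ops, sqrtL, coop)
print(np.max(np.abs(C - ops.A)))          # 7.497653754869115e-15

# focus on class "A": sweep the off-focus weight from 1 to 0
traj = sg.focus_sweep(g, g.class_indices("A"), n_steps=11)
r = np.linalg.norm(traj.endpoint, axis=1)
focus = np.isin(np.arange(g.n_nodes), traj.focus_idx)
print(r[focus].mean(), r[~focus].mean())  # 0.30147922306983255 0.03065378974922134

labels, k, sil = sg.cluster_endpoint(traj, range(2, 8), seed=7)
print(k, round(sil, 3))                   # 3 0.547
```

The first number shows the exact `M = I → A` identity (machine precision).
At the end of the sweep the focus-class nodes sit, on average, about ten
times farther from the origin than the de-emphasized ones — the focused
subsystem migrates to the periphery of the embedding, where its internal
organization becomes visible; k-means then finds 3 endpoint clusters with
mean silhouette 0.55.

The same pipeline is available from the shell:

```bash
specguide synth --sizes 20,20,20 --seed 7 --outdir out
specguide sweep --input out/fixture.mtx --format mtx \
    --metadata out/fixture_meta.tsv --focus-class A --steps 11 --outdir out
specguide spectrum --input out/fixture.mtx --format mtx \
    --metadata out/fixture_meta.tsv --focus-class A --outdir out
specguide validate --input out/fixture.mtx --format mtx --outdir out
```

Every figure written by the CLI has a TSV twin with exactly the plotted
numbers; runs are byte-reproducible under a fixed seed.

## Acceptance script

`scripts/acceptance.py` recomputes, from scratch, the full-bandwidth
degeneracy counts on a seeded connected 279-node graph with a binary
selection zeroing 128 nodes: the number of concentration eigenvalues equal
to 1 and the number of zero eigenvalues of the modified embedded distance
operator.

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/specguide/graph_core.py` — graph I/O (edge list / dense CSV / Matrix
  Market), validation, symmetric normalization, synthetic fixtures
- `src/specguide/spectral_ops.py` — Laplacian eigenbasis, GFT, exact and
  Taylor-approximated `L^{1/2}`, remainder bounds
- `src/specguide/slepian_designs.py` — classical concentration and
  embedded-distance Slepians, degeneracy diagnostics
- `src/specguide/guided_embedding.py` — guided criterion (exact / linear /
  quadratic / order-K), guided spectrum, embedding, Procrustes alignment,
  focus sweeps, endpoint clustering
- `src/specguide/cli.py` — `specguide` command-line tool
- `docs/methods.md` — modeling assumptions, parameter choices, limitations
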