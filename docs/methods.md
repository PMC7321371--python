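# Methods

## Problem setting and model

The package predicts one protein's tertiary structure from an ensemble of
candidate template structures (decoys) that all cover the same residue
range. Structures are represented as Cα traces only — one (x, y, z) per
residue, flattened atom-major into vectors of length `n = 3·residues`.
Cα-only is a deliberate scope choice: the templates guide the backbone
geometry, and full-atom reconstruction is a separate downstream problem.

The central idea is model reduction. Direct energy minimization over ℝⁿ is
ill-posed — the energy landscape is rugged and the number of coordinates
(10²–10³ residues → 3n up to ~10³–10⁴) vastly exceeds the number of
templates (~10²). Instead, the ensemble itself defines a small affine
subspace that concentrates the biologically meaningful variation, and the
optimization happens there.

## Stages and the parameters that matter

| parameter | default | meaning |
|---|---|---|
| `percentile` | 30 | energy cutoff for template selection (linear-interpolation quantile; ties kept) |
| `n_classes` | 4 | energy classes for the discriminant analysis (hard limit 10) |
| `lda_dim` | 4 | discriminant directions kept |
| `margin` | 0.1 | fractional padding of the projection-derived search box, per side |
| `swarm_size` / `iterations` | 40 / 50 | swarm sampling budget |
| `collapse_threshold` | 3 (%) | median-dispersion level declaring swarm collapse |
| `refine.delta` | 0.2 | half-width of the SVD β-box, relative to α |

**Selection and superposition.** Lower energy is better throughout. All
selected templates are Kabsch-superposed onto the lowest-energy decoy
(ties broken by label order) before any matrix is formed, so that scatter
reflects conformational rather than rigid-body differences.

**Energy partitioning.** 1-D k-means on the selected energies. Because
optimal 1-D k-means clusters are contiguous in sorted order, the partition
is computed *exactly* by dynamic programming over split points — a
deterministic, globally optimal replacement for seeded Lloyd iteration,
which can stall in local optima even on a dozen points. Classes are
labeled in increasing-centroid order; duplicate boundary values split by
stable sorted position.

**Scatter shrinkage.** Both scatter matrices are shrunk towards a scaled
identity, `S_reg = (1−λ)S + λsI`, with `s = trace(S)/p` and

```
λ = 2 Σ_{i>j} var(S_ij) / (2 Σ_{i>j} S_ij² + Σ_i (S_ii − 1)²)
```

clamped to [0, 1]; a zero denominator is defined as λ = 0. `var(S_ij)` is
the maximum-likelihood (divide-by-N) empirical variance of the per-sample
cross-products scaled so their mean is `S_ij`; for `S_B` the "samples" are
the `√n_k`-weighted class-mean deviations, for `S_W` the within-class
deviations. The identity target makes λ scale-dependent (the `(S_ii−1)²`
term compares diagonals to 1); on raw coordinate scatter this typically
drives λ to the clamp at 1, i.e. the within-class matrix becomes exactly
spherical — which is also what makes the eigenproblem well-posed, since
with far fewer templates than coordinates `S_W` is always singular.

**Discriminant basis.** The top-`d` eigenvectors of `S_W⁻¹S_B` are
computed as a symmetric generalized eigenproblem (Cholesky whitening
inside LAPACK), never by forming the inverse. Columns are unit-norm with
the largest-magnitude entry positive (cross-platform sign determinism).
With `k = 4` classes, `rank(S_B) ≤ 3`, so the 4th direction exists only
through regularization; the run logs a warning noting it is
regularization-dominated. The HF column is the least-squares residual of
the best decoy against the discriminant span; if that residual is
numerically zero (best decoy already in span, relative norm < 1e-10) the
HF column becomes a zero sentinel and the effective dimension drops to
`d`. All columns are QR-orthonormalized (span and order preserved;
pre-normalization scales kept in `column_norms`), which makes projection a
plain transpose product and reconstruction an isometry.

**Search space and sampling.** Bounds are the min/max projections of the
selected templates per coordinate, padded by `margin`; a zero-range
coordinate gets `±margin·max(1, |center|)` so the box never degenerates.
The default sampler is RR-PSO, the regressive/regressive (fully implicit)
discretization of the continuous swarm dynamics:

```
v(t+1) = [v(t) + φ₁(g − x(t)) + φ₂(p − x(t))] / [1 + (1−ω) + φ₁ + φ₂]
x(t+1) = x(t) + v(t+1)
```

with ω = 3 and per-dimension φ₁, φ₂ ~ U(0, 4.5) — on the family's
high-exploration line φ̄ = 3(ω − 3/2). The occasional small or negative
denominator produces large velocity kicks; these are harmless because
boundary handling is absorb-and-zero (out-of-bounds components clamp to
the bound, their velocity set to 0), which keeps every evaluated position
inside the box exactly. A constriction-coefficient PSO (χ = 0.7298,
c₁ = c₂ = 1.49618) is available as the `"constriction"` variant. One RNG
stream per run, consumed in fixed particle-index order, makes runs
bit-reproducible. Non-finite objective values are treated as +∞.

Iteration accounting: iteration 1 is the evaluated initial swarm (its
median centroid distance is the 100% dispersion baseline), followed by
`iterations − 1` update steps. Collapse is the first iteration with
dispersion below the threshold; from then on each iteration contributes
only its best particle to the sampled-model list, so the sample count is
`swarm_size·(c−1) + (iterations − c + 1)` when collapse occurs at `c`.

**Fallback and refinement.** If the sampled optimum is worse than the best
decoy, the pipeline falls back to the best decoy — the final energy can
never exceed the best selected template's. Refinement then searches the
three SVD coordinates β of the centered 3 × n_atoms coordinate matrix
inside `[(1−δ)α, (1+δ)α]` and accepts only a strict energy decrease.
Centering before the SVD makes the factorization translation-invariant;
the removed centroid is stored and restored. Planar/collinear structures
simply carry zero singular values. (β has exactly three components;
the rank of a 3-row coordinate matrix cannot exceed 3.)

## Energy models

The scoring function is a pluggable callable (deterministic, lower =
better). Real decoy scoring would use knowledge-based potentials such as
dDFIRE with a GB/SA solvation term; those are external programs and out of
scope here. Built-ins:

* **surrogate** — `w_bond Σ(d_{i,i+1} − 3.8)² + w_rep Σ_{|i−j|≥3, d<4}(4 − d)²
  + w_rg (Rg − 2.2·N^0.38)²`, defaults (1, 1, 0.1), distances in Å. Rigid-
  transform invariant; produces realistic-looking funnels on decoy sets.
* **go** — `k · rmsd(m, reference)²` after superposition; zero exactly at
  the (rigid-equivalence class of the) reference. Its known planted
  minimum is what makes the end-to-end recovery experiments verifiable.
* **table** — label → energy lookup from a two-column text file, for
  externally computed scores.

## Synthetic decoy generator

`make_template_ensemble` emulates the two-level structure of real decoy
sets: a few distinct backbone conformations plus per-decoy noise. The
reference backbone is built from ideal-helix Cα segments (exact 3.8 Å
steps, 100°/residue twist, 1.5 Å rise) joined by random axis turns;
candidates with any nonbonded pair (|i−j| ≥ 3) under 3.5 Å are redrawn
from the next sub-seed, so generation is deterministic per seed. Class
centers displace the reference along per-class sinusoidal fields
`sin(2πf_c t + φ_c)·u_c` (f_c = 1…k full waves, random direction u_c),
normalized to unit RMS so `class_shift_scale` (default 3.0 Å) is the
per-atom RMS deformation amplitude regardless of frequency or phase; full
waves keep the deformation from being absorbable by a rigid rotation.
Templates add isotropic Gaussian noise (`within_noise`, default 0.5 Å).
At these defaults the mean between-class pairwise RMSD exceeds the
within-class mean by ≥ 3×.

What the generator does **not** emulate: alignment errors and gaps,
heavy-tailed per-server error distributions, correlated (non-isotropic)
noise along the chain, and physically realistic bond geometry in the
deformed centers. Passing tests therefore demonstrate the machinery —
selection, reduction, sampling, refinement, and their contracts — not
predictive accuracy on real CASP-style decoys with knowledge-based
energies.

## Numerical choices and degenerate inputs

* Kabsch superposition via determinant-corrected SVD
  (`scipy.Rotation.align_vectors`); proper rotations always; rank-deficient
  (collinear/coincident) point sets resolve deterministically through the
  SVD sign convention.
* PDB I/O through gemmi, Cα subset, 3-decimal fixed columns; first
  altloc wins; residues without Cα are skipped with a warning; insertion
  codes ignored with a warning.
* Eigenvector and SVD sign conventions: largest-magnitude entry positive.
* `E_tol` (optional) only annotates how many sampled models fall in the
  low-energy equivalence region; it never gates the pipeline.
* Child seeds: the sampling swarm uses the run seed, the refinement swarm
  seed+1; every stage is deterministic given the run configuration.

## Problem sizes used in the shipped experiments

The end-to-end experiments use 120-residue ensembles, 4 classes × 15
templates, the full 40 × 50 swarm budget, and 10 generator seeds; the
optimizer benchmark uses the 5-D sphere over [−5, 5]⁵ with 100 seeds.
These sizes sit in the middle of realistic decoy-set dimensions while
keeping a full multi-seed study fast on a single CPU.

## Known limitations

* Cα-only; no side chains, no full backbone, no mmCIF.
* Templates must be pre-aligned to a common residue numbering with no
  gaps; mismatched lengths are rejected, never aligned.
* No iterative re-superposition between reduction rounds.
* The sampled post-collapse model list is exposed as-is; no probabilistic
  weighting of the low-energy region is attempted.
* With the surrogate energy, absolute energies are not comparable to
  knowledge-based potentials; reports always record which model produced
  them.
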