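# Methods

## Model and procedure

`spatscale` quantifies the spatial scale of smoothing implied by
including df unpenalized thin-plate regression splines (TPRS) in a
regression on planar point data.  The pipeline is:

1. **Distances.** For points s₁…sₙ (projected planar coordinates,
   consistent length units), form the Euclidean distance matrix
   **D** ∈ ℝⁿˣⁿ.
2. **Basis.** Build the low-rank TPRS basis from the radial matrix
   E[i,j] = η(D[i,j]), η(r) = r² log r (the 2-D second-order thin-plate
   radial function; η(0) = 0).  Eigendecompose **E**, retain the
   max_df+1 eigenpairs (U, λ) of largest |λ| (E is indefinite), and
   impose the thin-plate side condition Tᵀδ = 0 with T = [1, x, y]: an
   orthonormal null-space basis **Z** of TᵀU (full QR) gives the spline
   columns U diag(λ) Z.  The design matrix is
   H = [1, x, y, U diag(λ) Z] with max_df+1 columns.
3. **Smoother.** For df splines, the hat matrix is the orthogonal
   projection onto the first df+1 columns of **H**,
   S = H₍df₎(H₍df₎ᵀH₍df₎)⁻¹H₍df₎ᵀ, computed from a single QR
   orthonormalization of **H** (the triangularity of R makes the leading
   columns of Q a nested orthonormal basis; no normal-equations inverse
   is ever formed).  S is symmetric, idempotent, has trace df+1 and unit
   row sums.
4. **Bandwidth, minimum-radius method.**  Per column *i*, the
   first-negative distance k̂ᵢ = min{D[j,i] : S[j,i] < 0}; the effective
   bandwidth k̂ is the median of the defined k̂ᵢ (mean of the two central
   order statistics for an even count).  Each k̂ᵢ is an element of
   column *i* of **D**; no interpolation occurs.
5. **Bandwidth, loess variant.**  Per column, smooth the weights
   against distance with a local quadratic loess fit and predict on an
   even grid of n_eval distances over [0, max D]; k̂ is the first grid
   distance at which the across-column median prediction is negative.
   This averages over a neighbourhood of distances and so measures an
   average rather than minimum radius; it requires a span, which the
   minimum-radius method deliberately avoids.
6. **Sweep.**  For df = 3…max_df the projection is updated by a
   symmetric rank-one step S ← S + qqᵀ using the next column of Q,
   which agrees with the direct projection to floating-point accuracy
   (tested at 1e-8); the whole sweep costs one eigendecomposition.

## Why the constrained basis

A simpler construction — appending the leading eigenvectors of **E**
directly to [1, x, y] — spans a deceptively similar space but behaves
differently under the df sweep: on regular and random test grids its
k̂ is not monotone in df, whereas the constrained construction above
(the standard low-rank thin-plate construction, as in mgcv's
`bs = "tp"`) produces the expected monotone non-increasing bandwidths.
The eigenvalue scaling of the spline columns matters for the *nested*
column prefixes the sweep uses and is therefore kept, even though any
column rescaling leaves a single full-rank projection unchanged.

Two consequences are worth knowing:

- The basis is built **once at max_df** and truncated by column prefix
  for smaller df (exactly what the sweep needs).  Rebuilding the basis
  at a smaller max_df yields a slightly different span for the same df,
  because the retained eigenpair set depends on max_df.
- Prefix spans are invariant under rigid motions of the points up to
  eigendecomposition round-off: **E** depends only on distances, and a
  rotation alters only the leading 3×3 block of the null-space QR, so
  **Z** changes at most by column signs.  In floating point the
  eigenvectors of **E** inside near-degenerate clusters (exactly
  degenerate on symmetric grids) are sensitive to last-bit coordinate
  perturbations, so *entrywise* agreement of intermediate-df smoothers
  across a rotation is only approximate; k̂ itself is far more stable
  (asserted at 1e-8 in the tests) because the sign pattern of the
  weights, not their exact values, determines it.  The trend-level
  (df = 2) and full-basis projections are exactly invariant and are
  asserted entrywise.

`smoothing_matrix` accepts df = 2 — the pure planar trend [1, x, y],
whose projection equals the ordinary planar-regression hat matrix — as
a diagnostic level below the sweep's df ≥ 3 range; all invariants
(including trace = df+1 = 3) hold there.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `max_df` | largest spline count in the sweep | required | must be ≤ n−1; the web-app presets were 10/25/100/300/500 |
| `method` | `new` (minimum radius) or `loess` (average radius) | `new` | |
| `span` | loess neighbourhood, fraction of points | required iff loess | neighbourhood = ⌈span·n⌉ nearest by distance; span·n ≥ 3 required |
| `n_eval` | loess prediction grid size over [0, max D] | 1000 | k̂ resolution = max D / (n_eval−1) |
| `subsample_to` | cap on points before basis construction | none | app presets 1000/2000/5000; a seed is mandatory when it triggers |
| `increment` | grid spacing, input length units | — | grids anchor at the origin / bounding-box lower-left |

Numerical constants: weights count as negative only below −1e-12
(suppresses sign noise in exact-zero weights); singular values below
1e-10 × the largest count as zero in the design-rank check (columns are
norm-scaled first so units do not skew the tolerance); a relative
eigenvalue gap below 1e-10 at the retain/discard boundary triggers a
warning, since highly symmetric grids make the truncated span
implementation-dependent there.  Coordinates are **not** internally
rescaled, so k̂ is reported in input units.

## Loess dialect

The loess variant is a local quadratic regression with tricube weights
(1−u³)³ on u = |d−d₀|/h, h the distance to the ⌈span·n⌉-th nearest
abscissa, fitted per evaluation point by kernel-weighted normal
equations on abscissae centered and scaled by h.  Tied distances (ubiquitous
on regular grids) can make an individual 3×3 local system rank
deficient; the pseudoinverse (relative cutoff 1e-10) then gives the
minimum-norm local polynomial, which still predicts sensibly at the
window center.  These constants (degree 2, rank-based neighbourhood,
evaluation grid from 0 to max D) are this package's documented dialect;
other loess implementations differ in interpolation cells and boundary
handling, so bit-for-bit agreement with them is not promised — the
minimum-radius method, which has no dialect freedom, is the primary
estimator.

## Undefined bandwidths

A location whose weights never go negative has no k̂ᵢ; such locations
are excluded from the median and counted in `n_undefined`.  If more
than half the locations are undefined — in particular at df+1 = n,
where S is the identity and nothing is smoothed — the bandwidth at that
df is declared undefined: `effective_bandwidth` raises, and the sweep
keeps the row with k̂ = NaN and continues, so one degenerate df does not
abort a table.

## Fixtures and what they do and do not show

The built-in generators produce rectangular grids (`make_rect_grid`),
polygon-clipped grids (L-shape, notched rectangle, convex blob at any
scale) and seeded uniform random point sets.  They emulate the
regular-grid geometry of the country tabulations — including boundary
effects of non-convex outlines and heavy distance ties — at sizes
(≤ 400 points in the default suite) where the whole sweep runs in
seconds.  They do not emulate real administrative boundaries, coastline
fractality, or strongly non-uniform population-weighted point
distributions; passing tests demonstrate the algorithmic properties
(oracle agreement, monotonicity, invariances, method ordering), not
country-specific bandwidth values.  Reproducing the published country
tables requires the external Natural Earth boundaries via
`scripts/replicate_countries.py`; grid anchoring (bounding-box
lower-left) and boundary-point inclusion are conventions the source
tabulations do not state, so point counts there may differ by about one
grid row/column under other conventions.  Boundary points count as
inside during clipping to avoid dropping coastal grid points
nondeterministically under floating-point jitter.

## Known limitations

- Coordinates must already be projected; no geodesic distances.
- The full eigendecomposition is taken on the (possibly subsampled)
  point set — O(n³) — which is why the subsampling cap (the app used
  5000) exists; no knot subsampling is performed inside the basis.
- Duplicate points are allowed and logged; they produce zero
  off-diagonal distances but do not break the projection.
- `df_for_target_bandwidth` uses the rule "smallest df with
  k̂ ≤ target" (boundary inclusive).  Published worked examples do not
  state their rule, so lookups near a bandwidth plateau may differ by a
  few df from other conventions.
- The loess variant's published values depend on the reference
  implementation's exact dialect; only the ordering (average ≥ minimum
  radius, gap shrinking with df) is asserted.
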